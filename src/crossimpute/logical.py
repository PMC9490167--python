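"""Logical edits: the deterministic first step of the two-step imputation.

Certain survey responses are logically incompatible with being an
undocumented immigrant — citizenship, Medicare coverage, veteran or
active-duty military status, receipt of public assistance, supplemental or
social-security income.  Anyone reporting at least one of them is
*logically documented*; the residual is the *possibly undocumented* pool,
the only records the statistical imputers ever classify.  Restricting the
rule list to strict logical exclusions keeps the step's sensitivity at
exactly one: no truly undocumented respondent is ever excluded.

The same module builds the donor-side truth proxy: a non-citizen who
entered the country after a cutoff year (default 1981) without entering as,
or later adjusting to, lawful permanent resident (LPR) status — and with no
exclusion rule firing — is treated as truly undocumented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .survey import SurveyTable, VariableSchema

# Status labels (four-valued pipeline status plus donor-side truth).
DOC_LOGICAL = "doc_logical"
POSSIBLY_UNDOC = "possibly_undoc"
IMPUTED_DOC = "imputed_doc"
IMPUTED_UNDOC = "imputed_undoc"
TRUE_DOC = "true_doc"
TRUE_UNDOC = "true_undoc"

STATUS_COL = "status_label"
TRUTH_COL = "true_status"

_OPS = {
    "eq": lambda s, v: s == v,
    "ne": lambda s, v: s != v,
    "gt": lambda s, v: s > v,
    "ge": lambda s, v: s >= v,
    "lt": lambda s, v: s < v,
    "le": lambda s, v: s <= v,
    "in": lambda s, v: s.isin(list(v)),
}


@dataclass(frozen=True)
class Rule:
    """One exclusion predicate: satisfying it proves documented status."""

    variable: str
    op: str = "eq"
    value: object = 1

    def fires(self, df: pd.DataFrame) -> np.ndarray:
        if self.variable not in df.columns:
            raise KeyError(f"rule variable {self.variable!r} not in table")
        col = df[self.variable]
        if self.op not in _OPS:
            raise ValueError(f"unknown rule operator {self.op!r}")
        out = _OPS[self.op](col, self.value)
        # Missing values never fire a rule: conservative, keeps the record
        # in the possibly-undocumented pool.
        return (out.fillna(False) if hasattr(out, "fillna") else out) \
            .to_numpy(bool) & col.notna().to_numpy()


@dataclass(frozen=True)
class RuleSet:
    """Ordered (but order-invariant: pure disjunction) exclusion rules plus
    the entry-year cutoff and truth-component column names."""

    rules: tuple[Rule, ...]
    entry_year_cutoff: int = 1981
    citizen_var: str = "citizen"
    entry_year_var: str = "entry_year"
    entered_lpr_var: str = "entered_as_lpr"
    adjusted_lpr_var: str = "adjusted_to_lpr"

    def any_fires(self, df: pd.DataFrame) -> np.ndarray:
        fired = np.zeros(len(df), dtype=bool)
        for r in self.rules:
            fired |= r.fires(df)
        return fired

    # ---- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "logical_edits": {
                "entry_year_cutoff": self.entry_year_cutoff,
                "truth_components": {
                    "citizen": self.citizen_var,
                    "entry_year": self.entry_year_var,
                    "entered_as_lpr": self.entered_lpr_var,
                    "adjusted_to_lpr": self.adjusted_lpr_var,
                },
                "rules": [
                    {"variable": r.variable, "op": r.op, "value": r.value}
                    for r in self.rules
                ],
            }
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: Mapping) -> "RuleSet":
        d = d.get("logical_edits", d)
        tc = d.get("truth_components", {})
        return cls(
            rules=tuple(Rule(variable=r["variable"], op=r.get("op", "eq"),
                             value=r.get("value", 1)) for r in d.get("rules", [])),
            entry_year_cutoff=int(d.get("entry_year_cutoff", 1981)),
            citizen_var=tc.get("citizen", "citizen"),
            entry_year_var=tc.get("entry_year", "entry_year"),
            entered_lpr_var=tc.get("entered_as_lpr", "entered_as_lpr"),
            adjusted_lpr_var=tc.get("adjusted_to_lpr", "adjusted_to_lpr"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleSet":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_ruleset() -> RuleSet:
    """Citizenship, Medicare, veteran/military status, public benefits.

    Medicaid is deliberately NOT an exclusion: a small number of
    undocumented respondents report Medicaid coverage (state provisions for
    pregnant women and children, emergency coverage, misreporting), so
    excluding on it would break the sensitivity-one guarantee and induce
    selection on poverty.  Medicaid remains available as a predictor.
    """
    return RuleSet(rules=(
        Rule("citizen"),
        Rule("medicare"),
        Rule("veteran"),
        Rule("public_assistance"),
    ))


STATUS_LEVELS = (DOC_LOGICAL, POSSIBLY_UNDOC, IMPUTED_DOC, IMPUTED_UNDOC)
TRUTH_LEVELS = (TRUE_DOC, TRUE_UNDOC)


def _append_column(table: SurveyTable, name: str, values, levels,
                   role: str = "aux") -> SurveyTable:
    df = table.data.copy()
    df[name] = values
    schema = [v for v in table.schema if v.name != name]
    schema.append(VariableSchema(name=name, kind="categorical", role=role,
                                 levels=tuple(levels)))
    return table.with_data(df, schema=schema)


def apply_logical_edits(table: SurveyTable, ruleset: RuleSet) -> SurveyTable:
    """Label each record ``doc_logical`` if any exclusion rule fires, else
    ``possibly_undoc``.  Appends :data:`STATUS_COL`; row count unchanged.
    Idempotent and invariant to rule order (pure disjunction)."""
    fired = ruleset.any_fires(table.data)
    labels = np.where(fired, DOC_LOGICAL, POSSIBLY_UNDOC)
    return _append_column(table, STATUS_COL, labels, STATUS_LEVELS)


def derive_true_status(donor: SurveyTable, ruleset: RuleSet) -> SurveyTable:
    """Append the donor-side truth proxy (:data:`TRUTH_COL`).

    ``true_undoc`` iff non-citizen AND entry year strictly after the cutoff
    AND neither entered as nor adjusted to LPR AND no exclusion rule fires;
    otherwise ``true_doc``.  Missing components count as not satisfying the
    undocumented conditions (conservative toward documented).
    """
    df = donor.data
    for var in (ruleset.citizen_var, ruleset.entry_year_var,
                ruleset.entered_lpr_var, ruleset.adjusted_lpr_var):
        if var not in df.columns:
            raise KeyError(f"truth component {var!r} not in donor table")
    citizen = pd.to_numeric(df[ruleset.citizen_var], errors="coerce")
    entry = pd.to_numeric(df[ruleset.entry_year_var], errors="coerce")
    entered = pd.to_numeric(df[ruleset.entered_lpr_var], errors="coerce")
    adjusted = pd.to_numeric(df[ruleset.adjusted_lpr_var], errors="coerce")
    undoc = (
        (citizen == 0).fillna(False)
        & (entry > ruleset.entry_year_cutoff).fillna(False)
        & (entered == 0).fillna(False)
        & (adjusted == 0).fillna(False)
        & ~ruleset.any_fires(df)
    )
    labels = np.where(undoc.to_numpy(bool), TRUE_UNDOC, TRUE_DOC)
    return _append_column(donor, TRUTH_COL, labels, TRUTH_LEVELS,
                          role="truth_component")
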