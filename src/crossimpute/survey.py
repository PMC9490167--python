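"""Survey data model: typed columns with declared roles, CSV/codebook I/O,
and the missing-as-category encoding.

A :class:`SurveyTable` is a thin, validated wrapper around a pandas
DataFrame plus a codebook (list of :class:`VariableSchema`).  Every variable
declares a *kind* (categorical, numeric, binary) and a *role* in the
imputation pipeline (predictor, outcome, weight, ...).  Missing responses in
categorical predictors are represented by a reserved level rather than being
dropped or model-imputed, because survey non-response — especially to
immigration-related items — cannot be assumed missing at random.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: Reserved category label for missing values.  Fixed, never inferred, so
#: encoders are deterministic across runs.
MISSING_TOKEN = "__MISSING__"

KINDS = ("categorical", "numeric", "binary")
ROLES = (
    "truth_component",
    "logical_flag",
    "predictor",
    "outcome",
    "weight",
    "year",
    "id",
    "aux",
)


class SchemaValidationError(ValueError):
    """A table violated its declared codebook (names the row and column)."""


@dataclass(frozen=True)
class VariableSchema:
    """Declaration of one survey variable.

    Parameters
    ----------
    name : str
        Column name in the data file.
    kind : {"categorical", "numeric", "binary"}
        Storage/measurement type.  Binary variables are 0/1 numerics.
    role : str
        Pipeline role; one of ``truth_component``, ``logical_flag``,
        ``predictor``, ``outcome``, ``weight``, ``year``, ``id``, ``aux``.
    levels : tuple of str, optional
        Allowed category codes (categorical only).  A categorical variable
        with any missing values must carry the reserved missing level.
    missing_code : str
        Reserved level label representing missingness.
    """

    name: str
    kind: str
    role: str
    levels: tuple[str, ...] | None = None
    missing_code: str = MISSING_TOKEN

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaValidationError(f"{self.name}: unknown kind {self.kind!r}")
        if self.role not in ROLES:
            raise SchemaValidationError(f"{self.name}: unknown role {self.role!r}")
        if self.kind == "categorical" and self.levels is not None:
            object.__setattr__(self, "levels", tuple(str(v) for v in self.levels))

    def to_dict(self) -> dict:
        d = {"name": self.name, "kind": self.kind, "role": self.role}
        if self.levels is not None:
            d["levels"] = list(self.levels)
        if self.missing_code != MISSING_TOKEN:
            d["missing_code"] = self.missing_code
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "VariableSchema":
        return cls(
            name=d["name"],
            kind=d["kind"],
            role=d["role"],
            levels=tuple(d["levels"]) if d.get("levels") is not None else None,
            missing_code=d.get("missing_code", MISSING_TOKEN),
        )


@dataclass
class SurveyTable:
    """Person-level survey records with a codebook and provenance tag.

    Invariants enforced at construction: exactly one id and one weight
    variable; ids unique; weights strictly positive and finite; categorical
    cells drawn from their declared levels.  Labeling operations elsewhere in
    the package append columns and never drop rows.
    """

    data: pd.DataFrame
    schema: list[VariableSchema]
    provenance: str = ""
    #: columns retained for internal validation but masked for analysis
    #: (e.g. the hidden truth in a synthetic target sample)
    masked: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        self.validate()

    # ---- schema helpers -------------------------------------------------
    def schema_by_name(self, name: str) -> VariableSchema:
        for v in self.schema:
            if v.name == name:
                return v
        raise KeyError(name)

    def names_with_role(self, role: str) -> list[str]:
        return [v.name for v in self.schema if v.role == role]

    @property
    def id_col(self) -> str:
        return self.names_with_role("id")[0]

    @property
    def weight_col(self) -> str:
        return self.names_with_role("weight")[0]

    @property
    def ids(self) -> pd.Index:
        return pd.Index(self.data[self.id_col])

    def with_data(self, data: pd.DataFrame, schema: list[VariableSchema] | None = None,
                  **kw) -> "SurveyTable":
        return SurveyTable(data=data, schema=list(schema or self.schema),
                           provenance=kw.get("provenance", self.provenance),
                           masked=kw.get("masked", self.masked))

    def subset(self, mask: np.ndarray | pd.Series) -> "SurveyTable":
        """Row subset (explicit — silent row drops are never performed)."""
        return self.with_data(self.data.loc[np.asarray(mask)].reset_index(drop=True))

    # ---- validation -----------------------------------------------------
    def validate(self) -> None:
        ids = self.names_with_role("id")
        weights = self.names_with_role("weight")
        if len(ids) != 1 or len(weights) != 1:
            raise SchemaValidationError(
                f"need exactly one id and one weight variable, got {ids} / {weights}")
        for v in self.schema:
            if v.name not in self.data.columns:
                raise SchemaValidationError(f"column {v.name!r} missing from data")
        idc = self.data[ids[0]]
        if idc.duplicated().any():
            raise SchemaValidationError(f"duplicate ids in column {ids[0]!r}")
        w = pd.to_numeric(self.data[weights[0]], errors="coerce")
        bad = ~(np.isfinite(w) & (w > 0))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaValidationError(
                f"row {row}, column {weights[0]!r}: weights must be positive and finite")
        for v in self.schema:
            col = self.data[v.name]
            if v.kind == "categorical" and v.levels is not None:
                vals = col.dropna().astype(str)
                allowed = set(v.levels)
                bad_mask = ~vals.isin(allowed)
                if bad_mask.any():
                    row = int(bad_mask.idxmax())
                    raise SchemaValidationError(
                        f"row {row}, column {v.name!r}: value "
                        f"{vals.loc[row]!r} not in declared levels")
            elif v.kind == "binary":
                vals = pd.to_numeric(col, errors="coerce").dropna()
                if not vals.isin([0, 1]).all():
                    row = int((~vals.isin([0, 1])).idxmax())
                    raise SchemaValidationError(
                        f"row {row}, column {v.name!r}: binary values must be 0/1")
            elif v.kind == "numeric" and v.role != "id":
                coerced = pd.to_numeric(col, errors="coerce")
                bad_mask = coerced.isna() & col.notna()
                if bad_mask.any():
                    row = int(bad_mask.idxmax())
                    raise SchemaValidationError(
                        f"row {row}, column {v.name!r}: not numeric")

    def equals(self, other: "SurveyTable", rtol: float = 1e-9) -> bool:
        """Field-by-field equality with float tolerance (CSV round trips)."""
        if [v.to_dict() for v in self.schema] != [v.to_dict() for v in other.schema]:
            return False
        if list(self.data.columns) != list(other.data.columns):
            return False
        if len(self.data) != len(other.data):
            return False
        for v in self.schema:
            a, b = self.data[v.name], other.data[v.name]
            if v.kind in ("numeric", "binary") and v.role != "id":
                av = pd.to_numeric(a, errors="coerce").to_numpy(float)
                bv = pd.to_numeric(b, errors="coerce").to_numpy(float)
                both_nan = np.isnan(av) & np.isnan(bv)
                if not np.all(both_nan | np.isclose(av, bv, rtol=rtol, equal_nan=False)):
                    return False
            else:
                aa = a.astype("string")
                bb = b.astype("string")
                if not aa.fillna("\0").eq(bb.fillna("\0")).all():
                    return False
        return True


# ---- codebook I/O -------------------------------------------------------

def load_codebook(path: str | Path) -> list[VariableSchema]:
    """Read a codebook from YAML or JSON (a list of variable declarations)."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if isinstance(raw, Mapping) and "variables" in raw:
        raw = raw["variables"]
    return [VariableSchema.from_dict(d) for d in raw]


def save_codebook(schema: Sequence[VariableSchema], path: str | Path) -> None:
    payload = {"variables": [v.to_dict() for v in schema]}
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(payload, indent=2))
    else:
        p.write_text(yaml.safe_dump(payload, sort_keys=False))


# ---- data I/O -----------------------------------------------------------

def read_survey(path: str | Path, schema: Sequence[VariableSchema],
                provenance: str = "") -> SurveyTable:
    """Read a CSV against a codebook, validating kinds and levels.

    Columns in the file but absent from the codebook are retained with
    role ``aux`` (numeric if fully parseable as numbers, else categorical).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=True,
                     na_values=[""], float_precision="round_trip")
    missing_cols = [v.name for v in schema if v.name not in df.columns]
    if missing_cols:
        raise SchemaValidationError(f"file lacks declared columns: {missing_cols}")
    schema = list(schema)
    known = {v.name for v in schema}
    out = pd.DataFrame(index=df.index)
    for v in schema:
        col = df[v.name]
        if v.kind in ("numeric", "binary") and v.role != "id":
            out[v.name] = pd.to_numeric(col, errors="coerce")
            bad = out[v.name].isna() & col.notna()
            if bad.any():
                row = int(bad.idxmax())
                raise SchemaValidationError(
                    f"row {row}, column {v.name!r}: {col.loc[row]!r} is not numeric")
        else:
            out[v.name] = col
    for name in df.columns:
        if name in known:
            continue
        col = df[name]
        as_num = pd.to_numeric(col, errors="coerce")
        if as_num.notna().eq(col.notna()).all():
            out[name] = as_num
            schema.append(VariableSchema(name=name, kind="numeric", role="aux"))
        else:
            levels = tuple(sorted(col.dropna().astype(str).unique()))
            out[name] = col
            schema.append(VariableSchema(name=name, kind="categorical",
                                         role="aux", levels=levels))
    return SurveyTable(data=out, schema=schema, provenance=provenance)


def write_survey(table: SurveyTable, path: str | Path) -> None:
    """Write the data as CSV (header, period decimal separator)."""
    table.data.to_csv(path, index=False)


# ---- missing-as-category encoding ---------------------------------------

def numeric_fill_values(table: SurveyTable) -> dict[str, float]:
    """Median fill values for numeric/binary predictors, computed on `table`.

    Fit these on the training sample and pass them to
    :func:`encode_missing_as_level` for any other sample, so the encoding is
    learned on donor data only.
    """
    fills: dict[str, float] = {}
    for v in table.schema:
        if v.role == "predictor" and v.kind in ("numeric", "binary"):
            med = float(np.nanmedian(pd.to_numeric(table.data[v.name]).to_numpy(float)))
            fills[v.name] = 0.0 if np.isnan(med) else med
    return fills


def encode_missing_as_level(table: SurveyTable,
                            numeric_fill: Mapping[str, float] | None = None,
                            indicator_columns: Iterable[str] | None = None
                            ) -> SurveyTable:
    """Encode missing predictor values without dropping rows.

    Categorical predictors: missing cells become the reserved level
    (:data:`MISSING_TOKEN`), which is added to the declared levels.  Numeric
    and binary predictors: a paired 0/1 indicator column
    ``<name>__was_missing`` records missingness and the cell is filled with
    the (training-sample) median — distance- and tree-based classifiers need
    complete numeric inputs, and the median is scale-robust.

    Idempotent; the row count and id set are unchanged.
    ``indicator_columns`` forces creation of the named (training-side)
    indicator columns even where this table has no missing values, so a
    test/target table reproduces the training predictor manifest exactly.
    """
    if numeric_fill is None:
        numeric_fill = numeric_fill_values(table)
    forced = set(indicator_columns or ())
    df = table.data.copy()
    schema: list[VariableSchema] = []
    extra: list[VariableSchema] = []
    existing = {v.name for v in table.schema}
    for v in table.schema:
        col = df[v.name]
        if v.role == "predictor" and v.kind == "categorical":
            has_missing = col.isna().any()
            levels = tuple(v.levels) if v.levels is not None else tuple(
                sorted(col.dropna().astype(str).unique()))
            if has_missing or v.missing_code in levels:
                if v.missing_code not in levels:
                    levels = levels + (v.missing_code,)
                df[v.name] = col.fillna(v.missing_code)
                v = replace(v, levels=levels)
        elif v.role == "predictor" and v.kind in ("numeric", "binary"):
            ind_name = f"{v.name}__was_missing"
            if col.isna().any() or ind_name in existing or ind_name in forced:
                if ind_name not in existing and ind_name not in df.columns:
                    df[ind_name] = col.isna().astype(float)
                    extra.append(VariableSchema(name=ind_name, kind="binary",
                                                role="predictor"))
                df[v.name] = col.fillna(numeric_fill.get(v.name, 0.0))
        schema.append(v)
    return table.with_data(df, schema=schema + extra)
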