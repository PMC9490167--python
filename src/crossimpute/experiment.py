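"""Experiment orchestration.

Two modes mirror how the method is validated and deployed:

* **simulation study** — repeated random 80/20 splits of a donor survey that
  carries the truth proxy.  The 20% test half has its truth muted, both
  halves pass through the logical edits, each configured imputer is trained
  on the training pool and classifies the test pool, and confusion metrics
  plus status-outcome correlation diagnostics are computed against the
  un-muted truth.  Results are averaged over the splits so no single split
  drives them.
* **cross-survey application** — donor cohorts are matched to target year
  ranges; per cohort the pipeline is logical edits, optional
  propensity-score harmonization, fit on the donor cohort, and imputation
  of the matching target years.

Splits are drawn on the full donor sample *before* the logical edits (the
test fraction refers to the initial sample), then both halves are edited.
One master seed spawns per-(split, method) child seeds through a fixed
method registry, so adding a method never perturbs another method's
results.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import evaluation as ev
from .imputers import (FittedImputer, ImputerConfig, fit_imputer,
                       fit_propensity, predict_status, run_mi)
from .logical import (DOC_LOGICAL, IMPUTED_UNDOC, POSSIBLY_UNDOC, RuleSet,
                      STATUS_COL, TRUE_UNDOC, TRUTH_COL, apply_logical_edits,
                      default_ruleset, derive_true_status)
from .survey import SurveyTable, encode_missing_as_level, numeric_fill_values

#: fixed registry: child seeds depend on (master_seed, split, method index),
#: so results for one method are invariant to which others are requested
METHOD_INDEX = {"logical_only": 0, "logit": 1, "mi_logit": 2, "knn": 3, "rf": 4}


@dataclass(frozen=True)
class ExperimentConfig:
    mode: str = "simulation_study"
    n_splits: int = 10
    test_fraction: float = 0.20
    methods: tuple[str, ...] = ("logical_only", "logit", "mi_logit", "knn", "rf")
    cohort_map: tuple[tuple[int, int], ...] = ()
    master_seed: int = 0
    harmonize: bool = False
    harmonize_covariates: tuple[str, ...] = ("region_residence", "occupation")

    def __post_init__(self) -> None:
        if self.mode not in ("simulation_study", "cross_survey"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")
        for m in self.methods:
            if m not in METHOD_INDEX:
                raise ValueError(f"unknown method {m!r}")
        spans = sorted(self.cohort_map)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 <= a1:
                raise ValueError("cohort_map year ranges overlap")


def _child_seed(master_seed: int, split: int, method: str) -> int:
    ss = np.random.SeedSequence([master_seed, split, METHOD_INDEX[method]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def split_ids(ids: Sequence[str], master_seed: int, split: int,
              test_fraction: float) -> set[str]:
    """Test-half membership: a pure function of (master seed, split, id set).

    Ids are sorted before permutation, so membership does not depend on row
    order in the table.
    """
    ordered = sorted(str(i) for i in ids)
    rng = np.random.default_rng(np.random.SeedSequence([master_seed, 100 + split]))
    perm = rng.permutation(len(ordered))
    n_test = int(round(test_fraction * len(ordered)))
    return {ordered[j] for j in perm[:n_test]}


def _prepare_halves(donor: SurveyTable, ruleset: RuleSet, test_ids: set[str]
                    ) -> tuple[SurveyTable, SurveyTable]:
    """Split, logically edit, derive truth, and encode both halves (numeric
    fill values learned on the training half only)."""
    in_test = donor.data[donor.id_col].astype(str).isin(test_ids).to_numpy()
    train = donor.subset(~in_test)
    test = donor.subset(in_test)
    train = derive_true_status(apply_logical_edits(train, ruleset), ruleset)
    test = derive_true_status(apply_logical_edits(test, ruleset), ruleset)
    fill = numeric_fill_values(train)
    train_enc = encode_missing_as_level(train, fill)
    indicators = [v.name for v in train_enc.schema
                  if v.name.endswith("__was_missing")]
    return train_enc, encode_missing_as_level(test, fill, indicators)


def _full_sample_metrics(test: SurveyTable, undoc_pred_full: np.ndarray,
                         outcomes: Sequence[str]) -> dict[str, float]:
    """Confusion metrics on both denominators plus correlation diagnostics
    on the full test half."""
    truth_full = (test.data[TRUTH_COL] == TRUE_UNDOC).to_numpy()
    pool = (test.data[STATUS_COL] != DOC_LOGICAL).to_numpy()
    out: dict[str, float] = {}
    for tag, mask in (("pool", pool), ("full", np.ones(len(pool), bool))):
        cm = ev.confusion_metrics(truth_full[mask], undoc_pred_full[mask])
        for k, v in cm.as_dict().items():
            out[f"{k}_{tag}"] = v
        for k in ("tp", "fp", "fn", "tn"):
            out[f"{k}_{tag}"] = float(getattr(cm.counts, k))
        out[f"n_{tag}"] = float(mask.sum())
    for name in outcomes:
        y = test.data[name].to_numpy(float)
        ci = ev.correlation_bias(undoc_pred_full.astype(float), y)
        true_ci = ev.correlation_bias(truth_full.astype(float), y)
        out[f"r_{name}"] = ci.r
        out[f"r_{name}_lo"] = ci.lo
        out[f"r_{name}_hi"] = ci.hi
        out[f"r_true_{name}"] = true_ci.r
        out[f"bias_{name}"] = ci.r - true_ci.r
    return out


def run_simulation_study(
    donor: SurveyTable,
    config: ExperimentConfig,
    imputer_configs: Mapping[str, ImputerConfig] | None = None,
    ruleset: RuleSet | None = None,
) -> dict[str, ev.EvalReport]:
    """Repeated-split validation of every configured method on one donor.

    Returns one :class:`~crossimpute.evaluation.EvalReport` per method with
    per-split metrics (both denominators), correlation diagnostics on the
    held-out half, and their averages.  Fully reproducible from
    ``config.master_seed``.
    """
    ruleset = ruleset or default_ruleset()
    imputer_configs = dict(imputer_configs or {})
    for m in config.methods:
        if m not in ("logical_only",) and m not in METHOD_INDEX:
            raise ValueError(f"method {m!r} lacks configuration")
    outcomes = [v.name for v in donor.schema if v.role == "outcome"]
    reports = {m: ev.EvalReport(method=m) for m in config.methods}

    for split in range(config.n_splits):
        test_ids = split_ids(donor.data[donor.id_col], config.master_seed,
                             split, config.test_fraction)
        train, test = _prepare_halves(donor, ruleset, test_ids)
        pool_train = train.subset((train.data[STATUS_COL] == POSSIBLY_UNDOC).to_numpy())
        pool_mask = (test.data[STATUS_COL] == POSSIBLY_UNDOC).to_numpy()
        pool_test = test.subset(pool_mask)

        for method in config.methods:
            seed = _child_seed(config.master_seed, split, method)
            if method == "logical_only":
                pred_full = pool_mask.copy()
                reports[method].per_split.append(
                    _full_sample_metrics(test, pred_full, outcomes))
                continue
            base = imputer_configs.get(method, ImputerConfig(method=method))
            icfg = replace(base, method=method if method != "mi_logit"
                           else "mi_logit", seed=seed)
            if method == "mi_logit":
                mi = run_mi(pool_train, pool_test, icfg)
                stats = _mi_split_metrics(test, pool_mask, mi, outcomes)
            else:
                fitted = fit_imputer(pool_train, icfg)
                labeled = predict_status(fitted, pool_test, icfg)
                pred_full = np.zeros(len(test.data), dtype=bool)
                pred_full[np.flatnonzero(pool_mask)] = (
                    labeled.data[STATUS_COL] == IMPUTED_UNDOC).to_numpy()
                stats = _full_sample_metrics(test, pred_full, outcomes)
            reports[method].per_split.append(stats)
    return reports


def _mi_split_metrics(test: SurveyTable, pool_mask: np.ndarray,
                      mi, outcomes: Sequence[str]) -> dict[str, float]:
    """Per-split metrics for multiple imputation: confusion metrics averaged
    over the M completed datasets, correlations pooled with Rubin's rules."""
    truth_full = (test.data[TRUTH_COL] == TRUE_UNDOC).to_numpy()
    idx = np.flatnonzero(pool_mask)
    per_m: list[dict[str, float]] = []
    completed_full = {}
    for col in mi.completed.columns:
        pred_full = np.zeros(len(test.data), dtype=bool)
        pred_full[idx] = mi.completed[col].to_numpy() == 1
        completed_full[col] = pred_full.astype(float)
        d: dict[str, float] = {}
        for tag, mask in (("pool", pool_mask),
                          ("full", np.ones(len(pool_mask), bool))):
            cm = ev.confusion_metrics(truth_full[mask], pred_full[mask])
            for k, v in cm.as_dict().items():
                d[f"{k}_{tag}"] = v
            for k in ("tp", "fp", "fn", "tn"):
                d[f"{k}_{tag}"] = float(getattr(cm.counts, k))
            d[f"n_{tag}"] = float(mask.sum())
        per_m.append(d)
    out = {k: float(np.nanmean([d[k] for d in per_m])) for k in per_m[0]}
    comp_df = pd.DataFrame(completed_full)
    for name in outcomes:
        y = test.data[name].to_numpy(float)
        pooled = ev.pool_mi_diagnostics(comp_df, y)
        true_ci = ev.correlation_bias(truth_full.astype(float), y)
        out[f"r_{name}"] = pooled.estimate
        out[f"r_{name}_lo"] = pooled.lo
        out[f"r_{name}_hi"] = pooled.hi
        out[f"r_true_{name}"] = true_ci.r
        out[f"bias_{name}"] = pooled.estimate - true_ci.r
    return out


# ---- cross-survey application -------------------------------------------

def run_cross_survey(
    donor_cohorts: Sequence[SurveyTable],
    target: SurveyTable,
    config: ExperimentConfig,
    imputer_config: ImputerConfig | None = None,
    ruleset: RuleSet | None = None,
) -> SurveyTable:
    """Impute status into a target survey from cohort-matched donors.

    ``config.cohort_map`` pairs each donor cohort (by position) with an
    inclusive target year range; every target year must be covered by
    exactly one range.  Per cohort: logical edits on both sides, optional
    propensity-score harmonization (the score becomes one extra predictor),
    fit on the donor pool, classify the matching target pool rows.  Returns
    the target with the four-valued status label appended; rows are never
    dropped.  Multiple imputation is not a definitive classifier and is not
    accepted here.
    """
    ruleset = ruleset or default_ruleset()
    imputer_config = imputer_config or ImputerConfig(method="rf")
    if imputer_config.method == "mi_logit":
        raise ValueError("cross-survey application needs a definitive "
                         "classifier (logit, knn or rf)")
    if len(donor_cohorts) != len(config.cohort_map):
        raise ValueError("cohort_map must pair one year range per donor cohort")
    years = pd.to_numeric(target.data[target.names_with_role("year")[0]])
    covered = np.zeros(len(years), dtype=int)
    for (y0, y1) in config.cohort_map:
        covered += ((years >= y0) & (years <= y1)).to_numpy(int)
    if (covered == 0).any():
        missing = sorted(years[covered == 0].unique())
        raise ValueError(f"target years not covered by any cohort: {missing}")

    labels = pd.Series(index=target.data.index, dtype=object)
    scores = pd.Series(np.nan, index=target.data.index)
    for cohort, (y0, y1) in zip(donor_cohorts, config.cohort_map):
        sel = ((years >= y0) & (years <= y1)).to_numpy()
        slice_tbl = target.subset(sel)
        donor_ed = derive_true_status(apply_logical_edits(cohort, ruleset), ruleset)
        target_ed = apply_logical_edits(slice_tbl, ruleset)
        fill = numeric_fill_values(donor_ed)
        donor_ed = encode_missing_as_level(donor_ed, fill)
        indicators = [v.name for v in donor_ed.schema
                      if v.name.endswith("__was_missing")]
        target_ed = encode_missing_as_level(target_ed, fill, indicators)
        donor_pool = donor_ed.subset(
            (donor_ed.data[STATUS_COL] == POSSIBLY_UNDOC).to_numpy())
        t_pool_mask = (target_ed.data[STATUS_COL] == POSSIBLY_UNDOC).to_numpy()
        target_pool = target_ed.subset(t_pool_mask)
        if config.harmonize:
            donor_pool, target_pool = fit_propensity(
                donor_pool, target_pool,
                extra_covariates=config.harmonize_covariates,
                seed=_child_seed(config.master_seed, int(y0), "logit"))
        seed = _child_seed(config.master_seed, int(y0),
                           imputer_config.method if imputer_config.method
                           in METHOD_INDEX else "rf")
        icfg = replace(imputer_config, seed=seed)
        fitted = fit_imputer(donor_pool, icfg)
        labeled = predict_status(fitted, target_pool, icfg)
        sel_idx = np.flatnonzero(sel)
        slice_labels = target_ed.data[STATUS_COL].to_numpy(object)
        slice_labels[t_pool_mask] = labeled.data[STATUS_COL].to_numpy(object)
        labels.iloc[sel_idx] = slice_labels
        pool_scores = np.full(len(slice_labels), np.nan)
        pool_scores[t_pool_mask] = labeled.data["status_score"].to_numpy()
        scores.iloc[sel_idx] = pool_scores

    from .survey import VariableSchema
    df = target.data.copy()
    df[STATUS_COL] = labels.to_numpy(object)
    df["status_score"] = scores.to_numpy()
    schema = [v for v in target.schema
              if v.name not in (STATUS_COL, "status_score")]
    schema.append(VariableSchema(STATUS_COL, "categorical", "aux",
                                 levels=tuple(sorted(set(labels)))))
    schema.append(VariableSchema("status_score", "numeric", "aux"))
    return target.with_data(df, schema=schema)


# ---- weighted tabulation -------------------------------------------------

def weighted_summary(table: SurveyTable, group: str,
                     variables: Sequence[str]) -> pd.DataFrame:
    """Weighted column-percentage summary per status group.

    For categorical variables the weighted share of each level within a
    (group, variable) cell — shares sum to 100 within the cell; for numeric
    variables the weighted mean (level ``(mean)``).  Returns a tidy frame
    with columns ``group``, ``variable``, ``level``, ``value``.
    """
    w = pd.to_numeric(table.data[table.weight_col]).to_numpy(float)
    if not np.all(np.isfinite(w) & (w > 0)):
        raise ValueError("weights must be positive and finite")
    rows = []
    for g, gdf in table.data.groupby(group, sort=True):
        gw = w[gdf.index.to_numpy()]
        for name in variables:
            v = table.schema_by_name(name)
            col = gdf[name]
            if v.kind == "categorical":
                cats = col.fillna(v.missing_code).astype(str)
                denom = gw.sum()
                levels = v.levels or tuple(sorted(cats.unique()))
                seen = set(cats.unique())
                for lv in list(levels) + sorted(seen - set(levels or ())):
                    share = gw[(cats == lv).to_numpy()].sum() / denom * 100.0
                    rows.append({"group": g, "variable": name,
                                 "level": lv, "value": share})
            else:
                vals = pd.to_numeric(col).to_numpy(float)
                ok = ~np.isnan(vals)
                mean = float(np.sum(vals[ok] * gw[ok]) / np.sum(gw[ok]))
                rows.append({"group": g, "variable": name,
                             "level": "(mean)", "value": mean})
    return pd.DataFrame(rows)
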