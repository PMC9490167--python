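"""Validation framework: confusion metrics, correlation-bias diagnostics,
Rubin pooling, and averaging over repeated splits.

Metric conventions
------------------
sensitivity = tp / (tp + fn)   probability a truly undocumented respondent
                               is classified undocumented
specificity = tn / (tn + fp)   standard definition; the false-positive rate
                               (fp / (fp + tn)) is reported separately as
                               ``fpr`` because some sources describe
                               "specificity" by that quantity
ppv         = tp / (tp + fp)   share of imputed-undocumented who are truly
                               undocumented
accuracy    = (tp + tn) / n

Metrics are reported on two denominators: the possibly-undocumented *pool*
(the records the statistical imputers actually classify) and the *full*
sample including the logically documented.  Undefined ratios (zero
denominator) are reported as NaN with an explicit flag, never as zero.

Correlations between a binary status and a binary outcome are Pearson
coefficients — identical to the phi coefficient of the 2x2 table — with
confidence intervals on the Fisher-z scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts over a stated denominator population."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ConfusionMetrics:
    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    fpr: float
    ppv: float
    accuracy: float
    #: names of metrics whose denominator was zero (value NaN)
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {"sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "fpr": self.fpr, "ppv": self.ppv, "accuracy": self.accuracy}


def _ratio(num: int, den: int, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return float("nan")
    return num / den


def confusion_metrics(truth, imputed) -> ConfusionMetrics:
    """Confusion metrics for aligned boolean/0-1 vectors.

    ``truth`` and ``imputed`` may be pandas Series (aligned by index — an
    index mismatch is an error, preventing silent misalignment) or plain
    arrays of equal length.  Positive = undocumented.
    """
    if isinstance(truth, pd.Series) and isinstance(imputed, pd.Series):
        if len(truth) != len(imputed) or not truth.index.equals(imputed.index):
            raise ValueError("truth and imputed vectors are not id-aligned")
    t = np.asarray(truth, dtype=bool)
    p = np.asarray(imputed, dtype=bool)
    if t.shape != p.shape:
        raise ValueError("truth and imputed vectors differ in length")
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    tn = int(np.sum(~t & ~p))
    undefined: list[str] = []
    counts = ConfusionCounts(tp, fp, fn, tn)
    return ConfusionMetrics(
        counts=counts,
        sensitivity=_ratio(tp, tp + fn, "sensitivity", undefined),
        specificity=_ratio(tn, tn + fp, "specificity", undefined),
        fpr=_ratio(fp, fp + tn, "fpr", undefined),
        ppv=_ratio(tp, tp + fp, "ppv", undefined),
        accuracy=_ratio(tp + tn, counts.total, "accuracy", undefined),
        undefined=tuple(undefined),
    )


@dataclass(frozen=True)
class CorrelationCI:
    r: float
    lo: float
    hi: float
    n: int


def _fisher_ci(r: float, n: int, alpha: float) -> tuple[float, float]:
    if n <= 3:
        return float("-inf"), float("inf")
    z = math.atanh(min(max(r, -0.999999999), 0.999999999))
    se = 1.0 / math.sqrt(n - 3)
    crit = stats.norm.ppf(1.0 - alpha / 2.0)
    return math.tanh(z - crit * se), math.tanh(z + crit * se)


def correlation_bias(status, outcome, alpha: float = 0.05) -> CorrelationCI:
    """Pearson correlation between two binary vectors with a Fisher-z CI.

    For 0/1 vectors this equals the phi coefficient of the 2x2 table,
    (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)).  Constant vectors are an error:
    the correlation is undefined, and silently returning zero would hide a
    degenerate diagnostic.
    """
    x = np.asarray(status, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.shape != y.shape:
        raise ValueError("status and outcome vectors differ in length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(stats.pearsonr(x, y).statistic)
    lo, hi = _fisher_ci(r, len(x), alpha)
    return CorrelationCI(r=r, lo=lo, hi=hi, n=len(x))


# ---- Rubin's rules -------------------------------------------------------

@dataclass(frozen=True)
class PooledEstimate:
    estimate: float
    total_variance: float
    within: float
    between: float
    lo: float
    hi: float
    m: int
    df: float


def rubin_pool(estimates: Sequence[float], variances: Sequence[float],
               alpha: float = 0.05) -> PooledEstimate:
    """Combine M per-dataset estimates with Rubin's rules.

    Pooled point estimate = mean of the estimates; total variance
    T = W + (1 + 1/M) B with W the mean within variance and B the
    between-imputation variance.  When B = 0 the interval collapses to the
    single-dataset normal interval; otherwise the usual Rubin degrees of
    freedom (M - 1)(1 + W / ((1 + 1/M) B))^2 give a t interval.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.ndim != 1 or q.shape != u.shape or len(q) < 1:
        raise ValueError("need M >= 1 aligned estimates and variances")
    m = len(q)
    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1)) if m > 1 else 0.0
    t_var = w + (1.0 + 1.0 / m) * b
    if b > 0 and m > 1:
        df = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2
        crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    else:
        df = float("inf")
        crit = stats.norm.ppf(1.0 - alpha / 2.0)
    half = crit * math.sqrt(t_var)
    return PooledEstimate(estimate=qbar, total_variance=t_var, within=w,
                          between=b, lo=qbar - half, hi=qbar + half,
                          m=m, df=df)


def pool_mi_diagnostics(completed_status: pd.DataFrame, outcome,
                        alpha: float = 0.05) -> PooledEstimate:
    """Pool the status-outcome correlation across M completed datasets.

    Per-dataset Pearson correlations are moved to the variance-stabilized
    Fisher-z scale (within variance 1/(n-3)), combined with Rubin's rules,
    and the interval is transformed back; the returned point estimate is
    the back-transformed pooled z.  With identical completed datasets the
    between variance is zero and the interval equals the single-dataset CI.
    """
    y = np.asarray(outcome, dtype=float)
    if len(y) != len(completed_status):
        raise ValueError("outcome not aligned with completed datasets")
    zs, vs = [], []
    n = len(y)
    for col in completed_status.columns:
        r = correlation_bias(completed_status[col].to_numpy(float), y).r
        zs.append(math.atanh(min(max(r, -0.999999999), 0.999999999)))
        vs.append(1.0 / (n - 3))
    pooled = rubin_pool(zs, vs, alpha=alpha)
    return PooledEstimate(
        estimate=math.tanh(pooled.estimate),
        total_variance=pooled.total_variance, within=pooled.within,
        between=pooled.between, lo=math.tanh(pooled.lo),
        hi=math.tanh(pooled.hi), m=pooled.m, df=pooled.df)


# ---- reports over repeated splits ---------------------------------------

@dataclass
class EvalReport:
    """Per-split metric dictionaries for one method, plus their average."""

    method: str
    per_split: list[dict[str, float]] = field(default_factory=list)

    @property
    def averaged(self) -> dict[str, float]:
        if not self.per_split:
            return {}
        keys = self.per_split[0].keys()
        return {k: float(np.nanmean([s[k] for s in self.per_split]))
                for k in keys}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.per_split):
            for k, v in s.items():
                rows.append({"method": self.method, "split": i,
                             "metric": k, "value": v})
        return pd.DataFrame(rows)


def average_over_splits(reports: Sequence[EvalReport]) -> EvalReport:
    """Merge same-method reports; the averaged values are the element-wise
    arithmetic means and per-split values are retained for dispersion."""
    if not reports:
        raise ValueError("need at least one report")
    method = reports[0].method
    keysets = {frozenset(s.keys()) for r in reports for s in r.per_split}
    if len(keysets) > 1:
        raise ValueError("heterogeneous metric sets cannot be averaged")
    if any(r.method != method for r in reports):
        raise ValueError("reports mix methods")
    merged = EvalReport(method=method)
    for r in reports:
        merged.per_split.extend(dict(s) for s in r.per_split)
    return merged
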