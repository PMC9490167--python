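"""Statistical imputation backends for the possibly-undocumented pool.

Four backends share one interface: fit on the donor pool (records that
survived the logical edits and carry a truth label), then classify the
target pool.

* ``logit`` — additive logistic regression, classified at a strict
  probability cutoff (default > 0.5).
* ``mi_logit`` — multiple imputation: M completed label vectors drawn from
  the logistic predictive distribution (coefficients drawn from the
  approximate sampling posterior, then Bernoulli labels), analyses pooled
  with Rubin's rules downstream.
* ``knn`` — k-nearest neighbours on min-max-scaled numerics and one-hot
  categoricals, Euclidean distance, majority vote; k tuned by repeated
  stratified cross-validation when a grid is given.
* ``rf`` — random forest (bootstrap rows, random predictor subsets per
  split), majority/probability vote; the per-split predictor count (mtry)
  tuned by repeated cross-validation when a grid is given.

Survey weights are never used in fitting; they enter only in tabulation.
All tuning happens strictly inside the training sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .logical import (IMPUTED_DOC, IMPUTED_UNDOC, POSSIBLY_UNDOC, STATUS_COL,
                      TRUE_UNDOC, TRUTH_COL)
from .survey import SurveyTable, VariableSchema

#: near-MLE ridge strength for logistic fits; keeps coefficients finite
#: under complete separation (small possibly-undocumented pools)
_LOGIT_C = 1e4
#: |coefficient| beyond which separation is suspected and recorded
_SEPARATION_COEF = 15.0
#: relative tolerance for distance ties at the k-th neighbour
_DIST_TIE_RTOL = 1e-12

METHODS = ("logit", "mi_logit", "knn", "rf")


@dataclass(frozen=True)
class ImputerConfig:
    """Method selection and hyperparameters.

    ``threshold`` is the strict probability cutoff for single-classification
    methods; ``m_imputations`` the number of completed datasets for
    ``mi_logit``; ``k_grid``/``mtry_grid`` the candidate neighbour counts and
    per-split predictor counts (``None`` entries mean the square-root rule);
    tuning uses ``cv_repeats`` repetitions of stratified ``cv_folds``-fold
    cross-validated accuracy.
    """

    method: str = "rf"
    threshold: float = 0.5
    m_imputations: int = 10
    k_grid: tuple[int, ...] = (31,)
    cv_folds: int = 10
    cv_repeats: int = 2
    n_trees: int = 500
    mtry_grid: tuple[int | None, ...] = (None,)
    mi_iterations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if self.m_imputations < 1:
            raise ValueError("m_imputations must be >= 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not self.k_grid or not self.mtry_grid:
            raise ValueError("k_grid and mtry_grid must be non-empty")


class Encoder:
    """Design-matrix encoder fit on the training table.

    Categorical predictors are expanded into one indicator per declared
    level (optionally dropping the first for identified additive models);
    numeric and binary predictors pass through, with per-column min-max
    scaling to [0, 1] when requested (distance-based methods).  The encoder
    records its manifest — the encoded column names — and refuses tables
    whose predictor schema does not reproduce it.
    """

    def __init__(self, drop_first: bool = False, scale: bool = False,
                 extra_numeric: Sequence[str] = ()):
        self.drop_first = drop_first
        self.scale = scale
        self.extra_numeric = tuple(extra_numeric)
        self.manifest: tuple[str, ...] = ()

    def fit(self, table: SurveyTable) -> "Encoder":
        self._spec: list[tuple[str, str, tuple[str, ...]]] = []
        cols: list[str] = []
        for v in table.schema:
            if v.role != "predictor" and v.name not in self.extra_numeric:
                continue
            if v.kind == "categorical":
                levels = v.levels or tuple(
                    sorted(table.data[v.name].dropna().astype(str).unique()))
                used = levels[1:] if self.drop_first else levels
                self._spec.append((v.name, "categorical", tuple(used)))
                cols += [f"{v.name}={lv}" for lv in used]
            else:
                self._spec.append((v.name, "numeric", ()))
                cols.append(v.name)
        self.manifest = tuple(cols)
        X = self._raw(table)
        if self.scale:
            self._lo = X.min(axis=0)
            span = X.max(axis=0) - self._lo
            self._span = np.where(span > 0, span, 1.0)
        return self

    def _raw(self, table: SurveyTable) -> np.ndarray:
        parts = []
        df = table.data
        for name, kind, used in self._spec:
            if name not in df.columns:
                raise ValueError(f"predictor manifest mismatch: {name!r} absent")
            if kind == "categorical":
                col = df[name].astype(str)
                for lv in used:
                    parts.append((col == lv).to_numpy(float))
            else:
                vals = pd.to_numeric(df[name], errors="coerce").to_numpy(float)
                if np.isnan(vals).any():
                    raise ValueError(
                        f"predictor {name!r} still has missing values; "
                        "apply encode_missing_as_level first")
                parts.append(vals)
        return np.column_stack(parts) if parts else np.empty((len(df), 0))

    def transform(self, table: SurveyTable) -> np.ndarray:
        names = [v.name for v in table.schema]
        for name, _, _ in self._spec:
            if name not in names:
                raise ValueError(f"predictor manifest mismatch: {name!r} absent")
        X = self._raw(table)
        if self.scale and X.shape[1]:
            X = np.clip((X - self._lo) / self._span, 0.0, 1.0)
        return X


@dataclass
class FittedImputer:
    """A trained imputation backend plus everything needed to apply it."""

    method: str
    encoder: Encoder
    config: ImputerConfig
    model: object = None
    tuning_trace: dict = field(default_factory=dict)
    # knn stores its reference set explicitly
    X_train: np.ndarray | None = None
    y_train: np.ndarray | None = None
    constant_prob: float | None = None

    @property
    def manifest(self) -> tuple[str, ...]:
        return self.encoder.manifest

    # ---- scores ----------------------------------------------------------
    def predict_proba(self, table: SurveyTable) -> np.ndarray:
        """Undocumented-status score per row (probability or vote share)."""
        X = self.encoder.transform(table)
        if self.constant_prob is not None:
            return np.full(len(table.data), self.constant_prob)
        if self.method in ("logit", "mi_logit"):
            return self.model.predict_proba(X)[:, 1]
        if self.method == "rf":
            return self.model.predict_proba(X)[:, 1]
        if self.method == "knn":
            return _knn_vote_share(self.X_train, self.y_train, X,
                                   int(self.tuning_trace["selected_k"]))
        raise AssertionError(self.method)


# ---- shared plumbing -----------------------------------------------------

def _pool_training(train: SurveyTable) -> np.ndarray:
    """Validate the fit precondition and return the 0/1 label vector."""
    if STATUS_COL not in train.data.columns:
        raise ValueError("training table lacks the status label; "
                         "run apply_logical_edits first")
    labels = train.data[STATUS_COL]
    if (labels != POSSIBLY_UNDOC).any():
        raise ValueError("training table must be restricted to the "
                         "possibly-undocumented pool")
    if TRUTH_COL not in train.data.columns:
        raise ValueError("training table lacks truth labels")
    return (train.data[TRUTH_COL] == TRUE_UNDOC).to_numpy(float)


def _rng_int(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def _cv_accuracy(X: np.ndarray, y: np.ndarray, fit_predict, config: ImputerConfig,
                 seed: int) -> float:
    """Repeated stratified k-fold CV accuracy of a fit/predict closure."""
    accs = []
    n_splits = min(config.cv_folds, max(2, int(min(y.sum(), (1 - y).sum()))))
    for rep in range(config.cv_repeats):
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                              random_state=(seed + rep) % (2**31 - 1))
        for tr, te in skf.split(X, y):
            pred = fit_predict(X[tr], y[tr], X[te])
            accs.append(float(np.mean(pred == y[te])))
    return float(np.mean(accs))


# ---- logistic ------------------------------------------------------------

def _fit_logistic(X: np.ndarray, y: np.ndarray, seed: int,
                  trace: dict) -> LogisticRegression:
    model = LogisticRegression(C=_LOGIT_C, solver="lbfgs", max_iter=5000,
                               random_state=seed)
    model.fit(X, y)
    if np.abs(model.coef_).max() > _SEPARATION_COEF:
        trace["separation_suspected"] = True
        trace["max_abs_coef"] = float(np.abs(model.coef_).max())
    return model


def fit_single_logit(train: SurveyTable, config: ImputerConfig) -> FittedImputer:
    """Additive logistic regression on the encoded predictor set.

    Fit with a very small ridge penalty, which coincides with maximum
    likelihood away from separation and keeps coefficients finite under it
    (a suspicion of separation is recorded in the tuning trace).
    An empty predictor set degrades to the intercept-only model (constant
    probability equal to the training prevalence).
    """
    y = _pool_training(train)
    enc = Encoder(drop_first=True).fit(train)
    X = enc.transform(train)
    trace: dict = {}
    fitted = FittedImputer(method="logit", encoder=enc, config=config,
                           tuning_trace=trace)
    if X.shape[1] == 0 or y.min() == y.max():
        fitted.constant_prob = float(y.mean())
        return fitted
    seed = _rng_int(np.random.SeedSequence([config.seed, 11]))
    fitted.model = _fit_logistic(X, y, seed, trace)
    return fitted


def predict_status(model: FittedImputer, target: SurveyTable,
                   config: ImputerConfig | None = None) -> SurveyTable:
    """Classify the target pool: append ``imputed_undoc`` where the score
    strictly exceeds the threshold, else ``imputed_doc``.

    Refuses rows that are not in the possibly-undocumented pool — logically
    documented records are never re-imputed.  Deterministic given the model
    and input.
    """
    config = config or model.config
    if STATUS_COL not in target.data.columns:
        raise ValueError("target table lacks the status label; "
                         "run apply_logical_edits first")
    if (target.data[STATUS_COL] != POSSIBLY_UNDOC).any():
        raise ValueError("target rows must all be possibly-undocumented; "
                         "doc_logical rows are never re-imputed")
    p = model.predict_proba(target)
    labels = np.where(p > config.threshold, IMPUTED_UNDOC, IMPUTED_DOC)
    df = target.data.copy()
    df[STATUS_COL] = labels
    df["status_score"] = p
    schema = [v for v in target.schema if v.name != "status_score"]
    schema.append(VariableSchema("status_score", "numeric", "aux"))
    return target.with_data(df, schema=schema)


# ---- k-nearest neighbours ------------------------------------------------

def _knn_vote_share(X_train: np.ndarray, y_train: np.ndarray,
                    X_query: np.ndarray, k: int,
                    chunk: int = 2048) -> np.ndarray:
    """Vote share of undocumented among the k nearest training points.

    All neighbours tied with the k-th distance are included, making the
    result independent of row order.  Exact vote ties fall on the
    documented side downstream (strict > threshold).
    """
    out = np.empty(len(X_query))
    for lo in range(0, len(X_query), chunk):
        Q = X_query[lo:lo + chunk]
        D = cdist(Q, X_train, metric="euclidean")
        kth = np.partition(D, k - 1, axis=1)[:, k - 1]
        tol = _DIST_TIE_RTOL * np.maximum(kth, 1.0)
        within = D <= (kth + tol)[:, None]
        out[lo:lo + chunk] = (within * y_train).sum(axis=1) / within.sum(axis=1)
    return out


def fit_knn(train: SurveyTable, config: ImputerConfig) -> FittedImputer:
    """K-nearest-neighbour classifier with Euclidean distance.

    Numerics are min-max scaled to [0, 1] and categoricals one-hot encoded
    (fit on training data only).  When ``k_grid`` has several candidates the
    k with the best repeated-CV accuracy is selected (ties to the smaller k).
    """
    y = _pool_training(train)
    enc = Encoder(drop_first=False, scale=True).fit(train)
    X = enc.transform(train)
    for k in config.k_grid:
        if k > len(X):
            raise ValueError(f"k={k} exceeds training size {len(X)}")
        if k < 1:
            raise ValueError("k must be >= 1")
    trace: dict = {"k_grid": list(config.k_grid)}
    seed = _rng_int(np.random.SeedSequence([config.seed, 12]))
    if len(config.k_grid) == 1:
        best_k = config.k_grid[0]
    else:
        scores = {}
        for k in config.k_grid:
            def fp(Xtr, ytr, Xte, k=k):
                kk = min(k, len(Xtr))
                return (_knn_vote_share(Xtr, ytr, Xte, kk) > config.threshold)
            scores[k] = _cv_accuracy(X, y, fp, config, seed)
        trace["cv_scores"] = {int(k): v for k, v in scores.items()}
        best = max(scores.values())
        best_k = min(k for k, v in scores.items() if v == best)
    trace["selected_k"] = int(best_k)
    return FittedImputer(method="knn", encoder=enc, config=config,
                         tuning_trace=trace, X_train=X, y_train=y)


# ---- random forest -------------------------------------------------------

def fit_rf(train: SurveyTable, config: ImputerConfig) -> FittedImputer:
    """Random forest: ``n_trees`` trees on bootstrap row samples, a random
    predictor subset (mtry) considered at each split, aggregated by vote.

    ``mtry_grid`` entries are per-split predictor counts (``None`` = square
    root of the predictor count); a multi-entry grid is tuned by repeated
    CV accuracy.  The seed fixes the forest: identical seeds give identical
    votes.
    """
    y = _pool_training(train)
    enc = Encoder(drop_first=False).fit(train)
    X = enc.transform(train)
    n_feat = X.shape[1]
    grid = []
    for m in config.mtry_grid:
        m_eff = max(1, int(round(np.sqrt(n_feat)))) if m is None else int(m)
        if m_eff > n_feat:
            raise ValueError(f"mtry={m_eff} exceeds predictor count {n_feat}")
        grid.append(m_eff)
    trace: dict = {"mtry_grid": grid}
    if y.min() == y.max():
        return FittedImputer(method="rf", encoder=enc, config=config,
                             tuning_trace=trace, constant_prob=float(y[0]))
    seed = _rng_int(np.random.SeedSequence([config.seed, 13]))

    def make(mtry: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=config.n_trees, max_features=mtry,
            bootstrap=True, random_state=seed, n_jobs=1)

    if len(set(grid)) == 1:
        best_mtry = grid[0]
    else:
        scores = {}
        for mtry in sorted(set(grid)):
            def fp(Xtr, ytr, Xte, mtry=mtry):
                m = make(mtry).fit(Xtr, ytr)
                return m.predict_proba(Xte)[:, 1] > config.threshold
            scores[mtry] = _cv_accuracy(X, y, fp, config, seed)
        trace["cv_scores"] = {int(m): v for m, v in scores.items()}
        best = max(scores.values())
        best_mtry = min(m for m, v in scores.items() if v == best)
    trace["selected_mtry"] = int(best_mtry)
    model = make(best_mtry).fit(X, y)
    return FittedImputer(method="rf", encoder=enc, config=config, model=model,
                         tuning_trace=trace)


# ---- multiple imputation -------------------------------------------------

@dataclass
class MIResult:
    """M completed status-label vectors over the target ids.

    ``completed`` is a DataFrame indexed by target id with columns
    ``status_imp_1 .. status_imp_M`` holding 0/1 undocumented indicators.
    Analyses run per completed dataset are pooled with Rubin's rules in the
    evaluation module; the pooled point estimate is the mean of the
    per-dataset estimates by construction.
    """

    completed: pd.DataFrame
    tuning_trace: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return self.completed.shape[1]


def run_mi(train: SurveyTable, target: SurveyTable, config: ImputerConfig,
           include_outcomes: bool = True) -> MIResult:
    """Multiple imputation of the target pool's status.

    The donor pool and the target pool are stacked with the target status
    set missing; the status is the only incomplete variable after the
    missing-as-category encoding, so the chained-equations scheme reduces to
    its single logistic conditional: fit the status model on the complete
    (donor) rows, then for each of the M imputations draw a coefficient
    vector from the approximate sampling posterior
    N(beta_hat, (X'WX + lambda I)^-1) and draw Bernoulli labels from the
    implied probabilities.  Because multiple imputation retains the joint
    distribution of all analysis variables, the target's outcome variables
    are included in the imputation model by default (``include_outcomes``);
    switching them off reproduces the joint-observation violation, where
    the donor lacks the outcome of interest.
    """
    if config.m_imputations < 1:
        raise ValueError("m_imputations must be >= 1")
    y = _pool_training(train)
    if (target.data[STATUS_COL] != POSSIBLY_UNDOC).any():
        raise ValueError("target rows must all be possibly-undocumented")
    extra = ()
    if include_outcomes:
        extra = tuple(v.name for v in train.schema if v.role == "outcome"
                      if v.name in target.data.columns
                      and target.data[v.name].notna().all()
                      and train.data[v.name].notna().all())
    enc = Encoder(drop_first=True, extra_numeric=extra).fit(train)
    X = enc.transform(train)
    Xt = enc.transform(target)
    trace: dict = {"outcomes_in_model": list(extra)}
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 14]))

    if X.shape[1] == 0:
        p_hat = np.full(len(Xt), float(y.mean()))
        draws = rng.binomial(1, p_hat[None, :].repeat(config.m_imputations, 0))
    else:
        model = _fit_logistic(X, y, _rng_int(np.random.SeedSequence(
            [config.seed, 15])), trace)
        beta = np.concatenate([model.intercept_, model.coef_.ravel()])
        X1 = np.column_stack([np.ones(len(X)), X])
        p = model.predict_proba(X)[:, 1]
        W = p * (1.0 - p)
        info = (X1 * W[:, None]).T @ X1 + np.eye(X1.shape[1]) / _LOGIT_C
        cov = np.linalg.inv(info)
        L = np.linalg.cholesky((cov + cov.T) / 2.0 +
                               1e-12 * np.eye(len(cov)))
        Xt1 = np.column_stack([np.ones(len(Xt)), Xt])
        draws = np.empty((config.m_imputations, len(Xt)), dtype=int)
        for m in range(config.m_imputations):
            beta_star = beta + L @ rng.standard_normal(len(beta))
            p_star = expit(Xt1 @ beta_star)
            draws[m] = rng.binomial(1, p_star)
    ids = target.data[target.id_col].to_numpy()
    completed = pd.DataFrame(
        {f"status_imp_{m + 1}": draws[m] for m in range(config.m_imputations)},
        index=pd.Index(ids, name=target.id_col))
    return MIResult(completed=completed, tuning_trace=trace)


# ---- propensity-score harmonization --------------------------------------

def fit_propensity(donor: SurveyTable, target: SurveyTable,
                   extra_covariates: Sequence[str] = (),
                   seed: int = 0) -> tuple[SurveyTable, SurveyTable]:
    """Append a donor-membership propensity score to both tables.

    A logistic model of donor-vs-target membership is fit on the stacked
    tables using the shared predictors plus any ``extra_covariates``
    (harmonization-only variables such as region of residence and
    occupation).  The fitted probability of belonging to the donor survey is
    appended as a numeric predictor to both tables — each predictor manifest
    grows by exactly one column — absorbing observable sampling differences
    before cross-survey imputation.
    """
    shared = [v.name for v in donor.schema
              if v.role == "predictor" and v.name != "propensity_score"
              and any(w.name == v.name for w in target.schema)]
    extras = [c for c in extra_covariates
              if c in donor.data.columns and c in target.data.columns]
    if not shared and not extras:
        raise ValueError("no shared covariates between donor and target")
    # the membership model needs complete inputs; encode working copies
    # (fills learned on the donor side) and append scores to the originals
    from .survey import encode_missing_as_level, numeric_fill_values
    fill = numeric_fill_values(donor)
    donor_enc = encode_missing_as_level(donor, fill)
    target_enc = encode_missing_as_level(target, fill)

    def prep(table: SurveyTable) -> SurveyTable:
        # the membership model sees the shared predictors plus the extras;
        # everything else (including encoding artefacts) is set aside
        schema = []
        for v in table.schema:
            if v.name in extras and v.role != "predictor":
                schema.append(VariableSchema(v.name, v.kind, "predictor",
                                             v.levels, v.missing_code))
            elif v.role == "predictor" and v.name not in shared:
                schema.append(VariableSchema(v.name, v.kind, "aux",
                                             v.levels, v.missing_code))
            else:
                schema.append(v)
        return table.with_data(table.data, schema=schema)

    d_prep, t_prep = prep(donor_enc), prep(target_enc)
    enc = Encoder(drop_first=True).fit(d_prep)
    Xd, Xt = enc.transform(d_prep), enc.transform(t_prep)
    X = np.vstack([Xd, Xt])
    y = np.concatenate([np.ones(len(Xd)), np.zeros(len(Xt))])
    trace: dict = {}
    model = _fit_logistic(X, y, seed, trace)

    def append(table: SurveyTable, scores: np.ndarray) -> SurveyTable:
        df = table.data.copy()
        df["propensity_score"] = scores
        schema = [v for v in table.schema if v.name != "propensity_score"]
        schema.append(VariableSchema("propensity_score", "numeric", "predictor"))
        return table.with_data(df, schema=schema)

    return (append(donor, model.predict_proba(Xd)[:, 1]),
            append(target, model.predict_proba(Xt)[:, 1]))


# ---- dispatch ------------------------------------------------------------

def fit_imputer(train: SurveyTable, config: ImputerConfig) -> FittedImputer:
    """Fit the backend named by ``config.method`` (mi_logit is handled by
    :func:`run_mi`, which needs the target at fit time)."""
    if config.method == "logit":
        return fit_single_logit(train, config)
    if config.method == "knn":
        return fit_knn(train, config)
    if config.method == "rf":
        return fit_rf(train, config)
    raise ValueError(f"fit_imputer does not handle method {config.method!r}")
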