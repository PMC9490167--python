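"""Synthetic survey generator with a known hidden legal status.

Real donor/target pairs for this problem are survey microdata (a panel
survey carrying a legal-status proxy, and a large health survey lacking
one).  The generator emulates their statistical structure so that every
pipeline stage is testable with full knowledge of the truth:

* a foreign-born adult pool with categorical and numeric socio-demographic
  predictors (education, marital status, poverty, region of birth, English
  difficulty, ...) with nontrivial missingness;
* a hidden binary undocumented status driven by a logistic model in the
  predictors, with an optional pure-interaction (non-additive) term that an
  additive logit cannot represent but a tree ensemble can;
* logical-edit flags (citizenship, Medicare, veteran status, public
  benefits) structurally consistent with the status — no truly undocumented
  record ever carries an exclusion characteristic;
* truth-proxy components (citizenship, entry year, entered-as/adjusted-to
  LPR) constructed so the proxy recovers the hidden status exactly;
* two binary health outcomes (private insurance, poor/fair self-rated
  health) linked to status and covariates; documented citizens are markedly
  better insured, which reproduces the bias mechanism of logical-only
  imputation;
* donor-vs-target sampling differentials on observables, with weights equal
  to inverse selection probabilities.

All randomness flows from ``config.seed``; identical configs give
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .survey import SurveyTable, VariableSchema

# Effect maps: variable -> coefficient (numeric/binary) or
# variable -> {level: coefficient} (categorical).
EffectMap = Mapping[str, object]

_CATEGORICAL_LEVELS = {
    "education": ("less_hs", "hs", "some_college", "college"),
    "marital": ("married", "never_married", "divorced", "widowed"),
    "poverty": ("below_fpl", "below_2fpl", "above_2fpl"),
    "region_birth": ("latin_america", "asia", "europe", "africa", "other"),
    "region_residence": ("northeast", "midwest", "south", "west"),
    "occupation": ("service", "manual", "professional", "not_working"),
}

_CATEGORICAL_PROBS = {
    "education": (0.30, 0.30, 0.25, 0.15),
    "marital": (0.55, 0.30, 0.12, 0.03),
    "poverty": (0.20, 0.25, 0.55),
    "region_birth": (0.55, 0.25, 0.10, 0.05, 0.05),
    "region_residence": (0.18, 0.12, 0.35, 0.35),
    "occupation": (0.30, 0.30, 0.20, 0.20),
}

_DEFAULT_BETA: dict[str, object] = {
    "years_in_us": -0.10,
    "age": -0.035,
    "household_size": 0.05,
    "n_children": 0.05,
    "english_difficulty": 0.9,
    "hispanic": 0.6,
    "employed": -0.15,
    "spouse_citizen": -0.9,
    "medicaid": -0.2,
    "education": {"less_hs": 0.7, "hs": 0.25, "some_college": -0.2, "college": -0.7},
    "marital": {"married": -0.2, "never_married": 0.2},
    "poverty": {"below_fpl": 0.5, "below_2fpl": 0.25},
    "region_birth": {"latin_america": 0.5, "asia": -0.2, "europe": -0.6},
    "region_residence": {"west": 0.45, "south": 0.2, "northeast": -0.2},
    "occupation": {"manual": 0.4, "professional": -0.6},
}

_DEFAULT_OUTCOMES: dict[str, dict] = {
    # Documented citizens are markedly better insured; undocumented status
    # strongly depresses private coverage.
    "private_insurance": {
        "intercept": -0.8,
        "status": -0.8,
        "beta": {
            "employed": 0.8,
            "citizen": 1.8,
            "education": {"college": 0.9, "some_college": 0.4},
            "poverty": {"below_fpl": -0.6},
        },
    },
    # Weak "healthy migrant" pattern: undocumented slightly *less* likely
    # to report poor/fair health, net of age and poverty.
    "poor_fair_health": {
        "intercept": -3.3,
        "status": -0.25,
        "beta": {
            "age": 0.03,
            "poverty": {"below_fpl": 0.5},
        },
    },
}

# Strong-signal condition: large quantized effects concentrated on the
# discrete predictors, so almost every covariate cell is pure — the status
# is close to a deterministic function of observables and every method
# family (linear, distance- and tree-based) can in principle recover it.
_STRONG_BETA: dict[str, object] = {
    "english_difficulty": 8.0,
    "hispanic": 6.0,
    "spouse_citizen": -8.0,
    "employed": -2.0,
    "medicaid": -2.0,
    "education": {"less_hs": 6.0, "hs": 2.0, "some_college": -2.0,
                  "college": -6.0},
    "marital": {"married": -4.0, "never_married": 4.0},
    "poverty": {"below_fpl": 4.0, "below_2fpl": 2.0},
    "region_birth": {"latin_america": 4.0, "europe": -4.0, "asia": -2.0,
                     "africa": 2.0},
}

_DEFAULT_MISSING = {
    "marital": 0.02,
    "education": 0.03,
    "spouse_citizen": 0.25,
    "english_difficulty": 0.01,
    "years_in_us": 0.02,
    "medicaid": 0.02,
}

_DEFAULT_DIFFERENTIAL: dict[str, object] = {
    "english_difficulty": 0.8,
    "region_residence": {"west": 0.5, "south": 0.25},
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Full data-generating-process specification.

    ``prevalence`` is the share of truly undocumented records in the
    post-logical-edit pool (the population the statistical imputers see);
    the generator back-solves the population share from the expected
    exclusion-flag rate among documented records.  ``beta_status`` are
    per-predictor effects on the status logit, ``interaction_strength`` the
    coefficient of a pure two-way interaction (sign +1 when the pair agrees,
    -1 when it differs) that injects non-additivity, and ``signal_scale``
    a global multiplier on the status logit controlling class separation.
    """

    n_donor: int = 10_000
    n_target: int = 10_000
    prevalence: float = 0.33
    beta_status: EffectMap = field(default_factory=lambda: dict(_DEFAULT_BETA))
    interaction_strength: float = 2.0
    interaction_pair: tuple[str, str] = ("hispanic", "english_difficulty")
    signal_scale: float = 1.0
    missing_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MISSING))
    outcome_models: Mapping[str, dict] = field(
        default_factory=lambda: dict(_DEFAULT_OUTCOMES))
    sampling_differential: EffectMap = field(
        default_factory=lambda: dict(_DEFAULT_DIFFERENTIAL))
    survey_year: int = 2008
    entry_year_cutoff: int = 1981
    #: upper bound of the years-in-US distribution
    years_max: float = 40.0
    #: share of non-citizen documented records whose legality comes from
    #: pre-cutoff entry (the rest entered as / adjusted to LPR)
    doc_pre_cutoff_share: float = 0.2
    #: exclusion-flag probabilities depend on covariates (False gives the
    #: covariate-free null condition)
    flag_covariate_effects: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must lie in [0, 1]")
        if self.n_donor <= 0 or self.n_target <= 0:
            raise ValueError("n_donor and n_target must be positive")
        for name, rate in self.missing_rates.items():
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"missing rate for {name!r} must lie in [0, 1)")

    # Canonical study conditions --------------------------------------------
    @classmethod
    def default(cls, **kw) -> "SyntheticConfig":
        """Default conditions: ~33% pool prevalence, moderate signal, the
        non-additive interaction on, sampling differential on observables."""
        return cls(**kw)

    @classmethod
    def strong_signal(cls, **kw) -> "SyntheticConfig":
        """Well-separated status classes for parameter-recovery checks.

        Large quantized effects concentrated on the discrete predictors
        make almost every covariate cell pure, a balanced pool keeps
        precision comparable across classes, no information is removed by
        item non-response, and the entry-year bookkeeping never rewrites
        years-in-US (which would blur the status logit).
        """
        kw.setdefault("beta_status", dict(_STRONG_BETA))
        kw.setdefault("signal_scale", 2.0)
        kw.setdefault("interaction_strength", 0.0)
        kw.setdefault("prevalence", 0.5)
        kw.setdefault("sampling_differential", {})
        kw.setdefault("missing_rates", {})
        kw.setdefault("doc_pre_cutoff_share", 0.0)
        kw.setdefault("years_max", 26.0)
        return cls(**kw)

    @classmethod
    def null(cls, **kw) -> "SyntheticConfig":
        """No signal: status independent of every predictor; pool prevalence
        0.5 so threshold classifiers emit positives whose precision can be
        compared with the prevalence."""
        kw.setdefault("beta_status", {})
        kw.setdefault("interaction_strength", 0.0)
        kw.setdefault("prevalence", 0.5)
        kw.setdefault("sampling_differential", {})
        # remove every structural channel linking covariates to the status:
        # covariate-free exclusion flags, no pre-cutoff documented entries,
        # years-in-US bounded so the undocumented entry-year cap never binds
        kw.setdefault("flag_covariate_effects", False)
        kw.setdefault("doc_pre_cutoff_share", 0.0)
        kw.setdefault("years_max", 26.0)
        return cls(**kw)


# ---- helpers -------------------------------------------------------------

def _effect_eta(df: pd.DataFrame, effects: EffectMap) -> np.ndarray:
    """Linear predictor contribution of an effect map (no intercept)."""
    eta = np.zeros(len(df))
    for name, eff in effects.items():
        if isinstance(eff, Mapping):
            col = df[name].astype(str)
            for level, coef in eff.items():
                eta += float(coef) * (col == level).to_numpy(float)
        else:
            # missing cells contribute zero (relevant only for effects
            # evaluated after missingness injection, e.g. selection models)
            eta += float(eff) * np.nan_to_num(df[name].to_numpy(float))
    return eta


def _doc_flag_probs(df: pd.DataFrame, homogeneous: bool) -> dict[str, np.ndarray]:
    """Exclusion-characteristic probabilities *conditional on documented*.

    With ``homogeneous=True`` (the null condition) the probabilities are
    covariate-free constants, so pool membership carries no information
    about any predictor.
    """
    n = len(df)
    if homogeneous:
        return {
            "citizen": np.full(n, 0.43),
            "medicare": np.full(n, 0.05),
            "veteran": np.full(n, 0.03),
            "public_assistance": np.full(n, 0.12),
        }
    years = df["years_in_us"].to_numpy(float)
    age = df["age"].to_numpy(float)
    below_fpl = (df["poverty"] == "below_fpl").to_numpy(float)
    return {
        "citizen": expit(-1.5 + 0.10 * years),
        "medicare": np.where(age >= 65, 0.85, 0.02),
        "veteran": np.full(n, 0.03),
        "public_assistance": 0.08 + 0.17 * below_fpl,
    }


def _schema(year_col: bool = True) -> list[VariableSchema]:
    V = VariableSchema
    sch = [
        V("person_id", "categorical", "id"),
        V("weight", "numeric", "weight"),
        V("year", "numeric", "year"),
        V("true_undoc", "binary", "truth_component"),
        V("citizen", "binary", "truth_component"),
        V("entry_year", "numeric", "truth_component"),
        V("entered_as_lpr", "binary", "truth_component"),
        V("adjusted_to_lpr", "binary", "truth_component"),
        V("medicare", "binary", "logical_flag"),
        V("veteran", "binary", "logical_flag"),
        V("public_assistance", "binary", "logical_flag"),
        V("age", "numeric", "predictor"),
        V("years_in_us", "numeric", "predictor"),
        V("household_size", "numeric", "predictor"),
        V("n_children", "numeric", "predictor"),
        V("english_difficulty", "binary", "predictor"),
        V("hispanic", "binary", "predictor"),
        V("employed", "binary", "predictor"),
        V("spouse_citizen", "binary", "predictor"),
        V("medicaid", "binary", "predictor"),
    ]
    for name in ("education", "marital", "poverty", "region_birth"):
        sch.append(V(name, "categorical", "predictor",
                     levels=_CATEGORICAL_LEVELS[name]))
    for name in ("region_residence", "occupation"):
        sch.append(V(name, "categorical", "aux",
                     levels=_CATEGORICAL_LEVELS[name]))
    sch += [
        V("private_insurance", "binary", "outcome"),
        V("poor_fair_health", "binary", "outcome"),
    ]
    return sch


def generate_population(config: SyntheticConfig) -> SurveyTable:
    """Draw the full synthetic population (donor + target pool together).

    The status intercept is calibrated so the expected prevalence *among the
    post-logical-edit pool* equals ``config.prevalence``: if q is the mean
    probability of a documented record carrying at least one exclusion flag,
    the required population share is  p = pi (1 - q) / (1 - pi q).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n = config.n_donor + config.n_target
    df = pd.DataFrame(index=range(n))
    df["person_id"] = [f"p{i:07d}" for i in range(n)]
    df["age"] = np.clip(rng.normal(40, 12, n), 18, 85).round(1)
    df["years_in_us"] = np.clip(rng.exponential(12, n), 0.0,
                                config.years_max).round(1)
    df["household_size"] = 1.0 + rng.poisson(2.2, n)
    df["n_children"] = rng.poisson(1.0, n).astype(float)
    df["english_difficulty"] = rng.binomial(1, 0.35, n).astype(float)
    df["hispanic"] = rng.binomial(1, 0.45, n).astype(float)
    df["employed"] = rng.binomial(1, 0.70, n).astype(float)
    df["spouse_citizen"] = rng.binomial(1, 0.40, n).astype(float)
    df["medicaid"] = rng.binomial(1, 0.08, n).astype(float)
    for name in ("education", "marital", "poverty", "region_birth",
                 "region_residence", "occupation"):
        levels = _CATEGORICAL_LEVELS[name]
        df[name] = rng.choice(levels, size=n, p=_CATEGORICAL_PROBS[name])

    # Status model: additive logit plus optional pure interaction.
    eta = _effect_eta(df, config.beta_status)
    if config.interaction_strength:
        a, b = config.interaction_pair
        agree = (df[a].to_numpy(float) == df[b].to_numpy(float)).astype(float)
        eta += config.interaction_strength * (2.0 * agree - 1.0)
    eta *= config.signal_scale

    flag_p = _doc_flag_probs(df, homogeneous=not config.flag_covariate_effects)
    q = 1.0 - np.prod([1.0 - p for p in flag_p.values()], axis=0)
    pi = config.prevalence

    def pool_prev(c: float) -> float:
        # expected pool prevalence: undocumented never carry a flag, a
        # documented record stays in the pool with probability 1 - q_i
        p = expit(eta + c)
        return float(p.sum() / (p + (1.0 - p) * (1.0 - q)).sum())

    if pi <= 0.0:
        status = np.zeros(n)
    elif pi >= 1.0:
        status = np.ones(n)
    else:
        b0 = brentq(lambda c: pool_prev(c) - pi, -60, 60)
        status = rng.binomial(1, expit(eta + b0)).astype(float)
    df["true_undoc"] = status
    undoc = status == 1

    # Truth components and exclusion flags, consistent with the status.
    year = config.survey_year
    cutoff = config.entry_year_cutoff
    citizen = np.zeros(n)
    entered = np.zeros(n)
    adjusted = np.zeros(n)
    for name in ("medicare", "veteran", "public_assistance"):
        df[name] = 0.0
    doc = ~undoc
    n_doc = int(doc.sum())
    if n_doc:
        citizen[doc] = rng.binomial(1, flag_p["citizen"][doc])
        for name in ("medicare", "veteran", "public_assistance"):
            df.loc[doc, name] = rng.binomial(1, flag_p[name][doc]).astype(float)
        # Non-citizen documented records hold LPR status (entered as LPR or
        # adjusted) or entered before the cutoff — so the proxy is exact.
        noncit = doc & (citizen == 0)
        c = config.doc_pre_cutoff_share
        path = rng.choice(3, size=int(noncit.sum()),
                          p=(0.625 * (1 - c), 0.375 * (1 - c), c))
        idx = np.flatnonzero(noncit)
        entered[idx[path == 0]] = 1.0
        adjusted[idx[path == 1]] = 1.0
        pre = idx[path == 2]
        df.loc[pre, "years_in_us"] = (
            year - cutoff + rng.uniform(1.0, 15.0, len(pre))).round(1)
    if undoc.any():
        max_years = float(year - cutoff - 1)
        yrs = df.loc[undoc, "years_in_us"].to_numpy(float)
        df.loc[undoc, "years_in_us"] = np.minimum(yrs, max_years)
    df["citizen"] = citizen
    df["entered_as_lpr"] = entered
    df["adjusted_to_lpr"] = adjusted
    df["entry_year"] = (year - df["years_in_us"].to_numpy(float)).round(1)

    # Outcomes (generated from complete covariates, before missingness).
    for name, model in config.outcome_models.items():
        o_eta = (float(model.get("intercept", 0.0))
                 + float(model.get("status", 0.0)) * status
                 + _effect_eta(df, model.get("beta", {})))
        df[name] = rng.binomial(1, expit(o_eta)).astype(float)

    # MCAR missingness on predictors (missing-as-category downstream).
    for name, rate in config.missing_rates.items():
        if rate > 0:
            mask = rng.random(n) < rate
            df.loc[mask, name] = np.nan

    df["weight"] = 1.0
    df["year"] = float(year)
    schema = _schema()
    df = df[[v.name for v in schema]]
    return SurveyTable(data=df, schema=schema, provenance="synthetic-population")


def split_donor_target(population: SurveyTable,
                       config: SyntheticConfig) -> tuple[SurveyTable, SurveyTable]:
    """Partition the population into disjoint donor and target samples.

    Target records are sampled without replacement with probability
    proportional to ``exp(differential . x)``; the donor sample is drawn
    uniformly from the remainder.  With a zero differential both samples are
    exchangeable draws from one distribution.  Target weights are inverse
    relative selection probabilities (normalized to mean one) so weighted
    target summaries estimate population quantities; truth components stay
    in the target table but are flagged masked-for-analysis.
    """
    n = len(population.data)
    if config.n_donor + config.n_target > n:
        raise ValueError(
            f"requested donor+target sizes ({config.n_donor}+{config.n_target}) "
            f"exceed population size {n}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    logit_shift = _effect_eta(population.data, config.sampling_differential)
    w = np.exp(logit_shift - logit_shift.max())
    p = w / w.sum()
    target_idx = rng.choice(n, size=config.n_target, replace=False, p=p)
    rest = np.setdiff1d(np.arange(n), target_idx)
    donor_idx = np.sort(rng.choice(rest, size=config.n_donor, replace=False))
    target_idx = np.sort(target_idx)

    donor_df = population.data.iloc[donor_idx].reset_index(drop=True).copy()
    target_df = population.data.iloc[target_idx].reset_index(drop=True).copy()
    inv = 1.0 / w[target_idx]
    target_df["weight"] = inv / inv.mean()
    donor = SurveyTable(data=donor_df, schema=list(population.schema),
                        provenance="synthetic-donor")
    target = SurveyTable(
        data=target_df, schema=list(population.schema),
        provenance="synthetic-target",
        masked=("true_undoc", "entered_as_lpr", "adjusted_to_lpr"))
    return donor, target


def generate_donor_target(config: SyntheticConfig
                          ) -> tuple[SurveyTable, SurveyTable]:
    """Convenience: generate the population and split it in one call."""
    return split_donor_target(generate_population(config), config)
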