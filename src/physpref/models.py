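"""Per-scenario logistic models with HC3-robust Wald inference, plus the
simulation-based power-sensitivity check.

Each scenario gets a prespecified multivariable logistic regression for the
any-preference outcome (and, among preferrers, for the female-vs-male
direction) with a fixed predictor set: patient gender, age group, disease
category, four symptom-context flags, first-visit status, prior
specific-gender request, and immigration background.  Categorical predictors
are dummy-coded against fixed reference levels (female gender, age 20-39,
disease "other").

Inference is Wald with an HC3 sandwich covariance: for a binary-outcome GLM
this is the score-based sandwich whose bread is the inverse expected
information at the MLE and whose meat inflates each observation's score
contribution x_i (y_i - mu_i) by (1 - h_ii)^(-1) before squaring, with
leverage h_ii taken from the weighted hat matrix
W^(1/2) X (X'WX)^(-1) X' W^(1/2), W = mu(1 - mu).  Fitting goes through
statsmodels (IRLS, tolerance 1e-8, max 100 iterations); the HC3 sandwich is
computed here at the MLE (:func:`hc3_sandwich` — statsmodels' GLM robust
covariances omit the leverage adjustment), and the critical value is the
fixed normal quantile 1.959964.
Separation is reported, never repaired: fits with boundary probabilities or
runaway coefficients are returned flagged, with no inference values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from scipy.stats import norm

from . import study
from .codebook import Codebook, default_codebook
from .cohort import CohortTable, impute_covariates

Z_CRIT = 1.959964  # two-sided 95% normal quantile, fixed (Wald inference)

ANY_PREFERENCE = "any_preference"
DIRECTION_FEMALE = "direction_female"

#: Prespecified core predictor set, in reporting order.
DEFAULT_PREDICTORS = (
    "gender",
    "age_group",
    "disease_category",
    "limits_activities",
    "worrying",
    "painful",
    "embarrassing",
    "first_visit",
    "prior_request",
    "immigration",
)

#: Extra adjustment variables of the expanded model.
EXPANDED_EXTRAS = ("education", "religion", "relationship_status", "gp_status")


class DegenerateOutcomeError(ValueError):
    """Outcome constant after exclusions — the model is unestimable."""


class UnderIdentifiedError(ValueError):
    """Fewer usable observations than parameters."""


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome kind, predictor list, covariance type."""

    outcome: str = ANY_PREFERENCE
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    expanded: bool = False
    covariance: str = "HC3"

    def __post_init__(self) -> None:
        if self.outcome not in (ANY_PREFERENCE, DIRECTION_FEMALE):
            raise ValueError(f"unknown outcome kind {self.outcome!r}")
        if self.covariance not in ("HC3", "conventional"):
            raise ValueError(f"unknown covariance {self.covariance!r}")

    @property
    def all_predictors(self) -> tuple[str, ...]:
        if self.expanded:
            return self.predictors + EXPANDED_EXTRAS
        return self.predictors


@dataclass
class RegressionResult:
    """Odds ratios with robust intervals for one fitted scenario model."""

    scenario: str
    outcome: str
    #: index: term; columns: or_, ci_low, ci_high, se_log_or, p
    table: pd.DataFrame
    n_obs: int
    n_excluded: int
    exclusions: dict[str, int]
    converged: bool
    separation: bool
    llf: float | None

    @property
    def valid_inference(self) -> bool:
        return self.converged and not self.separation


@dataclass
class PowerResult:
    """Simulated power of the univariable logistic Wald test over an OR grid."""

    n: int
    baseline: float
    alpha: float
    or_grid: tuple[float, ...]
    power: tuple[float, ...]
    mc_se: tuple[float, ...]
    replicates: int
    seed: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"odds_ratio": self.or_grid, "power": self.power, "mc_se": self.mc_se}
        )


def term_name(variable: str, level: str) -> str:
    return f"{variable}[{level}]"


def build_design(
    cohort: CohortTable,
    scenario: str,
    spec: ModelSpec | None = None,
    codebook: Codebook | None = None,
) -> tuple[pd.DataFrame, pd.Series, dict[str, int]]:
    """Dummy-coded design matrix, outcome vector, and exclusion tally.

    Exclusions, each logged with a reason: gender-diverse respondents (too few
    for inference, analysed descriptively only), missing scenario responses,
    and — for the directional outcome — respondents without any preference.
    Column order is deterministic: intercept, then each predictor's
    non-reference levels in codebook order.
    """
    spec = spec or ModelSpec()
    codebook = codebook or default_codebook()
    data = cohort.data
    exclusions: dict[str, int] = {}

    keep = pd.Series(True, index=data.index)
    diverse = data["gender"] == "diverse"
    if diverse.any():
        exclusions["gender_diverse"] = int(diverse.sum())
        keep &= ~diverse
    pref = data[study.pref_column(scenario)]
    missing_pref = pref.isna()
    if (missing_pref & keep).any():
        exclusions["missing_scenario_response"] = int((missing_pref & keep).sum())
        keep &= ~missing_pref
    if spec.outcome == DIRECTION_FEMALE:
        non_pref = pref == "none"
        exclusions["no_preference"] = int((non_pref & keep).sum())
        keep &= ~non_pref

    sub = data.loc[keep]
    if sub.empty:
        raise UnderIdentifiedError("no records left after exclusions")

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(sub))}
    for name in spec.all_predictors:
        var = codebook[name]
        col = sub[name]
        if col.isna().any() or (
            var.no_response is not None and (col == var.no_response).any()
        ):
            raise ValueError(
                f"{name}: unimputed missing/no-response values; apply "
                "impute_covariates first"
            )
        for level in var.informative_categories:
            if level == var.reference:
                continue
            if name == "gender" and level == "diverse":
                continue  # excluded rows above; no column
            cols[term_name(name, level)] = (col == level).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=sub.index)

    if spec.outcome == ANY_PREFERENCE:
        y = sub[study.pref_column(scenario)].isin(["female", "male"]).astype(float)
    else:
        y = (sub[study.pref_column(scenario)] == "female").astype(float)

    if y.nunique() < 2:
        raise DegenerateOutcomeError(
            f"{scenario}/{spec.outcome}: outcome constant in the analysis set"
        )
    if len(y) <= X.shape[1]:
        raise UnderIdentifiedError(
            f"{scenario}/{spec.outcome}: {len(y)} records for {X.shape[1]} parameters"
        )
    return X, y, exclusions


def _fit(
    X: pd.DataFrame, y: pd.Series, covariance: str
) -> tuple[pd.DataFrame, bool, bool, float]:
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-8)
    converged = bool(getattr(res, "converged", True))
    mu = np.asarray(res.fittedvalues)
    separation = bool(
        (mu < 1e-8).any() or (mu > 1 - 1e-8).any() or (np.abs(res.params) > 15).any()
    )
    params = np.asarray(res.params)
    if covariance == "HC3" and not separation:
        cov = hc3_sandwich(X.to_numpy(), np.asarray(y, dtype=float), params)
        se = np.sqrt(np.diag(cov))
    else:
        se = np.asarray(res.bse)
    z = params / se
    table = pd.DataFrame(
        {
            "or_": np.exp(params),
            "ci_low": np.exp(params - Z_CRIT * se),
            "ci_high": np.exp(params + Z_CRIT * se),
            "se_log_or": se,
            "p": 2 * norm.sf(np.abs(z)),
        },
        index=X.columns,
    )
    return table, converged, separation, float(res.llf)


def _fit_scenario(
    cohort: CohortTable,
    scenario: str,
    spec: ModelSpec,
    codebook: Codebook,
) -> RegressionResult:
    cohort = impute_covariates(cohort, codebook)
    X, y, exclusions = build_design(cohort, scenario, spec, codebook)
    table, converged, separation, llf = _fit(X, y, spec.covariance)
    if not converged or separation:
        # flagged result: no inference values reported
        table = pd.DataFrame(
            np.nan, index=table.index, columns=table.columns
        )
        llf = None
    return RegressionResult(
        scenario=scenario,
        outcome=spec.outcome,
        table=table,
        n_obs=len(y),
        n_excluded=sum(exclusions.values()),
        exclusions=exclusions,
        converged=converged,
        separation=separation,
        llf=llf,
    )


def fit_any_preference(
    cohort: CohortTable,
    scenario: str,
    spec: ModelSpec | None = None,
    codebook: Codebook | None = None,
) -> RegressionResult:
    """Fit the any-preference logistic model for one scenario.

    Covariates are mode-imputed (idempotent) before the design is built.
    """
    spec = spec or ModelSpec()
    if spec.outcome != ANY_PREFERENCE:
        spec = replace(spec, outcome=ANY_PREFERENCE)
    return _fit_scenario(cohort, scenario, spec, codebook or default_codebook())


def fit_direction(
    cohort: CohortTable,
    scenario: str,
    spec: ModelSpec | None = None,
    codebook: Codebook | None = None,
) -> RegressionResult:
    """Fit the female-vs-male direction model among preferrers."""
    spec = spec or ModelSpec()
    if spec.outcome != DIRECTION_FEMALE:
        spec = replace(spec, outcome=DIRECTION_FEMALE)
    return _fit_scenario(cohort, scenario, spec, codebook or default_codebook())


def power_sensitivity(
    n: int = study.N_RESPONDENTS,
    baseline: float = 0.4,
    or_grid: tuple[float, ...] = (1.0, 1.2, 1.5, 1.8, 2.0, 2.5, 3.0),
    alpha: float = 0.05,
    replicates: int = 1000,
    seed: int = 0,
) -> PowerResult:
    """Simulated power of a univariable logistic Wald test at sample size n.

    Design: a balanced binary exposure (P = 0.5); the unexposed outcome
    probability is ``baseline`` and the exposed probability is shifted by
    log(OR) on the logit scale.  For a single binary predictor the logistic
    MLE is the saturated 2x2 fit, so the slope is the empirical log odds
    ratio and its Wald standard error is sqrt(1/a + 1/b + 1/c + 1/d); power is
    the fraction of replicates whose two-sided Wald p falls below alpha
    (replicates with an empty cell never reject).  Vectorised across
    replicates; deterministic under a fixed seed.
    """
    if not 0.0 < baseline < 1.0:
        raise ValueError("baseline must be in (0, 1)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if replicates < 100:
        raise ValueError("need at least 100 replicates")
    if len(or_grid) == 0 or any(or_ <= 0 for or_ in or_grid):
        raise ValueError("or_grid must be non-empty with positive odds ratios")

    rng = np.random.default_rng(seed)
    powers, ses = [], []
    for or_ in or_grid:
        p1 = float(expit(logit(baseline) + np.log(or_)))
        n_exposed = rng.binomial(n, 0.5, size=replicates)
        n_unexposed = n - n_exposed
        a = rng.binomial(n_exposed, p1)  # exposed events
        c = rng.binomial(n_unexposed, baseline)  # unexposed events
        b = n_exposed - a
        d = n_unexposed - c
        cells = np.stack([a, b, c, d], axis=0).astype(float)
        ok = (cells > 0).all(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.log(a * d / (b * c))
            se = np.sqrt((1.0 / cells).sum(axis=0))
        reject = ok & (np.abs(beta) / se > norm.ppf(1 - alpha / 2))
        p_hat = float(reject.mean())
        powers.append(p_hat)
        ses.append(float(np.sqrt(p_hat * (1 - p_hat) / replicates)))
    return PowerResult(
        n=n,
        baseline=baseline,
        alpha=alpha,
        or_grid=tuple(or_grid),
        power=tuple(powers),
        mc_se=tuple(ses),
        replicates=replicates,
        seed=seed,
    )


def hc3_sandwich(X: np.ndarray, y: np.ndarray, params: np.ndarray) -> np.ndarray:
    """HC3 sandwich covariance for a logistic fit at the MLE ``params``.

    Bread: inverse expected information (X'WX)^(-1), W = mu(1-mu); meat: sum of
    outer products of the leverage-inflated scores x_i (y_i - mu_i)/(1 - h_ii),
    with h_ii = w_i x_i' (X'WX)^(-1) x_i from the weighted hat matrix.  This is
    the standard HC3 generalization to binary-outcome GLMs (the one R's
    ``sandwich::vcovHC(type = "HC3")`` computes for ``glm`` fits).
    """
    X = np.asarray(X, dtype=float)
    mu = expit(X @ params)
    w = mu * (1 - mu)
    info = X.T @ (w[:, None] * X)
    bread = np.linalg.inv(info)
    h = w * np.einsum("ij,jk,ik->i", X, bread, X)
    u = X * ((y - mu) / (1 - h))[:, None]
    meat = u.T @ u
    return bread @ meat @ bread
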