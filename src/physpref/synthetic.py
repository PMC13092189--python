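"""Seeded synthetic cohorts calibrated to the reference survey's margins.

The study's respondent-level data were never deposited, so every downstream
stage is exercised on synthetic cohorts that reproduce what the study printed:
the demographic/contextual marginals, the per-scenario any-preference
prevalence and female-direction share, and the sparse covariate missingness.
Preference outcomes follow a per-scenario logistic model

    logit P(any preference) = intercept + sum of effect log-ORs over the
                              respondent's active predictor levels,

with direction among preferrers drawn Bernoulli(p_dir).  All effect log-ORs
default to zero, so the default configuration is the *null* generator whose
marginal prevalence equals expit(intercept); planting a nonzero effect turns
it into the parameter-recovery / power test-bed.

Covariates are drawn independently (only marginals were published); scenario
outcomes are drawn independently across the five scenarios (no cross-scenario
concordance was reported).  Both simplifications are documented in the methods
note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import study
from .codebook import INAPPLICABLE, Codebook, default_codebook
from .cohort import CohortTable, validate_cohort

_PROB_TOL = 1e-9


@dataclass
class ScenarioModel:
    """Generative logistic model for one scenario's any-preference outcome."""

    intercept: float
    #: term -> log odds ratio, term spelled "variable=level", e.g. "worrying=yes"
    effects: dict[str, float] = field(default_factory=dict)


@dataclass
class GeneratorConfig:
    """Full parameterisation of the synthetic cohort generator."""

    n: int
    covariate_marginals: dict[str, dict[str, float]]
    scenario_models: dict[str, ScenarioModel]
    direction_probs: dict[str, float]
    missingness_rates: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    #: optional joint sampler hook: (rng, n) -> DataFrame of covariate columns;
    #: ships unused (covariates are independent by default).
    joint_sampler: Callable[[np.random.Generator, int], pd.DataFrame] | None = None

    def validate(self, codebook: Codebook) -> None:
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        needed = {v.name for v in codebook.covariates}
        if self.joint_sampler is None and needed - set(self.covariate_marginals):
            raise ValueError(
                f"marginals missing for {sorted(needed - set(self.covariate_marginals))}"
            )
        for name, marg in self.covariate_marginals.items():
            probs = np.asarray(list(marg.values()), dtype=float)
            if (probs < -_PROB_TOL).any() or (probs > 1 + _PROB_TOL).any():
                raise ValueError(f"{name}: probabilities outside [0, 1]")
            if abs(probs.sum() - 1.0) > 1e-6:
                raise ValueError(f"{name}: probabilities sum to {probs.sum()}, not 1")
            unknown = set(marg) - set(codebook[name].categories)
            if unknown:
                raise ValueError(f"{name}: unknown categories {sorted(unknown)}")
        if set(self.scenario_models) != set(study.SCENARIOS):
            raise ValueError("scenario_models must cover all five scenarios")
        if set(self.direction_probs) != set(study.SCENARIOS):
            raise ValueError("direction_probs must cover all five scenarios")
        for s, p in self.direction_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"direction_probs[{s}] outside [0, 1]")
        for s, model in self.scenario_models.items():
            for term in model.effects:
                var, _, level = term.partition("=")
                if var not in codebook or level not in codebook[var].categories:
                    raise ValueError(f"{s}: unknown effect term {term!r}")
                if level == codebook[var].reference:
                    raise ValueError(f"{s}: effect on reference level {term!r}")
        for name, rate in self.missingness_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness rate for {name} outside [0, 1]")


def _proportions(counts: Mapping[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def default_config(seed: int = 0) -> GeneratorConfig:
    """Generator calibrated to the reference survey (n = 324).

    Covariate marginals are the published valid-percentage vectors; scenario
    intercepts are the logits of the published any-preference prevalences (so
    with all effects at zero the marginal prevalence matches); direction
    probabilities are the published female shares among preferrers; covariate
    missingness matches the published item-nonresponse counts.  The
    relationship-status and GP-status margins were not published: defaults use
    a uniform two-category split (non-survey placeholder values).
    """
    marginals = {
        "gender": _proportions(study.GENDER_COUNTS),
        "age_group": _proportions(study.AGE_COUNTS),
        "disease_category": _proportions(study.DISEASE_COUNTS),
        "education": _proportions(study.EDUCATION_COUNTS),
        "religion": _proportions(study.RELIGION_COUNTS),
        "relationship_status": {"partnered": 0.5, "single": 0.5},
        "gp_status": {"has_gp": 0.5, "no_gp": 0.5},
        "immigration": _proportions(study.IMMIGRATION_COUNTS),
        "first_visit": _proportions(study.FIRST_VISIT_COUNTS),
        "prior_request": _proportions(study.PRIOR_REQUEST_COUNTS),
        "limits_activities": _proportions(study.LIMITS_COUNTS),
        "worrying": _proportions(study.WORRYING_COUNTS),
        "painful": _proportions(study.PAINFUL_COUNTS),
        "embarrassing": _proportions(study.EMBARRASSING_COUNTS),
    }
    scenario_models = {
        s: ScenarioModel(intercept=float(logit(study.scenario_prevalence(s))))
        for s in study.SCENARIOS
    }
    direction_probs = {s: study.scenario_direction(s) for s in study.SCENARIOS}
    n = study.N_RESPONDENTS
    missingness = {
        "gender": study.GENDER_MISSING / n,
        "age_group": study.AGE_MISSING / n,
        "disease_category": study.DISEASE_MISSING / n,
    }
    return GeneratorConfig(
        n=n,
        covariate_marginals=marginals,
        scenario_models=scenario_models,
        direction_probs=direction_probs,
        missingness_rates=missingness,
        seed=seed,
    )


def _draw_categorical(
    rng: np.random.Generator, marg: Mapping[str, float], n: int
) -> np.ndarray:
    cats = np.array(list(marg), dtype=object)
    probs = np.asarray(list(marg.values()), dtype=float)
    probs = probs / probs.sum()
    return rng.choice(cats, size=n, p=probs)


def _active_term_mask(data: pd.DataFrame, term: str) -> np.ndarray:
    var, _, level = term.partition("=")
    return (data[var] == level).to_numpy()


def generate(
    config: GeneratorConfig, codebook: Codebook | None = None
) -> CohortTable:
    """Draw a synthetic cohort; bit-identical for a fixed config + seed."""
    codebook = codebook or default_codebook()
    config.validate(codebook)
    rng = np.random.default_rng(config.seed)
    n = config.n

    if config.joint_sampler is not None:
        data = config.joint_sampler(rng, n).copy()
    else:
        data = pd.DataFrame(
            {
                name: _draw_categorical(rng, marg, n)
                for name, marg in config.covariate_marginals.items()
            }
        )

    # skip-ruled items: populated only for return visitors.  No marginal was
    # published for either item; both use a 0.5 placeholder split.
    return_visit = (data["first_visit"] == "no").to_numpy()
    last_gender = np.where(rng.random(n) < 0.5, "female", "male")
    data["last_physician_gender"] = np.where(return_visit, last_gender, INAPPLICABLE)
    advice = np.where(rng.random(n) < 0.5, "yes", "no")
    data["advice_better_other_gender"] = np.where(return_visit, advice, INAPPLICABLE)

    # scenario outcomes: logistic any-preference, Bernoulli direction
    for s in study.SCENARIOS:
        model = config.scenario_models[s]
        lp = np.full(n, model.intercept, dtype=float)
        for term, beta in model.effects.items():
            lp += beta * _active_term_mask(data, term)
        any_pref = rng.random(n) < expit(lp)
        female = rng.random(n) < config.direction_probs[s]
        data[study.pref_column(s)] = np.where(
            any_pref, np.where(female, "female", "male"), "none"
        )

    data = data[list(codebook.names)].astype(object)
    cohort = CohortTable(
        data, provenance=f"synthetic:seed={config.seed},n={n}", seed=config.seed
    )
    if config.missingness_rates:
        cohort = _mask(cohort, config.missingness_rates, rng, codebook)
    validate_cohort(cohort.data, codebook)
    return cohort


def _mask(
    cohort: CohortTable,
    rates: Mapping[str, float],
    rng: np.random.Generator,
    codebook: Codebook,
) -> CohortTable:
    data = cohort.data.copy()
    for name, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missingness rate for {name} outside [0, 1]")
        col = data[name]
        eligible = (col != INAPPLICABLE).to_numpy() & col.notna().to_numpy()
        hit = (rng.random(len(data)) < rate) & eligible
        data.loc[hit, name] = pd.NA
    return CohortTable(data, cohort.provenance, cohort.seed)


def inject_missingness(
    cohort: CohortTable,
    rates: Mapping[str, float],
    seed: int,
    codebook: Codebook | None = None,
) -> CohortTable:
    """Independently mask eligible cells at per-variable rates.

    Structural inapplicability is never altered; deterministic under a fixed
    seed; returns a new table.
    """
    codebook = codebook or default_codebook()
    return _mask(cohort, rates, np.random.default_rng(seed), codebook)


def cohort_from_scenario_counts(
    counts: Mapping[str, tuple[int, int]] | None = None,
    n: int | None = None,
    codebook: Codebook | None = None,
) -> CohortTable:
    """Deterministic cohort carrying exact per-scenario preference counts.

    Builds a synthetic stand-in for the study's (undeposited) respondent table
    whose scenario responses reproduce the requested counts exactly: for each
    scenario the first ``n_any`` respondents are preferrers and the first
    ``n_female`` of those choose a female physician.  Covariates are drawn
    uniformly over categories from a hard-wired seed (so every stratum is
    populated without collinear columns, and the fixture is identical across
    runs); exactly one respondent is gender-diverse, matching the study's
    descriptive table.  Used as the exact-count fixture behind the
    summary-table twin.
    """
    codebook = codebook or default_codebook()
    counts = dict(counts or study.SCENARIO_COUNTS)
    if n is None:
        n = study.N_RESPONDENTS
    rng = np.random.default_rng(180_324)  # fixture constant, not a dial
    data = {}
    for var in codebook.covariates:
        cats = np.array(var.informative_categories, dtype=object)
        if var.name == "gender":
            col = rng.choice(np.array(["female", "male"], dtype=object), size=n)
            if n:
                col[n - 1] = "diverse"
            data[var.name] = col
        else:
            data[var.name] = rng.choice(cats, size=n)
    frame = pd.DataFrame(data)
    return_visit = (frame["first_visit"] == "no").to_numpy()
    for var in codebook.conditional:
        cats = np.array(var.informative_categories, dtype=object)
        fill = rng.choice(cats, size=n)
        frame[var.name] = np.where(return_visit, fill, INAPPLICABLE)
    for s in study.SCENARIOS:
        n_any, n_female = counts[s]
        if not 0 <= n_female <= n_any <= n:
            raise ValueError(f"{s}: inconsistent counts ({n_any}, {n_female})")
        col = np.full(n, "none", dtype=object)
        col[:n_female] = "female"
        col[n_female:n_any] = "male"
        frame[study.pref_column(s)] = col
    frame = frame[list(codebook.names)]
    validate_cohort(frame, codebook)
    return CohortTable(frame, provenance="synthetic:exact-counts")
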