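"""Operational preference-fulfilment model under a clinic staffing mix.

A clinic session has a female-physician share f and male share 1 - f, with
capacity assumed sufficient so that matching depends only on the gender mix.
A preferrer requesting a female physician is matched with probability f, one
requesting a male physician with probability 1 - f, independently per patient.
With p0 the female-direction share among preferrers, the expected fulfilment
rate among preferrers is the closed form

    E[fulfilment] = p0 * f + (1 - p0) * (1 - f),

affine in f with slope 2*p0 - 1 (flat when directions are balanced).  The
Monte Carlo simulator verifies this at the session level: each simulated
patient is a preferrer with the scenario's any-preference prevalence, and the
outcome is matched preferrers / preferrers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import check_proportion
from .summary import ScenarioSummary


@dataclass(frozen=True)
class StaffingScenario:
    """A clinic session's physician gender mix."""

    f: float

    def __post_init__(self) -> None:
        check_proportion(self.f, "f")


@dataclass
class FulfilmentEstimate:
    """Closed-form and simulated fulfilment for one (scenario, f) cell."""

    scenario: str
    f: float
    p0: float
    prevalence: float
    closed_form: float
    simulated_mean: float | None
    simulated_sd: float | None
    n_patients: int
    n_runs: int
    seed: int
    #: True when at least one run drew zero preferrers (outcome undefined
    #: for that run; such runs are dropped from the mean).
    zero_preferrer_runs: int = 0


def expected_fulfilment(p0: float, f: float) -> float:
    """Closed-form expected fulfilment among preferrers."""
    check_proportion(p0, "p0")
    check_proportion(f, "f")
    return p0 * f + (1 - p0) * (1 - f)


def _run_sessions(
    prevalence: float,
    p0: float,
    f: float,
    n_patients: int,
    n_runs: int,
    rng: np.random.Generator,
) -> tuple[list[float], int]:
    """Per-run fulfilment fractions; zero-preferrer runs are returned as a count."""
    outcomes: list[float] = []
    zero_runs = 0
    u = rng.random((n_runs, 3, n_patients))
    for r in range(n_runs):
        is_pref = u[r, 0] < prevalence
        n_pref = int(is_pref.sum())
        if n_pref == 0:
            zero_runs += 1
            continue
        wants_female = u[r, 1, is_pref] < p0
        matched = np.where(wants_female, u[r, 2, is_pref] < f, u[r, 2, is_pref] < 1 - f)
        outcomes.append(float(matched.sum()) / n_pref)
    return outcomes, zero_runs


def simulate_session(
    prevalence: float,
    p0: float,
    f: float,
    n_patients: int = 10_000,
    seed: int = 0,
    scenario: str = "unnamed",
) -> FulfilmentEstimate:
    """One Monte Carlo clinic session (default 10,000 patients, fixed seed).

    Each patient is independently a preferrer with probability ``prevalence``;
    preferrers request a female physician with probability ``p0`` and are
    matched with probability f (female request) or 1 - f (male request).  The
    outcome is the fraction of preferrers matched; a session that happens to
    draw zero preferrers has no defined outcome and is returned flagged.
    """
    check_proportion(prevalence, "prevalence")
    check_proportion(p0, "p0")
    check_proportion(f, "f")
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    outcomes, zero_runs = _run_sessions(prevalence, p0, f, n_patients, 1, rng)
    value = outcomes[0] if outcomes else None
    return FulfilmentEstimate(
        scenario=scenario,
        f=f,
        p0=p0,
        prevalence=prevalence,
        closed_form=expected_fulfilment(p0, f),
        simulated_mean=value,
        simulated_sd=None,
        n_patients=n_patients,
        n_runs=1,
        seed=seed,
        zero_preferrer_runs=zero_runs,
    )


#: Representative staffing mixes of the published fulfilment table.
DEFAULT_F_GRID = (0.2, 0.3, 0.4, 0.5, 0.6)
#: Finer grid used for the fulfilment-vs-f curve export.
CURVE_F_GRID = tuple(round(0.1 + 0.05 * i, 2) for i in range(17))


def cell_seed(base_seed: int, scenario_index: int, f_index: int) -> int:
    """Deterministic per-cell seed from (base seed, scenario index, f index)."""
    ss = np.random.SeedSequence([int(base_seed), int(scenario_index), int(f_index)])
    return int(ss.generate_state(1)[0])


def fulfilment_grid(
    summaries: list[ScenarioSummary],
    f_values: tuple[float, ...] = DEFAULT_F_GRID,
    n_patients: int = 10_000,
    n_runs: int = 1,
    seed: int = 0,
) -> list[FulfilmentEstimate]:
    """Closed form and simulation side by side over scenarios x staffing mixes.

    ``p0`` and prevalence come from each scenario's summary; every cell gets
    its own deterministic seed so the grid is reproducible cell-by-cell.
    Scenarios without any preferrer (p0 undefined) are skipped.
    """
    if len(f_values) == 0:
        raise ValueError("empty staffing-mix grid")
    estimates: list[FulfilmentEstimate] = []
    for s_idx, summ in enumerate(summaries):
        if summ.n_any == 0 or summ.n_valid == 0:
            continue
        p0 = summ.n_female_dir / summ.n_any
        prevalence = summ.n_any / summ.n_valid
        for f_idx, f in enumerate(f_values):
            cseed = cell_seed(seed, s_idx, f_idx)
            rng = np.random.default_rng(cseed)
            outcomes, zero_runs = _run_sessions(
                prevalence, p0, f, n_patients, n_runs, rng
            )
            if outcomes:
                mean = float(np.mean(outcomes))
                sd = float(np.std(outcomes, ddof=1)) if len(outcomes) > 1 else None
            else:
                mean, sd = None, None
            estimates.append(
                FulfilmentEstimate(
                    scenario=summ.scenario,
                    f=f,
                    p0=p0,
                    prevalence=prevalence,
                    closed_form=expected_fulfilment(p0, f),
                    simulated_mean=mean,
                    simulated_sd=sd,
                    n_patients=n_patients,
                    n_runs=n_runs,
                    seed=cseed,
                    zero_preferrer_runs=zero_runs,
                )
            )
    return estimates


def grid_long_frame(estimates: list[FulfilmentEstimate]) -> pd.DataFrame:
    """Long-format export: one row per (scenario, f) cell."""
    return pd.DataFrame(
        {
            "scenario": [e.scenario for e in estimates],
            "f": [e.f for e in estimates],
            "p0": [e.p0 for e in estimates],
            "prevalence": [e.prevalence for e in estimates],
            "closed_form": [e.closed_form for e in estimates],
            "simulated_mean": [e.simulated_mean for e in estimates],
            "simulated_sd": [e.simulated_sd for e in estimates],
            "n_patients": [e.n_patients for e in estimates],
            "n_runs": [e.n_runs for e in estimates],
        }
    )


def grid_wide_frame(estimates: list[FulfilmentEstimate]) -> pd.DataFrame:
    """Wide export (scenario rows, staffing-mix columns) of simulated
    fulfilment percentages, matching the published table layout."""
    long = grid_long_frame(estimates)
    wide = long.pivot(index="scenario", columns="f", values="simulated_mean")
    wide = wide.reindex([e.scenario for e in estimates if e.f == estimates[0].f])
    return (100 * wide).round(1)
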