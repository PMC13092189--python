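"""Per-scenario preference prevalence and direction summaries.

For each clinical scenario the summary reports how many respondents answered
the preference item (n_valid), how many expressed any physician-gender
preference (n_any: response female or male), and how many of those chose a
female physician (n_female_dir).  Percentages follow the survey-report
convention (one decimal, ties away from zero); Wilson score 95% intervals are
attached as supplementary output — chosen for small-count stability, since the
reference study printed no interval for these proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from . import study
from ._util import round_half_away
from .codebook import INAPPLICABLE, Codebook, default_codebook
from .cohort import CohortTable


@dataclass(frozen=True)
class ScenarioSummary:
    """Counts and derived percentages for one scenario (one table row)."""

    scenario: str
    n_valid: int
    n_any: int
    n_female_dir: int
    prevalence_pct: float | None
    female_dir_pct: float | None
    ci_prevalence: tuple[float, float] | None
    ci_direction: tuple[float, float] | None

    def __post_init__(self) -> None:
        if not 0 <= self.n_female_dir <= self.n_any <= self.n_valid:
            raise ValueError(
                f"{self.scenario}: inconsistent counts "
                f"{self.n_female_dir}/{self.n_any}/{self.n_valid}"
            )


def _wilson_pct(count: int, nobs: int) -> tuple[float, float]:
    low, high = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    # guard against sub-epsilon excursions so the interval stays inside
    # [0, 1] and always brackets the point estimate
    p_hat = count / nobs
    low = max(0.0, min(float(low), p_hat))
    high = min(1.0, max(float(high), p_hat))
    return (100 * low, 100 * high)


def summarize_scenario(cohort: CohortTable, scenario: str) -> ScenarioSummary:
    """Summarise one scenario; direction fields are None when nobody prefers."""
    col = cohort.data[study.pref_column(scenario)]
    valid = col[col.notna()]
    n_valid = len(valid)
    n_any = int(valid.isin(["female", "male"]).sum())
    n_female = int((valid == "female").sum())
    prevalence = (
        round_half_away(100 * n_any / n_valid, 1) if n_valid else None
    )
    direction = round_half_away(100 * n_female / n_any, 1) if n_any else None
    return ScenarioSummary(
        scenario=scenario,
        n_valid=n_valid,
        n_any=n_any,
        n_female_dir=n_female,
        prevalence_pct=prevalence,
        female_dir_pct=direction,
        ci_prevalence=_wilson_pct(n_any, n_valid) if n_valid else None,
        ci_direction=_wilson_pct(n_female, n_any) if n_any else None,
    )


def summarize_all(cohort: CohortTable) -> list[ScenarioSummary]:
    """All five scenarios in fixed reporting order."""
    return [summarize_scenario(cohort, s) for s in study.SCENARIOS]


def stratified_summary(
    cohort: CohortTable, by: str, codebook: Codebook | None = None
) -> dict[str, list[ScenarioSummary]]:
    """Scenario summaries within each category of a codebook variable.

    Every codebook category appears (zero-member strata included); counts are
    additive: summing n_any over strata (plus a ``missing`` stratum when the
    variable has missing values) recovers the unstratified counts.
    """
    codebook = codebook or default_codebook()
    if by not in codebook:
        raise KeyError(f"unknown variable: {by!r}")
    var = codebook[by]
    out: dict[str, list[ScenarioSummary]] = {}
    strata: list[str] = list(var.categories)
    if var.applicable_when is not None:
        strata.append(INAPPLICABLE)
    col = cohort.data[by]
    for cat in strata:
        sub = CohortTable(cohort.data[col == cat], provenance=cohort.provenance)
        out[cat] = summarize_all(sub)
    if col.isna().any():
        sub = CohortTable(cohort.data[col.isna()], provenance=cohort.provenance)
        out["missing"] = summarize_all(sub)
    return out


def summary_table(summaries: list[ScenarioSummary]) -> pd.DataFrame:
    """Flat DataFrame mirroring the published scenario-summary layout."""
    rows = []
    for s in summaries:
        row = asdict(s)
        ci_p = row.pop("ci_prevalence") or (None, None)
        ci_d = row.pop("ci_direction") or (None, None)
        row["prevalence_ci_low"], row["prevalence_ci_high"] = ci_p
        row["direction_ci_low"], row["direction_ci_high"] = ci_d
        rows.append(row)
    return pd.DataFrame(rows)
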