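"""Respondent tables: reading, writing, validation, and missing-data rules.

A cohort is a pandas DataFrame of category strings (one row per respondent,
one column per codebook variable) wrapped with provenance.  Missing cells are
``pd.NA`` in memory and the sentinel token ``NA`` on disk; structurally
inapplicable cells (skip-ruled items for first-time attendees) carry the
literal token ``inapplicable`` and are never imputed.

The survey's missing-data policy is implemented here: covariates with sparse
item nonresponse (0.0-1.3% in the reference study) are mode-imputed before
modelling, while skip-ruled items are reported as inapplicable rather than
missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ._util import round_half_away
from .codebook import INAPPLICABLE, MISSING_TOKEN, Codebook, default_codebook


class CohortError(Exception):
    """Base class for cohort I/O and validation failures."""


class CohortFormatError(CohortError):
    """Malformed file structure (e.g. header does not match the codebook)."""


class CohortValidationError(CohortError):
    """Cell values outside the codebook; carries per-offence details."""

    def __init__(self, offences: list[tuple[int, str, str]]):
        self.offences = offences
        lines = [
            f"row {row}: {variable}={value!r} not an allowed category"
            for row, variable, value in offences[:20]
        ]
        if len(offences) > 20:
            lines.append(f"... and {len(offences) - 20} more")
        super().__init__("invalid category values:\n" + "\n".join(lines))


@dataclass
class CohortTable:
    """Validated respondent table plus provenance."""

    data: pd.DataFrame
    provenance: str = "unspecified"
    seed: int | None = None

    @property
    def n(self) -> int:
        return len(self.data)

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), self.provenance, self.seed)

    def equals(self, other: "CohortTable") -> bool:
        return self.data.reset_index(drop=True).equals(
            other.data.reset_index(drop=True)
        )


def validate_cohort(data: pd.DataFrame, codebook: Codebook) -> None:
    """Raise :class:`CohortValidationError` listing every offending cell.

    Also enforces the skip rule: conditional items must be ``inapplicable``
    exactly when their governing condition fails.
    """
    offences: list[tuple[int, str, str]] = []
    for var in codebook:
        col = data[var.name]
        allowed = set(var.categories)
        if var.applicable_when is not None:
            allowed.add(INAPPLICABLE)
        mask_bad = col.notna() & ~col.isin(allowed)
        for row in data.index[mask_bad]:
            offences.append((int(row), var.name, str(col.loc[row])))
        if var.applicable_when is not None:
            dep, value = var.applicable_when
            inapplicable_expected = data[dep].notna() & (data[dep] != value)
            mismatch = col.notna() & (
                (col == INAPPLICABLE) != inapplicable_expected
            )
            for row in data.index[mismatch]:
                offences.append((int(row), var.name, f"{col.loc[row]} (skip rule)"))
    if offences:
        raise CohortValidationError(offences)


def load_cohort(path: str | Path, codebook: Codebook | None = None) -> CohortTable:
    """Read a delimited respondent table and validate it against the codebook.

    Empty cells and the ``NA`` sentinel are both read as missing; anything
    else must be an allowed category (or ``inapplicable`` for skip-ruled
    items).
    """
    codebook = codebook or default_codebook()
    path = Path(path)
    if not path.exists():
        raise CohortError(f"no such file: {path}")
    data = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = list(codebook.names)
    if list(data.columns) != expected:
        raise CohortFormatError(
            f"header mismatch: expected columns {expected}, got {list(data.columns)}"
        )
    data = data.replace({"": pd.NA, MISSING_TOKEN: pd.NA})
    validate_cohort(data, codebook)
    return CohortTable(data.reset_index(drop=True), provenance=f"file:{path.name}")


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort as UTF-8 comma-separated text (missing -> ``NA``)."""
    out = cohort.data.fillna(MISSING_TOKEN)
    out.to_csv(path, index=False)


def impute_covariates(
    cohort: CohortTable, codebook: Codebook | None = None
) -> CohortTable:
    """Mode-impute missing / no-response covariate cells.

    For every non-conditional, non-preference variable, missing entries (and
    declared no-response levels) are replaced by the modal observed category;
    ties break by codebook category order.  Skip-ruled items and scenario
    responses are left untouched.  Idempotent; returns a new table.
    """
    codebook = codebook or default_codebook()
    data = cohort.data.copy()
    for var in codebook.covariates:
        col = data[var.name]
        needs = col.isna()
        if var.no_response is not None:
            needs = needs | (col == var.no_response)
        if not needs.any():
            continue
        observed = col[~needs]
        if observed.empty:
            raise CohortError(f"{var.name}: all values missing, mode undefined")
        counts = observed.value_counts()
        top = counts.max()
        # tie-break: first codebook category among the tied modes
        mode = next(
            c for c in var.informative_categories if counts.get(c, 0) == top
        )
        data.loc[needs, var.name] = mode
    return CohortTable(data, cohort.provenance, cohort.seed)


def missingness_report(
    cohort: CohortTable, codebook: Codebook | None = None
) -> pd.DataFrame:
    """Per-variable missing and inapplicable counts and percentages.

    Percentages are of total records, half-away-from-zero rounded to two
    decimals; inapplicable (skip-rule) entries are tallied separately from
    genuine missingness.
    """
    codebook = codebook or default_codebook()
    n = cohort.n
    rows = []
    for var in codebook:
        col = cohort.data[var.name]
        n_missing = int(col.isna().sum())
        n_inapplicable = int((col == INAPPLICABLE).sum())
        rows.append(
            {
                "variable": var.name,
                "n_missing": n_missing,
                "pct_missing": round_half_away(100 * n_missing / n, 2) if n else 0.0,
                "n_inapplicable": n_inapplicable,
                "pct_inapplicable": (
                    round_half_away(100 * n_inapplicable / n, 2) if n else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)


def category_counts(
    cohort: CohortTable, codebook: Codebook | None = None
) -> pd.DataFrame:
    """Descriptive marginal table: n and % of valid per category.

    Mirrors the reference study's demographics table: percentages use valid
    (non-missing, applicable) denominators; no-response levels stay distinct
    rows; missing is reported as its own row with a count but no percentage.
    """
    codebook = codebook or default_codebook()
    rows = []
    for var in codebook:
        col = cohort.data[var.name]
        valid = col[col.notna() & (col != INAPPLICABLE)]
        denom = len(valid)
        for cat in var.categories:
            n_cat = int((valid == cat).sum())
            rows.append(
                {
                    "variable": var.name,
                    "category": cat,
                    "n": n_cat,
                    "pct_valid": round_half_away(100 * n_cat / denom, 1)
                    if denom
                    else float("nan"),
                }
            )
        n_missing = int(col.isna().sum())
        if n_missing:
            rows.append(
                {
                    "variable": var.name,
                    "category": "missing",
                    "n": n_missing,
                    "pct_valid": float("nan"),
                }
            )
    return pd.DataFrame(rows)
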