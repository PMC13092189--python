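"""Survey codebook: variables, categories, reference levels, skip rules.

The codebook is the single source of truth for what a respondent record may
contain.  Every variable is categorical (binary is the two-category special
case); scenario-preference items take values none/female/male.  Two items are
asked only of return visitors and are *structurally inapplicable* for
first-time attendees — a skip rule, distinct from missingness, expressed here
as an ``applicable_when`` condition on an earlier variable.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterator

import yaml

from . import study

#: Cell token written for a genuinely missing value.
MISSING_TOKEN = "NA"
#: Cell token for structurally inapplicable items (skip rule, never imputed).
INAPPLICABLE = "inapplicable"

CATEGORICAL = "categorical"
BINARY = "binary"
PREFERENCE = "scenario-preference"

PREFERENCE_LEVELS = ("none", "female", "male")


@dataclass(frozen=True)
class Variable:
    """One survey variable.

    Parameters
    ----------
    name : column name in the respondent table.
    kind : "categorical", "binary" or "scenario-preference".
    categories : allowed category strings, in fixed (reporting) order.
    reference : dummy-coding reference level; must be an allowed category.
    applicable_when : optional ``(variable, value)`` skip rule — the item is
        applicable iff the named earlier variable equals ``value``.
    no_response : optional category that represents declined answers; kept as
        its own level in descriptive output but treated as missing when the
        variable enters a regression model.
    """

    name: str
    kind: str
    categories: tuple[str, ...]
    reference: str | None = None
    applicable_when: tuple[str, str] | None = None
    no_response: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in (CATEGORICAL, BINARY, PREFERENCE):
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        if len(self.categories) < 2:
            raise ValueError(f"{self.name}: needs >= 2 categories")
        if self.kind == BINARY and len(self.categories) != 2:
            raise ValueError(f"{self.name}: binary variable must have 2 categories")
        if self.kind == PREFERENCE and tuple(self.categories) != PREFERENCE_LEVELS:
            raise ValueError(
                f"{self.name}: preference items use levels {PREFERENCE_LEVELS}"
            )
        if self.reference is not None and self.reference not in self.categories:
            raise ValueError(
                f"{self.name}: reference {self.reference!r} not among categories"
            )
        if self.no_response is not None and self.no_response not in self.categories:
            raise ValueError(f"{self.name}: no_response level not among categories")

    @property
    def informative_categories(self) -> tuple[str, ...]:
        """Categories that carry information (excludes the no-response level)."""
        return tuple(c for c in self.categories if c != self.no_response)


@dataclass(frozen=True)
class Codebook:
    """Ordered collection of :class:`Variable` with validated skip rules."""

    variables: tuple[Variable, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for var in self.variables:
            if var.name in seen:
                raise ValueError(f"duplicate variable {var.name!r}")
            if var.applicable_when is not None:
                dep, value = var.applicable_when
                if dep not in seen:
                    raise ValueError(
                        f"{var.name}: applicability rule references {dep!r}, "
                        "which is not defined earlier in the codebook"
                    )
                if value not in self[dep].categories:
                    raise ValueError(
                        f"{var.name}: applicability value {value!r} not a "
                        f"category of {dep!r}"
                    )
            seen.add(var.name)

    def __iter__(self) -> Iterator[Variable]:
        return iter(self.variables)

    def __getitem__(self, name: str) -> Variable:
        for var in self.variables:
            if var.name == name:
                return var
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    @property
    def covariates(self) -> tuple[Variable, ...]:
        """Variables eligible for mode imputation: everything except
        preference items and skip-ruled (conditional) items."""
        return tuple(
            v
            for v in self.variables
            if v.kind != PREFERENCE and v.applicable_when is None
        )

    @property
    def conditional(self) -> tuple[Variable, ...]:
        return tuple(v for v in self.variables if v.applicable_when is not None)

    @property
    def preference_variables(self) -> tuple[Variable, ...]:
        return tuple(v for v in self.variables if v.kind == PREFERENCE)


def default_codebook() -> Codebook:
    """Codebook of the reference outpatient survey instrument."""
    variables = [
        Variable("gender", CATEGORICAL, ("female", "male", "diverse"), "female"),
        Variable("age_group", CATEGORICAL, tuple(study.AGE_COUNTS), "20-39"),
        Variable("disease_category", CATEGORICAL, tuple(study.DISEASE_COUNTS), "other"),
        Variable(
            "education",
            CATEGORICAL,
            tuple(study.EDUCATION_COUNTS),
            "lower_secondary",
            no_response="no_response",
        ),
        Variable("religion", CATEGORICAL, tuple(study.RELIGION_COUNTS), "none"),
        Variable("relationship_status", BINARY, ("partnered", "single"), "partnered"),
        Variable("gp_status", BINARY, ("has_gp", "no_gp"), "has_gp"),
        Variable(
            "immigration",
            CATEGORICAL,
            ("no", "yes", "no_response"),
            "no",
            no_response="no_response",
        ),
        Variable("first_visit", BINARY, ("no", "yes"), "no"),
        Variable("prior_request", BINARY, ("no", "yes"), "no"),
        Variable("limits_activities", BINARY, ("no", "yes"), "no"),
        Variable("worrying", BINARY, ("no", "yes"), "no"),
        Variable("painful", BINARY, ("no", "yes"), "no"),
        Variable("embarrassing", BINARY, ("no", "yes"), "no"),
        Variable(
            "last_physician_gender",
            BINARY,
            ("female", "male"),
            applicable_when=("first_visit", "no"),
        ),
        Variable(
            "advice_better_other_gender",
            BINARY,
            ("no", "yes"),
            applicable_when=("first_visit", "no"),
        ),
    ]
    variables += [
        Variable(study.pref_column(s), PREFERENCE, PREFERENCE_LEVELS, "none")
        for s in study.SCENARIOS
    ]
    return Codebook(tuple(variables))


def save_codebook(codebook: Codebook, path: str | Path) -> None:
    payload = {
        "variables": [
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(var).items()}
            for var in codebook
        ]
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_codebook(path: str | Path) -> Codebook:
    payload = yaml.safe_load(Path(path).read_text())
    variables = []
    for entry in payload["variables"]:
        entry = dict(entry)
        entry["categories"] = tuple(entry["categories"])
        if entry.get("applicable_when") is not None:
            entry["applicable_when"] = tuple(entry["applicable_when"])
        variables.append(Variable(**entry))
    return Codebook(tuple(variables))
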