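"""Variable vocabulary for tryptophan-metabolite cohort tables.

The analysis operates on urinary concentrations of tryptophan and 18 of its
downstream catabolites (kynurenine, serotonin and indole pathways), plus five
non-metabolite covariates (birth size, BMI, dietary energy and protein).
Every variable is described by a :class:`VariableSpec` carrying its role —
``metabolite`` variables form the networks, ``covariate`` variables are
optional adjustment nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

ROLE_METABOLITE = "metabolite"
ROLE_COVARIATE = "covariate"
_VALID_ROLES = frozenset({ROLE_METABOLITE, ROLE_COVARIATE})


@dataclass(frozen=True)
class VariableSpec:
    """A named analysis variable with a role and a display unit."""

    name: str
    role: str
    display_unit: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("variable name must be non-empty")
        if self.role not in _VALID_ROLES:
            raise ValueError(
                f"role {self.role!r} for {self.name!r} not in {sorted(_VALID_ROLES)}"
            )


#: Tryptophan and its 18 quantified catabolites, in pathway order
#: (kynurenine pathway, serotonin pathway, indole pathway).
METABOLITE_NAMES: tuple[str, ...] = (
    "tryptophan",
    "picolinic-acid",
    "quinolinic-acid",
    "kynurenic-acid",
    "kynurenine",
    "xanthurenic-acid",
    "anthranilic-acid",
    "3-hydroxyanthranilic-acid",
    "3-hydroxykynurenine",
    "serotonin",
    "5-hydroxyindole-3-acetic-acid",
    "5-hydroxytryptophan",
    "indole-3-acetamide",
    "indole-3-acetic-acid",
    "indole-3-lactic-acid",
    "indole-3-propionic-acid",
    "indole-3-carboxaldehyde",
    "indole-3-carboxylic-acid",
    "tryptamine",
)

#: Adjustment covariates with their natural units.
COVARIATE_UNITS: dict[str, str] = {
    "birth-weight": "g",
    "birth-length": "cm",
    "bmi": "kg/m^2",
    "energy": "kcal/day",
    "protein": "g/day",
}
COVARIATE_NAMES: tuple[str, ...] = tuple(COVARIATE_UNITS)


def default_schema(include_covariates: bool = True) -> list[VariableSpec]:
    """The default 19-metabolite (+5 covariate) variable vocabulary."""
    schema = [VariableSpec(m, ROLE_METABOLITE, "uM") for m in METABOLITE_NAMES]
    if include_covariates:
        schema += [
            VariableSpec(c, ROLE_COVARIATE, u) for c, u in COVARIATE_UNITS.items()
        ]
    return schema


def validate_schema(schema: Sequence[VariableSpec]) -> None:
    """Check name uniqueness and that at least one role is present."""
    names = [v.name for v in schema]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate variable names: {dupes}")
    if not schema:
        raise ValueError("schema must contain at least one variable")


def metabolite_names(schema: Iterable[VariableSpec]) -> list[str]:
    return [v.name for v in schema if v.role == ROLE_METABOLITE]


def covariate_names(schema: Iterable[VariableSpec]) -> list[str]:
    return [v.name for v in schema if v.role == ROLE_COVARIATE]
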