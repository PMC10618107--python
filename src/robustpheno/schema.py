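"""Shared vocabulary: phenotype labels, units, perturbation groups, table schemas.

The long-format phenotype table is the central exchange object of the
package: one row per (strain, condition, group, replicate, phenotype)
with a numeric ``value``, fixed ``units`` per phenotype and a
``qc_flags`` string (semicolon-separated labels, empty when clean).
"""

from __future__ import annotations

from dataclasses import dataclass

# The five performance phenotypes of the screen.
MU_MAX = "mu_max"
LAG = "lag"
CDW = "cdw"
BIOMASS_YIELD = "biomass_yield"
ETHANOL_YIELD = "ethanol_yield"

PHENOTYPES: tuple[str, ...] = (MU_MAX, LAG, CDW, BIOMASS_YIELD, ETHANOL_YIELD)

UNITS: dict[str, str] = {
    MU_MAX: "1/h",
    LAG: "h",
    CDW: "g/L",
    BIOMASS_YIELD: "g/g",
    ETHANOL_YIELD: "g/g",
}

# Perturbation groups: medium components grouped by the physiological
# response they elicit.
GROUPS: tuple[str, ...] = (
    "acids",
    "pentoses",
    "hexoses",
    "aldehydes",
    "NaCl",
    "ethanol",
)

PHENOTYPE_COLUMNS: tuple[str, ...] = (
    "strain",
    "condition",
    "group",
    "replicate",
    "phenotype",
    "value",
    "units",
    "qc_flags",
)

KEY_COLUMNS: tuple[str, ...] = ("strain", "condition", "replicate", "phenotype")

CURVE_COLUMNS: tuple[str, ...] = (
    "strain",
    "condition",
    "group",
    "concentration_g_l",
    "replicate",
    "time_h",
    "signal",
)


@dataclass(frozen=True)
class Condition:
    """One perturbation: a medium component at a given concentration.

    ``group`` assigns the component to one of the six perturbation
    groups (acids, pentoses, hexoses, aldehydes, NaCl, ethanol).
    """

    name: str
    concentration: float  # g/L
    group: str

    def __post_init__(self) -> None:
        validate_group(self.group)
        if self.concentration < 0:
            raise ValueError(
                f"condition {self.name!r}: concentration must be >= 0, "
                f"got {self.concentration}"
            )


def validate_group(group: str) -> str:
    """Return *group* unchanged or raise ``ValueError`` naming the label."""
    if group not in GROUPS:
        raise ValueError(
            f"unknown perturbation group {group!r}; expected one of {', '.join(GROUPS)}"
        )
    return group


def validate_phenotype(phenotype: str) -> str:
    if phenotype not in PHENOTYPES:
        raise ValueError(
            f"unknown phenotype {phenotype!r}; expected one of {', '.join(PHENOTYPES)}"
        )
    return phenotype
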