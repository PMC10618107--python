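"""Shared fixtures: small random phenotype tables and synthetic datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from robustpheno import (
    Condition,
    EffectModel,
    make_perturbation_space,
    simulate_phenotype_table,
)
from robustpheno.schema import GROUPS, PHENOTYPES, UNITS


def random_table(
    rng: np.random.Generator,
    n_strains: int = 4,
    n_conditions: int = 6,
    n_replicates: int = 2,
    phenotypes: tuple[str, ...] = ("mu_max", "cdw"),
    scale: float = 1.0,
) -> pd.DataFrame:
    """Long-format table of positive random values, groups cycling."""
    rows = []
    for si in range(n_strains):
        for ci in range(n_conditions):
            group = GROUPS[ci % len(GROUPS)]
            for rep in range(1, n_replicates + 1):
                for phen in phenotypes:
                    rows.append(
                        {
                            "strain": f"s{si:02d}",
                            "condition": f"c{ci:02d}",
                            "group": group,
                            "replicate": rep,
                            "phenotype": phen,
                            "value": scale * rng.uniform(0.1, 2.0),
                            "units": UNITS[phen],
                            "qc_flags": "",
                        }
                    )
    return pd.DataFrame(rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230)


@pytest.fixture
def small_table(rng) -> pd.DataFrame:
    return random_table(rng)


@pytest.fixture(scope="session")
def study_scale_dataset():
    """24 strains x 29 conditions x 3 replicates x 5 phenotypes."""
    strains = [f"s{i:02d}" for i in range(24)]
    conditions = make_perturbation_space(29, seed=11)
    model = EffectModel.uniform(strains, noise_cv=0.2, seed=11)
    return simulate_phenotype_table(strains, conditions, 3, model)


@pytest.fixture
def hexose_condition() -> Condition:
    return Condition("glucose_20", 20.0, "hexoses")


assert set(PHENOTYPES) == {"mu_max", "lag", "cdw", "biomass_yield", "ethanol_yield"}
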