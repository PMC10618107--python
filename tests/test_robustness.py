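"""Fano-factor robustness: arithmetic oracles, invariants, group influence."""

from __future__ import annotations

import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from robustpheno import (
    group_influence,
    mean_robustness,
    normalization_constants,
    robustness,
    robustness_table,
)
from conftest import random_table


def brute_force_R(values, m):
    """Independent recomputation: pure-python sample variance and mean."""
    vals = [float(v) for v in values]
    return -(statistics.variance(vals) / statistics.mean(vals)) / m


class TestRobustnessStatistic:
    def test_zero_variance_gives_zero(self):
        assert robustness([2.0, 2.0, 2.0], m=5.0) == 0.0

    def test_arithmetic_oracle(self):
        assert robustness([1, 2, 3], m=2.0) == pytest.approx(-0.25, abs=1e-15)

    def test_scale_invariance(self):
        assert robustness([10, 20, 30], m=20.0) == pytest.approx(-0.25, abs=1e-15)

    @pytest.mark.parametrize(
        "values,m", [([1.0], 1.0), ([1, 2, 3], 0.0), ([-2, -1, 0], 1.0)]
    )
    def test_preconditions_rejected(self, values, m):
        with pytest.raises(ValueError):
            robustness(values, m)

    @given(
        values=st.lists(st.floats(0.01, 100.0), min_size=2, max_size=30),
        m=st.floats(0.01, 50.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_and_is_nonpositive(self, values, m):
        if statistics.mean(values) <= 0:
            return
        r = robustness(values, m)
        assert r <= 0
        assert r == pytest.approx(brute_force_R(values, m), abs=1e-12, rel=1e-9)


class TestNormalizationConstants:
    def test_grand_mean_over_all_values(self):
        table = pd.DataFrame(
            {
                "strain": ["a", "a", "b", "b"],
                "phenotype": "cdw",
                "value": [1.0, 1.0, 3.0, 3.0],
            }
        )
        assert normalization_constants(table)["cdw"] == pytest.approx(2.0)

    def test_single_value(self):
        table = pd.DataFrame({"strain": ["a"], "phenotype": ["cdw"], "value": [5.0]})
        assert normalization_constants(table)["cdw"] == 5.0

    def test_all_missing_phenotype_skipped(self, caplog):
        table = pd.DataFrame(
            {"strain": ["a"], "phenotype": ["cdw"], "value": [np.nan]}
        )
        assert "cdw" not in normalization_constants(table)


class TestRobustnessTable:
    def test_zero_noise_matches_closed_form(self):
        # deterministic values: strain baselines x condition factors
        baselines = {"a": 1.0, "b": 2.5}
        factors = [1.0, 0.8, 0.5, 1.2]
        rows = []
        for s, b in baselines.items():
            for ci, f in enumerate(factors):
                for rep in (1, 2):
                    rows.append(
                        {"strain": s, "condition": f"c{ci}", "group": "acids",
                         "replicate": rep, "phenotype": "cdw", "value": b * f,
                         "units": "g/L", "qc_flags": ""}
                    )
        table = pd.DataFrame(rows)
        m = statistics.mean(r["value"] for r in rows)
        rtable = robustness_table(table).set_index("strain")
        for s, b in baselines.items():
            expected = brute_force_R([b * f for f in factors], m)
            assert rtable.loc[s, "R"] == pytest.approx(expected, abs=1e-12)
            assert rtable.loc[s, "sem"] == 0.0  # identical replicates

    def test_sem_across_replicates(self):
        # construct a table whose per-replicate R values are known
        rows = []
        m = 1.0
        for rep, spread in zip((1, 2, 3), (0.2, 0.3, 0.4)):
            # two conditions with mean 1 and sample variance spread:
            # values 1 +- sqrt(spread/2) -> var = spread, mean = 1
            d = np.sqrt(spread / 2)
            for ci, v in enumerate((1 - d, 1 + d)):
                rows.append(
                    {"strain": "s", "condition": f"c{ci}", "group": "acids",
                     "replicate": rep, "phenotype": "cdw", "value": v,
                     "units": "g/L", "qc_flags": ""}
                )
        table = pd.DataFrame(rows)
        rtable = robustness_table(table, m={"cdw": m})
        assert rtable["R"].iloc[0] == pytest.approx(-0.3, abs=1e-12)
        assert rtable["sem"].iloc[0] == pytest.approx(0.1 / np.sqrt(3), abs=1e-9)

    def test_insufficient_conditions_reported_not_fatal(self):
        table = pd.DataFrame(
            [{"strain": "s", "condition": "c0", "group": "acids", "replicate": 1,
              "phenotype": "cdw", "value": 1.0, "units": "g/L", "qc_flags": ""}]
        )
        rtable = robustness_table(table)
        assert np.isnan(rtable["R"].iloc[0])
        assert rtable["reason"].iloc[0] == "insufficient_conditions"

    def test_oracle_equivalence_on_random_tables(self, rng):
        for _ in range(50):
            table = random_table(rng, n_strains=3, n_conditions=5, n_replicates=2)
            m = normalization_constants(table)
            rtable = robustness_table(table).set_index(["strain", "phenotype"])
            for (s, p), sub in table.groupby(["strain", "phenotype"]):
                reps = [
                    brute_force_R(g["value"], m[p])
                    for _, g in sub.groupby("replicate")
                ]
                assert rtable.loc[(s, p), "R"] == pytest.approx(
                    statistics.mean(reps), abs=1e-12
                )


class TestMeanRobustness:
    def test_unweighted_mean(self):
        rtable = pd.DataFrame(
            {"strain": "s", "phenotype": list("abcde"),
             "R": [-0.2, -0.3, -0.9, -0.9, -0.9]}
        )
        assert mean_robustness(rtable, "s") == pytest.approx(-0.64)

    def test_single_phenotype(self):
        rtable = pd.DataFrame({"strain": ["s"], "phenotype": ["a"], "R": [-0.5]})
        assert mean_robustness(rtable, "s") == -0.5

    def test_missing_strain_gives_nan(self):
        rtable = pd.DataFrame({"strain": ["s"], "phenotype": ["a"], "R": [-0.5]})
        assert np.isnan(mean_robustness(rtable, "other"))


class TestGroupInfluence:
    @staticmethod
    def one_strain_table(values, groups):
        return pd.DataFrame(
            [{"strain": "s", "condition": f"c{i}", "group": g, "replicate": 1,
              "phenotype": "cdw", "value": v, "units": "g/L", "qc_flags": ""}
             for i, (v, g) in enumerate(zip(values, groups))]
        )

    def test_variance_carrying_group_ratio_zero(self):
        table = self.one_strain_table(
            [1.0, 1.0, 1.0, 3.0], ["acids", "acids", "acids", "NaCl"]
        )
        result = group_influence(table, "NaCl", m={"cdw": 1.5})
        row = result.iloc[0]
        assert row["R_all"] == pytest.approx(-1.0 / (1.5 * 1.5), abs=1e-12)
        assert row["ratio"] == 0.0
        assert row["classification"] == "negative_impact"

    def test_empty_exclusion_ratio_exactly_one(self):
        table = self.one_strain_table(
            [1.0, 2.0, 3.0], ["acids", "acids", "acids"]
        )
        result = group_influence(table, "ethanol")
        assert result["ratio"].iloc[0] == 1.0
        assert result["classification"].iloc[0] == "neutral_or_positive"

    def test_constant_series_undefined(self):
        table = self.one_strain_table(
            [2.0, 2.0, 2.0, 2.0], ["acids", "acids", "NaCl", "NaCl"]
        )
        result = group_influence(table, "NaCl")
        assert result["classification"].iloc[0] == "undefined"

    def test_same_normalization_constant_reused(self):
        # The ratio must reflect only the dispersion change: check that
        # m is not recomputed on the reduced table.
        table = self.one_strain_table(
            [1.0, 2.0, 3.0, 10.0], ["acids", "acids", "acids", "NaCl"]
        )
        m = normalization_constants(table)
        result = group_influence(table, "NaCl")
        expected_excl = brute_force_R([1.0, 2.0, 3.0], m["cdw"])
        assert result["R_excluding"].iloc[0] == pytest.approx(expected_excl, 1e-12)
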