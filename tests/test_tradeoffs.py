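"""Correlation statistics: Spearman oracles, SE formula, group tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from robustpheno import (
    EffectModel,
    TradeoffSpec,
    correlation_se,
    cross_phenotype_correlations,
    embed_tradeoff,
    group_vs_reference_test,
    make_perturbation_space,
    performance_robustness_tradeoffs,
    robustness_table,
    simulate_phenotype_table,
    spearman,
)
from robustpheno.schema import GROUPS, UNITS


def brute_force_spearman(x, y):
    """Rank correlation via explicit average ranks and Pearson on ranks."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = list(range(1, 11))
        r, _ = spearman(x, [v**3 for v in x])
        assert r == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = list(range(1, 11))
        r, _ = spearman(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_rank_oracle(self):
        x, y = [1, 2, 3, 4, 5], [3, 1, 2, 5, 4]
        r, _ = spearman(x, y)
        assert r == pytest.approx(0.6)
        assert r == pytest.approx(brute_force_spearman(x, y))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    @given(
        x=st.lists(st.integers(-1000, 1000), min_size=5, max_size=30, unique=True),
        y_seed=st.integers(0, 2**31 - 1),
        shift=st.floats(0.1, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariance_under_monotone_transforms(self, x, y_seed, shift):
        y = np.random.default_rng(y_seed).normal(size=len(x))
        r0, _ = spearman(x, y)
        # exp(x/100) is strictly increasing and injective on integers
        r1, _ = spearman([np.exp(v / 100) * shift for v in x], y)
        assert r1 == pytest.approx(r0, abs=1e-12)


class TestCorrelationSE:
    def test_perfect_correlation_zero_se(self):
        assert correlation_se(1.0, 10) == 0.0
        assert correlation_se(-1.0, 10) == 0.0

    def test_study_scale_magnitudes(self):
        # |r| ~ 0.7 at 24 strains -> ~0.1; weak r at 26 -> 0.2
        assert correlation_se(-0.7, 24) == pytest.approx(0.106, abs=5e-3)
        assert round(correlation_se(-0.7, 24), 1) == 0.1
        assert correlation_se(0.0, 26) == pytest.approx(0.2)

    def test_monotone_in_n_and_r(self):
        grid_r = np.linspace(0, 0.95, 10)
        grid_n = [5, 10, 24, 50, 200]
        for n in grid_n:
            ses = [correlation_se(r, n) for r in grid_r]
            assert all(a > b for a, b in zip(ses, ses[1:]))
        for r in grid_r:
            ses = [correlation_se(r, n) for n in grid_n]
            assert all(a > b for a, b in zip(ses, ses[1:]))

    def test_preconditions(self):
        with pytest.raises(ValueError):
            correlation_se(1.5, 10)
        with pytest.raises(ValueError):
            correlation_se(0.5, 1)


class TestPerformanceRobustnessTradeoffs:
    def test_noiseless_perfect_tradeoff_recovered(self):
        strains = [f"s{i:02d}" for i in range(24)]
        model = embed_tradeoff(strains, TradeoffSpec("cdw", -1.0, seed=5))
        # remove sampling noise on the non-tradeoff phenotypes entirely
        conds = make_perturbation_space(12, seed=5)
        ds = simulate_phenotype_table(strains, conds, 3, model)
        rtable = robustness_table(ds.table)
        diagonal, matrix = performance_robustness_tradeoffs(ds.table, rtable)
        r = diagonal.loc[diagonal["phenotype"] == "cdw", "spearman_r"].iloc[0]
        assert r < -0.8  # strong recovery; sampling noise attenuates -1
        assert len(matrix) == 25  # full 5x5 performance x robustness grid

    def test_constant_robustness_skipped_with_reason(self):
        table = pd.DataFrame(
            [{"strain": f"s{i}", "condition": "c", "group": "acids",
              "replicate": 1, "phenotype": "cdw", "value": float(i + 1),
              "units": "g/L", "qc_flags": ""} for i in range(6)]
        )
        rtable = pd.DataFrame(
            {"strain": [f"s{i}" for i in range(6)], "phenotype": "cdw",
             "R": [-0.5] * 6}
        )
        diagonal, _ = performance_robustness_tradeoffs(table, rtable)
        assert diagonal["reason"].iloc[0] == "constant_vector"


class TestCrossPhenotypeCorrelations:
    @staticmethod
    def reciprocal_table(n=40):
        rng = np.random.default_rng(0)
        mus = rng.uniform(0.1, 0.5, n)
        rows = []
        for i, mu in enumerate(mus):
            for phen, value in (("mu_max", mu), ("lag", 1.0 / mu)):
                rows.append(
                    {"strain": f"s{i}", "condition": "c", "group":
                     GROUPS[i % len(GROUPS)], "replicate": 1, "phenotype": phen,
                     "value": value, "units": UNITS[phen], "qc_flags": ""}
                )
        return pd.DataFrame(rows)

    def test_exact_antimonotone_pair(self):
        result = cross_phenotype_correlations(self.reciprocal_table(),
                                              stratify_by_group=False)
        row = result.loc[(result["phenotype_x"] == "mu_max")
                         & (result["phenotype_y"] == "lag")].iloc[0]
        assert row["spearman_r"] == pytest.approx(-1.0)

    def test_stratified_output_shape(self):
        result = cross_phenotype_correlations(self.reciprocal_table())
        scopes = set(result["scope"])
        assert "overall" in scopes
        assert set(GROUPS) <= scopes
        # one entry per scope per pair
        assert (result.groupby("scope").size() == 1).all()


class TestGroupVsReference:
    @staticmethod
    def two_group_table(x, y, phenotype="mu_max", group="acids"):
        rows = []
        for i, v in enumerate(x):
            rows.append({"strain": "s", "condition": f"a{i}", "group": group,
                         "replicate": 1, "phenotype": phenotype, "value": v,
                         "units": "1/h", "qc_flags": ""})
        for i, v in enumerate(y):
            rows.append({"strain": "s", "condition": f"h{i}", "group": "hexoses",
                         "replicate": 1, "phenotype": phenotype, "value": v,
                         "units": "1/h", "qc_flags": ""})
        return pd.DataFrame(rows)

    def test_identical_samples_not_significant(self):
        vals = list(np.linspace(0.1, 0.5, 20))
        cmp_ = group_vs_reference_test(self.two_group_table(vals, vals), "mu_max",
                                       "acids")
        assert cmp_.p_value > 0.9
        assert not cmp_.significant

    def test_large_shift_detected(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.3, 0.05, 200)
        y = rng.normal(0.3 + 3 * 0.05, 0.05, 200)
        cmp_ = group_vs_reference_test(self.two_group_table(x, y), "mu_max", "acids")
        assert cmp_.p_value < 1e-10
        assert cmp_.significant

    def test_labels_carried_through(self):
        vals = list(np.linspace(0.1, 0.5, 5))
        cmp_ = group_vs_reference_test(
            self.two_group_table(vals, vals, group="NaCl"), "mu_max", "NaCl"
        )
        assert cmp_.group == "NaCl" and cmp_.reference == "hexoses"

    def test_empty_group_rejected(self):
        vals = list(np.linspace(0.1, 0.5, 5))
        with pytest.raises(ValueError, match="empty group"):
            group_vs_reference_test(self.two_group_table(vals, vals), "mu_max",
                                    "aldehydes")
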