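"""Performance-robustness trade-off statistics.

Rank (Spearman) correlations connect a strain's mean performance for a
phenotype with its robustness for the same or another phenotype;
negative correlations across strains are the signature of a
performance-robustness trade-off. Record-level cross-phenotype
correlations and rank-sum comparisons of perturbation groups against a
reference group (hexoses) complete the exploratory toolkit. Rank
statistics are used throughout because the phenotype distributions are
skewed and multimodal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .schema import PHENOTYPES

__all__ = [
    "spearman",
    "correlation_se",
    "strain_performance",
    "performance_robustness_tradeoffs",
    "cross_phenotype_correlations",
    "group_vs_reference_test",
    "GroupComparison",
]


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; two-sided p.

    Requires equal lengths of at least 4 and at least two distinct
    values in each vector (a constant vector has no rank ordering).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 4:
        raise ValueError(f"need at least 4 paired values, got {xa.size}")
    if np.unique(xa).size < 2 or np.unique(ya).size < 2:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.spearmanr(xa, ya)
    return float(r), float(p)


def correlation_se(r: float, n: int) -> float:
    """Sample-size-based standard error of a correlation coefficient.

    ``se = (1 - r^2) / sqrt(n - 1)``: zero at |r| = 1, decreasing in
    both |r| and n. At |r| = 0.7 and n = 24 strains this gives ~0.1.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    return (1.0 - r * r) / math.sqrt(n - 1)


def strain_performance(table: pd.DataFrame) -> pd.DataFrame:
    """Per-strain mean performance per phenotype.

    The mean is taken over all retained conditions and replicates —
    the strain-level aggregation used for trade-off detection.
    """
    sub = table.loc[np.isfinite(table["value"])]
    perf = (
        sub.groupby(["strain", "phenotype"], sort=True)["value"]
        .mean()
        .rename("performance")
        .reset_index()
    )
    return perf


def performance_robustness_tradeoffs(
    table: pd.DataFrame,
    rtable: pd.DataFrame,
    min_strains: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlations between mean performance and robustness.

    Returns ``(diagonal, matrix)``: the diagonal pairs each phenotype's
    performance with its own robustness across strains (the trade-off
    test proper); the matrix crosses every performance phenotype with
    every robustness phenotype. Each entry carries r, the two-sided p,
    the sample-size-based standard error and n; degenerate entries
    (too few strains, constant vector) are kept with a reason.
    """
    perf = strain_performance(table)
    merged_all = []
    phens = [p for p in PHENOTYPES if p in set(perf["phenotype"])]
    for perf_phen in phens:
        for rob_phen in phens:
            pp = perf.loc[perf["phenotype"] == perf_phen, ["strain", "performance"]]
            rr = rtable.loc[
                (rtable["phenotype"] == rob_phen) & np.isfinite(rtable["R"]),
                ["strain", "R"],
            ]
            both = pp.merge(rr, on="strain")
            row = {
                "performance_phenotype": perf_phen,
                "robustness_phenotype": rob_phen,
                "spearman_r": np.nan,
                "p_value": np.nan,
                "se": np.nan,
                "n": int(len(both)),
                "reason": "",
            }
            if len(both) < min_strains:
                row["reason"] = "insufficient_strains"
            else:
                try:
                    r, p = spearman(both["performance"], both["R"])
                except ValueError:
                    row["reason"] = "constant_vector"
                else:
                    row.update(
                        spearman_r=r, p_value=p, se=correlation_se(r, len(both))
                    )
            merged_all.append(row)
    matrix = pd.DataFrame(merged_all)
    diagonal = matrix.loc[
        matrix["performance_phenotype"] == matrix["robustness_phenotype"]
    ].rename(columns={"performance_phenotype": "phenotype"})[
        ["phenotype", "spearman_r", "p_value", "se", "n", "reason"]
    ].reset_index(drop=True)
    return diagonal, matrix


def cross_phenotype_correlations(
    table: pd.DataFrame, stratify_by_group: bool = True
) -> pd.DataFrame:
    """Record-level Spearman correlations between phenotype pairs.

    Records are matched on (strain, condition, replicate); every
    unordered phenotype pair is correlated over the pooled dataset and,
    optionally, within each perturbation group.
    """
    sub = table.loc[np.isfinite(table["value"])]
    wide = sub.pivot_table(
        index=["strain", "condition", "group", "replicate"],
        columns="phenotype",
        values="value",
        aggfunc="first",
    ).reset_index()
    phens = [p for p in PHENOTYPES if p in wide.columns]

    def corr_rows(frame: pd.DataFrame, scope: str) -> list[dict]:
        rows = []
        for a, b in combinations(phens, 2):
            pair = frame[[a, b]].dropna()
            row = {
                "phenotype_x": a,
                "phenotype_y": b,
                "scope": scope,
                "spearman_r": np.nan,
                "p_value": np.nan,
                "n": int(len(pair)),
                "reason": "",
            }
            try:
                r, p = spearman(pair[a], pair[b])
            except ValueError as err:
                row["reason"] = str(err)
            else:
                row.update(spearman_r=r, p_value=p)
            rows.append(row)
        return rows

    rows = corr_rows(wide, "overall")
    if stratify_by_group:
        for grp, frame in wide.groupby("group", sort=True):
            rows.extend(corr_rows(frame, str(grp)))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupComparison:
    """Rank-sum comparison of one perturbation group against a reference."""

    phenotype: str
    group: str
    reference: str
    statistic: float
    p_value: float
    n_group: int
    n_reference: int
    significant: bool
    alpha: float


def group_vs_reference_test(
    table: pd.DataFrame,
    phenotype: str,
    group: str,
    reference: str = "hexoses",
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-sided Mann-Whitney rank-sum test of group vs reference values.

    Pools the phenotype's records across strains, conditions and
    replicates within each group, mirroring an exploratory
    "is this perturbation group different from plain sugars?" check.
    """
    sub = table.loc[
        (table["phenotype"] == phenotype) & np.isfinite(table["value"])
    ]
    x = sub.loc[sub["group"] == group, "value"].to_numpy(dtype=float)
    y = sub.loc[sub["group"] == reference, "value"].to_numpy(dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError(
            f"empty group in comparison: {group!r} has {x.size} values, "
            f"{reference!r} has {y.size}"
        )
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 values per group")
    stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
    return GroupComparison(
        phenotype=phenotype,
        group=group,
        reference=reference,
        statistic=float(stat),
        p_value=float(p),
        n_group=int(x.size),
        n_reference=int(y.size),
        significant=bool(p < alpha),
        alpha=alpha,
    )


def all_group_tests(
    table: pd.DataFrame, reference: str = "hexoses", alpha: float = 0.05
) -> pd.DataFrame:
    """Run group_vs_reference_test for every phenotype x non-reference group."""
    rows = []
    groups = [g for g in table["group"].unique() if g != reference]
    for phen in [p for p in PHENOTYPES if p in set(table["phenotype"])]:
        for grp in groups:
            try:
                cmp_ = group_vs_reference_test(table, phen, grp, reference, alpha)
            except ValueError as err:
                rows.append(
                    {
                        "phenotype": phen,
                        "group": grp,
                        "reference": reference,
                        "statistic": np.nan,
                        "p_value": np.nan,
                        "significant": False,
                        "reason": str(err),
                    }
                )
                continue
            rows.append(
                {
                    "phenotype": phen,
                    "group": grp,
                    "reference": reference,
                    "statistic": cmp_.statistic,
                    "p_value": cmp_.p_value,
                    "significant": cmp_.significant,
                    "reason": "",
                }
            )
    return pd.DataFrame(rows)
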