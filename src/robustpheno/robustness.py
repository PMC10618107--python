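"""Fano-factor robustness across a perturbation space.

Robustness of a strain *S* for phenotype *i* over a perturbation set
*P* is the negative Fano factor normalized by the grand mean of the
phenotype:

    R(S, i, P) = -(sigma^2 / xbar) * (1 / m)

where ``sigma^2`` and ``xbar`` are the variance and mean of the
phenotype across perturbations, and ``m`` is the mean of the phenotype
over all strains. R is dimensionless and non-positive: 0 marks a
perfectly consistent (robust) phenotype; more negative values mean
larger relative spread across the perturbation space.

R is computed per replicate condition-series and then averaged across
replicates, giving a mean and a standard error of the mean per strain
and phenotype. The grand mean ``m`` is computed once on the full QC'd
table and reused when condition groups are excluded, so the
group-influence ratio reflects only the change in dispersion.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "robustness",
    "normalization_constants",
    "robustness_per_replicate",
    "robustness_table",
    "mean_robustness",
    "group_influence",
]

logger = logging.getLogger(__name__)


def robustness(values: Sequence[float] | np.ndarray, m: float) -> float:
    """R = -(sample variance / mean) / m over one condition series.

    ``values`` are one strain's phenotype measurements across the
    perturbation set (one replicate); ``m`` is the phenotype's grand
    mean over all strains. Uses the n-1 sample variance. Missing
    values must be removed by the caller or are rejected here.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError(f"robustness needs >= 2 values, got {x.size}")
    xbar = x.mean()
    if xbar <= 0:
        raise ValueError(f"mean across perturbations must be > 0, got {xbar}")
    if m <= 0:
        raise ValueError(f"normalization constant m must be > 0, got {m}")
    var = x.var(ddof=1)
    return float(-(var / xbar) / m)


def normalization_constants(table: pd.DataFrame) -> dict[str, float]:
    """Grand mean ``m`` per phenotype over all retained values."""
    out: dict[str, float] = {}
    for phen, sub in table.groupby("phenotype", sort=False):
        vals = sub["value"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            logger.warning("phenotype %r has no values; skipped", phen)
            continue
        out[phen] = float(vals.mean())
    return out


def robustness_per_replicate(
    table: pd.DataFrame,
    m: Mapping[str, float] | None = None,
    min_conditions: int = 2,
) -> pd.DataFrame:
    """R per (strain, phenotype, replicate) over the condition series.

    Missing condition values are dropped pairwise;
    ``n_conditions_used`` records how many entered each series. Series
    shorter than ``min_conditions`` are reported with NaN R and a
    reason.
    """
    m = dict(m) if m is not None else normalization_constants(table)
    rows = []
    grouped = table.groupby(["strain", "phenotype", "replicate"], sort=True)
    for (strain, phen, rep), sub in grouped:
        vals = sub["value"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        row = {
            "strain": strain,
            "phenotype": phen,
            "replicate": rep,
            "R": np.nan,
            "n_conditions_used": int(vals.size),
            "reason": "",
        }
        if phen not in m:
            row["reason"] = "no_normalization_constant"
        elif vals.size < min_conditions:
            row["reason"] = "insufficient_conditions"
        elif vals.mean() <= 0:
            row["reason"] = "nonpositive_mean"
        else:
            row["R"] = robustness(vals, m[phen])
        rows.append(row)
    return pd.DataFrame(rows)


def robustness_table(
    table: pd.DataFrame,
    m: Mapping[str, float] | None = None,
    min_conditions: int = 2,
) -> pd.DataFrame:
    """Mean R with SEM across replicates, per strain x phenotype.

    Returns columns ``strain, phenotype, R, sem, n_replicates,
    n_conditions_used, reason``; entries whose every replicate series
    was too short keep NaN R and carry the reason. The SEM uses the
    n-1 standard deviation over replicate R values (NaN for a single
    replicate).
    """
    per_rep = robustness_per_replicate(table, m=m, min_conditions=min_conditions)
    rows = []
    for (strain, phen), sub in per_rep.groupby(["strain", "phenotype"], sort=True):
        r = sub["R"].to_numpy(dtype=float)
        ok = np.isfinite(r)
        row = {
            "strain": strain,
            "phenotype": phen,
            "R": np.nan,
            "sem": np.nan,
            "n_replicates": int(ok.sum()),
            "n_conditions_used": int(sub.loc[ok, "n_conditions_used"].min()) if ok.any() else 0,
            "reason": "",
        }
        if not ok.any():
            row["reason"] = ";".join(sorted(set(sub["reason"]) - {""}))
        else:
            row["R"] = float(r[ok].mean())
            if ok.sum() > 1:
                row["sem"] = float(r[ok].std(ddof=1) / np.sqrt(ok.sum()))
            else:
                row["sem"] = 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def mean_robustness(rtable: pd.DataFrame, strain: str) -> float:
    """Unweighted mean of a strain's per-phenotype R values."""
    sub = rtable.loc[(rtable["strain"] == strain) & np.isfinite(rtable["R"])]
    if sub.empty:
        return float("nan")
    return float(sub["R"].mean())


def group_influence(
    table: pd.DataFrame,
    group: str,
    m: Mapping[str, float] | None = None,
    rtable_all: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Influence of one perturbation group on robustness.

    Computes ``ratio = R(excluding the group) / R(all conditions)`` per
    strain x phenotype, holding the normalization constant ``m`` fixed
    at its all-conditions value. ``ratio < 1`` means excluding the
    group *improves* robustness — the group has a negative impact;
    ``ratio >= 1`` means the group is neutral or positive. When
    ``R_all`` is exactly 0 the ratio is undefined.

    ``m`` and ``rtable_all`` may be passed to avoid recomputation when
    scanning several groups.
    """
    m = dict(m) if m is not None else normalization_constants(table)
    if rtable_all is None:
        rtable_all = robustness_table(table, m=m)
    reduced = table.loc[table["group"] != group]
    rtable_excl = robustness_table(reduced, m=m)

    merged = rtable_all.merge(
        rtable_excl,
        on=["strain", "phenotype"],
        how="left",
        suffixes=("_all", "_excl"),
    )
    rows = []
    for rec in merged.itertuples(index=False):
        r_all = rec.R_all
        r_excl = rec.R_excl
        row = {
            "strain": rec.strain,
            "phenotype": rec.phenotype,
            "excluded_group": group,
            "R_all": r_all,
            "R_excluding": r_excl,
            "ratio": np.nan,
            "classification": "undefined",
        }
        if np.isfinite(r_all) and np.isfinite(r_excl):
            if r_all == 0.0:
                row["classification"] = "undefined"
            else:
                ratio = r_excl / r_all
                row["ratio"] = float(ratio)
                row["classification"] = (
                    "neutral_or_positive" if ratio >= 1.0 else "negative_impact"
                )
        rows.append(row)
    return pd.DataFrame(rows)
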