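"""Culture-transfer improvement analysis.

When a culture is transferred into fresh medium of the same
composition, prior exposure to the perturbation often speeds up the
second cultivation. The improvement is quantified per well as

    %P = (mu_max2 - mu_max1) / mu_max1 * 100

where mu_max1/mu_max2 are the maximum specific growth rates of the
first and second cultivation. Wells that grew only after the transfer
(mu_max1 = 0, mu_max2 > 0) give an infinite ratio; those entries are
substituted with the largest finite %P in the dataset so they remain
in rank-based summaries. Wells that grew in neither cultivation carry
no improvement information and are left missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import MU_MAX
from .tradeoffs import correlation_se, spearman

__all__ = [
    "percent_improvement",
    "make_transfer_records",
    "resolve_infinities",
    "transfer_summary",
    "improvement_robustness_correlation",
    "TransferSummary",
]


def percent_improvement(mu1: float, mu2: float) -> float:
    """%P for one well; ``inf`` when growth appears only after transfer.

    Returns NaN (no information) when both rates are zero; raises on
    negative rates.
    """
    if mu1 < 0 or mu2 < 0:
        raise ValueError(f"growth rates must be >= 0, got ({mu1}, {mu2})")
    if mu1 == 0:
        return math.inf if mu2 > 0 else math.nan
    return (mu2 - mu1) / mu1 * 100.0


def make_transfer_records(
    first: pd.DataFrame, second: pd.DataFrame
) -> pd.DataFrame:
    """Pair first- and second-cultivation mu_max tables into transfer records.

    Both inputs are long-format phenotype tables (only their ``mu_max``
    rows are used), matched on (strain, condition, replicate). Returns
    columns ``strain, condition, group, replicate, mu_max_1, mu_max_2,
    percent_improvement, substituted, qc_flags`` with infinities still
    unresolved (see :func:`resolve_infinities`).
    """
    key = ["strain", "condition", "replicate"]
    f = first.loc[first["phenotype"] == MU_MAX, key + ["group", "value"]].rename(
        columns={"value": "mu_max_1"}
    )
    s = second.loc[second["phenotype"] == MU_MAX, key + ["value"]].rename(
        columns={"value": "mu_max_2"}
    )
    for name, frame in (("first", f), ("second", s)):
        if frame.duplicated(key).any():
            dupes = frame.loc[frame.duplicated(key), key].head(5).to_dict("records")
            raise ValueError(f"duplicate mu_max records in {name} cultivation: {dupes}")
    rec = f.merge(s, on=key, how="inner")
    imp = np.array(
        [percent_improvement(a, b) for a, b in zip(rec["mu_max_1"], rec["mu_max_2"])]
    )
    rec["percent_improvement"] = imp
    rec["substituted"] = False
    rec["qc_flags"] = np.where(
        np.isnan(imp), "no_growth_both", np.where(np.isinf(imp), "infinite", "")
    )
    return rec


def resolve_infinities(records: pd.DataFrame) -> pd.DataFrame:
    """Replace infinite %P entries with the dataset's maximum finite %P.

    The substitution keeps transfer-only growers at the top of the
    improvement ranking without letting an undefined ratio dominate
    summary statistics. Finite values are never altered.
    """
    out = records.copy()
    imp = out["percent_improvement"].to_numpy(dtype=float)
    is_inf = np.isinf(imp)
    if not is_inf.any():
        return out
    finite = imp[np.isfinite(imp)]
    if finite.size == 0:
        raise ValueError(
            "cannot resolve infinite improvements: no finite value in the dataset"
        )
    imp[is_inf] = finite.max()
    out["percent_improvement"] = imp
    out.loc[is_inf, "substituted"] = True
    return out


@dataclass
class TransferSummary:
    """Per-strain and per-group summaries of the transfer improvement."""

    per_strain: pd.DataFrame
    per_group: pd.DataFrame
    threshold_counts: dict[float, int] = field(default_factory=dict)


def transfer_summary(
    records: pd.DataFrame,
    thresholds: tuple[float, ...] = (20.0, 50.0),
) -> TransferSummary:
    """Summarize resolved transfer records.

    Per strain: mean %P across all perturbations, with the SD computed
    over replicate-level means (the replicate-to-replicate spread).
    Per group: Spearman correlation between first- and second-
    cultivation mu_max with its p-value. ``threshold_counts`` counts
    strains whose mean %P meets each improvement threshold (percent).
    """
    if records["percent_improvement"].isin([np.inf, -np.inf]).any():
        raise ValueError("resolve_infinities must be applied before summarizing")
    sub = records.loc[np.isfinite(records["percent_improvement"])]

    rep_means = (
        sub.groupby(["strain", "replicate"], sort=True)["percent_improvement"]
        .mean()
        .reset_index()
    )
    per_strain = (
        rep_means.groupby("strain", sort=True)["percent_improvement"]
        .agg(mean_percent_improvement="mean", sd="std", n_replicates="count")
        .reset_index()
    )

    rows = []
    for grp, frame in records.groupby("group", sort=True):
        row = {
            "group": grp,
            "spearman_r": np.nan,
            "p_value": np.nan,
            "se": np.nan,
            "n": int(len(frame)),
            "reason": "",
        }
        try:
            r, p = spearman(frame["mu_max_1"], frame["mu_max_2"])
        except ValueError as err:
            row["reason"] = str(err)
        else:
            row.update(spearman_r=r, p_value=p, se=correlation_se(r, len(frame)))
        rows.append(row)
    per_group = pd.DataFrame(rows)

    counts = {
        thr: int((per_strain["mean_percent_improvement"] >= thr).sum())
        for thr in thresholds
    }
    return TransferSummary(per_strain=per_strain, per_group=per_group,
                           threshold_counts=counts)


def improvement_robustness_correlation(
    records: pd.DataFrame,
    rtable: pd.DataFrame,
    min_strains: int = 4,
) -> pd.DataFrame:
    """Spearman correlation of per-strain mean %P with robustness, per phenotype.

    Reported whether or not significant — the absence of a correlation
    is itself informative (transfer improvement and robustness capture
    different properties).
    """
    per_strain = (
        records.loc[np.isfinite(records["percent_improvement"])]
        .groupby("strain", sort=True)["percent_improvement"]
        .mean()
        .rename("mean_percent_improvement")
        .reset_index()
    )
    rows = []
    for phen, sub in rtable.groupby("phenotype", sort=True):
        both = per_strain.merge(
            sub.loc[np.isfinite(sub["R"]), ["strain", "R"]], on="strain"
        )
        row = {
            "phenotype": phen,
            "spearman_r": np.nan,
            "p_value": np.nan,
            "n": int(len(both)),
            "reason": "",
        }
        if len(both) < min_strains:
            row["reason"] = "insufficient_strains"
        else:
            try:
                r, p = spearman(both["mean_percent_improvement"], both["R"])
            except ValueError as err:
                row["reason"] = str(err)
            else:
                row.update(spearman_r=r, p_value=p)
        rows.append(row)
    return pd.DataFrame(rows)
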