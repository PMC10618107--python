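"""Quality control for phenotype tables.

The cleaning rules mirror standard practice for fermentation
phenotyping: individual values are trimmed against physiological
bounds (theoretical maximum yields, maximum attainable biomass),
ethanol yields are discarded under ethanol perturbation (production
and consumption cannot be distinguished there), extreme values are
flagged — never removed — by the 0.1%/99.9% quantile rule, and a
Shapiro–Wilk check documents that phenotype distributions are
non-normal (so rank statistics are used downstream).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .schema import BIOMASS_YIELD, CDW, ETHANOL_YIELD, PHENOTYPES

__all__ = [
    "TrimBounds",
    "QCReport",
    "default_trim_bounds",
    "trim_values",
    "exclude_ethanol_yield_under_ethanol",
    "flag_outliers",
    "normality_check",
    "run_qc",
]

logger = logging.getLogger(__name__)

#: Maximum theoretical ethanol yield on glucose plus experimental
#: error margin: 0.51 + 0.1 g/g.
MAX_YIELD_G_G = 0.61
#: Maximum attainable biomass concentration, g/L.
MAX_CDW_G_L = 39.6


@dataclass(frozen=True)
class TrimBounds:
    """Per-phenotype admissible intervals; ``None`` means unbounded."""

    lower: dict[str, float | None]
    upper: dict[str, float | None]
    inclusive: bool = True

    def __post_init__(self) -> None:
        for phen in set(self.lower) | set(self.upper):
            if phen not in PHENOTYPES:
                raise ValueError(f"unknown phenotype in trim bounds: {phen!r}")
            lo = self.lower.get(phen)
            hi = self.upper.get(phen)
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"lower bound exceeds upper bound for {phen!r}")


@dataclass
class QCReport:
    """Counts and diagnostics from a QC pass."""

    n_input: int = 0
    n_retained: int = 0
    n_trimmed: int = 0
    n_excluded: int = 0
    n_outliers_flagged: int = 0
    per_rule: dict[str, int] = field(default_factory=dict)
    normality: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_trimmed": self.n_trimmed,
            "n_excluded": self.n_excluded,
            "n_outliers_flagged": self.n_outliers_flagged,
            "per_rule": dict(self.per_rule),
            "normality": {k: dict(v) for k, v in self.normality.items()},
        }


def default_trim_bounds() -> TrimBounds:
    """Physiological bounds: yields <= 0.61 g/g, CDW <= 39.6 g/L, all >= 0.

    Growth rate and lag have no upper bound. Bounds are inclusive: a
    value exactly at the theoretical maximum is admissible.
    """
    return TrimBounds(
        lower={p: 0.0 for p in PHENOTYPES},
        upper={
            ETHANOL_YIELD: MAX_YIELD_G_G,
            BIOMASS_YIELD: MAX_YIELD_G_G,
            CDW: MAX_CDW_G_L,
            "mu_max": None,
            "lag": None,
        },
    )


def trim_values(
    table: pd.DataFrame, bounds: TrimBounds | None = None
) -> tuple[pd.DataFrame, QCReport]:
    """Drop individual values outside the admissible bounds.

    Trimming is value-level: other phenotypes measured in the same well
    are untouched. Missing (NaN) values are also dropped here and
    counted under the ``missing`` rule.
    """
    bounds = bounds or default_trim_bounds()
    report = QCReport(n_input=len(table))
    if table.empty:
        return table.copy(), report

    values = table["value"].to_numpy(dtype=float)
    keep = np.ones(len(table), dtype=bool)

    missing = ~np.isfinite(values)
    if missing.any():
        keep &= ~missing
        report.per_rule["missing"] = int(missing.sum())

    for phen in PHENOTYPES:
        sel = (table["phenotype"] == phen).to_numpy() & ~missing
        if not sel.any():
            continue
        lo = bounds.lower.get(phen)
        hi = bounds.upper.get(phen)
        bad = np.zeros(len(table), dtype=bool)
        if lo is not None:
            bad |= sel & ((values < lo) if bounds.inclusive else (values <= lo))
        if hi is not None:
            bad |= sel & ((values > hi) if bounds.inclusive else (values >= hi))
        if bad.any():
            keep &= ~bad
            report.per_rule[f"trim_{phen}"] = int(bad.sum())
            logger.info("trim: removed %d %s values outside bounds", bad.sum(), phen)

    trimmed = table.loc[keep].copy()
    report.n_trimmed = int(len(table) - len(trimmed))
    report.n_retained = int(len(trimmed))
    return trimmed, report


def exclude_ethanol_yield_under_ethanol(table: pd.DataFrame) -> pd.DataFrame:
    """Drop ethanol-yield records measured under the ethanol perturbation group.

    With ethanol both supplied and produced, the yield is not
    interpretable; all other phenotypes under ethanol are retained.
    """
    if table.empty:
        return table.copy()
    drop = (table["phenotype"] == ETHANOL_YIELD) & (table["group"] == "ethanol")
    if drop.any():
        logger.info(
            "exclude: removed %d ethanol_yield values under ethanol", int(drop.sum())
        )
    return table.loc[~drop].copy()


def flag_outliers(
    table: pd.DataFrame, q_low: float = 0.001, q_high: float = 0.999
) -> tuple[pd.DataFrame, int]:
    """Flag — never remove — values outside per-phenotype extreme quantiles.

    Quantiles use linear interpolation between order statistics,
    computed per phenotype over all strains, conditions and replicates.
    Values strictly below the ``q_low`` or strictly above the
    ``q_high`` quantile get the ``outlier`` flag appended to
    ``qc_flags``. Returns the flagged table and the number of flags.
    """
    if not 0 <= q_low < q_high <= 1:
        raise ValueError(f"need 0 <= q_low < q_high <= 1, got ({q_low}, {q_high})")
    out = table.copy()
    if out.empty:
        return out, 0
    n_flagged = 0
    flags = out["qc_flags"].fillna("").astype(str).to_numpy(dtype=object)
    for phen, sub in out.groupby("phenotype", sort=False):
        vals = sub["value"].to_numpy(dtype=float)
        finite = np.isfinite(vals)
        if finite.sum() == 0:
            continue
        lo = np.quantile(vals[finite], q_low)
        hi = np.quantile(vals[finite], q_high)
        is_out = finite & ((vals < lo) | (vals > hi))
        if is_out.any():
            idx = np.flatnonzero(out.index.isin(sub.index[is_out]))
            for i in idx:
                flags[i] = "outlier" if not flags[i] else flags[i] + ";outlier"
            n_flagged += int(is_out.sum())
    out["qc_flags"] = flags
    return out, n_flagged


def normality_check(table: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Shapiro–Wilk statistic and p-value per phenotype (advisory only).

    Phenotypes with fewer than 3 finite values are skipped with a
    warning. Large samples trigger scipy's accuracy caveat for the
    p-value, which is acceptable for a qualitative normal/non-normal
    call.
    """
    results: dict[str, dict[str, float]] = {}
    for phen, sub in table.groupby("phenotype", sort=False):
        vals = sub["value"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 3:
            warnings.warn(
                f"normality check skipped for {phen!r}: fewer than 3 values",
                stacklevel=2,
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = stats.shapiro(vals)
        results[phen] = {"statistic": float(stat), "p_value": float(p)}
    return results


def run_qc(
    table: pd.DataFrame,
    bounds: TrimBounds | None = None,
    q_low: float = 0.001,
    q_high: float = 0.999,
) -> tuple[pd.DataFrame, QCReport]:
    """Full QC pass: trim, exclude ethanol yields under ethanol, flag, check.

    Returns the cleaned table (outliers flagged but retained) and a
    report with all counts.
    """
    trimmed, report = trim_values(table, bounds)
    excluded = exclude_ethanol_yield_under_ethanol(trimmed)
    report.n_excluded = int(len(trimmed) - len(excluded))
    if report.n_excluded:
        report.per_rule["exclude_ethanol_yield_under_ethanol"] = report.n_excluded
    report.n_retained = int(len(excluded))
    flagged, n_out = flag_outliers(excluded, q_low=q_low, q_high=q_high)
    report.n_outliers_flagged = n_out
    report.per_rule["outliers_flagged"] = n_out
    if not flagged.empty:
        report.normality = normality_check(flagged)
    return flagged, report
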