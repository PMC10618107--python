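"""Growth-curve and endpoint phenotyping.

Turns microtiter reader curves and endpoint assays into the five
performance phenotypes of a robustness screen:

* ``mu_max`` (1/h) — maximum specific growth rate, the steepest slope of
  ln(signal) found by sliding-window log-linear regression;
* ``lag`` (h) — lag phase, the intersection of the tangent at the
  steepest window with the initial ln-signal level;
* ``cdw`` (g/L) — final cell dry weight from optical density via a
  per-strain linear calibration;
* ``biomass_yield`` and ``ethanol_yield`` (g/g) — endpoint yields on
  total consumed sugars.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .schema import (
    BIOMASS_YIELD,
    CDW,
    ETHANOL_YIELD,
    LAG,
    MU_MAX,
    UNITS,
    Condition,
)

__all__ = [
    "GrowthCurve",
    "CalibrationCurve",
    "EndpointAssay",
    "MuMaxFit",
    "fit_mu_max",
    "estimate_lag",
    "od_to_cdw",
    "compute_yields",
    "extract_phenotypes",
]

#: Floor applied before the log transform (signal units).
_LOG_FLOOR = 1e-6


@dataclass
class GrowthCurve:
    """Reader signal over time for one well (strain x condition x replicate)."""

    strain: str
    condition: Condition
    replicate: int
    times: np.ndarray  # h, strictly increasing
    signal: np.ndarray  # reader units, > 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.size != self.signal.size:
            raise ValueError("times and signal must have equal length")
        if self.times.size < 4:
            raise ValueError("a growth curve needs at least 4 time points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(self.signal > 0):
            raise ValueError("all signal values must be > 0")


@dataclass(frozen=True)
class CalibrationCurve:
    """Per-strain linear OD -> cell dry weight calibration (g/L per OD unit)."""

    strain: str
    slope: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"calibration slope must be > 0, got {self.slope}")


@dataclass(frozen=True)
class EndpointAssay:
    """Endpoint sugar/ethanol/OD measurements for one well.

    ``initial_sugars`` / ``residual_sugars`` map sugar name to g/L.
    """

    strain: str
    condition: Condition
    replicate: int
    initial_sugars: Mapping[str, float]
    residual_sugars: Mapping[str, float]
    ethanol: float  # g/L
    final_od: float
    initial_od: float = 0.0

    def __post_init__(self) -> None:
        for name, conc in {**dict(self.initial_sugars), **dict(self.residual_sugars)}.items():
            if conc < 0:
                raise ValueError(f"sugar concentration for {name!r} must be >= 0")
        if self.ethanol < 0 or self.final_od < 0 or self.initial_od < 0:
            raise ValueError("ethanol and OD values must be >= 0")


@dataclass
class MuMaxFit:
    """Result of the sliding-window mu_max fit."""

    mu_max: float  # 1/h
    window_start: float  # h
    r2: float
    intercept: float  # ln-signal intercept of the best window's fit
    qc_flags: set[str] = field(default_factory=set)


def _log_signal(curve: GrowthCurve, blank: float) -> np.ndarray:
    return np.log(np.maximum(curve.signal - blank, _LOG_FLOOR))


def fit_mu_max(
    curve: GrowthCurve,
    window: int = 5,
    r2_min: float = 0.98,
    blank: float = 0.0,
) -> MuMaxFit:
    """Maximum specific growth rate by sliding-window log-linear regression.

    Ordinary least squares of ln(signal - blank) against time is fitted
    in every contiguous window of ``window`` points; ``mu_max`` is the
    largest positive slope among windows whose r-squared reaches
    ``r2_min``. If no window qualifies (flat, noisy or declining
    curves) the result is 0 with the ``no_growth`` flag.

    ``blank`` is an optional constant background to subtract before the
    log transform; the default 0 treats the signal as already
    background-corrected, which keeps the log-slope of an exponential
    (and of a Zwietering-Gompertz curve, defined in ln-signal space)
    exactly equal to the true rate.
    """
    if window < 3:
        raise ValueError("window must be >= 3 points")
    n = curve.times.size
    if window > n:
        raise ValueError(f"window of {window} points exceeds series length {n}")

    t = curve.times
    y = _log_signal(curve, blank)
    tw = np.lib.stride_tricks.sliding_window_view(t, window)
    yw = np.lib.stride_tricks.sliding_window_view(y, window)

    tm = tw.mean(axis=1, keepdims=True)
    ym = yw.mean(axis=1, keepdims=True)
    st = tw - tm
    sy = yw - ym
    sxx = np.einsum("ij,ij->i", st, st)
    sxy = np.einsum("ij,ij->i", st, sy)
    syy = np.einsum("ij,ij->i", sy, sy)
    slope = sxy / sxx
    ss_res = syy - np.square(sxy) / sxx
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(syy > 0, 1.0 - ss_res / syy, 0.0)

    ok = (r2 >= r2_min) & (slope > 0)
    if not ok.any():
        return MuMaxFit(
            mu_max=0.0,
            window_start=float(t[0]),
            r2=float(np.nanmax(r2)) if n > 0 else 0.0,
            intercept=float(y[0]),
            qc_flags={"no_growth"},
        )
    best = int(np.flatnonzero(ok)[np.argmax(slope[ok])])
    mu = float(slope[best])
    intercept = float(ym[best, 0] - mu * tm[best, 0])
    return MuMaxFit(
        mu_max=mu,
        window_start=float(t[best]),
        r2=float(r2[best]),
        intercept=intercept,
    )


def estimate_lag(
    curve: GrowthCurve,
    fit: MuMaxFit,
    blank: float = 0.0,
    inoculum_signal: float | None = None,
) -> tuple[float, set[str]]:
    """Lag phase by the tangent-intercept construction.

    The tangent of ln(signal) at the steepest window, ``y = intercept +
    mu_max * t``, is intersected with the initial ln-signal baseline;
    the crossing time, clipped at 0, is the lag. If the curve never
    grew the convention is ``lag = t_end`` with the ``no_growth`` flag.

    The baseline is ``ln(inoculum_signal - blank)`` when the inoculum
    signal level is known (screens start every well at a fixed OD, so
    this is usually an experimental constant); otherwise the minimum of
    the first three observed points stands in. For slow growers the
    known-inoculum variant is markedly more accurate, because the
    observed early signal can sit visibly above the true baseline.
    """
    if fit.mu_max <= 0:
        return float(curve.times[-1]), {"no_growth"}
    if inoculum_signal is not None:
        if inoculum_signal <= 0:
            raise ValueError("inoculum_signal must be > 0")
        y0 = float(np.log(max(inoculum_signal - blank, _LOG_FLOOR)))
    else:
        y0 = float(np.min(_log_signal(curve, blank)[:3]))
    lag = (y0 - fit.intercept) / fit.mu_max
    return max(lag, 0.0), set(fit.qc_flags)


def od_to_cdw(od: float, cal: CalibrationCurve) -> float:
    """Cell dry weight (g/L) from optical density, floored at 0."""
    if od < 0:
        raise ValueError(f"OD must be >= 0, got {od}")
    return max(cal.slope * od + cal.intercept, 0.0)


def compute_yields(
    assay: EndpointAssay,
    cal: CalibrationCurve,
    residual_tolerance: float = 0.5,
) -> dict[str, float | set[str]]:
    """Ethanol and biomass yields (g/g) on total consumed sugars.

    Consumption is summed over all sugars in the assay; a residual
    exceeding the initial concentration by more than
    ``residual_tolerance`` g/L (beyond assay noise) is rejected, smaller
    excesses are clamped to zero consumption. Zero total consumption
    yields missing values with the ``no_consumption`` flag. The biomass
    numerator is the cell dry weight gained over the cultivation
    (final minus initial OD, both through the calibration).
    """
    consumed = 0.0
    for sugar, initial in assay.initial_sugars.items():
        residual = assay.residual_sugars.get(sugar, 0.0)
        if residual > initial + residual_tolerance:
            raise ValueError(
                f"residual {sugar} ({residual} g/L) exceeds initial "
                f"({initial} g/L) beyond assay tolerance"
            )
        consumed += max(initial - residual, 0.0)

    flags: set[str] = set()
    if consumed <= 0:
        return {
            "ethanol_yield": float("nan"),
            "biomass_yield": float("nan"),
            "consumed": 0.0,
            "qc_flags": {"no_consumption"},
        }
    delta_cdw = od_to_cdw(assay.final_od, cal) - od_to_cdw(assay.initial_od, cal)
    return {
        "ethanol_yield": assay.ethanol / consumed,
        "biomass_yield": delta_cdw / consumed,
        "consumed": consumed,
        "qc_flags": flags,
    }


def _key(strain: str, condition: Condition, replicate: int) -> tuple:
    return (strain, condition.name, replicate)


def extract_phenotypes(
    curves: Iterable[GrowthCurve],
    assays: Sequence[EndpointAssay] | None = None,
    calibrations: Mapping[str, CalibrationCurve] | None = None,
    window: int = 5,
    r2_min: float = 0.98,
    blank: float = 0.0,
    inoculum_signal: float | None = None,
    allow_curve_only: bool = False,
) -> pd.DataFrame:
    """Extract the five phenotypes for every well into a long-format table.

    Each curve contributes ``mu_max`` and ``lag``; a matching endpoint
    assay (same strain, condition, replicate) plus the strain's
    calibration contributes ``cdw`` and the two yields. Without
    ``allow_curve_only`` a missing assay is an error; with it, the
    endpoint phenotypes are simply absent for that well.
    """
    curves = list(curves)
    assay_map: dict[tuple, EndpointAssay] = {}
    if assays:
        for a in assays:
            k = _key(a.strain, a.condition, a.replicate)
            if k in assay_map:
                raise ValueError(f"duplicate assay record for key {k}")
            assay_map[k] = a

    seen: set[tuple] = set()
    dupes = [
        k
        for c in curves
        if (k := _key(c.strain, c.condition, c.replicate)) in seen or seen.add(k)
    ]
    if dupes:
        raise ValueError(f"duplicate growth curves for keys: {sorted(set(dupes))[:10]}")

    rows = []

    def add(curve: GrowthCurve, phen: str, value: float, flags: set[str]) -> None:
        rows.append(
            {
                "strain": curve.strain,
                "condition": curve.condition.name,
                "group": curve.condition.group,
                "replicate": curve.replicate,
                "phenotype": phen,
                "value": value,
                "units": UNITS[phen],
                "qc_flags": ";".join(sorted(flags)),
            }
        )

    for curve in curves:
        fit = fit_mu_max(curve, window=window, r2_min=r2_min, blank=blank)
        add(curve, MU_MAX, fit.mu_max, fit.qc_flags)
        lag, lag_flags = estimate_lag(
            curve, fit, blank=blank, inoculum_signal=inoculum_signal
        )
        add(curve, LAG, lag, lag_flags)

        k = _key(curve.strain, curve.condition, curve.replicate)
        assay = assay_map.get(k)
        if assay is None:
            if not allow_curve_only:
                raise ValueError(
                    f"no endpoint assay for well {k}; pass allow_curve_only=True "
                    "to extract growth phenotypes alone"
                )
            continue
        if calibrations is None or curve.strain not in calibrations:
            raise ValueError(
                f"no OD->CDW calibration available for strain {curve.strain!r}"
            )
        cal = calibrations[curve.strain]
        add(curve, CDW, od_to_cdw(assay.final_od, cal), set())
        yields = compute_yields(assay, cal)
        yflags = set(yields["qc_flags"])  # type: ignore[arg-type]
        add(curve, BIOMASS_YIELD, float(yields["biomass_yield"]), yflags)
        add(curve, ETHANOL_YIELD, float(yields["ethanol_yield"]), yflags)

    if not rows:
        from .schema import PHENOTYPE_COLUMNS

        return pd.DataFrame(columns=list(PHENOTYPE_COLUMNS))
    return pd.DataFrame(rows)
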