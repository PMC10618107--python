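"""Synthetic perturbation screens with known ground truth.

This module emulates the statistical structure of a microtiter
robustness screen — strains with different baseline phenotype levels,
perturbation conditions that scale those levels, and multiplicative
replicate noise — so that every downstream stage (phenotype extraction,
QC, Fano-factor robustness, trade-off detection) can be tested against
analytic expectations.

The default study design is 24 strains x 29 conditions (spread over six
perturbation groups) x 3 replicates x 5 phenotypes.

Noise model
-----------
Replicate noise is multiplicative lognormal with unit mean,
parameterised by a coefficient of variation (CV): a draw is
``exp(sigma * Z - sigma**2 / 2)`` with ``sigma**2 = ln(1 + CV**2)``, so
a simulated value ``baseline * factor * noise`` has expectation
``baseline * factor`` and variance ``(baseline * factor)**2 * CV**2``.
Phenotypes therefore stay strictly positive, matching the skewed
distributions real yield/rate data show.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .phenotypes import GrowthCurve
from .schema import (
    CDW,
    BIOMASS_YIELD,
    ETHANOL_YIELD,
    GROUPS,
    LAG,
    MU_MAX,
    PHENOTYPES,
    UNITS,
    Condition,
    validate_group,
)

__all__ = [
    "EffectModel",
    "TradeoffSpec",
    "GompertzParams",
    "SimulatedDataset",
    "make_perturbation_space",
    "simulate_phenotype_table",
    "simulate_growth_curves",
    "condition_scores",
    "embed_tradeoff",
    "DEFAULT_STRAINS",
    "DEFAULT_GROUP_WEIGHTS",
    "TYPICAL_BASELINES",
]

#: 24 strain labels for the default design.
DEFAULT_STRAINS: tuple[str, ...] = tuple(f"strain_{i:02d}" for i in range(1, 25))

#: Default mix of the six perturbation groups (fractions of the space).
#: Acids, hexoses and aldehydes carry several individual components at
#: several concentrations; NaCl and ethanol are single components.
DEFAULT_GROUP_WEIGHTS: dict[str, float] = {
    "acids": 8 / 29,
    "pentoses": 5 / 29,
    "hexoses": 6 / 29,
    "aldehydes": 6 / 29,
    "NaCl": 2 / 29,
    "ethanol": 2 / 29,
}

#: Order-of-magnitude phenotype levels for an unstressed lab yeast:
#: growth rate ~0.35 1/h, lag ~4 h, final biomass ~5 g/L, biomass yield
#: ~0.12 g/g, ethanol yield ~0.40 g/g.
TYPICAL_BASELINES: dict[str, float] = {
    MU_MAX: 0.35,
    LAG: 4.0,
    CDW: 5.0,
    BIOMASS_YIELD: 0.12,
    ETHANOL_YIELD: 0.40,
}

# Concentration ranges (g/L) typical of lignocellulosic-hydrolysate
# perturbation screens, per group.
_CONCENTRATION_RANGES: dict[str, tuple[float, float]] = {
    "acids": (1.0, 9.0),
    "pentoses": (10.0, 60.0),
    "hexoses": (20.0, 65.0),
    "aldehydes": (0.5, 4.0),
    "NaCl": (10.0, 40.0),
    "ethanol": (20.0, 80.0),
}


@dataclass
class EffectModel:
    """Generative model for a phenotype table.

    Parameters
    ----------
    baselines
        ``{strain: {phenotype: mean}}`` — unperturbed phenotype level of
        each strain (all > 0).
    condition_factors
        ``{condition name: {phenotype: factor}}`` — multiplicative
        effect of each condition on each phenotype (all > 0). Missing
        entries default to 1 (no effect).
    noise_cv
        Per-phenotype replicate-noise coefficient of variation; either
        a scalar per phenotype or ``{strain: cv}`` for strain-specific
        dispersion.
    sensitivity
        ``{phenotype: {strain: gamma}}`` — strain-specific scale of the
        response to standardized condition scores (see
        :func:`condition_scores`): the condition effect for such a
        phenotype is ``1 + gamma * u_c`` on top of any explicit
        condition factor. This is how strains acquire different
        across-condition variances (hence robustness) from the *same*
        perturbation space, with the effect reproduced in every
        replicate.
    seed
        Root seed for the lognormal noise draws.
    """

    baselines: Mapping[str, Mapping[str, float]]
    condition_factors: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    noise_cv: Mapping[str, float | Mapping[str, float]] = field(default_factory=dict)
    sensitivity: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for strain, means in self.baselines.items():
            for phen, mean in means.items():
                if not mean > 0:
                    raise ValueError(
                        f"baseline mean for ({strain}, {phen}) must be > 0, got {mean}"
                    )
        for cond, factors in self.condition_factors.items():
            for phen, f in factors.items():
                if not f > 0:
                    raise ValueError(
                        f"condition factor for ({cond}, {phen}) must be > 0, got {f}"
                    )
        for phen in self.noise_cv:
            for strain, cv in self._cv_items(phen):
                if cv < 0:
                    raise ValueError(
                        f"noise CV for ({strain or 'all strains'}, {phen}) "
                        f"must be >= 0, got {cv}"
                    )

    def _cv_items(self, phenotype: str):
        spec = self.noise_cv.get(phenotype, 0.0)
        if isinstance(spec, Mapping):
            return [(s, float(v)) for s, v in spec.items()]
        return [(None, float(spec))]

    def cv(self, strain: str, phenotype: str) -> float:
        """Replicate-noise CV for one strain and phenotype."""
        spec = self.noise_cv.get(phenotype, 0.0)
        if isinstance(spec, Mapping):
            return float(spec[strain])
        return float(spec)

    def factor(self, condition: str, phenotype: str) -> float:
        return float(self.condition_factors.get(condition, {}).get(phenotype, 1.0))

    @classmethod
    def uniform(
        cls,
        strains: Sequence[str],
        baselines: Mapping[str, float] | None = None,
        noise_cv: float | Mapping[str, float] = 0.1,
        seed: int = 0,
    ) -> "EffectModel":
        """All strains share the same baseline means and noise CV."""
        base = dict(baselines or TYPICAL_BASELINES)
        cv = noise_cv if isinstance(noise_cv, Mapping) else {p: noise_cv for p in base}
        return cls(
            baselines={s: dict(base) for s in strains},
            noise_cv=dict(cv),
            seed=seed,
        )


@dataclass(frozen=True)
class TradeoffSpec:
    """Target rank correlation between mean performance and robustness."""

    phenotype: str
    rho: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"target Spearman rho must be in [-1, 1], got {self.rho}")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")


@dataclass(frozen=True)
class GompertzParams:
    """Zwietering-Gompertz parameters for one well.

    ``A`` is the carrying capacity and ``baseline`` the inoculum-level
    signal (same reader units); ``mu`` (1/h) and ``lam`` (h) are the
    maximum specific growth rate and lag of the curve in ln-signal
    space.
    """

    strain: str
    condition: Condition
    replicate: int
    A: float
    mu: float
    lam: float
    baseline: float

    def __post_init__(self) -> None:
        if not self.baseline > 0:
            raise ValueError("baseline signal must be > 0 (log undefined otherwise)")
        if not self.A > self.baseline:
            raise ValueError("carrying capacity A must exceed the baseline signal")
        if self.mu < 0 or self.lam < 0:
            raise ValueError("mu and lam must be >= 0")


@dataclass
class SimulatedDataset:
    """A simulated phenotype table plus its generative ground truth.

    ``truth`` has one row per strain x phenotype with the across-
    condition population mean and variance of the generated values and
    the analytic robustness they imply (negative Fano factor divided by
    the grand mean of the phenotype).
    """

    table: pd.DataFrame
    truth: pd.DataFrame
    model: EffectModel
    conditions: list[Condition]


def make_perturbation_space(
    n_conditions: int,
    group_weights: Mapping[str, float] | None = None,
    seed: int = 0,
    include_control: bool = True,
) -> list[Condition]:
    """Build a perturbation space of ``n_conditions`` conditions.

    Conditions are allocated to groups by largest-remainder rounding of
    ``group_weights`` (default: the study-like mix in
    :data:`DEFAULT_GROUP_WEIGHTS`), guaranteeing every group with
    positive weight at least one condition whenever ``n_conditions``
    allows. Concentrations are drawn uniformly from group-typical
    ranges. With ``include_control`` the first hexose slot (if any) is
    the unperturbed 20 g/L glucose comparator.
    """
    if n_conditions < 1:
        raise ValueError("n_conditions must be >= 1")
    weights = dict(group_weights or DEFAULT_GROUP_WEIGHTS)
    for g in weights:
        validate_group(g)
    total = sum(weights.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"group weights must sum to 1 (got {total})")

    positive = {g: w for g, w in weights.items() if w > 0}
    # Largest-remainder allocation, then top up empty groups if room.
    quotas = {g: w * n_conditions for g, w in positive.items()}
    counts = {g: int(math.floor(q)) for g, q in quotas.items()}
    remainder = n_conditions - sum(counts.values())
    by_frac = sorted(positive, key=lambda g: (counts[g] - quotas[g], g))
    for g in by_frac[:remainder]:
        counts[g] += 1
    if n_conditions >= len(positive):
        empty = [g for g in positive if counts[g] == 0]
        donors = sorted(positive, key=lambda g: -counts[g])
        for g in empty:
            for d in donors:
                if counts[d] > 1:
                    counts[d] -= 1
                    counts[g] += 1
                    break

    rng = np.random.default_rng(seed)
    conditions: list[Condition] = []
    for group in GROUPS:  # fixed order for determinism
        n = counts.get(group, 0)
        lo, hi = _CONCENTRATION_RANGES[group]
        for i in range(n):
            if include_control and group == "hexoses" and i == 0:
                conditions.append(Condition("glucose_20", 20.0, "hexoses"))
                continue
            conc = float(np.round(rng.uniform(lo, hi), 2))
            conditions.append(Condition(f"{group}_{i + 1}_{conc:g}", conc, group))
    return conditions


def _lognormal_noise(rng: np.random.Generator, cv: np.ndarray) -> np.ndarray:
    """Unit-mean multiplicative noise with elementwise CV."""
    sigma2 = np.log1p(np.square(cv))
    sigma = np.sqrt(sigma2)
    z = rng.standard_normal(cv.shape)
    return np.exp(sigma * z - sigma2 / 2.0)


def condition_scores(n_conditions: int, seed: int, skew_sigma: float = 1.5) -> np.ndarray:
    """Standardized right-skewed condition-response scores.

    Quantile points of a lognormal (log-sd ``skew_sigma``) standardized
    to exact zero mean and unit variance, then shuffled. They emulate a
    perturbation space where most conditions suppress the phenotype
    similarly and a few benign ones stand out — the skewed value
    distributions such screens show. Because the scores are exactly
    standardized, a strain with sensitivity ``gamma`` has
    across-condition mean ``baseline`` and variance
    ``(baseline * gamma)**2`` exactly (before replicate noise); the
    lower bound of the scores (> -0.4) keeps ``1 + gamma*u`` positive
    for every realistic sensitivity.
    """
    probs = (np.arange(n_conditions) + 0.5) / n_conditions
    raw = np.exp(skew_sigma * norm.ppf(probs))
    u = (raw - raw.mean()) / raw.std()
    rng = np.random.default_rng(seed)
    rng.shuffle(u)
    return u


def simulate_phenotype_table(
    strains: Sequence[str],
    conditions: Sequence[Condition],
    n_replicates: int,
    model: EffectModel,
) -> SimulatedDataset:
    """Draw a long-format phenotype table from ``model``.

    Each value is ``baseline(strain, phenotype) * factor(condition,
    phenotype) * noise`` with unit-mean lognormal noise at the model's
    CV. Returns the table together with the per-strain across-condition
    ground-truth moments and analytic robustness for recovery tests.
    """
    if len(strains) < 1 or len(conditions) < 1 or n_replicates < 1:
        raise ValueError("need at least 1 strain, 1 condition and 1 replicate")
    phens = [p for p in PHENOTYPES if any(p in m for m in model.baselines.values())]
    if not phens:
        raise ValueError("model defines no phenotype baselines")

    n_s, n_c, n_r, n_p = len(strains), len(conditions), n_replicates, len(phens)
    base = np.array(
        [[model.baselines[s].get(p, np.nan) for p in phens] for s in strains]
    )  # (s, p)
    if np.isnan(base).any():
        missing = [
            (s, p)
            for s in strains
            for p in phens
            if p not in model.baselines[s]
        ]
        raise ValueError(f"baselines missing for {missing[:5]}")
    fact = np.array(
        [[model.factor(c.name, p) for p in phens] for c in conditions]
    )  # (c, p)
    cv = np.array([[model.cv(s, p) for p in phens] for s in strains])  # (s, p)

    mean = base[:, None, :] * fact[None, :, :]  # (s, c, p)
    if model.sensitivity:
        scores = condition_scores(n_c, seed=model.seed)  # fixed per space
        gamma = np.array(
            [
                [model.sensitivity.get(p, {}).get(s, 0.0) for p in phens]
                for s in strains
            ]
        )  # (s, p)
        response = 1.0 + gamma[:, None, :] * scores[None, :, None]
        if np.any(response <= 0):
            raise ValueError(
                "condition response 1 + gamma*u is non-positive for some well; "
                "reduce the sensitivity"
            )
        mean = mean * response
    rng = np.random.default_rng(model.seed)
    cv_full = np.broadcast_to(cv[:, None, None, :], (n_s, n_c, n_r, n_p))
    noise = _lognormal_noise(rng, np.ascontiguousarray(cv_full))
    values = np.maximum(mean[:, :, None, :] * noise, 0.0)

    table = pd.DataFrame(
        {
            "strain": np.repeat(strains, n_c * n_r * n_p),
            "condition": np.tile(np.repeat([c.name for c in conditions], n_r * n_p), n_s),
            "group": np.tile(np.repeat([c.group for c in conditions], n_r * n_p), n_s),
            "replicate": np.tile(np.repeat(np.arange(1, n_r + 1), n_p), n_s * n_c),
            "phenotype": np.tile(phens, n_s * n_c * n_r),
            "value": values.ravel(),
        }
    )
    table["units"] = table["phenotype"].map(UNITS)
    table["qc_flags"] = ""

    # Ground truth: population moments across the fixed condition set
    # (replicate noise included), and the analytic robustness
    # R = -(var/mean)/m computed from the noiseless mean array.
    truth_rows = []
    mu_cond = mean.mean(axis=1)  # (s, p) across-condition mean
    mu2_cond = np.square(mean).mean(axis=1)
    grand_mean = mu_cond.mean(axis=0)  # (p,) mean over strains
    for i, s in enumerate(strains):
        for j, p in enumerate(phens):
            mu_sp = mu_cond[i, j]
            var_sp = mu2_cond[i, j] * (1.0 + cv[i, j] ** 2) - mu_sp**2
            truth_rows.append(
                {
                    "strain": s,
                    "phenotype": p,
                    "mean": mu_sp,
                    "variance": var_sp,
                    "fano": var_sp / mu_sp,
                    "grand_mean": grand_mean[j],
                    "robustness": -(var_sp / mu_sp) / grand_mean[j],
                }
            )
    truth = pd.DataFrame(truth_rows)
    return SimulatedDataset(table=table, truth=truth, model=model,
                            conditions=list(conditions))


def gompertz_log_signal(
    t: np.ndarray, A: float, mu: float, lam: float, baseline: float
) -> np.ndarray:
    """ln(signal) of the Zwietering-Gompertz model.

    ln(y/y0) = A_ln * exp(-exp(mu*e/A_ln * (lam - t) + 1)) with
    A_ln = ln(A/baseline); the maximum slope of ln(y) is exactly ``mu``
    and the tangent at that point crosses the baseline level at
    ``t = lam``.
    """
    log_base = math.log(baseline)
    if mu == 0:
        return np.full_like(np.asarray(t, dtype=float), log_base)
    a_ln = math.log(A / baseline)
    inner = mu * math.e / a_ln * (lam - np.asarray(t, dtype=float)) + 1.0
    return log_base + a_ln * np.exp(-np.exp(inner))


def simulate_growth_curves(
    params: Sequence[GompertzParams],
    dt: float,
    t_end: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[GrowthCurve]:
    """Sample Zwietering-Gompertz reader curves on a regular time grid.

    Additive Gaussian noise of ``noise_sd`` signal units is applied to
    the signal; noisy values are floored at a small positive level so
    the log transform downstream stays defined.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t_end <= dt:
        raise ValueError("t_end must exceed dt")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.arange(0.0, t_end + dt / 2, dt)
    rng = np.random.default_rng(seed)
    curves = []
    for p in params:
        signal = np.exp(gompertz_log_signal(t, p.A, p.mu, p.lam, p.baseline))
        if noise_sd > 0:
            signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
            signal = np.maximum(signal, 1e-6)
        curves.append(
            GrowthCurve(
                strain=p.strain,
                condition=p.condition,
                replicate=p.replicate,
                times=t.copy(),
                signal=signal,
            )
        )
    return curves


def embed_tradeoff(
    strains: Sequence[str],
    spec: TradeoffSpec,
    robustness_range: tuple[float, float] = (0.1, 0.9),
    performance_sd: float = 0.3,
    replicate_cv: float = 0.1,
) -> EffectModel:
    """Construct an EffectModel with a target performance-robustness rank correlation.

    A Gaussian copula couples per-strain mean performance (lognormal
    around the phenotype-typical level, spread ``performance_sd`` on the
    log scale) with the magnitude of the analytic robustness
    ``R = -(sigma^2/xbar)/m``, drawn over ``robustness_range``
    (0.1-0.9, the order of magnitude robustness screens report). The
    population Spearman correlation between mean performance and R
    equals ``spec.rho`` exactly in the copula's latent ranks; a finite
    strain panel realizes it up to rank-sampling noise.

    The across-condition variance is carried by strain-specific
    sensitivities to fixed condition scores (reproducible across
    replicates, like real condition effects), solved so that the
    analytic robustness of strain *s* is exactly ``-q_s`` once the
    ``replicate_cv`` noise is accounted for:
    ``gamma^2 = (q*m/b - cv^2) / (1 + cv^2)``.
    """
    if len(strains) < 5:
        raise ValueError("need at least 5 strains to realize a rank correlation")
    rho = spec.rho
    # Pearson correlation of the latent normals that yields a
    # population Spearman of rho.
    r_p = 2.0 * math.sin(math.pi * rho / 6.0)
    rng = np.random.default_rng(spec.seed)
    z1 = rng.standard_normal(len(strains))
    w = rng.standard_normal(len(strains))
    z2 = r_p * z1 + math.sqrt(max(0.0, 1.0 - r_p**2)) * w

    typical = TYPICAL_BASELINES[spec.phenotype]
    perf = typical * np.exp(performance_sd * z1 - performance_sd**2 / 2.0)
    q_lo, q_hi = robustness_range
    # Magnitude of R increases as z2 decreases -> R increasing in z2,
    # so Spearman(perf, R) = Spearman(z1, z2) = rho.
    q = q_lo + (q_hi - q_lo) * norm.cdf(-z2)

    m = float(perf.mean())  # grand mean: across-condition means equal b_s
    gamma_sq = (q * m / perf - replicate_cv**2) / (1.0 + replicate_cv**2)
    if np.any(gamma_sq <= 0):
        raise ValueError(
            "replicate_cv alone exceeds the smallest targeted dispersion; "
            "lower replicate_cv or raise the robustness range"
        )
    gamma = np.sqrt(gamma_sq)

    baselines = {}
    sens_strain = {}
    for i, s in enumerate(strains):
        means = dict(TYPICAL_BASELINES)
        means[spec.phenotype] = float(perf[i])
        baselines[s] = means
        sens_strain[s] = float(gamma[i])
    noise_cv: dict[str, float | Mapping[str, float]] = {
        p: replicate_cv for p in PHENOTYPES
    }
    return EffectModel(
        baselines=baselines,
        noise_cv=noise_cv,
        sensitivity={spec.phenotype: sens_strain},
        seed=spec.seed,
    )
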