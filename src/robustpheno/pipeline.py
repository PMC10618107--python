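"""End-to-end orchestration of the robustness analysis.

A single configuration drives either a fully synthetic run (the
generator produces the phenotype table) or the analysis of measured
tables read from CSV. Stages: data acquisition -> QC -> robustness ->
group influence -> trade-off statistics -> optional transfer analysis
-> report. All randomness fans out deterministically from one root
seed, and every stage table is written to the output directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import config_hash, read_phenotype_csv, write_phenotype_csv
from .qc import TrimBounds, run_qc
from .robustness import group_influence, normalization_constants, robustness_table
from .schema import GROUPS, MU_MAX
from .synthetic import (
    DEFAULT_STRAINS,
    EffectModel,
    TradeoffSpec,
    embed_tradeoff,
    make_perturbation_space,
    simulate_phenotype_table,
)
from .tradeoffs import (
    all_group_tests,
    cross_phenotype_correlations,
    performance_robustness_tradeoffs,
)
from .transfer import (
    improvement_robustness_correlation,
    make_transfer_records,
    resolve_infinities,
    transfer_summary,
)

__all__ = ["SimulationSpec", "PipelineConfig", "RunReport", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class SimulationSpec:
    """Synthetic-study design: counts, noise and optional trade-off."""

    n_strains: int = 24
    n_conditions: int = 29
    n_replicates: int = 3
    noise_cv: float = 0.2
    tradeoff_phenotype: str | None = None
    tradeoff_rho: float = -0.7
    include_transfer: bool = False
    transfer_improvement: float = 0.3  # mean fractional mu_max gain
    transfer_noise_cv: float = 0.1


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of ``simulation`` or ``phenotype_csv`` must be set;
    curve-level inputs go through :mod:`robustpheno.phenotypes` first.
    """

    output_dir: str | Path = "results"
    seed: int = 0
    simulation: SimulationSpec | None = None
    phenotype_csv: str | Path | None = None
    transfer_second_csv: str | Path | None = None
    trim_bounds: TrimBounds | None = None
    alpha: float = 0.05
    reference_group: str = "hexoses"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationSpec(**sim)
        return cfg

    def validate(self) -> None:
        if (self.simulation is None) == (self.phenotype_csv is None):
            raise ValueError(
                "exactly one of 'simulation' or 'phenotype_csv' must be provided"
            )


@dataclass
class RunReport:
    """Stage-by-stage record counts and skip reasons for one run."""

    version: str = __version__
    config: dict = field(default_factory=dict)
    config_hash: str = ""
    seed: int = 0
    started: str = ""
    finished: str = ""
    stage_counts: dict[str, int] = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    skipped: list[dict] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds below 2**31 from one root seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _simulate_stage(spec: SimulationSpec, seed: int):
    seeds = _spawn_seeds(seed, 3)
    strains = list(DEFAULT_STRAINS[: spec.n_strains])
    if spec.n_strains > len(DEFAULT_STRAINS):
        strains += [f"strain_{i:02d}" for i in range(25, spec.n_strains + 1)]
    conditions = make_perturbation_space(spec.n_conditions, seed=seeds[0])
    if spec.tradeoff_phenotype:
        model = embed_tradeoff(
            strains,
            TradeoffSpec(spec.tradeoff_phenotype, spec.tradeoff_rho, seed=seeds[1]),
        )
        # keep the configured replicate noise on the other phenotypes
        noise = dict(model.noise_cv)
        for p, v in noise.items():
            if p != spec.tradeoff_phenotype:
                noise[p] = spec.noise_cv
        model = EffectModel(
            baselines=model.baselines, condition_factors=model.condition_factors,
            noise_cv=noise, sensitivity=model.sensitivity, seed=seeds[2],
        )
    else:
        model = EffectModel.uniform(strains, noise_cv=spec.noise_cv, seed=seeds[2])
    return simulate_phenotype_table(strains, conditions, spec.n_replicates, model)


def _simulate_transfer(
    table: pd.DataFrame, spec: SimulationSpec, seed: int
) -> pd.DataFrame:
    """Second-cultivation mu_max table: first-run rates scaled up with noise."""
    rng = np.random.default_rng(seed)
    second = table.loc[table["phenotype"] == MU_MAX].copy()
    gain = 1.0 + spec.transfer_improvement
    sigma2 = np.log1p(spec.transfer_noise_cv**2)
    noise = np.exp(
        np.sqrt(sigma2) * rng.standard_normal(len(second)) - sigma2 / 2
    )
    second["value"] = second["value"].to_numpy() * gain * noise
    return second


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis described by ``config``.

    Writes all stage tables into ``config.output_dir`` and returns the
    run report (also written as ``run_report.json``).
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    conf_dict = asdict(config)
    # the hash covers analysis-relevant settings only, so identical
    # analyses into different directories yield byte-identical tables
    chash = config_hash(
        {k: v for k, v in conf_dict.items() if k not in ("output_dir", "log_level")}
    )
    report = RunReport(
        config=conf_dict, config_hash=chash, seed=config.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    seeds = _spawn_seeds(config.seed, 2)

    def save_csv(frame: pd.DataFrame, name: str) -> None:
        path = outdir / name
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"# robustpheno {__version__} config={chash}\n")
            frame.to_csv(fh, index=False, lineterminator="\n")
        report.outputs.append(str(path))

    # --- acquire -----------------------------------------------------
    if config.simulation is not None:
        dataset = _simulate_stage(config.simulation, seeds[0])
        table = dataset.table
        save_csv(dataset.truth, "ground_truth.csv")
    else:
        table = read_phenotype_csv(config.phenotype_csv)
    report.stage_counts["input"] = len(table)
    logger.info("input: %d records", len(table))
    write_phenotype_csv(table, outdir / "phenotypes_raw.csv", chash)
    report.outputs.append(str(outdir / "phenotypes_raw.csv"))

    # --- qc ----------------------------------------------------------
    clean, qc_report = run_qc(table, bounds=config.trim_bounds)
    report.qc = qc_report.to_dict()
    report.stage_counts["after_qc"] = len(clean)
    logger.info(
        "qc: %d -> %d records (%d trimmed, %d excluded, %d flagged)",
        len(table), len(clean), qc_report.n_trimmed, qc_report.n_excluded,
        qc_report.n_outliers_flagged,
    )
    write_phenotype_csv(clean, outdir / "phenotypes_qc.csv", chash)
    report.outputs.append(str(outdir / "phenotypes_qc.csv"))
    (outdir / "qc_report.json").write_text(json.dumps(qc_report.to_dict(), indent=2))
    report.outputs.append(str(outdir / "qc_report.json"))

    # --- robustness --------------------------------------------------
    m = normalization_constants(clean)
    rtable = robustness_table(clean, m=m)
    report.stage_counts["robustness_entries"] = int(np.isfinite(rtable["R"]).sum())
    for rec in rtable.loc[~np.isfinite(rtable["R"])].itertuples(index=False):
        report.skipped.append(
            {"stage": "robustness", "strain": rec.strain,
             "phenotype": rec.phenotype, "reason": rec.reason}
        )
    save_csv(rtable, "robustness.csv")

    # --- group influence --------------------------------------------
    influence = pd.concat(
        [
            group_influence(clean, g, m=m, rtable_all=rtable)
            for g in GROUPS
            if g in set(clean["group"])
        ],
        ignore_index=True,
    )
    save_csv(influence, "influence.csv")

    # --- trade-offs --------------------------------------------------
    diagonal, matrix = performance_robustness_tradeoffs(clean, rtable)
    save_csv(diagonal, "tradeoffs.csv")
    save_csv(matrix, "tradeoff_matrix.csv")
    cross = cross_phenotype_correlations(clean)
    save_csv(cross, "cross_correlations.csv")
    group_tests = all_group_tests(
        clean, reference=config.reference_group, alpha=config.alpha
    )
    save_csv(group_tests, "group_tests.csv")

    # --- transfer (optional) ----------------------------------------
    second = None
    if config.simulation is not None and config.simulation.include_transfer:
        second = _simulate_transfer(clean, config.simulation, seeds[1])
    elif config.transfer_second_csv is not None:
        second = read_phenotype_csv(config.transfer_second_csv)
    if second is not None:
        records = resolve_infinities(make_transfer_records(clean, second))
        summary = transfer_summary(records)
        save_csv(records, "transfer.csv")
        save_csv(summary.per_strain, "transfer_summary.csv")
        save_csv(summary.per_group, "transfer_groups.csv")
        save_csv(
            improvement_robustness_correlation(records, rtable),
            "transfer_robustness_correlation.csv",
        )
        report.stage_counts["transfer_records"] = len(records)

    report.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "run_report.json").write_text(report.to_json())
    report.outputs.append(str(outdir / "run_report.json"))
    return report
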