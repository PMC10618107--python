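"""CSV exchange formats.

All tables travel as RFC-4180 CSV, UTF-8, "." decimal separator, LF
line endings. Written files start with a ``#`` comment line recording
the tool version and a hash of the generating configuration; readers
skip comment lines, so write/read round-trips are identity maps on the
data.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import __version__
from .phenotypes import GrowthCurve
from .schema import (
    CURVE_COLUMNS,
    KEY_COLUMNS,
    PHENOTYPE_COLUMNS,
    PHENOTYPES,
    Condition,
)

__all__ = [
    "config_hash",
    "read_phenotype_csv",
    "write_phenotype_csv",
    "read_curves_csv",
    "write_curves_csv",
]


def config_hash(config: object) -> str:
    """Short stable hash of a JSON-serializable configuration object."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header_comment(conf_hash: str | None) -> str:
    return f"# robustpheno {__version__} config={conf_hash or 'none'}\n"


def write_phenotype_csv(
    table: pd.DataFrame, path: str | Path, conf_hash: str | None = None
) -> None:
    """Write a long-format phenotype table with a version comment line."""
    path = Path(path)
    cols = [c for c in PHENOTYPE_COLUMNS if c in table.columns]
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(_header_comment(conf_hash))
        table[cols].to_csv(fh, index=False, lineterminator="\n")


def read_phenotype_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a phenotype CSV written by :func:`write_phenotype_csv`.

    Rejects missing columns, unknown phenotype labels (with row
    numbers), duplicated key tuples and malformed numeric values
    (listing up to 10 offending lines).
    """
    path = Path(path)
    table = pd.read_csv(
        path, comment="#", dtype={"strain": str, "condition": str, "group": str}
    )
    missing = [c for c in PHENOTYPE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")

    bad_phen = ~table["phenotype"].isin(PHENOTYPES)
    if bad_phen.any():
        rows = (table.index[bad_phen] + 2).tolist()[:10]  # +2: header + 1-based
        labels = sorted(table.loc[bad_phen, "phenotype"].unique())
        raise ValueError(
            f"{path}: unknown phenotype label(s) {labels} at row(s) {rows}"
        )

    values = pd.to_numeric(table["value"], errors="coerce")
    raw_na = table["value"].isna()
    malformed = values.isna() & ~raw_na
    if malformed.any():
        rows = (table.index[malformed] + 2).tolist()[:10]
        raise ValueError(f"{path}: non-numeric value(s) at row(s) {rows}")
    table["value"] = values

    dup = table.duplicated(list(KEY_COLUMNS))
    if dup.any():
        tuples = (
            table.loc[dup, list(KEY_COLUMNS)].head(10).to_records(index=False).tolist()
        )
        raise ValueError(f"{path}: duplicated key tuple(s): {tuples}")

    table["qc_flags"] = table["qc_flags"].fillna("")
    return table


def write_curves_csv(
    curves: Iterable[GrowthCurve], path: str | Path, conf_hash: str | None = None
) -> None:
    """Write growth curves in the long reader format."""
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "strain": c.strain,
                    "condition": c.condition.name,
                    "group": c.condition.group,
                    "concentration_g_l": c.condition.concentration,
                    "replicate": c.replicate,
                    "time_h": c.times,
                    "signal": c.signal,
                }
            )
        )
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(CURVE_COLUMNS))
    )
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(_header_comment(conf_hash))
        table.to_csv(fh, index=False, lineterminator="\n")


def read_curves_csv(path: str | Path) -> list[GrowthCurve]:
    """Read growth curves from the long reader format."""
    table = pd.read_csv(Path(path), comment="#", dtype={"strain": str})
    missing = [c for c in CURVE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    curves = []
    for (strain, cond, grp, conc, rep), sub in table.groupby(
        ["strain", "condition", "group", "concentration_g_l", "replicate"], sort=True
    ):
        sub = sub.sort_values("time_h")
        curves.append(
            GrowthCurve(
                strain=str(strain),
                condition=Condition(str(cond), float(conc), str(grp)),
                replicate=int(rep),
                times=sub["time_h"].to_numpy(dtype=float),
                signal=sub["signal"].to_numpy(dtype=float),
            )
        )
    return curves
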