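"""Tabular I/O: time series, matrices, manifests and analysis reports.

All tabular artifacts are TSV (regions as rows, first column the region
label; matrices with region-name header row and column).  Numeric values
are written in scientific notation with 17 significant digits so write/read
round-trips are bitwise exact.  Per-series acquisition metadata (TR) lives
in a JSON sidecar next to the TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .connectivity import FCMatrix, RunTimeSeries
from .parcellation import ParcellationScheme, read_scheme, write_scheme

__all__ = [
    "Manifest",
    "ManifestRow",
    "read_manifest",
    "write_manifest",
    "read_timeseries",
    "write_timeseries",
    "read_matrix",
    "write_matrix",
    "write_report",
    "read_report",
]

_FLOAT_FMT = "%.17e"


@dataclass(frozen=True)
class ManifestRow:
    subject_id: str
    run_id: str
    path: str


@dataclass
class Manifest:
    """Two-run cohort listing: one row per subject-run series file."""

    rows: list[ManifestRow]
    dataset_name: str = ""
    scheme_path: str = ""

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for row in self.rows:
            counts[row.subject_id] = counts.get(row.subject_id, 0) + 1
        bad = sorted(s for s, c in counts.items() if c != 2)
        if bad:
            raise ValueError(
                f"every subject needs exactly 2 runs; offenders: {bad}"
            )

    @property
    def subjects(self) -> list[str]:
        seen: list[str] = []
        for row in self.rows:
            if row.subject_id not in seen:
                seen.append(row.subject_id)
        return seen

    def paths_for(self, subject_id: str) -> list[str]:
        return [r.path for r in self.rows if r.subject_id == subject_id]


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    lines = ["subject_id\trun_id\tpath"]
    lines += [f"{r.subject_id}\t{r.run_id}\t{r.path}" for r in manifest.rows]
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path: str | Path) -> Manifest:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["subject_id", "run_id", "path"]
    if list(df.columns)[:3] != expected:
        raise ValueError(f"manifest must have columns {expected}, got {list(df.columns)}")
    rows = [
        ManifestRow(subject_id=r.subject_id, run_id=r.run_id, path=r.path)
        for r in df.itertuples()
    ]
    return Manifest(rows=rows)


def write_timeseries(ts: RunTimeSeries, path: str | Path) -> None:
    """Region x time TSV plus a JSON sidecar with TR and ids."""
    path = Path(path)
    df = pd.DataFrame(ts.data, index=list(ts.region_names()))
    df.index.name = "region"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    sidecar = {
        "tr": ts.tr,
        "subject_id": ts.subject_id,
        "run_id": ts.run_id,
        "n_regions": ts.n_regions,
        "n_timepoints": ts.n_timepoints,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1) + "\n"
    )


def read_timeseries(
    path: str | Path, scheme: Optional[ParcellationScheme] = None
) -> RunTimeSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = {}
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    if scheme is not None and list(df.index) != list(scheme.names):
        raise ValueError(
            f"region rows in {path} do not match the scheme "
            f"({len(df.index)} rows vs {scheme.n_regions} scheme regions)"
        )
    return RunTimeSeries(
        data=df.to_numpy(dtype=float),
        tr=float(meta.get("tr", 1.0)),
        scheme=scheme,
        subject_id=str(meta.get("subject_id", "")),
        run_id=str(meta.get("run_id", "")),
    )


def write_matrix(
    values: np.ndarray | FCMatrix,
    path: str | Path,
    names: Optional[Sequence[str]] = None,
) -> None:
    """Square matrix TSV with region names as header row and column."""
    if isinstance(values, FCMatrix):
        if names is None and values.scheme is not None:
            names = values.scheme.names
        values = values.values
    values = np.asarray(values, dtype=float)
    if names is None:
        names = [f"r{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=list(names), columns=list(names))
    df.index.name = "region"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=float), list(df.index.astype(str))


def write_report(report: dict, path: str | Path) -> None:
    """JSON report at full float precision (default json repr round-trips)."""
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
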