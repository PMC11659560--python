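"""Reading sample files (FCS/CSV) plus sample metadata into a CytoTable.

Each input file is one sample's compensated per-cell marker intensities.  The
reader concatenates all files in metadata order, assigns unique cell ids
``"<file stem>_<1-based event index>"``, optionally subsamples a fixed number
of events per file (seed-deterministic, per-file independent), and replicates
the per-file metadata onto every cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CytoTable, check_integrity
from .fcs import read_fcs, write_fcs

__all__ = ["IngestSpec", "read_samples", "write_samples", "read_metadata"]


@dataclass
class IngestSpec:
    """What to ingest and how.

    ``metadata`` must have one row per file with columns ``file`` and
    ``sample_id`` (arbitrary extra columns — group, batch, date — are carried
    into both the per-cell annotation and the sample metadata table).
    """

    file_paths: list[str | Path]
    metadata: pd.DataFrame
    subsample_n: int | None = None
    seed: int = 0
    marker_include: list[str] | None = None
    marker_exclude: list[str] | None = None
    prefer_detector_names: bool = False  # use $PnN instead of $PnS

    def validate(self) -> None:
        if "file" not in self.metadata.columns or "sample_id" not in self.metadata.columns:
            raise ValueError("metadata requires columns 'file' and 'sample_id'")
        meta_files = [str(f) for f in self.metadata["file"]]
        spec_files = [str(f) for f in self.file_paths]
        if sorted(meta_files) != sorted(spec_files):
            raise ValueError(
                "file_paths and metadata['file'] must list the same files exactly once"
            )
        if len(set(spec_files)) != len(spec_files):
            raise ValueError("duplicate file paths")
        if self.subsample_n is not None and self.subsample_n <= 0:
            raise ValueError("subsample_n must be > 0 when set")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a delimited metadata table (columns ``file``, ``sample_id``, extras)."""
    return pd.read_csv(path)


def _read_one(path: Path, prefer_detector: bool) -> pd.DataFrame:
    if path.suffix.lower() == ".fcs":
        data, pnn, pns, _ = read_fcs(path)
        if prefer_detector:
            names = pnn
        else:
            # stain names where present, detector names otherwise
            names = [s if s else n for n, s in zip(pnn, pns)]
        return pd.DataFrame(data, columns=names)
    df = pd.read_csv(path)
    return df.astype(float)


def read_samples(spec: IngestSpec) -> CytoTable:
    """Ingest all files of a :class:`IngestSpec` into a fresh CytoTable."""
    spec.validate()
    meta = spec.metadata.set_index("file", drop=False)

    frames: list[pd.DataFrame] = []
    anno_frames: list[pd.DataFrame] = []
    markers_ref: list[str] | None = None
    for i, fp in enumerate(spec.file_paths):
        path = Path(fp)
        if not path.exists():
            raise FileNotFoundError(f"file listed in metadata not found on disk: {path}")
        df = _read_one(path, spec.prefer_detector_names)
        if spec.marker_include is not None:
            missing = set(spec.marker_include) - set(df.columns)
            if missing:
                raise ValueError(f"{path}: requested markers absent: {sorted(missing)}")
            df = df[[m for m in spec.marker_include]]
        if spec.marker_exclude:
            df = df[[c for c in df.columns if c not in set(spec.marker_exclude)]]
        if markers_ref is None:
            markers_ref = list(df.columns)
        elif set(df.columns) != set(markers_ref):
            diff = sorted(set(df.columns) ^ set(markers_ref))
            raise ValueError(
                f"marker sets differ across files (symmetric difference: {diff})"
            )
        else:
            df = df[markers_ref]

        n = len(df)
        if spec.subsample_n is not None and spec.subsample_n < n:
            rng = np.random.default_rng([spec.seed, i])
            keep = np.sort(rng.choice(n, size=spec.subsample_n, replace=False))
        else:
            keep = np.arange(n)
        ids = [f"{path.stem}_{j + 1}" for j in keep]
        sub = df.iloc[keep].copy()
        sub.index = pd.Index(ids, name="cell_id")
        frames.append(sub)

        row = meta.loc[str(fp)]
        anno = pd.DataFrame(index=sub.index)
        for col in spec.metadata.columns:
            if col != "file":
                anno[col] = row[col]
        anno_frames.append(anno)

    expr_raw = pd.concat(frames, axis=0)
    anno = pd.concat(anno_frames, axis=0)
    sample_meta = (
        spec.metadata.drop_duplicates(subset="sample_id")
        .set_index("sample_id", drop=False)
        .drop(columns=["sample_id"])
    )
    table = CytoTable(expr_raw=expr_raw, anno=anno, sample_meta=sample_meta)
    table.log_event(
        "read_samples",
        seed=spec.seed,
        n_files=len(spec.file_paths),
        subsample_n=spec.subsample_n,
        markers=markers_ref,
    )
    return table


def write_samples(
    table: CytoTable, out_dir: str | Path, format: str = "fcs"
) -> list[Path]:
    """Write ``expr_raw`` back to one file per sample (FCS float32 or CSV)."""
    if table.n_cells == 0:
        raise ValueError("empty table: nothing to write")
    if format not in ("fcs", "csv"):
        raise ValueError(f"unknown format {format!r}")
    report = check_integrity(table)
    if not report.passed:
        raise ValueError(f"table fails integrity checks: {report.violations}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for sample_id, sub in table.expr_raw.groupby(
        table.anno["sample_id"], sort=False
    ):
        path = out_dir / f"{sample_id}.{format}"
        if format == "fcs":
            write_fcs(path, sub.to_numpy(), table.markers)
        else:
            sub.to_csv(path, index=False)
        written.append(path)
    return written
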