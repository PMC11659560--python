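"""Unified analysis container for high-dimensional cytometry data.

A :class:`CytoTable` holds everything one analysis accumulates: the raw and
transformed cell-by-marker matrices, an optional batch-corrected matrix kept in
a *separate* slot (originals are never overwritten), per-cell annotation,
per-sample metadata, named dimensionality reductions, named clusterings,
trained models, and an ordered provenance log.

All cell-indexed structures are keyed by unique cell identifiers of the form
``"<filename>_<1-based event index>"``; joins are always by cell id, never by
position, so the container survives filtering.
"""

from __future__ import annotations

import datetime as _dt
import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CytoTable",
    "Reduction",
    "IntegrityReport",
    "check_integrity",
    "subset_cells",
    "save_archive",
    "load_archive",
]


@dataclass
class Reduction:
    """A named embedding (PCA scores, UMAP/tSNE/DM coordinates)."""

    coords: pd.DataFrame  # rows aligned to cell_ids
    kind: str  # "pca" | "umap" | "tsne" | "dm"
    input_slot: str  # "expr" | "expr_corrected" | "pca" | "pca_corrected"
    corrected: bool = False
    seed: int | None = None
    extras: dict = field(default_factory=dict)  # loadings, explained_variance, ...

    def copy(self) -> "Reduction":
        return Reduction(
            coords=self.coords.copy(),
            kind=self.kind,
            input_slot=self.input_slot,
            corrected=self.corrected,
            seed=self.seed,
            extras={
                k: (v.copy() if hasattr(v, "copy") else v)
                for k, v in self.extras.items()
            },
        )


@dataclass
class IntegrityReport:
    passed: bool
    violations: list[tuple[str, str]]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.passed:
            return "integrity: OK (0 violations)"
        lines = [f"integrity: FAILED ({len(self.violations)} violations)"]
        lines += [f"  [{slot}] {desc}" for slot, desc in self.violations]
        return "\n".join(lines)


@dataclass
class CytoTable:
    """Container for one cytometry analysis.

    Parameters
    ----------
    expr_raw
        Cells x markers matrix of raw (a.u.) intensities, indexed by cell id.
    anno
        Per-cell annotation; must contain a ``sample_id`` column.
    sample_meta
        Per-sample metadata indexed by sample id.
    """

    expr_raw: pd.DataFrame
    anno: pd.DataFrame
    sample_meta: pd.DataFrame
    expr: pd.DataFrame | None = None
    expr_corrected: pd.DataFrame | None = None
    reductions: dict[str, Reduction] = field(default_factory=dict)
    clusterings: dict[str, pd.Series] = field(default_factory=dict)
    models: dict[str, Any] = field(default_factory=dict)
    log: list[dict] = field(default_factory=list)

    # -- basic accessors ---------------------------------------------------
    @property
    def cell_ids(self) -> pd.Index:
        return self.expr_raw.index

    @property
    def n_cells(self) -> int:
        return len(self.expr_raw)

    @property
    def markers(self) -> list[str]:
        return list(self.expr_raw.columns)

    def get_matrix(self, slot: str) -> pd.DataFrame:
        """Return the cells x features matrix for a named slot.

        Valid slots: ``expr``, ``expr_raw``, ``expr_corrected``, ``pca``,
        ``pca_corrected`` and any reduction name.
        """
        if slot == "expr_raw":
            return self.expr_raw
        if slot == "expr":
            if self.expr is None:
                raise ValueError("slot 'expr' is empty: run a transform first")
            return self.expr
        if slot == "expr_corrected":
            if self.expr_corrected is None:
                raise ValueError("slot 'expr_corrected' is empty: run harmonize first")
            return self.expr_corrected
        if slot in self.reductions:
            return self.reductions[slot].coords
        raise ValueError(f"unknown slot {slot!r}")

    def log_event(self, operation: str, seed: int | None = None, **params: Any) -> None:
        self.log.append(
            {
                "operation": operation,
                "parameters": _jsonable(params),
                "timestamp": _dt.datetime.now().isoformat(timespec="seconds"),
                "seed": seed,
            }
        )

    def copy(self) -> "CytoTable":
        return CytoTable(
            expr_raw=self.expr_raw.copy(),
            anno=self.anno.copy(),
            sample_meta=self.sample_meta.copy(),
            expr=None if self.expr is None else self.expr.copy(),
            expr_corrected=(
                None if self.expr_corrected is None else self.expr_corrected.copy()
            ),
            reductions={k: v.copy() for k, v in self.reductions.items()},
            clusterings={k: v.copy() for k, v in self.clusterings.items()},
            models=dict(self.models),
            log=[dict(r) for r in self.log],
        )


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return repr(obj)


# -- integrity -------------------------------------------------------------

def check_integrity(table: CytoTable) -> IntegrityReport:
    """Validate the structural contracts of a :class:`CytoTable`.

    Checks row counts and cell-id ordering across every cell-indexed slot,
    marker-name uniqueness and identity across expression slots, and the
    bijection between annotation sample ids and the sample-metadata table.
    Violations are reported, never raised; the table is not mutated.
    """
    violations: list[tuple[str, str]] = []
    ref_ids = table.expr_raw.index

    if ref_ids.has_duplicates:
        violations.append(("expr_raw", "duplicate cell ids"))

    def _check_rows(slot: str, idx: pd.Index) -> None:
        if len(idx) != len(ref_ids):
            violations.append(
                (slot, f"row count {len(idx)} != {len(ref_ids)} cells")
            )
        elif not idx.equals(ref_ids):
            violations.append((slot, "cell id ordering differs from expr_raw"))

    for slot in ("expr", "expr_corrected"):
        mat = getattr(table, slot)
        if mat is not None:
            _check_rows(slot, mat.index)
            if list(mat.columns) != list(table.expr_raw.columns):
                violations.append((slot, "marker names differ from expr_raw"))
    _check_rows("anno", table.anno.index)
    for name, red in table.reductions.items():
        _check_rows(f"reduction:{name}", red.coords.index)
        if not np.all(np.isfinite(red.coords.to_numpy())):
            violations.append((f"reduction:{name}", "non-finite coordinates"))
    for name, labels in table.clusterings.items():
        _check_rows(f"clustering:{name}", labels.index)

    cols = pd.Index(table.expr_raw.columns)
    if cols.has_duplicates:
        violations.append(("expr_raw", "duplicate marker names"))

    if "sample_id" not in table.anno.columns:
        violations.append(("anno", "missing 'sample_id' column"))
    else:
        anno_samples = set(table.anno["sample_id"].unique())
        meta_samples = set(table.sample_meta.index)
        missing = anno_samples - meta_samples
        extra = meta_samples - anno_samples
        if missing:
            violations.append(
                ("sample_meta", f"sample ids absent from sample_meta: {sorted(missing)}")
            )
        if extra:
            violations.append(
                ("sample_meta", f"sample ids with no cells in anno: {sorted(extra)}")
            )

    return IntegrityReport(passed=not violations, violations=violations)


# -- subsetting ------------------------------------------------------------

def subset_cells(table: CytoTable, mask: Iterable[bool]) -> CytoTable:
    """Return a new table restricted to the cells where ``mask`` is True.

    Expression values of surviving cells are carried over bit-identical: the
    subset is *not* re-transformed or re-scaled, so marker intensities remain
    comparable with the full dataset.  Trained models and embeddings refer to
    the full dataset and are dropped (a provenance record notes this);
    clusterings and annotation are filtered, and ``sample_meta`` is restricted
    to samples that still have cells.
    """
    mask = np.asarray(list(mask), dtype=bool)
    if mask.shape[0] != table.n_cells:
        raise ValueError(
            f"mask length {mask.shape[0]} != cell count {table.n_cells}"
        )
    if not mask.any():
        raise ValueError("no cells selected")

    anno = table.anno.loc[mask].copy()
    kept_samples = anno["sample_id"].unique()
    out = CytoTable(
        expr_raw=table.expr_raw.loc[mask].copy(),
        anno=anno,
        sample_meta=table.sample_meta.loc[
            table.sample_meta.index.isin(kept_samples)
        ].copy(),
        expr=None if table.expr is None else table.expr.loc[mask].copy(),
        expr_corrected=(
            None
            if table.expr_corrected is None
            else table.expr_corrected.loc[mask].copy()
        ),
        clusterings={k: v.loc[mask].copy() for k, v in table.clusterings.items()},
        log=[dict(r) for r in table.log],
    )
    dropped = sorted(table.reductions) + sorted(table.models)
    out.log_event(
        "subset_cells",
        n_selected=int(mask.sum()),
        n_total=int(table.n_cells),
        dropped_models_and_embeddings=dropped,
    )
    return out


# -- serialization ---------------------------------------------------------
# Single-directory archive: a JSON manifest plus one delimited table per
# slot.  Floats are written with 17 significant digits so a save/load
# round-trip is value-exact for float64.

_FLOAT_FMT = "%.17g"


def save_archive(table: CytoTable, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "format": "hdcyto-archive",
        "version": 1,
        "n_cells": table.n_cells,
        "markers": table.markers,
        "slots": [],
        "reductions": {},
        "clusterings": sorted(table.clusterings),
        "models": sorted(table.models),
    }

    def _write(df: pd.DataFrame, name: str) -> None:
        df.to_csv(path / f"{name}.csv", float_format=_FLOAT_FMT)
        manifest["slots"].append(name)

    _write(table.expr_raw.rename_axis("cell_id"), "expr_raw")
    if table.expr is not None:
        _write(table.expr.rename_axis("cell_id"), "expr")
    if table.expr_corrected is not None:
        _write(table.expr_corrected.rename_axis("cell_id"), "expr_corrected")
    _write(table.anno.rename_axis("cell_id"), "anno")
    _write(table.sample_meta.rename_axis("sample_id"), "sample_meta")

    for name, red in table.reductions.items():
        fname = f"reduction_{name}"
        _write(red.coords.rename_axis("cell_id"), fname)
        manifest["reductions"][name] = {
            "kind": red.kind,
            "input_slot": red.input_slot,
            "corrected": red.corrected,
            "seed": red.seed,
            "extra_keys": sorted(red.extras),
        }
        for key, val in red.extras.items():
            if isinstance(val, pd.DataFrame):
                val.to_csv(path / f"{fname}__{key}.csv", float_format=_FLOAT_FMT)
            elif isinstance(val, (list, tuple, np.ndarray)):
                np.savetxt(path / f"{fname}__{key}.txt", np.asarray(val, dtype=float))

    if table.clusterings:
        clus = pd.DataFrame(table.clusterings)
        clus.rename_axis("cell_id").to_csv(path / "clusterings.csv")

    with open(path / "log.json", "w") as fh:
        json.dump(table.log, fh, indent=1)

    # Models are arbitrary fitted objects (e.g. a retained UMAP transform);
    # they are pickled alongside the text tables for pipeline continuity.
    for name, model in table.models.items():
        with open(path / f"model_{name}.pkl", "wb") as fh:
            pickle.dump(model, fh)

    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return path


def load_archive(path: str | Path) -> CytoTable:
    path = Path(path)
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    if manifest.get("format") != "hdcyto-archive":
        raise ValueError(f"{path} is not an hdcyto archive")

    def _read(name: str) -> pd.DataFrame:
        return pd.read_csv(path / f"{name}.csv", index_col=0)

    slots = set(manifest["slots"])
    table = CytoTable(
        expr_raw=_read("expr_raw"),
        anno=_read("anno"),
        sample_meta=_read("sample_meta"),
        expr=_read("expr") if "expr" in slots else None,
        expr_corrected=_read("expr_corrected") if "expr_corrected" in slots else None,
    )
    for name, meta in manifest["reductions"].items():
        fname = f"reduction_{name}"
        extras: dict[str, Any] = {}
        for key in meta["extra_keys"]:
            df_path = path / f"{fname}__{key}.csv"
            txt_path = path / f"{fname}__{key}.txt"
            if df_path.exists():
                extras[key] = pd.read_csv(df_path, index_col=0)
            elif txt_path.exists():
                extras[key] = np.atleast_1d(np.loadtxt(txt_path))
        table.reductions[name] = Reduction(
            coords=_read(fname),
            kind=meta["kind"],
            input_slot=meta["input_slot"],
            corrected=meta["corrected"],
            seed=meta["seed"],
            extras=extras,
        )
    if manifest["clusterings"]:
        clus = pd.read_csv(path / "clusterings.csv", index_col=0)
        for name in manifest["clusterings"]:
            table.clusterings[name] = clus[name]
    log_path = path / "log.json"
    if log_path.exists():
        with open(log_path) as fh:
            table.log = json.load(fh)
    for name in manifest.get("models", []):
        pkl = path / f"model_{name}.pkl"
        if pkl.exists():
            with open(pkl, "rb") as fh:
                table.models[name] = pickle.load(fh)
    return table
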