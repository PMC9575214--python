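"""Text-format round-tripping: matrices, manifests, results.

All artefacts are delimited text (TSV/CSV), JSON or YAML so runs diff
cleanly.  A dataset on disk is a manifest CSV with columns
``subject_id, group, path`` (paths resolved relative to the manifest) and
one square matrix file per subject; an optional ``input`` column set to
``timeseries`` marks a ``regions x time`` table from which Pearson
correlations and Fisher-z values are computed on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import (
    ConnectivityDataset,
    ConnectivityMatrix,
    RegionSet,
    connectivity_from_time_series,
    devectorize,
)

__all__ = [
    "read_matrix_file",
    "write_matrix_file",
    "read_manifest",
    "load_dataset",
    "write_dataset",
    "write_json",
]

MANIFEST_COLUMNS = ("subject_id", "group", "path")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix_file(path) -> tuple[np.ndarray, list[str] | None]:
    """Read a square delimited matrix, detecting an optional label header.

    Returns ``(values, labels)`` where ``labels`` is ``None`` for headerless
    files.
    """
    path = Path(path)
    sep = _sep_for(path)
    raw = pd.read_csv(path, sep=sep, header=None, dtype=str)
    try:
        values = raw.to_numpy(dtype=float)
        return values, None
    except ValueError:
        pass
    labelled = pd.read_csv(path, sep=sep, header=0, index_col=0)
    try:
        values = labelled.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: could not parse matrix values") from exc
    labels = [str(c) for c in labelled.columns]
    if list(labelled.index.astype(str)) != labels:
        raise ValueError(f"{path}: row and column labels disagree")
    return values, labels


def write_matrix_file(path, values: np.ndarray, labels=None) -> None:
    path = Path(path)
    sep = _sep_for(path)
    if labels is None:
        pd.DataFrame(values).to_csv(path, sep=sep, header=False, index=False,
                                    float_format="%.10g")
    else:
        df = pd.DataFrame(values, index=list(labels), columns=list(labels))
        df.to_csv(path, sep=sep, float_format="%.10g")


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    manifest = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"{path}: manifest is missing columns {missing}")
    return manifest


def load_dataset(manifest_path) -> ConnectivityDataset:
    """Assemble a dataset from a manifest of per-subject matrix files."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    base = manifest_path.parent
    matrices = []
    labels_seen = None
    for row in manifest.itertuples(index=False):
        mpath = Path(row.path)
        if not mpath.is_absolute():
            mpath = base / mpath
        if not mpath.exists():
            raise FileNotFoundError(f"matrix file not found: {mpath}")
        kind = getattr(row, "input", "matrix")
        if isinstance(kind, float) and np.isnan(kind):
            kind = "matrix"
        values, labels = read_matrix_file(mpath)
        if kind == "timeseries":
            mat = connectivity_from_time_series(values, subject_id=str(row.subject_id))
            labels = labels  # region labels carry over from the table rows
        elif kind == "matrix":
            try:
                mat = ConnectivityMatrix(values=values, subject_id=str(row.subject_id))
            except ValueError as exc:
                raise ValueError(f"{mpath}: {exc}") from exc
        else:
            raise ValueError(f"{manifest_path}: unknown input kind {kind!r}")
        if labels_seen is None:
            labels_seen = labels
        matrices.append(mat)
    if not matrices:
        raise ValueError(f"{manifest_path}: manifest lists no subjects")
    V = matrices[0].V
    for m in matrices:
        if m.V != V:
            raise ValueError(
                f"subject {m.subject_id!r} has {m.V} regions, expected {V}"
            )
    regions = RegionSet(tuple(labels_seen)) if labels_seen else None
    return ConnectivityDataset.from_matrices(
        matrices, groups=manifest["group"].to_numpy(dtype=object), regions=regions
    )


def write_dataset(dataset: ConnectivityDataset, out_dir) -> Path:
    """Write per-subject matrix files plus the manifest; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, sid in enumerate(dataset.subject_ids):
        fname = f"{sid}.tsv"
        matrix = devectorize(dataset.Y[k], dataset.edge_map)
        write_matrix_file(out_dir / fname, matrix, labels=dataset.regions.labels)
        rows.append({"subject_id": sid, "group": dataset.groups[k], "path": fname})
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path


def write_json(path, payload: dict) -> None:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serialisable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=_default) + "\n")
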