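"""Reading and writing cohort artifacts.

Matrices are plain whitespace-delimited N x N text files (one per
subject, ``<subject_id>.txt``), metadata a CSV table; both round-trip to
full float precision.  N=90 networks use the bundled AAL-order region
label table.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MatrixValidationError, ParameterError
from .synthgen import COGNITIVE_TESTS
from .types import ConnectivityMatrix

METADATA_COLUMNS = ["subject_id", "group", "age", "sex", "education", *COGNITIVE_TESTS]


def load_node_labels(path: str | Path | None = None) -> list[str]:
    """Ordered region abbreviations; bundled AAL-90 table by default."""
    if path is None:
        ref = importlib.resources.files("csvdnet.data") / "aal90_labels.txt"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    labels = [line.strip() for line in text.splitlines() if line.strip()]
    if len(labels) != len(set(labels)):
        raise ParameterError("node labels must be unique")
    return labels


def write_matrix(weights: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(weights, dtype=float), fmt="%.17g")


def read_matrix(path: str | Path, node_labels=None) -> ConnectivityMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file missing: {path}")
    try:
        w = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise MatrixValidationError(f"{path.name}: non-numeric content ({exc})") from exc
    try:
        return ConnectivityMatrix(weights=w, node_labels=node_labels)
    except MatrixValidationError as exc:
        raise MatrixValidationError(f"{path.name}: {exc}") from exc


def write_cohort(matrices, table: pd.DataFrame, outdir: str | Path) -> Path:
    """Write per-subject matrix files plus the metadata CSV; returns outdir."""
    outdir = Path(outdir)
    mdir = outdir / "matrices"
    mdir.mkdir(parents=True, exist_ok=True)
    ids = table["subject_id"].tolist()
    if len(ids) != len(matrices):
        raise ParameterError(f"{len(ids)} metadata rows for {len(matrices)} matrices")
    for sid, mat in zip(ids, matrices):
        write_matrix(mat.weights, mdir / f"{sid}.txt")
    cols = [c for c in METADATA_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(outdir / "metadata.csv", index=False)
    return outdir


def read_cohort(
    matrix_dir: str | Path,
    metadata_csv: str | Path,
    node_labels=None,
) -> tuple[list[ConnectivityMatrix], pd.DataFrame]:
    """Load and validate one matrix per metadata row.

    Raises with the offending file / coordinates on asymmetry, NaN,
    non-square input or dimension mismatch across the cohort.
    """
    matrix_dir = Path(matrix_dir)
    table = pd.read_csv(metadata_csv)
    if "subject_id" not in table.columns:
        raise ParameterError("metadata CSV must have a subject_id column")
    matrices = []
    n_ref = None
    for sid in table["subject_id"]:
        cm = read_matrix(matrix_dir / f"{sid}.txt", node_labels=node_labels)
        if n_ref is None:
            n_ref = cm.n_nodes
            if node_labels is None and n_ref == 90:
                # AAL-ordered matrices: attach the bundled region names
                node_labels = tuple(load_node_labels())
                cm = ConnectivityMatrix(weights=cm.weights, node_labels=node_labels)
        elif cm.n_nodes != n_ref:
            raise MatrixValidationError(
                f"{sid}: {cm.n_nodes} nodes, but cohort dimension is {n_ref}"
            )
        matrices.append(cm)
    return matrices, table


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
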