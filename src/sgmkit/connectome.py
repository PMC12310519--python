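"""Structural connectome containers and delimited-text I/O.

The forward model consumes two square matrices over the same set of brain
regions: connection weights (arbitrary units, typically streamline counts or
densities) and inter-region distances in millimetres.  Both are read from
plain delimited text so that template connectomes can be shipped and inspected
as CSV/TSV.  Validation is strict: the complex-Laplacian construction divides
by the degree vector, so isolated regions and non-finite entries are rejected
at load time rather than surfacing as numerical failures downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Connectome", "DegreeVector", "load_connectome", "write_connectome", "degree_vector"]

logger = logging.getLogger(__name__)


class ConnectomeError(ValueError):
    """Raised when a connectome violates a structural invariant."""


def _name_cell(mat: np.ndarray, mask: np.ndarray, what: str, kind: str) -> str:
    i, j = map(int, np.argwhere(mask)[0])
    return f"{what} entry in {kind} matrix at row {i}, column {j} (value {mat[i, j]!r})"


@dataclass(frozen=True)
class Connectome:
    """Validated structural connectome.

    Parameters
    ----------
    labels : list of str
        Region names, one per row/column of the matrices.
    weights : (n, n) ndarray
        Non-negative connection strengths ``c_jk``. Diagonal entries
        (self-connections) are zeroed with a logged warning.
    distances : (n, n) ndarray
        Symmetric non-negative inter-region distances in millimetres with a
        zero diagonal.
    """

    labels: list[str]
    weights: np.ndarray
    distances: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        d = np.asarray(self.distances, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ConnectomeError(f"weights matrix is not square: shape {w.shape}")
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ConnectomeError(f"distances matrix is not square: shape {d.shape}")
        if w.shape != d.shape:
            raise ConnectomeError(
                f"dimension mismatch: weights are {w.shape[0]}x{w.shape[1]} "
                f"but distances are {d.shape[0]}x{d.shape[1]}"
            )
        n = w.shape[0]
        if len(self.labels) != n:
            raise ConnectomeError(f"{len(self.labels)} labels for {n} regions")
        for mat, kind in ((w, "weights"), (d, "distances")):
            bad = ~np.isfinite(mat)
            if bad.any():
                raise ConnectomeError(_name_cell(mat, bad, "non-finite", kind))
            neg = mat < 0
            if neg.any():
                raise ConnectomeError(_name_cell(mat, neg, "negative", kind))
        if not np.allclose(d, d.T):
            raise ConnectomeError("distances matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ConnectomeError("distances matrix has a nonzero diagonal")
        if np.any(np.diag(w) != 0):
            logger.warning("zeroing %d nonzero diagonal weight(s) (self-connections)", int(np.count_nonzero(np.diag(w))))
            w = w.copy()
            np.fill_diagonal(w, 0.0)
        row_deg = w.sum(axis=1)
        col_deg = w.sum(axis=0)
        for deg, which in ((row_deg, "row"), (col_deg, "column")):
            if np.any(deg == 0):
                k = int(np.flatnonzero(deg == 0)[0])
                raise ConnectomeError(
                    f"isolated region {self.labels[k]!r} ({which} {k} of weights has zero degree)"
                )
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "distances", d)
        object.__setattr__(self, "labels", list(self.labels))

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class DegreeVector:
    """Column-sum degrees ``deg_k = sum_j c_jk`` of a connectome."""

    deg: np.ndarray


def degree_vector(conn: Connectome) -> DegreeVector:
    """Column sums of the weight matrix (equal to row sums when symmetric)."""
    return DegreeVector(deg=conn.weights.sum(axis=0))


def _read_matrix(path: str | Path) -> tuple[np.ndarray, list[str] | None]:
    """Read a delimited numeric matrix, auto-detecting delimiter, header row
    and a leading label column."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    if "," in first:
        sep: str = ","
    elif "\t" in first:
        sep = "\t"
    else:
        sep = r"\s+"
    df = pd.read_csv(path, sep=sep, header=None, engine="python")

    def _is_numeric(series: pd.Series) -> bool:
        return not pd.to_numeric(series, errors="coerce").isna().all()

    labels: list[str] | None = None
    # Header row: first row entirely non-numeric.
    if not _is_numeric(df.iloc[0]):
        df = df.iloc[1:].reset_index(drop=True)
    # Label column: first column non-numeric.
    if not _is_numeric(df.iloc[:, 0]):
        labels = [str(v) for v in df.iloc[:, 0]]
        df = df.iloc[:, 1:]
    try:
        mat = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ConnectomeError(f"non-numeric entry in {path}: {exc}") from exc
    return mat, labels


def load_connectome(
    weights_path: str | Path,
    distances_path: str | Path,
    labels_path: str | Path | None = None,
) -> Connectome:
    """Load and validate a connectome from delimited-text matrices.

    Delimiters (comma, tab, whitespace), header rows and leading label columns
    are auto-detected.  ``labels_path``, if given, is a one-label-per-line
    text file and overrides any labels embedded in the weights file.
    """
    weights, w_labels = _read_matrix(weights_path)
    distances, _ = _read_matrix(distances_path)
    if labels_path is not None:
        labels = [ln.strip() for ln in Path(labels_path).read_text().splitlines() if ln.strip()]
    elif w_labels is not None:
        labels = w_labels
    else:
        labels = [f"region_{i:03d}" for i in range(weights.shape[0])]
    return Connectome(labels=labels, weights=weights, distances=distances)


def write_connectome(
    conn: Connectome,
    weights_path: str | Path,
    distances_path: str | Path,
    labels_path: str | Path | None = None,
) -> None:
    """Write a connectome as CSV with 12-significant-digit floats."""
    np.savetxt(weights_path, conn.weights, fmt="%.12g", delimiter=",")
    np.savetxt(distances_path, conn.distances, fmt="%.12g", delimiter=",")
    if labels_path is not None:
        Path(labels_path).write_text("\n".join(conn.labels) + "\n")
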