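"""Conformational classification by superposition RMSD.

Array conformations are compared by optimal rigid-body superposition of
their bp traces (proper rotations only: the chirality of the DNA wrap must
be preserved) and ordered by single-linkage hierarchical clustering of the
resulting distance matrix, whose merge heights equal the sorted edge weights
of the minimum spanning tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .errors import InvalidArgumentError
from .model import ArrayModel

__all__ = ["RmsdMatrix", "ClusterOrder", "kabsch_rmsd", "rmsd_matrix", "single_linkage_order"]


@dataclass(frozen=True)
class RmsdMatrix:
    values: np.ndarray  # (n, n), symmetric, zero diagonal, A
    labels: tuple[str, ...]


@dataclass(frozen=True)
class ClusterOrder:
    leaf_order: tuple[int, ...]
    linkage_matrix: np.ndarray  # scipy format: (n-1, 4)

    def to_records(self) -> list[dict]:
        return [
            {"idx1": int(a), "idx2": int(b), "height": float(h), "size": int(s)}
            for a, b, h, s in self.linkage_matrix
        ]

    def to_newick(self, labels: Sequence[str] | None = None) -> str:
        """Dendrogram as a Newick string with merge heights as branch lengths."""
        n = len(self.linkage_matrix) + 1
        labels = list(labels) if labels is not None else [str(i) for i in range(n)]
        heights = {i: 0.0 for i in range(n)}
        nodes = {i: labels[i] for i in range(n)}
        for rec_i, (a, b, h, _s) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            nodes[n + rec_i] = f"({nodes[a]}:{la:g},{nodes[b]}:{lb:g})"
            heights[n + rec_i] = h
        return nodes[2 * n - 2] + ";"


def kabsch_rmsd(a: np.ndarray, b: np.ndarray):
    """Minimized RMSD between matched point sets under proper rigid motion.

    Returns (rmsd_A, rotation, translation) with rotation @ a + translation
    superposing a onto b.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise InvalidArgumentError("point sets must both be (n, 3) with equal n")
    if len(a) < 3:
        raise InvalidArgumentError("need at least 3 points")
    ac, bc = a.mean(axis=0), b.mean(axis=0)
    # classic SVD solution; the proper-rotation constraint flips the smallest
    # singular direction when the unconstrained optimum is a reflection
    H = (a - ac).T @ (b - bc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = bc - R @ ac
    rmsd = float(np.sqrt(((a @ R.T + t - b) ** 2).sum() / len(a)))
    return rmsd, R, t


def rmsd_matrix(models: Sequence[ArrayModel]) -> RmsdMatrix:
    """All-pairs superposition RMSD over the bp traces of a model population."""
    models = list(models)
    if not models:
        raise InvalidArgumentError("empty model list")
    template = models[0].template
    if any(m.template != template for m in models):
        raise InvalidArgumentError("models mix different templates")
    n = len(models)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = kabsch_rmsd(models[i].trace, models[j].trace)[0]
    return RmsdMatrix(values=vals, labels=tuple(m.label for m in models))


def single_linkage_order(matrix: RmsdMatrix) -> ClusterOrder:
    """Single-linkage agglomeration and dendrogram leaf order.

    Merge heights equal the sorted MST edge weights; leaf order is the
    standard recursive dendrogram order (scipy), deterministic with
    lower-index-first tie handling.
    """
    v = np.asarray(matrix.values, dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise InvalidArgumentError("matrix must be square")
    if v.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 models to cluster")
    if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0) or (v < 0).any():
        raise InvalidArgumentError("matrix must be symmetric, non-negative, zero-diagonal")
    Z = linkage(squareform(v, checks=False), method="single")
    return ClusterOrder(leaf_order=tuple(int(i) for i in leaves_list(Z)), linkage_matrix=Z)
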