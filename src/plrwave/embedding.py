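"""Multidimensional scaling and hierarchical clustering of distance data.

Three embedding modes are provided:

``classical``
    Torgerson scaling — eigendecomposition of the double-centered squared
    distance matrix. Deterministic; exact when the distances are Euclidean
    distances of a configuration in <= ``dims`` dimensions.
``stress_majorization``
    Metric SMACOF: iterative majorization of raw stress
    ``sigma(X) = sum_{i<j} (delta_ij - d_ij(X))^2`` via the Guttman
    transform, which guarantees a non-increasing stress sequence. Seeded
    random initialization; the per-iteration stress trace is returned.
``individual_difference``
    INDSCAL-style weighted-Euclidean model for several distance matrices:
    a common configuration X plus a nonnegative weight per (matrix,
    dimension). Fitted by alternating steps — X from classical scaling of
    the averaged double-centered matrix followed by guarded majorization
    refinement, weights by nonnegative least squares on the scalar-product
    matrices. The recorded total-stress trace is non-increasing (updates
    that would increase it are rejected).

Coordinates are defined only up to rotation/reflection/translation;
columns are sign-canonicalized (largest-magnitude entry positive) so that
rendered configurations are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.optimize import nnls
from scipy.spatial.distance import pdist, squareform

from .errors import DataError, ParameterError

__all__ = [
    "EmbeddingResult",
    "Dendrogram",
    "mds_embed",
    "hierarchical_cluster",
    "export_dendrogram",
]


@dataclass
class EmbeddingResult:
    """Low-dimensional configuration fitted to one or more distance matrices.

    ``stress`` is raw stress summed over all input matrices;
    ``stress_history`` traces the (non-increasing) stress per iteration for
    the iterative modes; ``weights`` holds the per-matrix dimension weights
    in individual-difference mode (row m scales the axes for matrix m).
    """

    coordinates: np.ndarray
    stress: float
    mode: str
    stress_history: list[float] = field(default_factory=list)
    labels: list[str] | None = None
    weights: np.ndarray | None = None


def _check_matrix(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise DataError("distance matrix must be square")
    if not np.allclose(m, m.T, atol=1e-8):
        raise DataError("distance matrix must be symmetric")
    if not np.allclose(np.diag(m), 0.0, atol=1e-8):
        raise DataError("distance matrix must have a zero diagonal")
    if np.any(m < -1e-12):
        raise DataError("distance matrix entries must be non-negative")
    return m


def _canonicalize(x: np.ndarray) -> np.ndarray:
    """Flip axis signs so the largest-magnitude coordinate is positive."""
    x = x.copy()
    for a in range(x.shape[1]):
        col = x[:, a]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            x[:, a] = -col
    return x


def _raw_stress(delta: np.ndarray, x: np.ndarray) -> float:
    d = squareform(pdist(x))
    iu = np.triu_indices(len(delta), k=1)
    return float(np.sum((delta[iu] - d[iu]) ** 2))


def _double_center(m: np.ndarray) -> np.ndarray:
    n = len(m)
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (m**2) @ j


def _classical(delta: np.ndarray, dims: int) -> np.ndarray:
    b = _double_center(delta)
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:dims]
    lam = np.clip(evals[order], 0.0, None)
    return evecs[:, order] * np.sqrt(lam)


def _guttman_step(delta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """One SMACOF majorization update (unit weights)."""
    n = len(delta)
    d = squareform(pdist(x))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, delta / d, 0.0)
    b = -ratio
    np.fill_diagonal(b, 0.0)
    np.fill_diagonal(b, -b.sum(axis=1))
    return b @ x / n


def _smacof(
    delta: np.ndarray,
    dims: int,
    seed: int | None,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, list[float]]:
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(len(delta), dims))
    history = [_raw_stress(delta, x)]
    for _ in range(max_iter):
        x = _guttman_step(delta, x)
        history.append(_raw_stress(delta, x))
        if history[-2] - history[-1] < tol:
            break
    return x, history


def _indscal(
    mats: list[np.ndarray],
    dims: int,
    seed: int | None,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Alternating fit of the weighted-Euclidean (INDSCAL) model."""
    bs = [_double_center(m) for m in mats]
    x = _classical(sum(bs) / len(bs), dims=dims)
    # guard against zero columns (degenerate inputs)
    for a in range(dims):
        if np.allclose(x[:, a], 0.0):
            x[:, a] = np.random.default_rng(seed).normal(scale=1e-6, size=len(x))

    def weights_for(xc: np.ndarray) -> np.ndarray:
        # B_m ~ X diag(w_m) X^T  =>  NNLS on the vectorized scalar products
        cols = np.stack(
            [np.outer(xc[:, a], xc[:, a]).ravel() for a in range(dims)], axis=1
        )
        return np.stack([nnls(cols, b.ravel())[0] for b in bs])

    def total_stress(xc: np.ndarray, w: np.ndarray) -> float:
        return sum(
            _raw_stress(mats[m], xc * np.sqrt(w[m])) for m in range(len(mats))
        )

    w = weights_for(x)
    history = [total_stress(x, w)]
    for _ in range(max_iter):
        # majorize the averaged weighted problem, then refit weights;
        # accept the pair only if total stress does not increase
        mean_w = w.mean(axis=0)
        scale = np.sqrt(np.clip(mean_w, 1e-12, None))
        delta_bar = sum(mats) / len(mats)
        x_new = _guttman_step(delta_bar, x * scale) / scale
        w_new = weights_for(x_new)
        s_new = total_stress(x_new, w_new)
        if s_new > history[-1] - tol:
            break
        x, w = x_new, w_new
        history.append(s_new)
    return x, w, history


def mds_embed(
    distances: np.ndarray | Sequence[np.ndarray],
    dims: int = 3,
    mode: str = "classical",
    seed: int | None = None,
    max_iter: int = 300,
    tol: float = 1e-12,
    labels: Sequence[str] | None = None,
) -> EmbeddingResult:
    """Embed one or more symmetric distance matrices in ``dims`` dimensions.

    Parameters
    ----------
    distances : matrix or sequence of matrices
        Symmetric, zero-diagonal, non-negative; matching sizes. A single
        matrix may be passed for the ``classical`` and
        ``stress_majorization`` modes; ``individual_difference`` accepts
        several (a single matrix degenerates to ordinary fitting).
    dims : int
        Target dimensionality (3 by default, the exploratory setting).
    mode : {"classical", "stress_majorization", "individual_difference"}
    seed : int, optional
        Initialization seed for the iterative modes.

    Returns
    -------
    EmbeddingResult
        Sign-canonicalized coordinates; raw stress; per-iteration stress
        history for iterative modes; per-matrix dimension weights in
        individual-difference mode.
    """
    if isinstance(distances, np.ndarray) and distances.ndim == 2:
        mats = [_check_matrix(distances)]
    else:
        mats = [_check_matrix(m) for m in distances]
    if len({m.shape for m in mats}) != 1:
        raise DataError("all distance matrices must have the same size")
    n = len(mats[0])
    if dims >= n:
        raise ParameterError(f"dims={dims} must be smaller than n_points={n}")

    weights = None
    history: list[float] = []
    if mode == "classical":
        delta = sum(mats) / len(mats)
        x = _classical(delta, dims)
        stress = _raw_stress(delta, x)
    elif mode == "stress_majorization":
        delta = sum(mats) / len(mats)
        x, history = _smacof(delta, dims, seed, max_iter, tol)
        stress = history[-1]
    elif mode == "individual_difference":
        x, weights, history = _indscal(mats, dims, seed, max_iter, tol)
        stress = history[-1]
    else:
        raise ParameterError(f"unknown MDS mode {mode!r}")

    return EmbeddingResult(
        coordinates=_canonicalize(x),
        stress=stress,
        mode=mode,
        stress_history=history,
        labels=list(labels) if labels is not None else None,
        weights=weights,
    )


@dataclass
class Dendrogram:
    """Agglomerative merge tree over labelled leaves.

    ``linkage_matrix`` is in scipy ``linkage`` format (merge heights in
    column 2, non-decreasing from leaves to root for Ward and average
    linkage).
    """

    linkage_matrix: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cut(self, k: int) -> np.ndarray:
        """Flat cluster assignment (1..k) at a k-cluster cut."""
        if self.n_leaves == 1:
            return np.array([1])
        return sch.fcluster(self.linkage_matrix, t=k, criterion="maxclust")


def hierarchical_cluster(
    distances: np.ndarray,
    labels: Sequence[str],
    linkage: str = "ward",
) -> Dendrogram:
    """Agglomerative clustering of a distance matrix.

    ``linkage`` is ``"ward"`` (minimum within-cluster variance increase)
    or ``"average"``. Deterministic for fixed input (scipy's tie-breaking
    is stable).
    """
    m = _check_matrix(distances)
    if np.any(m < 0):
        raise DataError("distance matrix entries must be non-negative")
    if linkage not in ("ward", "average"):
        raise ParameterError(f"unsupported linkage {linkage!r}")
    labels = [str(label) for label in labels]
    if len(labels) != len(m):
        raise DataError("label count must match matrix size")
    if len(m) == 1:
        return Dendrogram(linkage_matrix=np.empty((0, 4)), labels=labels)
    z = sch.linkage(squareform(m, checks=False), method=linkage)
    return Dendrogram(linkage_matrix=z, labels=labels)


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " \t()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(d: Dendrogram) -> str:
    """Render a dendrogram as a Newick string.

    Branch lengths are height differences between a node and its parent,
    so root-to-leaf path lengths equal merge heights.
    """
    if d.n_leaves == 1:
        return f"({_quote_label(d.labels[0])}:0.0);"
    tree = sch.to_tree(d.linkage_matrix)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{_quote_label(d.labels[node.id])}:{length:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    root = f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"
    return root


def export_dendrogram(d: Dendrogram, path: str | Path) -> Path:
    """Write the dendrogram to ``path`` in Newick format."""
    path = Path(path)
    path.write_text(to_newick(d) + "\n", encoding="utf-8")
    return path
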