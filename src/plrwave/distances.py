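"""Dissimilarity matrices between condition features and the FE vector.

For one eye, the Euclidean distances between the feature vectors of the
four stimulus conditions form a symmetric 4x4 matrix (condition order
fixed: r10, r100, b10, b100). Its strict upper triangle, read row-major,
is the 6-component *FE vector*

    [r10-r100, r10-b10, r10-b100, r100-b10, r100-b100, b10-b100]

used as the classifier input. For one subject, stacking both eyes'
condition sets yields an 8x8 cross-eye matrix whose diagonal blocks are
the per-eye matrices.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import DataError
from .io import CONDITIONS

__all__ = [
    "FE_COMPONENTS",
    "condition_distances",
    "cross_eye_distances",
    "fe_vector",
]

#: FE component names in fixed extraction order.
FE_COMPONENTS: tuple[str, ...] = (
    "r10-r100",
    "r10-b10",
    "r10-b100",
    "r100-b10",
    "r100-b100",
    "b10-b100",
)


def _stack(features: Mapping[str, np.ndarray]) -> np.ndarray:
    missing = [c for c in CONDITIONS if c not in features]
    if missing:
        raise DataError(f"missing condition feature(s): {missing}")
    vecs = [np.asarray(features[c], dtype=float) for c in CONDITIONS]
    lengths = {v.shape for v in vecs}
    if len(lengths) != 1 or vecs[0].ndim != 1:
        raise DataError(f"condition feature vectors must share one 1-D shape, got {lengths}")
    return np.stack(vecs)


def condition_distances(features: Mapping[str, np.ndarray]) -> np.ndarray:
    """4x4 Euclidean distance matrix between one eye's condition features.

    Parameters
    ----------
    features : mapping condition -> 1-D feature vector
        All four conditions required, equal lengths.
    """
    return squareform(pdist(_stack(features), metric="euclidean"))


def cross_eye_distances(
    features_eye_a: Mapping[str, np.ndarray],
    features_eye_b: Mapping[str, np.ndarray],
) -> np.ndarray:
    """8x8 distance matrix over both eyes' condition features.

    Block order is [eye A conditions, eye B conditions]; the two 4x4
    diagonal blocks equal the per-eye matrices.
    """
    stacked = np.vstack([_stack(features_eye_a), _stack(features_eye_b)])
    return squareform(pdist(stacked, metric="euclidean"))


def fe_vector(m: np.ndarray) -> np.ndarray:
    """Flatten a condition distance matrix into the 6-component FE vector.

    Extracts the strict upper triangle in row-major order, which matches
    the fixed component order of :data:`FE_COMPONENTS`.
    """
    m = np.asarray(m, dtype=float)
    if m.shape != (4, 4):
        raise DataError(f"expected a 4x4 condition distance matrix, got {m.shape}")
    if not np.allclose(m, m.T, atol=1e-12):
        raise DataError("distance matrix must be symmetric")
    iu = np.triu_indices(4, k=1)
    return m[iu]
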