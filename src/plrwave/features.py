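"""Fourier-descriptor features of pupillogram waveforms.

The analysis window of a pupillogram is transformed with the DFT and the
coefficient magnitudes are used as *Fourier descriptors* (FDs): FD_0 is the
DC/amplitude component, FD_k (k >= 1) carry waveform shape.

Scaling convention
------------------
``FD_k = |X[k]|`` where ``X = numpy.fft.rfft(window)`` — raw transform
magnitudes, no 1/N or 2/N factor. Every downstream feature is a ratio
(FD_k / FD_1 shape components; FD_0 standardized by a per-eye mean), so any
global scale factor cancels; the raw-magnitude convention is fixed here and
asserted by the test suite against a direct DFT-sum oracle. Under this
convention Parseval's relation reads

    sum_n x(n)^2 = (FD_0^2 + FD_{N/2}^2 [N even] + 2 * sum_{0<k<N/2} FD_k^2) / N.

The shape feature is the 4-vector [FD_2/FD_1, FD_3/FD_1, FD_4/FD_1,
FD_5/FD_1]: dividing by FD_1 suppresses amplitude differences between
individuals, and dropping FD_0 removes the offset, making the vector
invariant to any affine transform a*x + b (a > 0) of the window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DataError, ParameterError
from .io import CONDITIONS

__all__ = [
    "FDVector",
    "AmplitudeFeature",
    "AMPLITUDE_ONLY",
    "compute_fd",
    "shape_vector",
    "standardize_fd0",
    "peak_standardized_amplitudes",
    "combine",
]

#: Sentinel weight selecting amplitude-only combined features (only the
#: standardized FD_0 component is used, no shape components).
AMPLITUDE_ONLY = math.inf

#: Minimum window length so that FD_5 (the last shape component) exists.
MIN_WINDOW = 12


@dataclass(frozen=True)
class FDVector:
    """DFT magnitude sequence FD_0 ... FD_{N/2 - 1} of one window.

    ``magnitudes[k]`` is |X[k]| of the length-``n`` transform; ``source``
    optionally records the (subject, eye, condition) origin.
    """

    magnitudes: np.ndarray
    n: int
    source: tuple[str, str, str] | None = None

    @property
    def fd0(self) -> float:
        """DC component — proportional to the window's mean diameter."""
        return float(self.magnitudes[0])


@dataclass(frozen=True)
class AmplitudeFeature:
    """Per-eye standardized FD_0 amplitude components, one per condition.

    ``fd0_std`` divides each condition's FD_0 by the arithmetic mean of the
    four (its mean is exactly 1); ``peak_std`` divides by the eye's maximum
    condition value (the strongest response, typically b100, maps to 1).
    """

    fd0: np.ndarray
    fd0_std: np.ndarray
    peak_std: np.ndarray
    conditions: tuple[str, ...] = CONDITIONS


def compute_fd(window: np.ndarray, source: tuple[str, str, str] | None = None) -> FDVector:
    """Fourier descriptors of an analysis window.

    Parameters
    ----------
    window : array of float, length N >= 12
        Diameter samples over the stimulus period.

    Returns
    -------
    FDVector
        ``floor(N/2)`` magnitudes ``|X[0]| ... |X[N/2 - 1]|``.
    """
    x = np.asarray(window, dtype=float)
    if x.ndim != 1:
        raise DataError("window must be one-dimensional")
    n = len(x)
    if n < MIN_WINDOW:
        raise DataError(f"window of {n} samples is too short (need >= {MIN_WINDOW})")
    mags = np.abs(np.fft.rfft(x))[: n // 2]
    return FDVector(magnitudes=mags, n=n, source=source)


def shape_vector(fd: FDVector | np.ndarray, n_components: int = 4) -> np.ndarray:
    """FD_1-standardized shape vector [FD_2/FD_1, ..., FD_{1+n}/FD_1].

    The default 4 components capture the low-order harmonics that carry
    most of the waveform's shape. Invariant to positive scaling and to
    constant offsets of the source window.

    Raises
    ------
    DataError
        If FD_1 is zero (degenerate, e.g. constant signal) or the FD vector
        is too short for the requested dimensionality.
    """
    mags = fd.magnitudes if isinstance(fd, FDVector) else np.asarray(fd, dtype=float)
    if len(mags) < n_components + 2:
        raise DataError(
            f"need at least {n_components + 2} FD magnitudes, got {len(mags)}"
        )
    fd1 = mags[1]
    if fd1 == 0:
        raise DataError("degenerate signal: FD_1 is zero, cannot standardize")
    return np.asarray(mags[2 : 2 + n_components] / fd1, dtype=float)


def standardize_fd0(fd0_by_condition: np.ndarray) -> AmplitudeFeature:
    """Standardize the four per-condition FD_0 values of one eye.

    Each value is divided by the arithmetic mean of the four, so the output
    mean is exactly 1; this removes between-individual amplitude scale
    while preserving the relative response strengths across conditions.
    """
    v = np.asarray(fd0_by_condition, dtype=float)
    if v.shape != (4,):
        raise DataError("expected exactly 4 per-condition FD_0 values")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise DataError("FD_0 values must be positive and finite")
    return AmplitudeFeature(fd0=v, fd0_std=v / v.mean(), peak_std=v / v.max())


def peak_standardized_amplitudes(fd0_by_condition: np.ndarray) -> np.ndarray:
    """Amplitudes standardized by the eye's maximum-response condition.

    The maximizing condition (typically b100, the strongest stimulus) maps
    to exactly 1; used for cross-individual amplitude comparisons.
    """
    return standardize_fd0(fd0_by_condition).peak_std


def combine(shape: np.ndarray, fd0_std: float, w: float) -> np.ndarray:
    """Fuse shape and standardized amplitude into one feature vector.

    Returns ``[shape_1..shape_4, w * fd0_std]`` for finite weight w >= 0.
    The sentinel :data:`AMPLITUDE_ONLY` (infinity) selects the
    amplitude-only mode and returns the 1-component vector ``[fd0_std]``.
    """
    if w == AMPLITUDE_ONLY:
        return np.array([fd0_std], dtype=float)
    if not (np.isfinite(w) and w >= 0):
        raise ParameterError("weight must be >= 0 or AMPLITUDE_ONLY")
    s = np.asarray(shape, dtype=float)
    return np.concatenate([s, [w * fd0_std]])
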