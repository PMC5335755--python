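"""Pairwise distance measures between MS2 spectra.

Three measures are provided:

* **cosine** -- one minus the cosine similarity of the binned intensity
  vectors (sum over the union of occupied bins; unoccupied bins count 0).
  Lies in [0, 1] because intensities are non-negative.
* **angle** -- an intensity-free measure on peak positions:
  ``arccos(c / sqrt(p_a * p_b))`` where ``c`` counts peaks of the first
  spectrum having at least one peak of the second within ``epsilon`` Th.
  Because several peaks of ``a`` may share one partner in ``b`` the raw
  ratio can exceed 1; it is clamped to [0, 1] before the arccos, so the
  result lies in [0, pi/2].
* **parametrized Hausdorff** -- ``max(h(a,b), h(b,a))`` with
  ``h(a,b) = (1/p_a) * sum_q (m_q * 1{m_q > delta})^(1/k)`` where ``m_q``
  is the minimal absolute position difference between peak ``q`` of ``a``
  and any peak of ``b``; differences within the tolerance ``delta``
  contribute exactly 0 (``0^(1/k)`` is taken as 0).

The angle and Hausdorff measures operate on the representative peak
positions of preprocessed (binned) spectra, so all measures see one
preprocessing path; they also accept raw :class:`~disms2.spectra.Spectrum`
objects, in which case the raw m/z values are used.

A distance involving an empty spectrum is undefined and raises
:class:`UndefinedDistance`; callers in the matching layer convert that to
"no match".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import BinnedSpectrum

__all__ = [
    "UndefinedDistance",
    "DistanceSpec",
    "cosine_distance",
    "angle_distance",
    "parametrized_hausdorff_distance",
    "spectrum_distance",
]

_NAMES = {"cos": "cosine", "cosine": "cosine", "angle": "angle",
          "hausdorff": "hausdorff", "ph": "hausdorff"}


class UndefinedDistance(ValueError):
    """Raised when a distance is requested against an empty spectrum."""


@dataclass(frozen=True)
class DistanceSpec:
    """Named spectrum distance with its hyperparameters.

    ``epsilon`` is the peak-match tolerance of the angle distance (Th),
    ``delta`` the tolerance of the Hausdorff distance (Th) and ``k_root``
    its root exponent. Defaults follow the published evaluation design:
    angle(eps=0.05), Hausdorff(delta=0.05, k=50).
    """

    name: str = "cosine"
    epsilon: float = 0.05
    delta: float = 0.05
    k_root: float = 50.0

    def __post_init__(self) -> None:
        canon = _NAMES.get(self.name.lower())
        if canon is None:
            raise ValueError(f"unknown distance {self.name!r}; "
                             f"expected one of cos, angle, hausdorff")
        object.__setattr__(self, "name", canon)
        if self.epsilon < 0 or self.delta < 0:
            raise ValueError("epsilon and delta must be >= 0")
        if self.k_root < 1:
            raise ValueError("k_root must be >= 1")

    def __str__(self) -> str:
        if self.name == "angle":
            return f"angle(eps={self.epsilon:g})"
        if self.name == "hausdorff":
            return f"hausdorff(delta={self.delta:g},k={self.k_root:g})"
        return "cos"


def _positions(s) -> np.ndarray:
    """Sorted peak positions of a raw or binned spectrum."""
    if isinstance(s, BinnedSpectrum):
        return s.positions
    return np.asarray(s.mz, dtype=float)


def _check_nonempty(*spectra) -> None:
    for s in spectra:
        n = s.n_bins if isinstance(s, BinnedSpectrum) else s.n_peaks
        if n == 0:
            raise UndefinedDistance("distance undefined on an empty spectrum")


def cosine_distance(a: BinnedSpectrum, b: BinnedSpectrum) -> float:
    """Cosine distance of two binned intensity vectors, in [0, 1]."""
    if not isinstance(a, BinnedSpectrum) or not isinstance(b, BinnedSpectrum):
        raise TypeError("cosine_distance operates on binned spectra")
    if a.bin_width != b.bin_width:
        raise ValueError(f"bin widths differ: {a.bin_width} vs {b.bin_width}")
    _check_nonempty(a, b)
    _, ia, ib = np.intersect1d(a.bin_indices, b.bin_indices,
                               assume_unique=True, return_indices=True)
    dot = float(a.intensities[ia] @ b.intensities[ib])
    denom = float(np.linalg.norm(a.intensities) * np.linalg.norm(b.intensities))
    return float(np.clip(1.0 - dot / denom, 0.0, 1.0))


def _min_abs_diff(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """For each element of sorted x, the minimal |x - y_j| over sorted y."""
    pos = np.searchsorted(y, x)
    left = y[np.clip(pos - 1, 0, y.size - 1)]
    right = y[np.clip(pos, 0, y.size - 1)]
    return np.minimum(np.abs(x - left), np.abs(x - right))


def angle_distance(a, b, epsilon: float = 0.05) -> float:
    """Angle distance on peak positions, in [0, pi/2]."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    _check_nonempty(a, b)
    xa, xb = _positions(a), _positions(b)
    c = int(np.count_nonzero(_min_abs_diff(xa, xb) <= epsilon))
    ratio = min(c / np.sqrt(xa.size * xb.size), 1.0)
    return float(np.arccos(ratio))


def _directed_hausdorff(xa: np.ndarray, xb: np.ndarray,
                        delta: float, k_root: float) -> float:
    m = _min_abs_diff(xa, xb)
    terms = np.where(m > delta, m, 0.0) ** (1.0 / k_root)
    terms[m <= delta] = 0.0  # 0^(1/k) := 0, and kill tolerated differences
    return float(terms.mean())


def parametrized_hausdorff_distance(a, b, delta: float = 0.05,
                                    k_root: float = 50.0) -> float:
    """Parametrized Hausdorff distance on peak positions, >= 0."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if k_root < 1:
        raise ValueError("k_root must be >= 1")
    _check_nonempty(a, b)
    xa, xb = _positions(a), _positions(b)
    return max(_directed_hausdorff(xa, xb, delta, k_root),
               _directed_hausdorff(xb, xa, delta, k_root))


def spectrum_distance(a, b, spec: DistanceSpec) -> float:
    """Dispatch to the measure named by ``spec``.

    Cosine uses the binned intensities; angle and Hausdorff use the
    representative peak positions of the same binned spectra.
    """
    if spec.name == "cosine":
        return cosine_distance(a, b)
    if spec.name == "angle":
        return angle_distance(a, b, spec.epsilon)
    return parametrized_hausdorff_distance(a, b, spec.delta, spec.k_root)
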