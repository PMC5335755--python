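"""Spectrum preprocessing: top-n peak selection and fixed-width binning.

Preprocessing has two sub-steps, applied in this order:

1. ``select_top_peaks`` keeps only the ``topn`` most intense peaks
   (``topn = inf`` keeps everything).
2. ``bin_peaks`` partitions the m/z axis into half-open intervals
   ``[n* . bin, (n* + 1) . bin)`` of width ``bin`` and replaces all peaks
   falling into one interval by a single representative: the maximum
   intensity placed at the central m/z value ``(n* + 0.5) . bin``.

All downstream distance measures operate on the binned representation, so
every measure sees identical preprocessing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .spectra import Spectrum

__all__ = ["BinnedSpectrum", "select_top_peaks", "bin_peaks", "preprocess_spectrum"]


@dataclass
class BinnedSpectrum:
    """Sparse binned spectrum: occupied bin indices and their intensities.

    ``bin_indices`` is sorted ascending; ``intensities[i]`` is the maximum
    intensity of the source peaks that fell into bin ``bin_indices[i]``.
    The representative m/z of bin ``n*`` is ``(n* + 0.5) * bin_width``.
    """

    bin_width: float
    bin_indices: np.ndarray
    intensities: np.ndarray
    scan_number: int
    precursor_mz: float
    precursor_charge: Optional[int]
    retention_time: Optional[float] = None

    def __post_init__(self) -> None:
        self.bin_indices = np.asarray(self.bin_indices, dtype=np.int64)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.bin_indices.shape != self.intensities.shape:
            raise ValueError("bin_indices and intensities lengths differ")

    @property
    def positions(self) -> np.ndarray:
        """Representative m/z values of the occupied bins (sorted ascending)."""
        return (self.bin_indices + 0.5) * self.bin_width

    @property
    def n_bins(self) -> int:
        return int(self.bin_indices.size)

    @property
    def is_empty(self) -> bool:
        return self.bin_indices.size == 0

    def __len__(self) -> int:
        return self.n_bins


def select_top_peaks(s: Spectrum, topn: float) -> Spectrum:
    """Keep only the ``topn`` highest-intensity peaks of a spectrum.

    Ties at the cutoff intensity are broken in favour of the lower m/z
    peak (sort by intensity descending, then m/z ascending). The result is
    re-sorted ascending by m/z. ``topn = math.inf`` (or any value >= the
    peak count) returns the spectrum unchanged.
    """
    if not topn > 0:
        raise ValueError(f"topn must be positive, got {topn!r}")
    if math.isinf(topn) or s.n_peaks <= topn:
        return s
    topn = int(topn)
    # primary key: intensity descending; tie-break: m/z ascending
    order = np.lexsort((s.mz, -s.intensity))
    keep = np.sort(order[:topn])
    return Spectrum(
        scan_number=s.scan_number,
        precursor_mz=s.precursor_mz,
        precursor_charge=s.precursor_charge,
        mz=s.mz[keep],
        intensity=s.intensity[keep],
        retention_time=s.retention_time,
    )


def bin_peaks(s: Spectrum, bin_width: float) -> BinnedSpectrum:
    """Bin a spectrum at fixed width; one representative (max) per bin.

    A peak with m/z exactly on a boundary belongs to the upper bin, per
    the half-open interval convention.
    """
    if not bin_width > 0:
        raise ValueError(f"bin width must be positive, got {bin_width!r}")
    if s.n_peaks == 0:
        return BinnedSpectrum(
            bin_width=bin_width,
            bin_indices=np.empty(0, dtype=np.int64),
            intensities=np.empty(0),
            scan_number=s.scan_number,
            precursor_mz=s.precursor_mz,
            precursor_charge=s.precursor_charge,
            retention_time=s.retention_time,
        )
    idx = np.floor(s.mz / bin_width).astype(np.int64)
    uniq, inverse = np.unique(idx, return_inverse=True)
    rep = np.zeros(uniq.size)
    np.maximum.at(rep, inverse, s.intensity)
    return BinnedSpectrum(
        bin_width=bin_width,
        bin_indices=uniq,
        intensities=rep,
        scan_number=s.scan_number,
        precursor_mz=s.precursor_mz,
        precursor_charge=s.precursor_charge,
        retention_time=s.retention_time,
    )


def preprocess_spectrum(s: Spectrum, topn: float, bin_width: float) -> BinnedSpectrum:
    """Top-n selection followed by binning (the full step-1 pipeline)."""
    return bin_peaks(select_top_peaks(s, topn), bin_width)
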