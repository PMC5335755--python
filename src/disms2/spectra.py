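"""Core in-memory containers for MS/MS data.

A :class:`Spectrum` is one MS2 scan: a pair of equal-length vectors of
fragment m/z values (sorted ascending) and non-negative intensities, plus
the precursor m/z, the precursor charge state (``None`` when the file did
not record one) and the scan number. A :class:`Run` is the ordered
collection of spectra from one LC-MS/MS acquisition; the *rank* of a
spectrum is its 1-based position in scan-number order and stands in for
retention time when comparing runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = ["Spectrum", "Run"]


@dataclass
class Spectrum:
    """One centroided MS2 spectrum.

    Parameters
    ----------
    scan_number : int
        Positive scan identifier, unique within a run.
    precursor_mz : float
        m/z of the isolated precursor ion (Th).
    precursor_charge : int or None
        Charge state of the precursor; ``None`` means unknown.
    mz : ndarray
        Fragment m/z values, sorted ascending.
    intensity : ndarray
        Fragment intensities, same length as ``mz``, all >= 0.
    retention_time : float or None
        Scan start time in seconds, when available.
    """

    scan_number: int
    precursor_mz: float
    precursor_charge: Optional[int]
    mz: np.ndarray
    intensity: np.ndarray
    retention_time: Optional[float] = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("mz and intensity must be 1-D vectors")
        if self.mz.shape != self.intensity.shape:
            raise ValueError(
                f"scan {self.scan_number}: mz and intensity lengths differ "
                f"({self.mz.size} vs {self.intensity.size})"
            )
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError(f"scan {self.scan_number}: negative intensity")
        if self.scan_number <= 0:
            raise ValueError("scan_number must be positive")
        if not self.precursor_mz > 0:
            raise ValueError(f"scan {self.scan_number}: precursor_mz must be positive")
        if self.precursor_charge is not None and self.precursor_charge < 1:
            raise ValueError(f"scan {self.scan_number}: charge must be >= 1 or None")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def __len__(self) -> int:
        return self.n_peaks


@dataclass
class Run:
    """An LC-MS/MS run: spectra ordered by ascending scan number."""

    run_id: str
    spectra: Sequence[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spectra = sorted(self.spectra, key=lambda s: s.scan_number)
        scans = [s.scan_number for s in self.spectra]
        if len(set(scans)) != len(scans):
            raise ValueError(f"run {self.run_id!r}: duplicate scan numbers")

    @property
    def n_spectra(self) -> int:
        return len(self.spectra)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, idx: int) -> Spectrum:
        return self.spectra[idx]

    def rank_of_scan(self, scan_number: int) -> int:
        """1-based rank of a scan in scan-number order."""
        for rank, s in enumerate(self.spectra, start=1):
            if s.scan_number == scan_number:
                return rank
        raise KeyError(scan_number)
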