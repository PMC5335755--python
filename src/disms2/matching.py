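"""Run-level matching and distances (the core DISMS2 procedure).

For every spectrum ``k`` of run ``i``, candidate partners in run ``j``
are reduced by three constraints checked in order:

(a) *rank window*: the candidate's rank ``l`` (1-based position in the
    scan-number-ordered list of retained MS2 spectra) lies in
    ``[k - ret, k + ret]``, so at most ``2*ret + 1`` candidates remain;
(b) *charge*: identical precursor charge state (unknown only matches
    unknown);
(c) *precursor mass*: ``|m_l - m_k| / m_k * 1e6 <= prec`` ppm.

The spectrum counts as *matched* when the candidate set is non-empty and
the minimal spectrum distance over the candidates is strictly below the
cutoff ``cdis``. The directed run distance ``d*(i, j)`` is the fraction of
spectra of run ``i`` with no match in run ``j``; the reported distance is
the mean ``d(i, j) = (d*(i, j) + d*(j, i)) / 2``. Spectra emptied by
preprocessing always count as unmatched and stay in the denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .distances import DistanceSpec, spectrum_distance
from .preprocess import BinnedSpectrum, preprocess_spectrum
from .spectra import Run

__all__ = [
    "MatchParams",
    "DistanceMatrix",
    "PreprocessedRun",
    "preprocess_run",
    "candidate_indices",
    "directed_run_distance",
    "run_distance",
    "run_distance_matrix",
]

_UNKNOWN_CHARGE = -1


@dataclass(frozen=True)
class MatchParams:
    """The six tunables of the matching procedure.

    Defaults are the optimum of the published parameter search:
    topn = inf (no selection), bin = 0.2 Th, ret = 3000 ranks,
    prec = 10 ppm, cosine distance, cdis = 0.3.
    """

    topn: float = math.inf
    bin: float = 0.2
    ret: int = 3000
    prec: float = 10.0
    dist: DistanceSpec = field(default_factory=DistanceSpec)
    cdis: float = 0.3

    def __post_init__(self) -> None:
        if not self.topn > 0:
            raise ValueError("topn must be positive")
        if not self.bin > 0:
            raise ValueError("bin must be positive")
        if self.ret < 0:
            raise ValueError("ret must be >= 0")
        if self.prec < 0:
            raise ValueError("prec must be >= 0")
        if not self.cdis > 0:
            raise ValueError("cdis must be positive")


class DistanceMatrix:
    """Symmetric run-level distance matrix with run labels."""

    def __init__(self, labels: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        labels = list(labels)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(labels) != values.shape[0]:
            raise ValueError("label count does not match matrix size")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate run labels")
        if not np.allclose(values, values.T, rtol=0, atol=0):
            raise ValueError("distance matrix must be symmetric")
        self.labels = labels
        self.values = values

    def __eq__(self, other) -> bool:
        return (isinstance(other, DistanceMatrix)
                and self.labels == other.labels
                and np.array_equal(self.values, other.values))

    def __getitem__(self, key):
        a, b = key
        return self.values[self.labels.index(a), self.labels.index(b)]

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class PreprocessedRun:
    """A run after top-n selection and binning, rank-indexed.

    ``spectra[r - 1]`` is the binned spectrum of rank ``r``; the precursor
    m/z and charge arrays are aligned with it (unknown charge coded -1).
    """

    run_id: str
    spectra: List[BinnedSpectrum]
    precursor_mz: np.ndarray
    charge: np.ndarray
    nonempty: np.ndarray

    @property
    def n_spectra(self) -> int:
        return len(self.spectra)


def preprocess_run(run: Run, params: MatchParams) -> PreprocessedRun:
    """Apply step-1 preprocessing to every spectrum of a run."""
    binned = [preprocess_spectrum(s, params.topn, params.bin) for s in run]
    charge = np.array(
        [s.precursor_charge if s.precursor_charge is not None else _UNKNOWN_CHARGE
         for s in run], dtype=np.int64)
    pm = np.array([s.precursor_mz for s in run], dtype=float)
    nonempty = np.array([not b.is_empty for b in binned], dtype=bool)
    return PreprocessedRun(run.run_id, binned, pm, charge, nonempty)


def candidate_indices(k: int, run_j: PreprocessedRun, s_k: BinnedSpectrum,
                      params: MatchParams) -> np.ndarray:
    """Ranks in ``run_j`` satisfying constraints (a)-(c) for query rank ``k``.

    Returns a sorted array of 1-based ranks; an empty array is a legal
    result and means "no match available".
    """
    n_j = run_j.n_spectra
    lo = max(1, k - params.ret)
    hi = min(n_j, k + params.ret)
    if lo > hi:
        return np.empty(0, dtype=np.int64)
    sl = slice(lo - 1, hi)
    q_charge = (s_k.precursor_charge if s_k.precursor_charge is not None
                else _UNKNOWN_CHARGE)
    mask = run_j.charge[sl] == q_charge
    ppm = np.abs(run_j.precursor_mz[sl] - s_k.precursor_mz) / s_k.precursor_mz * 1e6
    mask &= ppm <= params.prec
    return np.nonzero(mask)[0].astype(np.int64) + lo


def _directed(pi: PreprocessedRun, pj: PreprocessedRun, params: MatchParams,
              query_ok: Optional[np.ndarray] = None,
              cand_ok: Optional[np.ndarray] = None,
              use_constraints: bool = True) -> float:
    """Directed no-match fraction from ``pi`` to ``pj``.

    ``query_ok`` / ``cand_ok`` are optional boolean masks (aligned with the
    runs' rank order) that admit spectra as queries / candidates; a query
    failing its mask counts as unmatched but stays in the denominator.
    ``use_constraints=False`` drops constraints (a)-(c) and considers the
    whole of ``pj`` (the unfiltered variant).
    """
    n_i = pi.n_spectra
    if n_i == 0:
        raise ValueError(f"run {pi.run_id!r} is empty; directed distance undefined")
    n_j = pj.n_spectra
    unmatched = 0
    all_ranks = np.arange(1, n_j + 1, dtype=np.int64)
    for idx in range(n_i):
        s_k = pi.spectra[idx]
        if (query_ok is not None and not query_ok[idx]) or s_k.is_empty:
            unmatched += 1
            continue
        if use_constraints:
            ranks = candidate_indices(idx + 1, pj, s_k, params)
        else:
            ranks = all_ranks
        if ranks.size:
            keep = pj.nonempty[ranks - 1]
            if cand_ok is not None:
                keep = keep & cand_ok[ranks - 1]
            ranks = ranks[keep]
        if ranks.size == 0:
            unmatched += 1
            continue
        best = min(spectrum_distance(s_k, pj.spectra[r - 1], params.dist)
                   for r in ranks)
        if not best < params.cdis:
            unmatched += 1
    return unmatched / n_i


def _as_preprocessed(run, params: MatchParams) -> PreprocessedRun:
    if isinstance(run, PreprocessedRun):
        return run
    return preprocess_run(run, params)


def directed_run_distance(run_i, run_j, params: MatchParams) -> float:
    """d*(i, j): fraction of spectra of run i with no match in run j."""
    return _directed(_as_preprocessed(run_i, params),
                     _as_preprocessed(run_j, params), params)


def run_distance(run_i, run_j, params: MatchParams) -> float:
    """Symmetrized run distance d(i, j) = (d*(i, j) + d*(j, i)) / 2."""
    pi = _as_preprocessed(run_i, params)
    pj = _as_preprocessed(run_j, params)
    return 0.5 * (_directed(pi, pj, params) + _directed(pj, pi, params))


def run_distance_matrix(runs: Sequence[Run], params: MatchParams) -> DistanceMatrix:
    """Pairwise run distances for N runs (N*(N-1) directed computations)."""
    labels = [r.run_id for r in runs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate run ids")
    if len(runs) < 2:
        raise ValueError("need at least two runs")
    pre = [_as_preprocessed(r, params) for r in runs]
    n = len(pre)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 0.5 * (_directed(pre[i], pre[j], params)
                       + _directed(pre[j], pre[i], params))
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)
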