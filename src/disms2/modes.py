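"""Comparison modes: distance-based and database-annotation-based searches.

Six canonical modes compare two runs by the average fraction of "no hit"
spectra of a directed search, differing in the hit definition, the
spectrum universe, the annotation and filter checks, and duplicate
handling:

========== ========= ======== ========== ====== ==========
name        search    universe annotation filter duplicates
========== ========= ======== ========== ====== ==========
DB.ra       database  reduced  yes        no     kept
DB.ra.nodup database  reduced  yes        no     removed
DISMS2.f    distance  all      no         yes    kept
DB.a        database  all      yes        no     kept
DISMS2.af   distance  all      yes        yes    kept
DB.af       database  all      yes        yes    kept
========== ========= ======== ========== ====== ==========

A seventh preset, ``DISMS2.nofilter``, is the distance search over the
whole candidate run (no rank/charge/ppm constraints).

*Database* hit: some candidate spectrum is annotated with the same
peptide string (exact sequence-plus-modifications equality). *Distance*
hit: the minimal spectrum distance over the candidates is below ``cdis``.
The *reduced* universe keeps only annotated spectra. The annotation check
downgrades any spectrum pair with a missing annotation (query or
candidate) to "no hit". Removing duplicates replaces each run by its set
of peptides annotated at least once and scores set membership.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .matching import (DistanceMatrix, MatchParams, PreprocessedRun,
                       _directed, candidate_indices, preprocess_run)
from .spectra import Run

__all__ = [
    "AnnotationTable",
    "ModeSpec",
    "MODE_PRESETS",
    "spectrum_universe",
    "directed_no_hit_fraction",
    "mode_distance_matrix",
]


class AnnotationTable:
    """Mapping (run_id, scan_number) -> peptide string (rank-1 PSMs only)."""

    def __init__(self, mapping: Optional[Dict[Tuple[str, int], str]] = None):
        self._map: Dict[Tuple[str, int], str] = dict(mapping or {})

    def get(self, run_id: str, scan_number: int) -> Optional[str]:
        return self._map.get((run_id, scan_number))

    def add(self, run_id: str, scan_number: int, peptide: str) -> None:
        self._map[(run_id, scan_number)] = peptide

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, key: Tuple[str, int]) -> bool:
        return key in self._map

    def peptides(self, run: Run) -> list:
        """Peptide per spectrum of a run, aligned with rank order (None = unannotated)."""
        return [self.get(run.run_id, s.scan_number) for s in run]

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", dtype={"run_id": str, "peptide": str})
        required = {"run_id", "scan_number", "peptide"}
        if not required.issubset(df.columns):
            raise ValueError(f"annotation table needs columns {sorted(required)}")
        table = cls()
        for row in df.itertuples(index=False):
            table.add(str(row.run_id), int(row.scan_number), str(row.peptide))
        return table

    def to_tsv(self, path: Union[str, Path]) -> None:
        rows = [(r, s, p) for (r, s), p in sorted(self._map.items())]
        pd.DataFrame(rows, columns=["run_id", "scan_number", "peptide"]).to_csv(
            path, sep="\t", index=False)


@dataclass(frozen=True)
class ModeSpec:
    """One comparison algorithm, decomposed into its five switches."""

    search_method: str        # "database" | "distance"
    universe: str             # "all" | "reduced"
    annotation_check: bool
    filter_check: bool
    duplicates: str = "kept"  # "kept" | "removed"

    def __post_init__(self) -> None:
        if self.search_method not in ("database", "distance"):
            raise ValueError(f"unknown search method {self.search_method!r}")
        if self.universe not in ("all", "reduced"):
            raise ValueError(f"unknown universe {self.universe!r}")
        if self.duplicates not in ("kept", "removed"):
            raise ValueError(f"unknown duplicate handling {self.duplicates!r}")
        if self.duplicates == "removed" and self.search_method != "database":
            raise ValueError("duplicate removal is only defined for the "
                             "database search method")


MODE_PRESETS: Dict[str, ModeSpec] = {
    "DB.ra": ModeSpec("database", "reduced", True, False, "kept"),
    "DB.ra.nodup": ModeSpec("database", "reduced", True, False, "removed"),
    "DISMS2.f": ModeSpec("distance", "all", False, True, "kept"),
    "DB.a": ModeSpec("database", "all", True, False, "kept"),
    "DISMS2.af": ModeSpec("distance", "all", True, True, "kept"),
    "DB.af": ModeSpec("database", "all", True, True, "kept"),
    "DISMS2.nofilter": ModeSpec("distance", "all", False, False, "kept"),
}


def spectrum_universe(run: Run, ann: AnnotationTable, universe: str) -> Run:
    """Apply the spectrum universe: ``all`` keeps the run, ``reduced``
    keeps only annotated spectra (order preserved, ranks recomputed)."""
    if universe == "all":
        return run
    if universe != "reduced":
        raise ValueError(f"unknown universe {universe!r}")
    kept = [s for s in run if ann.get(run.run_id, s.scan_number) is not None]
    return Run(run_id=run.run_id, spectra=kept)


def _dedup_no_hit(run_i: Run, run_j: Run, ann: AnnotationTable) -> float:
    peps_i = {p for p in ann.peptides(run_i) if p is not None}
    peps_j = {p for p in ann.peptides(run_j) if p is not None}
    if not peps_i:
        raise ValueError(f"run {run_i.run_id!r} has no annotated peptides; "
                         f"deduplicated fraction undefined")
    return len(peps_i - peps_j) / len(peps_i)


def _database_no_hit(run_i: Run, run_j: Run, ann: AnnotationTable,
                     mode: ModeSpec, params: MatchParams,
                     pre_i: Optional[PreprocessedRun] = None,
                     pre_j: Optional[PreprocessedRun] = None) -> float:
    if run_i.n_spectra == 0:
        raise ValueError(f"run {run_i.run_id!r} is empty")
    peps_i = ann.peptides(run_i)
    peps_j = ann.peptides(run_j)
    if mode.filter_check:
        pre_i = pre_i or preprocess_run(run_i, params)
        pre_j = pre_j or preprocess_run(run_j, params)
    pep_j_arr = np.array([p if p is not None else "" for p in peps_j], dtype=object)
    annotated_j = np.array([p is not None for p in peps_j], dtype=bool)
    no_hit = 0
    for idx, pep in enumerate(peps_i):
        if pep is None:  # annotation check: unannotated query is a no hit
            no_hit += 1
            continue
        if mode.filter_check:
            ranks = candidate_indices(idx + 1, pre_j, pre_i.spectra[idx], params)
            if ranks.size == 0:
                no_hit += 1
                continue
            sel = ranks - 1
        else:
            sel = slice(None)
        ok = annotated_j[sel] & (pep_j_arr[sel] == pep)
        if not np.any(ok):
            no_hit += 1
    return no_hit / run_i.n_spectra


def directed_no_hit_fraction(run_i: Run, run_j: Run, ann: AnnotationTable,
                             mode: ModeSpec, params: MatchParams) -> float:
    """Directed fraction of run-i spectra with no hit in run j.

    Expects the spectrum universe to have been applied already (see
    :func:`spectrum_universe`); :func:`mode_distance_matrix` does this.
    """
    if mode.duplicates == "removed":
        return _dedup_no_hit(run_i, run_j, ann)
    if mode.search_method == "database":
        return _database_no_hit(run_i, run_j, ann, mode, params)
    pre_i = preprocess_run(run_i, params)
    pre_j = preprocess_run(run_j, params)
    query_ok = cand_ok = None
    if mode.annotation_check:
        query_ok = np.array([p is not None for p in ann.peptides(run_i)], dtype=bool)
        cand_ok = np.array([p is not None for p in ann.peptides(run_j)], dtype=bool)
    return _directed(pre_i, pre_j, params, query_ok=query_ok, cand_ok=cand_ok,
                     use_constraints=mode.filter_check)


def mode_distance_matrix(runs: Sequence[Run], ann: AnnotationTable,
                         mode: Union[str, ModeSpec],
                         params: MatchParams) -> DistanceMatrix:
    """Symmetrized no-hit-fraction matrix for one comparison mode."""
    if isinstance(mode, str):
        mode = MODE_PRESETS[mode]
    labels = [r.run_id for r in runs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate run ids")
    reduced = [spectrum_universe(r, ann, mode.universe) for r in runs]
    n = len(reduced)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 0.5 * (directed_no_hit_fraction(reduced[i], reduced[j], ann, mode, params)
                       + directed_no_hit_fraction(reduced[j], reduced[i], ann, mode, params))
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)
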