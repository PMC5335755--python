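"""Candidate constraints, directed matching, run distance matrix."""

import math

import numpy as np
import pytest

from disms2 import (DistanceSpec, MatchParams, Run, candidate_indices,
                    directed_run_distance, preprocess_run, run_distance,
                    run_distance_matrix)
from disms2.matching import _directed

from conftest import make_spectrum, random_spectrum


def uniform_run(run_id, n, charge=2, precursor=1000.0, seed=0):
    rng = np.random.default_rng(seed)
    spectra = [random_spectrum(rng, scan=i + 1, charge=charge)
               for i in range(n)]
    for s in spectra:
        s.precursor_mz = precursor
    return Run(run_id, spectra)


class TestCandidateIndices:
    def test_rank_window(self):
        run_j = preprocess_run(uniform_run("j", 10), MatchParams(ret=2, prec=1e9))
        query = preprocess_run(uniform_run("i", 10), MatchParams(ret=2)).spectra[4]
        ranks = candidate_indices(5, run_j, query, MatchParams(ret=2, prec=1e9))
        assert set(ranks) == {3, 4, 5, 6, 7}
        assert len(ranks) <= 2 * 2 + 1

    def test_window_clipped_at_run_bounds(self):
        params = MatchParams(ret=3, prec=1e9)
        run_j = preprocess_run(uniform_run("j", 5), params)
        query = preprocess_run(uniform_run("i", 5), params).spectra[0]
        assert set(candidate_indices(1, run_j, query, params)) == {1, 2, 3, 4}

    def test_ppm_tolerance(self):
        params = MatchParams(ret=10, prec=10.0)
        spectra = [make_spectrum([100.0], scan=1, precursor=1000.009),
                   make_spectrum([100.0], scan=2, precursor=1000.02)]
        run_j = preprocess_run(Run("j", spectra), params)
        query = preprocess_run(
            Run("i", [make_spectrum([100.0], scan=1, precursor=1000.0)]),
            params).spectra[0]
        ranks = candidate_indices(1, run_j, query, params)
        assert set(ranks) == {1}  # 9 ppm passes, 20 ppm fails

    def test_charge_mismatch_empty(self):
        params = MatchParams(ret=10, prec=1e9)
        run_j = preprocess_run(uniform_run("j", 4, charge=3), params)
        query = preprocess_run(uniform_run("i", 4, charge=2), params).spectra[0]
        assert candidate_indices(1, run_j, query, params).size == 0

    def test_unknown_charge_only_matches_unknown(self):
        params = MatchParams(ret=10, prec=1e9)
        known = preprocess_run(uniform_run("j", 3, charge=2), params)
        unknown = preprocess_run(uniform_run("k", 3, charge=None), params)
        q_unknown = preprocess_run(uniform_run("i", 3, charge=None), params).spectra[0]
        assert candidate_indices(1, known, q_unknown, params).size == 0
        assert candidate_indices(1, unknown, q_unknown, params).size == 3


class TestDirectedDistance:
    def test_self_distance_zero(self):
        run = uniform_run("i", 8, seed=1)
        assert directed_run_distance(run, run, MatchParams()) == 0.0

    def test_unmatched_fraction(self):
        # run i: 4 spectra; construct run j so that exactly 2 match
        params = MatchParams(ret=10, prec=10.0, cdis=0.3)
        si = [make_spectrum([100.0, 200.0], [1, 1], scan=k, precursor=p, charge=c)
              for k, (p, c) in enumerate([(500.0, 2), (600.0, 2),
                                          (700.0, 2), (800.0, 3)], start=1)]
        # j: copies of spectra 1,2; a disjoint spectrum at precursor 700;
        # nothing at charge 3 (empty candidates for spectrum 4)
        sj = [make_spectrum([100.0, 200.0], [1, 1], scan=1, precursor=500.0, charge=2),
              make_spectrum([100.0, 200.0], [1, 1], scan=2, precursor=600.0, charge=2),
              make_spectrum([900.0, 1000.0], [1, 1], scan=3, precursor=700.0, charge=2)]
        d = directed_run_distance(Run("i", si), Run("j", sj), params)
        assert d == pytest.approx(2 / 4)

    def test_empty_run_errors(self):
        with pytest.raises(ValueError, match="empty"):
            directed_run_distance(Run("i", []), uniform_run("j", 3), MatchParams())

    def test_mean_of_directed(self):
        # asymmetric construction: j contains everything of i plus extras
        params = MatchParams(ret=100, prec=1e9, cdis=0.3)
        rng = np.random.default_rng(4)
        base = [random_spectrum(rng, scan=k + 1) for k in range(6)]
        run_i = Run("i", base[:3])
        run_j = Run("j", [make_spectrum(s.mz, s.intensity, scan=k + 1,
                                        precursor=s.precursor_mz)
                          for k, s in enumerate(base)])
        dij = directed_run_distance(run_i, run_j, params)
        dji = directed_run_distance(run_j, run_i, params)
        assert dij == 0.0 and dji == pytest.approx(0.5)
        assert run_distance(run_i, run_j, params) == pytest.approx((dij + dji) / 2)

    def test_no_shared_charges_gives_one(self):
        run_i = uniform_run("i", 5, charge=2)
        run_j = uniform_run("j", 5, charge=3)
        assert run_distance(run_i, run_j, MatchParams()) == 1.0


class TestDistanceMatrix:
    def test_symmetric_zero_diagonal(self, small_dataset, default_params):
        runs, _, _ = small_dataset
        dm = run_distance_matrix(runs[:4], default_params)
        assert np.array_equal(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0.0)
        assert np.all((dm.values >= 0) & (dm.values <= 1))

    def test_identical_runs_zero_matrix(self):
        run = uniform_run("a", 6, seed=9)
        copies = [Run(f"c{k}", [make_spectrum(s.mz, s.intensity, scan=s.scan_number,
                                              precursor=s.precursor_mz)
                                for s in run]) for k in range(3)]
        dm = run_distance_matrix(copies, MatchParams())
        assert np.all(dm.values == 0.0)

    def test_duplicate_ids_rejected(self):
        run = uniform_run("a", 3)
        with pytest.raises(ValueError, match="duplicate"):
            run_distance_matrix([run, run], MatchParams())

    def test_within_species_below_between(self, small_dataset, default_params):
        runs, labels, _ = small_dataset
        dm = run_distance_matrix(runs, default_params)
        n = dm.n
        within = [dm.values[i, j] for i in range(n) for j in range(i + 1, n)
                  if labels[i] == labels[j]]
        between = [dm.values[i, j] for i in range(n) for j in range(i + 1, n)
                   if labels[i] != labels[j]]
        assert max(within) < min(between)


def oracle_unconstrained_directed(run_i, run_j, params):
    """All-pairs nearest-neighbor, ignoring rank/charge/ppm constraints."""
    from disms2 import UndefinedDistance, preprocess_spectrum, spectrum_distance
    bi = [preprocess_spectrum(s, params.topn, params.bin) for s in run_i]
    bj = [preprocess_spectrum(s, params.topn, params.bin) for s in run_j]
    unmatched = 0
    for a in bi:
        best = math.inf
        for b in bj:
            try:
                best = min(best, spectrum_distance(a, b, params.dist))
            except UndefinedDistance:
                continue
        if not best < params.cdis:
            unmatched += 1
    return unmatched / len(bi)


class TestBruteForceEquivalence:
    def test_constrained_equals_oracle_when_constraints_maximal(self):
        rng = np.random.default_rng(42)
        for trial in range(5):
            ni, nj = rng.integers(5, 50, size=2)
            run_i = Run("i", [random_spectrum(rng, scan=k + 1) for k in range(ni)])
            run_j = Run("j", [random_spectrum(rng, scan=k + 1) for k in range(nj)])
            params = MatchParams(ret=10 ** 6, prec=math.inf, cdis=0.7,
                                 dist=DistanceSpec("cos"))
            assert directed_run_distance(run_i, run_j, params) == pytest.approx(
                oracle_unconstrained_directed(run_i, run_j, params), abs=1e-12)

    def test_monotone_in_ret_prec_cdis(self):
        rng = np.random.default_rng(12)
        run_i = Run("i", [random_spectrum(rng, scan=k + 1) for k in range(20)])
        run_j = Run("j", [random_spectrum(rng, scan=k + 1) for k in range(20)])
        base = dict(topn=math.inf, bin=0.2)
        for knob, levels in (("ret", [1, 5, 50]),
                             ("prec", [5.0, 100.0, 1e7]),
                             ("cdis", [0.1, 0.3, 0.9])):
            vals = []
            for lv in levels:
                kw = dict(base, ret=10 ** 5, prec=1e7, cdis=0.5)
                kw[knob] = lv
                vals.append(directed_run_distance(run_i, run_j, MatchParams(**kw)))
            assert all(x >= y - 1e-12 for x, y in zip(vals, vals[1:]))
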