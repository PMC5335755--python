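"""One-way PERMANOVA on run distance matrices and the parameter grid.

Anderson's non-parametric multivariate ANOVA partitions the squared
distances of N runs into between-group and within-group sums of squares:

    SS_total  = (1/N)   * sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    SS_between = SS_total - SS_within

The goodness-of-fit measure is the partial R-squared
``SS_between / SS_total`` (between-species variation over total
variation); the test statistic is the pseudo-F ratio

    F = (SS_between / (g - 1)) / (SS_within / (N - g)),

whose null distribution is obtained by uniformly permuting the group
labels (Monte-Carlo, with the +1 small-sample correction on the p-value).

The module also carries the published factorial evaluation designs for
the matching parameters, the grid search ranking parameter combinations
by partial R-squared, and the coefficient-of-variation statistic used to
compare two methods' distance matrices.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .distances import DistanceSpec
from .matching import DistanceMatrix, MatchParams, run_distance_matrix
from .spectra import Run

__all__ = [
    "PermanovaResult",
    "sums_of_squares",
    "permutation_test",
    "FactorialDesign",
    "DESIGN_1",
    "DESIGN_2",
    "enumerate_grid",
    "grid_search",
    "compare_methods_cv",
]


@dataclass
class PermanovaResult:
    """Sum-of-squares decomposition plus the permutation test outcome."""

    ss_total: float
    ss_between: float
    ss_within: float
    pseudo_f: float
    partial_r2: float
    n_groups: int
    n_samples: int
    p_value: Optional[float] = None
    n_permutations: int = 0

    def summary(self) -> str:
        lines = [
            "PERMANOVA (one-way, on distances)",
            f"  samples: {self.n_samples}   groups: {self.n_groups}",
            f"  SS total:   {self.ss_total:.6g}",
            f"  SS between: {self.ss_between:.6g}",
            f"  SS within:  {self.ss_within:.6g}",
            f"  partial R2: {self.partial_r2:.4f}",
            f"  pseudo-F:   {self.pseudo_f:.4f}",
        ]
        if self.p_value is not None:
            lines.append(f"  p-value:    {self.p_value:.4g} "
                         f"({self.n_permutations} permutations)")
        return "\n".join(lines)


def _group_indices(groups: Sequence[str]) -> List[np.ndarray]:
    order: Dict[str, list] = {}
    for i, g in enumerate(groups):
        order.setdefault(g, []).append(i)
    return [np.asarray(v, dtype=np.intp) for v in order.values()]


def _ss_decomposition(d2: np.ndarray, idx_groups: List[np.ndarray]) -> tuple:
    n = d2.shape[0]
    ss_total = float(d2[np.triu_indices(n, k=1)].sum()) / n
    ss_within = 0.0
    for idx in idx_groups:
        sub = d2[np.ix_(idx, idx)]
        ss_within += float(sub.sum()) / (2.0 * idx.size)
    return ss_total, ss_within


def _pseudo_f(ss_between: float, ss_within: float, g: int, n: int) -> float:
    if ss_within == 0.0:
        return math.inf
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def sums_of_squares(d: DistanceMatrix, groups: Sequence[str]) -> PermanovaResult:
    """Anderson's sum-of-squares decomposition (no permutation test)."""
    n = d.n
    if len(groups) != n:
        raise ValueError("one group label per run is required")
    idx_groups = _group_indices(groups)
    g = len(idx_groups)
    if g < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    d2 = d.values ** 2
    ss_total, ss_within = _ss_decomposition(d2, idx_groups)
    ss_between = ss_total - ss_within
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return PermanovaResult(
        ss_total=ss_total, ss_between=ss_between, ss_within=ss_within,
        pseudo_f=_pseudo_f(ss_between, ss_within, g, n),
        partial_r2=r2, n_groups=g, n_samples=n)


def permutation_test(d: DistanceMatrix, groups: Sequence[str],
                     n_perm: int = 10000,
                     seed: Optional[int] = None) -> PermanovaResult:
    """Monte-Carlo permutation test of the pseudo-F statistic.

    ``p = (#{permuted F >= observed F} + 1) / (n_perm + 1)``; labels are
    shuffled uniformly at random, reproducibly for a given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    result = sums_of_squares(d, groups)
    groups = np.asarray(list(groups), dtype=object)
    d2 = d.values ** 2
    n, g = result.n_samples, result.n_groups
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        idx_groups = _group_indices(groups[perm])
        ss_total, ss_within = _ss_decomposition(d2, idx_groups)
        f = _pseudo_f(ss_total - ss_within, ss_within, g, n)
        if f >= result.pseudo_f:
            count += 1
    result.p_value = (count + 1) / (n_perm + 1)
    result.n_permutations = n_perm
    return result


# --- factorial designs ----------------------------------------------------

_INF = math.inf
_D_ANGLE = DistanceSpec("angle", epsilon=0.05)
_D_COS = DistanceSpec("cosine")
_D_PH = DistanceSpec("hausdorff", delta=0.05, k_root=50)


@dataclass(frozen=True)
class FactorialDesign:
    """Per-parameter level lists whose Cartesian product forms a grid."""

    topn: Sequence[float]
    bin: Sequence[float]
    ret: Sequence[int]
    prec: Sequence[float]
    dist: Sequence[DistanceSpec]
    cdis: Sequence[float]

    @property
    def size(self) -> int:
        return (len(self.topn) * len(self.bin) * len(self.ret)
                * len(self.prec) * len(self.dist) * len(self.cdis))


#: Evaluation design 1: 3 x 2 x 2 x 1 x 3 x 2 = 72 combinations.
DESIGN_1 = FactorialDesign(
    topn=(20, 50, _INF),
    bin=(0.01, 0.2),
    ret=(1000, 3000),
    prec=(10.0,),
    dist=(_D_ANGLE, _D_COS, _D_PH),
    cdis=(0.1, 0.3),
)

#: Evaluation design 2 (angle distance with higher cutoffs): 9 combinations.
DESIGN_2 = FactorialDesign(
    topn=(20, 50, _INF),
    bin=(0.2,),
    ret=(3000,),
    prec=(10.0,),
    dist=(_D_ANGLE,),
    cdis=(0.4, 0.5, 0.6),
)


def enumerate_grid(design: Union[FactorialDesign, Sequence[FactorialDesign]]
                   ) -> List[MatchParams]:
    """Cartesian product of the design levels; multiple designs are
    concatenated without deduplication."""
    designs = [design] if isinstance(design, FactorialDesign) else list(design)
    grid: List[MatchParams] = []
    for dsg in designs:
        for topn, bn, ret, prec, dist, cdis in itertools.product(
                dsg.topn, dsg.bin, dsg.ret, dsg.prec, dsg.dist, dsg.cdis):
            grid.append(MatchParams(topn=topn, bin=bn, ret=ret, prec=prec,
                                    dist=dist, cdis=cdis))
    return grid


def grid_search(runs: Sequence[Run], groups: Sequence[str],
                design: Union[FactorialDesign, Sequence[FactorialDesign]],
                n_perm: int = 10000,
                seed: Optional[int] = None) -> pd.DataFrame:
    """Evaluate every grid setting; rank by partial R-squared descending.

    Ties keep grid order (stable sort). Returns a DataFrame with columns
    rank, topn, bin, ret, prec, dist, cdis, partial_r2, p_value.
    """
    grid = enumerate_grid(design)
    rows = []
    for params in grid:
        dm = run_distance_matrix(runs, params)
        res = permutation_test(dm, groups, n_perm=n_perm, seed=seed)
        rows.append({
            "topn": params.topn, "bin": params.bin, "ret": params.ret,
            "prec": params.prec, "dist": str(params.dist), "cdis": params.cdis,
            "partial_r2": res.partial_r2, "p_value": res.p_value,
        })
    df = pd.DataFrame(rows)
    df = df.sort_values("partial_r2", ascending=False, kind="stable")
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df.reset_index(drop=True)


def compare_methods_cv(d1: DistanceMatrix, d2: DistanceMatrix) -> float:
    """Coefficient of variation of |d1 - d2| over the upper triangle.

    ``CV = sd / mean`` with the n-1 standard-deviation denominator. Small
    values flag a systematic (relevant) difference between methods; a CV
    is undefined when the matrices are identical (mean difference 0).
    """
    if d1.labels != d2.labels:
        raise ValueError("distance matrices must share labels")
    diffs = np.abs(d1.condensed() - d2.condensed())
    mean = diffs.mean()
    if mean == 0:
        raise ValueError("matrices are identical; CV undefined (mean |diff| = 0)")
    return float(diffs.std(ddof=1) / mean)
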