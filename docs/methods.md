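# Methods

## Model and assumptions

`disms2` treats an LC-MS/MS run as an ordered bag of MS2 spectra and
defines the dissimilarity of two runs as the symmetrized fraction of
spectra without a sufficiently similar counterpart. The approach assumes
centroided spectra, data-dependent acquisition (so replicate runs sample
overlapping but non-identical sets of precursors), and chromatographic
reproducibility good enough that a window on the *rank* of the scan
number can replace retention-time alignment. No peptide identification is
performed or required; annotations, when supplied, are consumed only by
the comparison modes that benchmark against database search.

## Pipeline

1. **Preprocessing** (per spectrum): keep the `topn` most intense peaks
   (ties at the cutoff prefer the lower-m/z peak, making selection
   deterministic), then bin at width `bin` with half-open intervals
   `[n*·bin, (n*+1)·bin)`; each occupied bin is represented by its
   maximum intensity at the central m/z `(n*+0.5)·bin`. A peak exactly on
   a boundary belongs to the upper bin. Binning at the same width is
   idempotent. Spectra emptied by preprocessing are retained in the run:
   they can never match and always count in the denominator of the
   directed distance.
2. **Candidate filtering** for query rank `k` against run `j`: rank
   window `[k−ret, k+ret]` over the scan-ordered retained spectra of `j`
   (never more than `2·ret+1` candidates), equal precursor charge
   (a spectrum with unknown charge matches only unknown charge — the
   conservative reading of "same charge state"), and precursor m/z
   agreement within `prec` ppm (applied to the recorded precursor m/z;
   with equal charges this is equivalent to a ppm window on neutral
   mass). The constraints are checked in the order (a) window, (b)
   charge, (c) ppm, which affects speed only.
3. **Spectrum distances.** Cosine distance uses the binned intensity
   vectors over the union of occupied bins. The angle and Hausdorff
   distances use the representative peak *positions* of the same binned
   spectra, so all measures see one preprocessing path. The angle
   numerator counts, per peak of the first spectrum, the existence of a
   partner within ε in the second; because several query peaks can share
   one partner the ratio can exceed 1 and is clamped to [0, 1] before the
   arccos — this also makes the measure total. The measure is directional
   by construction; the implementation evaluates it as written, and the
   test suite measures (rather than hides) its asymmetry on random
   spectra. In the Hausdorff term the `1/k`-th root applies to the
   product `min·indicator` and `0^(1/k)` is taken as 0, keeping the term
   continuous at the tolerance δ.
4. **Matching and run distance.** A query is matched iff its candidate
   set is non-empty and the minimal distance is *strictly* below `cdis`
   (equality counts as no match; the boundary case is otherwise
   undefined). `d*(i,j)` is the unmatched fraction; `d(i,j)` the mean of
   both directions; the N×N matrix needs `N(N−1)` directed computations
   and is symmetric with a zero diagonal by construction.

Defaults (`topn=Inf, bin=0.2, ret=3000, prec=10 ppm, cosine, cdis=0.3`)
are the best-ranked setting of the published factorial evaluation.

## PERMANOVA and parameter optimization

Anderson's decomposition on the distance matrix:
`SS_total = (1/N)·Σ_{i<j} d²_ij`,
`SS_within = Σ_g (1/n_g)·Σ_{i<j∈g} d²_ij`, `SS_between` by difference.
Partial R² = `SS_between/SS_total` (defined as 0 for an all-zero matrix,
which carries no between-group signal); pseudo-F =
`(SS_between/(g−1))/(SS_within/(N−g))`, +∞ at zero within-group variation.
The permutation test shuffles labels uniformly (Monte-Carlo, not
exhaustive) and applies the +1 correction,
`p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1)`; given a seed it is
deterministic. Note the combinatorial floor: with `g` groups of sizes
`n_g` the smallest attainable p is approximately the probability of
re-drawing the observed partition (for 3 groups of 3, 1/280 ≈ 0.0036),
regardless of effect size. Partial R² is invariant under positive
rescaling of the matrix, since every sum of squares scales by the square
of the constant.

The factorial designs are built in: design 1 crosses
topn {20, 50, ∞} × bin {0.01, 0.2} × ret {1000, 3000} × prec {10} ×
dist {angle(ε=0.05), cos, Hausdorff(δ=0.05, k=50)} × cdis {0.1, 0.3}
(72 settings); design 2, added because the angle distance is not bounded
by 1, crosses topn {20, 50, ∞} × bin {0.2} × ret {3000} × prec {10} ×
angle(ε=0.05) × cdis {0.4, 0.5, 0.6} (9 settings). `grid_search` ranks
all settings by partial R² (stable sort; ties keep grid order).

The method-comparison statistic is the coefficient of variation of the
absolute entrywise differences of two matrices (upper triangle, sd with
the n−1 denominator); it is undefined for identical matrices.

## Comparison modes

The six benchmark algorithms decompose into five switches (search method,
spectrum universe, annotation check, filter check, duplicate handling);
the presets reproduce the canonical combinations, and `DISMS2.nofilter`
adds the unfiltered distance search. Peptide equality is exact string
equality of sequence-plus-modifications — no I/L or modification
collapsing. With duplicates removed the directed denominator is the
number of unique peptides of the query run. An unannotated query under
the annotation check is itself a no-hit (not merely its candidates).
Database modes without the filter check score hits against the whole
candidate run. `DISMS2.f` is bit-identical to the core matrix by
construction (same code path with no annotation mask).

## Clustering

UPGMA with a deterministic tie-break (merge the pair whose smallest
member labels are lexicographically least) and lexicographic child
ordering in the Newick output. Branch length of a node =
`parent_height/2 − own_height/2`, so leaves sit at depth `root_height/2`
and the path length between two leaves equals the merge height of their
lowest common ancestor (ultrametric).

## Synthetic data

The generator emulates a multi-species replicate study. Each species owns
`spectra_per_run` template spectra (uniform peak positions in
[100, 1500] Th, lognormal intensities, uniform precursors in
[300, 1500] Th, charges 2:3 weighted 0.6:0.4); a configurable fraction of
templates is shared across species. A technical replicate re-measures the
library with: whole-spectrum dropout 0.25 (the DDA effect — replicates
fragment overlapping but different precursor sets), fragment m/z jitter
sd 0.002 Th (far below the 0.2 Th bin), precursor jitter sd 2 ppm (far
below the 10 ppm tolerance), multiplicative lognormal intensity noise
with CV 0.25, per-peak dropout 0.05, and elution-order shuffling within
windows of 10 scans. Each surviving spectrum is annotated with its
template identifier except a missing fraction of 0.4, in the middle of
the 30–60% annotation-failure range typical of database searches. The
noise levels were fixed once so the within-species run distance sits near
0.3, the regime reported for real technical replicates; under these
defaults the end-to-end pipeline yields within-species distances
≈ 0.27–0.31, between-species distances 1.0 for disjoint libraries, and
partial R² ≈ 0.90–0.93 across seeds.

What the generator does **not** model: real fragmentation chemistry (b/y
ion series), isotope envelopes, chimeric spectra, intensity-dependent
precursor selection, retention-time drift beyond local shuffling, and
cross-species peptide conservation beyond identical shared templates.
Passing tests on synthetic data therefore demonstrate the correctness and
discriminative behaviour of the pipeline under controlled noise, not
performance on real instrument data.

## Numerical choices and problem sizes

- Distances returning values in closed ranges are clipped against
  floating-point overshoot (cosine to [0, 1], the arccos argument to
  [0, 1]).
- Distance of/with an empty spectrum is an explicit "undefined" signal,
  converted by the matching layer to "no match" — no NaNs propagate.
- Tests and the acceptance script run at desk scale: runs of 20–120
  spectra, 9-run matrices, 10 000 permutations; the full pipeline
  completes in seconds.

## Known limitations

- The angle distance is asymmetric for spectra with unequal peak counts;
  it is computed as defined, with the first argument as the query.
- No retention-time alignment: the rank window assumes comparable
  acquisition ordering across runs.
- Single-process execution; matrices are O(N²) in runs and O(n·ret) in
  spectra per directed comparison.
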