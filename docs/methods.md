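# Methods

## Locus handling

Alignments are per-locus FASTA files over `{A,C,G,T,-,N,?}` (IUPAC
ambiguity codes are tolerated and treated as missing data in every
downstream computation, but only `-`, `N` and `?` count as "empty" for
column cleanup, so an all-`R` column would not be removed). A
parsimony-informative site requires at least two unambiguous nucleotide
states each present in at least two taxa. The completeness filter keeps
loci with at least `ceil(p * T)` of the `T` study taxa; the ceiling
convention is a documented choice (a floor rule can be emulated by
adjusting `p`), since "at least p% complete" does not fix the rounding.
Concatenated matrices order loci lexicographically by locus id, pad
absent taxa with `?`, and write all charset coordinates 1-based
inclusive (NEXUS/RAxML convention); internal coordinates are 0-based
half-open throughout.

## Core/flank character sets

`locate_core` centres a 160 bp window with left offset
`floor((L - 160) / 2)`; when `L - 160` is odd the extra column falls to
the right flank. Each flank is divided independently into five
contiguous bins of width `floor(F / 5)`, and the remainder `r = F mod 5`
adds one site to each of the `r` *outermost* bins — the per-site
informativeness profile changes fastest near the core, so keeping the
inner bins at exactly the base width keeps them most homogeneous. Bin
`k` of the left flank is pooled with bin `k` of the right flank into
charset `flank_k`, `k = 1` adjacent to the core. Loci shorter than the
core become single-charset (`core`) loci rather than errors. Charsets
always partition the columns: disjoint and exhaustive for every length.

## Likelihood engine and guide tree

The engine implements Felsenstein pruning under GTR+Γ. Exchangeabilities
are relative to `r_GT = 1`; the rate matrix is normalized to one
expected substitution per unit branch length at stationarity. Rate
variation uses the discrete-gamma category-mean scheme with four
equal-probability categories (the de facto standard of the inference
tools this pipeline feeds): category `k` carries the conditional mean of
its Gamma(α, α) slice, computed from regularized incomplete gamma
functions so the category means integrate exactly to one. Missing tip
states get all-ones partial vectors; identical site patterns are
compressed and weighted. No numerical rescaling is applied within the
pruning recursion: at the taxon counts this package targets (≤ ~40) the
smallest partial products stay far above the double-precision underflow
threshold.

Guide trees are neighbor-joining trees (scikit-bio) on Jukes–Cantor
corrected p-distances; saturated pairs (p ≥ 0.75) are capped at distance
5 substitutions/site, negative NJ branch lengths are clamped to zero. A
taxon pair with no overlapping data has no defined distance and is an
error. Optionally the branch lengths are refined once per locus by
bounded coordinate ascent under a default GTR+Γ model; they are then
held fixed for all subsets of that locus.

Subset fitting maximizes lnL over the five free exchangeabilities, three
free base-frequency weights, α and the subset rate multiplier by
coordinate ascent with bounded scalar line searches in log space
(bounds: rates [1e-6, 100], α [0.02, 100], multiplier [1e-3, 100];
weights [1e-3, 1e3] before normalization). A sweep ends when lnL
improves by less than 1e-6 or after 200 sweeps; the first two sweeps use
a coarse line-search tolerance and coordinates that stop contributing
are frozen, which cuts fitting time roughly in half without affecting
the ascent property (the likelihood never decreases from its
initialization). Non-convergence returns the best-so-far fit with a
flag.

## Scheme selection

Schemes are set-partitions of a locus's charsets. Branch lengths are
estimated once per locus and shared across subsets, so K counts them
once (2T−3); each subset contributes 9 substitution parameters; subset
rate multipliers satisfy a mean-rate-one constraint
(Σ n_s·m_s / n = 1), so S subsets contribute S−1 free multipliers —
fitting each multiplier freely and rescaling is equivalent because the
shared branch lengths absorb one global scale. The AICc sample size is
the number of *sites* (not site patterns); the literature is split on
this and the choice is deliberate and documented. The greedy search
starts fully split and accepts the merge that most decreases AICc,
breaking ties lexicographically; the exhaustive search scores every
set-partition (≤ 6 charsets, Bell(6) = 203) and serves as the reference
optimum in the benchmark suites. Fits are cached per charset subset, so
greedy and exhaustive searches on the same context share work.

## Gene-tree QC

Mean support averages over non-trivial internal edges only; support
scales are auto-detected ([0,1] posteriors are rescaled to [0,100]).
The "lowest 10% quantile" filter drops loci strictly below the type-7
(linear-interpolation) 0.10 quantile of mean supports. Saturation is
diagnosed by OLS of uncorrected p-distances on patristic distances over
the upper-triangle taxon pairs: multiple hits depress the slope, so
loci whose slope falls below the lower Tukey fence (Q1 − 1.5·IQR,
multiplier configurable) are flagged. The outlier rule for
"potentially over-saturated" loci was an open design point; the Tukey
fence was chosen because it is scale-free and needs no tuning against a
reference distribution. Burn-in removal drops the first
`floor(b·N)` trees (default b = 0.25). ASDSF includes splits reaching
frequency ≥ 0.10 in at least one run and averages the n−1-denominator
standard deviation of per-run frequencies. The MCCT is the *sampled*
tree maximizing the sum of log clade frequencies (clades taken from the
rooted representation, frequencies over the full post-burn-in sample),
ties broken by first occurrence — not a consensus construction, so the
result is always a topology that was actually visited.

## Tree distances

All metrics are topological: trees are reduced to unrooted adjacency
structures, branch lengths ignored, degree-2 nodes suppressed.
RF is the size of the symmetric difference of non-trivial bipartition
sets (multifurcations allowed). Path distance is the Euclidean norm of
the difference of the two trees' vectors of leaf-pair edge counts. The
exact SPR distance is a breadth-first search over SPR neighborhoods
(≤ 10 leaves; published closed form 2(n−3)(2n−7) for the neighborhood
size is verified in the tests). The approximate SPR distance first
collapses cherries shared by both trees (kernelization), then greedily
deletes the leaf whose removal most reduces RF, one move per deletion,
until the restricted topologies agree. Every deleted leaf could be
re-inserted correctly with one SPR move, so the count is an upper bound
on the true distance and is zero exactly for identical topologies. No
numeric agreement with any specific published SPR implementation is
claimed; the heuristic is validated against the exact BFS oracle.

## Capture statistics

Welch's t-test uses the Welch–Satterthwaite degrees of freedom,
two-sided. The "GLM" of locus count on age and preservation is
identity-link Gaussian by default (the identity-link Gaussian GLM is
fitted via its exact OLS equivalent; a log-link Poisson variant is
available), with treatment coding and ethanol as the reference level.
Capture fractions are counts divided by the within-study maximum; since
the maximum specimen has fraction exactly 1 (infinite logit), the
Smithson–Verkuilen squeeze p' = (p(n−1) + 0.5)/n is applied before the
logit. The common-slope test compares Gaussian ML fits with per-study
intercepts and either per-study or shared age slopes;
2(lnL_full − lnL_reduced) is referred to χ² with (#studies − 1) degrees
of freedom. Ages are sequencing year minus collection year.

## Synthetic data

The generators emulate the study conditions the pipeline targets:
~33-taxon datasets, locus lengths uniform on 231–802 sites, a 160 bp
core, and a per-charset rate profile rising from 0.2 (core) to 1.5
(outermost flank) — chosen to reproduce the qualitative core/flank
informativeness shape, not fitted to any dataset. Trees are Yule
topologies with ultrametric branch lengths scaled to a configurable
height (default 0.15 substitutions/site root-to-tip). Sequence
evolution uses eigendecomposition of the normalized GTR matrix for
transition probabilities, with i.i.d. per-site gamma-category
assignment. Museum degradation retains each specimen × locus sequence
with probability expit(a + b·age) and truncates surviving sequences of
aged specimens symmetrically from both ends (fraction
min(0.9, truncation_rate·age)), mimicking the shorter contigs recovered
from degraded DNA. Pseudo-posterior samples apply Poisson(λ) random SPR
moves per sampled tree. Capture tables draw logit fractions linear in
age with Gaussian noise and map them back to counts through each
study's maximum locus count. Every generator is a pure function of
(configuration, seed).

What the generators do *not* emulate: alignment error, indels,
contamination, non-stationary base composition, and linked loci. Passing
calibrations therefore demonstrate correctness of the algorithms under
the generating model, not robustness to real-data artefacts.

## Benchmark suites and problem sizes

The packaged suites (in `corepart.benchmarks`, driven by
`scripts/acceptance.py` and the acceptance tests) use deliberately
scaled problem sizes: 6-taxon, 300–600-site loci for the scheme-search
calibrations (100 replicates each of the homogeneous-merge and
heterogeneous-split conditions; heterogeneity is gamma shape 0.1 vs 10
with rate multipliers 0.2 vs 2); 10 kb, 8-taxon alignments for parameter
recovery; the exhaustive 105-topology six-leaf suite for tree-distance
oracles; 10 sets of 18 normal + 2 ten-fold-rate loci for saturation
flagging; 100 mild-perturbation posterior samples for MCCT recovery; and
3 studies × 30 specimens with logit noise sd 0.8 (matching the scatter
of published capture-decay regressions) for the LRT size/power
calibration, with 500 null replicates. The GLM coverage check uses 60
specimens per replicate so the 2·SE band matches its nominal normal
coverage. These sizes are the package's reference conditions; all are
configurable.

## Known limitations

- The likelihood engine has no partial-likelihood rescaling and is not
  intended for hundreds of taxa.
- Guide-tree branch lengths shared across subsets trade a small amount
  of likelihood accuracy for an AICc bookkeeping that keeps small
  charsets identifiable; subset-specific branch lengths are deliberately
  out of scope.
- Exact SPR is exponential and restricted to ≤ 10 leaves; the
  approximate SPR is an upper bound with no approximation-ratio
  guarantee.
- The common-slope test calibrates its size at the logit-regression
  level; on count-level data the squeeze and within-study-max
  renormalization shift the effective slope slightly, which is inherent
  to the transform, not to the test.
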