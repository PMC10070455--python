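# Methods

`rewire3d` compares the 3D genome organization of two related samples — a
primary state (PR) and a derived state such as a drug-resistant subline (CR)
— across Hi-C contact maps, A/B compartments, chromatin loops and TADs,
whole-genome-sequencing copy number, and expression, and integrates the
layers into a per-gene evidence score. Because real datasets of this kind
require billions of read pairs, the package ships a synthetic-data generator
with recorded ground truth so that every stage can be validated end to end
at desk scale.

## Generative model

One chromosome is simulated as an `n_bins × n_bins` Poisson contact matrix
with mean

```
lambda(i,j) ∝ (1 + |i−j|)^(−α) · exp(ε·s_i·s_j) · tad(i,j) · loop(i,j) · c_i·c_j
```

scaled so the expected upper-triangle total equals `depth`.

- **α** (default 1.0, dimensionless) — power-law distance-decay exponent.
  The family decays in `(d + 1 bin)`, so `fit_power_law` accepts a
  `distance_offset_bp` to linearize short-range fits.
- **s** — blockwise ±1 checkerboard (block length default 40 bins), the A/B
  compartment truth. `ε ≥ 0` (default 0.4) is the compartmentalization
  effect; note `s_i·s_j = +1` rewards both A–A and B–B contacts, and only
  cross-compartment pairs are depleted.
- **TADs** — square blocks multiplied by a boost ≥ 1; the rewired condition
  may split a TAD at given boundaries.
- **Loops** — single boosted pixels. Default random placement puts loops at
  distances of 2–5 bins inside one compartment block: focal enrichments
  nested within a domain, in the count-rich band near the diagonal where a
  3× single-pixel boost is a detectable Poisson signal at a planted depth of
  10⁶ contacts per chromosome.
- **CNV** — the derived condition multiplies contacts by `c_i·c_j`
  (copy-ratio per bin) and scales its coverage track by `c_i`; coverage is
  Poisson around a mean depth per bin (default 200).

The rewiring specification flips a fraction of compartment blocks, adds and
removes loops, splits TADs, and plants CNV intervals; everything planted is
recorded in a `GroundTruth` object. Expression tables couple each gene's
log2 fold change to its bin's compartment delta and CNV log ratio plus
Gaussian noise, with a two-sided z p-value and Benjamini–Hochberg FDR.
Annotation tracks place genes with an A-compartment bias, motifs uniformly
with balanced strands, and construct GC as a Gaussian-copula mixture with a
configurable correlation to the compartment signs.

What the generator does **not** emulate: restriction-fragment structure,
read-level noise, replicate batch effects, inter-chromosomal contacts,
overdispersion beyond Poisson, and translocation-type SVs in the contact
map. Passing tests therefore demonstrate correctness of the algorithms
under a clean, known model — not robustness to every artifact of real Hi-C.

## Contact-map analysis

- **Balancing** — vanilla coverage (entry ÷ product of marginals, rescaled)
  or iterative correction run until the coefficient of variation of
  non-masked row sums falls below `tol` (default 1e-5, max 200 iterations).
  The bottom 2% of positive-coverage bins are masked first.
- **Distance decay** — mean contact per log-spaced distance stratum
  (single-distance strata at short range), with differential decay as
  `log2((a+pc)/(b+pc))`; the default pseudocount is the smallest positive
  stratum mean.
- **Map-resolution rule** — pass when at least 80% of bins have more than
  1000 raw contacts.
- **Reproducibility** — a stratum-adjusted correlation: 2D mean-filter
  smoothing (half-window 1 bin), per-diagonal Pearson correlations up to
  5 Mb, averaged with weights `N_d·sd_a·sd_d`; symmetric and scale-invariant.
  Sample relationships are embedded by classical (Torgerson) MDS of
  `1 − scc` distances with a deterministic sign convention.

## Compartments

The compartment score is the eigenvector of the O/E correlation matrix
(among the top 3 by eigenvalue) that best correlates with gene density, with
GC content breaking near-ties and the sign fixed so the gene-density
correlation is positive (A = positive). Orientation tracks are mean-smoothed
over 5 bins before correlating — compartments are broad and per-bin gene
counts at fine resolution are Poisson-sparse. If no component reaches
|r| ≥ 0.1 the call is refused (`OrientationAmbiguousError`) rather than
silently guessed.

Saddle analysis groups bins into score quantiles and records the log2
aggregate enrichment `Σobs/Σexp` per group pair; corner means (top/bottom
20% of groups) give the A–A, B–B and A–B strengths on the ratio scale, and
the compartmentalization score is `log2(AA·BB/AB²)` (base configurable).

Differential compartments: scores from all samples are quantile-normalized
(target = mean of sorted vectors, ties averaged); per bin, the squared
Mahalanobis distance of the between-condition mean difference is taken
against a variance pooled genome-wide from within-condition replicate
deviations; p-values come from chi-square with 1 degree of freedom (the
per-bin score difference is one-dimensional), then BH FDR with significance
at FDR < 0.3. The estimator is validated by null calibration (type-I error
0.049–0.053 at nominal 0.05), not claimed identical to any published tool.
Switch classes follow the sign pair (AA, AB, BA, BB); significant same-class
bins are merged into regions before gene overlap counting, and a gene counts
toward a class on ≥ 1 bp overlap.

## Loops and TADs

The loop caller is a donut-style local-enrichment test on raw counts: the
expected count at a pixel is the per-diagonal mean times the local
background of the O/E surface, where the background is the **maximum** of
three estimators — the donut (outer half-width 5, inner 1) and the
horizontal/vertical 3-wide bands through the pixel — so that background
inhomogeneity crossing the ring (e.g. a compartment-block edge) cannot
deflate the expectation. Significance is an upper-tail Poisson p with BH
correction over all tested pixels (distances 2–150 bins), filtered at
p ≤ 0.1 then FDR < 0.05, followed by non-maximum suppression within the
donut radius. It is validated against planted truth (recall/precision ≥ 0.9
at the study conditions), not against any published caller.

Loop/anchor set algebra uses a one-sided flank: two intervals match when
their gap is smaller than `flank_bins · resolution`, so anchors in adjacent
bins match and anchors two bins apart do not. Anchors are pooled, filtered
against excludable regions, clustered by single-linkage within the flank,
and a merged anchor is common when both conditions contribute. Both
operations are cross-checked against brute-force all-pairs oracles.

APA averages O/E submatrices centered on loop pixels; the strength is the
center pixel over the mean of the lower-left corner quadrant. Insulation
scores are `log2` of the windowed square mean crossing each bin relative to
the chromosome mean of such squares; boundaries are local minima with local
prominence ≥ `delta_threshold` (prominence evaluated within ±25 bins so
flat-background dips cannot borrow prominence from distant domain
plateaus). CTCF annotation counts stranded motifs per anchor (multiple /
single / adjacent-only after a one-bin flank / none) and classifies loop
convergence by the strand of the motif nearest each anchor midpoint.

Region association uses a circular-permutation null: all query regions are
shifted by a common random offset modulo the universe length, preserving
their lengths and spacing, with `p = (1 + #{null ≥ obs})/(1 + n_perm)` and
the mirrored tail for depletion (ties broken toward depletion when the
observation is below the null mean).

## Copy number and SVs

Coverage log2 ratios (equal-total scaling, pseudocount 1) are segmented by
circular binary segmentation: the arc maximizing the between-segment
t-statistic (global-variance form) is accepted when its sequential
permutation p-value is below `alpha` (default 0.01, ≥ 100 permutations;
early stopping once acceptance is guaranteed), recursing on the resulting
pieces with a minimum segment of 3 bins. Segments are classed loss/gain at
mean ∓0.3 (configurable). The scan is O(n²) per permutation with cached
index grids; tracks of a few thousand bins segment in seconds.

Consensus SVs: calls with < 5 paired-end reads are dropped; survivors are
clustered greedily in genomic order within (type, chromosome-pair) groups —
a call joins the first cluster whose seed matches it within the
type-specific window (1 kb for translocations, 500 bp otherwise) — and
clusters with ≥ 2 distinct callers are emitted with median coordinates.
Cross-condition intersection with the same windows yields shared and
condition-specific sets. Gene CNV class is the class of the
maximal-overlap segment.

## Integration

Three ranking metrics (signed −log10 p; log2 coverage difference × mean
coverage; compartment-score delta), a 1-SD change filter before Pearson
correlation, pre-ranked GSEA (weighted KS running sum, weight exponent 1,
gene-label permutation for sign-matched p and NES, permutation-ratio FDR),
an upper-tail hypergeometric test with BH across sets, and the importance
score: five equal-weight binary flags (DE direction at FDR 0.1, CNV
gain/loss, significant switch ending in the active/inactive state,
condition-specific anchor overlap, condition-specific boundary overlap),
summed and thresholded at ≥ 4. The PR direction mirrors every layer. The
optical-density utility computes `OD = log10(255/mean intensity)` and a
Welch two-sided t-test.

## Numerical choices and problem sizes

Fixed seeds drive every stochastic path; the same seed reproduces bitwise
identical synthetic data. The validation suite runs the recovery experiment
on one 2000-bin chromosome at depth 10⁶ (ε = 0.4, 20 loops at 3×, three CNV
segments at ×2/×0.5/×3), with loop recall/precision averaged over three
Poisson replicates because the false-positive count at FDR 0.05 with only
20 true loops has variance ~1 per draw. Null calibrations use 200
replicates per statistic. These sizes keep the whole suite within a few
minutes on one CPU while leaving each check's power intact.

Known limitations: the caller tests single pixels (no multi-scale
aggregation), CBS uses a global-variance t rather than DNAcopy's exact
statistic (decisions are permutation-calibrated either way), the
differential-compartment covariance is pooled genome-wide, and the GSEA
FDR is the standard permutation-ratio approximation.
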