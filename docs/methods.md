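# Methods

This note records the model assumptions, parameter choices, numerical
conventions and known limitations of `tetraqtl`.

## Inheritance model

Meiosis is strictly **bivalent** and **polysomic**: per linkage group
the four homologs form two pairs, the pairing configuration is drawn
uniformly from the three possibilities, independently per meiosis and
per linkage group.  Within each bivalent the transmitted chromatid
switches homolog at crossover points generated as a Poisson process
with rate 1 per Morgan (no interference), so the recombination
fraction between positions x cM apart is Haldane's
r = (1 − e^(−2x/100))/2.  **Double reduction is fixed at zero** — the
36-class framework has no state for it, and the simulator never
produces it.  Multivalent or preferential pairing, aneuploidy and
read-level simulation are out of scope.

## The genotype-probability HMM

Hidden state per parent: (pairing configuration, chromatid choice per
bivalent) = 3 × 4 = 12 states; the two parents are independent (144
joint states).  Pairing is static along a linkage group with a uniform
prior, implemented as a block-diagonal transition matrix, which makes
the forward–backward pass an exact mixture over the 3 × 3 pairing
configurations; the posterior then collapses onto the 36
transmitted-pair classes.  The per-step transition factorizes into
2-state chromatid kernels [[1−r, r], [r, 1−r]], so composing steps is
exact (inserting uninformative grid positions between markers does not
change marker posteriors).

* **Emission**: P(obs | class) = 1 − ε if the observed dosage equals
  the class dosage implied by the marker phase, else ε/4; missing
  observations emit 1.  Default ε = 0.05 in the API; the studies in
  this repo use ε matched to the simulator's dosage-error rate (0.02).
* **Grid**: every `grid_step` cM (default 1) anchored at the first
  marker of each linkage group, plus the exact marker positions
  (reported only when `include_markers=True`).  Marker positions are
  never rounded; a grid point within 1e-6 cM of a marker is
  represented by the marker itself.
* **Pairing mode**: mixing over pairings is the default; conditioning
  each individual on its maximum-posterior pairing block is exposed as
  `pairing_mode="condition"`.
* **Degenerate inputs**: an all-zero posterior row (possible only with
  ε = 0 and data inconsistent with every class) falls back to uniform
  rather than raising mid-chain.
* Numerical underflow is handled by per-position row renormalization;
  posteriors are invariant to the scaling.

The forward–backward implementation is verified against exhaustive
enumeration over all (pairing, chromatid-path) combinations on chains
of 4–5 markers (agreement < 1e-10).

## Relationship matrices

share(u, v) = (|u.p1 ∩ v.p1| + |u.p2 ∩ v.p2|)/4, counted within
parent only (homologs of different parents are never IBD in an
outcross F1).  Π is 36×36 with unit diagonal, entries in
{0, ¼, ½, ¾, 1}, constant row sum 18, and is positive semidefinite.
G_q = Z_q Π Z_qᵀ (rows of Z_q must sum to 1 within 1e-6); K_g averages
G_q over all grid positions with equal weight regardless of
linkage-group length.  Marker-based identity-by-state kinship
(VanRaden-type) is deliberately not provided.

## Score test and REML

With e₀ = y − ȳ and the null ML variance σ̂_e² (divisor n), the score
statistic is U = ½ e₀ᵀ G_q e₀ / σ̂_e⁴.  Its null distribution is a
weighted sum of chi-squares with weights eig(C G_q C)/(2σ̂_e²), C the
centering projector.  Because G_q = Z Π Zᵀ has rank ≤ 36, the weights
are obtained from the 36×36 matrix Π^{1/2} Z_cᵀ Z_c Π^{1/2}, making
genome scans and permutation batches cheap.  p-values use
Satterthwaite moment matching (scaled chi-square matching mean and
variance); an exact Imhof characteristic-function inversion
(`imhof_sf`) serves as the independent cross-check — its quadrature
converges slowly for very few weights (integrand ~ u^(−m/2−1)), which
is irrelevant for the 36-eigenvalue spectra of real scans.  p-values
are floored at 1e-300 so LOP stays finite.  The scan is invariant to
affine transformations of the phenotype.

REML profiles the ratio φ = σ_q²/σ_e² through the eigendecomposition
of G_q: a log-spaced grid (10^-4…10^4, 65 points, plus φ = 0) followed
by bounded refinement to 1e-6.  Boundary estimates report σ_q² = 0
with `converged=True`.  When G_q is numerically proportional to the
identity the partition (σ_q², σ_e²) is unidentifiable and the fit is
flagged (`identifiable=False`).  BLUPs are σ_q² G_q V⁻¹(y − μ̂);
allelic effects are probability-weighted BLUP means per homolog (and
per pair), centered on the grand BLUP mean.

## Thresholds, peaks, intervals

Permutations shuffle the phenotype only, preserving the probability
tensor; each permutation's per-linkage-group maximum LOPs are sorted
and the rank-2/rank-3 values collected.  The threshold is the 95%
quantile taken as the **ceiling order statistic**
(`np.quantile(..., method="higher")`): the linear-interpolation
quantile of ~100 permutation peaks is anti-conservative for
exceedance (≈6/101 instead of 5%), while the ceiling convention is
the standard conservative choice for permutation thresholds.  Under
the null the rank-k genome-wide peak then exceeds the rank-k threshold
at ≈ 5% — note that the genome-wide *maximum* exceeds the rank-2
threshold far more often (~30% with 12 independent linkage groups);
the rank-2 threshold calibrates the rank-2 peak.

Peaks: one per linkage group, at the LOP argmax (ties broken toward
the smallest cM); the support interval is the maximal contiguous grid
run containing the peak with LOP ≥ peak − 1 (LOP 1-drop rule).  The
permutation scan refits the null variance per phenotype (it is
invariant under permutation, so per-position work reduces to the
quadratic form).  Only single-QTL scans are provided; multiple-QTL
forward search, fixed-effect interval mapping, epistasis and
multi-environment models are out of scope.

## Marker QC

1. dosage calls with maximum posterior < 0.80 become missing (the
   surviving call is the argmax class);
2. markers with missing fraction strictly above 0.20 are dropped;
3. chi-square goodness of fit of progeny dosage counts against the
   polysomic expectation (convolution of hypergeometric gamete laws
   P(k|d) = C(d,k)C(4−d,2−k)/6), Bonferroni-corrected at α = 0.05
   with denominator M = markers entering the test.

Chi-square classes with zero expectation are excluded from the
statistic (df = non-empty classes − 1); observations falling in such
classes are dosage-call errors, not segregation signal, and are
excluded from the test — except when the support is a single class,
where any disagreement gives p = 0.  Upstream read-level filters
(mapping quality, depth, MAF, biallelicity) belong to variant calling
and are treated as provenance, not recomputed.

## Phenotypes

Firmness (g/mm) replicates are averaged per genotype within year;
retention = firmness before minus after four weeks of cold storage
(positive = softening, consistent with a positive offspring mean);
ΔFDF = mean ripe-berry minus mean green-berry detachment force, with
fallen berries censored at the 0.1 N recording floor before
averaging.  ls-means use an additive genotype + year OLS fit with
sum-to-zero contrasts, so the ls-mean is intercept + genotype effect
and reduces exactly to plain means on balanced designs.  Genomic
heritability fits y = μ + g + e with g ~ (0, K_g σ_g²) by the same
REML machinery.  The original two-year analysis used an unstructured
2×2 year covariance; this package deliberately simplifies to per-year
and single-environment fits — the within-year heritability ratio
σ_g²/(σ_g²+σ_e²) consumes the per-year components directly, and the
unstructured-covariance machinery is out of scope.

## Simulator

Defaults mirror the study conditions: 12 linkage groups of 162.83 cM
with 941 uniformly spaced markers each (~11,292 markers, ~1,954 cM),
237 offspring, dosage-call error 2% (uniform over the four wrong
classes, matching the HMM emission), 5% missingness.  Parental
dosages are drawn i.i.d. from a spectrum weighted toward
simplex/duplex configurations (0.30/0.30/0.20/0.15/0.05 over dosages
0–4), redrawing configurations with no heterozygous parent.  Marker
positions are uniformly spaced because the study's realized
recombination landscape is not available.  Posterior confidence is
heterogeneous across markers (per-marker Beta concentration uniform
in 0.25–2.5 × `posterior_sharpness`, default 8), chosen so the
mask+missingness filter chain retains roughly the same fraction of
markers (~2/3) as the real pipeline did.

**Heritability scale.**  `TraitModel.qtl_h2` targets the model-scale
QTL heritability h_q² = σ_q²/(σ_q² + σ_e²), where σ_q² is the
variance scale of the relationship-matrix model (unit diagonal of Π).
In a single full-sib family the mean off-diagonal IBD share is ½, so
about half of σ_q² is a family-mean component invisible within the
family; the simulator therefore scales the QTL genetic values so
their centered sample variance equals σ_q² times the family's mean
centered IBD share.  This makes the REML estimate of h_q² unbiased
for the planted value; the in-sample phenotypic variance fraction of
the QTL is correspondingly smaller than the nominal h_q².

What the simulator does **not** emulate: linkage-disequilibrium
structure beyond a single family, segregation distortion, genotyping
error correlated with dosage class, read-depth models, multi-year
genotype-by-environment structure.  Passing tests therefore
demonstrate internal statistical consistency of the pipeline under
its own model, not robustness to those real-data features.

## Study problem sizes

The calibration studies (`tetraqtl.studies`, also driven by
`scripts/acceptance.py`) keep the study's population size n = 237 and,
for genome-wide questions, 12 linkage groups, but use scaled maps as
the package's desk-scale choice:

* type-I error: 12 LG × 100 cM × 40 markers, 500 null traits on one
  population, 100 permutations each (exchangeability makes the
  per-trait threshold test valid conditional on the population);
* h_q² recovery and interval coverage: 1 LG × 100 cM × 150 markers
  (~1.5 markers/cM keeps posterior mass on the true class ≈ 0.97),
  200 replicates per target with fresh i.i.d. homolog effects
  (i.i.d. effects make Cov(g) ∝ Π exactly in expectation), detection
  cutoff LOP ≥ 3 in line with genome-wide thresholds;
* two-point recombination: 200 replicates of n = 200 simplex-coupling
  pairs at r = 0.1;
* p-value uniformity: 1,000 permutations at one locus.

## Determinism

Every stochastic stage takes an explicit seed
(`numpy.random.default_rng`); identical seeds reproduce byte-identical
arrays and serialized artifacts.  The CLI refuses pipeline configs
without a seed.  Threads never affect results.
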