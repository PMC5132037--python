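# Methods

This note documents the models and procedures implemented in `ecomorph`,
the numerical choices behind them, what the synthetic-data generators do and
do not emulate, and known limitations.

## Superimposition and shape variables

Generalized Procrustes analysis removes position, scale, and orientation:
each configuration is centered, scaled to unit centroid size
(CS = sqrt(Σ‖xᵢ − x̄‖²)), and rotated onto the running consensus by SVD with
the determinant forced to +1 — reflections never enter the fit, except for
the explicit mirroring inside the object-symmetry decomposition. The
consensus is recomputed until its change falls below `tol` (default 1e-10,
hard iteration cap 100 with an error on non-convergence). Aligned
coordinates are finally projected orthogonally onto the tangent space at
the consensus: x ← x − (⟨x, c⟩ − 1)·c with c the unit consensus vector.
The projection perturbs centroid size only at second order in shape spread;
shape variables are the flattened 2k coordinates. The summed squared
residual about the consensus is non-increasing over iterations (tracked in
`residual_ss_history`).

The full Procrustes distance scales and rotates one unit-size configuration
onto the other, giving d = sqrt(1 − (s₁ + sign·s₂)²) from the singular
values of the cross-product matrix, with the sign enforcing a proper
rotation. Reflection-free fitting makes the distance between a shape and
its mirror image nonzero, which is the behavior wanted for bilateral
structures.

**Object symmetry.** Each configuration is doubled with its reflected,
pair-relabeled copy; GPA runs on the doubled sample; the symmetric shape
component is the mean of each original/mirror pair of aligned copies. The
output is mirror-symmetric up to an arbitrary global rotation of the
consensus frame (the consensus axis need not coincide with the anatomical
midline), so symmetry checks compare via Procrustes distance, not raw
coordinates.

**Semilandmark sliding.** The bending-energy matrix is the upper-left k×k
block of the inverse bordered thin-plate-spline system with kernel
U(r) = r² log r²; it is symmetric positive semidefinite and annihilates
affine transforms of the reference. Per iteration (default 10): GPA, take
the consensus as reference, then for each specimen solve the linear normal
equations for the chord-direction displacements of all semilandmarks
jointly (tangent = unit chord between the scheme's (prev, next) neighbors,
recomputed from the specimen's own current coordinates; endpoints of open
curves list themselves as one neighbor). The solve minimizes a quadratic
exactly, so total bending energy never increases within an iteration;
re-superimposition between iterations can reset the reference. The sliding
reference is the sample consensus, not an external template. Degenerate
systems fall back to the minimum-norm least-squares solution.

**Allometry.** A single pooled OLS of every shape variable on log10
centroid size; residuals (column means zero) feed all downstream analyses,
and the reported percentage is 100·SS_model/SS_total summed over variables.
Log base 10 throughout, matching the relative-gut-length convention. A
pooled single slope is the default; fitting within groups first is possible
by subsetting, but pooled regression is what the pipeline stages expect.

## Ordination and permutation inference

PCA is the eigendecomposition of the sample covariance (ddof = 1) with a
deterministic sign convention (largest-magnitude loading positive). CVA
first projects onto the PCA subspace with eigenvalues above 1e-12 of the
largest — Procrustes shape data have rank 2k − 4 — then solves the
between- vs pooled-within-group eigenproblem; canonical axes are scaled to
unit within-group variance. Group separation is reported per pair as the
Mahalanobis distance (pooled within-covariance of the pair) and the
Euclidean distance between means. Permutation p-values are provided for
both statistics: in high-dimensional, low-n settings the Mahalanobis
permutation test is conservative (the within estimate is near-singular for
every permutation), while the Euclidean statistic retains power; both are
reported rather than choosing for the user. The global test permutes labels
with trace(W⁻¹B) as statistic.

NPMANOVA follows the sums-of-squared-pairwise-distances partitioning:
SS_total = Σ_{i<j} d²ᵢⱼ/N, SS_within analogous per group, pseudo-F =
(SS_between/(g−1))/(SS_within/(N−g)); labels are permuted, and the pairwise
table multiplies raw p-values by the number of comparisons (plain
Bonferroni, the convention of the pairwise tables this mirrors); Holm is
used where an analysis calls for sequential Bonferroni. Distances default
to Euclidean on the size-corrected shape variables. With perfect group
separation SS_within = 0 and the statistic is reported as +∞; permutations
preserving the partition also attain +∞, so the p-value floor is set by the
partition's symmetry, not by the permutation count.

All permutation p-values use the add-one correction
(exceedances + 1)/(n_permutations + 1) and therefore never equal zero;
group labels, never residuals, are permuted; every routine takes a seed or
Generator.

Equal-frequency ellipses place the boundary at the chi-square(2 df)
quantile of the requested probability (area = π·q·sqrt(det S)); under
bivariate normality the ellipse contains that fraction of the population.
SEA = π·sqrt(λ₁λ₂) from the covariance eigenvalues; SEAc multiplies by
(n−1)/(n−2). Ellipse overlap is computed by polygon intersection on
512-point boundary approximations (relative error well under 1%).

## Stable isotopes

δ values are (R_sample/R_standard − 1)·1000 in per mille. Lipid
normalization is the arithmetic two-equation chain: lipid percentage
L = a/(1 + (b·C:N − c)⁻¹), then δ¹³C′ = δ¹³C + D·(I + k₁/(1 + k₂/L)).
Defaults (D = 7.018‰, I = 0.048, a = 93, b = 0.246, c = 0.775, k₁ = 3.90,
k₂ = 287) are the published estimates for this normalization model; they
are configuration, not constants, since tissue-specific re-estimates exist.
The correction is the identity at D = 0, strictly monotone in C:N on the
valid branch (C:N above c/b ≈ 3.15), and preserves within-sample ordering
at constant C:N. L outside [0, 100] is clamped with a warning. Raw δ¹³C is
always retained beside the corrected value. No ethanol-preservation
correction is applied after lipid normalization — the paired
dried-vs-preserved comparison is provided to verify that the C:N-corrected
values show no preservation effect. Baseline correction is deliberately
not implemented; cross-site comparisons are refused unless explicitly
overridden (`cross_site_guard`), because uncorrected sites are not on a
common isotopic scale.

Within-site tests are one-way ANOVAs per site and element (corrected δ¹³C,
raw δ¹⁵N) between the species present; single-species sites are skipped
with a log entry and sites with any species below n = 3 are flagged.
Individual diet distances treat (δ¹³C′, δ¹⁵N) as Cartesian coordinates.

## Diet and trophic traits

Compositions are six-category percentages by volume; totals in [95, 105]
(rounded field estimates) are renormalized to 100, anything else is an
error. Schoener's D = 1 − ½Σ|pᵢ − qᵢ| on proportions, with D > 0.6 flagged
as substantial overlap. Relative gut length is log10(gut)/log10(SL);
adults-only filtering is the caller's responsibility via a filter callback.
The gut-length model comparison fits linear, exponential, logarithmic, and
quadratic mean functions for y = log10(gut) against x = log10(SL) with
Gaussian error on the common log response scale and ranks them by AICc;
"polynomial" is interpreted as the quadratic (lowest-order nonlinearity,
configurable in principle by refitting `numpy.polyfit` at higher degree).
AICc was chosen as the selection statistic because it behaves sensibly at
the n = 20–40 per species this data scale implies; the winner is
reproducible given the table.

## Phylogenetic comparative methods

Trees are rooted with branch lengths in units of molecular change. Pruning
to a taxon subset collapses internal unifurcations additively and keeps the
root stem, so root-to-tip path lengths of kept taxa are exactly preserved.

Ancestral states minimize Σ_edges (Δstate)²/length — squared-change
parsimony weighted by branch length — solved per trait as a sparse linear
system in the internal block of the 1/length-weighted graph Laplacian.
These are point-identical to Brownian-motion GLS estimates, which is the
basis of the dual oracle used in the tests (numerical minimizer and the
conditional-expectation formula). Multivariate traits are handled
per-dimension with a shared tree: the weighted criterion is separable, so
no evolutionary covariance matrix is estimated. Zero-length branches are
replaced by 1e-8 × tree height (logged) to keep weights finite. Solutions
are invariant to uniform branch-length rescaling and obey the maximum
principle (every reconstructed state lies within the tip range per trait).

For a univariate trait, σ² is estimated by REML
(quadratic form of GLS residuals divided by n − 1; ML divides by n) — REML
is the default to reduce small-n bias on the handful-of-taxa trees this
targets. Conditional node variances given the tips are the diagonal of the
inverse internal Laplacian block times σ²; 95% intervals are
states ± 1.96·sqrt(σ²·v). Plotting states against node depth with these
intervals gives the 95% phenogram; tips have zero-width intervals.
Phylomorphospace places internal nodes in a 2-D ordination by the same
solver and returns node coordinates plus the edge list.

## Integration

Two-block PLS takes the SVD of the cross-covariance of the column-centered
blocks; per-axis significance permutes the specimen rows of the second
block with the singular value as statistic, and the per-axis correlation of
paired scores is reported alongside. Mantel tests correlate off-diagonal
vectors, permuting rows and columns of the first matrix simultaneously;
one-tailed positive association is the default (the usual question is
whether matrices co-vary positively), with a two-sided option. The partial
Mantel residualizes both matrices on the control over their off-diagonal
entries and permutes the residualized first matrix; exact collinearity with
the control is an error.

SNP thinning drops loci with any missing genotype, then keeps loci greedily
left-to-right per chromosome at a minimum spacing (default 500 kb) — a
deterministic rule, chosen over random thinning so that the retained set is
reproducible without a seed. Genotype PCA centers dosage columns without
scaling by default (the convention of the standard population-genetics PCA
workflow); unit-variance scaling is available. Pairwise F_ST is the Hudson
estimator combined as a ratio of averages across loci — robust to rare
alleles and sample-size imbalance, invariant to allele-label swapping;
negative combined estimates are floored at zero for distance-matrix use
with the raw value reported beside. Geographic distances can be supplied as
a matrix or computed by the spherical-law-of-cosines helper.

## Synthetic data

The generators encode the study conditions the analyses assume, with one
deterministic stream per generator forked from the global seed (adding a
generator never perturbs another's draws; everything is bit-reproducible
given seed and config).

- **Landmarks**: a fixed 16-point fish-body template (an explicit
  coordinate constant); per specimen, shape = template + group mean offset
  + allometry·(log10 CS − mid-range) + isotropic Gaussian noise, then a
  random similarity transform so superimposition has real work to do.
  Defaults: 3 species × n = 15 at one site, offset magnitude 0.05
  Procrustes units, noise SD 0.01 per coordinate, sizes log-uniform over
  32–158 mm, allometry 0.15 Procrustes units per log10 unit (≈10% of shape
  variance — typical ontogenetic strength).
- **Isotopes**: bivariate normal niches per species; the default scenario
  shifts one species +4‰ in δ¹³C at equal δ¹⁵N (different carbon source,
  same trophic level). C:N is gamma-distributed around 4.5 (clipped to the
  valid branch of the lipid curve), and raw δ¹³C is back-computed by
  inverting the lipid correction so that corrected values hit the
  configured targets.
- **Diet**: Dirichlet draws scaled to percentages; defaults give one
  cellulose-dominated species (≈43% plant material) against algae-dominated
  species (≈70% algae), with one grit-enriched variant.
- **Brownian motion**: recursive normal increments with variance
  σ²·branch length on the default five-taxon tree.
- **Genotypes**: Balding–Nichols structure — ancestral frequencies
  Uniform(0.05, 0.95), population frequencies Beta-distributed with
  variance F·p·(1−p), genotypes binomial(2, p); under this
  parameterization the expected pairwise Hudson F_ST between two
  populations at drift F is F itself. Inter-SNP spacings are drawn from
  100–900 kb so the 500 kb thinning filter is exercised.

What the generators do **not** emulate: digitization error structure
(noise is isotropic and homoscedastic), measurement covariance between
landmarks, isotopic baseline variation between sites, diet-composition
zero-inflation, linkage disequilibrium beyond physical spacing, and any
phylogenetic signal in the group mean shapes (offsets are drawn once,
independently of the tree). Passing tests therefore demonstrate
correctness and calibration of the estimators under their stated
assumptions, not robustness to these real-data features.

## Numerical choices and degenerate inputs

- Permutation tests: add-one-corrected p-values, label permutation, seeded.
- GPA: convergence on consensus change < 1e-10; error on non-convergence.
- CVA rank threshold: 1e-12 of the leading eigenvalue.
- TPS system: singular for duplicate landmarks (error); energies are
  symmetrized and reported as exact quadratic forms.
- Degenerate errors rather than silent results: constant centroid size,
  zero-variance ANOVA/correlation inputs, singular covariances, collinear
  Mantel controls, monomorphic-only genotype matrices, ≤2-tip rate
  estimation.
- Problem sizes in the test suite (hundreds of null simulations, tens to
  hundreds of specimens, 6–8-taxon trees, hundreds of loci) were chosen to
  match the scale of the sampled systems this package targets while keeping
  the calibration suites statistically meaningful (binomial intervals on
  500 null replicates).

## Limitations

2-D landmarks only; no Procrustes ANOVA of fluctuating asymmetry; no
Bayesian ellipse estimation or isotope mixing models; no OU or multi-rate
evolutionary models; no tree inference (trees are inputs); no full VCF
support (dosage CSV and a minimal GT-only dialect); no phylogenetic PCA.
The Mantel tail convention and the CVA permutation statistic are exposed as
options because field conventions differ.
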