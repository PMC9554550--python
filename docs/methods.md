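# Methods

## Scope and data model

The pipeline begins at per-accession, per-locus reference/alternate read
counts of bi-allelic SNPs; alignment and variant calling are upstream and
out of scope. An *accession* is one pool of `N` diploid individuals
(default 10) sequenced together; all statistics treat the pool as a sample
of `n = 2N` chromosomes. Tetraploid accessions are deliberately treated as
diploid pools (`n = 2N`, not `4N`): read counts cannot resolve allele
dosage within a tetraploid genotype, so the pooled frequency is the only
usable observable; the true ploidy is kept in the metadata for reporting.

Missing data policy: a cell is missing exactly when its filtered coverage
is zero, and every pairwise statistic uses the loci complete for that pair
(pairwise-complete). The dataset-wide minor allele frequency used by the
locus filter is the minor side of the *unweighted* mean of per-accession
frequencies over non-missing accessions, so deeply sequenced pools do not
dominate the screen.

## Estimators

**H_S.** Mean over loci of `2p(1−p)`. The plain (uncorrected) version is
the default; the finite-pool correction `n/(n−1)` is exposed as an option
because it is unclear whether standard packages apply it to pooled data.

**Nei's standard distance.** `D = −ln(J_XY / √(J_X J_Y))` with allele
vectors `x = (1−p, p)` and per-pair means over shared loci. `J_XY = 0`
(pools fixed for opposite alleles at all shared loci) returns an `inf`
sentinel which group summaries exclude from means; by Cauchy–Schwarz
`D ≥ 0` always, and a floating-point guard clamps at 0.

**Pool F_ST.** Reads are a two-stage sample: the pool is `n` chromosomes
drawn from the population, and each read re-samples the pool with
replacement. The raw read identity `Σ_a c_a(c_a−1)/(C(C−1))` therefore
over-counts identity; `Q̂₁ = (n·raw − 1)/(n − 1)` is unbiased for the
identity of two distinct chromosomes of the source population (cells with
coverage < 2 are unusable). With the between-pool identity
`Q̂₂ = Σ_a f_{ia} f_{ja}`, per-locus `F̂_ST = (Q̄₁ − Q̂₂)/(1 − Q̂₂)` and the
multilocus estimate is the ratio of sums over informative loci
(`1 − Q̂₂ ≠ 0`). At infinite depth this estimator coincides with the
Weir–Cockerham ANOVA estimator on the pool allele counts (a test asserts
agreement to 1e-3), and under the generator's sampling model it is
unbiased — the tests verify recovery of a planted F = 0.10 to ±0.02 and a
panmictic null within ±0.02 of 0. Negative estimates are reported, never
truncated: they are the expected signature of no structure.

**Tajima's D.** The package sees a fixed locus panel, not sliding windows,
so D is computed per accession over the assayed loci: allele counts are
recovered as `k = round(p·n)` clamped to `[0, n]`; `π̂` sums
`2(k/n)(1−k/n)·n/(n−1)`; `θ̂_W = S/a₁`; the variance uses the standard 1989
constants for `n` (checked against exact rational arithmetic to 1e-10).
This is an approximation of the read-level windowed computation and is
meaningful for comparing accessions genotyped on the same panel, not as an
absolute neutrality test. Fewer than 3 segregating loci yields no value.

**Mantel.** Great-circle (haversine) distance on a sphere of radius
6371 km; `r` is the Pearson correlation of lower triangles; the p-value is
`(#{r_perm ≥ r_obs} + 1)/(n_perm + 1)` under simultaneous row/column
permutation. Null p-values are uniform (KS-checked over 500 simulated
nulls).

**PCoA.** Classical scaling (`B = −½ J D² J`); only positive eigenvalues
(relative tolerance 1e-10) become axes, and explained fractions are shares
of the positive-eigenvalue sum — negative eigenvalues from non-Euclidean
distances are dropped from the denominator.

**Outlier scan.** Columns are centered and scaled by the binomial SD
`√(p̄(1−p̄))` (centering-only is an option); per-SNP z-vectors are the
t-like statistics of the regression on the K leading left singular
vectors; Mahalanobis D² uses a minimum-covariance-determinant estimate
(K ≥ 2) or median-centered squared z (K = 1); the genomic inflation factor
`median(D²)/median(χ²_K)` rescales D² before the χ²_K tail test and
Benjamini–Hochberg adjustment. K is a required analysis choice, not
inferred.

**Cluster search and DAPC.** k-means (20 seeded restarts) on PCA scores,
scored by `BIC(k) = n·ln(WSS_k/n) + k·ln(n)`; the discriminant step is
linear discriminant analysis on the retained PC scores (generalised
eigenproblem of between- over within-group covariance), with membership
probabilities from the equal-covariance Gaussian classifier — the
membership model behind the usual structure-like bar plots is not uniquely
defined, and this is the documented choice. Cross-validation holds out
10 % of each group (the "90 % test set" phrasing in the field is read as
90 % training), repeats 30 times by default, and ties go to fewer PCs.
Note the BIC variant is *not* invariant to duplicating the dataset when
the k → k+1 contrast is marginal (the fit term doubles, the penalty grows
only by `k·ln 2`); tests therefore assert the argmin only where the
contrast is decisive.

**Neighbor joining.** Standard Saitou–Nei Q-matrix joins. A negative
branch length at a join is set to zero and its deficit moved to the
sibling branch (Kuhner–Felsenstein), preserving path lengths through the
join. On additive matrices the reconstruction is exact (50 random 8-leaf
trees, paths to 1e-9; cross-checked against an independent NJ
implementation).

**Snow AUC.** Trapezoidal area under the 10 monthly means
(September–June) at unit month spacing: constant thickness `h` gives `9h`;
the unit is whatever thickness unit the input uses, times months. The
variable screen uses `|sd/mean|`, or `sd/range` for signed variables where
a CV is meaningless.

**GEA.** Restricted to wild-population accessions (the only ones
plausibly adapted to their collection sites). Pre-selection takes, for
each unordered pair of populations, the `⌈0.01·L⌉` loci with the largest
per-locus F_ST (ties broken by locus id) and unions them across pairs —
on panels of a few hundred loci this union is large (60–75 % of loci), as
it is in real targeted panels. Each environmental variable gets a LASSO
(`(1/2n)RSS + λ‖β‖₁`) with λ chosen by leave-one-out MAE over 50
log-spaced values spanning 4 decades below `λ_max = max_j |x_jᵀy|/n`; ties
resolve to the sparser model. Standardization happens inside each
training fold; the final coefficients are a full-data refit at λ*,
reported on the original scale. The effect decision is strict:
`RMSE_L < SD` **and** `RMSE_L < RMSE_LM`, where RMSE_LM is the LOOCV RMSE
of ordinary least squares on the remaining bioclimatic variables
(including latitude). Models with `RMSE_L > 0.95·SD` carry an additional
"about equal to SD" soft flag (threshold configurable) — nominally passing
models in that band have no practically useful precision.

## The synthetic generator

The generator defines the study conditions: 80 pools (half wild, half
cultivated), 661 loci, pools of 10 diploids, Poisson coverage with mean
500. Structure is hierarchical Balding–Nichols: a global ancestral
frequency `p̄ ~ U(0.05, 0.95)` per locus; each stratum (wild/cultivated)
draws its ancestral pool at `F_stratum = 0.03`; populations drift within
their stratum at `F = 0.04` (wild) or `0.01` (cultivated). The closed-form
expectations — `(F_i^tot + F_j^tot)/2` across strata with
`F^tot = F_s + (1−F_s)F_pop`, `(F_i^pop + F_j^pop)/2` within — are recorded
in the truth table and verified against Weir–Cockerham on the true
frequencies. This reproduces the qualitative anatomy of a Nordic
germplasm panel: a tight cultivated gene pool, divergent wild populations,
and a first principal coordinate that separates the two (point-biserial
|r| ≥ 0.7; ~33 % of the variation on default settings).

A fraction of loci (default 10/661) carry environmental clines in the
wild stratum: on top of the drifted frequency `p`, the population's value
becomes `logit⁻¹(logit(p) + s·z)` with `s = 1` logit unit per SD of the
(temperature-like) variable. Applying the cline on top of drift (rather
than replacing it) makes a flat cline exactly neutral, which the null
tests require. Environmental variables follow weak latitudinal gradients
dominated by site noise, with SD scales echoing a Scandinavian panel
(temperature ≈ 2.2 °C, precipitation ≈ 220 mm, isothermality ≈ 2.3 %,
seasonality ≈ 6 CV %); consequently a climate-only linear model has LOOCV
RMSE ≈ SD, which is the observed behaviour of such panels and the regime
in which the SNP models' added value is measurable. Snow thickness follows
a triangular September–June profile whose peak grows with latitude plus
site noise.

Reads are generated in two stages on purpose — pool of `2N` chromosomes
binomial from the population frequency, reads binomial on the realized
pool at Poisson coverage — because that is exactly the sampling the F_ST
estimator corrects for; an optional Dirichlet weighting models uneven
individual contribution to the pooled DNA (off by default). The
individual-genotyping mode draws each plant's dosage and sequences the
*same* realized pool, enabling the pool-validity experiment (per-accession
Pearson r > 0.95 at depth 500, approaching 1 as depth grows).

What the generator does **not** emulate: linkage (loci are exchangeable
and unlinked), a coalescent site-frequency spectrum (ancestral
frequencies are uniform, mimicking an ascertained targeted panel — one
visible consequence is that simulated Tajima's D sits above 0 rather than
slightly below as in panels with rare-allele content), sequencing error
beyond the count filter, and geography-correlated *genetic* structure
(drift is exchangeable across sites, so isolation by distance is absent
unless planted). Passing tests therefore certify the estimators and
decision rules under the stated sampling model, not the demographic
realism of any particular panel.

## Numerical choices and degenerate inputs

- Low-count zeroing is per allele and cell, strictly `< min_count`, and
  idempotent; a cell whose two counts are both zeroed becomes missing.
- Balding–Nichols draws clip parent frequencies to `[1e-9, 1−1e-9]` so
  boundary drift cannot produce invalid Beta parameters.
- Monomorphic columns are excluded (with a warning) from the outlier scan;
  constant responses and < 3 sites are errors in the LASSO; collinear
  baseline predictors fall back to the minimum-norm least-squares solution
  with a warning.
- All randomness flows through explicit integer seeds; same seed, same
  bytes.

## Known limitations

- Reporting the LOOCV error at the LOOCV-selected penalty is optimistic
  (winner's curse). At ~40 sites with hundreds of candidate SNPs, a pure
  noise response passes the `RMSE < SD` check in roughly a third of
  replicates — an independent check with R's `cv.glmnet` on the same
  design shows the identical rate, so this is a property of the published
  procedure, not of this implementation. Effect decisions on small site
  panels should be read with that base rate in mind; the soft "≈ SD" flag
  and the linear baseline mitigate but do not remove it.
- Tajima's D from rounded pool frequencies inherits rounding granularity
  `1/n` and panel ascertainment; compare accessions within a panel only.
- The NJ tree carries no bootstrap support; the scan's χ² calibration
  relies on the genomic-inflation rescaling being adequate, which holds
  for exchangeable nulls but is approximate under strong structure.
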