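# Methods

This note documents the statistical models, estimators, numerical choices
and known limitations of `landgen`, in the order the pipeline runs them.

## Genotype data model

Diploid codominant SSR calls are an `(n, L, 2)` integer array: an unordered
pair of positive allele codes per individual × locus, code 0 reserved for
missing. A genotype is missing only when both slots are missing;
half-missing genotypes are rejected at parse time — the simplest contract
that keeps gene-copy counting (2 copies per scored genotype) unambiguous.
Allele codes are fragment sizes or arbitrary labels; no binning is done
(binning belongs to the upstream fragment-calling software). Coordinates
are WGS84 decimal degrees; rasters are north-up with half-open
[west, east) × (south, north] cells, and all grids snap to the global
lattice aligned to integer degrees so results are independent of data
layout.

## Diversity and inbreeding estimators

Per locus, within one sample set: allelic richness `A_l` = number of
distinct alleles; Shannon `I_l = -Σ p ln p`; expected heterozygosity
`He_l = 1 - Σ p²` (the biased/plug-in estimator by default, for
comparability with the R packages most SSR tables are built with; the
`2n/(2n-1)` small-sample correction sits behind `unbiased=True`);
`Ho_l` = fraction of scored genotypes that are heterozygous. Multilocus
values are unweighted means over loci and `sd` columns are the standard
deviation over loci. The inbreeding coefficient is the ratio of multilocus
means, `Fis = 1 - mean(Ho)/mean(He)`, not a mean of per-locus ratios —
this keeps the identity `Fis = 1 - Ho/He` exact at the reported precision
and is well defined when individual loci are monomorphic. Loci with fewer
than 2 scored individuals in a group are dropped from that group's means
(logged).

The `Fis` permutation test shuffles allele copies among individuals within
the population, per locus: this destroys heterozygote deficit/excess while
preserving allele frequencies exactly. p-values are two-sided with the
`(1 + hits)/(n_perm + 1)` continuity rule, so `n_perm = 0` returns 1.

## Pairwise F_ST

Per locus, for a pair of populations: `H_S` = mean of the two
within-population `He`, `H_T` = `He` of the mean frequency vector. Loci
are combined as a ratio of sums (more stable than averaging per-locus
ratios when some loci are nearly monomorphic). By default the
between-population component is rescaled by `r/(r-1) = 2` for the pair of
demes (Nei's `D_m`), giving `F_ST = D_m / (H_S + D_m)`: without this
rescaling the pooled `H_T` of only two demes contains half a
within-population term, and the coefficient estimates `F/(2-F)` rather
than `F` under the Balding–Nichols model — the package's recovery tests
document this directly. `deme_correction=False` restores the raw pooled
coefficient. Raw (possibly slightly negative) values are retained;
`FstMatrix.display()` truncates negatives for reporting.

## AMOVA

Two-level analysis of molecular variance on squared inter-individual
distances, where the distance at one locus is the number of allele
differences between the two genotype multisets (0, 1 or 2), summed over
loci both individuals scored and rescaled by `L / L_shared` for pairwise
missingness. Sums of squares follow the standard
`SS = Σ_pairs d² / group size` decomposition; the among-population
component uses the unequal-size coefficient
`n̄ = (N - Σ n_p²/N)/(P-1)`; `Φ_ST = σ²_a/(σ²_a + σ²_b)`; percentages are
components over their total and sum to 100 by construction. Significance
is assessed by permuting individuals among populations (999 by default,
seeded, one-sided on Φ).

## Diversity rasters

Each tree with coordinates is replicated into every 30 arc-second cell
whose **center** lies within a circle of 10 arc-minutes diameter around
the tree. Membership is tested in geographic degree space, consistent with
the arc-minute/arc-second parameterization; at low tropical latitudes the
longitudinal distortion is ≲ 2% and no geodesic correction is applied.
Because cells then hold unequal tree counts, per-cell statistics are
computed as the mean over 1,000 subsamples of the minimum size (3 trees),
drawn **without** replacement (rarefaction): with-replacement sampling
would inflate homozygosity and would not reproduce the exact
corrected-equals-uncorrected identity at n = 3 cells, which the test suite
asserts. A `replace=True` flag exists for comparison. Per-cell `Fis` is
computed from the subsample's own Ho/He. Subsample draws use a canonical
content-based ordering of trees, making raster values exactly invariant to
the input order of individuals; cells with identical memberships share one
computation.

Locally common alleles are classified **once from the full dataset**: an
allele qualifies iff it occurs in strictly fewer than 25% of the sampled
populations (the 12 sampling sites are the occupancy unit) and exceeds 5%
frequency in at least one population where it occurs. The per-cell LCA
statistic is the count of classified alleles present in the cell's trees,
divided by the number of loci, and is bootstrap-corrected like any other
statistic.

## Admixture model and Δ*K*

The likelihood is the classic admixture model: allele copy `c` of
individual `i` at locus `l` comes from cluster `k` with probability
`Q_ik`, then is allele `a` with probability `P_kla`;
`L = Σ log Σ_k Q_ik P_kla`. Instead of MCMC posterior sampling the
likelihood is maximized by EM: per-copy responsibilities
`r ∝ Q_ik P_kla`, then `Q` rows are responsibility means and `P` rows
responsibility-weighted tallies with a Laplace pseudo-count `α = 0.01`
(a symmetric Dirichlet prior that prevents zero-frequency lock-in;
configurable). EM monotonically increases the penalized objective
`L + α Σ log P`, which the tests assert at every iteration; both the raw
and penalized paths are recorded. Missing genotypes contribute nothing.
Ten seeded restarts per K by default; the best-likelihood fit is the
representative, and replicate Q matrices are aligned by the Hungarian
assignment maximizing column inner products before averaging.

Evanno's method consumes the per-replicate log-likelihood table exactly as
it would consume per-run `Ln P(D)` values from external software (a
results-file reader is provided): `L'(K) = L̄(K) - L̄(K-1)`,
`L''(K) = L'(K+1) - L'(K)`, `ΔK = |L''(K)|/sd(L(K))`, defined for interior
K with positive replicate spread; ties in the argmax break toward the
smallest K (parsimony). ΔK cannot evaluate the endpoints, so a run over
K = 1..8 adjudicates 2..7.

## Suitability framework

Background: at most 10,000 points, one per cell, sampled uniformly from
the convex hull of the presences buffered by 10% of the hull's largest
axis (maximum pairwise presence distance), excluding presence cells.
Collinear predictors are pruned by iteratively dropping the largest VIF
(`1/(1-R²)` from regressing each layer on the others) until all < 5;
perfect collinearity counts as infinite VIF and among tied layers the
later one in stack order is dropped. Edaphic depth profiles collapse to a
0–100 cm mean with thickness weights (0.05, 0.1, 0.15, 0.3, 0.4).

Two reference learners ship — a percentile envelope (suitability =
fraction of predictors inside the presences' [p5, p95] band) and an
L2-regularized logistic regression on standardized features — and any
object with `fit`/`predict` can be registered; the evaluation and
ensembling machinery is learner-agnostic.

Spatial sorting bias is handled with the calibrated AUC: the geographic
null model scores a location by a rank-normalized decreasing transform of
its distance to the nearest training presence (no environmental input).
Per cross-validation fold (4 random folds, seeded), each test presence is
greedily matched — in increasing order of its own distance-to-training,
without replacement — to the background point with the most similar
distance-to-training, and `cAUC = AUC_model - (AUC_null - 0.5)` on that
matched set, capped into [0, 1] (uncapped values are kept). Evaluating the
null against itself gives exactly 0.5 on every fold, an algebraic identity
the tests assert. Models are retained when a one-sided Mann–Whitney test
over 20 cAUC iterations beats the null at α = 0.05; fully tied samples
return p = 1. The ensemble search enumerates all subsets of retained
models containing the anchor (2^(m−1); guarded above m = 16), weights
members by their mean cAUC (raw, normalized — recentering by −0.5 is
available behind the weight floor), scores every subset on shared
precomputed fold scores, and returns the argmax. Binary maps use the
maximum training sensitivity+specificity threshold (ties toward the lower
score); multi-scenario consensus is optimistic (suitable in ≥ 1 scenario)
or pessimistic (≥ ⌈N/2⌉).

## Synthetic generators

Genotypes: per locus an ancestral frequency vector `p ~ Dirichlet(1)`
over 13–28 alleles (uniform per locus), cluster frequencies
`~ Dirichlet(p (1-F)/F)` — the Balding–Nichols construction, validated by
moment checks (mean ≈ p, variance ≈ F p (1-p)). Populations map to
clusters round-robin (or one cluster per population for
differentiation-recovery designs); ancestry is pure by site or
`Dirichlet(α)`-admixed. Inbreeding enters at the genotype draw: the second
allele copies the first with conditional probability `p + Fis(1-p)`
(clipped), realizing `P(hom a) = p² + Fis·p(1-p)` for both signs of Fis
where feasible. The default survey mirrors the replicated design: 12
sites of 3–14 trees (100 total), 12 loci, sites scattered over ~8°×8°
with ≥ 0.5° separation so 10′ neighborhoods of distinct sites never
merge, within-site scatter 0.01° (~1 km). Inbreeding is injected at the
draw, not by mating simulation — sufficient for estimator testing, but
not a forward-time model (no drift trajectories, linkage, or mutation).

Landscapes: unit-variance Gaussian fields smoothed to an 8-cell
autocorrelation length; true suitability is logistic with default
coefficients (5, −4, 0, …) and intercept −4 — a strongly
environment-determined, low-prevalence habitat, emulating a dry-forest
specialist whose distribution models achieve high discrimination; 151
presence cells are drawn proportional to suitability. Passing tests on
these landscapes show the machinery recovers known logistic structure and
ranks models correctly; they do not show robustness to real-world issues
the generator omits: sampling bias unrelated to geography, predictor
measurement error, non-logistic responses, or temporal non-equilibrium.

## Problem sizes and determinism

Simulation-based tests use deliberately modest designs chosen as the
smallest that make the statistical assertions stable: differentiation
recovery uses 6 populations × 20 individuals × 12 loci over 50 replicates;
ΔK recovery uses 3 clusters × 30 individuals × 10 loci, K = 1..5 with 4
restarts, 25 replicates; the ensemble search demonstration uses 11 base
models (1,024 combinations) on a 100×100-cell landscape. Every stochastic
component takes an explicit seed; generators are bit-reproducible given
the seed, pipeline reruns reproduce CSV outputs byte-identically, and the
acceptance script derives all of its randomness from `--seed`.

## Known limitations

- Degree-space (not geodesic) distances throughout; fine near the equator,
  increasingly distorted poleward.
- The EM maximizer finds local optima; restarts mitigate but do not
  guarantee the global maximum, and ΔK consumes whatever likelihoods the
  runs produce.
- Nei-style F_ST and the allele-difference AMOVA ignore allele size
  relationships (no R_ST / stepwise-mutation weighting).
- GeoTIFF I/O is not implemented; rasters are ESRI ASCII grids.
- Only two base learners are bundled; the other algorithms commonly used
  in ensemble platforms must be supplied through the registry.
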