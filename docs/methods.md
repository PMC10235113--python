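# Methods

`divkit` implements an integrative community-assembly analysis for
site × species abundance data: functional diversity over trait
categories, abundance-weighted phylogenetic diversity, phylogenetic
signal of the traits, null-model standardized effect sizes, and Bayesian
mixed models of each diversity index against species richness. This note
records the models, the numerical choices, and what the synthetic-data
experiments do and do not demonstrate.

## Data model and reconciliation

Four artifacts are reconciled onto one species/site set: a community
matrix of specimen counts (used as an abundance surrogate; per-site
relative abundances `w_i` are row-normalized counts), a species × trait
table with a schema assigning each trait a type (quantitative or
categorical) and functional-category memberships (body size, skull, jaw,
foraging, and their union "overall"), a rooted phylogeny with branch
lengths, and per-site covariates (sampling days, altitude). Names are
matched exactly after whitespace→underscore normalization. Individual
measurements, when supplied, are averaged to species level globally
(arithmetic mean over all individuals pooled across sites; categorical
traits must be constant within species). Community species missing from
the tree are substituted onto an unused congeneric tip — among several
free congeners, the one with the smallest mean cophenetic distance to
the tips already mapped for that genus, ties broken alphabetically —
which is deterministic and keeps the substitute as close as possible to
its congeners' neighborhood.

## Functional trait space

Within each category, pairwise species dissimilarity is Gower's
coefficient: quantitative traits contribute |x_i − x_j| / range (range
over the full analyzed pool, not per site), categorical traits a 0/1
mismatch; traits are averaged with pairwise-complete weighting so
missing values drop out per pair. Zero-range traits are excluded with a
warning. The dissimilarity matrix is embedded by classical PCoA; the
default correction replaces d with √d before embedding (Gower
dissimilarities are then Euclidean-embeddable), with Cailliez and no
correction selectable. Axes with eigenvalue above 1e−10 × the largest
are retained, capped at S − 1. The space is built **once on the full
pool** per category and per-site computations subset its rows; this
keeps index values comparable across sites, which re-embedding per site
would destroy.

## Diversity indices

With `x_i` the species coordinates, `w_i` the relative abundances of the
species present at a site (renormalized over present species):

- **FDis** = Σ w_i‖x_i − c‖ with c = Σ w_i x_i (abundance-weighted
  dispersion around the weighted centroid).
- **FDiv**: with V the convex-hull vertices of the present species, g
  the unweighted vertex centroid, dG_i = ‖x_i − g‖, Δd = Σ w_i(dG_i −
  mean dG) and Δ|d| its absolute counterpart,
  FDiv = (Δd + mean dG)/(Δ|d| + mean dG) ∈ [0, 1].
- **FEve**: minimum spanning tree over the present species' Euclidean
  distances; branch (i,j) has EW = dist/(w_i + w_j), normalized to PEW;
  FEve rescales Σ min(PEW, 1/(S−1)) to [0, 1].
- **U** (uniqueness) = Rao Q / Simpson D with Q = ΣΣ w_i w_j d_ij from
  the Gower matrix directly and D = 1 − Σ w_i²; 1 − U is redundancy.
- **MPD** = Σ_{i≠j} w_i w_j d_ij / Σ_{i≠j} w_i w_j and
  **MNTD** = Σ_i w_i min_{j≠i} d_ij on cophenetic distances. The MNTD
  abundance weight applies to the focal species only — the standard
  abundance-weighted form.

FDiv and FEve require S ≥ 3 and are reported as missing below that;
missing values propagate into downstream models rather than being
imputed. For the hull/MST constructions the per-site space is truncated
to the leading min(S − 1, 6) axes: hulls need more points than
dimensions, and Qhull becomes numerically unreliable in high dimension,
so a fixed leading-axis cap (6) is applied on top of the S − 1 rule.
FDis and U use the full information (all retained axes / the full
dissimilarity matrix). A degenerate (flat) point cloud falls back to the
hull in the largest non-degenerate subspace via SVD projection.

## Phylogenetic signal

Pagel's λ is fitted per quantitative trait by maximum likelihood: y ~
MVN(μ1, σ²C(λ)) where C_ij is the shared root-to-MRCA path length
(stem edges above the tips' MRCA are ignored) and λ multiplies the
off-diagonal of C. λ is profiled on [0, λ_max] by bounded scalar search
(tolerance 1e−6) with closed-form GLS estimates of μ and σ² at each λ;
λ_max is the largest value keeping C(λ) positive definite, found by
bisection on Cholesky feasibility (tolerance 1e−8), so estimates
slightly above 1 are attainable on real trees. Significance is a
likelihood-ratio test against λ = 0 with p from χ²(1). Because the null
places λ on the boundary of its range, this test is conservative — its
empirical size is nearer 2% than the nominal 5% (it matches
`phytools::phylosig` estimate-for-estimate). Star phylogenies make λ
unidentifiable and are flagged as such.

## Null models and SES

The randomization is the independent swap: 2×2 submatrices with a
checkerboard occupancy pattern are located by uniform sampling and the
two occupied cells are exchanged between their sites, within their
species columns. This conserves exactly: per-site richness, per-species
occurrence frequency, and each species' multiset of abundance values.
Each null replicate is a fresh chain from the observed matrix of
2 × (occupied cells) successful swaps (a candidate that is not a
checkerboard does not count), which keeps the replicates nearly
independent instead of serially correlated along one chain. Trait space
and phylogeny are held fixed; only the community matrix is randomized.
SES = (obs − null mean)/null SD with the sample (n−1) SD; SES < −2 is
read as clustering, > 2 as overdispersion, otherwise random. Null draws
on which a metric is undefined are excluded from the moments and
counted. The swap kernel is JIT-compiled (numba) so the default 1000
iterations per analysis are cheap.

## Richness-association models

Indices bounded in (0,1) (FDiv, FEve, U) get a beta GLMM with logit
link; unbounded indices (FDis, MPD, MNTD) a normal model with identity
link:

    y_s ~ Beta(μ_s φ, (1−μ_s) φ),  logit(μ_s) = β0 + β1 S_s + a·log(days_s) + b·zalt_s
    y_s ~ Normal(η_s, σ²),          η_s as above

Sampling effort and altitude are nuisance terms: the slopes a and b have
zero-mean Gaussian priors whose standard deviations σ_u, σ_v carry
half-normal(0, 5) hyperpriors, i.e. shrunken nuisance slopes — the
model estimates them but pulls them to zero unless the data insist.
(Alternative readings of a "random effect" of a continuous site-level
covariate exist, e.g. random intercepts over binned altitude; the
shrunken-slope form is the one implemented.) Altitude is z-scored for
numerical stability. Beta responses receive the Smithson–Verkuilen
boundary compression y′ = (y(n−1) + 0.5)/n, but only when a 0 or 1 is
actually present: compressing unconditionally attenuates the richness
slope by ~1/n, which is enough to bias its credible interval at n = 20
sites, whereas compressing on demand leaves interior-valued data
untouched. Priors: Normal(0, 10²) on
β0, β1; half-normal(0, 5) on all SDs; Gamma(0.1, 0.1) on φ. The scale
parameters σ_u, σ_v are bounded below at 1e−3 — below that the term is
numerically indistinguishable from zero, and an unbounded half-normal
lets MCMC chains wander arbitrarily deep into the funnel neck.

Posteriors are sampled by a composition of Metropolis kernels, run as
vectorized parallel chains: (i) a joint random-walk proposal whose
covariance and scale adapt during burn-in (Haario-style, acceptance
target 0.3); (ii) scalar updates of log σ_u, log σ_v from their full
conditionals given the slopes, which are likelihood-free and
log-concave; (iii) an extra slope move whose proposal width follows the
current prior scale min(σ, 1), keeping the funnel neck traversable.
Adaptation stops at the end of burn-in. Defaults are desk-scaled — 3
chains × 20,000 iterations, burn-in 5,000, thinning 10 (1,500 retained
draws per chain) — chosen so a full 22-model analysis completes in
minutes; heavier configurations (millions of iterations with aggressive
thinning, as used with JAGS-class samplers) are reachable through the
config. Convergence is monitored with the rank-normalized split-chain
R-hat (bulk and folded; flagged, not fatal, above 1.1).

Goodness of fit is a posterior-predictive check with the chi-squared
discrepancy T(y, θ) = Σ_s (y_s − E[y_s|θ])²/Var[y_s|θ]: per retained
draw a replicate y_rep is simulated and bayes_p = Pr(T(y_rep) > T(y))
(ties split), with fit ratio mean T(y_rep)/mean T(y). Adequate fit shows
0.025 ≤ p ≤ 0.975 and ratio ≈ 1. Like all plug-in posterior-predictive
checks this is conservative; in particular, for the normal family a
lone outlier is absorbed into the fitted variance and does not move p.
The sampling-effort bias screen is a Spearman rank correlation
(mid-rank ties, two-sided p) between per-site richness and sampling
days.

## Synthetic studies

The generator emulates the structure of a museum-collection bat survey
along an Andean elevation gradient; its defaults are the study
conditions used throughout the tests: 20 sites, a 97-species pool
dominated by clade structure (genera of ~5 adjacent tips on a simulated
Yule tree; tips coeval, with one extra exponential holding time so
terminal branches are positive), per-site richness uniform on 5–43,
lognormal(0, 1.5) abundances rounded up to ≥1 individual (singletons
common, a few species dominant), 14 quantitative traits simulated as
λ-Brownian motion with λ drawn per trait from [0.7, 1.0] and per-trait
variances set to ~8% coefficient of variation around plausible
morphometric baselines, one 8-level categorical feeding strategy with
clade-biased level probabilities (species adopt their genus' preferred
level with probability 0.8), sampling effort uniform on 3–30 days and
altitude uniform on 0–3670 m. Species are sampled into sites with
lognormal regional weights, independently of traits and phylogeny, and
sites are exchangeable (no spatial autocorrelation).

What this does and does not show: the generator provides ground truth
for estimator recovery (λ, GLMM slopes), exact conservation laws, and
null calibration — but its assembly process is neutral by construction,
so passing tests demonstrate correctness of the machinery, not that the
pipeline would detect any particular assembly mechanism in real data.
Real surveys add detection bias, spatial structure, trait measurement
error and phylogenetic uncertainty, none of which are modelled.

## Problem sizes used in validation

The validation suite uses: 200 random small instances (S ≤ 8, ≤ 3 axes)
for index-oracle equivalence; 100 random 20×60 matrices × 10,000 swap
attempts for the conservation laws; 200 self-null draws × 100-iteration
null ensembles (all 20 sites scored) for SES calibration; 50 replicates
per λ ∈ {0, 0.5, 1} on a 100-tip Yule tree; and 50 replicates per GLMM
family at 20 sites with the desk-scaled MCMC. The acceptance script
runs the full pipeline at the default study conditions with the
1000-iteration null model.

## Known limitations

- FRic and standalone Rao's Q are not reported; no fuzzy-coded traits or
  unequal trait weights within a category.
- The congener substitution rule needs binomial "Genus_species" labels.
- The χ²(1) LRT for λ is boundary-conservative (see above); a mixture
  reference would be closer to nominal but is not what is implemented.
- The beta/normal GLMMs assume independent sites; no spatial or
  phylogenetic residual structure.
- The swap null model requires at least one checkerboard; saturated
  matrices are returned unchanged with a warning.
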