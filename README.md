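# divkit

Integrative diversity analysis for ecological assemblages: how do the
functional and phylogenetic structure of local communities relate to
their species richness, and do they differ from chance?

Given a site × species abundance matrix, a species × trait table, a
rooted phylogeny and per-site covariates, `divkit`:

1. builds a **multidimensional functional space** per trait category
   (Gower dissimilarity over mixed quantitative/categorical traits,
   then PCoA with √d correction);
2. computes four per-site **functional diversity indices** — dispersion
   (FDis), divergence (FDiv), evenness (FEve) and uniqueness
   (U = Rao Q / Simpson D) — and two abundance-weighted **phylogenetic
   diversity indices**, MPD = Σ_{i≠j} w_i w_j d_ij / Σ_{i≠j} w_i w_j and
   MNTD = Σ_i w_i min_{j≠i} d_ij on cophenetic distances;
3. estimates **Pagel's λ** per quantitative trait by maximum likelihood
   (y ~ MVN(μ1, σ²C(λ)), λ profiled on [0, λ_max] with closed-form GLS,
   likelihood-ratio test against λ = 0);
4. contrasts every index against **independent-swap null models**
   (checkerboard swaps preserving site richness, species occurrence
   frequency and species abundance multisets; 1000 fresh chains by
   default) and classifies the standardized effect size
   SES = (obs − null mean)/null SD with the ±2 rule;
5. fits **Bayesian mixed models** of each index against species richness
   — beta GLMMs with logit link for (0,1)-bounded indices, normal models
   otherwise, with shrunken log-effort and altitude nuisance slopes —
   with rank-normalized split R-hat convergence checks and a χ²
   posterior-predictive goodness-of-fit test.

A first-class synthetic-data generator emulates the structure of a
tropical bat survey (20 sites, ~97-species pool, skewed abundances,
clade-structured traits with strong phylogenetic signal), so the whole
pipeline is testable with known ground truth. It was built with
museum-collection bat data in mind but is agnostic to taxon.

The two inferential stages follow a statsmodels-style design: a model
object (`PagelLambda`, `DiversityRichnessModel`) is constructed from
data and `.fit()` returns a results object carrying estimates,
uncertainties, diagnostics and a `summary()` table.

## Worked example

```python
from divkit import SimConfig, simulate_dataset, fit_lambda, DiversityRichnessModel
from divkit.functional import fd_table

study = simulate_dataset(SimConfig(seed=42, n_sites=12, pool_size=40,
                                   richness_range=(5, 20)))
ds = study.reconciled()

fd = fd_table(ds)
print(fd[fd.category == "overall"].head(4).round(3))

lam = fit_lambda(ds.tree, ds.traits.values["mass"], name="mass")
print(f"Pagel's lambda for body mass: {lam.lambda_:.3f} (p = {lam.pvalue:.2g})")

df = fd[fd.category == "overall"].merge(ds.covariates.table,
                                        left_on="site", right_index=True)
res = DiversityRichnessModel.from_dataframe(df, "FDiv", family="beta").fit(seed=0)
print(res.summary().round(3))
```

prints

```
  site category  FDis  FDiv  FEve  Uniq  S
site01  overall 0.333 0.809 0.709 0.320  5
site02  overall 0.352 0.840 0.635 0.341 10
site03  overall 0.388 0.818 0.746 0.333 18
site04  overall 0.386 0.843 0.684 0.348 15

Pagel's lambda for body mass: 0.724 (p = 0.048)

 parameter   mean     sd   q2.5  q97.5  rhat
     beta0  1.241  0.945 -0.638  3.132 1.002
     beta1 -0.026  0.035 -0.097  0.043 1.001
  a_effort  0.216  0.333 -0.396  0.922 1.004
b_altitude  0.090  0.146 -0.186  0.400 1.002
   sigma_u  1.944  2.130  0.043  7.781 1.000
   sigma_v  1.482  1.942  0.021  7.042 1.003
       phi 28.431 13.179  9.397 59.769 1.003
```

Reading this: each site gets its four functional indices and richness S;
body mass carries clear phylogenetic signal (λ̂ = 0.72, close to the
λ ∈ [0.7, 1] range the generator draws from); and the richness slope β1
for overall functional divergence has a 95% credible interval spanning
zero — as it should, since the generator assembles communities with no
trait–richness coupling. All R-hat values sit at 1.00, so the three
chains agree.

The same analysis runs from the shell against a YAML config naming the
four input files (or a `simulate:` block):

```sh
divkit simulate config.yaml --out data/   # write the four input files
divkit run config.yaml --out results/     # validate -> spaces -> FD/PD
                                          #   -> lambda -> SES -> GLMMs
```

Stage subcommands (`validate`, `space`, `fd`, `pd`, `signal`, `ses`,
`glmm`) run any step on its own; everything is seed-deterministic.

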