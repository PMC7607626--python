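# mosqsurv

Occupancy and abundance modelling for stratified mosquito trap surveys.

Adult mosquito surveys — trap arrays run monthly across land-cover strata
— underpin vector surveillance: they tell you which species are present,
where, and how their numbers move with season. Raw catch data answer
neither question directly, because species are detected imperfectly and
counts are hugely overdispersed. `mosqsurv` provides the two model stages
such surveys need, in a statsmodels-style model/results API, for
ecologists and public-health entomologists analysing trap-count tables:

1. **Community diversity under imperfect detection** — a hierarchical
   Bayesian multi-species occupancy model (MSOM) with data augmentation:

   ```
   w_i ~ Bernoulli(Ω)                    community inclusion
   Z_ji ~ Bernoulli(ψ_i w_i)             occupancy,  logit(ψ_i) = u_i
   X_jki ~ Bernoulli(p_i Z_ji)           detection,  logit(p_i) = v_i
   u_i ~ N(µ_u, τ_u⁻¹),  v_i ~ N(µ_v, τ_v⁻¹)
   ```

   fitted by a bespoke Metropolis-within-Gibbs sampler (exact discrete
   conditionals with a collapsed inclusion update; adaptive random-walk
   Metropolis for the logits; conjugate hyperparameter updates). It yields
   regional richness `R = n + Σ w_aug`, alpha/beta/zeta diversity and
   per-species occupied-site counts, as posterior medians with 90%
   credible intervals, plus rank-normalized split R-hat diagnostics.

2. **Species-specific relative abundance** — negative-binomial (NB2,
   `Var = µ(1 + µ/φ)`) mixed-effects regressions of counts on seasonal
   precipitation and local land cover:

   ```
   log µ_ijs = β₀ + α₀(s) + (β₁ + α₁(s))·Precip_j + β₂·m_trait_s
             + β₃·Mangrove_i + β_4(s)·Agri_i + β_5(s)·Urban_i
             + β_6(s)·Rainforest_i + β₇·m_trait_s·Mangrove_i + α₂(i)
   ```

   with correlated species random intercepts/slopes and site random
   intercepts, fitted by Laplace-approximated maximum likelihood (inner
   Newton for the random-effect modes, analytic-in-β outer gradient).
   Twelve candidate fixed-effect structures (H1–H12) are VIF-screened,
   fitted, and ranked by ΔAIC; the best model is diagnosed with
   simulation-based quantile residuals (KS uniformity test), Nakagawa
   marginal/conditional R², BLUPs and per-stratum predicted time series.

A synthetic-survey generator reproduces the study design (30 sites, six
replicates in each of five land covers, monthly 48-h deployments over 17
months with two storm-lost months, wet/dry-season rainfall, dominant and
rare species, genus-only damage records), always returning the latent
truth so every estimator is testable by parameter recovery. See
`docs/methods.md` for the full model and design notes.

## Worked example

```python
import mosqsurv as ms

# a synthetic survey at the default (study-design) scenario
sc = ms.CountScenario(seed=11)
sites = ms.generate_sites(sc)
precip = ms.generate_precip(sc)
traits = ms.generate_traits(sc)
table, truth = ms.generate_count_data(sc, sites, precip, traits)

# -- diversity: occupancy model on detection histories -------------------
detections = ms.counts_to_detections(ms.filter_genus_only(table), n_aug=0)
cfg = ms.MsomConfig(n_chains=2, n_iter=4000, n_burn=2000, n_adapt=500, seed=1)
msom = ms.MultiSpeciesOccupancy(detections, n_aug=40, config=cfg).fit()
print(msom.summary().to_string(index=False))

# -- abundance: candidate count models on the four dominant species ------
focal = ms.top_species(table, 4)
sub = ms.CountTable(table.frame[table.frame.species.isin(focal)].reset_index(drop=True))
precip_std, _ = ms.standardize_covariates(precip, sites)
specs = {s.name: s for s in ms.build_candidate_set(sorted(focal), traits)}
fits = [
    ms.NegBinomMixedModel.from_tables(specs[n], sub, sites, precip_std, traits).fit(restarts=1)
    for n in ("H2", "H9", "H12")
]
print(ms.aic_table(fits).to_string(index=False))
best = min(fits, key=lambda f: f.aic)
diag = best.simulate_residuals(n_sim=200)
print(f"best {best.spec.name}: KS D = {diag.ks_D:.3f}, P = {diag.ks_p:.3f}")
```

prints (numbers from this exact seed):

```
parameter    median        q5       q95     rhat
    omega  0.273342  0.156060  0.454502 1.066726
     mu_u -0.908050 -3.384406  1.370950 1.120606
  sigma_u  4.022238  1.884029  8.423111 1.254464
     mu_v -0.971025 -1.251210 -0.738929 1.012925
  sigma_v  0.426461  0.274557  0.673231 1.011069
        R 13.000000 10.000000 21.000000 1.125743
    alpha  4.566667  4.500000  4.666667 1.020917
     beta  2.846715  2.173913  4.500000 1.109732
     zeta  1.000000  1.000000  2.000000 1.060942
name  K       loglik         aic  converged  delta_aic
 H12 22 -1246.951038 2537.902075       True   0.000000
  H9 20 -1256.731882 2553.463763       True  15.561688
  H2 11 -1318.088180 2658.176359       True 120.274284
best H12: KS D = 0.017, P = 0.647
```

The diversity block reads as: the survey observed 10 species and the model
puts regional richness `R` at a median of 13 (90% CrI 10-21); `alpha`,
`beta` and `zeta` summarize per-site richness (~4.6 species), turnover and
ubiquitous species (~1). The `rhat` column flags the occupancy
hyperparameters as not yet mixed at these deliberately short example
chains (2 x 4000) — the defaults (3 x 20,000) drive them below 1.1. In the
selection table the full-structure candidate (H12 — the generating model
here) wins with ΔAIC 0, and its simulation-based residuals are consistent
with uniformity (KS P = 0.647), i.e. no evidence of misfit.

The same pipeline runs from the shell:

```bash
mosqsurv --seed 11 --out run simulate
mosqsurv --seed 11 --out run fit-msom
mosqsurv --seed 11 --out run fit-counts
mosqsurv --seed 11 --out run report     # assembles run/report.md
```

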