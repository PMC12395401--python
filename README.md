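# sitarbayes

Bayesian SITAR growth modelling for longitudinal stature: pubertal
landmark estimation, maturity-group classification, model checking, and a
calibrated synthetic-cohort generator with full ground truth.

## Who this is for

Auxologists, sports scientists and biostatisticians working with repeated
stature measurements of children and adolescents who want, per subject
and per population: the age at takeoff growth velocity (ATGV), takeoff
velocity (TGV), age at peak height velocity (APHV) and peak height
velocity (PHV), each with 68% credible intervals, plus early/average/late
maturity classification and the usual model checks.

## The model

SITAR (Super Imposition by Translation And Rotation) is a shape-invariant
nonlinear mixed model: every child follows one population curve, shifted
and stretched individually. Stature of subject *i* at age *x<sub>ij</sub>* is

$$y_{ij} = (\alpha_0+\alpha_i) + \sum_{k=1}^{K}\beta_k\,
h_k\!\big((x_{ij}-\bar x-(\zeta_0+\zeta_i))\,e^{-(\gamma_0+\gamma_i)}\big)
+ \varepsilon_{ij},\qquad \varepsilon_{ij}\sim N(0,\sigma^2)$$

with natural cubic spline functions *h<sub>k</sub>* and zero-mean trivariate
normal individual effects for size (α, cm), timing (ζ, years) and
intensity (γ, log age-scale; velocity scales by e<sup>−γ</sup>). Priors are
weakly regularising and scaled to the data. Estimation is either a fast
joint posterior mode (`fit_map`) or Hamiltonian Monte Carlo
(`sample_posterior`, default 2 chains x 6000 iterations, 3000 warmup,
with split R-hat / bulk ESS diagnostics). Landmarks are extracted per
posterior draw by root-finding on the analytic acceleration; details in
`docs/methods.md`.

## Worked example

```python
from sitarbayes import (simulate, apply_inclusion_filter, fit_map,
                        population_landmarks, individual_landmarks,
                        classify, timing_tempo_correlations)

# a 100-girl synthetic cohort whose true population landmarks are the
# published Brazilian reference values (APHV 11.30 yr, PHV 8.38 cm/yr, ...)
cohort, truth = simulate.generate_default_cohort("F", n_subjects=100, seed=11)
kept, excluded = apply_inclusion_filter(cohort)   # >=4 pubertal measurements etc.
fit = fit_map(kept)                               # seconds; sample_posterior for full MCMC
pop = population_landmarks(fit)
print(f"APHV {pop.aphv[0]:.2f} yr  PHV {pop.phv[0]:.2f} cm/yr  "
      f"ATGV {pop.atgv[0]:.2f} yr  TGV {pop.tgv[0]:.2f} cm/yr")

ind = individual_landmarks(fit)
groups = classify(ind.estimates)                  # 16th/84th APHV percentiles
print(groups.table["label"].value_counts().to_dict())
r = timing_tempo_correlations(ind, groups)
print(r.query("stratum=='all' and pair=='aphv_vs_phv'")["r"].iloc[0])
```

prints

```
APHV 11.15 yr  PHV 8.34 cm/yr  ATGV 8.50 yr  TGV 5.76 cm/yr
{'average': 63, 'late': 15, 'early': 15}
-0.3916450600419905
```

The fitted population landmarks recover the generator's calibrated truth
(11.30 / 8.38 / 8.41 / 5.85) to within fractions of their credible
spread; the 15/63/15 split is the 16th/84th percentile rule on 93
included subjects; and the negative APHV-PHV correlation reproduces the
expected direction — earlier maturers spurt faster.

Short narrative scripts for each capability live in `examples/`; a thin
CLI (`sitarbayes simulate|fit|landmarks|classify|ppc|sensitivity|report`)
chains the same stages through artifacts on disk.

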