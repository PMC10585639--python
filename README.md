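# octnorms

Statistical toolkit for cross-population comparisons of macular OCT
thickness. It targets the common study design in which two groups of
subjects (here an indigenous Ghanaian cohort and a European-ancestry
cohort) contribute up to two eyes each, thickness is reported on the
9-sector ETDRS grid (central fovea, parafoveal and perifoveal rings
split into superior/nasal/inferior/temporal quadrants, μm) plus a
central choroidal measurement, and the scientific questions are:

1. **Association** — how much thinner (or thicker) is each sector in
   one group after adjusting for age and sex, given that fellow eyes
   are strongly correlated?
2. **Robustness** — how large would a measurement error induced by
   unmeasured confounders have to be before that association loses
   significance?
3. **Context** — how do the group means compare with published reports
   once those are pooled by random-effects meta-analysis and
   stratified by age?
4. **Design** — was the sample size adequate (a priori), and how
   detectable is each fitted effect (post hoc)?

## Models

**Association.** Each response k (9 sectors + choroid) is modelled
independently with a subject-level random intercept,

```
T_ijk = β0 + β_eth·1[Ghanaian] + β_age·(age−60)/10 + β_sex·1[male] + b_ik + ε_ijk,
b_ik ~ N(0, σ_b²),  ε_ijk ~ N(0, σ_e²),
```

fitted by REML through a one-dimensional profile over θ = σ_b²/σ_e²
(closed-form GLS at fixed θ using the rank-one block inverse). Wald
95% intervals; Bonferroni over the 9-sector family. The implied
fellow-eye correlation is ρ = σ_b²/(σ_b²+σ_e²).

**Sensitivity.** For error magnitude e ∈ [0, 1], each simulation sets
y′ = y·(1+u), u ~ Uniform(−e, e), on the targeted eyes, refits, and
records whether the ethnicity p-value (P_sim) stays below α = 0.05.
The error threshold at criterion c is the largest e with the
isotonic-smoothed significant fraction ≥ c on the whole grid up to e.

**Meta-analysis.** DerSimonian–Laird: w_i = n_i/sd_i², Q = Σw_i(y_i−ȳ)²,
τ² = max(0, (Q−df)/(Σw−Σw²/Σw)), I² = max(0, (Q−df)/Q)·100, pooled
mean re-weighted by 1/(v_i+τ²). Studies stratify into half-open decade
bins of mean age.

**Power.** Overall-F power from the noncentral F(p, n−p−1; λ) with
f² = R²/(1−R²), λ = f²·n; post-hoc power by parametric bootstrap of
the fitted mixed model on the observed design.

Because cohorts like this are rarely deposited, the package ships a
calibrated synthetic-cohort generator (`octnorms.simulate`) whose
defaults encode the study conditions — group sizes 42/37, group age
laws, sex ratios, eye missingness, published effect magnitudes — so
every stage is testable end to end without any external data.

## Worked example

```python
from octnorms import default_config, generate, fit_sector

cohort, truth = generate(default_config(seed=1))   # 79 subjects, 153 eyes
fit = fit_sector(cohort, "c0")                     # central fovea
print(fit.coef.loc["ethnicity"].round(2))
```

```
estimate        -48.90
se                3.92
ci_lo           -56.58
ci_hi           -41.21
p_raw             0.00
p_bonferroni      0.00
```

The fovea of the simulated Ghanaian group is 48.9 μm thinner than the
European group's after adjusting for age and sex (the generative truth
is −45.3 μm, inside the 95% interval), with the fellow-eye dependence
absorbed by the subject intercept (`fit.icc` ≈ 0.71 here). The
narrative scripts under `examples/` walk through each capability —
simulation, association fits with descriptive statistics, the
sensitivity curve and its thresholds, age-stratified pooling, and both
power calculations — each printing the numbers it computes and a line
on how to read them. A thin CLI mirrors the stages
(`octnorms simulate|fit|sensitivity|meta|power|run`).

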