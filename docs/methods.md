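# Methods

This note records the statistical model, the generator's calibration,
the numerical choices and the known limits of what the test suite
demonstrates.

## The bilateral mixed model

The unit of analysis is the eye; the unit of independence is the
subject. For response k (each of the nine ETDRS sectors and the
central choroid, μm) on eye j of subject i:

    T_ijk = β0k + β_eth,k·1[Ghanaian] + β_age,k·(age_i − 60)/10
            + β_sex,k·1[male] + b_ik + ε_ijk,
    b_ik ~ N(0, σ_b,k²),   ε_ijk ~ N(0, σ_e,k²).

Reference levels are European ancestry and female sex; age enters in
decades centred at 60 years so the intercept is the expected thickness
of a 60-year-old European female and slopes read as μm per decade.
Responses are modelled independently — no cross-sector correlation —
because the scientific outputs are per-sector estimates; subjects
contributing a single eye stay in the model (random-intercept
likelihoods handle unbalanced clusters).

Estimation is REML, profiled to one dimension. With θ = σ_b²/σ_e² the
marginal covariance is σ_e²(I + θZZᵀ), block diagonal over subjects
with blocks of size 1 or 2, whose inverse per cluster is
I − θ/(1+n_iθ)·J. At fixed θ, β̂ and σ̂_e² are closed-form GLS
expressions assembled from per-cluster sums; the restricted likelihood
(n−p)·log σ̂_e² + Σᵢ log(1+n_iθ) + log|XᵀWX| is minimised over log θ on
[log 1e−8, log 1e4] by bounded scalar search (absolute tolerance
1e−10), with the σ_b² = 0 boundary admitted whenever the bound value
matches the interior optimum. Tests verify equality with a dense
block-covariance GLS oracle at the fitted θ (1e−6) and with an
independent general-purpose mixed-model implementation.

Inference is Wald with normal quantiles (CI half-width 1.96·SE). No
Satterthwaite or Kenward–Roger degrees-of-freedom correction is
applied; at the default design (79 subjects, ~150 eyes) the measured
interval coverage of the ethnicity effect is 95–96%, so the simpler
rule is adequate, but intervals may undercover noticeably below ~20
subjects. Bonferroni uses family m = 9 (the sector family per
covariate); the choroid is a single pre-specified test with m = 1.

Descriptives around the model: fellow-eye Pearson correlation with
Fisher-z intervals (≥ 4 pairs required), Bland–Altman bias with
bias ± 1.96·SD limits, the sex-by-group 2×2 chi-square with Yates
continuity correction, and the Wilcoxon rank-sum test for age using
midranks and the continuity-corrected normal approximation. The
rank-sum statistic follows the Mann–Whitney U convention (first sample:
Europeans), matching the convention of the common R implementation.

## The synthetic-cohort generator

The generator draws exactly the model above, so parameter-recovery
tests are well-posed: per subject an age (see below), a sex
(group-specific female probability), one b_ik per response, then per
eye a retention draw and residuals. Fellow eyes share b_ik; eyes drop
independently with a per-group missingness probability (Ghanaian
6/84 ≈ 0.071, European 0). A single seeded generator with a fixed draw
order (Ghanaians then Europeans, OD before OS, residuals drawn even
for dropped eyes) makes any prefix of the cohort invariant to later
records and the whole cohort reproducible from the seed.

Ages follow a normal law truncated to the group's observed range, with
location and scale solved numerically so the truncated distribution's
median and IQR equal the targets (Ghanaian 60/8.5 on [45, 82];
European 58/20 on [41, 85]). Plain moment matching would bias the
median by ~1–2 years for the heavily truncated European law.

Defaults encode the study conditions. Published magnitudes: group
sizes 42/37; ethnicity differences −45.3 μm (fovea), −30.07…−32.17
(parafovea), −14.93…−19.23 (perifovea), −60.28 (choroid); age slopes
−6.8/−5.2/−4.9 μm/decade (parafovea S/N/I), −4.4 (perifovea S), −6.7
(choroid); male−female choroid −14.87 μm. Calibration defaults, not
estimates: baseline thicknesses μ_k (normative-range values, e.g.
260 μm European fovea); retinal sex effects (+10 μm male in
fovea/parafovea, −5 μm male in perifovea — directions as reported,
magnitudes invented); −3 μm/decade for sectors without a published
slope; and all variance components, σ_b = 18 / σ_e = 9 μm (retina) and
40/20 μm (choroid), chosen to put the fellow-eye correlation at
ρ = 0.8, inside the observed 0.60–0.95 range, with interval widths of
the published order. Parafoveal and perifoveal differences without
printed values interpolate between the printed extremes.

What the generator does **not** emulate: cross-sector correlation
within an eye (real maps are spatially smooth), non-Gaussian tails and
device-specific segmentation artefacts, axial-length confounding, any
ethnicity×age interaction, and recruitment structure (site effects,
exclusion cascades). Passing tests therefore demonstrate correctness
of the estimators under the stated model and calibration — not that
real cohorts satisfy that model.

## Measurement-error sensitivity

The procedure quantifies robustness to unmeasured confounders as an
equivalent measurement error: at each magnitude e on a grid (default
0, 0.05, …, 1.0), simulations multiply each targeted eye's response by
(1+u), u ~ Uniform(−e, e) i.i.d. per eye, refit, and record whether
the raw ethnicity p-value stays below α = 0.05. Uniform-symmetric is
the weakest law consistent with "a fraction of the original
measurement"; normal and one-sided (pure attenuation) laws are
config-switchable, as is the target group (Ghanaian eyes by default,
`all` or European available) and per-eye independence. Because only
the response vector changes between simulations, refits reuse a
precomputed design workspace; a test pins this fast path to the
literal perturb-then-refit loop p-value for p-value.

The significant fraction is smoothed by decreasing isotonic regression
(weighted by simulation counts) before thresholding, since the true
curve is non-increasing but Monte Carlo estimates need not be; the
threshold at criterion c is the largest grid e with smoothed fraction
≥ c at every grid point up to e, or none if it fails at e = 0.
Convergence checks use the binomial MCSE of the running proportion
over equal-size batches, with the required simulation count
extrapolated as p̂(1−p̂)/tol².

Calibration, measured at 12,000 simulations/level: with a null
ethnicity effect and **every** eye perturbed, the rejection rate is
0.047–0.050 across the whole grid — the procedure is exact under an
exchangeable null. Perturbing **one** group only is mildly
conservative at extreme magnitudes (rate ≈ 0.040–0.047 for e ≥ 0.8),
because strongly asymmetric error variance is absorbed into a single
pooled residual variance; thresholds from the default (one-group)
configuration therefore err on the safe side. Note also that the
significance curve of a single observed cohort is conditional on that
cohort: at e = 0 the fraction is exactly 0 or 1, and "fraction ≈ α
under the null" is a statement marginal over null data, not per
dataset. Default budget is 21 levels × 2,000 simulations; the grid,
budget and seed are config fields, so much larger runs (the procedure
is linear in the budget) are a config change, not a code change.

## Meta-analysis

Eligibility mirrors a systematic review of ETDRS thickness reports:
at least one sector mean with dispersion convertible to a variance
(SD with n, SE, or a normal 95% CI via divisor 3.92 — the conversion
is recorded per summary), a named device, a stated mean/median age,
and healthy-only participants; exclusions carry the first failed rule.
When a study reports both eyes, one is chosen uniformly with a seeded
generator. Pooling is DerSimonian–Laird on raw means in μm (the
comparisons of interest are in μm, not standardized units), with
Cochran's Q, I² = max(0,(Q−df)/Q)·100 and the τ²-re-weighted CI.
DL is fully specified and closed-form; it is the historical default of
the major meta-analysis packages, one of which cross-checks the
implementation in the tests. Age stratification uses half-open decade
bins [lo, lo+10) on mean age, reproducing verbal groupings like
"between 20 and 30" exactly.

The bundled study table is **synthetic**: it copies only the
age-group structure of published reports (mean ages 21, 28.9, 36.2,
47.7, 49, plus one African cohort) with invented placeholder means so
the pipeline runs without external data; real extractions are supplied
by the user as `StudyRecord`s or CSV.

## Power

A priori: overall-F power with f² = R²/(1−R²) and λ = f²·n (Cohen's
convention; λ = f²·(n−p−1) selectable — both clear 85% at n = 79,
R² = 0.20, where the default gives 96.6%). n counts subjects, not
eyes, as the calculation predates the eye-level model. Post hoc:
parametric bootstrap at the observed design — same subjects,
covariates and missing-eye pattern, responses re-drawn from the fitted
β̂, σ̂_b², σ̂_e² — refitting each replicate and reporting the Wald
rejection rate of the target coefficient with its binomial MCSE; a
closed-form single-coefficient Wald power serves as the cross-check in
the independent-errors (σ_b = 0) limit.

## Pipeline and reproducibility

`run_pipeline` executes simulate → fit → sensitivity → meta → power
with per-stage seeds derived as SHA-256(global_seed:stage) mod 2³¹, so
stages rerun independently yet reproducibly; the manifest records the
package version, stage seeds and SHA-256 digests of every output, and
reruns are byte-identical. CSV outputs use fixed column orders and
fixed decimal formatting; cohort files round-trip bit-exactly
(2-decimal thicknesses, empty field for a missing choroid, LF
endings). Left-eye grids are assumed already anatomically labelled
(nasal/temporal), as device software reports; a `screen_coordinates`
flag mirrors OS maps on read for exports in screen orientation.

## Problem sizes used by the checks

The shipped checks run at deliberately modest scale: 500 replicate
cohorts for interval coverage, 50 cohorts of 500 subjects for bias,
2,000 simulations per error level for calibration, 2,000 subjects for
fellow-eye correlation, and 200 simulations/level for the example
sensitivity thresholds. These sizes give Monte Carlo standard errors
comfortably inside the tolerances asserted; all are parameters, and
larger runs only tighten them.

## Known limitations

- Wald-z inference (no small-sample df correction); see coverage note.
- Sensitivity thresholds computed on synthetic cohorts depend on the
  calibrated variance components and are not estimates of any real
  cohort's thresholds.
- The generator's independence across sectors means multi-sector joint
  statements (e.g. "significant in all 9 sectors simultaneously") are
  optimistic relative to spatially correlated real data.
- τ² estimators are DL (default) and Paule–Mandel; no full
  restricted-likelihood τ², though PM typically tracks it closely.
- No funnel-plot/publication-bias machinery and no mechanistic
  modelling of specific confounders (axial length) — the sensitivity
  analysis treats confounding as equivalent measurement error.
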