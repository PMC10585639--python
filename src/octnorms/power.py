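"""A priori analytic power and post-hoc simulation power.

The a priori calculation covers the overall F-test of a multiple
regression with p covariates explaining a fraction R² of the variance:
effect size f² = R²/(1−R²), noncentrality λ = f²·n (Cohen's
convention; λ = f²·(n−p−1) available), and

    power = P( F′ > F_crit ),   F′ ~ F(p, n−p−1; λ),
    F_crit = (1−α) quantile of the central F(p, n−p−1).

Post-hoc power for a fitted mixed model is estimated by parametric
bootstrap at the observed design: cohorts are re-simulated from the
fitted fixed effects and variance components on the same subjects,
covariates and missing-eye pattern, refitted, and the rejection rate
of the target coefficient's Wald test is the power estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import Cohort
from .lmm import COEFFICIENTS, SectorFit, design_matrix, workspace_for

__all__ = [
    "PowerSpec",
    "PowerResult",
    "analytic_power",
    "posthoc_power",
    "coefficient_power",
]


@dataclass
class PowerSpec:
    """Design of an overall-F power calculation."""

    n: int
    r_squared: float
    p_covariates: int = 3
    alpha: float = 0.05
    ncp_convention: str = "n"  # "n" (λ = f²·n) or "error_df" (λ = f²·(n−p−1))

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared < 1.0:
            raise ValueError("r_squared must lie in [0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n <= self.p_covariates + 1:
            raise ValueError("need n > p_covariates + 1")
        if self.ncp_convention not in ("n", "error_df"):
            raise ValueError(f"unknown ncp_convention {self.ncp_convention!r}")

    @property
    def f_squared(self) -> float:
        return self.r_squared / (1.0 - self.r_squared)

    @property
    def noncentrality(self) -> float:
        scale = self.n if self.ncp_convention == "n" else self.n - self.p_covariates - 1
        return self.f_squared * scale


@dataclass
class PowerResult:
    power: float
    method: str  # "analytic" or "simulation"
    n_sims: int | None = None
    mcse: float | None = None
    n_failed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.power <= 1.0:
            raise ValueError("power must lie in [0, 1]")


def analytic_power(spec: PowerSpec) -> PowerResult:
    """Noncentral-F power of the overall regression F-test."""
    df1 = spec.p_covariates
    df2 = spec.n - spec.p_covariates - 1
    f_crit = stats.f.ppf(1.0 - spec.alpha, df1, df2)
    lam = spec.noncentrality
    if lam == 0.0:
        power = spec.alpha  # central case: rejection rate is the level
    else:
        power = float(stats.ncf.sf(f_crit, df1, df2, lam))
    return PowerResult(power=power, method="analytic")


def coefficient_power(effect: float, se: float, alpha: float = 0.05) -> float:
    """Analytic Wald power for a single coefficient z-test.

    P(|Z| > z_{1−α/2}) with Z ~ N(effect/se, 1); the large-sample
    counterpart of the simulated rejection rate, used to cross-check
    the parametric bootstrap in the independent-errors limit.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    shift = effect / se
    return float(stats.norm.sf(z_crit - shift) + stats.norm.cdf(-z_crit - shift))


def posthoc_power(
    fit: SectorFit,
    cohort: Cohort,
    target_coefficient: str = "ethnicity",
    n_sims: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PowerResult:
    """Parametric-bootstrap power of one coefficient at the observed design.

    Simulates ``n_sims`` response vectors from the fitted model — the
    subject intercept drawn once per subject with SD σ̂_b, residuals per
    eye with SD σ̂_e, fixed effects at their estimates — on the cohort's
    own design rows for the fitted response, refits each, and reports
    the proportion of raw Wald p-values below α, with its binomial
    Monte Carlo SE. Failed refits are excluded and counted.
    """
    if target_coefficient not in COEFFICIENTS:
        raise KeyError(f"unknown coefficient {target_coefficient!r}")
    if not fit.converged:
        raise ValueError("post-hoc power requires a converged fit")
    target_index = COEFFICIENTS.index(target_coefficient)
    ws, _, frame = workspace_for(cohort, fit.sector)
    X = design_matrix(frame)
    mean = X @ fit.coef["estimate"].to_numpy(float)
    codes = ws.codes
    k = ws.k
    sigma_b = np.sqrt(fit.sigma_b2)
    sigma_e = np.sqrt(fit.sigma_e2)
    rng = np.random.default_rng(seed)

    hits = 0
    failed = 0
    for _ in range(n_sims):
        b = rng.normal(0.0, sigma_b, size=k)
        eps = rng.normal(0.0, sigma_e, size=len(mean))
        y = mean + b[codes] + eps
        try:
            raw = ws.fit(y)
        except np.linalg.LinAlgError:
            failed += 1
            continue
        z = raw["beta"][target_index] / raw["se"][target_index]
        p = 2.0 * stats.norm.sf(abs(z))
        hits += p < alpha
    n_ok = n_sims - failed
    if n_ok == 0:
        raise RuntimeError("all bootstrap refits failed")
    power = hits / n_ok
    mcse = float(np.sqrt(power * (1.0 - power) / n_ok))
    return PowerResult(
        power=float(power), method="simulation", n_sims=n_ok, mcse=mcse, n_failed=failed
    )
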