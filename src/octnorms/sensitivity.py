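"""Monte Carlo sensitivity of the ethnicity association to measurement error.

The question answered: how large would a measurement error induced by
unmeasured confounders have to be before the ethnicity association
(adjusted for age and sex) stops being reliably significant? For each
error magnitude e on a grid in [0, 1], many simulations each perturb
the targeted eyes' response multiplicatively — y′ = y·(1 + u) with
u ~ Uniform(−e, e) drawn independently per eye — refit the
random-intercept model, and record whether the raw ethnicity p-value
(P_sim) stays below α. The association is deemed robust to error level
e if the proportion of significant simulations exceeds a criterion
(0.95 and 0.99 by default); the largest such e is the error threshold.

Proportions are smoothed by decreasing isotonic regression before
thresholding, since the true significance curve is non-increasing in e
but the raw Monte Carlo estimates need not be. Per-level batch traces
support convergence checks on the binomial Monte Carlo standard error.

By default only Ghanaian eyes are perturbed; the error law and target
group are configurable (uniform/normal/one-sided; either group or all).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.isotonic import IsotonicRegression

from .io import Cohort
from .lmm import COEFFICIENTS, workspace_for

__all__ = [
    "SensitivityConfig",
    "SensitivityResult",
    "perturb",
    "run_sensitivity",
    "check_convergence",
]

_ETH_INDEX = COEFFICIENTS.index("ethnicity")


def _default_grid() -> np.ndarray:
    return np.round(np.arange(0.0, 1.0001, 0.05), 10)


@dataclass
class SensitivityConfig:
    """Grid, budget and decision rules for a sensitivity run."""

    error_grid: np.ndarray = field(default_factory=_default_grid)
    n_sims_per_level: int = 2000
    alpha: float = 0.05
    criteria: tuple[float, ...] = (0.95, 0.99)
    target_group: str = "Ghanaian"  # "Ghanaian", "European" or "all"
    response: str = "c0"
    error_law: str = "uniform"  # "uniform", "normal" or "one_sided"
    seed: int = 0
    batch_size: int = 100
    mcse_tol: float = 0.005
    n_max: int = 200_000

    def __post_init__(self) -> None:
        grid = np.asarray(self.error_grid, dtype=float)
        if grid.ndim != 1 or len(grid) == 0:
            raise ValueError("error_grid must be a non-empty 1-D array")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("error_grid must be strictly increasing")
        if grid[0] < 0 or grid[-1] > 1:
            raise ValueError("error magnitudes must lie in [0, 1]")
        self.error_grid = grid
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if any(not 0 < c < 1 for c in self.criteria):
            raise ValueError("criteria must lie in (0, 1)")
        if self.target_group not in ("Ghanaian", "European", "all"):
            raise ValueError(f"unknown target_group {self.target_group!r}")
        if self.error_law not in ("uniform", "normal", "one_sided"):
            raise ValueError(f"unknown error_law {self.error_law!r}")
        if self.n_sims_per_level < 1:
            raise ValueError("n_sims_per_level must be >= 1")


@dataclass
class SensitivityResult:
    """Per-level significance proportions and estimated error thresholds.

    ``levels``: one row per grid magnitude with the simulation count,
    failures, raw and isotonic-smoothed significance proportion and its
    binomial Monte Carlo SE. ``thresholds``: criterion → largest grid e
    at which the smoothed proportion stays at or above the criterion for
    every grid point up to and including e (None if it fails at e = 0).
    """

    levels: pd.DataFrame
    thresholds: dict[float, float | None]
    trace: dict[float, np.ndarray]
    config: SensitivityConfig

    def threshold(self, criterion: float) -> float | None:
        return self.thresholds[criterion]


def _error_draw(rng: np.random.Generator, e: float, size: int, law: str) -> np.ndarray:
    if law == "uniform":
        return rng.uniform(-e, e, size=size)
    if law == "normal":
        # SD chosen so the law has the same variance as Uniform(−e, e)
        return rng.normal(0.0, e / np.sqrt(3.0), size=size)
    return rng.uniform(-e, 0.0, size=size)  # one_sided: pure attenuation


def perturb(
    cohort: Cohort,
    e: float,
    response: str,
    target_group: str = "Ghanaian",
    rng: np.random.Generator | None = None,
    error_law: str = "uniform",
) -> Cohort:
    """Inject a random relative error of magnitude e into one response.

    Each targeted eye's value y becomes y·(1 + u) with u drawn from the
    error law (default Uniform(−e, e)), independently per eye. All
    other responses, covariates and untargeted records are unchanged.
    Draws are consumed in record order, one per targeted eye.
    """
    if not 0.0 <= e <= 1.0:
        raise ValueError(f"error magnitude must lie in [0, 1], got {e}")
    rng = np.random.default_rng(0) if rng is None else rng
    targeted = [
        i
        for i, rec in enumerate(cohort.records)
        if (target_group == "all" or rec.ethnicity == target_group)
        and rec.response(response) is not None
    ]
    u = _error_draw(rng, e, len(targeted), error_law)
    factors = dict(zip(targeted, 1.0 + u))
    records = []
    for i, rec in enumerate(cohort.records):
        if i not in factors:
            records.append(rec)
            continue
        factor = factors[i]
        if response == "choroid":
            records.append(replace(rec, choroid=rec.choroid * factor))
        else:
            field_name = {
                "c0": "center_fovea",
                "p_sup": "parafovea_superior", "p_nas": "parafovea_nasal",
                "p_inf": "parafovea_inferior", "p_tem": "parafovea_temporal",
                "f_sup": "perifovea_superior", "f_nas": "perifovea_nasal",
                "f_inf": "perifovea_inferior", "f_tem": "perifovea_temporal",
            }[response]
            grid = replace(rec.grid, **{field_name: rec.grid[response] * factor})
            records.append(replace(rec, grid=grid))
    return Cohort(records=records, provenance=f"{cohort.provenance}+perturb(e={e})")


def run_sensitivity(cohort: Cohort, config: SensitivityConfig) -> SensitivityResult:
    """Estimate the significance proportion across the error grid.

    For each grid magnitude e, ``n_sims_per_level`` simulations perturb
    the response, refit the mixed model on the fixed design (only the
    response vector changes, so the design workspace is shared), and
    test the raw ethnicity p-value against α. Deterministic given the
    config seed. Simulations whose fit fails are counted and excluded;
    a level with > 1% failures is flagged in the ``levels`` table.
    """
    ws, y_base, frame = workspace_for(cohort, config.response)
    target_mask = (
        np.ones(len(frame), dtype=bool)
        if config.target_group == "all"
        else (frame["ethnicity"] == config.target_group).to_numpy()
    )
    n_target = int(target_mask.sum())
    if n_target == 0:
        raise ValueError(f"no records in target group {config.target_group!r}")
    rng = np.random.default_rng(config.seed)

    rows = []
    trace: dict[float, np.ndarray] = {}
    for e in config.error_grid:
        significant = 0
        failed = 0
        batch_props: list[float] = []
        batch_hits = 0
        batch_n = 0
        for sim in range(config.n_sims_per_level):
            u = _error_draw(rng, float(e), n_target, config.error_law)
            y = y_base.copy()
            y[target_mask] *= 1.0 + u
            try:
                fit = ws.fit(y)
            except np.linalg.LinAlgError:
                failed += 1
                continue
            z = fit["beta"][_ETH_INDEX] / fit["se"][_ETH_INDEX]
            p_sim = 2.0 * float(norm.sf(abs(z)))
            hit = p_sim < config.alpha
            significant += hit
            batch_hits += hit
            batch_n += 1
            if batch_n == config.batch_size:
                batch_props.append(batch_hits / batch_n)
                batch_hits = 0
                batch_n = 0
        if batch_n:
            batch_props.append(batch_hits / batch_n)
        n_ok = config.n_sims_per_level - failed
        prop = significant / n_ok if n_ok else np.nan
        mcse = float(np.sqrt(prop * (1 - prop) / n_ok)) if n_ok else np.nan
        rows.append(
            {
                "e": float(e),
                "n_sims": n_ok,
                "n_failed": failed,
                "proportion": prop,
                "mcse": mcse,
                "failure_warning": failed > 0.01 * config.n_sims_per_level,
            }
        )
        trace[float(e)] = np.asarray(batch_props)

    levels = pd.DataFrame(rows)
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    levels["proportion_smoothed"] = iso.fit_transform(
        levels["e"], levels["proportion"], sample_weight=levels["n_sims"]
    )
    thresholds: dict[float, float | None] = {}
    for criterion in config.criteria:
        ok = levels["proportion_smoothed"] >= criterion
        if not bool(ok.iloc[0]):
            thresholds[float(criterion)] = None
        else:
            # largest e with the criterion met at every grid point up to it
            below = np.where(~ok.to_numpy())[0]
            last = (below[0] - 1) if len(below) else len(levels) - 1
            thresholds[float(criterion)] = float(levels["e"].iloc[last])
    return SensitivityResult(levels=levels, thresholds=thresholds, trace=trace, config=config)


def check_convergence(
    batch_proportions: np.ndarray,
    batch_size: int,
    mcse_tol: float,
) -> tuple[bool, int]:
    """Judge Monte Carlo convergence of one level's batch trace.

    The running proportion over all batches has binomial MCSE
    √(p̂(1−p̂)/n); the level has converged when that falls below
    ``mcse_tol``. ``n_recommended`` extrapolates the simulation count
    needed to reach the tolerance, ⌈p̂(1−p̂)/tol²⌉ (at least 1).
    """
    props = np.asarray(batch_proportions, dtype=float)
    if props.ndim != 1 or len(props) < 2:
        raise ValueError("need >= 2 batches")
    if mcse_tol <= 0:
        raise ValueError("mcse_tol must be positive")
    n = len(props) * batch_size
    p_hat = float(np.mean(props))
    mcse = np.sqrt(p_hat * (1 - p_hat) / n)
    n_recommended = max(1, int(np.ceil(p_hat * (1 - p_hat) / mcse_tol**2)))
    return bool(mcse < mcse_tol), n_recommended
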