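"""Random-effects pooling of published ETDRS thickness summaries.

Implements the systematic-review arithmetic: eligibility screening of
study summaries, random selection of one eye when both are reported,
DerSimonian–Laird random-effects pooling per sector with Cochran's Q,
I² and τ², stratification of studies into decade bins of mean age, and
between-group difference tables.

For sector means y_i with variance v_i = sd_i²/n_i (back-computed from
a 95% CI or SE when the SD is not reported):

    w_i = 1/v_i,  ȳ_FE = Σw_i y_i / Σw_i,  Q = Σw_i (y_i − ȳ_FE)²,
    τ² = max(0, (Q − (k−1)) / (Σw_i − Σw_i²/Σw_i)),
    I² = max(0, (Q − (k−1))/Q) · 100,
    w*_i = 1/(v_i + τ²),  pooled = Σw*_i y_i / Σw*_i,
    CI = pooled ± 1.96/√Σw*_i.

An optional iterated (Paule–Mandel-style restricted moment) τ² is
provided for cross-checks but DL is the default estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import SECTORS

__all__ = [
    "SectorSummary",
    "StudyRecord",
    "PooledEstimate",
    "filter_eligible",
    "select_eye",
    "pool",
    "stratify_by_age",
    "compare_groups",
    "forest_table",
    "synthetic_study_table",
]


@dataclass(frozen=True)
class SectorSummary:
    """Published mean thickness for one sector, with some dispersion.

    Exactly the information extraction tables carry: a mean, the sample
    size, and one of SD, SE, or a 95% CI from which the variance of the
    mean is recovered (normal-CI divisor 3.92).
    """

    mean: float
    n: int | None = None
    sd: float | None = None
    se: float | None = None
    ci95: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n is not None and self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd is not None and self.sd <= 0:
            raise ValueError("sd must be > 0 when present")

    def variance_of_mean(self) -> float | None:
        """v_i = Var(mean), from SD/n, SE, or CI width; None if unrecoverable."""
        if self.sd is not None and self.n is not None:
            return self.sd**2 / self.n
        if self.se is not None:
            return self.se**2
        if self.ci95 is not None:
            lo, hi = self.ci95
            if hi <= lo:
                return None
            return ((hi - lo) / 3.92) ** 2
        return None

    def resolved_sd(self) -> float | None:
        """SD, back-computed as √n·(ci_hi−ci_lo)/3.92 or √n·SE if needed."""
        if self.sd is not None:
            return self.sd
        if self.n is None:
            return None
        if self.se is not None:
            return self.se * math.sqrt(self.n)
        if self.ci95 is not None:
            lo, hi = self.ci95
            return math.sqrt(self.n) * (hi - lo) / 3.92
        return None


@dataclass(frozen=True)
class StudyRecord:
    """One study's extracted summary row."""

    label: str
    population: str
    mean_age: float | None
    sectors: dict[str, SectorSummary] = field(default_factory=dict)
    eye_reported: str = "unspecified"  # OD | OS | both | unspecified
    device: str | None = None
    healthy_only: bool = True
    sectors_od: dict[str, SectorSummary] | None = None
    sectors_os: dict[str, SectorSummary] | None = None

    @property
    def age_group(self) -> tuple[int, int] | None:
        """Half-open decade bin [lo, lo+10) containing the mean age."""
        if self.mean_age is None:
            return None
        lo = 10 * math.floor(self.mean_age / 10)
        return (lo, lo + 10)


@dataclass
class PooledEstimate:
    """DerSimonian–Laird pooled mean for one sector across studies."""

    sector: str
    k: int
    pooled_mean: float
    ci95: tuple[float, float]
    tau2: float
    q: float
    df: int
    i2: float
    p_q: float

    def __post_init__(self) -> None:
        if not self.ci95[0] <= self.pooled_mean <= self.ci95[1]:
            raise ValueError("CI must contain the pooled mean")


def filter_eligible(
    records: list[StudyRecord],
) -> tuple[list[StudyRecord], list[tuple[StudyRecord, str]]]:
    """Apply the review's inclusion rules; exclusions carry the first
    failed rule.

    A study is eligible when it reports at least one ETDRS sector mean
    whose dispersion is convertible to a variance (SD with n, SE, or
    95% CI), names the imaging device, states the participants' mean or
    median age, and measured healthy subjects only.
    """
    eligible: list[StudyRecord] = []
    excluded: list[tuple[StudyRecord, str]] = []
    for record in records:
        known = {s: summ for s, summ in record.sectors.items() if s in SECTORS}
        if not known:
            excluded.append((record, "no ETDRS sector means"))
            continue
        usable = {s: m for s, m in known.items() if m.variance_of_mean() is not None}
        if not usable:
            excluded.append((record, "no convertible dispersion"))
            continue
        if not record.device:
            excluded.append((record, "no device"))
            continue
        if record.mean_age is None:
            excluded.append((record, "no age"))
            continue
        if not record.healthy_only:
            excluded.append((record, "not restricted to healthy subjects"))
            continue
        eligible.append(replace(record, sectors=usable))
    return eligible, excluded


def select_eye(record: StudyRecord, rng: np.random.Generator) -> StudyRecord:
    """Pick one eye uniformly when a study reports both; otherwise identity."""
    if record.eye_reported != "both" or not (record.sectors_od and record.sectors_os):
        return record
    eye = "OD" if rng.uniform() < 0.5 else "OS"
    chosen = record.sectors_od if eye == "OD" else record.sectors_os
    return replace(record, sectors=dict(chosen), eye_reported=eye)


def _paule_mandel_tau2(y: np.ndarray, v: np.ndarray) -> float:
    """Iterated restricted-moment τ²: solve Q_gen(τ²) = k−1 by bisection,
    where Q_gen(τ²) = Σ wᵢ(τ²)(yᵢ−μ̂(τ²))² with wᵢ = 1/(vᵢ+τ²)."""
    k = len(y)

    def q_gen(tau2: float) -> float:
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        return float(np.sum(w * (y - mu) ** 2))

    if q_gen(0.0) <= k - 1:  # no excess heterogeneity
        return 0.0
    hi = float(np.var(y)) + float(np.max(v))
    while q_gen(hi) > k - 1:
        hi *= 2.0
    lo = 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if q_gen(mid) > k - 1:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def pool(records: list[StudyRecord], sector: str, tau2_method: str = "dl") -> PooledEstimate:
    """Random-effects pooled mean for one sector.

    ``tau2_method`` selects the between-study variance estimator:
    ``"dl"`` (DerSimonian–Laird closed form, the default) or ``"pm"``
    (Paule–Mandel iterated restricted moment, which often tracks
    likelihood-based estimators more closely). Q, I² and their p-value
    are method-independent.
    """
    if tau2_method not in ("dl", "pm"):
        raise ValueError(f"unknown tau2_method {tau2_method!r}")
    data = [
        (r.sectors[sector].mean, r.sectors[sector].variance_of_mean())
        for r in records
        if sector in r.sectors and r.sectors[sector].variance_of_mean() is not None
    ]
    if not data:
        raise ValueError(f"no study reports sector {sector!r} with usable dispersion")
    y = np.array([d[0] for d in data])
    v = np.array([d[1] for d in data])
    k = len(y)
    w = 1.0 / v
    fixed = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - fixed) ** 2))
    df = k - 1
    if k == 1:
        tau2, i2, p_q = 0.0, 0.0, 1.0
    else:
        if tau2_method == "dl":
            c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
            tau2 = max(0.0, (q - df) / c)
        else:
            tau2 = _paule_mandel_tau2(y, v)
        i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
        p_q = float(stats.chi2.sf(q, df))
    w_star = 1.0 / (v + tau2)
    pooled = float(np.sum(w_star * y) / np.sum(w_star))
    half = 1.96 / math.sqrt(float(np.sum(w_star)))
    return PooledEstimate(
        sector=sector,
        k=k,
        pooled_mean=pooled,
        ci95=(pooled - half, pooled + half),
        tau2=float(tau2),
        q=q,
        df=df,
        i2=float(i2),
        p_q=p_q,
    )


def stratify_by_age(
    records: list[StudyRecord],
) -> dict[tuple[int, int], list[StudyRecord]]:
    """Partition studies into half-open decade bins of mean age.

    Bin edges follow [lo, lo+10): a study with mean age exactly 30.0
    falls in [30, 40). Studies without a mean age are skipped (they are
    ineligible anyway).
    """
    bins: dict[tuple[int, int], list[StudyRecord]] = {}
    for record in records:
        group = record.age_group
        if group is None:
            continue
        bins.setdefault(group, []).append(record)
    return dict(sorted(bins.items()))


def pool_by_age(
    records: list[StudyRecord], sector: str
) -> dict[tuple[int, int], PooledEstimate]:
    """DL pooling per decade age bin for one sector."""
    out = {}
    for group, members in stratify_by_age(records).items():
        with_sector = [r for r in members if sector in r.sectors]
        if with_sector:
            out[group] = pool(with_sector, sector)
    return out


def compare_groups(
    pooled: dict[str, PooledEstimate],
    reference: dict[str, tuple[float, tuple[float, float]]],
) -> pd.DataFrame:
    """Pooled-minus-reference differences with independent-normal CIs.

    ``reference`` maps sector → (mean, 95% CI). SEs are recovered from
    the CI widths and the difference CI adds variances.
    """
    rows = []
    for sector, estimate in pooled.items():
        if sector not in reference:
            raise KeyError(f"reference is missing sector {sector!r}")
        ref_mean, (ref_lo, ref_hi) = reference[sector]
        se_pooled = (estimate.ci95[1] - estimate.ci95[0]) / 3.92
        se_ref = (ref_hi - ref_lo) / 3.92
        diff = estimate.pooled_mean - ref_mean
        half = 1.96 * math.sqrt(se_pooled**2 + se_ref**2)
        rows.append(
            {
                "sector": sector,
                "difference": diff,
                "ci_lo": diff - half,
                "ci_hi": diff + half,
            }
        )
    return pd.DataFrame(rows).set_index("sector")


def forest_table(records: list[StudyRecord], sector: str) -> pd.DataFrame:
    """Forest-plot export: one row per contributing study plus the pooled
    row (k + 1 rows)."""
    contributing = [
        r
        for r in records
        if sector in r.sectors and r.sectors[sector].variance_of_mean() is not None
    ]
    estimate = pool(contributing, sector)
    rows = []
    for r in contributing:
        summary = r.sectors[sector]
        se = math.sqrt(summary.variance_of_mean())
        rows.append(
            {
                "label": r.label,
                "mean": summary.mean,
                "ci_lo": summary.mean - 1.96 * se,
                "ci_hi": summary.mean + 1.96 * se,
                "weight_pct": np.nan,
                "pooled": False,
            }
        )
    v = np.array(
        [contributing[i].sectors[sector].variance_of_mean() for i in range(len(rows))]
    )
    w_star = 1.0 / (v + estimate.tau2)
    for i, row in enumerate(rows):
        row["weight_pct"] = 100.0 * float(w_star[i] / np.sum(w_star))
    rows.append(
        {
            "label": f"Pooled (k={estimate.k})",
            "mean": estimate.pooled_mean,
            "ci_lo": estimate.ci95[0],
            "ci_hi": estimate.ci95[1],
            "weight_pct": 100.0,
            "pooled": True,
        }
    )
    return pd.DataFrame(rows)


def synthetic_study_table() -> list[StudyRecord]:
    """SYNTHETIC stand-in for a review extraction table.

    Five single-ethnicity studies mirroring the age-group structure of
    a published review of macular thickness among African Americans
    (two studies with mean ages in the twenties, one in the thirties,
    two in the forties) plus a South-African cohort. All thickness
    means and SDs are invented placeholders on a normative scale; they
    are NOT extracted from any publication and exist so the pooling
    pipeline is runnable end to end without external data.
    """

    def grid(base: float, sd: float, n: int) -> dict[str, SectorSummary]:
        offsets = {
            "c0": 0.0,
            "p_sup": 62.0, "p_nas": 65.0, "p_inf": 58.0, "p_tem": 52.0,
            "f_sup": 22.0, "f_nas": 36.0, "f_inf": 12.0, "f_tem": 8.0,
        }
        return {s: SectorSummary(mean=base + d, sd=sd, n=n) for s, d in offsets.items()}

    return [
        StudyRecord("synthetic-study-A", "African American", 21.0,
                    grid(250.0, 18.0, 60), device="SD-OCT"),
        StudyRecord("synthetic-study-B", "African American", 28.9,
                    grid(246.0, 20.0, 45), device="SD-OCT"),
        StudyRecord("synthetic-study-C", "African American", 36.2,
                    grid(238.0, 17.0, 52), device="SD-OCT"),
        StudyRecord("synthetic-study-D", "African American", 47.7,
                    grid(232.0, 19.0, 40), device="SD-OCT"),
        StudyRecord("synthetic-study-E", "African American", 49.0,
                    grid(228.0, 21.0, 35), device="SD-OCT"),
        StudyRecord("synthetic-study-F", "South African", 33.0,
                    grid(256.0, 22.0, 70), device="SD-OCT"),
    ]
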