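"""Mixed-model estimation against brute-force oracles, plus the
descriptive statistics (fellow-eye agreement, demographic tests)."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from octnorms import (
    Cohort,
    bland_altman,
    bonferroni,
    default_config,
    fit_sector,
    generate,
    intereye_correlation,
    sex_chi_square,
    yates_chi_square,
    age_rank_sum,
)
from octnorms.lmm import COEFFICIENTS, RemlWorkspace, design_matrix, workspace_for

from conftest import make_record


def _toy_cohort(n_subjects=8, seed=0, sigma_b=12.0, sigma_e=6.0, both_eyes=True):
    """Small hand-rolled cohort with known structure."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_subjects):
        ethnicity = "Ghanaian" if i % 2 else "European"
        sex = "male" if i % 3 == 0 else "female"
        age = float(rng.uniform(45, 80))
        b = rng.normal(0, sigma_b)
        eyes = ("OD", "OS") if both_eyes else ("OD",)
        for eye in eyes:
            base = 300 + (-40 if ethnicity == "Ghanaian" else 0) + b
            records.append(
                make_record(
                    f"S{i}", ethnicity=ethnicity, age=age, sex=sex, eye=eye,
                    base=base + rng.normal(0, sigma_e),
                )
            )
    return Cohort(records=records)


def _dense_gls(X, y, codes, theta):
    """Brute-force GLS with an explicitly assembled block covariance."""
    n = len(y)
    Z = np.zeros((n, codes.max() + 1))
    Z[np.arange(n), codes] = 1.0
    V = np.eye(n) + theta * Z @ Z.T
    Vinv = np.linalg.inv(V)
    return np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)


class TestRemlAgainstOracles:
    @pytest.mark.parametrize("theta", [0.1, 1.0, 7.5])
    def test_gls_at_fixed_theta_matches_dense_covariance(self, theta):
        cohort = _toy_cohort(n_subjects=4, seed=2)
        ws, y, frame = workspace_for(cohort, "c0")
        Xty = ws.X.T @ y
        Sy = np.zeros(ws.k)
        np.add.at(Sy, ws.codes, y)
        beta, _, _ = ws._gls(theta, Xty, float(y @ y), Sy)
        expected = _dense_gls(ws.X, y, ws.codes, theta)
        assert beta == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_reml_beta_matches_dense_gls_at_fitted_theta(self, seed):
        """On <= 10-subject instances the profile fit's fixed effects must
        reproduce an explicit block-covariance GLS at the fitted theta."""
        cohort = _toy_cohort(n_subjects=seed + 5, seed=seed)
        ws, y, _ = workspace_for(cohort, "c0")
        fit = ws.fit(y)
        expected = _dense_gls(ws.X, y, ws.codes, fit["theta"])
        assert fit["beta"] == pytest.approx(expected, abs=1e-6)

    def test_reml_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        cohort, _ = generate(default_config(seed=3))
        frame = cohort.to_dataframe()
        frame["gh"] = (frame.ethnicity == "Ghanaian").astype(float)
        frame["aged"] = (frame.age - 60) / 10
        frame["male"] = (frame.sex == "male").astype(float)
        reference = smf.mixedlm(
            "p_inf ~ gh + aged + male", frame, groups=frame.subject_id
        ).fit(reml=True)
        fit = fit_sector(cohort, "p_inf")
        assert fit.coef["estimate"].to_numpy() == pytest.approx(
            reference.fe_params.to_numpy(), abs=1e-5
        )
        assert fit.sigma_e2 == pytest.approx(reference.scale, rel=1e-4)
        assert fit.sigma_b2 == pytest.approx(
            float(reference.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-3
        )

    def test_single_eye_cohort_collapses_to_ols(self):
        cohort = _toy_cohort(n_subjects=12, seed=4, both_eyes=False)
        fit = fit_sector(cohort, "c0")
        frame = cohort.to_dataframe()
        X = design_matrix(frame)
        ols = np.linalg.lstsq(X, frame["c0"].to_numpy(), rcond=None)[0]
        assert fit.coef["estimate"].to_numpy() == pytest.approx(ols, abs=1e-8)

    def test_variance_recovery_on_synthetic_cohorts(self):
        """Estimated fellow-eye ICC recovers the generative 0.8 within
        0.05 when averaged over replicates at n = 500 subjects."""
        from dataclasses import replace

        iccs = []
        for seed in range(20):
            config = replace(
                default_config(seed=seed), n_ghanaian=250, n_european=250
            )
            cohort, _ = generate(config)
            iccs.append(fit_sector(cohort, "c0").icc)
        assert np.mean(iccs) == pytest.approx(0.8, abs=0.05)

    def test_single_group_cohort_rejected(self):
        records = [
            make_record(f"S{i}", ethnicity="European", age=60.0, sex="female",
                        eye=eye, base=300 + i)
            for i in range(4) for eye in ("OD", "OS")
        ]
        with pytest.raises(ValueError, match="2 subjects"):
            fit_sector(Cohort(records=records), "c0")

    def test_singular_design_raises(self):
        # constant age (zero centred-age column) makes the design rank deficient
        records = []
        for i in range(8):
            eth = "Ghanaian" if i % 2 else "European"
            records.append(make_record(f"S{i}", ethnicity=eth, age=60.0,
                                       sex="female", base=290 + i))
        with pytest.raises(np.linalg.LinAlgError, match="singular design"):
            fit_sector(Cohort(records=records), "c0")

    def test_too_few_subjects_per_group_rejected(self):
        records = [
            make_record("S1", ethnicity="European"),
            make_record("S2", ethnicity="Ghanaian"),
            make_record("S3", ethnicity="European", age=50.0),
        ]
        with pytest.raises(ValueError, match="Ghanaian"):
            fit_sector(Cohort(records=records), "c0")


class TestBonferroni:
    def test_scales_and_caps(self):
        assert bonferroni(0.01, 9) == pytest.approx(0.09)
        assert bonferroni(0.2, 9) == 1.0

    def test_vector_elementwise_order_preserved(self):
        out = bonferroni([0.001, 0.5, 0.02], 9)
        assert out == pytest.approx([0.009, 1.0, 0.18])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20),
           st.integers(1, 12))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_never_decreases_and_monotone(self, p_values, m):
        adjusted = bonferroni(p_values, m)
        assert np.all(adjusted >= np.asarray(p_values))
        order = np.argsort(p_values)
        assert np.all(np.diff(adjusted[order]) >= -1e-12)


class TestIntereyeCorrelation:
    def test_identical_eyes_give_unit_correlation(self):
        records = []
        for i in range(5):
            for eye in ("OD", "OS"):
                records.append(make_record(f"S{i}", eye=eye, base=290 + 4 * i))
        r, ci = intereye_correlation(Cohort(records=records), "c0")
        assert r == pytest.approx(1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(8)
        od = rng.uniform(240, 320, 10)
        os_ = od + rng.normal(0, 10, 10)
        records = []
        for i, (a, b) in enumerate(zip(od, os_)):
            records.append(make_record(f"S{i}", eye="OD", center_fovea=a))
            records.append(make_record(f"S{i}", eye="OS", center_fovea=b))
        r, (lo, hi) = intereye_correlation(Cohort(records=records), "c0")
        cov = np.mean((od - od.mean()) * (os_ - os_.mean()))
        expected = cov / (od.std() * os_.std())
        assert r == pytest.approx(expected, abs=1e-10)
        z = np.arctanh(expected)
        half = stats.norm.ppf(0.975) / np.sqrt(10 - 3)
        assert lo == pytest.approx(np.tanh(z - half), abs=1e-9)
        assert hi == pytest.approx(np.tanh(z + half), abs=1e-9)

    def test_requires_four_pairs(self):
        records = [make_record(f"S{i}", eye=e) for i in range(3) for e in ("OD", "OS")]
        with pytest.raises(ValueError, match=">= 4"):
            intereye_correlation(Cohort(records=records), "c0")


class TestBlandAltman:
    def test_identical_eyes_all_zero(self):
        records = [make_record(f"S{i}", eye=e, base=300 + i)
                   for i in range(4) for e in ("OD", "OS")]
        assert bland_altman(Cohort(records=records), "c0") == (0.0, 0.0, 0.0)

    def test_constant_offset_has_degenerate_limits(self):
        records = []
        for i in range(4):
            records.append(make_record(f"S{i}", eye="OD", center_fovea=260 + i + 5))
            records.append(make_record(f"S{i}", eye="OS", center_fovea=260 + i))
        bias, lo, hi = bland_altman(Cohort(records=records), "c0")
        assert (bias, lo, hi) == pytest.approx((5.0, 5.0, 5.0))

    def test_matches_hand_formula_on_five_pairs(self):
        diffs = np.array([3.0, -1.0, 4.0, 0.5, -2.5])
        records = []
        for i, d in enumerate(diffs):
            records.append(make_record(f"S{i}", eye="OD", center_fovea=260 + d))
            records.append(make_record(f"S{i}", eye="OS", center_fovea=260.0))
        bias, lo, hi = bland_altman(Cohort(records=records), "c0")
        assert bias == pytest.approx(diffs.mean())
        sd = diffs.std(ddof=1)
        assert lo == pytest.approx(diffs.mean() - 1.96 * sd)
        assert hi == pytest.approx(diffs.mean() + 1.96 * sd)
        assert hi - bias == pytest.approx(bias - lo)


class TestDemographicTests:
    def test_published_table_counts_give_073(self):
        # 37 Europeans (28 F / 9 M) vs 42 Ghanaians (27 F / 15 M)
        chi2, p = yates_chi_square([[28, 9], [27, 15]])
        assert round(chi2, 2) == 0.73
        assert p > 0.05

    def test_proportional_table_gives_zero(self):
        chi2, _ = yates_chi_square([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)

    @pytest.mark.parametrize("table", [
        [[28, 9], [27, 15]], [[5, 20], [18, 7]], [[40, 2], [35, 9]],
    ])
    def test_matches_brute_force_yates_formula(self, table):
        observed = np.asarray(table, dtype=float)
        total = observed.sum()
        expected = np.outer(observed.sum(1), observed.sum(0)) / total
        brute = float(np.sum((np.abs(observed - expected) - 0.5) ** 2 / expected))
        chi2, _ = yates_chi_square(table)
        assert chi2 == pytest.approx(brute, abs=1e-10)

    def test_sex_chi_square_counts_subjects_not_eyes(self):
        records = []
        for i in range(6):
            eth = "Ghanaian" if i < 3 else "European"
            sex = "male" if i % 2 else "female"
            for eye in ("OD", "OS"):
                records.append(make_record(f"S{i}", ethnicity=eth, sex=sex, eye=eye))
        chi2, _ = sex_chi_square(Cohort(records=records))
        expected, _ = yates_chi_square([[2, 1], [2, 1]])
        assert chi2 == pytest.approx(expected)

    def test_rank_sum_identical_groups(self):
        records = [
            make_record(f"E{i}", ethnicity="European", age=40.0 + i)
            for i in range(6)
        ] + [
            make_record(f"G{i}", ethnicity="Ghanaian", age=40.0 + i)
            for i in range(6)
        ]
        w, p = age_rank_sum(Cohort(records=records))
        assert w == pytest.approx(6 * 6 / 2)  # U at perfect overlap
        assert p > 0.9

    def test_rank_sum_complete_separation_is_maximal(self):
        records = [
            make_record("E1", ethnicity="European", age=63.0),
            make_record("E2", ethnicity="European", age=64.0),
            make_record("G1", ethnicity="Ghanaian", age=51.0),
            make_record("G2", ethnicity="Ghanaian", age=52.0),
        ]
        w, _ = age_rank_sum(Cohort(records=records))
        assert w == 4.0  # n1*n2: every European older than every Ghanaian

    def test_rank_sum_statistic_against_exact_enumeration(self):
        rng = np.random.default_rng(42)
        eur = rng.uniform(40, 70, 4).round(1)
        gha = rng.uniform(40, 70, 4).round(1)
        records = [make_record(f"E{i}", ethnicity="European", age=a)
                   for i, a in enumerate(eur)]
        records += [make_record(f"G{i}", ethnicity="Ghanaian", age=a)
                    for i, a in enumerate(gha)]
        w, p = age_rank_sum(Cohort(records=records))
        # exact U and its permutation p-value by full enumeration
        pooled = np.concatenate([eur, gha])
        u_obs = sum((a > b) + 0.5 * (a == b) for a in eur for b in gha)
        assert w == pytest.approx(u_obs)
        count = 0
        total = 0
        for idx in itertools.combinations(range(8), 4):
            group1 = pooled[list(idx)]
            group2 = np.delete(pooled, list(idx))
            u = sum((a > b) + 0.5 * (a == b) for a in group1 for b in group2)
            total += 1
            count += abs(u - 8) >= abs(u_obs - 8)  # two-sided around n1n2/2
        exact_p = count / total
        assert p == pytest.approx(exact_p, abs=0.06)
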