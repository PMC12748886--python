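import numpy as np
import pandas as pd
import pytest

from heatattrib.dlnm import ReducedAssociation, SubperiodScheme
from heatattrib.metareg import (
    MetaData,
    build_meta_design,
    compute_blups,
    counterfactual_blups,
    fit_mvmeta,
    heterogeneity,
    lr_test,
    predict_pooled,
    select_model,
)

SCHEME = SubperiodScheme.from_range(1993, 2022, 5)


def univariate_data(y, v, groups=None, X=None, columns=None):
    y = np.asarray(y, dtype=float)[:, None]
    S = np.asarray(v, dtype=float)[:, None, None]
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
        columns = ["intercept"]
    groups = np.asarray(groups if groups is not None else [f"u{i}" for i in range(n)])
    return MetaData(
        y=y, S=S, X=X, columns=columns, groups=groups,
        z=np.ones((n, 1)), city=groups,
        subperiod=np.asarray(["s1"] * n),
    )


def simulate_reduced(seed, n_cities=15, psi_scale=0.05, le_effect=-0.08,
                     sd_within=0.08, le_slope=0.25):
    """City x subperiod 3-dim estimates driven by LE, with known S and Psi."""
    rng = np.random.default_rng(seed)
    reduced, rows = [], []
    base = np.array([0.2, 0.4, 0.8])
    for i in range(n_cities):
        city = f"c{i:02d}"
        b = rng.normal(0.0, psi_scale, 3)
        le0 = rng.normal(76.0, 1.0)
        slope = rng.normal(le_slope, 0.05)
        for label, s, e in SCHEME.blocks:
            mid = (s + e) / 2
            le = le0 + slope * (mid - 1993)
            theta = base * (1.0 + le_effect * (le - 76.0)) + b
            S = np.diag(rng.uniform(0.5, 1.5, 3)) * sd_within**2
            y = rng.multivariate_normal(theta, S)
            reduced.append(ReducedAssociation(city, label, y, S, 18.0))
            rows.append({
                "city": city, "subperiod": label, "le": le,
                "noise1": rng.normal(), "noise2": rng.normal(),
            })
    return reduced, pd.DataFrame(rows)


class TestFixedEffectsOracle:
    def test_psi_zero_equals_inverse_variance_weighting(self):
        y = np.array([0.3, 0.7])
        v = np.array([0.04, 0.09])
        data = univariate_data(y, v)
        model = fit_mvmeta(data, psi_fixed=np.zeros((1, 1)))
        w = 1.0 / v
        expected = np.sum(w * y) / np.sum(w)
        assert model.beta[0] == pytest.approx(expected, abs=1e-10)
        assert model.cov_beta[0, 0] == pytest.approx(1.0 / np.sum(w), abs=1e-12)

    def test_duplicating_units_preserves_fixed_effects(self):
        rng = np.random.default_rng(4)
        y = rng.normal(0.5, 0.3, 8)
        v = rng.uniform(0.02, 0.08, 8)
        d1 = univariate_data(y, v)
        d2 = univariate_data(
            np.r_[y, y], np.r_[v, v],
            groups=[f"u{i}" for i in range(8)] + [f"w{i}" for i in range(8)],
        )
        m1 = fit_mvmeta(d1)
        m2 = fit_mvmeta(d2)
        assert m2.beta[0] == pytest.approx(m1.beta[0], abs=1e-5)
        assert m2.loglik != pytest.approx(m1.loglik, abs=1e-3)

    def test_loglik_improves_over_start(self):
        reduced, meta = simulate_reduced(0)
        model = fit_mvmeta(reduced, meta, SCHEME, predictors=("le",))
        base = fit_mvmeta(
            reduced, meta, SCHEME, predictors=("le",),
            psi_fixed=np.zeros((3, 3)),
        )
        assert model.converged
        assert model.loglik >= base.loglik - 1e-6


class TestLRTest:
    def test_identical_models(self):
        data = univariate_data([0.1, 0.5, 0.4], [0.02, 0.02, 0.05])
        m = fit_mvmeta(data)
        stat, df, p = lr_test(m, m)
        assert stat == 0.0 and df == 0 and p == 1.0

    def test_non_nested_rejected(self):
        reduced, meta = simulate_reduced(1)
        m1 = fit_mvmeta(reduced, meta, SCHEME, predictors=("noise1",))
        m2 = fit_mvmeta(reduced, meta, SCHEME, predictors=("noise2",))
        with pytest.raises(ValueError, match="nested"):
            lr_test(m1, m2)

    def test_nested_has_lower_likelihood(self):
        reduced, meta = simulate_reduced(2)
        m0 = fit_mvmeta(reduced, meta, SCHEME)
        m1 = fit_mvmeta(reduced, meta, SCHEME, predictors=("le",))
        stat, df, p = lr_test(m0, m1)
        assert stat >= 0.0 and df == 3
        assert p < 0.05  # LE truly drives the coefficients here


class TestHeterogeneity:
    def test_no_heterogeneity_gives_zero_q(self):
        data = univariate_data([0.4, 0.4, 0.4], [0.05, 0.05, 0.05])
        m = fit_mvmeta(data, psi_fixed=np.zeros((1, 1)))
        het = heterogeneity(m)
        assert het.Q == pytest.approx(0.0, abs=1e-20)
        assert het.I2 == 0.0

    def test_hand_computed_three_studies(self):
        y = np.array([0.2, 0.5, 0.9])
        v = np.array([0.04, 0.02, 0.08])
        data = univariate_data(y, v)
        m = fit_mvmeta(data, psi_fixed=np.zeros((1, 1)))
        het = heterogeneity(m)
        w = 1.0 / v
        bw = np.sum(w * y) / np.sum(w)
        q = float(np.sum(w * (y - bw) ** 2))
        assert het.Q == pytest.approx(q, abs=1e-10)
        assert het.df == 2
        assert het.I2 == pytest.approx(max(0.0, (q - 2) / q) * 100.0)

    def test_i2_floored_at_zero(self):
        y = np.array([0.4, 0.401, 0.399])
        v = np.array([0.5, 0.5, 0.5])  # huge variances -> Q << df
        m = fit_mvmeta(univariate_data(y, v), psi_fixed=np.zeros((1, 1)))
        assert heterogeneity(m).I2 == 0.0

    def test_invariant_to_joint_rescaling(self):
        y = np.array([0.2, 0.5, 0.9])
        v = np.array([0.04, 0.02, 0.08])
        m1 = fit_mvmeta(univariate_data(y, v), psi_fixed=np.zeros((1, 1)))
        c = 3.7
        m2 = fit_mvmeta(
            univariate_data(c * y, c**2 * v), psi_fixed=np.zeros((1, 1))
        )
        assert heterogeneity(m2).Q == pytest.approx(heterogeneity(m1).Q, rel=1e-10)
        assert heterogeneity(m2).I2 == pytest.approx(heterogeneity(m1).I2, rel=1e-10)


class TestPredictPooled:
    def test_intercept_only(self):
        data = univariate_data([0.3, 0.7], [0.04, 0.09])
        m = fit_mvmeta(data, psi_fixed=np.zeros((1, 1)))
        theta, cov = predict_pooled(m, {})
        assert theta[0] == pytest.approx(m.beta[0])
        assert cov[0, 0] == pytest.approx(m.cov_beta[0, 0])

    def test_le_difference_is_linear(self):
        reduced, meta = simulate_reduced(3)
        m = fit_mvmeta(reduced, meta, SCHEME, predictors=("le",),
                       year_spline=False)
        v1 = {"le": 76.0}
        v2 = {"le": 80.0}
        t1, _ = predict_pooled(m, v1)
        t2, _ = predict_pooled(m, v2)
        mu, sd = m.data.scaler["le"]
        j = m.data.columns.index("le")
        expected = m.B[j] * (80.0 - 76.0) / sd
        assert np.allclose(t2 - t1, expected, atol=1e-12)

    def test_covariance_sandwich(self):
        reduced, meta = simulate_reduced(5)
        m = fit_mvmeta(reduced, meta, SCHEME, predictors=("le",),
                       year_spline=False)
        vals = {"le": 78.0}
        x = m.data.design_row(vals)
        A = np.kron(x[None, :], np.eye(3)).reshape(3, -1)
        _, cov = predict_pooled(m, vals)
        assert np.allclose(cov, A @ m.cov_beta @ A.T, atol=1e-14)


class TestBLUPs:
    def test_psi_zero_gives_fixed_prediction(self):
        reduced, meta = simulate_reduced(6)
        m = fit_mvmeta(reduced, meta, SCHEME, predictors=("le",),
                       psi_fixed=np.zeros((3, 3)))
        blups = compute_blups(m)
        for i in range(m.data.n):
            A = np.kron(m.data.X[i][None, :], np.eye(3)).reshape(3, -1)
            assert np.allclose(blups.theta[i], A @ m.beta, atol=1e-10)

    def test_tiny_within_variance_returns_unit_estimates(self):
        rng = np.random.default_rng(9)
        y = rng.normal(0.5, 0.3, 6)
        data = univariate_data(y, np.full(6, 1e-12))
        m = fit_mvmeta(data, psi_fixed=np.array([[0.09]]))
        blups = compute_blups(m)
        assert np.allclose(blups.theta[:, 0], y, atol=1e-6)

    def test_univariate_shrinkage_weights(self):
        y = np.array([0.2, 0.8])
        v = np.array([0.04, 0.04])
        psi = 0.02
        data = univariate_data(y, v)
        m = fit_mvmeta(data, psi_fixed=np.array([[psi]]))
        blups = compute_blups(m)
        beta = m.beta[0]
        expected = beta + psi / (psi + v) * (y - beta)
        assert np.allclose(blups.theta[:, 0], expected, atol=1e-10)
        # conditional variance: x cov x + psi - psi^2/(psi+v)
        expected_var = m.cov_beta[0, 0] + psi - psi**2 / (psi + v)
        assert np.allclose(blups.cov[:, 0, 0], expected_var, atol=1e-10)

    def test_blup_between_pooled_and_unit_estimate(self):
        y = np.array([0.2, 0.8])
        v = np.array([0.04, 0.04])
        data = univariate_data(y, v)
        m = fit_mvmeta(data, psi_fixed=np.array([[0.02]]))
        b = compute_blups(m).theta[:, 0]
        beta = m.beta[0]
        for i in range(2):
            lo, hi = sorted([beta, y[i]])
            assert lo - 1e-12 <= b[i] <= hi + 1e-12


@pytest.fixture(scope="module")
def cf_fitted():
    reduced, meta = simulate_reduced(7)
    m = fit_mvmeta(reduced, meta, SCHEME, predictors=("le",))
    blups = compute_blups(m)
    cf = counterfactual_blups(m, blups, meta, predictor="le")
    return m, blups, cf, meta


class TestCounterfactualBLUPs:

    def test_first_subperiod_unchanged(self, cf_fitted):
        m, blups, cf, meta = cf_fitted
        first = SCHEME.labels[0]
        mask = blups.subperiod == first
        assert np.allclose(cf.theta[mask], blups.theta[mask], atol=1e-12)

    def test_difference_is_le_coefficient_times_delta(self, cf_fitted):
        m, blups, cf, meta = cf_fitted
        mt = meta.set_index(["city", "subperiod"])["le"]
        j = m.data.columns.index("le")
        mu, sd = m.data.scaler["le"]
        first = SCHEME.labels[0]
        for i in range(m.data.n):
            c, s = blups.city[i], blups.subperiod[i]
            dle = (mt.loc[(c, first)] - mt.loc[(c, s)]) / sd
            assert np.allclose(
                cf.theta[i] - blups.theta[i], m.B[j] * dle, atol=1e-10
            )

    def test_covariance_carried_over(self, cf_fitted):
        _, blups, cf, _ = cf_fitted
        assert np.array_equal(cf.cov, blups.cov)

    def test_zero_le_coefficient_means_no_change(self):
        reduced, meta = simulate_reduced(8, le_effect=0.0)
        m = fit_mvmeta(reduced, meta, SCHEME, predictors=("le",))
        # force the LE coefficient to exactly zero before the construction
        j = m.data.columns.index("le")
        B = m.B.copy()
        B[j] = 0.0
        m.beta = B.reshape(-1)
        blups = compute_blups(m)
        cf = counterfactual_blups(m, blups, meta, predictor="le")
        assert np.allclose(cf.theta, blups.theta, atol=1e-12)

    def test_missing_predictor_rejected(self):
        reduced, meta = simulate_reduced(9)
        m = fit_mvmeta(reduced, meta, SCHEME)
        blups = compute_blups(m)
        with pytest.raises(ValueError, match="not in the fitted model"):
            counterfactual_blups(m, blups, meta, predictor="le")


class TestSelection:
    def test_single_improving_candidate_selected(self):
        reduced, meta = simulate_reduced(10)
        model, trace = select_model(reduced, meta, SCHEME, candidates=("le",))
        assert "le" in model.data.columns
        assert {"base"} <= set(trace["action"])

    def test_no_improvement_returns_base(self):
        reduced, meta = simulate_reduced(11, le_effect=0.0, psi_scale=0.02)
        model, trace = select_model(
            reduced, meta, SCHEME, candidates=("noise1", "noise2")
        )
        assert not ({"noise1", "noise2"} & set(model.data.columns))

    def test_le_selected_when_it_drives_coefficients(self):
        hits = 0
        n_rep = 15
        for seed in range(n_rep):
            reduced, meta = simulate_reduced(100 + seed)
            model, _ = select_model(
                reduced, meta, SCHEME, candidates=("le", "noise1", "noise2")
            )
            hits += "le" in model.data.columns
        assert hits >= int(0.8 * n_rep)


class TestPsiRecovery:
    def test_trace_recovered_within_25_percent(self):
        psi_true = 0.01 * np.eye(3)
        traces = []
        for seed in range(40):
            rng = np.random.default_rng(2000 + seed)
            reduced = []
            for i in range(15):
                b = rng.multivariate_normal(np.zeros(3), psi_true)
                for label in SCHEME.labels:
                    S = np.eye(3) * rng.uniform(0.002, 0.006)
                    y = rng.multivariate_normal(np.array([0.2, 0.4, 0.8]) + b, S)
                    reduced.append(
                        ReducedAssociation(f"c{i}", label, y, S, 18.0)
                    )
            m = fit_mvmeta(reduced, None, SCHEME, year_spline=False)
            traces.append(np.trace(m.psi))
        med = float(np.median(traces))
        assert abs(med - 0.03) / 0.03 < 0.25


class TestRandomSlopes:
    def test_random_time_structure_fits(self):
        reduced, meta = simulate_reduced(12)
        m = fit_mvmeta(reduced, meta, SCHEME, predictors=("le",),
                       random_time=True)
        assert m.psi.shape == (6, 6)
        assert np.all(np.linalg.eigvalsh(m.psi) > -1e-10)
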