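import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import curve_fit, minimize

from tgios.tgi_model import (
    FitSettings,
    PopulationTGIFit,
    TGIIndividualParams,
    eta_shrinkage,
    fit_population,
    gof_diagnostics,
    marginal_loglik,
    nadir_time,
    ts_model,
)

TABLE_PARAMS = TGIIndividualParams(ts0=57.0, kg=0.00196, ks=0.0342)


def adaptive_gh_loglik(tumor, theta, omega2, sigma2, nodes=25):
    """Independent oracle: adaptive Gauss-Hermite marginal log-likelihood.

    Mode located by Nelder-Mead + BFGS (scipy, independent of the package's
    Newton solver); curvature by central differences; tensor-product GH
    quadrature centered and scaled at the mode.
    """
    x, w = hermgauss(nodes)
    total = 0.0
    for _, g in tumor.groupby("subject_id"):
        sfx = "treatment" if g["arm"].iloc[0] == "treatment" else "control"
        t = g["time_weeks"].to_numpy()
        y = g["sld_mm"].to_numpy()
        o = np.array([omega2["ts0"], omega2[f"kg_{sfx}"], omega2[f"ks_{sfx}"]])
        typ = np.array([theta["ts0"], theta[f"kg_{sfx}"], theta[f"ks_{sfx}"]])

        def f_of(eta):
            ts0, kg, ks = typ * np.exp(eta)
            return np.where(
                t < 0,
                ts0 * np.exp(kg * t),
                ts0 * (np.exp(-ks * t) + np.exp(np.clip(kg * t, -60, 60)) - 1.0),
            )

        def negjoint(eta):
            r = y - f_of(eta)
            return 0.5 * np.sum(r * r) / sigma2 + 0.5 * np.sum(eta * eta / o)

        res = minimize(negjoint, np.zeros(3), method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 10000})
        res = minimize(negjoint, res.x, method="BFGS", options={"gtol": 1e-10})
        mode = res.x
        h = 1e-4
        H = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                ei = np.zeros(3); ej = np.zeros(3)
                ei[i] = h; ej[j] = h
                H[i, j] = (
                    negjoint(mode + ei + ej) - negjoint(mode + ei - ej)
                    - negjoint(mode - ei + ej) + negjoint(mode - ei - ej)
                ) / (4 * h * h)
        C = np.linalg.inv(H)
        L = np.linalg.cholesky(C)
        E = np.array(np.meshgrid(x, x, x, indexing="ij")).reshape(3, -1)
        W = (w[:, None, None] * w[None, :, None] * w[None, None, :]).ravel()
        pts = mode[:, None] + np.sqrt(2.0) * (L @ E)
        vals = np.array([-negjoint(pts[:, m]) for m in range(pts.shape[1])])
        vals += np.sum(E**2, axis=0)
        c = vals.max()
        logint = c + np.log(np.sum(W * np.exp(vals - c)))
        logint += 0.5 * np.log(np.linalg.det(2 * C))
        total += (
            -0.5 * len(t) * np.log(2 * np.pi * sigma2)
            - 0.5 * np.sum(np.log(2 * np.pi * o))
            + logint
        )
    return total


def _simulate_subjects(theta, omega2, sigma2, visits, arms, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for i, arm in enumerate(arms):
        sfx = "treatment" if arm == "treatment" else "control"
        kg = theta[f"kg_{sfx}"] * np.exp(np.sqrt(omega2[f"kg_{sfx}"]) * rng.standard_normal())
        ks = theta[f"ks_{sfx}"] * np.exp(np.sqrt(omega2[f"ks_{sfx}"]) * rng.standard_normal())
        ts0 = theta["ts0"] * np.exp(np.sqrt(omega2["ts0"]) * rng.standard_normal())
        f = ts_model(visits, (ts0, kg, ks))
        y = f + np.sqrt(sigma2) * rng.standard_normal(len(visits))
        for t, yy in zip(visits, y):
            rows.append((f"S{i}", arm, float(t), float(yy)))
    return pd.DataFrame(rows, columns=["subject_id", "arm", "time_weeks", "sld_mm"])


class TestStructuralModel:
    def test_value_at_zero_is_ts0(self):
        assert ts_model(0.0, TABLE_PARAMS) == pytest.approx(57.0)

    def test_on_treatment_example(self):
        # independent scalar evaluation of the two-exponential form
        assert ts_model(8.0, TABLE_PARAMS) == pytest.approx(44.25707117484209)

    def test_pre_treatment_example_ignores_ks(self):
        v = ts_model(-4.0, TABLE_PARAMS)
        assert v == pytest.approx(56.55486720060086)
        other_ks = TGIIndividualParams(ts0=57.0, kg=0.00196, ks=0.9)
        assert ts_model(-4.0, other_ks) == pytest.approx(v)

    @given(
        st.floats(min_value=1.0, max_value=200.0),
        st.floats(min_value=1e-4, max_value=0.1),
        st.floats(min_value=1e-3, max_value=0.3),
    )
    @settings(derandomize=True, max_examples=50)
    def test_continuity_at_zero(self, ts0, kg, ks):
        p = TGIIndividualParams(ts0=ts0, kg=kg, ks=ks)
        eps = 1e-9
        assert ts_model(-eps, p) == pytest.approx(ts_model(eps, p), abs=1e-5)

    @given(
        st.floats(min_value=1e-4, max_value=0.01),
        st.floats(min_value=0.02, max_value=0.3),
    )
    @settings(derandomize=True, max_examples=30)
    def test_nadir_closed_form(self, kg, ks):
        # for KS > KG the curve dips then regrows; the minimum sits at
        # ln(KS/KG)/(KS+KG)
        p = TGIIndividualParams(ts0=60.0, kg=kg, ks=ks)
        t_star = nadir_time(p)
        tt = np.linspace(max(t_star - 5, 0.0), t_star + 5, 2001)
        numeric = tt[np.argmin(ts_model(tt, p))]
        assert numeric == pytest.approx(t_star, abs=0.01)

    def test_positive_params_required(self):
        with pytest.raises(ValueError):
            TGIIndividualParams(ts0=57.0, kg=0.0, ks=0.03)


class TestLikelihood:
    def test_laplace_matches_quadrature_small_variability(self):
        # near-Gaussian posterior regime: the Laplace integral should track
        # full adaptive quadrature very closely
        theta = {"kg_treatment": 0.002, "ks_treatment": 0.034,
                 "kg_control": 0.0044, "ks_control": 0.037, "ts0": 57.0}
        omega2 = {k: 0.0025 for k in theta}
        sigma2 = 0.25
        visits = np.arange(0, 8.0 * 21, 8.0)
        tumor = _simulate_subjects(theta, omega2, sigma2, visits,
                                   ["treatment", "control", "treatment"], seed=42)
        oracle = adaptive_gh_loglik(tumor, theta, omega2, sigma2)
        laplace = marginal_loglik(tumor, theta, omega2, sigma2)
        assert laplace == pytest.approx(oracle, abs=1e-3)

    def test_two_subject_instance(self):
        theta = {"kg_treatment": 0.002, "ks_treatment": 0.034,
                 "kg_control": 0.0044, "ks_control": 0.037, "ts0": 57.0}
        omega2 = {k: 0.0025 for k in theta}
        sigma2 = 1.0
        visits = np.arange(0, 8.0 * 11, 8.0)
        tumor = _simulate_subjects(theta, omega2, sigma2, visits,
                                   ["treatment", "control"], seed=5)
        oracle = adaptive_gh_loglik(tumor, theta, omega2, sigma2)
        laplace = marginal_loglik(tumor, theta, omega2, sigma2)
        assert laplace == pytest.approx(oracle, abs=1e-3)


class TestShrinkage:
    def test_no_shrinkage_when_sd_matches_omega(self, rng):
        etas = rng.standard_normal(2000) * 0.5
        omega2 = np.var(etas, ddof=1)  # SD(eta) == sqrt(omega2) by construction
        assert eta_shrinkage(etas, omega2) == pytest.approx(0.0, abs=1e-9)

    def test_identical_ebes_give_total_shrinkage(self):
        assert eta_shrinkage(np.zeros(10), 0.5) == pytest.approx(100.0)

    def test_zero_variance_signalled(self):
        with pytest.raises(ValueError):
            eta_shrinkage(np.array([0.1, -0.1]), 0.0)


class TestPopulationFit:
    def test_single_subject_reduces_to_nls(self):
        p_true = (60.0, 0.004, 0.05)
        visits = np.arange(0, 81, 8.0)
        rng = np.random.default_rng(0)
        y = ts_model(visits, p_true) + 2.0 * rng.standard_normal(len(visits))
        tumor = pd.DataFrame({
            "subject_id": "only", "arm": "treatment",
            "time_weeks": visits, "sld_mm": y,
        })
        fit = fit_population(tumor, FitSettings(fix_omega2_zero=True))

        def model(t, ts0, kg, ks):
            return ts0 * (np.exp(-ks * t) + np.exp(kg * t) - 1.0)

        popt, _ = curve_fit(model, visits, y, p0=[55.0, 0.003, 0.04],
                            maxfev=20000)
        assert fit.theta["ts0"] == pytest.approx(popt[0], rel=1e-3)
        assert fit.theta["kg_treatment"] == pytest.approx(popt[1], rel=1e-2)
        assert fit.theta["ks_treatment"] == pytest.approx(popt[2], rel=1e-2)

    def test_degenerate_constant_sld_flagged(self):
        tumor = pd.DataFrame({
            "subject_id": np.repeat(["a", "b"], 3),
            "arm": "treatment",
            "time_weeks": [0.0, 8.0, 16.0] * 2,
            "sld_mm": 50.0,
        })
        with pytest.raises(ValueError, match="degenerate"):
            fit_population(tumor)

    def test_small_fit_smoke_and_ebe_shapes(self):
        theta = {"kg_treatment": 0.003, "ks_treatment": 0.04,
                 "kg_control": 0.005, "ks_control": 0.04, "ts0": 55.0}
        omega2 = {k: 0.2 for k in theta}
        visits = np.arange(0, 81, 8.0)
        arms = ["treatment", "control"] * 15
        tumor = _simulate_subjects(theta, omega2, 9.0, visits, arms, seed=2)
        fit = fit_population(tumor, FitSettings(compute_rse=False))
        assert fit.converged
        assert len(fit.ebes) == 30
        assert (fit.ebes[["ts0", "kg", "ks"]] > 0).all().all()
        assert np.allclose(fit.ebes["log_kg"], np.log(fit.ebes["kg"]))
        # optimum cannot be worse than the generating values
        ll_truth = marginal_loglik(tumor, theta, omega2, 9.0)
        assert fit.loglik >= ll_truth - 1e-3

    def test_serialization_round_trip(self, tmp_path):
        theta = {"kg_treatment": 0.003, "ks_treatment": 0.04,
                 "kg_control": 0.005, "ks_control": 0.04, "ts0": 55.0}
        omega2 = {k: 0.2 for k in theta}
        visits = np.arange(0, 49, 8.0)
        tumor = _simulate_subjects(theta, omega2, 9.0, visits,
                                   ["treatment", "control"] * 4, seed=3)
        fit = fit_population(tumor, FitSettings(compute_rse=False))
        path = tmp_path / "fit.json"
        fit.to_json(path)
        back = PopulationTGIFit.from_json(path)
        assert back.theta == pytest.approx(fit.theta)
        assert back.sigma2 == pytest.approx(fit.sigma2)
        pd.testing.assert_frame_equal(
            back.ebes, fit.ebes, check_dtype=False, check_exact=False
        )


class TestGOF:
    def test_noise_free_data_at_ebes_has_correlation_one(self):
        theta = {"kg_treatment": 0.002, "ks_treatment": 0.034,
                 "kg_control": 0.0044, "ks_control": 0.037, "ts0": 57.0}
        visits = np.arange(0, 81, 8.0)
        ebes = pd.DataFrame({
            "subject_id": ["a", "b"],
            "arm": ["treatment", "control"],
            "ts0": [50.0, 70.0],
            "kg": [0.001, 0.006],
            "ks": [0.05, 0.02],
        })
        ebes["log_kg"] = np.log(ebes["kg"])
        rows = []
        for _, e in ebes.iterrows():
            y = ts_model(visits, (e["ts0"], e["kg"], e["ks"]))
            for t, yy in zip(visits, y):
                rows.append((e["subject_id"], e["arm"], t, yy))
        tumor = pd.DataFrame(rows, columns=["subject_id", "arm", "time_weeks", "sld_mm"])
        fit = PopulationTGIFit(
            theta=theta, omega2={k: 0.1 for k in theta}, sigma2=1.0,
            rse={}, shrinkage={}, ebes=ebes, loglik=0.0, converged=True,
            n_subjects=2,
        )
        table, summary = gof_diagnostics(fit, tumor)
        assert summary["corr_obs_ipred"] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(table["iresidual"], 0.0, atol=1e-9)

    def test_residual_sd_tracks_generating_sigma(self):
        theta = {"kg_treatment": 0.003, "ks_treatment": 0.04,
                 "kg_control": 0.005, "ks_control": 0.04, "ts0": 55.0}
        omega2 = {k: 0.2 for k in theta}
        sigma2 = 25.0
        visits = np.arange(0, 81, 8.0)
        tumor = _simulate_subjects(theta, omega2, sigma2, visits,
                                   ["treatment", "control"] * 20, seed=9)
        fit = fit_population(tumor, FitSettings(compute_rse=False))
        table, summary = gof_diagnostics(fit, tumor)
        assert summary["corr_obs_ipred"] > 0.95
        assert summary["iresidual_sd"] == pytest.approx(np.sqrt(sigma2), rel=0.25)
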