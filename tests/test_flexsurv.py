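import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import mmtraj as mt
from mmtraj.flexsurv import RCSpline, SurvivalError, spline_from_quantiles


def sim_two_group(rng, n, base_rate, log_hr, cens):
    grp = rng.integers(0, 2, n)
    rate = base_rate * np.exp(log_hr * grp)
    t = rng.exponential(1 / rate)
    return pd.DataFrame(
        {
            "start": 0.0,
            "stop": np.minimum(t, cens),
            "event": (t < cens).astype(int),
            "cluster": grp + 1,
        }
    )


def test_rcs_basis_is_smooth_at_knots():
    sp = RCSpline((0.0, 0.5, 1.2, 2.0))
    for k in sp.knots[1:-1]:
        lo, hi = sp.basis(np.array([k - 1e-7])), sp.basis(np.array([k + 1e-7]))
        np.testing.assert_allclose(lo, hi, atol=1e-5)
        dlo, dhi = sp.deriv(np.array([k - 1e-7])), sp.deriv(np.array([k + 1e-7]))
        np.testing.assert_allclose(dlo, dhi, atol=1e-4)


def test_rcs_linear_beyond_boundaries():
    sp = RCSpline((0.0, 0.5, 1.0))
    d_left = sp.deriv(np.array([-5.0, -2.0]))
    d_right = sp.deriv(np.array([3.0, 8.0]))
    np.testing.assert_allclose(d_left[0], d_left[1], atol=1e-12)
    np.testing.assert_allclose(d_right[0], d_right[1], atol=1e-12)


def test_deriv_matches_finite_difference():
    sp = spline_from_quantiles(np.linspace(0.1, 3.0, 100), df=4)
    u = np.linspace(0.2, 2.8, 17)
    h = 1e-6
    fd = (sp.basis(u + h) - sp.basis(u - h)) / (2 * h)
    np.testing.assert_allclose(sp.deriv(u), fd, atol=1e-5)


def test_recovers_planted_log_hazard_ratio():
    rng = np.random.default_rng(3)
    eps = sim_two_group(rng, 3000, 0.1, 1.0, 15.0)
    fit = mt.fit_flexible_parametric(eps, spline_df=6, covariates=("cluster",))
    beta = fit.beta[0]
    se = np.sqrt(np.diag(fit.cov))[-1]
    assert abs(beta - 1.0) < 2 * se


def test_null_data_gives_null_effect():
    rng = np.random.default_rng(4)
    eps = sim_two_group(rng, 2000, 0.1, 0.0, 15.0)
    fit = mt.fit_flexible_parametric(eps, spline_df=4, covariates=("cluster",))
    beta = fit.beta[0]
    se = np.sqrt(np.diag(fit.cov))[-1]
    assert abs(beta) < 2 * se


def test_fitted_survival_matches_exponential_truth():
    rng = np.random.default_rng(5)
    lam = 0.1
    t = rng.exponential(1 / lam, 3000)
    cens = 15.0
    eps = pd.DataFrame(
        {"start": 0.0, "stop": np.minimum(t, cens), "event": (t < cens).astype(int)}
    )
    fit = mt.fit_flexible_parametric(eps, spline_df=6, covariates=())
    med = np.log(2) / lam
    s_hat = fit.predict_survival(eps.iloc[:1], [med])[0, 0]
    assert abs(s_hat - 0.5) < 0.02


def test_km_and_flexible_fit_agree_at_deciles():
    rng = np.random.default_rng(6)
    lam = 0.12
    t = rng.exponential(1 / lam, 3000)
    cens = 12.0
    tt, d = np.minimum(t, cens), (t < cens).astype(int)
    eps = pd.DataFrame({"start": 0.0, "stop": tt, "event": d})
    fit = mt.fit_flexible_parametric(eps, spline_df=6, covariates=())
    curve = mt.km_fit(tt, d)
    deciles = np.quantile(tt, np.linspace(0.1, 0.9, 9))
    for q in deciles:
        s_model = fit.predict_survival(eps.iloc[:1], [q])[0, 0]
        assert abs(s_model - curve.s(q)) < 0.03


def test_delayed_entry_episodes_reproduce_single_row_fit():
    # splitting a subject's time into yearly left-truncated episodes must not
    # change the likelihood, hence not the estimate
    rng = np.random.default_rng(7)
    whole = sim_two_group(rng, 1500, 0.15, 0.8, 10.0)
    rows = []
    for r in whole.itertuples(index=False):
        y = 0
        while y < r.stop:
            stop = min(y + 1.0, r.stop)
            rows.append(
                {"start": float(y), "stop": stop,
                 "event": int(r.event and stop == r.stop), "cluster": r.cluster}
            )
            y += 1
    split = pd.DataFrame(rows)
    f_whole = mt.fit_flexible_parametric(whole, spline_df=3, covariates=("cluster",))
    f_split = mt.fit_flexible_parametric(split, spline_df=3, covariates=("cluster",))
    np.testing.assert_allclose(f_whole.beta, f_split.beta, atol=1e-4)
    np.testing.assert_allclose(f_whole.loglik, f_split.loglik, rtol=1e-8)


def test_hazard_ratio_table_hand_arithmetic():
    rng = np.random.default_rng(8)
    eps = sim_two_group(rng, 1000, 0.1, 0.7, 15.0)
    fit = mt.fit_flexible_parametric(eps, spline_df=2, covariates=("cluster",))
    hr = mt.hazard_ratios(fit)
    assert hr.loc[0, "hr"] == 1.0
    beta = fit.beta[0]
    se = np.sqrt(np.diag(fit.cov))[-1]
    assert hr.loc[1, "hr"] == pytest.approx(np.exp(beta))
    assert hr.loc[1, "ci_low"] == pytest.approx(np.exp(beta - 1.959963984540054 * se))


def test_no_events_is_error():
    eps = pd.DataFrame({"start": [0.0], "stop": [1.0], "event": [0]})
    with pytest.raises(SurvivalError):
        mt.fit_flexible_parametric(eps, spline_df=2, covariates=())


def test_standardized_survival_properties():
    rng = np.random.default_rng(9)
    eps = sim_two_group(rng, 1500, 0.1, 0.9, 15.0)
    eps["age_at_index"] = rng.normal(70, 8, len(eps))
    fit = mt.fit_flexible_parametric(
        eps, spline_df=3, covariates=("cluster", "age_at_index"), age_spline_df=3
    )
    times = np.array([1.0, 2.0, 5.0, 8.0])
    one = mt.standardized_survival(fit, eps.iloc[:1], cluster=2, times=times)
    direct = fit.predict_survival(eps.iloc[:1].assign(cluster=2), times)[0]
    np.testing.assert_allclose(one["s"], direct, rtol=1e-10)
    pop = mt.standardized_survival(fit, eps.iloc[:300], cluster=1, times=times)
    assert (np.diff(pop["s"]) <= 0).all()  # monotone non-increasing
    assert ((pop["ci_low"] <= pop["s"]) & (pop["s"] <= pop["ci_high"])).all()


def test_time_dependent_effects_fit_runs_and_nests_proportional_model():
    rng = np.random.default_rng(10)
    eps = sim_two_group(rng, 1200, 0.12, 0.8, 12.0)
    ph = mt.fit_flexible_parametric(eps, spline_df=3, covariates=("cluster",))
    tvc = mt.fit_flexible_parametric(
        eps, spline_df=3, covariates=("cluster",), tvc=("cluster",), tvc_df=2
    )
    assert tvc.loglik >= ph.loglik - 1e-6  # richer model can't fit worse


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_against_r_flexsurvspline_oracle(tmp_path):
    # identical model (log cumulative hazard scale, one interior knot at the
    # median uncensored log time): coefficients and log-likelihood must agree
    rng = np.random.default_rng(42)
    n = 1000
    grp = rng.integers(0, 2, n)
    rate = 0.12 * np.exp(0.7 * grp)
    t = rng.exponential(1 / rate)
    cens = 12.0
    tt, d = np.minimum(t, cens), (t < cens).astype(int)
    csv = tmp_path / "data.csv"
    pd.DataFrame({"time": tt, "event": d, "group": grp}).to_csv(csv, index=False)

    eps = pd.DataFrame({"start": 0.0, "stop": tt, "event": d, "cluster": grp + 1})
    fit = mt.fit_flexible_parametric(eps, spline_df=2, covariates=("cluster",))

    script = (
        'suppressMessages(library(flexsurv));'
        f'd <- read.csv("{csv}");'
        'f <- flexsurvspline(Surv(time, event) ~ group, data=d, k=1, scale="hazard");'
        'cat(coef(f)[["group"]], f$loglik)'
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    beta_r, ll_r = map(float, out.stdout.split())
    assert fit.beta[0] == pytest.approx(beta_r, abs=1e-3)
    assert fit.loglik == pytest.approx(ll_r, abs=1e-2)
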