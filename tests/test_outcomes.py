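import numpy as np
import pandas as pd
import pytest

import mmtraj as mt
from mmtraj.flexsurv import SurvivalError


def make_patient(pid, fu_years, died, index="2010-01-01"):
    idx = pd.Timestamp(index)
    return {
        "patient_id": pid,
        "index_date": idx,
        "age_at_index": 70.0,
        "sex": "female",
        "deprivation_quintile": 2,
        "rurality": "urban",
        "end_date": idx + pd.Timedelta(days=round(fu_years * 365.25)),
        "end_reason": "death" if died else "censored",
    }


def membership_rows(pid, clusters):
    return pd.DataFrame(
        {
            "patient_id": pid,
            "year_offset": np.arange(len(clusters)),
            "dominant_cluster": clusters,
        }
    )


def test_episode_split_hand_case():
    patients = pd.DataFrame([make_patient("p1", 2.5, died=True)])
    eps = mt.episode_split(membership_rows("p1", [3, 3, 1]), patients)
    fu = (patients.loc[0, "end_date"] - patients.loc[0, "index_date"]).days / 365.25
    expected = [(0.0, 1.0, 0, 3), (1.0, 2.0, 0, 3), (2.0, fu, 1, 1)]
    got = list(zip(eps["start"], eps["stop"], eps["event"], eps["cluster"]))
    assert got == expected


def test_episode_split_censored_single_year():
    patients = pd.DataFrame([make_patient("p1", 1.0, died=False)])
    eps = mt.episode_split(membership_rows("p1", [2]), patients)
    assert len(eps) == 1 and eps.loc[0, "event"] == 0


def test_episode_person_time_conservation_exact(planted_cohort, planted_matrix, planted_fit):
    cohort, _, _ = planted_cohort
    m = mt.yearly_membership(planted_fit.W, planted_matrix.row_index)
    eps = mt.episode_split(m, cohort.patients)
    per_patient = eps.assign(dur=eps["stop"] - eps["start"]).groupby("patient_id")["dur"].sum()
    fu = cohort.follow_up_years()
    # telescoping sums make conservation exact in floating point
    assert (per_patient == fu.loc[per_patient.index]).all()
    at_most_one_death = eps.groupby("patient_id")["event"].sum()
    assert (at_most_one_death <= 1).all()
    last = eps.groupby("patient_id").tail(1).set_index("patient_id")["event"]
    died = (cohort.patients.set_index("patient_id")["end_reason"] == "death").astype(int)
    assert (last == died.loc[last.index]).all()


def test_episode_split_gap_in_coverage_is_error():
    patients = pd.DataFrame([make_patient("p1", 3.0, died=False)])
    m = membership_rows("p1", [1, 1])  # missing year 2
    with pytest.raises(SurvivalError, match="cover"):
        mt.episode_split(m, patients)


def test_km_hand_product_limit():
    curve = mt.km_fit([1.0, 2.0, 3.0], [1, 0, 1])
    assert curve.s(1.0) == pytest.approx(2 / 3)
    assert curve.s(2.5) == pytest.approx(2 / 3)
    assert curve.s(3.0) == pytest.approx(0.0)


def test_km_all_censored_stays_at_one():
    curve = mt.km_fit([1.0, 2.0, 5.0], [0, 0, 0])
    assert curve.s(5.0) == 1.0


def test_km_empty_input_is_error():
    with pytest.raises(SurvivalError):
        mt.km_fit([], [])


def test_km_matches_exponential_survival():
    rng = np.random.default_rng(12)
    lam, n = 0.1, 4000
    t = rng.exponential(1 / lam, n)
    cens = 15.0
    curve = mt.km_fit(np.minimum(t, cens), (t < cens).astype(int))
    s_true = np.exp(-lam * 5)
    se = np.sqrt(s_true * (1 - s_true) / n)
    assert abs(curve.s(5.0) - s_true) < 3 * se


def test_rmst_degenerate_cases():
    all_cens = mt.km_fit([2.0, 3.0], [0, 0])
    assert mt.rmst(all_cens, 5.0) == pytest.approx(5.0)  # S=1 throughout
    single = mt.km_fit([2.0], [1])
    assert mt.rmst(single, 5.0) == pytest.approx(2.0)
    with pytest.raises(SurvivalError):
        mt.rmst(single, 0.0)


def test_rmst_matches_closed_form_exponential():
    rng = np.random.default_rng(13)
    lam, n, tau = 0.1, 4000, 10.0
    t = rng.exponential(1 / lam, n)
    cens = 15.0
    curve = mt.km_fit(np.minimum(t, cens), (t < cens).astype(int))
    truth = (1 - np.exp(-lam * tau)) / lam  # 6.3212
    # MC SE of mean(min(T, tau)): sd(min(T, tau)) / sqrt(n)
    var = 2 * (1 - np.exp(-lam * tau) * (1 + lam * tau)) / lam**2 - truth**2
    se = np.sqrt(var / n)
    assert abs(mt.rmst(curve, tau) - truth) < 3 * se
    # half-step continuity correction moves the estimate only slightly
    assert abs(mt.rmst(curve, tau, continuity="half") - mt.rmst(curve, tau)) < 0.05


def test_rmst_per_cluster_orders_planted_hazards():
    cfg = mt.SyntheticConfig(n_patients=1500, k_true=3,
                             hazard_ratios=(1.0, 2.5, 6.0), seed=8)
    cohort, truth, _ = mt.generate_cohort(cfg)
    traj = truth.to_frame().rename(columns={"true_cluster": "predominant_trajectory"})
    tab = mt.rmst_per_cluster(traj, cohort.patients)
    r = tab.sort_values("cluster")["rmst"].to_numpy()
    assert r[0] > r[1] > r[2]


def test_multinomial_probabilities_sum_to_one():
    rng = np.random.default_rng(21)
    n = 500
    data = pd.DataFrame(
        {
            "dominant_cluster": rng.integers(1, 4, n),
            "age_in_year": rng.normal(70, 8, n),
            "sex": rng.choice(["female", "male"], n),
        }
    )
    res, table = mt.fit_multinomial(data, covariates=("age_in_year", "sex"))
    probs = res.predict()
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-10)
    assert {"coef", "se", "rrr", "ci_low", "ci_high"} <= set(table.columns)


def test_multinomial_single_label_is_error():
    data = pd.DataFrame({"dominant_cluster": [1] * 10, "age_in_year": range(10)})
    with pytest.raises(SurvivalError):
        mt.fit_multinomial(data, covariates=("age_in_year",))
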