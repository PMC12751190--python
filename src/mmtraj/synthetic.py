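"""Synthetic electronic-health-record cohort generator with planted structure.

The generator emulates the shape of a post-index-event diagnosis history:
each patient has an index event (time zero of follow-up), a set of chronic
conditions accrued before and after the index date, recurrent acute events,
and a death or administrative-censoring time.  A latent cluster label is
planted per patient: the label selects a disjoint *signature* set of
conditions that occur at elevated rates, and multiplies the patient's
mortality hazard.  Demographics (age, sex) shift cluster assignment through
a multinomial-logit model, so downstream determinant models also have a
recoverable truth.

Every quantity a downstream stage estimates — the signature condition sets,
the per-cluster hazard ratios, the demographic coefficients, the per-patient
labels — is returned in :class:`SyntheticTruth`.

Survival is exponential per cluster, which gives closed-form medians and
restricted means for use as test oracles.  Chronic conditions produce at
most one event per (patient, condition); acute conditions may recur across
years.  Events are dated mid-year since the person-time matrix only resolves
whole years of follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Cohort, CohortError, ConditionDef, ConditionDictionary, DAYS_PER_YEAR

#: cohort-level demographics: median age at index ~72, ~40.6% female,
#: roughly two-thirds urban — the scale of a national MI cohort.
AGE_MEAN = 72.0
AGE_SD = 10.0
AGE_MIN, AGE_MAX = 30.0, 99.0
P_FEMALE = 0.406
RURALITY_PROBS = (0.68, 0.18, 0.14)  # urban, town_fringe, rural
INDEX_YEARS = (2005, 2019)


@dataclass
class SyntheticConfig:
    """Parameters of the planted-structure cohort.

    Defaults define the package's reference study conditions: 2000 patients,
    four well-separated clusters of eight signature conditions each
    (six chronic + two acute), modest background diagnosis noise, and
    cluster hazard ratios spanning 1–4 over a 15-year horizon.
    """

    n_patients: int = 2000
    k_true: int = 4
    n_chronic: int = 40
    n_acute: int = 16
    signature_size: int = 8  # per cluster; 3/4 chronic, 1/4 acute
    p_signature_chronic: float = 0.25  # per-year first-diagnosis probability
    p_signature_acute: float = 0.30  # per-year occurrence probability
    p_background: float = 0.02  # per-year probability, any non-signature condition
    p_pre_index_chronic: float = 0.30  # pre-index seeding of signature chronics
    baseline_hazard: float = 0.05  # deaths per person-year, cluster 1
    hazard_ratios: tuple[float, ...] = (1.0, 1.5, 2.5, 4.0)
    admin_horizon: float = 15.0  # years
    # log-odds of cluster c vs cluster 1 per unit of (z_age, female);
    # row 0 is the reference cluster and must be zero.
    demographic_effect: np.ndarray | None = None
    seed: int = 12345

    def __post_init__(self) -> None:
        if self.demographic_effect is None:
            eff = np.zeros((self.k_true, 2))
            # older patients drift to later clusters, sex effects alternate
            for c in range(1, self.k_true):
                eff[c] = (0.4 * c / max(self.k_true - 1, 1), 0.5 * (-1) ** c)
            self.demographic_effect = eff
        self.demographic_effect = np.asarray(self.demographic_effect, dtype=float)
        probs = (
            self.p_signature_chronic,
            self.p_signature_acute,
            self.p_background,
            self.p_pre_index_chronic,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise CohortError("all event probabilities must lie in [0, 1]")
        hr = np.asarray(self.hazard_ratios, dtype=float)
        if len(hr) != self.k_true:
            raise CohortError("hazard_ratios must have length k_true")
        if hr[0] != 1.0 or (hr <= 0).any():
            raise CohortError("hazard_ratios must be positive with first element 1")
        if self.demographic_effect.shape != (self.k_true, 2):
            raise CohortError("demographic_effect must have shape (k_true, 2)")
        if np.any(self.demographic_effect[0] != 0.0):
            raise CohortError("demographic_effect row for cluster 1 must be zero")
        n_sig_chronic, n_sig_acute = self.signature_split()
        if self.k_true * n_sig_chronic > self.n_chronic:
            raise CohortError("not enough chronic conditions for disjoint signatures")
        if self.k_true * n_sig_acute > self.n_acute:
            raise CohortError("not enough acute conditions for disjoint signatures")

    def signature_split(self) -> tuple[int, int]:
        """Number of (chronic, acute) conditions in each cluster signature."""
        n_acute = max(self.signature_size // 4, 1) if self.signature_size > 1 else 0
        return self.signature_size - n_acute, n_acute


@dataclass
class SyntheticTruth:
    labels: pd.Series  # patient_id -> true cluster (1..k_true)
    signatures: dict[int, set[str]]  # cluster -> condition_id set
    hazard_ratios: np.ndarray
    demographic_effect: np.ndarray
    death_times: pd.Series = field(default=None)  # latent, pre-censoring

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient_id": self.labels.index, "true_cluster": self.labels.to_numpy()}
        )


def make_dictionary(n_chronic: int, n_acute: int) -> ConditionDictionary:
    """Small synthetic condition dictionary: chronic ids first, then acute."""
    conds = [ConditionDef(f"c{i + 1:03d}", f"chronic condition {i + 1}", "chronic") for i in range(n_chronic)]
    conds += [ConditionDef(f"a{i + 1:03d}", f"acute condition {i + 1}", "acute") for i in range(n_acute)]
    return ConditionDictionary(conds)


def _draw_ages(rng: np.random.Generator, n: int) -> np.ndarray:
    ages = rng.normal(AGE_MEAN, AGE_SD, size=2 * n + 16)
    ages = ages[(ages >= AGE_MIN) & (ages <= AGE_MAX)]
    while len(ages) < n:  # pragma: no cover - truncation rarely this severe
        extra = rng.normal(AGE_MEAN, AGE_SD, size=n)
        ages = np.concatenate([ages, extra[(extra >= AGE_MIN) & (extra <= AGE_MAX)]])
    return ages[:n]


def generate_cohort(config: SyntheticConfig) -> tuple[Cohort, SyntheticTruth, ConditionDictionary]:
    """Simulate a cohort with planted clusters; returns (cohort, truth, dictionary)."""
    rng = np.random.default_rng(config.seed)
    k = config.k_true
    dictionary = make_dictionary(config.n_chronic, config.n_acute)
    chronic_ids = np.array(dictionary.chronic_ids)
    acute_ids = np.array(dictionary.acute_ids)

    n_sig_c, n_sig_a = config.signature_split()
    signatures: dict[int, set[str]] = {}
    sig_chronic: dict[int, np.ndarray] = {}
    sig_acute: dict[int, np.ndarray] = {}
    for c in range(k):
        sc = chronic_ids[c * n_sig_c : (c + 1) * n_sig_c]
        sa = acute_ids[c * n_sig_a : (c + 1) * n_sig_a]
        sig_chronic[c], sig_acute[c] = sc, sa
        signatures[c + 1] = set(sc) | set(sa)

    n = config.n_patients
    ages = _draw_ages(rng, n)
    female = rng.random(n) < P_FEMALE
    z_age = (ages - AGE_MEAN) / AGE_SD

    # multinomial-logit cluster assignment from demographics
    design = np.column_stack([z_age, female.astype(float)])  # n x 2
    logits = design @ config.demographic_effect.T  # n x k
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(n)
    labels = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)  # 0-based

    hr = np.asarray(config.hazard_ratios, dtype=float)
    rates = config.baseline_hazard * hr[labels]
    death_t = rng.exponential(1.0 / rates)
    fu = np.minimum(death_t, config.admin_horizon)
    died = death_t < config.admin_horizon
    # a death at exactly time zero would leave no person-time; floor at ~3 days
    fu = np.maximum(fu, 0.01)

    index_year = rng.integers(INDEX_YEARS[0], INDEX_YEARS[1] + 1, size=n)
    index_doy = rng.integers(0, 365, size=n)
    index_dates = pd.to_datetime(
        {"year": index_year, "month": 1, "day": 1}
    ) + pd.to_timedelta(index_doy, unit="D")
    end_dates = index_dates + pd.to_timedelta(np.round(fu * DAYS_PER_YEAR).astype(int), unit="D")

    patient_ids = np.array([f"p{i + 1:05d}" for i in range(n)])
    patients = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "index_date": index_dates,
            "age_at_index": np.round(ages, 1),
            "sex": np.where(female, "female", "male"),
            "deprivation_quintile": rng.integers(1, 6, size=n),
            "rurality": rng.choice(
                ["urban", "town_fringe", "rural"], size=n, p=RURALITY_PROBS
            ),
            "end_date": end_dates,
            "end_reason": np.where(died, "death", "censored"),
        }
    )

    # follow-up as seen through the stored dates (rounding-consistent)
    fu_years = (end_dates - index_dates).dt.days.to_numpy() / DAYS_PER_YEAR
    n_years = np.maximum(np.ceil(fu_years - 1e-9).astype(int), 1)

    bg_chronic = {c: chronic_ids[~np.isin(chronic_ids, sig_chronic[c])] for c in range(k)}
    bg_acute = {c: acute_ids[~np.isin(acute_ids, sig_acute[c])] for c in range(k)}

    ev_pid: list[str] = []
    ev_cid: list[str] = []
    ev_off: list[float] = []  # years relative to index; mid-year placement

    for i in range(n):
        c = labels[i]
        pid = patient_ids[i]
        t_max = n_years[i]

        # pre-index chronic accrual: signature chronics seeded with one event
        # dated one year before index; background chronics at background rate
        pre_sig = sig_chronic[c][rng.random(n_sig_c) < config.p_pre_index_chronic]
        pre_bg = bg_chronic[c][rng.random(len(bg_chronic[c])) < config.p_background]
        diagnosed = set(pre_sig) | set(pre_bg)
        for cid in sorted(diagnosed):
            ev_pid.append(pid)
            ev_cid.append(cid)
            ev_off.append(-1.0)

        for y in range(t_max):
            mid = y + 0.5
            new_sig = sig_chronic[c][
                (rng.random(n_sig_c) < config.p_signature_chronic)
                & ~np.isin(sig_chronic[c], list(diagnosed))
            ]
            new_bg = bg_chronic[c][
                (rng.random(len(bg_chronic[c])) < config.p_background)
                & ~np.isin(bg_chronic[c], list(diagnosed))
            ]
            for cid in np.concatenate([new_sig, new_bg]):
                diagnosed.add(cid)
                ev_pid.append(pid)
                ev_cid.append(cid)
                ev_off.append(mid)
            # acute conditions recur: independent draw each year
            hits_sig = sig_acute[c][rng.random(n_sig_a) < config.p_signature_acute]
            hits_bg = bg_acute[c][rng.random(len(bg_acute[c])) < config.p_background]
            for cid in np.concatenate([hits_sig, hits_bg]):
                ev_pid.append(pid)
                ev_cid.append(cid)
                ev_off.append(mid)

    events = pd.DataFrame({"patient_id": ev_pid, "condition_id": ev_cid})
    idx_map = pd.Series(index_dates.to_numpy(), index=patient_ids)
    offsets = pd.to_timedelta(
        np.round(np.asarray(ev_off) * DAYS_PER_YEAR).astype(int), unit="D"
    )
    events["event_date"] = idx_map.loc[events["patient_id"]].to_numpy() + offsets
    # mid-year placement can overshoot a short final partial year; clamp to end
    end_map = pd.Series(end_dates.to_numpy(), index=patient_ids)
    ends = pd.to_datetime(end_map.loc[events["patient_id"]].to_numpy())
    events["event_date"] = np.minimum(events["event_date"].to_numpy(), ends.to_numpy())

    truth = SyntheticTruth(
        labels=pd.Series(labels + 1, index=patient_ids, name="true_cluster"),
        signatures=signatures,
        hazard_ratios=hr,
        demographic_effect=config.demographic_effect,
        death_times=pd.Series(death_t, index=patient_ids, name="death_time"),
    )
    return Cohort(patients=patients, events=events), truth, dictionary


def planted_membership_sets(truth: SyntheticTruth) -> dict[int, set[str]]:
    """Partition patient ids by true cluster label (for recovery scoring)."""
    out: dict[int, set[str]] = {}
    for pid, lab in truth.labels.items():
        out.setdefault(int(lab), set()).add(pid)
    return out


def noise_cohort(
    n_patients: int = 600,
    n_chronic: int = 30,
    n_acute: int = 10,
    p_event: float = 0.08,
    seed: int = 0,
) -> tuple[Cohort, ConditionDictionary]:
    """Cohort with no planted cluster structure: every condition occurs
    independently at the same rate.  Used to calibrate instability checks."""
    cfg = SyntheticConfig(
        n_patients=n_patients,
        k_true=1,
        n_chronic=n_chronic,
        n_acute=n_acute,
        signature_size=1,
        p_signature_chronic=p_event,
        p_signature_acute=p_event,
        p_background=p_event,
        p_pre_index_chronic=p_event,
        hazard_ratios=(1.0,),
        seed=seed,
    )
    cohort, _, dictionary = generate_cohort(cfg)
    return cohort, dictionary
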