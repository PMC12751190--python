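"""Trajectory-outcome association models.

Episode splitting turns yearly cluster memberships into a counting-process
table (one left-truncated episode per person-year carrying that year's
dominant cluster) for the flexible parametric survival model; Kaplan-Meier
curves and restricted mean survival time summarise crude survival per
trajectory; multinomial logistic regression relates person-year cluster
membership to sociodemographic covariates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .flexsurv import SurvivalError, Z_95
from .io import DAYS_PER_YEAR
from .matrix import year_count


def episode_split(memberships: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    """One episode per person-year [y, min(y+1, follow-up)) with covariates.

    ``memberships`` must cover every follow-up year of every patient
    (columns patient_id, year_offset, dominant_cluster); a gap is a hard
    error.  The death indicator sits on the final episode only.  Summed
    episode durations reproduce each patient's follow-up years exactly.
    """
    p = patients.set_index("patient_id")
    fu_years = (p["end_date"] - p["index_date"]).dt.days / DAYS_PER_YEAR

    m = memberships.sort_values(["patient_id", "year_offset"], kind="stable")
    rows = []
    for pid, g in m.groupby("patient_id", sort=False):
        fu = float(fu_years.loc[pid])
        t = year_count(fu)
        offsets = g["year_offset"].to_numpy()
        if len(offsets) != t or not np.array_equal(offsets, np.arange(t)):
            raise SurvivalError(
                f"patient {pid!r}: yearly membership does not cover follow-up "
                f"(expected years 0..{t - 1}, got {offsets.tolist()})"
            )
        died = p.loc[pid, "end_reason"] == "death"
        clusters = g["dominant_cluster"].to_numpy()
        for y in range(t):
            stop = min(y + 1.0, fu)
            rows.append(
                {
                    "patient_id": pid,
                    "start": float(y),
                    "stop": stop,
                    "event": int(died and y == t - 1),
                    "cluster": int(clusters[y]),
                    "age_at_index": p.loc[pid, "age_at_index"],
                    "sex": p.loc[pid, "sex"],
                    "index_year": int(pd.Timestamp(p.loc[pid, "index_date"]).year),
                    "deprivation_quintile": int(p.loc[pid, "deprivation_quintile"]),
                    "rurality": p.loc[pid, "rurality"],
                }
            )
    return pd.DataFrame(rows)


class KMCurve:
    """Product-limit survival curve (thin wrapper over lifelines)."""

    def __init__(self, times: np.ndarray, events: np.ndarray):
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=int)
        if len(times) == 0:
            raise SurvivalError("empty input to the Kaplan-Meier estimator")
        if (times <= 0).any():
            raise SurvivalError("survival times must be positive")
        self._kmf = KaplanMeierFitter()
        self._kmf.fit(times, events)
        sf = self._kmf.survival_function_
        self.grid = sf.index.to_numpy(dtype=float)
        self.survival = sf.iloc[:, 0].to_numpy(dtype=float)
        self.n = len(times)
        self.n_events = int(events.sum())
        self.max_time = float(times.max())

    def s(self, t: float) -> float:
        """S(t), right-continuous step function; S(0) = 1."""
        idx = np.searchsorted(self.grid, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.grid, "s": self.survival})


def km_fit(times: np.ndarray, events: np.ndarray) -> KMCurve:
    return KMCurve(times, events)


def rmst(curve: KMCurve, tau: float, continuity: str = "none") -> float:
    """Area under the KM step function from 0 to ``tau`` (years).

    Beyond the last observation the curve is extended flat.  With
    ``continuity="half"`` each drop contributes at the midpoint of the step
    (trapezoid between consecutive estimates) rather than fully after it.
    """
    if tau <= 0:
        raise SurvivalError("tau must be positive")
    grid = np.concatenate([[0.0], curve.grid, [np.inf]])
    surv = np.concatenate([[1.0], curve.survival, [curve.survival[-1]]])
    total = 0.0
    for left, right, s_left, s_right in zip(
        grid[:-1], grid[1:], surv[:-1], surv[1:]
    ):
        if left >= tau:
            break
        width = min(right, tau) - left
        if width <= 0:
            continue
        if continuity == "half" and right <= tau:
            total += width * 0.5 * (s_left + s_right)
        else:
            total += width * s_left
    return total


def rmst_per_cluster(
    trajectories: pd.DataFrame,
    patients: pd.DataFrame,
    tau: float | None = None,
    label_col: str = "predominant_trajectory",
) -> pd.DataFrame:
    """KM-based RMST for the patients following each trajectory.

    ``tau`` defaults to the maximum observed follow-up across the cohort.
    """
    p = patients.set_index("patient_id")
    fu = (p["end_date"] - p["index_date"]).dt.days / DAYS_PER_YEAR
    died = (p["end_reason"] == "death").astype(int)
    if tau is None:
        tau = float(fu.max())
    rows = []
    for lab in sorted(trajectories[label_col].unique()):
        pids = trajectories.loc[trajectories[label_col] == lab, "patient_id"]
        times = np.maximum(fu.loc[pids].to_numpy(), 1e-6)
        events = died.loc[pids].to_numpy()
        curve = km_fit(times, events)
        rows.append(
            {"cluster": int(lab), "rmst": rmst(curve, tau), "tau": tau, "n": len(pids)}
        )
    return pd.DataFrame(rows)


def fit_multinomial(
    data: pd.DataFrame,
    outcome_col: str = "dominant_cluster",
    covariates: tuple[str, ...] = (
        "age_in_year",
        "age_at_index",
        "sex",
        "index_year",
        "deprivation_quintile",
        "rurality",
    ),
):
    """Multinomial (softmax) regression of per-year cluster membership.

    Unit of analysis is the person-year; the lowest cluster label is the
    reference outcome.  Returns (statsmodels result, tidy coefficient table
    with log relative-risk ratios and Wald 95% CIs).  Within-person
    correlation across years is ignored, so standard errors are those of an
    independence working model.
    """
    import statsmodels.api as sm

    labels = np.sort(data[outcome_col].unique())
    if len(labels) < 2:
        raise SurvivalError("multinomial model needs >= 2 observed cluster labels")
    y = pd.Categorical(data[outcome_col], categories=labels).codes

    cols = [pd.Series(np.ones(len(data)), name="const", index=data.index)]
    for c in covariates:
        x = data[c]
        if x.dtype == object or str(x.dtype) == "category":
            levels = sorted(pd.unique(x))
            for lev in levels[1:]:
                cols.append((x == lev).astype(float).rename(f"{c}[{lev}]"))
        else:
            cols.append((x.astype(float) - float(x.mean())).rename(c))
    X = pd.concat(cols, axis=1)

    model = sm.MNLogit(y, X)
    try:
        res = model.fit(method="newton", maxiter=200, disp=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise SurvivalError(
            "multinomial fit failed (possible perfect separation; consider "
            "penalised estimation)"
        ) from exc
    if not res.mle_retvals.get("converged", True):
        raise SurvivalError(
            "multinomial fit did not converge (possible perfect separation; "
            "consider penalised estimation)"
        )

    params = res.params  # columns = non-reference outcomes
    bse = res.bse
    rows = []
    for j, lab in enumerate(labels[1:]):
        for term in X.columns:
            coef = params.loc[term].iloc[j]
            se = bse.loc[term].iloc[j]
            rows.append(
                {
                    "outcome_cluster": int(lab),
                    "term": term,
                    "coef": coef,
                    "se": se,
                    "rrr": float(np.exp(coef)),
                    "ci_low": float(np.exp(coef - Z_95 * se)),
                    "ci_high": float(np.exp(coef + Z_95 * se)),
                }
            )
    return res, pd.DataFrame(rows)
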