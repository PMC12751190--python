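"""Bootstrap validation of cluster stability via matched Jaccard indices.

The full factorisation procedure is repeated on bootstrap resamples of the
cohort (patients drawn with replacement, sample size equal to the original
cohort).  Each replicate's clusters are matched one-to-one to the original
clusters by maximising total cosine similarity between the condition-loading
rows of H (a linear assignment problem); patient sets are then compared per
matched cluster with the Jaccard index, restricted to patients present in
the replicate, counting a patient drawn more than once only once.

Per-cluster means with percentile 95% confidence intervals over replicates
summarise stability.  Conventionally, a mean Jaccard index above 0.75
indicates a highly stable cluster and below 0.5 an unstable one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import nmf
from .io import Cohort, ConditionDictionary
from .matrix import build_matrix
from .trajectories import predominant_trajectory, yearly_membership

logger = logging.getLogger(__name__)

HIGH_STABILITY = 0.75
UNSTABLE = 0.5


@dataclass
class StabilityReport:
    per_cluster: pd.DataFrame  # cluster, mean_jaccard, ci_low, ci_high
    B: int
    seed: int
    replicates_failed: int = 0
    replicate_jaccard: np.ndarray | None = None  # B x k, NaN where failed

    def to_frame(self) -> pd.DataFrame:
        out = self.per_cluster.copy()
        out["B"] = self.B
        out["replicates_failed"] = self.replicates_failed
        return out


def jaccard(set_a: set, set_b: set) -> float:
    """|A n B| / |A u B|; 0 when both sets are empty."""
    union = len(set_a | set_b)
    if union == 0:
        return 0.0
    return len(set_a & set_b) / union


def match_clusters(H_ref: np.ndarray, H_boot: np.ndarray) -> np.ndarray:
    """One-to-one boot->ref cluster matching by maximal cosine similarity.

    Returns ``mapping`` with ``mapping[boot_label - 1] = ref_label``.
    """
    H_ref = np.asarray(H_ref, dtype=float)
    H_boot = np.asarray(H_boot, dtype=float)
    if H_ref.shape != H_boot.shape:
        raise ValueError(f"H shapes differ: {H_ref.shape} vs {H_boot.shape}")
    norm_r = np.linalg.norm(H_ref, axis=1, keepdims=True)
    norm_b = np.linalg.norm(H_boot, axis=1, keepdims=True)
    sim = (H_boot / np.maximum(norm_b, 1e-300)) @ (H_ref / np.maximum(norm_r, 1e-300)).T
    boot_idx, ref_idx = linear_sum_assignment(-sim)
    mapping = np.empty(H_ref.shape[0], dtype=int)
    mapping[boot_idx] = ref_idx + 1
    return mapping


def _trajectory_sets(trajectories: pd.DataFrame, k: int) -> dict[int, set[str]]:
    out = {c: set() for c in range(1, k + 1)}
    for pid, lab in zip(
        trajectories["patient_id"], trajectories["predominant_trajectory"]
    ):
        if lab >= 1:
            out[int(lab)].add(pid)
    return out


def _resample_cohort(cohort: Cohort, rng: np.random.Generator) -> tuple[Cohort, pd.Series]:
    """Patients drawn with replacement; duplicates get suffixed ids.

    Returns the resampled cohort and a map from resampled id to original id.
    """
    n = cohort.n_patients
    draw = rng.integers(0, n, size=n)
    patients = cohort.patients.iloc[draw].reset_index(drop=True)
    counts: dict[str, int] = {}
    new_ids = []
    for pid in patients["patient_id"]:
        c = counts.get(pid, 0)
        counts[pid] = c + 1
        new_ids.append(pid if c == 0 else f"{pid}#{c}")
    origin = pd.Series(patients["patient_id"].to_numpy(), index=new_ids)
    patients = patients.copy()
    patients["patient_id"] = new_ids

    ev = cohort.events
    ev_by_pid = {pid: g for pid, g in ev.groupby("patient_id", sort=False)}
    parts = []
    for new_id, old_id in origin.items():
        g = ev_by_pid.get(old_id)
        if g is not None and len(g):
            g = g.copy()
            g["patient_id"] = new_id
            parts.append(g)
    events = (
        pd.concat(parts, ignore_index=True)
        if parts
        else ev.iloc[:0].copy()
    )
    return Cohort(patients=patients, events=events), origin


def bootstrap_stability(
    cohort: Cohort,
    dictionary: ConditionDictionary,
    k: int,
    B: int = 1000,
    seed: int = 0,
    reference: nmf.FactorizationResult | None = None,
    n_restarts: int = 20,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> StabilityReport:
    """Bootstrap the factorise-and-assign procedure and score reproducibility.

    ``n_restarts`` applies within each replicate (reduced from the headline
    run to keep large B tractable; configurable).  Replicate r is a pure
    function of (seed, r), so reports are exactly reproducible.
    """
    ptm = build_matrix(cohort, dictionary)
    if reference is None:
        reference = nmf.factorize(
            ptm, k, n_restarts=n_restarts, max_iter=max_iter, tol=tol, seed=seed
        )
    ref_traj = predominant_trajectory(
        yearly_membership(reference.W, ptm.row_index)
    )
    ref_sets = _trajectory_sets(ref_traj, k)

    ji = np.full((B, k), np.nan)
    failed = 0
    for r in range(B):
        rng = np.random.default_rng([seed, r])
        boot, origin = _resample_cohort(cohort, rng)
        try:
            boot_ptm = build_matrix(boot, dictionary)
            rep_seed = int(rng.integers(2**31))
            fit = nmf.factorize(
                boot_ptm, k, n_restarts=n_restarts, max_iter=max_iter,
                tol=tol, seed=rep_seed,
            )
        except nmf.NMFError:
            failed += 1
            logger.warning("bootstrap replicate %d failed; skipped", r)
            continue
        mapping = match_clusters(reference.H, fit.H)
        traj = predominant_trajectory(yearly_membership(fit.W, boot_ptm.row_index))
        # first duplicate block decides a twice-drawn patient's trajectory
        traj["original_id"] = origin.loc[traj["patient_id"]].to_numpy()
        traj = traj[~traj["patient_id"].str.contains("#")]
        present = set(origin.to_numpy())

        boot_sets = {c: set() for c in range(1, k + 1)}
        for pid, lab in zip(traj["original_id"], traj["predominant_trajectory"]):
            if lab >= 1:
                boot_sets[int(mapping[lab - 1])].add(pid)
        for c in range(1, k + 1):
            ji[r, c - 1] = jaccard(ref_sets[c] & present, boot_sets[c])

    rows = []
    for c in range(1, k + 1):
        vals = ji[:, c - 1]
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            rows.append({"cluster": c, "mean_jaccard": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan})
            continue
        rows.append(
            {
                "cluster": c,
                "mean_jaccard": float(vals.mean()),
                "ci_low": float(np.percentile(vals, 2.5)),
                "ci_high": float(np.percentile(vals, 97.5)),
            }
        )
    return StabilityReport(
        per_cluster=pd.DataFrame(rows),
        B=B,
        seed=seed,
        replicates_failed=failed,
        replicate_jaccard=ji,
    )
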