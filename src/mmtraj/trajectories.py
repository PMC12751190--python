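"""From W to per-year cluster memberships and per-patient trajectories.

Each row of W gives a person-year's (raw, unnormalised) expression of every
disease cluster; the dominant cluster of the year is the argmax.  A
patient's *predominant multimorbidity trajectory* is the cluster with the
greatest area under that patient's cluster-expression-time curve, with
rectangular unit-width integration since person-time is discretised to
years.  All ties break to the lowest cluster label, deterministically.

Clusters are finally relabelled in descending order of their restricted
mean survival time, so label 1 is always the longest-surviving trajectory;
the same permutation must be applied to H rows, W columns and every
downstream table (see :func:`apply_relabelling`).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def yearly_membership(W: np.ndarray, row_index: pd.DataFrame) -> pd.DataFrame:
    """One record per person-year: expression vector plus dominant cluster.

    Dominant cluster labels are 1-based; an all-zero expression row gets the
    sentinel label 0 ("none") and is flagged in the log.
    """
    W = np.asarray(W, dtype=float)
    if W.shape[0] != len(row_index):
        raise ValueError("W row count does not match row_index length")
    k = W.shape[1]
    dominant = np.argmax(W, axis=1) + 1  # argmax takes the first (lowest) max
    zero = ~(W > 0).any(axis=1)
    if zero.any():
        logger.warning("%d person-year rows have all-zero expression", int(zero.sum()))
        dominant = np.where(zero, 0, dominant)
    out = row_index[["patient_id", "year_offset"]].copy()
    for j in range(k):
        out[f"expression_{j + 1}"] = W[:, j]
    out["dominant_cluster"] = dominant
    return out


def _expression_columns(memberships: pd.DataFrame) -> list[str]:
    return [c for c in memberships.columns if c.startswith("expression_")]


def predominant_trajectory(memberships: pd.DataFrame) -> pd.DataFrame:
    """Per-patient area under each cluster-time curve and its argmax.

    Areas are sums of yearly expression (unit-width rectangles).  Returns
    one row per patient: patient_id, area_1..area_k, n_years,
    predominant_trajectory.  Patient order follows first appearance in the
    membership table (i.e. the matrix row order).
    """
    expr_cols = _expression_columns(memberships)
    if not expr_cols:
        raise ValueError("membership table has no expression columns")
    grouped = memberships.groupby("patient_id", sort=False)
    areas = grouped[expr_cols].sum()
    n_years = grouped.size()
    area_mat = areas.to_numpy()
    predominant = np.argmax(area_mat, axis=1) + 1
    out = pd.DataFrame({"patient_id": areas.index})
    for j, c in enumerate(expr_cols):
        out[f"area_{j + 1}"] = area_mat[:, j]
    out["n_years"] = n_years.to_numpy()
    out["predominant_trajectory"] = predominant
    return out


def relabel_by_rmst(rmst_per_cluster: np.ndarray, k: int | None = None) -> np.ndarray:
    """Permutation old->new ordering clusters by decreasing RMST.

    ``perm[old_label - 1] = new_label``; new label 1 is the cluster with the
    longest restricted mean survival.  Equal RMSTs keep their old relative
    order (stable sort).
    """
    rmst = np.asarray(rmst_per_cluster, dtype=float)
    if k is not None and len(rmst) != k:
        raise ValueError(f"expected {k} RMST values, got {len(rmst)}")
    order = np.argsort(-rmst, kind="stable")  # old labels in new-label order
    perm = np.empty(len(rmst), dtype=int)
    perm[order] = np.arange(1, len(rmst) + 1)
    return perm


def apply_relabelling(
    perm: np.ndarray,
    W: np.ndarray | None = None,
    H: np.ndarray | None = None,
    memberships: pd.DataFrame | None = None,
    trajectories: pd.DataFrame | None = None,
):
    """Apply a cluster label permutation consistently to every artefact.

    Returns the same tuple of objects (None where not supplied) with W
    columns / H rows reordered and label columns remapped.
    """
    perm = np.asarray(perm, dtype=int)
    k = len(perm)
    inv = np.argsort(perm)  # new-label order -> old index
    out_W = W[:, inv] if W is not None else None
    out_H = H[inv, :] if H is not None else None

    def _remap_labels(series: pd.Series) -> pd.Series:
        mapping = {old + 1: int(perm[old]) for old in range(k)}
        mapping[0] = 0  # "none" sentinel unchanged
        return series.map(mapping)

    out_m = None
    if memberships is not None:
        out_m = memberships.copy()
        expr = _expression_columns(memberships)
        vals = memberships[expr].to_numpy()[:, inv]
        for j, c in enumerate(expr):
            out_m[c] = vals[:, j]
        out_m["dominant_cluster"] = _remap_labels(memberships["dominant_cluster"])
    out_t = None
    if trajectories is not None:
        out_t = trajectories.copy()
        area_cols = [c for c in trajectories.columns if c.startswith("area_")]
        vals = trajectories[area_cols].to_numpy()[:, inv]
        for j, c in enumerate(area_cols):
            out_t[c] = vals[:, j]
        out_t["predominant_trajectory"] = _remap_labels(
            trajectories["predominant_trajectory"]
        )
    return out_W, out_H, out_m, out_t
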