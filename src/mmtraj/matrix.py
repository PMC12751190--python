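"""Construction of the binary person-year x condition indicator matrix.

Each patient contributes one row per discrete year of follow-up, measured
from their own index date (anniversary years, not calendar years); a final
partial year still contributes a full row.  Chronic (long-term) conditions
are carried forward: a diagnosis at any time up to the end of year t sets
the indicator from year max(0, t) through the patient's last row, with
pre-index diagnoses setting the indicator from year 0.  Acute conditions
mark only the year containing the event, and acute events before the index
date are ignored.  Indicators are unweighted 0/1: duplicate events within a
year collapse to a single 1.

The per-patient blocks are concatenated in patient-table order to form the
factorisation input A (u person-year rows x v conditions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import Cohort, CohortError, ConditionDictionary, DAYS_PER_YEAR, write_table


@dataclass
class PersonTimeMatrix:
    """Sparse binary matrix A with its row and column index.

    ``row_index`` has columns (patient_id, year_offset); rows for one
    patient are contiguous with year_offset 0,1,2,... up to that patient's
    last follow-up year.  ``col_index`` is the dictionary's condition order.
    """

    A: sp.csr_matrix
    row_index: pd.DataFrame
    col_index: list[str]

    @property
    def u(self) -> int:
        return self.A.shape[0]

    @property
    def v(self) -> int:
        return self.A.shape[1]

    def patient_row_slices(self) -> dict[str, slice]:
        """Map patient_id -> slice of its contiguous row block."""
        pids = self.row_index["patient_id"].to_numpy()
        starts = np.flatnonzero(np.r_[True, pids[1:] != pids[:-1]])
        ends = np.r_[starts[1:], len(pids)]
        return {pids[s]: slice(int(s), int(e)) for s, e in zip(starts, ends)}


def year_count(follow_up_years: float) -> int:
    """Number of person-year rows: one per started year, minimum one.

    A follow-up of exactly 3.0 years gives 3 rows; 2.4 years gives 3 rows
    (the partial third year is kept); 0.2 years gives 1 row.
    """
    if follow_up_years < 0:
        raise CohortError(f"negative follow-up: {follow_up_years}")
    return max(int(math.ceil(follow_up_years - 1e-9)), 1)


def build_matrix(cohort: Cohort, dictionary: ConditionDictionary) -> PersonTimeMatrix:
    """Build the concatenated person-year indicator matrix from a cohort."""
    patients = cohort.patients
    col_index = dictionary.ids
    col_pos = {cid: j for j, cid in enumerate(col_index)}
    chronic = set(dictionary.chronic_ids)

    pids = patients["patient_id"].to_numpy()
    fu_days = (patients["end_date"] - patients["index_date"]).dt.days.to_numpy()
    if (fu_days < 0).any():
        raise CohortError("negative follow-up encountered")
    fu_years = fu_days / DAYS_PER_YEAR
    n_years = np.array([year_count(f) for f in fu_years])
    row_start = np.concatenate([[0], np.cumsum(n_years)[:-1]])
    u = int(n_years.sum())

    row_index = pd.DataFrame(
        {
            "patient_id": np.repeat(pids, n_years),
            "year_offset": np.concatenate([np.arange(t) for t in n_years]),
        }
    )

    ev = cohort.events
    if len(ev):
        missing = ~ev["condition_id"].isin(col_pos)
        if missing.any():
            raise CohortError(
                f"event condition {ev.loc[missing, 'condition_id'].iloc[0]!r} not in dictionary"
            )
        pmeta = pd.DataFrame(
            {"index_date": patients["index_date"].to_numpy(),
             "row_start": row_start, "n_years": n_years,
             "end_date": patients["end_date"].to_numpy()},
            index=pids,
        )
        meta = pmeta.loc[ev["patient_id"]]
        after_end = ev["event_date"].to_numpy() > meta["end_date"].to_numpy()
        if after_end.any():
            i = int(np.flatnonzero(after_end)[0])
            raise CohortError(
                f"event for patient {ev['patient_id'].iloc[i]!r} dated after end of follow-up"
            )
        days = (ev["event_date"].to_numpy() - meta["index_date"].to_numpy()).astype(
            "timedelta64[D]"
        ).astype(int)
        year = np.floor(days / DAYS_PER_YEAR).astype(int)
        t_max = meta["n_years"].to_numpy()
        # an event dated exactly at end of follow-up belongs to the last row
        year = np.minimum(year, t_max - 1)
        start = meta["row_start"].to_numpy()
        cols = ev["condition_id"].map(col_pos).to_numpy()
        is_chr = ev["condition_id"].isin(chronic).to_numpy()

        rows_list = []
        cols_list = []
        # chronic: fill from max(0, diagnosis year) to the last row
        c_year = np.maximum(year[is_chr], 0)
        c_span = t_max[is_chr] - c_year
        if len(c_span):
            rows_list.append(
                np.repeat(start[is_chr] + c_year, c_span)
                + _ragged_arange(c_span)
            )
            cols_list.append(np.repeat(cols[is_chr], c_span))
        # acute: only the year of the event, pre-index events ignored
        a_in = (~is_chr) & (year >= 0)
        rows_list.append(start[a_in] + year[a_in])
        cols_list.append(cols[a_in])

        rows = np.concatenate(rows_list) if rows_list else np.array([], dtype=int)
        colv = np.concatenate(cols_list) if cols_list else np.array([], dtype=int)
    else:
        rows = np.array([], dtype=int)
        colv = np.array([], dtype=int)

    data = np.ones(len(rows), dtype=np.float64)
    A = sp.csr_matrix((data, (rows, colv)), shape=(u, len(col_index)))
    A.data[:] = 1.0  # duplicates collapse to indicator 1
    A.sum_duplicates()
    A.data[:] = 1.0
    return PersonTimeMatrix(A=A, row_index=row_index, col_index=list(col_index))


def _ragged_arange(lengths: np.ndarray) -> np.ndarray:
    """Concatenated [0..l) ranges, vectorised: [0,1,2, 0,1, ...]."""
    if len(lengths) == 0:
        return np.array([], dtype=int)
    ends = np.cumsum(lengths)
    idx = np.arange(ends[-1])
    return idx - np.repeat(ends - lengths, lengths)


def save_matrix(ptm: PersonTimeMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Serialise A in MatrixMarket format with sidecar row/column indices."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mtx_path = out_dir / "A.mtx"
    from scipy.io import mmwrite

    mmwrite(mtx_path, ptm.A.tocoo())
    write_table(ptm.row_index, out_dir / "row_index.csv")
    write_table(pd.DataFrame({"condition_id": ptm.col_index}), out_dir / "col_index.csv")
    return {
        "A": mtx_path,
        "row_index": out_dir / "row_index.csv",
        "col_index": out_dir / "col_index.csv",
    }
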