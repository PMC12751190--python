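import numpy as np
import pandas as pd
import pytest

import mmtraj as mt
from mmtraj.io import Cohort, ConditionDef, ConditionDictionary


@pytest.fixture(scope="session")
def hand_cohort():
    """Three patients exercising every matrix encoding rule.

    p1: pre-index chronic carried from year 0; in-window acute in year 1.
    p2: pre-index acute only (must be ignored) -> all-zero rows.
    p3: chronic first diagnosed in year 2 of 4; acute in the partial final year.
    """
    dictionary = ConditionDictionary(
        [
            ConditionDef("c1", "hypertension", "chronic"),
            ConditionDef("c2", "heart failure", "chronic"),
            ConditionDef("a1", "urinary tract infection", "acute"),
        ]
    )
    patients = pd.DataFrame(
        {
            "patient_id": ["p1", "p2", "p3"],
            "index_date": pd.to_datetime(["2010-01-01"] * 3),
            "age_at_index": [70.0, 65.0, 80.0],
            "sex": ["female", "male", "male"],
            "deprivation_quintile": [1, 3, 5],
            "rurality": ["urban", "rural", "urban"],
            "end_date": pd.to_datetime(["2012-12-31", "2011-12-31", "2013-10-01"]),
            "end_reason": ["death", "censored", "censored"],
        }
    )
    events = pd.DataFrame(
        {
            "patient_id": ["p1", "p1", "p2", "p3", "p3"],
            "condition_id": ["c1", "a1", "a1", "c2", "a1"],
            "event_date": pd.to_datetime(
                ["2008-01-05", "2011-06-15", "2009-06-15", "2012-06-15", "2013-08-01"]
            ),
        }
    )
    expected = np.array(
        [
            # c1 c2 a1
            [1, 0, 0],  # p1 year 0
            [1, 0, 1],  # p1 year 1
            [1, 0, 0],  # p1 year 2
            [0, 0, 0],  # p2 year 0
            [0, 0, 0],  # p2 year 1
            [0, 0, 0],  # p3 year 0
            [0, 0, 0],  # p3 year 1
            [0, 1, 0],  # p3 year 2
            [0, 1, 1],  # p3 year 3 (partial)
        ],
        dtype=float,
    )
    return Cohort(patients=patients, events=events), dictionary, expected


@pytest.fixture(scope="session")
def planted_cohort():
    """Reference planted-structure cohort: 2000 patients, 4 disjoint
    signatures, default noise.  Shared by the recovery checks."""
    cfg = mt.SyntheticConfig(n_patients=2000, k_true=4, seed=20)
    cohort, truth, dictionary = mt.generate_cohort(cfg)
    return cohort, truth, dictionary


@pytest.fixture(scope="session")
def planted_matrix(planted_cohort):
    cohort, truth, dictionary = planted_cohort
    return mt.build_matrix(cohort, dictionary)


@pytest.fixture(scope="session")
def planted_fit(planted_matrix):
    return mt.factorize(
        planted_matrix, 4, n_restarts=10, max_iter=300, tol=1e-5, seed=77
    )


def greedy_signature_match(H, col_index, signatures):
    """Greedy maximal-overlap matching of recovered clusters to planted
    signatures; recovered set j = top-|signature| conditions of H row j.

    Returns (mean condition-set Jaccard, mapping recovered label -> true label).
    """
    ids = np.asarray(col_index)
    k = H.shape[0]
    sig_size = len(next(iter(signatures.values())))
    rec_sets = [set(ids[np.argsort(-H[j])[:sig_size]]) for j in range(k)]
    remaining = set(range(k))
    jaccards = []
    mapping = {}
    for c in sorted(signatures):
        best = max(remaining, key=lambda j: len(signatures[c] & rec_sets[j]))
        remaining.discard(best)
        mapping[best + 1] = c
        jaccards.append(mt.jaccard(signatures[c], rec_sets[best]))
    return float(np.mean(jaccards)), mapping
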