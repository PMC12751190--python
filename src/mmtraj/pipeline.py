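"""End-to-end orchestration: cohort -> matrix -> NMF -> trajectories ->
stability -> outcome models, from a single config with one master seed.

The master seed fans out to per-stage seeds by fixed offsets so a single
integer reproduces the whole run.  Every stage's wall time and seed is
logged; outputs are written through :func:`mmtraj.io.write_outputs`, whose
manifest records a content hash per file so rerun identity can be checked.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, nmf, outcomes, stability, synthetic, trajectories as traj
from .flexsurv import fit_flexible_parametric, hazard_ratios, standardized_survival
from .matrix import build_matrix

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets from the master seed
SEED_SYNTHETIC = 1
SEED_NMF = 2
SEED_RANK_SCAN = 3
SEED_BOOTSTRAP = 4


@dataclass
class PipelineConfig:
    """Everything one run needs.  Exactly one of ``synthetic`` /
    (``events_path``, ``patients_path``, ``conditions_path``) is given."""

    out_dir: str = "mmtraj_out"
    seed: int = 0
    # input: synthetic generator settings (dict of SyntheticConfig fields)...
    synthetic: dict | None = None
    # ...or real tables
    events_path: str | None = None
    patients_path: str | None = None
    conditions_path: str | None = None
    # NMF
    k: int | None = None
    k_range: tuple[int, int] | None = None
    n_restarts: int = 100
    runs_per_k: int = 10
    max_iter: int = 500
    tol: float = 1e-5
    # bootstrap
    bootstrap_B: int = 1000
    bootstrap_restarts: int = 20
    run_bootstrap: bool = True
    # survival
    spline_df: int = 6
    age_spline_df: int = 3
    run_outcomes: bool = True
    standardize_times: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0)

    def __post_init__(self) -> None:
        real = all(p is not None for p in (self.events_path, self.patients_path))
        if real == (self.synthetic is not None):
            raise ValueError(
                "config must provide exactly one of synthetic settings or "
                "real input paths"
            )
        if self.k is None and self.k_range is None:
            raise ValueError("config needs k or k_range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        if "k_range" in raw and raw["k_range"] is not None:
            raw["k_range"] = tuple(raw["k_range"])
        if "standardize_times" in raw:
            raw["standardize_times"] = tuple(raw["standardize_times"])
        return cls(**raw)


@dataclass
class PipelineResult:
    manifest: pd.DataFrame
    tables: dict[str, pd.DataFrame]
    truth: synthetic.SyntheticTruth | None = None
    fit: nmf.FactorizationResult | None = None
    stage_seconds: dict[str, float] = field(default_factory=dict)


def _stage(name: str, timings: dict[str, float]):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            timings[name] = dt
            if exc_type is None:
                logger.info("stage %s: done in %.2fs", name, dt)
            else:
                logger.error("stage %s: FAILED after %.2fs", name, dt)
            return False

    return _T()


def run(config: PipelineConfig) -> PipelineResult:
    timings: dict[str, float] = {}
    tables: dict[str, pd.DataFrame] = {}
    truth = None

    with _stage("load", timings):
        if config.synthetic is not None:
            syn_cfg = synthetic.SyntheticConfig(
                **{**config.synthetic, "seed": config.seed + SEED_SYNTHETIC}
            )
            cohort, truth, dictionary = synthetic.generate_cohort(syn_cfg)
            tables["truth"] = truth.to_frame()
        else:
            dictionary = io.load_condition_dictionary(config.conditions_path)
            cohort = io.load_cohort(
                config.events_path, config.patients_path, dictionary
            )

    with _stage("build_matrix", timings):
        ptm = build_matrix(cohort, dictionary)
        logger.info("matrix: %d person-years x %d conditions, nnz=%d",
                    ptm.u, ptm.v, ptm.A.nnz)

    k = config.k
    if config.k_range is not None:
        with _stage("rank_scan", timings):
            report = nmf.rank_scan(
                ptm,
                config.k_range,
                runs_per_k=config.runs_per_k,
                max_iter=min(config.max_iter, 200),
                tol=max(config.tol, 1e-4),
                seed=config.seed + SEED_RANK_SCAN,
            )
            tables["rank_scan"] = report.to_frame()
            if k is None:
                k = report.suggest_elbow()
                logger.info("rank scan suggests elbow at k=%d (advisory)", k)

    with _stage("factorize", timings):
        fit = nmf.factorize(
            ptm, k, n_restarts=config.n_restarts, max_iter=config.max_iter,
            tol=config.tol, seed=config.seed + SEED_NMF,
        )
        logger.info("NMF k=%d: loss %.4f from restart %d after %d iterations",
                    k, fit.loss, fit.restart_id, fit.n_iter)

    with _stage("trajectories", timings):
        memberships = traj.yearly_membership(fit.W, ptm.row_index)
        assignments = traj.predominant_trajectory(memberships)

    with _stage("rmst_relabel", timings):
        rmst_tab = outcomes.rmst_per_cluster(assignments, cohort.patients)
        full = pd.DataFrame({"cluster": np.arange(1, k + 1)})
        rmst_tab = full.merge(rmst_tab, on="cluster", how="left")
        rmst_vals = rmst_tab["rmst"].fillna(0.0).to_numpy()
        perm = traj.relabel_by_rmst(rmst_vals, k)
        W, H, memberships, assignments = traj.apply_relabelling(
            perm, fit.W, fit.H, memberships, assignments
        )
        fit.W, fit.H = W, H
        rmst_tab["cluster"] = [int(perm[c - 1]) for c in rmst_tab["cluster"]]
        rmst_tab = rmst_tab.sort_values("cluster").reset_index(drop=True)
        tables["rmst"] = rmst_tab
        tables["H"] = pd.DataFrame(H, columns=ptm.col_index).assign(
            cluster=np.arange(1, k + 1)
        )[["cluster", *ptm.col_index]]
        tables["W_memberships"] = memberships
        fu = cohort.follow_up_years()
        assignments = assignments.assign(
            follow_up_years=fu.loc[assignments["patient_id"]].to_numpy()
        )
        tables["trajectories"] = assignments

    if config.run_bootstrap:
        with _stage("bootstrap", timings):
            rep = stability.bootstrap_stability(
                cohort, dictionary, k,
                B=config.bootstrap_B,
                seed=config.seed + SEED_BOOTSTRAP,
                reference=fit,
                n_restarts=config.bootstrap_restarts,
            )
            tables["stability"] = rep.to_frame()

    if config.run_outcomes:
        with _stage("outcomes", timings):
            episodes = outcomes.episode_split(memberships, cohort.patients)
            episodes = episodes[episodes["cluster"] >= 1]
            unadj = fit_flexible_parametric(
                episodes, spline_df=config.spline_df, covariates=("cluster",)
            )
            adj = fit_flexible_parametric(
                episodes,
                spline_df=config.spline_df,
                covariates=(
                    "cluster", "age_at_index", "sex", "index_year",
                    "deprivation_quintile", "rurality",
                ),
                age_spline_df=config.age_spline_df,
            )
            hr_u = hazard_ratios(unadj).rename(
                columns={"hr": "hr_unadjusted", "ci_low": "u_ci_low",
                         "ci_high": "u_ci_high"}
            )
            hr_a = hazard_ratios(adj).rename(
                columns={"hr": "hr_adjusted", "ci_low": "a_ci_low",
                         "ci_high": "a_ci_high"}
            )
            py = episodes.assign(py=episodes["stop"] - episodes["start"]) \
                .groupby("cluster")["py"].sum()
            hr_tab = hr_u.merge(hr_a, on="term")
            hr_tab.insert(1, "person_years",
                          [float(x) for x in py.reindex(
                              sorted(episodes["cluster"].unique())).fillna(0.0)])
            tables["survival_hr"] = hr_tab

            if config.standardize_times:
                pop = episodes.drop_duplicates("patient_id")
                std = pd.concat(
                    [
                        standardized_survival(
                            adj, pop, c, np.asarray(config.standardize_times)
                        )
                        for c in sorted(episodes["cluster"].unique())
                    ],
                    ignore_index=True,
                )
                tables["standardized_survival"] = std

            person_years = memberships.merge(
                cohort.patients, on="patient_id", how="left"
            )
            person_years["age_in_year"] = (
                person_years["age_at_index"] + person_years["year_offset"]
            )
            person_years["index_year"] = person_years["index_date"].dt.year
            person_years = person_years[person_years["dominant_cluster"] >= 1]
            _, mn_table = outcomes.fit_multinomial(person_years)
            tables["multinomial"] = mn_table

    with _stage("write_outputs", timings):
        manifest = io.write_outputs(tables, config.out_dir)

    return PipelineResult(
        manifest=manifest, tables=tables, truth=truth, fit=fit,
        stage_seconds=timings,
    )
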