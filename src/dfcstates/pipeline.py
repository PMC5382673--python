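"""End-to-end orchestration of the dFC state analysis.

Stages: simulate (optional synthetic cohort) -> postproc -> dfc (windowed
connectivity) -> cluster (two-stage k-means states) -> metrics (occupancy /
transition statistics and behaviour correlations) -> hubs -> mtd -> report.
Every run directory carries a manifest (config echo, derived seeds, input
hashes) and a plain-markdown report; per-stage seeds are derived from the
master seed by hashing (master, stage, subject), so runs are reproducible
and subject-level work is order-independent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .cluster import choose_k_elbow, fit_states
from .hubs import centroid_to_graph, hub_table
from .mtd import mtd, mtd_states, spatial_similarity
from .panel import default_subnetwork_labels
from .preprocess import TimeCourseCleaner, framewise_displacement
from .simulate import RegimeSwitchingSpec, derive_seed, simulate_cohort
from .stats import (chi_square_table, group_count_tables, partial_correlation,
                    per_subject_group_means, posthoc_categories,
                    profiles_from_model, state_pairs, transition_rate_table)
from .windows import SlidingWindowConnectivity

log = logging.getLogger("dfcstates")

ALL_STAGES = ("simulate", "postproc", "dfc", "cluster", "metrics", "hubs",
              "mtd", "report")


@dataclass
class RunConfig:
    """Run-level configuration; defaults mirror the reference analysis."""

    out_dir: str = "dfc_run"
    sample_sheet: str | None = None        # existing cohort inputs
    timecourse_dir: str | None = None
    motion_dir: str | None = None

    # windowing
    rect_len: int = 22
    sigma: float = 3.0
    step: int = 1
    lambda_l1: float = 0.1
    fisher_windows: bool = False

    # cleaning
    detrend_order: int = 3
    lowpass_hz: float = 0.15
    mad_thresh: float = 3.5

    # clustering
    k: int = 4
    k_range: list[int] | None = None       # enables elbow selection
    n_replicates: int = 500

    # hubs
    consensus_runs: int = 100
    gamma: float = 1.0
    alpha_fdr: float = 0.05
    min_state_windows: int = 10

    # MTD
    mtd_w: int = 15

    master_seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))

    # synthetic cohort parameters (used when the simulate stage is enabled)
    n_per_group: int = 22
    T: int = 240
    tr_seconds: float = 2.0
    n_components: int = 42
    n_blocks: int = 7
    sim_K: int = 4
    noise_sd: float = 2.0 ** -0.5
    switch_prob_high: float = 0.10
    switch_prob_low: float = 0.05
    behavior_coupling_high: float = 0.8
    behavior_coupling_low: float = 0.0

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in ALL_STAGES:
                raise ValueError(f"unknown stage {s!r}")
        if self.rect_len < 2 or self.step < 1:
            raise ValueError("invalid window parameters")
        if not 0 <= self.alpha_fdr <= 1:
            raise ValueError("alpha_fdr must be in [0, 1]")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def simulation_spec(self) -> RegimeSwitchingSpec:
        return RegimeSwitchingSpec(
            n_components=self.n_components, n_blocks=self.n_blocks,
            K=self.sim_K, T=self.T, tr_seconds=self.tr_seconds,
            n_per_group=self.n_per_group, noise_sd=self.noise_sd,
            switch_prob_per_group={"high": self.switch_prob_high,
                                   "low": self.switch_prob_low},
            behavior_coupling={"high": self.behavior_coupling_high,
                               "low": self.behavior_coupling_low},
            seed=derive_seed(self.master_seed, "simulate"))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, run: Path) -> None:
    spec = cfg.simulation_spec()
    cohort = simulate_cohort(spec)
    tc_dir = run / "timecourses"
    mo_dir = run / "motion"
    tc_dir.mkdir(parents=True, exist_ok=True)
    mo_dir.mkdir(parents=True, exist_ok=True)
    for sid, panel in cohort["panels"].items():
        dio.write_timecourse_table(panel, tc_dir / f"{sid}.tsv")
        dio.write_motion_table(cohort["motion"][sid], mo_dir / f"{sid}.tsv")
    cohort["sample_sheet"].to_csv(run / "sample_sheet.csv", index=False)
    dio.write_ground_truth(cohort["ground_truth"], run / "ground_truth.json")


def _load_cohort(cfg: RunConfig, run: Path):
    sheet_path = Path(cfg.sample_sheet) if cfg.sample_sheet \
        else run / "sample_sheet.csv"
    tc_dir = Path(cfg.timecourse_dir) if cfg.timecourse_dir \
        else run / "timecourses"
    mo_dir = Path(cfg.motion_dir) if cfg.motion_dir else run / "motion"
    if not sheet_path.exists():
        raise FileNotFoundError(
            f"sample sheet {sheet_path} not found (enable the simulate "
            "stage or point sample_sheet at existing data)")
    sheet = pd.read_csv(sheet_path)
    panels, motion = {}, {}
    for sid in sheet["subject_id"]:
        panels[sid] = dio.read_timecourse_table(tc_dir / f"{sid}.tsv")
        mo_path = mo_dir / f"{sid}.tsv"
        motion[sid] = dio.read_motion_table(mo_path, sid) \
            if mo_path.exists() else None
    return sheet, panels, motion


def stage_postproc(cfg: RunConfig, run: Path) -> None:
    sheet, panels, motion = _load_cohort(cfg, run)
    out_dir = run / "cleaned"
    out_dir.mkdir(exist_ok=True)
    cleaner = TimeCourseCleaner(max_order=cfg.detrend_order,
                                cutoff_hz=cfg.lowpass_hz,
                                mad_thresh=cfg.mad_thresh)
    fd_rows = []
    for sid, panel in panels.items():
        cleaned = cleaner.fit(panel).transform(panel, motion[sid])
        dio.write_timecourse_table(cleaned, out_dir / f"{sid}.tsv")
        mask = cleaner.outlier_mask_
        np.savetxt(out_dir / f"{sid}_outliers.csv",
                   np.argwhere(mask), fmt="%d", delimiter=",",
                   header="row,component", comments="")
        if motion[sid] is not None:
            _, mean_fd = framewise_displacement(motion[sid])
            fd_rows.append({"subject_id": sid, "mean_fd": mean_fd})
    if fd_rows:
        pd.DataFrame(fd_rows).to_csv(run / "framewise_displacement.csv",
                                     index=False)


def stage_dfc(cfg: RunConfig, run: Path) -> None:
    sheet, _, _ = _load_cohort(cfg, run)
    clean_dir = run / "cleaned"
    src = clean_dir if clean_dir.exists() else run / "timecourses"
    out_dir = run / "dfc"
    out_dir.mkdir(exist_ok=True)
    swc = SlidingWindowConnectivity(rect_len=cfg.rect_len, sigma=cfg.sigma,
                                    step=cfg.step, lambda_l1=cfg.lambda_l1,
                                    fisher=cfg.fisher_windows).fit()
    for sid in sheet["subject_id"]:
        panel = dio.read_timecourse_table(src / f"{sid}.tsv")
        dio.write_dfc_series(swc.transform(panel), out_dir / f"{sid}.tsv")


def stage_cluster(cfg: RunConfig, run: Path) -> None:
    sheet = pd.read_csv(run / "sample_sheet.csv" if cfg.sample_sheet is None
                        else cfg.sample_sheet)
    dfc = {sid: dio.read_dfc_series(run / "dfc" / f"{sid}.tsv")
           for sid in sheet["subject_id"]}
    seed = derive_seed(cfg.master_seed, "cluster")
    elbow = None
    k = cfg.k
    if cfg.k_range:
        exemplars = np.vstack([d.values for d in dfc.values()])
        elbow = choose_k_elbow(exemplars, cfg.k_range, seed=seed)
        k = elbow.k
    model = fit_states(dfc, k=k, seed=seed, n_replicates=cfg.n_replicates)
    np.savetxt(run / "state_centroids.tsv", model.centroids, delimiter="\t")
    dio.write_assignments(model.assignments, run / "state_assignments.csv")
    meta = {"k": int(k), "seed": int(seed), "inertia": model.inertia,
            "n_replicates": cfg.n_replicates}
    if elbow is not None:
        meta["elbow"] = {"k_range": elbow.k_range.tolist(),
                         "inertia": elbow.inertia.tolist(),
                         "weak_elbow": elbow.weak_elbow}
    (run / "state_model.json").write_text(json.dumps(meta, indent=1))


def _read_model(run: Path):
    meta = json.loads((run / "state_model.json").read_text())
    assignments = dio.read_assignments(run / "state_assignments.csv")
    centroids = np.loadtxt(run / "state_centroids.tsv", delimiter="\t",
                           ndmin=2)
    return meta, assignments, centroids


def stage_metrics(cfg: RunConfig, run: Path) -> None:
    meta, assignments, _ = _read_model(run)
    K = meta["k"]
    sheet = pd.read_csv(run / "sample_sheet.csv" if cfg.sample_sheet is None
                        else cfg.sample_sheet)
    from .cluster import StateModel
    model = StateModel(K=K, centroids=np.zeros((K, 1)),
                       assignments=assignments, inertia=0.0)
    profiles = profiles_from_model(model)
    profiles.to_csv(run / "state_profiles.csv", index=False)

    results: dict = {}
    occ, trans, groups = group_count_tables(profiles, sheet, K)
    occ_test = chi_square_table(occ)
    trans_test = chi_square_table(trans)
    results["groups"] = groups
    results["occupancy_table"] = occ.tolist()
    results["transition_table"] = trans.tolist()
    results["occupancy_chi2"] = {"statistic": occ_test.statistic,
                                 "df": occ_test.df, "p": occ_test.p}
    results["transition_chi2"] = {"statistic": trans_test.statistic,
                                  "df": trans_test.df, "p": trans_test.p}
    rate = transition_rate_table(profiles, sheet)
    rate_test = chi_square_table(rate)
    results["transition_rate_table"] = rate.tolist()
    results["transition_rate_chi2"] = {"statistic": rate_test.statistic,
                                       "df": rate_test.df, "p": rate_test.p}
    posthoc_occ = posthoc_categories(
        occ, cfg.alpha_fdr, categories=[f"state_{k}" for k in
                                        range(1, K + 1)])
    posthoc_trans = posthoc_categories(
        trans, cfg.alpha_fdr,
        categories=[f"{a}-{b}" for a, b in state_pairs(K)])
    posthoc_occ.to_csv(run / "posthoc_occupancy.csv", index=False)
    posthoc_trans.to_csv(run / "posthoc_transitions.csv", index=False)
    per_subject_group_means(profiles, sheet).to_csv(
        run / "group_means_per_subject.csv")

    # behaviour correlations within each group, covariate adjusted
    merged = profiles.merge(sheet, on="subject_id")
    corr_rows = []
    covar_cols = [c for c in ("iq", "age", "gender") if c in merged.columns]
    if "score" in merged.columns:
        metric_cols = ([f"occupancy_{k}" for k in range(1, K + 1)]
                       + [f"trans_{a}_{b}" for a, b in state_pairs(K)]
                       + ["total_transitions"])
        for g in groups:
            sub = merged[merged["group"] == g]
            Z = sub[covar_cols].to_numpy(float) if covar_cols else None
            for col in metric_cols:
                x = sub[col].to_numpy(float)
                if x.std() == 0:
                    continue
                try:
                    r, p, df = partial_correlation(
                        x, sub["score"].to_numpy(float), Z)
                except ValueError:
                    continue
                corr_rows.append({"group": g, "metric": col, "r": r,
                                  "p": p, "df": df})
    pd.DataFrame(corr_rows).to_csv(run / "behavior_correlations.csv",
                                   index=False)
    (run / "group_tests.json").write_text(json.dumps(results, indent=1))


def stage_hubs(cfg: RunConfig, run: Path) -> None:
    meta, assignments, _ = _read_model(run)
    K = meta["k"]
    sheet = pd.read_csv(run / "sample_sheet.csv" if cfg.sample_sheet is None
                        else cfg.sample_sheet)
    subjects = sorted(assignments)
    dfc = {sid: dio.read_dfc_series(run / "dfc" / f"{sid}.tsv")
           for sid in subjects}
    first = dfc[subjects[0]]
    hub_dir = run / "hubs"
    hub_dir.mkdir(exist_ok=True)
    for k in range(1, K + 1):
        rows = [dfc[s].values[assignments[s] == k] for s in subjects]
        windows = np.vstack([r for r in rows if r.size])
        if windows.shape[0] < cfg.min_state_windows:
            log.warning("state %d: only %d windows, skipping hub analysis",
                        k, windows.shape[0])
            continue
        graph = centroid_to_graph(windows, first.component_ids,
                                  first.subnetwork_labels,
                                  alpha_fdr=cfg.alpha_fdr, state=k,
                                  already_fisher=first.fisher_z,
                                  min_windows=cfg.min_state_windows)
        seed = derive_seed(cfg.master_seed, "hubs", k)
        table = hub_table(graph, n_runs=cfg.consensus_runs,
                          gamma=cfg.gamma, seed=seed)
        table.to_csv(hub_dir / f"state_{k}_hubs.csv", index=False)
        dio.write_edge_list(graph.adjacency, graph.node_ids,
                            hub_dir / f"state_{k}_edges.tsv")


def stage_mtd(cfg: RunConfig, run: Path) -> None:
    meta, _, _ = _read_model(run)
    K = meta["k"]
    sheet = pd.read_csv(run / "sample_sheet.csv" if cfg.sample_sheet is None
                        else cfg.sample_sheet)
    clean_dir = run / "cleaned"
    src = clean_dir if clean_dir.exists() else run / "timecourses"
    series = {}
    for sid in sheet["subject_id"]:
        panel = dio.read_timecourse_table(src / f"{sid}.tsv")
        series[sid] = mtd(panel, w=cfg.mtd_w)
    seed = derive_seed(cfg.master_seed, "mtd")
    assignments, _ = mtd_states(series, k=K, seed=seed, n_init=50)
    dio.write_assignments(assignments, run / "mtd_assignments.csv")

    from .cluster import StateModel
    model = StateModel(K=K, centroids=np.zeros((K, 1)),
                       assignments=assignments, inertia=0.0)
    profiles = profiles_from_model(model)
    profiles.to_csv(run / "mtd_profiles.csv", index=False)
    _, trans, groups = group_count_tables(profiles, sheet, K)
    test = chi_square_table(trans)
    sim = spatial_similarity(series, seed=seed)
    payload = {
        "groups": groups,
        "transition_table": trans.tolist(),
        "transition_chi2": {"statistic": test.statistic, "df": test.df,
                            "p": test.p},
        "spatial_similarity": {"n_timepoints": sim["n_timepoints"],
                               "mean": sim["mean"],
                               "quantiles": sim["quantiles"]},
    }
    (run / "mtd_results.json").write_text(json.dumps(payload, indent=1))


def stage_report(cfg: RunConfig, run: Path) -> None:
    lines = ["# dFC state analysis report", ""]
    tests_path = run / "group_tests.json"
    if tests_path.exists():
        res = json.loads(tests_path.read_text())
        lines += ["## Group tests (sliding-window states)", ""]
        for name in ("occupancy_chi2", "transition_chi2"):
            t = res[name]
            lines.append(
                f"- {name}: chi2({t['df']}) = {t['statistic']:.2f}, "
                f"p = {t['p']:.3g}")
        lines.append("")
    bc = run / "behavior_correlations.csv"
    if bc.exists() and bc.stat().st_size > 1:
        df = pd.read_csv(bc)
        if len(df):
            lines += ["## Behaviour correlations (covariate adjusted)", ""]
            sig = df[df["p"] < 0.05]
            lines.append(f"- {len(sig)} of {len(df)} metric/group "
                         "correlations significant at p < 0.05")
            for _, row in sig.iterrows():
                lines.append(f"  - {row['group']} {row['metric']}: "
                             f"r = {row['r']:.2f}, p = {row['p']:.3g}")
            lines.append("")
    hub_dir = run / "hubs"
    if hub_dir.exists():
        lines += ["## Hub tables", ""]
        for f in sorted(hub_dir.glob("state_*_hubs.csv")):
            df = pd.read_csv(f)
            hubs = df[df["role"] != "non-hub"]
            lines.append(f"- {f.stem}: {len(hubs)} hubs "
                         f"({(df['role'] == 'connector').sum()} connector, "
                         f"{(df['role'] == 'provincial').sum()} provincial)")
        lines.append("")
    mtd_path = run / "mtd_results.json"
    if mtd_path.exists():
        res = json.loads(mtd_path.read_text())
        t = res["transition_chi2"]
        lines += ["## MTD confirmation", "",
                  f"- transition chi2({t['df']}) = {t['statistic']:.2f}, "
                  f"p = {t['p']:.3g}",
                  f"- mean spatial similarity "
                  f"{res['spatial_similarity']['mean']:.3f}", ""]
    (run / "report.md").write_text("\n".join(lines))


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "postproc": stage_postproc,
    "dfc": stage_dfc,
    "cluster": stage_cluster,
    "metrics": stage_metrics,
    "hubs": stage_hubs,
    "mtd": stage_mtd,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    run = Path(cfg.out_dir)
    run.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    timings = {}
    try:
        for stage in ALL_STAGES:
            if stage not in cfg.stages:
                continue
            t0 = time.time()
            log.info("stage %s: start", stage)
            try:
                _STAGE_FUNCS[stage](cfg, run)
            except Exception as e:
                log.error("stage %s failed: %s", stage, e)
                raise RuntimeError(f"stage {stage!r} failed: {e}") from e
            timings[stage] = time.time() - t0
            log.info("stage %s: done in %.1f s", stage, timings[stage])
    finally:
        log.removeHandler(handler)
        handler.close()
    cfg.to_yaml(run / "config.yaml")
    manifest = {
        "config": dataclasses.asdict(cfg),
        "stage_seconds": timings,
        "stage_seeds": {s: derive_seed(cfg.master_seed, s)
                        for s in cfg.stages},
        "input_hashes": {
            p.name: _sha256(p)
            for p in sorted(run.glob("timecourses/*.tsv"))[:5]
        },
    }
    (run / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return run
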