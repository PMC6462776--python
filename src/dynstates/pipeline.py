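"""End-to-end orchestration: postprocessing -> sliding-window connectivity
-> state clustering -> network dynamics -> group statistics.

:func:`process_cohort` runs the whole analysis on in-memory time courses
and returns a :class:`PipelineResult`; :func:`run_pipeline` wraps it with
disk I/O (TSV/CSV/JSON only) and stamps every artifact with the config
hash and seed so reruns are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import dfc, netdyn, postproc, states, stats
from .io import read_manifest, read_timecourses, write_json
from .postproc import TimecourseSet

logger = logging.getLogger("dynstates")

__all__ = ["RunConfig", "PipelineResult", "process_cohort", "run_pipeline"]


@dataclass
class RunConfig:
    """Run configuration; defaults match the reference analysis settings
    (22-TR tapered window with sigma 3 TR and step 1, per-subject lambda CV
    with 20 folds, k-means over k = 2..8 with the elbow criterion, densities
    3.7%..39.3%)."""

    timecourse_dir: str = ""
    manifest_path: str = ""
    out_dir: str = "results/run"
    tr: float = 3.0
    # postprocessing
    do_postprocess: bool = True
    detrend_order: int = 3
    mad_threshold: float = 4.0
    despike_window: int = 11
    lowpass_hz: float = 0.15
    filter_order: int = 5
    # sliding window
    window_width_tr: int = 22
    window_sigma_tr: float = 3.0
    window_step_tr: int = 1
    # graphical LASSO; None grid -> unregularized windowed correlations
    lambda_grid: list[float] | None = field(
        default_factory=lambda: list(dfc.default_lambda_grid())
    )
    lambda_folds: int = 20
    # residualization
    covariate_columns: list[str] = field(default_factory=lambda: ["age", "gender", "study"])
    # clustering
    k: int | None = None            # None -> elbow selection over k_range
    k_min: int = 2
    k_max: int = 8
    n_init: int = 500
    sweep_n_init: int = 50
    max_iter: int = 100
    # network dynamics
    run_efficiency: bool = True
    density_min: float = 0.037
    density_max: float = 0.393
    density_max_points: int | None = None
    # statistics
    n_perm: int = 9999
    alpha: float = 0.05
    seed: int = 0

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded, so the same
        analysis on the same data hashes identically wherever it runs)."""
        d = asdict(self)
        for key in ("timecourse_dir", "manifest_path", "out_dir"):
            d.pop(key, None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


@dataclass
class PipelineResult:
    taper: dfc.TaperSpec
    lambdas: dict[str, float]
    z_windows: np.ndarray             # (n_subjects, W, n_pairs) residualized
    variability: dict[str, dfc.VariabilityResult]
    cluster_model: states.ClusterModel
    selected_k: int
    validity_curve: pd.DataFrame | None
    assignments: dict[str, np.ndarray]
    per_state_metrics: pd.DataFrame
    per_subject_metrics: pd.DataFrame
    efficiency: dict[str, netdyn.EfficiencySeries]
    group_stats: dict
    manifest: pd.DataFrame
    cleaning_reports: dict[str, postproc.CleaningReport]


def _stage(name: str, subject: str | None = None):
    ctx = f" [{subject}]" if subject else ""
    logger.info("stage %s%s", name, ctx)


def process_cohort(
    tcs: list[TimecourseSet],
    manifest: pd.DataFrame,
    config: RunConfig,
) -> PipelineResult:
    """Run the full analysis on an in-memory cohort."""
    if not tcs:
        raise ValueError("no subjects")
    order = {sid: i for i, sid in enumerate(manifest["subject_id"])}
    tcs = sorted(tcs, key=lambda tc: order.get(tc.subject_id, 10**9))
    rng = np.random.default_rng(config.seed)

    # --- postprocessing ------------------------------------------------
    reports: dict[str, postproc.CleaningReport] = {}
    if config.do_postprocess:
        cleaned = []
        for tc in tcs:
            try:
                c, rep = postproc.postprocess(
                    tc,
                    max_order=config.detrend_order,
                    mad_threshold=config.mad_threshold,
                    despike_window=config.despike_window,
                    cutoff_hz=config.lowpass_hz,
                    filter_order=config.filter_order,
                )
            except Exception as exc:
                raise RuntimeError(f"stage postproc failed for {tc.subject_id}: {exc}") from exc
            cleaned.append(c)
            reports[tc.subject_id] = rep
        tcs = cleaned
    _stage("postproc done")

    # --- sliding-window connectivity ------------------------------------
    taper = dfc.make_taper(config.window_width_tr, config.window_sigma_tr,
                           config.window_step_tr)
    lambdas: dict[str, float] = {}
    z_list = []
    for tc in tcs:
        try:
            covs = dfc.windowed_covariance(tc.data, taper)
            if config.lambda_grid is not None:
                sel = dfc.select_lambda(covs, np.asarray(config.lambda_grid),
                                        n_folds=config.lambda_folds)
                lambdas[tc.subject_id] = sel.chosen
                covs = dfc.regularized_windows(covs, sel.chosen)
            else:
                lambdas[tc.subject_id] = 0.0
            z = dfc.to_fisher_z(covs)
        except Exception as exc:
            raise RuntimeError(f"stage dfc failed for {tc.subject_id}: {exc}") from exc
        z_list.append(dfc.triu_vector(z))
    W = {z.shape[0] for z in z_list}
    if len(W) > 1:
        raise RuntimeError(f"stage dfc: inconsistent window counts across subjects: {sorted(W)}")
    z_stack = np.stack(z_list)  # (subjects, W, pairs)
    _stage("dfc windows done")

    # --- residualization -------------------------------------------------
    cov_cols = [c for c in config.covariate_columns if c in manifest.columns]
    if cov_cols:
        z_stack = dfc.residualize(z_stack, manifest[cov_cols])

    names = tcs[0].network_names
    N = len(names)
    variability = {
        tc.subject_id: dfc.connectivity_variability(z_stack[i], names)
        for i, tc in enumerate(tcs)
    }
    _stage("variability done")

    # --- state clustering -------------------------------------------------
    n_sub, n_win, _ = z_stack.shape
    features = z_stack.reshape(n_sub * n_win, -1)
    validity_curve = None
    if config.k is None:
        k_star, validity_curve, _ = states.select_k(
            features, range(config.k_min, config.k_max + 1),
            n_init=config.sweep_n_init, max_iter=config.max_iter,
            seed=int(rng.integers(2**31 - 1)),
        )
    else:
        k_star = config.k
    model = states.kmeans_l1(features, k_star, n_init=config.n_init,
                             max_iter=config.max_iter,
                             seed=int(rng.integers(2**31 - 1)))
    model, _ = states.relabel_by_frequency(model)
    assignments = {
        tc.subject_id: model.assignments[i * n_win:(i + 1) * n_win] + 1
        for i, tc in enumerate(tcs)
    }
    per_state, per_subject = states.state_metrics(
        assignments, states=list(range(1, k_star + 1))
    )
    _stage("states done")

    # --- network dynamics -------------------------------------------------
    efficiency: dict[str, netdyn.EfficiencySeries] = {}
    if config.run_efficiency:
        grid = netdyn.DensityGrid.default(
            N, config.density_min, config.density_max, config.density_max_points
        )
        for i, tc in enumerate(tcs):
            mats = dfc.triu_to_matrix(np.abs(z_stack[i]), N)
            efficiency[tc.subject_id] = netdyn.efficiency_dynamics(mats, grid)
    _stage("netdyn done")

    # --- group statistics -------------------------------------------------
    group_stats = _group_statistics(manifest, variability, per_state, per_subject,
                                    efficiency, config, rng)
    _stage("stats done")

    return PipelineResult(
        taper=taper, lambdas=lambdas, z_windows=z_stack, variability=variability,
        cluster_model=model, selected_k=k_star, validity_curve=validity_curve,
        assignments=assignments, per_state_metrics=per_state,
        per_subject_metrics=per_subject, efficiency=efficiency,
        group_stats=group_stats, manifest=manifest, cleaning_reports=reports,
    )


def _group_statistics(manifest, variability, per_state, per_subject,
                      efficiency, config, rng) -> dict:
    """Omnibus + univariate group comparisons of the dynamic measures."""
    out: dict = {}
    groups = manifest.set_index("subject_id")["group"]
    labels = sorted(groups.unique())
    if len(labels) < 2:
        return out

    def by_group(series: pd.Series) -> list[np.ndarray]:
        return [series[groups[groups == g].index].to_numpy(dtype=float) for g in labels]

    # variability: MANOVA over per-network mean SD
    sids = list(groups.index)
    net_sd = np.array([variability[s].network_mean for s in sids if s in variability])
    glab = np.array([groups[s] for s in sids if s in variability])
    if net_sd.shape[0] >= net_sd.shape[1] + len(labels):
        stat, p = stats.nonparametric_manova(
            net_sd, glab, n_perm=config.n_perm, seed=int(rng.integers(2**31 - 1))
        )
        out["variability_manova"] = {"pillai": stat, "p": p}
    overall = pd.Series({s: variability[s].overall_mean for s in sids if s in variability})
    H, df, p = stats.kruskal_wallis(by_group(overall))
    out["overall_sd_kruskal"] = {"H": H, "df": df, "p": p}

    # state metrics: KW + Dunn per state for frequency and dwell
    out["state_tests"] = {}
    for measure in ("frequency", "mean_dwell"):
        for s, sub in per_state.groupby("state"):
            ser = sub.set_index("subject_id")[measure].dropna()
            gs = [ser[ser.index.intersection(groups[groups == g].index)].to_numpy()
                  for g in labels]
            if any(len(g) < 2 for g in gs):
                continue
            H, df, p = stats.kruskal_wallis(gs)
            dunn = stats.dunn_posthoc(gs, labels=labels)
            out["state_tests"][f"{measure}_state{s}"] = {
                "H": H, "df": df, "p": p,
                "dunn": dunn.to_dict(orient="records"),
            }

    # transitions / intertransition interval
    for measure in ("n_transitions", "intertransition_interval"):
        ser = per_subject.set_index("subject_id")[measure]
        H, df, p = stats.kruskal_wallis(by_group(ser))
        out[f"{measure}_kruskal"] = {"H": H, "df": df, "p": p}

    # efficiency variability
    if efficiency:
        for name, attr in (("global", "sd_global"), ("local", "sd_local")):
            ser = pd.Series({s: getattr(efficiency[s], attr) for s in sids if s in efficiency})
            H, df, p = stats.kruskal_wallis(by_group(ser))
            dunn = stats.dunn_posthoc(by_group(ser), labels=labels)
            out[f"{name}_efficiency_sd"] = {
                "H": H, "df": df, "p": p, "dunn": dunn.to_dict(orient="records"),
            }
    return out


def window_size_sweep(
    tcs: list[TimecourseSet],
    manifest: pd.DataFrame,
    config: RunConfig,
    widths: range = range(18, 29),
) -> dict[int, dict[str, dfc.VariabilityResult]]:
    """Robustness sweep over window widths: rerun the windowing -> Fisher z
    -> residualize -> SD stages at each width, returning per-width,
    per-subject variability results (one result set per width)."""
    out: dict[int, dict[str, dfc.VariabilityResult]] = {}
    cov_cols = [c for c in config.covariate_columns if c in manifest.columns]
    for w in widths:
        taper = dfc.make_taper(w, config.window_sigma_tr, config.window_step_tr)
        z_list = []
        for tc in tcs:
            covs = dfc.windowed_covariance(tc.data, taper)
            if config.lambda_grid is not None:
                sel = dfc.select_lambda(covs, np.asarray(config.lambda_grid),
                                        n_folds=config.lambda_folds)
                covs = dfc.regularized_windows(covs, sel.chosen)
            z_list.append(dfc.triu_vector(dfc.to_fisher_z(covs)))
        z_stack = np.stack(z_list)
        if cov_cols:
            z_stack = dfc.residualize(z_stack, manifest[cov_cols])
        names = tcs[0].network_names
        out[w] = {
            tc.subject_id: dfc.connectivity_variability(z_stack[i], names)
            for i, tc in enumerate(tcs)
        }
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Disk-to-disk run: read manifest + TSVs, analyze, write the output tree."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(config.manifest_path)
    tcs = read_timecourses(config.timecourse_dir, manifest, config.tr)
    result = process_cohort(tcs, manifest, config)

    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    write_json({**stamp, "lambdas": result.lambdas,
                "selected_k": result.selected_k}, out / "run_summary.json")
    if result.validity_curve is not None:
        result.validity_curve.to_csv(out / "validity_curve.csv", index=False)
    rows = []
    for sid, a in result.assignments.items():
        rows.extend({"subject_id": sid, "window_index": i, "state": int(s)}
                    for i, s in enumerate(a))
    pd.DataFrame(rows).to_csv(out / "assignments.tsv", sep="\t", index=False)
    result.per_state_metrics.to_csv(out / "state_metrics.csv", index=False)
    result.per_subject_metrics.to_csv(out / "subject_metrics.csv", index=False)
    sd_rows = {sid: v.network_mean for sid, v in result.variability.items()}
    names = result.variability[next(iter(result.variability))].network_names
    pd.DataFrame(sd_rows, index=names if names else None).T.to_csv(out / "network_sd.csv")
    if result.efficiency:
        eff = {sid: {"sd_global": e.sd_global, "sd_local": e.sd_local}
               for sid, e in result.efficiency.items()}
        write_json({**stamp, "efficiency": eff}, out / "efficiency_summary.json")
    write_json({**stamp, "group_stats": result.group_stats}, out / "group_stats.json")
    cleaning = {sid: rep.to_dict() for sid, rep in result.cleaning_reports.items()}
    write_json({**stamp, "reports": cleaning}, out / "cleaning_reports.json")
    logger.info("pipeline complete: %d subjects, k=%d", len(tcs), result.selected_k)
    return out
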