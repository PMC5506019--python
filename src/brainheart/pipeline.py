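"""Orchestration of the full analysis graph on a synthetic cohort.

Stage order: ``synth`` (cohort generation) -> ``physio`` (PPG to heart
rate) and ``preprocess`` (temporal preprocessing) -> ``seedfc`` (seed-based
z-maps) and ``gica`` (group ICA, dual regression, inter-network FC) ->
``coupling`` (sliding-window FC-HR synchronization) -> ``stats``
(behaviour regressions) -> ``report``. Each stage writes its tables under
the run directory and appends to the run manifest; the in-memory context is
cached (pickle) after every stage so individual stages can be re-run from
the command line.
"""

from __future__ import annotations

import hashlib
import json
import pickle
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import coupling as cpl
from . import gica, physio, seedfc, stats
from .config import RunConfig
from .preprocess import preprocess_session
from .synth import (
    INTERVENTIONS,
    NETWORK_NAMES,
    CouplingSpec,
    make_network_atlas,
    simulate_cohort,
)

__all__ = ["run_pipeline", "report", "StageError", "RunContext", "STAGES"]

REST_SESSIONS = ("rest_baseline", "rest_post_gratitude", "rest_post_resentment")
STAGES = ("synth", "physio", "preprocess", "seedfc", "gica", "coupling", "stats")


class StageError(RuntimeError):
    def __init__(self, stage: str, msg: str):
        super().__init__(f"stage '{stage}': {msg}")
        self.stage = stage


@dataclass
class RunContext:
    config: RunConfig
    cohort: object = None
    network_labels: list[str] = field(default_factory=list)
    hr_windows: dict = field(default_factory=dict)  # (sid, cond) -> WindowedSeries
    hr_means: pd.DataFrame | None = None
    preprocessed: dict = field(default_factory=dict)  # (sid, cond) -> TimeSeriesImage
    zmaps: dict = field(default_factory=dict)  # (seed, cond) -> (n_subj, V) array
    ica: object = None
    matched: dict = field(default_factory=dict)
    fc_matrices: dict = field(default_factory=dict)  # (sid, cond) -> FCMatrix
    edge_sync: dict = field(default_factory=dict)  # cond -> DataFrame
    manifest: dict = field(default_factory=dict)

    def subjects(self):
        return self.cohort.subjects

    def grid(self):
        cfg = self.config
        n_vol = self.cohort.spec.n_volumes - cfg.n_discard
        return cpl.window_grid(n_vol, self.cohort.spec.tr_s, cfg.window_s, cfg.step_s)


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _record(ctx: RunContext, out: Path, path: Path) -> None:
    ctx.manifest.setdefault("outputs", {})[str(path.relative_to(out))] = _sha256_file(path)


def _save_cache(ctx: RunContext, out: Path) -> None:
    cache = out / "cache"
    cache.mkdir(exist_ok=True)
    with open(cache / "context.pkl", "wb") as fh:
        pickle.dump(ctx, fh)


def load_context(out_dir: str | Path) -> RunContext:
    path = Path(out_dir) / "cache" / "context.pkl"
    if not path.exists():
        raise FileNotFoundError(
            f"no cached run context at {path}; run earlier stages first"
        )
    with open(path, "rb") as fh:
        return pickle.load(fh)


# ---------------------------------------------------------------------------
# stages

def stage_synth(ctx: RunContext, out: Path) -> None:
    cfg = ctx.config
    overrides = dict(cfg.synth_overrides)
    overrides.setdefault("random_seed", cfg.master_seed)
    spec = CouplingSpec(**overrides)
    atlas = make_network_atlas(cfg.grid_shape, cfg.n_networks, seed=cfg.master_seed)
    ctx.cohort = simulate_cohort(cfg.n_subjects, spec, atlas, seed=cfg.master_seed)
    ctx.network_labels = NETWORK_NAMES[: atlas.n_networks]
    ctx.cohort.behaviors.to_csv(out / "behaviors.tsv", sep="\t", index=False)
    _record(ctx, out, out / "behaviors.tsv")


def stage_physio(ctx: RunContext, out: Path) -> None:
    grid = ctx.grid()
    rows = []
    for subj in ctx.subjects():
        for cond in INTERVENTIONS:
            bundle = subj.sessions.get(cond)
            if bundle is None or bundle.ppg is None:
                continue
            beats = physio.detect_beats(bundle.ppg)
            hr = physio.beats_to_hr(beats, start_time_s=bundle.ppg.start_time_s)
            ctx.hr_windows[(subj.subject_id, cond)] = physio.windowed_hr(hr, grid)
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "condition": cond,
                    "mean_hr_bpm": physio.session_mean_hr(hr),
                    "n_beats": beats.beat_times_ms.size,
                    "n_artifacts": beats.n_artifacts,
                }
            )
    ctx.hr_means = pd.DataFrame(rows)
    ctx.hr_means.to_csv(out / "hr_sessions.tsv", sep="\t", index=False)
    _record(ctx, out, out / "hr_sessions.tsv")

    # session-mean paired t (gratitude vs resentment)
    wide = ctx.hr_means.pivot(index="subject_id", columns="condition", values="mean_hr_bpm")
    res = stats.paired_t(
        wide["gratitude"].to_numpy(), wide["resentment"].to_numpy(),
        contrast_label="mean HR: gratitude - resentment",
    )
    summary = {
        "contrast": res.contrast_label,
        "t": float(res.stat_map[0]),
        "df": res.df[0],
        "p": float(res.p_map[0]),
        "mean_difference_bpm": float(
            (wide["gratitude"] - wide["resentment"]).mean()
        ),
    }
    with open(out / "hr_paired_t.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    _record(ctx, out, out / "hr_paired_t.json")

    # per-window paired t, reported uncorrected at both conventional thresholds
    grid_n = ctx.grid().n_windows
    g = np.vstack([
        ctx.hr_windows[(s.subject_id, "gratitude")].values for s in ctx.subjects()
    ])
    r = np.vstack([
        ctx.hr_windows[(s.subject_id, "resentment")].values for s in ctx.subjects()
    ])
    win_rows = []
    for w in range(grid_n):
        ok = np.isfinite(g[:, w]) & np.isfinite(r[:, w])
        if ok.sum() < 3:
            win_rows.append({"window": w, "t": np.nan, "p": np.nan})
            continue
        res_w = stats.paired_t(g[ok, w], r[ok, w])
        win_rows.append(
            {
                "window": w,
                "start_s": ctx.grid().window_starts_s[w],
                "t": float(res_w.stat_map[0]),
                "p": float(res_w.p_map[0]),
                "sig_p05_uncorrected": bool(res_w.p_map[0] < 0.05),
                "sig_p005_uncorrected": bool(res_w.p_map[0] < 0.005),
            }
        )
    pd.DataFrame(win_rows).to_csv(out / "hr_windowwise_t.tsv", sep="\t", index=False)
    _record(ctx, out, out / "hr_windowwise_t.tsv")


def stage_preprocess(ctx: RunContext, out: Path) -> None:
    cfg = ctx.config
    atlas = ctx.cohort.atlas
    masks = {"wm": atlas.wm_mask, "csf": atlas.csf_mask}
    for subj in ctx.subjects():
        for cond, bundle in subj.sessions.items():
            if bundle.image is None:
                raise StageError("preprocess", f"no image for {subj.subject_id}/{cond}")
            ctx.preprocessed[(subj.subject_id, cond)] = preprocess_session(
                bundle.image,
                bundle.motion,
                masks,
                n_discard=cfg.n_discard,
                fwhm_mm=cfg.fwhm_mm,
                low_hz=cfg.low_hz,
                high_hz=cfg.high_hz,
            )


def _zmap_stack(ctx: RunContext, seed_name: str, cond: str) -> np.ndarray:
    return ctx.zmaps[(seed_name, cond)]


def stage_seedfc(ctx: RunContext, out: Path) -> None:
    cfg = ctx.config
    atlas = ctx.cohort.atlas
    mask = atlas.analysis_mask
    rois = {
        name: seedfc.make_sphere_roi(
            name, atlas.seed_mm(name), cfg.roi_radius_mm, atlas.grid_shape, atlas.affine
        )
        for name in cfg.seed_names
    }
    conds = list(ctx.subjects()[0].sessions)
    for seed_name, roi in rois.items():
        for cond in conds:
            maps = []
            for subj in ctx.subjects():
                img = ctx.preprocessed[(subj.subject_id, cond)]
                series = seedfc.roi_timeseries(img, roi)
                zm = seedfc.fc_map(img, series, mask, seed_name, cond)
                maps.append(zm.values)
            ctx.zmaps[(seed_name, cond)] = np.vstack(maps)

    if not cfg.voxelwise_contrasts:
        return
    rng_seed = cfg.master_seed + 1
    rows = []
    for seed_name in cfg.seed_names:
        # paired contrast: during gratitude vs during resentment
        a = np.nan_to_num(_zmap_stack(ctx, seed_name, "gratitude"))
        b = np.nan_to_num(_zmap_stack(ctx, seed_name, "resentment"))
        table = stats.cluster_inference(
            a, grid_shape=atlas.grid_shape, mask=mask, cdt_p=cfg.cdt_fc,
            n_perm=cfg.n_permutations, scheme="condition_swap", data_b=b,
            alpha=cfg.fwe_alpha, connectivity=cfg.connectivity,
            seed=rng_seed, affine=atlas.affine,
        )
        rows += _cluster_rows(table, seed_name, "gratitude_vs_resentment", cfg.fwe_alpha)
        # RM-ANOVA across the three resting states
        rest = np.stack(
            [np.nan_to_num(_zmap_stack(ctx, seed_name, c)) for c in REST_SESSIONS], axis=1
        )
        table_f = stats.cluster_inference(
            rest, grid_shape=atlas.grid_shape, mask=mask, cdt_p=cfg.cdt_fc,
            n_perm=cfg.n_permutations, scheme="condition_swap",
            alpha=cfg.fwe_alpha, connectivity=cfg.connectivity,
            seed=rng_seed, affine=atlas.affine,
        )
        rows += _cluster_rows(table_f, seed_name, "rm_anova_rest", cfg.fwe_alpha)
        # post-hoc pairwise on significant RM-ANOVA clusters
        for ci, cluster in enumerate(table_f.significant(cfg.fwe_alpha)):
            members = (table_f.labels == ci + 1)[mask]
            vals = rest[:, :, members].mean(axis=2)  # (n, 3)
            post = stats.posthoc_pairwise(vals)
            for (i, j), pres in post.items():
                rows.append(
                    {
                        "seed": seed_name,
                        "contrast": f"posthoc_{REST_SESSIONS[i]}_vs_{REST_SESSIONS[j]}",
                        "peak_x_mm": cluster.peak_mm[0],
                        "peak_y_mm": cluster.peak_mm[1],
                        "peak_z_mm": cluster.peak_mm[2],
                        "n_voxels": cluster.n_voxels,
                        "stat": float(pres.stat_map[0]),
                        "p": float(pres.p_map[0]),
                        "significant": bool(pres.p_map[0] < 0.05),
                    }
                )
    pd.DataFrame(rows).to_csv(out / "seedfc_clusters.tsv", sep="\t", index=False)
    _record(ctx, out, out / "seedfc_clusters.tsv")


def _cluster_rows(table: stats.ClusterTable, seed_name: str, contrast: str, alpha: float):
    rows = []
    if not table.clusters:
        rows.append(
            {
                "seed": seed_name, "contrast": contrast, "peak_x_mm": np.nan,
                "peak_y_mm": np.nan, "peak_z_mm": np.nan, "n_voxels": 0,
                "stat": np.nan, "p": np.nan, "significant": False,
                "note": "not significant",
            }
        )
        return rows
    for c in table.clusters:
        rows.append(
            {
                "seed": seed_name, "contrast": contrast,
                "peak_x_mm": c.peak_mm[0], "peak_y_mm": c.peak_mm[1],
                "peak_z_mm": c.peak_mm[2], "n_voxels": c.n_voxels,
                "stat": c.peak_stat, "p": c.p_fwe,
                "significant": bool(c.p_fwe < alpha), "note": "",
            }
        )
    return rows


def stage_gica(ctx: RunContext, out: Path) -> None:
    cfg = ctx.config
    atlas = ctx.cohort.atlas
    mask = atlas.analysis_mask
    conds = list(ctx.subjects()[0].sessions)

    pcs = []
    var_rows = []
    for subj in ctx.subjects():
        mats = [
            ctx.preprocessed[(subj.subject_id, c)].timeseries_2d()[:, mask.ravel()]
            for c in conds
        ]
        sp = gica.subject_pca(np.vstack(mats), n_pcs=cfg.n_pcs, subject_id=subj.subject_id)
        pcs.append(sp)
        var_rows.append(
            {"subject_id": subj.subject_id, "variance_explained": sp.variance_explained}
        )
    group = gica.concatenate_pcs(pcs)
    whitened, _ = gica.group_pca_whiten(group, n_dims=cfg.n_components)
    try:
        ica = gica.infomax_ica(
            whitened, seed=cfg.master_seed, max_iter=cfg.ica_max_iter, tol=cfg.ica_tol
        )
    except gica.ConvergenceError as exc:
        raise StageError("gica", str(exc)) from exc
    ctx.ica = ica

    templates = {
        name: atlas.network_mask(k + 1)[mask].astype(float)
        for k, name in enumerate(ctx.network_labels)
    }
    assignment, signs, corrs = gica.match_templates(ica.group_maps, templates)
    ctx.matched = {"assignment": assignment, "signs": signs, "correlations": corrs}

    for subj in ctx.subjects():
        for cond in conds:
            x = ctx.preprocessed[(subj.subject_id, cond)].timeseries_2d()[:, mask.ravel()]
            tc, smaps = gica.dual_regression(x, ica.group_maps)
            ica.subject_timecourses[(subj.subject_id, cond)] = tc
            net_tc = np.column_stack(
                [signs[n] * tc[:, assignment[n]] for n in ctx.network_labels]
            )
            ctx.fc_matrices[(subj.subject_id, cond)] = gica.internetwork_fc(
                net_tc, ctx.network_labels, session_label=cond
            )

    pd.DataFrame(var_rows).to_csv(out / "gica_variance.tsv", sep="\t", index=False)
    _record(ctx, out, out / "gica_variance.tsv")
    with open(out / "gica_matching.json", "w") as fh:
        json.dump(
            {"assignment": assignment, "signs": signs, "correlations": corrs}, fh, indent=2
        )
    _record(ctx, out, out / "gica_matching.json")

    # inter-network edge statistics
    edges = list(combinations(ctx.network_labels, 2))
    def edge_matrix(cond):
        return np.array(
            [
                [ctx.fc_matrices[(s.subject_id, cond)].edge(a, b) for a, b in edges]
                for s in ctx.subjects()
            ]
        )

    rows = []
    zg, zr = edge_matrix("gratitude"), edge_matrix("resentment")
    res = stats.paired_t(zg, zr, contrast_label="gratitude vs resentment")
    fdr = stats.fdr_bh(res.p_map, q=cfg.fdr_q)
    for e, (a, b) in enumerate(edges):
        rows.append(
            {
                "edge": f"{a}-{b}", "contrast": "gratitude_vs_resentment",
                "stat": float(res.stat_map[e]), "p": float(res.p_map[e]),
                "p_fdr": float(fdr.p_adjusted[e]), "significant": bool(fdr.significant[e]),
            }
        )
    rest = np.stack([edge_matrix(c) for c in REST_SESSIONS], axis=1)  # (n, 3, E)
    res_f = stats.rm_anova(rest, contrast_label="rest sessions RM-ANOVA")
    fdr_f = stats.fdr_bh(res_f.p_map, q=cfg.fdr_q)
    post = stats.posthoc_pairwise(rest)
    for e, (a, b) in enumerate(edges):
        rows.append(
            {
                "edge": f"{a}-{b}", "contrast": "rm_anova_rest",
                "stat": float(res_f.stat_map[e]), "p": float(res_f.p_map[e]),
                "p_fdr": float(fdr_f.p_adjusted[e]),
                "significant": bool(fdr_f.significant[e]),
            }
        )
        if fdr_f.significant[e]:
            for (i, j), pres in post.items():
                rows.append(
                    {
                        "edge": f"{a}-{b}",
                        "contrast": f"posthoc_{REST_SESSIONS[i]}_vs_{REST_SESSIONS[j]}",
                        "stat": float(pres.stat_map[e]), "p": float(pres.p_map[e]),
                        "p_fdr": np.nan, "significant": bool(pres.p_map[e] < 0.05),
                    }
                )
    pd.DataFrame(rows).to_csv(out / "internetwork_fc_stats.tsv", sep="\t", index=False)
    _record(ctx, out, out / "internetwork_fc_stats.tsv")

    # mean FC matrix per session for reporting (diagonals are all-NaN by
    # construction, which nanmean would warn about)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mats = {
            cond: np.nanmean(
                [ctx.fc_matrices[(s.subject_id, cond)].z_values for s in ctx.subjects()], axis=0
            )
            for cond in conds
        }
    np.savez(out / "fc_matrices_mean.npz", labels=ctx.network_labels, **mats)
    _record(ctx, out, out / "fc_matrices_mean.npz")


def stage_coupling(ctx: RunContext, out: Path) -> None:
    cfg = ctx.config
    atlas = ctx.cohort.atlas
    mask = atlas.analysis_mask
    grid = ctx.grid()
    edges = list(combinations(ctx.network_labels, 2))
    rows = []
    for cond in INTERVENTIONS:
        per_subject = []
        for subj in ctx.subjects():
            whr = ctx.hr_windows[(subj.subject_id, cond)]
            fcm = ctx.fc_matrices.get((subj.subject_id, cond))
            tc = ctx.ica.subject_timecourses[(subj.subject_id, cond)]
            assignment = ctx.matched["assignment"]
            signs = ctx.matched["signs"]
            r_edges = []
            for a, b in edges:
                sa = signs[a] * tc[:, assignment[a]]
                sb = signs[b] * tc[:, assignment[b]]
                wfc = cpl.sliding_fc(sa, sb, grid)
                r_edges.append(cpl.fc_hr_sync(wfc, whr))
            per_subject.append(r_edges)
        sync = np.array(per_subject)  # (n, E)
        df = pd.DataFrame(
            sync, columns=[f"{a}-{b}" for a, b in edges],
            index=[s.subject_id for s in ctx.subjects()],
        )
        ctx.edge_sync[cond] = df
        res, fdr = cpl.group_sync(sync, mode="edges", q=cfg.fdr_q_exploratory)
        for e, (a, b) in enumerate(edges):
            rows.append(
                {
                    "condition": cond, "edge": f"{a}-{b}",
                    "mean_sync_r": float(np.nanmean(sync[:, e])),
                    "t": float(res.stat_map[e]), "p": float(res.p_map[e]),
                    "p_fdr": float(fdr.p_adjusted[e]),
                    "significant": bool(fdr.significant[e]),
                }
            )
        df.to_csv(out / f"edge_sync_{cond}.tsv", sep="\t")
        _record(ctx, out, out / f"edge_sync_{cond}.tsv")
    pd.DataFrame(rows).to_csv(out / "edge_sync_stats.tsv", sep="\t", index=False)
    _record(ctx, out, out / "edge_sync_stats.tsv")

    if not cfg.voxelwise_sync:
        return
    # voxelwise seed-based FC-HR synchronization during each intervention
    roi = seedfc.make_sphere_roi(
        cfg.sync_seed_roi, atlas.seed_mm(cfg.sync_seed_roi), cfg.roi_radius_mm,
        atlas.grid_shape, atlas.affine,
    )
    vrows = []
    for cond in INTERVENTIONS:
        subj_r = []
        for subj in ctx.subjects():
            img = ctx.preprocessed[(subj.subject_id, cond)]
            series = seedfc.roi_timeseries(img, roi)
            stack = img.data[mask]  # (V, t)
            wfc = cpl.sliding_fc(series, stack, grid)
            subj_r.append(cpl.fc_hr_sync(wfc, ctx.hr_windows[(subj.subject_id, cond)]))
        subj_r = np.vstack(subj_r)
        z = seedfc.fisher_z(np.nan_to_num(subj_r))
        table = stats.cluster_inference(
            z, grid_shape=atlas.grid_shape, mask=mask, cdt_p=cfg.cdt_sync,
            n_perm=cfg.n_permutations, scheme="sign_flip", alpha=cfg.fwe_alpha,
            connectivity=cfg.connectivity, seed=cfg.master_seed + 2, affine=atlas.affine,
        )
        vrows += _cluster_rows(table, cfg.sync_seed_roi, f"sync_{cond}", cfg.fwe_alpha)
    pd.DataFrame(vrows).to_csv(out / "voxel_sync_clusters.tsv", sep="\t", index=False)
    _record(ctx, out, out / "voxel_sync_clusters.tsv")


_BEHAVIOR_SEEDS = {
    "amygdala_l": ("hads_anxiety", "hads_depression"),
    "amygdala_r": ("hads_anxiety", "hads_depression"),
    "na_l": ("sdt_autonomy", "sdt_competence", "sdt_relatedness"),
    "na_r": ("sdt_autonomy", "sdt_competence", "sdt_relatedness"),
}


def stage_stats(ctx: RunContext, out: Path) -> None:
    """Behaviour-connectivity relationships in the three resting states."""
    cfg = ctx.config
    atlas = ctx.cohort.atlas
    mask = atlas.analysis_mask
    behaviors = ctx.cohort.behaviors
    rows = []
    if cfg.behavior_regressions:
        for seed_name, scores in _BEHAVIOR_SEEDS.items():
            if seed_name not in cfg.seed_names:
                continue
            for cond in REST_SESSIONS:
                maps = np.nan_to_num(_zmap_stack(ctx, seed_name, cond))
                for score_name in scores:
                    score = behaviors[score_name].to_numpy(dtype=float)
                    table = stats.cluster_inference(
                        maps, grid_shape=atlas.grid_shape, mask=mask,
                        cdt_p=cfg.cdt_sync, n_perm=cfg.n_permutations,
                        scheme="score_permute", score=score, alpha=cfg.fwe_alpha,
                        connectivity=cfg.connectivity, seed=cfg.master_seed + 3,
                        affine=atlas.affine,
                    )
                    for row in _cluster_rows(
                        table, seed_name, f"{cond}:{score_name}", cfg.fwe_alpha
                    ):
                        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "behavior_clusters.tsv", sep="\t", index=False)
    _record(ctx, out, out / "behavior_clusters.tsv")

    # edge-level Pearson correlations between behaviour and inter-network FC
    edges = list(combinations(ctx.network_labels, 2))
    erows = []
    for cond in REST_SESSIONS:
        edge_z = np.array(
            [
                [ctx.fc_matrices[(s.subject_id, cond)].edge(a, b) for a, b in edges]
                for s in ctx.subjects()
            ]
        )
        for score_name in behaviors.columns.drop("subject_id"):
            score = behaviors[score_name].to_numpy(dtype=float)
            for e, (a, b) in enumerate(edges):
                from scipy.stats import pearsonr

                r, p = pearsonr(score, edge_z[:, e])
                erows.append(
                    {
                        "session": cond, "score": score_name, "edge": f"{a}-{b}",
                        "r": float(r), "p": float(p),
                    }
                )
    pd.DataFrame(erows).to_csv(out / "behavior_edge_correlations.tsv", sep="\t", index=False)
    _record(ctx, out, out / "behavior_edge_correlations.tsv")


_STAGE_FUNCS = {
    "synth": stage_synth,
    "physio": stage_physio,
    "preprocess": stage_preprocess,
    "seedfc": stage_seedfc,
    "gica": stage_gica,
    "coupling": stage_coupling,
    "stats": stage_stats,
}


def run_stage(name: str, ctx: RunContext, out_dir: str | Path) -> RunContext:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    try:
        _STAGE_FUNCS[name](ctx, out)
    except StageError:
        raise
    except Exception as exc:  # annotate with stage name per the error contract
        raise StageError(name, str(exc)) from exc
    ctx.manifest.setdefault("stage_seconds", {})[name] = round(
        time.perf_counter() - t0, 3
    )
    _save_cache(ctx, out)
    return ctx


def run_pipeline(
    config: RunConfig, out_dir: str | Path, stages: tuple[str, ...] = STAGES
) -> dict:
    """Run the analysis graph and return the run manifest."""
    from importlib.metadata import version as _pkg_version

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ctx = RunContext(config=config)
    ctx.manifest = {
        "config": config.to_dict(),
        "master_seed": config.master_seed,
    }
    try:
        ctx.manifest["version"] = _pkg_version("brainheart")
    except Exception:
        ctx.manifest["version"] = "unknown"
    for name in stages:
        ctx = run_stage(name, ctx, out)
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(ctx.manifest, fh, indent=2, sort_keys=True)
    return ctx.manifest


# ---------------------------------------------------------------------------
# reporting

def report(out_dir: str | Path) -> list[Path]:
    """Render human-readable tables and figures from a completed run."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    produced = []

    hr = pd.read_csv(out / "hr_windowwise_t.tsv", sep="\t")
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(hr["start_s"], hr["t"], marker="o")
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("window start (s)")
    ax.set_ylabel("paired t (gratitude - resentment)")
    ax.set_title("Window-wise HR difference between interventions")
    fig.tight_layout()
    fig.savefig(out / "hr_windows.png", dpi=120)
    plt.close(fig)
    produced.append(out / "hr_windows.png")

    npz = np.load(out / "fc_matrices_mean.npz", allow_pickle=True)
    labels = list(npz["labels"])
    conds = [k for k in npz.files if k != "labels"]
    fig, axes = plt.subplots(1, len(conds), figsize=(3.2 * len(conds), 3.2))
    for ax, cond in zip(np.atleast_1d(axes), conds):
        m = npz[cond]
        im = ax.imshow(m, vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=6)
        ax.set_yticks(range(len(labels)), labels, fontsize=6)
        ax.set_title(cond, fontsize=8)
    fig.colorbar(im, ax=np.atleast_1d(axes).tolist(), shrink=0.7)
    fig.savefig(out / "fc_heatmaps.png", dpi=120)
    plt.close(fig)
    produced.append(out / "fc_heatmaps.png")

    # formatted cluster tables (peak mm, Nvox, peak stat), sorted by size
    lines = []
    for name in ("seedfc_clusters.tsv", "voxel_sync_clusters.tsv", "behavior_clusters.tsv"):
        path = out / name
        if not path.exists():
            continue
        df = pd.read_csv(path, sep="\t")
        lines.append(f"## {name}")
        if df.empty or (df.get("n_voxels", pd.Series(dtype=int)) == 0).all():
            lines.append("not significant")
        else:
            df = df.sort_values("n_voxels", ascending=False)
            lines.append(df.to_string(index=False))
        lines.append("")
    (out / "report.txt").write_text("\n".join(lines))
    produced.append(out / "report.txt")
    return produced
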