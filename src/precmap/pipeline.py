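"""End-to-end orchestration: simulate → censor → priors → fit → metrics → stats.

Each stage reads the previous stage's outputs from the run directory and
writes its own, so any stage can be re-run from intermediates; a manifest
records the configuration hash, the per-stage seeds (spawned from the single
global seed by a fixed counter scheme) and per-stage record counts.
Reference sessions used to build the empirical prior are excluded from every
downstream analysis.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .cohort import fit_all_networks, DEFAULT_TERM_EQUIVALENT_WINDOW
from .mesh import make_icosphere
from .metrics import session_records, wta_parcellation
from .preprocess import censor_session, extract_block, normalize_series, smooth_geodesic
from .preprocess import BoldSeries
from .priors import build_template, concat_reduce, match_components, spatial_ica
from .priors import TemplatePrior
from .subject_model import fit_template_ica, threshold_masks, compute_tstat
from .synthetic import CohortParams, make_templates, simulate_cohort

log = logging.getLogger("precmap")

STAGES = ["simulate", "censor", "priors", "fit", "metrics", "stats"]


@dataclass
class PipelineConfig:
    """Pipeline constants; defaults are the intended acquisition conditions
    (2300-frame session at TR 392 ms, 1600-frame retained block, 1.5×IQR
    DVARS threshold, 10% exclusion, 3 mm FWHM smoothing, eight networks)."""

    block_length: int = 1600
    dvars_iqr_mult: float = 1.5
    exclusion_fraction: float = 0.10
    fwhm_mm: float = 3.0
    n_networks: int = 8
    alpha: float = 0.05
    gamma: float = 0.0
    gamma_peak_fraction: float = 0.15
    correction: str = "bonferroni"
    seed: int = 0
    # simulation block
    mesh_subdivisions: int = 3
    mesh_radius_mm: float = 50.0
    n_frames: int = 2300
    n_term: int = 40
    n_preterm: int = 20
    n_longitudinal_pairs: int = 0
    n_reference: int = 12
    template_smoothness_mm: float = 10.0
    template_var_scale: float = 0.05
    age_slope: float = 0.05
    preterm_offset: float = -0.3
    interaction: float = 0.0
    noise_sd: float = 1.0
    # priors block
    pca_factor: int = 4  # PCA reduction dim = pca_factor × n_networks
    correct_noise: bool = True
    # subject-model block
    em_max_iter: int = 100
    em_tol: float = 1e-6

    def to_dict(self) -> dict:
        return asdict(self)


def stage_seed(config_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: child `i` of SeedSequence(config_seed),
    where `i` is the stage's position in the pipeline."""
    idx = STAGES.index(stage)
    child = np.random.SeedSequence(config_seed).spawn(len(STAGES))[idx]
    return int(child.generate_state(1)[0] % (2**31))


@dataclass
class RunState:
    """In-memory handles accumulated while running stages."""

    config: PipelineConfig
    run_dir: Path
    mesh: object = None
    sessions: list = field(default_factory=list)
    cohort_table: pd.DataFrame | None = None
    truth: object = None
    template: TemplatePrior | None = None
    reference_ids: list = field(default_factory=list)
    censor_results: dict = field(default_factory=dict)
    posteriors: dict = field(default_factory=dict)
    masks: dict = field(default_factory=dict)
    records: pd.DataFrame | None = None
    stats: dict = field(default_factory=dict)
    write_outputs: bool = True


def _stage_simulate(state: RunState) -> None:
    cfg = state.config
    seed = stage_seed(cfg.seed, "simulate")
    state.mesh = make_icosphere(cfg.mesh_subdivisions, cfg.mesh_radius_mm)
    template = make_templates(
        state.mesh, cfg.n_networks, cfg.template_smoothness_mm,
        cfg.template_var_scale, seed=seed,
    )
    params = CohortParams(
        age_slope=cfg.age_slope, preterm_offset=cfg.preterm_offset,
        interaction=cfg.interaction, noise_sd=cfg.noise_sd,
    )
    sessions, table, truth = simulate_cohort(
        template, cfg.n_term, cfg.n_preterm, cfg.n_longitudinal_pairs,
        params=params, n_frames=cfg.n_frames, seed=seed,
    )
    state.sessions, state.cohort_table, state.truth = sessions, table, truth
    # reference sample for the empirical prior: sessions at uniform scan-age
    # quantiles across the whole cohort (not an age-extreme subset), so the
    # prior's implicit amplitude level sits mid-cohort and shrinkage does not
    # bias one group more than the other; withheld from downstream analyses
    singles = table[~table["subject_id"].duplicated(keep=False)]
    ranked = singles.sort_values("scan_age").reset_index(drop=True)
    idx = np.unique(np.linspace(0, len(ranked) - 1, cfg.n_reference).round()
                    .astype(int))
    state.reference_ids = ranked.loc[idx, "session_id"].tolist()
    if state.write_outputs:
        d = state.run_dir / "simulate"
        d.mkdir(parents=True, exist_ok=True)
        pio.save_mesh_gifti(state.mesh, d / "mesh.surf.gii")
        pio.save_records(table, d / "cohort.tsv")
        (d / "reference_ids.txt").write_text("\n".join(state.reference_ids))


def _stage_censor(state: RunState) -> None:
    cfg = state.config
    rows = []
    kept = []
    for series in state.sessions:
        res = censor_session(series, cfg.block_length, cfg.dvars_iqr_mult,
                             cfg.exclusion_fraction)
        state.censor_results[series.session_id] = res
        rows.append({
            "session_id": series.session_id,
            "block_start": res.block_start,
            "n_outliers_in_block": res.n_outliers_in_block,
            "mean_dvars": res.mean_dvars_in_block,
            "excluded": res.excluded,
        })
        if res.excluded:
            continue
        block = extract_block(series, res)
        smoothed = smooth_geodesic(block.data, state.mesh, cfg.fwhm_mm)
        kept.append(normalize_series(
            BoldSeries(smoothed, block.tr_seconds, block.session_id)
        ))
    report = pd.DataFrame(rows)
    if state.write_outputs:
        d = state.run_dir / "censor"
        d.mkdir(parents=True, exist_ok=True)
        pio.save_records(report, d / "censor_report.tsv")
    state.sessions = kept
    motion = report.set_index("session_id")["mean_dvars"]
    tab = state.cohort_table.set_index("session_id")
    tab["motion"] = motion
    excluded_ids = report.loc[report["excluded"], "session_id"]
    tab = tab.drop(index=[s for s in excluded_ids if s in tab.index])
    state.cohort_table = tab.reset_index()
    if state.write_outputs:
        pio.save_records(state.cohort_table,
                         state.run_dir / "censor" / "cohort_censored.tsv")


def _stage_priors(state: RunState) -> None:
    cfg = state.config
    seed = stage_seed(cfg.seed, "priors")
    ref = [s for s in state.sessions if s.session_id in state.reference_ids]
    if len(ref) < 2:
        raise RuntimeError("priors stage: fewer than 2 reference sessions survive")
    target_dim = min(cfg.pca_factor * cfg.n_networks,
                     sum(s.n_frames for s in ref))
    reduced, _ = concat_reduce(ref, target_dim)
    decomp = spatial_ica(reduced, cfg.n_networks, seed=seed)
    maps = decomp.group_maps
    if state.truth is not None:
        # automated stand-in for visual network identification: align ICA
        # components to the generator's templates by spatial correlation
        perm, signs = match_components(maps, state.truth.template.mean)
        maps = signs[:, None] * maps[perm]
        names = state.truth.template.network_names
    else:
        names = [f"net{i:02d}" for i in range(cfg.n_networks)]
    state.template = build_template(
        ref, maps, names,
        reference_ids=[s.session_id for s in ref],
        correct_noise=cfg.correct_noise,
    )
    if state.write_outputs:
        d = state.run_dir / "priors"
        d.mkdir(parents=True, exist_ok=True)
        pio.save_maps_gifti(state.template.mean, d / "template_mean.func.gii",
                            names)
        pio.save_maps_gifti(state.template.between_var,
                            d / "template_var.func.gii", names)
        pio.save_manifest(
            {"network_names": names,
             "reference_ids": state.template.reference_ids},
            d / "template.json",
        )


def _stage_fit(state: RunState) -> None:
    cfg = state.config
    seed = stage_seed(cfg.seed, "fit")
    analysis = [s for s in state.sessions
                if s.session_id not in state.template.reference_ids]
    # engagement threshold: at least gamma_peak_fraction of each network's
    # template peak, so "engaged" means a meaningful amplitude, not merely a
    # detectably positive one
    import numpy as _np
    gamma = _np.maximum(cfg.gamma,
                        cfg.gamma_peak_fraction * state.template.mean.max(axis=1))
    for series in analysis:
        post = fit_template_ica(series, state.template,
                                max_iter=cfg.em_max_iter, tol=cfg.em_tol,
                                seed=seed)
        state.posteriors[series.session_id] = post
        state.masks[series.session_id] = threshold_masks(
            post, alpha=cfg.alpha, gamma=gamma, correction=cfg.correction
        )
    if state.write_outputs:
        d = state.run_dir / "fit"
        d.mkdir(parents=True, exist_ok=True)
        pio.save_manifest(
            {"alpha": cfg.alpha, "gamma": cfg.gamma,
             "correction": cfg.correction,
             "n_sessions": len(state.posteriors)},
            d / "fit.json",
        )


def _stage_metrics(state: RunState) -> None:
    d = state.run_dir / "metrics"
    if state.write_outputs:
        d.mkdir(parents=True, exist_ok=True)
    tab = state.cohort_table.set_index("session_id")
    frames = []
    for sid, post in state.posteriors.items():
        if sid in state.template.reference_ids:
            raise RuntimeError(f"reference session {sid} leaked into metrics")
        cov = tab.loc[sid]
        frames.append(session_records(
            post, state.masks[sid], state.mesh,
            {"subject_id": cov["subject_id"], "scan_age": float(cov["scan_age"]),
             "birth_age": float(cov["birth_age"]), "sex": cov["sex"],
             "preterm": bool(cov["preterm"]), "motion": float(cov["motion"])},
        ))
        if state.write_outputs:
            labels = wta_parcellation(compute_tstat(post))
            pio.save_labels_gifti(
                labels, d / f"{sid}_wta.label.gii",
                {i + 1: n for i, n in enumerate(post.network_names)},
            )
    state.records = pd.concat(frames, ignore_index=True)
    if state.write_outputs:
        pio.save_records(state.records, d / "records.tsv")


def _stage_stats(state: RunState) -> None:
    d = state.run_dir / "stats"
    if state.write_outputs:
        d.mkdir(parents=True, exist_ok=True)
    fits = fit_all_networks(state.records, model="age")
    summary = {}
    tables = []
    for network, fit in fits.items():
        t = fit.table.copy()
        t.insert(0, "network", network)
        tables.append(t.reset_index(names="term"))
        summary[network] = {
            "p_scan_age": fit.pvalue("scan_age"),
            "p_preterm": fit.pvalue("preterm"),
            "p_interaction": fit.pvalue("preterm:scan_age"),
            "beta_scan_age": fit.estimate("scan_age"),
            "beta_preterm": fit.estimate("preterm"),
            "n_sessions": fit.n_sessions,
        }
    if state.write_outputs:
        pio.save_records(pd.concat(tables, ignore_index=True),
                         d / "age_model_coefficients.tsv")
    try:
        group = fit_all_networks(state.records, model="group",
                                 age_window=DEFAULT_TERM_EQUIVALENT_WINDOW)
        for network, fit in group.items():
            summary[network]["group_difference"] = fit.extras["group_difference"]
            summary[network]["group_pvalue"] = fit.extras["group_pvalue"]
    except ValueError as exc:
        log.info("group comparison skipped: %s", exc)
    if state.write_outputs:
        pio.save_manifest(summary, d / "summary.json")
    state.stats = summary


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "censor": _stage_censor,
    "priors": _stage_priors,
    "fit": _stage_fit,
    "metrics": _stage_metrics,
    "stats": _stage_stats,
}


_STAGE_SENTINELS = {
    "simulate": "simulate/cohort.tsv",
    "censor": "censor/cohort_censored.tsv",
    "priors": "priors/template.json",
    "fit": "fit/fit.json",
    "metrics": "metrics/records.tsv",
    "stats": "stats/summary.json",
}


def run_pipeline(config: PipelineConfig, run_dir,
                 resume: bool = False) -> RunState:
    """Execute all stages into `run_dir`, writing a manifest at the end.

    With ``resume=True``, stages whose outputs already exist (up to the first
    missing one) are replayed in memory without rewriting their outputs —
    stage-level seeding makes the replay bit-identical — and only stages from
    the first missing intermediate onward are recomputed on disk.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    state = RunState(config=config, run_dir=run_dir)
    first_missing = 0
    if resume:
        for i, stage in enumerate(STAGES):
            if not (run_dir / _STAGE_SENTINELS[stage]).exists():
                first_missing = i
                break
        else:
            first_missing = len(STAGES)
    manifest = {
        "config": config.to_dict(),
        "config_hash": pio.config_hash(config.to_dict()),
        "seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "stages": {},
    }
    for i, stage in enumerate(STAGES):
        state.write_outputs = not resume or i >= first_missing
        t0 = time.perf_counter()
        log.info("stage %s%s ...", stage,
                 "" if state.write_outputs else " (replay)")
        try:
            _STAGE_FUNCS[stage](state)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "completed": True,
            "recomputed": bool(state.write_outputs),
            "seconds": round(time.perf_counter() - t0, 3),
            "n_records": _stage_count(state, stage),
        }
        pio.save_manifest(manifest, run_dir / "manifest.json")
    return state


def _stage_count(state: RunState, stage: str) -> int:
    if stage == "simulate":
        return len(state.cohort_table) if state.cohort_table is not None else 0
    if stage == "censor":
        return len(state.sessions)
    if stage == "priors":
        return len(state.template.reference_ids) if state.template else 0
    if stage == "fit":
        return len(state.posteriors)
    if stage == "metrics":
        return len(state.records) if state.records is not None else 0
    return len(state.stats)
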