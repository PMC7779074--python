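"""End-to-end orchestration: simulate a cohort, run both analysis
approaches, and assemble the summary association table.

The stages mirror the analysis order: simulate (or load) parcellated
rest and task runs per subject -> trim/demean/detrend + 64-parameter
nuisance regression -> canonical-HRF GLM activations and FIR-residual
task FC (GLM approach) in parallel with block-peak activations and
block-to-block FC (peak approach) -> matched-interval rest FC and
delta-GBC maps -> per-subject timescale fits -> activity flow mapping
MAE -> group maps, paired partition contrasts, and pairwise map
associations with surrogate-permutation p-values and bootstrap CIs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import activity_flow, connectivity, peaks, preprocess, surrogates, synthetic, task_glm, timescale
from .core import ParcelTimeSeries, TaskDesign, write_map_tsv, write_matrix_tsv

__all__ = ["AnalysisConfig", "AnalysisOutputs", "run_pipeline", "simulate_subject"]

logger = logging.getLogger(__name__)

MAP_VARIABLES = ["hierarchy", "activation", "fc_change", "timescale", "myelin", "actflow_mae"]


@dataclass
class AnalysisConfig:
    """Everything a run needs; serialized alongside every output directory."""

    n_parcels: int = synthetic.DEFAULT_N_PARCELS
    n_subjects: int = 20
    n_conditions: int = synthetic.DEFAULT_N_CONDITIONS
    blocks_per_condition: int = 3
    block_len_s: float = 15.0
    rest_len_s: float = 15.0
    tr_s: float = synthetic.DEFAULT_TR_S
    rest_n_tr: int = 3200
    n_drop_frames: int = preprocess.DEFAULT_N_DROP_FRAMES
    fir_post_offset_lags: int = task_glm.DEFAULT_FIR_POST_OFFSET_LAGS
    acf_max_lag: int = timescale.DEFAULT_MAX_LAG
    n_surrogates: int = surrogates.DEFAULT_N_SURROGATES
    n_boot: int = 1000
    seed: int = 0
    approach: str = "both"  # glm | peak | both
    positive_only: bool = False
    effect: synthetic.EffectConfig = field(default_factory=synthetic.EffectConfig)

    def __post_init__(self) -> None:
        if self.approach not in ("glm", "peak", "both"):
            raise ValueError("approach must be one of glm | peak | both")
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        if self.rest_len_s < self.n_drop_frames * self.tr_s:
            raise ValueError("leading rest must be longer than the trimmed frames")

    @property
    def approaches(self) -> list[str]:
        return ["glm", "peak"] if self.approach == "both" else [self.approach]

    def to_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o).__name__)

        return json.dumps(dataclasses.asdict(self), default=default, indent=2)


@dataclass
class SubjectResult:
    activation: task_glm.ActivationResult
    abs_beta_map: np.ndarray
    fc_change: np.ndarray
    peak_activation: np.ndarray
    peak_fc_change: np.ndarray
    tau_map: np.ndarray
    actflow_mae: np.ndarray


@dataclass
class AnalysisOutputs:
    config: AnalysisConfig
    ground_truth: synthetic.GroundTruth
    group_maps: dict  # approach -> {variable -> (n_parcels,) map}
    subject_results: list[SubjectResult]
    association_tables: dict  # approach -> DataFrame (var_a, var_b, rho, p, ci)
    contrasts: dict  # approach -> {variable -> (mean_diff, t, p)}
    partition: surrogates.NetworkPartition


def _design(cfg: AnalysisConfig) -> TaskDesign:
    return synthetic.generate_block_design(
        cfg.n_conditions, cfg.blocks_per_condition, cfg.block_len_s, cfg.rest_len_s, cfg.tr_s
    )


def simulate_subject(
    gt: synthetic.GroundTruth, design: TaskDesign, cfg: AnalysisConfig, subject_seed: int
) -> tuple[ParcelTimeSeries, ParcelTimeSeries, synthetic.ConfoundSet, synthetic.ConfoundSet]:
    """One subject's raw rest and task runs plus per-run confound sets."""
    rng = np.random.default_rng(subject_seed)
    s_rest, s_task, s_conf_r, s_conf_t = rng.integers(2**31, size=4)
    rest = synthetic.simulate_rest_timeseries(gt, cfg.rest_n_tr, cfg.tr_s, int(s_rest))
    task = synthetic.simulate_task_timeseries(gt, design, int(s_task))
    conf_rest = synthetic.generate_confounds(cfg.rest_n_tr, int(s_conf_r))
    conf_task = synthetic.generate_confounds(design.n_tr, int(s_conf_t))
    return rest, task, conf_rest, conf_task


def _preprocess_run(
    ts: ParcelTimeSeries, confounds: synthetic.ConfoundSet, n_drop: int
) -> tuple[ParcelTimeSeries, preprocess.NuisanceDesign]:
    trimmed = preprocess.trim_demean_detrend(ts, n_drop)
    motion24 = preprocess.build_motion_regressors(confounds.motion[n_drop:])
    wm = preprocess.acompcor(confounds.wm_ts[n_drop:])
    vent = preprocess.acompcor(confounds.ventricle_ts[n_drop:])
    design = preprocess.assemble_nuisance(motion24, wm, vent)
    return preprocess.nuisance_regress(trimmed, design), design


def _analyze_subject(
    gt: synthetic.GroundTruth, design: TaskDesign, cfg: AnalysisConfig, subject_seed: int, subject_id: str
) -> SubjectResult:
    rest_raw, task_raw, conf_rest, conf_task = simulate_subject(gt, design, cfg, subject_seed)
    rest, _ = _preprocess_run(rest_raw, conf_rest, cfg.n_drop_frames)
    task, task_nuisance = _preprocess_run(task_raw, conf_task, cfg.n_drop_frames)
    design_t = design.shifted(cfg.n_drop_frames)

    # GLM approach: canonical-HRF activations; FIR residual task FC.
    # The nuisance columns ride along in the task-side models so the
    # residuals stay jointly orthogonal to evoked and noise regressors.
    hrf = task_glm.canonical_hrf(cfg.tr_s)
    regs = task_glm.build_condition_regressors(design_t, hrf)
    activation = task_glm.fit_activation_glm(
        task, regs, design_t.conditions, nuisance=task_nuisance.columns, subject_id=subject_id
    )
    residual = task_glm.fir_regress(
        task, design_t, cfg.fir_post_offset_lags, extra_regressors=task_nuisance.columns
    )
    intervals = connectivity.intervals_from_design(design_t, design_t.n_tr)
    task_fc = connectivity.correlation_fc(residual, intervals)
    rest_fc = connectivity.matched_rest_fc(rest, design_t, extra_regressors=task_nuisance.columns)
    fc_change = connectivity.fc_change_map(task_fc, rest_fc, cfg.positive_only)

    # peak approach: no task regression anywhere on this path
    baselined = peaks.baseline_to_interblock_rest(task, design_t)
    block_peaks = peaks.extract_block_peaks(baselined, design_t)
    peak_act = peaks.peak_activation_map(block_peaks)
    peak_task_fc = peaks.peak_fc(block_peaks)
    peak_rest_fc = peaks.pseudo_block_rest_peak_fc(rest, design_t)
    peak_change = connectivity.fc_change_map(peak_task_fc, peak_rest_fc, cfg.positive_only)

    tau_map, _ = timescale.subject_timescale_map(rest, cfg.acf_max_lag)

    fc_weights = activity_flow.multreg_fc(rest)
    pred = activity_flow.actflow_predict(activation.betas, fc_weights)
    mae = activity_flow.actflow_mae(pred)

    return SubjectResult(
        activation=activation,
        abs_beta_map=np.abs(activation.betas).mean(axis=1),
        fc_change=fc_change,
        peak_activation=peak_act,
        peak_fc_change=peak_change,
        tau_map=tau_map,
        actflow_mae=mae,
    )


def _association_table(
    group_maps: dict, geometry, cfg: AnalysisConfig, seed: int
) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    ensembles = {}
    rows = []
    for var_a, var_b in combinations(MAP_VARIABLES, 2):
        if var_a not in ensembles:
            ensembles[var_a] = surrogates.surrogate_maps(
                group_maps[var_a], geometry, cfg.n_surrogates, int(rng.integers(2**31))
            )
        rho, p = surrogates.sa_perm_correlation_test(
            group_maps[var_a], group_maps[var_b], ensembles[var_a]
        )
        ci_lo, ci_hi = surrogates.bootstrap_spearman_ci(
            group_maps[var_a], group_maps[var_b], cfg.n_boot, seed=int(rng.integers(2**31))
        )
        rows.append(
            {"var_a": var_a, "var_b": var_b, "rho": rho, "p": p, "ci_low": ci_lo, "ci_high": ci_hi}
        )
    df = pd.DataFrame(rows)
    df["significant_fdr01"] = surrogates.fdr_correct(df["p"].to_numpy(), q=0.01)
    return df


def run_pipeline(config: AnalysisConfig) -> AnalysisOutputs:
    """Run the full synthetic-cohort analysis; deterministic given config.seed."""
    cfg = config
    master = np.random.default_rng(cfg.seed)
    gt_seed, assoc_seed = (int(s) for s in master.integers(2**31, size=2))
    subject_seeds = [int(s) for s in master.integers(2**31, size=cfg.n_subjects)]

    logger.info("stage: simulate ground truth (%d parcels)", cfg.n_parcels)
    gt = synthetic.generate_ground_truth(cfg.n_parcels, cfg.n_conditions, cfg.effect, gt_seed)
    design = _design(cfg)
    if design.n_tr > cfg.rest_n_tr:
        raise ValueError(
            f"rest run ({cfg.rest_n_tr} TRs) must cover the task design ({design.n_tr} TRs)"
        )

    results = []
    for s, sseed in enumerate(subject_seeds):
        logger.info("stage: subject %d/%d", s + 1, cfg.n_subjects)
        results.append(_analyze_subject(gt, design, cfg, sseed, f"sub{s:03d}"))

    logger.info("stage: group maps")
    group_act = task_glm.group_activation_magnitude([r.activation for r in results])
    base_maps = {
        "hierarchy": gt.hierarchy,
        "timescale": timescale.group_timescale_map([r.tau_map for r in results]),
        "myelin": gt.myelin_true,
        "actflow_mae": np.mean([r.actflow_mae for r in results], axis=0),
    }
    group_maps = {}
    group_maps["glm"] = dict(
        base_maps,
        activation=group_act.values,
        fc_change=np.mean([r.fc_change for r in results], axis=0),
    )
    group_maps["peak"] = dict(
        base_maps,
        activation=np.mean([r.peak_activation for r in results], axis=0),
        fc_change=np.mean([r.peak_fc_change for r in results], axis=0),
    )

    partition = surrogates.NetworkPartition.from_hierarchy(gt.hierarchy)
    subject_maps = {
        "glm": {
            "activation": [r.abs_beta_map for r in results],
            "fc_change": [r.fc_change for r in results],
        },
        "peak": {
            "activation": [r.peak_activation for r in results],
            "fc_change": [r.peak_fc_change for r in results],
        },
    }
    shared_subject_maps = {
        "timescale": [np.nan_to_num(r.tau_map, nan=np.nanmean(r.tau_map)) for r in results],
        "actflow_mae": [r.actflow_mae for r in results],
    }

    logger.info("stage: statistics")
    tables, contrasts = {}, {}
    for approach in cfg.approaches:
        tables[approach] = _association_table(group_maps[approach], gt.geometry, cfg, assoc_seed)
        per_subj = dict(shared_subject_maps, **subject_maps[approach])
        contrasts[approach] = {
            var: surrogates.partition_contrast(np.asarray(maps_), partition)
            for var, maps_ in per_subj.items()
        }

    return AnalysisOutputs(
        config=cfg,
        ground_truth=gt,
        group_maps={a: group_maps[a] for a in cfg.approaches},
        subject_results=results,
        association_tables=tables,
        contrasts=contrasts,
        partition=partition,
    )


# ---------------------------------------------------------------------------
# Output serialization with provenance
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(outputs: AnalysisOutputs, out_dir: str | Path) -> None:
    """TSV/JSON export of every map, table, and contrast, plus provenance."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(path: Path, writer) -> None:
        writer(path)
        written.append(path)

    gt = outputs.ground_truth
    for name, values in (
        ("hierarchy", gt.hierarchy),
        ("tau_true", gt.tau_true),
        ("myelin_true", gt.myelin_true),
        ("task_coupling_scale", gt.task_coupling_scale),
    ):
        _write(out / f"ground_truth_{name}.tsv", lambda p, v=values: write_map_tsv(p, v))
    _write(out / "geometry_distance.tsv", lambda p: write_matrix_tsv(p, gt.geometry.distance_matrix))
    for approach, maps in outputs.group_maps.items():
        for var, values in maps.items():
            _write(out / f"group_{approach}_{var}.tsv", lambda p, v=values: write_map_tsv(p, v))
    for approach, table in outputs.association_tables.items():
        _write(
            out / f"associations_{approach}.tsv",
            lambda p, t=table: t.to_csv(p, sep="\t", index=False),
        )
    contrast_records = {
        approach: {var: {"mean_diff": m, "t": t, "p": p} for var, (m, t, p) in by_var.items()}
        for approach, by_var in outputs.contrasts.items()
    }
    _write(
        out / "contrasts.json",
        lambda p: p.write_text(json.dumps(contrast_records, indent=2)),
    )
    _write(out / "config.json", lambda p: p.write_text(outputs.config.to_json()))
    provenance = {
        "seed": outputs.config.seed,
        "sha256": {p.name: _sha256(p) for p in written},
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
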