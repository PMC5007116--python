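"""Seeded end-to-end orchestration: simulate -> extract-reference -> fit -> ROI -> stats.

Two execution modes share the same fitting and statistics code:

``volumetric``
    Per-subject 4D phantoms are generated, the SVCA4 reference is extracted
    from each image, RPM-Vb parametric maps are fitted voxelwise and composite
    ROI means are taken from the BP_ND map.

``roi_tac``
    Region-level TACs are simulated and fitted directly (one SRTM fit per
    subject and region).  This desk-scale path is used for replicated
    statistical experiments such as null calibration, where the voxel
    dimension adds cost but no information.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .cohort import (
    BLOOD,
    GRAY_NONSPECIFIC,
    GRAY_SPECIFIC,
    WHITE_MATTER,
    REGIONAL_ROIS,
    ROI_NAMES,
    CohortSpec,
    GroupSpec,
    PhantomSpec,
    SubjectRecord,
    class_frame_tacs,
    default_class_kinetics,
    default_class_map,
    default_cohort_spec,
    make_class_templates,
    sample_cohort,
    subjects_to_frame,
)
from .kinetics import (
    FrameSchedule,
    InputError,
    InputFunctionParams,
    SRTMParams,
    TimeActivityCurve,
    decay_factor,
    expconv,
    fine_time_grid,
    plasma_input,
    srtm_forward,
    two_tissue_tac,
    whole_blood,
)
from .roistats import (
    anova_oneway,
    composite_roi_mean,
    default_label_ids,
    default_roi_definitions,
    group_report,
)
from .rpm import default_frame_weights, fit_srtm_vb, make_basis, parametric_map
from .svca import SvcaConfig, extract_reference

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "null_calibration",
    "frame_average_matrix",
]

_VERSION = "0.1.0"


def frame_average_matrix(schedule: FrameSchedule, t_fine: np.ndarray) -> np.ndarray:
    """Trapezoid frame-averaging operator W with ``tac = fine_values @ W.T``.

    Requires every frame boundary to coincide with a fine-grid sample (the
    default 0.5-s grid satisfies this for any schedule with 0.5-s-aligned
    frames).
    """
    w = np.zeros((schedule.n_frames, t_fine.size))
    for i, (s, e) in enumerate(zip(schedule.frame_start, schedule.end_times)):
        i0 = int(np.searchsorted(t_fine, s - 1e-9))
        i1 = int(np.searchsorted(t_fine, e - 1e-9))
        if abs(t_fine[i0] - s) > 1e-6 or abs(t_fine[i1] - e) > 1e-6:
            raise InputError("frame boundaries must align with the fine grid")
        seg = np.diff(t_fine[i0 : i1 + 1])
        row = np.zeros(i1 - i0 + 1)
        row[:-1] += seg / 2.0
        row[1:] += seg / 2.0
        w[i, i0 : i1 + 1] = row / (e - s)
    return w


# ---------------------------------------------------------------------------
# configuration and manifest
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything a run needs; (config, seed) fully determines all numbers."""

    seed: int
    outdir: str = "pkpet_out"
    mode: str = "roi_tac"                      # or "volumetric"
    alpha_noise: float = 0.3
    equal_group_means: bool = False
    n_control: int | None = None
    n_patient: int | None = None
    phantom_shape: tuple[int, int, int] = (32, 32, 16)
    svca_threshold: float = 0.10
    svca_min_voxels: int = 50
    theta3_min: float = 0.006
    theta3_max: float = 0.6
    n_basis: int = 64
    stats_alpha: float = 0.05
    blood_source: str = "true"                 # or "svca"
    write_dynamic: bool = False
    fine_dt_s: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise InputError("a seed is mandatory for any stochastic run")
        if self.mode not in ("volumetric", "roi_tac"):
            raise InputError("mode must be 'volumetric' or 'roi_tac'")
        if self.blood_source not in ("true", "svca"):
            raise InputError("blood_source must be 'true' or 'svca'")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "phantom_shape" in d:
            d["phantom_shape"] = tuple(d["phantom_shape"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phantom_shape"] = list(d["phantom_shape"])
        return d


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config_hash: str
    seed: int
    version: str
    stages: dict
    timestamps: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _cohort_spec(config: PipelineConfig) -> CohortSpec:
    spec = default_cohort_spec()
    control, patient = spec.control, spec.patient
    if config.equal_group_means:
        patient = GroupSpec(
            **{**asdict(patient), "roi_mean": dict(control.roi_mean),
               "roi_sd": dict(control.roi_sd)}
        )
    if config.n_control is not None or config.n_patient is not None:
        control = _resize_group(control, config.n_control or control.n)
        patient = _resize_group(patient, config.n_patient or patient.n)
    return CohortSpec(control=control, patient=patient,
                      roi_correlation=spec.roi_correlation)


def _resize_group(gs: GroupSpec, n: int) -> GroupSpec:
    d = asdict(gs)
    ratio = n / gs.n
    d.update(
        n=n,
        n_male=min(n, int(round(gs.n_male * ratio))),
        n_nicotine=min(n, int(round(gs.n_nicotine * ratio))),
        n_cannabis=min(n, int(round(gs.n_cannabis * ratio))),
    )
    d["n_female"] = n - d["n_male"]
    return GroupSpec(**d)


# ---------------------------------------------------------------------------
# shared simulation context
# ---------------------------------------------------------------------------

class _SimContext:
    """Curves and operators shared by every subject of a run."""

    def __init__(self, config: PipelineConfig):
        self.schedule = FrameSchedule.default()
        self.input_params = InputFunctionParams()
        self.class_kinetics = default_class_kinetics()
        self.t_fine = fine_time_grid(self.schedule, config.fine_dt_s)
        self.w_frames = frame_average_matrix(self.schedule, self.t_fine)
        cp = plasma_input(self.input_params, self.t_fine)
        self.cb_fine = whole_blood(self.input_params, self.t_fine)
        # fine-grid tissue curve of the reference class (no blood share):
        # the substrate all gray-matter voxel TACs are built from
        ref_par = self.class_kinetics[GRAY_NONSPECIFIC]
        self.gray_vb = ref_par.vb
        self.gray_k2 = ref_par.k2t
        tissue_only = type(ref_par)(K1=ref_par.K1, k2t=ref_par.k2t, vb=0.0)
        self.ref_tissue_fine = two_tissue_tac(cp, tissue_only, cb=self.cb_fine)
        self.class_frames = class_frame_tacs(
            self.input_params, self.class_kinetics, self.schedule, config.fine_dt_s
        )
        self.blood_frame = self.class_frames[BLOOD]
        self.ref_frame = self.class_frames[GRAY_NONSPECIFIC]
        self.templates = make_class_templates(
            self.input_params, self.class_kinetics, self.schedule, config.fine_dt_s
        )
        self.weights = default_frame_weights(self.schedule)

    def gray_frame_tac(self, bp_nd: float) -> np.ndarray:
        """Frame TAC of gray matter with binding potential ``bp_nd``.

        Built with the SRTM forward model against the reference tissue curve
        (r1 = 1, k2 = reference efflux) plus the class blood-volume share, so
        bp = 0 reproduces the reference-class TAC exactly.
        """
        p = SRTMParams.from_binding(1.0, self.gray_k2, bp_nd, vb=self.gray_vb)
        fine = srtm_forward(self.ref_tissue_fine, p, cb=self.cb_fine)
        return self.w_frames @ fine.values

    def gray_frame_tacs(self, bps: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`gray_frame_tac` over many bp values (n, n_frames)."""
        out = np.empty((len(bps), self.schedule.n_frames))
        crv = self.ref_tissue_fine.values
        t = self.ref_tissue_fine.times
        for i, bp in enumerate(np.asarray(bps, dtype=float)):
            theta3 = self.gray_k2 / (1.0 + bp)
            coef = self.gray_k2 - theta3
            tissue = crv + coef / 60.0 * expconv(crv, t, theta3)
            fine = (1.0 - self.gray_vb) * tissue + self.gray_vb * self.cb_fine.values
            out[i] = self.w_frames @ fine
        return out


def _apply_noise(values: np.ndarray, schedule: FrameSchedule, alpha: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Frame-noise surrogate on an array whose last axis is frames."""
    if alpha == 0:
        return values
    dur_min = schedule.frame_duration / 60.0
    d = decay_factor(schedule.mid_times / 60.0)
    sd = alpha * np.sqrt(np.maximum(values, 0.0) / (dur_min * d))
    return values + rng.normal(0.0, 1.0, size=values.shape) * sd


# ---------------------------------------------------------------------------
# label bookkeeping for the volumetric path
# ---------------------------------------------------------------------------

def assign_subregion_labels(class_map: np.ndarray) -> np.ndarray:
    """Partition the specific-binding gray voxels into the anatomical
    subregion labels, in contiguous flat-index chunks so every subregion is
    populated."""
    label_ids = default_label_ids()
    labels = np.zeros(class_map.shape, dtype=np.int16)
    idx = np.flatnonzero(class_map.ravel() == GRAY_SPECIFIC)
    if idx.size < len(label_ids):
        raise InputError("too few gray voxels to populate every subregion")
    chunks = np.array_split(idx, len(label_ids))
    flat = labels.ravel()
    for lid, chunk in zip(label_ids.values(), chunks):
        flat[chunk] = lid
    return labels


def _roi_of_label() -> dict[int, str]:
    """Map each subregion label id to its (regional) composite ROI."""
    defs = default_roi_definitions()
    ids = default_label_ids()
    out = {}
    for roi in REGIONAL_ROIS:
        for sub in defs[roi].subregions:
            out[ids[sub]] = roi
    return out


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def _fit_subject_roi_tacs(
    ctx: _SimContext, record: SubjectRecord, basis, alpha: float,
    rng: np.random.Generator,
) -> dict[str, float]:
    fitted = {}
    for roi in ROI_NAMES:
        target = ctx.gray_frame_tac(record.roi_bpnd[roi])
        noisy = _apply_noise(target, ctx.schedule, alpha, rng)
        res = fit_srtm_vb(
            TimeActivityCurve(ctx.schedule.mid_times, noisy),
            basis, blood=ctx.blood_frame, weights=ctx.weights,
        )
        fitted[roi] = np.nan if res.params is None else res.params.bp_nd
    return fitted


def _simulate_subject_volume(
    ctx: _SimContext, record: SubjectRecord, class_map: np.ndarray,
    labels: np.ndarray, alpha: float, rng: np.random.Generator,
) -> np.ndarray:
    n_frames = ctx.schedule.n_frames
    image = np.zeros(class_map.shape + (n_frames,))
    for cls in (GRAY_NONSPECIFIC, WHITE_MATTER, BLOOD):
        image[class_map == cls] = ctx.class_frames[cls].values
    roi_of = _roi_of_label()
    for lid, roi in roi_of.items():
        sel = labels == lid
        if np.any(sel):
            image[sel] = ctx.gray_frame_tac(record.roi_bpnd[roi])
    return _apply_noise(image, ctx.schedule, alpha, rng)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full chain and write all artifacts under ``config.outdir``."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    ctx = _SimContext(config)
    stages: dict[str, list[str]] = {}
    timestamps = {"start": t0}

    # --- simulate ---------------------------------------------------------
    spec = _cohort_spec(config)
    records = sample_cohort(spec, rng)
    true_table = subjects_to_frame(records)
    true_path = outdir / "subjects_true.tsv"
    pio.write_subject_table(true_path, true_table)
    timing_path = outdir / "frame_timing.json"
    ctx.schedule.to_json(timing_path)
    stages["simulate"] = [str(true_path), str(timing_path)]
    timestamps["simulate"] = time.time()

    # --- extract-reference / fit / roi ------------------------------------
    svca_cfg = SvcaConfig(threshold=config.svca_threshold,
                          min_voxels=config.svca_min_voxels)
    basis = make_basis(ctx.ref_frame, ctx.schedule, config.theta3_min,
                       config.theta3_max, config.n_basis, config.fine_dt_s)
    fitted_rows = []
    fit_files: list[str] = []
    if config.mode == "roi_tac":
        for rec in records:
            fitted = _fit_subject_roi_tacs(ctx, rec, basis, config.alpha_noise, rng)
            fitted_rows.append(fitted)
    else:
        class_map = default_class_map(config.phantom_shape)
        labels = assign_subregion_labels(class_map)
        mask = class_map >= 0
        roi_defs = default_roi_definitions()
        label_ids = default_label_ids()
        lab_path = outdir / "labels.nii.gz"
        pio.write_map(lab_path, labels.astype(float))
        fit_files.append(str(lab_path))
        for rec in records:
            image = _simulate_subject_volume(
                ctx, rec, class_map, labels, config.alpha_noise, rng
            )
            if config.write_dynamic:
                dyn = outdir / f"dyn_{rec.subject_id}.nii.gz"
                pio.write_dynamic(dyn, image, ctx.schedule,
                                  outdir / f"dyn_{rec.subject_id}_timing.json")
                fit_files.append(str(dyn))
            svca = extract_reference(image, ctx.templates, mask, ctx.schedule, svca_cfg)
            sub_basis = make_basis(svca.reference_tac, ctx.schedule,
                                   config.theta3_min, config.theta3_max,
                                   config.n_basis, config.fine_dt_s)
            if config.blood_source == "svca":
                blood = extract_reference(
                    image, ctx.templates, mask, ctx.schedule, svca_cfg,
                    class_index=BLOOD,
                ).reference_tac
            else:
                blood = ctx.blood_frame
            maps = parametric_map(image, svca.reference_tac, blood, mask,
                                  ctx.schedule, weights=ctx.weights, basis=sub_basis)
            bp_path = outdir / f"bpnd_{rec.subject_id}.nii.gz"
            pio.write_map(bp_path, maps.bp_nd)
            ref_path = outdir / f"reftac_{rec.subject_id}.tsv"
            pio.write_tac_tsv(ref_path, svca.reference_tac, ctx.schedule)
            fit_files += [str(bp_path), str(ref_path)]
            fitted = {
                roi: composite_roi_mean(maps.bp_nd, roi_defs[roi], labels, label_ids)
                for roi in ROI_NAMES
            }
            fitted_rows.append(fitted)
    timestamps["fit"] = time.time()

    fitted_table = true_table.copy()
    for roi in ROI_NAMES:
        fitted_table[f"bpnd_{roi}"] = [row[roi] for row in fitted_rows]
    fitted_path = outdir / "subjects_fitted.tsv"
    pio.write_subject_table(fitted_path, fitted_table)
    stages["extract_reference_fit_roi"] = fit_files + [str(fitted_path)]
    timestamps["roi"] = time.time()

    # --- stats -------------------------------------------------------------
    report, summary = group_report(fitted_table, ROI_NAMES, config.stats_alpha)
    report_path = outdir / "stats_report.tsv"
    report.to_csv(report_path, sep="\t", index=False)
    summary_path = outdir / "stats_summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=1)
    stages["stats"] = [str(report_path), str(summary_path)]
    timestamps["end"] = time.time()

    manifest = RunManifest(
        config_hash=_config_hash(config),
        seed=config.seed,
        version=_VERSION,
        stages=stages,
        timestamps=timestamps,
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# replicated null calibration
# ---------------------------------------------------------------------------

def null_calibration(
    n_replicates: int = 1000,
    seed: int = 0,
    n_control: int = 17,
    n_patient: int = 19,
    bp_mean: float = 0.14,
    bp_sd: float = 0.09,
    alpha_noise: float = 0.3,
    test_alpha: float = 0.05,
    config: PipelineConfig | None = None,
) -> float:
    """Rejection rate of the end-to-end chain under a true null.

    Every replicate draws equal-mean control and patient BP_ND values,
    forward-simulates region-level TACs, adds frame noise, fits RPM-Vb and
    runs the one-way ANOVA; returns the fraction of replicates rejecting at
    ``test_alpha``.  Region-level fitting stands in for full volumes, whose
    voxel dimension adds cost but no information to the calibration.
    """
    if config is None:
        config = PipelineConfig(seed=seed, alpha_noise=alpha_noise)
    ctx = _SimContext(config)
    basis = make_basis(ctx.ref_frame, ctx.schedule, config.theta3_min,
                       config.theta3_max, config.n_basis, config.fine_dt_s)
    rng = np.random.default_rng(seed)
    n = n_control + n_patient

    # pre-computed weighted-LS machinery, one solve per (theta3, subject)
    from .rpm import _designs, _solve_all  # internal fast path

    designs = _designs(basis, ctx.blood_frame, vascular=True)
    rejections = 0
    for _ in range(n_replicates):
        bps = rng.normal(bp_mean, bp_sd, size=n)
        targets = ctx.gray_frame_tacs(bps)
        targets = _apply_noise(targets, ctx.schedule, alpha_noise, rng)
        coefs, rss = _solve_all(designs, targets, ctx.weights)
        jbest = np.argmin(rss, axis=0)
        sel = np.arange(n)
        c = coefs[jbest, sel]
        theta3 = basis.theta3_grid[jbest]
        vb = np.clip(c[:, 2], 0.0, 1.0 - 1e-6)
        r1 = c[:, 0] / (1.0 - vb)
        k2 = c[:, 1] / (1.0 - vb) + r1 * theta3
        bp_hat = k2 / theta3 - 1.0
        res = anova_oneway([bp_hat[:n_control], bp_hat[n_control:]])
        if res.p_value < test_alpha:
            rejections += 1
    return rejections / n_replicates
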