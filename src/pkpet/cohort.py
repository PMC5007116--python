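"""Synthetic subjects, kinetic-class templates, dynamic phantoms and cohorts.

The simulator emulates a 60.5-min dynamic [11C]PK11195 acquisition at
2x2x2 mm voxels.  Voxel time-activity curves are drawn from four kinetic
classes — gray matter with specific tracer binding, gray matter without
specific binding, white matter, and blood — and a two-group cohort whose
per-region BP_ND and demographic distributions match a recent-onset-psychosis
case-control design (17 controls / 19 patients).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import (
    FrameSchedule,
    InputFunctionParams,
    InputError,
    SRTMParams,
    TimeActivityCurve,
    TissueKineticParams,
    ValidationError,
    add_noise,
    fine_time_grid,
    frame_average,
    noise_sd,
    plasma_input,
    srtm_forward,
    two_tissue_tac,
    whole_blood,
)

__all__ = [
    "CLASS_NAMES",
    "KineticClassTemplates",
    "PhantomSpec",
    "PhantomResult",
    "GroupSpec",
    "CohortSpec",
    "SubjectRecord",
    "ROI_NAMES",
    "default_class_kinetics",
    "make_class_templates",
    "default_class_map",
    "make_phantom",
    "default_cohort_spec",
    "sample_cohort",
    "subjects_to_frame",
]

#: the four supervised-cluster kinetic classes, in canonical order
CLASS_NAMES = ("gray_specific", "gray_nonspecific", "white_matter", "blood")

GRAY_SPECIFIC, GRAY_NONSPECIFIC, WHITE_MATTER, BLOOD = range(4)
BACKGROUND = -1

#: regions of interest carried by subject records
ROI_NAMES = ("total_gray", "frontal", "temporal", "parietal", "striatum", "thalamus")
REGIONAL_ROIS = ROI_NAMES[1:]


def default_class_kinetics() -> tuple[TissueKineticParams, ...]:
    """Plausible PK11195-scale two-tissue parameters for the four classes.

    Specific-binding gray matter has k3/k4 = 0.5; the reference class is the
    same tissue without the bound compartment; white matter has lower delivery
    and slower washout; the blood class is pure blood (vb = 1).
    """
    return (
        TissueKineticParams(K1=0.10, k2t=0.20, k3=0.04, k4=0.08, vb=0.03),
        TissueKineticParams(K1=0.10, k2t=0.20, k3=0.0, k4=0.0, vb=0.03),
        TissueKineticParams(K1=0.05, k2t=0.12, k3=0.0, k4=0.0, vb=0.02),
        TissueKineticParams(K1=0.0, k2t=0.0, k3=0.0, k4=0.0, vb=1.0),
    )


@dataclass(frozen=True)
class KineticClassTemplates:
    """The four class TACs, unit-area normalized, used for voxel decomposition."""

    class_tacs: tuple[TimeActivityCurve, ...]
    normalization: str = "unit_auc"

    def __post_init__(self) -> None:
        if len(self.class_tacs) != 4:
            raise ValidationError("exactly four kinetic classes are required")
        n = len(self.class_tacs[0])
        if any(len(tac) != n for tac in self.class_tacs):
            raise ValidationError("class templates must share a frame grid")

    @property
    def matrix(self) -> np.ndarray:
        """Template matrix, shape (4, n_frames)."""
        return np.stack([tac.values for tac in self.class_tacs])

    @property
    def times(self) -> np.ndarray:
        return self.class_tacs[0].times


def _trapezoid_auc(values: np.ndarray, times: np.ndarray) -> float:
    return float(np.trapezoid(values, times))


def class_frame_tacs(
    input_params: InputFunctionParams,
    class_kinetics: tuple[TissueKineticParams, ...],
    schedule: FrameSchedule,
    dt_s: float = 0.5,
) -> list[TimeActivityCurve]:
    """Noiseless frame-averaged TAC of each kinetic class (raw scale)."""
    t_fine = fine_time_grid(schedule, dt_s)
    cp = plasma_input(input_params, t_fine)
    cb = whole_blood(input_params, t_fine)
    out = []
    for params in class_kinetics:
        fine = two_tissue_tac(cp, params, cb=cb)
        out.append(frame_average(fine, schedule))
    return out


def make_class_templates(
    input_params: InputFunctionParams,
    class_kinetics: tuple[TissueKineticParams, ...] | None = None,
    schedule: FrameSchedule | None = None,
    dt_s: float = 0.5,
) -> KineticClassTemplates:
    """Build unit-AUC class templates from declared class kinetics."""
    if class_kinetics is None:
        class_kinetics = default_class_kinetics()
    if schedule is None:
        schedule = FrameSchedule.default()
    if len(class_kinetics) != 4:
        raise ValidationError("exactly four kinetic classes are required")
    for i in range(4):
        for j in range(i + 1, 4):
            if class_kinetics[i] == class_kinetics[j]:
                raise ValidationError(f"kinetic classes {i} and {j} are identical")
    tacs = class_frame_tacs(input_params, class_kinetics, schedule, dt_s)
    mids = schedule.mid_times
    normed = []
    for tac in tacs:
        auc = _trapezoid_auc(tac.values, mids)
        if auc <= 0:
            raise ValidationError("class template has non-positive area under curve")
        normed.append(tac.with_values(tac.values / auc))
    templates = KineticClassTemplates(tuple(normed))
    if np.linalg.matrix_rank(templates.matrix, tol=1e-10) < 4:
        raise ValidationError("class templates are degenerate (rank < 4)")
    return templates


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, per-voxel class labels and noise level of a dynamic phantom."""

    shape: tuple[int, int, int] = (32, 32, 16)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    class_map: np.ndarray | None = None
    subject_kinetics: tuple | None = None  # per-class TissueKineticParams or SRTMParams
    alpha: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape):
            raise ValidationError("phantom shape must be positive")
        if self.class_map is not None:
            cm = np.asarray(self.class_map)
            if cm.shape != tuple(self.shape):
                raise InputError("class_map shape must match phantom shape")
            vals = np.unique(cm)
            if not np.all(np.isin(vals, [BACKGROUND, 0, 1, 2, 3])):
                raise ValidationError("class_map values must be in {-1, 0, 1, 2, 3}")
        if self.alpha < 0:
            raise ValidationError("alpha must be non-negative")


@dataclass(frozen=True)
class PhantomResult:
    """Dynamic phantom plus the ground truth used for validation."""

    image: np.ndarray          # (nx, ny, nz, n_frames)
    schedule: FrameSchedule
    class_map: np.ndarray      # (nx, ny, nz) int, -1 = background
    mask: np.ndarray           # boolean brain mask
    bp_true: np.ndarray        # true BP_ND per voxel (NaN outside mask)
    vb_true: np.ndarray        # true blood volume fraction per voxel
    class_tacs: list[TimeActivityCurve]
    voxel_size: tuple[float, float, float]


def default_class_map(shape: tuple[int, int, int] = (32, 32, 16)) -> np.ndarray:
    """Deterministic desk-scale brain: ellipsoidal mask with a central blood
    pool, a white-matter shell, and a cortical ribbon split between the two
    gray classes on a voxel-parity checkerboard."""
    nx, ny, nz = shape
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    rho = np.sqrt(
        ((ix - cx) / (0.45 * nx)) ** 2
        + ((iy - cy) / (0.45 * ny)) ** 2
        + ((iz - cz) / (0.45 * nz)) ** 2
    )
    cm = np.full(shape, BACKGROUND, dtype=np.int8)
    mask = rho <= 1.0
    cm[mask & (rho < 0.20)] = BLOOD
    cm[mask & (rho >= 0.20) & (rho < 0.55)] = WHITE_MATTER
    gray = mask & (rho >= 0.55)
    parity = (ix + iy + iz) % 2 == 0
    cm[gray & parity] = GRAY_SPECIFIC
    cm[gray & ~parity] = GRAY_NONSPECIFIC
    return cm


def _class_truth(params) -> tuple[float, float]:
    """(bp_nd, vb) ground truth for one class parameter object."""
    if isinstance(params, TissueKineticParams):
        return params.bp_nd, params.vb
    if isinstance(params, SRTMParams):
        return params.bp_nd, params.vb
    raise ValidationError("class kinetics must be TissueKineticParams or SRTMParams")


def make_phantom(
    spec: PhantomSpec,
    input_params: InputFunctionParams | None = None,
    schedule: FrameSchedule | None = None,
    reference_fine: TimeActivityCurve | None = None,
    dt_s: float = 0.5,
) -> PhantomResult:
    """Generate a 4D dynamic phantom with per-class kinetics and frame noise.

    Class kinetics may be two-tissue parameter sets (forward-modelled against
    the plasma input) or SRTM parameter sets (forward-modelled against
    ``reference_fine``, which then must be supplied on the fine grid).
    Ground-truth class, BP_ND and vb maps are returned alongside.
    """
    if input_params is None:
        input_params = InputFunctionParams()
    if schedule is None:
        schedule = FrameSchedule.default()
    kinetics = spec.subject_kinetics or default_class_kinetics()
    if len(kinetics) != 4:
        raise ValidationError("exactly four kinetic classes are required")
    cm = spec.class_map if spec.class_map is not None else default_class_map(spec.shape)
    cm = np.asarray(cm)
    if cm.shape != tuple(spec.shape):
        raise InputError("class_map shape must match phantom shape")

    t_fine = fine_time_grid(schedule, dt_s)
    cp = plasma_input(input_params, t_fine)
    cb = whole_blood(input_params, t_fine)
    class_tacs = []
    for params in kinetics:
        if isinstance(params, SRTMParams):
            if reference_fine is None:
                raise InputError("SRTM class kinetics require a fine-grid reference curve")
            fine = srtm_forward(reference_fine, params, cb=cb)
        else:
            fine = two_tissue_tac(cp, params, cb=cb)
        class_tacs.append(frame_average(fine, schedule))

    n_frames = schedule.n_frames
    image = np.zeros(spec.shape + (n_frames,), dtype=float)
    bp_true = np.full(spec.shape, np.nan)
    vb_true = np.full(spec.shape, np.nan)
    rng = np.random.default_rng(spec.seed)
    for c in range(4):
        sel = cm == c
        if not np.any(sel):
            continue
        values = class_tacs[c].values
        image[sel] = values
        if spec.alpha > 0:
            sd = noise_sd(values, schedule, spec.alpha)
            image[sel] += rng.normal(0.0, 1.0, size=(int(sel.sum()), n_frames)) * sd
        bp, vb = _class_truth(kinetics[c])
        bp_true[sel] = bp
        vb_true[sel] = vb
    return PhantomResult(
        image=image,
        schedule=schedule,
        class_map=cm,
        mask=cm != BACKGROUND,
        bp_true=bp_true,
        vb_true=vb_true,
        class_tacs=class_tacs,
        voxel_size=spec.voxel_size,
    )


# ---------------------------------------------------------------------------
# cohort emulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """Distributional description of one clinical group."""

    n: int
    roi_mean: dict
    roi_sd: dict
    age_mean: float = 26.0
    age_sd: float = 4.0
    age_range: tuple[float, float] = (20.0, 34.0)
    n_male: int = 0
    n_female: int = 0
    dose_mean: float = 420.0      # MBq
    dose_sd: float = 50.0
    sa_mean: float = 85.0         # GBq/umol
    sa_sd: float = 25.0
    mass_mean: float = 1.9        # ug
    mass_sd: float = 0.6
    n_nicotine: int = 0
    n_cannabis: int = 0
    panss_mean: float | None = None
    panss_sd: float | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValidationError("group size must be positive")
        if self.n_male + self.n_female != self.n:
            raise ValidationError("gender counts must sum to group size")
        if any(sd < 0 for sd in self.roi_sd.values()):
            raise ValidationError("ROI SDs must be non-negative")
        if set(self.roi_mean) != set(self.roi_sd) or not set(self.roi_mean) <= set(ROI_NAMES):
            raise ValidationError("roi_mean/roi_sd keys must match and be known ROIs")


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort description; defaults emulate the study demographics
    and group BP_ND summaries."""

    control: GroupSpec
    patient: GroupSpec
    roi_correlation: float = 0.8
    truncate_negative_bp: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.roi_correlation <= 1.0):
            raise ValidationError("roi_correlation must lie in [0, 1]")


def default_cohort_spec() -> CohortSpec:
    """17 controls / 19 patients with the published group BP_ND means/SDs and
    demographic margins."""
    control = GroupSpec(
        n=17,
        roi_mean={"total_gray": 0.14, "frontal": 0.12, "temporal": 0.08,
                  "parietal": 0.15, "striatum": 0.09, "thalamus": 0.20},
        roi_sd={"total_gray": 0.09, "frontal": 0.09, "temporal": 0.09,
                "parietal": 0.07, "striatum": 0.10, "thalamus": 0.12},
        n_male=14, n_female=3,
        dose_mean=433.0, dose_sd=23.0,
        sa_mean=96.0, sa_sd=28.0,
        mass_mean=1.7, mass_sd=0.6,
        n_nicotine=5, n_cannabis=0,
    )
    patient = GroupSpec(
        n=19,
        roi_mean={"total_gray": 0.17, "frontal": 0.12, "temporal": 0.12,
                  "parietal": 0.15, "striatum": 0.10, "thalamus": 0.23},
        roi_sd={"total_gray": 0.09, "frontal": 0.07, "temporal": 0.08,
                "parietal": 0.07, "striatum": 0.10, "thalamus": 0.12},
        n_male=16, n_female=3,
        dose_mean=407.0, dose_sd=73.0,
        sa_mean=74.0, sa_sd=19.0,
        mass_mean=2.1, mass_sd=0.6,
        n_nicotine=13, n_cannabis=4,
        panss_mean=53.0, panss_sd=10.0,
    )
    return CohortSpec(control=control, patient=patient)


@dataclass(frozen=True)
class SubjectRecord:
    """One simulated subject: demographics, dose fields and per-ROI BP_ND."""

    subject_id: str
    group: str                      # "control" or "patient"
    age: float
    gender: str                     # "M" or "F"
    injected_dose: float            # MBq
    specific_activity: float        # GBq/umol
    injected_mass: float            # ug
    nicotine: bool
    cannabis: bool
    panss_total: float | None
    roi_bpnd: dict

    def __post_init__(self) -> None:
        if self.group not in ("control", "patient"):
            raise ValidationError("group must be 'control' or 'patient'")
        if self.group == "control" and self.panss_total is not None:
            raise ValidationError("control records carry no PANSS score")
        if not set(self.roi_bpnd) <= set(ROI_NAMES):
            raise ValidationError("unknown ROI in roi_bpnd")


def _shuffled_flags(n: int, n_true: int, rng: np.random.Generator) -> np.ndarray:
    flags = np.zeros(n, dtype=bool)
    flags[:n_true] = True
    rng.shuffle(flags)
    return flags


def _sample_group(
    group: str, gs: GroupSpec, rho: float, truncate: bool, rng: np.random.Generator,
    id_offset: int,
) -> list[SubjectRecord]:
    n = gs.n
    rois = list(gs.roi_mean)
    # shared subject factor induces inter-ROI correlation rho
    z_subj = rng.normal(size=n)
    z_roi = rng.normal(size=(n, len(rois)))
    z = np.sqrt(rho) * z_subj[:, None] + np.sqrt(1.0 - rho) * z_roi
    ages = np.clip(rng.normal(gs.age_mean, gs.age_sd, size=n), *gs.age_range)
    genders = np.where(_shuffled_flags(n, gs.n_male, rng), "M", "F")
    doses = rng.normal(gs.dose_mean, gs.dose_sd, size=n)
    sas = rng.normal(gs.sa_mean, gs.sa_sd, size=n)
    masses = rng.normal(gs.mass_mean, gs.mass_sd, size=n)
    nicotine = _shuffled_flags(n, gs.n_nicotine, rng)
    cannabis = _shuffled_flags(n, gs.n_cannabis, rng)
    panss = (
        np.round(rng.normal(gs.panss_mean, gs.panss_sd, size=n))
        if gs.panss_mean is not None else [None] * n
    )
    records = []
    for i in range(n):
        bp = {
            roi: gs.roi_mean[roi] + gs.roi_sd[roi] * z[i, j]
            for j, roi in enumerate(rois)
        }
        if truncate:
            bp = {k: max(v, 0.0) for k, v in bp.items()}
        records.append(
            SubjectRecord(
                subject_id=f"sub-{id_offset + i + 1:03d}",
                group=group,
                age=float(ages[i]),
                gender=str(genders[i]),
                injected_dose=float(doses[i]),
                specific_activity=float(sas[i]),
                injected_mass=float(masses[i]),
                nicotine=bool(nicotine[i]),
                cannabis=bool(cannabis[i]),
                panss_total=None if panss[i] is None else float(panss[i]),
                roi_bpnd=bp,
            )
        )
    return records


def sample_cohort(
    spec: CohortSpec | None = None, seed: int | np.random.Generator = 0
) -> list[SubjectRecord]:
    """Draw a full two-group cohort; deterministic under a fixed seed."""
    if spec is None:
        spec = default_cohort_spec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    controls = _sample_group(
        "control", spec.control, spec.roi_correlation, spec.truncate_negative_bp, rng, 0
    )
    patients = _sample_group(
        "patient", spec.patient, spec.roi_correlation, spec.truncate_negative_bp,
        rng, spec.control.n,
    )
    return controls + patients


def subjects_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Tabulate subject records; ROI BP_ND in ``bpnd_<roi>`` columns."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "group": r.group,
            "age": r.age,
            "gender": r.gender,
            "injected_dose": r.injected_dose,
            "specific_activity": r.specific_activity,
            "injected_mass": r.injected_mass,
            "nicotine": r.nicotine,
            "cannabis": r.cannabis,
            "panss_total": r.panss_total,
        }
        for roi, v in r.roi_bpnd.items():
            row[f"bpnd_{roi}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
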