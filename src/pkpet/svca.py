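"""Supervised cluster analysis with four kinetic classes (SVCA4).

Each within-mask voxel TAC is normalized to unit area and decomposed by
non-negative least squares onto the four kinetic-class templates; the
reference-tissue input curve is the class-weight-weighted mean of the raw
TACs of the voxels scoring highest on the gray-matter-without-specific-binding
class.  This supplies a reference input when no anatomical reference region
exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .cohort import GRAY_NONSPECIFIC, KineticClassTemplates
from .kinetics import FrameSchedule, InputError, TimeActivityCurve, ValidationError

__all__ = [
    "SvcaConfig",
    "SvcaResult",
    "apply_anatomical_mask",
    "normalize_tac",
    "nnls_weights",
    "extract_reference",
]


@dataclass(frozen=True)
class SvcaConfig:
    """Normalization and voxel-selection policy for reference extraction."""

    normalization: str = "unit_auc"
    selection_mode: str = "top_fraction"   # or "weight_threshold"
    threshold: float = 0.10
    min_voxels: int = 50

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ValidationError("threshold must lie in (0, 1]")
        if self.min_voxels < 1:
            raise ValidationError("min_voxels must be at least 1")
        if self.selection_mode not in ("top_fraction", "weight_threshold"):
            raise ValidationError("unknown selection_mode")
        if self.normalization != "unit_auc":
            raise ValidationError("only unit_auc normalization is supported")


@dataclass(frozen=True)
class SvcaResult:
    """Per-voxel class weights and the extracted reference curve."""

    weight_maps: np.ndarray        # (4, nx, ny, nz); NaN outside mask
    reference_tac: TimeActivityCurve
    selected_voxel_count: int
    selected_mask: np.ndarray      # boolean volume


def apply_anatomical_mask(image: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Restrict a 4D dynamic image to in-brain voxels.

    Returns ``(tacs, index)`` where ``tacs`` has shape (n_voxels, n_frames)
    and ``index`` the flat voxel indices into the spatial grid.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.ndim != 4:
        raise InputError("expected a 4D dynamic image (x, y, z, frames)")
    if mask.shape != image.shape[:3]:
        raise InputError("mask shape must match the image spatial shape")
    sel = mask > 0
    if not np.any(sel):
        raise InputError("anatomical mask is empty")
    idx = np.flatnonzero(sel.ravel())
    return image.reshape(-1, image.shape[3])[idx], idx


def normalize_tac(tac: TimeActivityCurve, schedule: FrameSchedule) -> TimeActivityCurve:
    """Scale a TAC to unit trapezoid area under curve on frame mid-times."""
    auc = float(np.trapezoid(tac.values, schedule.mid_times))
    if auc <= 0:
        raise ValidationError("TAC has non-positive area under curve")
    return tac.with_values(tac.values / auc)


def _normalize_matrix(tacs: np.ndarray, mid_times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise unit-AUC normalization; rows with AUC <= 0 flagged invalid."""
    auc = np.trapezoid(tacs, mid_times, axis=1)
    valid = auc > 0
    normed = np.zeros_like(tacs)
    normed[valid] = tacs[valid] / auc[valid, None]
    return normed, valid


def _check_templates(templates: KineticClassTemplates) -> np.ndarray:
    mat = templates.matrix
    if np.linalg.matrix_rank(mat, tol=1e-10) < 4:
        raise ValidationError("template matrix is rank deficient")
    return mat


def nnls_weights(
    tac: TimeActivityCurve | np.ndarray, templates: KineticClassTemplates
) -> tuple[np.ndarray, float]:
    """Non-negative class weights minimizing ||tac - sum_i w_i template_i||^2."""
    mat = _check_templates(templates)
    values = tac.values if isinstance(tac, TimeActivityCurve) else np.asarray(tac, dtype=float)
    if values.shape != (mat.shape[1],):
        raise InputError("tac and templates must share a frame grid")
    w, rnorm = nnls(mat.T, values)
    return w, float(rnorm)


def extract_reference(
    image: np.ndarray,
    templates: KineticClassTemplates,
    mask: np.ndarray,
    schedule: FrameSchedule,
    config: SvcaConfig | None = None,
    class_index: int = GRAY_NONSPECIFIC,
) -> SvcaResult:
    """SVCA4 reference extraction from a dynamic image.

    Voxels are ranked by their weight on ``class_index`` (default: gray matter
    without specific binding); the reference TAC is the weight-weighted mean
    of the selected voxels' raw (unnormalized) TACs.  Setting ``class_index``
    to the blood class extracts an image-derived whole-blood surrogate instead.
    """
    if config is None:
        config = SvcaConfig()
    mat = _check_templates(templates)
    tacs, idx = apply_anatomical_mask(image, mask)
    if tacs.shape[0] < config.min_voxels:
        raise InputError(
            f"only {tacs.shape[0]} in-mask voxels; at least {config.min_voxels} required"
        )
    if tacs.shape[1] != mat.shape[1]:
        raise InputError("image and templates must share a frame grid")
    normed, valid = _normalize_matrix(tacs, schedule.mid_times)
    weights = np.zeros((tacs.shape[0], 4))
    a = mat.T
    for i in np.flatnonzero(valid):
        weights[i], _ = nnls(a, normed[i])

    w_cls = weights[:, class_index]
    if config.selection_mode == "top_fraction":
        k = max(config.min_voxels, int(np.ceil(config.threshold * tacs.shape[0])))
        k = min(k, tacs.shape[0])
        order = np.argsort(-w_cls, kind="stable")
        selected = order[:k]
        # exclude voxels with (numerically) no class membership at all
        selected = selected[w_cls[selected] > 1e-9]
    else:
        share = np.zeros_like(w_cls)
        total = weights.sum(axis=1)
        nz = total > 0
        share[nz] = w_cls[nz] / total[nz]
        selected = np.flatnonzero(share >= config.threshold)
    if selected.size < config.min_voxels:
        raise InputError(
            f"only {selected.size} voxels selected at threshold {config.threshold}; "
            f"at least {config.min_voxels} required"
        )

    sel_w = w_cls[selected]
    reference = (sel_w[:, None] * tacs[selected]).sum(axis=0) / sel_w.sum()

    spatial = mask.shape
    weight_maps = np.full((4,) + spatial, np.nan)
    flat = weight_maps.reshape(4, -1)
    flat[:, idx] = weights.T
    selected_mask = np.zeros(np.prod(spatial), dtype=bool)
    selected_mask[idx[selected]] = True
    return SvcaResult(
        weight_maps=weight_maps,
        reference_tac=TimeActivityCurve(schedule.mid_times, reference),
        selected_voxel_count=int(selected.size),
        selected_mask=selected_mask.reshape(spatial),
    )
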