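"""Receptor parametric mapping: basis-function SRTM with vascular correction.

The simplified reference tissue model

    Ct(t) = R1 Cr(t) + (k2 - R1 theta3) (Cr * e^(-theta3 t))(t)

is linear in (R1, k2 - R1 theta3) once theta3 is fixed, so the fit reduces to
a weighted linear least-squares problem per candidate theta3 on a
logarithmic grid, with the best grid point chosen by residual sum of squares.
The vascular correction adds the whole-blood curve as a third linear column:

    Ct(t) ~ theta_1 Cr + theta_2 B(theta3) + theta_v Cb

and tissue parameters are recovered after removing the blood-volume share of
the signal: R1 = theta_1/(1-Vb), k2 = theta_2/(1-Vb) + R1 theta3,
BP_ND = k2/theta3 - 1, Vb = theta_v.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import (
    C11_HALF_LIFE_MIN,
    FrameSchedule,
    InputError,
    SRTMParams,
    TimeActivityCurve,
    ValidationError,
    decay_factor,
    expconv,
    fine_time_grid,
    frame_average,
)

__all__ = [
    "BasisSet",
    "FitResult",
    "ParametricMaps",
    "make_basis",
    "fit_srtm_vb",
    "parametric_map",
    "default_frame_weights",
    "STATUS_OK",
    "STATUS_BOUNDARY",
    "STATUS_DEGENERATE",
]

STATUS_OK = "ok"
STATUS_BOUNDARY = "boundary"
STATUS_DEGENERATE = "degenerate"
_STATUS_CODES = {0: STATUS_OK, 1: STATUS_BOUNDARY, 2: STATUS_DEGENERATE}

_VB_MAX = 1.0 - 1e-6


@dataclass(frozen=True)
class BasisSet:
    """Pre-computed convolution basis for the theta3 grid."""

    theta3_grid: np.ndarray            # 1/min, strictly increasing
    basis_curves: np.ndarray           # (n_theta3, n_frames)
    reference_tac: TimeActivityCurve
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        g = np.asarray(self.theta3_grid, dtype=float)
        object.__setattr__(self, "theta3_grid", g)
        if np.any(g <= 0) or np.any(np.diff(g) <= 0):
            raise ValidationError("theta3 grid must be positive and strictly increasing")
        if not np.all(np.isfinite(self.basis_curves)):
            raise ValidationError("basis curves must be finite")
        if self.basis_curves.shape != (g.size, len(self.reference_tac)):
            raise ValidationError("basis matrix shape mismatch")

    @property
    def n_basis(self) -> int:
        return int(self.theta3_grid.size)


@dataclass(frozen=True)
class FitResult:
    """Outcome of one SRTM basis-function fit."""

    params: SRTMParams | None
    rss: float
    theta3_index: int
    status: str


def default_frame_weights(schedule: FrameSchedule) -> np.ndarray:
    """Duration-and-decay frame weights, proportional to duration * 2^(-t/T_half)."""
    w = schedule.frame_duration * decay_factor(schedule.mid_times / 60.0)
    return w / w.max()


def make_basis(
    reference: TimeActivityCurve,
    schedule: FrameSchedule,
    theta3_min: float = 0.006,
    theta3_max: float = 0.6,
    n_basis: int = 64,
    dt_s: float = 0.5,
) -> BasisSet:
    """Build the log-spaced theta3 basis by fine-grid convolution.

    The frame-level reference curve is linearly interpolated onto a fine
    uniform grid (anchored at zero activity at t = 0), convolved with
    ``e^(-theta3 t)`` for each grid value, then frame-averaged back.
    """
    if not (0 < theta3_min < theta3_max):
        raise ValidationError("require 0 < theta3_min < theta3_max")
    if n_basis < 2:
        raise ValidationError("n_basis must be at least 2")
    mids = schedule.mid_times
    if reference.times.shape != mids.shape or not np.allclose(reference.times, mids):
        raise InputError("reference must be sampled at the schedule's frame mid-times")
    t_fine = fine_time_grid(schedule, dt_s)
    anchor_t = np.concatenate([[0.0], reference.times])
    anchor_v = np.concatenate([[0.0], reference.values])
    cr_fine = np.interp(t_fine, anchor_t, anchor_v)
    grid = np.geomspace(theta3_min, theta3_max, n_basis)
    rows = np.empty((n_basis, schedule.n_frames))
    for j, theta3 in enumerate(grid):
        conv = expconv(cr_fine, t_fine, theta3) / 60.0  # rates per min, time in s
        rows[j] = frame_average(TimeActivityCurve(t_fine, conv), schedule).values
    return BasisSet(grid, rows, reference, schedule)


def _designs(basis: BasisSet, blood: TimeActivityCurve | None, vascular: bool) -> np.ndarray:
    cr = basis.reference_tac.values
    n = basis.n_basis
    if vascular:
        if blood is None:
            raise InputError("vascular fitting requires a blood curve")
        if blood.times.shape != basis.reference_tac.times.shape or not np.allclose(
            blood.times, basis.reference_tac.times
        ):
            raise InputError("blood curve must share the basis frame grid")
        cols = 3
    else:
        cols = 2
    designs = np.empty((n, cr.size, cols))
    designs[:, :, 0] = cr
    designs[:, :, 1] = basis.basis_curves
    if vascular:
        designs[:, :, 2] = blood.values
    return designs


def _solve_all(
    designs: np.ndarray, targets: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted LS over every (theta3, target) pair.

    designs: (n_theta3, n_frames, p); targets: (n_targets, n_frames).
    Returns (coefs (n_theta3, n_targets, p), rss (n_theta3, n_targets)).
    """
    sw = np.sqrt(weights)
    aw = designs * sw[None, :, None]
    yw = targets * sw[None, :]
    # normal equations per theta3; p <= 3 so conditioning is benign
    ata = np.einsum("jfp,jfq->jpq", aw, aw)
    aty = np.einsum("jfp,nf->jnp", aw, yw)
    coefs = np.linalg.solve(ata[:, None, :, :], aty[..., None])[..., 0]
    fitted = np.einsum("jfp,jnp->jnf", aw, coefs)
    resid = yw[None, :, :] - fitted
    rss = np.einsum("jnf,jnf->jn", resid, resid)
    return coefs, rss


def _params_from_theta(
    coef: np.ndarray, theta3: float, vascular: bool, rescale: bool
) -> SRTMParams:
    theta1 = float(coef[0])
    theta2 = float(coef[1])
    vb = float(np.clip(coef[2], 0.0, _VB_MAX)) if vascular else 0.0
    scale = (1.0 - vb) if rescale else 1.0
    r1 = theta1 / scale
    k2 = theta2 / scale + r1 * theta3
    return SRTMParams(r1=r1, k2=k2, theta3=theta3, bp_nd=k2 / theta3 - 1.0, vb=vb)


def fit_srtm_vb(
    target: TimeActivityCurve,
    basis: BasisSet,
    blood: TimeActivityCurve | None = None,
    weights: np.ndarray | None = None,
    vascular: bool = True,
    rescale: bool = True,
) -> FitResult:
    """Fit one TAC against the basis; vascular term optional.

    Ties in weighted RSS across the theta3 grid resolve to the smallest grid
    index.  An all-zero target yields a degenerate result with no parameters.
    """
    mids = basis.schedule.mid_times
    if target.times.shape != mids.shape or not np.allclose(target.times, mids):
        raise InputError("target must be sampled at the basis frame mid-times")
    if weights is None:
        weights = default_frame_weights(basis.schedule)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != mids.shape or np.any(weights < 0):
        raise InputError("weights must be non-negative, one per frame")
    if not np.any(target.values != 0):
        return FitResult(params=None, rss=np.nan, theta3_index=-1, status=STATUS_DEGENERATE)
    designs = _designs(basis, blood, vascular)
    coefs, rss = _solve_all(designs, target.values[None, :], weights)
    j = int(np.argmin(rss[:, 0]))
    params = _params_from_theta(coefs[j, 0], float(basis.theta3_grid[j]), vascular, rescale)
    status = STATUS_BOUNDARY if j in (0, basis.n_basis - 1) else STATUS_OK
    return FitResult(params=params, rss=float(rss[j, 0]), theta3_index=j, status=status)


@dataclass(frozen=True)
class ParametricMaps:
    """Voxelwise SRTM parameter maps; NaN outside the mask / degenerate voxels."""

    bp_nd: np.ndarray
    r1: np.ndarray
    k2: np.ndarray
    vb: np.ndarray
    theta3: np.ndarray
    rss: np.ndarray
    status: np.ndarray  # int: 0 ok, 1 boundary, 2 degenerate, -1 outside mask

    def status_name(self, code: int) -> str:
        return _STATUS_CODES.get(code, "outside")


def parametric_map(
    image: np.ndarray,
    reference: TimeActivityCurve,
    blood: TimeActivityCurve | None,
    mask: np.ndarray,
    schedule: FrameSchedule,
    theta3_min: float = 0.006,
    theta3_max: float = 0.6,
    n_basis: int = 64,
    weights: np.ndarray | None = None,
    vascular: bool = True,
    rescale: bool = True,
    basis: BasisSet | None = None,
) -> ParametricMaps:
    """Voxelwise RPM(-Vb) fit over a masked 4D image.

    All in-mask voxels are fitted simultaneously: the weighted least-squares
    solution is computed for every theta3 grid point in one vectorized pass
    and the per-voxel optimum selected by RSS (ties to the smallest index).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 4:
        raise InputError("expected a 4D dynamic image (x, y, z, frames)")
    if image.shape[3] != schedule.n_frames:
        raise InputError("image frame count must match the schedule")
    mids = schedule.mid_times
    if reference.times.shape != mids.shape or not np.allclose(reference.times, mids):
        raise InputError("reference and image frame grids do not match")
    mask = np.asarray(mask) > 0
    if mask.shape != image.shape[:3]:
        raise InputError("mask shape must match the image spatial shape")
    if basis is None:
        basis = make_basis(reference, schedule, theta3_min, theta3_max, n_basis)
    if weights is None:
        weights = default_frame_weights(schedule)

    targets = image[mask]
    n_vox = targets.shape[0]
    designs = _designs(basis, blood, vascular)
    nonzero = np.any(targets != 0, axis=1)

    bp = np.full(n_vox, np.nan)
    r1 = np.full(n_vox, np.nan)
    k2 = np.full(n_vox, np.nan)
    vb = np.full(n_vox, np.nan)
    th = np.full(n_vox, np.nan)
    rs = np.full(n_vox, np.nan)
    st = np.full(n_vox, 2, dtype=np.int8)

    if np.any(nonzero):
        coefs, rss = _solve_all(designs, targets[nonzero], weights)
        jbest = np.argmin(rss, axis=0)
        sel = np.arange(jbest.size)
        c = coefs[jbest, sel]                      # (n, p)
        theta3 = basis.theta3_grid[jbest]
        vb_v = np.clip(c[:, 2], 0.0, _VB_MAX) if vascular else np.zeros(jbest.size)
        scale = (1.0 - vb_v) if rescale else np.ones_like(vb_v)
        r1_v = c[:, 0] / scale
        k2_v = c[:, 1] / scale + r1_v * theta3
        bp_v = k2_v / theta3 - 1.0
        st_v = np.where((jbest == 0) | (jbest == basis.n_basis - 1), 1, 0).astype(np.int8)
        bp[nonzero], r1[nonzero], k2[nonzero], vb[nonzero] = bp_v, r1_v, k2_v, vb_v
        th[nonzero] = theta3
        rs[nonzero] = rss[jbest, sel]
        st[nonzero] = st_v

    def _vol(flat: np.ndarray, fill=np.nan, dtype=float) -> np.ndarray:
        out = np.full(mask.shape, fill, dtype=dtype)
        out[mask] = flat
        return out

    return ParametricMaps(
        bp_nd=_vol(bp), r1=_vol(r1), k2=_vol(k2), vb=_vol(vb),
        theta3=_vol(th), rss=_vol(rs),
        status=_vol(st, fill=-1, dtype=np.int8),
    )
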