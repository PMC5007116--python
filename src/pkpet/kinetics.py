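"""Forward kinetic models and acquisition operators for dynamic PET simulation.

Time-activity curves (TACs) carry activity concentration in kBq/mL on a time
axis in seconds.  All kinetic rate constants are expressed per minute, the
convention of the PET kinetic-modelling literature; conversion happens inside
each operator.  Simulated TACs are decay-corrected, as reconstructed clinical
data are; radioactive decay of carbon-11 enters only the frame-noise variance
model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.signal import lfilter

__all__ = [
    "C11_HALF_LIFE_MIN",
    "FrameSchedule",
    "TimeActivityCurve",
    "InputFunctionParams",
    "TissueKineticParams",
    "SRTMParams",
    "plasma_input",
    "whole_blood",
    "two_tissue_tac",
    "srtm_forward",
    "frame_average",
    "add_noise",
    "expconv",
    "fine_time_grid",
    "decay_factor",
]

#: half-life of carbon-11 in minutes
C11_HALF_LIFE_MIN = 20.4

_SEC_PER_MIN = 60.0


class ValidationError(ValueError):
    """A parameter object violates one of its invariants."""


class InputError(ValueError):
    """Operation inputs are inconsistent (grids, shapes, ordering)."""


def decay_factor(t_min: np.ndarray | float) -> np.ndarray | float:
    """Fraction of C-11 remaining at ``t_min`` minutes post injection."""
    return 2.0 ** (-np.asarray(t_min, dtype=float) / C11_HALF_LIFE_MIN)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

#: default acquisition frame durations in seconds (22 frames, 3630 s total)
DEFAULT_FRAME_DURATIONS_S: tuple[float, ...] = (
    (30.0,) * 1 + (5.0,) * 6 + (10.0,) * 3 + (60.0,) * 4
    + (150.0,) * 2 + (300.0,) * 2 + (600.0,) * 4
)


@dataclass(frozen=True)
class FrameSchedule:
    """Start time and duration (both seconds) of each acquisition frame.

    Frames must be contiguous and non-overlapping; the default schedule spans
    a 60.5-min (3630 s) dynamic acquisition.
    """

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)
        if start.ndim != 1 or start.shape != dur.shape:
            raise ValidationError("frame_start and frame_duration must be 1-D and equal length")
        if np.any(dur <= 0):
            raise ValidationError("frame durations must be positive")
        if start.size > 1 and not np.allclose(start[1:], start[:-1] + dur[:-1], atol=1e-9):
            raise ValidationError("frames must be contiguous and non-overlapping")

    @classmethod
    def from_durations(cls, durations_s: Sequence[float], start_s: float = 0.0) -> "FrameSchedule":
        dur = np.asarray(durations_s, dtype=float)
        start = start_s + np.concatenate([[0.0], np.cumsum(dur[:-1])])
        return cls(start, dur)

    @classmethod
    def default(cls) -> "FrameSchedule":
        return cls.from_durations(DEFAULT_FRAME_DURATIONS_S)

    @property
    def n_frames(self) -> int:
        return int(self.frame_start.size)

    @property
    def mid_times(self) -> np.ndarray:
        """Frame mid-times in seconds."""
        return self.frame_start + 0.5 * self.frame_duration

    @property
    def end_times(self) -> np.ndarray:
        return self.frame_start + self.frame_duration

    @property
    def total_span(self) -> float:
        """Scan length in seconds."""
        return float(self.end_times[-1] - self.frame_start[0])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "frame_start_s": self.frame_start.tolist(),
                    "frame_duration_s": self.frame_duration.tolist(),
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "FrameSchedule":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["frame_start_s"]), np.asarray(d["frame_duration_s"]))


@dataclass(frozen=True)
class TimeActivityCurve:
    """Activity concentration (kBq/mL) versus time (s) for one voxel/region/pool."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValidationError("times and values must be 1-D and equal length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValidationError("TAC values must be finite")

    def with_values(self, values: np.ndarray) -> "TimeActivityCurve":
        return TimeActivityCurve(self.times, np.asarray(values, dtype=float))

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class InputFunctionParams:
    """Tri-exponential bolus plasma-input model (Feng-type).

    ``Cp(tau) = (A1*tau - A2 - A3) e^(-lam1*tau) + A2 e^(-lam2*tau) + A3 e^(-lam3*tau)``
    for ``tau = t - delay > 0``, clipped at zero from below.  Amplitudes in
    kBq/mL (A1 in kBq/mL/min), eigenvalues per minute, delay in minutes.
    """

    A1: float = 851.1
    A2: float = 21.9
    A3: float = 20.8
    lam1: float = 4.1339
    lam2: float = 0.1191
    lam3: float = 0.0104
    delay: float = 0.5

    def __post_init__(self) -> None:
        if not (self.lam1 > self.lam2 > self.lam3 > 0):
            raise ValidationError("require lam1 > lam2 > lam3 > 0")
        if self.A2 < 0 or self.A3 < 0:
            raise ValidationError("A2, A3 must be non-negative")


@dataclass(frozen=True)
class TissueKineticParams:
    """Two-tissue-compartment rate constants (per minute) plus blood volume fraction.

    K1 [mL/cm3/min] delivery, k2t efflux from the free compartment, k3/k4
    exchange with the specifically bound compartment (TSPO binding enters
    through k3/k4), vb fractional blood volume.
    """

    K1: float
    k2t: float
    k3: float = 0.0
    k4: float = 0.0
    vb: float = 0.05

    def __post_init__(self) -> None:
        if min(self.K1, self.k2t, self.k3, self.k4) < 0:
            raise ValidationError("rate constants must be non-negative")
        if not (0.0 <= self.vb <= 1.0):
            raise ValidationError("vb must lie in [0, 1]")

    @property
    def bp_nd(self) -> float:
        """k3/k4 binding potential; 0 when there is no bound compartment."""
        return self.k3 / self.k4 if self.k4 > 0 else 0.0


@dataclass(frozen=True)
class SRTMParams:
    """Simplified-reference-tissue-model parameters for one fit.

    r1 = K1/K1' delivery ratio, k2 efflux rate [1/min], theta3 = k2/(1+BP_ND)
    [1/min], bp_nd the non-displaceable binding potential, vb the fractional
    blood volume of the vascular correction.
    """

    r1: float
    k2: float
    theta3: float
    bp_nd: float
    vb: float = 0.0

    def __post_init__(self) -> None:
        if not self.theta3 > 0:
            raise ValidationError("theta3 must be positive")
        if not (0.0 <= self.vb < 1.0):
            raise ValidationError("vb must lie in [0, 1)")
        if abs(self.bp_nd - (self.k2 / self.theta3 - 1.0)) > 1e-6 * max(1.0, abs(self.bp_nd)):
            raise ValidationError("inconsistent parameters: bp_nd must equal k2/theta3 - 1")

    @classmethod
    def from_binding(cls, r1: float, k2: float, bp_nd: float, vb: float = 0.0) -> "SRTMParams":
        return cls(r1=r1, k2=k2, theta3=k2 / (1.0 + bp_nd), bp_nd=bp_nd, vb=vb)

    @classmethod
    def from_theta(cls, r1: float, k2: float, theta3: float, vb: float = 0.0) -> "SRTMParams":
        return cls(r1=r1, k2=k2, theta3=theta3, bp_nd=k2 / theta3 - 1.0, vb=vb)


# ---------------------------------------------------------------------------
# continuous-time forward models
# ---------------------------------------------------------------------------

def fine_time_grid(schedule: FrameSchedule, dt_s: float = 0.5) -> np.ndarray:
    """Uniform internal grid (seconds) covering the scan from t = 0."""
    t_end = schedule.end_times[-1]
    n = int(round(t_end / dt_s))
    return np.linspace(0.0, n * dt_s, n + 1)


def _check_sorted(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or (t.size > 1 and np.any(np.diff(t) <= 0)):
        raise InputError("time grid must be 1-D and strictly increasing")
    if np.any(t < 0):
        raise InputError("time grid must be non-negative")
    return t


def plasma_input(params: InputFunctionParams, t: np.ndarray) -> TimeActivityCurve:
    """Evaluate the tri-exponential bolus plasma input on ``t`` (seconds)."""
    t = _check_sorted(t)
    tau = t / _SEC_PER_MIN - params.delay
    cp = np.where(
        tau > 0,
        (params.A1 * tau - params.A2 - params.A3) * np.exp(-params.lam1 * np.maximum(tau, 0.0))
        + params.A2 * np.exp(-params.lam2 * np.maximum(tau, 0.0))
        + params.A3 * np.exp(-params.lam3 * np.maximum(tau, 0.0)),
        0.0,
    )
    return TimeActivityCurve(t, np.maximum(cp, 0.0))


def whole_blood(params: InputFunctionParams, t: np.ndarray, ratio: float = 1.0) -> TimeActivityCurve:
    """Whole-blood curve as a constant multiple of the plasma input.

    With no metabolite or plasma-to-blood modelling the default ratio is 1,
    i.e. whole blood equals plasma.
    """
    cp = plasma_input(params, t)
    return cp.with_values(ratio * cp.values)


def _expconv_coeffs(a_per_s: float, dt: float) -> tuple[float, float, float]:
    """Recursion coefficients for piecewise-linear convolution with e^(-a t).

    Returns (E, b_new, b_old) such that y[n] = E*y[n-1] + b_new*f[n] + b_old*f[n-1].
    Exact for piecewise-linear f.
    """
    x = a_per_s * dt
    if x < 1e-4:
        # series expansion; avoids catastrophic cancellation for small rates
        i0 = dt * (1.0 - x / 2.0 + x * x / 6.0 - x ** 3 / 24.0)
        j = dt * (0.5 - x / 3.0 + x * x / 8.0 - x ** 3 / 30.0)
        e = np.exp(-x)
    else:
        e = np.exp(-x)
        i0 = (1.0 - e) / a_per_s
        j = (1.0 - e * (1.0 + x)) / (a_per_s * a_per_s * dt)
    return float(e), float(i0 - j), float(j)


def expconv(values: np.ndarray, times: np.ndarray, rate_per_min: float) -> np.ndarray:
    """Convolution ``(f * e^(-rate t))(t)`` on the grid of ``f``.

    ``times`` in seconds, ``rate_per_min`` per minute.  The integrand is
    treated as piecewise linear between samples, which makes the scheme exact
    for linear segments; on a uniform grid the recursion runs through an IIR
    filter.  ``rate = 0`` degenerates to the running integral.
    """
    f = np.asarray(values, dtype=float)
    t = _check_sorted(times)
    if f.shape != t.shape:
        raise InputError("values and times must have equal length")
    if rate_per_min < 0:
        raise ValidationError("convolution rate must be non-negative")
    a = rate_per_min / _SEC_PER_MIN  # per second
    dts = np.diff(t)
    if dts.size == 0:
        return np.zeros_like(f)
    if np.allclose(dts, dts[0], rtol=1e-9, atol=1e-12):
        e, b_new, b_old = _expconv_coeffs(a, float(dts[0]))
        y = lfilter([b_new, b_old], [1.0, -e], f)
        # the filter seeds y[0] = b_new*f[0]; the true initial condition is 0
        y -= (b_new * f[0]) * e ** np.arange(f.size)
        y[0] = 0.0
        return y
    out = np.zeros_like(f)
    for i, dt in enumerate(dts):
        e, b_new, b_old = _expconv_coeffs(a, float(dt))
        out[i + 1] = e * out[i] + b_new * f[i + 1] + b_old * f[i]
    return out


def _two_tissue_modes(p: TissueKineticParams) -> tuple[float, float, float, float]:
    """Eigen-decomposition of the 2x2 rate matrix.

    Returns (a1, a2, c1, c2) such that the total-tissue impulse response is
    ``h(t) = K1 * (c1 e^(-a1 t) + c2 e^(-a2 t))`` (rates per minute).
    """
    s = p.k2t + p.k3 + p.k4
    disc = np.sqrt(max(s * s - 4.0 * p.k2t * p.k4, 0.0))
    if disc < 1e-10:  # repeated root; nudge to keep the two-mode form valid
        disc = 1e-10
    a1 = max(0.5 * (s - disc), 0.0)
    a2 = 0.5 * (s + disc)
    c1 = (p.k3 + p.k4 - a1) / (a2 - a1)
    c2 = (a2 - p.k3 - p.k4) / (a2 - a1)
    return a1, a2, c1, c2


def two_tissue_tac(
    cp: TimeActivityCurve,
    params: TissueKineticParams,
    t: np.ndarray | None = None,
    cb: TimeActivityCurve | None = None,
) -> TimeActivityCurve:
    """Total-tissue TAC of the two-tissue compartment model.

    ``Ct = (1 - vb) (C1 + C2) + vb Cb`` where C1, C2 solve
    ``dC1/dt = K1 Cp - (k2t + k3) C1 + k4 C2`` and ``dC2/dt = k3 C1 - k4 C2``.
    The solution uses the analytic bi-exponential impulse response convolved
    against ``cp`` on its own (fine) grid; if ``t`` is given the result is
    linearly resampled onto it.  ``cb`` defaults to ``cp``.
    """
    if cb is None:
        cb = cp
    if cb.times.shape != cp.times.shape or not np.allclose(cb.times, cp.times):
        raise InputError("cp and cb must share a time grid")
    a1, a2, c1, c2 = _two_tissue_modes(params)
    # expconv integrates over seconds; K1 is per minute, hence the 1/60
    tissue = params.K1 / _SEC_PER_MIN * (
        c1 * expconv(cp.values, cp.times, a1) + c2 * expconv(cp.values, cp.times, a2)
    )
    total = (1.0 - params.vb) * tissue + params.vb * cb.values
    if t is None:
        return TimeActivityCurve(cp.times, total)
    t = _check_sorted(t)
    if t[0] < cp.times[0] - 1e-9 or t[-1] > cp.times[-1] + 1e-9:
        raise InputError("requested times fall outside the cp grid")
    return TimeActivityCurve(t, np.interp(t, cp.times, total))


def srtm_forward(
    cr: TimeActivityCurve,
    params: SRTMParams,
    cb: TimeActivityCurve | None = None,
) -> TimeActivityCurve:
    """Forward simplified reference tissue model with vascular term.

    ``Ct = (1 - vb) [ r1 Cr + (k2 - r1 theta3) (Cr * e^(-theta3 t)) ] + vb Cb``.
    """
    if cb is None:
        if params.vb != 0.0:
            raise InputError("a blood curve is required when vb > 0")
        cb = cr.with_values(np.zeros_like(cr.values))
    if cb.times.shape != cr.times.shape or not np.allclose(cb.times, cr.times):
        raise InputError("cr and cb must share a time grid")
    coef = params.k2 - params.r1 * params.theta3
    if coef == 0.0:
        tissue = params.r1 * cr.values
    else:
        # coef is per minute; expconv integrates over seconds
        tissue = params.r1 * cr.values + coef / _SEC_PER_MIN * expconv(
            cr.values, cr.times, params.theta3
        )
    total = (1.0 - params.vb) * tissue + params.vb * cb.values
    return TimeActivityCurve(cr.times, total)


# ---------------------------------------------------------------------------
# acquisition operators
# ---------------------------------------------------------------------------

def frame_average(
    curve: Callable[[np.ndarray], np.ndarray] | TimeActivityCurve,
    schedule: FrameSchedule,
) -> TimeActivityCurve:
    """Average a continuous-time curve over each acquisition frame.

    ``curve`` is either a vectorized callable of time (seconds) — integrated
    per frame with adaptive quadrature — or a finely sampled
    :class:`TimeActivityCurve`, integrated by the trapezoid rule on its grid
    (exact for linear integrands).  Output times are the frame mid-times.
    """
    starts, ends = schedule.frame_start, schedule.end_times
    out = np.empty(schedule.n_frames)
    if isinstance(curve, TimeActivityCurve):
        t, v = curve.times, curve.values
        if starts[0] < t[0] - 1e-9 or ends[-1] > t[-1] + 1e-9:
            raise InputError("frame schedule extends outside the sampled curve support")
        for i, (s, e) in enumerate(zip(starts, ends)):
            inside = (t > s) & (t < e)
            seg_t = np.concatenate([[s], t[inside], [e]])
            seg_v = np.concatenate([
                [np.interp(s, t, v)], v[inside], [np.interp(e, t, v)]
            ])
            out[i] = np.trapezoid(seg_v, seg_t) / (e - s)
    elif callable(curve):
        def scalar_curve(x: float) -> float:
            return float(np.asarray(curve(x)).reshape(-1)[0])

        for i, (s, e) in enumerate(zip(starts, ends)):
            integral, _ = quad(scalar_curve, s, e, limit=200)
            out[i] = integral / (e - s)
    else:
        raise InputError("curve must be callable or a TimeActivityCurve")
    return TimeActivityCurve(schedule.mid_times, out)


def noise_sd(
    values: np.ndarray,
    schedule: FrameSchedule,
    alpha: float,
) -> np.ndarray:
    """Per-frame noise SD of the count-statistics surrogate model.

    ``sd = alpha * sqrt(max(C, 0) / (duration_min * d(t)))`` with
    ``d(t) = 2^(-t/20.4 min)`` the C-11 decay factor at frame mid-time: noise
    grows for short frames and late (decayed) frames, as in reconstructed
    decay-corrected images.
    """
    if alpha < 0:
        raise ValidationError("alpha must be non-negative")
    dur_min = schedule.frame_duration / _SEC_PER_MIN
    d = decay_factor(schedule.mid_times / _SEC_PER_MIN)
    return alpha * np.sqrt(np.maximum(np.asarray(values, dtype=float), 0.0) / (dur_min * d))


def add_noise(
    tac: TimeActivityCurve,
    schedule: FrameSchedule,
    alpha: float,
    seed: int | np.random.Generator,
) -> TimeActivityCurve:
    """Add independent zero-mean Gaussian frame noise; reproducible under seed."""
    if tac.times.shape != schedule.mid_times.shape or not np.allclose(tac.times, schedule.mid_times):
        raise InputError("tac must be sampled at the schedule's frame mid-times")
    sd = noise_sd(tac.values, schedule, alpha)
    if alpha == 0:
        return tac
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return tac.with_values(tac.values + rng.normal(0.0, 1.0, size=sd.shape) * sd)
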