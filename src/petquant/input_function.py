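"""Arterial parent-plasma input function (ppIF) construction.

The arterial input to all plasma-driven models is the radioactivity
concentration of the *unmetabolised* tracer in plasma.  It is assembled
from three measurement streams:

1. a continuous whole-blood detector covering the first ~15 min,
2. intermittent discrete samples giving whole-blood and plasma activity
   (and, via HPLC, the fraction of unmetabolised parent tracer),
3. two fitted sigmoid models — plasma-over-blood ratio and parent
   fraction — that carry the sparse discrete information onto a fine
   time grid.

The construction follows four steps: cross-calibrate the continuous
detector against the early discrete whole-blood samples; convert the
calibrated whole-blood curve to plasma via the plasma-over-blood sigmoid;
splice in the late discrete plasma samples with a cubic spline; and
multiply by the parent-fraction sigmoid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize

from .frames import FrameSchedule

SECONDS_PER_HOUR = 3600.0


@dataclass
class SigmoidModel:
    """Four-parameter sigmoid f(t) = 1 - (x1 + x2*t_h) / ((x3/t_h)^x4 + 1).

    ``t_h`` is time in hours.  For ``x4 > 0`` the value tends to 1 as
    t -> 0, then declines (or rises, for x1 < 0) on the time scale ``x3``.
    The same functional form describes both the parent fraction (clipped
    to [0, 1]) and the plasma-over-blood ratio (clipped to be positive).
    """

    x1: float
    x2: float
    x3: float
    x4: float
    kind: str = "parent_fraction"  # or "plasma_over_blood"

    def __post_init__(self) -> None:
        if self.x3 <= 0:
            raise ValueError("time-scale parameter x3 must be positive")

    def __call__(self, t_seconds) -> np.ndarray:
        t_h = np.asarray(t_seconds, dtype=float) / SECONDS_PER_HOUR
        with np.errstate(divide="ignore", over="ignore"):
            denom = np.where(t_h > 0, (self.x3 / np.maximum(t_h, 1e-300)) ** self.x4, np.inf) + 1.0
            val = 1.0 - (self.x1 + self.x2 * t_h) / denom
        val = np.where(t_h <= 0, 1.0, val)
        if self.kind == "parent_fraction":
            return np.clip(val, 0.0, 1.0)
        return np.maximum(val, 1e-12)


def eval_sigmoid(model: SigmoidModel, t_seconds) -> np.ndarray:
    """Evaluate a sigmoid model at times in seconds (limit 1 at t=0)."""
    return model(t_seconds)


def fit_sigmoid(times, values, kind: str = "parent_fraction") -> tuple[SigmoidModel, float]:
    """Least-squares sigmoid fit (Nelder-Mead on the residual sum of squares).

    Returns the fitted model and its residual sum of squares.  A small set
    of deterministic starting points guards against the local minima of
    the 4-parameter form.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 4:
        raise ValueError("need at least 4 points to fit a 4-parameter sigmoid")
    t_h = times / SECONDS_PER_HOUR
    pos = t_h[t_h > 0]
    med_t = float(np.median(pos)) if pos.size else 0.5

    def ssr(p):
        x1, x2, logx3, x4 = p
        if abs(logx3) > 50:  # keep the optimiser out of overflow territory
            return 1e30
        m = SigmoidModel(x1, x2, np.exp(logx3), abs(x4), kind)
        return float(np.sum((m(times) - values) ** 2))

    drop = 1.0 - float(values[-1])  # total decline, crude asymptote guess
    starts = [
        (drop, 0.0, np.log(med_t), 2.0),
        (drop * 0.7, 0.1, np.log(max(med_t / 2, 1e-3)), 1.5),
        (0.5, 0.0, np.log(0.3), 3.0),
        (0.0, drop, np.log(max(med_t, 1e-3)), 1.0),
    ]
    best = None
    for s in starts:
        res = minimize(ssr, s, method="Nelder-Mead",
                       options={"maxiter": 5000, "xatol": 1e-10, "fatol": 1e-14})
        if best is None or res.fun < best.fun:
            best = res
    x1, x2, logx3, x4 = best.x
    return SigmoidModel(x1, x2, float(np.exp(logx3)), abs(float(x4)), kind), float(best.fun)


@dataclass
class BloodSamples:
    """Continuous and discrete arterial measurements for one scan.

    Times are seconds from scan start.  ``continuous_*`` covers the early
    part of the scan on a dense grid; ``discrete_*`` are the intermittent
    syringe samples (whole blood and centrifuged plasma); the parent
    fraction series comes from HPLC analysis of the discrete samples.
    All activities are decay-corrected to scan start, kBq/ml.
    """

    continuous_time: np.ndarray
    continuous_whole_blood: np.ndarray
    discrete_time: np.ndarray
    discrete_whole_blood: np.ndarray
    discrete_plasma: np.ndarray
    parent_fraction_time: np.ndarray
    parent_fraction: np.ndarray

    def __post_init__(self) -> None:
        for name in ("continuous_time", "continuous_whole_blood", "discrete_time",
                     "discrete_whole_blood", "discrete_plasma",
                     "parent_fraction_time", "parent_fraction"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for tname in ("continuous_time", "discrete_time", "parent_fraction_time"):
            t = getattr(self, tname)
            if t.size > 1 and np.any(np.diff(t) <= 0):
                raise ValueError(f"{tname} must be strictly increasing")


@dataclass
class PlasmaInputFunction:
    """Metabolite-corrected parent-plasma curve on a fine uniform grid.

    ``whole_blood`` is the companion whole-blood curve used for vascular
    terms in tissue models.  Both are zero before injection.
    """

    time: np.ndarray
    parent_plasma: np.ndarray
    whole_blood: np.ndarray
    calibration_factor: float = 1.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.parent_plasma = np.asarray(self.parent_plasma, dtype=float)
        self.whole_blood = np.asarray(self.whole_blood, dtype=float)
        if not (self.time.shape == self.parent_plasma.shape == self.whole_blood.shape):
            raise ValueError("time, parent_plasma and whole_blood must share a shape")
        if self.dt > 1.0 + 1e-9:
            raise ValueError("grid spacing must be <= 1 s for convolution accuracy")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def plasma_at(self, t) -> np.ndarray:
        return np.interp(t, self.time, self.parent_plasma)

    def blood_at(self, t) -> np.ndarray:
        return np.interp(t, self.time, self.whole_blood)


def cross_calibrate(continuous_time, continuous_values, sample_times, sample_values) -> float:
    """Least-squares scale factor aligning the continuous detector to
    the discrete samples.

    Minimising sum (d_i - f * c_i)^2 over the calibration samples gives
    the closed form f = sum(d*c) / sum(c^2), where c_i is the continuous
    curve interpolated at each discrete sample time.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    continuous_time = np.asarray(continuous_time, dtype=float)
    inside = (sample_times >= continuous_time[0]) & (sample_times <= continuous_time[-1])
    if not np.any(inside):
        raise ValueError("no discrete samples fall inside the continuous window")
    d = np.asarray(sample_values, dtype=float)[inside]
    c = np.interp(sample_times[inside], continuous_time, np.asarray(continuous_values, float))
    denom = float(np.sum(c * c))
    if denom == 0:
        raise ValueError("continuous curve is zero at all calibration times")
    return float(np.sum(d * c) / denom)


def build_ppif(
    blood: BloodSamples,
    pob: SigmoidModel,
    parent: SigmoidModel,
    schedule: FrameSchedule,
    grid_dt: float = 1.0,
) -> PlasmaInputFunction:
    """Assemble the parent-plasma input function on a fine grid.

    Steps: (1) cross-calibrate the continuous whole-blood curve against
    the discrete whole-blood samples inside its window; (2) multiply by
    the plasma-over-blood sigmoid to get continuous plasma; (3) join with
    the late discrete plasma samples by natural cubic spline; (4) multiply
    by the parent-fraction sigmoid.  The whole-blood curve is extended
    over the full scan by the same spline for vascular terms.
    """
    cont_t = blood.continuous_time
    cont_end = float(cont_t[-1])
    inj = schedule.injection_time

    calib_mask = blood.discrete_time > inj
    factor = cross_calibrate(cont_t, blood.continuous_whole_blood,
                             blood.discrete_time[calib_mask],
                             blood.discrete_whole_blood[calib_mask])
    cont_wb = factor * blood.continuous_whole_blood

    t = np.arange(0.0, schedule.total_duration + grid_dt / 2, grid_dt)
    early = t <= cont_end

    # -- plasma over the full grid
    cont_plasma = cont_wb * pob(cont_t)
    late_mask = blood.discrete_time > cont_end
    if np.count_nonzero(late_mask) < 2:
        raise ValueError("need at least two discrete plasma samples after the "
                         "continuous window to bridge to scan end")
    knots_t = np.concatenate([[cont_end], blood.discrete_time[late_mask]])
    knots_p = np.concatenate([[cont_plasma[-1]], blood.discrete_plasma[late_mask]])
    plasma_spline = CubicSpline(knots_t, knots_p, bc_type="natural")
    plasma = np.where(early, np.interp(t, cont_t, cont_plasma), plasma_spline(t))

    # -- whole blood over the full grid (for vascular terms)
    knots_wb = np.concatenate([[cont_wb[-1]], blood.discrete_whole_blood[late_mask]])
    wb_spline = CubicSpline(knots_t, knots_wb, bc_type="natural")
    whole_blood = np.where(early, np.interp(t, cont_t, cont_wb), wb_spline(t))

    ppif = plasma * parent(t)
    pre = t < inj
    ppif[pre] = 0.0
    whole_blood[pre] = 0.0
    ppif = np.maximum(ppif, 0.0)
    whole_blood = np.maximum(whole_blood, 0.0)
    return PlasmaInputFunction(t, ppif, whole_blood, factor)
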