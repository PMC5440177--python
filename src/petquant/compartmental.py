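"""Reversible compartmental models with variable blood volume (2kbv, 4kbv).

The 2kbv model is the reversible one-tissue-compartment model: influx K1
(ml cm^-3 min^-1) from plasma into a single tissue compartment, efflux k2
(min^-1) back to plasma, plus a fitted fractional blood volume bv.  The
4kbv model adds a second tissue compartment (specific binding) with
exchange rates k3, k4.  Total volume of distribution:

    VT = K1/k2                (2kbv)
    VT = K1/k2 * (1 + k3/k4)  (4kbv)

The measured voxel/ROI signal mixes tissue and blood:

    C_meas(t) = C_tissue(t) + bv * C_wholeblood(t)

(the tissue term is not scaled by 1-bv; this unscaled convention is the
one under which the Logan plot of the two-tissue model has slope VT + bv,
so subtracting the vascular contribution before a graphical analysis
leaves a slope of exactly VT).

Fitting minimises the frame-weighted residual sum of squares with
Nelder-Mead from fixed small starting estimates (K1 = 0.01 ml cm^-3
min^-1, k2..k4 = 0.001 min^-1, bv = 0.05), with rates kept non-negative
through a log transform and bv in (0, 1) through a logit transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from ._conv import exp_conv, frame_average
from .frames import FrameSchedule, FrameWeights, TimeActivityCurve
from .input_function import PlasmaInputFunction

#: fixed Nelder-Mead starting estimates (units: K1 ml cm^-3 min^-1, k min^-1)
START_2KBV = {"K1": 0.01, "k2": 0.001, "bv": 0.05}
START_4KBV = {"K1": 0.01, "k2": 0.001, "k3": 0.001, "k4": 0.001, "bv": 0.05}

MAX_ITER = 5000


@dataclass
class CompartmentalParams:
    """Rate constants (min^-1, K1 in ml cm^-3 min^-1) and blood volume."""

    K1: float
    k2: float
    k3: float | None = None
    k4: float | None = None
    bv: float = 0.0

    def __post_init__(self) -> None:
        if self.K1 < 0 or self.k2 < 0:
            raise ValueError("rate constants must be non-negative")
        if (self.k3 is None) != (self.k4 is None):
            raise ValueError("k3 and k4 must both be set (4kbv) or both absent (2kbv)")
        if self.k3 is not None and (self.k3 < 0 or self.k4 < 0):
            raise ValueError("rate constants must be non-negative")
        if not 0 <= self.bv < 1:
            raise ValueError("bv must lie in [0, 1)")

    @property
    def is_two_tissue(self) -> bool:
        return self.k3 is not None


@dataclass
class FitResult:
    """Outcome of a weighted model fit on one TAC."""

    params: object
    vt_or_bp: float
    weighted_rss: float
    n_iter: int
    converged: bool
    fitted: np.ndarray | None = None

    def residual_cv(self, n_params: int) -> float:
        """Within-fit residual coefficient of variation (%).

        100 * sqrt(weighted_rss / (n_frames - n_params)) / mean(fitted TAC);
        a rough per-fit noise summary used by the outlier rule for
        regional variants.
        """
        if self.fitted is None:
            return float("nan")
        dof = self.fitted.size - n_params
        mean = float(np.mean(self.fitted))
        if dof <= 0 or mean == 0:
            return float("nan")
        return 100.0 * float(np.sqrt(self.weighted_rss / dof)) / abs(mean)


def vt_from_params(p: CompartmentalParams) -> float:
    """Total volume of distribution from the rate constants."""
    if p.k2 <= 0:
        raise ValueError("k2 must be positive for a finite VT")
    if not p.is_two_tissue:
        return p.K1 / p.k2
    if p.k4 <= 0:
        raise ValueError("k4 must be positive for a finite VT")
    return (p.K1 / p.k2) * (1.0 + p.k3 / p.k4)


def _impulse_response(p: CompartmentalParams):
    """Exponential decomposition (amplitudes 1/min, rates 1/min) of the
    tissue impulse response."""
    if not p.is_two_tissue:
        return [(p.K1, p.k2)]
    s = p.k2 + p.k3 + p.k4
    disc = np.sqrt(max(s * s - 4.0 * p.k2 * p.k4, 0.0))
    a1 = 0.5 * (s - disc)
    a2 = 0.5 * (s + disc)
    if a2 - a1 < 1e-12:  # degenerate repeated eigenvalue: nudge apart
        a2 = a1 + 1e-12
    c1 = p.K1 * (p.k3 + p.k4 - a1) / (a2 - a1)
    c2 = p.K1 * (a2 - p.k3 - p.k4) / (a2 - a1)
    return [(c1, a1), (c2, a2)]


def simulate_tissue_tac(
    p: CompartmentalParams,
    ppif: PlasmaInputFunction,
    schedule: FrameSchedule,
    label: str = "",
) -> TimeActivityCurve:
    """Forward-model the measured frame TAC for given parameters.

    The tissue response (sum of one or two exponentials, convolved with
    the ppIF on the fine grid) is mixed with whole blood as
    C_T + bv*C_WB, then averaged over each frame.
    """
    dt = ppif.dt
    tissue = np.zeros_like(ppif.parent_plasma)
    for amp, rate in _impulse_response(p):
        # rates are per minute, the grid is in seconds
        tissue += amp / 60.0 * exp_conv(ppif.parent_plasma, dt, rate / 60.0)
    signal = tissue + p.bv * ppif.whole_blood
    frames = frame_average(signal, ppif.time, schedule.frame_start, schedule.frame_end)
    return TimeActivityCurve(schedule, frames, decay_corrected=True, label=label)


def _weighted_rss(obs, model, w) -> float:
    return float(np.sum(w * (obs - model) ** 2))


def _fit_compartmental(tac, ppif, weights, start: dict, two_tissue: bool,
                       multistart: bool = True) -> FitResult:
    obs = tac.activity
    w = weights.values if isinstance(weights, FrameWeights) else np.asarray(weights)
    schedule = tac.schedule

    def unpack(x) -> CompartmentalParams:
        rates = np.exp(x[:-1])
        bv = 1.0 / (1.0 + np.exp(-x[-1]))
        if two_tissue:
            return CompartmentalParams(rates[0], rates[1], rates[2], rates[3], bv)
        return CompartmentalParams(rates[0], rates[1], bv=bv)

    def objective(x):
        try:
            p = unpack(x)
        except (ValueError, OverflowError, FloatingPointError):
            return 1e30
        sim = simulate_tissue_tac(p, ppif, schedule)
        return _weighted_rss(obs, sim.activity, w)

    names = ("K1", "k2", "k3", "k4") if two_tissue else ("K1", "k2")
    x0 = np.array([np.log(start[n]) for n in names]
                  + [np.log(start["bv"] / (1 - start["bv"]))])
    starts = [x0]
    if multistart:
        # deterministic alternates: faster kinetics / higher delivery, to
        # escape the shallow basin around the very small default start
        for scale in (np.log(10.0), np.log(100.0)):
            alt = x0.copy()
            alt[:-1] += scale
            starts.append(alt)
    best = None
    total_iter = 0
    for s in starts:
        res = minimize(objective, s, method="Nelder-Mead",
                       options={"maxiter": MAX_ITER, "xatol": 1e-9, "fatol": 1e-12,
                                "adaptive": two_tissue})
        total_iter += res.nit
        if best is None or res.fun < best.fun:
            best = res
    p = unpack(best.x)
    fitted = simulate_tissue_tac(p, ppif, schedule).activity
    return FitResult(
        params=p,
        vt_or_bp=vt_from_params(p),
        weighted_rss=float(best.fun),
        n_iter=total_iter,
        converged=bool(best.success or best.fun < 1e-12),
        fitted=fitted,
    )


def fit_2kbv(tac: TimeActivityCurve, ppif: PlasmaInputFunction,
             weights: FrameWeights) -> FitResult:
    """Weighted Nelder-Mead fit of the one-tissue model; VT = K1/k2."""
    return _fit_compartmental(tac, ppif, weights, START_2KBV, two_tissue=False)


def fit_4kbv(tac: TimeActivityCurve, ppif: PlasmaInputFunction,
             weights: FrameWeights) -> FitResult:
    """Weighted Nelder-Mead fit of the two-tissue model;
    VT = K1/k2*(1+k3/k4)."""
    return _fit_compartmental(tac, ppif, weights, START_4KBV, two_tissue=True)
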