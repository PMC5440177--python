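"""Simplified reference tissue model (SRTM) and two-pass voxelwise SRTM2.

When no arterial input is available, binding can be quantified against a
(pseudo-)reference region with negligible specific binding.  The SRTM
operational equation for a target TAC C(t) given the reference TAC Cr(t):

    C(t) = R1*Cr(t) + R1*(k2ref - k2a) * (Cr * exp(-k2a t))(t)

with R1 = K1/K1' the relative delivery, k2a = k2/(1+BP_ND) the apparent
efflux rate and k2ref the reference-region efflux rate, giving

    BP_ND = R1 * k2ref / k2a - 1.

Regional fits use Nelder-Mead over (R1, k2a, k2ref) from fixed starting
estimates (R1 = 0.95, k2a = k2ref = 0.001 min^-1).  Voxelwise maps use
SRTM2: a first pass of basis-function SRTM (apparent-rate grid theta_j,
100 log-spaced members) estimates k2ref per voxel inside a tight brain
mask; the global median k2ref is then fixed and a second basis pass
solves only for (R1, k2a) per voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from ._conv import exp_conv, frame_average
from .frames import FrameSchedule, FrameWeights, TimeActivityCurve, sum_frames
from .compartmental import FitResult
from .spectral import log_spaced_betas

#: fixed Nelder-Mead starting estimates, rates in min^-1
START_SRTM = {"r1": 0.95, "k2a": 0.001, "k2ref": 0.001}

MAX_ITER = 5000


@dataclass
class SRTMParams:
    """SRTM parameters; rates in min^-1."""

    r1: float
    k2a: float
    k2ref: float

    def __post_init__(self) -> None:
        if self.r1 <= 0 or self.k2a <= 0 or self.k2ref <= 0:
            raise ValueError("r1, k2a and k2ref must be positive")

    @property
    def bp_nd(self) -> float:
        return self.r1 * self.k2ref / self.k2a - 1.0


@dataclass
class SRTM2Config:
    """Settings of the two-pass voxelwise SRTM2."""

    n_basis: int = 100
    beta_min: float = 0.00063   # s^-1, apparent-rate grid lower bound
    beta_max: float = 0.014     # s^-1, upper bound
    k2ref_fixed: float | None = None  # s^-1; None = estimate via pass 1
    tight_mask_fraction: float = 0.4  # of the robust max of the summed image

    def __post_init__(self) -> None:
        if not 0 < self.beta_min < self.beta_max:
            raise ValueError("need 0 < beta_min < beta_max")


def _ref_on_grid(ref_tac: TimeActivityCurve, dt: float = 1.0):
    """Linearly interpolate a frame TAC onto a fine uniform grid.

    The curve is anchored at zero at injection time and held constant
    beyond the last frame midpoint.
    """
    sched = ref_tac.schedule
    t = np.arange(0.0, sched.total_duration + dt / 2, dt)
    knots_t = np.concatenate([[min(sched.injection_time, sched.frame_mid[0])],
                              sched.frame_mid])
    knots_v = np.concatenate([[0.0], ref_tac.activity])
    vals = np.interp(t, knots_t, knots_v)
    vals[t < sched.injection_time] = 0.0
    return t, vals


def simulate_srtm_tac(p: SRTMParams, ref_tac: TimeActivityCurve,
                      label: str = "") -> TimeActivityCurve:
    """Forward SRTM model: R1*Cr plus the convolution term.

    The linear R1*Cr term uses the measured reference frame values
    directly (as in basis-function implementations), so r1 = 1 with
    k2a = k2ref reproduces the reference TAC exactly; only the
    convolution term needs the fine-grid interpolation of Cr.
    """
    sched = ref_tac.schedule
    t, cr = _ref_on_grid(ref_tac)
    dt = float(t[1] - t[0])
    conv = exp_conv(cr, dt, p.k2a / 60.0)
    conv_frames = frame_average(conv, t, sched.frame_start, sched.frame_end)
    frames = p.r1 * ref_tac.activity \
        + p.r1 * (p.k2ref - p.k2a) / 60.0 * conv_frames
    return TimeActivityCurve(sched, frames, decay_corrected=True, label=label)


def fit_srtm(tac: TimeActivityCurve, ref_tac: TimeActivityCurve,
             weights: FrameWeights) -> FitResult:
    """Weighted Nelder-Mead SRTM fit; outcome is BP_ND."""
    obs = tac.activity
    w = weights.values if isinstance(weights, FrameWeights) else np.asarray(weights)
    sched = tac.schedule
    t, cr = _ref_on_grid(ref_tac)
    dt = float(t[1] - t[0])

    def model_frames(r1, k2a, k2ref):
        conv = exp_conv(cr, dt, k2a / 60.0)
        conv_frames = frame_average(conv, t, sched.frame_start, sched.frame_end)
        return r1 * ref_tac.activity + r1 * (k2ref - k2a) / 60.0 * conv_frames

    def objective(x):
        r1, k2a, k2ref = np.exp(x)
        if not np.all(np.isfinite([r1, k2a, k2ref])):
            return 1e30
        return float(np.sum(w * (obs - model_frames(r1, k2a, k2ref)) ** 2))

    x0 = np.log([START_SRTM["r1"], START_SRTM["k2a"], START_SRTM["k2ref"]])
    starts = [x0]
    for scale in (np.log(10.0), np.log(100.0)):
        alt = x0.copy()
        alt[1:] += scale
        starts.append(alt)
    best, total_iter = None, 0
    for s in starts:
        res = minimize(objective, s, method="Nelder-Mead",
                       options={"maxiter": MAX_ITER, "xatol": 1e-10, "fatol": 1e-13})
        total_iter += res.nit
        if best is None or res.fun < best.fun:
            best = res
    r1, k2a, k2ref = np.exp(best.x)
    p = SRTMParams(r1, k2a, k2ref)
    fitted = model_frames(r1, k2a, k2ref)
    return FitResult(params=p, vt_or_bp=p.bp_nd, weighted_rss=float(best.fun),
                     n_iter=total_iter, converged=bool(best.success or best.fun < 1e-12),
                     fitted=fitted)


def _srtm_basis(ref_tac: TimeActivityCurve, thetas: np.ndarray) -> np.ndarray:
    """Frame-averaged (Cr * exp(-theta t)) columns, thetas in s^-1."""
    sched = ref_tac.schedule
    t, cr = _ref_on_grid(ref_tac)
    dt = float(t[1] - t[0])
    cols = np.empty((sched.n_frames, thetas.size))
    for j, th in enumerate(thetas):
        cols[:, j] = frame_average(exp_conv(cr, dt, th), t,
                                   sched.frame_start, sched.frame_end)
    return cols


def tight_brain_mask(dyn: np.ndarray, schedule: FrameSchedule,
                     fraction: float = 0.4) -> np.ndarray:
    """First-pass mask: voxels above ``fraction`` of the robust maximum
    (99th percentile) of the full-scan summed image."""
    summed = sum_frames(dyn, schedule, (1, schedule.n_frames))
    robust_max = np.percentile(summed, 99.0)
    return summed > fraction * robust_max


def fit_srtm2_voxelwise(
    dyn: np.ndarray,
    schedule: FrameSchedule,
    ref_tac: TimeActivityCurve,
    weights: FrameWeights,
    mask: np.ndarray,
    cfg: SRTM2Config | None = None,
) -> tuple[np.ndarray, float]:
    """Two-pass basis-function SRTM2 BP_ND map.

    Returns the BP_ND map (NaN outside the mask) and the fixed k2ref
    (s^-1) actually used in pass 2.
    """
    cfg = cfg or SRTM2Config()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dyn.shape[:-1]:
        raise ValueError("mask shape must match the image grid")
    w = weights.values if isinstance(weights, FrameWeights) else np.asarray(weights)
    thetas = log_spaced_betas(cfg.n_basis, cfg.beta_min, cfg.beta_max)
    basis = _srtm_basis(ref_tac, thetas)  # (n_frames, n_theta)
    cr = ref_tac.activity

    if cfg.k2ref_fixed is not None:
        k2ref = float(cfg.k2ref_fixed)
    else:
        tight = tight_brain_mask(dyn, schedule, cfg.tight_mask_fraction) & mask
        if not np.any(tight):
            raise ValueError("tight brain mask is empty; cannot estimate k2ref")
        k2ref_vox = _pass1_k2ref(dyn[tight], cr, basis, thetas, w)
        k2ref_vox = k2ref_vox[np.isfinite(k2ref_vox) & (k2ref_vox > 0)]
        if k2ref_vox.size == 0:
            raise ValueError("no valid first-pass k2ref estimates")
        k2ref = float(np.median(k2ref_vox))

    Y = np.asarray(dyn, dtype=float)[mask]  # (n_vox, n_frames)
    bp_vals = _pass2_bp(Y, cr, basis, thetas, w, k2ref)
    out = np.full(mask.shape, np.nan, dtype=np.float32)
    out[mask] = bp_vals
    return out, k2ref


def _pass1_k2ref(Y: np.ndarray, cr: np.ndarray, basis: np.ndarray,
                 thetas: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-voxel k2ref from unconstrained two-coefficient basis SRTM.

    For each theta the model C = c1*Cr + c2*(Cr x e^-theta) is a weighted
    linear solve; the best theta per voxel (minimum weighted RSS) gives
    k2ref = c2/c1 + theta, via the SRTM identity R1*(k2ref - k2a) = c2.
    """
    n_vox = Y.shape[0]
    Yw = Y * w[None, :]
    yy = np.einsum("vf,vf->v", Yw, Y)
    best_rss = np.full(n_vox, np.inf)
    best_k2ref = np.full(n_vox, np.nan)
    for j, th in enumerate(thetas):
        D = np.column_stack([cr, basis[:, j]])
        M = D.T @ (w[:, None] * D)          # 2x2
        rhs = D.T @ Yw.T                    # 2 x n_vox
        det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
        if det <= 0:
            continue
        c1 = (M[1, 1] * rhs[0] - M[0, 1] * rhs[1]) / det
        c2 = (-M[1, 0] * rhs[0] + M[0, 0] * rhs[1]) / det
        rss = yy - (c1 * rhs[0] + c2 * rhs[1])
        better = rss < best_rss
        valid = better & (c1 > 0)
        best_rss = np.where(better, rss, best_rss)
        best_k2ref = np.where(valid, c2 / np.where(c1 > 0, c1, 1.0) + th, best_k2ref)
    return best_k2ref


def _pass2_bp(Y: np.ndarray, cr: np.ndarray, basis: np.ndarray,
              thetas: np.ndarray, w: np.ndarray, k2ref: float) -> np.ndarray:
    """Per-voxel BP_ND with k2ref fixed: single-coefficient basis search."""
    n_vox = Y.shape[0]
    Yw = Y * w[None, :]
    yy = np.einsum("vf,vf->v", Yw, Y)
    best_rss = np.full(n_vox, np.inf)
    best_bp = np.full(n_vox, np.nan)
    for j, th in enumerate(thetas):
        X = cr + (k2ref - th) * basis[:, j]
        xx = float(np.sum(w * X * X))
        if xx <= 0:
            continue
        xy = Yw @ X
        r1 = xy / xx
        rss = yy - xy**2 / xx
        better = rss < best_rss
        valid = better & (r1 > 0)
        best_rss = np.where(better, rss, best_rss)
        best_bp = np.where(valid, r1 * k2ref / th - 1.0, best_bp)
    return best_bp
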