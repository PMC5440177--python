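"""Logan graphical analysis with arterial input, regional and voxelwise.

For reversible tracers the plot of int_0^t TAC / TAC(t) against
int_0^t ppIF / TAC(t) becomes linear after an equilibration time t*, with
slope equal to the total volume of distribution VT.  This implementation
uses the study's fixed settings: t* = 1680 s, a fixed fractional blood
volume of 0.028 whose whole-blood contribution is subtracted from the TAC
before the regression, equal frame weights, and (voxelwise only) a 2 mm
FWHM isotropic Gaussian pre-smoothing of the dynamic frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .compartmental import FitResult
from .frames import FrameSchedule, TimeActivityCurve
from .input_function import PlasmaInputFunction

_FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass
class LoganConfig:
    """Fixed settings of the graphical analysis."""

    t_star: float = 1680.0          # s; start of the linear segment
    fixed_bv: float = 0.028         # fractional blood volume subtracted
    presmooth_fwhm_mm: float = 2.0  # voxelwise pre-smoothing kernel

    def __post_init__(self) -> None:
        if not 0 <= self.fixed_bv < 1:
            raise ValueError("fixed_bv must lie in [0, 1)")


def _cumulative_at_midpoints(activity: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Running integral of a frame TAC evaluated at frame midpoints.

    Frame values are averages over their frames, so the integral up to a
    frame midpoint is the sum of (value x duration) over earlier frames
    plus half the current frame's contribution.  Exact for frame data.
    """
    per_frame = activity * schedule.frame_duration
    before = np.concatenate([[0.0], np.cumsum(per_frame)[:-1]])
    return before + 0.5 * per_frame


def _logan_design(ppif: PlasmaInputFunction, schedule: FrameSchedule,
                  cfg: LoganConfig):
    mids = schedule.frame_mid
    use = mids >= cfg.t_star
    if np.count_nonzero(use) < 3:
        raise ValueError("need at least 3 frames with midpoint >= t_star")
    from scipy.integrate import cumulative_trapezoid

    ppif_cum_grid = cumulative_trapezoid(ppif.parent_plasma, ppif.time, initial=0.0)
    ppif_cum = np.interp(mids, ppif.time, ppif_cum_grid)
    blood_mid = ppif.blood_at(mids)
    return use, ppif_cum, blood_mid


def _logan_slope(activity: np.ndarray, schedule: FrameSchedule, use, ppif_cum,
                 blood_mid, fixed_bv: float) -> tuple[float, float, int]:
    """Return (slope, rss, n_points) of the Logan regression for one TAC."""
    tac = activity - fixed_bv * blood_mid
    tac_cum = _cumulative_at_midpoints(tac, schedule)
    # guard: points where the vascular-subtracted TAC is tiny or negative
    # would blow up the transformed coordinates
    ok = use & (tac > 0.01 * np.max(np.abs(tac)))
    if np.count_nonzero(ok) < 3:
        raise ValueError("fewer than 3 usable frames after t* exclusions")
    x = ppif_cum[ok] / tac[ok]
    y = tac_cum[ok] / tac[ok]
    A = np.column_stack([x, np.ones_like(x)])
    coef, res, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < 2:
        raise ValueError("singular Logan regression")
    rss = float(res[0]) if res.size else float(np.sum((A @ coef - y) ** 2))
    return float(coef[0]), rss, int(np.count_nonzero(ok))


def logan_regional(tac: TimeActivityCurve, ppif: PlasmaInputFunction,
                   cfg: LoganConfig | None = None) -> FitResult:
    """Regional Logan VT: OLS slope over frames with midpoint >= t*."""
    cfg = cfg or LoganConfig()
    use, ppif_cum, blood_mid = _logan_design(ppif, tac.schedule, cfg)
    slope, rss, n = _logan_slope(tac.activity, tac.schedule, use, ppif_cum,
                                 blood_mid, cfg.fixed_bv)
    return FitResult(params=cfg, vt_or_bp=slope, weighted_rss=rss,
                     n_iter=0, converged=True, fitted=None)


def smooth_frames(dyn: np.ndarray, voxel_size_mm, fwhm_mm: float) -> np.ndarray:
    """Gaussian-smooth each frame of a 4-D image in-plane and axially."""
    if fwhm_mm <= 0:
        return dyn
    sigma_vox = [fwhm_mm * _FWHM_TO_SIGMA / vs for vs in voxel_size_mm]
    out = np.empty_like(dyn, dtype=float)
    for i in range(dyn.shape[-1]):
        out[..., i] = gaussian_filter(np.asarray(dyn[..., i], dtype=float), sigma_vox)
    return out


def logan_voxelwise(
    dyn: np.ndarray,
    schedule: FrameSchedule,
    ppif: PlasmaInputFunction,
    mask: np.ndarray,
    cfg: LoganConfig | None = None,
    voxel_size_mm=(1.0, 1.0, 1.0),
) -> np.ndarray:
    """Voxelwise Logan VT map (NaN outside the mask or on failed voxels).

    Frames are pre-smoothed with the configured Gaussian kernel, then the
    regression runs per voxel, fully vectorised.
    """
    cfg = cfg or LoganConfig()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dyn.shape[:-1]:
        raise ValueError("mask shape must match the image grid")
    sm = smooth_frames(dyn, voxel_size_mm, cfg.presmooth_fwhm_mm)
    use, ppif_cum, blood_mid = _logan_design(ppif, schedule, cfg)

    vox = sm[mask]  # (n_vox, n_frames)
    tac = vox - cfg.fixed_bv * blood_mid
    per_frame = tac * schedule.frame_duration
    tac_cum = np.cumsum(per_frame, axis=1) - 0.5 * per_frame

    out = np.full(mask.shape, np.nan, dtype=np.float32)
    vals = np.full(vox.shape[0], np.nan)
    thresh = 0.01 * np.max(np.abs(tac), axis=1, keepdims=True)
    ok = use[None, :] & (tac > thresh)
    n_ok = ok.sum(axis=1)
    fit_rows = n_ok >= 3
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(ok, ppif_cum[None, :] / tac, np.nan)
        y = np.where(ok, tac_cum / tac, np.nan)
    # per-row OLS slope with row-specific valid points
    xm = np.nanmean(np.where(ok, x, np.nan), axis=1)
    ym = np.nanmean(np.where(ok, y, np.nan), axis=1)
    sxx = np.nansum(np.where(ok, (x - xm[:, None]) ** 2, 0.0), axis=1)
    sxy = np.nansum(np.where(ok, (x - xm[:, None]) * (y - ym[:, None]), 0.0), axis=1)
    good = fit_rows & (sxx > 0)
    vals[good] = sxy[good] / sxx[good]
    n_failed = int(np.count_nonzero(~good))
    if vox.shape[0] and n_failed > 0.5 * vox.shape[0]:
        raise RuntimeError(f"Logan failed on {n_failed}/{vox.shape[0]} voxels")
    out[mask] = vals
    return out
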