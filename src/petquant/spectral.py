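"""Classic (non-regularised) spectral analysis via non-negative least squares.

The TAC is decomposed into a non-negative sum of the input function
convolved with decaying exponentials:

    TAC(t) ~= sum_j alpha_j * (ppIF * exp(-beta_j t))(t),  alpha_j >= 0

on a fixed logarithmic grid of frequencies beta_j (default 100 members
between 0.00063 s^-1 and 0.1 s^-1; the slow boundary sits just above the
C-11 decay constant, the fast boundary absorbs vascular-speed kinetics).
The total volume of distribution is the zero-frequency gain,
VT = sum_j alpha_j / beta_j.  Weighted fitting reduces to plain NNLS by
scaling rows with sqrt(w_i).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from ._conv import exp_conv, frame_average
from .frames import FrameSchedule, FrameWeights, TimeActivityCurve
from .input_function import PlasmaInputFunction

#: study defaults for the frequency grid (s^-1)
DEFAULT_N_BASIS = 100
DEFAULT_BETA_MIN = 0.00063
DEFAULT_BETA_MAX = 0.1


@dataclass
class SpectralBasis:
    """Log-spaced frequency grid and its frame-averaged convolved columns."""

    betas: np.ndarray             # s^-1, strictly increasing
    convolved: np.ndarray         # (n_frames, n_basis)
    schedule: FrameSchedule

    @property
    def n(self) -> int:
        return self.betas.size


@dataclass
class Spectrum:
    """NNLS solution for one TAC."""

    alphas: np.ndarray
    basis: SpectralBasis
    rss: float

    @property
    def vt(self) -> float:
        """Zero-frequency gain sum(alpha/beta) over all components."""
        return float(np.sum(self.alphas / self.basis.betas))

    @property
    def boundary_mass(self) -> float:
        """Fraction of sum(alpha) sitting on the grid end members
        (diagnostic: large values suggest the grid is too narrow)."""
        total = float(np.sum(self.alphas))
        if total == 0:
            return 0.0
        return float((self.alphas[0] + self.alphas[-1]) / total)


def log_spaced_betas(n: int, beta_min: float, beta_max: float) -> np.ndarray:
    """beta_j = beta_min * (beta_max/beta_min)^((j-1)/(n-1)), j = 1..n."""
    if beta_min <= 0 or beta_max <= 0 or beta_min >= beta_max:
        raise ValueError("need 0 < beta_min < beta_max")
    if n < 2:
        raise ValueError("need at least 2 basis members")
    return beta_min * (beta_max / beta_min) ** (np.arange(n) / (n - 1))


def build_basis(
    ppif: PlasmaInputFunction,
    schedule: FrameSchedule,
    n: int = DEFAULT_N_BASIS,
    beta_min: float = DEFAULT_BETA_MIN,
    beta_max: float = DEFAULT_BETA_MAX,
) -> SpectralBasis:
    """Convolve the ppIF with each basis exponential and frame-average."""
    betas = log_spaced_betas(n, beta_min, beta_max)
    cols = np.empty((schedule.n_frames, n))
    for j, beta in enumerate(betas):
        y = exp_conv(ppif.parent_plasma, ppif.dt, beta)
        cols[:, j] = frame_average(y, ppif.time, schedule.frame_start,
                                   schedule.frame_end)
    return SpectralBasis(betas=betas, convolved=cols, schedule=schedule)


def sa_fit(tac: TimeActivityCurve, basis: SpectralBasis,
           weights: FrameWeights) -> Spectrum:
    """Weighted NNLS spectrum of one TAC."""
    w = weights.values if isinstance(weights, FrameWeights) else np.asarray(weights)
    sw = np.sqrt(w)
    A = basis.convolved * sw[:, None]
    b = tac.activity * sw
    if not np.any(b):
        return Spectrum(np.zeros(basis.n), basis, 0.0)
    alphas, rnorm = nnls(A, b)
    return Spectrum(alphas, basis, float(rnorm**2))


def sa_voxelwise(
    dyn: np.ndarray,
    schedule: FrameSchedule,
    basis: SpectralBasis,
    weights: FrameWeights,
    mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel spectral VT and residual-sum-of-squares maps.

    No pre-smoothing is applied.  Masked-out and failed voxels are NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dyn.shape[:-1]:
        raise ValueError("mask shape must match the image grid")
    w = weights.values if isinstance(weights, FrameWeights) else np.asarray(weights)
    sw = np.sqrt(w)
    A = basis.convolved * sw[:, None]
    inv_betas = 1.0 / basis.betas

    vox = np.asarray(dyn, dtype=float)[mask] * sw[None, :]
    vt = np.full(mask.shape, np.nan, dtype=np.float32)
    rss = np.full(mask.shape, np.nan, dtype=np.float32)
    vt_vals = np.empty(vox.shape[0])
    rss_vals = np.empty(vox.shape[0])
    n_failed = 0
    for i in range(vox.shape[0]):
        b = vox[i]
        if not np.any(b):
            vt_vals[i], rss_vals[i] = 0.0, 0.0
            continue
        try:
            alphas, rnorm = nnls(A, b)
            vt_vals[i] = alphas @ inv_betas
            rss_vals[i] = rnorm**2
        except RuntimeError:
            vt_vals[i], rss_vals[i] = np.nan, np.nan
            n_failed += 1
    if vox.shape[0] and n_failed > 0.5 * vox.shape[0]:
        raise RuntimeError(f"NNLS failed on {n_failed}/{vox.shape[0]} voxels")
    vt[mask] = vt_vals
    rss[mask] = rss_vals
    return vt, rss
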