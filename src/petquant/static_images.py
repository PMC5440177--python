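"""SUV images, global radioactivity, and ROI sampling of parametric maps.

The standardised uptake value normalises tissue activity by injected dose
per body weight:  SUV = activity [kBq/ml] * weight [kg] / dose [MBq]
(dimensionally g/ml under the 1 ml ~ 1 g tissue convention).  SUV images
are computed from decay-corrected summation images over two late windows
(frames 16-21 and 22-24, i.e. 30.5-60.5 and 60.5-90.5 min of the default
schedule).

ROI sampling pools the voxels of both bilateral homologues (grey-matter
masked where the region spec says so; the brainstem is unpaired and
unmasked) and reports mean, sample SD, the within-ROI coefficient of
variation WS-CV = 100*SD/mean, and the voxel count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import FrameSchedule, sum_frames

#: 1-based frame windows of the two SUV variants on the default schedule
SUV_WINDOWS = {"suv_30_60": (16, 21), "suv_60_90": (22, 24)}


@dataclass
class ScanMeta:
    """Injection metadata for one scan session."""

    injected_dose: float   # MBq
    body_weight: float     # kg
    subject_id: str = ""
    session: str = "test"  # "test" | "retest"

    def __post_init__(self) -> None:
        if self.injected_dose <= 0 or self.body_weight <= 0:
            raise ValueError("injected dose and body weight must be positive")


@dataclass
class RegionSpec:
    """One ROI of the atlas: label ids of its homologues and masking rule."""

    name: str
    labels: tuple[int, ...]      # one id (unpaired) or two (left, right)
    gm_masked: bool = True
    is_reference: bool = False


def compute_suv(summed: np.ndarray, meta: ScanMeta) -> np.ndarray:
    """Per-voxel SUV from a decay-corrected summation image (kBq/ml)."""
    return np.asarray(summed, dtype=float) * meta.body_weight / meta.injected_dose


def suv_image(dyn: np.ndarray, schedule: FrameSchedule, meta: ScanMeta,
              window: str = "suv_30_60") -> np.ndarray:
    """SUV image for one of the standard late frame windows."""
    summed = sum_frames(dyn, schedule, SUV_WINDOWS[window])
    return compute_suv(summed, meta)


def global_radioactivity(summed: np.ndarray) -> float:
    """Mean activity within the global mask.

    The mask keeps voxels exceeding one-eighth of the whole-matrix mean,
    discarding the empty background around the head.
    """
    img = np.asarray(summed, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    threshold = img.mean() / 8.0
    mask = img > threshold
    if not np.any(mask):
        raise ValueError("global mask is empty (all-zero image?)")
    return float(img[mask].mean())


def sample_parametric(
    pmap: np.ndarray,
    labels: np.ndarray,
    region: RegionSpec,
    gm_mask: np.ndarray | None = None,
) -> dict:
    """Pooled ROI statistics of a parametric map.

    Voxels of all homologue labels are concatenated (grey-matter masked if
    the region spec requires and a mask is given); NaNs are excluded and
    counted.  Returns mean, sample SD, WS-CV (%), n_voxels, n_nan.
    """
    pmap = np.asarray(pmap, dtype=float)
    labels = np.asarray(labels)
    sel = np.isin(labels, region.labels)
    if region.gm_masked and gm_mask is not None:
        sel &= np.asarray(gm_mask, dtype=bool)
    vals = pmap[sel]
    finite = np.isfinite(vals)
    n_nan = int(np.count_nonzero(~finite))
    vals = vals[finite]
    if vals.size == 0:
        raise ValueError(f"ROI '{region.name}' is empty after masking")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    ws_cv = 100.0 * sd / mean if mean != 0 else float("nan")
    return {"mean": mean, "sd": sd, "ws_cv": ws_cv,
            "n_voxels": int(vals.size), "n_nan": n_nan}


def roi_tac(dyn: np.ndarray, labels: np.ndarray, region: RegionSpec,
            gm_mask: np.ndarray | None = None) -> np.ndarray:
    """Mean frame activity over the pooled homologue voxels of one ROI."""
    dyn = np.asarray(dyn, dtype=float)
    sel = np.isin(np.asarray(labels), region.labels)
    if region.gm_masked and gm_mask is not None:
        sel &= np.asarray(gm_mask, dtype=bool)
    if not np.any(sel):
        raise ValueError(f"ROI '{region.name}' is empty after masking")
    return dyn[sel].mean(axis=0)
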