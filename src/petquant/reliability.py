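"""Test-retest reproducibility and reliability statistics.

For a cohort scanned twice, each outcome (VT, BP_ND or SUV) per region and
quantification variant is summarised by:

* the signed symmetric percentage difference
  TD = 200 * (test - retest) / (test + retest),
* MA-TD, the median across subjects of |TD|, with qualitative categories
  (<10 low, 10-15 moderate, 15-20 high, >=20 very high),
* BS-CV, the between-subject coefficient of variation (the per-session
  CV across subjects, averaged over the two sessions),
* the one-way random-effects, single-measures intraclass correlation
  ICC = (MS_BS - MS_WS) / (MS_BS + (k-1)*MS_WS),
* the hippocampus/occipital heterogeneity ratio with its categories, and
* outlier flags (non-positive outcome, or WS-CV above 50% regional /
  100% voxelwise).

Region summaries report the median and interquartile range over the six
non-reference regions, rounded half-up to display precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

#: the six non-reference regions summarised in the report tables
SUMMARY_REGIONS = ("acg", "fusiform", "hippocampus",
                   "inferior_frontal", "insula", "occipital")

#: the 12 quantification variants, in report-column order
VARIANTS = ("2kbv", "4kbv", "logan_regional", "logan_voxelwise",
            "sa_regional", "sa_voxelwise", "suv_30_60", "suv_60_90",
            "srtm_brainstem", "srtm2_brainstem",
            "srtm_cerebellum", "srtm2_cerebellum")


@dataclass
class PairedMeasurements:
    """Test and retest outcome values for one region x variant."""

    subjects: list
    test: np.ndarray
    retest: np.ndarray
    region: str = ""
    variant: str = ""

    def __post_init__(self) -> None:
        self.test = np.asarray(self.test, dtype=float)
        self.retest = np.asarray(self.retest, dtype=float)
        if self.test.shape != self.retest.shape or self.test.ndim != 1:
            raise ValueError("test and retest must be equal-length 1-D arrays")
        if len(self.subjects) != self.test.size:
            raise ValueError("subjects must match the number of value pairs")
        if not (np.all(np.isfinite(self.test)) and np.all(np.isfinite(self.retest))):
            raise ValueError("values must be finite")


@dataclass
class ICCResult:
    """One-way ANOVA decomposition behind the ICC."""

    icc: float
    ms_bs: float
    ms_ws: float
    df_ws: int


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal half-up rounding as used in printed tables (0.825 -> 0.83)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def signed_td(test: float, retest: float) -> float:
    """Symmetric percentage test-retest difference, in (-200, 200)."""
    denom = test + retest
    if denom == 0:
        raise ZeroDivisionError("test + retest must be nonzero")
    return 200.0 * (test - retest) / denom


def td_category(ma_td_percent: float) -> str:
    if ma_td_percent < 10:
        return "low"
    if ma_td_percent < 15:
        return "moderate"
    if ma_td_percent < 20:
        return "high"
    return "very high"


def ma_td(pairs: PairedMeasurements) -> tuple[float, str]:
    """Median absolute symmetric test-retest difference (%) + category."""
    tds = np.array([abs(signed_td(t, r)) for t, r in zip(pairs.test, pairs.retest)])
    value = float(np.median(tds))
    return value, td_category(value)


def bs_cv(pairs: PairedMeasurements) -> float:
    """Between-subject CV (%): per-session sample CV, averaged over sessions."""
    if pairs.test.size < 2:
        raise ValueError("need at least 2 subjects for a between-subject CV")
    cvs = []
    for session in (pairs.test, pairs.retest):
        mean = session.mean()
        if mean <= 0:
            raise ValueError("non-positive session mean")
        cvs.append(100.0 * session.std(ddof=1) / mean)
    return float(np.mean(cvs))


def icc_oneway(pairs: PairedMeasurements) -> ICCResult:
    """One-way random-effects, single-measures ICC for two sessions.

    MS_BS and MS_WS come from the one-way ANOVA with subjects as the
    grouping factor and the k = 2 sessions as replicates;
    ICC = (MS_BS - MS_WS) / (MS_BS + (k-1)*MS_WS).
    """
    x = np.stack([pairs.test, pairs.retest], axis=1)  # (n, k)
    n, k = x.shape
    if n < 2:
        raise ValueError("need at least 2 subjects for an ICC")
    subj_means = x.mean(axis=1)
    grand = x.mean()
    ss_bs = k * float(np.sum((subj_means - grand) ** 2))
    ss_ws = float(np.sum((x - subj_means[:, None]) ** 2))
    ms_bs = ss_bs / (n - 1)
    ms_ws = ss_ws / (n * (k - 1))
    denom = ms_bs + (k - 1) * ms_ws
    if denom == 0:
        raise ValueError("zero total variance; ICC undefined")
    return ICCResult(icc=(ms_bs - ms_ws) / denom, ms_bs=ms_bs, ms_ws=ms_ws,
                     df_ws=k - 1)


def summarize_by_region(values_by_region: dict, display_decimals: int | None = None):
    """Median and IQR over the six non-reference regions.

    ``values_by_region`` maps each of the six region names to one metric
    value.  Returns (median, (q25, q75)); with ``display_decimals`` the
    three numbers are rounded half-up to that precision, matching the
    printed report convention (integer % for TD/CV, 2 decimals for ICC).
    """
    missing = [r for r in SUMMARY_REGIONS if r not in values_by_region]
    if missing:
        raise KeyError(f"missing regions: {missing}")
    vals = np.array([float(values_by_region[r]) for r in SUMMARY_REGIONS])
    med = float(np.median(vals))
    q25, q75 = (float(q) for q in np.percentile(vals, [25, 75]))
    if display_decimals is not None:
        med = round_half_up(med, display_decimals)
        q25 = round_half_up(q25, display_decimals)
        q75 = round_half_up(q75, display_decimals)
    return med, (q25, q75)


def heterogeneity_ratio(high_region_value: float, low_region_value: float):
    """Hippocampus/occipital binding ratio + category."""
    if low_region_value <= 0:
        raise ValueError("low-binding region value must be positive")
    ratio = high_region_value / low_region_value
    if ratio >= 2.0:
        cat = "very high"
    elif ratio >= 1.8:
        cat = "high"
    elif ratio >= 1.5:
        cat = "moderate"
    else:
        cat = "low"
    return float(ratio), cat


def flag_outlier(value: float, ws_cv: float | None, variant_kind: str) -> bool:
    """Outlier rule: non-positive outcome, or WS-CV beyond the kind's cap
    (50% for regional variants, 100% for voxelwise)."""
    if variant_kind not in ("regional", "voxelwise"):
        raise ValueError("variant_kind must be 'regional' or 'voxelwise'")
    if value <= 0:
        return True
    if ws_cv is None or not np.isfinite(ws_cv):
        return False
    cap = 50.0 if variant_kind == "regional" else 100.0
    return bool(ws_cv > cap)
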