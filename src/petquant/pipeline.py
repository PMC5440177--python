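"""End-to-end orchestration: quantify scans with all variants, then run
the test-retest reliability analysis.

``quantify_scan`` takes one dynamic scan (image + atlas + blood samples +
injection metadata) and returns a tidy table with one row per region x
variant: the outcome value (VT, BP_ND or SUV), a within-fit or within-ROI
variability summary, and convergence/outlier flags.  ``reliability_tables``
pairs the test and retest tables of a cohort and produces the three
report tables (MA-TD, BS-CV, ICC) plus summary rows and heterogeneity
ratios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import reliability as rel
from .compartmental import fit_2kbv, fit_4kbv
from .frames import (FrameSchedule, TimeActivityCurve, compute_frame_weights,
                     normalize_weights, uniform_weights)
from .graphical import LoganConfig, logan_regional, logan_voxelwise
from .input_function import BloodSamples, PlasmaInputFunction, build_ppif, fit_sigmoid
from .reference_tissue import SRTM2Config, fit_srtm, fit_srtm2_voxelwise
from .spectral import build_basis, sa_fit, sa_voxelwise
from .static_images import RegionSpec, ScanMeta, sample_parametric, roi_tac, suv_image

#: variants that need an arterial input function
ARTERIAL_VARIANTS = frozenset(
    {"2kbv", "4kbv", "logan_regional", "logan_voxelwise",
     "sa_regional", "sa_voxelwise"})

REGIONAL_VARIANTS = frozenset(
    {"2kbv", "4kbv", "logan_regional", "sa_regional",
     "srtm_brainstem", "srtm_cerebellum"})


def ppif_from_blood(blood: BloodSamples, schedule: FrameSchedule) -> PlasmaInputFunction:
    """Fit the two sigmoid models to the discrete samples and assemble
    the ppIF (the standard four-step construction)."""
    post = blood.discrete_time > schedule.injection_time
    pob_t = blood.discrete_time[post]
    pob_vals = blood.discrete_plasma[post] / blood.discrete_whole_blood[post]
    pob_model, _ = fit_sigmoid(pob_t, pob_vals, kind="plasma_over_blood")
    parent_model, _ = fit_sigmoid(blood.parent_fraction_time,
                                  blood.parent_fraction, kind="parent_fraction")
    return build_ppif(blood, pob_model, parent_model, schedule)


def quantify_scan(
    dyn: np.ndarray,
    schedule: FrameSchedule,
    labels: np.ndarray,
    gm_mask: np.ndarray,
    regions: list[RegionSpec],
    meta: ScanMeta,
    trues_rate: np.ndarray,
    blood: BloodSamples | None = None,
    ppif: PlasmaInputFunction | None = None,
    variants: tuple = tuple(rel.VARIANTS),
    voxel_size_mm=(4.0, 4.0, 4.0),
) -> pd.DataFrame:
    """Run the requested quantification variants on one scan.

    Either ``blood`` (raw samples; the ppIF is constructed internally) or
    a prebuilt ``ppif`` must be given for arterial variants.
    """
    variants = tuple(variants)
    unknown = set(variants) - set(rel.VARIANTS)
    if unknown:
        raise ValueError(f"unknown variants: {sorted(unknown)}")
    needs_ppif = sorted(set(variants) & ARTERIAL_VARIANTS)
    if needs_ppif and blood is None and ppif is None:
        raise ValueError(
            f"variant(s) {needs_ppif} require an arterial input function; "
            "provide blood samples or a ppIF")
    if ppif is None and blood is not None:
        ppif = ppif_from_blood(blood, schedule)

    roi_w = normalize_weights(compute_frame_weights(schedule, trues_rate), "roi")
    vox_w = normalize_weights(compute_frame_weights(schedule, trues_rate), "voxel")
    mask = np.asarray(labels) > 0
    by_name = {r.name: r for r in regions}
    tacs = {r.name: TimeActivityCurve(
        schedule, roi_tac(dyn, labels, r, gm_mask), label=r.name)
        for r in regions}

    rows = []

    def add_row(variant, region, value, ws_cv=np.nan, n_voxels=0, converged=True):
        kind = "regional" if variant in REGIONAL_VARIANTS else "voxelwise"
        rows.append({
            "subject": meta.subject_id, "session": meta.session,
            "variant": variant, "region": region, "value": float(value),
            "ws_cv": float(ws_cv), "n_voxels": int(n_voxels),
            "converged": bool(converged),
            "outlier": rel.flag_outlier(float(value),
                                        float(ws_cv) if np.isfinite(ws_cv) else None,
                                        kind),
        })

    def sample_all(variant, pmap):
        for r in regions:
            s = sample_parametric(pmap, labels, r, gm_mask)
            add_row(variant, r.name, s["mean"], s["ws_cv"], s["n_voxels"])

    basis = None
    for variant in variants:
        if variant in ("2kbv", "4kbv"):
            fitter = fit_2kbv if variant == "2kbv" else fit_4kbv
            n_par = 3 if variant == "2kbv" else 5
            for r in regions:
                res = fitter(tacs[r.name], ppif, roi_w)
                add_row(variant, r.name, res.vt_or_bp,
                        res.residual_cv(n_par), converged=res.converged)
        elif variant == "logan_regional":
            for r in regions:
                res = logan_regional(tacs[r.name], ppif)
                add_row(variant, r.name, res.vt_or_bp)
        elif variant == "logan_voxelwise":
            vt_map = logan_voxelwise(dyn, schedule, ppif, mask,
                                     LoganConfig(), voxel_size_mm)
            sample_all(variant, vt_map)
        elif variant == "sa_regional":
            basis = basis if basis is not None else build_basis(ppif, schedule)
            for r in regions:
                spec = sa_fit(tacs[r.name], basis, roi_w)
                add_row(variant, r.name, spec.vt)
        elif variant == "sa_voxelwise":
            basis = basis if basis is not None else build_basis(ppif, schedule)
            vt_map, _ = sa_voxelwise(dyn, schedule, basis, vox_w, mask)
            sample_all(variant, vt_map)
        elif variant in ("srtm_brainstem", "srtm_cerebellum"):
            ref = variant.split("_")[1]
            ref_tac = tacs[ref]
            for r in regions:
                if r.name == ref:
                    continue
                res = fit_srtm(tacs[r.name], ref_tac, roi_w)
                add_row(variant, r.name, res.vt_or_bp,
                        res.residual_cv(3), converged=res.converged)
        elif variant in ("srtm2_brainstem", "srtm2_cerebellum"):
            ref = variant.split("_")[1]
            ref_tac = tacs[ref]
            ref_sel = np.isin(labels, by_name[ref].labels)
            bp_map, _ = fit_srtm2_voxelwise(dyn, schedule, ref_tac, vox_w,
                                            mask & ~ref_sel, SRTM2Config())
            for r in regions:
                if r.name == ref:
                    continue
                s = sample_parametric(bp_map, labels, r, gm_mask)
                add_row(variant, r.name, s["mean"], s["ws_cv"], s["n_voxels"])
        elif variant in ("suv_30_60", "suv_60_90"):
            img = suv_image(dyn, schedule, meta, variant)
            sample_all(variant, img)
    return pd.DataFrame(rows)


def quantify_cohort(scans, regions=None, variants=tuple(rel.VARIANTS),
                    voxel_size_mm=(4.0, 4.0, 4.0)) -> pd.DataFrame:
    """Quantify every scan of a synthetic cohort (list of SyntheticScan)."""
    frames = []
    for scan in scans:
        d = scan.data
        regs = regions
        if regs is None:
            from .synthetic import default_phantom_spec
            regs = [r.spec for r in default_phantom_spec().regions]
        frames.append(quantify_scan(
            d["dyn"], scan.schedule, d["labels"], d["gm_mask"], regs,
            scan.meta, d["trues_rate"], blood=scan.blood,
            variants=variants, voxel_size_mm=voxel_size_mm))
    return pd.concat(frames, ignore_index=True)


def reliability_tables(outcomes: pd.DataFrame) -> dict:
    """Test-retest report tables from a two-session outcome table.

    Returns a dict with DataFrames ``ma_td``, ``bs_cv``, ``icc`` (rows =
    regions plus median/IQR summary rows, columns = variants), and
    ``heterogeneity`` (hippocampus/occipital ratio per variant).
    """
    wide = outcomes.pivot_table(index=["variant", "region", "subject"],
                                columns="session", values="value")
    if not {"test", "retest"}.issubset(wide.columns):
        raise ValueError("outcome table must contain 'test' and 'retest' sessions")
    if wide["test"].isna().any() or wide["retest"].isna().any():
        raise ValueError("unpaired subjects: every subject needs both sessions")

    variants = [v for v in rel.VARIANTS if v in outcomes["variant"].unique()]
    regions = list(outcomes["region"].unique())
    tables = {m: pd.DataFrame(index=regions, columns=variants, dtype=float)
              for m in ("ma_td", "bs_cv", "icc")}
    het_rows = {}
    for variant in variants:
        for region in regions:
            try:
                sub = wide.loc[(variant, region)]
            except KeyError:
                continue
            pairs = rel.PairedMeasurements(
                subjects=list(sub.index), test=sub["test"].to_numpy(),
                retest=sub["retest"].to_numpy(), region=region, variant=variant)
            # a metric can be undefined for a cell (e.g. a near-zero-mean
            # reference region under the other reference); leave it NaN
            for metric, fn in (("ma_td", lambda p: rel.ma_td(p)[0]),
                               ("bs_cv", rel.bs_cv),
                               ("icc", lambda p: rel.icc_oneway(p).icc)):
                if metric == "icc" and pairs.test.size < 2:
                    continue
                try:
                    tables[metric].loc[region, variant] = fn(pairs)
                except (ValueError, ZeroDivisionError):
                    pass
        mask_v = outcomes["variant"] == variant
        mean_of = lambda reg: outcomes.loc[
            mask_v & (outcomes["region"] == reg), "value"].mean()
        try:
            het_rows[variant] = rel.heterogeneity_ratio(
                mean_of("hippocampus"), mean_of("occipital"))[0]
        except (ValueError, ZeroDivisionError):
            het_rows[variant] = float("nan")

    for name, tab in tables.items():
        decimals = 2 if name == "icc" else 0
        med_row, q25_row, q75_row = {}, {}, {}
        for variant in variants:
            vals = {r: tab.loc[r, variant] for r in rel.SUMMARY_REGIONS
                    if r in tab.index and np.isfinite(tab.loc[r, variant])}
            if len(vals) == len(rel.SUMMARY_REGIONS):
                med, (q25, q75) = rel.summarize_by_region(vals, decimals)
                med_row[variant], q25_row[variant], q75_row[variant] = med, q25, q75
        tab.loc["median"] = pd.Series(med_row)
        tab.loc["iqr_25"] = pd.Series(q25_row)
        tab.loc["iqr_75"] = pd.Series(q75_row)

    tables["heterogeneity"] = pd.DataFrame(
        {"ratio": pd.Series(het_rows)}).rename_axis("variant")
    return tables
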