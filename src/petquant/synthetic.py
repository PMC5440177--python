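"""Synthetic dynamic-phantom generator with known ground truth.

No raw scanner data ship with this package; instead every pipeline stage
is exercised on a digital phantom that emulates the study design: the
24-frame 90.5-min acquisition, the continuous (0-15 min) plus discrete
arterial sampling scheme, regional kinetics spanning the tracer's binding
range (hippocampus highest, occipital lowest among cortical regions,
brainstem/cerebellum lowest overall, usable as pseudo-references), and a
test-retest cohort with controllable between-subject and within-subject
(session) variance of VT.

The phantom is a 32x32x16 grid of 4 mm voxels tiled with rectangular
bilateral regions — anatomically naive by design, but large enough
(>10^4 in-mask voxels) to give voxelwise methods realistic statistics.
Voxel noise is Gaussian with variance proportional to the
non-decay-corrected activity divided by frame length (count-statistics
scaling, the same model that motivates the frame weights), not a full
sinogram simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._conv import frame_average
from .compartmental import CompartmentalParams, simulate_tissue_tac, vt_from_params
from .frames import FrameSchedule, build_frame_schedule, compute_frame_weights
from .input_function import BloodSamples, PlasmaInputFunction, SigmoidModel
from .static_images import RegionSpec, ScanMeta

#: discrete arterial sample times (s): baseline + 4,6,8,10,20,35,50,65,80,90 min
DISCRETE_SAMPLE_TIMES = np.array(
    [0.0, 240.0, 360.0, 480.0, 600.0, 1200.0, 2100.0, 3000.0, 3900.0, 4800.0, 5400.0])

#: true plasma-over-blood ratio model of the phantom (rises above 1 late)
TRUE_POB = SigmoidModel(-0.45, -0.12, 0.2, 1.8, kind="plasma_over_blood")

#: true parent-fraction model (declines from 1 to ~0.35 by scan end)
TRUE_PARENT = SigmoidModel(0.62, 0.06, 0.4, 1.6, kind="parent_fraction")

#: non-displaceable delivery/clearance shared by all regions.  Chosen so
#: that both tissue eigenvalues of every region fall inside the spectral
#: grid [0.00063, 0.1] s^-1 and equilibrate well before the Logan t* —
#: the same internal consistency the published analysis settings assume.
_BASE_K1 = 0.45   # ml cm^-3 min^-1
_BASE_K2 = 0.30   # min^-1  -> V_ND = K1/k2 = 1.5
_BASE_K4 = 0.15   # min^-1
_BASE_BV = 0.03

#: target regional VT (ml/cm^3), spanning the tracer's binding range.
#: Pseudo-reference VTs sit low enough that even the occipital lobes
#: keep an appreciable BP_ND (~0.45) against them, consistent with the
#: binding heterogeneity a reference-tissue analysis of this tracer
#: class reports; the cerebellum keeps slightly more specific binding
#: than the brainstem.
REGION_VT = {
    "hippocampus": 8.0,
    "acg": 7.0,
    "insula": 6.3,
    "fusiform": 6.0,
    "inferior_frontal": 5.6,
    "occipital": 4.2,
    "cerebellum": 2.9,
    "brainstem": 2.8,
}


def _params_for_vt(vt: float) -> CompartmentalParams:
    """Two-tissue parameters hitting a target VT with the shared base rates."""
    v_nd = _BASE_K1 / _BASE_K2
    k3 = _BASE_K4 * max(vt / v_nd - 1.0, 0.0)
    return CompartmentalParams(_BASE_K1, _BASE_K2, k3, _BASE_K4, _BASE_BV)


@dataclass
class RegionDef:
    """One phantom region: ROI metadata plus its ground-truth kinetics."""

    spec: RegionSpec
    params: CompartmentalParams


@dataclass
class PhantomSpec:
    """Geometry, kinetics and noise model of the digital phantom."""

    grid_shape: tuple = (32, 32, 16)
    voxel_size_mm: tuple = (4.0, 4.0, 4.0)
    regions: list = field(default_factory=list)
    count_scale: float = 0.1   # counts per (kBq/ml)*s per voxel
    noise_scale: float = 1.0   # 0 disables all measurement noise
    seed: int = 0

    def region(self, name: str) -> RegionDef:
        for r in self.regions:
            if r.spec.name == name:
                return r
        raise KeyError(name)


def default_phantom_spec(**overrides) -> PhantomSpec:
    """The standard phantom: six cortical ROIs + two pseudo-references."""
    region_specs = {
        "acg": RegionSpec("acg", (1, 2)),
        "fusiform": RegionSpec("fusiform", (3, 4)),
        "hippocampus": RegionSpec("hippocampus", (5, 6)),
        "inferior_frontal": RegionSpec("inferior_frontal", (7, 8)),
        "insula": RegionSpec("insula", (9, 10)),
        "occipital": RegionSpec("occipital", (11, 12)),
        "cerebellum": RegionSpec("cerebellum", (13, 14), is_reference=True),
        "brainstem": RegionSpec("brainstem", (15,), gm_masked=False,
                                is_reference=True),
    }
    regions = [RegionDef(region_specs[name], _params_for_vt(vt))
               for name, vt in REGION_VT.items()]
    return PhantomSpec(regions=regions, **overrides)


def build_atlas(grid_shape=(32, 32, 16)):
    """Integer label image + grey-matter mask for the default region set.

    Bilateral regions get separate left/right labels; the brainstem is a
    single unpaired label excluded from the grey-matter mask.
    """
    nx, ny, nz = grid_shape
    if min(grid_shape) < 16 or nx < 32 or ny < 32:
        raise ValueError("grid too small for the default atlas (needs >= 32x32x16)")
    labels = np.zeros(grid_shape, dtype=np.int16)

    def box(label, xs, ys, zs):
        labels[xs[0]:xs[1], ys[0]:ys[1], zs[0]:zs[1]] = label

    left, right = (2, 15), (17, 30)
    # cortical slabs
    for (lo, hi), (llab, rlab) in (
        ((2, 12), (5, 6)),    # hippocampus, lower slab y 2-12
        ((12, 22), (1, 2)),   # acg
        ((22, 30), (9, 10)),  # insula
    ):
        box(llab, left, (lo, hi), (2, 8))
        box(rlab, right, (lo, hi), (2, 8))
    for (lo, hi), (llab, rlab) in (
        ((2, 12), (3, 4)),    # fusiform, upper slab
        ((12, 22), (7, 8)),   # inferior frontal
        ((22, 30), (11, 12)),  # occipital
    ):
        box(llab, left, (lo, hi), (8, 14))
        box(rlab, right, (lo, hi), (8, 14))
    # cerebellum: bottom slab, split at the midline
    box(13, (2, 16), (2, 30), (0, 2))
    box(14, (16, 30), (2, 30), (0, 2))
    # brainstem: central unpaired column carved out of the bottom slab
    box(15, (14, 18), (12, 20), (0, 2))

    gm_mask = (labels > 0) & (labels != 15)
    return labels, gm_mask


def generate_input_function(
    rng: np.random.Generator,
    schedule: FrameSchedule,
    peak_amp: float = 20.0,
    noise_scale: float = 1.0,
    detector_scale: float = 1.1,
    grid_dt: float = 1.0,
):
    """Analytic arterial curves + the blood-sample table measuring them.

    The true plasma curve is a three-exponential bolus model (linear rise
    into a fast spike, then intermediate and slow clearance), scaled to
    ``peak_amp`` kBq/ml.  Whole blood follows from the plasma-over-blood
    sigmoid; the parent fraction sigmoid gives the metabolite-corrected
    ppIF.  Measurements: continuous whole-blood at 1 Hz for 15 min with
    an (unknown to the pipeline) detector gain and 1.5% noise, discrete
    samples at the standard times with 2% noise, parent fractions with
    SD 0.015 — all scaled by ``noise_scale``.

    Returns (truth ppIF, BloodSamples).
    """
    inj = schedule.injection_time
    t = np.arange(0.0, schedule.total_duration + grid_dt / 2, grid_dt)
    tau = np.maximum(t - inj, 0.0) / 60.0  # minutes post injection
    lam1, lam2, lam3 = 4.0, 0.25, 0.012    # min^-1
    a1, a2, a3 = 60.0, 4.0, 1.0
    shape = (a1 * tau - a2 - a3) * np.exp(-lam1 * tau) \
        + a2 * np.exp(-lam2 * tau) + a3 * np.exp(-lam3 * tau)
    shape[t < inj] = 0.0
    plasma = peak_amp * shape / shape.max()

    pob = TRUE_POB(t)
    whole_blood = plasma / pob
    ppif = plasma * TRUE_PARENT(t)
    truth = PlasmaInputFunction(t, ppif, whole_blood, calibration_factor=1.0)

    # --- measurements
    cont_t = np.arange(0.0, 900.0 + 1e-9, 1.0)
    cont_wb = np.interp(cont_t, t, whole_blood) / detector_scale
    cont_wb = cont_wb * (1.0 + noise_scale * 0.015 * rng.standard_normal(cont_t.size))
    disc_t = DISCRETE_SAMPLE_TIMES.copy()
    disc_wb_true = np.interp(disc_t, t, whole_blood)
    disc_pl_true = np.interp(disc_t, t, plasma)
    disc_wb = disc_wb_true * (1.0 + noise_scale * 0.02 * rng.standard_normal(disc_t.size))
    disc_pl = disc_pl_true * (1.0 + noise_scale * 0.02 * rng.standard_normal(disc_t.size))
    pf_true = np.where(disc_t <= inj, 1.0, TRUE_PARENT(disc_t))
    pf = np.clip(pf_true + noise_scale * 0.015 * rng.standard_normal(disc_t.size), 0.0, 1.0)
    blood = BloodSamples(
        continuous_time=cont_t, continuous_whole_blood=np.maximum(cont_wb, 0.0),
        discrete_time=disc_t, discrete_whole_blood=np.maximum(disc_wb, 0.0),
        discrete_plasma=np.maximum(disc_pl, 0.0),
        parent_fraction_time=disc_t, parent_fraction=pf,
    )
    return truth, blood


def generate_phantom_dynamic(
    spec: PhantomSpec,
    ppif: PlasmaInputFunction,
    schedule: FrameSchedule,
    rng: np.random.Generator,
    vt_multipliers: dict | None = None,
):
    """One dynamic scan of the phantom.

    ``vt_multipliers`` maps region name -> multiplicative VT effect
    (subject/session variation); it is realised by dividing k2, which
    scales VT exactly while keeping all rates positive.  Noise is added
    on the non-decay-corrected scale with variance C_ndc/(L_i *
    count_scale) per voxel, then the data are decay-corrected back, so
    the returned 4-D image is decay-corrected like reconstructed frames.

    Returns a dict with dyn, labels, gm_mask, trues_rate, region TACs and
    the realised ground-truth parameters/VT per region.
    """
    labels, gm_mask = build_atlas(spec.grid_shape)
    vt_multipliers = vt_multipliers or {}
    n_frames = schedule.n_frames
    dyn = np.zeros(spec.grid_shape + (n_frames,))
    true_params, true_vt, region_tacs = {}, {}, {}
    for region in spec.regions:
        name = region.spec.name
        m = float(vt_multipliers.get(name, 1.0))
        p0 = region.params
        p = CompartmentalParams(p0.K1, p0.k2 / m, p0.k3, p0.k4, p0.bv)
        tac = simulate_tissue_tac(p, ppif, schedule, label=name)
        sel = np.isin(labels, region.spec.labels)
        dyn[sel] = tac.activity
        true_params[name] = p
        true_vt[name] = vt_from_params(p)
        region_tacs[name] = tac

    mids = schedule.frame_mid
    lam = schedule.decay_constant
    decay = np.exp(-lam * mids)
    ndc = dyn * decay  # non-decay-corrected frame values

    voxvol_ml = float(np.prod(spec.voxel_size_mm)) / 1000.0
    trues = spec.count_scale * voxvol_ml * ndc.sum(axis=(0, 1, 2))
    trues = np.maximum(trues, 1e-6 * trues.max())

    if spec.noise_scale > 0:
        var = np.maximum(ndc, 1e-3 * ndc.max()) / (
            schedule.frame_duration * spec.count_scale)
        ndc = ndc + spec.noise_scale * np.sqrt(var) * rng.standard_normal(ndc.shape)
        dyn = ndc / decay

    return {
        "dyn": dyn,
        "labels": labels,
        "gm_mask": gm_mask,
        "trues_rate": trues,
        "region_tacs": region_tacs,
        "true_params": true_params,
        "true_vt": true_vt,
    }


def true_bp_nd(true_vt: dict, reference: str) -> dict:
    """Ground-truth BP_ND of every region relative to a pseudo-reference."""
    ref = true_vt[reference]
    return {name: vt / ref - 1.0 for name, vt in true_vt.items() if name != reference}


@dataclass
class SyntheticScan:
    """One synthetic session of one subject, with its ground truth."""

    subject_id: str
    session: str
    meta: ScanMeta
    schedule: FrameSchedule
    ppif_true: PlasmaInputFunction
    blood: BloodSamples
    data: dict  # output of generate_phantom_dynamic


def _multipliers(rng, names, cv_percent: float) -> dict:
    """Independent lognormal multipliers with the given CV (%)."""
    if cv_percent <= 0:
        return {n: 1.0 for n in names}
    cv = cv_percent / 100.0
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    draws = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=len(names))
    return dict(zip(names, draws))


def generate_test_retest_cohort(
    n_subjects: int = 5,
    spec: PhantomSpec | None = None,
    bs_cv_true: float = 10.0,
    ws_cv_true: float = 3.0,
    seed: int = 0,
    make_images: bool = True,
):
    """Paired test/retest scans for a synthetic cohort.

    The VT of every region is multiplied by a subject effect and a session
    effect.  Each effect has a global component shared by all regions and
    an independent per-region component combining in quadrature to the
    requested CV.  The per-region share is small — 20% of the
    between-subject CV and 25% of the session CV — because regional
    binding *ratios* are far more stable than absolute VT, both across
    people and especially across scan days; this is what makes
    reference-ratio outcomes (BP_ND) more reproducible than VT, while
    absolute outcomes carry the full CV.  Input functions are regenerated
    per session (fresh measurement noise, amplitude jitter tied to the
    session CV).

    Returns (scans, ground_truth) where ``scans`` is a list of
    SyntheticScan and ``ground_truth`` maps (subject, session) ->
    region -> true VT.  With ``make_images=False`` the image and blood
    data are omitted (ground truth only), which keeps large-cohort
    variance studies cheap.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if bs_cv_true < 0 or ws_cv_true < 0:
        raise ValueError("CVs must be non-negative")
    spec = spec or default_phantom_spec()
    rng = np.random.default_rng(seed)
    schedule = build_frame_schedule()
    names = [r.spec.name for r in spec.regions]
    bs_region_share, ws_region_share = 0.20, 0.25
    bs_global = bs_cv_true * np.sqrt(1.0 - bs_region_share**2)
    bs_region = bs_cv_true * bs_region_share
    ws_global = ws_cv_true * np.sqrt(1.0 - ws_region_share**2)
    ws_region = ws_cv_true * ws_region_share

    scans, ground_truth = [], {}
    for i in range(n_subjects):
        sid = f"sub{i+1:02d}"
        subj_global = _multipliers(rng, ["_g"], bs_global)["_g"]
        subj_region = _multipliers(rng, names, bs_region)
        weight = float(rng.normal(78.0, 9.0))
        for session in ("test", "retest"):
            sess_global = _multipliers(rng, ["_g"], ws_global)["_g"]
            sess_region = _multipliers(rng, names, ws_region)
            mult = {n: subj_global * subj_region[n] * sess_global * sess_region[n]
                    for n in names}
            true_vt = {}
            for region in spec.regions:
                base_vt = vt_from_params(region.params)
                true_vt[region.spec.name] = base_vt * mult[region.spec.name]
            ground_truth[(sid, session)] = true_vt
            if not make_images:
                continue
            peak = 20.0 * float(
                _multipliers(rng, ["_a"], ws_global)["_a"])
            ppif_true, blood = generate_input_function(
                rng, schedule, peak_amp=peak, noise_scale=spec.noise_scale)
            data = generate_phantom_dynamic(spec, ppif_true, schedule, rng,
                                            vt_multipliers=mult)
            meta = ScanMeta(injected_dose=float(rng.normal(441.0, 7.0)),
                            body_weight=weight, subject_id=sid, session=session)
            scans.append(SyntheticScan(sid, session, meta, schedule,
                                       ppif_true, blood, data))
    return scans, ground_truth
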