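# Methods

This note documents the models, conventions and design choices behind
`petquant`, in the spirit of a software methods appendix: what is
computed, under which assumptions, and what the synthetic validation
does and does not demonstrate.

## Acquisition model and timing conventions

The default frame schedule is 24 contiguous frames covering 90.5 min
(1×30 s, 4×15 s, 4×60 s, 2×150 s, 10×300 s, 3×600 s), with the time
origin at scan start and the bolus injected at 30 s; frames 16–21 and
22–24 therefore span 30.5–60.5 and 60.5–90.5 min, the two SUV windows.
Frame midpoints serve both as decay-correction reference times and as
the abscissa where models meet frame data; frames are short relative to
1/λ (λ = 5.663×10⁻⁴ s⁻¹ for ¹¹C), so midpoint decay factors are
adequate. All model evaluation happens on a 1-s uniform grid; frame
values are trapezoidal averages of the fine-grid signal over each frame,
matching what a scanner reports.

Frame weights follow count statistics: w_i = L_i/T_i with L_i the frame
length and T_i the true-coincidence rate of the non-decay-corrected
data. ROI weights are normalised to sum to the frame count with a cap of
2.5; the cap and the sum constraint are enforced simultaneously by
solving the clip-then-rescale fixed point exactly (water-filling over
the capped set) rather than iterating. Voxel weights keep their scale
but the max/min ratio is floored to ≤ 1000.

## Input function

The ppIF is assembled in four steps: (1) the continuous whole-blood
detector (0–15 min) is cross-calibrated against the early discrete
samples by the closed-form least-squares ratio Σdc/Σc²; (2) calibrated
whole blood is converted to plasma with a fitted plasma-over-blood
model; (3) the continuous plasma segment is joined to the late discrete
plasma samples by a natural cubic spline on the 1-s grid; (4) the result
is multiplied by the fitted parent-fraction model. Both ratio models use
the same four-parameter sigmoid f(t) = 1 − (x1 + x2·t_h)/((x3/t_h)^x4 + 1)
(t_h in hours), which tends to 1 at t → 0 for x4 > 0. The exact
bracketing of this functional form is ambiguous in the source material;
the adopted form satisfies the boundary behaviour and declines (or
rises, x1 < 0) sigmoidally, and fits are by Nelder–Mead from a small
deterministic start set. Values are clipped to [0,1] (parent fraction)
or to positive values (plasma-over-blood). Negative interpolated plasma
is clipped to zero; the whole-blood curve is extended past 15 min by the
same spline through the discrete whole-blood samples for vascular terms.

## Kinetic models

**Convolution core.** Every model reduces to convolutions of a curve
with decaying exponentials. For a piecewise-linear input on a uniform
grid the step-wise convolution integral has a closed form, implemented
as a first-order IIR filter — exact for piecewise-linear inputs, so no
ODE stepping is needed; an independent stiff-ODE oracle in the test
suite confirms agreement to <0.1%.

**Compartmental (2kbv/4kbv).** Rates are min⁻¹ internally (converted
once at the module boundary). The measured signal convention is
C_meas = C_T + bv·C_WB, i.e. the tissue term is *not* scaled by (1−bv).
This choice is deliberate: under it the Logan plot of the two-tissue
model has slope V_T + bv, so subtracting the fixed vascular contribution
before the graphical analysis leaves a slope of exactly V_T without any
rescaling — the convention the downstream graphical analysis assumes.
Fitting is Nelder–Mead on the weighted residual sum of squares from
fixed small starting estimates (K1 = 0.01 ml·cm⁻³·min⁻¹, k2–k4 = 0.001
min⁻¹, bv = 0.05), with rates log-transformed and bv logit-transformed
to enforce the constraints in an unconstrained optimiser; two
deterministic alternate starts (rates ×10, ×100) guard against the
shallow basin around the very small default start, and the best of the
three runs is returned.

**Logan graphical analysis.** Equal weights, t* = 1680 s (at least
three frames beyond t* required), fixed bv = 0.028 multiplied by the
whole-blood curve and subtracted from the TAC before regression; the
slope is reported directly as V_T. The running TAC integral at frame
midpoints is computed from frame values as Σ(value×L) over earlier
frames plus half the current frame — exact for frame-averaged data;
the ppIF integral is trapezoidal on the fine grid. Points where the
vascular-subtracted TAC falls below 1% of its maximum are excluded to
avoid division blow-ups. Voxelwise maps pre-smooth each frame with a
2 mm FWHM Gaussian and run the same regression fully vectorised.

**Spectral analysis.** 100 log-spaced frequencies between 0.00063 and
0.1 s⁻¹ (the slow boundary just above the ¹¹C decay constant); weighted
NNLS by row-scaling with √w; V_T = Σ α_j/β_j over *all* retained
components, with no separate blood column — the fast boundary absorbs
vascular-speed kinetics; the fraction of spectral mass on the grid end
members is reported as a diagnostic. Voxelwise maps are fitted without
pre-smoothing.

**SRTM / SRTM2.** The operational equation is evaluated with the
measured reference frame values carrying the linear R1·Cr term (as in
basis-function implementations) and the fine-grid interpolated reference
feeding only the convolution term; this makes "target ≡ reference"
recover BP_ND = 0 exactly. Regional SRTM fits (R1, k2a, k2′) by
Nelder–Mead from R1 = 0.95, k2a = k2′ = 0.001 min⁻¹ with the same
multi-start guard; BP_ND = R1·k2′/k2a − 1 holds as an identity of the
returned parameters. Voxelwise SRTM2 is two-pass: pass 1 runs
basis-function SRTM (θ grid log-spaced over [0.00063, 0.014] s⁻¹, 100
members, per-θ linear solve) inside a tight brain mask — voxels above
40% of the 99th-percentile of the full-scan summed image — and derives
per-voxel k2′ = c2/c1 + θ; pass 2 fixes k2′ at the unweighted global
median and re-solves (R1, k2a) per voxel. The θ grid bounds imply
apparent rates ≥ 0.038 min⁻¹; kinetics slower than that are outside the
model space, as for any basis-function scheme.

**SUV and global activity.** SUV = activity[kBq/ml] × weight[kg] /
dose[MBq] on decay-corrected summation images (duration-weighted frame
means). The global-activity mask keeps voxels above one-eighth of the
whole-matrix mean. ROI sampling pools both bilateral homologues
(grey-matter-masked for cortical regions and cerebellum; the brainstem
is unpaired and unmasked), excludes NaN voxels and counts them, and uses
sample (n−1) SDs throughout.

## Reliability statistics

MA-TD is the median across subjects of |200(test−retest)/(test+retest)|,
with categories <10 low, 10–15 moderate, 15–20 high, ≥20 very high
(boundaries inclusive below). The between-subject CV is defined as the
per-session sample CV across subjects averaged over the two sessions
(the source material names but does not define it; the definition is
isolated in one function). The ICC is the one-way random-effects,
single-measures form (MS_BS − MS_WS)/(MS_BS + (k−1)·MS_WS), verified in
the tests against both a brute-force ANOVA oracle and an independent
implementation. Region summaries take the median and the
linearly-interpolated 25th–75th percentiles over the six comparison
regions, rounded half-up to display precision (integer % for TD/CV, two
decimals for ICC); internal values keep full precision. Outlier flags:
outcome ≤ 0, or a within-ROI CV above 50% (regional variants, where it
is derived from the weighted-RSS residual CV of the fit) or 100%
(voxelwise variants, where it is the voxel SD/mean within the ROI).
Heterogeneity ratio categories: 1.5–1.8 moderate, 1.8–2.0 high, ≥2.0
very high, boundaries inclusive below.

## Synthetic phantom

The generator emulates the study design, not anatomy: a 32×32×16 grid of
4 mm voxels tiled with rectangular bilateral regions (>10⁴ in-mask
voxels — big enough for meaningful voxelwise statistics, small enough
for desk-scale runs), six cortical ROIs spanning the binding range
(hippocampus V_T 8.0 down to occipital 4.2) plus cerebellum (2.9) and
brainstem (2.8) as pseudo-references with near-zero specific binding;
the cerebellar V_T sits slightly above the brainstem's because neither
pseudo-reference is truly binding-free, and both sit low enough that
even the lowest-binding cortical region keeps an appreciable BP_ND
(~0.45) against them, consistent with the binding heterogeneity
reference-tissue analyses of this tracer class report. The shared base kinetics
(K1 = 0.45 ml·cm⁻³·min⁻¹, k2 = 0.3, k4 = 0.15 min⁻¹, bv = 0.03) place
both tissue eigenvalues of every region inside the spectral grid and
give equilibration well before the Logan t* — the same internal
consistency between tracer kinetics and fixed analysis settings that the
published settings assume for the real tracer.

The true plasma curve is a three-exponential bolus model scaled to a
20 kBq/ml peak; whole blood and the ppIF follow from the generator's own
plasma-over-blood and parent-fraction sigmoids. Measurements mirror the
sampling design: 1 Hz continuous whole blood for 15 min with an unknown
detector gain and 1.5% noise, discrete samples at baseline and 4–90 min
with 2% noise, parent fractions with SD 0.015.

Voxel noise is Gaussian with variance C_ndc/(L_i × count_scale) on the
non-decay-corrected scale (count_scale = 0.1 counts per kBq/ml·s gives
~25% relative noise in late-frame voxels, a realistic figure), then
decay-corrected — consistent with the weighting model, but *not* a
sinogram-level simulation: no scanner PSF, attenuation, scatter, randoms
or motion. Test–retest structure: each region's V_T is multiplied by a
subject effect and a session effect, each decomposed (in quadrature)
into a global component shared by all regions and an independent
per-region component, with total CVs of 10% (between-subject) and 3%
(session) by default. The per-region share is deliberately small (20%
of the between-subject CV, 25% of the session CV): regional binding
*ratios* are far more stable than absolute V_T — across people, and
especially across scan days — which is precisely why reference-ratio
outcomes (BP_ND) come out more reproducible and less between-subject
variable than V_T or SUV, the qualitative pattern the reliability
comparison is about. Effects are
realised by dividing k2, which scales V_T exactly while keeping all
rates positive. Session-level input functions are regenerated with
amplitude jitter tied to the session CV, and all noise sources scale
with a single `noise_scale` (0 = fully noiseless, bit-reproducible per
seed).

Consequently, passing tests demonstrate internal consistency, correct
implementation of each estimator, and the qualitative reliability
ordering under realistic noise — they cannot certify behaviour under
scanner physics, anatomy-dependent partial-volume effects or subject
motion, which the phantom does not model.

## Numerical choices and problem sizes

Nelder–Mead runs up to 5000 iterations per start (xatol/fatol tight
enough that noiseless recovery is limited by the model, not the
optimiser); non-convergence is flagged, never silently returned.
Voxelwise Logan and SRTM2 are vectorised across voxels; spectral NNLS
loops per voxel (~10⁴ voxels in seconds). The validation suite uses a
five-subject cohort (10 scans) for the end-to-end reliability check, 100
replicates for noisy-recovery medians, and five independent 50-subject
ground-truth cohorts for the variance-components ICC check (the
single-cohort ICC estimator has SD ≈ 0.03 at n = 50, so the five-cohort
mean is the statistic held to its 0.05 band).

## Known limitations

No delay/dispersion correction of the continuous detector; no
parameter covariance or standard errors from the fits; no irreversible
or bandpass-spectral variants; NIfTI affines carry voxel size only (no
anatomical orientation); the phantom's atlas is geometric, not
anatomical.
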