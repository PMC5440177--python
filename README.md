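# petquant

Dynamic PET quantification and test–retest reliability analysis for
reversible radiotracers, built around the workflow used to validate
GABA_A α5-subunit radioligands: construct an arterial parent-plasma
input function (ppIF) from continuous and discrete blood sampling, fit
six quantification method families (12 variants) to a 24-frame, 90.5-min
dynamic acquisition, and summarise paired test/retest scans with the
field's standard reproducibility and reliability statistics.

**Who it is for.** PET modellers who need a transparent, scriptable
implementation of the classical quantification stack — and a synthetic
dynamic phantom with known ground truth to validate every stage, since
raw human scan data of this kind are rarely shareable.

## Methods implemented

| Variant | Outcome | Input |
|---|---|---|
| `2kbv`, `4kbv` | V_T | ppIF (Nelder–Mead, frame-weighted) |
| `logan_regional`, `logan_voxelwise` | V_T | ppIF (t* = 1680 s, fixed b_v = 0.028) |
| `sa_regional`, `sa_voxelwise` | V_T | ppIF (NNLS, 100 log-spaced β ∈ [0.00063, 0.1] s⁻¹) |
| `suv_30_60`, `suv_60_90` | SUV | injected dose + body weight |
| `srtm_{brainstem,cerebellum}` | BP_ND | pseudo-reference TAC |
| `srtm2_{brainstem,cerebellum}` | BP_ND | two-pass basis-function SRTM2 (β ∈ [0.00063, 0.014] s⁻¹) |

Core relations: the one/two-tissue compartment models with blood volume
give V_T = K1/k2 and V_T = (K1/k2)(1 + k3/k4); spectral analysis
decomposes a TAC into Σ_j α_j · (ppIF ⊗ e^{−β_j t}) with α_j ≥ 0 and
V_T = Σ α_j/β_j; the SRTM operational equation is
C(t) = R1·Cr(t) + R1(k2′ − k2a)·(Cr ⊗ e^{−k2a t}) with
BP_ND = R1·k2′/k2a − 1.

Reliability statistics: signed symmetric test–retest difference
TD = 200(test − retest)/(test + retest); MA-TD (median |TD|) with
low/moderate/high/very-high categories; between-subject CV; the one-way
random-effects single-measures ICC = (MS_BS − MS_WS)/(MS_BS + MS_WS) for
two sessions; hippocampus/occipital heterogeneity ratios; outlier flags.

## Worked example

```python
import numpy as np
from petquant import (build_frame_schedule, default_phantom_spec,
                      generate_test_retest_cohort, quantify_cohort,
                      reliability_tables)

scans, truth = generate_test_retest_cohort(n_subjects=5, seed=20)
outcomes = quantify_cohort(scans, variants=("sa_voxelwise",
                                            "srtm_cerebellum"))
tables = reliability_tables(outcomes)
print(tables["ma_td"].loc[["hippocampus", "occipital", "median"]].round(1))
```

prints (seed 20):

```
             sa_voxelwise  srtm_cerebellum
hippocampus           3.1              0.6
occipital             3.8              1.2
median                2.0              2.0
```

i.e. on a five-subject synthetic cohort with 10% between-subject and 3%
session-level variability of V_T plus count-scaled voxel noise, both
voxelwise spectral analysis and cerebellar-reference SRTM reproduce the
outcome to within a few percent median absolute test–retest difference —
the "low MA-TD" regime. `tables["icc"]` and `tables["bs_cv"]` hold the
companion reliability and between-subject spread tables, and
`tables["heterogeneity"]` the hippocampus/occipital binding ratio per
variant.

The same workflow is available from the shell:

```bash
petquant simulate --subjects 5 --seed 1 --out cohort/
petquant quantify --subjects 5 --seed 1 --out results/
petquant reliability --outcomes results/outcomes.csv --out results/
```

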