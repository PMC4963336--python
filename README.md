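# bonetrack

Longitudinal quantitative bone-SPECT/CT analysis for tracking osseous
metastases under therapy. The package covers the full measurement chain used
to decide, per lesion, whether skeletal tracer uptake is progressing,
stable, or regressing between a baseline and a follow-up scan — and the
agreement statistics used to compare that quantitative call against visual
reading.

## Who this is for

Physicists and physicians working with calibrated (quantitative) SPECT/CT of
the skeleton, and methodologists studying observer agreement in response
assessment. Everything runs on synthetic voxel phantoms, so the pipeline is
fully testable without patient data.

## What it computes

**SUV quantification.** Reconstructed counts are converted to activity
concentration via a linear calibration factor S (counts·s⁻¹ per kBq in a
voxel) and the dwell time T, decay-corrected to injection time
(factor 2^(Δt/T½), Tc-99m T½ = 360.4 min), then normalised by the net
injected activity A_net (prepared minus residual syringe activity, both
decayed to injection time) per gram of body weight:

    SUV = C[kBq/mL] · W[g] / A_net[kBq]      (1 g/mL tissue density)

From an ellipsoidal VOI the package extracts SUV_max, SUV_mean, and
SUV_peak — the mean over a 1 cm³ sphere centred on the hottest VOI voxel
(the PERCIST-style convention) — plus the lesion-to-reference uptake ratio
SUV_peak / SUV_mean(healthy vertebra), which cancels global fluctuations in
bone metabolism between time points.

**Response classification.** A lesion is progressive if its value rises by
strictly more than 30 %, regressive if it falls by strictly more than 30 %,
stable otherwise — applied to SUV_peak (absolute mode) or to the uptake
ratio (ratio mode).

**Agreement.** Cohen's kappa k = (p0 − pe)/(1 − pe) from full 3×3
cross-tabulations or directly from marginal counts plus an agreement count
(unweighted kappa needs nothing else), with Landis–Koch verbal labels,
discrepancy counts, Mann–Whitney U and Spearman rank correlation.

**Synthetic phantoms.** Two-time-point subjects with up to six ellipsoidal
lesions, a vertebral reference region, Poisson count noise, and stochastic
confusion-matrix readers, all seed-reproducible.

## Worked example

```python
from bonetrack import (classify_lesions, default_phantom, extract_metrics,
                       quantify_counts)
from bonetrack.phantom import build_activity_volume, expected_counts

spec = default_phantom(3, (0.5, 0.0, -0.5))   # true changes +50 %, 0 %, -50 %
vois = [l.to_voi() for l in spec.lesions] + [spec.reference_voi]
metrics = {}
for tp in (1, 2):
    meta = spec.meta(tp)
    suv = quantify_counts(expected_counts(build_activity_volume(spec, tp), meta), meta)
    metrics[tp] = extract_metrics(suv, vois)
print(classify_lesions(metrics[1], metrics[2], mode="absolute").to_string(index=False))
```

prints

```
lesion_id     mode  value_tp1  value_tp2  delta    category
      L01 absolute       20.4       30.6    0.5 progressive
      L02 absolute       20.4       20.4    0.0      stable
      L03 absolute       20.4       10.2   -0.5  regressive
```

i.e. the noiseless pipeline recovers each lesion's painted SUV_peak exactly
(20.4 at baseline) and classifies every true change correctly; ratio mode
(`mode="ratio"`) does the same after normalising by the reference vertebra
(SUV_mean 5.6 → 4.9). The `examples/` directory has one narrative script
per capability, and the same stages are exposed as a CLI:
`bonetrack simulate | quantify | classify | agree | report`.

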