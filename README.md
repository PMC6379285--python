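# sitvolumetry

Signal-intensity-threshold (SIT) volumetry of lung nodules: digital
phantoms with exactly known volumes, threshold-based 3D segmentation, and
the method-agreement statistics used to compare a radiation-free MRI
workflow against a CT (or mass-derived) reference.

## The problem

Indeterminate pulmonary nodules are followed by measuring their volume
over time: growth of at least 25% between scans, or a volume doubling time
(VDT) under 400 days, flags a nodule as suspicious. CT volumetry is the
clinical reference, but every follow-up scan adds radiation dose. MRI with
ultra-short-echo-time sequences now reaches ~1 mm isotropic resolution in
the lung, making MRI volumetry plausible — provided a segmentation rule
measures the same volumes CT does.

This package implements and evaluates the simplest such rule. Around each
nodule the user places a spherical region of interest (ROI) containing the
whole lesion plus an air margin. With `I_max` and `I_min` the intensity
extremes inside the ROI, every ROI voxel with intensity in

```
[ C · (I_max − I_min) + I_min ,  I_max ]
```

is part of the nodule. The fraction `C ∈ [0, 1]` is the only tunable
parameter: at `C = 0` the whole ROI is selected, and raising `C` discards
progressively dimmer voxels, so masks are nested and the measured volume
is non-increasing in `C`.

`C` is calibrated on phantoms: nodules of exactly known volume are imaged,
segmented at `C ∈ {20, 30, 40, 50}%`, and the value maximising Lin's
concordance correlation with the true volumes is selected. Agreement of
the calibrated method with the reference is then summarised by

* **Lin's concordance** ρ_c = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²),
  factored as ρ_c = ρ · C_b (precision × accuracy),
* **reduced major axis regression** (slope = sign(ρ)·s_y/s_x), and
* **percent Bland-Altman**: d_i = 100·(y_i − x_i)/x_i, bias = mean(d),
  limits of agreement = bias ± 1.96·SD(d).

Because no physical phantom or scanner is available to this code, a
synthetic generator stands in for both: spherical/hemispherical nodules of
analytic volume are rasterized with sub-voxel precision into a textured
background, blurred by a Gaussian point-spread function, and degraded with
Rician (MRI) or Gaussian (CT) noise. Ground truth is exact by
construction, playing the role of mass-derived volumes from precision
weighing.

## Worked example

Measure a synthetic 121 mm³ nodule and compare against a 110 mm³
reference:

```python
from sitvolumetry import (NoduleSpec, PhantomSpec, SphericalROI,
                          compose_phantom, run_single_case)

nod = NoduleSpec("case", center=(14.0, 14.0, 14.0), volume_true=121.0,
                 shape="sphere")
spec = PhantomSpec(grid_shape=(29, 29, 29), spacing=(1.0, 1.0, 1.0),
                   nodules=[nod], nodule_signal=100.0, background_mean=20.0,
                   background_texture_sd=5.0, blur_fwhm=1.2,
                   noise_model="rician", noise_sd=2.0, seed=8)
image, truth = compose_phantom(spec)
out = run_single_case(image, SphericalROI(nod.center, 9.0), c=0.50,
                      reference_volume=110.0)
```

`out` (the 120 mm³ SIT volume is within 1 mm³ of the manufactured 121 mm³;
the +9% difference is relative to the deliberately smaller reference):

```json
{
  "avg_diam_mm": 7.0,
  "c": 0.5,
  "eq_diam_mm": 6.12,
  "method": "sit_mri",
  "percent_difference": 9.09,
  "percent_difference_rounded": 9,
  "reference_volume_mm3": 110.0,
  "volume_mm3": 120.0
}
```

The full phantom study — 22 nodules of 16–561 mm³, four of which fall
under the 50 mm³ analysis cutoff — runs end to end in seconds:

```python
from sitvolumetry import ExperimentConfig, MethodAgreement, run_phantom_experiment

report = run_phantom_experiment(ExperimentConfig(seed=1))
x = report.volumes_per_c["truth"]
y = report.volumes_per_c[f"c={report.selected_c:.2f}"]
print(MethodAgreement(x, y, xname="truth", yname="sit_mri").fit().summary())
```

```
Method agreement: sit_mri vs truth (n = 18)
----------------------------------------------------------
Pearson rho                0.9994
Bias correction C_b        0.9996
Lin's rho_c                0.9990
RMA slope                  0.9858
RMA intercept              -0.761 mm^3
Bland-Altman bias           -1.64 %
Limits of agreement    [-9.13, 5.84] %
```

Eighteen of the 22 manufactured nodules are analyzed; the calibration
sweep selects `C = 0.50` for these synthetic acquisition conditions
(ρ_c = 0.999), and the SIT volumes agree with ground truth to a −1.6%
bias with limits of agreement inside ±10%. On real scanner data the
optimal `C` depends on the point-spread function and background signal —
which is exactly why the calibration sweep exists.

The same operations are scriptable from the shell via the `sitvol` CLI:
`sitvol phantom generate`, `sitvol segment sit`, `sitvol measure`,
`sitvol agree`, `sitvol study run`, `sitvol case`.

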