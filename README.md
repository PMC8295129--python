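# mmphantom

Ground-truth data for abdominal image registration is scarce: patient
positioning is never reproduced between scans, organs deform with breathing,
and manual multi-organ annotation does not scale. `mmphantom` sidesteps the
problem by *simulating* the data. It procedurally generates labeled 3D
abdominal phantoms with a known respiratory displacement field, derives
CT, CBCT and T1-weighted (VIBE) MRI volumes from the same label map — so all
modalities are co-registered by construction and every organ mask is exact —
and provides the two evaluation suites and the registration benchmark needed
to put numbers on synthetic image quality and deformable-registration
settings.

It is aimed at researchers developing or tuning multimodal registration and
segmentation methods who need annotated, deformation-ground-truthed volumes
without clinical data.

## What is inside

| Module | Purpose |
|---|---|
| `mmphantom.phantom` | superellipsoid organ phantoms, respiratory displacement fields, warping, organ masks |
| `mmphantom.modality` | attenuation → HU (90–120 keV), liver-centered CBCT FOV, VIBE signal `SI = ρ sin α (1−E1)/(1−cos α·E1)·e^{−TE/T2}`, ±5 % tissue-property jitter, windowing to [−1, 1], spectrally shaped noise |
| `mmphantom.gan` | unpaired translation (CycleGAN) with the extended generator objective `L_adv + λ_cyc L_cyc + λ_int L_int + λ_gdl (L_gdl(G,x) + L_gdl(F,y))`; presets 10/10/5 (CT, CBCT) and 10/0.4/0.4 (MRI); pure-numpy networks with verified backprop |
| `mmphantom.metrics` | MAE, SSIM, FSIM, EPR/EGR vs. phantom; radial NPS + NCC, noise magnitude, HistCC vs. reference; Gaussian MAE/NM anchor √(2/π) |
| `mmphantom.registration` | B-spline registration benchmark (MMI/NC/MS × 50–150 mm grid spacing), liver-mask closing, Dice scoring, sweep aggregation |

## Worked example

```python
import numpy as np
from mmphantom import phantom as ph, modality as mo, registration as reg

# exhaled/inhaled phantom pair with exact ground-truth displacement field
motion = ph.MotionParameters(diaphragm_motion_mm=15.0, chest_expansion_mm=6.0)
exhaled, inhaled, field = ph.make_breathing_pair(ph.PhantomConfig(), motion, seed=1)

# simulate two co-registered CT volumes, windowed and normalized to [-1, 1]
ct_ex = mo.simulate_modality(exhaled, "CT", seed=1)
ct_in = mo.simulate_modality(inhaled, "CT", seed=1)

# liver masks come free with the phantom; close interior vessels into them
liver_ex = reg.close_liver_mask(ph.extract_organ_mask(exhaled, {ph.LIVER}),
                                ph.extract_organ_mask(exhaled, {ph.HEPATIC_VESSELS}))
liver_in = reg.close_liver_mask(ph.extract_organ_mask(inhaled, {ph.LIVER}),
                                ph.extract_organ_mask(inhaled, {ph.HEPATIC_VESSELS}))

# deformable registration at the best-reported setting: MMI, 50 mm grid
cfg = reg.RegistrationConfig(metric="MMI", grid_spacing_mm=50.0)
tx, _ = reg.register_bspline(ct_ex, ct_in, cfg)
warped = reg.propagate_mask(liver_in, tx, reference=ct_ex)
print(f"Dice pre  = {reg.dice(liver_in, liver_ex):.3f}")
print(f"Dice post = {reg.dice(warped, liver_ex):.3f}")
```

Output:

```
Dice pre  = 0.729
Dice post = 0.827
```

Breathing moved the liver enough to drop the inter-state overlap to 0.73;
the B-spline registration recovers a Dice of 0.83. Warping through the
*known* inverse displacement field scores ≈ 0.995, which is the ceiling any
registration of this pair can reach — exactly the kind of calibrated
comparison the synthetic ground truth exists to enable.

A command-line interface mirrors the library —
`mmphantom phantom | simulate | train | synthesize | evaluate | register` —
see `mmphantom --help`.

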