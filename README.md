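# n2ibone

Low-dose synchrotron micro-CT (SRµCT) simulation, self-supervised
**Noise2Inverse** denoising, and osteocyte-lacuna morphometry for bone
imaging — with the radiation-dose budgeting that motivates all of it.

## The problem

In-situ SRµCT mechanical testing of bone requires many scans of the same
sample, but synchrotron radiation degrades collagen: above a cumulative
dose of ~35 kGy the tissue's mechanical properties are no longer
trustworthy. Dose can be cut by acquiring fewer projections per scan, at
the price of noise and streak artifacts that make micrometre-scale features
— osteocyte lacunae (ellipsoidal cavities of ~50–2000 µm³) and the
hydroxyapatite mineral density of the matrix — hard or impossible to
segment and quantify.

Noise2Inverse (N2I) denoises such scans *without any clean reference*: the
projection set is split into K parts with statistically independent noise
(every Kth angle, K = 2 here), each part is reconstructed by filtered back
projection (FBP), and a network is trained to predict one sub-reconstruction
from the other. Because the noise is independent between splits, the
minimum-MSE predictor is the common noise-free reconstruction; at inference
the K network outputs are averaged:

    sinogram → split (every Kth angle) → FBP ×K → train net: recon_A → recon_B
             → output = mean_k net(mean of sub-recons except k)

This package implements the full experimental pipeline on synthetic data: a
seeded cortical-bone phantom with analytically known lacunae, parallel-beam
projection with Poisson counting noise, angular subsampling as the dose
model, FBP and N2I (a NumPy mixed-scale dense network trained with
Adam/MSE), Yen-threshold segmentation with 26-connected labeling, KDE-mode
summaries of lacunar volume, aspect ratio (shortest/longest principal axis)
and mineralization (linear calibration against reference materials, in
mgHA cm⁻³), paired statistics, and Beer–Lambert dose budgeting.

## Worked example

Dose budget for the in-situ bone geometry (3.28 mm² region of interest,
24 keV, 100 ms per projection, full scan of 3937 projections calibrated to
8.0 kGy), via `n2ibone dose`:

```
 fraction  projections  dose_kGy  dose_kGy_display  scans_before_damage
        1         3937  8.000000               8.0                    4
        2         1969  4.001016               4.0                    8
        3         1313  2.668021               2.7                   13
        4          985  2.001524               2.0                   17
        6          657  1.335027               1.3                   26
```

Reading: a one-third-dose scan keeps every third projection (1313 of 3937),
deposits 2.7 kGy, and allows 13 full scans before the 35 kGy damage
threshold — the regime where repeated in-situ imaging becomes practical.

Quantifying the noise-free default phantom (64×192×192 voxels at 1.6 µm,
150 lacunae) recovers its ground truth:

```python
import numpy as np
import n2ibone as nb
import n2ibone.quantify as q

ph = nb.generate_phantom(nb.default_bone_spec())
zs, ys, xs = ph.bone_box
roi = (zs, slice(ys.start + 4, ys.stop - 4), slice(xs.start + 4, xs.stop - 4))
thr = q.threshold(ph.attenuation[roi], "yen")
table = q.label_lacunae((ph.attenuation < thr) & ph.bone_mask, 1.6)
```

prints (via the obvious summaries):

```
lacunae recovered: 150 of 150
Yen threshold: 0.0577 mm^-1
mode volume (recovered): 432.9 um3
mode volume (truth):     438.7 um3
mode aspect ratio:       0.52
matrix mineralization:   1226 mgHA/cm3
```

The recovered kernel-density mode agrees with the analytic truth table to
~1%, and the matrix gray level calibrated against the water bath and the
alumina inclusion lands on the healthy-bovine reference of 1226 mgHA cm⁻³.

A full simulated dose sweep (phantom → noisy sinograms → subsample → split →
FBP → N2I → quantify) is one call:

```python
from n2ibone.pipeline import desk_config, run_dose_sweep
report = run_dose_sweep(desk_config(seed=0, fractions=(1, 3, 6)))
print(report.table)
```

At one-sixth dose the denoised image is still far cleaner than its FBP
(PSNR gain > 10 dB), but the recovered lacunar-volume and mineralization
modes drop below their full-dose values — the feature-distortion trade-off
that makes one-half to one-third dose the practical operating range.

## Command-line interface

`n2ibone` exposes subcommands mirroring the pipeline stages: `phantom`,
`simulate`, `reconstruct`, `train`, `denoise`, `baseline`, `quantify`,
`mineralize`, `compare`, `metrics`, `dose`, `run-sweep`, `run-paired`.
Volumes are 32-bit TIFF stacks, sinograms HDF5, tables CSV, reports JSON.

See `docs/methods.md` for the models, parameter choices and limitations.
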