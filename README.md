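# gliaquant

Quantification toolkit for cuprizone-model neuroinflammation studies:
microglia soma/process morphometry from DAB/hematoxylin brightfield
sections, generic stained-area and optical-density readouts, MRI
magnetization-transfer-ratio and T2 relaxometry, and the group statistics
layer (Holm–Šídák multiple comparisons, one-/two-way and random-effects
ANOVA, qPCR/ELISA/assay normalizations). It is aimed at image-analysis
and preclinical-imaging scientists who need the full measurement chain —
from raw RGB section or MRI signal to an adjusted p-value — as tested,
scriptable Python instead of a chain of proprietary platforms.

Every stage is validated against a built-in synthetic ground-truth
generator (ramified DAB-stained microglia over hematoxylin tissue; MTR
pairs and 16-echo spin-echo stacks; genotype × treatment × timepoint
study tables), so correctness is checked end to end without external
data.

## The measurements

**Color deconvolution.** Brightfield stains obey Beer–Lambert absorption,
so per-channel optical density `OD = -log10(I/I0)` is linear in stain
amount. With unit-norm stain color vectors as rows of `V` (default: the
standard H-DAB basis), per-pixel concentrations solve `OD = c·V` — brown
DAB is separated from blue hematoxylin exactly on noise-free images.

**Microglia morphometry.** From the DAB channel: tissue mask → adaptive
soma segmentation (threshold derived from the mean OD of the darkest
tissue quantile, so it tracks staining intensity) → process segmentation
by white top-hat sized for 1-px processes → thinning, with skeleton
length counted as 1 per axial and √2 per diagonal link → partition into
proximal processes (inside a circle of 4× the median soma equivalent
radius around each soma, overlaps resolved by nearest-centre influence
zones) and distal processes (the rest of the same skeleton components,
background fragments ignored). Per-cell outputs: soma area, form factor
`4πA/P²`, proximal/distal lengths, background-corrected OD. Per-ROI
readouts: microglia numbers (soma per mm²) and microglia activation
(soma + proximal area over distal process area).

**Stain quantification.** Stained-area % above an OD threshold, and
integrated optical density (ΣOD over ROI) for myelin stains, with
within-study reference-group normalization.

**MRI.** `MTR = (S0 − SMTR)/S0` per pixel with a noise-floor validity
mask; T2 by mono-exponential fit `S(TE) = S0·e^(−TE/T2)` to ROI-mean
signals over a 16-echo schedule (11–176 ms); baseline-relative signal
ratios.

**Statistics.** Holm–Šídák step-down adjustment
`adj(i) = 1 − (1 − p(i))^(m−i+1)`; one-way/two-way ANOVA with pooled-MSE
contrasts; longitudinal analysis as a random-intercept linear mixed model
(REML) with containment degrees of freedom; `2^(−ΔΔCt)` relative
expression; four-parameter-logistic ELISA standard curves with inverse
prediction; trapezoidal AUC; percent-of-reference. All group operations
are fenced by `study_id` and refuse to pool across studies.

See `docs/methods.md` for models, assumptions, parameter defaults and
limitations.

## Worked example

```python
import numpy as np
from gliaquant import (IhcSceneParams, MriSimParams, analyze_image,
                       compute_mtr, fit_t2, generate_ihc_image,
                       generate_mtr_pair, generate_multiecho_stack,
                       roi_mean_signal)

# synthetic 512x512 Iba1-like section with 25 microglia, then the full
# morphometry pipeline
params = IhcSceneParams(n_cells=25, seed=7)
rgb, truth = generate_ihc_image(params)
records, summary, masks = analyze_image(rgb)
print(f"somas detected: {summary.n_soma} (truth: {len(truth.soma_centers)})")
print(f"soma density:   {summary.soma_density_per_mm2:.1f} per mm^2")
print(f"activation:     {summary.activation_ratio:.2f}")

# MTR pair and 16-echo stack with 1% noise
mri = MriSimParams(noise_sd=10.0, seed=7)
s0, smtr, rois = generate_mtr_pair(mri)
mtr = compute_mtr(s0, smtr)
print(f"MTR in cc: {mtr.roi_mean(rois['cc']):.4f} (truth {mri.mtr_per_roi['cc']})")
stack, _, rois = generate_multiecho_stack(MriSimParams(noise_sd=10.0, seed=8))
fit = fit_t2(mri.te_list_ms, [roi_mean_signal(sl, rois['cc']) for sl in stack])
print(f"T2 in cc:  {fit.t2_ms:.1f} ms (truth 55 ms)")
```

prints

```
somas detected: 25 (truth: 25)
soma density:   479.7 per mm^2
activation:     3.33
MTR in cc: 0.3202 (truth 0.32)
T2 in cc:  55.0 ms (truth 55 ms)
```

All 25 generated cells are found (the scene is well separated by
construction), the activation ratio is the soma-plus-proximal area over
distal process area, and the MTR/T2 estimates recover the simulated
tissue values through the full measurement chain.

A command-line surface mirrors the library for shell use, e.g.

```sh
gliaquant simulate --kind ihc --seed 5 --out scene
gliaquant morphometry --image scene_rgb.png --out morph
gliaquant mri --s0 s0.txt --smtr smtr.txt --roi roi_cc.png
```

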