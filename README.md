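# sparkquant

Quantification of phase-separation kinase-activity reporter
condensates in live-cell fluorescence microscopy.

Phase-separation reporters (SPARK-type biosensors) read out kinase
activity as the formation of bright fluorescent droplets: when the
target kinase — here AMPK, the cellular energy-stress sensor — is
active, reporter molecules condense into puncta whose **count and
size** are the activity signal. A dual variant replaces the
fluorophore with the Ca²⁺ biosensor GCaMP6f, so a single green channel
carries two signals at once: diffuse cytosolic intensity tracks Ca²⁺,
while punctum formation tracks kinase activity. `sparkquant`
implements the image-quantification side of such experiments as a
tested, reproducible pipeline:

- **Counting** — local-maxima counting with topographic *prominence*
  (the minimum intensity drop to the ridge toward any brighter
  maximum) as the detection tolerance, plus the dual-threshold
  procedure that disentangles the single-channel Ca²⁺/kinase readout:
  a high intensity floor on frames where the Ca²⁺ gate is on, a low
  floor otherwise, merged into one trace.
- **Conditioning** — background-ROI subtraction, rolling-ball
  (grayscale opening by a non-flat ball) subtraction, pixel-wise
  self-multiplication for contrast, 8-bit rescaling, per-frame display
  normalization.
- **3D morphometry** — z-stack segmentation (rolling ball → squaring →
  8-bit → Triangle threshold on the stack histogram → 26-connected
  labelling) with physical-unit volume, mesh-based surface area and
  sphericity Ψ = π^⅓ (6V)^⅔ / A on anisotropic voxels, and
  expression-vs-morphology rank correlations.
- **Cell typing** — largest-condensate equivalent diameter d: type 1
  (d < 1.0 µm), type 2 (1.0 ≤ d ≤ 3.6 µm), type 3 (d > 3.6 µm), with
  population presence summaries.
- **Dynamics** — integrated intensity traces, formation latency
  (first sustained count ≥ k), washout dispersion fraction
  (100 × (peak − washout floor)/peak), per-cell max normalization for
  heatmaps.
- **Synthetic scenes** — a generator producing movies and z-stacks of
  cells whose condensates nucleate, grow, coalesce and dissolve under
  a kinase-activity trace, with exact ground truth, Poisson + Gaussian
  noise, and per-cell photon-flux conservation; every estimator is
  validated against it end-to-end.

## Worked example

Run the full pipeline on a simulated dual-reporter movie (64 × 64 px,
60 frames at 5 s; baseline → stimulation → washout with a Ca²⁺
elevation window):

```bash
spark-quant run --out demo_out --seed 1
```

prints

```json
{
  "mean_dispersion_percent": 100.0,
  "mean_latency_min": 0.6666666666666666,
  "n_cells": 1,
  "presence": {
    "fraction_with_clusters": 1.0,
    "type_distribution": [0.0, 1.0, 0.0]
  }
}
```

i.e. the one simulated cell responded 0.67 min after stimulus onset
(count ≥ 3 sustained for 2 frames), all condensates dispersed after
washout (none were persistent in this scene), and the largest
condensate (1.24 µm equivalent diameter, see `demo_out/per_cell.csv`)
makes it a type 2 cell. `demo_out/` also contains the movie
(OME-TIFF), the generator ground truth, per-frame dual-threshold
counts, normalized traces and a run manifest; rerunning with the same
seed reproduces every table byte-for-byte.

The same stages are available individually (`spark-quant simulate |
preprocess | count | segment3d | classify | trace | heatmap`) and as
library functions (`sparkquant.find_maxima_count`,
`sparkquant.segment_stack`, `sparkquant.dispersion_fraction`, …).

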