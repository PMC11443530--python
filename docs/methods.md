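# Methods

## Scope and data model

`sparkquant` quantifies condensate-forming kinase-activity reporters
in single-channel fluorescence microscopy. Images are handled as
calibrated stacks (`ImageStack`): axis order (T|Z, Y, X), 0-based
indices, lateral pixel size in µm/px, axial step in µm/slice, frame
interval in seconds. All outputs are in µm and seconds; frame windows
are half-open `[start, end)`.

## Maxima counting and prominence

Condensates are counted as local intensity maxima filtered by
**topographic prominence**: a maximum (a connected plateau with no
brighter neighbour) has prominence equal to its value minus the
highest level at which its superlevel-set component reaches a strictly
brighter pixel; global maxima take value − image minimum. Prominence
is exactly the persistence of maxima in the superlevel filtration and
is computed in one pass with a union-find over pixels sorted by
decreasing intensity (8-connectivity, lexicographic tie-breaks;
plateaus count once and report their centroid). We chose prominence —
rather than reproducing any particular GUI tool's flood-variant
"noise tolerance" — because it is precisely definable and testable
against a brute-force oracle; the test suite checks exact agreement on
thousands of random plateau-rich images.

The dual-reporter channel is disentangled by **dual thresholding**:
per frame, maxima are counted against a high intensity floor when the
Ca²⁺ gate is on and a low floor otherwise, and the gated counts are
merged into one trace. The gate defaults to the integrated cell
intensity exceeding 1.5× its pre-stimulus baseline; merging by an
explicit deterministic rule (instead of by hand) makes runs
reproducible, and both raw traces are always emitted so a human can
re-merge. In the pipeline all detection parameters are *relative* to
each cell's baseline mean intensity b₀ (low floor 2.5 b₀, prominence
1.0 b₀; the high floor scales the low one by the observed peak Ca²⁺
intensity ratio), so estimates are invariant to uniform intensity
rescaling. These defaults were calibrated on synthetic scenes; real
data may need adjustment through `DetectConfig`.

## Histogram thresholds

- **Triangle**: chord from the histogram peak (ties → lowest bin) to
  the far non-empty bin on the longer tail; threshold at the bin of
  maximal perpendicular distance, computed on raw (index, count)
  geometry. On background-dominated histograms this lands a few bins
  above the background peak — a *generous* threshold suited to faint
  objects (see Limitations).
- **Max-Entropy (Kapur)**: the split maximizing the summed Shannon
  entropies of the background and foreground histogram distributions;
  integer images use their exact integer histogram, making the
  threshold shift-equivariant.

Both are validated bin-exactly against exhaustive scans of their
objectives.

## 3D segmentation and morphometry

The z-stack chain is: per-slice rolling-ball background subtraction
(grayscale opening by a non-flat ball of radius r px; default 15 px ≈
5× an expected droplet radius), pixel-wise self-multiplication
(contrast boost; a monotone transform), global 8-bit rescale
(min/max, round half-up), Triangle threshold on the whole-stack
histogram, 26-connected labelling. Components under `min_voxels`
(default 4) are discarded as shot-noise specks; the reported
foreground is the union of retained clusters, so cluster volumes sum
exactly to the foreground voxel volume.

Volume is voxel count × voxel volume (anisotropy enters through
physical units, never resampling). Surface area comes from a
marching-cubes mesh of the binary cluster smoothed by ~10 Taubin
passes: the raw binary isosurface is faceted and overestimates a
ball's area by ~9%, which would depress sphericity to ~0.91 for an
ideal ball; Taubin's λ/ν scheme removes the faceting without the
shrinkage of plain Laplacian smoothing. Sphericity
Ψ = π^⅓ (6V)^⅔ / A uses the **mesh-enclosed** volume so numerator and
denominator describe one surface (mixing voxel-count volume with mesh
area inflates Ψ for thin shapes). A rasterized r = 10 ball scores
Ψ ≈ 0.98; a 1×1×20 rod ≈ 0.34. Clusters under 8 voxels are flagged
unreliable.

Expression-vs-morphology association uses Spearman rank correlation
(intensity scales are arbitrary, ranks are robust to them) with a
seeded permutation p-value (default 10 000 permutations, two-sided);
constant covariates are reported as undefined rather than guessed.

## Cell typing and dynamics

Typing uses the maximum equivalent diameter over detected condensates
(area-derived in 2D, volume-derived in 3D; the estimator choice is
tagged in the output). The 1.0–3.6 µm middle class is closed on both
boundaries; boundaries are configurable. Cells without condensates are
reported separately, never typed.

Formation latency is the time from stimulus onset to the first frame
with count ≥ k for m consecutive frames (defaults k = 3, m = 2 — an
explicit operationalization of an "onset call", configurable).
Dispersion fraction is 100 × (peak-window max − washout-window min) /
peak-window max; the washout *minimum* makes it robust to
re-nucleation blips; it is undefined when the peak is zero. Heatmap
normalization divides each cell's count and intensity traces by that
cell's own maxima.

## Synthetic scenes

The generator emulates the study conditions rather than any specific
dataset: elliptical cells (default one cell, semi-axes 4.5 × 3.5 µm)
on a 64 × 64 grid at 0.2 µm/px, 5 s frames, expression level 50
counts/px, PSF σ 0.2 µm, camera offset 20, Poisson gain 1, read noise
σ 2 — photon-starved but workable confocal conditions giving a
nominal per-droplet detection SNR ≈ 30 for a freshly nucleated 0.8 µm
condensate.

Kinetics under an activity trace a(t) ∈ [0, 1] and Ca²⁺ trace c(t):

- nucleation: Poisson, rate 4 min⁻¹ · a(t) per cell, uniform in the
  cell, suppressed within a depletion zone (merge distance + 0.6 µm)
  around existing condensates — local monomer depletion; it also keeps
  newborn droplets optically resolvable from their neighbours;
- growth: diameter + 0.25 µm/min · a(t); nuclei start at 0.8 µm;
- coalescence: droplets whose discs overlap merge with
  volume-conserving diameter and volume-weighted centre;
- dissolution: hazard 1 − exp(−3 min⁻¹ · (1 − a(t)) · Δt) for
  non-persistent droplets; a configurable persistent fraction never
  dissolves (the "memory" population surviving washout).

Rendering conserves reporter flux per cell before noise: condensate
integrated brightness (expression × 10-fold enrichment × volume,
through a 1 µm optical-section depth in 2D) is drawn from the diffuse
pool, so the cytosol dims as condensates grow — total cell photons
stay constant to machine precision, and in GCaMP mode all
reporter-derived intensity is multiplied by c(t). Movie condensates
are Gaussian blobs (σ² = (d/4)² + σ_PSF²), discretely normalized so
each contributes exactly its budgeted counts; z-stack condensates are
uniform-density spheres with an erfc (PSF-softened) edge — the
appropriate forward model when thresholded *volume* is the readout.
Poisson noise is applied to gain-scaled counts, then Gaussian read
noise. All randomness derives from one scene seed; identical
configuration is bit-reproducible.

What the generator does **not** model: phase-separation
thermodynamics, realistic (Airy/astigmatic) PSFs, photobleaching,
cell movement, focus drift, intracellular intensity texture. Passing
the recovery study therefore demonstrates estimator correctness under
the stated imaging model, not robustness to every real-world artifact.

## Study sizes and numerical choices

The end-to-end recovery study uses 20 seeded movies of 60 frames
(64 × 64 px, one cell each, 14% persistent condensates, Ca²⁺ step to
3× during frames 20–45, stimulation frames 10–40), chosen to give
tight aggregate statistics while keeping the whole suite fast on a
single CPU. Degenerate inputs fail loudly: constant frames for
auto-thresholds, empty ROIs and cell masks, non-binary masks for
particle analysis, missing calibration, overlapping analysis windows.
Ties break deterministically everywhere (lowest bin, lexicographic
pixel order, raster labelling). CSV floats are written at 6
significant digits so reruns are byte-identical.

## Known limitations

- The Triangle threshold on background-dominated stacks is generous:
  for a PSF-softened sphere it selects roughly the 10% isophote, so
  measured condensate volumes exceed the nominal sphere volume by
  ≈ (1 + 1.3 σ_PSF/R)³ — about 2× for d = 2 µm at σ_PSF = 0.2 µm. The
  closed-form isophote prediction matches the measured volume within a
  few percent (tested); absolute volumes should be read as
  threshold-isophote volumes, comparable across conditions at fixed
  optics.
- Rolling-ball subtraction with a non-flat ball leaves a rim artifact
  at step edges whose height is comparable to the ball radius (in
  intensity units); with bright condensates present it is negligible
  after thresholding, but condensate-free cells can segment their own
  rim. Background-ROI subtraction does not share this artifact.
- Maxima counting resolves condensates separated by more than roughly
  2σ of their blob profile; the generator's coalescence rule merges
  droplets before they become unresolvable, so counts on synthetic
  data are near-exact, which flatters the counter relative to data
  with genuinely unresolved doublets.
- No droplet tracking: counts are per-frame; identities across frames
  exist only in the generator's ground truth.
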