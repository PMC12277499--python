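# Methods

## SUV model

The body-weight SUV of a PET voxel is the decay-corrected activity
concentration divided by injected dose per gram of patient:

SUV_bw = (v·s + i) · m_g / (D · 2^(−Δt/T½)),

where v is the stored voxel value, s and i the DICOM rescale slope and
intercept (i defaults to 0 when the series carries none), m_g the patient
weight in grams, D the injected dose in Bq and Δt the interval from tracer
injection to the series (scan-start) time. With concentrations in Bq/mL
this is the conventional dimensionless g/mL SUV; a uniformly distributed
tracer in a 1 g/mL body gives SUV 1. Implementation choices:

- **Time source.** The decay interval uses the series time by default; an
  `acquisition` switch is provided because clinical headers carry both and
  sites disagree about which to use. A series time earlier than the
  injection time is treated as a midnight crossing (+24 h): uptake periods
  are on the order of an hour and never negative.
- **Half-life.** Read from the radiopharmaceutical sequence; when absent,
  the F-18 constant 6586.2 s is assumed (the package targets ¹⁸F-FDG).
- **Negative values.** Rescaled values below zero pass through unchanged;
  clipping is a display concern and would bias region means.

## Synthetic phantom

The phantom emulates a dual-grid PET/CT study: a fine CT lattice and a
coarse PET lattice covering one patient-space extent, five ellipsoidal
organs (two breasts, liver, spleen, a long thin bone-marrow compartment)
with distinct attenuation values, and optionally a 9 mm tumor nested in
the right breast. Default target SUVs (breast 0.7–0.8, liver 2.2, spleen
1.6, marrow 1.2, tumor 8) sit in the range reported for FDG-avid tissue;
acquisition metadata default to a 60 kg patient, 5.18 MBq/kg injected
dose and a 60-minute uptake.

Raw PET values are synthesized by **inverting** the SUV formula, so the
conversion path is checked against an oracle that never executes it.
A voxel belongs to an organ iff its center lies inside the ellipsoid — no
fractional occupancy — so masks are exactly reproducible, and the mask
volume converges to the analytic 4/3·π·abc as spacing shrinks (within 2 %
at 1 mm isotropic). Noise, when requested, is additive Gaussian on the raw
values, clipped at zero; PET physics (scatter, attenuation, reconstruction
correlations, partial-volume blur) is deliberately not modelled. Passing
tests therefore demonstrate correctness of the quantification arithmetic
and geometry, not robustness to reconstruction artifacts.

Two geometry presets exist: the clinical-scale grids (CT 512×512 in-plane
at 2–3 mm slices, PET 200×200 at 3 mm) for end-to-end demonstrations, and
a reduced common-extent geometry (CT 64×64×40 at 3×3×4 mm, PET 40×40×40 at
4.8×4.8×4 mm) that the test suite, examples and acceptance script use so
everything runs in minutes on one CPU.

## Regions and statistics

Organ centroids are unweighted means of member-voxel centers; for concave
organs the centroid can fall outside the mask and the 1.2 cm sphere VOI is
still placed there — no snapping — which is exactly the failure mode that
makes single-VOI SUVmean readings method-dependent. Sphere membership is
center-in-sphere, matching the mask convention. SUVmax ties break to the
lowest linear index of the (x, y, z) C-ordered lattice and the winning
location is reported in both index and patient coordinates.

## Lesion delineation, TLG, histograms

The lesion at fraction f is the set of organ voxels with SUV ≥ f·SUVmax.
The comparison is inclusive so the maximum voxel always belongs to its own
lesion, and thresholds nest: f′ > f implies lesion(f′) ⊆ lesion(f), hence
TLG(0.5) ≤ TLG(0.4) on any input. No connected-component filtering is
applied by default (an optional flag keeps only the largest 26-connected
component); a delineation that touches disconnected hot spots inside the
organ mask is reported as-is. TLG is stated in SUV·mL with voxel volumes
in mL. Delineation requires a positive organ SUVmax — a non-positive
maximum makes a fractional threshold meaningless and raises.

Cumulative SUV histograms default to a 101-point 0–100 %-of-SUVmax ladder
(an absolute-SUV ladder is available); each entry is the fraction of
region volume at or above the threshold, hence non-increasing, 1 at
threshold 0 for non-negative SUV. A uniformly hot lesion keeps its volume
fraction near 1 far up the percent ladder (convex-downward organ curve
once a hot focus dominates the region maximum), while homogeneous tissue
holds near 1 only until its noise ceiling (convex upward) — the shape
contrast the histogram is meant to expose.

## Mask transfer and rigid alignment

Masks move between grids by nearest-neighbor resampling of the label
volume itself (masks, not contour vertices, are the interchange format);
images use trilinear interpolation, with 0 as the out-of-extent fill.
Volumes and masks agree on a grid by value equality of dims, spacing,
origin and orientation (float metadata compared at 1e-6 mm).

Rigid registration maximizes Mattes mutual information (32 bins,
full-volume sampling for determinism — "multimodal" pairs rule out
intensity-difference metrics) over a centered Euler transform, with a
one-plus-one evolutionary optimizer at the common multimodal preset:
initial search radius 0.009, convergence epsilon 1.5e-4, at most 1000
iterations, under a 3-level shrink/smooth pyramid. Those scalars are this
optimizer family's semantics in the originating toolbox; an exact match to
any commercial implementation is not claimed. The optimizer's sampler is
seeded, so a fixed input/config pair is bit-reproducible. When the
iteration budget is exhausted the best transform so far is returned with
`converged=False` — on desk phantoms this still recovers 6–10 mm synthetic
shifts to within a few tenths of a millimetre, well under the half-PET-
voxel bound the property suite enforces. Dice is 2|A∩B|/(|A|+|B|), 1 by
convention when both masks are empty.

## Method-agreement summaries

Per organ: mean absolute per-patient difference between two methods, with
the **population** (divisor n) standard deviation — pinned by the packaged
tables, whose published "±" values a sample sd does not reproduce. Across
organs: the unweighted mean of the per-organ means with its range,
computed from the 2-decimal rounded per-organ values, mirroring how such
summary rows are derived from a printed table; reports round at 2 decimals
(the single-VOI aggregate is quoted at 3, 0.138).

## Segmentation backend

Two interchangeable backends:

- **Intensity-atlas baseline** — nearest-mean-intensity voxel classifier;
  transparent, instant, and structurally blind (it cannot split the
  equal-intensity left/right breasts), which is exactly its value as a
  floor in tests.
- **Swin-UNETR-topology network in numpy** — 2×2×2 patch embedding to a
  48-feature token (12 at desk scale), four encoder stages of two
  shifted-window attention blocks (W-MSA, then SW-MSA via a cyclic
  half-window shift; window 7³ capped by the token-map size and rounded to
  a divisor of it; no boundary masking across the cyclic seam) each
  followed by patch merging that halves resolution and doubles channels; a
  decoder of 3³ convolution residual blocks with instance normalization,
  nearest-neighbor upsampling and stage-wise skip concatenation, plus a
  full-resolution stem block on the raw input; a 1×1×1 softmax head over 6
  classes (background, right/left breast, liver, spleen, bone marrow — the
  breasts are separate classes because organ-level reporting is per side).

All feature weights are drawn once from a seeded generator and frozen;
**training optimizes the readout head** (the final 1×1×1 convolution) with
Adam on an equally weighted soft-dice + cross-entropy loss, using exact
closed-form gradients through the softmax. The head's input stack carries
the decoder features plus the raw intensity and three normalized
coordinate channels, so a linear readout can separate spatially symmetric
classes. Because features are frozen they are computed once per sample and
cached; at desk scale the whole dataset fits in one batch and 300
iterations take seconds. This is a deliberately CPU-honest training
scheme in the spirit of random-feature (ELM-style) readouts;
backpropagation through the attention stack is out of scope. Preprocessing
clips CT to [−175, 250] HU, maps to [0, 1] and resamples to
1.5×1.5×2.0 mm (trilinear); augmentation applies per-axis flips and 90°
rotations (probability 0.1 each), and intensity shifts (probability 0.5,
offset 0.1) to the volume only, with one seeded generator driving all
coins. Default learning rate 0.2 and the ≤300-iteration desk budget are
the package's choices for the readout scheme; the 20,000-iteration default
records the full-scale recipe. On three desk phantoms the readout training
reaches mean foreground dice ≥ 0.95 — an overfit check of the training
loop and loss gradients, not a claim about clinical segmentation accuracy,
which would require end-to-end training on real cohorts at GPU scale.

## Known limitations

- Phantom realism: geometric primitives, no PET physics; results on real
  data depend additionally on reconstruction and partial-volume effects.
- The registration optimizer's scalar settings approximate the multimodal
  preset of the originating toolbox; exact parity with commercial
  alignment modules is not claimed.
- The segmentation network's attention stack is inference-only; only the
  readout is trained.
- Multi-frame enhanced DICOM and RTSTRUCT contours are unsupported; masks
  are exchanged as label volumes.
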