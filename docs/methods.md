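# Methods

This note documents the models, parameter choices and known limitations of
`rarescan`. It is the companion to the API docstrings: those say *what* each
function does, this says *why* it is built that way.

## Problem setting

A slide-based CTC workflow deposits the entire nucleated-cell fraction of a
blood sample (~10⁶–10⁷ cells per slide) on glass, stains four fluorescence
channels — nuclear dye, cytokeratin (CK), CD45 and an auxiliary epithelial
marker — and scans the slide as a grid of overlapping camera fields of view.
The computational task is to find the handful of CK-positive, CD45-negative,
nucleated cells among the leukocyte carpet, reject artifacts and contaminants,
merge duplicate views from tile overlaps, and emit retrieval coordinates, plus
the statistics used to validate recovery in spike-in experiments.

## Slide simulator

### What it emulates

The simulator (`simslide`) generates the study conditions of a spike-in
validation: a dense uniform carpet of WBCs with a small number of rare cells —
model tumor cells (mCTCs), squamous venipuncture contaminants and debris — at
configured counts, rendered into an overlapping tile grid with per-tile noise.
Slide-scale designs in this setting spike on the order of 100 cells (range
~70–210) per sample, or 1–6 cells for limit-of-detection experiments; the
desk-scale default (4×4 tiles of 512 px at 0.65 µm/px, ~2000 WBCs, a few rare
cells) keeps one slide at a couple of seconds to generate and scan while
preserving realistic per-tile crowding (~1400 WBC/mm²).

### Rendering model

Cells are smooth radial intensity profiles added onto a linear background:

* **Profile**: truncated Gaussian disk, σ = radius/2, cut at 2.5σ. Chosen
  because it is differentiable, cheap, and has the closed-form integral
  2πσ²A(1−e^{−2.5²/2}) used as a rendering oracle in tests. The mCTC
  auxiliary marker is an annular (membrane) profile peaking at 0.8× the
  cytoplasm radius; debris is an anisotropic Gaussian fragment with random
  axis ratio and orientation stored in the truth record so re-rendering is
  deterministic.
* **Phenotypes**: mCTC = nuclear disk + CK disk + marker rim; WBC = nuclear
  disk + CD45 disk; squamous = large dim CK disk (cytoplasm radius 3× the
  mCTC default → N:C area ratio < 0.1) with a normal nucleus; debris = small
  CK fragment, no nucleus. With noise off, a WBC contributes exactly zero CK
  and an mCTC exactly zero CD45 (no channel-bleed model).
* **Intensity scale**: unsigned 16-bit counts. Defaults — background 500,
  noise SD 50, gradient 50 counts/mm along x, cell amplitudes 1.5–12 × 10³
  above background — give signal-to-background ratios typical of stained
  buffy-coat slides and place the default k = 6 threshold ~300 counts above
  background.
* **Noise**: additive Gaussian clipped at zero, seeded per tile from
  (seed, row, col), so a cell in an overlap strip is rendered consistently in
  both tiles but with independent exposure noise, as on a real scanner.
  Poisson shot noise is deliberately omitted; it adds nothing the algorithms
  under test are sensitive to.
* **Placement**: WBCs uniform with overlaps allowed (crowding is part of the
  model). Rare cells are rejection-resampled until they clear every
  previously placed cell by `min_separation_um` (default 30 µm), reflecting
  the "well-separated spiked cell" condition of recovery experiments; members
  of a declared mCTC cluster are exempt and pack around a shared center.
  Placement fails loudly (`ConfigurationError`) if the slide is too crowded
  for the requested clearance.
* **Chromatic aberration**: optional per-channel (dx, dy) pixel shifts,
  applied by bilinear interpolation before noise. A bead-field calibration
  tile (bright in every channel) carries the same shifts for registration.

### What the simulator does not model

No point-spread function or defocus, no z-stacks, no red cells/platelets, no
staining variability, no autofluorescence texture, no channel bleed-through.
Passing tests on synthetic slides therefore demonstrate the correctness of
the *algorithms* (thresholding adapts, geometry is consistent, the decision
table discriminates the modelled phenotypes) — not the biological sensitivity
or specificity of the platform on real slides, where marker expression varies
continuously and artifacts are richer.

## Detection

* **Adaptive threshold**: T = median + k·1.4826·MAD per tile and channel.
  Median/MAD over the full tile is robust to the sparse bright objects that
  would inflate a mean/SD estimate, and per-tile computation absorbs
  illumination drift across the slide. Default k = 6: with Gaussian noise
  this sits ~6σ above background, making a false supra-threshold *component*
  (≥ 48 connected pixels at the area gate) vanishingly unlikely while staying
  a factor ≥ 5 below the dimmest modelled cell amplitude. A constant plane
  yields MAD = 0 and is flagged `degenerate`. The nuclear channel is excluded
  from detection; its threshold only feeds nuclear-overlap and N:C measures.
* **Segmentation**: strict `plane > T`, 8-connectivity, hole filling, area
  gate 20–2000 µm². The lower bound removes debris specks and noise; the
  upper bound generously admits clusters while discarding confluent sheets.
  No watershed splitting in v1: touching cells form one object, and the
  number of distinct nuclear components inside each object is reported as an
  auxiliary column (`nuclear_components`) rather than guessing a per-cell
  counting convention for clusters.
* **Centroids** are weighted by background-subtracted intensity (sub-pixel);
  ordering is row-major by bounding-box origin so runs are reproducible.
* **CD45 correlation**: Pearson r of CK vs CD45 over the mask dilated by
  2 px, so membrane CD45 ringing a CK object is captured. If either channel
  is constant on the footprint, r ≔ 0 (no evidence of colocalization).
* **Nuclear overlap vs N:C ratio** — two deliberately different questions:
  `nuclear_overlap_fraction` asks *does the object carry a nucleus*: the
  fraction of the intersecting nuclear components' area lying inside the
  mask (1.0 for a fully contained nucleus, regardless of how much cytoplasm
  surrounds it). `nc_ratio` asks *how much of the object is nucleus*:
  nuclear supra-threshold pixels inside the mask over mask area. Keeping
  them distinct is what lets a huge squamous cell count as "nucleated"
  (a review candidate) while still failing the N:C morphology gate — the
  behaviour of a human reviewer.
* **Registration**: FFT cross-correlation peak with per-axis parabolic
  sub-pixel refinement, estimated on a bead calibration tile against the
  nuclear channel as reference; the negated shift is applied (bilinear) to
  co-register before detection. Typical recovery error on the simulator is
  < 0.05 px, and the independent phase-correlation routine in scikit-image
  agrees within 0.2 px in tests.

## Classification

The decision table (see README) is evaluated in fixed order with ties at
thresholds resolving positive (≥). Defaults and rationale:

| parameter | default | rationale |
|---|---|---|
| `k` (threshold multiplier) | 6 | ~6σ above background; see above |
| `corr_reject_r` | 0.5 | no field-standard value exists for "highly correlative"; 0.5 rejects clear colocalization while tolerating incidental overlap. Config-exposed for sensitivity analysis |
| `min_nuclear_overlap` | 0.2 | a fifth of a nucleus inside the object suffices to call it nucleated; robust to edge truncation |
| `max_area_um2_cell` | 700 µm² | ≈ 30 µm equivalent diameter, the upper end of single epithelial tumor cells; squamous plate cells (40–60 µm) exceed it |
| `min_nc_ratio` | 0.15 | tumor cells have high N:C (~0.4 in the simulator); squamous contaminants < 0.1 |
| dedup radius | 15 µm | under half the 50 µm tile overlap and larger than any plausible centroid jitter for 10–20 µm cells |

`candidate_flag` (CK⁺/nucleated/CD45⁻, before the morphology gate) is kept
separate from the final label so the "contaminants identified, then demoted
on review" scenario is countable: 3 mCTC + 2 squamous yields 5 candidates and
3 Cells. The auxiliary marker is interpretive only — it can promote an
anucleate CK⁺ object to Indeterminate but never vetoes a Cell — because
epithelial marker expression (EpCAM in particular) is too variable to use as
a requirement.

## Geometry and deduplication

Tile (r, c) originates at (c·stride, r·stride) with
stride = tile_px·pitch − overlap; slide coordinates are µm from the top-left
of tile (0,0). Duplicates are merged by single-linkage grouping within the
dedup radius; the representative is the member farthest from its own tile's
border (the least truncated view), with deterministic tie-breaks. Single
linkage is exact and trivially idempotent at desk scale (representatives of
distinct groups are > radius apart by construction); pathological chains
longer than the radius merge into one group, which is accepted and
documented. The load-bearing correctness property is tiling invariance: the
same slide rendered as 1×1 and 2×2 tile grids yields identical unique Cell
counts. Picklists order Cells serpentine by 200 µm y-bands, alternating x
direction, purely as a function of coordinates (stable under input
permutation).

## Recovery statistics

Percent recovery = 100·identified/spiked at full precision; tally displays
floor to whole percent (22/27 → 81%). Line summaries use the sample SD
(n−1); a single-replicate line reports SD 0 with a `degenerate` flag (the
convention for published SDs is not knowable from totals, so per-line SDs are
reported, never asserted). The "grand mean" is reported both as the
unweighted mean of line means and as the pooled mean over experiments —
both are defensible readings of an "average recovery" and they differ when
replicate counts are unbalanced. The regression of identified on spiked
counts is ordinary least squares (`scipy.stats.linregress`), requiring ≥ 2
distinct spike counts. The spike-in simulator draws the spiked count
uniform-integer in [n_min, n_max] and identifies each cell independently
with probability p (all loss mechanisms folded into one rate); at the
validation design (20 experiments, 70–210 cells, p = 0.905) the median R²
across seeds is ≈ 0.99.

## Numerical and degenerate-input conventions

* Thresholding is shift-equivariant exactly; segmentation uses strict `>`.
* Empty slides, empty detection tables and empty picklists are valid outputs,
  not errors; percent recovery and the single-digit summary raise on an
  empty denominator instead of returning NaN.
* All randomness flows from explicit integer seeds (`numpy` `default_rng` /
  `SeedSequence`); identical config + seed reproduces pixel-identical slides
  and byte-identical CSV outputs. The scan is a single-process per-tile loop —
  determinism before parallelism.
* Chromatic-shift compensation uses bilinear interpolation: integer shifts
  round-trip exactly; fractional shifts lose high-frequency content at the
  half-pixel scale, bounded in tests by the registration residual (≤ 0.5 px).

## Problem sizes

Default validation scenarios run a 4×4-tile slide (~1.2 × 1.2 mm, ~2000
cells) in a few seconds on one core; the regression study uses 31 seeded
repeats of 20 experiments. These sizes were chosen so the full test suite
and the reproduction script complete in minutes while every scenario retains
the crowding, overlap and contaminant structure that makes the problem
non-trivial; all scale knobs (grid, counts, repeats) are plain parameters.

## Known limitations

* No watershed: touching cells and clusters count as one object.
* The Indeterminate category is an automated stand-in for human-review
  ambiguity; its boundaries are config values, not learned behaviour.
* The correlation-rejection cutoff (0.5) and morphology-gate defaults are
  this package's operational choices, exposed in `RuleConfig`; they are not
  inferences of any instrument vendor's internal values.
* Simulator realism limits are listed above; in particular, perfect marker
  specificity in the simulator means end-to-end recall/precision of 1.0 on
  synthetic slides is an algorithmic sanity check, not a clinical claim.
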