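# Methods

## Overview

`netquant` quantifies NETosis — the release of neutrophil extracellular
traps (NETs) — from two-channel high-content fluorescence microscopy. The
biological readouts are:

1. **Nuclear decondensation.** Early NETosis unpacks chromatin: the nucleus
   enlarges and its per-pixel stain intensity falls. A nucleus is called a
   NET-forming event when it is *simultaneously* larger than an area
   threshold and dimmer than an intensity threshold, both calibrated on
   control wells.
2. **Extracellular DNA release.** Later NETosis extrudes DNA into the
   extracellular space as web-like filaments, visible in a membrane-
   impermeant DNA stain. These are detected after excluding intact cells.
3. **Modulator screening.** Per-well %NET-forming values feed a plate-
   screening layer that scores compounds against untreated controls and
   classifies them as inducers, inhibitors, enhancers or biphasic
   modulators, with apoptosis and literature-based exclusion filters.

Because no instrument images ship with the package, a synthetic field
generator with exact per-object ground truth defines the reference
conditions; every algorithm is validated by recovering that truth
end-to-end (rendered images in, statistics out).

## Nucleus segmentation

Pipeline per field: optional median-background subtraction → Gaussian
smoothing (σ = 2 px) → global Otsu threshold → hole filling → watershed
splitting of oversized objects → size/border exclusions. Features (area in
pixels, mean/integrated intensity) are measured on the raw raster so
intensity units remain comparable across wells and to control calibrations.

Numerical choices:

* **Per-field thresholding.** Otsu is recomputed per field, adapting to
  background drift. A threshold that keeps nothing or close to half of the
  frame is treated as degenerate (e.g. a blank field, where Otsu would split
  the noise) and the field reports zero nuclei with a warning.
* **Split gating.** Only objects above `split_min_area` (900 px, 1.5× the
  nominal condensed-nucleus area) are split candidates, and a candidate
  split is accepted only when the watershed boundary's distance-transform
  saddle is < 0.75× the shallowest seed peak. Two touching nuclei meet at a
  thin neck and pass; a single elongated decondensed nucleus has a flat
  ridge whose twin "peaks" are artefacts, and splitting it would create two
  fake NETotic-sized objects. Without the saddle test the PMA-control
  %NETotic noise roughly doubles.
* **Border and size exclusions.** Objects touching the frame edge (partially
  imaged) and objects outside [100, 5000] px are dropped before any
  statistic is computed.

**Apoptotic-body flagging.** Apoptotic neutrophil nuclei present dark
internal spots and peripheral bright fragments while mimicking the
enlarged-dim NETotic signature; they must be excluded from NETotic
statistics. A nucleus is flagged when its eroded interior contains ≥ 2
connected regions, each ≥ 5 px, of pixels below
`mean − max(2·SD, 0.15·mean)`. Two departures from a plain mean − 2·SD rule
matter: statistics are computed over the *eroded interior* (the dim
partial-volume skirt at the segmentation boundary otherwise inflates the SD
until real holes fall inside the band), and the 15 % relative depth floor
keeps noise dips on smooth dim nuclei from reading as holes. On the
generator's apoptotic phenotype this recovers ≈ 95 % of apoptotic nuclei
with ≤ 3 % false flags.

## Decondensation thresholds and classification

Thresholds follow the two-sigma control-band convention of plate screening:

* `area_threshold = mean(control areas) + k·SD`, k = 2
* `intensity_threshold = mean(control intensities) − k·SD`, k = 2

calibrated per plate on that plate's untreated control wells (unstimulated
controls for induction readouts; a PMA-calibrated variant applies the same
formulas to PMA-stimulated controls). Degenerate zero-SD control
populations fall back to mean ± 1 unit with a warning; calibration refuses
fewer than 50 control nuclei. The NETotic call is a strict AND —
`area > area_threshold and intensity < intensity_threshold` — deliberately
without an OR mode: enlargement alone (touching nuclei, segmentation
merges) or dimming alone (focus drift) each have innocent explanations;
only the joint signature is decondensation. Mean (not integrated) intensity
is the feature, because decondensation dilutes signal per pixel while
roughly conserving total chromatin signal.

Aggregation: per-well %NETotic over retained (non-apoptotic, non-border)
nuclei; per-(condition, timepoint) mean ± SEM across replicate wells (not
across nuclei), matching replicate-level error structure.

## NET detection

The DNA channel images nuclei as well as NETs, so intact cells are excluded
first: the exclusion mask is the union of segmented nuclei dilated by 10 px,
and no NET pixel may intersect it (asserted as an invariant). The DNA
channel is thresholded at `background + 3·SD`, with background level/SD
estimated per field as the median and scaled MAD of non-foreground pixels —
robust to filament-rich fields and unbiased for Gaussian noise, where a
"dimmest-half" estimate understates the SD by ~2.5×. Connected components
≥ 50 px survive; a filament filter keeps elongated regions (eccentricity
≥ 0.8 or skeleton_length²/area ≥ 4) and rescues large diffuse regions
(≥ 4× the minimum area) as NET clouds, which late NETs form. Per-region
features: area, skeleton length (the "size" readout, distinguishing length
from pixel count), eccentricity, and background-subtracted integrated
intensity. The per-well NET signal is the sum of integrated intensities over
all retained regions of all fields — additive by construction and offset-free
because of the background subtraction. A perinuclear-ring quantifier (mean
DNA intensity in a width-w annulus around each nucleus, other nuclei
excluded) is included as a simple baseline comparator.

## Screening layer

Each compound well's %NETotic value is scored as a robust z against the
matching untreated control population on the same readout:

    z = (pct − median(controls)) / (1.4826 · MAD(controls))

Unstimulated compound wells score against unstimulated-untreated controls
(induction); PMA compound wells against PMA-untreated controls
(inhibition/enhancement). Median/MAD rather than mean/SD because a screen's
own strong hits would inflate a naive SD. When the scaled MAD collapses —
unstimulated controls are almost all exactly 0 % NETotic — a floor of 1
percentage point keeps z finite and conservative.

Hit calling: induction if z ≥ 3 at ≥ 2 doses (unstimulated); inhibition /
enhancement if z ≤ −3 / z ≥ +3 at ≥ 2 doses (PMA). The two-dose
replication requirement is the package's multiple-testing control: a
56-compound × 5-dose × 2-condition screen has ~560 compound wells, and a
single-well 3σ rule alone admits of order one spurious call per run;
requiring the effect at two doses suppresses that to a negligible rate while
leaving genuine dose-responsive modulators (significant at 3–5 doses)
untouched. A modulator is *biphasic* when one condition carries significant
calls of opposite sign in the lower vs upper half of the ordered dose range
(five doses → two low, two high, middle unassigned). Filters: compounds
whose mean apoptotic well fraction exceeds 0.25 at any significant dose are
excluded (`apoptotic_phenotype`); compounds on the configured exclusion list
— modelling literature-curated removal of neutropenia/neutrophil-death
associated agents, which cannot be automated — are excluded
(`exclusion_list`). Selected = hits surviving both filters.

`normalize_doseresponse` divides any scalar plate readout by the same
plate's media-only control, removing donor-baseline differences before
cross-donor summaries.

## Synthetic data generator

What it emulates, per condition: condensed multi-lobed nuclei (2–4
overlapping ellipse lobes; area ~N(600, 50²) px; intensity ~N(1200, 80²)
units on a 12-bit-like scale with background 100 ± 10), decondensed nuclei
(single larger blob, area ~N(1500, 150²) px), apoptotic nuclei (condensed-
sized with 3–4 conical dark spots and peripheral bright fragments),
extracellular filaments (momentum-random-walk strands, width 2–5 px, length
100–400 px, 0–2 branches, DNA channel only), and Gaussian background noise.
Masks are rendered as filled lobe unions with a near-flat plateau profile
and a shallow 2.5 px edge ramp, then lightly blurred (σ = 0.8): the plateau
makes the measured mean intensity track the sampled amplitude and a
two-pass radius rescaling calibrates the rendered pixel count to the
sampled area, so area/intensity statistics are directly steerable.
Placement is rejection sampling with a minimum centre distance
(r₁ + r₂ + 6 px), large objects first; an unplaceable request raises a
capacity error stating what fitted.

Intensity model: every nucleus in a stimulated condition is dimmed by the
condition's `intensity_drop` (200 units through 3 h, 500 units at 4 h) —
this is what a *population* mean-intensity gap of 200/500 units between
unstimulated and stimulated wells requires when only a few percent of nuclei
are decondensed early on. Decondensed nuclei are additionally dimmed to at
least `decondensed_intensity_drop` (500 units) below the condensed mean,
because chromatin dilution is intrinsic to decondensation whether or not the
well was stimulated; this is what makes compound-induced NETosis in
unstimulated wells classifiable. The decondensed area default (1500 px,
2.5× condensed) is set so the pooled 4-h mean nuclear area over the 60/40
decondensed/condensed mix sits near 1100–1150 px, comfortably above the
1000 px landmark rather than straddling it.

Time-course presets (`unstim_t`, `pma_t`, t ∈ {0, 60, 90, 120, 180, 240}
min): unstimulated wells have decondensed fraction 0 and no filaments at
every timepoint; PMA wells ramp the decondensed fraction 0.02 → 0.10 through
180 min and jump to 0.60 at 240 min, with filament load rising to a 3-h
peak (1 → 8 strands/field) and falling after.

The 56-compound screen fixture encodes the screening funnel as ground
truth: 8 named modulators (2 inducers, 3 inhibitors, 2 biphasic
inhibit-low/induce-high, 1 biphasic induce-low/inhibit-high), 3 apoptotic
confounders (induce + enhance + 45 % apoptotic bodies at effective doses),
12/7/7 additional inducers/inhibitors/enhancers carried on a 26-name
exclusion list, and 19 inert compounds — yielding 17 induction, 13
inhibition and 13 enhancement hits with exactly the 8 named compounds
surviving all filters. Signed per-dose magnitudes map linearly onto the
decondensed fraction (clamped to [0, 1]) around a PMA baseline fraction of
0.25 at 3 h; the baseline is a fixture choice giving the inhibition assay
dynamic range (a published 3-h NETotic fraction does not exist to pin it).
Two 384-well plates are used (one per stimulation condition); the PMA plate
carries a few unstimulated wells so thresholds can be calibrated per plate.

What the generator does **not** emulate: optics (PSF, vignetting, uneven
illumination), saturation, cell clumping/overlap, debris, donor-to-donor
variability, stain bleed-through, or the vital/suicidal NETosis
distinction. Passing tests therefore demonstrate that the algorithms
recover truth under idealised imaging with realistic statistical structure,
not that they are robust to instrument artefacts — parameters
(`SegmentationParams`, `NetDetectionParams`, `ScreenConfig`) are exposed
precisely because real data would need retuning.

## Problem sizes and reproducibility

All randomness flows from one integer seed through
`numpy.random.SeedSequence`; identical (config, seed) reproduce bit-identical
rasters and tables. The reproduction script
(`scripts/acceptance.py`) runs the time-course panel at 4 wells per
timepoint (8 at 240 min) × 4 fields × 80 cells on 640×640 px fields, and
the full 56-compound screen (596 wells, one field each). The test suite
exercises the same computations on reduced panels (2 wells/point × 2
fields × 60 cells; a 6-compound mini screen for the 20-seed hit-recovery
property), sizes chosen to keep each statistic's sampling error well inside
its tolerance band.

## Known limitations

* Per-field Otsu thresholding makes the measured nuclear area depend weakly
  on well composition (dimmer, decondensation-rich wells get a slightly
  lower threshold and fatter masks, inflating %NETotic by a few points in
  stimulated wells). All screen statistics are scored relative to controls
  of identical composition, so hit calls are unaffected; absolute per-well
  percentages carry this bias.
* The apoptosis flag is tuned to the generator's dark-spot phenotype; real
  apoptotic morphologies are more varied, and production screening workflows
  typically resolve them by manual review.
* Filament "size" is reported as skeleton length; where strands overlap the
  skeleton under-counts total strand length.
* `pma_calibrated` thresholds on a strongly mixed population are wide; they
  are provided for completeness, but screening operates on
  unstimulated-calibrated percentages scored against each condition's own
  controls.

## Addendum: feature measurement and class allocation

Two implementation details matter for reproducibility. First, per-nucleus
features (area, mean intensity) are measured inside each object's
half-amplitude contour — background + 0.5 × (object plateau − background),
plateau estimated as the 75th intensity percentile — rather than inside the
global-threshold footprint. The global threshold decides *which* objects
exist, but its value drifts with field composition (a decondensation-rich
field is dimmer, Otsu drops, and every mask fattens); the half-amplitude
boundary is invariant to that drift and to intensity rescaling, which keeps
the area criterion stable across wells of different composition. Second,
the generator allocates cell classes per field by exact stratification
(round(fraction × n) decondensed/apoptotic cells) instead of a binomial
draw: the encoded condition is then the field's truth, and well-to-well
spread reflects the measurement pipeline — the thing under test — rather
than sampling noise in the truth itself.
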