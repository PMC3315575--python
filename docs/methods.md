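# Methods

This note records the models, defaults and numerical choices behind
`mitoscreen`, and what the synthetic-data-driven tests do and do not
establish about real microscopy data.

## The measurement model

The screen's object of interest is the per-cell pair (cytoplasm area $A$,
integrated mitochondrial-stain intensity $M$) in a confluent monolayer, and
its population summary per well: the medians of $A$, $M$ and $M/A$ over the
measured cells of one image (one site per well). The normalized readout
$M/A$ is the size-corrected mitochondrial-content proxy; the screen's logic
is that compounds moving $M$ and $A$ proportionally leave $M/A$ unchanged,
while size-dissociated compounds move it.

## Synthetic scenes

**Geometry.** Cell centers are dart-thrown with pairwise separation at
least the mean of the two cells' radii; radii are normal with mean 12 px
and CV 0.25 (clipped at 0.35 of the mean). Pixels join the center
minimizing distance/radius — a multiplicatively weighted Voronoi
tessellation that tiles the field with touching, convex-ish cells, the
morphology the seeded-propagation segmenter is designed for. With full
survival the monolayer is confluent (no background); under a toxic effect
survivors keep a bounded footprint (1.3 × radius) and gaps remain. The
nucleus is a disk of 0.4 × the cell radius at the cell center, clipped to
its cell. Packing that cannot place the requested count within bounded
retries fails loudly with the achieved count.

**Content law.** Each cell's expected integrated content is
$a\,A_0^{\gamma}$ with $a = 40$ AU/px^γ and $\gamma = 1$ by default, where
$A_0$ is the baseline (pre-effect) area; per-cell lognormal scatter with
CV 0.15 models biological variation around the law. Planted effects act as
multipliers on this law: actual area $= m_A A_0$, content
$= a A_0^{\gamma} m_C$. A proportional effect uses
$m_A = m_C^{1/\gamma}$, which leaves the per-cell content/area relation
exactly unchanged; mito-only effects set $m_A = 1$. Because a confluent
field of fixed size is tiled by its cells, scaling cell area by $m_A$
necessarily divides the expected per-image cell count by $m_A$
(default target: 130 cells per 256×256 field; the 40-cell toxicity cutoff
is ~30% of that). Toxicity binomially thins the cell count by the survival
fraction.

**Rendering.** Channel rasters (nuclei at 3000 AU over 100 AU background;
boundary stain with a bright cortical ridge at 1600 AU over 400 AU
cytoplasm; mitochondrial content distributed over the cytoplasm as a
mixture of Gaussian clumps, σ = 2.5 px, one clump per ~80 px², over a 15%
uniform floor) are blurred (σ = 1 px), multiplied by a per-(plate, channel)
smooth illumination field with max/min exactly 1 + amplitude (default 0.3),
scaled by a per-(well, channel) lognormal staining gain (CV 0.04), and
degraded by Poisson noise (variance 2 × intensity) plus Gaussian read noise
(SD 4 AU), clipped to the 16-bit range. A 5% bleed of each cell's content
into its nucleus footprint gives the downstream nucleus masking a
measurable benefit. Per-well seeds derive from
blake2s(master_seed, plate, well), so generation is order-independent and
byte-reproducible.

**Tabular mode.** Screen-wide statistics need thousands of wells; rendering
and segmenting them all is unnecessary to test the statistics layer.
`simulate_well_records` samples per-cell records directly from the same
model: gamma-distributed areas (CV 0.50, the empirical dispersion of the
rendered tessellation), the content law with the same effect multipliers,
scatter and staining gain. All sampled cells count as measured (no border
truncation), so a control well carries ~130 records. The rendered and
tabular paths share effect semantics and seeds; the image-level properties
(segmentation recovery, mask conservation, illumination correction) are
always exercised on rendered scenes.

**What the generator does not emulate:** optical PSF structure, z-extent,
photobleaching, spatial plate effects (edge wells), staining artifacts,
debris, mitotic/apoptotic morphologies, or realistic mitochondrial network
texture. Passing tests demonstrate the pipeline's internal correctness and
statistical calibration under this model, not segmentation accuracy on real
micrographs.

## Image analysis

- **Illumination**: per (plate, channel), the mean image is Gaussian-blurred
  with σ = width/10 (only slowly varying shading survives), floored at a
  small epsilon, rescaled to unit mean; correction divides by it.
- **Three-class Otsu**: exhaustive vectorized search over all boundary-bin
  pairs (128 bins by default) maximizing between-class variance; each class
  must end on an occupied bin, which makes the argmax unique up to genuine
  variance ties (resolved to the lexicographically smallest pair). The
  middle class defaults to foreground — the background cutoff is
  $t_{low}$ — preserving dim mitochondrial signal; pixels below the cutoff
  contribute zero (masking, not subtraction; subtraction is available).
- **Nuclei**: two-class Otsu foreground; watershed on the distance
  transform smoothed at σ = 2 px with h-maxima suppression (h = 1 px)
  against noise-driven over-segmentation; any connected component whose
  maximum was suppressed entirely gets its distance-argmax back as a marker
  so no object vanishes; size filter 8–4000 px².
- **Propagation**: multi-source Dijkstra over the 8-connected pixel graph
  with step cost $\sqrt{\lambda s^2 + \Delta I^2}$ ($s = 1$ or $\sqrt 2$),
  λ = 0.05 by default; cost ties resolve to the smaller seed label via
  (cost, label) priority ordering; seed pixels always keep their labels.
  Cells are propagated over the whole image by default (confluent
  monolayer); an optional boundary-stain Otsu foreground restriction exists
  for sparse fields.
- **Measurement**: cytoplasm = cell minus nucleus; a nucleus overlapping
  two cell labels is a hard error. Border-touching cells are excluded by
  default (truncated cytoplasm biases area and intensity). The partition
  contracts (nuclei ⊆ cells, cytoplasm ∩ nuclei = ∅, per-label
  cytoplasm + nucleus = cell) are asserted on every pipeline run.

Coordinates are 0-based, areas in px², intensities in arbitrary units; no
physical calibration is used anywhere.

## Screen statistics

Control wells are pooled per screening day (the layout generator places
full 384-well DMSO control plates per day, plus 16 in-plate DMSO wells on
each treatment plate). The null distribution per (day, metric) uses the
robust estimator (median, 1.4826 × MAD) by default; moment (mean, SD) is
available. Replicate z's combine by Stouffer's rule $\sum z_i/\sqrt n$,
which has unit variance under the null and reduces to $z$ for a single
replicate. Wells under 40 measured cells are dropped before scoring
(strict: 39 fails, 40 passes); a compound passes toxicity if at least one
replicate survives, and composite z's use only surviving replicates. Hits
require composite z strictly above 1.98 (two-sided normal tail 0.0477).
Fold changes divide each well median by the mean of its day's control
medians, then average over replicates.

Effect classes operationalize the proportional/dissociated distinction:
`dissociated_up` iff $z_{norm} > 1.98$ (resp. `_down` below −1.98);
`proportional` iff $|z_{norm}| \le 1$ while both $z_{raw} > 1.98$ and
$z_{area} > 1.98$; otherwise `none`. Note an intrinsic ceiling: for a truly
proportional compound $z_{norm}$ is standard normal under correct
calibration, so at most ~68% of such compounds can fall in the ±1 null
band — the classifier's `proportional` recall is bounded accordingly, which
is a property of any calibrated z, not of this implementation.

Control-count arithmetic motivated the control-plate layout: a robust scale
from only 16 control wells has ~28% sampling error, inflating composite-z
variance to ~1.5 and shifting its mean by ±0.3 — uninterpretable
calibration. With ~784 control wells/day the composite z over an all-null
duplicate screen is calibrated to a few percent.

## Problem sizes and determinism

Statistical checks pool three independently seeded 2304-well screens
(368 compounds in duplicate plus control plates); image-level checks use
three rendered 256×256 scenes (~130 cells each) plus six flat-field
images, sizes at which the whole suite and the acceptance script each run
in well under a minute per block. Every stochastic step draws from
numpy Generators seeded via blake2s hashes of a single master seed; rerunning
any stage with the same seed reproduces tables and TIFFs byte-for-byte
(content hashes are recorded in the run manifest).

## Known limitations

- Segmentation defaults (λ, smoothing scales, h-maxima depth, border
  policy, Otsu middle-class assignment) are conventional choices, not
  values fitted to any published pipeline configuration; on real images
  they would need tuning.
- The propagation implementation is a pure-Python priority-queue Dijkstra:
  exact, but ~1 s per 256×256 field; large rendered screens should use the
  tabular path for statistics.
- One site per well; no multi-site averaging, no B-score/spatial polish,
  no dose-response modelling.
- qPCR calculators assume perfect (2.0) amplification efficiency unless
  overridden; group summaries are arithmetic means, with significance
  testing left to standard statistics libraries.
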