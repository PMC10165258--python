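# Methods

## Viability score

Wide-field epifluorescence integrates signal along the optical axis, so a
pixel's propidium-iodide (PI) intensity is read as a column integral of
dead-cell signal. The score is built from three pieces:

1. **Masking.** The overall spheroid mask is the union of a GFP mask
   (Otsu threshold) and a PI mask (median + 2σ over the complete field of
   view), reduced to its largest 4-connected component with holes filled.
   One spheroid per droplet justifies keeping a single component. Both
   thresholds use strict `>`; σ is always the population standard
   deviation (the pixel set is exhaustive, not a sample), so every toy
   example is exactly reproducible.
2. **Normalisation factor K** — the PI intensity a fully dead pixel
   column would carry — is estimated per image as mean + 2σ of the
   above-threshold PI pixels. If no pixel clears the threshold there is
   no evidence of death: the well is scored fully viable and flagged
   (`no_pi_signal`) rather than failed.
3. **Viability** = 1 − ∫PI/(K·Area), integrating raw PI intensity over
   the PI mask (no background subtraction — the formula is applied as
   stated; a subtraction switch exists but defaults off) and dividing by
   the theoretical integral of a fully dead spheroid of the same area.
   The value is clamped to [0, 1]; the raw value is retained per record.

Otsu is implemented in-package as exhaustive minimisation of within-class
variance over the observed grey levels, because the strict-`>` convention
and exact agreement with a 256-level brute-force scan are part of the
module's contract; library Otsu implementations use bin-center
conventions that differ in the last grey level.

Two guards are not part of the formula but are needed for featureless
frames: a GFP mask covering more than 45% of the field of view is treated
as degenerate (Otsu always splits a histogram, even pure noise — a
spheroid never fills the well), and components under 10 px are rejected.
An all-background frame therefore yields an empty, flagged mask instead
of a noise mask.

The size readout is the equivalent-circle radius √(Area_μm²/π).

## Barcode decoding

Calibration is a least-squares line in log10(intensity) vs
log10(concentration), refused outright if intensities are not strictly
increasing (a dye without a consistent calibration range cannot encode a
dilution series). Decoding assigns the level whose predicted intensity is
nearest in log space; ties resolve to the lower concentration
(conservative toward under-dosing), and the margin — log distance to the
decision boundary with the runner-up — is recorded per well. Intensities
at or below blank + 3·σ_blank decode to the zero level; the blank margin
form is a design choice, recorded in output metadata. A blank drug axis
with no green control dye is recorded as zero concentration for that axis
(droplets can fuse with a single drug droplet), which is what populates
the single-drug edges of the heatmaps. Green control dye together with a
high drug dye is contradictory and flags the well ambiguous; ambiguous
wells are excluded from fits and heatmaps but retained in the manifest.

Decoding is invariant to a global gain applied to calibration and well
intensities alike, since only log-space distances matter.

## Dose–response fitting

The four-parameter logistic V(c) = bottom + (top−bottom)/(1+(c/IC50)^hill)
is fitted on log10 concentration by bound-constrained least squares
(top ∈ [0, 1.1], bottom ∈ [0, 1], hill ∈ (0, 10], IC50 within data
range ×10⁻²…10²), with multi-start initialisation over hill ∈
{0.5, 1, 2, 4} × five log-spaced IC50 grid points; the lowest SSR wins,
ties going to the smaller hill. Solver tolerances are 1e-14 so noise-free
synthetic data is recovered to ~1e-7 relative. Zero-concentration
controls never sit on the log axis; they are summarised separately and,
by default, pin the top plateau to their mean viability. A response whose
span is under 0.05 raises a flat-response error rather than returning a
meaningless IC50. Per-spheroid points are fitted directly, preserving
well-to-well heterogeneity.

## Synergy

The diagonal of the condition grid — equal ascending level index on both
axes, not equal absolute concentration, since the two drugs span
different ranges — gives the combination's dose series. The combined
IC50 is fitted against the **total dose c_A + c_B**: this is the only
convention under which a drug combined with itself is exactly
Loewe-additive with FIC = 1, which is the boundary the index is
interpreted against. FIC = IC50_combined / mean(IC50_A, IC50_B).

Protocol comparison uses a two-sided Wilcoxon–Mann–Whitney test with the
chip as the replicate unit. For combined n ≤ 12 the p-value is computed
by exact enumeration of all C(n, n₁) group splits of the pooled
(average-)ranks; larger samples use the tie-corrected normal
approximation (scipy).

## Synthetic generator

The generator emulates the chip experiment, not any particular cell
line's biology; all parameters are configuration.

* **Wells** are rendered as a disk of live intensity over background
  (GFP) plus dead pixels at a PI plateau (`dead_intensity_scale` × the
  background, default 8×). Dead geometry: `uniform` scatters exactly
  round(f·n) pixels (so the rendered dead fraction is exact up to one
  pixel), `speckle` draws per-pixel Bernoulli(f), `core` fills a
  concentric disk of area fraction f (necrotic core). Additive Gaussian
  read noise (default σ = 2 counts on a 100-count background), clipped to
  the bit depth. Emulated ground truth: viability = 1 − dead fraction.
* **Response surface.** With x = c_A/IC50_A(day), y = c_B/IC50_B(day),
  the effective dose is U = max(x, y, x + y + α√(xy)) and viability =
  bottom + (top−bottom)/(1+U^hill). At α = 0 this reduces exactly to
  Loewe additivity (U = x+y), giving the analytic FIC = 1 identity the
  tests exploit; α > 0 is synergy, α < 0 antagonism. The max() guard is a
  deliberate choice: the bare Greco-type term x+y+α√(xy) is not monotone
  in each dose for α < 0 (for α = −1 it decreases in x wherever y > 4x),
  which would let a combination appear *less* potent than its stronger
  component alone; taking the maximum restores monotonicity for all
  α ≥ −1 while leaving α ≥ 0 unchanged.
* **Kinetics.** IC50(day) = IC50∞ · (1 + inflation · e^(−k·day)) makes
  the apparent IC50 fall over the assay days; per-drug exposure start
  days shift each drug's clock, encoding sequential protocols in the
  generator while the analysis layer stays identical across protocols.
* **Barcodes.** Dye intensity follows the calibration line with
  multiplicative log-normal noise (default σ = 0.05 of the log); blanks
  sit at a 10-count autofluorescence floor, two decades below the lowest
  encoded level, and double-negative controls carry the green dye at
  4000 counts. Default calibrations are proportional (slope 1) with bases
  chosen so the full 3-decade dilution range stays inside 16-bit.
* **Chip.** 80 anchors by default (8 columns); all (n_A+1)(n_B+1)
  condition cells are covered and extra anchors cycle through cells as
  replicates, in a seeded random permutation. All randomness flows from
  one `numpy.random.Generator` passed explicitly, so a fixed seed gives
  byte-identical images and tables.

What the generator does **not** emulate: optics (no PSF, no vignetting,
no cross-talk), cell-level texture within the spheroid, droplet shrinkage
or movement, focus drift, or spheroid growth coupled to drug response
(radius is constant unless specified). Passing tests therefore validate
the analysis chain's correctness and calibration on idealised inputs,
not its robustness to those real-world effects.

## Pipeline conventions

* The earliest imaged day — right after drug addition — is used only for
  barcode reading; viability is scored on later days.
* Anchor identity across days comes from the fixed trap positions;
  `match_anchors` (mutual nearest neighbours after removing the median
  rigid shift, failing loudly past `max_shift`) re-establishes identity
  when a session shifted the stage. The registration method is this
  package's choice.
* Heatmap cells hold the arithmetic mean viability of their included
  wells, so cell mean × cell count sums exactly to the included wells'
  total (conservation, asserted in tests). Flagged wells are excluded
  and counted.
* Default problem sizes (96×96 px wells, ≤ 80 anchors, a handful of
  days) keep a full simulated screen in the low seconds; they are desk-
  scale stand-ins for the original format, chosen so the whole suite
  iterates quickly.

## Known limitations

* The viability score inherits the thresholds' assumptions: a PI
  background gradient or a spheroid filling most of the frame breaks the
  median+2σ logic.
* K is estimated per image from above-threshold pixels; with very few
  dead pixels it is noisy, and with none it is undefined (well flagged
  fully viable).
* The 4PL fit reports no confidence intervals; replicate spread across
  chips is the intended uncertainty measure.
* Exact rank-sum enumeration is limited to combined n ≤ 12 by
  combinatorics; beyond that the normal approximation is used.
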