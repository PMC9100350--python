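# Methods

## The measurement problem

Stratum-corneum characterisation rests on two complementary readouts. A
capacitive imaging die (256 × 300 pixels, 8-bit grey, ~50 µm pitch) maps the
skin surface's relative permittivity: water (ε ≈ 81) dominates the dielectric
response, so brighter pixels mean more surface water. A TEWL probe measures
the water flux density through the skin (g·m⁻²·h⁻¹) in a handful of replicate
readings. An occlusive film — here, sunscreen — raises the capacitive signal
(the film carries and traps moisture) and lowers TEWL, and both shifts are
small relative to between-site and between-capture variability, which is what
makes the analysis interesting: ROI tracking, repeat-measurement statistics
and a multivariate similarity measure are all needed to resolve them.

## Template-matching scores

All six scores slide the ROI template `T` (w × h) over every valid placement
of the target frame `I` and evaluate a sum over the window; surfaces contain
only valid placements (the template never leaves the image), in double
precision. Best match = argmin for the difference family, argmax for the
correlation families; ties resolve to the smallest y, then x.

Standard mode implements the canonical definitions (the ones the method
names denote in the image-processing literature): plain products in the
correlation numerators and square-rooted product-of-energies denominators.
Literal mode squares each product term — `Σ(T·I)²`, `Σ(T′·I′)²` — and drops
the square root from the denominators. Transcriptions of this squared form
appear in parts of the applied literature under the same method names, so
both are implemented and both are verified elementwise against an
independent nested-loop oracle; the canonical form is the default because
only it carries the usual guarantees (bounded scores via Cauchy–Schwarz,
exact recovery of noiseless planted templates).

Degenerate cases: a zero-energy template (all-zero under the normalised
difference/cross-correlation scores, constant under the normalised
correlation coefficient) is an error — no placement can be scored. A
zero-energy *window* only invalidates that placement: it is flagged in the
surface's `degenerate` mask and assigned the worst possible score (0 for
maximised scores, +inf for the normalised difference), which deterministically
excludes featureless regions.

Design choice: no sub-pixel peak interpolation and no FFT path — the direct
row-blocked summation is exact, and at the study's sizes (64 × 64 ROI in a
256 × 300 frame) costs well under a second per frame.

## Permittivity calibration

The imaging device's internal grey→permittivity calibration is proprietary.
The default here is a linear map anchored at physically motivated endpoints —
grey 0 → ε 1 (air) and grey 255 → ε 81 (water at ~20 °C) — and every analysis
accepts an override. Statistics over an ROI use the sample SD (n−1); the
histogram spans the calibration range with equal-width bins, the last bin
right-closed, so counts always sum to the pixel count. The combined index is
hydration over TEWL (ε̄ / TEWL̄): both effects of an occlusive film move it
upward. The reciprocal, if wanted, is the inverse.

## TEWL statistics

Replicates are summarised by the arithmetic mean and the sample SD (n−1
denominator — the study design uses only n = 5 replicates per group), and the
coefficient of variation CV = 100·SD/mean as the repeatability metric.
Changes are differences of group means versus the site's baseline timepoint,
also expressed in percent of baseline. Deliberately no hypothesis testing:
with four sites and five replicates the analysis is descriptive, and raw
replicates are exposed for any external inference.

## PCA distance

Frames are flattened row-major, centred by the collection mean, and the
components are taken from an exact SVD of the centred data matrix —
equivalent to the eigendecomposition of the sample covariance, deterministic,
with each component's sign fixed by making its largest-magnitude coordinate
positive. The model is fitted on the pooled study frames (all sites and
timepoints), N = min(8, rank) components by default.

A frame's representation is the N × P matrix `pc(i, j) = score_i ·
component_i[j]` — the rank-N reconstruction split by component. This
interpretation is one deliberate choice among several the distance formula
would admit (raw scores, per-image PCA); it is basis-stable (invariant to
the sign/rotation conventions of the solver) and, at full rank, reduces to
the image-space Euclidean geometry, which is why it was chosen. It is
isolated behind `project()`, so an alternative is a one-function swap.

The default distance is the mean-over-components squared difference
`d = (1/N)ΣΣ(pc1−pc2)²`; `rooted=True` gives the plain Euclidean norm
`sqrt(ΣΣ(·)²)` (no 1/N), so that at full rank the rooted distance between two
training frames equals the norm of their centred difference (Parseval). The
two are mutually consistent: `literal = rooted²/N`.

## Synthetic study generator

The generator defines the study conditions under which everything is tested.

**Texture.** Skin micro-relief is drawn as two oriented families of thin dark
lines (Gaussian profile, half-width 1.3 px) with mean spacing 24 px, gently
meandered by low-frequency sinusoids so they are neither straight nor
periodic, over a plateau at base grey 80 with additive pixel noise SD 4 —
reproducing the plateau/line structure of capacitive skin images without any
skin physics. With ~50 µm pixels this puts relief lines ~1.2 mm apart, in the
plausible range for volar forearm micro-relief.

**Hydration.** Encoded purely as an additive mean-brightness shift on the
site's fixed relief (the film wets the surface; the relief does not move).
Default shifts, grey levels: SPF 20 → 60 (1 h) / 50 (2 h), SPF 30 → 40 / 35,
SPF 50+ → 25 / 20, control → 0 — the moisturiser content of these products
falls as SPF rises, and partially dissipates between 1 h and 2 h.

**Capture jitter.** Later frames are re-captures of the site's base texture
translated by integer offsets drawn uniformly from [−10, 10] px, the
uncovered border refilled with fresh texture at the matching brightness, plus
independent capture noise. This creates the relocation problem the template
matching solves; the true offsets are recorded as ground truth.

**TEWL.** Replicates are drawn from a normal law truncated at zero — the
minimal model for data reported as mean ± SD — with mean = 12 g·m⁻²·h⁻¹
(typical volar forearm) times a per-product factor: SPF 20 → 0.90 (1 h) /
0.85 (2 h), SPF 30 → 0.80 / 0.72, SPF 50+ → 0.68 / 0.58, control → 1. The
film's occlusivity rises with SPF (thicker, more filter-laden formulations),
opposite to the moisturiser ordering. SD = mean · CV/100 with CV 3 % for the
accurate instrument ("AquaFlux") and 15 % for the noisy one ("VapoMeter"),
n = 5 replicates.

All randomness flows from a single design seed through numpy `SeedSequence`
spawning (per-site streams for images and measurements), so studies are
bit-reproducible.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: probe-pressure and contact-area variation,
occlusion kinetics during the capture itself, non-stationary ambient drift,
anisotropic stretch of the skin between captures (only rigid translation),
spatially correlated sensor noise, and any real sunscreen chemistry. Results
on the synthetic study validate the *algorithms* under the stated noise
model, not the physiology.

## Numerical choices and degenerate inputs

- Pixels are cast to float64 once; all sums are direct (no FFT, no
  expansion into difference-of-products), so scores are exact to rounding.
- SqDiff is exactly 0 iff the window equals the template (no cancellation).
- PCA rank is detected at a relative singular-value tolerance of 1e-10;
  requesting more components than the rank is an error rather than silently
  returning noise directions.
- Zero-CV instruments and zero-effect designs are valid inputs: replicates
  become exactly the design mean, and the pipeline's ordering checks then
  report "no separation" (detected at an effect floor of 1e-9) instead of
  pass/fail.
- The pipeline's summary and CSVs are byte-reproducible for a fixed config.

## Problem sizes

The shipped analyses use the full 256 × 300 frame, a 64 × 64 ROI, 12 frames
per study, 20 seeds for the across-seed ordering-recovery rates and 200
seeds for the CV-discrimination rate — large enough for stable rates while
keeping a full test-plus-acceptance run to a couple of minutes on one CPU.

## Known limitations

- The grey→permittivity calibration is a documented stand-in; absolute ε
  values are only as meaningful as the supplied calibration.
- Template matching is translation-only; rotation, scale or skin deformation
  between captures will degrade relocation silently (the peak score is
  reported so callers can threshold it).
- The PCA distance is computed on one pooled model; it is not comparable
  across differently composed collections.
- The hydration/TEWL ratio divides two noisy means; at small TEWL changes
  its between-product ordering is markedly noisier than either ingredient.
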