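# Methods

## Model

The model is the classic four-layer HMAX feedforward hierarchy. Every
model neuron outputs a response in [0, 1], where 1 means the input matches
the neuron's optimal stimulus perfectly.

**Image pyramid.** Each 256×256 grayscale input is resized (bilinear, no
anti-aliasing, each scale computed directly from the base image) to 10
scales at factor 2^(1/4): 256, 215, 181, 152, 128, 107, 90, 76, 64, 53 px
(floor rounding).

**S1.** Every scale is filtered with 11×11 Gabor filters at 4 orientations
(0°, 45°, 90°, 135°; wavelength 5.6 px, envelope σ 4.5 px, aspect ratio
0.3 — the published HMAX defaults, which the original simulation software
ships but does not print). Filters are zero-mean and unit-norm; the
response is the absolute normalized dot product |G·x| / ‖x‖ over the valid
convolution region (no padding), so responses are contrast-invariant,
bounded by 1 (Cauchy–Schwarz), and exactly 0 on constant patches. A
config-exposed saturation constant ε (response = |G·x|/√(ε²+‖x‖²),
default 0) is available but off: with the final stimulus statistics the
pure normalized dot product reproduces all three effects.

**C1.** Band *b* (of 9) pools S1 scales *b* and *b*+1: an 8×8 spatial max
with stride 3 on each scale's own grid, the coarser grid registered to the
finer by nearest-neighbor matching of receptive-field centers in image
coordinates, then an elementwise max across the two scales — 128 S1 values
per C1 unit.

**S2/C2.** A stored template *t* (a C1 patch) is matched against every C1
patch at every position of every band it fits in (smaller bands are
skipped, never padded): response = exp(−d²/(2σ²)) with σ = 1/3 and *d* the
raw Euclidean distance. C2 is the global max over the template's whole S2
pyramid. A fused im2col/matrix-product path computes C2 without
materializing S2 pyramids; tests assert it equals the literal composition,
and that re-presenting a training image drives each of its own templates
to exactly 1.

**Distance normalization.** We deliberately use the *unnormalized*
Euclidean distance with σ = 1/3 rather than dividing by √(#entries).
At the C1 energies real stimuli produce (template RMS ≈ 0.13), the
RMS-normalized distance bounds every response above ≈0.9 — the whole
response scale collapses and graded analyses (e.g. the response-band
selection below) become impossible. With the raw distance, best-match
distances stay moderate because C2 searches every position and scale, and
mean responses order by tuning size (small ≈ 0.90, medium ≈ 0.67, large
≈ 0.51 on held-out faces) — the graded, size-dependent regime the
experiments presuppose. The normalized variant remains selectable in
config.

## Template learning

Learning stores patterns of C1 responses — nothing else is trained. From
each of 50 training faces, 20 large (12×12×4) patches are sampled at
uniformly random positions such that the whole patch lies inside the
face's C1 footprint at band 7 (sampling the black background would store
empty templates; a config flag allows it). Medium (8×8×4) and small
(4×4×4) banks are the central sub-blocks of each large patch, linked by
parent id — 1000 templates per tuning size, differing *only* in extent.
The face footprint (bounding box of above-threshold C1 activity, threshold
10⁻³) measures ≈17×21 C1 units for the default 80×120 px face, matching
the nominal 17×22 within the coordinate chain's rounding; a calibration
test asserts ±2 units. Odd-numbered identities train, even-numbered
identities test.

## Synthetic faces

The face photographs used in the original behavioral-modeling literature
are not redistributable, so the stimulus module synthesizes schematic
faces with the same format and summary statistics: a 80×120 px oval on a
256×256 black field, six anti-aliased elliptical parts (two brows, two
eyes, nose ridge, mouth), radial shading, and identity-specific albedo
texture. In-oval pixels are standardized to mean 0.5, SD 0.08 (outliers
clipped and re-standardized in the rare identities that overshoot [0, 1]);
the background stays exactly 0.

Three design properties of the generator matter, and each was forced by a
measurable failure mode of the naive alternative:

1. **Identity variation is spatially uniform** (every part jitters with
   the same SDs: position 4 px, semi-axes 2 px, intensity 0.12). If any
   region varies less than the rest, the C2 global max relocates each
   template's best match *into* that stable region and identity
   information never reaches the C2 code.
2. **Texture is multi-scale** (independent Gaussian fields on 12×12 and
   96×96 grids, bilinearly upsampled, amplitudes 1.0 : 0.9 at overall
   amplitude 0.05). Smooth single-scale faces are approximately
   self-similar across pyramid bands, so a coarse-band template can find
   spurious near-perfect matches at fine bands, where it covers a small
   image region and behaves like a *small* template. Scale-distinctive
   content locks templates to their native band, as photographs do.
3. **Distinctiveness is heterogeneous**: each identity scales all its
   jitters and texture by a lognormal factor exp(N(0, 0.7²)). Prototypical
   identities yield broadly-matching templates (populating the upper
   response range); distinctive identities carry discrimination signal.

What the generator does **not** emulate: photographic micro-texture,
asymmetry, 3D shading and pose, hair and external features, and
correlations between features that real face populations show. Passing
tests therefore demonstrate the *mechanism* — that tuning size controls
the three markers given identity-bearing part-structured stimuli — not
quantitative agreement with human data on photographs.

## Experiments

All three experiments consume C2 vectors only; conditions differ in
stimulus construction, never in the model.

**Composite Face Effect.** For 20 identities, composites pair the top
half of one face with the bottom half of another (split at the oval
midline, 2 px background gap; misaligned composites shift the bottom half
right by 40 px — half the face width, the literature's convention, since
the original offset is unstated). Attention to the top half is simulated
by multiplying bottom-half pixels by 0.1 and recentering on the top half;
the attentional window's edge is a linear ramp over 8 px (a hard step
would cut an artificial full-contrast edge across the face). *Same*
trials are all (top, {bottom₁, bottom₂}) combinations with three distinct
identities; the pair is judged "same" if the C2 distance falls below a
threshold calibrated per tuning size so the aligned hit-rate is closest
to 75% (candidate thresholds are midpoints of consecutive sorted aligned
distances plus extremes; ties resolve to the lower threshold, and the
threshold is recalibrated inside every bootstrap resample). The effect is
the misaligned − aligned hit-rate difference. A per-neuron variant gives
every C2 neuron its own calibrated threshold and tests the per-neuron
effects across the population by Wilcoxon signed-rank.

**Face Inversion Effect.** Behavioral level: mean C2 distance over all
C(50,2) = 1225 pairs of faces, upright vs inverted (rows reversed); the
effect is the upright − inverted drop, per tuning size. The neuron
bootstrap first subsamples without replacement (100 large / 150 medium /
all 1000 small, compensating coverage area), then resamples with
replacement; tuning sizes are compared on paired resamples. Neural level:
the per-face drop of the mean C2 response under inversion, tested across
faces by Wilcoxon signed-rank. The response-matched variant (only neurons
with mean upright response in [0.75, 0.80], counts equalized across sizes)
is implemented and raises with the achieved distributions when the band is
empty — which it necessarily is for the synthetic population, whose
per-size response distributions are disjoint (large ≤ ~0.72, small ≥
~0.74): no band intersects all three sizes. The package therefore reports
the full-population neural effect (`band=None`); the banded analysis works
on any two classes whose distributions overlap (e.g. medium + small).

**Whole-Part Effect.** Stimuli blend the eye region of one face (upper
0.4 of the oval, full width, 1 px feathered boundary) with the rest of
another. Trials are all ordered triples (A, B, C) of distinct identities:
the study face is whole(A, C). Attention to the eyes multiplies non-eye
pixels by 0.5 and recenters on the eye region. Because the study face is
re-presented as one of the two test faces, the test-face weighting applies
to it as well; the remembered study percept is therefore the weighted
image. (With an *unweighted* study trace, the weighting mismatch between
study and test percepts — ~5× the eye-identity signal for large templates
— drives whole-condition accuracy to chance for every tuning size and no
effect can be expressed; the unweighted reading remains selectable.) The
whole condition compares the two weighted wholes to the study percept —
the correct choice is that percept, so whole accuracy is at ceiling — and
the part condition compares the cropped eye regions; the model picks the
smaller C2 distance (exact ties resolved by a seeded coin flip and
counted). The effect, whole − part accuracy, is carried by the part
condition: removing the face context costs large (context-integrating)
templates more than small (part-sized) ones.

## Statistics

The paired bootstrap resamples the C2 neuron population uniformly with
replacement (B = 1000 by default; the directional hypotheses are one-sided
and the p-value is the proportion of resamples in which the effect is ≤ 0,
so p has granularity 1/B and p = 0 means "< 1/B"). SEMs are the SD of the
resample statistics; item-level SEMs (over faces) are reported separately
where computed. The Wilcoxon signed-rank test drops zeros, mid-ranks
ties, uses the exact null distribution of W⁺ (dynamic programming over
doubled ranks, valid under ties) for n ≤ 15 and the normal approximation
with tie correction and 0.5 continuity correction otherwise; tests verify
exact agreement with full 2ⁿ enumeration and with the reference
implementation in scipy.

## Numerical choices and tolerances

* float32 for template stacks and distance matrices; float64 elsewhere.
* Resample distances are computed as matrix–vector products with the
  resample's neuron-count vector, so a bootstrap run costs one GEMV per
  condition.
* C2 position search is restricted to the dilated bounding box of nonzero
  C1 activity; all-background patches are handled in closed form (the
  background is exactly 0, so this is an exact optimization).
* Approximate invariances, measured on default faces with large templates:
  a one-C1-stride shift (≈9 px) changes C2 by ≈0.16–0.22 median absolute
  difference with population-pattern correlation 0.6–0.86; one pyramid
  step of rescaling changes it by ≈0.34–0.43. Tests assert 0.3/0.5.
  The drift comes from off-grid resampling amplified by the exponential
  tuning curve; max pooling preserves the pattern, not the exact values.
* Max pooling is value-only; where a position is reported for
  diagnostics, first-in-scan-order wins.

## Problem sizes

Default runs use the study's sizes: 50 training faces × 20 templates,
20 CFE identities (3420 collapsed same-trials), 50 FIE identities (1225
pairs), and 12 WPE identities (1320 ordered triples) with 200 bootstrap
resamples in the shipped scripts; all counts are config. The test suite
uses the same sizes except where a smaller count exercises the identical
code path.

## Known limitations

* The paper-level p-values from the original photographs are not
  reproducible; all behavioral comparisons here are directional, on
  synthetic faces.
* The response-band-matched neural analysis cannot run across all three
  tuning sizes on the synthetic population (disjoint response ranges; see
  above).
* Scale invariance at C2 is weak under the raw-distance response regime;
  conclusions relying on exact response values across rescaling should
  use the dissimilarity structure instead.
* The whole-part experiment's whole condition is at ceiling by
  construction under the weighted-study reading; its information content
  lies in the part condition.
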