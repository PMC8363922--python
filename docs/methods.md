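# Methods

## The problem

Collagen proportionate area (CPA) — the percentage of tissue staining
positive with picrosirius red (PSR) — is the standard continuous measure of
liver scarring. Computational CPA pipelines segment scanned sections either
with a fixed hue–saturation–brightness (HSB) threshold or with a trainable
pixel classifier, and report

    CPA% = 100 · PSR / (PSR + tissue + lumen)

over a whole section (the HSB comparator uses the two-class denominator
`PSR + tissue`, since lumen is not one of its threshold classes; the
difference is bounded by the lumen fraction, ~2%). Both approaches read the
*colour* of the stain, so anything that changes colour — which laboratory
stained the slide, which batch, how old the section was when stained —
perturbs the measurement. This package reproduces that phenomenon end to
end on synthetic sections where the true scar fraction is known, and
quantifies it as the inter/intra-laboratory consistency of per-case scores.

## Synthetic sections

A section is a four-class label raster: empty `SPACE` around the tissue,
`TISSUE` (parenchymal nodules), `PSR` (fibrous septa + capsule), and vessel
`LUMEN`. Tissue is an irregular ellipse (low-order harmonic boundary
modulation); nodules are a Voronoi tessellation of random seed points;
septa are the pixels closest to Voronoi boundaries or the tissue edge under
one distance key, taken in order of that key until the requested scar
fraction of non-SPACE pixels is met exactly at pixel precision (so the
generator either meets its target or raises). Lumina are small ellipses
carved into septa until the lumen target (default 2% of non-SPACE) is
reached. Per-case scar targets are drawn uniformly from 8–40%: all cases
are cirrhotic, the spread is what the ranking statistics operate on.

Serial sections of a block warp the parent raster with a smooth random
displacement field (≤ `jitter_px`, default 2 px) plus sparse boundary
re-labelling; scar fractions stay within 0.01 of the parent, matching
adjacent 5 µm sections of one block.

## The staining model

Rendering maps each class to a base palette colour — PSR (200, 30, 60),
tissue (230, 190, 120), lumen (235, 225, 200), space white — and pushes it
through a `StainTransform` in HSB space:

| parameter | meaning | identity |
|---|---|---|
| `hue_shift_deg` | reagent/protocol hue rotation (mod 360) | 0 |
| `saturation_scale` | stain intensity | 1 |
| `brightness_scale` | counterstain / illumination | 1 |
| `fade_factor` | section-age fade, multiplies PSR saturation only | 1 |
| `noise_sd` | sensor noise, 8-bit units per channel | 0 |
| `texture_sd` | smooth log-normal saturation (and 0.3× brightness) fields over tissue: uneven stain uptake | 0 |
| `blur_sigma` | optical blur, mixes colours at class boundaries | 0 |

With the identity transform and zero noise the palette colours are
reproduced bit-exactly, which is what the exact-recovery checks rely on.
`texture_sd` and `blur_sigma` matter: without within-section appearance
variation and boundary mixing, every class is a constant colour plus iid
noise, every segmenter is near-perfect, and there is no staining-variation
phenomenon to study.

The four stain sets emulate two laboratories × two batches:

| set | hue | sat | bri | fade |
|---|---|---|---|---|
| E1 | 0° | 1.00 | 1.00 | 1.00 |
| E2 | +4° | 0.90 | 1.05 | 0.85 |
| N1 | −15° | 1.10 | 0.95 | 0.95 |
| N2 | −19° | 0.80 | 1.05 | 0.75 |

(all with noise 4, texture 0.35, blur 1.0; `rN3` = N1 without fade, the
fresh-section restain). The laboratory effect lives mainly in hue — sets
cluster by laboratory — while the batch effect is a small hue drift plus
saturation loss and fade: second batches were stained six months later on
sections cut at study start, and even first-batch sections carry some age
by staining time. This clustering is what makes same-laboratory pairs more
alike than cross-laboratory pairs, the structure behind "intra ≥ inter".

On top of the batch transform every slide receives jitter with two
components: a **case × laboratory** interaction (hue sd 4°, log-sat sd
0.08, log-brightness sd 0.03) shared by both batches of a laboratory for a
given case — a block's tissue chemistry (five aetiologies in the study
population) reacts to a laboratory's protocol consistently — and an
independent **per-slide** component (hue sd 2.5°, 0.05, 0.03) for
day-to-day variation. Slide-level variation is essential: a purely
batch-level transform distorts every case of a set identically and, Spearman
correlation being rank-based, could never degrade consistency at all. The
shared component is equally essential: without it, pair consistency is
driven by set "difficulty" alone and two easy sets from different
laboratories pair better than a lab's easy/faded pair, inverting the
intra/inter ordering.

## Scoring methods

**HSB.** One PSR rule (circular hue interval, saturation floor) and one
tissue rule, PSR tested first, applied inside a tissue mask
(brightness ≥ 0.92 ∧ saturation < 0.08 is background; foreground specks
< 64 px are debris). Calibration replaces the by-eye loop with a
deterministic two-stage procedure: a grid search over hue centre/half-width
(red band, centres ±40°, half-widths ≤ 20°) and saturation floor maximising
balanced PSR/tissue pixel accuracy on labelled calibration pixels (ties →
wider interval, then interval centred on the labelled PSR hues), followed by
selection, among near-best candidates, of the threshold whose slide scores
on representative calibration tiles deviate least from the calibrator's
perceived scar fractions — the "testing on representative tiles from all
cases, adjusting and iterating" step. The threshold is calibrated once on
the E1 set and applied unchanged to all sets; per-set re-tuning is exactly
the failure mode under study and is deliberately absent.

**Pixel classifier.** Per pixel and RGB channel: the raw value plus mean,
minimum, maximum, median and variance over square windows at radii
{1, 2, 4, 8} (edge-replicated; median via a rank filter on a padded tile so
it matches a naive sliding window exactly). A random forest (100 trees by
default) is trained on sparse annotations after minority-class upsampling
to the majority count. Annotations are sampled from the label rasters as
one contiguous stroke (≤ 21×21 patch) of up to 60 pixels per class per
slide, drawn from class *cores* (mask eroded 2 px): annotators outline
unambiguous regions and avoid blurred boundaries. Three regimes:

* `per_set` — one classifier per stain set, trained on and applied to that
  set only;
* `combined` — one classifier trained on the annotations of all four sets;
* `combined_retrained` — the combined classifier retrained after adding
  annotations (boundary-inclusive, six patches, up to 120 px/class) from
  the cases any inter-laboratory pair scored with a strict >2× ratio,
  using the combined classifier's own scores to flag them.

Annotation is by eye, and the model says so: on a slide whose PSR signal
is faint — mean PSR saturation below a well-stained scar's — a PSR stroke
is labelled `TISSUE` with probability `1 − visibility` (capped at 0.5):
faint septa are simply not seen. On the unfaded calibration set this never
triggers; on a strongly faded second-batch set roughly a third of PSR
strokes are lost. A classifier trained only on such a set inherits the
full error; the combined pool dilutes it, which is a large part of why
combined training is more consistent. Targeted retraining annotates with
scrutiny (misses disabled), which is why it recovers the divergent cases.

**Stain-free reference.** The per-case true scar percentage read off the
parent label raster stands in for SHG/TPEF collagen percentage; a per-section
`GROUND_TRUTH` scorer reads each section's own raster.

Slide scores always sum pixel counts over a slide's tiles before applying
the percentage formula; averaging per-tile percentages would overweight
low-tissue tiles.

## Consistency analysis

Four sets give six unordered pairs (2 intra-, 4 inter-laboratory). Per
method and pair: Spearman ρ of per-case scores (mid-ranks; pairwise-complete
deletion with logged counts; zero rank variance → reported missing, never
coerced to 0). Grouping summaries are reported both as the median of
per-pair ρ and as the pooled-observations ρ, because a single printed
summary value could be either; the median is the headline. Reference
correlations relate each method's E1 scores to the stain-free values.

## Problem sizes

Defaults describe the study analogue (20 cases, 4 sets, 512² tiles). The
shipped experiments run at desk scale: the regime-consistency experiment at
160² tiles, 60 trees, 7 master seeds (enough that the smallest effect —
combined versus per-set training — is resolved by the across-seed median);
the noiseless-recovery check at
128–160² tiles; the drift curve at 128–160² with 12–20 cases. At these
sizes the full acceptance run takes ~10 minutes on one core. The noiseless
check uses scattered, boundary-inclusive annotations (150 px/class/slide):
it verifies pipeline correctness in the zero-variation limit — the end
state of iterating training until segmentation is judged accurate — not
annotation economy.

## What the synthetic study does and does not show

The generator reproduces the *structure* of the phenomenon: a fixed
threshold collapses under hue drift; per-set classifiers are consistent
within their set but decorrelate across sets; combined training helps;
divergence-targeted retraining helps more; the stain-free reference is
immune. Absolute ρ values are not calibrated to the real study — the real
drift magnitudes were never quantified, real annotation is noisier, and
real tissue has texture no Voronoi model captures — so synthetic ρ values
sit higher than the published ones while preserving every ordering. Real
confounds not modelled: scanner differences, tissue folds and debris
beyond specks, chromatic aberration, human annotation error, and stains
other than PSR.

## Numerical and design notes

* All randomness flows from one master seed through SHA-256-derived
  per-entity streams (< 2³¹), so studies are bit-reproducible and adding a
  case or set does not reshuffle the others.
* Hue arithmetic is circular throughout; the PSR band straddles 0°.
* Windowed mean/variance use separable uniform filters (population
  variance, clipped at 0); min/max/median are exact.
* Degenerate inputs fail loudly: unreachable fraction targets, single-class
  training tables, empty denominators, undefined correlations, conflicting
  annotations.
* The tissue mask's brightness/saturation cutoffs assume a bright-field
  background; the lumen palette colour carries a faint counterstain tint so
  lumina stay inside the analysable area, as they do in the lumen-inclusive
  CPA denominator.
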