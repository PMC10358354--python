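# Methods

This note records the models, conventions, parameter choices and known
limitations behind fieldsynth.

## Pixel and box conventions

Images are `uint8` H×W×3 arrays, row-major, origin top-left; masks are
boolean arrays aligned pixel-for-pixel. All boxes are 0-based and half-open
(`[x0, x1) × [y0, y1)`), so `area = (x1−x0)(y1−y0)`; exporters convert at the
boundary (YOLO normalizes centers/sizes to [0,1]; VOC XML is 1-based
inclusive). Using one convention everywhere removes an entire class of
off-by-one errors between masking, scene assembly and evaluation.

## Chroma keying

A pixel is blue-screen background when `B − max(R, G) ≥ t`. The default
`t = 30` leaves a wide margin between keying-fabric blue and foliage greens,
but is configurable because real fabric tone varies with lighting. An
optional morphological cleanup removes plant components smaller than a
configurable area (default 16 px when enabled) to suppress sensor speckle;
it is off by default because the procedural fixtures are noise-free. The
tight bounding box is simply the mask's row/column extent; an optional
margin pads it. Geometric pre-cropping from camera metadata is out of scope
(it requires capture-rig geometry that images alone do not carry).

## Compositing

Plant scale is defined as the plant image's longest side divided by the tile
side (256 px by default, the input size expected by common translation
generators). Scales are drawn uniformly from [0.50, 0.85]; these bounds keep
plants large enough to translate well and small enough to leave visible
soil. Images are resampled bilinearly (with anti-aliasing when shrinking);
masks use nearest-neighbor so they stay boolean and acquire no soft edge.
Side lengths round half-even — the choice is arbitrary but fixed, and the
re-measured scale is always within 1/side of the drawn one. Random placement
is implemented as uniform padding offsets. Soil backgrounds larger than the
tile are randomly cropped, never resized, so soil texture keeps its spatial
scale. No blending or feathering is applied at the plant boundary: the
compositor's conservation property (plant pixels bit-exact from the cutout,
background bit-exact from the soil) is load-bearing for testing and for
label fidelity.

## CIELAB8 and color correction

The 8-bit CIELAB encoding scales L from [0,100] to [0,255] and offsets a and
b by +128 ("greener than neutral" is a < 128). The default plant targets
(L, a, b) = (170, 100, 160) describe bright green-yellow field foliage; the
correction shifts every masked pixel by (target − masked mean) per channel,
rounds half-even, clamps to [0,255], and never touches unmasked pixels.
Mean matching is deliberate — a histogram match would impose a full
distribution that a downstream translator is expected to adjust anyway.

Conversions use the D65 sRGB↔CIELAB transform from scikit-image. The
round trip RGB→CIELAB8→RGB is bounded at ≤3 intensity levels per channel on
plant/soil imagery (tested); extreme saturated colors can deviate by more
(up to ~16 levels near the gamut boundary) because a and b quantize to whole
levels. Pipeline math therefore converts once, corrects in float, and
converts back only the pixels it changed.

Background correction computes, per RGB channel, the mean difference between
the pre-translation composite and the translated tile over a region outside
the plant box, and adds it uniformly. The default region is the full
exterior of the box within the tile; a configurable band width restricts it
to a ring for very large tiles. The correction is a fixed point up to
rounding: recomputed offsets are ≤0.5 absent clamping, because the residual
after adding a constant offset and rounding is the same for every pixel of a
channel.

## Translation boundary

The translator contract is a map from a square RGB tile to a same-size RGB
tile, validated on both sides. Training a generator is behind this boundary:
the package implements the objective's mathematics exactly (PatchNCE with
temperature 0.07, log-sum-exp stabilized; the non-saturating adversarial
value with probability clipping at 1e-7; the weighted total with
λ_X = λ_Y = 1) so that any training loop can be verified against it, but
ships no network. Two built-ins make the pipeline runnable end to end: the
identity map, and a deterministic CIELAB8 mean-shift toward reference
statistics. A subprocess adapter wraps an external generator checkpoint
(command template with `{input}`/`{output}` PNG paths) with contract
validation and content-hash caching. The identity constraint on the target
domain is expressed by evaluating the same PatchNCE loss on target-domain
features.

## Scene assembly

Scenes replace rectangular soil windows with translated composite tiles —
window replacement, not mask blending, so the pasted tile's background must
match its surroundings, which is exactly what background correction
provides. Non-overlap is enforced on tile boxes (stronger than plant-pixel
overlap) by rejection sampling with a 100-attempt budget; row layouts center
tiles in a rows × ceil(n/rows) grid of cells with optional jitter. The scene
canvas is the full soil image, so canvas resolution is a property of the
soil pool.

Determinism is structural: one master seed; per-scene seeds derived by a
counter scheme; within a scene, per-plant generators spawned by counter so
that adding an n+1-th plant never perturbs the first n. A dataset manifest
records the full config snapshot and all seeds; rebuilding from the manifest
is byte-identical (asserted in tests).

Classes default to the single label "plant"; species-level labels are a
config switch. Splits are 80/10/10 by default, with val/test sizes rounded
and the remainder assigned to train.

## Detection metrics

IoU uses the half-open area convention. Matching is greedy: predictions in
descending confidence each claim the unmatched ground truth of highest IoU,
accepted when IoU ≥ threshold (ties included — the ≥ reading differs from >
only on measure-zero cases and matches common tooling). Precision is
interpolated over the 101-point recall grid {0.00, …, 1.00} as the suffix
maximum, and AP is the grid mean; mAP@0.5:0.95 averages thresholds 0.50 to
0.95 in steps of 0.05. The scenario with no ground truths and no predictions
has AP defined as 0 with a warning. Reported precision/recall use all
predictions at IoU 0.5, a documented choice since detector validators vary
in their operating point. All metrics are checked against independent
brute-force re-implementations (pixel-count IoU, re-derived greedy matcher,
point-by-point staircase AP) on seeded random scenarios.

## Procedural fixtures

Fixtures emulate only the properties the pipeline relies on. Plants are
rosettes of elliptical leaves (default 5 leaves, eccentricity 0.55, ~192 px)
in CIELAB8 colors near (120, 110, 150) — deliberately darker and less yellow
than the correction targets so the corrective shift is visible and testable
— on uniform reference blue (40, 60, 200) RGB, chosen to dominate the blue
channel under the default chroma rule while resembling keying fabric. The
generator returns the exact painted-pixel mask, so mask recovery is exact at
the default rule; a pixel-noise knob exists for robustness experiments and
exactness is only guaranteed at noise 0. Soil is smoothed Gaussian noise
(sigma 6 px) around base brown (120, 85, 55) with per-channel gains and
optional bright speckles, hard-clamped so no pixel is ever blue-dominant.
Detection scenarios derive predictions from ground truth by corner jitter,
independent drops and spurious boxes, with confidence decreasing in jitter.

What fixtures do not emulate: leaf self-occlusion and thin structures,
shadows, specular highlights, non-uniform keying fabric, perspective, or
real soil statistics. Passing tests therefore demonstrate the pipeline's
arithmetic and bookkeeping are correct under ideal separability, not that
the chroma rule or a given translator suffices on difficult real imagery.

## Problem sizes in tests and the acceptance script

Sweeps run at sizes chosen to exercise every code path while staying quick:
color- and background-correction sweeps use 100 composites at tile side 128
with 96 px plants; label-fidelity and determinism checks use 96 px tiles on
288² soil with 2-3 plants over 20 and 6 scenes respectively; metric-oracle
sweeps use 100 scenarios of up to ~30 boxes. The corresponding properties
are size-independent (means, rounding residuals, exact box equalities), so
small tiles lose no generality.

## Known limitations

- Non-overlap can fail on crowded canvases; the placement error surfaces to
  the caller rather than silently dropping plants (the CLI skips the scene
  with a warning).
- Background correction assumes the translated plant stays inside its box;
  plant spill into the exterior region biases the offsets slightly.
- The "small region" variant of the correction region (band width) defaults
  to the full exterior; very large tiles may prefer a band.
- AP with zero ground truths for a class present only in predictions is
  scored 0 for that class, which penalizes hallucinated classes.
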