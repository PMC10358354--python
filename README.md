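# fieldsynth

Labeled training images for in-field plant detection are expensive: every
plant in every field photo must be boxed by hand. Plants photographed indoors
against blue keying fabric, by contrast, can be segmented and localized
automatically. **fieldsynth** turns such blue-screen photographs into
synthetic labeled *field* imagery: it chroma-keys the plant out, composites
it onto real or procedural soil, corrects its color toward field statistics,
passes the tile through a pluggable domain translator (e.g. a trained
contrastive unpaired translation generator), corrects the translated
background, and assembles multi-plant scenes whose bounding-box labels are
known by construction. A detection-metric suite (IoU, precision/recall,
101-point interpolated AP, mAP@0.5, mAP@0.5:0.95) closes the loop.

It is aimed at digital-agriculture researchers building object-detection
datasets from indoor phenotyping imagery.

## Method

For a blue-screen image, a pixel is background when its blue channel
dominates: `B − max(R, G) ≥ t` (default `t = 30`). The mask's tight box
crops a single-plant *cutout*.

A composite tile (side 256 px) is built by drawing a plant scale
`s ~ U(0.50, 0.85)` — scale is the plant's longest side over the tile side —
resizing the cutout, placing it at a uniformly random offset, and filling the
rest with soil.

Plant color correction works in 8-bit CIELAB (L scaled to [0,255]; a, b
offset by +128). With mask `m` and masked channel means `x̄_k`, each plant
pixel becomes

    x'_ijk = x_ijk + m_ij (x̄'_k − x̄_k),   clamped to [0, 255],

with default targets `x̄'_L = 170, x̄'_a = 100, x̄'_b = 160` (brighter,
greener, yellower — field-like foliage).

Translation is a black box `G: tile → tile`. The contrastive objective used
to train such a generator is implemented exactly: the PatchNCE unit loss

    ℓ(z, z⁺, z⁻) = −log [ exp(z·z⁺/τ) / (exp(z·z⁺/τ) + Σₙ exp(z·z⁻ₙ/τ)) ]

with τ = 0.07, summed over layers and locations, plus the adversarial term
`E log D(y) + E log(1 − D(G(x)))`, with weights λ_X = λ_Y = 1.

After translation, a per-channel offset `d_k` — the mean of
(composite − translated) over the plant box's exterior — is added back so
the tile's soil matches the surrounding field.

Scenes place tiles without overlap (rejection sampling) or on a row grid;
each plant's label is its mask extent shifted to scene coordinates. Datasets
are split 80/10/10 and written as `images/{split}/*.png` +
`labels/{split}/*.txt` (YOLO dialect) + `manifest.json`.

## Worked example

```python
import numpy as np
import fieldsynth as fs

cutout = fs.gen_plant_cutout(fs.PlantStyle(seed=3))      # blue-screen fixture
soil = fs.gen_soil(fs.SoilStyle(seed=1), 300, 300)
tile = fs.make_composite(cutout, soil, fs.ScaleRange(0.50, 0.85),
                         256, np.random.default_rng(0))
print(round(tile.scale, 3), tuple(tile.plant_bbox))

lab = fs.rgb_to_lab8(tile.image)
corrected = fs.correct_plant_color(lab, tile.mask)
print(np.round(fs.masked_means(corrected, tile.mask), 2))

print(round(fs.compute_scale(150, 200, 256), 2))
print(fs.iou(fs.BBox(0, 0, 2, 2), fs.BBox(1, 1, 3, 3)))
```

prints

```
0.594 (32, 4, 182, 156)
[170.47 100.07 159.66]
0.78
0.14285714285714285
```

The drawn scale 0.594 lies in [0.50, 0.85]; the corrected masked CIELAB8
means sit within rounding of the (170, 100, 160) targets; a 150×200 plant in
a 256 tile has scale 200/256 = 0.78; two unit-offset 2×2 boxes overlap in
1 of 7 pixels.

From the shell:

```bash
fieldsynth fixtures --out pack --n-plants 8 --n-soils 4 --seed 0
fieldsynth segment pack/plants out/cutouts
fieldsynth build-dataset --out dataset --n-scenes 20
fieldsynth eval --pred-dir preds --gt-dir dataset/labels/test --width 768 --height 768
fieldsynth losses-selftest
```

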