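# elytra-id

Species identification of food-contaminating beetles from microscope images
of elytra fragments.

Storage-product beetles are a key indicator of insanitation in food
inspection, and the fragments most often recovered from processed food are
pieces of elytra — the hardened forewings, which carry species-characteristic
surface patterns (hairs, holes/grooves, lines, and tiled unit shapes).
`elytra-id` implements an image-analysis pipeline that identifies the
species of such a fragment:

1. **Enhancement** — a rotationally symmetric low-pass Gaussian filter
   (variance σ² = 2, 10×10 window) followed by contrast-limited adaptive
   histogram equalization on the luminance channel.
2. **Segmentation** — two complementary binary masks (histogram peak–valley
   analysis with a dynamic-variance smoothing of the intensity histogram,
   and Euclidean RGB distance to a reference colour sampled at the image
   centre), each hole-filled and opened, then intersected.
3. **Fragment simulation** — random-position, random-size subimages
   (300–2500 px per side, ≥ 80 % foreground) cropped within the segmented
   elytron to emulate broken fragments; 100 per specimen by default.
4. **Global description (210 values)** — histogram statistics and 7 Hu
   moments (13); radial sums of the centred FFT magnitude,
   `S(r) = Σ_θ ‖F(r, θ)‖` for r = 1…80 with the dc term excluded (80);
   10-bin-per-channel RGB histograms (30); sum/mean/std of the magnitude
   responses of six oriented complex Gabor filters plus the
   maximum-response angle (19); and a Difference-of-Gaussian key-object
   descriptor (σ² = 100 and 1, both polarities, Otsu-averaged threshold,
   connected components) with colour, density and size statistics (68).
5. **Local description (415 values)** — Harris corners refined by
   density rejection (25 % truncated-mean cap) and merging (disk dilation,
   connected components, 15-px centroid merging); around each point a
   101×101 window on the colour-gradient edge map is split into a 5×5 grid
   of 20×20 cells contributing mean, variance and 7-point-interpolated
   projection profiles (16 × 25), plus a 5-bin-per-channel window colour
   histogram (15); per-point vectors are averaged.
6. **Classification** — z-scoring fitted on training fragments only, then a
   feed-forward network with two sigmoid hidden layers of 50 nodes, softmax
   output and early stopping on a 70:20:10 split of the training fragments.
   Cross-validation is leave-one-specimen-out: each round holds out one
   whole specimen per species, so fragments of a test specimen never leak
   into training.
7. **Feature selection** — mRMR ranking (MID and MIQ schemes) and
   correlation-based subset search (CFS merit, forward/backward best-first),
   with a top-K evaluation harness.

Because the original microscope images are not distributed, the package
ships a seeded synthetic specimen generator (`elytra_id.synthdata`) that
renders elliptical elytra with species-specific base colours, the four
pattern categories, border defocus, salt noise and contrast bias — with
ground-truth masks and object centres — so every stage is testable.

## Worked example

```python
from elytra_id import classify, pipeline

dataset = pipeline.build_recovery_dataset(seed=1)   # 4 species x 3 specimens x 20 fragments
result = classify.loso_cv(dataset, feature_set="all", rounds=10, seed=2)
print(f"overall accuracy {result.overall_accuracy:.3f} +/- {result.overall_std:.3f}")
print(result.per_species.round(3))
```

```
overall accuracy 0.988 +/- 0.021
    mean    std
1  0.990  0.032
2  0.985  0.034
3  0.975  0.054
4  1.000  0.000
```

The four synthetic species instantiate the four pattern categories; species
1 and 2 share the same base colour and differ only in their key-object
patterns (hairs vs holes).  With all 625 features the network recovers the
species of held-out specimens at 99 % despite the look-alike pair; on that
pair alone, local features match or beat the global set without key-object
features, mirroring the qualitative advantage of local description for
same-genus species.  Accuracy varies with the rendered collection
(0.86–0.99 across generator seeds; three specimens per species is a
scarce-specimen regime).

The same pipeline is scriptable from the shell:

```sh
elytra-id cv --config config.yaml --out run/       # synth -> extract -> LOSO CV
elytra-id select --config config.yaml --out run/ --method mrmr-mid --k 50
```

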