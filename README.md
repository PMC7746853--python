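# acbf — hybrid active-contour segmentation of speckled ultrasound images

Lesion segmentation on radiological ultrasound (breast and thyroid
nodules) is hard because speckle noise and intensity inhomogeneity break
both classic families of active contours: edge-based geodesic contours
(GAC) leak through weak gradients, and region-based Chan–Vese (CV)
contours mis-cluster heterogeneous tissue. This package implements a
combinatorial remedy for users who need a seeded, reproducible 2-D
segmentation tool:

1. **Speckle reduction** with an exact windowed bilateral filter
   (spatial Gaussian σₛ × range Gaussian σᵢ), which homogenizes tissue
   regions while preserving lesion boundaries.
2. **Global phase** — a simplified two-phase piecewise-constant model on
   a binary level set φ (interior: φ < 0):

   ∂φ/∂t = { div(∇φ/|∇φ|) + [I_BF − (c₁+c₂)/2] } |∇φ|,

   where c₁, c₂ are the interior/exterior mean intensities, recomputed
   every iteration. With all weights fixed at one, the classic CV data
   force factors as 2(c₂−c₁)[I − (c₁+c₂)/2], so this threshold form
   converges to the same partition.
3. **Binary stopping function (BSF)** — on first convergence the
   interior H(φ) (or its complement) is frozen into a {0,1} field κ.
4. **Local phase** — the same update with the data force switched off
   and a unit balloon force ±κ: the contour evolves only where κ = 1 and
   stops exactly at the κ = 0 boundary, so it cannot leak. The direction
   α ∈ {−1 expand, +1 shrink} is inferred automatically from the sign of
   Σφ over the seed boundary.
5. **Regularization** — after every update the field is binarized to ±1
   and diffused once (φ ← φ + 0.2 Δφ), replacing signed-distance
   re-initialization.
6. Convergence is declared when contour length and interior area change
   by at most θ (default 0) for 3 consecutive checks (every 10
   iterations); the run ends at the second convergence, after exactly
   one global→local switch. Accuracy is scored with the Dice coefficient
   DC = 2|A∩B|/(|A|+|B|)·100 %.

No clinical data is required: `acbf.phantom` generates speckled lesion
phantoms with known masks under the additive-transformed speckle model
g = f + h∗w (Gaussian PSF h convolved with white noise w).

## Worked example

```
$ acbf phantom --n 1 --seed 7 --outdir phantoms
wrote 1 phantom(s) to phantoms

$ acbf segment --input phantoms/img_000.png --seeds seeds.json \
      --out preds/mask_000.png --history history.csv
converged after 90 iterations (alpha=-1, area=1285 px)

$ acbf evaluate --pred-dir preds --truth-dir phantoms --out results.csv
DC = 100.00 +/- 0.00 % (n=1)
```

`seeds.json` holds one or more regions in 0-based (row, col) pixel
coordinates, e.g.
`{"seeds": [{"type": "ellipse", "center": [62, 66], "radii": [13.6, 13.6]}]}` —
here a disc inside the lesion, so the run infers expanding mode
(alpha=-1). The history CSV shows the two-phase run: the area grows from
the 577-px seed and stabilizes at 1285 px by iteration 40 (error-length
and error-area hit 0), the run switches to the local phase (alpha
column flips to −1) and converges again with zero errors:

```
iteration,length,area,error_length,error_area,alpha
0,108.0,577.0,,,0
10,142.0,1052.0,34.0,475.0,0
...
40,158.0,1285.0,0.0,0.0,0
...
90,158.0,1285.0,0.0,0.0,-1
```

The final mask matches the generating truth exactly (DC = 100 %). A
small benchmark of the two pipeline arms:

```
$ acbf benchmark --n 5 --seed 1 --out bench.csv
with BF   : DC = 99.98 +/- 0.02 % (n=5)
without BF: DC = 99.97 +/- 0.02 % (n=5)
```

The same functionality is available as a library
(`acbf.run_acbf(image, seeds, config)`; see `docs/methods.md` for the
model and parameter details).

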