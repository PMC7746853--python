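# Methods

## Model

The segmenter is a two-phase hybrid active contour on a binary level set
φ defined on the pixel grid, interior = {φ < 0}, contour = {φ = 0}. One
evolution equation serves both phases:

∂φ/∂t = { div(κ ∇φ/|∇φ|) + (1−|α|)·[I_BF − (c₁+c₂)/2] + α·κ } · |∇φ|

* **Global phase** (α = 0, κ ≡ 1): curvature plus an intensity-threshold
  data force. c₁ and c₂ are the exact mean intensities of interior and
  exterior, recomputed every iteration. The force pushes φ negative
  where the (bilateral-filtered) intensity lies below the running class
  midpoint, so the interior converges onto the darker class — the
  hypoechoic lesion. A `polarity` flag flips the data force for
  hyperechoic (bright) targets.
* **Switch**: at the first convergence the binary stopping function
  κ = H(φ) (expanding) or 1 − H(φ) (shrinking) is frozen, and
  α ∈ {−1, +1} is set by the sign of Σφ over the boundary pixels of the
  original seed region: seed inside the object → expand, seed enclosing
  it → shrink. The switch happens exactly once per run.
* **Local phase** (α = ±1): the data force vanishes and ±κ acts as a
  unit balloon speed confined to the BSF foreground. The total local
  force is gated by the raw binary κ, which realizes the stopping
  semantics exactly: the contour moves where κ = 1 and freezes where
  κ = 0, so it cannot leak past the global segmentation by more than the
  1-px regularization band.

The formal Dirac δ(φ) of the variational derivation is replaced by
|∇φ|; on the binary representation this confines updates to a band of
±1–2 px around the contour. Consequence worth knowing: the data force
has **contour-local support** — a seed placed wholly in homogeneous
background, disjoint from every lesion, cannot discover a lesion and
will collapse. Seeds inside, enclosing, or straddling the target all
work and converge to the same partition.

### Regularization

After every explicit update the field is binarized by sign to ±1 and
diffused once with φ ← φ + 0.2 Δφ (5-point Laplacian, replicate
boundaries). This reaction–diffusion pass replaces signed-distance
re-initialization: it is O(N), never moves a pixel whose 4-neighborhood
is sign-uniform, and erases single-pixel specks. Its side effect is a
flip threshold: after the pass, contour-adjacent values sit at ≈ ±0.6
(straight interface) down to ≈ ±0.2 (corners), and a pixel changes
region only when the next update crosses zero. All time-step reasoning
below follows from this hysteresis.

### Original vs simplified global model

The classic weighted model
∂φ/∂t = [μ·div(∇φ/|∇φ|) + λ₁(I−c₁)² − λ₂(I−c₂)²]·|∇φ| is kept as a
baseline (`cv_step_original`). Note the data-term orientation: under
this package's convention (H = 1 on φ < 0, interior = darker class) the
descent direction is +λ₁(I−c₁)² − λ₂(I−c₂)², which with μ = λ₁ = λ₂ = 1
factors exactly as 2(c₂−c₁)·[I − (c₁+c₂)/2] — a positive multiple of the
simplified force whenever the interior is the darker class. The factor
2(c₂−c₁) only rescales the speed, hence the two models converge to the
same partition (verified to Dice = 100 on the bimodal suite).

## Numerical choices

* **Geometric stencils.** All spatial derivatives are central
  differences on a unit grid with replicate boundaries, with |∇φ|
  floored at 1e−8 inside divisions. Curvature and the unit normal used
  *inside the evolution forces* are evaluated on a Gaussian-presmoothed
  copy of φ (σ = 1.5 px): the regularized field is binary up to a 1-px
  band, and raw stencils there measure the pixel staircase, not the
  contour (disc of radius 18: raw estimate 0.02 ± 0.47 vs true 0.056;
  presmoothed 0.055 ± 0.02). Without presmoothing the staircase noise
  (±0.8) dwarfs the data force (±0.15) and the contour performs a random
  walk. The public `curvature()`/`unit_normal()` default to the raw
  stencil; evolutions pass `smooth=CURVATURE_SIGMA`.
* **Time step dt = 10** for every explicit update. A contour pixel flips
  only when dt·|force|·|∇φ| exceeds its regularized magnitude (~0.6);
  with the half-contrast data force ≥ 0.12 under the default study
  conditions and |∇φ| ≈ 0.8 at the contour, dt = 10 provides a ~50 %
  flip margin while keeping updates confined to the contour band.
  Stability comes from the binarization, not a CFL bound: over- and
  under-shoots are clipped to ±1 every iteration.
* **Divergence term.** div(κ∇φ/|∇φ|) is expanded by the product rule as
  κₛ·curvature + ∇κₛ·n with κₛ a 1-px-Gaussian-smoothed copy of κ (a raw
  binary κ has a distributional gradient). In the local phase the whole
  force is additionally multiplied by the raw binary κ; otherwise the
  smoothed tail of ∇κₛ drags the contour 2–3 px past the stopping
  boundary.
* **Perimeter and area.** Area = ΣH(φ) (φ = 0 counts as interior, so a
  fresh ±1 initialization round-trips exactly). Length = anisotropic
  (L1) total variation of H with forward differences: exactly one unit
  per axis-aligned interface crossing, exactly 4s for an s×s square,
  flip/transpose invariant. Only *differences* of length matter to the
  convergence test, so the orientation bias of the L1 perimeter is
  harmless.
* **Convergence.** |ΔLength| ≤ θ and |ΔArea| ≤ θ (absolute values — the
  signed one-sided form would accept an oscillating contour), sampled
  every 10 iterations, 3 consecutive passes required, θ = 0 by default
  (both quantities are integers on the binary representation). Cap of
  2000 iterations per phase; exhaustion returns the partial result
  flagged non-converged.

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| σₛ | 3.0 | px | bilateral spatial bandwidth; window radius ⌈3σₛ⌉ |
| σᵢ | 0.1 | intensity ([0,1]) | bilateral range bandwidth; ≈ 2× the default speckle sd, ≈ ⅓ of lesion contrast |
| dt | 10 | — | explicit step (see above) |
| θ | 0 | px / px² | convergence tolerance |
| check interval / stable checks | 10 / 3 | iterations / checks | convergence sampling |
| max_iter | 2000 | iterations | per-phase cap |
| polarity | dark | — | hypoechoic vs hyperechoic target |
| rd coefficient | 0.2 | — | fixed scheme constant of the regularization |

## Synthetic phantoms: what they emulate and what they do not

`acbf.phantom` draws hypoechoic lesions (default background 0.55, lesion
0.25 on [0,1]) as rotated ellipses whose polar radius is perturbed by a
truncated Fourier series (harmonics 2–5, amplitude below the smaller
semi-axis), mimicking the irregular margins described by clinical
reporting lexicons. Speckle follows the additive-transformed model
g = f + h∗w with a unit-integral Gaussian PSF (σ = 1.5 px) convolving
zero-mean white noise. The white-noise sd defaults to 0.3, delivering a
correlated speckle field of pixelwise sd ≈ 0.056 — about a fifth of the
lesion contrast, strong enough that raw midpoint thresholding
misclassifies coherent blobs at the boundary while remaining within the
bilateral filter's range bandwidth. An optional smooth inhomogeneity
field is available (off by default).

Dataset jitter (position, size, rotation, margin, contrast) is bounded
so every phantom stays inside the method's **operating envelope**: a
unit-weight curvature penalty imposes the classic scale selection — a
region of radius r is stable only if its boundary data force (≈ half the
contrast) exceeds 1/r. The suite keeps contrast ≥ 0.28 and the smaller
semi-axis ≥ ~14 px, and `seed_inside` starts the contour at 0.8× the
inscribed radius of the truth mask (deepest point of the distance
transform). Clinical lesions in the intended application are far inside
this envelope; phantoms or seeds below it are collapsed by the length
penalty, which is model behavior, not a numerical failure.

Not emulated: physical beamforming (Rayleigh/log-compressed envelope
statistics, depth-dependent attenuation, shadowing), multiplicative
speckle, 3-D geometry, and operator variability in seeding. Passing
tests therefore demonstrate correctness of the algorithm and its stated
properties under the additive speckle model, not clinical-grade accuracy
on real ultrasound.

## Design choices on open points

* φ = 0 is assigned to the interior (H = 1), making area = count(φ ≤ 0)
  unambiguous for ±1 fields.
* The RD Laplacian is the 5-point (4-neighbor) stencil.
* The "boundary of the seed region" used for mode inference is the seed
  mask minus its 4-connected erosion, evaluated in the converged global
  φ; an exactly balanced sum raises an error asking for a clearer seed.
* The BSF is computed once per run; a degenerate BSF (empty or
  full-frame) aborts with a diagnostic rather than silently returning
  the global mask. The local phase never recomputes it.
* All randomness (phantom suites, jitters) flows from explicit integer
  seeds via a counter-based scheme; identical (spec, seed) pairs are
  bit-identical.
* Summaries report the sample (n−1) standard deviation.

## Known limitations

* Seeds or structures below the curvature scale r* ≈ 2/contrast are
  removed by the length penalty (see operating envelope above).
* The data force is contour-local; fully automatic lesion discovery is
  out of scope — a seed per target (or one seed region covering several
  targets' basin) is required, though one shared φ segments multiple
  lesions with topology changes handled implicitly.
* The exact windowed bilateral filter is O(N·(2⌈3σₛ⌉+1)²); fast
  approximations are deliberately not implemented.
* The L1 perimeter over-counts diagonal boundaries by up to √2; use the
  area/Dice outputs for quantitative shape comparison.
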