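"""Synthetic ultrasound-like phantoms with known lesion masks.

Every downstream stage of the pipeline is testable without clinical data:
this module draws hypoechoic (darker-than-background) lesions with
smoothly irregular margins and corrupts the clean piecewise-constant
image with speckle in its additive-transformed form,

    g = f + h * w,

where ``f`` is the clean image, ``w`` zero-mean Gaussian white noise and
``h`` a Gaussian point-spread function applied by convolution.  The PSF
gives the noise the short-range spatial correlation that makes speckle
look granular rather than salt-and-pepper.

Lesion boundaries are ellipses whose polar radius is perturbed by a
truncated Fourier series (harmonics 2..5), which produces the
irregular-margin shapes clinical reporting systems describe without any
extra dependencies.

Determinism contract: identical (spec, seed) pairs produce bit-identical
masks, images and datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

#: harmonics used for the boundary perturbation (low order keeps margins smooth)
_HARMONICS = (2, 3, 4, 5)


class GeometryError(ValueError):
    """Raised when a lesion does not fit strictly inside the image frame."""


class ParameterError(ValueError):
    """Raised for physically meaningless phantom parameters."""


@dataclass(frozen=True)
class LesionSpec:
    """One lesion: a rotated ellipse with a perturbed boundary.

    center : (row, col) in pixels.
    radii : (a, b) semi-axes in pixels, each >= 2.
    perturb_amp : peak boundary perturbation in pixels; must stay below
        the smaller radius so the lesion remains star-shaped.
    rotation : ellipse orientation in radians.
    """

    center: tuple[float, float]
    radii: tuple[float, float]
    perturb_amp: float = 0.0
    rotation: float = 0.0

    def __post_init__(self) -> None:
        if min(self.radii) < 2.0:
            raise ParameterError("lesion radii must be >= 2 px")
        if self.perturb_amp < 0 or self.perturb_amp >= min(self.radii):
            raise ParameterError(
                "perturbation amplitude must be in [0, min radius)"
            )


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom image.

    Defaults emulate a hypoechoic breast/thyroid lesion on a brighter
    tissue background: 128 x 128 frame, background 0.55, lesion 0.25.
    ``noise_sigma`` is the standard deviation of the white-noise field
    *before* PSF convolution; with the default PSF of 1.5 px the
    delivered speckle has a pixelwise standard deviation of about 0.056
    intensity units — roughly a fifth of the lesion/background contrast,
    enough that raw intensity thresholding misclassifies coherent blobs
    at the boundary while remaining within the range bandwidth the
    bilateral filter can average out.
    """

    height: int = 128
    width: int = 128
    lesions: tuple[LesionSpec, ...] = (
        LesionSpec(center=(64.0, 64.0), radii=(20.0, 16.0), perturb_amp=2.0, rotation=0.4),
    )
    background_level: float = 0.55
    lesion_level: float = 0.25
    psf_sigma: float = 1.5
    noise_sigma: float = 0.3
    inhomogeneity_amp: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_level == self.lesion_level:
            raise ParameterError("background and lesion levels must differ")
        for level in (self.background_level, self.lesion_level):
            if not 0.0 <= level <= 1.0:
                raise ParameterError("intensity levels must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ParameterError("noise sigma must be >= 0")
        if self.psf_sigma < 0:
            raise ParameterError("psf sigma must be >= 0")
        if not self.lesions:
            raise ParameterError("a phantom needs at least one lesion")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


def _lesion_mask(lesion: LesionSpec, shape, rng: np.random.Generator) -> np.ndarray:
    """Rasterize one perturbed-ellipse lesion; reject out-of-frame shapes."""
    (cr, cc), (a, b) = lesion.center, lesion.radii
    rmax = max(a, b) + lesion.perturb_amp
    if (
        cr - rmax < 1 or cc - rmax < 1
        or cr + rmax > shape[0] - 2 or cc + rmax > shape[1] - 2
    ):
        raise GeometryError(
            f"lesion at {lesion.center} with reach {rmax:.1f} px exceeds the frame"
        )

    # random harmonic mixture, normalized so the peak perturbation is
    # exactly perturb_amp pixels (measured at the smaller semi-axis)
    amps = rng.uniform(0.3, 1.0, size=len(_HARMONICS))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(_HARMONICS))
    if lesion.perturb_amp > 0:
        amps *= lesion.perturb_amp / amps.sum()
    else:
        amps[:] = 0.0

    rr, cc_grid = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = rr - cr
    dx = cc_grid - cc
    cos_t, sin_t = np.cos(lesion.rotation), np.sin(lesion.rotation)
    u = cos_t * dx + sin_t * dy
    v = -sin_t * dx + cos_t * dy
    rho = np.hypot(u / a, v / b)
    theta = np.arctan2(v, u)
    perturb = np.zeros_like(theta)
    for k, amp, phase in zip(_HARMONICS, amps, phases):
        perturb += amp * np.cos(k * theta + phase)
    return rho <= 1.0 + perturb / min(a, b)


def make_lesion_mask(spec: PhantomSpec) -> np.ndarray:
    """Union of all lesion masks of the spec as a {0,1} uint8 field."""
    mask = np.zeros(spec.shape, dtype=bool)
    for i, lesion in enumerate(spec.lesions):
        rng = np.random.default_rng([abs(int(spec.seed)), 101, i])
        mask |= _lesion_mask(lesion, spec.shape, rng)
    return mask.astype(np.uint8)


def clean_image(mask: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Noise-free image: piecewise-constant levels plus the optional
    smooth intensity-inhomogeneity field."""
    f = np.where(mask > 0, spec.lesion_level, spec.background_level).astype(float)
    if spec.inhomogeneity_amp > 0:
        rng = np.random.default_rng([abs(int(spec.seed)), 211])
        rough = rng.standard_normal(spec.shape)
        smooth = gaussian_filter(rough, sigma=min(spec.shape) / 4.0, mode="nearest")
        peak = np.abs(smooth).max()
        if peak > 0:
            f += spec.inhomogeneity_amp * smooth / peak
    return f


def render_phantom(mask: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Speckled image g = f + (PSF * white noise), clipped to [0, 1]."""
    if mask.shape != spec.shape:
        raise ParameterError("mask shape does not match the spec")
    f = clean_image(mask, spec)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng([abs(int(spec.seed)), 307])
        w = rng.normal(0.0, spec.noise_sigma, size=spec.shape)
        speckle = gaussian_filter(w, sigma=spec.psf_sigma, mode="nearest") if spec.psf_sigma > 0 else w
        g = f + speckle
    else:
        g = f
    return np.clip(g, 0.0, 1.0)


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: (image, truth mask) for one spec."""
    mask = make_lesion_mask(spec)
    return render_phantom(mask, spec), mask


def make_dataset(
    n: int, base_spec: PhantomSpec | None = None, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray, PhantomSpec]]:
    """Reproducible suite of ``n`` phantoms jittered around a base spec.

    Per item, lesion position (+/- 6 % of the frame, at most 8 px),
    semi-axes (-10/+15 %), rotation,
    margin perturbation and the two intensity levels (+/- 0.05 each) are
    drawn from a generator seeded by a fixed counter scheme, so the whole
    dataset is a pure function of (base_spec, seed).

    The jitter bounds keep every phantom inside the operating envelope of
    a unit-weight curvature penalty: the contrast never drops below 0.28
    and the smaller semi-axis never below ~14 px, so the maximum boundary
    curvature of a lesion body stays under half its contrast and the
    length penalty cannot collapse it.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    base = base_spec if base_spec is not None else PhantomSpec()
    out = []
    for i in range(n):
        rng = np.random.default_rng([abs(int(seed)), 401, i])
        shift = min(8.0, 0.06 * min(base.height, base.width))
        jittered_lesions = []
        for lesion in base.lesions:
            center = (
                lesion.center[0] + rng.uniform(-shift, shift),
                lesion.center[1] + rng.uniform(-shift, shift),
            )
            radii = tuple(r * rng.uniform(0.9, 1.15) for r in lesion.radii)
            amp = min(lesion.perturb_amp, 0.4 * min(radii)) * rng.uniform(0.5, 1.5)
            jittered_lesions.append(
                LesionSpec(
                    center=center,
                    radii=radii,
                    perturb_amp=min(amp, 0.8 * min(radii)),
                    rotation=rng.uniform(0.0, np.pi),
                )
            )
        dark = min(base.lesion_level, base.background_level)
        bright = max(base.lesion_level, base.background_level)
        contrast = bright - dark
        lesion_level = dark + rng.uniform(-0.05, 0.05)
        background_level = lesion_level + max(contrast + rng.uniform(-0.05, 0.05), 0.28)
        if base.lesion_level > base.background_level:
            lesion_level, background_level = background_level, lesion_level
        item_seed = (abs(int(seed)) * 100003 + 7919 * i + 13) % (2**31)
        spec = replace(
            base,
            lesions=tuple(jittered_lesions),
            lesion_level=float(np.clip(lesion_level, 0.0, 1.0)),
            background_level=float(np.clip(background_level, 0.0, 1.0)),
            seed=item_seed,
        )
        image, mask = make_phantom(spec)
        out.append((image, mask, spec))
    return out


def seed_inside(mask: np.ndarray, frac: float = 0.8) -> "SeedRegion":
    """Disc seed at the deepest interior point of a truth mask — a
    stand-in for the region a sonographer would draw inside the lesion.

    Centred on the maximum of the interior distance transform with radius
    ``frac`` times that distance, so the seed is guaranteed inside the
    mask and starts the evolution at a low-curvature scale the
    unit-weight length penalty cannot collapse.
    """
    from scipy.ndimage import distance_transform_edt

    from .levelset import SeedRegion

    arr = np.asarray(mask) > 0
    if not arr.any():
        raise GeometryError("cannot seed an empty mask")
    edt = distance_transform_edt(arr)
    cr, cc = np.unravel_index(int(np.argmax(edt)), arr.shape)
    radius = max(3.0, frac * float(edt[cr, cc]))
    return SeedRegion(kind="ellipse", center=(float(cr), float(cc)), extents=(radius, radius))


def seed_enclosing(mask: np.ndarray, margin: float = 8.0) -> "SeedRegion":
    """Elliptical seed that surrounds the truth mask with a margin, the
    'initial contour outside the object' placement of shrinking mode."""
    from scipy.ndimage import center_of_mass

    from .levelset import SeedRegion

    arr = np.asarray(mask) > 0
    if not arr.any():
        raise GeometryError("cannot seed an empty mask")
    cr, cc = center_of_mass(arr)
    rows, cols = np.nonzero(arr)
    reach_r = float(np.abs(rows - cr).max()) + margin
    reach_c = float(np.abs(cols - cc).max()) + margin
    h, w = arr.shape
    reach_r = min(reach_r, cr - 1.0, h - 2.0 - cr)
    reach_c = min(reach_c, cc - 1.0, w - 2.0 - cc)
    if reach_r <= 0 or reach_c <= 0:
        raise GeometryError("mask leaves no room for an enclosing seed")
    return SeedRegion(
        kind="ellipse", center=(float(cr), float(cc)), extents=(reach_r, reach_c)
    )
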