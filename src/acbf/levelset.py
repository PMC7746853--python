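"""Binary level-set primitives shared by every contour evolution.

The contour is carried implicitly by a scalar field ``phi`` with a single
global sign convention: ``phi < 0`` inside the contour, ``phi > 0``
outside, ``phi = 0`` on the contour itself.  Between evolution steps the
field is kept essentially binary (+/-1) by a reaction-diffusion
regularization pass (sign binarization followed by one small explicit
diffusion step) instead of signed-distance re-initialization.  This keeps
every step O(N) on the pixel grid and avoids the contour drift that
re-initialization schemes introduce.

All spatial derivatives use central differences on a unit grid with
replicate (Neumann) boundary handling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: floor applied to |grad phi| wherever it appears in a denominator
GRAD_EPS = 1e-8

#: diffusion coefficient of the reaction-diffusion regularization step
RD_COEFF = 0.2

#: Gaussian pre-smoothing applied to phi before geometric stencils
#: (curvature, unit normal) inside the evolution equations.  The
#: regularized field is binary up to a one-pixel transition band, so raw
#: central differences see only the staircase of the pixel grid: on a
#: disc of radius 18 the raw curvature estimate is 0.02 +/- 0.47 whereas
#: the true value is 0.056.  Smoothing with sigma = 1.5 px recovers
#: 0.055 +/- 0.02 while still resolving radii of a few pixels, keeping
#: the curvature force subordinate to the data force at real boundaries.
CURVATURE_SIGMA = 1.5


class SeedError(ValueError):
    """Raised for empty, degenerate or unusable seed regions."""


@dataclass(frozen=True)
class SeedRegion:
    """Rectangular or elliptical initial region (the user-drawn seed C0).

    Coordinates are (row, col), 0-based, origin at the top-left pixel.
    For ``kind="rect"`` the ``extents`` are half-heights/half-widths so a
    seed with extents (a, b) covers a 2a x 2b pixel block; for
    ``kind="ellipse"`` they are the two radii.
    """

    kind: str
    center: tuple[float, float]
    extents: tuple[float, float]

    def __post_init__(self) -> None:
        if self.kind not in ("rect", "ellipse"):
            raise SeedError(f"unknown seed kind {self.kind!r}")
        if len(self.center) != 2 or len(self.extents) != 2:
            raise SeedError("center and extents must be (row, col) pairs")
        if min(self.extents) <= 0:
            raise SeedError("seed extents must be positive")

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize the region as a boolean mask on the given grid."""
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        (cr, cx), (a, b) = self.center, self.extents
        if self.kind == "rect":
            inside = (rr >= cr - a) & (rr < cr + a) & (cc >= cx - b) & (cc < cx + b)
        else:
            inside = ((rr - cr) / a) ** 2 + ((cc - cx) / b) ** 2 <= 1.0
        if not inside.any():
            raise SeedError("seed region does not cover any pixel of the frame")
        return inside


def seeds_to_mask(seeds, shape) -> np.ndarray:
    """Union of all seed regions as a boolean mask."""
    if not seeds:
        raise SeedError("at least one seed region is required")
    mask = np.zeros(shape, dtype=bool)
    for seed in seeds:
        mask |= seed.to_mask(shape)
    return mask


def init_level_set(seeds, shape) -> np.ndarray:
    """Binary initial level set: -1 on the union of seeds, +1 elsewhere.

    Several disjoint seeds may be given to segment multiple lesions under
    one shared level-set field (topology changes are handled implicitly).
    """
    mask = seeds_to_mask(seeds, shape)
    return np.where(mask, -1.0, 1.0)


def gradient(field: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient (d/drow, d/dcol), replicate boundaries."""
    p = np.pad(field, 1, mode="edge")
    gr = 0.5 * (p[2:, 1:-1] - p[:-2, 1:-1])
    gc = 0.5 * (p[1:-1, 2:] - p[1:-1, :-2])
    return gr, gc


def grad_norm(field: np.ndarray) -> np.ndarray:
    """Pointwise Euclidean norm of the central-difference gradient."""
    gr, gc = gradient(field)
    return np.hypot(gr, gc)


def heaviside(phi: np.ndarray) -> np.ndarray:
    """Indicator of the interior: 1 where phi <= 0, else 0.

    The contour itself (phi = 0) is assigned to the interior so that a
    freshly initialized field (values exactly -1/+1) and its region area
    behave consistently.
    """
    return np.where(np.asarray(phi) <= 0, 1.0, 0.0)


def _presmooth(phi: np.ndarray, smooth: float) -> np.ndarray:
    if smooth <= 0:
        return np.asarray(phi, dtype=float)
    from scipy.ndimage import gaussian_filter

    return gaussian_filter(np.asarray(phi, dtype=float), smooth, mode="nearest")


def unit_normal(phi: np.ndarray, smooth: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """grad(phi)/|grad(phi)| with the global magnitude floor.

    ``smooth`` applies a Gaussian of that sigma to phi before the
    stencil; evolution steps pass CURVATURE_SIGMA so the normal reflects
    the contour rather than the pixel staircase.
    """
    gr, gc = gradient(_presmooth(phi, smooth))
    mag = np.maximum(np.hypot(gr, gc), GRAD_EPS)
    return gr / mag, gc / mag


def curvature(phi: np.ndarray, smooth: float = 0.0) -> np.ndarray:
    """div(grad(phi)/|grad(phi)|), the mean-curvature term.

    Finite everywhere: the gradient magnitude is floored at GRAD_EPS, so
    flat plateaus of the binary field simply contribute zero.  See
    ``unit_normal`` for the meaning of ``smooth``.
    """
    nr, nc = unit_normal(phi, smooth)
    dnr_r, _ = gradient(nr)
    _, dnc_c = gradient(nc)
    return dnr_r + dnc_c


def contour_length(phi: np.ndarray) -> float:
    """Discrete perimeter of the zero set: sum of |grad H(phi)|.

    The gradient of the binary indicator is taken with forward
    differences (replicate boundary) and summed in the anisotropic
    (L1) sense, which counts exactly one unit per axis-aligned interface
    crossing: an axis-aligned square of side s measures exactly 4s, a
    disc of radius r about 8r.  Only differences of this length matter to
    the convergence criterion, so the grid-orientation bias of the L1
    perimeter is harmless and buys exact flip/transpose invariance.
    """
    h = heaviside(phi)
    p = np.pad(h, ((0, 1), (0, 1)), mode="edge")
    dr = p[1:, :-1] - h
    dc = p[:-1, 1:] - h
    return float(np.abs(dr).sum() + np.abs(dc).sum())


def region_area(phi: np.ndarray) -> float:
    """Interior area in pixels: sum of H(phi)."""
    return float(heaviside(phi).sum())


def laplacian(field: np.ndarray) -> np.ndarray:
    """5-point discrete Laplacian with replicate boundaries."""
    p = np.pad(field, 1, mode="edge")
    return (
        p[2:, 1:-1] + p[:-2, 1:-1] + p[1:-1, 2:] + p[1:-1, :-2] - 4.0 * field
    )


def rd_regularize(phi: np.ndarray, coeff: float = RD_COEFF) -> np.ndarray:
    """Reaction-diffusion regularization of a level-set field.

    Binarize by sign (phi > 0 -> +1, else -1), then apply one explicit
    diffusion step ``phi + coeff * laplacian(phi)``.  A pixel whose
    4-neighborhood shares its sign is never flipped (its Laplacian is
    zero), so large uniform regions are left untouched while single-pixel
    specks and staircase roughness are smoothed away.
    """
    b = np.where(np.asarray(phi) > 0, 1.0, -1.0)
    return b + coeff * laplacian(b)
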