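"""Hybrid global-to-local active contour evolution (the ACBF model).

One evolution equation serves both phases:

    d(phi)/dt = { div(kappa * grad(phi)/|grad(phi)|)
                  + (1 - |alpha|) * [I_BF - (c1 + c2)/2]
                  + alpha * kappa } * |grad phi|

* Global phase (alpha = 0, kappa = 1): the divergence term reduces to
  plain curvature and the threshold data force drives a region-based
  two-phase clustering of the bilateral-filtered image — identical,
  term by term, to the simplified global model.
* Switch: on first convergence the interior is frozen into the binary
  stopping function (BSF) kappa, and alpha is set from the position of
  the original seed relative to the converged contour (-1 expanding if
  the seed lies inside the object, +1 shrinking if it encloses it).
* Local phase (alpha = +/-1): the data force vanishes and +/- kappa acts
  as a unit-speed balloon force confined to the BSF foreground, a
  geodesic-style motion whose stopping field is binary and therefore
  leak-proof: the contour can move only where kappa = 1.

The run converges when contour length and interior area are stationary a
second time; exactly one alpha transition occurs per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter

from .bilateral import bilateral_filter
from .config import AcbfConfig
from .convergence import History, check_convergence
from .cv_global import (
    DegenerateRegionError,
    make_bsf,
    region_means,
    threshold_force,
)
from .levelset import (
    CURVATURE_SIGMA,
    contour_length,
    curvature,
    grad_norm,
    gradient,
    heaviside,
    init_level_set,
    rd_regularize,
    region_area,
    seeds_to_mask,
    unit_normal,
)

#: Gaussian sigma used to pre-smooth the binary BSF before taking its
#: gradient in the divergence term (a raw binary field has no meaningful
#: pointwise gradient at its edge).
KAPPA_SMOOTH_SIGMA = 1.0


class AmbiguousModeError(ValueError):
    """Raised when the seed boundary straddles the converged contour so
    evenly that the expanding/shrinking mode cannot be decided."""


def esf_g(image: np.ndarray, kernel_size: int = 7, sigma: float = 1.5) -> np.ndarray:
    """Conventional edge-stopping function g = 1 / (1 + |grad(G_sigma * I)|^2).

    Values lie in (0, 1]: exactly 1 on flat regions, smaller at sharper
    edges.  Kept as the baseline stopping field of the classic geodesic
    model; the hybrid pipeline replaces it with the BSF.
    """
    if kernel_size % 2 == 0:
        raise ValueError("kernel size must be odd")
    img = np.asarray(image, dtype=float)
    if sigma > 0:
        truncate = ((kernel_size - 1) / 2) / sigma
        smoothed = gaussian_filter(img, sigma=sigma, truncate=truncate, mode="nearest")
    else:
        smoothed = img
    return 1.0 / (1.0 + grad_norm(smoothed) ** 2)


def gac_step(
    image: np.ndarray,
    phi: np.ndarray,
    stopping: np.ndarray,
    v: float,
    dt: float = 10.0,
) -> np.ndarray:
    """One explicit geodesic active-contour update, then regularization.

    d(phi)/dt = [ div(g * grad(phi)/|grad(phi)|) + v * g ] * |grad phi|

    with the divergence expanded by the product rule as
    g * curvature + grad(g) . n.  The balloon speed v is negative for an
    expanding contour and positive for a shrinking one.
    """
    if v == 0:
        raise ValueError("balloon speed v must be nonzero")
    g = np.asarray(stopping, dtype=float)
    if (g < 0).any():
        raise ValueError("stopping field must be nonnegative")
    nr, nc = unit_normal(phi, smooth=CURVATURE_SIGMA)
    g_r, g_c = gradient(g)
    force = g * curvature(phi, smooth=CURVATURE_SIGMA) + g_r * nr + g_c * nc + v * g
    return rd_regularize(phi + dt * force * grad_norm(phi))


def infer_alpha(phi_global: np.ndarray, seeds) -> int:
    """Deformation mode from the seed boundary in the converged field.

    Sums the converged phi over the boundary pixels of the original seed
    region(s): a negative sum means the seed boundary lies inside the
    segmented object (expand, alpha = -1); positive means it lies outside
    (shrink, alpha = +1).
    """
    mask = seeds_to_mask(seeds, np.asarray(phi_global).shape)
    interior = binary_erosion(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    boundary = mask & ~interior
    total = float(np.asarray(phi_global)[boundary].sum())
    if total < 0:
        return -1
    if total > 0:
        return +1
    raise AmbiguousModeError(
        "seed boundary is evenly split across the converged contour; "
        "choose a seed clearly inside or clearly enclosing the target"
    )


@dataclass
class EvolutionState:
    """Mutable record of one hybrid run.

    ``kappa`` stays all-ones exactly while alpha = 0 (global phase) and
    becomes the BSF at the single global-to-local transition.
    """

    phi: np.ndarray
    kappa: np.ndarray
    alpha: int = 0
    iteration: int = 0
    history: History = dataclass_field(default_factory=History)
    polarity: int = 1
    kappa_smooth: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kappa_smooth is None:
            self.kappa_smooth = np.asarray(self.kappa, dtype=float)

    def set_bsf(self, kappa: np.ndarray, alpha: int) -> None:
        if self.alpha != 0:
            raise ValueError("the global-to-local switch may happen only once")
        self.kappa = kappa
        self.kappa_smooth = gaussian_filter(
            kappa.astype(float), KAPPA_SMOOTH_SIGMA, mode="nearest"
        )
        self.alpha = int(alpha)


def acbf_rhs(image_bf: np.ndarray, state: EvolutionState) -> np.ndarray:
    """Right-hand side of the hybrid evolution (before the |grad phi| factor)."""
    phi = state.phi
    ks = state.kappa_smooth
    nr, nc = unit_normal(phi, smooth=CURVATURE_SIGMA)
    k_r, k_c = gradient(ks)
    force = ks * curvature(phi, smooth=CURVATURE_SIGMA) + k_r * nr + k_c * nc
    if state.alpha == 0:
        means = region_means(image_bf, phi)
        force = force + threshold_force(image_bf, means, state.polarity)
    else:
        # local phase: the contour evolves where kappa = 1 and stops where
        # kappa = 0, so the total speed is gated by the raw binary BSF;
        # the smoothed kappa of the divergence term would otherwise bleed
        # a gradient tail a few pixels past the stopping boundary.
        force = np.asarray(state.kappa, dtype=float) * (force + state.alpha)
    return force


def acbf_step(image_bf: np.ndarray, state: EvolutionState, dt: float = 10.0) -> EvolutionState:
    """One explicit hybrid update followed by regularization (in place)."""
    force = acbf_rhs(image_bf, state)
    state.phi = rd_regularize(state.phi + dt * force * grad_norm(state.phi))
    state.iteration += 1
    return state


def run_acbf(
    image: np.ndarray,
    seeds,
    config: AcbfConfig | None = None,
) -> tuple[np.ndarray, EvolutionState]:
    """Full pipeline: filter, global evolution, BSF switch, local evolution.

    Returns the final interior mask H(phi) as a {0,1} uint8 field and the
    complete evolution state.  If either phase exhausts ``max_iter``
    without meeting the convergence criterion the partial result is
    returned with ``state.history.converged = False``; a degenerate BSF
    (empty or full frame) aborts the local phase with an error instead of
    silently returning the global mask.
    """
    config = config or AcbfConfig()
    img = np.asarray(image, dtype=float)
    ibf = bilateral_filter(img, config.bilateral_params) if config.use_bf else img

    phi = init_level_set(seeds, ibf.shape)
    state = EvolutionState(
        phi=phi,
        kappa=np.ones(ibf.shape, dtype=np.uint8),
        alpha=0,
        polarity=config.polarity_sign,
    )
    conv = config.convergence_params
    state.history.append(0, contour_length(phi), region_area(phi), alpha=0)

    phase_iter = 0
    rows_in_phase = 0  # samples recorded since the current phase began
    while True:
        acbf_step(ibf, state, config.dt)
        phase_iter += 1
        if phase_iter % conv.check_interval == 0:
            state.history.append(
                state.iteration,
                contour_length(state.phi),
                region_area(state.phi),
                alpha=state.alpha,
            )
            rows_in_phase += 1
            if rows_in_phase >= conv.stable_checks and check_convergence(
                state.history, conv
            ):
                if state.alpha == 0:
                    alpha = infer_alpha(state.phi, seeds)
                    mode = "expanding" if alpha == -1 else "shrinking"
                    kappa = make_bsf(state.phi, mode)
                    if kappa.all():
                        raise DegenerateRegionError(
                            "binary stopping function covers the whole frame; "
                            "the global phase found no object boundary"
                        )
                    state.set_bsf(kappa, alpha)
                    phase_iter = 0
                    rows_in_phase = 0
                else:
                    state.history.converged = True
                    break
        if phase_iter >= config.max_iter:
            state.history.converged = False
            break

    mask = heaviside(state.phi).astype(np.uint8)
    return mask, state
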