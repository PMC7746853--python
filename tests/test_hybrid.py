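import numpy as np
import pytest
from scipy.ndimage import binary_dilation

from acbf.config import AcbfConfig
from acbf.convergence import ConvergenceParams, History, check_convergence
from acbf.cv_global import CvParams, cv_step_simplified
from acbf.evaluate import dice
from acbf.hybrid import (
    AmbiguousModeError,
    EvolutionState,
    acbf_rhs,
    acbf_step,
    esf_g,
    gac_step,
    infer_alpha,
    run_acbf,
)
from acbf.levelset import SeedRegion, heaviside, init_level_set, rd_regularize, region_area
from acbf.phantom import seed_enclosing, seed_inside


def random_state(rng, shape=(16, 16)):
    """Random near-binary level set with both phases present."""
    phi = np.where(rng.random(shape) < 0.4, -1.0, 1.0)
    phi[0, 0], phi[-1, -1] = -1.0, 1.0
    return rd_regularize(phi)


class TestEsf:
    def test_constant_image_gives_one(self):
        assert (esf_g(np.full((16, 16), 0.7)) == 1.0).all()

    def test_sharper_edge_gives_smaller_g(self):
        soft = np.tile(np.linspace(0, 0.3, 32), (32, 1))
        hard = np.zeros((32, 32))
        hard[:, 16:] = 0.3
        assert esf_g(hard)[16, 16] < esf_g(soft)[16, 16]

    def test_ramp_closed_form(self):
        slope = 0.3
        img = slope * np.arange(32)[None, :] * np.ones((32, 1))
        g = esf_g(img, kernel_size=3, sigma=0.05)
        assert np.allclose(g[8:-8, 8:-8], 1.0 / (1.0 + slope**2), atol=1e-6)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            esf_g(np.zeros((8, 8)), kernel_size=4)


class TestGacStep:
    def test_zero_stopping_field_freezes_evolution(self, rng):
        phi = random_state(rng)
        out = gac_step(np.zeros((16, 16)), phi, np.zeros((16, 16)), v=-1.0)
        assert np.array_equal(out, rd_regularize(phi))

    def test_expanding_balloon_grows_interior(self):
        phi = init_level_set([SeedRegion("ellipse", (32.0, 32.0), (6.0, 6.0))], (64, 64))
        area0 = region_area(phi)
        for _ in range(10):
            phi = gac_step(np.zeros((64, 64)), phi, np.ones((64, 64)), v=-1.0)
        assert region_area(phi) > area0

    def test_binary_stopping_field_confines_contour(self):
        rr, cc = np.mgrid[0:64, 0:64]
        kappa = (np.hypot(rr - 32, cc - 32) <= 15).astype(np.uint8)
        phi = init_level_set([SeedRegion("ellipse", (32.0, 32.0), (5.0, 5.0))], (64, 64))
        for _ in range(150):
            phi = gac_step(np.zeros((64, 64)), phi, kappa, v=-1.0)
        interior = heaviside(phi).astype(bool)
        assert not (interior & ~binary_dilation(kappa.astype(bool))).any()

    def test_invalid_arguments_rejected(self, rng):
        phi = random_state(rng)
        with pytest.raises(ValueError):
            gac_step(np.zeros((16, 16)), phi, np.ones((16, 16)), v=0.0)
        with pytest.raises(ValueError):
            gac_step(np.zeros((16, 16)), phi, -np.ones((16, 16)), v=1.0)


class TestInferAlpha:
    def setup_method(self):
        rr, cc = np.mgrid[0:32, 0:32]
        self.phi = np.where(np.hypot(rr - 16, cc - 16) <= 10, -1.0, 1.0)

    def test_seed_inside_object_expands(self):
        assert infer_alpha(self.phi, [SeedRegion("ellipse", (16.0, 16.0), (4.0, 4.0))]) == -1

    def test_seed_enclosing_object_shrinks(self):
        assert infer_alpha(self.phi, [SeedRegion("ellipse", (16.0, 16.0), (14.0, 14.0))]) == +1

    def test_balanced_boundary_is_ambiguous(self):
        phi = np.where(np.arange(16)[None, :] < 8, -1.0, 1.0) * np.ones((16, 16))
        seed = SeedRegion("rect", (8.0, 8.0), (2.0, 2.0))  # straddles the interface evenly
        with pytest.raises(AmbiguousModeError):
            infer_alpha(phi, [seed])


class TestAcbfStep:
    def test_global_phase_equals_simplified_cv_step(self, rng):
        image = rng.random((16, 16))
        for _ in range(10):
            phi = random_state(rng)
            state = EvolutionState(phi=phi.copy(), kappa=np.ones((16, 16), np.uint8))
            acbf_step(image, state, dt=10.0)
            expected = cv_step_simplified(image, phi, CvParams(dt=10.0))
            assert np.abs(state.phi - expected).max() <= 1e-12

    def test_local_phase_ignores_image_intensities(self, rng):
        phi = random_state(rng)
        kappa = (rng.random((16, 16)) < 0.5).astype(np.uint8)
        state = EvolutionState(phi=phi, kappa=np.ones((16, 16), np.uint8))
        state.set_bsf(kappa, alpha=-1)
        rhs_a = acbf_rhs(rng.random((16, 16)), state)
        rhs_b = acbf_rhs(rng.random((16, 16)), state)
        assert np.array_equal(rhs_a, rhs_b)

    def test_zero_kappa_region_has_zero_force(self, rng):
        phi = random_state(rng)
        state = EvolutionState(phi=phi, kappa=np.ones((16, 16), np.uint8))
        state.set_bsf(np.zeros((16, 16), np.uint8), alpha=+1)
        assert (acbf_rhs(rng.random((16, 16)), state) == 0).all()

    def test_switch_may_happen_only_once(self):
        state = EvolutionState(phi=-np.ones((8, 8)), kappa=np.ones((8, 8), np.uint8))
        state.set_bsf(np.ones((8, 8), np.uint8), alpha=-1)
        with pytest.raises(ValueError):
            state.set_bsf(np.ones((8, 8), np.uint8), alpha=+1)


class TestCheckConvergence:
    @staticmethod
    def history_from(rows):
        h = History()
        for i, (length, area) in enumerate(rows):
            h.append(10 * i, length, area, alpha=0)
        return h

    def test_two_identical_rows_converge_at_zero_tolerance(self):
        h = self.history_from([(40.0, 100.0), (40.0, 100.0)])
        assert check_convergence(h, ConvergenceParams(theta=0.0, stable_checks=1))

    def test_changing_area_not_converged(self):
        h = self.history_from([(40.0, 100.0), (40.0, 105.0)])
        assert not check_convergence(h, ConvergenceParams(theta=0.0, stable_checks=1))

    def test_threshold_arithmetic_with_two_stable_checks(self):
        h = self.history_from([(40.0, 100.0), (40.0, 107.0), (40.0, 110.0)])
        assert check_convergence(h, ConvergenceParams(theta=10.0, stable_checks=2))
        assert not check_convergence(h, ConvergenceParams(theta=5.0, stable_checks=2))

    def test_first_row_never_counts(self):
        h = self.history_from([(40.0, 100.0)])
        assert not check_convergence(h, ConvergenceParams(theta=1e9, stable_checks=1))


class TestRunAcbf:
    def test_noiseless_phantom_recovers_truth(self, noiseless_phantom):
        image, mask, _ = noiseless_phantom
        pred, state = run_acbf(image, [seed_inside(mask)])
        assert state.history.converged
        assert dice(pred, mask) >= 99.0

    def test_final_interior_confined_to_bsf(self, speckled_phantom):
        image, mask, _ = speckled_phantom
        pred, state = run_acbf(image, [seed_inside(mask)])
        assert not (pred.astype(bool) & ~binary_dilation(state.kappa.astype(bool))).any()

    def test_single_alpha_switch_and_zero_final_errors(self, speckled_phantom):
        image, mask, _ = speckled_phantom
        _, state = run_acbf(image, [seed_inside(mask)])
        alphas = [r.alpha for r in state.history.rows]
        assert sum(1 for a, b in zip(alphas, alphas[1:]) if a != b) == 1
        assert alphas[0] == 0 and alphas[-1] in (-1, 1)
        last = state.history.rows[-1]
        assert abs(last.error_length) <= 0 and abs(last.error_area) <= 0

    def test_expanding_mode_area_monotone_non_decreasing(self, speckled_phantom):
        image, mask, _ = speckled_phantom
        _, state = run_acbf(image, [seed_inside(mask)])
        assert state.alpha == -1
        local = [r.area for r in state.history.rows if r.alpha != 0]
        assert all(a <= b for a, b in zip(local, local[1:]))

    def test_shrinking_mode_area_monotone_non_increasing(self, speckled_phantom):
        image, mask, _ = speckled_phantom
        pred, state = run_acbf(image, [seed_enclosing(mask)])
        assert state.alpha == +1
        local = [r.area for r in state.history.rows if r.alpha != 0]
        assert all(a >= b for a, b in zip(local, local[1:]))
        assert dice(pred, mask) >= 95.0

    def test_non_convergence_flagged(self, speckled_phantom):
        image, mask, _ = speckled_phantom
        import dataclasses

        cfg = dataclasses.replace(AcbfConfig(), max_iter=5)
        _, state = run_acbf(image, [seed_inside(mask)], cfg)
        assert not state.history.converged
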