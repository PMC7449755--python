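"""Spatially variant Richardson-Lucy iteration and its shift-invariant limit."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.signal import fftconvolve

from svmpsf import (
    DeconvConfig,
    EigenPSFModel,
    IterationState,
    deconvolve,
    flip_psf,
    forward_convolve,
    generate_bead_phantom,
    make_ground_truth_field,
    render_observed_image,
    rl_step,
    tv_factor,
)


def _uniform_model(kernel: np.ndarray, shape: tuple[int, int]) -> EigenPSFModel:
    """A single-mode model with a spatially constant coefficient map."""
    positions = np.array(
        [[r, c] for r in np.linspace(8, shape[0] - 9, 4)
         for c in np.linspace(8, shape[1] - 9, 4)]
    )
    return EigenPSFModel(
        eigen_psfs=kernel[None].astype(float),
        eigenvalues=np.array([1.0]),
        coeff_samples=np.ones((1, 16)),
        coeff_maps=np.ones((1, *shape)),
        positions=positions,
        crop_size=kernel.shape[0],
    )


def _gaussian_kernel(sigma: float, half: int = 7) -> np.ndarray:
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    k = np.exp(-(x**2 + y**2) / (2 * sigma**2))
    return k / k.sum()


def _delta_kernel(size: int = 15) -> np.ndarray:
    k = np.zeros((size, size))
    k[size // 2, size // 2] = 1.0
    return k


class TestTvFactor:
    def test_constant_image_gives_unity(self):
        np.testing.assert_array_equal(tv_factor(np.full((8, 8), 3.7), 0.02), 1.0)

    def test_zero_lambda_gives_unity(self, rng):
        S = rng.uniform(size=(8, 8))
        np.testing.assert_array_equal(tv_factor(S, 0.0), 1.0)

    def test_nan_input_rejected(self):
        S = np.ones((4, 4))
        S[1, 1] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            tv_factor(S, 0.002)

    def test_matches_finite_difference_oracle(self):
        """Loop-coded forward-gradient / backward-divergence evaluation of
        1/(1 - lambda*div(grad S/|grad S|)) on a ramp-plus-step image."""
        S = np.add.outer(np.arange(5.0), np.zeros(5))
        S[:, 3:] += 4.0
        lam, floor = 0.01, 1e-8 * S.max()
        gr = np.zeros_like(S)
        gc = np.zeros_like(S)
        for i in range(4):
            gr[i, :] = S[i + 1, :] - S[i, :]
        for j in range(4):
            gc[:, j] = S[:, j + 1] - S[:, j]
        mag = np.maximum(np.sqrt(gr**2 + gc**2), floor)
        nr, nc = gr / mag, gc / mag
        div = np.zeros_like(S)
        for i in range(5):
            for j in range(5):
                div[i, j] = (nr[i, j] - (nr[i - 1, j] if i > 0 else 0.0)
                             + nc[i, j] - (nc[i, j - 1] if j > 0 else 0.0))
        expected = 1.0 / (1.0 - lam * div)
        np.testing.assert_allclose(tv_factor(S, lam), expected, atol=1e-10)


class TestFlipPsf:
    def test_symmetric_gaussian_unchanged(self):
        g = _gaussian_kernel(2.0)
        np.testing.assert_array_equal(flip_psf(g), g)

    def test_offset_impulse_reflects_through_center(self):
        p = np.zeros((5, 5))
        p[2 + 1, 2] = 1.0
        assert flip_psf(p)[2 - 1, 2] == 1.0

    @given(seed=st.integers(0, 10_000))
    def test_involution(self, seed):
        p = np.random.default_rng(seed).normal(size=(9, 9))
        np.testing.assert_array_equal(flip_psf(flip_psf(p)), p)


class TestRlStep:
    def test_delta_psf_fixed_point(self, rng):
        """With a delta kernel, uniform coefficients and no TV, any
        nonnegative estimate reproducing the data is exactly invariant."""
        shape = (32, 32)
        model = _uniform_model(_delta_kernel(), shape)
        I = rng.uniform(0.1, 1.0, shape)
        cfg = DeconvConfig(iterations=1, n_modes=1, lambda_tv=0.0,
                           post_filter_sigma=0.0)
        state = rl_step(I, IterationState(S=I.copy()), model, cfg)
        np.testing.assert_allclose(state.S, I, atol=1e-13)
        assert state.k == 1

    def test_matches_textbook_richardson_lucy(self, rng):
        """Single uniform mode, no TV: the update must equal independently
        coded standard RL over 100 iterations on a 64x64 case."""
        shape = (64, 64)
        kernel = _gaussian_kernel(2.0)
        model = _uniform_model(kernel, shape)
        S_true = rng.uniform(0.1, 1.0, shape)
        I = fftconvolve(S_true, kernel, mode="same")
        cfg = DeconvConfig(iterations=1, n_modes=1, lambda_tv=0.0,
                           post_filter_sigma=0.0)
        flipped = kernel[::-1, ::-1]
        state = IterationState(S=I.copy())
        T = I.copy()
        for _ in range(100):
            state = rl_step(I, state, model, cfg)
            T = T * fftconvolve(I / fftconvolve(T, kernel, mode="same"),
                                flipped, mode="same")
        assert np.abs(state.S - T).max() < 1e-8

    def test_residual_nonincreasing_on_model_generated_data(self, model, rng):
        """Noiseless data from the model itself: the data-fit residual of
        the iterates must not increase over the first 50 iterations.

        The multiplicative update (like the original scheme) carries no
        ML-EM sensitivity normalization, so monotone data fit holds where
        the forward operator conserves flux: the eigen-PSF kernels are
        rescaled to unit local flux and the source is kept away from the
        frame border, where zero-padding truncates the blur.
        """
        from scipy import ndimage

        from svmpsf import EigenPSFModel

        shape = model.frame_shape
        kernel_sums = model.eigen_psfs.sum(axis=(1, 2))
        kappa = np.tensordot(kernel_sums, model.coeff_maps, axes=(0, 0))
        normalized = EigenPSFModel(
            eigen_psfs=model.eigen_psfs,
            eigenvalues=model.eigenvalues,
            coeff_samples=model.coeff_samples,
            coeff_maps=model.coeff_maps / kappa[None],
            positions=model.positions,
            crop_size=model.crop_size,
        )
        source = np.zeros(shape)
        source[20:100, 20:100] = (
            ndimage.gaussian_filter(rng.uniform(0.0, 1.0, (80, 80)), 3.0) + 0.05
        )
        I = np.clip(forward_convolve(source, normalized, 30), 0, None)
        cfg = DeconvConfig(iterations=1, n_modes=30, lambda_tv=0.0,
                           post_filter_sigma=0.0)
        state = IterationState(S=I.copy())
        residuals = []
        for _ in range(50):
            state = rl_step(I, state, normalized, cfg)
            residuals.append(
                np.linalg.norm(forward_convolve(state.S, normalized, 30) - I)
            )
        assert (np.diff(residuals) <= 1e-9 * residuals[0]).all()

    def test_nonnegativity_preserved(self, rng):
        shape = (48, 48)
        model = _uniform_model(_gaussian_kernel(1.5), shape)
        I = rng.uniform(0.0, 1.0, shape)
        cfg = DeconvConfig(iterations=1, n_modes=1, lambda_tv=0.02,
                           post_filter_sigma=0.0)
        state = IterationState(S=I.copy())
        for _ in range(20):
            state = rl_step(I, state, model, cfg)
            assert state.S.min() >= 0
            assert np.isfinite(state.S).all()

    def test_zero_estimate_warns(self):
        shape = (32, 32)
        model = _uniform_model(_delta_kernel(), shape)
        cfg = DeconvConfig(n_modes=1)
        with pytest.warns(UserWarning, match="fixed point"):
            rl_step(np.ones(shape), IterationState(S=np.zeros(shape)), model, cfg)

    def test_negative_observation_rejected(self):
        shape = (32, 32)
        model = _uniform_model(_delta_kernel(), shape)
        I = -np.ones(shape)
        with pytest.raises(ValueError, match="negative"):
            rl_step(I, IterationState(S=np.ones(shape)), model,
                    DeconvConfig(n_modes=1))


class TestDeconvolve:
    def test_zero_iterations_no_filter_returns_input(self, model, rng):
        I = rng.uniform(0.0, 1.0, model.frame_shape)
        cfg = DeconvConfig(iterations=0, n_modes=30, post_filter_sigma=0.0)
        result = deconvolve(I, model, cfg)
        np.testing.assert_array_equal(result.image, I)
        assert len(result.diagnostics) == 0

    def test_too_many_modes_rejected(self, model):
        cfg = DeconvConfig(iterations=1, n_modes=500)
        with pytest.raises(ValueError, match="225"):
            deconvolve(np.ones(model.frame_shape), model, cfg)

    def test_bead_positions_recovered(self, default_spec, model):
        """Deconvolved bead positions (intensity centroid of the response)
        match the phantom's ground truth.

        The default geometry emulates the NA-0.22 fiber, whose PSF is 3-7x
        wider than a 1-um bead; beads are then effective point sources and
        prolonged Richardson-Lucy develops the usual sub-pixel spike
        splitting, so the truthful localization bound is ~1.5 px worst-case
        with sub-pixel accuracy on average.
        """
        # resolvable beads: separation well beyond the broadest local PSF
        phantom, centers = generate_bead_phantom(default_spec, 10,
                                                 min_separation=12.0)
        field = make_ground_truth_field(default_spec)
        observed = render_observed_image(phantom, field)
        cfg = DeconvConfig(iterations=150, n_modes=30)
        result = deconvolve(observed, model, cfg)
        errors = []
        for r, c in centers:
            ri, ci = int(round(r)), int(round(c))
            win = result.image[ri - 4 : ri + 5, ci - 4 : ci + 5]
            gr, gc = np.mgrid[ri - 4 : ri + 5, ci - 4 : ci + 5]
            mass = win.sum()
            assert mass > 0
            fitted = ((win * gr).sum() / mass, (win * gc).sum() / mass)
            errors.append(np.hypot(fitted[0] - r, fitted[1] - c))
        assert max(errors) <= 1.5
        assert np.mean(errors) <= 0.5

    def test_single_mode_leaves_edge_beads_elliptical(self, default_spec, model):
        """Edge beads deconvolved with the average PSF stay radially
        elongated; the 30-mode model symmetrizes them."""
        from svmpsf.metrics import measure_radial_profiles

        phantom, centers = generate_bead_phantom(default_spec, 14, min_separation=14.0)
        field = make_ground_truth_field(default_spec)
        observed = render_observed_image(phantom, field)
        ellip = {}
        for n_modes in (1, 30):
            cfg = DeconvConfig(iterations=150, n_modes=n_modes)
            result = deconvolve(observed, model, cfg)
            rep = measure_radial_profiles(
                result.image, centers,
                fov_center=default_spec.fov_center,
                core_radius=default_spec.core_radius,
                edge_zone=0.6,
            )
            edge = rep.per_object[
                rep.per_object.r_from_center >= 0.6 * default_spec.core_radius
            ]
            ellip[n_modes] = edge.ellipticity.mean()
        assert ellip[1] > ellip[30]

    def test_diagnostics_schema(self, invariant_model, rng):
        I = rng.uniform(0.0, 1.0, invariant_model.frame_shape)
        cfg = DeconvConfig(iterations=5, n_modes=1)
        result = deconvolve(I, invariant_model, cfg)
        assert list(result.diagnostics.columns) == [
            "iteration", "flux", "max_intensity", "max_ratio",
            "ratio_floor_hits", "clipped_pixels",
        ]
        assert len(result.diagnostics) == 5
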