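"""Eigen-PSF model construction and the spatially variant forward imaging model.

A shift-variant imaging system maps a source ``S`` to an image ``I`` through
a point spread function that depends on the absolute source position::

    I(x, y) = sum_{u,v} S(u, v) P(u, v, x - u, y - v)

Direct evaluation of this superposition is quadratic in the pixel count.
The modal (eigen-PSF) approach separates the variables by expanding the
local PSF on an orthonormal basis obtained from the eigendecomposition of
the second-moment matrix of measured focal-spot patches::

    P(u, v, x, y) = sum_i a_i(u, v) p_i(x, y)

The eigen-PSFs ``p_i`` are spatially invariant; the coefficient maps
``a_i(u, v)`` — sampled at the calibration grid points and interpolated
bicubically across the field of view — carry all spatial variability.
Image formation then becomes a sum of ordinary convolutions,

    I = sum_i p_i * (a_i . S),

evaluated with zero-padded FFTs, which is what makes shift-variant
Richardson-Lucy deconvolution tractable.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.fft
from scipy import ndimage
from scipy.interpolate import (
    CloughTocher2DInterpolator,
    NearestNDInterpolator,
    RectBivariateSpline,
)

__all__ = [
    "FocusGrid",
    "PatchSet",
    "EigenPSFModel",
    "ModalConvolver",
    "crop_focus_patches",
    "build_second_moment_matrix",
    "compute_eigen_psfs",
    "project_coefficients",
    "interpolate_coefficient_maps",
    "reconstruct_psf",
    "forward_convolve",
    "reconstruction_rms_error",
    "build_eigen_psf_model",
]


@dataclass
class FocusGrid:
    """A stack of focal-spot calibration frames with their nominal positions.

    Parameters
    ----------
    frames : ndarray, shape (J, H, W)
        One grayscale frame per recorded focus, nonnegative.
    positions : pandas.DataFrame
        Columns ``index, row, col``; 0-based floating-point pixel centers,
        origin at the top-left corner, (row, col) order.
    pixel_size : float
        Micrometers per pixel.
    meta : dict
        Free-form provenance (acquisition parameters, intensity scaling).
    """

    frames: np.ndarray
    positions: pd.DataFrame
    pixel_size: float = 0.435
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (J, H, W) stack of 2-D images")
        if not isinstance(self.positions, pd.DataFrame):
            pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
            self.positions = pd.DataFrame(
                {"index": np.arange(len(pos)), "row": pos[:, 0], "col": pos[:, 1]}
            )
        if len(self.positions) != len(self.frames):
            raise ValueError(
                f"{len(self.frames)} frames but {len(self.positions)} positions"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def position_array(self) -> np.ndarray:
        """Positions as a (J, 2) float array in (row, col) order."""
        return self.positions[["row", "col"]].to_numpy(dtype=float)

    def validate(self) -> None:
        """Check positions lie in-frame and each frame holds a single focus.

        A frame is flagged (warning, not error) when, after flooring the
        background at half the frame maximum, more than one connected bright
        region remains — usually a sign of a corrupted calibration frame.
        """
        h, w = self.frame_shape
        pos = self.position_array
        if (pos < 0).any() or (pos[:, 0] > h - 1).any() or (pos[:, 1] > w - 1).any():
            raise ValueError("grid positions fall outside the frame")
        for j, frame in enumerate(self.frames):
            peak = frame.max()
            if peak <= 0:
                warnings.warn(f"frame {j} has no positive intensity", stacklevel=2)
                continue
            _, n_regions = ndimage.label(frame > 0.5 * peak)
            if n_regions != 1:
                warnings.warn(
                    f"frame {j}: {n_regions} connected maximum regions "
                    "after background flooring (expected 1)",
                    stacklevel=2,
                )


@dataclass
class PatchSet:
    """Square focus crops, peak-centered and normalized to unit L2 norm.

    ``normalization[j]`` records the scale the raw crop was divided by, so
    the original intensities can always be recovered.
    """

    patches: np.ndarray  # (J, s, s)
    centers: np.ndarray  # (J, 2) integer peak positions in the source frames
    normalization: np.ndarray  # (J,) applied divisors

    @property
    def crop_size(self) -> int:
        return self.patches.shape[1]

    @property
    def n_patches(self) -> int:
        return len(self.patches)


@dataclass
class EigenPSFModel:
    """Ordered eigen-PSFs with eigenvalues and coefficient maps.

    Attributes
    ----------
    eigen_psfs : ndarray, shape (N, s, s)
        Orthonormal basis patches, sorted by nonincreasing eigenvalue. The
        pixel of largest magnitude in each patch is made positive, which
        renders mode 1 an average-PSF-like nonnegative patch.
    eigenvalues : ndarray, shape (N,)
        Nonincreasing, nonnegative.
    coeff_samples : ndarray, shape (N, J)
        Coefficients at the calibration grid points.
    coeff_maps : ndarray, shape (N, H, W)
        Full-FOV coefficient maps (bicubic interpolation of the samples).
    positions : ndarray, shape (J, 2)
        Grid-point positions, (row, col).
    """

    eigen_psfs: np.ndarray
    eigenvalues: np.ndarray
    coeff_samples: np.ndarray
    coeff_maps: np.ndarray
    positions: np.ndarray
    crop_size: int
    pixel_size: float = 0.435
    metadata: dict = field(default_factory=dict)

    @property
    def n_max(self) -> int:
        return len(self.eigen_psfs)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.coeff_maps.shape[1], self.coeff_maps.shape[2]

    def coefficients_at(self, position: tuple[float, float]) -> np.ndarray:
        """Coefficient vector at an absolute (row, col) position.

        Looks up the interpolated maps at the nearest pixel; at integer grid
        points this equals the projected sample to interpolation accuracy.
        """
        h, w = self.frame_shape
        r, c = int(round(position[0])), int(round(position[1]))
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"position {position} outside the modeled frame")
        return self.coeff_maps[:, r, c]


def crop_focus_patches(grid: FocusGrid, crop_size: int = 15) -> PatchSet:
    """Crop a peak-centered square patch from every calibration frame.

    The crop is centered on the integer argmax pixel of each frame (ties
    resolved row-major, first occurrence); sub-pixel registration is not
    attempted.  Each crop is normalized to unit L2 norm so the downstream
    eigendecomposition treats every focus with equal weight and the mode-1
    coefficient is ~1 across the field of view; the applied scale is kept.
    """
    if crop_size % 2 != 1 or crop_size < 1:
        raise ValueError("crop_size must be a positive odd integer")
    half = crop_size // 2
    h, w = grid.frame_shape
    patches = np.empty((grid.n_frames, crop_size, crop_size))
    centers = np.empty((grid.n_frames, 2), dtype=int)
    norms = np.empty(grid.n_frames)
    for j, frame in enumerate(grid.frames):
        if frame.max() <= 0:
            raise ValueError(f"frame {j} is non-positive: no focus peak to center on")
        r, c = np.unravel_index(int(np.argmax(frame)), frame.shape)
        if r < half or c < half or r >= h - half or c >= w - half:
            raise ValueError(
                f"frame {j}: focus peak at ({r}, {c}) is closer than "
                f"{half} pixels to the frame edge; cannot crop {crop_size}x{crop_size}"
            )
        crop = frame[r - half : r + half + 1, c - half : c + half + 1]
        scale = float(np.linalg.norm(crop))
        patches[j] = crop / scale
        centers[j] = (r, c)
        norms[j] = scale
    return PatchSet(patches=patches, centers=centers, normalization=norms)


def build_second_moment_matrix(patches: PatchSet) -> np.ndarray:
    """Second-moment matrix M = (1/J) sum_j vec(patch_j) vec(patch_j)^T.

    No mean subtraction is performed: keeping the mean in the decomposition
    makes the leading eigenvector the average PSF, which is the natural
    first mode of the expansion.
    """
    if patches.n_patches < 1:
        raise ValueError("need at least one patch")
    v = patches.patches.reshape(patches.n_patches, -1)
    m = v.T @ v / patches.n_patches
    return (m + m.T) / 2.0  # kill rounding asymmetry


def compute_eigen_psfs(
    m: np.ndarray, n_keep: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecompose the second-moment matrix into ordered eigen-PSFs.

    Returns ``(eigen_psfs, eigenvalues)`` with eigenvalues nonincreasing and
    eigenvectors reshaped to square patches.  The sign of each eigenvector is
    fixed by making its largest-magnitude pixel positive (first occurrence on
    ties), which removes the inherent sign ambiguity of eigenvectors.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("second-moment matrix must be square")
    scale = np.abs(m).max() or 1.0
    if np.abs(m - m.T).max() > 1e-10 * scale:
        raise ValueError("matrix is not symmetric within tolerance")
    side = int(round(np.sqrt(m.shape[0])))
    if side * side != m.shape[0]:
        raise ValueError("matrix side is not a perfect square; cannot reshape patches")
    n_total = m.shape[0]
    if n_keep is None:
        n_keep = n_total
    if not 1 <= n_keep <= n_total:
        raise ValueError(f"n_keep must be in [1, {n_total}]")
    eigvals, eigvecs = np.linalg.eigh(m)
    order = np.argsort(eigvals)[::-1][:n_keep]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order].T  # (n_keep, side*side)
    # sign convention: largest-|value| pixel positive
    flip = eigvecs[np.arange(n_keep), np.abs(eigvecs).argmax(axis=1)] < 0
    eigvecs[flip] *= -1.0
    return eigvecs.reshape(n_keep, side, side), eigvals


def project_coefficients(patches: PatchSet, eigen_psfs: np.ndarray) -> np.ndarray:
    """Per-grid-point coefficients a_i(u_j, v_j) = <patch_j, p_i>.

    With all modes kept the expansion is complete and ``sum_i a_i p_i``
    reproduces every patch exactly.
    """
    if eigen_psfs.shape[1:] != patches.patches.shape[1:]:
        raise ValueError("patch and eigen-PSF sizes do not match")
    basis = eigen_psfs.reshape(len(eigen_psfs), -1)
    v = patches.patches.reshape(patches.n_patches, -1)
    return basis @ v.T  # (N, J)


def _lattice_from_positions(
    positions: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """Detect a tensor-product lattice; return (rows, cols, sample index grid)."""
    rows = np.unique(np.round(positions[:, 0], 6))
    cols = np.unique(np.round(positions[:, 1], 6))
    if len(rows) * len(cols) != len(positions):
        return None
    idx = np.full((len(rows), len(cols)), -1, dtype=int)
    ri = np.searchsorted(rows, np.round(positions[:, 0], 6))
    ci = np.searchsorted(cols, np.round(positions[:, 1], 6))
    idx[ri, ci] = np.arange(len(positions))
    if (idx < 0).any():
        return None
    return rows, cols, idx


def interpolate_coefficient_maps(
    coeff_samples: np.ndarray,
    positions: np.ndarray,
    frame_shape: tuple[int, int],
) -> np.ndarray:
    """Bicubic interpolation of per-grid-point coefficients to full maps.

    On a regular calibration lattice each mode's samples are interpolated
    with a tensor-product cubic spline; scattered positions fall back to
    piecewise-cubic (Clough-Tocher) interpolation.  Pixels outside the grid
    hull are clamped to the nearest in-hull coordinate rather than
    extrapolated, so coefficient maps stay bounded at the FOV corners.
    """
    coeff_samples = np.atleast_2d(np.asarray(coeff_samples, dtype=float))
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 16:
        raise ValueError("bicubic interpolation needs at least a 4x4 grid of samples")
    n_modes = coeff_samples.shape[0]
    h, w = frame_shape
    maps = np.empty((n_modes, h, w))
    lattice = _lattice_from_positions(positions)
    if lattice is not None:
        rows, cols, idx = lattice
        if len(rows) < 4 or len(cols) < 4:
            raise ValueError(
                "bicubic interpolation needs at least 4 grid points per axis"
            )
        rr = np.clip(np.arange(h, dtype=float), rows[0], rows[-1])
        cc = np.clip(np.arange(w, dtype=float), cols[0], cols[-1])
        ur, ir = np.unique(rr, return_inverse=True)
        uc, ic = np.unique(cc, return_inverse=True)
        for i in range(n_modes):
            spline = RectBivariateSpline(
                rows, cols, coeff_samples[i][idx], kx=3, ky=3, s=0
            )
            maps[i] = spline(ur, uc)[np.ix_(ir, ic)]
        return maps
    # scattered fallback
    rmin, rmax = positions[:, 0].min(), positions[:, 0].max()
    cmin, cmax = positions[:, 1].min(), positions[:, 1].max()
    gr, gc = np.meshgrid(
        np.clip(np.arange(h, dtype=float), rmin, rmax),
        np.clip(np.arange(w, dtype=float), cmin, cmax),
        indexing="ij",
    )
    pts = np.column_stack([gr.ravel(), gc.ravel()])
    for i in range(n_modes):
        interp = CloughTocher2DInterpolator(positions, coeff_samples[i])
        vals = interp(pts)
        nan = ~np.isfinite(vals)
        if nan.any():
            nearest = NearestNDInterpolator(positions, coeff_samples[i])
            vals[nan] = nearest(pts[nan])
        maps[i] = vals.reshape(h, w)
    return maps


def reconstruct_psf(
    model: EigenPSFModel, position: tuple[float, float], n_modes: int
) -> np.ndarray:
    """Local PSF at an absolute position from the truncated modal expansion.

    Truncated sums are returned as-is (they may contain small negative
    values); clip before using the result as a physical kernel.
    """
    if not 1 <= n_modes <= model.n_max:
        raise ValueError(f"n_modes must be in [1, {model.n_max}]")
    a = model.coefficients_at(position)[:n_modes]
    return np.tensordot(a, model.eigen_psfs[:n_modes], axes=(0, 0))


class ModalConvolver:
    """Shift-variant forward operator ``S -> sum_i p_i * (a_i . S)``.

    Zero-padded linear convolution evaluated in the frequency domain; each
    kernel's origin is its central pixel, so a single uniform mode reduces
    to ordinary 'same'-mode convolution.  Kernel FFTs are precomputed once,
    which matters inside iterative deconvolution.
    """

    def __init__(self, kernels: np.ndarray, coeff_maps: np.ndarray):
        kernels = np.asarray(kernels, dtype=float)
        coeff_maps = np.asarray(coeff_maps, dtype=float)
        if kernels.ndim != 3 or coeff_maps.ndim != 3:
            raise ValueError("kernels and coeff_maps must be 3-D stacks")
        if len(kernels) != len(coeff_maps):
            raise ValueError("one coefficient map per kernel is required")
        self.side = kernels.shape[1]
        if kernels.shape[2] != self.side or self.side % 2 != 1:
            raise ValueError("kernels must be square with odd side")
        self.image_shape = coeff_maps.shape[1:]
        h, w = self.image_shape
        self._pad = (
            scipy.fft.next_fast_len(h + self.side - 1),
            scipy.fft.next_fast_len(w + self.side - 1),
        )
        self.coeff_maps = coeff_maps
        self._kfft = scipy.fft.rfft2(kernels, s=self._pad)
        self._off = self.side // 2

    def _check(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=float)
        if image.shape != self.image_shape:
            raise ValueError(
                f"image shape {image.shape} does not match "
                f"coefficient maps {self.image_shape}"
            )
        return image

    def apply(self, source: np.ndarray) -> np.ndarray:
        """sum_i p_i * (a_i . source) — the modal forward model (weight first)."""
        source = self._check(source)
        x = scipy.fft.rfft2(self.coeff_maps * source[None], s=self._pad)
        y = scipy.fft.irfft2((x * self._kfft).sum(axis=0), s=self._pad)
        o, (h, w) = self._off, self.image_shape
        return y[o : o + h, o : o + w]

    def apply_outer(self, image: np.ndarray) -> np.ndarray:
        """sum_i a_i . (p_i * image) — weighting after convolution.

        With flipped kernels this is the exact adjoint of :meth:`apply`.
        """
        image = self._check(image)
        y = scipy.fft.irfft2(self._kfft * scipy.fft.rfft2(image, s=self._pad)[None],
                             s=self._pad)
        o, (h, w) = self._off, self.image_shape
        return (self.coeff_maps * y[:, o : o + h, o : o + w]).sum(axis=0)


def forward_convolve(
    source: np.ndarray, model: EigenPSFModel, n_modes: int
) -> np.ndarray:
    """Image formed from a source through the truncated eigen-PSF model."""
    if not 1 <= n_modes <= model.n_max:
        raise ValueError(f"n_modes must be in [1, {model.n_max}]")
    source = np.asarray(source, dtype=float)
    if source.shape != model.frame_shape:
        raise ValueError(
            f"source shape {source.shape} does not match model FOV {model.frame_shape}"
        )
    conv = ModalConvolver(model.eigen_psfs[:n_modes], model.coeff_maps[:n_modes])
    return conv.apply(source)


def reconstruction_rms_error(measured: np.ndarray, reconstructed: np.ndarray) -> float:
    """Normalized RMS error: RMS(measured - reconstructed) / RMS(measured)."""
    measured = np.asarray(measured, dtype=float)
    reconstructed = np.asarray(reconstructed, dtype=float)
    if measured.shape != reconstructed.shape:
        raise ValueError("images must share a shape")
    denom = np.sqrt(np.mean(measured**2))
    if denom == 0:
        raise ValueError("measured image is identically zero; normalization undefined")
    return float(np.sqrt(np.mean((measured - reconstructed) ** 2)) / denom)


def build_eigen_psf_model(
    grid: FocusGrid, crop_size: int = 15, n_modes: int | None = None
) -> EigenPSFModel:
    """Full pipeline: crop, decompose, project, interpolate.

    ``n_modes`` limits how many modes are retained in the model (default:
    all ``crop_size**2``); deconvolution can always truncate further.
    """
    t0 = time.perf_counter()
    patches = crop_focus_patches(grid, crop_size)
    m = build_second_moment_matrix(patches)
    eigen_psfs, eigenvalues = compute_eigen_psfs(m, n_keep=n_modes)
    coeff_samples = project_coefficients(patches, eigen_psfs)
    coeff_maps = interpolate_coefficient_maps(
        coeff_samples, grid.position_array, grid.frame_shape
    )
    elapsed = time.perf_counter() - t0
    metadata = {
        "crop_size": crop_size,
        "n_frames": grid.n_frames,
        "frame_shape": list(grid.frame_shape),
        "pixel_size_um": grid.pixel_size,
        "patch_normalization": "unit-l2",
        "n_modes": len(eigen_psfs),
        "build_seconds": round(elapsed, 3),
    }
    metadata.update({f"input_{k}": v for k, v in grid.meta.items()})
    return EigenPSFModel(
        eigen_psfs=eigen_psfs,
        eigenvalues=eigenvalues,
        coeff_samples=coeff_samples,
        coeff_maps=coeff_maps,
        positions=grid.position_array,
        crop_size=crop_size,
        pixel_size=grid.pixel_size,
        metadata=metadata,
    )
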