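"""Synthetic focus grids and phantoms with a known spatially variant PSF.

In a step-index multimode-fiber micro-endoscope the effective numerical
aperture of the scanned focus decreases from the core center outward, so
foci at the edge of the field of view are broader and radially elongated.
This module emulates that geometry with an analytic ground-truth PSF field:
an anisotropic Gaussian whose radial-axis width grows linearly with the
distance from the FOV center while the tangential width stays constant.
Every downstream stage (eigen-PSF modeling, deconvolution, metrics) can then
be validated against exact ground truth without any optical acquisition.

Coordinates are 0-based pixel indices, origin at the top-left corner,
(row, col) order; positions are floating-point pixel centers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .model import FocusGrid

__all__ = [
    "SyntheticSceneSpec",
    "GroundTruthPSFField",
    "make_ground_truth_field",
    "generate_focus_grid",
    "generate_bead_phantom",
    "render_observed_image",
]


@dataclass(frozen=True)
class SyntheticSceneSpec:
    """Parameters of the simulated fiber field of view.

    Defaults emulate the NA-0.22, 50-µm-core configuration: 120×120-pixel
    frames at 0.435 µm/pixel, a 13×13 focus grid, a ~0.65-µm (1.5-px)
    diffraction-limited focus at the center, and a radial width growth that
    makes the outermost grid foci ≈1.9× elongated.

    Parameters
    ----------
    frame_size : int
        Pixels per (square) frame side.
    grid_points_per_side : int
        Calibration grid is ``n × n`` equidistant points.
    pixel_size : float
        Micrometers per pixel.
    core_radius : float
        Radius of the usable FOV disk, pixels (25 µm core radius).
    base_sigma : float
        Gaussian intensity s.d. of the focus at the FOV center, pixels.
    radial_broadening : float
        Dimensionless rate b in sigma_radial = base_sigma * (1 + b*r/core_radius);
        0 gives a spatially invariant, isotropic focus everywhere.
    noise_level : float
        S.d. of additive zero-mean Gaussian noise (clipped at 0), as a
        fraction of the brightest clean pixel in the stack.
    seed : int
        Seed for all randomness derived from this spec.
    grid_margin : int
        Distance from the frame edge to the outermost grid points, pixels;
        must be at least ``patch_size // 2`` so foci can be cropped.
    patch_size : int
        Odd side of the rendered ground-truth PSF patches.
    """

    frame_size: int = 120
    grid_points_per_side: int = 13
    pixel_size: float = 0.435
    core_radius: float = 57.5
    base_sigma: float = 1.5
    radial_broadening: float = 1.1
    noise_level: float = 0.0
    seed: int = 0
    grid_margin: int = 13
    patch_size: int = 15

    def __post_init__(self) -> None:
        if self.frame_size < 1 or self.grid_points_per_side < 1:
            raise ValueError("frame_size and grid_points_per_side must be positive")
        if self.patch_size % 2 != 1 or self.patch_size < 1:
            raise ValueError("patch_size must be a positive odd integer")
        if self.base_sigma <= 0 or self.core_radius <= 0 or self.pixel_size <= 0:
            raise ValueError("base_sigma, core_radius and pixel_size must be positive")
        if self.radial_broadening < 0 or self.noise_level < 0:
            raise ValueError("radial_broadening and noise_level must be >= 0")
        if self.grid_margin < self.patch_size // 2:
            raise ValueError(
                f"grid_margin {self.grid_margin} leaves no room to crop "
                f"{self.patch_size}x{self.patch_size} patches "
                f"(need >= {self.patch_size // 2})"
            )
        if self.frame_size - 1 - 2 * self.grid_margin < self.grid_points_per_side - 1:
            raise ValueError(
                f"a {self.grid_points_per_side}x{self.grid_points_per_side} grid "
                f"with margin {self.grid_margin} does not fit in a "
                f"{self.frame_size}-pixel frame"
            )

    @property
    def fov_center(self) -> tuple[float, float]:
        c = (self.frame_size - 1) / 2.0
        return (c, c)

    def grid_coordinates(self) -> np.ndarray:
        """1-D integer grid coordinates shared by rows and columns."""
        lo, hi = self.grid_margin, self.frame_size - 1 - self.grid_margin
        return np.round(np.linspace(lo, hi, self.grid_points_per_side)).astype(int)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSceneSpec":
        return cls(**json.loads(text))


@dataclass
class GroundTruthPSFField:
    """The true local PSF as a function of absolute position.

    ``evaluator(u, v)`` returns the unit-sum, nonnegative PSF patch centered
    at pixel ``(u, v)`` (row, col).  This is the simulation-side container
    for the shift-variant kernel of the superposition imaging model.
    """

    evaluator: Callable[[float, float], np.ndarray]
    patch_size: int

    def psf_at(self, u: float, v: float) -> np.ndarray:
        return self.evaluator(u, v)


def make_ground_truth_field(spec: SyntheticSceneSpec) -> GroundTruthPSFField:
    """Anisotropic-Gaussian PSF field emulating the radial NA decrease.

    At distance r from the FOV center the intensity s.d. along the local
    radial direction is ``base_sigma * (1 + radial_broadening * r / core_radius)``
    while the tangential s.d. stays at ``base_sigma``; the Gaussian is
    rotated so its long axis points radially.  With ``radial_broadening=0``
    the field is isotropic and spatially invariant.
    """
    half = spec.patch_size // 2
    dr, dc = np.meshgrid(
        np.arange(-half, half + 1, dtype=float),
        np.arange(-half, half + 1, dtype=float),
        indexing="ij",
    )
    c_r, c_c = spec.fov_center

    def evaluator(u: float, v: float) -> np.ndarray:
        rr, cc = u - c_r, v - c_c
        r = float(np.hypot(rr, cc))
        sigma_rad = spec.base_sigma * (1.0 + spec.radial_broadening * r / spec.core_radius)
        sigma_tan = spec.base_sigma
        if sigma_rad == sigma_tan:
            # isotropic: evaluate without rotation so a broadening-free field
            # is bit-identical at every position
            patch = np.exp(-(dr**2 + dc**2) / (2.0 * sigma_tan**2))
            return patch / patch.sum()
        if r < 1e-12:
            e_rad = (1.0, 0.0)  # direction degenerate at the exact center
        else:
            e_rad = (rr / r, cc / r)
        s_rad = dr * e_rad[0] + dc * e_rad[1]
        s_tan = -dr * e_rad[1] + dc * e_rad[0]
        patch = np.exp(
            -(s_rad**2) / (2.0 * sigma_rad**2) - s_tan**2 / (2.0 * sigma_tan**2)
        )
        return patch / patch.sum()

    return GroundTruthPSFField(evaluator=evaluator, patch_size=spec.patch_size)


def generate_focus_grid(spec: SyntheticSceneSpec) -> FocusGrid:
    """Render one calibration frame per grid point.

    Each frame contains a single focus: the ground-truth PSF patch pasted
    at the (integer) grid position, plus optional clipped Gaussian noise.
    The returned positions table matches the rendered peak locations.
    Identical specs and seeds give bit-identical stacks.
    """
    field = make_ground_truth_field(spec)
    coords = spec.grid_coordinates()
    half = spec.patch_size // 2
    n = spec.grid_points_per_side
    frames = np.zeros((n * n, spec.frame_size, spec.frame_size))
    rows = np.empty(n * n)
    cols = np.empty(n * n)
    j = 0
    for r in coords:
        for c in coords:
            frames[j, r - half : r + half + 1, c - half : c + half + 1] = field.psf_at(
                float(r), float(c)
            )
            rows[j], cols[j] = r, c
            j += 1
    if spec.noise_level > 0:
        rng = np.random.default_rng(spec.seed)
        sd = spec.noise_level * frames.max()
        frames = np.clip(frames + rng.normal(0.0, sd, frames.shape), 0.0, None)
    positions = pd.DataFrame({"index": np.arange(n * n), "row": rows, "col": cols})
    return FocusGrid(
        frames=frames,
        positions=positions,
        pixel_size=spec.pixel_size,
        meta={"synthetic_spec": json.loads(spec.to_json())},
    )


def generate_bead_phantom(
    spec: SyntheticSceneSpec,
    n_beads: int,
    bead_diameter: float = 1.0,
    min_separation: float | None = None,
    max_attempts: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Scatter non-overlapping fluorescent beads inside the core disk.

    ``bead_diameter`` is in micrometers and is converted with the spec's
    pixel size (1 µm at 0.435 µm/px -> ≈2.3-px disks).  Returns the source
    image and the (n_beads, 2) array of bead centers for metric ground
    truth.  Placement is drawn from ``spec.seed`` and is reproducible.
    """
    if n_beads < 0:
        raise ValueError("n_beads must be >= 0")
    diameter_px = bead_diameter / spec.pixel_size
    if diameter_px < 1.0:
        raise ValueError(
            f"bead diameter {bead_diameter} um is below one pixel "
            f"({spec.pixel_size} um/px)"
        )
    radius_px = diameter_px / 2.0
    if min_separation is None:
        min_separation = diameter_px + 3.0
    image = np.zeros((spec.frame_size, spec.frame_size))
    centers: list[tuple[float, float]] = []
    if n_beads == 0:
        return image, np.empty((0, 2))
    rng = np.random.default_rng(spec.seed + 104729)  # decorrelate from frame noise
    c_r, c_c = spec.fov_center
    # keep beads inside both the core disk and the calibrated region (the
    # focus grid spans the frame minus grid_margin; outside it the PSF model
    # is only a clamped extrapolation)
    place_radius = min(
        spec.core_radius,
        spec.frame_size / 2.0 - spec.grid_margin,
        spec.frame_size / 2.0 - radius_px - 2.0,
    )
    attempts = 0
    while len(centers) < n_beads:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"placed only {len(centers)}/{n_beads} beads after {max_attempts} "
                f"attempts: non-overlapping placement with separation "
                f">= {min_separation:.2f} px inside radius {place_radius:.1f} px failed"
            )
        attempts += 1
        r = place_radius * np.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * np.pi)
        cand = (c_r + r * np.cos(theta), c_c + r * np.sin(theta))
        if any(np.hypot(cand[0] - p[0], cand[1] - p[1]) < min_separation for p in centers):
            continue
        centers.append(cand)
    gr, gc = np.meshgrid(
        np.arange(spec.frame_size, dtype=float),
        np.arange(spec.frame_size, dtype=float),
        indexing="ij",
    )
    for p in centers:
        dist = np.hypot(gr - p[0], gc - p[1])
        # disk with one-pixel anti-aliased rim
        image += np.clip(radius_px - dist + 0.5, 0.0, 1.0)
    return image, np.asarray(centers)


def render_observed_image(
    source: np.ndarray, field: GroundTruthPSFField
) -> np.ndarray:
    """Brute-force shift-variant image formation by explicit superposition.

    ``output(x, y) = sum_{u,v} source(u, v) * P(u, v, x-u, y-v)`` evaluated
    in the spatial domain, one local-PSF patch per nonzero source pixel.
    Quadratic cost: this is the independent oracle against which the FFT
    forward model is checked, not a production path.  Flux falling outside
    the frame is lost (no wrap-around).
    """
    source = np.asarray(source, dtype=float)
    if source.ndim != 2:
        raise ValueError("source must be a 2-D image")
    if (source < 0).any():
        raise ValueError("source must be nonnegative")
    half = field.patch_size // 2
    h, w = source.shape
    padded = np.zeros((h + 2 * half, w + 2 * half))
    for u, v in zip(*np.nonzero(source)):
        padded[u : u + field.patch_size, v : v + field.patch_size] += source[
            u, v
        ] * field.psf_at(float(u), float(v))
    return padded[half : half + h, half : half + w]
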