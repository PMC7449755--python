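"""Quantitative validation of the PSF model and of deconvolution output.

Operators: 1/e² radii measured along the radial or tangential direction,
the edge-to-center radius ratio that quantifies spatial uniformity of the
point response, normalized-RMS-error-vs-mode-count curves for model
truncation, and the FOV-enhancement factor (ratio of areas over which the
normalized deconvolved point response stays above a threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .model import (
    EigenPSFModel,
    FocusGrid,
    crop_focus_patches,
    project_coefficients,
)

__all__ = [
    "RadialProfileReport",
    "e2_radius",
    "measure_radial_profiles",
    "edge_to_center_ratio",
    "fov_enhancement",
    "rms_vs_modes_curve",
    "peak_intensity_map",
]

E2 = float(np.exp(-2.0))


@dataclass
class RadialProfileReport:
    """Per-object 1/e² radii and the aggregated edge/center statistics."""

    per_object: pd.DataFrame  # row, col, r_from_center, radial, tangential, ellipticity
    center_radius: float
    edge_radius: float
    edge_to_center_ratio: float


class _ImageSampler:
    """Cubic-spline sampler; prefilters the image once for repeated profiles."""

    def __init__(self, image: np.ndarray):
        self.image = np.asarray(image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("expected a 2-D image")
        self._coeffs = ndimage.spline_filter(self.image, order=3)

    def __call__(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(
            self._coeffs, [rows, cols], order=3, prefilter=False, mode="nearest"
        )


def _refine_peak(
    image: np.ndarray, r: int, c: int
) -> tuple[float, float]:
    """Sub-pixel peak via per-axis parabolic fit on the raw image."""
    h, w = image.shape

    def offset(m1: float, m0: float, p1: float) -> float:
        denom = m1 - 2.0 * m0 + p1
        if denom >= 0:  # not a local max along this axis
            return 0.0
        return float(np.clip(0.5 * (m1 - p1) / denom, -0.5, 0.5))

    dr = offset(image[r - 1, c], image[r, c], image[r + 1, c]) if 0 < r < h - 1 else 0.0
    dc = offset(image[r, c - 1], image[r, c], image[r, c + 1]) if 0 < c < w - 1 else 0.0
    return r + dr, c + dc


def _locate_peak(
    image: np.ndarray, center: tuple[float, float], search_radius: float
) -> tuple[float, float]:
    """Find the object's peak near ``center``.

    A 3x3 mean filter resists single-pixel noise while locating the peak
    pixel; the sub-pixel position is then refined on the raw image.
    """
    h, w = image.shape
    smoothed = ndimage.uniform_filter(image, size=3)
    r0, c0 = int(round(center[0])), int(round(center[1]))
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError(f"object center {center} outside the image")
    s = int(np.ceil(search_radius))
    rlo, rhi = max(r0 - s, 0), min(r0 + s + 1, h)
    clo, chi = max(c0 - s, 0), min(c0 + s + 1, w)
    window = smoothed[rlo:rhi, clo:chi]
    rr, cc = np.unravel_index(int(np.argmax(window)), window.shape)
    return _refine_peak(image, rlo + rr, clo + cc)


def e2_radius(
    image: np.ndarray,
    center: tuple[float, float],
    direction: str = "radial",
    fov_center: tuple[float, float] | None = None,
    step: float = 0.05,
    search_radius: float = 4.0,
    _sampler: _ImageSampler | None = None,
) -> float:
    """1/e² radius of an object, along the radial or tangential direction.

    The radial direction runs from ``fov_center`` (default: the geometric
    image center) through the object's peak; tangential is perpendicular.
    The intensity profile is sampled by cubic-spline interpolation at
    ``step``-pixel intervals on both sides of the peak; the first crossing
    of ``peak / e²`` is located by linear interpolation between samples and
    the two half-widths are averaged.
    """
    sampler = _sampler if _sampler is not None else _ImageSampler(image)
    image = sampler.image
    h, w = image.shape
    pr, pc = _locate_peak(image, center, search_radius)
    peak_val = float(sampler(np.array([pr]), np.array([pc]))[0])
    if peak_val <= 0:
        raise ValueError(f"no positive peak near {center}")
    if fov_center is None:
        fov_center = ((h - 1) / 2.0, (w - 1) / 2.0)
    vr, vc = pr - fov_center[0], pc - fov_center[1]
    norm = float(np.hypot(vr, vc))
    e = (1.0, 0.0) if norm < 1e-9 else (vr / norm, vc / norm)
    if direction == "tangential":
        e = (-e[1], e[0])
    elif direction != "radial":
        raise ValueError("direction must be 'radial' or 'tangential'")
    threshold = peak_val * E2
    crossings = []
    for sign in (1.0, -1.0):
        # longest in-frame extent along this ray
        tmax = min(
            _ray_extent(pr, e[0] * sign, h), _ray_extent(pc, e[1] * sign, w)
        )
        n = int(tmax / step)
        if n < 2:
            continue
        t = step * np.arange(1, n + 1)
        vals = sampler(pr + sign * e[0] * t, pc + sign * e[1] * t)
        below = np.nonzero(vals <= threshold)[0]
        if len(below) == 0:
            continue
        i = below[0]
        v_hi = peak_val if i == 0 else vals[i - 1]
        t_lo = 0.0 if i == 0 else t[i - 1]
        frac = (v_hi - threshold) / (v_hi - vals[i]) if v_hi != vals[i] else 0.0
        crossings.append(t_lo + frac * (t[i] - t_lo))
    if not crossings:
        raise ValueError(
            "intensity profile never falls to 1/e^2 of the peak within the frame"
        )
    return float(np.mean(crossings))


def _ray_extent(pos: float, d: float, size: int) -> float:
    """Distance from ``pos`` to the frame border along component ``d``."""
    if abs(d) < 1e-12:
        return np.inf
    return (size - 1 - pos) / d if d > 0 else -pos / d


def measure_radial_profiles(
    image: np.ndarray,
    objects: np.ndarray,
    fov_center: tuple[float, float] | None = None,
    core_radius: float | None = None,
    center_zone: float = 0.25,
    edge_zone: float = 0.75,
) -> RadialProfileReport:
    """Radial/tangential 1/e² radii for every object, with zone statistics.

    Objects within ``center_zone * core_radius`` of the FOV center form the
    center group and objects beyond ``edge_zone * core_radius`` the edge
    group; the report's ratio is mean(edge radial radius) / mean(center
    radial radius).  The FOV center defaults to the object centroid (robust
    to off-center fiber cores) and ``core_radius`` to the largest object
    distance from that center.
    """
    objects = np.atleast_2d(np.asarray(objects, dtype=float))
    if objects.shape[1] != 2:
        raise ValueError("objects must be an (n, 2) array of (row, col) positions")
    if fov_center is None:
        fov_center = tuple(objects.mean(axis=0))
    dist = np.hypot(objects[:, 0] - fov_center[0], objects[:, 1] - fov_center[1])
    if core_radius is None:
        core_radius = float(dist.max())
    sampler = _ImageSampler(image)
    rows = []
    for (r, c), d in zip(objects, dist):
        radial = e2_radius(image, (r, c), "radial", fov_center, _sampler=sampler)
        tangential = e2_radius(image, (r, c), "tangential", fov_center, _sampler=sampler)
        rows.append(
            {
                "row": r,
                "col": c,
                "r_from_center": d,
                "radial_e2": radial,
                "tangential_e2": tangential,
                "ellipticity": radial / tangential,
            }
        )
    table = pd.DataFrame(rows)
    center_mask = table["r_from_center"] <= center_zone * core_radius
    edge_mask = table["r_from_center"] >= edge_zone * core_radius
    if not center_mask.any():
        raise ValueError(
            f"no objects in the center zone (<= {center_zone:.0%} of core radius)"
        )
    if not edge_mask.any():
        raise ValueError(
            f"no objects in the edge zone (>= {edge_zone:.0%} of core radius)"
        )
    center_radius = float(table.loc[center_mask, "radial_e2"].mean())
    edge_radius = float(table.loc[edge_mask, "radial_e2"].mean())
    return RadialProfileReport(
        per_object=table,
        center_radius=center_radius,
        edge_radius=edge_radius,
        edge_to_center_ratio=edge_radius / center_radius,
    )


def edge_to_center_ratio(
    deconvolved: np.ndarray,
    objects: np.ndarray,
    fov_center: tuple[float, float] | None = None,
    core_radius: float | None = None,
) -> float:
    """Mean radial 1/e² radius of edge objects over that of center objects.

    The uniformity figure of merit for the point response: 1 means the
    response is spatially regularized; values well above 1 mean edge
    objects remain broader than central ones.
    """
    report = measure_radial_profiles(
        deconvolved, objects, fov_center=fov_center, core_radius=core_radius
    )
    return report.edge_to_center_ratio


def _plateau_radius(peak_map: np.ndarray, threshold: float) -> float:
    """Radius (in map units) of the centered disk where the azimuthally
    averaged, self-normalized peak-intensity profile stays >= threshold."""
    m = np.asarray(peak_map, dtype=float)
    if m.ndim != 2:
        raise ValueError("peak map must be 2-D")
    top = m.max()
    if top <= 0:
        raise ValueError("peak map has no positive values")
    m = m / top
    h, w = m.shape
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    gr, gc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    radii = np.hypot(gr - cr, gc - cc).ravel()
    vals = m.ravel()
    # azimuthal average: samples sharing a radius (to 1e-6) are pooled
    uniq, inv = np.unique(np.round(radii, 6), return_inverse=True)
    prof = np.bincount(inv, weights=vals) / np.bincount(inv)
    if prof[0] < threshold:
        raise ValueError(
            f"peak intensity at the map center ({prof[0]:.3f}) is below the "
            f"threshold {threshold}"
        )
    below = np.nonzero(prof < threshold)[0]
    if len(below) == 0:
        return float(uniq[-1])
    i = below[0]
    frac = (prof[i - 1] - threshold) / (prof[i - 1] - prof[i])
    return float(uniq[i - 1] + frac * (uniq[i] - uniq[i - 1]))


def fov_enhancement(
    deconv_multi: np.ndarray,
    deconv_single: np.ndarray,
    threshold: float = 0.8,
) -> float:
    """Ratio of usable-FOV areas between two deconvolved point-response maps.

    Each map holds the peak intensity of the deconvolved point response
    versus grid position and is normalized to its own maximum, making the
    metric invariant to overall intensity scale.  The usable FOV is the
    largest centered circle within which the azimuthally averaged response
    stays at or above ``threshold`` (0.8); the enhancement is
    ``area(multi) / area(single)``.
    """
    r_multi = _plateau_radius(deconv_multi, threshold)
    r_single = _plateau_radius(deconv_single, threshold)
    if r_single == 0:
        raise ValueError("single-mode map drops below threshold immediately")
    return float((r_multi / r_single) ** 2)


def peak_intensity_map(
    image: np.ndarray,
    positions: np.ndarray,
    grid_shape: tuple[int, int],
    window: int = 2,
) -> np.ndarray:
    """Peak intensity of the point response at each grid position.

    Takes the maximum of ``image`` in a ``(2*window+1)²`` neighborhood of
    every position and reshapes the result to ``grid_shape`` (positions in
    row-major grid order, as written by the synthetic generator).
    """
    image = np.asarray(image, dtype=float)
    positions = np.asarray(positions, dtype=float)
    h, w = image.shape
    if len(positions) != grid_shape[0] * grid_shape[1]:
        raise ValueError("positions do not fill the requested grid shape")
    peaks = np.empty(len(positions))
    for j, (r, c) in enumerate(positions):
        ri, ci = int(round(r)), int(round(c))
        rlo, rhi = max(ri - window, 0), min(ri + window + 1, h)
        clo, chi = max(ci - window, 0), min(ci + window + 1, w)
        peaks[j] = image[rlo:rhi, clo:chi].max()
    return peaks.reshape(grid_shape)


def rms_vs_modes_curve(
    grid: FocusGrid,
    model: EigenPSFModel,
    mode_counts: list[int],
    radii_bins: list[float] | None = None,
) -> pd.DataFrame:
    """Normalized RMS reconstruction error per (mode count, radial bin).

    For each calibration focus the normalized RMS error between the
    measured (normalized) patch and its ``n``-mode reconstruction is
    computed, then averaged over grid points falling in each radial bin
    (distances from the grid centroid, in pixels).  Because truncation
    error is a projection residual, the curve is nonincreasing in the mode
    count within every bin.  Empty bins are dropped with a warning.
    """
    mode_counts = sorted(set(int(n) for n in mode_counts))
    if not mode_counts or mode_counts[0] < 1 or mode_counts[-1] > model.n_max:
        raise ValueError(f"mode counts must lie in [1, {model.n_max}]")
    patches = crop_focus_patches(grid, model.crop_size)
    coeffs = project_coefficients(patches, model.eigen_psfs)  # (N, J)
    v = patches.patches.reshape(patches.n_patches, -1)
    norms = np.linalg.norm(v, axis=1)
    pos = grid.position_array
    centroid = pos.mean(axis=0)
    radii = np.hypot(pos[:, 0] - centroid[0], pos[:, 1] - centroid[1])
    if radii_bins is None:
        edges = np.linspace(0.0, radii.max() + 1e-9, 5)
    else:
        edges = np.asarray(radii_bins, dtype=float)
    # residual of the n-term expansion; with a complete basis this equals
    # the tail sum of squared coefficients, but computing the explicit
    # reconstruction stays valid for truncated models too
    basis = model.eigen_psfs.reshape(model.n_max, -1)
    rows = []
    for n in mode_counts:
        recon = coeffs[:n].T @ basis[:n]  # (J, s*s)
        err = np.linalg.norm(v - recon, axis=1) / norms
        for b in range(len(edges) - 1):
            mask = (radii >= edges[b]) & (radii < edges[b + 1])
            if b == len(edges) - 2:
                mask |= radii == edges[b + 1]
            if not mask.any():
                warnings.warn(
                    f"radial bin [{edges[b]:.1f}, {edges[b + 1]:.1f}) px is empty",
                    stacklevel=2,
                )
                continue
            rows.append(
                {
                    "mode_count": n,
                    "radius_lo": edges[b],
                    "radius_hi": edges[b + 1],
                    "n_points": int(mask.sum()),
                    "nrmse": float(err[mask].mean()),
                }
            )
    return pd.DataFrame(rows)
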