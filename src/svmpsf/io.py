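"""Readers and writers for the pipeline's on-disk formats.

Images travel as multi-page grayscale TIFF (32-bit float internally;
integer input is rescaled to [0, 1] on read with the scale recorded),
grid positions as CSV with an ``index,row,col`` header, eigen-PSF models
as a single HDF5 container, and configuration/provenance as JSON.
"""

from __future__ import annotations

import json
import platform
import time
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .model import EigenPSFModel, FocusGrid

__all__ = [
    "FocusStackError",
    "ModelIOError",
    "read_focus_stack",
    "write_focus_stack",
    "read_model",
    "write_model",
    "read_image",
    "write_image",
    "write_provenance",
]

MODEL_FORMAT_VERSION = "1"
_POSITIONS_HEADER = (
    "# svmpsf focus-grid positions\n"
    "# coordinates: 0-based floating-point pixel centers, (row, col) order,\n"
    "#              origin at the top-left frame corner\n"
)


class FocusStackError(RuntimeError):
    """Raised when a focus stack and its positions table are inconsistent."""


class ModelIOError(RuntimeError):
    """Raised when a model container is missing, truncated, or incompatible."""


def _to_float(frames: np.ndarray) -> tuple[np.ndarray, float]:
    """Convert integer image data to float32 in [0, 1]; return the scale."""
    if np.issubdtype(frames.dtype, np.integer):
        scale = float(np.iinfo(frames.dtype).max)
        return frames.astype(np.float32) / scale, scale
    return frames.astype(np.float32), 1.0


def write_focus_stack(
    tiff_path: str | Path, positions_path: str | Path, grid: FocusGrid
) -> None:
    """Write the calibration frames as multi-page TIFF plus a positions CSV."""
    tifffile.imwrite(tiff_path, grid.frames.astype(np.float32))
    with open(positions_path, "w") as fh:
        fh.write(_POSITIONS_HEADER)
        fh.write(f"# pixel_size_um: {grid.pixel_size}\n")
        grid.positions.to_csv(fh, index=False)


def read_focus_stack(
    tiff_path: str | Path,
    positions_path: str | Path,
    pixel_size: float | None = None,
) -> FocusGrid:
    """Read a focus stack and its positions into a validated FocusGrid.

    The pixel size is taken from the positions-CSV header comment when
    present, then from the ``pixel_size`` argument, defaulting to 0.435 µm.
    """
    frames = np.asarray(tifffile.imread(tiff_path))
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise FocusStackError(
            f"expected grayscale pages, got array of shape {frames.shape}"
        )
    if frames.shape[0] == 0 or frames.size == 0:
        raise FocusStackError("focus stack is empty")
    frames, scale = _to_float(frames)
    header_pixel_size = None
    with open(positions_path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "pixel_size_um:" in line:
                header_pixel_size = float(line.split(":", 1)[1])
    positions = pd.read_csv(positions_path, comment="#")
    required = {"index", "row", "col"}
    if not required.issubset(positions.columns):
        raise FocusStackError(
            f"positions CSV must have columns {sorted(required)}, "
            f"got {list(positions.columns)}"
        )
    if len(positions) != len(frames):
        raise FocusStackError(
            f"TIFF has {len(frames)} pages but the positions table has "
            f"{len(positions)} rows"
        )
    if pixel_size is None:
        pixel_size = header_pixel_size if header_pixel_size is not None else 0.435
    meta = {"source": str(tiff_path)}
    if scale != 1.0:
        meta["intensity_scale"] = scale
    grid = FocusGrid(
        frames=frames.astype(float),
        positions=positions,
        pixel_size=float(pixel_size),
        meta=meta,
    )
    grid.validate()
    return grid


def write_model(path: str | Path, model: EigenPSFModel) -> None:
    """Serialize an eigen-PSF model to a single HDF5 container."""
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = MODEL_FORMAT_VERSION
        fh.attrs["metadata"] = json.dumps(
            {
                **model.metadata,
                "crop_size": model.crop_size,
                "pixel_size_um": model.pixel_size,
                "n_modes": model.n_max,
            }
        )
        fh.create_dataset("eigen_psfs", data=model.eigen_psfs)
        fh.create_dataset("eigenvalues", data=model.eigenvalues)
        fh.create_dataset("coeff_samples", data=model.coeff_samples)
        fh.create_dataset("coeff_maps", data=model.coeff_maps)
        fh.create_dataset("positions", data=model.positions)


def read_model(path: str | Path) -> EigenPSFModel:
    """Read a model container back; lossless at stored precision."""
    datasets = ["eigen_psfs", "eigenvalues", "coeff_samples", "coeff_maps", "positions"]
    try:
        with h5py.File(path, "r") as fh:
            version = fh.attrs.get("format_version")
            if version != MODEL_FORMAT_VERSION:
                raise ModelIOError(
                    f"model container at {path} has format version {version!r}; "
                    f"this build reads version {MODEL_FORMAT_VERSION!r} "
                    "(rebuild the model from its focus stack to migrate)"
                )
            arrays = {}
            for name in datasets:
                if name not in fh:
                    raise ModelIOError(f"model container is missing dataset '{name}'")
                arrays[name] = fh[name][()]
            metadata = json.loads(fh.attrs.get("metadata", "{}"))
    except OSError as exc:
        raise ModelIOError(f"cannot read model container at {path}: {exc}") from exc
    return EigenPSFModel(
        eigen_psfs=arrays["eigen_psfs"],
        eigenvalues=arrays["eigenvalues"],
        coeff_samples=arrays["coeff_samples"],
        coeff_maps=arrays["coeff_maps"],
        positions=arrays["positions"],
        crop_size=int(metadata.get("crop_size", arrays["eigen_psfs"].shape[1])),
        pixel_size=float(metadata.get("pixel_size_um", 0.435)),
        metadata=metadata,
    )


def read_image(path: str | Path) -> np.ndarray:
    """Read a single grayscale TIFF image as float."""
    image = tifffile.imread(path)
    if image.ndim == 3 and image.shape[0] == 1:
        image = image[0]
    if image.ndim != 2:
        raise FocusStackError(f"expected a single 2-D page, got shape {image.shape}")
    image, _ = _to_float(image)
    return image.astype(float)


def write_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def write_provenance(
    path: str | Path,
    command: str,
    parameters: dict,
    inputs: dict,
    outputs: dict,
    elapsed_s: float,
) -> None:
    """Record everything needed to reproduce a run alongside its outputs."""
    from . import __version__

    record = {
        "tool": "svmpsf",
        "version": __version__,
        "command": command,
        "parameters": parameters,
        "inputs": inputs,
        "outputs": outputs,
        "elapsed_s": round(elapsed_s, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "python": platform.python_version(),
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2)
        fh.write("\n")
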