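"""Voxel containers and TIFF I/O for confocal z-stacks.

The z axis is the optical axis: index 0 is the shallowest slice and depth
increases with the slice index.  Meristems are mounted on their side, so the
stack z axis approximates the apical-basal axis of the meristem and depth
below the apex can be read directly off the slice index.  All physical
distances are in micrometres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """A 3D (one channel) or 4D (channel-first) fluorescence stack.

    Parameters
    ----------
    data:
        Voxel intensities, shape ``(nz, ny, nx)`` or ``(nc, nz, ny, nx)``.
    dx, dy, dz:
        Physical voxel sizes in micrometres; ``dz`` is the z-step.
    channel:
        Free-form tag ("structural", "reporter", ...) for 3D stacks.
    """

    data: np.ndarray
    dx: float
    dy: float
    dz: float
    channel: str | None = None
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"expected 3D or 4D data, got ndim={self.data.ndim}")
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("voxel sizes must be positive")
        if np.issubdtype(self.data.dtype, np.floating) and np.nanmin(self.data) < 0:
            raise ValueError("intensities must be non-negative")

    # -- geometry helpers ---------------------------------------------------

    @property
    def n_channels(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[-3:])

    @property
    def nz(self) -> int:
        return self.data.shape[-3]

    @property
    def ny(self) -> int:
        return self.data.shape[-2]

    @property
    def nx(self) -> int:
        return self.data.shape[-1]

    def get_channel(self, index: int) -> "ImageStack":
        """Return a single-channel view of a multi-channel stack."""
        if self.data.ndim == 3:
            if index != 0:
                raise IndexError("single-channel stack has only channel 0")
            return self
        name = None
        if self.channel_names and index < len(self.channel_names):
            name = self.channel_names[index]
        return ImageStack(self.data[index], self.dx, self.dy, self.dz, channel=name)

    def x_um(self) -> np.ndarray:
        return np.arange(self.nx) * self.dx

    def y_um(self) -> np.ndarray:
        return np.arange(self.ny) * self.dy

    def z_um(self) -> np.ndarray:
        return np.arange(self.nz) * self.dz


def write_stack(path: str | Path, stack: ImageStack, truth: dict | None = None) -> Path:
    """Write a stack as an ImageJ-style TIFF with voxel sizes in metadata.

    Multi-channel stacks are stored with axes ZCYX (ImageJ hyperstack
    convention).  If ``truth`` is given it is written as a JSON sidecar next
    to the TIFF (``<stem>.truth.json``).
    """
    path = Path(path)
    data = stack.data
    if data.ndim == 3:
        data = data[None]
    ij = np.ascontiguousarray(np.moveaxis(data, 0, 1))  # (Z, C, Y, X)
    tifffile.imwrite(
        path,
        ij,
        imagej=True,
        resolution=(1.0 / stack.dx, 1.0 / stack.dy),
        metadata={"spacing": stack.dz, "unit": "um", "axes": "ZCYX"},
    )
    if truth is not None:
        sidecar_path(path).write_text(json.dumps(truth, indent=2))
    return path


def sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".truth.json")


def read_truth(path: str | Path) -> dict:
    """Read the ground-truth sidecar written next to a synthetic stack."""
    return json.loads(sidecar_path(path).read_text())


def read_stack(path: str | Path) -> ImageStack:
    """Read a TIFF stack written by :func:`write_stack` (or compatible).

    Voxel sizes default to (0.3, 0.3, 0.4) um when metadata is missing.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        dz = 0.4
        dx = dy = 0.3
        if tif.imagej_metadata and "spacing" in tif.imagej_metadata:
            dz = float(tif.imagej_metadata["spacing"])
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if xres is not None:
            num, den = xres.value
            if num:
                dx = den / num
        if yres is not None:
            num, den = yres.value
            if num:
                dy = den / num
    # normalise axis order to (C, Z, Y, X)
    order = [axes.index(a) for a in "CZYX" if a in axes]
    missing = [a for a in "CZYX" if a not in axes]
    data = np.transpose(data, order)
    for _ in missing:
        data = data[None]
    data = data.reshape(data.shape[-4:])
    if data.shape[0] == 1:
        return ImageStack(data[0], dx, dy, dz)
    return ImageStack(data, dx, dy, dz)
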