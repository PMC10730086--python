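"""Apex detection and 3D paraboloid masking of the meristem dome.

Fluorescence at the meristem boundaries (organ primordia, cauline-leaf
axils) must not leak into the axial profile, so quantification is restricted
to a paraboloid region fitted to the dome surface: the apex is located on
the structural (cell-wall) channel, curvatures are fitted in the two
orthogonal midplanes through the apex, and the mask keeps voxels at or below
the fitted surface within a lateral cutoff radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .stack import ImageStack


@dataclass
class ParaboloidModel:
    """Downward-opening paraboloid fitted to the dome surface.

    ``z(x, y) = z_apex + cx (x - x0)^2 + cy (y - y0)^2`` with apex
    coordinates in um and curvatures in 1/um.  ``cutoff_radius_um`` bounds
    the mask laterally (default 40 um) to exclude axillary signal.
    """

    apex_um: tuple[float, float, float]
    cx: float
    cy: float
    cutoff_radius_um: float = 40.0

    def __post_init__(self) -> None:
        if self.cx <= 0 or self.cy <= 0:
            raise ValueError("not dome-shaped: curvatures must be positive")
        if self.cutoff_radius_um <= 0:
            raise ValueError("cutoff radius must be positive")

    def surface_z(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        x0, y0, z0 = self.apex_um
        return z0 + self.cx * (x_um - x0) ** 2 + self.cy * (y_um - y0) ** 2


@dataclass
class RegionMask:
    """Boolean occupancy aligned voxel-for-voxel with its parent stack."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D (nz, ny, nx)")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _surface_depth_map(
    stack: ImageStack, threshold: float | None, median_size: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column z index of the topmost above-threshold voxel.

    Columns with no foreground are assigned ``nz`` (deeper than any slice).
    The depth map is median-filtered to suppress single-column noise.
    """
    data = stack.data
    if data.ndim != 3:
        raise ValueError("surface extraction needs a single-channel stack")
    if threshold is None:
        if data.max() == data.min():
            raise ValueError("no surface detected: stack is constant")
        threshold = float(threshold_otsu(data))
    fg = data > threshold
    if not fg.any():
        raise ValueError("no surface detected: no voxel above threshold")
    has_fg = fg.any(axis=0)
    top = np.argmax(fg, axis=0).astype(float)
    top[~has_fg] = stack.nz
    if median_size > 1:
        top = ndimage.median_filter(top, size=median_size, mode="nearest")
    return top, has_fg, fg


def detect_apex(
    structural: ImageStack,
    threshold: float | None = None,
    central_fraction: float = 0.5,
    median_size: int = 3,
) -> tuple[float, float, float]:
    """Locate the meristem apex as the shallowest central surface point.

    The structural channel is thresholded (Otsu by default), the topmost
    foreground voxel of each (y, x) column defines a surface depth map, the
    map is median-filtered, and the apex column is the global minimum-depth
    point within the central ``central_fraction`` of the field (which avoids
    picking up primordia at the field edge).  The apex z is refined to the
    midline of the stained wall: the centre of the contiguous foreground
    run at the top of the apex column, rather than its first voxel.
    Returns (x, y, z) in um.
    """
    top, _, fg = _surface_depth_map(structural, threshold, median_size)
    ny, nx = top.shape
    y0 = int(round(ny * (1 - central_fraction) / 2))
    x0 = int(round(nx * (1 - central_fraction) / 2))
    y1, x1 = ny - y0, nx - x0
    sub = top[y0:y1, x0:x1]
    if sub.min() >= structural.nz:
        raise ValueError("no surface detected in the central region")
    # the discrete depth map is flat around the apex of a shallow dome, so
    # take the plateau member nearest the plateau centroid, not the first
    ys, xs = np.nonzero(sub == sub.min())
    cy_, cx_ = ys.mean(), xs.mean()
    j = int(np.argmin((ys - cy_) ** 2 + (xs - cx_) ** 2))
    iy = int(ys[j]) + y0
    ix = int(xs[j]) + x0
    column = fg[:, iy, ix]
    if column.any():
        start = int(np.argmax(column))
        stop = start
        while stop + 1 < len(column) and column[stop + 1]:
            stop += 1
        z_idx = (start + stop) / 2.0
    else:  # median filter borrowed the depth from a neighbour column
        z_idx = top[iy, ix]
    return (ix * structural.dx, iy * structural.dy, z_idx * structural.dz)


def fit_quadratic_curvature(
    u_um: np.ndarray, z_um: np.ndarray, u0: float, z0: float
) -> float:
    """Least-squares curvature of ``z = z0 + c (u - u0)^2`` through fixed apex.

    One-parameter linear least squares: ``c = sum(d q) / sum(q^2)`` with
    ``d = z - z0`` and ``q = (u - u0)^2``.  Raises if fewer than 5 points or
    if the fitted curvature is not positive (surface not dome-shaped).
    """
    u_um = np.asarray(u_um, dtype=float)
    z_um = np.asarray(z_um, dtype=float)
    if u_um.size < 5:
        raise ValueError("need at least 5 surface points for the quadratic fit")
    q = (u_um - u0) ** 2
    denom = float(np.sum(q * q))
    if denom == 0:
        raise ValueError("degenerate abscissae: all points at the apex")
    c = float(np.sum((z_um - z0) * q) / denom)
    if c <= 0:
        raise ValueError("not dome-shaped: fitted curvature <= 0")
    return c


def _midplane_surface_points(
    stack: ImageStack,
    apex_um: tuple[float, float, float],
    axis: str,
    halfwidth_um: float,
    threshold: float | None,
) -> tuple[np.ndarray, np.ndarray]:
    top, has_fg, _ = _surface_depth_map(stack, threshold)
    x0, y0, _ = apex_um
    if axis == "x":
        iy = int(round(y0 / stack.dy))
        line = top[iy, :]
        valid = has_fg[iy, :]
        coords = stack.x_um()
        centre = x0
    else:
        ix = int(round(x0 / stack.dx))
        line = top[:, ix]
        valid = has_fg[:, ix]
        coords = stack.y_um()
        centre = y0
    sel = valid & (np.abs(coords - centre) <= halfwidth_um) & (line < stack.nz)
    return coords[sel], line[sel] * stack.dz


def fit_paraboloid(
    structural: ImageStack,
    apex_um: tuple[float, float, float],
    halfwidth_um: float = 25.0,
    threshold: float | None = None,
    cutoff_radius_um: float = 40.0,
) -> ParaboloidModel:
    """Fit dome curvatures in the two orthogonal midplanes through the apex.

    Surface points are the topmost above-threshold voxels per column within
    ``halfwidth_um`` of the apex in the xz and yz midplanes; each plane gets
    an independent one-parameter quadratic fit with the apex held fixed.
    """
    ux, zx = _midplane_surface_points(structural, apex_um, "x", halfwidth_um, threshold)
    uy, zy = _midplane_surface_points(structural, apex_um, "y", halfwidth_um, threshold)
    cx = fit_quadratic_curvature(ux, zx, apex_um[0], apex_um[2])
    cy = fit_quadratic_curvature(uy, zy, apex_um[1], apex_um[2])
    return ParaboloidModel(apex_um=apex_um, cx=cx, cy=cy,
                           cutoff_radius_um=cutoff_radius_um)


def build_mask(
    model: ParaboloidModel, stack: ImageStack, margin_um: float = 0.0
) -> RegionMask:
    """Voxels at or below the fitted surface within the lateral cutoff.

    The boundary is closed: a voxel exactly on the surface is included.
    ``margin_um`` moves the surface upward, admitting a skin of voxels above
    it; the mask grows monotonically with both margin and cutoff radius.
    """
    x0, y0, _ = model.apex_um
    X, Y = np.meshgrid(stack.x_um(), stack.y_um())
    z_surf = model.surface_z(X, Y)
    r2 = (X - x0) ** 2 + (Y - y0) ** 2
    Z = stack.z_um()[:, None, None]
    mask = (Z >= z_surf[None, :, :] - margin_um) & (
        r2[None, :, :] <= model.cutoff_radius_um ** 2
    )
    return RegionMask(
        mask,
        provenance={
            "model": "paraboloid",
            "apex_um": list(model.apex_um),
            "cx": model.cx,
            "cy": model.cy,
            "cutoff_radius_um": model.cutoff_radius_um,
            "margin_um": margin_um,
        },
    )
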