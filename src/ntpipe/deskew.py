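"""Deskew reconstruction of stage-scanned diagonal slice stacks.

Stage scanning advances the specimen through a fixed light sheet, so
consecutive camera frames sample planes that are displaced both laterally
(along the in-plane scan axis x) and in depth (z).  Reconstruction places
slice k at depth ``k * scan_step * sin(angle)`` and shears it along x by
``k * scan_step * cos(angle)``, producing an orthogonal x,y,z voxel grid
with spacing ``voxel_xy`` laterally and ``scan_step * sin(angle)``
axially.  Projections ignore the zero-filled padding introduced by the
shear via a validity mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class DiagonalStack:
    """Raw sheared slice series with its scan geometry.

    ``slices`` is indexed (k, i, j): slice number, camera row (y), camera
    column (x at the slice's own depth).  ``voxel_xy`` is nm/pixel,
    ``scan_step`` um, ``scan_angle`` degrees.  ``origin`` is the world
    position (um) of voxel (0, 0, 0).
    """

    slices: np.ndarray
    voxel_xy: float | None = None
    scan_step: float | None = None
    scan_angle: float | None = None
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=float)
        if self.slices.ndim != 3 or self.slices.shape[0] < 1:
            raise ValueError("stack must be a (k, i, j) array with k >= 1")


@dataclass
class Volume:
    """Axis-aligned voxel grid; ``voxels`` indexed (z, y, x).

    ``spacing`` is um per voxel for (z, y, x); ``origin`` the world
    coordinate (x, y, z) of voxel (0, 0, 0) in um.  ``mask`` marks voxels
    that received data (False where the shear left padding).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mask: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("volume must be 3D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite voxels")
        if self.mask is None:
            self.mask = np.ones(self.voxels.shape, dtype=bool)

    def world_to_index(self, points_um: np.ndarray) -> np.ndarray:
        """Map world (x, y, z) um to fractional (z, y, x) voxel indices."""
        p = np.atleast_2d(np.asarray(points_um, dtype=float))
        ox, oy, oz = self.origin
        sz, sy, sx = self.spacing
        return np.column_stack([(p[:, 2] - oz) / sz, (p[:, 1] - oy) / sy, (p[:, 0] - ox) / sx])

    def index_to_world(self, idx_zyx: np.ndarray) -> np.ndarray:
        """Map fractional (z, y, x) indices to world (x, y, z) um."""
        i = np.atleast_2d(np.asarray(idx_zyx, dtype=float))
        ox, oy, oz = self.origin
        sz, sy, sx = self.spacing
        return np.column_stack([ox + i[:, 2] * sx, oy + i[:, 1] * sy, oz + i[:, 0] * sz])


def deskew_volume(stack: DiagonalStack, interpolation: str = "linear") -> Volume:
    """Reconstruct an orthogonal volume from a diagonal slice stack.

    Each slice k is translated along x by ``k * scan_step * cos(angle)``
    and placed at depth ``k * scan_step * sin(angle)``.  The generally
    non-integer pixel shift is applied by linear-weight splatting (default)
    or rounded to the nearest pixel (``nearest``); linear splatting
    conserves total intensity exactly.
    """
    if interpolation not in ("nearest", "linear"):
        raise ValueError("interpolation must be 'nearest' or 'linear'")
    if stack.voxel_xy is None or stack.scan_step is None or stack.scan_angle is None:
        raise ValueError("no scan geometry")
    if stack.scan_angle == 0:
        raise ValueError("degenerate geometry")

    theta = math.radians(stack.scan_angle)
    vx_um = stack.voxel_xy / 1000.0
    shift_px = stack.scan_step * math.cos(theta) / vx_um  # per-slice x shift
    dz_um = stack.scan_step * math.sin(theta)

    nk, ni, nj = stack.slices.shape
    nx = nj + int(math.ceil((nk - 1) * shift_px)) + 1
    out = np.zeros((nk, ni, nx), dtype=float)
    mask = np.zeros((nk, ni, nx), dtype=bool)

    for k in range(nk):
        s = k * shift_px
        if interpolation == "nearest":
            base = int(round(s))
            out[k, :, base : base + nj] = stack.slices[k]
            mask[k, :, base : base + nj] = True
        else:
            base = int(math.floor(s))
            frac = s - base
            out[k, :, base : base + nj] += (1.0 - frac) * stack.slices[k]
            if frac > 0.0:
                out[k, :, base + 1 : base + 1 + nj] += frac * stack.slices[k]
                # edge columns receive partial splat weight only
                mask[k, :, base + 1 : base + nj] = True
            else:
                mask[k, :, base : base + nj] = True

    return Volume(
        voxels=out,
        spacing=(dz_um, vx_um, vx_um),
        origin=stack.origin,
        mask=mask,
        provenance={"interpolation": interpolation, **stack.meta},
    )


_PROJECTION_AXES = {"z_top": 0, "y_side": 1, "x_side": 2}


def max_projection(vol: Volume, axis: str = "z_top") -> np.ndarray:
    """Maximum-intensity projection along z (top view) or a lateral axis.

    Padding voxels outside the validity mask are ignored; pixels with no
    valid voxel along the projection axis are 0.
    """
    if axis not in _PROJECTION_AXES:
        raise ValueError(f"axis must be one of {sorted(_PROJECTION_AXES)}")
    if vol.voxels.size == 0:
        raise ValueError("empty volume")
    ax = _PROJECTION_AXES[axis]
    data = np.where(vol.mask, vol.voxels, -np.inf)
    proj = data.max(axis=ax)
    return np.where(np.isfinite(proj), proj, 0.0)
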