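"""Volume rendering and diagonal-slice acquisition simulation.

Both operations evaluate the same analytic blurred scene density
(:func:`ntpipe.scene.evaluate_scene`), differing only in where they
sample it: ``render_scene`` on the orthogonal output grid of the deskew
step, ``simulate_diagonal_acquisition`` on the sheared slice planes of a
stage scan.  Deskewing a simulated acquisition therefore reconstructs the
rendered volume up to interpolation error, which is the round-trip oracle
used throughout the tests.
"""

from __future__ import annotations

import numpy as np

from ntpipe.deskew import DiagonalStack, Volume
from ntpipe.optics import OpticsModel
from ntpipe.scene import VolumeScene, evaluate_scene


def _scene_grid_shape(scene: VolumeScene, optics: OpticsModel) -> tuple[int, int, int]:
    (x0, x1), (y0, y1), (z0, z1) = scene.bounds
    vx = optics.voxel_xy_um
    vz = optics.axial_spacing_um
    nx = int(np.ceil((x1 - x0) / vx)) + 1
    ny = int(np.ceil((y1 - y0) / vx)) + 1
    nz = int(np.ceil((z1 - z0) / vz)) + 1
    return nz, ny, nx


def render_scene(
    scene: VolumeScene,
    optics: OpticsModel,
    shape_zyx: tuple[int, int, int] | None = None,
    origin: tuple[float, float, float] | None = None,
) -> Volume:
    """Render the ground-truth scene on an orthogonal voxel grid.

    Grid spacing is ``voxel_xy`` laterally and ``scan_step * sin(angle)``
    axially — the native grid of the deskew reconstruction — so rendered
    volumes are directly comparable with deskewed acquisitions.  Noise is
    applied per the optics model; intensities are non-negative.
    """
    if scene.is_empty:
        raise ValueError("empty scene")
    if shape_zyx is None:
        shape_zyx = _scene_grid_shape(scene, optics)
    if origin is None:
        (x0, _), (y0, _), (z0, _) = scene.bounds
        origin = (x0, y0, z0)
    nz, ny, nx = shape_zyx
    ox, oy, oz = origin
    vx = optics.voxel_xy_um
    vz = optics.axial_spacing_um
    z = oz + vz * np.arange(nz)[:, None, None]
    y = oy + vx * np.arange(ny)[None, :, None]
    x = ox + vx * np.arange(nx)[None, None, :]
    vol = evaluate_scene(scene, x, y, z, optics.sigma_lateral_um, optics.sigma_axial_um)
    vol = optics.apply_noise(vol, np.random.default_rng(optics.rng_seed))
    return Volume(
        voxels=vol,
        spacing=(vz, vx, vx),
        origin=origin,
        provenance={"source": "render_scene", "seed": optics.rng_seed},
    )


def simulate_diagonal_acquisition(
    scene: VolumeScene,
    optics: OpticsModel,
    n_slices: int | None = None,
    slice_shape: tuple[int, int] | None = None,
    origin: tuple[float, float, float] | None = None,
) -> DiagonalStack:
    """Simulate a stage-scanned acquisition as a sheared slice series.

    Slice k, camera pixel (i, j) samples the world point
    ``origin + (j * voxel_xy + k * step * cos(angle),
    i * voxel_xy, k * step * sin(angle))`` — each frame is laterally
    offset by the stage advance, so the stack covers a sheared
    parallelepiped, exactly as on the instrument.  The stored geometry
    makes the deskew transform invertible.
    """
    if scene.is_empty:
        raise ValueError("empty scene")
    (x0, x1), (y0, y1), (z0, z1) = scene.bounds
    vx = optics.voxel_xy_um
    if origin is None:
        origin = (x0, y0, z0)
    ox, oy, oz = origin
    if n_slices is None:
        n_slices = int(np.ceil((z1 - oz) / optics.axial_spacing_um)) + 1
    if slice_shape is None:
        ni = int(np.ceil((y1 - oy) / vx)) + 1
        nj = int(np.ceil((x1 - ox) / vx)) + 1
    else:
        ni, nj = slice_shape

    if n_slices < 1:
        raise ValueError("scan traverses no part of the scene bounds")
    k = np.arange(n_slices)
    z_k = oz + k * optics.axial_spacing_um
    x_shift = ox + k * optics.lateral_shift_um
    if z_k[0] > z1 or z_k[-1] < z0:
        raise ValueError("scan traverses no part of the scene bounds")

    z = z_k[:, None, None] + np.zeros((1, ni, nj))
    y = oy + vx * np.arange(ni)[None, :, None] + np.zeros((n_slices, 1, nj))
    x = x_shift[:, None, None] + vx * np.arange(nj)[None, None, :]
    slices = evaluate_scene(scene, x, y, z, optics.sigma_lateral_um, optics.sigma_axial_um)
    slices = optics.apply_noise(slices, np.random.default_rng(optics.rng_seed))
    return DiagonalStack(
        slices=slices,
        voxel_xy=optics.voxel_xy,
        scan_step=optics.scan_step,
        scan_angle=optics.scan_angle,
        origin=origin,
        meta={"source": "simulate_diagonal_acquisition", "seed": optics.rng_seed},
    )
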