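"""Ground-truth 3D scene geometry for the volume simulator.

A scene holds membrane-labelled cell bodies (ellipsoids), nanotubes
(3D polylines with a physical diameter, typically below the lateral PSF)
and a substrate plane.  The blurred fluorescence density of a scene can be
evaluated analytically at arbitrary world coordinates, which lets the same
function drive both orthogonal rendering and diagonal-slice acquisition
without a rasterisation round-trip.

Coordinate convention: world coordinates (x, y, z) in um, x the in-plane
scan axis, z the detection/depth axis; the substrate is the plane
z = substrate_z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0e
from scipy.stats import norm

CONTACT_CELL_CELL = "cell_cell"
CONTACT_SUBSTRATE = "substrate"


@dataclass
class Ellipsoid:
    """Axis-aligned ellipsoidal cell body (centre and radii in um)."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    intensity: float = 1.0


@dataclass
class Tube:
    """Nanotube: centreline polyline (um), physical diameter (nm), label.

    ``diameter_nm`` may be far below the lateral PSF FWHM; sub-resolution
    tubes are the norm.  A single-point centreline renders as a point
    source.
    """

    points: np.ndarray  # (N, 3) um
    diameter_nm: float = 100.0
    intensity: float = 1.0
    contact_class: str = CONTACT_CELL_CELL

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 3:
            raise ValueError("tube centerline must be (N, 3)")
        if self.diameter_nm <= 0:
            raise ValueError("tube diameter must be positive")

    @property
    def length_um(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


@dataclass
class VolumeScene:
    """Ground-truth scene: cell bodies, tubes, substrate, bounding box."""

    cell_bodies: list[Ellipsoid] = field(default_factory=list)
    tubes: list[Tube] = field(default_factory=list)
    substrate_z: float = 0.0
    bounds: tuple[tuple[float, float], tuple[float, float], tuple[float, float]] = (
        (0.0, 20.0),
        (0.0, 20.0),
        (0.0, 10.0),
    )

    def __post_init__(self) -> None:
        (x0, x1), (y0, y1), (z0, z1) = self.bounds
        lo = np.array([x0, y0, z0])
        hi = np.array([x1, y1, z1])
        if np.any(hi <= lo):
            raise ValueError("bounds must have positive extent on every axis")
        for tube in self.tubes:
            if np.any(tube.points < lo - 1e-9) or np.any(tube.points > hi + 1e-9):
                raise ValueError("tube centerline leaves the scene bounds")

    @property
    def is_empty(self) -> bool:
        return not self.cell_bodies and not self.tubes


def _blurred_disk_profile(diameter_um: float, sigma_um: float) -> tuple[np.ndarray, np.ndarray]:
    """Radial profile of a uniform 2D disk convolved with a 2D Gaussian.

    Returns (rho grid, profile) with the profile normalised to 1 at the
    centre.  Computed with the Rice-distribution integral
    f(rho) = int_0^R r/sigma^2 exp(-(r-rho)^2 / 2 sigma^2) i0e(r rho / sigma^2) dr,
    which converges to a Gaussian as the diameter goes to zero.
    """
    R = diameter_um / 2.0
    cutoff = R + 5.0 * sigma_um
    rho = np.linspace(0.0, cutoff, 512)
    if R < sigma_um * 1e-3:
        return rho, np.exp(-0.5 * (rho / sigma_um) ** 2)
    r = np.linspace(0.0, R, 256)[None, :]
    rr = rho[:, None]
    integrand = (r / sigma_um**2) * np.exp(-0.5 * ((r - rr) / sigma_um) ** 2) * i0e(
        r * rr / sigma_um**2
    )
    prof = np.trapezoid(integrand, r[0], axis=1)
    return rho, prof / prof[0]


def _nearest_offsets(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Offset vectors from query points to their nearest point on a polyline.

    Exact per-segment projection; segments are visited in order and ties go
    to the earlier segment.  Returns (K, 3) offsets (point - nearest).
    """
    pts = np.asarray(points, dtype=float)
    poly = np.atleast_2d(polyline)
    if len(poly) == 1:
        return pts - poly[0]
    best_d2 = np.full(len(pts), np.inf)
    best_off = np.zeros_like(pts)
    for a, b in zip(poly[:-1], poly[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            proj = np.zeros(len(pts))
        else:
            proj = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
        nearest = a + proj[:, None] * ab
        off = pts - nearest
        d2 = np.einsum("ij,ij->i", off, off)
        better = d2 < best_d2 - 1e-15
        best_d2[better] = d2[better]
        best_off[better] = off[better]
    return best_off


def evaluate_scene(
    scene: VolumeScene,
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    sigma_lateral_um: float,
    sigma_axial_um: float,
) -> np.ndarray:
    """Blurred fluorescence density of the scene at world points (um).

    Tubes are modelled as uniform disks of stain convolved with the PSF:
    laterally the exact disk (x) Gaussian radial profile, axially a
    Gaussian at the sheet sigma.  The decomposition assumes tubes run
    roughly parallel to the lateral plane (they are suspended above the
    substrate), which makes it exact for horizontal tubes and for point
    sources.  Cell-body ellipsoids get a soft (erf) edge of lateral sigma.
    """
    x, y, z = np.broadcast_arrays(np.asarray(x, float), np.asarray(y, float), np.asarray(z, float))
    out = np.zeros(x.shape, dtype=float)
    pts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    flat = out.ravel()

    for body in scene.cell_bodies:
        c = np.asarray(body.center, float)
        r = np.asarray(body.radii, float)
        rho = np.linalg.norm((pts - c) / r, axis=1)
        signed = (rho - 1.0) * float(np.min(r))
        flat += body.intensity * norm.sf(signed / sigma_lateral_um)

    for tube in scene.tubes:
        rho_grid, prof = _blurred_disk_profile(tube.diameter_nm / 1000.0, sigma_lateral_um)
        cutoff_lat = rho_grid[-1]
        cutoff_ax = 5.0 * sigma_axial_um
        # cheap bounding-box rejection before exact projection
        lo = tube.points.min(axis=0) - np.array([cutoff_lat, cutoff_lat, cutoff_ax])
        hi = tube.points.max(axis=0) + np.array([cutoff_lat, cutoff_lat, cutoff_ax])
        sel = np.all((pts >= lo) & (pts <= hi), axis=1)
        if not np.any(sel):
            continue
        off = _nearest_offsets(pts[sel], tube.points)
        rho_lat = np.hypot(off[:, 0], off[:, 1])
        dz = off[:, 2]
        lat = np.interp(rho_lat, rho_grid, prof, right=0.0)
        ax = np.exp(-0.5 * (dz / sigma_axial_um) ** 2)
        flat[sel] += tube.intensity * lat * ax

    return flat.reshape(x.shape)
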