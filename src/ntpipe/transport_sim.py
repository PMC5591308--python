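"""Synthetic puncta-transport movies along a nanotube path.

Vesicle-scale membrane constituents move along the tube at near-constant
speed (a few um/min, the signature of motor-driven transport).  Each
particle is rendered as a 2D Gaussian spot at its arc-length position per
frame; particles that run off either end of the path exit, ending their
track.  Ground-truth arc-length series are exported alongside the movie.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ntpipe.tracking import Track


@dataclass
class ParticleSpec:
    """One particle: start arc length (um), speed (um/min), direction."""

    start_s_um: float
    speed_um_min: float
    direction: int = 1
    start_frame: int = 0
    intensity: float = 200.0


@dataclass
class TransportScenario:
    """Path geometry, particle kinematics and imaging parameters.

    The path is a 2D polyline in um (image coordinates, (y, x)).
    ``particle_sigma_nm`` is the rendered spot's Gaussian sigma — the
    PSF-limited size of a sub-resolution punctum.
    """

    path_um: np.ndarray
    particles: list[ParticleSpec]
    n_frames: int = 60
    frame_interval_s: float = 1.0
    pixel_size_um: float = 0.105
    shape: tuple[int, int] = (128, 256)
    particle_sigma_nm: float = 200.0
    background_level: float = 10.0
    noise_model: str = "none"  # none | poisson_gaussian
    read_noise_sigma: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.path_um = np.atleast_2d(np.asarray(self.path_um, dtype=float))
        if len(self.path_um) < 2:
            raise ValueError("path needs at least two points")
        seg = np.linalg.norm(np.diff(self.path_um, axis=0), axis=1)
        if seg.sum() <= 0:
            raise ValueError("path length must be positive")
        self._cum = np.concatenate([[0.0], np.cumsum(seg)])
        self._seg = seg

    @property
    def path_length_um(self) -> float:
        return float(self._cum[-1])

    def point_at(self, s_um: np.ndarray) -> np.ndarray:
        """World (y, x) um position at arc length(s) along the path."""
        s = np.atleast_1d(np.asarray(s_um, dtype=float))
        i = np.clip(np.searchsorted(self._cum, s, side="right") - 1, 0, len(self._seg) - 1)
        f = np.where(self._seg[i] > 0, (s - self._cum[i]) / self._seg[i], 0.0)
        return self.path_um[i] + f[:, None] * (self.path_um[i + 1] - self.path_um[i])


def simulate_transport_movie(sc: TransportScenario) -> tuple[np.ndarray, list[Track]]:
    """Render the scenario; returns (movie (T, H, W), ground-truth tracks).

    Ground-truth tracks carry the exact per-frame positions and
    arc-length series; their velocity fields are left unset (they are
    what the tracker estimates).  Zero particles produce a warning and a
    background-only movie.
    """
    h, w = sc.shape
    movie = np.full((sc.n_frames, h, w), float(sc.background_level))
    if not sc.particles:
        warnings.warn("transport scenario has no particles; returning empty movie")
        return _finalize(movie, sc), []

    sigma_px = sc.particle_sigma_nm / 1000.0 / sc.pixel_size_um
    yy, xx = np.mgrid[0:h, 0:w]
    L = sc.path_length_um
    truths: list[Track] = []
    for pid, p in enumerate(sc.particles):
        frames, ss = [], []
        for t in range(p.start_frame, sc.n_frames):
            dt_min = (t - p.start_frame) * sc.frame_interval_s / 60.0
            s = p.start_s_um + p.direction * p.speed_um_min * dt_min
            if s < 0.0 or s > L:
                break  # particle exits: track ends
            frames.append(t)
            ss.append(s)
        if not frames:
            continue
        ss = np.asarray(ss)
        pos = sc.point_at(ss)  # (n, 2) (y, x) um
        for t, (py, px) in zip(frames, pos):
            cy, cx = py / sc.pixel_size_um, px / sc.pixel_size_um
            movie[t] += p.intensity * np.exp(
                -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma_px**2)
            )
        times = np.asarray(frames) * sc.frame_interval_s
        truths.append(
            Track(
                particle_id=pid,
                frames=np.asarray(frames),
                t_s=times,
                xy_um=pos[:, ::-1].copy(),  # store (x, y)
                s_um=ss,
            )
        )
    return _finalize(movie, sc), truths


def _finalize(movie: np.ndarray, sc: TransportScenario) -> np.ndarray:
    if sc.noise_model == "poisson_gaussian":
        rng = np.random.default_rng(sc.rng_seed)
        movie = rng.poisson(np.clip(movie, 0.0, None)).astype(float)
        movie = np.clip(movie + rng.normal(0.0, sc.read_noise_sigma, movie.shape), 0.0, None)
    elif sc.noise_model != "none":
        raise ValueError("noise_model must be 'none' or 'poisson_gaussian'")
    return movie
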