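"""Synthetic Ca2+ uncaging movies with ground truth.

A scenario places circular cells in a 2D field: one stimulated cell that
responds at the stimulus, nanotube-connected responder cells that respond
after a per-cell delay, and non-connected cells that never respond.  Each
responding pixel follows a rise-then-exponential-decay kernel scaled by
the cell's true peak dF/F0 on top of a constant baseline; within a
responder the activation front spreads from an initiation point at
constant speed while every pixel of the cell reaches its peak at a common
cell-level peak time, so both the initiation geometry and the
peak-to-peak lag are exact generator truths.  Nanotube pixels carry
baseline fluorescence but no dF/F0 rise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import line as draw_line

from ntpipe.calcium import CalciumMovie


@dataclass
class CellSpec:
    """One cell: geometry in um (image coordinates, (y, x)) and truth."""

    cell_id: str
    center_um: tuple[float, float]
    radius_um: float
    peak_dff: float = 0.0
    lag_s: float = 0.0
    init_point_um: tuple[float, float] | None = None
    connected: bool = False
    stimulated: bool = False


@dataclass
class CalciumScenario:
    """Scene and acquisition parameters for one simulated movie.

    Defaults follow the widefield recording geometry used throughout:
    0.166 um pixels at 10 frames/s; the stimulus must leave more than 100
    baseline frames.  ``rise_s`` is the cell-level rise duration (onset to
    peak) and ``decay_tau_s`` the exponential decay constant;
    ``wave_speed_um_s`` the intracellular activation-front speed.
    """

    cells: list[CellSpec]
    stim_frame: int = 110
    n_frames: int = 700
    frame_rate: float = 10.0
    pixel_size: float = 0.166
    shape: tuple[int, int] = (512, 512)
    baseline_level: float = 100.0
    background_level: float = 10.0
    rise_s: float = 5.0
    decay_tau_s: float = 20.0
    wave_speed_um_s: float = 10.0
    noise_model: str = "none"  # none | poisson_gaussian
    read_noise_sigma: float = 2.0
    rng_seed: int = 0
    draw_tubes: bool = True

    def __post_init__(self) -> None:
        if self.stim_frame <= 100:
            raise ValueError("stim_frame must exceed 100 (F0 baseline window)")
        if self.n_frames <= self.stim_frame:
            raise ValueError("movie ends before the stimulus")
        stim = [c for c in self.cells if c.stimulated]
        if len(stim) > 1:
            raise ValueError("at most one stimulated cell")
        for c in self.cells:
            if not c.stimulated and not c.connected and c.peak_dff != 0.0:
                raise ValueError(
                    f"non-connected cell {c.cell_id!r} must have true peak dF/F0 = 0"
                )

    @property
    def stim_time_s(self) -> float:
        return self.stim_frame / self.frame_rate


@dataclass
class CellTruth:
    """Ground truth exported with each simulated movie."""

    cell_id: str
    polygon_px: np.ndarray  # (N, 2) (row, col)
    peak_dff: float
    lag_s: float
    peak_time_s: float | None
    init_point_um: tuple[float, float] | None
    connected: bool
    stimulated: bool
    trace: np.ndarray = field(default=None, repr=False)


def _circle_polygon(center_px: np.ndarray, radius_px: float, n: int = 48) -> np.ndarray:
    ang = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    return np.column_stack(
        [center_px[0] + radius_px * np.sin(ang), center_px[1] + radius_px * np.cos(ang)]
    )


def simulate_calcium_movie(sc: CalciumScenario) -> tuple[CalciumMovie, list[CellTruth]]:
    """Render the scenario to a movie plus per-cell ground truth.

    Per-pixel fluorescence is
    ``baseline * (1 + peak * k(p, t)) + background (+ noise)`` inside
    cells, ``background`` elsewhere, with ``k`` rising (half-cosine) from
    the pixel's wavefront arrival time to 1 at the cell's common peak
    time and decaying exponentially thereafter.
    """
    h, w = sc.shape
    t = np.arange(sc.n_frames) / sc.frame_rate
    movie = np.full((sc.n_frames, h, w), float(sc.background_level))
    yy, xx = np.mgrid[0:h, 0:w]
    pos_um = np.stack([yy * sc.pixel_size, xx * sc.pixel_size])

    truths: list[CellTruth] = []
    stim_cells = [c for c in sc.cells if c.stimulated]
    for cell in sc.cells:
        c_um = np.asarray(cell.center_um, dtype=float)
        dist_c = np.hypot(pos_um[0] - c_um[0], pos_um[1] - c_um[1])
        mask = dist_c <= cell.radius_um
        npix = int(mask.sum())
        if npix == 0:
            raise ValueError(f"cell {cell.cell_id!r} lies outside the field")
        movie[:, mask] = sc.baseline_level + sc.background_level

        peak_time = None
        trace = np.zeros(sc.n_frames)
        if cell.peak_dff != 0.0:
            peak_time = sc.stim_time_s + sc.rise_s + cell.lag_s
            onset = peak_time - sc.rise_s
            if cell.stimulated or cell.init_point_um is None:
                t_act = np.full(npix, onset)
            else:
                init = np.asarray(cell.init_point_um, dtype=float)
                d_init = np.hypot(
                    pos_um[0][mask] - init[0], pos_um[1][mask] - init[1]
                )
                t_act = onset + d_init / sc.wave_speed_um_s
                if t_act.max() >= peak_time:
                    raise ValueError(
                        "wavefront slower than the rise: increase wave_speed_um_s"
                    )
            k = _kernel(t, t_act, peak_time, sc.decay_tau_s)
            movie[:, mask] += sc.baseline_level * cell.peak_dff * k
            trace = cell.peak_dff * k.mean(axis=1)

        truths.append(
            CellTruth(
                cell_id=cell.cell_id,
                polygon_px=_circle_polygon(c_um / sc.pixel_size, cell.radius_um / sc.pixel_size),
                peak_dff=cell.peak_dff,
                lag_s=cell.lag_s,
                peak_time_s=peak_time,
                init_point_um=cell.init_point_um,
                connected=cell.connected,
                stimulated=cell.stimulated,
                trace=trace,
            )
        )

    if sc.draw_tubes and stim_cells:
        _draw_tubes(movie, sc, stim_cells[0])

    if sc.noise_model == "poisson_gaussian":
        rng = np.random.default_rng(sc.rng_seed)
        movie = rng.poisson(np.clip(movie, 0.0, None)).astype(float)
        movie = np.clip(movie + rng.normal(0.0, sc.read_noise_sigma, movie.shape), 0.0, None)
    elif sc.noise_model != "none":
        raise ValueError("noise_model must be 'none' or 'poisson_gaussian'")

    cal = CalciumMovie(
        frames=movie,
        frame_rate=sc.frame_rate,
        pixel_size=sc.pixel_size,
        stim_frame=sc.stim_frame,
        background=float(sc.background_level),
        meta={"source": "simulate_calcium_movie", "seed": sc.rng_seed},
    )
    return cal, truths


def _kernel(t: np.ndarray, t_act: np.ndarray, t_peak: float, tau: float) -> np.ndarray:
    """Rise-decay kernel, (T, npix); 0 before activation, 1 at t_peak."""
    tt = t[:, None]
    ta = t_act[None, :]
    rise_dur = np.maximum(t_peak - ta, 1e-9)
    phase = np.clip((tt - ta) / rise_dur, 0.0, 1.0)
    rise = 0.5 - 0.5 * np.cos(math.pi * phase)
    decay = np.exp(-np.maximum(tt - t_peak, 0.0) / tau)
    k = np.where(tt < ta, 0.0, np.where(tt <= t_peak, rise, decay))
    return k


def _draw_tubes(movie: np.ndarray, sc: CalciumScenario, stim: CellSpec) -> None:
    """Stamp baseline-level (non-responding) nanotube lines from the
    stimulated cell to each connected cell."""
    h, w = sc.shape
    a = np.asarray(stim.center_um) / sc.pixel_size
    for cell in sc.cells:
        if not cell.connected or cell.stimulated:
            continue
        b = np.asarray(cell.center_um) / sc.pixel_size
        rr, cc = draw_line(int(a[0]), int(a[1]), int(b[0]), int(b[1]))
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        rr, cc = rr[keep], cc[keep]
        movie[:, rr, cc] = np.maximum(
            movie[:, rr, cc], sc.baseline_level * 0.5 + sc.background_level
        )
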