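"""Puncta detection, linking, path projection and motion classification.

Detection finds local maxima of a Laplacian-of-Gaussian response with
sub-pixel quadratic refinement; linking is globally optimal
nearest-neighbour assignment per frame pair (Hungarian algorithm) with
gap closing.  Tracks are projected onto a reference path to obtain an
arc-length series s(t), from which the mean track velocity (net
arc-length displacement over duration, in um/min), a regression-slope
velocity, a straightness index and the MSD scaling exponent alpha are
computed.  Directed transport shows straightness near 1 and alpha near
2; a diffusive random walk has alpha near 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

MOTION_DIRECTED = "directed"
MOTION_DIFFUSIVE = "diffusive"
MOTION_AMBIGUOUS = "ambiguous"


@dataclass
class Track:
    """Time-stamped particle positions with path-projected coordinates."""

    particle_id: int
    frames: np.ndarray  # frame indices, strictly increasing
    t_s: np.ndarray  # times in s
    xy_um: np.ndarray  # (N, 2) positions (x, y) um
    s_um: np.ndarray | None = None  # arc length along reference path
    off_path: np.ndarray | None = None
    velocity_um_min: float | None = None
    slope_velocity_um_min: float | None = None
    direction: int | None = None
    straightness: float | None = None
    msd_alpha: float | None = None
    motion_class: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.t_s = np.asarray(self.t_s, dtype=float)
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("track times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


def detect_spots(
    frame: np.ndarray,
    sigma_px: float,
    snr_min: float = 5.0,
    rel_min: float = 1e-3,
) -> np.ndarray:
    """Sub-pixel spot positions ((row, col) px) in one frame.

    Local maxima of the scale-normalised negative Laplacian-of-Gaussian
    response at ``sigma_px`` are kept when the peak exceeds both
    ``snr_min`` robust noise s.d. (1.4826 MAD) of the response and
    ``rel_min`` of the global response maximum (which also rejects the
    flat-background plateaus of a noise-free image); plateau ties are
    collapsed to a single detection.  Positions are refined per axis by a
    quadratic fit to the three-point neighbourhood.  A blank frame yields
    an empty (0, 2) array.
    """
    img = np.asarray(frame, dtype=float)
    if np.ptp(img) == 0:
        return np.empty((0, 2))
    resp = -(sigma_px**2) * ndimage.gaussian_laplace(img, sigma_px)
    noise = 1.4826 * np.median(np.abs(resp - np.median(resp)))
    thr = max(snr_min * noise, rel_min * float(resp.max()), 1e-8 * float(np.ptp(img)))
    is_max = (resp == ndimage.maximum_filter(resp, size=3)) & (resp > thr)
    is_max[0, :] = is_max[-1, :] = is_max[:, 0] = is_max[:, -1] = False
    labels, n = ndimage.label(is_max)
    out = []
    for comp in range(1, n + 1):
        rows, cols = np.nonzero(labels == comp)
        best = np.argmax(resp[rows, cols])
        r, c = int(rows[best]), int(cols[best])
        dr = _quadratic_offset(resp[r - 1, c], resp[r, c], resp[r + 1, c])
        dc = _quadratic_offset(resp[r, c - 1], resp[r, c], resp[r, c + 1])
        out.append((r + dr, c + dc))
    return np.asarray(out, dtype=float).reshape(-1, 2)


def _quadratic_offset(fm: float, f0: float, fp: float) -> float:
    denom = fm - 2.0 * f0 + fp
    if denom >= 0:  # not a proper maximum; keep integer position
        return 0.0
    return float(np.clip(0.5 * (fm - fp) / denom, -0.5, 0.5))


def link_tracks(
    detections: list[np.ndarray],
    max_disp_px: float,
    max_gap: int = 2,
    min_length: int = 2,
) -> list[Track]:
    """Link per-frame detections into tracks.

    Frame-to-frame correspondences are the global minimum-cost assignment
    (Hungarian) where each active track's cost for a detection is the
    distance from its constant-velocity prediction (last position plus
    the last step, scaled by the gap); the velocity term is what lets two
    particles crossing at distinct velocities keep their identities.
    Candidates are gated at ``max_disp_px * (gap + 1)`` from the last
    observed position; a track missing for up to ``max_gap`` consecutive
    frames is bridged, beyond that it is terminated and a new track is
    born.  Positions are in pixels ((row, col)); calibrate with
    :func:`calibrate_track`.
    """
    if len(detections) < 2:
        raise ValueError("need detections from at least 2 frames")
    active: list[dict] = []
    done: list[dict] = []
    for t, dets in enumerate(detections):
        dets = np.asarray(dets, dtype=float).reshape(-1, 2)
        # retire tracks whose gap exceeded max_gap
        still = []
        for tr in active:
            if t - tr["frames"][-1] > max_gap + 1:
                done.append(tr)
            else:
                still.append(tr)
        active = still
        assigned = np.full(len(dets), -1)
        if active and len(dets):
            cost = np.full((len(active), len(dets)), 1e12)
            for i, tr in enumerate(active):
                gap = t - tr["frames"][-1] - 1
                gate = max_disp_px * (gap + 1)
                last = tr["pos"][-1]
                if len(tr["pos"]) >= 2:
                    dt_last = tr["frames"][-1] - tr["frames"][-2]
                    vel = (last - tr["pos"][-2]) / dt_last
                else:
                    vel = np.zeros(2)
                pred = last + vel * (gap + 1)
                d_gate = np.linalg.norm(dets - last, axis=1)
                d_pred = np.linalg.norm(dets - pred, axis=1)
                ok = d_gate <= gate
                cost[i, ok] = d_pred[ok]
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if cost[i, j] < 1e11:
                    active[i]["frames"].append(t)
                    active[i]["pos"].append(dets[j])
                    assigned[j] = i
        for j, det in enumerate(dets):
            if assigned[j] < 0:
                active.append({"frames": [t], "pos": [det]})
    done.extend(active)
    tracks = []
    for pid, tr in enumerate(d for d in done if len(d["frames"]) >= min_length):
        frames = np.asarray(tr["frames"])
        pos = np.asarray(tr["pos"])
        tracks.append(
            Track(
                particle_id=pid,
                frames=frames,
                t_s=frames.astype(float),
                xy_um=pos[:, ::-1].copy(),  # (col, row) -> (x, y) in px units
            )
        )
    return tracks


def calibrate_track(track: Track, pixel_size_um: float, frame_interval_s: float) -> Track:
    """Convert a pixel/frame-unit track to um and seconds in place."""
    track.xy_um = track.xy_um * pixel_size_um
    track.t_s = track.frames * frame_interval_s
    return track


def project_on_path(
    track: Track, path_um: np.ndarray, capture_um: float = 1.0
) -> Track:
    """Project track positions onto a reference path polyline ((x, y) um).

    Each position maps to its nearest point on the path (ties go to the
    earlier segment); s(t) is that point's arc length.  Points farther
    than ``capture_um`` are flagged off-path; more than 50% off-path
    raises ``track not on path``.
    """
    path = np.atleast_2d(np.asarray(path_um, dtype=float))
    seg = np.diff(path, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    pts = track.xy_um
    best_d = np.full(len(pts), np.inf)
    best_s = np.zeros(len(pts))
    for i, (a, ab, l) in enumerate(zip(path[:-1], seg, seg_len)):
        if l == 0:
            continue
        proj = np.clip((pts - a) @ ab / (l * l), 0.0, 1.0)
        d = np.linalg.norm(pts - (a + proj[:, None] * ab), axis=1)
        better = d < best_d - 1e-12
        best_d[better] = d[better]
        best_s[better] = cum[i] + proj[better] * l
    off = best_d > capture_um
    if off.mean() > 0.5:
        raise ValueError("track not on path")
    track.s_um = best_s
    track.off_path = off
    return track


def track_velocity(track: Track) -> tuple[float, float]:
    """Mean track velocity and regression-slope velocity, um/min.

    Primary definition: net arc-length displacement over track duration
    (robust to localisation noise).  Secondary: least-squares slope of
    s(t).  Velocity is unsigned; ``track.direction`` records the sign.
    Requires a projected track spanning >= 3 frames.
    """
    if track.s_um is None:
        raise ValueError("project the track on a path first")
    if len(track) < 3:
        raise ValueError("track too short")
    s, t = track.s_um, track.t_s
    net = s[-1] - s[0]
    v = abs(net) / (t[-1] - t[0]) * 60.0
    slope = float(np.polyfit(t, s, 1)[0] * 60.0)
    track.velocity_um_min = float(v)
    track.slope_velocity_um_min = abs(slope)
    track.direction = int(np.sign(net)) if net != 0 else 0
    return track.velocity_um_min, track.slope_velocity_um_min


def msd_exponent(s_um: np.ndarray, t_s: np.ndarray, max_lag_frac: float = 0.25) -> float:
    """MSD scaling exponent alpha from a log-log fit of the time-averaged
    MSD over lags up to ``max_lag_frac`` of the series length.

    The fit is weighted by 1/lag: time-averaged MSD estimates at long
    lags are built from few, heavily overlapping displacement pairs and
    their variance grows steeply with lag, so downweighting them sharply
    reduces the estimator's spread without biasing the ballistic limit
    (a constant-velocity series still fits alpha = 2 exactly).  Returns
    NaN for a perfectly stationary series.
    """
    n = len(s_um)
    max_lag = max(2, int(n * max_lag_frac))
    lags = np.arange(1, max_lag + 1)
    msd = np.array([np.mean((s_um[l:] - s_um[:-l]) ** 2) for l in lags])
    keep = msd > 0
    if keep.sum() < 2:
        return float("nan")
    dt = float(np.median(np.diff(t_s)))
    w = 1.0 / lags[keep]
    return float(np.polyfit(np.log(lags[keep] * dt), np.log(msd[keep]), 1, w=w)[0])


def classify_motion(
    track: Track,
    straightness_min: float = 0.8,
    alpha_directed: float = 1.5,
    alpha_diffusive: float = 1.2,
    straightness_diffusive: float = 0.5,
) -> str:
    """Directed / diffusive / ambiguous classification of a projected track.

    straightness = |net displacement| / total path travelled along s;
    directed iff straightness >= 0.8 and alpha >= 1.5; diffusive iff
    alpha <= 1.2 and straightness < 0.5; else ambiguous.
    """
    if track.s_um is None:
        raise ValueError("project the track on a path first")
    if len(track) < 10:
        raise ValueError("need at least 10 on-path points")
    s = track.s_um
    total = float(np.sum(np.abs(np.diff(s))))
    straightness = abs(s[-1] - s[0]) / total if total > 0 else 0.0
    alpha = msd_exponent(s, track.t_s)
    track.straightness = float(straightness)
    track.msd_alpha = alpha
    if not np.isnan(alpha) and straightness >= straightness_min and alpha >= alpha_directed:
        track.motion_class = MOTION_DIRECTED
    elif not np.isnan(alpha) and alpha <= alpha_diffusive and straightness < straightness_diffusive:
        track.motion_class = MOTION_DIFFUSIVE
    else:
        track.motion_class = MOTION_AMBIGUOUS
    return track.motion_class
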