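"""Whole-cell Ca2+ signal analysis for widefield movies.

The workflow mirrors standard practice for uncaging experiments: subtract
a background estimate from the whole stack, divide by the per-pixel mean
of the 100 frames preceding stimulation (F0) to obtain dF/F0, then reduce
to per-ROI traces from which peak amplitude (change from the baseline
immediately preceding the event to the maximum), peak-to-peak lag between
the stimulated and a connected cell, responder classification,
kymographs along a nanotube line, and the distance from the nanotube
contact point to the Ca2+ initiation site are measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage.draw import polygon2mask


@dataclass
class CalciumMovie:
    """2D fluorescence time series with acquisition calibration.

    ``frames`` is (T, H, W); ``frame_rate`` Hz; ``pixel_size`` um/pixel;
    ``stim_frame`` the index of the stimulus (must leave >= 100 baseline
    frames for F0); ``background`` a scalar, per-pixel image, or None.
    """

    frames: np.ndarray
    frame_rate: float = 10.0
    pixel_size: float = 0.166
    stim_frame: int = 100
    background: float | np.ndarray | None = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("movie frames must be (T, H, W)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.stim_frame < 100:
            raise ValueError("stim_frame must be >= 100 (F0 baseline window)")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.frames.shape[0]) / self.frame_rate


@dataclass
class DffStack:
    """Normalised dF/F0 stack with its F0 image and validity mask."""

    frames: np.ndarray
    f0: np.ndarray
    valid: np.ndarray
    frame_rate: float
    pixel_size: float
    stim_frame: int
    provenance: dict = field(default_factory=dict)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.frames.shape[0]) / self.frame_rate


@dataclass
class RoiTrace:
    """Per-ROI dF/F0 trace and its amplitude/timing summaries."""

    roi_id: str
    polygon: np.ndarray  # (N, 2) pixel coordinates (row, col)
    trace: np.ndarray
    frame_rate: float
    stim_frame: int
    peak_amplitude: float | None = None
    peak_time_s: float | None = None
    lag_s: float | None = None
    responder: bool | None = None
    connected: bool | None = None

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.trace.shape[0]) / self.frame_rate


@dataclass
class Kymograph:
    """Time (rows) x distance (columns) dF/F0 image along a band."""

    data: np.ndarray
    line: np.ndarray
    width_px: int
    um_per_col: float
    s_per_row: float


def normalize_stack(movie: CalciumMovie, baseline_n: int = 100, eps: float = 1e-9) -> DffStack:
    """Background-subtract and normalise a movie to dF/F0.

    F0 is the per-pixel mean of the ``baseline_n`` frames before the
    stimulus (after background subtraction);
    dF/F0(p, t) = (F(p, t) - B) / F0(p) - 1.  Pixels with F0 <= eps are
    flagged invalid and excluded from ROI means.
    """
    if movie.stim_frame < baseline_n:
        raise ValueError("insufficient baseline")
    b = 0.0 if movie.background is None else movie.background
    f = movie.frames - b
    f0 = f[movie.stim_frame - baseline_n : movie.stim_frame].mean(axis=0)
    valid = f0 > eps
    if not np.any(valid):
        raise ValueError("all-zero F0: nothing to normalize")
    f0_safe = np.where(valid, f0, 1.0)
    dff = f / f0_safe - 1.0
    dff[:, ~valid] = 0.0
    return DffStack(
        frames=dff,
        f0=f0,
        valid=valid,
        frame_rate=movie.frame_rate,
        pixel_size=movie.pixel_size,
        stim_frame=movie.stim_frame,
        provenance={"baseline_n": baseline_n, "background": np.mean(b)},
    )


def _roi_mask(dff: DffStack, polygon: np.ndarray) -> np.ndarray:
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or len(poly) < 3:
        raise ValueError("roi polygon needs at least 3 vertices")
    mask = polygon2mask(dff.frames.shape[1:], poly) & dff.valid
    if not np.any(mask):
        raise ValueError("roi does not intersect the image")
    return mask


def measure_peak(
    trace: np.ndarray,
    stim_frame: int,
    frame_rate: float,
    pre_window: int = 20,
) -> tuple[float, float]:
    """Peak amplitude and time of the post-stimulus response.

    Amplitude is the change from the baseline immediately preceding the
    event (mean over ``pre_window`` frames before the post-stimulus rise
    departs from baseline) to the maximum value; argmax ties resolve to
    the earliest frame.
    """
    post = trace[stim_frame:]
    peak_idx = stim_frame + int(np.argmax(post))
    pre = trace[max(0, stim_frame - pre_window) : stim_frame]
    base_mean = float(pre.mean())
    base_sd = float(pre.std())
    # event onset: first sustained departure from pre-stimulus baseline
    onset = None
    above = trace > base_mean + 3.0 * base_sd + 1e-12
    for t in range(stim_frame, peak_idx + 1):
        if above[t]:
            onset = t
            break
    if onset is not None and onset > pre_window:
        baseline = float(trace[onset - pre_window : onset].mean())
    else:
        baseline = base_mean
    amplitude = float(trace[peak_idx] - baseline)
    return amplitude, peak_idx / frame_rate


def roi_trace(dff: DffStack, polygon: np.ndarray, roi_id: str = "roi") -> RoiTrace:
    """Mean dF/F0 over the valid pixels of a polygonal ROI, per frame."""
    mask = _roi_mask(dff, polygon)
    trace = dff.frames[:, mask].mean(axis=1)
    amp, t_peak = measure_peak(trace, dff.stim_frame, dff.frame_rate)
    return RoiTrace(
        roi_id=roi_id,
        polygon=np.asarray(polygon, dtype=float),
        trace=trace,
        frame_rate=dff.frame_rate,
        stim_frame=dff.stim_frame,
        peak_amplitude=amp,
        peak_time_s=t_peak,
    )


def classify_responder(
    trace: RoiTrace, threshold_k: float = 5.0, sustain_frames: int = 3
) -> bool:
    """Detectable-response rule: post-stimulus dF/F0 must exceed the
    baseline mean + k sd for at least ``sustain_frames`` consecutive
    frames (defaults k = 5, 3 frames)."""
    if trace.stim_frame < 20:
        raise ValueError("need at least 20 baseline frames")
    base = trace.trace[: trace.stim_frame]
    thr = float(base.mean()) + threshold_k * float(base.std(ddof=1))
    above = trace.trace[trace.stim_frame :] > thr
    run = 0
    for a in above:
        run = run + 1 if a else 0
        if run >= sustain_frames:
            trace.responder = True
            return True
    trace.responder = False
    return False


def peak_and_lag(
    stim: RoiTrace, other: RoiTrace, threshold_k: float = 5.0
) -> tuple[float, float, float | None]:
    """Peak amplitudes of both ROIs and the peak-to-peak lag in seconds.

    Lag = (time of the other cell's peak) - (time of the stimulated
    cell's peak); undefined (None) when the other cell is not a
    responder.
    """
    if stim.trace.shape != other.trace.shape or stim.frame_rate != other.frame_rate:
        raise ValueError("traces must come from the same movie")
    for tr in (stim, other):
        if tr.peak_time_s is None:
            tr.peak_amplitude, tr.peak_time_s = measure_peak(
                tr.trace, tr.stim_frame, tr.frame_rate
            )
    responder = classify_responder(other, threshold_k=threshold_k)
    lag = None
    if responder:
        lag = float(other.peak_time_s - stim.peak_time_s)
    other.lag_s = lag
    return stim.peak_amplitude, other.peak_amplitude, lag


def kymograph(dff: DffStack, line: np.ndarray, width_px: int = 15) -> Kymograph:
    """Band kymograph along a polyline (pixel coordinates, (row, col)).

    Columns advance at 1 pixel of arc length; each column is the mean
    dF/F0 over ``width_px`` pixels perpendicular to the line (bilinear
    sampling).  Width must be odd so the band is symmetric.
    """
    if width_px % 2 == 0:
        raise ValueError("band width must be odd")
    line = np.atleast_2d(np.asarray(line, dtype=float))
    if len(line) < 2:
        raise ValueError("line needs at least two points")
    seg = np.linalg.norm(np.diff(line, axis=0), axis=1)
    total = seg.sum()
    n_cols = max(2, int(np.floor(total)) + 1)
    s = np.linspace(0.0, total, n_cols)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    i = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    f = np.where(seg[i] > 0, (s - cum[i]) / seg[i], 0.0)
    centers = line[i] + f[:, None] * (line[i + 1] - line[i])
    tangents = (line[i + 1] - line[i]) / seg[i][:, None]
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    half = width_px // 2
    offsets = np.arange(-half, half + 1)
    coords = centers[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    h, w = dff.frames.shape[1:]
    if centers[:, 0].min() < 0 or centers[:, 0].max() > h - 1 or centers[:, 1].min() < 0 or centers[:, 1].max() > w - 1:
        raise ValueError("line leaves the image")
    flat = coords.reshape(-1, 2).T  # (2, width*n_cols) in (row, col)
    rows = np.empty((dff.frames.shape[0], n_cols))
    for t, frame in enumerate(dff.frames):
        vals = ndimage.map_coordinates(frame, flat, order=1, mode="nearest")
        rows[t] = vals.reshape(width_px, n_cols).mean(axis=0)
    return Kymograph(
        data=rows,
        line=line,
        width_px=width_px,
        um_per_col=dff.pixel_size * (s[1] - s[0]),
        s_per_row=1.0 / dff.frame_rate,
    )


def initiation_distance(
    dff: DffStack,
    roi_polygon: np.ndarray,
    contact_point_um: tuple[float, float],
    threshold_k: float = 5.0,
    core_fraction: float = 0.75,
) -> tuple[float, dict]:
    """Distance from the nanotube contact point to the Ca2+ initiation site.

    The initiation site is located from the first spatially contiguous
    pixel cluster inside the ROI whose dF/F0 exceeds the per-pixel
    baseline mean + k sd after the stimulus, as the intensity-weighted
    centroid of the cluster's half-maximum core.  Restricting to the core
    matters when the site sits at the ROI boundary: there the wavefront
    is clipped to a half-disk and a plain centroid is biased inward,
    while the earliest-activated (brightest) core stays at the true
    origin.  If several clusters appear in the same frame the largest is
    taken and the result flagged ambiguous.  Returns (distance um,
    diagnostics).
    """
    mask = _roi_mask(dff, roi_polygon)
    pre = dff.frames[: dff.stim_frame]
    thr = pre.mean(axis=0) + threshold_k * pre.std(axis=0) + 1e-12
    for t in range(dff.stim_frame, dff.frames.shape[0]):
        above = (dff.frames[t] > thr) & mask
        if not np.any(above):
            continue
        labels, n = ndimage.label(above)
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        best = int(np.argmax(sizes)) + 1
        excess = np.where(labels == best, dff.frames[t] - thr, 0.0)
        core = np.where(excess >= core_fraction * excess.max(), excess, 0.0)
        cy, cx = ndimage.center_of_mass(core)
        site_um = np.array([cy, cx]) * dff.pixel_size
        contact = np.asarray(contact_point_um, dtype=float)
        dist = float(np.linalg.norm(site_um - contact))
        return dist, {
            "frame": t,
            "site_um": tuple(site_um),
            "n_clusters": int(n),
            "ambiguous": bool(n > 1),
        }
    raise ValueError("no initiation site")


@dataclass
class PairedTTestResult:
    t: float
    p: float
    df: int
    degenerate: bool = False


def paired_ttest(x: np.ndarray, y: np.ndarray) -> PairedTTestResult:
    """Two-sided paired Student's t-test with n-1 degrees of freedom.

    Identical samples return t = 0, p = 1 by convention; nonzero
    differences of zero variance return an infinite t (p = 0) flagged
    degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be equal-length 1D arrays")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return PairedTTestResult(t=0.0, p=1.0, df=n - 1, degenerate=True)
        return PairedTTestResult(
            t=float(np.sign(d.mean()) * np.inf), p=0.0, df=n - 1, degenerate=True
        )
    res = stats.ttest_rel(x, y)
    return PairedTTestResult(t=float(res.statistic), p=float(res.pvalue), df=n - 1)
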