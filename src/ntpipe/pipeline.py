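"""End-to-end pipeline runs: simulate -> reconstruct -> quantify.

Builds the standard study scenarios from a :class:`~ntpipe.config.RunConfig`
and executes the three chains (volume morphometry, Ca2+ analysis, puncta
velocimetry), writing intermediate artifacts, a machine-readable summary
and a short human-readable report.  The scenario builders are plain
functions so scripts can reuse them directly.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from ntpipe import calcium as ca
from ntpipe import morphometry as mm
from ntpipe import tracking as tk
from ntpipe.calcium_sim import CalciumScenario, CellSpec, simulate_calcium_movie
from ntpipe.config import RunConfig
from ntpipe.deskew import deskew_volume
from ntpipe.io import write_stack, write_volume
from ntpipe.optics import OpticsModel
from ntpipe.render import render_scene, simulate_diagonal_acquisition
from ntpipe.scene import Tube, VolumeScene
from ntpipe.transport_sim import ParticleSpec, TransportScenario, simulate_transport_movie

log = logging.getLogger("ntpipe")

TUBE_MARGIN_UM = 1.5


def optics_from_config(cfg: RunConfig, seed: int | None = None) -> OpticsModel:
    o = cfg.optics
    return OpticsModel(
        lateral_psf_fwhm=o["lateral_psf_fwhm"],
        sheet_fwhm=o["sheet_fwhm"],
        voxel_xy=o["voxel_xy"],
        scan_step=o["scan_step"],
        scan_angle=o["scan_angle"],
        noise_model=o["noise_model"],
        read_noise_sigma=o["read_noise_sigma"],
        rng_seed=cfg.seed if seed is None else seed,
    )


def draw_tube_lengths(mean_um: float, sd_um: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a cohort of tube lengths from a zero-truncated normal."""
    a = (0.0 - mean_um) / sd_um
    return truncnorm.rvs(a, np.inf, loc=mean_um, scale=sd_um, size=n, random_state=rng)


def single_tube_scene(
    length_um: float,
    diameter_nm: float = 150.0,
    elevation_um: float = 1.25,
    intensity: float = 1.0,
) -> tuple[VolumeScene, np.ndarray, np.ndarray]:
    """A straight tube along x, elevated above the substrate plane z = 0.

    Returns (scene, seed_a, seed_b) with seeds at the tube endpoints.
    """
    m = TUBE_MARGIN_UM
    a = np.array([m, 2.0, elevation_um])
    b = np.array([m + length_um, 2.0, elevation_um])
    scene = VolumeScene(
        tubes=[Tube(points=np.stack([a, b]), diameter_nm=diameter_nm, intensity=intensity)],
        substrate_z=0.0,
        bounds=((0.0, length_um + 2 * m), (0.0, 4.0), (0.0, max(2.5, elevation_um * 2))),
    )
    return scene, a, b


def measure_tube_cohort(
    lengths_um: np.ndarray,
    optics: OpticsModel,
    diameter_nm: float = 150.0,
    via_acquisition: bool = False,
    n_profile_stations: int = 0,
) -> list[mm.NanotubePath]:
    """Render and trace a cohort of single-tube scenes.

    ``via_acquisition`` runs the full chain (diagonal acquisition then
    deskew) instead of rendering the orthogonal volume directly.
    """
    paths = []
    for L in np.asarray(lengths_um, dtype=float):
        scene, a, b = single_tube_scene(L, diameter_nm=diameter_nm)
        if via_acquisition:
            stack = simulate_diagonal_acquisition(scene, optics)
            vol = deskew_volume(stack)
        else:
            vol = render_scene(scene, optics)
        path = mm.trace_path(vol, a, b)
        for frac in np.linspace(0.25, 0.75, n_profile_stations):
            try:
                prof = mm.transverse_profile(vol, path, frac * path.length_um)
                path.profiles.append(mm.fit_fwhm(prof))
            except ValueError:
                log.warning("profile fit rejected at station %.2f", frac)
        mm.classify_contact(path, scene.substrate_z)
        paths.append(path)
    return paths


def standard_calcium_scenario(
    cfg_ca: dict,
    seed: int = 0,
    noise_model: str | None = None,
) -> CalciumScenario:
    """The canonical three-cell uncaging scenario.

    A stimulated cell, a nanotube-connected responder whose wave seeds
    ``init_offset_um`` from the contact point on its boundary facing the
    stimulated cell, and a non-connected bystander.
    """
    pix = cfg_ca["pixel_size"]
    h, w = cfg_ca["shape"]
    r = 8.0
    cy = h * pix / 2.0
    stim_x, resp_x = w * pix * 0.22, w * pix * 0.62
    far = (cy + 14.0, (stim_x + resp_x) / 2.0)
    contact = (cy, resp_x - r)  # responder boundary facing the stimulated cell
    init = (cy, resp_x - r + cfg_ca["init_offset_um"])
    cells = [
        CellSpec("stim", (cy, stim_x), r, peak_dff=cfg_ca["stim_peak_dff"], stimulated=True),
        CellSpec(
            "responder",
            (cy, resp_x),
            r,
            peak_dff=cfg_ca["responder_peak_dff"],
            lag_s=cfg_ca["responder_lag_s"],
            init_point_um=init,
            connected=True,
        ),
        CellSpec("bystander", far, 6.0),
    ]
    sc = CalciumScenario(
        cells=cells,
        stim_frame=cfg_ca["stim_frame"],
        n_frames=cfg_ca["n_frames"],
        frame_rate=cfg_ca["frame_rate"],
        pixel_size=pix,
        shape=(h, w),
        baseline_level=cfg_ca["baseline_level"],
        background_level=cfg_ca["background_level"],
        noise_model=noise_model if noise_model is not None else cfg_ca["noise_model"],
        rng_seed=seed,
    )
    sc.contact_point_um = contact  # type: ignore[attr-defined]
    return sc


def straight_transport_scenario(
    cfg_tr: dict, speeds_um_min: np.ndarray, seed: int = 0
) -> TransportScenario:
    """Particles at the given speeds on one straight horizontal path."""
    L = cfg_tr["path_length_um"]
    pix = cfg_tr["pixel_size_um"]
    y = 6.0
    path = np.array([[y, 2.0], [y, 2.0 + L]])
    particles = [
        ParticleSpec(start_s_um=1.0 + 0.5 * i, speed_um_min=float(v), direction=1)
        for i, v in enumerate(np.atleast_1d(speeds_um_min))
    ]
    shape = (int(2 * y / pix), int((L + 4.0) / pix))
    return TransportScenario(
        path_um=path,
        particles=particles,
        n_frames=cfg_tr["n_frames"],
        frame_interval_s=cfg_tr["frame_interval_s"],
        pixel_size_um=pix,
        shape=shape,
        noise_model=cfg_tr["noise_model"],
        rng_seed=seed,
    )


def track_transport_movie(
    movie: np.ndarray, sc: TransportScenario, cfg_tr: dict
) -> list[tk.Track]:
    """Full velocimetry chain: detect, link, calibrate, project, classify."""
    sigma_px = sc.particle_sigma_nm / 1000.0 / sc.pixel_size_um
    dets = [tk.detect_spots(f, sigma_px, snr_min=cfg_tr["snr_min"]) for f in movie]
    tracks = tk.link_tracks(dets, max_disp_px=cfg_tr["max_disp_px"], max_gap=cfg_tr["max_gap"], min_length=3)
    path_xy = sc.path_um[:, ::-1]
    out = []
    for tr in tracks:
        tk.calibrate_track(tr, sc.pixel_size_um, sc.frame_interval_s)
        try:
            tk.project_on_path(tr, path_xy)
        except ValueError:
            log.info("excluding off-path track %d", tr.particle_id)
            continue
        tk.track_velocity(tr)
        if len(tr) >= 10:
            tk.classify_motion(tr)
        out.append(tr)
    return out


def _save_kymograph_png(path: Path, kym) -> None:
    """Pseudocolour kymograph: distance horizontal, time down the rows."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_rows, n_cols = kym.data.shape
    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(
        kym.data,
        aspect="auto",
        cmap="inferno",
        extent=[0, n_cols * kym.um_per_col, n_rows * kym.s_per_row, 0],
    )
    ax.set_xlabel("distance (um)")
    ax.set_ylabel("time (s)")
    fig.colorbar(im, ax=ax, label="dF/F0")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# stage runners


def run_llsm(cfg: RunConfig, outdir: Path) -> dict:
    rng = np.random.default_rng(cfg.seed)
    optics = optics_from_config(cfg)
    c = cfg.llsm
    lengths = draw_tube_lengths(c["length_mean_um"], c["length_sd_um"], c["n_tubes"], rng)
    paths = measure_tube_cohort(
        lengths,
        optics,
        diameter_nm=c["tube_diameter_nm"],
        via_acquisition=True,
        n_profile_stations=c["profile_stations"],
    )
    summary = mm.summarize(paths, bin_width_um=c["bin_width_um"])
    df = pd.DataFrame(
        {
            "path_id": range(len(paths)),
            "true_length_um": lengths,
            "length_um": [p.length_um for p in paths],
            "contact_class": [p.contact_class for p in paths],
            "fwhm_nm": [
                np.mean([pr.fwhm_nm for pr in p.profiles]) if p.profiles else np.nan
                for p in paths
            ],
        }
    )
    df.to_csv(outdir / "nanotube_paths.csv", index=False)
    # keep one worked volume as an artifact
    scene, a, b = single_tube_scene(float(lengths[0]), diameter_nm=c["tube_diameter_nm"])
    stack = simulate_diagonal_acquisition(scene, optics)
    write_stack(outdir / "diagonal_stack.tif", stack.slices, meta={
        "voxel_xy": optics.voxel_xy, "scan_step": optics.scan_step,
        "scan_angle": optics.scan_angle, "origin": list(stack.origin), "seed": cfg.seed,
    })
    write_volume(outdir / "volume.tif", deskew_volume(stack, interpolation=c["interpolation"]))
    return {
        "n_paths": summary.n_paths,
        "length_mean_um": summary.length_mean_um,
        "length_sd_um": summary.length_sd_um,
        "fwhm_mean_nm": summary.fwhm_mean_nm,
        "histogram": {
            "edges_um": summary.hist_edges_um.tolist(),
            "counts": summary.hist_counts.tolist(),
        },
    }


def run_calcium(cfg: RunConfig, outdir: Path) -> dict:
    c = cfg.calcium
    sc = standard_calcium_scenario(c, seed=cfg.seed)
    movie, truth = simulate_calcium_movie(sc)
    dff = ca.normalize_stack(movie)
    traces = {t.cell_id: ca.roi_trace(dff, t.polygon_px, t.cell_id) for t in truth}
    stim = traces["stim"]
    rows = []
    for t in truth:
        tr = traces[t.cell_id]
        tr.connected = t.connected
        if not t.stimulated:
            ca.peak_and_lag(stim, tr, threshold_k=c["threshold_k"])
        else:
            tr.responder = True
        rows.append(
            {
                "roi": t.cell_id,
                "amplitude_dff": tr.peak_amplitude,
                "peak_time_s": tr.peak_time_s,
                "lag_s": tr.lag_s,
                "responder": tr.responder,
                "connected": tr.connected,
                "true_peak_dff": t.peak_dff,
                "true_lag_s": t.lag_s,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "roi_summary.csv", index=False)
    pd.DataFrame({t.cell_id: traces[t.cell_id].trace for t in truth}).to_csv(
        outdir / "traces.csv", index=False
    )
    stim_c = np.asarray(sc.cells[0].center_um) / sc.pixel_size
    resp_c = np.asarray(sc.cells[1].center_um) / sc.pixel_size
    kym = ca.kymograph(dff, np.stack([stim_c, resp_c]), width_px=c["kymo_width_px"])
    write_stack(outdir / "kymograph.tif", kym.data, meta={
        "um_per_col": kym.um_per_col, "s_per_row": kym.s_per_row, "width_px": kym.width_px,
    })
    _save_kymograph_png(outdir / "kymograph.png", kym)
    init_dist, diag = ca.initiation_distance(
        dff, truth[1].polygon_px, sc.contact_point_um, threshold_k=c["threshold_k"]
    )
    resp = traces["responder"]
    return {
        "stim_amplitude_dff": stim.peak_amplitude,
        "responder_amplitude_dff": resp.peak_amplitude,
        "lag_s": resp.lag_s,
        "initiation_distance_um": init_dist,
        "initiation_ambiguous": diag["ambiguous"],
        "bystander_responder": traces["bystander"].responder,
    }


def run_transport(cfg: RunConfig, outdir: Path) -> dict:
    c = cfg.transport
    rng = np.random.default_rng(cfg.seed)
    speeds = rng.normal(c["speed_mean_um_min"], c["speed_sd_um_min"], c["n_particles"])
    speeds = np.clip(speeds, 0.3, None)
    # one movie per particle: each track comes from its own nanotube
    tracks = []
    for i, v in enumerate(speeds):
        sc = straight_transport_scenario(c, [v], seed=cfg.seed + i)
        movie, _ = simulate_transport_movie(sc)
        for tr in track_transport_movie(movie, sc, c):
            tr.particle_id = i
            tracks.append(tr)
    df = pd.DataFrame(
        [
            {
                "track_id": tr.particle_id,
                "n_points": len(tr),
                "velocity_um_min": tr.velocity_um_min,
                "slope_velocity_um_min": tr.slope_velocity_um_min,
                "straightness": tr.straightness,
                "msd_alpha": tr.msd_alpha,
                "motion_class": tr.motion_class,
            }
            for tr in tracks
        ]
    )
    df.to_csv(outdir / "track_summary.csv", index=False)
    pd.concat(
        [
            pd.DataFrame(
                {"track_id": tr.particle_id, "frame": tr.frames, "t_s": tr.t_s,
                 "x_um": tr.xy_um[:, 0], "y_um": tr.xy_um[:, 1], "s_um": tr.s_um}
            )
            for tr in tracks
        ]
    ).to_csv(outdir / "tracks.csv", index=False)
    vels = df["velocity_um_min"].to_numpy()
    counts, edges = np.histogram(vels, bins=np.arange(0.0, max(6.0, vels.max() + 1.0), 0.5))
    (outdir / "velocity_histogram.json").write_text(
        json.dumps({"edges_um_min": edges.tolist(), "counts": counts.tolist()})
    )
    return {
        "n_tracks": len(tracks),
        "velocity_mean_um_min": float(vels.mean()) if len(vels) else None,
        "velocity_sd_um_min": float(vels.std(ddof=1)) if len(vels) > 1 else None,
        "true_speed_mean_um_min": float(np.mean(speeds)),
        "n_directed": int((df["motion_class"] == "directed").sum()) if len(df) else 0,
    }


def run(cfg: RunConfig) -> dict:
    """Execute the configured stage chain; returns the summary dict."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = ("llsm", "calcium", "transport") if cfg.mode == "all" else (cfg.mode,)
    runners = {"llsm": run_llsm, "calcium": run_calcium, "transport": run_transport}
    summary: dict = {"mode": cfg.mode, "seed": cfg.seed}
    report = [f"ntpipe run  mode={cfg.mode}  seed={cfg.seed}"]
    for stage in stages:
        t0 = time.time()
        log.info("stage %s starting", stage)
        sub = outdir / stage
        sub.mkdir(exist_ok=True)
        summary[stage] = runners[stage](cfg, sub)
        report.append(f"\n[{stage}]  ({time.time() - t0:.1f} s)")
        for k, v in summary[stage].items():
            if isinstance(v, float):
                report.append(f"  {k}: {v:.4g}")
            elif not isinstance(v, dict):
                report.append(f"  {k}: {v}")
    cfg.to_yaml(outdir / "config_used.yaml")
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    (outdir / "report.txt").write_text("\n".join(report) + "\n")
    return summary
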