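"""Run configuration: one YAML file drives end-to-end pipeline runs.

Every tunable threshold and simulation parameter used by the pipeline
stages has exactly one home here; unknown keys are rejected so typos
fail fast, and a config round-trips losslessly through its file form.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

MODES = ("llsm", "calcium", "transport", "all")

DEFAULTS: dict = {
    "mode": "all",
    "seed": 0,
    "output_dir": "results",
    "optics": {
        "lateral_psf_fwhm": 460.0,  # nm
        "sheet_fwhm": 1.2,  # um
        "voxel_xy": 105.0,  # nm/pixel
        "scan_step": 0.4,  # um
        "scan_angle": 45.0,  # degrees
        "noise_model": "none",
        "read_noise_sigma": 2.0,
    },
    "llsm": {
        "n_tubes": 5,
        "length_mean_um": 14.85,
        "length_sd_um": 6.3,
        "tube_diameter_nm": 150.0,
        "elevation_um": 1.5,
        "interpolation": "linear",
        "bin_width_um": 2.0,
        "z_tol_um": 0.5,
        "profile_stations": 3,
    },
    "calcium": {
        "shape": [256, 256],
        "n_frames": 700,
        "stim_frame": 110,
        "frame_rate": 10.0,  # Hz
        "pixel_size": 0.166,  # um/pixel
        "baseline_level": 100.0,
        "background_level": 10.0,
        "stim_peak_dff": 3.75,
        "responder_peak_dff": 1.22,
        "responder_lag_s": 45.0,
        "init_offset_um": 6.18,
        "threshold_k": 5.0,
        "sustain_frames": 3,
        "kymo_width_px": 15,
        "noise_model": "none",
    },
    "transport": {
        "n_particles": 5,
        "speed_mean_um_min": 2.7,
        "speed_sd_um_min": 1.37,  # 0.3 s.e.m. at n = 21
        "path_length_um": 15.0,
        "n_frames": 100,
        "frame_interval_s": 1.0,
        "pixel_size_um": 0.105,
        "max_disp_px": 6.0,
        "max_gap": 2,
        "snr_min": 5.0,
        "noise_model": "none",
    },
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``DEFAULTS`` for every key)."""

    mode: str = "all"
    seed: int = 0
    output_dir: str = "results"
    optics: dict = field(default_factory=dict)
    llsm: dict = field(default_factory=dict)
    calcium: dict = field(default_factory=dict)
    transport: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        for section in ("optics", "llsm", "calcium", "transport"):
            merged = copy.deepcopy(DEFAULTS[section])
            overrides = getattr(self, section)
            unknown = set(overrides) - set(merged)
            if unknown:
                raise ValueError(f"unknown config key(s) in {section}: {sorted(unknown)}")
            merged.update(overrides)
            setattr(self, section, merged)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        unknown = set(d) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "seed": self.seed,
            "output_dir": self.output_dir,
            "optics": copy.deepcopy(self.optics),
            "llsm": copy.deepcopy(self.llsm),
            "calcium": copy.deepcopy(self.calcium),
            "transport": copy.deepcopy(self.transport),
        }

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path
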