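"""Optical model of the stage-scanned light-sheet microscope.

The microscope is summarised by four numbers: the lateral detection PSF
(FWHM, nm), the illumination-sheet thickness (FWHM, um, which sets the
axial resolution of each slice), the camera pixel pitch at the sample
(nm/pixel) and the stage-scan geometry (step in um and scan angle in
degrees relative to the detection axis).  Both blur terms are modelled as
Gaussians; no aberrations or bleaching are simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: FWHM of a Gaussian in units of its sigma: 2 sqrt(2 ln 2).
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

_NOISE_MODELS = ("none", "gaussian", "poisson_gaussian")


@dataclass(frozen=True)
class OpticsModel:
    """Acquisition parameters shared by the simulators.

    Parameters
    ----------
    lateral_psf_fwhm : float
        Lateral detection PSF full width at half maximum, in nm.
    sheet_fwhm : float
        Illumination light-sheet thickness (FWHM), in um.  The axial blur
        of each slice is folded into this single Gaussian.
    voxel_xy : float
        In-plane pixel pitch at the sample, in nm/pixel.
    scan_step : float
        Stage advance between consecutive slices, in um.
    scan_angle : float
        Angle between the slice plane and the detection axis, in degrees
        (0 < angle <= 90; 45 for the standard stage-scan geometry).
    noise_model : str
        One of ``none``, ``gaussian``, ``poisson_gaussian``.
    read_noise_sigma : float
        Additive Gaussian read-noise s.d. in counts (used by both noisy
        models).
    rng_seed : int
        Seed for the noise generator; identical seed and parameters give
        bit-identical output.
    """

    lateral_psf_fwhm: float = 460.0
    sheet_fwhm: float = 1.2
    voxel_xy: float = 105.0
    scan_step: float = 0.4
    scan_angle: float = 45.0
    noise_model: str = "none"
    read_noise_sigma: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lateral_psf_fwhm", "sheet_fwhm", "voxel_xy", "scan_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.scan_angle <= 90.0:
            raise ValueError("scan_angle must be in (0, 90] degrees")
        if self.noise_model not in _NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {_NOISE_MODELS}")

    # -- derived geometry -------------------------------------------------

    @property
    def sigma_lateral_um(self) -> float:
        """Lateral PSF sigma in um."""
        return self.lateral_psf_fwhm / 1000.0 / FWHM_PER_SIGMA

    @property
    def sigma_axial_um(self) -> float:
        """Axial (sheet) sigma in um."""
        return self.sheet_fwhm / FWHM_PER_SIGMA

    @property
    def voxel_xy_um(self) -> float:
        return self.voxel_xy / 1000.0

    @property
    def scan_angle_rad(self) -> float:
        return math.radians(self.scan_angle)

    @property
    def axial_spacing_um(self) -> float:
        """Depth advance per slice: scan_step * sin(scan_angle)."""
        return self.scan_step * math.sin(self.scan_angle_rad)

    @property
    def lateral_shift_um(self) -> float:
        """In-plane shift per slice: scan_step * cos(scan_angle)."""
        return self.scan_step * math.cos(self.scan_angle_rad)

    # -- physics helpers --------------------------------------------------

    def sheet_profile(self, z_um: np.ndarray) -> np.ndarray:
        """Axial intensity profile of the illumination sheet (peak 1)."""
        z = np.asarray(z_um, dtype=float)
        s = self.sigma_axial_um
        return np.exp(-0.5 * (z / s) ** 2)

    def apply_noise(self, image: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        """Apply the configured noise model; output is clipped at zero."""
        if self.noise_model == "none":
            return np.asarray(image, dtype=float)
        if rng is None:
            rng = np.random.default_rng(self.rng_seed)
        img = np.asarray(image, dtype=float)
        if self.noise_model == "poisson_gaussian":
            img = rng.poisson(np.clip(img, 0.0, None)).astype(float)
        img = img + rng.normal(0.0, self.read_noise_sigma, size=img.shape)
        return np.clip(img, 0.0, None)
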