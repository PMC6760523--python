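"""Quantitative model of the acquisition chain.

The expected photoelectron signal for a pixel of object-space area ``A``
(µm²) receiving a photon flux ``γ`` (photons·µm⁻²·s⁻¹) over an exposure
``t`` is

    S = γ · A · QE · t        [electrons]

where QE is the sensor quantum efficiency.  The total noise combines the
signal-independent camera noise (dark + read, ``σ_camera``) with photon
shot noise ``σ_shot = √S`` in quadrature, which holds for uncorrelated
noise sources:

    N = √(σ_camera² + S)      [electrons]

The noise-equivalent photon floor is the photon count at which S = N,
i.e. the smallest signal not dominated by noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CameraSpec",
    "OpticsGeometry",
    "PAPER_CAMERA",
    "PAPER_OPTICS",
    "expected_signal",
    "total_noise",
    "noise_equivalent_photons",
    "electrons_to_dn",
    "object_pixel_area_um2",
    "circle_area_px",
]


@dataclass(frozen=True)
class CameraSpec:
    """Sensor parameters of the acquisition camera.

    Parameters
    ----------
    qe : float
        Quantum efficiency, photoelectrons per incident photon, in (0, 1].
    pixel_size_um : float
        Physical sensor pixel pitch δ in µm (pre-binning).
    camera_noise_e : float
        Combined dark + read noise σ_camera in electrons (RMS).
    bit_depth : int
        Output quantization, 8 or 16 bits.
    binning : int
        On-sensor pixels combined per axis (4 → 4×4 binning).
    gain_e_per_dn : float
        Conversion gain, electrons per digital number.
    """

    qe: float = 0.79
    pixel_size_um: float = 2.4
    camera_noise_e: float = 3.30
    bit_depth: int = 16
    binning: int = 4
    gain_e_per_dn: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.qe <= 1.0:
            raise ValueError(f"qe must be in (0, 1], got {self.qe}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.camera_noise_e < 0:
            raise ValueError("camera_noise_e must be non-negative")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.binning < 1:
            raise ValueError("binning must be >= 1")
        if self.gain_e_per_dn <= 0:
            raise ValueError("gain_e_per_dn must be positive")

    @property
    def dn_max(self) -> int:
        """Largest representable digital number."""
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class OpticsGeometry:
    """Object-space field of view and captured frame size.

    ``fov_um`` is the (width, height) of one field of view in µm;
    ``resolution_px`` is the matching (width, height) in pixels.
    """

    fov_um: tuple[float, float] = (818.0, 547.0)
    resolution_px: tuple[int, int] = (1368, 912)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.fov_um) or any(v <= 0 for v in self.resolution_px):
            raise ValueError("fov_um and resolution_px entries must be positive")
        px, py = self.pixel_pitch_um
        if abs(px - py) > 0.01 * max(px, py):
            raise ValueError(
                f"anisotropic pixel pitch beyond 1%: {px:.4f} vs {py:.4f} µm/px"
            )

    @property
    def pixel_pitch_um(self) -> tuple[float, float]:
        """Object-space size of one pixel, (x, y) in µm."""
        return (
            self.fov_um[0] / self.resolution_px[0],
            self.fov_um[1] / self.resolution_px[1],
        )


#: Instrument defaults: IMX183-class sensor, 4×4 binning, 20× objective.
PAPER_CAMERA = CameraSpec()
PAPER_OPTICS = OpticsGeometry()


def expected_signal(
    photon_flux: float, camera: CameraSpec, exposure_s: float
) -> float:
    """Expected photoelectron count S = γ·δ²·QE·t for one sensor pixel.

    ``photon_flux`` is photons·µm⁻²·s⁻¹ at the pixel; the pixel collects
    over its δ² area.  Linear in flux, exposure and QE.
    """
    if photon_flux < 0:
        raise ValueError("photon_flux must be non-negative")
    if exposure_s < 0:
        raise ValueError("exposure_s must be non-negative")
    return photon_flux * camera.pixel_size_um**2 * camera.qe * exposure_s


def total_noise(signal_e: float, camera: CameraSpec) -> float:
    """Total noise √(σ_camera² + S) in electrons for a mean signal S."""
    if signal_e < 0:
        raise ValueError("signal_e must be non-negative")
    return math.sqrt(camera.camera_noise_e**2 + signal_e)


def noise_equivalent_photons(camera: CameraSpec) -> float:
    """Photon count at which the expected signal equals the total noise.

    Solves S = √(σ_camera² + S) for S in electrons; squaring gives
    S² − S − σ² = 0 with positive root S = (1 + √(1 + 4σ²))/2.  The
    electron value is converted to photons by dividing by QE.
    """
    sigma = camera.camera_noise_e
    s_electrons = (1.0 + math.sqrt(1.0 + 4.0 * sigma**2)) / 2.0
    return s_electrons / camera.qe


def electrons_to_dn(electrons, camera: CameraSpec):
    """Quantize electron values to digital numbers.

    Divides by the conversion gain, rounds to nearest, and clips to
    [0, 2^bit_depth − 1].  Accepts scalars or arrays; returns the
    camera's unsigned integer dtype for arrays.
    """
    import numpy as np

    dn = np.round(np.asarray(electrons, dtype=np.float64) / camera.gain_e_per_dn)
    dn = np.clip(dn, 0, camera.dn_max)
    dtype = np.uint8 if camera.bit_depth == 8 else np.uint16
    out = dn.astype(dtype)
    return out if out.ndim else dtype(out)


def object_pixel_area_um2(optics: OpticsGeometry) -> float:
    """Object-space area imaged by one pixel, in µm²."""
    px, py = optics.pixel_pitch_um
    return px * py


def circle_area_px(diameter_um: float, optics: OpticsGeometry) -> int:
    """Pixel area of a circle of the given object-space diameter.

    Rounds half away from zero to the nearest integer; this is the
    minimum-area gate used by the size discrimination step (107 px for a
    7 µm cell, 14 px for a 2.5 µm nucleus at the instrument geometry).
    """
    if diameter_um <= 0:
        raise ValueError("diameter_um must be positive")
    area_um2 = math.pi * (diameter_um / 2.0) ** 2
    px = area_um2 / object_pixel_area_um2(optics)
    return int(math.floor(px + 0.5))
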