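"""Synthetic filtering-membrane simulator and virtual microscope.

Generates ground-truthed multi-channel fluorescence tiles that emulate a
microfiltration membrane carrying a few large, bright tumor cells (CTCs)
on a dense background of leukocytes (WBCs) and other nucleated blood
cells.  Phenotypes follow the immunostaining logic of the four-color
assay:

* CTC — nucleated (blue, Hoechst), cytokeratin-positive (green),
  PSMA-positive (orange), CD45-negative (no red);
* WBC — nucleated (blue) and CD45-positive (red), nothing else;
* other nucleated cells — blue only.

Each cell is rendered as a uniform disc of its physical diameter
convolved with an isotropic Gaussian whose width grows linearly with the
distance between the stage plane and the cell's focal plane (defocus).
The convolution is evaluated in closed form through the noncentral-χ²(2)
CDF, so total flux is conserved under defocus and the in-focus peak is
the global brightness maximum — the property the brightness autofocus
relies on.

Pixel statistics follow the acquisition-chain model: the mean
photoelectron count of a pixel is S = γ·A·QE·t (flux γ referred to the
sample plane, A the object-space pixel footprint), photoelectrons are
Poisson-distributed (shot noise √S), and the camera adds Gaussian
read/dark noise of σ_camera electrons before quantization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import ncx2

from .camera import CameraSpec, OpticsGeometry, electrons_to_dn, object_pixel_area_um2

__all__ = [
    "CHANNELS",
    "PHENOTYPES",
    "CTC",
    "WBC",
    "NUCLEATED_OTHER",
    "GroundTruthCell",
    "SyntheticScene",
    "SimulationConfig",
    "FocalStack",
    "make_scene",
    "render_snap",
    "render_focal_stack",
    "virtual_acquire",
    "pixel_mean_electrons",
    "noise_free_flux",
    "save_scene",
    "load_scene",
]

CHANNELS: tuple[str, ...] = ("blue", "green", "orange", "red")

CTC = "CTC"
WBC = "WBC"
NUCLEATED_OTHER = "NUCLEATED_OTHER"
PHENOTYPES: tuple[str, ...] = (CTC, WBC, NUCLEATED_OTHER)

#: Channels in which each phenotype emits; all others must be dark.
PHENOTYPE_CHANNELS: dict[str, frozenset[str]] = {
    CTC: frozenset({"blue", "green", "orange"}),
    WBC: frozenset({"blue", "red"}),
    NUCLEATED_OTHER: frozenset({"blue"}),
}

#: Per-channel exposure times of the four-color assay, seconds.
DEFAULT_EXPOSURE_S: dict[str, float] = {
    "blue": 0.050,
    "green": 0.100,
    "orange": 1.500,
    "red": 0.100,
}

# Nominal peak photon flux per channel (photons·µm⁻²·s⁻¹), chosen so a
# typical cell yields ~1.5e3 photoelectrons per pixel at the default
# exposures and instrument geometry — bright but far from 16-bit
# saturation at unit gain.
DEFAULT_PEAK_FLUX: dict[str, float] = {
    "blue": 1.06e5,
    "green": 5.3e4,
    "orange": 3.5e3,
    "red": 5.3e4,
}

# Uniform membrane autofluorescence background, ~15 e⁻ per pixel at the
# default exposures.
DEFAULT_BACKGROUND_FLUX: dict[str, float] = {
    "blue": 1.06e3,
    "green": 5.3e2,
    "orange": 35.0,
    "red": 5.3e2,
}

# Cell-to-cell brightness variation: multiplicative factor drawn
# uniformly from this interval per cell and channel.
_BRIGHTNESS_RANGE = (0.7, 1.5)

# Default diameter ranges (µm): CTCs are large epithelial cells; WBCs
# span lymphocytes to granulocytes; other nucleated blood cells reach
# down to ~4 µm, comfortably above the 2.5 µm nucleus gate so the size
# discrimination never bisects a ground-truth population.
_DIAMETER_RANGES = {CTC: (8.0, 14.0), WBC: (6.0, 12.0), NUCLEATED_OTHER: (4.0, 9.0)}


@dataclass(frozen=True)
class GroundTruthCell:
    """One simulated cell with its phenotype-consistent emission."""

    phenotype: str
    center_um: tuple[float, float]
    diameter_um: float
    emission: dict[str, float]  # channel -> peak photon flux
    z_um: float = 0.0

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPE_CHANNELS:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.diameter_um <= 0:
            raise ValueError("diameter_um must be positive")
        allowed = PHENOTYPE_CHANNELS[self.phenotype]
        for ch, flux in self.emission.items():
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel {ch!r}")
            if flux < 0:
                raise ValueError("emission flux must be non-negative")
            if flux > 0 and ch not in allowed:
                raise ValueError(
                    f"{self.phenotype} cell must be dark in channel {ch!r}"
                )
        for ch in allowed:
            if self.emission.get(ch, 0.0) <= 0:
                raise ValueError(
                    f"{self.phenotype} cell must emit in channel {ch!r}"
                )


@dataclass(frozen=True)
class SyntheticScene:
    """Ground-truth cell list on a rectangular membrane region."""

    extent_um: tuple[float, float]
    cells: tuple[GroundTruthCell, ...]
    background_flux: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_FLUX)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.extent_um
        if w <= 0 or h <= 0:
            raise ValueError("extent_um must be positive")
        for cell in self.cells:
            x, y = cell.center_um
            if not (0 <= x <= w and 0 <= y <= h):
                raise ValueError(
                    f"cell at {cell.center_um} lies outside extent {self.extent_um}"
                )

    def count(self, phenotype: str) -> int:
        return sum(1 for c in self.cells if c.phenotype == phenotype)


@dataclass(frozen=True)
class SimulationConfig:
    """Virtual-microscope rendering parameters.

    ``defocus_sigma0_um`` is the residual Gaussian blur of a perfectly
    focused cell; the blur grows by ``defocus_slope`` µm of σ per µm of
    axial distance between the stage plane and the cell's focal plane.
    ``noise`` disables the Poisson/Gaussian noise path for ground-truth
    renders when False.
    """

    camera: CameraSpec = field(default_factory=CameraSpec)
    optics: OpticsGeometry = field(default_factory=OpticsGeometry)
    exposure_s: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXPOSURE_S)
    )
    defocus_sigma0_um: float = 0.3  # diffraction-scale PSF of a 20×/0.4 objective
    defocus_slope: float = 0.25
    stage_jitter_um: float = 2.2  # bi-directional stage repeatability
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.defocus_sigma0_um <= 0:
            raise ValueError("defocus_sigma0_um must be positive")
        if self.defocus_slope < 0:
            raise ValueError("defocus_slope must be non-negative")
        if self.stage_jitter_um < 0:
            raise ValueError("stage_jitter_um must be non-negative")


@dataclass(frozen=True)
class FocalStack:
    """Equidistant z-series of one field, with per-image z metadata."""

    z_um: tuple[float, ...]
    images: tuple[np.ndarray, ...]

    def __len__(self) -> int:
        return len(self.images)


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------


def make_scene(
    n_ctc: int,
    n_wbc: int,
    n_other: int,
    extent_um: tuple[float, float] = (818.0, 547.0),
    seed: int = 0,
    min_sep_um: float | None = None,
    background_flux: dict[str, float] | None = None,
    z_um: float = 0.0,
    max_tries: int = 2000,
) -> SyntheticScene:
    """Place cells uniformly at random on the membrane region.

    Cell centres are inset from the border by one radius plus 2 µm so
    whole cells are imaged.  When ``min_sep_um`` is given, centres are
    rejection-sampled to respect that minimum pairwise distance; an
    infeasible packing raises after ``max_tries`` attempts per cell.
    Reproducible for a fixed seed.
    """
    for name, n in (("n_ctc", n_ctc), ("n_wbc", n_wbc), ("n_other", n_other)):
        if n < 0:
            raise ValueError(f"{name} must be non-negative")
    rng = np.random.default_rng(seed)
    w, h = extent_um
    placed_xy: list[tuple[float, float]] = []
    cells: list[GroundTruthCell] = []
    specs = [(CTC, n_ctc), (WBC, n_wbc), (NUCLEATED_OTHER, n_other)]
    for phenotype, n in specs:
        dlo, dhi = _DIAMETER_RANGES[phenotype]
        for _ in range(n):
            d = float(rng.uniform(dlo, dhi))
            margin = d / 2.0 + 2.0
            if w <= 2 * margin or h <= 2 * margin:
                raise ValueError(
                    f"extent {extent_um} too small for a {d:.1f} µm cell"
                )
            for _ in range(max_tries):
                x = float(rng.uniform(margin, w - margin))
                y = float(rng.uniform(margin, h - margin))
                if min_sep_um is None or all(
                    math.hypot(x - px, y - py) >= min_sep_um
                    for px, py in placed_xy
                ):
                    break
            else:
                raise RuntimeError(
                    f"could not place {phenotype} cell with min_sep_um="
                    f"{min_sep_um} after {max_tries} tries"
                )
            emission = {
                ch: float(DEFAULT_PEAK_FLUX[ch] * rng.uniform(*_BRIGHTNESS_RANGE))
                for ch in PHENOTYPE_CHANNELS[phenotype]
            }
            placed_xy.append((x, y))
            cells.append(
                GroundTruthCell(
                    phenotype=phenotype,
                    center_um=(x, y),
                    diameter_um=d,
                    emission=emission,
                    z_um=z_um,
                )
            )
    bg = dict(DEFAULT_BACKGROUND_FLUX) if background_flux is None else dict(background_flux)
    return SyntheticScene(extent_um=extent_um, cells=tuple(cells), background_flux=bg, seed=seed)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _disc_blur_profile(radius_um: float, sigma_um: float, n: int = 512):
    """Radial profile of a unit disc convolved with a Gaussian PSF.

    The value at distance r from the disc centre is the probability that
    a 2-D Gaussian displacement of scale σ lands inside the disc, i.e.
    ncx2.cdf((R/σ)², df=2, nc=(r/σ)²) — the exact convolution.  Returned
    as (r grid, values) for interpolation; the profile is ~0 beyond
    R + 6σ.
    """
    r_max = radius_um + 6.0 * sigma_um
    r = np.linspace(0.0, r_max, n)
    vals = ncx2.cdf((radius_um / sigma_um) ** 2, 2, (r / sigma_um) ** 2)
    return r, vals


def noise_free_flux(
    scene: SyntheticScene,
    channel: str,
    z_stage_um: float,
    config: SimulationConfig,
    origin_px: tuple[float, float] = (0.0, 0.0),
    shape_px: tuple[int, int] | None = None,
    offset_um: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Noise-free photon-flux field (photons·µm⁻²·s⁻¹) on a pixel grid.

    Pixel (row j, col i) is sampled at sample-plane coordinates
    ((origin_px_x + i + 0.5)·pitch_x + offset_x, …): ``origin_px`` is the
    tile origin in global pixel units so that pixel-aligned tilings of a
    scene reproduce the whole-scene render exactly, and ``offset_um``
    carries sub-pixel displacements such as stage jitter.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    pitch_x, pitch_y = config.optics.pixel_pitch_um
    if shape_px is None:
        w, h = scene.extent_um
        shape_px = (int(round(h / pitch_y)), int(round(w / pitch_x)))
    n_rows, n_cols = shape_px
    img = np.full(shape_px, scene.background_flux.get(channel, 0.0), dtype=np.float64)
    ox, oy = origin_px
    offx, offy = offset_um
    for cell in scene.cells:
        peak = cell.emission.get(channel, 0.0)
        if peak <= 0.0:
            continue
        radius = cell.diameter_um / 2.0
        sigma = config.defocus_sigma0_um + config.defocus_slope * abs(
            z_stage_um - cell.z_um
        )
        r_grid, profile = _disc_blur_profile(radius, sigma)
        r_max = r_grid[-1]
        cx, cy = cell.center_um
        # local pixel-index window covering the cell support
        i0 = max(0, int(math.floor((cx - offx - r_max) / pitch_x - ox - 0.5)))
        i1 = min(n_cols, int(math.ceil((cx - offx + r_max) / pitch_x - ox + 0.5)))
        j0 = max(0, int(math.floor((cy - offy - r_max) / pitch_y - oy - 0.5)))
        j1 = min(n_rows, int(math.ceil((cy - offy + r_max) / pitch_y - oy + 0.5)))
        if i0 >= i1 or j0 >= j1:
            continue
        xs = (ox + np.arange(i0, i1) + 0.5) * pitch_x + offx - cx
        ys = (oy + np.arange(j0, j1) + 0.5) * pitch_y + offy - cy
        r = np.hypot(xs[np.newaxis, :], ys[:, np.newaxis])
        img[j0:j1, i0:i1] += peak * np.interp(r, r_grid, profile, right=0.0)
    return img


def pixel_mean_electrons(
    flux: np.ndarray | float,
    channel: str,
    config: SimulationConfig,
) -> np.ndarray | float:
    """Expected photoelectrons per pixel, S = γ·A·QE·t.

    ``A`` is the object-space pixel footprint of the optics; the flux is
    referred to the sample plane (magnification and collection
    efficiency are folded into γ).
    """
    area = object_pixel_area_um2(config.optics)
    return flux * area * config.camera.qe * config.exposure_s[channel]


def _derive_rng(config: SimulationConfig, channel: str, *keys: float) -> np.random.Generator:
    """Deterministic per-acquisition RNG from the config seed and call site."""
    entropy = [int(config.seed) & 0x7FFFFFFF, CHANNELS.index(channel)]
    for k in keys:
        entropy.append(int(np.float64(k).view(np.uint64)))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _digitize(
    flux: np.ndarray,
    channel: str,
    config: SimulationConfig,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Apply the pixel noise model and quantize to digital numbers."""
    mean_e = pixel_mean_electrons(flux, channel, config)
    if config.noise:
        if rng is None:
            raise ValueError("noise rendering requires an RNG")
        electrons = rng.poisson(mean_e).astype(np.float64)
        if config.camera.camera_noise_e > 0:
            electrons += rng.normal(0.0, config.camera.camera_noise_e, mean_e.shape)
    else:
        electrons = mean_e
    return electrons_to_dn(electrons, config.camera)


def render_snap(
    scene: SyntheticScene,
    channel: str,
    z_stage_um: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render the whole scene extent in one channel at a stage z.

    Returns a quantized grayscale image at the optics' pixel pitch.
    With ``config.noise`` enabled the RNG defaults to one derived from
    (config.seed, channel, z), so repeated calls reproduce the image.
    """
    flux = noise_free_flux(scene, channel, z_stage_um, config)
    if rng is None and config.noise:
        rng = _derive_rng(config, channel, z_stage_um)
    return _digitize(flux, channel, config, rng)


def render_focal_stack(
    scene: SyntheticScene,
    channel: str,
    z_range_um: tuple[float, float],
    n_steps: int,
    config: SimulationConfig,
) -> FocalStack:
    """Render equidistant z-planes covering [z_min, z_max] inclusive."""
    z_min, z_max = z_range_um
    if not z_max > z_min:
        raise ValueError(f"empty z range {z_range_um}")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    zs = np.linspace(z_min, z_max, n_steps)
    images = tuple(render_snap(scene, channel, float(z), config) for z in zs)
    return FocalStack(z_um=tuple(float(z) for z in zs), images=images)


def virtual_acquire(
    scene: SyntheticScene,
    stage_xy_um: tuple[float, float],
    z_um: float,
    channel: str,
    config: SimulationConfig,
    jitter_sigma_um: float = 0.0,
    jitter_offset_um: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Capture one field of view with the stage centred at ``stage_xy_um``.

    The tile's origin (centre of pixel (0, 0) minus half a pixel) sits at
    stage − FOV/2; a cell centred at the stage position therefore appears
    at the image centre.  Optional Gaussian stage jitter of the given σ
    displaces the realized position (default 0; the instrument's
    bi-directional repeatability is ``config.stage_jitter_um``);
    ``jitter_offset_um`` instead imposes a known realized displacement —
    the mapping routine uses it to share one stage settle across the
    channels of a snap.  With a fixed config seed, repeated acquisitions
    at the same position are identical.
    """
    fov_w, fov_h = config.optics.fov_um
    res_w, res_h = config.optics.resolution_px
    sx, sy = stage_xy_um
    if rng is None and (config.noise or jitter_sigma_um > 0):
        rng = _derive_rng(config, channel, z_um, sx, sy)
    if jitter_offset_um is not None:
        jx, jy = jitter_offset_um
    elif jitter_sigma_um > 0:
        jx, jy = rng.normal(0.0, jitter_sigma_um, 2)
    else:
        jx = jy = 0.0
    ox_um, oy_um = sx - fov_w / 2.0, sy - fov_h / 2.0
    w, h = scene.extent_um
    if not (-1e-6 <= ox_um and ox_um + fov_w <= w + 1e-6) or not (
        -1e-6 <= oy_um and oy_um + fov_h <= h + 1e-6
    ):
        raise ValueError(
            f"tile at stage {stage_xy_um} extends outside the scene extent {scene.extent_um}"
        )
    pitch_x, pitch_y = config.optics.pixel_pitch_um
    ox_px, oy_px = ox_um / pitch_x, oy_um / pitch_y
    # snap pixel-aligned stage targets to exact integer pixel origins so
    # tiled renders reproduce whole-scene renders bit for bit
    if abs(ox_px - round(ox_px)) < 1e-6:
        ox_px = float(round(ox_px))
    if abs(oy_px - round(oy_px)) < 1e-6:
        oy_px = float(round(oy_px))
    flux = noise_free_flux(
        scene,
        channel,
        z_um,
        config,
        origin_px=(ox_px, oy_px),
        shape_px=(res_h, res_w),
        offset_um=(jx, jy),
    )
    return _digitize(flux, channel, config, rng)


# ---------------------------------------------------------------------------
# Ground-truth serialization
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "cell_id",
    "phenotype",
    "x_um",
    "y_um",
    "diameter_um",
    "z_um",
    "flux_blue",
    "flux_green",
    "flux_orange",
    "flux_red",
]


def save_scene(scene: SyntheticScene, csv_path, header_path) -> None:
    """Write the ground-truth cell table (CSV) and scene header (YAML)."""
    rows = [
        {
            "cell_id": i,
            "phenotype": c.phenotype,
            "x_um": c.center_um[0],
            "y_um": c.center_um[1],
            "diameter_um": c.diameter_um,
            "z_um": c.z_um,
            **{f"flux_{ch}": c.emission.get(ch, 0.0) for ch in CHANNELS},
        }
        for i, c in enumerate(scene.cells)
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(csv_path, index=False)
    header = {
        "extent_um": list(scene.extent_um),
        "background_flux": {k: float(v) for k, v in scene.background_flux.items()},
        "seed": int(scene.seed),
        "cells_csv": str(csv_path),
    }
    with open(header_path, "w") as fh:
        yaml.safe_dump(header, fh, sort_keys=False)


def load_scene(header_path) -> SyntheticScene:
    """Reconstruct a scene from its YAML header + ground-truth CSV."""
    with open(header_path) as fh:
        header = yaml.safe_load(fh)
    df = pd.read_csv(header["cells_csv"])
    cells = tuple(
        GroundTruthCell(
            phenotype=row.phenotype,
            center_um=(float(row.x_um), float(row.y_um)),
            diameter_um=float(row.diameter_um),
            emission={
                ch: float(getattr(row, f"flux_{ch}"))
                for ch in CHANNELS
                if float(getattr(row, f"flux_{ch}")) > 0
            },
            z_um=float(row.z_um),
        )
        for row in df.itertuples(index=False)
    )
    return SyntheticScene(
        extent_um=tuple(header["extent_um"]),
        cells=cells,
        background_flux=dict(header["background_flux"]),
        seed=int(header.get("seed", 0)),
    )
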