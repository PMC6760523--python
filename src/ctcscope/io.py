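"""File formats, run configuration, and report serialization.

Images travel as single-channel 8- or 16-bit grayscale TIFF/PNG, one
file per channel per field of view.  Phenotype rules and run
configuration are YAML; counts and detected cells are CSV.  All loaders
validate strictly: unknown keys are rejected with their key path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .autofocus import FocusSearchConfig
from .camera import CameraSpec, OpticsGeometry
from .classify import CountReport, PhenotypeRule, PipelineConfig
from .simulate import SimulationConfig

__all__ = [
    "read_image",
    "write_image",
    "write_rgb_png",
    "write_report",
    "write_cells",
    "read_rules",
    "write_rules",
    "RunConfig",
    "load_config",
]

_GRAY_DTYPES = (np.uint8, np.uint16)


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-channel 8- or 16-bit grayscale TIFF/PNG."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        image = tifffile.imread(path)
    elif suffix == ".png":
        image = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format {suffix!r}: {path}")
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(
            f"unsupported image: expected single-channel grayscale, "
            f"got shape {image.shape} in {path}"
        )
    if image.dtype not in _GRAY_DTYPES:
        raise ValueError(
            f"unsupported image dtype {image.dtype} in {path}: expected uint8/uint16"
        )
    return image


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a single-channel grayscale image losslessly (dtype preserved)."""
    path = Path(path)
    image = np.asarray(image)
    if image.ndim != 2 or image.dtype not in _GRAY_DTYPES:
        raise ValueError(
            f"write_image expects a 2-D uint8/uint16 image, got "
            f"shape {image.shape}, dtype {image.dtype}"
        )
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    elif suffix == ".png":
        iio.imwrite(path, image)
    else:
        raise ValueError(f"unsupported image format {suffix!r}: {path}")


def write_rgb_png(image: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit RGB display image (colorized merges)."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise ValueError("write_rgb_png expects an (H, W, 3) uint8 image")
    iio.imwrite(Path(path), image)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = ["snap_id", "phenotype", "count"]


def write_report(report: CountReport, path: str | Path) -> None:
    """Write per-snap counts as CSV (snap_id, phenotype, count)."""
    rows = [
        {"snap_id": sid, "phenotype": label, "count": n}
        for sid, counts in sorted(report.per_snap.items())
        for label, n in sorted(counts.items())
    ]
    pd.DataFrame(rows, columns=_REPORT_COLUMNS).to_csv(path, index=False)


def write_cells(report: CountReport, path: str | Path) -> None:
    """Write one row per detected cell, with per-channel mean intensities."""
    channels = sorted({ch for c in report.cells for ch in c.mean_intensity})
    columns = ["cell_id", "snap_id", "phenotype", "x_px", "y_px", "area_px"] + [
        f"mean_{ch}" for ch in channels
    ]
    rows = [
        {
            "cell_id": i,
            "snap_id": c.snap_id,
            "phenotype": c.label,
            "x_px": c.centroid_px[0],
            "y_px": c.centroid_px[1],
            "area_px": c.area_px,
            **{f"mean_{ch}": c.mean_intensity.get(ch, np.nan) for ch in channels},
        }
        for i, c in enumerate(report.cells)
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Phenotype rules (YAML)
# ---------------------------------------------------------------------------

_RULE_KEYS = {"label", "required", "excluded", "min_diameter_um", "priority"}


def read_rules(path: str | Path) -> list[PhenotypeRule]:
    """Load phenotype rules from YAML (top-level key ``phenotypes``)."""
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValueError(f"malformed YAML in {path}: {exc}") from exc
    if not isinstance(data, dict) or "phenotypes" not in data:
        raise ValueError(f"{path}: expected a top-level 'phenotypes' list")
    extra = set(data) - {"phenotypes"}
    if extra:
        raise ValueError(f"{path}: unknown top-level keys {sorted(extra)}")
    rules = []
    labels = set()
    for i, entry in enumerate(data["phenotypes"]):
        where = f"{path}: phenotypes[{i}]"
        if not isinstance(entry, dict):
            raise ValueError(f"{where}: expected a mapping")
        unknown = set(entry) - _RULE_KEYS
        if unknown:
            raise ValueError(f"{where}: unknown keys {sorted(unknown)}")
        if "label" not in entry or "required" not in entry:
            raise ValueError(f"{where}: 'label' and 'required' are mandatory")
        if entry["label"] in labels:
            raise ValueError(f"{where}: duplicate phenotype label {entry['label']!r}")
        labels.add(entry["label"])
        rules.append(
            PhenotypeRule(
                label=entry["label"],
                required_channels=frozenset(entry["required"]),
                excluded_channels=frozenset(entry.get("excluded", [])),
                min_diameter_um=float(entry.get("min_diameter_um", 2.5)),
                priority=int(entry.get("priority", i)),
            )
        )
    return rules


def write_rules(rules, path: str | Path) -> None:
    data = {
        "phenotypes": [
            {
                "label": r.label,
                "required": sorted(r.required_channels),
                "excluded": sorted(r.excluded_channels),
                "min_diameter_um": r.min_diameter_um,
                "priority": r.priority,
            }
            for r in rules
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration assembled from YAML sections."""

    camera: CameraSpec = field(default_factory=CameraSpec)
    optics: OpticsGeometry = field(default_factory=OpticsGeometry)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    autofocus: FocusSearchConfig = field(default_factory=FocusSearchConfig)
    phenotypes: tuple[PhenotypeRule, ...] = ()
    simulation: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."

    def sim_config(self, seed: int | None = None) -> SimulationConfig:
        """Assemble the virtual-microscope configuration."""
        return _build(
            SimulationConfig,
            dict(self.simulation),
            "simulation",
            camera=self.camera,
            optics=self.optics,
            seed=self.seed if seed is None else seed,
        )


def _build(cls, data: dict, where: str, **overrides):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ValueError(f"config section {where!r} must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"config section {where!r}: unknown keys {sorted(unknown)}")
    kwargs = dict(data)
    kwargs.update(overrides)
    for key in ("fov_um", "resolution_px"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


_TOP_KEYS = {
    "camera",
    "optics",
    "pipeline",
    "autofocus",
    "simulation",
    "phenotypes",
    "seed",
    "output_dir",
}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a run configuration from YAML.

    Defaults (camera, optics, exposures, search parameters) are the
    instrument's values; any section may be omitted.
    """
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ValueError(f"malformed YAML in {path}: {exc}") from exc
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown top-level keys {sorted(unknown)}")
    phenotypes: tuple[PhenotypeRule, ...] = ()
    if "phenotypes" in data:
        labels = set()
        rules = []
        for i, entry in enumerate(data["phenotypes"]):
            unknown = set(entry) - _RULE_KEYS
            if unknown:
                raise ValueError(f"{path}: phenotypes[{i}]: unknown keys {sorted(unknown)}")
            if entry["label"] in labels:
                raise ValueError(
                    f"{path}: phenotypes[{i}]: duplicate label {entry['label']!r}"
                )
            labels.add(entry["label"])
            rules.append(
                PhenotypeRule(
                    label=entry["label"],
                    required_channels=frozenset(entry["required"]),
                    excluded_channels=frozenset(entry.get("excluded", [])),
                    min_diameter_um=float(entry.get("min_diameter_um", 2.5)),
                    priority=int(entry.get("priority", i)),
                )
            )
        phenotypes = tuple(rules)
    sim_section = data.get("simulation", {})
    if isinstance(sim_section, dict):
        sim_names = {f.name for f in dataclasses.fields(SimulationConfig)}
        unknown = set(sim_section) - (sim_names - {"camera", "optics", "seed"})
        if unknown:
            raise ValueError(
                f"{path}: config section 'simulation': unknown keys {sorted(unknown)}"
            )
    return RunConfig(
        camera=_build(CameraSpec, data.get("camera", {}), "camera"),
        optics=_build(OpticsGeometry, data.get("optics", {}), "optics"),
        pipeline=_build(PipelineConfig, data.get("pipeline", {}), "pipeline"),
        autofocus=_build(FocusSearchConfig, data.get("autofocus", {}), "autofocus"),
        phenotypes=phenotypes,
        simulation=dict(sim_section),
        seed=int(data.get("seed", 0)),
        output_dir=str(data.get("output_dir", ".")),
    )
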