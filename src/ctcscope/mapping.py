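"""Tile-grid mapping and panorama stitching.

The limited field of view is compensated by a mapping routine that
captures contiguous zones on a regular grid and assembles a panoramic
picture.  Stitching is pure abutting placement — no overlap and no
image-based registration — relying on the stage's bi-directional
repeatability for mechanical alignment.  Detections are per-snap;
a cell straddling a tile seam may be counted in both tiles (documented
bias of the per-snap counting design).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autofocus import FocusSearchConfig, autofocus_search
from .camera import OpticsGeometry
from .classify import (
    CountReport,
    PhenotypeRule,
    PipelineConfig,
    SnapSet,
    classify_and_count,
)
from .simulate import CHANNELS, SimulationConfig, SyntheticScene, virtual_acquire

__all__ = ["TileGrid", "Panorama", "plan_grid", "stitch", "run_mapping"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TileGrid:
    """Regular abutting tile layout covering a rectangular extent."""

    origin_um: tuple[float, float]
    rows: int
    cols: int
    tile_fov_um: tuple[float, float]
    serpentine: bool = True

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must contain at least one tile")

    def tile_origin_um(self, row: int, col: int) -> tuple[float, float]:
        """Top-left corner of a tile in sample coordinates."""
        return (
            self.origin_um[0] + col * self.tile_fov_um[0],
            self.origin_um[1] + row * self.tile_fov_um[1],
        )

    def stage_target_um(self, row: int, col: int) -> tuple[float, float]:
        """Stage position (FOV centre) for a tile."""
        ox, oy = self.tile_origin_um(row, col)
        return (ox + self.tile_fov_um[0] / 2.0, oy + self.tile_fov_um[1] / 2.0)

    def traversal(self):
        """(row, col) acquisition order; serpentine rows minimize travel."""
        for row in range(self.rows):
            cols = range(self.cols)
            if self.serpentine and row % 2 == 1:
                cols = reversed(cols)
            for col in cols:
                yield row, col


@dataclass
class Panorama:
    """Per-channel stitched mosaic plus tile provenance."""

    images: dict[str, np.ndarray]
    provenance: dict[tuple[int, int], dict] = field(default_factory=dict)


def plan_grid(
    extent_um: tuple[float, float],
    optics: OpticsGeometry,
    origin_um: tuple[float, float] = (0.0, 0.0),
    serpentine: bool = True,
) -> TileGrid:
    """Smallest abutting grid of full fields of view covering the extent."""
    fov_w, fov_h = optics.fov_um
    w, h = extent_um
    if w <= 0 or h <= 0:
        raise ValueError("extent_um must be positive")
    cols = max(1, int(np.ceil(w / fov_w)))
    rows = max(1, int(np.ceil(h / fov_h)))
    return TileGrid(
        origin_um=origin_um,
        rows=rows,
        cols=cols,
        tile_fov_um=(fov_w, fov_h),
        serpentine=serpentine,
    )


def stitch(
    tiles: dict[tuple[int, int], np.ndarray],
    rows: int | None = None,
    cols: int | None = None,
    missing: str = "error",
) -> np.ndarray:
    """Place grid-indexed tiles abutting at (row·H, col·W); no blending.

    ``missing`` is "error" (default) or "zero" (fill absent tiles with
    zeros).  All tiles must share shape and dtype.
    """
    if not tiles:
        raise ValueError("no tiles to stitch")
    if missing not in ("error", "zero"):
        raise ValueError(f"unknown missing-tile policy {missing!r}")
    shapes = {t.shape for t in tiles.values()}
    dtypes = {t.dtype for t in tiles.values()}
    if len(shapes) != 1 or len(dtypes) != 1:
        raise ValueError(f"inconsistent tile shapes/dtypes: {shapes} / {dtypes}")
    tile_h, tile_w = shapes.pop()
    rows = rows if rows is not None else max(r for r, _ in tiles) + 1
    cols = cols if cols is not None else max(c for _, c in tiles) + 1
    out = np.zeros((rows * tile_h, cols * tile_w), dtype=dtypes.pop())
    for row in range(rows):
        for col in range(cols):
            tile = tiles.get((row, col))
            if tile is None:
                if missing == "error":
                    raise ValueError(f"missing tile at (row={row}, col={col})")
                continue
            out[row * tile_h : (row + 1) * tile_h, col * tile_w : (col + 1) * tile_w] = tile
    return out


def run_mapping(
    source: SyntheticScene | str | Path,
    rules: list[PhenotypeRule] | tuple[PhenotypeRule, ...],
    sim_config: SimulationConfig | None = None,
    pipeline_config: PipelineConfig | None = None,
    focus_config: FocusSearchConfig | None = None,
    optics: OpticsGeometry | None = None,
    jitter_sigma_um: float = 0.0,
    focus_channel: str = "blue",
    channels: tuple[str, ...] = CHANNELS,
) -> tuple[Panorama, CountReport]:
    """Map a whole sample: per tile, (optionally) focus, acquire every
    channel, classify and count; then stitch panoramas and aggregate the
    per-snap reports.

    ``source`` is a synthetic scene driven through the virtual
    microscope, or a directory of pre-acquired tiles named
    ``tile_{row}_{col}_{channel}.tif``.
    """
    if isinstance(source, (str, Path)):
        return _run_mapping_dir(Path(source), rules, pipeline_config, optics)
    if sim_config is None:
        raise ValueError("sim_config is required for a virtual-microscope source")
    scene = source
    optics = optics or sim_config.optics
    grid = plan_grid(scene.extent_um, optics)
    tile_stacks: dict[str, dict[tuple[int, int], np.ndarray]] = {ch: {} for ch in channels}
    reports: list[CountReport] = []
    provenance: dict[tuple[int, int], dict] = {}
    for row, col in grid.traversal():
        target = grid.stage_target_um(row, col)
        # one stage settle per tile: every channel (and the focus pass)
        # shares the same realized positioning error
        jitter = (0.0, 0.0)
        if jitter_sigma_um > 0:
            jrng = np.random.default_rng(
                np.random.SeedSequence(
                    [int(sim_config.seed) & 0x7FFFFFFF, 0x5EA7, row, col]
                )
            )
            jitter = tuple(jrng.normal(0.0, jitter_sigma_um, 2))
        z = 0.0
        if focus_config is not None:
            result = autofocus_search(
                lambda zz: virtual_acquire(
                    scene, target, zz, focus_channel, sim_config,
                    jitter_offset_um=jitter,
                ),
                focus_config,
            )
            z = result.best_z_um
        try:
            images = {
                ch: virtual_acquire(
                    scene, target, z, ch, sim_config, jitter_offset_um=jitter
                )
                for ch in channels
            }
        except Exception as exc:
            raise RuntimeError(f"acquisition failed at tile (row={row}, col={col})") from exc
        snap = SnapSet(
            images=images,
            exposure_s=dict(sim_config.exposure_s),
            snap_id=f"tile_{row}_{col}",
        )
        report, _ = classify_and_count(snap, rules, optics, pipeline_config)
        reports.append(report)
        for ch in channels:
            tile_stacks[ch][(row, col)] = images[ch]
        provenance[(row, col)] = {
            "stage_target_um": target,
            "focus_z_um": z,
            "snap_id": snap.snap_id,
        }
        logger.info(
            "tile (%d,%d) @ %s µm z=%.2f: %s", row, col, target, z, report.totals
        )
    panorama = Panorama(
        images={
            ch: stitch(tile_stacks[ch], rows=grid.rows, cols=grid.cols)
            for ch in channels
        },
        provenance=provenance,
    )
    return panorama, CountReport.combine(reports)


def _run_mapping_dir(
    tile_dir: Path,
    rules,
    pipeline_config: PipelineConfig | None,
    optics: OpticsGeometry | None,
) -> tuple[Panorama, CountReport]:
    from .io import read_image

    if optics is None:
        raise ValueError("optics is required for a tile-directory source")
    tiles: dict[str, dict[tuple[int, int], np.ndarray]] = {}
    for path in sorted(tile_dir.glob("tile_*_*_*.tif*")) + sorted(
        tile_dir.glob("tile_*_*_*.png")
    ):
        parts = path.stem.split("_")
        if len(parts) != 4:
            continue
        _, row, col, channel = parts
        tiles.setdefault(channel, {})[(int(row), int(col))] = read_image(path)
    if not tiles:
        raise FileNotFoundError(f"no tile_{{row}}_{{col}}_{{channel}} images in {tile_dir}")
    positions = sorted({pos for grid in tiles.values() for pos in grid})
    reports = []
    for row, col in positions:
        images = {ch: grid[(row, col)] for ch, grid in tiles.items() if (row, col) in grid}
        snap = SnapSet(images=images, snap_id=f"tile_{row}_{col}")
        report, _ = classify_and_count(snap, rules, optics, pipeline_config)
        reports.append(report)
    panorama = Panorama(
        images={ch: stitch(grid) for ch, grid in tiles.items()},
        provenance={pos: {"snap_id": f"tile_{pos[0]}_{pos[1]}"} for pos in positions},
    )
    return panorama, CountReport.combine(reports)
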