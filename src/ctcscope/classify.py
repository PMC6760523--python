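"""Six-step cell recognition and counting pipeline.

For each field of view ("snap", one grayscale image per excitation
channel): (1) raw channel images in, (2) median filtering plus
window/level contrast stretching for background reduction, (3) a
classification mask per phenotype built by pixel-wise addition of the
phenotype's required channels and subtraction of its excluded channels,
(4) Otsu thresholding of the mask, (5) connected-component contour
extraction discriminated by size (minimum pixel area of a circle of the
phenotype's minimum diameter), and (6) a merged, colorized image for
display.  Classification therefore uses appearance channel, brightness
and size.

Because an additive mask alone cannot rule out a pixel that is merely
very bright in a single required channel, each surviving component is
additionally checked for channel coincidence: its mean intensity must
exceed the per-channel Otsu threshold in every required channel and stay
at or below it in every excluded channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .camera import OpticsGeometry, circle_area_px

__all__ = [
    "SnapSet",
    "PhenotypeRule",
    "DetectedCell",
    "CountReport",
    "PipelineConfig",
    "FOUR_COLOR_RULES",
    "TWO_COLOR_RULES",
    "DEFAULT_CHANNEL_COLORS",
    "median_filter",
    "window_level",
    "compose_mask",
    "otsu_threshold",
    "extract_components",
    "filter_by_area",
    "classify_and_count",
    "merge_colorize",
]

logger = logging.getLogger(__name__)

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SnapSet:
    """One field of view: registered grayscale channel images."""

    images: dict[str, np.ndarray]
    exposure_s: dict[str, float] = field(default_factory=dict)
    snap_id: str = "snap"

    def __post_init__(self) -> None:
        if not self.images:
            raise ValueError("SnapSet needs at least one channel image")
        shapes = {img.shape for img in self.images.values()}
        dtypes = {img.dtype for img in self.images.values()}
        if len(shapes) != 1 or len(dtypes) != 1:
            raise ValueError(
                f"channel images must share shape and dtype, got {shapes} / {dtypes}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.images.values())).shape

    @property
    def dtype(self) -> np.dtype:
        return next(iter(self.images.values())).dtype


@dataclass(frozen=True)
class PhenotypeRule:
    """Channel logic and size gate defining one phenotype.

    A cell of this phenotype must appear in every ``required_channels``
    member, must not appear in any ``excluded_channels`` member, and
    must span at least ``min_diameter_um``.  Rules are applied in
    increasing ``priority``; components claimed by an earlier rule are
    excluded from later ones.
    """

    label: str
    required_channels: frozenset[str]
    excluded_channels: frozenset[str] = frozenset()
    min_diameter_um: float = 2.5
    priority: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "required_channels", frozenset(self.required_channels))
        object.__setattr__(self, "excluded_channels", frozenset(self.excluded_channels))
        if not self.required_channels:
            raise ValueError("required_channels must be non-empty")
        if self.required_channels & self.excluded_channels:
            raise ValueError("required and excluded channels overlap")
        if self.min_diameter_um <= 0:
            raise ValueError("min_diameter_um must be positive")


#: Four-color immunostaining logic: CTC = nucleus + cytokeratin + PSMA,
#: CD45-negative, ≥7 µm; WBC = nucleus + CD45, ≥2.5 µm; remaining
#: nucleated cells are blue-only.
FOUR_COLOR_RULES: tuple[PhenotypeRule, ...] = (
    PhenotypeRule("CTC", {"blue", "green", "orange"}, {"red"}, 7.0, priority=0),
    PhenotypeRule("WBC", {"blue", "red"}, {"green", "orange"}, 2.5, priority=1),
    PhenotypeRule(
        "NUCLEATED_OTHER", {"blue"}, {"green", "orange", "red"}, 2.5, priority=2
    ),
)

#: Pre-stained two-color assay: CTC = CellTracker orange + nucleus,
#: ≥7 µm; every other nucleated object ≥2.5 µm counts as a nucleus.
TWO_COLOR_RULES: tuple[PhenotypeRule, ...] = (
    PhenotypeRule("CTC", {"orange", "blue"}, frozenset(), 7.0, priority=0),
    PhenotypeRule("NUCLEATED", {"blue"}, frozenset(), 2.5, priority=1),
)

DEFAULT_CHANNEL_COLORS: dict[str, tuple[float, float, float]] = {
    "blue": (0.0, 0.25, 1.0),
    "green": (0.0, 1.0, 0.0),
    "orange": (1.0, 0.65, 0.0),
    "red": (1.0, 0.0, 0.0),
}

_PHENOTYPE_OUTLINE: dict[str, tuple[int, int, int]] = {
    "CTC": (255, 255, 0),
    "WBC": (255, 0, 255),
    "NUCLEATED_OTHER": (0, 255, 255),
    "NUCLEATED": (0, 255, 255),
}


@dataclass(frozen=True)
class DetectedCell:
    """One labeled connected component."""

    label: str | None
    centroid_px: tuple[float, float]  # (x, y)
    area_px: int
    bounding_box: tuple[int, int, int, int]  # (x0, y0, x1, y1), half-open
    mean_intensity: dict[str, float] = field(default_factory=dict)
    snap_id: str = ""

    def __post_init__(self) -> None:
        if self.area_px < 1:
            raise ValueError("area_px must be >= 1")
        x0, y0, x1, y1 = self.bounding_box
        cx, cy = self.centroid_px
        if not (x0 - 0.5 <= cx <= x1 - 0.5 and y0 - 0.5 <= cy <= y1 - 0.5):
            raise ValueError("centroid outside bounding box")


@dataclass
class CountReport:
    """Per-snap and total phenotype tallies plus the detected cells."""

    per_snap: dict[str, dict[str, int]] = field(default_factory=dict)
    totals: dict[str, int] = field(default_factory=dict)
    cells: list[DetectedCell] = field(default_factory=list)

    @classmethod
    def from_cells(
        cls, cells: list[DetectedCell], snap_ids: list[str] | None = None,
        labels: list[str] | None = None,
    ) -> "CountReport":
        per_snap: dict[str, dict[str, int]] = {}
        if snap_ids is not None:
            for sid in snap_ids:
                per_snap.setdefault(sid, {})
        for cell in cells:
            snap = per_snap.setdefault(cell.snap_id, {})
            snap[cell.label] = snap.get(cell.label, 0) + 1
        if labels is not None:
            for snap in per_snap.values():
                for lab in labels:
                    snap.setdefault(lab, 0)
        totals: dict[str, int] = {}
        for snap in per_snap.values():
            for lab, n in snap.items():
                totals[lab] = totals.get(lab, 0) + n
        return cls(per_snap=per_snap, totals=totals, cells=list(cells))

    @classmethod
    def combine(cls, reports: list["CountReport"]) -> "CountReport":
        cells = [c for r in reports for c in r.cells]
        per_snap: dict[str, dict[str, int]] = {}
        for r in reports:
            for sid, counts in r.per_snap.items():
                merged = per_snap.setdefault(sid, {})
                for lab, n in counts.items():
                    merged[lab] = merged.get(lab, 0) + n
        totals: dict[str, int] = {}
        for counts in per_snap.values():
            for lab, n in counts.items():
                totals[lab] = totals.get(lab, 0) + n
        return cls(per_snap=per_snap, totals=totals, cells=cells)


@dataclass(frozen=True)
class PipelineConfig:
    """Preprocessing and discrimination knobs.

    The window/level anchors are histogram percentiles: the low anchor
    subtracts the background pedestal, the high anchor sets full scale.
    The high anchor defaults to 100 (the image maximum) because an
    interior anchor saturates channels whose foreground occupies less
    than the clipped tail — a handful of CTCs in a full field — and a
    background-to-background stretch destroys Otsu separability.
    """

    median_kernel_px: int = 3
    window_low_pct: float = 1.0
    window_high_pct: float = 100.0
    stretch_guard_ratio: float = 10.0
    coincidence_check: bool = True

    def __post_init__(self) -> None:
        if self.median_kernel_px % 2 == 0 or self.median_kernel_px < 1:
            raise ValueError("median_kernel_px must be odd and >= 1")
        if not 0 <= self.window_low_pct < self.window_high_pct <= 100:
            raise ValueError("window percentiles must satisfy 0 <= low < high <= 100")
        if self.stretch_guard_ratio < 0:
            raise ValueError("stretch_guard_ratio must be non-negative")


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------


def median_filter(image: np.ndarray, kernel_px: int) -> np.ndarray:
    """Median-filter with an odd square kernel (edge-replicated borders)."""
    if kernel_px % 2 == 0 or kernel_px < 1:
        raise ValueError(f"kernel_px must be odd and >= 1, got {kernel_px}")
    if kernel_px == 1:
        return image.copy()
    return ndimage.median_filter(image, size=kernel_px, mode="nearest")


def window_level(
    image: np.ndarray, low_percentile: float, high_percentile: float
) -> np.ndarray:
    """Linear window/level contrast stretch between histogram percentiles.

    Intensities at or below the low-percentile value map to 0, at or
    above the high-percentile value to the dtype maximum, linearly in
    between.  A degenerate (constant-window) image is returned unchanged
    with a logged warning.
    """
    if not 0 <= low_percentile < high_percentile <= 100:
        raise ValueError("percentiles must satisfy 0 <= low < high <= 100")
    if not np.issubdtype(image.dtype, np.integer):
        raise TypeError(f"window_level expects an integer image, got {image.dtype}")
    lo, hi = np.percentile(image, [low_percentile, high_percentile])
    if hi <= lo:
        logger.warning(
            "window_level: degenerate window [%s, %s]; image returned unchanged", lo, hi
        )
        return image.copy()
    dmax = np.iinfo(image.dtype).max
    out = (image.astype(np.float64) - lo) * (dmax / (hi - lo))
    return np.clip(np.round(out), 0, dmax).astype(image.dtype)


def compose_mask(snap: SnapSet, rule: PhenotypeRule) -> np.ndarray:
    """Classification mask: Σ required channels − Σ excluded channels.

    Computed in widened (int64) arithmetic, then saturated to the
    channel dtype's [0, max] range.
    """
    for ch in rule.required_channels | rule.excluded_channels:
        if ch not in snap.images:
            raise KeyError(f"channel {ch!r} missing from snap {snap.snap_id!r}")
    acc = np.zeros(snap.shape, dtype=np.int64)
    for ch in sorted(rule.required_channels):
        acc += snap.images[ch].astype(np.int64)
    for ch in sorted(rule.excluded_channels):
        acc -= snap.images[ch].astype(np.int64)
    dmax = np.iinfo(snap.dtype).max
    return np.clip(acc, 0, dmax).astype(snap.dtype)


def otsu_threshold(image: np.ndarray) -> tuple[int, bool]:
    """Otsu's threshold over the intensity histogram, from scratch.

    Returns ``(t, separable)`` where ``t`` maximizes the between-class
    variance ω₀ω₁(µ₀−µ₁)² with class 0 = pixels ≤ t; ties are broken by
    the smallest t.  A constant image returns its value with
    ``separable=False``.
    """
    if image.size == 0:
        raise ValueError("cannot threshold an empty image")
    flat = image.ravel()
    if not np.issubdtype(flat.dtype, np.integer):
        raise TypeError(f"otsu_threshold expects an integer image, got {flat.dtype}")
    vmin = int(flat.min())
    counts = np.bincount((flat.astype(np.int64) - vmin).ravel())
    levels = np.arange(vmin, vmin + counts.size, dtype=np.float64)
    n = flat.size
    w0 = np.cumsum(counts)  # pixels <= t
    s0 = np.cumsum(counts * levels)
    w1 = n - w0
    total = s0[-1]
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        return vmin, False
    mu0 = np.where(w0 > 0, s0 / np.maximum(w0, 1), 0.0)
    mu1 = np.where(w1 > 0, (total - s0) / np.maximum(w1, 1), 0.0)
    bcv = np.where(valid, (w0 / n) * (w1 / n) * (mu0 - mu1) ** 2, -np.inf)
    t = int(np.argmax(bcv))  # first maximum -> smallest threshold
    return vmin + t, True


def _label_components(binary_mask: np.ndarray):
    labels, n = ndimage.label(binary_mask, structure=_EIGHT_CONNECTED)
    return labels, n


def extract_components(
    binary_mask: np.ndarray, snap_id: str = ""
) -> list[DetectedCell]:
    """8-connected components of a binary mask as unlabeled detections.

    Area is the foreground pixel count, the centroid the mean of pixel
    centres; components touching the border are kept.
    """
    labels, n = _label_components(np.asarray(binary_mask, dtype=bool))
    return _components_from_labels(labels, n, snap_id)


def _components_from_labels(
    labels: np.ndarray, n: int, snap_id: str = ""
) -> list[DetectedCell]:
    if n == 0:
        return []
    idx = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones(labels.shape), labels, idx)
    centroids = ndimage.center_of_mass(np.ones(labels.shape), labels, idx)
    slices = ndimage.find_objects(labels)
    cells = []
    for k, (area, (cy, cx), sl) in enumerate(zip(areas, centroids, slices)):
        ys, xs = sl
        cells.append(
            DetectedCell(
                label=None,
                centroid_px=(float(cx), float(cy)),
                area_px=int(round(area)),
                bounding_box=(xs.start, ys.start, xs.stop, ys.stop),
                snap_id=snap_id,
            )
        )
    return cells


def filter_by_area(cells: list[DetectedCell], min_area_px: float) -> list[DetectedCell]:
    """Keep components strictly larger than ``min_area_px``, order preserved."""
    if min_area_px < 0:
        raise ValueError("min_area_px must be non-negative")
    return [c for c in cells if c.area_px > min_area_px]


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def _subtract_pedestal(image: np.ndarray, low_percentile: float) -> np.ndarray:
    lo = np.percentile(image, low_percentile)
    out = image.astype(np.int64) - int(round(lo))
    return np.clip(out, 0, np.iinfo(image.dtype).max).astype(image.dtype)


def _preprocess(snap: SnapSet, config: PipelineConfig) -> SnapSet:
    """Median-denoise, then background-reduce and contrast-stretch.

    The window/level stretch is applied per channel only when the channel
    shows dynamic range well beyond its noise band — specifically when
    the upper window half (high anchor − median) exceeds
    ``stretch_guard_ratio`` times the lower half (median − low anchor).
    A channel with no emitters fails that guard (its whole histogram is
    the background noise band, so a percentile stretch would amplify
    pure noise to full scale and corrupt the mask arithmetic); such
    channels only get their background pedestal subtracted.
    """
    pre: dict[str, np.ndarray] = {}
    signal: dict[str, bool] = {}
    for ch, img in snap.images.items():
        img = median_filter(img, config.median_kernel_px)
        lo, mid, hi = np.percentile(
            img, [config.window_low_pct, 50.0, config.window_high_pct]
        )
        signal[ch] = hi - mid > config.stretch_guard_ratio * max(mid - lo, 1.0)
        if signal[ch]:
            pre[ch] = window_level(img, config.window_low_pct, config.window_high_pct)
        else:
            logger.info(
                "channel %s: no signal beyond the noise band; pedestal subtraction only",
                ch,
            )
            pre[ch] = _subtract_pedestal(img, config.window_low_pct)
    return SnapSet(images=pre, exposure_s=snap.exposure_s, snap_id=snap.snap_id), signal


def classify_and_count(
    snap: SnapSet,
    rules: list[PhenotypeRule] | tuple[PhenotypeRule, ...],
    optics: OpticsGeometry,
    config: PipelineConfig | None = None,
) -> tuple[CountReport, dict[str, np.ndarray]]:
    """Run the recognition pipeline on one snap.

    Returns the count report and, per phenotype label, the binary mask
    of the components that kept that label.
    """
    config = config or PipelineConfig()
    rules = sorted(rules, key=lambda r: r.priority)
    if len({r.priority for r in rules}) != len(rules):
        raise ValueError("rules must have distinct priorities")
    if len({r.label for r in rules}) != len(rules):
        raise ValueError("rules must have distinct labels")
    logger.info(
        "classify_and_count snap=%s rules=%s median=%d window=(%g,%g)",
        snap.snap_id,
        [r.label for r in rules],
        config.median_kernel_px,
        config.window_low_pct,
        config.window_high_pct,
    )
    pre, signal = _preprocess(snap, config)
    channel_thr: dict[str, int] = {}
    if config.coincidence_check:
        used = set().union(*(r.required_channels | r.excluded_channels for r in rules))
        # thresholds are meaningful only where the channel carries signal
        for ch in sorted(used & {c for c, has in signal.items() if has}):
            channel_thr[ch], _ = otsu_threshold(pre.images[ch])
            logger.info("channel %s Otsu threshold: %d", ch, channel_thr[ch])

    claimed = np.zeros(snap.shape, dtype=bool)
    kept: list[DetectedCell] = []
    label_masks: dict[str, np.ndarray] = {}
    for rule in rules:
        mask = compose_mask(pre, rule)
        thr, separable = otsu_threshold(mask)
        label_masks[rule.label] = np.zeros(snap.shape, dtype=bool)
        if not separable:
            logger.info("rule %s: mask not separable, no detections", rule.label)
            continue
        binary = mask > thr
        labels, n = _label_components(binary)
        cells = _components_from_labels(labels, n, snap.snap_id)
        min_area = circle_area_px(rule.min_diameter_um, optics)
        logger.info(
            "rule %s: mask threshold %d, %d components, area gate > %d px",
            rule.label, thr, len(cells), min_area,
        )
        # label ids are 1..n in extraction order; keep them aligned
        pairs = [
            (comp_id, cell)
            for comp_id, cell in enumerate(cells, start=1)
            if cell.area_px > min_area
        ]
        for comp_id, cell in pairs:
            comp = labels == comp_id
            cy, cx = int(round(cell.centroid_px[1])), int(round(cell.centroid_px[0]))
            if claimed[cy, cx]:
                continue
            means = {
                ch: float(pre.images[ch][comp].mean()) for ch in pre.images
            }
            if config.coincidence_check and not _coincident(
                rule, means, channel_thr, signal
            ):
                continue
            claimed |= comp
            label_masks[rule.label] |= comp
            kept.append(replace(cell, label=rule.label, mean_intensity=means))
    report = CountReport.from_cells(
        kept, snap_ids=[snap.snap_id], labels=[r.label for r in rules]
    )
    return report, label_masks


def _coincident(
    rule: PhenotypeRule,
    means: dict[str, float],
    channel_thr: dict[str, int],
    signal: dict[str, bool],
) -> bool:
    """Component-level channel coincidence.

    Every required channel must carry signal in this snap and the
    component's mean there must exceed that channel's Otsu threshold;
    every excluded channel with signal must stay at or below its
    threshold (an excluded channel without signal excludes nothing).
    """
    for ch in rule.required_channels:
        if not signal.get(ch, False):
            return False
        if ch in channel_thr and means.get(ch, 0.0) <= channel_thr[ch]:
            return False
    for ch in rule.excluded_channels:
        if signal.get(ch, False) and ch in channel_thr and means.get(ch, 0.0) > channel_thr[ch]:
            return False
    return True


def merge_colorize(
    snap: SnapSet,
    cells: list[DetectedCell] | None = None,
    channel_colors: dict[str, tuple[float, float, float]] | None = None,
) -> np.ndarray:
    """Additively blend tinted channels into an 8-bit RGB display image.

    Detected cells are outlined with their phenotype's display color
    along the bounding box.  Deterministic.
    """
    colors = channel_colors or DEFAULT_CHANNEL_COLORS
    out = np.zeros((*snap.shape, 3), dtype=np.float64)
    dmax = np.iinfo(snap.dtype).max
    for ch, img in snap.images.items():
        tint = colors.get(ch)
        if tint is None:
            raise KeyError(f"no display color for channel {ch!r}")
        norm = img.astype(np.float64) / dmax
        for plane, weight in enumerate(tint):
            if weight:
                out[..., plane] += weight * norm
    rgb = np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)
    for cell in cells or []:
        color = _PHENOTYPE_OUTLINE.get(cell.label, (255, 255, 255))
        x0, y0, x1, y1 = cell.bounding_box
        x0, y0 = max(x0 - 1, 0), max(y0 - 1, 0)
        x1, y1 = min(x1 + 1, rgb.shape[1]), min(y1 + 1, rgb.shape[0])
        rgb[y0, x0:x1] = color
        rgb[y1 - 1, x0:x1] = color
        rgb[y0:y1, x0] = color
        rgb[y0:y1, x1 - 1] = color
    return rgb
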