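"""Brightness-based coarse/fine autofocus over a predefined Z range.

Cell brightness peaks when the image is in focus (assuming no
over-exposure), so the focus plane is found by acquiring a predefined
number of equidistant pictures across the range and selecting the one
of maximum global brightness — the maximum pixel value after a median
denoise that rejects hot pixels.  A normalized-variance contrast metric
is provided for comparison; on nearly empty samples the brightness
metric is the more reliable of the two because the contrast of a sparse
field is dominated by background noise.

The search is two-stage: a coarse equidistant pass over the full range
(default 15 samples) followed by an optional fine pass centred on the
coarse optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .classify import median_filter

__all__ = [
    "FocusSearchConfig",
    "FocusResult",
    "SaturationWarning",
    "brightness_metric",
    "contrast_metric",
    "autofocus_search",
]


class SaturationWarning(UserWarning):
    """The focus image reaches the dtype maximum; brightness is clipped."""


@dataclass(frozen=True)
class FocusSearchConfig:
    z_min_um: float = -20.0
    z_max_um: float = 20.0
    n_coarse: int = 15
    n_fine: int = 7
    fine_halfwidth_um: float | None = None  # None -> one coarse step
    metric: str = "brightness"
    denoise_kernel_px: int = 3

    def __post_init__(self) -> None:
        if not self.z_min_um < self.z_max_um:
            raise ValueError("z_min_um must be below z_max_um")
        if self.n_coarse < 2:
            raise ValueError("n_coarse must be >= 2")
        if self.n_fine < 0 or self.n_fine == 1:
            raise ValueError("n_fine must be 0 (skip fine pass) or >= 2")
        if self.metric not in ("brightness", "contrast"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.fine_halfwidth_um is not None and self.fine_halfwidth_um <= 0:
            raise ValueError("fine_halfwidth_um must be positive")

    @property
    def coarse_step_um(self) -> float:
        return (self.z_max_um - self.z_min_um) / (self.n_coarse - 1)


@dataclass(frozen=True)
class FocusResult:
    best_z_um: float
    metric_curve: tuple[tuple[float, float], ...]  # (z, score) per acquisition
    stage: str  # "coarse" or "fine"


def brightness_metric(image: np.ndarray, denoise_kernel_px: int = 3) -> float:
    """Maximum pixel value after a median denoise.

    Invariant to adding dark, out-of-focus area around the field.  A
    saturated input (raw maximum at the dtype ceiling) emits a
    :class:`SaturationWarning`, since a clipped peak no longer
    discriminates focus.
    """
    if image.size == 0:
        raise ValueError("empty image")
    if np.issubdtype(image.dtype, np.integer) and image.max() == np.iinfo(image.dtype).max:
        warnings.warn(
            "focus image is saturated; brightness metric may be unreliable",
            SaturationWarning,
            stacklevel=2,
        )
    return float(median_filter(image, denoise_kernel_px).max())


def contrast_metric(image: np.ndarray) -> float:
    """Normalized variance: var(pixels)/mean(pixels); 0 for a dark image."""
    if image.size == 0:
        raise ValueError("empty image")
    arr = image.astype(np.float64)
    mean = arr.mean()
    return float(arr.var() / mean) if mean > 0 else 0.0


def _score(image: np.ndarray, config: FocusSearchConfig) -> float:
    if config.metric == "brightness":
        return brightness_metric(image, config.denoise_kernel_px)
    return contrast_metric(image)


def autofocus_search(acquire_fn, config: FocusSearchConfig) -> FocusResult:
    """Two-stage equidistant focus search.

    ``acquire_fn(z_um) -> image`` is called exactly ``n_coarse + n_fine``
    times.  The fine pass spans the coarse optimum ± one coarse step (or
    ``fine_halfwidth_um``), clipped to the search range.  The returned
    plane is the argmax of the metric over every acquisition; ties go to
    the lowest z.
    """
    curve: list[tuple[float, float]] = []

    def sample(zs: np.ndarray) -> None:
        for z in zs:
            try:
                image = acquire_fn(float(z))
            except Exception as exc:
                raise RuntimeError(f"acquisition failed at z={z:g} µm") from exc
            curve.append((float(z), _score(image, config)))

    sample(np.linspace(config.z_min_um, config.z_max_um, config.n_coarse))
    stage = "coarse"
    if config.n_fine > 0:
        best_z, _ = _argmax_lowest_z(curve)
        hw = config.fine_halfwidth_um or config.coarse_step_um
        lo = max(config.z_min_um, best_z - hw)
        hi = min(config.z_max_um, best_z + hw)
        sample(np.linspace(lo, hi, config.n_fine))
        stage = "fine"
    best_z, _ = _argmax_lowest_z(curve)
    return FocusResult(best_z_um=best_z, metric_curve=tuple(curve), stage=stage)


def _argmax_lowest_z(curve: list[tuple[float, float]]) -> tuple[float, float]:
    best_score = max(score for _, score in curve)
    best_z = min(z for z, score in curve if score == best_score)
    return best_z, best_score
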