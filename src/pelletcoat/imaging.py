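"""Coated-surface estimation from RGB images of pellets.

Pellets carrying a methylene-blue-dyed coating are photographed on a
dark background.  Coverage is quantified per pixel: blue-dominant pixels
count as coated film, white/grey pixels as exposed cellulose, and
near-black pixels as background.  Two estimators are provided:

* **threshold mode** — classify every pixel and report
  ``100 * coated / (coated + uncoated)``;
* **reference-differential mode** — compare the quantized RGB histogram
  of the sample against the histogram of uncoated pellets and attribute
  the positive excess frequency mass to coated or uncoated colour bins.

Both treat the image as a projected area; no correction for pellet
curvature is attempted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "BACKGROUND",
    "COATED",
    "UNCOATED",
    "AMBIGUOUS",
    "LABEL_NAMES",
    "ClassifierThresholds",
    "PelletImage",
    "RGBHistogram",
    "CoverageResult",
    "classify_pixel",
    "classify_pixels",
    "rgb_histogram",
    "coated_surface_percent",
    "batch_coverage",
    "read_image",
]

BACKGROUND, COATED, UNCOATED, AMBIGUOUS = 0, 1, 2, 3
LABEL_NAMES = {BACKGROUND: "background", COATED: "coated",
               UNCOATED: "uncoated", AMBIGUOUS: "ambiguous"}


@dataclass(frozen=True)
class ClassifierThresholds:
    """Pixel-classification thresholds in normalized [0, 1] units.

    ``t_bg``: a pixel is background when its brightest channel falls
    below this.  ``t_blue``/``v_min``: coated when blue exceeds the
    larger of red and green by at least ``t_blue`` and is at least
    ``v_min`` bright.  ``t_white``/``t_gray``: uncoated when the darkest
    channel is at least ``t_white`` and the channel spread is at most
    ``t_gray``.  Anything else is ambiguous.
    """

    t_bg: float = 0.16
    t_blue: float = 0.08
    v_min: float = 0.25
    t_white: float = 0.50
    t_gray: float = 0.15


@dataclass
class PelletImage:
    """An RGB raster of pellets with acquisition metadata.

    ``pixels`` is an H x W x 3 float array with channels normalized to
    [0, 1].  ``ground_truth`` carries the known coated fraction for
    synthetic images; ``coated_mask``/``pellet_mask`` hold the painting
    masks the synthetic generator worked from, enabling pixel-count
    oracles.
    """

    pixels: np.ndarray
    source_id: str = ""
    lux: float | None = None
    ground_truth: float | None = None
    coated_mask: np.ndarray | None = field(default=None, repr=False)
    pellet_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected an H x W x 3 raster, got shape {px.shape}")
        if px.min() < -1e-9 or px.max() > 1 + 1e-9:
            raise ValueError("channel values must be normalized to [0, 1]")
        self.pixels = np.clip(px, 0.0, 1.0)


@dataclass
class RGBHistogram:
    """Quantized 3-D colour histogram as per-bin pixel percentages."""

    bins_per_channel: int
    frequencies: np.ndarray  # shape (b, b, b), sums to 100 over counted pixels

    def __post_init__(self) -> None:
        total = float(self.frequencies.sum())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"histogram frequencies sum to {total}, expected 100")

    @property
    def bin_centers(self) -> np.ndarray:
        b = self.bins_per_channel
        return (np.arange(b) + 0.5) / b


@dataclass
class CoverageResult:
    """Coated-surface estimate for one image."""

    coated_pct: float
    n_coated_px: int
    n_uncoated_px: int
    n_background_px: int
    n_ambiguous_px: int
    mode: Literal["threshold", "reference_differential"]
    source_id: str = ""

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def classify_pixel(rgb: Sequence[float],
                   thresholds: ClassifierThresholds | None = None) -> str:
    """Classify one normalized RGB triple; returns the label name."""
    arr = np.asarray(rgb, dtype=float).reshape(1, 1, 3)
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError(f"RGB channels must lie in [0, 1], got {tuple(rgb)}")
    label = classify_pixels(arr, thresholds)[0, 0]
    return LABEL_NAMES[int(label)]


def classify_pixels(pixels: np.ndarray,
                    thresholds: ClassifierThresholds | None = None) -> np.ndarray:
    """Vectorised pixel classification; returns an H x W integer label map."""
    t = thresholds or ClassifierThresholds()
    px = np.asarray(pixels, dtype=float)
    r, g, b = px[..., 0], px[..., 1], px[..., 2]
    cmax = px.max(axis=-1)
    cmin = px.min(axis=-1)
    labels = np.full(px.shape[:-1], AMBIGUOUS, dtype=np.uint8)
    is_bg = cmax < t.t_bg
    is_coated = ~is_bg & ((b - np.maximum(r, g)) >= t.t_blue) & (b >= t.v_min)
    is_uncoated = ~is_bg & ~is_coated & (cmin >= t.t_white) & ((cmax - cmin) <= t.t_gray)
    labels[is_bg] = BACKGROUND
    labels[is_coated] = COATED
    labels[is_uncoated] = UNCOATED
    return labels


def rgb_histogram(image: PelletImage,
                  bins_per_channel: int = 32,
                  exclude_background: bool = True,
                  thresholds: ClassifierThresholds | None = None) -> RGBHistogram:
    """Quantized colour histogram of an image, as pixel percentages.

    With ``exclude_background`` the denominator counts only pixels not
    classified as background, mirroring histograms taken over the pellet
    foreground.
    """
    px = image.pixels.reshape(-1, 3)
    if exclude_background:
        labels = classify_pixels(image.pixels, thresholds).reshape(-1)
        px = px[labels != BACKGROUND]
        if px.size == 0:
            raise ValueError("no pellet (foreground) pixels in image")
    idx = np.minimum((px * bins_per_channel).astype(int), bins_per_channel - 1)
    counts = np.zeros((bins_per_channel,) * 3)
    np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    return RGBHistogram(bins_per_channel, counts * (100.0 / counts.sum()))


def _bin_center_labels(bins_per_channel: int,
                       thresholds: ClassifierThresholds | None) -> np.ndarray:
    centers = (np.arange(bins_per_channel) + 0.5) / bins_per_channel
    rr, gg, bb = np.meshgrid(centers, centers, centers, indexing="ij")
    grid = np.stack([rr, gg, bb], axis=-1)
    return classify_pixels(grid, thresholds)


def coated_surface_percent(
    image: PelletImage,
    reference: RGBHistogram | None = None,
    mode: Literal["threshold", "reference_differential"] = "threshold",
    thresholds: ClassifierThresholds | None = None,
    bins_per_channel: int = 32,
) -> CoverageResult:
    """Estimate the coated surface (%) of one image.

    In threshold mode, ``coated_pct = 100 * coated / (coated +
    uncoated)``; ambiguous pixels are excluded from the denominator.  In
    reference-differential mode the positive excess of the sample
    histogram over an uncoated-pellet reference, ``D(b) = max(0,
    f_sample(b) - f_ref(b))``, is attributed to bins whose centre colour
    classifies as coated; a zero total excess (sample indistinguishable
    from the reference) is reported as 0 % with a warning.
    """
    labels = classify_pixels(image.pixels, thresholds)
    counts = {
        lab: int((labels == lab).sum())
        for lab in (BACKGROUND, COATED, UNCOATED, AMBIGUOUS)
    }
    if mode == "threshold":
        denom = counts[COATED] + counts[UNCOATED]
        if denom == 0:
            raise ValueError("no coated or uncoated pixels found in image")
        pct = 100.0 * counts[COATED] / denom
    elif mode == "reference_differential":
        if reference is None:
            raise ValueError("reference_differential mode requires an "
                             "uncoated-pellet reference histogram")
        sample = rgb_histogram(image, reference.bins_per_channel,
                               exclude_background=True, thresholds=thresholds)
        excess = np.maximum(0.0, sample.frequencies - reference.frequencies)
        bin_labels = _bin_center_labels(reference.bins_per_channel, thresholds)
        foreground = bin_labels != BACKGROUND
        total = float(excess[foreground].sum())
        if total == 0.0:
            warnings.warn("sample histogram does not exceed the reference in "
                          "any bin; reporting 0 % coverage", stacklevel=2)
            pct = 0.0
        else:
            coated_mass = float(excess[foreground & (bin_labels == COATED)].sum())
            pct = 100.0 * coated_mass / total
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return CoverageResult(
        coated_pct=pct,
        n_coated_px=counts[COATED],
        n_uncoated_px=counts[UNCOATED],
        n_background_px=counts[BACKGROUND],
        n_ambiguous_px=counts[AMBIGUOUS],
        mode=mode,
        source_id=image.source_id,
    )


def batch_coverage(
    images: Iterable[PelletImage],
    reference: RGBHistogram | None = None,
    mode: Literal["threshold", "reference_differential"] = "threshold",
    thresholds: ClassifierThresholds | None = None,
) -> tuple[float, float, list[CoverageResult]]:
    """Mean and sd of coated surface over a set of images.

    Returns ``(mean_pct, sd_pct, per_image_results)``; the per-image
    list preserves input order for audit.  The sd is the population sd
    of a single image (0 for a single image).
    """
    results = [
        coated_surface_percent(img, reference=reference, mode=mode,
                               thresholds=thresholds)
        for img in images
    ]
    if not results:
        raise ValueError("batch_coverage requires at least one image")
    values = np.array([r.coated_pct for r in results])
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return float(values.mean()), sd, results


def read_image(path: str | Path, source_id: str | None = None) -> PelletImage:
    """Read a PNG or TIFF file into a normalized :class:`PelletImage`.

    8- and 16-bit integer rasters are scaled to [0, 1]; alpha channels
    are dropped and greyscale images broadcast to three channels.
    """
    import imageio.v3 as iio

    arr = iio.imread(Path(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] > 3:
        arr = arr[..., :3]
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    return PelletImage(arr.astype(float), source_id=source_id or Path(path).stem)
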