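"""Synthetic inputs with known ground truth for every pipeline stage.

Real inputs to the coating analytics — stereoscope images of pellets,
design-table responses, laser-diffraction size distributions, dissolution
time courses and repose-pile photographs — all come from bench work.
This module generates look-alikes whose ground truth is known exactly,
so each downstream estimator can be validated end to end:

* pellet images as bright discs on a near-black field, with a
  blue-dominant "coated" paint applied over an exact pixel-count mask;
* design-table responses drawn from a coded-factor model plus Gaussian
  error;
* first-order-with-burst cumulative release profiles;
* log-normal volume-weighted size distributions;
* conical pile silhouettes of known repose angle.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .doe import TERM_NAMES, FactorLevels, encode_run
from .imaging import PelletImage
from .powder import SizeDistribution
from .dissolution import ReleaseProfile

__all__ = [
    "ImageGroundTruth",
    "SimulationSpec",
    "COATED_COLOR",
    "UNCOATED_COLOR",
    "BACKGROUND_COLOR",
    "gen_pellet_image",
    "gen_doe_response",
    "gen_release_profile",
    "gen_size_distribution",
    "gen_pile_silhouette",
]

# Normalized RGB paints: methylene-blue-dyed film, white cellulose, black glass.
COATED_COLOR = (0.15, 0.20, 0.75)
UNCOATED_COLOR = (0.92, 0.92, 0.92)
BACKGROUND_COLOR = (0.03, 0.03, 0.03)


@dataclass(frozen=True)
class ImageGroundTruth:
    """Recipe for one synthetic pellet image."""

    coated_fraction: float
    n_pellets: int = 10
    pellet_radius_px: int = 12
    noise_sd: float = 0.0
    seed: int = 0
    image_size: tuple[int, int] = (192, 192)

    def __post_init__(self) -> None:
        if not 0.0 <= self.coated_fraction <= 1.0:
            raise ValueError("coated_fraction must lie in [0, 1]")
        if self.n_pellets < 1:
            raise ValueError("need at least one pellet")
        if self.pellet_radius_px < 2:
            raise ValueError("pellet radius must be at least 2 px")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class SimulationSpec:
    """Generating model for design-table responses.

    ``model_coefficients`` maps term names (intercept, A, B1, ... B2C2)
    to coated-surface-percent coefficients; ``noise_sd`` is the Gaussian
    response error in percentage points.
    """

    model_coefficients: Mapping[str, float]
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.model_coefficients) - set(TERM_NAMES)
        if unknown:
            raise ValueError(f"unknown model terms: {sorted(unknown)}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _place_discs(rng: np.random.Generator, truth: ImageGroundTruth,
                 max_tries: int = 1000) -> list[tuple[int, int]]:
    h, w = truth.image_size
    r = truth.pellet_radius_px
    centers: list[tuple[int, int]] = []
    for i in range(truth.n_pellets):
        for _ in range(max_tries):
            cy = int(rng.integers(r, h - r))
            cx = int(rng.integers(r, w - r))
            if all((cy - y) ** 2 + (cx - x) ** 2 >= (2 * r + 1) ** 2
                   for y, x in centers):
                centers.append((cy, cx))
                break
        else:
            raise ValueError(
                f"could not place disc {i + 1}/{truth.n_pellets} of radius "
                f"{r}px in a {h}x{w} image without overlap after {max_tries} "
                "attempts; reduce n_pellets or pellet_radius_px"
            )
    return centers


def gen_pellet_image(truth: ImageGroundTruth) -> PelletImage:
    """Render a synthetic pellet image with an exact coated-pixel budget.

    Non-overlapping discs are painted the uncoated (white) colour on a
    near-black background, then a coated (blue) angular sector of each
    disc is painted so the total coated pixel count equals
    ``round(coated_fraction * total pellet pixels)`` exactly.  Gaussian
    channel noise is added last and clipped to [0, 1].  The painting
    masks and the ground-truth fraction travel with the image.
    """
    rng = np.random.default_rng(truth.seed)
    h, w = truth.image_size
    centers = _place_discs(rng, truth)

    yy, xx = np.mgrid[0:h, 0:w]
    pellet_mask = np.zeros((h, w), dtype=bool)
    disc_masks = []
    for cy, cx in centers:
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= truth.pellet_radius_px**2
        disc_masks.append(disc)
        pellet_mask |= disc

    total_px = int(pellet_mask.sum())
    budget = int(round(truth.coated_fraction * total_px))
    # proportional per-disc quotas, residual assigned greedily so the
    # image-wide coated count is exact
    sizes = np.array([int(d.sum()) for d in disc_masks])
    quotas = np.floor(budget * sizes / total_px).astype(int)
    shortfall = budget - int(quotas.sum())
    order = rng.permutation(len(disc_masks))
    for i in order:
        if shortfall == 0:
            break
        room = sizes[i] - quotas[i]
        take = min(room, shortfall)
        quotas[i] += take
        shortfall -= take

    coated_mask = np.zeros((h, w), dtype=bool)
    for disc, quota, (cy, cx) in zip(disc_masks, quotas, centers):
        if quota == 0:
            continue
        ys, xs = np.nonzero(disc)
        angles = np.arctan2(ys - cy, xs - cx)
        start = rng.uniform(-math.pi, math.pi)
        # angular sector sweep from a random start angle
        rank = np.argsort((angles - start) % (2 * math.pi), kind="stable")
        chosen = rank[:quota]
        coated_mask[ys[chosen], xs[chosen]] = True

    img = np.empty((h, w, 3))
    img[:] = BACKGROUND_COLOR
    img[pellet_mask] = UNCOATED_COLOR
    img[coated_mask] = COATED_COLOR
    if truth.noise_sd > 0:
        img = img + rng.normal(0.0, truth.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return PelletImage(
        pixels=img,
        source_id=f"synthetic-seed{truth.seed}",
        ground_truth=truth.coated_fraction,
        coated_mask=coated_mask,
        pellet_mask=pellet_mask,
    )


def gen_doe_response(design: pd.DataFrame, spec: SimulationSpec) -> pd.DataFrame:
    """Simulate coated-surface responses for a design table.

    The response at each run is the coded-factor model evaluated at that
    run's levels plus N(0, noise_sd^2) error, clamped to [0, 100] after
    the noise is applied.
    """
    from .doe import CodedModel, predict, validate_design_table

    design = validate_design_table(design, require_response=False)
    model = CodedModel.from_coefficients(spec.model_coefficients)
    mean = np.array([
        predict(model, FactorLevels(p, c, r))
        for p, c, r in zip(design["polymer"], design["concentration_pct"],
                           design["ratio"])
    ])
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, size=len(mean)) if spec.noise_sd > 0 else 0.0
    out = design.copy()
    out["coated_surface_pct"] = np.clip(mean + noise, 0.0, 100.0)
    return out


def gen_release_profile(
    times_min: Sequence[float],
    f_burst: float,
    k_per_min: float,
    plateau: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ReleaseProfile:
    """First-order release with a burst.

    Cumulative % at time t is ``f_burst + plateau * (1 - exp(-k t))``
    plus Gaussian noise, then repaired to be non-decreasing with a
    running maximum (noise first, repair second — measurements are noisy,
    cumulative reports are monotone).
    """
    t = np.asarray(times_min, dtype=float)
    if t.size and (np.diff(t) <= 0).any():
        raise ValueError("times must be strictly increasing")
    if k_per_min < 0:
        raise ValueError("rate constant must be non-negative")
    if f_burst < 0 or plateau < 0 or f_burst + plateau > 100:
        raise ValueError("need f_burst, plateau >= 0 and f_burst + plateau <= 100")
    mean = f_burst + plateau * (1.0 - np.exp(-k_per_min * t))
    rng = np.random.default_rng(seed)
    values = mean + (rng.normal(0.0, noise_sd, size=t.shape) if noise_sd > 0 else 0.0)
    values = np.maximum.accumulate(np.clip(values, 0.0, None))
    return ReleaseProfile(t, values)


def gen_size_distribution(
    median_um: float,
    gsd: float,
    n_bins: int = 50,
    range_um: tuple[float, float] | None = None,
) -> SizeDistribution:
    """Log-normal volume-weighted size distribution on geometric bins.

    ``gsd`` is the geometric standard deviation (> 1); the default bin
    range spans ±4 geometric sd around the median.
    """
    if median_um <= 0:
        raise ValueError("median diameter must be positive")
    if gsd <= 1:
        raise ValueError("geometric standard deviation must exceed 1")
    if range_um is None:
        span = gsd**4
        range_um = (median_um / span, median_um * span)
    low, high = range_um
    if low <= 0 or high <= low:
        raise ValueError("bin range must be positive and increasing")
    edges = np.geomspace(low, high, n_bins + 1)
    centers = np.sqrt(edges[:-1] * edges[1:])
    sigma = math.log(gsd)
    z = (np.log(centers) - math.log(median_um)) / sigma
    weights = np.exp(-0.5 * z**2) * np.diff(np.log(edges))
    return SizeDistribution(centers, weights)


def gen_pile_silhouette(
    angle_deg: float,
    base_width_px: int = 200,
    noise_px: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Binary silhouette of a conical pile of known repose angle.

    Returns the raster (rows top to bottom, base on the last occupied
    row) and a ground-truth record.  ``noise_px`` jitters each row's
    half-width to mimic a ragged pile edge.
    """
    if not 0.0 < angle_deg < 90.0:
        raise ValueError("repose angle must lie strictly between 0 and 90 degrees")
    if base_width_px < 4:
        raise ValueError("base width too small")
    rng = np.random.default_rng(seed)
    half_base = base_width_px / 2.0
    height = half_base * math.tan(math.radians(angle_deg))
    n_rows = int(round(height)) + 1
    width = base_width_px + 2 * (int(math.ceil(3 * noise_px)) + 1)
    cx = width / 2.0
    mask = np.zeros((n_rows, width), dtype=bool)
    for i in range(n_rows):
        # row 0 is the apex; half-width grows linearly down to the base
        hw = half_base * i / max(n_rows - 1, 1)
        if noise_px > 0 and 0 < i < n_rows - 1:
            hw = max(0.5, hw + rng.normal(0.0, noise_px))
        lo = int(round(cx - hw))
        hi = int(round(cx + hw))
        mask[i, lo:hi + 1] = True
    truth = {
        "angle_deg": angle_deg,
        "base_width_px": base_width_px,
        "height_px": n_rows - 1,
        "noise_px": noise_px,
        "seed": seed,
    }
    return mask, truth
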