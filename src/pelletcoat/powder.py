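"""Powder flowability, particle-size moments and microsphere loading.

Covers the bench characterisation around the coating step: bulk/tapped
density derived flow indices (Hausner ratio, Carr's compressibility
index), the static angle of repose measured from pile photographs,
volume-moment particle-size statistics (De Brouckere mean D4,3, Sauter
mean D3,2, specific surface area), counting-chamber calibration and the
microsphere load of coated pellets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "DensitySet",
    "FlowIndices",
    "SizeDistribution",
    "CalibrationCurve",
    "FLOW_SCALE",
    "hausner_ratio",
    "carr_index",
    "replicate_flow_indices",
    "classify_flow",
    "angle_of_repose",
    "angle_from_dimensions",
    "d43",
    "d32",
    "ssa",
    "fit_calibration",
    "concentration_from_count",
    "loading",
    "load_yield",
]


@dataclass
class DensitySet:
    """Replicate bulk, tapped and true densities (g/cm^3)."""

    bulk_g_cm3: Sequence[float]
    tapped_g_cm3: Sequence[float]
    true_g_cm3: Sequence[float] = ()

    def __post_init__(self) -> None:
        for name in ("bulk_g_cm3", "tapped_g_cm3", "true_g_cm3"):
            vals = np.asarray(getattr(self, name), dtype=float)
            if vals.size and (vals <= 0).any():
                raise ValueError(f"{name} must be strictly positive")
            setattr(self, name, vals)
        if len(self.bulk_g_cm3) != len(self.tapped_g_cm3):
            raise ValueError("bulk and tapped replicates must pair up")
        bad = self.tapped_g_cm3 < self.bulk_g_cm3
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} replicate(s) have tapped density below bulk "
                "density; flow indices will fall below their physical floor",
                stacklevel=2,
            )


@dataclass
class FlowIndices:
    """Flow-indicative indices with replicate dispersion."""

    hausner: float
    carr_pct: float
    hausner_sd: float = 0.0
    carr_sd: float = 0.0
    angle_deg: float | None = None
    classification: str | None = None


# USP <1174>-style flow scale: (upper HR bound, label); the boundary value
# belongs to the better class.
FLOW_SCALE: tuple[tuple[float, str], ...] = (
    (1.11, "excellent"),
    (1.18, "good"),
    (1.25, "fair"),
    (1.34, "passable"),
    (1.45, "poor"),
    (1.59, "very poor"),
    (math.inf, "very, very poor"),
)


def hausner_ratio(bulk_g_cm3: float, tapped_g_cm3: float) -> float:
    """Hausner ratio HR = tapped density / bulk density."""
    if bulk_g_cm3 <= 0 or tapped_g_cm3 <= 0:
        raise ValueError("densities must be strictly positive")
    return tapped_g_cm3 / bulk_g_cm3


def carr_index(bulk_g_cm3: float, tapped_g_cm3: float) -> float:
    """Carr's compressibility index CI% = 100 * (tapped - bulk) / tapped."""
    if bulk_g_cm3 <= 0 or tapped_g_cm3 <= 0:
        raise ValueError("densities must be strictly positive")
    return 100.0 * (tapped_g_cm3 - bulk_g_cm3) / tapped_g_cm3


def replicate_flow_indices(densities: DensitySet,
                           mode: str = "per_replicate") -> FlowIndices:
    """Flow indices from replicate densities.

    ``per_replicate`` computes HR and CI per paired replicate and reports
    their mean and sd (matching the mean ± sd presentation of replicate
    bench measurements); ``pooled`` computes single indices from the mean
    densities.
    """
    rb, rt = densities.bulk_g_cm3, densities.tapped_g_cm3
    if mode == "per_replicate":
        hrs = rt / rb
        cis = 100.0 * (rt - rb) / rt
        hr, ci = float(hrs.mean()), float(cis.mean())
        hr_sd = float(hrs.std(ddof=1)) if len(hrs) > 1 else 0.0
        ci_sd = float(cis.std(ddof=1)) if len(cis) > 1 else 0.0
    elif mode == "pooled":
        hr = hausner_ratio(float(rb.mean()), float(rt.mean()))
        ci = carr_index(float(rb.mean()), float(rt.mean()))
        hr_sd = ci_sd = 0.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = FlowIndices(hr, ci, hr_sd, ci_sd)
    out.classification = classify_flow(out)
    return out


def classify_flow(indices: FlowIndices | float,
                  scale: Sequence[tuple[float, str]] = FLOW_SCALE) -> str:
    """Map a Hausner ratio onto a pharmacopeial flow-character label."""
    hr = indices.hausner if isinstance(indices, FlowIndices) else float(indices)
    for bound, label in scale:
        if hr <= bound:
            return label
    return scale[-1][1]


def angle_from_dimensions(height: float, base_half_width: float) -> float:
    """Repose angle (degrees) from pile height and base half-width."""
    if height < 0 or base_half_width <= 0:
        raise ValueError("need height >= 0 and base half-width > 0")
    return math.degrees(math.atan2(height, base_half_width))


def angle_of_repose(silhouette: np.ndarray, base_band_frac: float = 0.05) -> float:
    """Static angle of repose from a binary pile silhouette.

    The pile must form one connected region.  The base is the widest
    occupied row within the bottom ``base_band_frac`` of the pile's
    height (robust to baseline noise); the apex is the highest occupied
    row.  The angle is ``atan(height / base half-width)``.
    """
    mask = np.asarray(silhouette).astype(bool)
    if mask.ndim != 2 or not mask.any():
        raise ValueError("silhouette must be a non-empty 2-D binary raster")
    _, n_components = ndimage.label(mask)
    if n_components != 1:
        raise ValueError(f"expected one connected pile, found {n_components} regions")
    rows = np.flatnonzero(mask.any(axis=1))
    top, bottom = rows[0], rows[-1]
    height_px = bottom - top
    band_start = bottom - max(1, int(round(base_band_frac * (height_px + 1)))) + 1
    widths = mask[band_start:bottom + 1].sum(axis=1)
    base_px = int(widths.max())
    if base_px < 2:
        raise ValueError("pile base too narrow to measure")
    return angle_from_dimensions(float(height_px), base_px / 2.0)


@dataclass
class SizeDistribution:
    """Volume-weighted particle-size distribution.

    ``bin_centers_um`` are strictly increasing particle diameters;
    ``volume_fractions`` are the volume fraction in each bin and are
    normalized to sum to one.
    """

    bin_centers_um: np.ndarray
    volume_fractions: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.bin_centers_um, dtype=float)
        v = np.asarray(self.volume_fractions, dtype=float)
        if d.shape != v.shape or d.ndim != 1 or d.size == 0:
            raise ValueError("bin centers and fractions must be matching 1-D arrays")
        if (d <= 0).any():
            raise ValueError("bin diameters must be strictly positive")
        if (np.diff(d) <= 0).any():
            raise ValueError("bin centers must be strictly increasing")
        if (v < 0).any() or v.sum() <= 0:
            raise ValueError("volume fractions must be non-negative with positive sum")
        self.bin_centers_um = d
        self.volume_fractions = v / v.sum()

    @classmethod
    def from_number_weights(cls, diameters_um: Sequence[float],
                            number_fractions: Sequence[float]) -> "SizeDistribution":
        """Convert number-weighted data: v_i is proportional to n_i * d_i^3."""
        d = np.asarray(diameters_um, dtype=float)
        n = np.asarray(number_fractions, dtype=float)
        return cls(d, n * d**3)


def d43(dist: SizeDistribution) -> float:
    """De Brouckere (volume-moment) mean diameter, D4,3 = sum(v_i d_i)."""
    return float((dist.volume_fractions * dist.bin_centers_um).sum())


def d32(dist: SizeDistribution) -> float:
    """Sauter (surface-moment) mean diameter, D3,2 = 1 / sum(v_i / d_i)."""
    return float(1.0 / (dist.volume_fractions / dist.bin_centers_um).sum())


def ssa(dist: SizeDistribution, true_density_g_cm3: float) -> float:
    """Specific surface area, SSA = 6 / (rho * D3,2), in m^2/g.

    With the true density in g/cm^3 and D3,2 in micrometres the units
    work out to m^2/g directly.
    """
    if true_density_g_cm3 <= 0:
        raise ValueError("true density must be strictly positive")
    return 6.0 / (true_density_g_cm3 * d32(dist))


@dataclass
class CalibrationCurve:
    """Linear counting-chamber calibration: count = slope * conc + intercept."""

    slope: float
    intercept: float
    range_ug_mL: tuple[float, float]
    r2: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")


def fit_calibration(concentrations_ug_mL: Sequence[float],
                    counts: Sequence[float]) -> CalibrationCurve:
    """Least-squares line through (concentration, particle count) pairs."""
    x = np.asarray(concentrations_ug_mL, dtype=float)
    y = np.asarray(counts, dtype=float)
    if x.size < 3:
        raise ValueError("calibration requires at least 3 concentration levels")
    res = stats.linregress(x, y)
    if res.slope <= 0:
        raise ValueError(f"non-positive calibration slope ({res.slope:.4g})")
    return CalibrationCurve(float(res.slope), float(res.intercept),
                            (float(x.min()), float(x.max())),
                            float(res.rvalue**2))


def concentration_from_count(curve: CalibrationCurve, count: float) -> float:
    """Invert the calibration; warns when outside the fitted range."""
    conc = (count - curve.intercept) / curve.slope
    low, high = curve.range_ug_mL
    if not (low <= conc <= high):
        warnings.warn(
            f"inverted concentration {conc:.3g} ug/mL lies outside the "
            f"calibrated range {low:.3g}-{high:.3g} ug/mL",
            stacklevel=2,
        )
    return conc


def loading(concentration_ug_mL: float, dispersion_volume_mL: float,
            pellet_mass_g: float) -> float:
    """Microsphere load of pellets in mg per g of pellets."""
    if pellet_mass_g <= 0 or dispersion_volume_mL <= 0 or concentration_ug_mL < 0:
        raise ValueError("volume and mass must be positive, concentration >= 0")
    return concentration_ug_mL * dispersion_volume_mL / (1000.0 * pellet_mass_g)


def load_yield(measured_mg_g: float, theoretical_mg_g: float,
               process_yield_pct: float | None = None) -> float:
    """Load yield in percent, 100 * measured / theoretical.

    When ``process_yield_pct`` is given, the theoretical load is first
    scaled by the mass yield of the coating process, crediting material
    lost during processing rather than missing from the product.
    """
    if theoretical_mg_g <= 0:
        raise ValueError("theoretical load must be positive")
    if process_yield_pct is not None:
        theoretical_mg_g = theoretical_mg_g * process_yield_pct / 100.0
    return 100.0 * measured_mg_g / theoretical_mg_g
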