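"""Dissolution and detachment analytics.

Cumulative drug-release computation with aliquot-sampling correction,
profile comparison by the similarity factor f2, and microsphere
detachment tracking over reciprocating-cylinder dips.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ReleaseProfile",
    "DetachmentProfile",
    "cumulative_release",
    "f2",
    "classify_similarity",
    "detachment_profile",
]


@dataclass
class ReleaseProfile:
    """Cumulative release (%) at increasing time points (minutes)."""

    times_min: np.ndarray
    cumulative_pct: np.ndarray
    repaired: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        c = np.asarray(self.cumulative_pct, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and cumulative values must be matching 1-D arrays")
        if t.size and (np.diff(t) <= 0).any():
            raise ValueError("times must be strictly increasing")
        self.times_min = t
        self.cumulative_pct = c

    def monotone(self) -> "ReleaseProfile":
        """Running-maximum repair of small non-monotone dips; flagged."""
        repaired = np.maximum.accumulate(self.cumulative_pct)
        changed = bool((repaired != self.cumulative_pct).any())
        return ReleaseProfile(self.times_min, repaired,
                              repaired=self.repaired or changed)


@dataclass
class DetachmentProfile:
    """Cumulative microsphere detachment (%) versus dip count."""

    dips: np.ndarray
    detached_pct: np.ndarray
    mean_size_um: np.ndarray | None = None
    capped: bool = False

    def __post_init__(self) -> None:
        d = np.asarray(self.dips, dtype=int)
        p = np.asarray(self.detached_pct, dtype=float)
        if d.shape != p.shape or d.ndim != 1:
            raise ValueError("dips and percentages must be matching 1-D arrays")
        if d.size and (np.diff(d) <= 0).any():
            raise ValueError("dip counts must be strictly increasing")
        if p.size and ((p < 0).any() or (p > 100).any()):
            raise ValueError("detached percentages must lie in [0, 100]")
        self.dips = d
        self.detached_pct = p
        if self.mean_size_um is not None:
            s = np.asarray(self.mean_size_um, dtype=float)
            if s.shape != d.shape:
                raise ValueError("mean sizes must pair with dips")
            self.mean_size_um = s


def cumulative_release(
    aliquot_conc_mg_mL: Sequence[float],
    times_min: Sequence[float],
    vessel_volume_mL: float,
    aliquot_volume_mL: float,
    dose_mg: float,
    replacement: bool = True,
) -> ReleaseProfile:
    """Cumulative release (%) from sampled aliquot concentrations.

    With medium replacement (standard paddle-apparatus practice), the
    released mass at sampling point n is
    ``C_n * V + sum_{i<n} C_i * V_a`` — the drug currently in the vessel
    plus the drug removed in earlier aliquots.  Without replacement the
    vessel volume shrinks by one aliquot per sample, so the in-vessel
    term uses ``V - (n-1) * V_a``.
    """
    conc = np.asarray(aliquot_conc_mg_mL, dtype=float)
    if (conc < 0).any():
        raise ValueError("concentrations must be non-negative")
    if vessel_volume_mL <= 0 or dose_mg <= 0:
        raise ValueError("vessel volume and dose must be positive")
    if not 0 <= aliquot_volume_mL < vessel_volume_mL:
        raise ValueError("aliquot volume must be smaller than the vessel volume")
    n = conc.size
    removed = np.concatenate([[0.0], np.cumsum(conc * aliquot_volume_mL)[:-1]])
    if replacement:
        in_vessel = conc * vessel_volume_mL
    else:
        volumes = vessel_volume_mL - np.arange(n) * aliquot_volume_mL
        if (volumes <= 0).any():
            raise ValueError("sampling schedule drains the vessel")
        in_vessel = conc * volumes
    mass = in_vessel + removed
    return ReleaseProfile(np.asarray(times_min, dtype=float), 100.0 * mass / dose_mg)


def f2(
    reference: ReleaseProfile,
    test: ReleaseProfile,
    truncate_at_85: bool = True,
    min_points: int = 3,
) -> float:
    """Similarity factor f2 between two dissolution profiles.

    ``f2 = 50 * log10(100 * (1 + mean squared difference)**-0.5)`` over
    the common time points, reported to two decimals.  Following
    regulatory convention, points after the first at which both profiles
    exceed 85 % release are dropped (configurable); at least
    ``min_points`` common points are required.
    """
    common, r_idx, t_idx = np.intersect1d(reference.times_min, test.times_min,
                                          return_indices=True)
    r = reference.cumulative_pct[r_idx]
    t = test.cumulative_pct[t_idx]
    if truncate_at_85:
        both = np.flatnonzero((r > 85.0) & (t > 85.0))
        if both.size:
            cut = both[0] + 1
            r, t = r[:cut], t[:cut]
    if r.size < min_points:
        raise ValueError(
            f"f2 needs at least {min_points} common time points, have {r.size}"
        )
    msd = float(np.mean((r - t) ** 2))
    return round(50.0 * math.log10(100.0 / math.sqrt(1.0 + msd)), 2)


def classify_similarity(f2_value: float, threshold: float = 50.0) -> str:
    """Label two profiles ``similar`` iff f2 >= threshold (boundary in)."""
    return "similar" if f2_value >= threshold else "dissimilar"


def detachment_profile(
    counts_per_dip: Sequence[float],
    total_load_count: float,
    dips: Sequence[int] | None = None,
    mean_size_um: Sequence[float] | None = None,
    dips_per_sample: int = 2,
) -> DetachmentProfile:
    """Cumulative detachment (%) from per-sample detached-particle counts.

    ``counts_per_dip`` are the newly detached counts at each sampling
    point (one sample every ``dips_per_sample`` dips unless explicit dip
    indices are given).  Percentages are cumulative over samples and
    capped at 100 with a flag when counting noise overshoots the load.
    """
    counts = np.asarray(counts_per_dip, dtype=float)
    if (counts < 0).any():
        raise ValueError("detached counts must be non-negative")
    if total_load_count <= 0:
        raise ValueError("total load count must be positive")
    if dips is None:
        dips = dips_per_sample * np.arange(1, counts.size + 1)
    pct = 100.0 * np.cumsum(counts) / total_load_count
    capped = bool((pct > 100.0).any())
    if capped:
        warnings.warn("cumulative detached count exceeds the total load; "
                      "percentages capped at 100", stacklevel=2)
        pct = np.minimum(pct, 100.0)
    sizes = None if mean_size_um is None else np.asarray(mean_size_um, dtype=float)
    return DetachmentProfile(np.asarray(dips, dtype=int), pct,
                             mean_size_um=sizes, capped=capped)
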