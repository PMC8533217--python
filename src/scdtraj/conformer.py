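"""Acyl-chain dihedral statistics and their coupling to the tunnel kink.

The substrate's C8-C9-C10-C11 torsion χ must sit near −60° (negative gauche)
for desaturation at the C9-C10 bond to proceed.  This module bins χ into a
circular distribution ρ(χ), converts it to a free-energy profile
ϕ = −0.6 ln ρ(χ) in kcal/mol (0.6 ≈ RT near 300 K), classifies conformers
(gauche−/gauche+/trans/other, with an "actionable" flag near −60°), and
conditions the actionable fraction on whether the Gln147-Trp153 and
Gln147-Thr261 distances are simultaneously within hydrogen-bonding range.

The hydrogen-bond criterion is geometric and distance-only: both pair
distances ≤ ``max_distance`` (default 2.5 Å, boundary inclusive).  The
default is an interpretation — the source material leaves the cutoff
under-specified — so it is an explicit, configurable parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import RangeError
from .geometry import Series

DEFAULT_PREFACTOR = 0.6        # kcal/mol, ≈ RT at 300 K
DEFAULT_HBOND_CUTOFF = 2.5     # Å, applied to both pairs simultaneously
DEFAULT_BIN_WIDTH_DEG = 5.0
ACTIONABLE_CENTER = -60.0      # degrees, negative gauche


class ConformerClass(Enum):
    GAUCHE_MINUS = "gauche_minus"
    GAUCHE_PLUS = "gauche_plus"
    TRANS = "trans"
    OTHER = "other"


@dataclass(frozen=True)
class ClassifiedDihedral:
    conformer: ConformerClass
    actionable: bool


@dataclass(frozen=True)
class HBondCriterion:
    """Both pair distances ≤ max_distance (Å), boundary inclusive."""

    max_distance: float = DEFAULT_HBOND_CUTOFF

    def __post_init__(self):
        if self.max_distance <= 0:
            raise ValueError("hydrogen-bond cutoff must be positive")


@dataclass
class DihedralDistribution:
    """Normalized circular histogram of χ; bins tile (−180, 180]."""

    bin_width: float
    rho: np.ndarray
    counts: np.ndarray
    origin: float = -180.0

    @property
    def bin_edges(self) -> np.ndarray:
        return self.origin + self.bin_width * np.arange(len(self.rho) + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        return self.origin + self.bin_width * (np.arange(len(self.rho)) + 0.5)


@dataclass
class DihedralPMF:
    """ϕ = −prefactor · ln ρ(χ) per bin, kcal/mol; empty bins are NaN
    (undefined), never 0, and ϕ is reported unshifted."""

    distribution: DihedralDistribution
    phi: np.ndarray
    prefactor: float = DEFAULT_PREFACTOR


def _circular_diff(chi, center):
    """Signed angular difference wrapped to (−180, 180]."""
    d = (np.asarray(chi, dtype=float) - center + 180.0) % 360.0 - 180.0
    return np.where(d == -180.0, 180.0, d)


def wrap_degrees(chi):
    """Wrap angles to (−180, 180]."""
    return _circular_diff(chi, 0.0)


def dihedral_distribution(chi: Union[Series, np.ndarray],
                          bin_width: float = DEFAULT_BIN_WIDTH_DEG
                          ) -> DihedralDistribution:
    """Bin χ values (degrees, (−180, 180]) into a normalized distribution.

    Bins are half-open on the left, (edge, edge+width], so that +180 lands in
    the last bin; −180 and +180 denote the same torsion and callers must
    supply the +180 representative (wrap with :func:`wrap_degrees` first).
    """
    values = chi.values if isinstance(chi, Series) else np.asarray(chi, dtype=float)
    if values.size == 0:
        raise ValueError("cannot bin an empty dihedral series")
    if np.any(values <= -180.0) or np.any(values > 180.0):
        raise RangeError("dihedral values must lie in (-180, 180]; wrap first")
    if 360.0 / bin_width != round(360.0 / bin_width):
        raise ValueError("bin width must divide 360 degrees")
    n_bins = int(round(360.0 / bin_width))
    shifted = (values + 180.0) / bin_width          # in (0, n_bins]
    idx = np.ceil(np.round(shifted, 6)).astype(int) - 1
    counts = np.bincount(idx, minlength=n_bins)
    return DihedralDistribution(bin_width=bin_width, rho=counts / values.size,
                                counts=counts)


def pmf(dist: DihedralDistribution,
        prefactor: float = DEFAULT_PREFACTOR) -> DihedralPMF:
    """Free-energy profile of the dihedral distribution, in kcal/mol."""
    phi = np.full(dist.rho.shape, np.nan)
    populated = dist.rho > 0
    phi[populated] = -prefactor * np.log(dist.rho[populated])
    return DihedralPMF(distribution=dist, phi=phi, prefactor=prefactor)


def classify(chi: float, tolerance: float = 10.0) -> ClassifiedDihedral:
    """Classify a torsion (degrees, (−180, 180]) into its conformer class.

    gauche− for |χ+60| ≤ 30, gauche+ for |χ−60| ≤ 30, trans for |χ| ≥ 150,
    other elsewhere; the classes partition the circle.  ``actionable`` flags
    |χ+60| ≤ tolerance (±10° by default; ±5° for the stricter conditional
    statistic).
    """
    if not (-180.0 < chi <= 180.0):
        raise RangeError("chi must lie in (-180, 180]")
    actionable = abs(_circular_diff(chi, ACTIONABLE_CENTER)) <= tolerance
    if abs(chi - (-60.0)) <= 30.0:
        cls = ConformerClass.GAUCHE_MINUS
    elif abs(chi - 60.0) <= 30.0:
        cls = ConformerClass.GAUCHE_PLUS
    elif abs(chi) >= 150.0:
        cls = ConformerClass.TRANS
    else:
        cls = ConformerClass.OTHER
    return ClassifiedDihedral(cls, bool(actionable))


def hbond_state(d1, d2, crit: HBondCriterion = HBondCriterion()):
    """True where both distances are within hydrogen-bonding range
    (d1 ≤ cutoff and d2 ≤ cutoff, inclusive).  Accepts scalars or arrays."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    out = (d1 <= crit.max_distance) & (d2 <= crit.max_distance)
    return bool(out) if out.ndim == 0 else out


@dataclass
class ConditionalActionable:
    """Actionable-dihedral fractions conditioned on the hydrogen-bond state.

    Fractions are None when the conditioning class is empty (undefined, not
    zero).  Counts are reported so the law of total probability can be
    verified exactly on counts.
    """

    fraction_bonded: Optional[float]
    fraction_unbonded: Optional[float]
    n_bonded: int
    n_bonded_actionable: int
    n_unbonded: int
    n_unbonded_actionable: int
    tolerance: float
    criterion: HBondCriterion


def conditional_actionable(chi: Series, d1: Series, d2: Series,
                           crit: HBondCriterion = HBondCriterion(),
                           tolerance: float = 5.0) -> ConditionalActionable:
    """P(χ within ``tolerance`` of −60° | hydrogen-bonded) and its complement
    class, on frame-aligned χ / d1 / d2 series."""
    if not (len(chi) == len(d1) == len(d2)):
        raise ValueError("chi, d1, d2 series must be frame-aligned (equal length)")
    bonded = hbond_state(d1.values, d2.values, crit)
    actionable = np.abs(_circular_diff(chi.values, ACTIONABLE_CENTER)) <= tolerance
    n_b = int(bonded.sum())
    n_u = int((~bonded).sum())
    n_ba = int((bonded & actionable).sum())
    n_ua = int((~bonded & actionable).sum())
    return ConditionalActionable(
        fraction_bonded=n_ba / n_b if n_b else None,
        fraction_unbonded=n_ua / n_u if n_u else None,
        n_bonded=n_b, n_bonded_actionable=n_ba,
        n_unbonded=n_u, n_unbonded_actionable=n_ua,
        tolerance=tolerance, criterion=crit,
    )


def pmf_to_dataframe(p: DihedralPMF) -> pd.DataFrame:
    """CSV layout: chi_bin_start_deg, rho, phi_kcal_mol."""
    d = p.distribution
    return pd.DataFrame({
        "chi_bin_start_deg": d.bin_edges[:-1],
        "rho": d.rho,
        "phi_kcal_mol": p.phi,
    })


def conditional_to_dataframe(c: ConditionalActionable) -> pd.DataFrame:
    """CSV layout: class, n_frames, n_actionable, fraction."""
    return pd.DataFrame({
        "class": ["hbonded", "not_hbonded"],
        "n_frames": [c.n_bonded, c.n_unbonded],
        "n_actionable": [c.n_bonded_actionable, c.n_unbonded_actionable],
        "fraction": [c.fraction_bonded, c.fraction_unbonded],
    })
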