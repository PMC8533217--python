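"""Population-based free-energy landscapes over paired hydrogen-bond distances.

Every observed (d1, d2) pair is grouped into square bins (default 0.1 Å) whose
edges sit at exact multiples of the bin width, so histograms from different
replicates align by absolute edge and can be pooled by addition.  Free energy
per bin is the Boltzmann inversion of the bin population,

    ΔG_i = −kT ln(ρ_i / ρ_max),

in units of kT, with ρ_i the fraction of observations in bin i and ρ_max the
fraction in the most populated bin; the minimum bin therefore has ΔG = 0
exactly.  Bins with no observations carry an arbitrary sentinel (default
10 kT) that is excluded from any statistics.  ``level_populations`` reports
the percent of observations per integer-kT stratum; ``basins`` locates the
global minimum and secondary subpopulations separated by a free-energy
barrier.  1D utilities (``hist1d``/``modal_bin``) serve active-site distance
summaries such as the iron–iron separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from heapq import heappop, heappush
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import Series

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 0.1  # Å, "tenths of angstroms"
DEFAULT_EMPTY_BIN_KT = 10.0  # sentinel ΔG for unobserved bins


def _bin_index(values: np.ndarray, width: float) -> np.ndarray:
    """Absolute half-open bin index: value v falls in [k·width, (k+1)·width).

    A value sitting numerically on an edge (within 1e-6 of k·width) is
    assigned to the bin starting at that edge, so 2.10 lands in the 2.1 bin
    despite binary rounding of 2.1/0.1.
    """
    q = np.asarray(values, dtype=float) / width
    return np.floor(np.round(q, 6)).astype(int)


@dataclass
class Histogram2D:
    x_label: str
    y_label: str
    bin_width: float
    x_origin: float  # start of first bin, a multiple of bin_width
    y_origin: float
    counts: np.ndarray  # integer grid, shape (nx, ny)
    total: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.sum() != self.total:
            raise ValueError("histogram counts do not sum to total")
        if np.any(self.counts < 0):
            raise ValueError("negative bin count")

    @property
    def x_edges(self) -> np.ndarray:
        return self.x_origin + self.bin_width * np.arange(self.counts.shape[0] + 1)

    @property
    def y_edges(self) -> np.ndarray:
        return self.y_origin + self.bin_width * np.arange(self.counts.shape[1] + 1)

    def x_center(self, ix: int) -> float:
        return self.x_origin + self.bin_width * (ix + 0.5)

    def y_center(self, iy: int) -> float:
        return self.y_origin + self.bin_width * (iy + 0.5)


@dataclass
class FreeEnergySurface:
    histogram: Histogram2D
    rho: np.ndarray          # counts / total
    rho_max: float
    dG: np.ndarray           # kT; empty bins carry empty_bin_value
    empty_bin_value: float = DEFAULT_EMPTY_BIN_KT
    minimum_center: tuple[float, float] = (np.nan, np.nan)

    @property
    def populated(self) -> np.ndarray:
        return self.histogram.counts > 0


@dataclass
class LevelPopulations:
    """Percent of observations per integer-kT band, level n ≡ (n−1, n] kT
    (level 1 also includes ΔG = 0)."""

    levels: list[tuple[int, float]]

    def as_dict(self) -> dict[int, float]:
        return dict(self.levels)


@dataclass
class Histogram1D:
    bin_width: float
    origin: float
    counts: np.ndarray
    value_min: float
    value_max: float

    @property
    def edges(self) -> np.ndarray:
        return self.origin + self.bin_width * np.arange(len(self.counts) + 1)


def bin2d(x: Series, y: Series, bin_width: float = DEFAULT_BIN_WIDTH) -> Histogram2D:
    """Bin frame-aligned (x, y) observations into a 2D count grid."""
    if len(x) != len(y):
        raise ValueError(
            f"series lengths differ: {x.label!r} has {len(x)}, {y.label!r} has {len(y)}"
        )
    if len(x) == 0:
        raise ValueError("cannot bin empty series")
    ix = _bin_index(x.values, bin_width)
    iy = _bin_index(y.values, bin_width)
    x0, y0 = ix.min(), iy.min()
    counts = np.zeros((ix.max() - x0 + 1, iy.max() - y0 + 1), dtype=np.int64)
    np.add.at(counts, (ix - x0, iy - y0), 1)
    return Histogram2D(
        x_label=x.label, y_label=y.label, bin_width=bin_width,
        x_origin=x0 * bin_width, y_origin=y0 * bin_width,
        counts=counts, total=len(x),
    )


def pool(series_groups: Sequence[tuple[Series, Series]],
         bin_width: float = DEFAULT_BIN_WIDTH) -> Histogram2D:
    """Pool replicate (x, y) series pairs into one histogram.

    Because bin edges are absolute multiples of the width, pooling by
    concatenation equals summing per-replicate histograms bin by bin.
    """
    if not series_groups:
        raise ValueError("no series pairs to pool")
    labels = {(x.label, y.label) for x, y in series_groups}
    if len(labels) != 1:
        raise ValueError(f"cannot pool series with mismatched labels: {labels}")
    x_all = np.concatenate([x.values for x, _ in series_groups])
    y_all = np.concatenate([y.values for _, y in series_groups])
    xs = Series(series_groups[0][0].label, "pooled", x_all)
    ys = Series(series_groups[0][1].label, "pooled", y_all)
    return bin2d(xs, ys, bin_width)


def free_energy(hist: Histogram2D,
                empty_bin_value: float = DEFAULT_EMPTY_BIN_KT) -> FreeEnergySurface:
    """Boltzmann-invert bin populations into a ΔG surface in kT."""
    if hist.total <= 0:
        raise ValueError("histogram holds no observations")
    rho = hist.counts / hist.total
    rho_max = float(rho.max())
    dG = np.full(rho.shape, float(empty_bin_value))
    populated = hist.counts > 0
    with np.errstate(divide="ignore"):
        dG[populated] = -np.log(rho[populated] / rho_max) + 0.0  # kill -0.0
    ix, iy = _argmax_bin(hist.counts)
    return FreeEnergySurface(
        histogram=hist, rho=rho, rho_max=rho_max, dG=dG,
        empty_bin_value=float(empty_bin_value),
        minimum_center=(hist.x_center(ix), hist.y_center(iy)),
    )


def _argmax_bin(counts: np.ndarray) -> tuple[int, int]:
    """Most-populated bin; ties broken toward the smallest (x, then y) center."""
    flat = int(np.argmax(counts))  # row-major => smallest ix, then iy
    if (counts == counts.flat[flat]).sum() > 1:
        logger.warning("tie for most-populated bin; smallest-center bin chosen")
    return np.unravel_index(flat, counts.shape)  # type: ignore[return-value]


def minimum(surface: FreeEnergySurface) -> tuple[float, float, float]:
    """ΔG-minimum bin as (x center Å, y center Å, percent of observations)."""
    hist = surface.histogram
    ix, iy = _argmax_bin(hist.counts)
    percent = 100.0 * hist.counts[ix, iy] / hist.total
    return hist.x_center(ix), hist.y_center(iy), float(percent)


def level_populations(surface: FreeEnergySurface,
                      max_level: int = 10) -> LevelPopulations:
    """Percent of observations in each integer-kT ΔG band.

    Level n collects bins with n−1 < ΔG ≤ n; level 1 additionally includes
    the ΔG = 0 minimum bin.  Percentages are over observations (counts), not
    bins, and sum to 100 because empty bins hold no observations.  Bands are
    extended past ``max_level`` if populated bins require it.
    """
    hist = surface.histogram
    populated = hist.counts > 0
    dG = surface.dG
    needed = int(np.ceil(dG[populated].max())) if populated.any() else 1
    top = max(max_level, max(needed, 1))
    levels = []
    for n in range(1, top + 1):
        lo, hi = n - 1.0, float(n)
        if n == 1:
            mask = populated & (dG <= hi)
        else:
            mask = populated & (dG > lo) & (dG <= hi)
        levels.append((n, float(100.0 * hist.counts[mask].sum() / hist.total)))
    return LevelPopulations(levels=levels)


@dataclass
class Basin:
    x_center: float
    y_center: float
    dG: float
    percent: float  # percent of total observations in the basin's minimum bin
    barrier: float  # minimax-path barrier to the global minimum, kT (0 for it)


def basins(surface: FreeEnergySurface, barrier_kT: float = 1.0,
           max_basins: int = 5, min_percent: float = 0.02) -> list[Basin]:
    """Locate the ΔG minimum and secondary subpopulations.

    Candidates are populated bins that are local minima of ΔG over their
    8-neighborhood (empty bins count as the sentinel ceiling).  A candidate
    qualifies as a distinct basin when the lowest-barrier path to the global
    minimum must cross a ridge at least ``barrier_kT`` above the candidate's
    own ΔG, computed with a Dijkstra-style minimax search on the bin grid.
    ``min_percent`` suppresses sampling noise: an isolated bin holding less
    than that percent of observations is not a subpopulation.  Returned in
    increasing ΔG order, the global minimum first.
    """
    hist = surface.histogram
    dG = surface.dG
    nx, ny = dG.shape
    populated = surface.populated

    gx, gy = _argmax_bin(hist.counts)
    ridge = _minimax_to(dG, (gx, gy))

    candidates = []
    for ix in range(nx):
        for iy in range(ny):
            if not populated[ix, iy]:
                continue
            neigh = dG[max(ix - 1, 0):ix + 2, max(iy - 1, 0):iy + 2]
            if dG[ix, iy] <= neigh.min():
                candidates.append((dG[ix, iy], ix, iy))
    candidates.sort()

    out = []
    for g, ix, iy in candidates:
        barrier = float(ridge[ix, iy] - g)
        if (ix, iy) == (gx, gy):
            out.append(Basin(hist.x_center(ix), hist.y_center(iy), float(g),
                             100.0 * hist.counts[ix, iy] / hist.total, 0.0))
        elif barrier >= barrier_kT \
                and 100.0 * hist.counts[ix, iy] / hist.total >= min_percent:
            # drop near-duplicate minima inside an already-claimed basin
            if any(abs(b.x_center - hist.x_center(ix)) <= hist.bin_width
                   and abs(b.y_center - hist.y_center(iy)) <= hist.bin_width
                   for b in out):
                continue
            out.append(Basin(hist.x_center(ix), hist.y_center(iy), float(g),
                             100.0 * hist.counts[ix, iy] / hist.total, barrier))
        if len(out) >= max_basins:
            break
    return out


def _minimax_to(dG: np.ndarray, source: tuple[int, int]) -> np.ndarray:
    """For every bin, the minimal over 8-connected paths to ``source`` of the
    maximal ΔG encountered along the path (including both endpoints)."""
    nx, ny = dG.shape
    best = np.full((nx, ny), np.inf)
    sx, sy = source
    best[sx, sy] = dG[sx, sy]
    heap = [(dG[sx, sy], sx, sy)]
    while heap:
        h, x, y = heappop(heap)
        if h > best[x, y]:
            continue
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                if dx == 0 and dy == 0:
                    continue
                u, v = x + dx, y + dy
                if 0 <= u < nx and 0 <= v < ny:
                    cand = max(h, dG[u, v])
                    if cand < best[u, v]:
                        best[u, v] = cand
                        heappush(heap, (cand, u, v))
    return best


def hist1d(s: Series, bin_width: float) -> Histogram1D:
    """1D absolute-edge histogram of a series, with observed min/max."""
    if len(s) == 0:
        raise ValueError("cannot bin empty series")
    idx = _bin_index(s.values, bin_width)
    i0 = idx.min()
    counts = np.bincount(idx - i0, minlength=idx.max() - i0 + 1)
    return Histogram1D(bin_width=bin_width, origin=i0 * bin_width,
                       counts=counts, value_min=float(s.values.min()),
                       value_max=float(s.values.max()))


def modal_bin(h: Histogram1D) -> tuple[float, float]:
    """Bounds (start Å, end Å) of the most-populated 1D bin."""
    i = int(np.argmax(h.counts))
    start = h.origin + i * h.bin_width
    return start, start + h.bin_width


def surface_to_dataframe(surface: FreeEnergySurface) -> pd.DataFrame:
    """Long-format surface: x_bin_start, y_bin_start (plus centers), count,
    rho, dG_kT — one row per bin."""
    hist = surface.histogram
    nx, ny = hist.counts.shape
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    return pd.DataFrame({
        "x_bin_start": np.round(hist.x_origin + hist.bin_width * ix.ravel(), 6),
        "y_bin_start": np.round(hist.y_origin + hist.bin_width * iy.ravel(), 6),
        "x_bin_center": np.round(hist.x_origin + hist.bin_width * (ix.ravel() + 0.5), 6),
        "y_bin_center": np.round(hist.y_origin + hist.bin_width * (iy.ravel() + 0.5), 6),
        "count": hist.counts.ravel(),
        "rho": surface.rho.ravel(),
        "dG_kT": surface.dG.ravel(),
    })


def levels_to_dataframe(lp: LevelPopulations) -> pd.DataFrame:
    return pd.DataFrame(lp.levels, columns=["level_kT", "percent"])


def plot_surface(surface: FreeEnergySurface, path=None, ax=None):
    """Render the ΔG surface with integer-kT contours; the empty-bin sentinel
    is the color ceiling."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hist = surface.histogram
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 4))
    else:
        fig = ax.figure
    mesh = ax.pcolormesh(hist.x_edges, hist.y_edges, surface.dG.T,
                         vmin=0.0, vmax=surface.empty_bin_value, cmap="viridis")
    xc = hist.x_origin + hist.bin_width * (np.arange(hist.counts.shape[0]) + 0.5)
    yc = hist.y_origin + hist.bin_width * (np.arange(hist.counts.shape[1]) + 0.5)
    if len(xc) > 1 and len(yc) > 1:
        ax.contour(xc, yc, surface.dG.T,
                   levels=np.arange(1, int(surface.empty_bin_value)),
                   colors="white", linewidths=0.5)
    ax.set_xlabel(f"{hist.x_label} (Å)")
    ax.set_ylabel(f"{hist.y_label} (Å)")
    fig.colorbar(mesh, ax=ax, label="ΔG (kT)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax
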