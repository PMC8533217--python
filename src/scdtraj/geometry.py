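"""Core frame measurements: interatomic distances, proper dihedral angles,
per-trajectory observable extraction, and internal-coordinate chain placement.

Dihedrals follow the IUPAC sign convention (cis = 0°; positive when, sighting
from the second to the third atom, the far bond rotates clockwise from the
near bond) and are reported in degrees on (−180, +180].  No periodic-boundary
minimum-image correction is applied: inputs are assumed whole, which holds for
intramolecular measurements like the Gln147/Trp153/Thr261 hydrogen-bond
distances and the acyl-chain C8-C9-C10-C11 torsion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .errors import GeometryError
from .trajio import AtomSpec, Frame, Topology, Trajectory, resolve

_COLLINEAR_TOL = 1e-10


@dataclass(frozen=True)
class DistancePairSpec:
    """A labeled atom pair, e.g. the Gln147(OE1)–Trp153(HE1) distance."""

    label: str
    a: AtomSpec
    b: AtomSpec

    def __post_init__(self):
        if self.a == self.b:
            raise ValueError(f"distance pair {self.label!r}: atoms must differ")


@dataclass(frozen=True)
class DihedralSpec:
    """A labeled proper-torsion quad, e.g. the ligand C8-C9-C10-C11 dihedral."""

    label: str
    atoms: tuple[AtomSpec, AtomSpec, AtomSpec, AtomSpec]

    def __post_init__(self):
        if len(set(self.atoms)) != 4:
            raise ValueError(f"dihedral {self.label!r}: four distinct atoms required")


@dataclass
class Series:
    """Per-frame scalar observable (Å for distances, degrees for dihedrals)."""

    label: str
    replicate_id: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"series {self.label!r} contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)


def distance(frame: Frame, i: int, j: int) -> float:
    """Euclidean distance in Å between atoms ``i`` and ``j`` of a frame."""
    n = frame.coords.shape[0]
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"atom index out of range (n_atoms={n})")
    if i == j:
        raise ValueError("distance requires two distinct atom indices")
    return float(np.linalg.norm(frame.coords[i] - frame.coords[j]))


def _dihedral_from_points(p1, p2, p3, p4) -> np.ndarray:
    """Vectorized signed torsion in degrees on (−180, +180] for (...,3) arrays."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    scale = (np.linalg.norm(b1, axis=-1) * np.linalg.norm(b2, axis=-1),
             np.linalg.norm(b2, axis=-1) * np.linalg.norm(b3, axis=-1))
    if np.any(np.linalg.norm(n1, axis=-1) <= _COLLINEAR_TOL * np.maximum(scale[0], 1.0)) \
            or np.any(np.linalg.norm(n2, axis=-1) <= _COLLINEAR_TOL * np.maximum(scale[1], 1.0)):
        raise GeometryError("undefined torsion: three consecutive atoms are collinear")
    b2u = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2u, axis=-1)
    deg = np.degrees(np.arctan2(y, x))
    return np.where(deg <= -180.0, deg + 360.0, deg)


def dihedral(frame: Frame, i: int, j: int, k: int, l: int) -> float:
    """Signed proper dihedral i-j-k-l in degrees on (−180, +180]."""
    idx = (i, j, k, l)
    n = frame.coords.shape[0]
    if len(set(idx)) != 4:
        raise ValueError("dihedral requires four distinct atom indices")
    if not all(0 <= m < n for m in idx):
        raise IndexError(f"atom index out of range (n_atoms={n})")
    p = frame.coords[list(idx)]
    return float(_dihedral_from_points(p[0], p[1], p[2], p[3]))


def place_chain(bond_lengths: Sequence[float], bond_angles: Sequence[float],
                torsions: Sequence[float]) -> np.ndarray:
    """Build Cartesian coordinates for an n-atom chain from internal coordinates.

    Natural-extension reference frame (NeRF) construction: atom 0 at the
    origin, atom 1 on +x, atom 2 in the xy-plane; atom i ≥ 3 placed from bond
    length i−1, bond angle i−2 (at atom i−1, degrees in (0, 180)) and torsion
    i−3 (degrees, IUPAC sign).  Measuring any torsion of the result with
    :func:`dihedral` recovers the input to ~1e-6°.
    """
    bond_lengths = np.asarray(bond_lengths, dtype=float)
    bond_angles = np.asarray(bond_angles, dtype=float)
    torsions = np.asarray(torsions, dtype=float)
    n = len(bond_lengths) + 1
    if n < 2:
        raise GeometryError("chain needs at least one bond")
    if len(bond_angles) != max(n - 2, 0) or len(torsions) != max(n - 3, 0):
        raise GeometryError(
            f"{n}-atom chain needs {n-1} bond lengths, {n-2} angles, {n-3} torsions"
        )
    if np.any(bond_lengths <= 0):
        raise GeometryError("bond lengths must be positive")
    if np.any(bond_angles <= 0) or np.any(bond_angles >= 180):
        raise GeometryError("bond angles must lie strictly inside (0, 180) degrees")

    coords = np.zeros((n, 3))
    coords[1] = [bond_lengths[0], 0.0, 0.0]
    if n >= 3:
        theta = np.radians(bond_angles[0])
        coords[2] = coords[1] + bond_lengths[1] * np.array(
            [-np.cos(theta), np.sin(theta), 0.0])
    for i in range(3, n):
        coords[i] = place_fourth_atom(
            coords[i - 3], coords[i - 2], coords[i - 1],
            bond_lengths[i - 1], bond_angles[i - 2], torsions[i - 3])
    return coords


def place_fourth_atom(a, b, c, bond_length, bond_angle, torsion) -> np.ndarray:
    """Place atom D given atoms A, B, C and the internal coordinates of D.

    ``bond_angle`` is the B-C-D angle; ``torsion`` the A-B-C-D dihedral
    (degrees, IUPAC sign).  ``torsion`` may be an array, in which case one D
    per torsion value is returned — used to embed per-frame dihedrals quickly.
    """
    a, b, c = (np.asarray(v, dtype=float) for v in (a, b, c))
    theta = np.radians(bond_angle)
    chi = np.radians(np.asarray(torsion, dtype=float))

    bc = c - b
    bc_len = np.linalg.norm(bc)
    ab = b - a
    if bc_len <= _COLLINEAR_TOL or np.linalg.norm(np.cross(ab, bc)) <= _COLLINEAR_TOL:
        raise GeometryError("reference atoms are collinear; torsion frame undefined")
    bc_u = bc / bc_len
    n = np.cross(ab, bc_u)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc_u)

    d_local_x = -bond_length * np.cos(theta)
    d_local_y = bond_length * np.sin(theta) * np.cos(chi)
    d_local_z = bond_length * np.sin(theta) * np.sin(chi)
    d = (c + np.multiply.outer(d_local_x, bc_u)
         + np.multiply.outer(d_local_y, m)
         + np.multiply.outer(d_local_z, n))
    return d


def extract(trajectory: Trajectory,
            specs: Sequence[Union[DistancePairSpec, DihedralSpec]]) -> list[Series]:
    """Measure every spec on every frame; one :class:`Series` per spec.

    All specs are resolved against the topology before any frame is touched,
    so an unresolvable spec fails fast.
    """
    top = trajectory.topology
    resolved: list[tuple] = []
    for spec in specs:
        if isinstance(spec, DistancePairSpec):
            resolved.append(("d", spec.label,
                             resolve(top, spec.a), resolve(top, spec.b)))
        elif isinstance(spec, DihedralSpec):
            resolved.append(("t", spec.label,
                             tuple(resolve(top, s) for s in spec.atoms)))
        else:
            raise TypeError(f"unsupported spec type {type(spec).__name__}")

    coords = trajectory.coords_array()  # (F, n, 3)
    out = []
    for item in resolved:
        if item[0] == "d":
            _, label, i, j = item
            vals = np.linalg.norm(coords[:, i] - coords[:, j], axis=-1)
        else:
            _, label, (i, j, k, l) = item
            vals = _dihedral_from_points(coords[:, i], coords[:, j],
                                         coords[:, k], coords[:, l])
        out.append(Series(label=label, replicate_id=trajectory.replicate_id,
                          values=vals))
    return out


def series_to_dataframe(series_list: Sequence[Series]) -> pd.DataFrame:
    """Long-format export: columns replicate_id, frame, label, value."""
    parts = [
        pd.DataFrame({
            "replicate_id": s.replicate_id,
            "frame": np.arange(len(s)),
            "label": s.label,
            "value": s.values,
        })
        for s in series_list
    ]
    return pd.concat(parts, ignore_index=True)
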