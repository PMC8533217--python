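"""Topology and multi-frame coordinate I/O for standard structural-biology formats.

Coordinates are Cartesian angstroms everywhere.  Atoms are addressed by
residue number + PDB v3 atom name (``OE1``, ``HE1``, ``HE22``, ``OG1`` — the
PDB spellings of the Greek-letter names Oε1, Hε1, Hε22, Oγ1), optionally
disambiguated by chain.  PDB parsing/writing is delegated to biotite and DCD
to mdtraj's native reader; this module adds the package's data model, atom
resolution, and the error contracts downstream code relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import (
    AmbiguousSelectionError,
    PDBParseError,
    SelectionError,
    StructureError,
)

logger = logging.getLogger(__name__)

#: Bondi van der Waals radii (Å), the set used by common volumetrics tools.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "FE": 1.40,
}

#: Radius assigned to elements missing from the table (logged when used).
FALLBACK_RADIUS = 1.70

_TWO_LETTER_ELEMENTS = {"FE", "ZN", "MG", "MN", "CU", "NI", "CO", "NA", "CL", "BR", "SE"}


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    atom_name: str
    residue_name: str
    residue_number: int
    chain_id: str = ""
    element: str = ""

    def __post_init__(self):
        if not self.atom_name:
            raise StructureError("atom_name must be non-empty")


@dataclass(frozen=True)
class AtomSpec:
    """Residue number + atom name address, e.g. ``AtomSpec(147, "OE1")``."""

    residue_number: int
    atom_name: str
    chain_id: Optional[str] = None

    def __str__(self) -> str:
        chain = f"/{self.chain_id}" if self.chain_id else ""
        return f"{self.residue_number}:{self.atom_name}{chain}"


class Topology:
    """Ordered atom list whose order is the frame coordinate order."""

    def __init__(self, atoms: Sequence[AtomRecord], vdw_radii: Optional[dict] = None):
        self.atoms = list(atoms)
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise StructureError("duplicate atom serial numbers in topology")
        self.vdw_radii = dict(BONDI_RADII if vdw_radii is None else vdw_radii)
        self._warned_elements: set[str] = set()

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def vdw_radius(self, element: str) -> float:
        key = element.upper()
        if key in self.vdw_radii:
            return self.vdw_radii[key]
        if key not in self._warned_elements:
            logger.warning(
                "element %r has no vdW radius entry; using fallback %.2f A",
                element, FALLBACK_RADIUS,
            )
            self._warned_elements.add(key)
        return FALLBACK_RADIUS

    def resolve(self, spec: AtomSpec) -> int:
        return resolve(self, spec)


@dataclass
class Frame:
    index: int
    coords: np.ndarray  # (n_atoms, 3), Å

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError("frame coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"frame {self.index} contains non-finite coordinates")


@dataclass
class Trajectory:
    topology: Topology
    frames: list[Frame]
    replicate_id: str = "rep0"

    def __post_init__(self):
        if len(self.frames) == 0:
            raise StructureError("a trajectory must contain at least one frame")
        n = self.topology.n_atoms
        for f in self.frames:
            if f.coords.shape[0] != n:
                raise StructureError(
                    f"frame {f.index} has {f.coords.shape[0]} atoms, topology has {n}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coords_array(self) -> np.ndarray:
        """All coordinates stacked as (n_frames, n_atoms, 3)."""
        return np.stack([f.coords for f in self.frames])


def resolve(topology: Topology, spec: AtomSpec) -> int:
    """Return the unique atom index matching ``spec``.

    Raises :class:`SelectionError` on zero matches and
    :class:`AmbiguousSelectionError` on more than one (add a ``chain_id``).
    """
    matches = [
        i for i, a in enumerate(topology.atoms)
        if a.residue_number == spec.residue_number
        and a.atom_name == spec.atom_name
        and (spec.chain_id is None or a.chain_id == spec.chain_id)
    ]
    if not matches:
        raise SelectionError(f"no atom matches spec {spec}")
    if len(matches) > 1:
        raise AmbiguousSelectionError(
            f"spec {spec} matches {len(matches)} atoms; add a chain_id"
        )
    return matches[0]


def infer_element(atom_name: str) -> str:
    """Guess the element from a PDB atom name when the element column is blank."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[:2].upper() in _TWO_LETTER_ELEMENTS and len(atom_name.strip()) <= 2:
        return stripped[:2].upper()
    return stripped[0].upper()


def _prescan_pdb(path: Path) -> None:
    """Validate ATOM/HETATM coordinate fields, naming the offending line.

    Also logs how many non-primary alternate-location records the file holds
    (biotite keeps the first-occurring altloc when reading).
    """
    dropped_altloc = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(
                    f"{path}: line {lineno}: {rec} record shorter than coordinate fields"
                )
            for lo, hi, name in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PDBParseError(
                        f"{path}: line {lineno}: cannot parse {name} coordinate "
                        f"{line[lo:hi]!r}"
                    ) from None
            if line[16] not in (" ", "A"):
                dropped_altloc += 1
    if dropped_altloc:
        logger.warning(
            "%s: %d non-primary altloc records present (first altloc kept)",
            path, dropped_altloc,
        )


def read_structure(path, replicate_id: Optional[str] = None) -> Trajectory:
    """Read a (possibly multi-model) PDB file into a :class:`Trajectory`.

    One frame per MODEL record; a single frame if the file has no MODEL
    records.  Atom order matches the file.
    """
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_pdb(path)
    pdb_file = pdb.PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure(model=None, altloc="first",
                                       extra_fields=["atom_id"])
    except Exception as exc:  # biotite InvalidFileError and friends
        raise StructureError(f"{path}: {exc}") from exc
    if stack.array_length() == 0:
        raise StructureError(f"{path}: no atoms")

    atoms = []
    for i in range(stack.array_length()):
        element = str(stack.element[i]).strip()
        name = str(stack.atom_name[i]).strip()
        atoms.append(AtomRecord(
            serial=int(stack.atom_id[i]),
            atom_name=name,
            residue_name=str(stack.res_name[i]).strip(),
            residue_number=int(stack.res_id[i]),
            chain_id=str(stack.chain_id[i]).strip(),
            element=element if element else infer_element(name),
        ))
    topology = Topology(atoms)
    frames = [Frame(index=m, coords=stack.coord[m])
              for m in range(stack.stack_depth())]
    return Trajectory(topology, frames, replicate_id=replicate_id or path.stem)


def write_structure(trajectory: Trajectory, path) -> None:
    """Write a trajectory as a (multi-model if >1 frame) PDB file."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = trajectory.topology.n_atoms
    stack = struc.AtomArrayStack(trajectory.n_frames, n)
    top = trajectory.topology
    stack.chain_id = np.array([a.chain_id or "A" for a in top.atoms])
    stack.res_id = np.array([a.residue_number for a in top.atoms])
    stack.res_name = np.array([a.residue_name for a in top.atoms])
    stack.atom_name = np.array([a.atom_name for a in top.atoms])
    stack.element = np.array([a.element or infer_element(a.atom_name)
                              for a in top.atoms])
    stack.hetero = np.array([a.residue_name not in _AMINO_ACIDS for a in top.atoms])
    stack.coord = trajectory.coords_array()
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
    "TYR", "VAL",
}


def read_trajectory(topology_path, frames_path, format: str,
                    replicate_id: Optional[str] = None) -> Trajectory:
    """Read frames (``dcd`` or multi-model ``pdb``) against a PDB topology."""
    top_traj = read_structure(topology_path)
    topology = top_traj.topology
    rep = replicate_id or Path(frames_path).stem

    if format == "pdb":
        traj = read_structure(frames_path, replicate_id=rep)
        if traj.topology.n_atoms != topology.n_atoms:
            raise StructureError(
                f"frames file has {traj.topology.n_atoms} atoms, "
                f"topology has {topology.n_atoms}"
            )
        return Trajectory(topology, traj.frames, replicate_id=rep)

    if format == "dcd":
        from mdtraj.formats import DCDTrajectoryFile

        try:
            with DCDTrajectoryFile(str(frames_path)) as fh:
                xyz, _, _ = fh.read()
        except (OSError, IOError) as exc:
            raise PDBParseError(f"{frames_path}: cannot read DCD: {exc}") from exc
        if xyz is None or len(xyz) == 0:
            raise StructureError(f"{frames_path}: DCD contains no frames")
        if xyz.shape[1] != topology.n_atoms:
            raise StructureError(
                f"DCD frames have {xyz.shape[1]} atoms, topology has "
                f"{topology.n_atoms}"
            )
        frames = [Frame(index=i, coords=xyz[i]) for i in range(len(xyz))]
        return Trajectory(topology, frames, replicate_id=rep)

    raise ValueError(f"unknown trajectory format {format!r} (expected 'pdb' or 'dcd')")


def write_trajectory(trajectory: Trajectory, frames_path, format: str) -> None:
    """Write trajectory frames as multi-model PDB or DCD (Å, single precision)."""
    if format == "pdb":
        write_structure(trajectory, frames_path)
    elif format == "dcd":
        from mdtraj.formats import DCDTrajectoryFile

        with DCDTrajectoryFile(str(frames_path), "w") as fh:
            fh.write(trajectory.coords_array().astype(np.float32))
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
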