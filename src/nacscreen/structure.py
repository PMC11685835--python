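"""Structures, trajectories and exact 3-D geometry primitives.

A :class:`Structure` is an ordered list of atoms with author residue
numbering (no renumbering is ever applied — mutation tokens like ``D192``
are author-numbered).  A :class:`Trajectory` couples one topology with a
stack of coordinate frames and doubles as a docked-pose set.  PDB I/O is
delegated to biotite; coordinates are Angstrom throughout and angles are
degrees — there is no internal unit conversion.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as _struc
import biotite.structure.io.pdb as _pdb

from .errors import (
    DegenerateInputError,
    EmptyInputError,
    PDBParseError,
    SelectorError,
    StructuralError,
    VdwLookupError,
)

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "AtomSelector",
    "read_structure",
    "read_trajectory",
    "read_xyz",
    "write_structure",
    "write_trajectory",
    "resolve_selector",
    "vdw_radius",
    "distance",
    "angle",
    "VDW_RADII",
    "WATER_RESNAMES",
]

# Bondi (1964) van der Waals radii, Angstrom.  The set used for vdw-sum
# distance thresholds; configurable at the criterion level but never
# silently defaulted for unknown elements.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}

WATER_RESNAMES = frozenset({"HOH", "WAT", "H2O", "DOD", "TIP", "TIP3", "SPC"})


@dataclass(frozen=True)
class AtomRecord:
    """One atom: PDB-style identity plus Cartesian coordinates (Angstrom)."""

    serial: int
    name: str
    resname: str
    chain: str
    resid: int
    element: str
    coords: tuple[float, float, float]
    icode: str = ""
    hetero: bool = False

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"atom {self.name}: non-finite coordinates")


@dataclass
class Structure:
    """An ordered collection of atoms identified by (chain, resid, icode, name)."""

    atoms: list[AtomRecord]
    id: str = ""
    annotations: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Angstrom."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise StructuralError(
                f"coordinate array {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        atoms = [replace(a, coords=tuple(c)) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, id=self.id, annotations=dict(self.annotations))

    def residue_ids(self) -> list[tuple[str, int, str]]:
        """Unique (chain, resid, icode) triples in order of first appearance."""
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain, a.resid, a.icode), None)
        return list(seen)

    def residue_atoms(self, chain: str | None, resid: int, icode: str = "") -> list[int]:
        return [
            i
            for i, a in enumerate(self.atoms)
            if a.resid == resid
            and a.icode == icode
            and (chain is None or a.chain == chain)
        ]


@dataclass
class Trajectory:
    """A topology plus >= 1 coordinate frames; also models docked-pose sets."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise StructuralError(
                f"frames must be (n_frames, n_atoms, 3), got {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise EmptyInputError("trajectory must contain at least one frame")
        if self.frames.shape[1] != len(self.topology.atoms):
            raise StructuralError(
                f"frames have {self.frames.shape[1]} atoms but topology has "
                f"{len(self.topology.atoms)}"
            )
        if self.frame_labels is not None and len(self.frame_labels) != len(self):
            raise StructuralError("frame_labels length does not match frame count")

    def __len__(self) -> int:
        return int(self.frames.shape[0])

    def subset(self, indices) -> "Trajectory":
        indices = list(indices)
        labels = (
            [self.frame_labels[i] for i in indices] if self.frame_labels else None
        )
        return Trajectory(self.topology, self.frames[indices], labels)


@dataclass(frozen=True)
class AtomSelector:
    """Names exactly one atom: residue number + atom name, optionally chain,
    residue name and an enzyme/ligand entity tag.

    The entity tag disambiguates enzyme residues from HETATM ligands whose
    author numbering may clash with the protein's.
    """

    resid: int
    atom_name: str
    chain: str | None = None
    resname: str | None = None
    entity: str | None = None  # "enzyme" | "ligand" | None
    icode: str = ""

    def __post_init__(self) -> None:
        if self.entity not in (None, "enzyme", "ligand"):
            raise ValueError(f"entity must be 'enzyme' or 'ligand', got {self.entity!r}")

    def matches(self, atom: AtomRecord) -> bool:
        if atom.resid != self.resid or atom.icode != self.icode:
            return False
        if atom.name != self.atom_name:
            return False
        if self.chain is not None and atom.chain != self.chain:
            return False
        if self.resname is not None and atom.resname != self.resname:
            return False
        if self.entity == "enzyme" and atom.hetero:
            return False
        if self.entity == "ligand" and not atom.hetero:
            return False
        return True

    def __str__(self) -> str:
        tag = f"[{self.entity}]" if self.entity else ""
        ch = f"{self.chain}:" if self.chain else ""
        rn = self.resname or ""
        return f"{tag}{ch}{rn}{self.resid}{self.icode}:{self.atom_name}"


# ---------------------------------------------------------------------------
# PDB / XYZ I/O


def _validate_pdb_lines(text: str) -> int:
    """Cheap fixed-width sanity pass so parse errors can name the line."""
    n_atoms = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        n_atoms += 1
        if len(line) < 54:
            raise PDBParseError(
                f"line {lineno}: ATOM/HETATM record shorter than 54 columns"
            )
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed {what}-coordinate field "
                    f"{line[lo:hi]!r}"
                ) from None
        try:
            int(line[22:26])
        except ValueError:
            raise PDBParseError(
                f"line {lineno}: malformed residue number {line[22:26]!r}"
            ) from None
    return n_atoms


def _atoms_from_array(arr: _struc.AtomArray) -> list[AtomRecord]:
    records = []
    for i in range(arr.array_length()):
        elem = str(arr.element[i]).strip().upper()
        if not elem:
            # biotite guesses from the atom name; fall back to first letter
            elem = "".join(ch for ch in str(arr.atom_name[i]) if ch.isalpha())[:1].upper()
        records.append(
            AtomRecord(
                serial=i + 1,
                name=str(arr.atom_name[i]),
                resname=str(arr.res_name[i]),
                chain=str(arr.chain_id[i]),
                resid=int(arr.res_id[i]),
                element=elem,
                coords=tuple(float(c) for c in arr.coord[i]),
                icode=str(arr.ins_code[i]) if "ins_code" in arr.get_annotation_categories() else "",
                hetero=bool(arr.hetero[i]),
            )
        )
    return records


def _parse_pdb(text: str, model: int | None):
    if _validate_pdb_lines(text) == 0:
        raise EmptyInputError("no ATOM/HETATM records in input")
    pdb_file = _pdb.PDBFile.read(io.StringIO(text))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # element guessed from atom name
        try:
            return pdb_file.get_structure(model=model, altloc="occupancy")
        except Exception as exc:  # biotite raises plain ValueError/InvalidFileError
            raise PDBParseError(f"PDB parse failed: {exc}") from exc


def read_structure(pdb_text: str, id: str = "") -> Structure:
    """Parse PDB text into a :class:`Structure` (first model if several).

    Altloc policy: highest occupancy wins, ties to the first occurrence.
    Elements come from columns 77-78 when present, else are inferred from
    the atom name.  Waters and additives are retained; callers filter.
    """
    arr = _parse_pdb(pdb_text, model=1)
    return Structure(_atoms_from_array(arr), id=id)


def read_trajectory(
    source: str, topology: Structure | None = None, id: str = ""
) -> Trajectory:
    """Parse a multi-model PDB (or XYZ text with ``topology``) into a trajectory.

    Frames follow MODEL order; a single-model PDB yields a 1-frame
    trajectory.  All frames must share the topology's atom count.
    """
    stripped = source.lstrip()
    if topology is not None and not stripped.startswith(
        ("ATOM", "HETATM", "MODEL", "REMARK", "HEADER", "CRYST", "TITLE")
    ):
        return read_xyz(source, topology)
    arr = _parse_pdb(source, model=None)
    if isinstance(arr, _struc.AtomArray):  # single model
        arr = _struc.stack([arr])
    top = Structure(_atoms_from_array(arr[0]), id=id)
    frames = np.asarray(arr.coord, dtype=float)
    if topology is not None:
        if len(topology.atoms) != frames.shape[1]:
            raise StructuralError(
                f"trajectory frames have {frames.shape[1]} atoms but supplied "
                f"topology has {len(topology.atoms)}"
            )
        top = topology
    return Trajectory(top, frames)


def read_xyz(text: str, topology: Structure) -> Trajectory:
    """Parse multi-frame XYZ text against a supplied topology.

    Atom names in the XYZ body are ignored; identity comes from the
    topology, which fixes the per-frame atom count.
    """
    lines = text.splitlines()
    n_top = len(topology.atoms)
    frames: list[np.ndarray] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise PDBParseError(
                f"XYZ line {i + 1}: expected atom count, got {lines[i]!r}"
            ) from None
        if n != n_top:
            raise StructuralError(
                f"XYZ frame at line {i + 1} has {n} atoms; topology has {n_top}"
            )
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise PDBParseError(f"XYZ frame at line {i + 1}: truncated")
        coords = np.empty((n, 3))
        for j, row in enumerate(block):
            parts = row.split()
            if len(parts) < 4:
                raise PDBParseError(f"XYZ line {i + 3 + j}: expected 'El x y z'")
            coords[j] = [float(p) for p in parts[1:4]]
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise EmptyInputError("XYZ input contains no frames")
    return Trajectory(topology, np.stack(frames))


def _array_from_structure(structure: Structure) -> _struc.AtomArray:
    n = len(structure.atoms)
    if n == 0:
        raise EmptyInputError("cannot serialize an empty structure")
    arr = _struc.AtomArray(n)
    arr.coord = structure.coords
    arr.chain_id = np.array([a.chain or "A" for a in structure.atoms])
    arr.res_id = np.array([a.resid for a in structure.atoms])
    arr.ins_code = np.array([a.icode for a in structure.atoms])
    arr.res_name = np.array([a.resname for a in structure.atoms])
    arr.atom_name = np.array([a.name for a in structure.atoms])
    arr.element = np.array([a.element for a in structure.atoms])
    arr.hetero = np.array([a.hetero for a in structure.atoms])
    return arr


def write_structure(structure: Structure) -> str:
    """Serialize a structure as PDB text."""
    pdb_file = _pdb.PDBFile()
    pdb_file.set_structure(_array_from_structure(structure))
    return "\n".join(pdb_file.lines) + "\n"


def write_trajectory(traj: Trajectory) -> str:
    """Serialize a trajectory as multi-model PDB text (MODEL/ENDMDL blocks)."""
    arr = _array_from_structure(traj.topology)
    stack = _struc.stack([arr] * len(traj))
    stack.coord = traj.frames.copy()
    pdb_file = _pdb.PDBFile()
    pdb_file.set_structure(stack)
    return "\n".join(pdb_file.lines) + "\n"


# ---------------------------------------------------------------------------
# Selector resolution and geometry primitives


def resolve_selector(structure: Structure, sel: AtomSelector) -> int:
    """Index of the unique atom matching ``sel``; typed error otherwise."""
    hits = [i for i, a in enumerate(structure.atoms) if sel.matches(a)]
    if len(hits) == 1:
        return hits[0]
    if len(hits) > 1:
        desc = ", ".join(
            f"#{i} {structure.atoms[i].resname}{structure.atoms[i].resid}:"
            f"{structure.atoms[i].name}" for i in hits
        )
        raise SelectorError(f"selector {sel} is ambiguous: matches {desc}")
    # not found: report the nearest residue number as a hint
    resids = sorted({a.resid for a in structure.atoms})
    nearest = min(resids, key=lambda r: abs(r - sel.resid)) if resids else None
    raise SelectorError(
        f"selector {sel} matches no atom"
        + (f" (nearest residue number: {nearest})" if nearest is not None else "")
    )


def vdw_radius(element: str) -> float:
    """Bondi van der Waals radius (Angstrom) for an element symbol."""
    key = element.strip().upper()
    try:
        return VDW_RADII[key]
    except KeyError:
        raise VdwLookupError(
            f"no van der Waals radius for element {element!r}; "
            f"known: {sorted(VDW_RADII)}"
        ) from None


def distance(frame: np.ndarray, i: int, j: int) -> float:
    """Euclidean distance (Angstrom) between atoms ``i`` and ``j`` of a frame."""
    if i == j:
        raise DegenerateInputError(f"distance requires two distinct atoms, got {i} twice")
    frame = np.asarray(frame, dtype=float)
    return float(np.linalg.norm(frame[i] - frame[j]))


def angle(frame: np.ndarray, i: int, j: int, k: int) -> float:
    """Angle at vertex ``j`` of the triple (i, j, k), degrees in [0, 180]."""
    if len({i, j, k}) != 3:
        raise DegenerateInputError(f"angle requires three distinct atoms, got {(i, j, k)}")
    frame = np.asarray(frame, dtype=float)
    u = frame[i] - frame[j]
    v = frame[k] - frame[j]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateInputError("angle arm has zero length (coincident points)")
    cosine = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosine)))
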