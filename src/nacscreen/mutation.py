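"""Mutation tokens, saturation-mutagenesis spaces and mutant building.

Mutations are written as ``X#Y`` tokens (wild-type letter, author residue
number, new letter).  Single-point saturation over N positions yields a
19*N space; x-point combinations yield C(N, x) * 19^x.  Mutant structures
are built by side-chain grafting: the new residue's ideal side chain
(CCD template) is aligned on the existing backbone and a small discrete
chi-angle rotamer grid is scanned for the placement with the fewest
steric clashes — a deterministic surrogate for force-field side-chain
relaxation, with ties broken by library order.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace as _dc_replace
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

import biotite.structure.info as _info

from .errors import ConfigError, EmptyInputError, MutationError, WtMismatchError
from .structure import (
    AtomRecord,
    AtomSelector,
    Structure,
    WATER_RESNAMES,
    resolve_selector,
    vdw_radius,
)

__all__ = [
    "AA_3TO1",
    "AA_1TO3",
    "CANONICAL_AA1",
    "Mutation",
    "Variant",
    "MutationSpace",
    "SideChainTemplateLibrary",
    "parse_mutation_token",
    "positions_within_radius",
    "enumerate_single",
    "enumerate_combinations",
    "combination_space_size",
    "apply_mutation",
    "clash_count",
    "DEFAULT_CLASH_TOLERANCE",
]

logger = logging.getLogger(__name__)

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}
CANONICAL_AA1 = tuple(sorted(AA_1TO3))  # alphabetical, fixes enumeration order

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})
# Backbone-attached hydrogens retained through a mutation.
BACKBONE_HYDROGENS = frozenset({"H", "H1", "H2", "H3", "HA", "HA2", "HA3", "HXT"})

#: Clash when d < tolerance * (vdw_i + vdw_j); 0.6 admits normal packing
#: contact while flagging genuine overlap.
DEFAULT_CLASH_TOLERANCE = 0.6

# Standard chi-angle atom quadruples; only the first two chis are scanned,
# deeper chis keep their ideal-template values.
CHI_ATOMS: dict[str, tuple[tuple[str, str, str, str], ...]] = {
    "ARG": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")),
    "ASN": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")),
    "ASP": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")),
    "CYS": (("N", "CA", "CB", "SG"),),
    "GLN": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")),
    "GLU": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")),
    "HIS": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")),
    "ILE": (("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")),
    "LEU": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "LYS": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")),
    "MET": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD")),
    "PHE": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "SER": (("N", "CA", "CB", "OG"),),
    "THR": (("N", "CA", "CB", "OG1"),),
    "TRP": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "TYR": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "VAL": (("N", "CA", "CB", "CG1"),),
    "ALA": (),
    "GLY": (),
    "PRO": (),  # ring conformation kept at template values
}

CHI_VALUES = (-60.0, 60.0, 180.0)  # gauche-, gauche+, trans


@dataclass(frozen=True, order=True)
class Mutation:
    """A single substitution: wild-type letter, author position, new letter."""

    position: int
    wt: str
    new: str
    chain: str | None = None

    def __post_init__(self) -> None:
        for letter, what in ((self.wt, "wild-type"), (self.new, "mutant")):
            if letter not in AA_1TO3:
                raise MutationError(f"{what} residue {letter!r} is not canonical")
        if self.wt == self.new:
            raise MutationError(
                f"self-mutation {self.wt}{self.position}{self.new} is not a mutation"
            )

    @property
    def token(self) -> str:
        return f"{self.wt}{self.position}{self.new}"


@dataclass(frozen=True)
class Variant:
    """A set of mutations at distinct positions; the empty set is wild type."""

    mutations: frozenset[Mutation]

    def __init__(self, mutations=()) -> None:
        mutations = frozenset(mutations)
        positions = [m.position for m in mutations]
        if len(set(positions)) != len(positions):
            raise MutationError(
                f"variant has multiple mutations at one position: {sorted(positions)}"
            )
        object.__setattr__(self, "mutations", mutations)

    @property
    def id(self) -> str:
        if not self.mutations:
            return "WT"
        return "+".join(m.token for m in sorted(self.mutations))

    @property
    def is_wildtype(self) -> bool:
        return not self.mutations

    def __str__(self) -> str:
        return self.id


@dataclass(frozen=True)
class MutationSpace:
    """Closed-form description of a saturation-mutagenesis space."""

    positions: tuple[int, ...]
    order: int = 1

    @property
    def size(self) -> int:
        return combination_space_size(len(self.positions), self.order)


def parse_mutation_token(token: str) -> Mutation:
    """Parse an ``X#Y`` token, e.g. ``"L89Y"`` -> (L, 89, Y)."""
    t = token.strip()
    if len(t) < 3 or not t[0].isalpha() or not t[-1].isalpha() or not t[1:-1].isdigit():
        raise MutationError(
            f"malformed mutation token {token!r}: expected letter-digits-letter"
        )
    return Mutation(wt=t[0].upper(), position=int(t[1:-1]), new=t[-1].upper())


def parse_variant(text: str) -> Variant:
    """Parse a variant id: ``"WT"`` or ``X#Y`` tokens joined by ``+``."""
    t = text.strip()
    if t.upper() == "WT" or not t:
        return Variant()
    return Variant(parse_mutation_token(tok) for tok in t.split("+"))


# ---------------------------------------------------------------------------
# Mutation-space enumeration


def positions_within_radius(
    structure: Structure,
    ligand: list[AtomSelector],
    radius: float,
    reference: str = "heavy",
) -> list[int]:
    """Residue numbers with any heavy atom within ``radius`` of any ligand heavy atom.

    This is the substrate-shell rule used to bound a saturation space
    (e.g. a 12-Angstrom shell around the bound substrate).  The ligand's
    own residues and waters are excluded.  ``reference="ca"`` measures
    from C-alpha atoms instead of all heavy atoms.
    """
    if radius <= 0:
        raise ConfigError(f"shell radius must be > 0, got {radius}")
    if not ligand:
        raise EmptyInputError("no ligand selectors given")
    lig_idx = [resolve_selector(structure, sel) for sel in ligand]
    lig_atoms = [structure.atoms[i] for i in lig_idx]
    lig_coords = np.array(
        [a.coords for a in lig_atoms if a.element != "H"], dtype=float
    )
    if lig_coords.size == 0:
        raise EmptyInputError("ligand selectors resolve to no heavy atoms")
    lig_residues = {(a.chain, a.resid, a.icode) for a in lig_atoms}

    tree = cKDTree(lig_coords)
    shell: set[int] = set()
    for i, atom in enumerate(structure.atoms):
        if atom.element == "H":
            continue
        if reference == "ca" and atom.name != "CA":
            continue
        if atom.resname in WATER_RESNAMES:
            continue
        if (atom.chain, atom.resid, atom.icode) in lig_residues:
            continue
        if tree.query(np.asarray(atom.coords))[0] <= radius:
            shell.add(atom.resid)
    return sorted(shell)


def _wt_letter(structure: Structure, position: int, chain: str | None = None) -> str:
    idx = structure.residue_atoms(chain, position)
    if not idx:
        raise MutationError(f"structure has no residue {position}")
    resname = structure.atoms[idx[0]].resname
    try:
        return AA_3TO1[resname]
    except KeyError:
        raise MutationError(
            f"residue {position} ({resname}) is not a canonical amino acid"
        ) from None


def enumerate_single(
    positions: list[int],
    exclusions: list[int] | None = None,
    structure: Structure | None = None,
    wt_sequence: dict[int, str] | None = None,
) -> list[Variant]:
    """All single-point variants over ``positions`` minus ``exclusions``.

    Yields 19 variants per kept position (every canonical residue except
    the wild type), ordered by position ascending then mutant letter
    alphabetical; the total is 19 x (kept positions).  Wild-type identity
    comes from ``structure`` or an explicit ``wt_sequence`` map.
    """
    exclusions = list(exclusions or [])
    stray = [e for e in exclusions if e not in positions]
    if stray:
        logger.warning("exclusions not in position list (ignored): %s", stray)
    excluded = set(exclusions)
    if structure is None and wt_sequence is None:
        raise ConfigError("enumerate_single needs a structure or a wt_sequence map")

    variants: list[Variant] = []
    for pos in sorted(set(positions)):
        if pos in excluded:
            continue
        wt = wt_sequence[pos] if wt_sequence is not None else _wt_letter(structure, pos)
        for aa in CANONICAL_AA1:
            if aa != wt:
                variants.append(Variant([Mutation(wt=wt, position=pos, new=aa)]))
    return variants


def enumerate_combinations(
    positions: list[int],
    order: int,
    structure: Structure | None = None,
    wt_sequence: dict[int, str] | None = None,
):
    """Generator over all ``order``-point combination variants (C(n,x) * 19^x)."""
    if order < 0 or order > len(positions):
        raise ConfigError(f"order {order} outside [0, {len(positions)}]")
    wt_of = {}
    for pos in positions:
        wt_of[pos] = (
            wt_sequence[pos] if wt_sequence is not None else _wt_letter(structure, pos)
        )
    for site_combo in itertools.combinations(sorted(set(positions)), order):
        choices = [
            [aa for aa in CANONICAL_AA1 if aa != wt_of[p]] for p in site_combo
        ]
        for assignment in itertools.product(*choices):
            yield Variant(
                Mutation(wt=wt_of[p], position=p, new=aa)
                for p, aa in zip(site_combo, assignment)
            )


def combination_space_size(n: int, x: int) -> int:
    """Exact size of an x-point combination space over n positions: C(n,x) * 19^x."""
    if x < 0 or n < 0 or x > n:
        raise ConfigError(f"invalid combination space: n={n}, x={x}")
    return math.comb(n, x) * 19**x


# ---------------------------------------------------------------------------
# Side-chain templates and rotamers


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _rotate_about_axis(points, origin, axis, angle_deg):
    rot = Rotation.from_rotvec(np.radians(angle_deg) * axis / np.linalg.norm(axis))
    return rot.apply(points - origin) + origin


@dataclass(frozen=True)
class ResidueTemplate:
    resname: str
    atom_names: tuple[str, ...]  # heavy atoms, template order
    elements: tuple[str, ...]
    coords: np.ndarray  # (n_heavy, 3) ideal coordinates
    adjacency: dict[str, tuple[str, ...]]  # heavy-atom bond graph

    @property
    def sidechain_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.atom_names if n not in BACKBONE_ATOMS)


@lru_cache(maxsize=None)
def _load_template(res3: str) -> ResidueTemplate:
    arr = _info.residue(res3)
    heavy = np.array([e != "H" for e in arr.element])
    idx = np.flatnonzero(heavy)
    names = tuple(str(arr.atom_name[i]) for i in idx)
    elements = tuple(str(arr.element[i]).upper() for i in idx)
    coords = np.array(arr.coord[idx], dtype=float)
    pos_of = {int(i): n for n, i in zip(names, idx)}
    adj: dict[str, set[str]] = {n: set() for n in names}
    bonds = arr.bonds.as_array()
    for a, b, _ in bonds:
        if int(a) in pos_of and int(b) in pos_of:
            adj[pos_of[int(a)]].add(pos_of[int(b)])
            adj[pos_of[int(b)]].add(pos_of[int(a)])
    return ResidueTemplate(
        resname=res3,
        atom_names=names,
        elements=elements,
        coords=coords,
        adjacency={k: tuple(sorted(v)) for k, v in adj.items()},
    )


class SideChainTemplateLibrary:
    """Ideal heavy-atom residue templates plus a discrete rotamer grid.

    Templates are the CCD ideal coordinates shipped with biotite.  The
    rotamer grid scans chi1 (and chi2 where defined) over the canonical
    gauche-/gauche+/trans values, 9 rotamers at most, in a fixed order so
    clash-count ties resolve deterministically.
    """

    def template(self, res3: str) -> ResidueTemplate:
        if res3 not in AA_3TO1:
            raise MutationError(f"no template for residue {res3!r}")
        return _load_template(res3)

    def rotamers(self, res3: str) -> list[tuple[tuple[float, ...], dict[str, np.ndarray]]]:
        """(chi-values, {atom_name: coords}) per rotamer, library order."""
        tpl = self.template(res3)
        chis = CHI_ATOMS.get(res3, ())[:2]
        name_to_idx = {n: i for i, n in enumerate(tpl.atom_names)}
        base = {n: tpl.coords[name_to_idx[n]].copy() for n in tpl.atom_names}
        if not chis:
            return [((), base)]

        def distal_set(p2: str, p3: str) -> list[str]:
            seen = {p2, p3}
            stack = [n for n in tpl.adjacency[p3] if n != p2]
            out = []
            while stack:
                n = stack.pop()
                if n in seen:
                    continue
                seen.add(n)
                out.append(n)
                stack.extend(tpl.adjacency[n])
            return out

        rotamers = []
        for values in itertools.product(CHI_VALUES, repeat=len(chis)):
            coords = {n: c.copy() for n, c in base.items()}
            ok = True
            for (a0, a1, a2, a3), target in zip(chis, values):
                if not all(n in coords for n in (a0, a1, a2, a3)):
                    ok = False
                    break
                current = _dihedral(coords[a0], coords[a1], coords[a2], coords[a3])
                moving = distal_set(a1, a2)
                pts = np.array([coords[n] for n in moving])
                new_pts = _rotate_about_axis(
                    pts, coords[a1], coords[a2] - coords[a1], target - current
                )
                for n, p in zip(moving, new_pts):
                    coords[n] = p
            if ok:
                rotamers.append((values, coords))
        return rotamers


# ---------------------------------------------------------------------------
# Clash counting and mutant building


def _heavy_coords_and_radii(structure: Structure):
    idx = [i for i, a in enumerate(structure.atoms) if a.element != "H"]
    coords = np.array([structure.atoms[i].coords for i in idx], dtype=float)
    radii = np.array([vdw_radius(structure.atoms[i].element) for i in idx])
    return idx, coords, radii


def _count_clashes_against(
    structure: Structure,
    chain: str | None,
    resid: int,
    sc_coords: np.ndarray,
    sc_radii: np.ndarray,
    tolerance: float,
) -> int:
    """Clashes of candidate side-chain atoms against the rest of the structure.

    Pairs within the same residue and against backbone atoms of the two
    sequence-adjacent residues are exempt (they are bonded or 1-3/1-4
    neighbours, not steric clashes).
    """
    if sc_coords.size == 0:
        return 0
    env_idx, env_coords, env_radii = _heavy_coords_and_radii(structure)
    keep = []
    for n, i in enumerate(env_idx):
        a = structure.atoms[i]
        same_chain = chain is None or a.chain == chain
        if same_chain and a.resid == resid:
            continue
        if same_chain and abs(a.resid - resid) == 1 and a.name in BACKBONE_ATOMS:
            continue
        keep.append(n)
    if not keep:
        return 0
    env_coords = env_coords[keep]
    env_radii = env_radii[keep]
    cutoff = tolerance * (sc_radii.max() + env_radii.max())
    tree = cKDTree(env_coords)
    count = 0
    for p, r in zip(sc_coords, sc_radii):
        for n in tree.query_ball_point(p, cutoff):
            if np.linalg.norm(p - env_coords[n]) < tolerance * (r + env_radii[n]):
                count += 1
    return count


def clash_count(
    structure: Structure,
    residue: int,
    tolerance: float = DEFAULT_CLASH_TOLERANCE,
    chain: str | None = None,
) -> int:
    """Steric clashes of a residue's side chain against the rest of the structure.

    A clash is a non-bonded heavy-atom pair closer than
    ``tolerance * (vdw_i + vdw_j)``; same-residue and adjacent-backbone
    pairs are exempt.
    """
    idx = structure.residue_atoms(chain, residue)
    if not idx:
        raise MutationError(f"structure has no residue {residue}")
    sc = [
        structure.atoms[i]
        for i in idx
        if structure.atoms[i].name not in BACKBONE_ATOMS
        and structure.atoms[i].element != "H"
    ]
    sc_coords = np.array([a.coords for a in sc], dtype=float).reshape(-1, 3)
    sc_radii = np.array([vdw_radius(a.element) for a in sc])
    ch = chain if chain is not None else (structure.atoms[idx[0]].chain if idx else None)
    return _count_clashes_against(structure, ch, residue, sc_coords, sc_radii, tolerance)


def _graft_transform(tpl: ResidueTemplate, target_bb: dict[str, np.ndarray]):
    """Rigid transform mapping template N/CA/C onto the target backbone."""
    name_to_idx = {n: i for i, n in enumerate(tpl.atom_names)}
    for n in ("N", "CA", "C"):
        if n not in name_to_idx or n not in target_bb:
            raise MutationError(f"backbone atom {n} missing for grafting")
    tpl_pts = np.array([tpl.coords[name_to_idx[n]] for n in ("N", "CA", "C")])
    tgt_pts = np.array([target_bb[n] for n in ("N", "CA", "C")])
    tpl_centroid = tpl_pts.mean(axis=0)
    tgt_centroid = tgt_pts.mean(axis=0)
    rot, _ = Rotation.align_vectors(tgt_pts - tgt_centroid, tpl_pts - tpl_centroid)

    def transform(points: np.ndarray) -> np.ndarray:
        return rot.apply(points - tpl_centroid) + tgt_centroid

    return transform


def apply_mutation(
    structure: Structure,
    variant: Variant,
    lib: SideChainTemplateLibrary | None = None,
    clash_tolerance: float = DEFAULT_CLASH_TOLERANCE,
) -> Structure:
    """Build a mutant structure by grafting new side chains onto the backbone.

    For each mutation the wild-type identity is checked against the
    structure (a ``D192`` token demands Asp at 192), the old side chain is
    removed, and the new residue's ideal side chain is aligned on the
    unchanged backbone.  Every rotamer in the library grid is scored by
    :func:`clash_count`; the fewest-clash rotamer wins, ties going to the
    first in library order.  The result carries ``annotations["rotamers"]``
    and ``annotations["clash_count"]`` (total residual clashes).
    """
    lib = lib or SideChainTemplateLibrary()
    atoms = list(structure.atoms)
    chosen_rotamers: dict[str, tuple[float, ...]] = {}

    for mut in sorted(variant.mutations):
        res_idx = [
            i
            for i, a in enumerate(atoms)
            if a.resid == mut.position
            and a.icode == ""
            and (mut.chain is None or a.chain == mut.chain)
        ]
        if not res_idx:
            raise MutationError(f"structure has no residue {mut.position}")
        found_res3 = atoms[res_idx[0]].resname
        if AA_3TO1.get(found_res3) != mut.wt:
            raise WtMismatchError(
                f"mutation {mut.token}: residue {mut.position} is "
                f"{found_res3}, not {AA_1TO3[mut.wt]}"
            )
        chain = atoms[res_idx[0]].chain
        present = {atoms[i].name for i in res_idx}
        missing_bb = {"N", "CA", "C", "O"} - present
        if missing_bb:
            raise MutationError(
                f"mutation {mut.token}: backbone atoms {sorted(missing_bb)} missing"
            )
        if found_res3 == "PRO":
            logger.info("mutating a proline position: %s", mut.token)

        target_bb = {
            atoms[i].name: np.asarray(atoms[i].coords)
            for i in res_idx
            if atoms[i].name in ("N", "CA", "C")
        }
        new_res3 = AA_1TO3[mut.new]
        tpl = lib.template(new_res3)
        transform = _graft_transform(tpl, target_bb)

        kept = [
            atoms[i]
            for i in res_idx
            if atoms[i].name in BACKBONE_ATOMS
            or (atoms[i].element == "H" and atoms[i].name in BACKBONE_HYDROGENS)
        ]
        # Scratch structure without this residue's side chain, for clash scoring
        scratch_atoms = [
            a for i, a in enumerate(atoms) if i not in set(res_idx)
        ] + kept
        scratch = Structure(scratch_atoms, id=structure.id)

        sc_names = tpl.sidechain_names
        elem_of = dict(zip(tpl.atom_names, tpl.elements))
        sc_radii = np.array([vdw_radius(elem_of[n]) for n in sc_names])
        best = None
        for chi_values, coords in lib.rotamers(new_res3):
            sc_coords = (
                transform(np.array([coords[n] for n in sc_names]))
                if sc_names
                else np.empty((0, 3))
            )
            n_clash = _count_clashes_against(
                scratch, chain, mut.position, sc_coords, sc_radii, clash_tolerance
            )
            if best is None or n_clash < best[0]:
                best = (n_clash, chi_values, sc_coords)
        n_clash, chi_values, sc_coords = best

        new_res_atoms = [_dc_replace(a, resname=new_res3) for a in kept] + [
            AtomRecord(
                serial=0,
                name=n,
                resname=new_res3,
                chain=chain,
                resid=mut.position,
                element=elem_of[n],
                coords=tuple(float(x) for x in c),
                hetero=False,
            )
            for n, c in zip(sc_names, sc_coords)
        ]
        # splice the rebuilt residue back at its original position
        first = res_idx[0]
        atoms = (
            [a for i, a in enumerate(atoms) if i < first and i not in set(res_idx)]
            + new_res_atoms
            + [a for i, a in enumerate(atoms) if i > first and i not in set(res_idx)]
        )
        chosen_rotamers[mut.token] = chi_values

    atoms = [_dc_replace(a, serial=i + 1) for i, a in enumerate(atoms)]
    result = Structure(atoms, id=f"{structure.id}|{variant.id}" if structure.id else variant.id)
    total_clashes = sum(
        clash_count(result, m.position, clash_tolerance, m.chain)
        for m in variant.mutations
    )
    result.annotations["rotamers"] = chosen_rotamers
    result.annotations["clash_count"] = total_clashes
    result.annotations["variant"] = variant.id
    return result
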