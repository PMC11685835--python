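"""Programmatic fixture builders: toy complexes, pockets and benchmarks.

Everything here is synthetic, generated at call time from ideal residue
templates — no structural data ships with the package.  These builders
define the desk-scale study conditions the test-suite and the
reproduction script run under.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigError
from .model import AngleCriterion, DistanceCriterion, NACModel
from .mutation import AA_1TO3, SideChainTemplateLibrary
from .sampler import PocketModel
from .stats import PredictionRecord
from .structure import AtomRecord, AtomSelector, Structure

__all__ = [
    "make_peptide",
    "make_epoxide_ligand",
    "make_complex",
    "epoxide_attack_model",
    "aneh_like_complex",
    "make_pocket",
    "random_geometry_case",
    "transaminase_benchmark",
]

_LIG_RESNAME = "LIG"
_LIG_RESID = 900


def make_peptide(
    residues: dict[int, str],
    chain: str = "A",
    spacing: float = 6.0,
    id: str = "peptide",
) -> Structure:
    """A synthetic chain of ideal residues laid out along x.

    ``residues`` maps author residue numbers to one-letter codes.  Each
    residue is an ideal heavy-atom template translated to its own slot
    (``spacing`` Angstrom apart, alternating y-offset), so residues do not
    overlap and side chains stay resolvable.  This is a geometric fixture,
    not a chemically bonded chain.
    """
    lib = SideChainTemplateLibrary()
    atoms: list[AtomRecord] = []
    serial = 1
    for slot, resid in enumerate(sorted(residues)):
        aa1 = residues[resid]
        if aa1 not in AA_1TO3:
            raise ConfigError(f"residue {resid}: unknown amino acid {aa1!r}")
        tpl = lib.template(AA_1TO3[aa1])
        offset = np.array([slot * spacing, (slot % 2) * 2.0, 0.0])
        for name, elem, coord in zip(tpl.atom_names, tpl.elements, tpl.coords):
            if name == "OXT":
                continue
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    resname=AA_1TO3[aa1],
                    chain=chain,
                    resid=resid,
                    element=elem,
                    coords=tuple(float(x) for x in coord + offset),
                )
            )
            serial += 1
    return Structure(atoms, id=id)


def make_epoxide_ligand(
    center: np.ndarray, resid: int = _LIG_RESID, serial_start: int = 1
) -> list[AtomRecord]:
    """A minimal epoxide-like ligand: C1-C2 bridged by O, as HETATM records."""
    center = np.asarray(center, dtype=float)
    geom = {
        "C1": np.array([-0.74, 0.0, 0.0]),
        "C2": np.array([0.74, 0.0, 0.0]),
        "O1": np.array([0.0, 1.21, 0.0]),
    }
    return [
        AtomRecord(
            serial=serial_start + i,
            name=name,
            resname=_LIG_RESNAME,
            chain="L",
            resid=resid,
            element=name[0],
            coords=tuple(float(x) for x in center + off),
            hetero=True,
        )
        for i, (name, off) in enumerate(geom.items())
    ]


def make_complex(
    residues: dict[int, str],
    ligand_near: int,
    ligand_distance: float = 3.5,
    spacing: float = 6.0,
    id: str = "complex",
) -> Structure:
    """Peptide fixture plus an epoxide ligand placed near one residue's CA."""
    protein = make_peptide(residues, spacing=spacing, id=id)
    ca = next(
        a for a in protein.atoms if a.resid == ligand_near and a.name == "CA"
    )
    center = np.asarray(ca.coords) + np.array([0.0, 0.0, ligand_distance])
    atoms = list(protein.atoms) + make_epoxide_ligand(
        center, serial_start=len(protein.atoms) + 1
    )
    return Structure(atoms, id=id)


def epoxide_attack_model(
    nucleophile_resid: int,
    nucleophile_atom: str = "OD2",
    threshold: float = 4.0,
    tyrosine_resids: tuple[int, ...] = (),
    tyrosine_threshold: float = 3.5,
    attack_angle: float | None = None,
    angle_tolerance: float = 20.0,
    name: str = "epoxide-attack",
) -> NACModel:
    """NAC model for nucleophilic attack on an epoxide carbon.

    The core criterion is carboxylate oxygen to attacked carbon (C2)
    under an explicit cutoff (4 Angstrom by default).  Optional tyrosine
    criteria anchor the hydroxyls to the epoxide oxygen — oxyanion-hole
    style stabilisation expressed as distances.
    """
    dists = [
        DistanceCriterion(
            a=AtomSelector(resid=nucleophile_resid, atom_name=nucleophile_atom, entity="enzyme"),
            b=AtomSelector(resid=_LIG_RESID, atom_name="C2", entity="ligand"),
            threshold_mode="explicit",
            threshold=threshold,
            label=f"D_O{nucleophile_resid}-C2",
        )
    ]
    for resid in tyrosine_resids:
        dists.append(
            DistanceCriterion(
                a=AtomSelector(resid=resid, atom_name="OH", entity="enzyme"),
                b=AtomSelector(resid=_LIG_RESID, atom_name="O1", entity="ligand"),
                threshold_mode="explicit",
                threshold=tyrosine_threshold,
                label=f"D_OH{resid}-O1",
            )
        )
    angles = []
    if attack_angle is not None:
        angles.append(
            AngleCriterion(
                a=AtomSelector(resid=nucleophile_resid, atom_name=nucleophile_atom, entity="enzyme"),
                vertex=AtomSelector(resid=_LIG_RESID, atom_name="C2", entity="ligand"),
                c=AtomSelector(resid=_LIG_RESID, atom_name="O1", entity="ligand"),
                target_deg=attack_angle,
                tolerance_deg=angle_tolerance,
                label=f"A_O{nucleophile_resid}-C2-O1",
            )
        )
    return NACModel(name=name, distance_criteria=tuple(dists), angle_criteria=tuple(angles))


def aneh_like_complex() -> tuple[Structure, NACModel]:
    """Epoxide-hydrolase-style fixture: Asp nucleophile at 192, two Tyr anchors.

    A synthetic stand-in for an epoxide hydrolase active site — an
    aspartate whose OD2 attacks the less hindered epoxide carbon, with
    Tyr251/Tyr314 hydroxyls anchoring the epoxide oxygen.
    """
    residues = {190: "G", 191: "F", 192: "D", 193: "W", 251: "Y", 314: "Y", 315: "L"}
    structure = make_complex(residues, ligand_near=192, id="aneh-like")
    model = epoxide_attack_model(
        nucleophile_resid=192, tyrosine_resids=(251, 314), name="aneh-like-nac"
    )
    return structure, model


def make_pocket(
    d0: float = 3.5,
    k: float = 4.0,
    wall_radius: float = 2.0,
    wall_k: float = 10.0,
    temperature: float = 1.0,
) -> PocketModel:
    """Minimal pocket: one fixed carboxylate oxygen, one-atom ligand at d0.

    The anchor is an Asp116-style OD2 at the origin; the ligand carbon
    starts at the well centre so sampling begins at equilibrium.
    """
    atoms = [
        AtomRecord(
            serial=1, name="OD2", resname="ASP", chain="A", resid=116,
            element="O", coords=(0.0, 0.0, 0.0),
        ),
        AtomRecord(
            serial=2, name="C1", resname=_LIG_RESNAME, chain="L", resid=_LIG_RESID,
            element="C", coords=(d0, 0.0, 0.0), hetero=True,
        ),
    ]
    top = Structure(atoms, id="pocket")
    return PocketModel(
        topology=top,
        ligand_indices=(1,),
        attack_anchor=0,
        attack_ligand=1,
        d0=d0,
        k=k,
        wall_radius=wall_radius,
        wall_k=wall_k,
        temperature=temperature,
    )


def pocket_nac_model(threshold: float = 4.0) -> NACModel:
    """NAC model matching :func:`make_pocket`: anchor-to-ligand distance < threshold."""
    return NACModel(
        name="pocket-nac",
        distance_criteria=(
            DistanceCriterion(
                a=AtomSelector(resid=116, atom_name="OD2", entity="enzyme"),
                b=AtomSelector(resid=_LIG_RESID, atom_name="C1", entity="ligand"),
                threshold_mode="explicit",
                threshold=threshold,
                label="D_OD116-C1",
            ),
        ),
    )


def random_geometry_case(
    seed: int, n_atoms: int = 8, n_frames: int = 200
) -> tuple[Structure, NACModel, np.ndarray]:
    """A random topology, random NAC model, and random frames.

    Used for oracle-equivalence sweeps: frames are uniform in a 10 A box,
    criteria pick random atom pairs/triples with thresholds spanning the
    box scale so both classes occur.
    """
    rng = np.random.default_rng(seed)
    atoms = [
        AtomRecord(
            serial=i + 1,
            name=f"C{i + 1}",
            resname="UNK" if i else "ASP",
            chain="A",
            resid=i + 1,
            element=rng.choice(["C", "N", "O", "S"]),
            coords=tuple(rng.uniform(0, 10, 3)),
        )
        for i in range(n_atoms)
    ]
    top = Structure(atoms, id=f"random-{seed}")
    n_dist = int(rng.integers(1, 4))
    n_ang = int(rng.integers(0, 3))
    dists, angles = [], []
    for ci in range(n_dist):
        i, j = rng.choice(n_atoms, size=2, replace=False)
        explicit = rng.random() < 0.7
        dists.append(
            DistanceCriterion(
                a=AtomSelector(resid=int(i) + 1, atom_name=f"C{int(i) + 1}"),
                b=AtomSelector(resid=int(j) + 1, atom_name=f"C{int(j) + 1}"),
                threshold_mode="explicit" if explicit else "vdw_sum",
                threshold=float(rng.uniform(3, 12)) if explicit else None,
                label=f"D{ci}",
            )
        )
    for ci in range(n_ang):
        i, j, k = rng.choice(n_atoms, size=3, replace=False)
        angles.append(
            AngleCriterion(
                a=AtomSelector(resid=int(i) + 1, atom_name=f"C{int(i) + 1}"),
                vertex=AtomSelector(resid=int(j) + 1, atom_name=f"C{int(j) + 1}"),
                c=AtomSelector(resid=int(k) + 1, atom_name=f"C{int(k) + 1}"),
                target_deg=float(rng.uniform(60, 170)),
                tolerance_deg=float(rng.uniform(10, 45)),
                label=f"A{ci}",
            )
        )
    model = NACModel(
        name=f"random-model-{seed}",
        distance_criteria=tuple(dists),
        angle_criteria=tuple(angles),
    )
    frames = rng.uniform(0, 10, size=(n_frames, n_atoms, 3))
    return top, model, frames


def transaminase_benchmark() -> tuple[dict[str, float], float, dict[str, str]]:
    """Synthetic 40-variant benchmark with the published confusion structure.

    The real benchmark is a literature set of 40 transaminase variants
    with experimentally labelled higher/lower activity against wild type;
    the per-variant populations are not shipped here, so this stand-in is
    *synthetic*: populations are constructed such that strict
    classification against the wild-type population (0.200) reproduces
    the published outcome —
    15 variants experimentally higher (13 predicted higher, 2 missed) and
    25 lower (24 predicted lower, 1 false positive), i.e. 37/40 correct.

    Returns (populations by variant id, wild-type population, experimental
    labels by variant id).
    """
    wt_p = 0.200
    populations: dict[str, float] = {}
    labels: dict[str, str] = {}
    # deterministic variant ids in saturation-token style
    rng = np.random.default_rng(20240901)
    wt_letters = "ACDEFGHIKLMNPQRSTVWY"
    ids: list[str] = []
    while len(ids) < 40:
        wt = wt_letters[int(rng.integers(0, 20))]
        new = wt_letters[int(rng.integers(0, 20))]
        pos = int(rng.integers(10, 420))
        tok = f"{wt}{pos}{new}"
        if wt != new and tok not in ids:
            ids.append(tok)
    # 15 experimentally higher: 13 predicted higher, 2 predicted lower
    for n, vid in enumerate(ids[:15]):
        labels[vid] = "higher"
        if n < 13:
            populations[vid] = round(wt_p + 0.02 + 0.01 * n, 3)
        else:
            populations[vid] = round(wt_p - 0.03 - 0.01 * (n - 13), 3)
    # 25 experimentally lower: 24 predicted lower, 1 predicted higher
    for n, vid in enumerate(ids[15:]):
        labels[vid] = "lower"
        if n < 24:
            populations[vid] = round(max(wt_p - 0.02 - 0.005 * n, 0.01), 3)
        else:
            populations[vid] = round(wt_p + 0.05, 3)
    return populations, wt_p, labels


def transaminase_records() -> list[PredictionRecord]:
    """The benchmark as classified prediction records (predicted vs experimental)."""
    from .stats import classify_vs_reference

    populations, wt_p, labels = transaminase_benchmark()
    return [
        PredictionRecord(
            variant_id=vid,
            predicted=classify_vs_reference(p, wt_p),
            experimental=labels[vid],
        )
        for vid, p in populations.items()
    ]
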