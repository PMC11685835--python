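import itertools
import math

import numpy as np
import pytest

from nacscreen import (
    AtomSelector,
    ConfigError,
    MutationError,
    Variant,
    WtMismatchError,
    apply_mutation,
    clash_count,
    combination_space_size,
    enumerate_combinations,
    enumerate_single,
    parse_mutation_token,
    positions_within_radius,
    vdw_radius,
)
from nacscreen.fixtures import make_complex, make_peptide
from nacscreen.mutation import AA_3TO1, BACKBONE_ATOMS, SideChainTemplateLibrary
from nacscreen.structure import Structure


class TestParseToken:
    @pytest.mark.parametrize(
        "token,wt,pos,new", [("L89Y", "L", 89, "Y"), ("G119I", "G", 119, "I")]
    )
    def test_valid_tokens(self, token, wt, pos, new):
        m = parse_mutation_token(token)
        assert (m.wt, m.position, m.new) == (wt, pos, new)
        assert m.token == token

    @pytest.mark.parametrize("bad", ["A10A", "X10Y", "AA10Y", "A1OY", "89Y", "L89"])
    def test_invalid_tokens(self, bad):
        with pytest.raises(MutationError):
            parse_mutation_token(bad)

    def test_variant_rejects_duplicate_positions(self):
        with pytest.raises(MutationError):
            Variant([parse_mutation_token("L89Y"), parse_mutation_token("L89W")])

    def test_variant_id_is_sorted_tokens(self):
        v = Variant([parse_mutation_token("G119I"), parse_mutation_token("L89Y")])
        assert v.id == "L89Y+G119I"
        assert Variant().id == "WT"


class TestShellSelection:
    def test_constructed_single_residue_shell(self):
        s = make_complex({1: "A", 2: "G", 3: "L", 4: "S", 5: "V"}, ligand_near=2,
                         ligand_distance=3.0, spacing=14.0)
        ligand = [AtomSelector(resid=900, atom_name=n, entity="ligand")
                  for n in ("C1", "C2", "O1")]
        assert positions_within_radius(s, ligand, radius=5.0) == [2]

    def test_tiny_radius_empty(self):
        s = make_complex({1: "A", 2: "G", 3: "L"}, ligand_near=2, spacing=14.0)
        ligand = [AtomSelector(resid=900, atom_name="C1", entity="ligand")]
        assert positions_within_radius(s, ligand, radius=0.1) == []

    def test_matches_brute_force_oracle(self):
        """Randomized fixtures agree with an all-pairs shell recomputation."""
        base = make_complex(
            {i: aa for i, aa in enumerate("ACDEFGHIKL", start=1)}, ligand_near=5
        )
        ligand = [AtomSelector(resid=900, atom_name=n, entity="ligand")
                  for n in ("C1", "C2", "O1")]
        rng = np.random.default_rng(42)
        for trial in range(50):
            jittered = base.with_coords(
                base.coords + rng.normal(0, 3.0, size=base.coords.shape)
            )
            radius = float(rng.uniform(2, 15))
            got = positions_within_radius(jittered, ligand, radius)
            # brute force: all heavy-atom pairs
            lig_xyz = [np.array(a.coords) for a in jittered.atoms
                       if a.hetero and a.element != "H"]
            expected = sorted({
                a.resid for a in jittered.atoms
                if not a.hetero and a.element != "H"
                and any(np.linalg.norm(np.array(a.coords) - l) <= radius
                        for l in lig_xyz)
            })
            assert got == expected, f"trial {trial}"


class TestEnumeration:
    def test_97_positions_gives_1843(self):
        """Saturation over 97 positions is 19 x 97 = 1843 variants."""
        seq = {i: "ACDEFGHIKLMNPQRSTVWY"[i % 20] for i in range(1, 98)}
        variants = enumerate_single(list(seq), wt_sequence=seq)
        assert len(variants) == 1843
        assert len({v.id for v in variants}) == 1843
        assert combination_space_size(97, 1) == 1843

    def test_single_position_gives_19(self, small_peptide):
        variants = enumerate_single([3], structure=small_peptide)
        assert len(variants) == 19
        wt = AA_3TO1[small_peptide.atoms[
            small_peptide.residue_atoms(None, 3)[0]].resname]
        assert all(next(iter(v.mutations)).wt == wt for v in variants)
        assert all(next(iter(v.mutations)).new != wt for v in variants)

    def test_exclusion_drops_19_and_matches_brute_force(self, small_peptide):
        variants = enumerate_single([1, 2, 3], exclusions=[2], structure=small_peptide)
        assert len(variants) == 38
        expected = set()
        for pos in (1, 3):
            wt = AA_3TO1[small_peptide.atoms[
                small_peptide.residue_atoms(None, pos)[0]].resname]
            for aa in "ACDEFGHIKLMNPQRSTVWY":
                if aa != wt:
                    expected.add(f"{wt}{pos}{aa}")
        assert {v.id for v in variants} == expected

    def test_stray_exclusion_warns_not_errors(self, small_peptide, caplog):
        with caplog.at_level("WARNING", logger="nacscreen.mutation"):
            variants = enumerate_single([1], exclusions=[99], structure=small_peptide)
        assert len(variants) == 19
        assert any("exclusions" in r.message for r in caplog.records)

    def test_combination_size_formulas(self):
        assert combination_space_size(5, 0) == 1
        assert combination_space_size(5, 2) == 3610
        for n in (1, 4, 97):
            assert combination_space_size(n, 1) == 19 * n
        with pytest.raises(ConfigError):
            combination_space_size(3, 4)

    def test_two_site_enumeration_matches_closed_form(self):
        seq = {1: "A", 2: "C", 3: "D", 4: "E", 5: "F"}
        variants = list(enumerate_combinations(list(seq), 2, wt_sequence=seq))
        assert len(variants) == 3610
        assert len({v.id for v in variants}) == 3610
        # brute-force: distinct 2-site assignments avoiding the wild type
        brute = sum(
            1
            for p, q in itertools.combinations(seq, 2)
            for a in "ACDEFGHIKLMNPQRSTVWY"
            for b in "ACDEFGHIKLMNPQRSTVWY"
            if a != seq[p] and b != seq[q]
        )
        assert brute == 3610


class TestApplyMutation:
    def test_gly_to_ile_adds_sidechain_atoms(self):
        s = make_peptide({1: "A", 2: "G", 3: "L"}, spacing=10.0)
        built = apply_mutation(s, Variant([parse_mutation_token("G2I")]))
        lib = SideChainTemplateLibrary()
        gain = len(lib.template("ILE").sidechain_names) - len(
            lib.template("GLY").sidechain_names
        )
        assert len(built) == len(s) + gain
        assert built.annotations["clash_count"] == 0

    def test_mutation_to_glycine_strips_sidechain(self):
        s = make_peptide({1: "A", 2: "L", 3: "V"}, spacing=10.0)
        built = apply_mutation(s, Variant([parse_mutation_token("L2G")]))
        res2 = [built.atoms[i] for i in built.residue_atoms(None, 2)]
        assert {a.name for a in res2} <= BACKBONE_ATOMS
        assert all(a.resname == "GLY" for a in res2)
        assert built.annotations["clash_count"] == 0

    def test_wt_mismatch_raises(self):
        s = make_peptide({1: "A", 2: "G"})
        with pytest.raises(WtMismatchError, match="GLY"):
            apply_mutation(s, Variant([parse_mutation_token("D2I")]))

    def test_backbone_unchanged_and_revert_restores(self):
        s = make_peptide({1: "A", 2: "L", 3: "V"}, spacing=10.0)
        forward = apply_mutation(s, Variant([parse_mutation_token("L2Y")]))
        back = apply_mutation(forward, Variant([parse_mutation_token("Y2L")]))
        assert len(back) == len(s)

        def backbone(st):
            return {
                (a.resid, a.name): a.coords
                for a in st.atoms
                if a.name in BACKBONE_ATOMS
            }

        assert backbone(back) == backbone(s)

    def test_reapply_consumes_identity(self):
        s = make_peptide({1: "A", 2: "L"}, spacing=10.0)
        v = Variant([parse_mutation_token("L2Y")])
        built = apply_mutation(s, v)
        with pytest.raises(WtMismatchError):
            apply_mutation(built, v)

    def test_missing_backbone_atom_errors(self):
        s = make_peptide({1: "A", 2: "L"})
        pruned = Structure(
            [a for a in s.atoms if not (a.resid == 2 and a.name == "O")]
        )
        with pytest.raises(MutationError, match="backbone"):
            apply_mutation(pruned, Variant([parse_mutation_token("L2Y")]))

    def test_rotamer_scan_avoids_constructed_clash(self):
        """With a blocking atom on one side, the chosen rotamer clashes less
        than the worst one."""
        s = make_peptide({1: "A", 2: "G", 3: "L"}, spacing=10.0)
        built = apply_mutation(s, Variant([parse_mutation_token("G2R")]))
        assert built.annotations["clash_count"] <= 2  # long side chain, open fixture


class TestClashCount:
    def test_isolated_residue_zero(self):
        s = make_peptide({1: "W"})
        assert clash_count(s, 1) == 0

    def test_constructed_overlap_detected(self):
        s = make_peptide({1: "A", 2: "G"}, spacing=10.0)
        # place a foreign atom right on top of residue 1's CB
        cb = next(a for a in s.atoms if a.resid == 1 and a.name == "CB")
        from nacscreen.structure import AtomRecord

        clasher = AtomRecord(
            serial=99, name="CX", resname="UNK", chain="A", resid=5,
            element="C", coords=tuple(np.array(cb.coords) + 0.3),
        )
        bumped = Structure(list(s.atoms) + [clasher])
        assert clash_count(bumped, 1) >= 1

    def test_matches_brute_force_oracle(self):
        seqs = {1: "L", 2: "F", 3: "K", 4: "W", 5: "Y"}
        base = make_peptide(seqs, spacing=5.0)
        rng = np.random.default_rng(3)
        tolerance = 0.6
        for trial in range(50):
            s = base.with_coords(base.coords + rng.normal(0, 1.2, base.coords.shape))
            resid = int(rng.integers(1, 6))
            got = clash_count(s, resid, tolerance)
            # independent all-pairs recount
            res_atoms = [a for a in s.atoms if a.resid == resid
                         and a.name not in BACKBONE_ATOMS and a.element != "H"]
            expected = 0
            for a in res_atoms:
                for b in s.atoms:
                    if b.element == "H" or b.resid == resid:
                        continue
                    if abs(b.resid - resid) == 1 and b.name in BACKBONE_ATOMS:
                        continue
                    d = math.dist(a.coords, b.coords)
                    if d < tolerance * (vdw_radius(a.element) + vdw_radius(b.element)):
                        expected += 1
            assert got == expected, f"trial {trial}"
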