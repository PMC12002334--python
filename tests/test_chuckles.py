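"""Monomer-level representation: assembly, masking, mutation, cyclization."""

import numpy as np
import pytest
from rdkit import Chem

from pepfill.building_blocks import NATURAL_CHUCKLES
from pepfill.chuckles import (
    ChucklesError,
    IneligibleResidueError,
    MalformedTopologyError,
    MaskedInputError,
    Peptide,
    Residue,
    Topology,
    TopologyConstraintError,
    annotate_cyclization,
    assemble_smiles,
    canonicalize,
    flip_stereo,
    is_valid,
    largest_ring_size,
    map_fillers,
    mask,
    n_methylate,
    parse_rho,
    try_assemble,
)

GLY = Residue("NCC(=O)")
ALA = Residue("N[C@@H](C)C(=O)")


def _peptide(residues, topology=Topology.LINEAR):
    return Peptide(residues=tuple(residues), topology=topology)


class TestAssemble:
    def test_triglycine_matches_reference_molecule(self):
        smi = assemble_smiles(_peptide([GLY] * 3))
        assert smi == "NCC(=O)NCC(=O)NCC(=O)O"
        # independent oracle: RDKit's peptide builder from sequence
        ref = Chem.MolToSmiles(Chem.MolFromSequence("GGG"))
        assert canonicalize(smi) == ref

    def test_single_glycine_completes_to_free_acid(self):
        assert assemble_smiles(_peptide([GLY])) == "NCC(=O)O"

    def test_cyclo_triglycine_ring_has_nine_atoms(self):
        residues = [Residue("N%10CC(=O)"), GLY, Residue("NCC%10(=O)")]
        smi = assemble_smiles(_peptide(residues, Topology.HEAD_TO_TAIL))
        mol = Chem.MolFromSmiles(smi)
        assert max(len(r) for r in mol.GetRingInfo().AtomRings()) == 9

    def test_unpaired_ring_label_is_malformed(self):
        residues = [Residue("N%10CC(=O)"), GLY]
        with pytest.raises(MalformedTopologyError):
            assemble_smiles(_peptide(residues, Topology.HEAD_TO_TAIL))

    def test_masked_input_rejected(self):
        with pytest.raises(MaskedInputError):
            assemble_smiles(_peptide([GLY, Residue("N?C(=O)")]))

    def test_try_assemble_returns_none_for_malformed(self):
        residues = [Residue("N%10CC(=O)"), GLY]
        assert try_assemble(_peptide(residues, Topology.HEAD_TO_TAIL)) is None


class TestMask:
    def test_positions_two_and_five_of_six_mer(self):
        p = _peptide([GLY, ALA, GLY, GLY, ALA, GLY])
        masked, target = mask(p, [1, 4])
        slots = masked.source.split("|")
        assert slots[1] == "?" and slots[4] == "?"
        assert target == f"{ALA.chuckles}|{ALA.chuckles}"

    def test_full_masking(self):
        p = _peptide([GLY] * 3)
        masked, target = mask(p, [0, 1, 2])
        assert masked.source == "?|?|?"
        assert target == p.rho

    def test_mask_head_position(self):
        p = _peptide([GLY, ALA])
        masked, target = mask(p, [0])
        assert masked.source == f"?|{ALA.chuckles}"
        assert target == GLY.chuckles

    def test_empty_and_out_of_range_positions(self):
        p = _peptide([GLY, ALA])
        with pytest.raises(ChucklesError):
            mask(p, [])
        with pytest.raises(IndexError):
            mask(p, [5])

    def test_unmask_is_identity(self):
        p = _peptide([GLY, ALA, GLY, ALA])
        masked, target = mask(p, [1, 3])
        outcome = map_fillers(masked, target.split("|"))
        assert not outcome.task_failure
        assert outcome.peptide.rho == p.rho


class TestMapFillers:
    def test_single_substitution(self):
        p = _peptide([GLY, ALA])
        masked, _ = mask(p, [0])
        outcome = map_fillers(masked, ["NCC(=O)"])
        assert outcome.peptide.rho == f"NCC(=O)|{ALA.chuckles}"

    def test_count_mismatch_is_task_failure_not_exception(self):
        p = _peptide([GLY, ALA, GLY])
        masked, _ = mask(p, [0, 2])
        outcome = map_fillers(masked, ["NCC(=O)", "NCC(=O)", "NCC(=O)"])
        assert outcome.task_failure
        assert outcome.peptide is None
        assert outcome.n_fillers == 3

    def test_round_trip_canonical_identity(self):
        p = _peptide([GLY, ALA, GLY, ALA, GLY, ALA])
        masked, target = mask(p, [1, 4])
        outcome = map_fillers(masked, target.split("|"))
        assert canonicalize(assemble_smiles(outcome.peptide)) == canonicalize(
            assemble_smiles(p)
        )


class TestNMethylate:
    @pytest.mark.parametrize(
        "before,after",
        [("NCC(=O)", "N(C)CC(=O)"), ("N[C@@H](C)C(=O)", "N(C)[C@@H](C)C(=O)")],
    )
    def test_methyl_lands_on_backbone_nitrogen(self, before, after):
        res = n_methylate(Residue(before))
        assert res.chuckles == after
        mol = Chem.MolFromSmiles(after + "O")
        n_atom = mol.GetAtomWithIdx(0)
        assert n_atom.GetSymbol() == "N"
        assert any(nb.GetSymbol() == "C" and nb.GetDegree() == 1
                   for nb in n_atom.GetNeighbors())

    def test_double_methylation_rejected(self):
        once = n_methylate(GLY)
        with pytest.raises(IneligibleResidueError):
            n_methylate(once)

    def test_proline_rejected(self):
        with pytest.raises(IneligibleResidueError):
            n_methylate(Residue(NATURAL_CHUCKLES["P"]))

    def test_heavy_atom_count_changes_by_one(self):
        for code in "GASV":
            res = Residue(NATURAL_CHUCKLES[code])
            before = Chem.MolFromSmiles(res.chuckles + "O").GetNumHeavyAtoms()
            after = Chem.MolFromSmiles(
                n_methylate(res).chuckles + "O"
            ).GetNumHeavyAtoms()
            assert after - before == 1


class TestFlipStereo:
    def test_alpha_inversion_keeps_constitution(self):
        res = flip_stereo(ALA)
        assert res.chuckles == "N[C@H](C)C(=O)"
        assert canonicalize(res.chuckles + "O", keep_stereo=True) != canonicalize(
            ALA.chuckles + "O", keep_stereo=True
        )
        assert canonicalize(res.chuckles + "O", keep_stereo=False) == canonicalize(
            ALA.chuckles + "O", keep_stereo=False
        )

    def test_involution(self):
        assert flip_stereo(flip_stereo(ALA)).chuckles == ALA.chuckles

    def test_glycine_has_no_stereocenter(self):
        with pytest.raises(IneligibleResidueError):
            flip_stereo(GLY)


class TestCyclization:
    def test_disulfide_bridges_the_sulfurs(self):
        cys = Residue(NATURAL_CHUCKLES["C"])
        p = _peptide([cys, ALA, ALA, ALA, ALA, cys])
        cyc = annotate_cyclization(p, Topology.DISULFIDE, (0, 5))
        smi = assemble_smiles(cyc)
        mol = Chem.MolFromSmiles(smi)
        assert mol.HasSubstructMatch(Chem.MolFromSmarts("[SX2]-[SX2]"))

    def test_head_to_tail_nine_alanines_ring27(self):
        p = _peptide([ALA] * 9)
        cyc = annotate_cyclization(p, Topology.HEAD_TO_TAIL)
        assert largest_ring_size(assemble_smiles(cyc)) == 27

    def test_sidechain_to_tail_short_span_rejected(self):
        lys = Residue(NATURAL_CHUCKLES["K"])
        p = _peptide([ALA, ALA, ALA, ALA, ALA, lys, ALA, ALA])
        with pytest.raises(TopologyConstraintError):
            annotate_cyclization(p, Topology.SIDECHAIN_TO_TAIL, (5, 7))

    def test_sidechain_to_tail_forms_lactam(self):
        lys = Residue(NATURAL_CHUCKLES["K"])
        p = _peptide([lys, ALA, ALA, ALA, ALA, ALA])
        cyc = annotate_cyclization(p, Topology.SIDECHAIN_TO_TAIL, (0, 5))
        smi = assemble_smiles(cyc)
        assert is_valid(smi)
        assert largest_ring_size(smi) >= 12

    def test_missing_functional_group_rejected(self):
        p = _peptide([ALA] * 6)
        with pytest.raises(IneligibleResidueError):
            annotate_cyclization(p, Topology.DISULFIDE, (0, 5))


class TestValidityAndCanonical:
    @pytest.mark.parametrize(
        "smiles,expected",
        [("NCC(=O)O", True), ("NCC(=O", False), ("N%10CC(=O)NCC(=O)O", False)],
    )
    def test_is_valid(self, smiles, expected):
        assert is_valid(smiles) is expected

    def test_canonicalize_same_molecule_different_order(self):
        assert canonicalize("OC(=O)CN") == canonicalize("NCC(=O)O")

    def test_stereoisomers_distinct_until_stereo_stripped(self):
        d = "N[C@H](C)C(=O)O"
        l = "N[C@@H](C)C(=O)O"
        assert canonicalize(d, True) != canonicalize(l, True)
        assert canonicalize(d, False) == canonicalize(l, False)


class TestRingAtomLaw:
    @pytest.mark.parametrize("L", range(5, 13))
    def test_head_to_tail_ring_is_three_L(self, L):
        p = _peptide([ALA] * L)
        cyc = annotate_cyclization(p, Topology.HEAD_TO_TAIL)
        assert largest_ring_size(assemble_smiles(cyc)) == 3 * L


class TestRoundTripProperty:
    def test_mask_fill_assemble_identity_on_generated_peptides(
        self, dataset_small, rng
    ):
        for p in dataset_small.peptides[:100]:
            k = rng.integers(1, len(p))
            positions = sorted(
                rng.choice(len(p), size=k, replace=False).tolist()
            )
            masked, target = mask(p, positions)
            outcome = map_fillers(masked, target.split("|"))
            assert canonicalize(assemble_smiles(outcome.peptide)) == canonicalize(
                assemble_smiles(p)
            )

    def test_generated_dataset_assembles_valid(self, dataset_small):
        bad = [
            p.rho
            for p in dataset_small.peptides
            if not is_valid(assemble_smiles(p))
        ]
        assert not bad


def test_parse_rho_round_trip(dataset_small):
    for p in dataset_small.peptides[:20]:
        again = parse_rho(p.rho, p.topology)
        assert again.rho == p.rho
        assert assemble_smiles(again) == assemble_smiles(p)
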