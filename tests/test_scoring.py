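"""Score transforms, components, aggregation, diversity filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepfill.building_blocks import NATURAL_CHUCKLES
from pepfill.chuckles import (
    Peptide,
    Residue,
    Topology,
    annotate_cyclization,
    assemble_smiles,
)
from pepfill.scoring import (
    DEFAULT_ALERT_SMARTS,
    DiversityFilter,
    ScoreTransform,
    ScoringComponent,
    ScoringFunction,
    TransformShape,
    aggregate,
    largest_ring_size,
    make_custom_alerts,
    murcko_scaffold,
    permeability_surrogate,
    solubility_surrogate,
    transform,
)

ALA = Residue(NATURAL_CHUCKLES["A"])


def _cyclo_ala9() -> str:
    p = annotate_cyclization(
        Peptide(residues=(ALA,) * 9), Topology.HEAD_TO_TAIL
    )
    return assemble_smiles(p)


class TestLargestRing:
    def test_cyclo_ala9_is_27(self):
        assert largest_ring_size(_cyclo_ala9()) == 27

    def test_linear_triglycine_acyclic(self):
        assert largest_ring_size("NCC(=O)NCC(=O)NCC(=O)O") == 0

    def test_phenylalanine_sidechain_ring(self):
        phe = Residue(NATURAL_CHUCKLES["F"])
        smi = assemble_smiles(Peptide(residues=(ALA, phe, ALA)))
        assert largest_ring_size(smi) == 6

    def test_invalid_smiles_scores_zero(self):
        assert largest_ring_size("NCC(=O") == 0


class TestTransforms:
    def test_sigmoid_midpoint(self):
        t = ScoreTransform(TransformShape.SIGMOID, 0, 60)
        assert t(30) == pytest.approx(0.5)

    def test_reverse_sigmoid_midpoint_and_limit(self):
        t = ScoreTransform(TransformShape.REVERSE_SIGMOID, 0, 60)
        assert t(30) == pytest.approx(0.5)
        assert t(0) > 0.99

    def test_double_sigmoid_window(self):
        t = ScoreTransform(TransformShape.DOUBLE_SIGMOID, 0, 30)
        assert t(21) >= 0.9
        assert t(45) <= 0.1

    def test_macrocycle_floor_ordering(self):
        t = ScoreTransform(TransformShape.DOUBLE_SIGMOID, 0, 30)
        assert t(11) < t(12)

    def test_monotonicity_on_grid(self):
        grid = np.linspace(-10, 80, 200)
        sig = ScoreTransform(TransformShape.SIGMOID, 0, 60)
        rev = ScoreTransform(TransformShape.REVERSE_SIGMOID, 0, 60)
        sig_vals = [sig(v) for v in grid]
        rev_vals = [rev(v) for v in grid]
        assert all(b >= a for a, b in zip(sig_vals, sig_vals[1:]))
        assert all(b <= a for a, b in zip(rev_vals, rev_vals[1:]))
        assert all(0 <= v <= 1 for v in sig_vals + rev_vals)

    @settings(max_examples=150, derandomize=True)
    @given(
        shape=st.sampled_from(list(TransformShape)),
        low=st.floats(-50, 49),
        width=st.floats(0.5, 100),
        value=st.floats(-200, 200),
    )
    def test_output_always_in_unit_interval(self, shape, low, width, value):
        t = ScoreTransform(shape, low, low + width)
        assert 0.0 <= t(value) <= 1.0

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            ScoreTransform(TransformShape.SIGMOID, 10, 10)

    def test_transform_function_alias(self):
        t = ScoreTransform(TransformShape.SIGMOID, 0, 60)
        assert transform(30, t) == t(30)


class TestCustomAlerts:
    def test_acyl_halide_fires(self):
        score = make_custom_alerts(["[CX3](=O)[F,Cl,Br,I]"])
        assert score("CC(=O)Cl") == 0.0
        assert score("CC(=O)N") == 1.0

    def test_empty_pattern_list_always_passes(self):
        score = make_custom_alerts([])
        assert score("CC(=O)Cl") == 1.0

    def test_match_is_substructure_not_string(self):
        # same alert written with different atom order in the molecule
        score = make_custom_alerts(["[N+](=O)[O-]"])
        assert score("c1ccccc1[N+](=O)[O-]") == 0.0
        assert score("O=[N+]([O-])c1ccccc1") == 0.0

    def test_bad_pattern_rejected(self):
        with pytest.raises(ValueError):
            make_custom_alerts(["[[["])


class TestAggregate:
    def test_geometric_mean_simple(self):
        assert aggregate([0.5, 0.5], [1, 1]) == pytest.approx(0.5)

    def test_geometric_mean_zeroes(self):
        assert aggregate([0.9, 0.0], [1, 1]) == 0.0

    def test_weighted_average(self):
        assert aggregate([1.0, 0.0], [3, 1], "weighted_average") == pytest.approx(0.75)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            aggregate([0.5], [0.0])


class TestDiversityFilter:
    def test_first_members_pass_then_bucket_closes(self):
        f = DiversityFilter(threshold=0.4, bucket_size=2)
        smi = _cyclo_ala9()
        assert f(smi, 0.8) == 0.8
        assert f(smi, 0.8) == 0.8
        assert f(smi, 0.8) == 0.0  # bucket full

    def test_low_scores_bypass_memory(self):
        f = DiversityFilter(threshold=0.4, bucket_size=1)
        smi = _cyclo_ala9()
        for _ in range(5):
            assert f(smi, 0.1) == 0.1
        assert f(smi, 0.9) == 0.9  # first high score still passes

    def test_halogen_variants_share_scaffold(self):
        a = "Fc1ccc(CCN)cc1"
        b = "Clc1ccc(CCN)cc1"
        assert murcko_scaffold(a) == murcko_scaffold(b)
        f = DiversityFilter(threshold=0.0, bucket_size=1)
        assert f(a, 0.9) == 0.9
        assert f(b, 0.9) == 0.0


class TestSurrogatesAndFunction:
    def test_permeability_in_unit_interval(self):
        for smi in [_cyclo_ala9(), "NCC(=O)O", "CCCCCCCCCCCC"]:
            assert 0.0 <= permeability_surrogate(smi) <= 1.0

    def test_solubility_transform_midpoint(self):
        t = ScoreTransform(TransformShape.SIGMOID, 0.0, 0.5, k=10.0)
        assert t(0.25) == pytest.approx(0.5)

    def test_hydrophilic_beats_greasy(self):
        assert solubility_surrogate("NCC(=O)NCC(=O)O") > solubility_surrogate(
            "CCCCCCCCCCCCCCCC"
        )

    def test_constant_scorer_plumbs_through(self):
        fn = ScoringFunction(
            components=[ScoringComponent(name="const", scorer=lambda s: 0.7)]
        )
        score, detail = fn("NCC(=O)O")
        assert score == pytest.approx(0.7)
        assert detail["const"] == (0.7, 0.7)

    def test_invalid_molecule_scores_zero(self):
        fn = ScoringFunction(
            components=[ScoringComponent(name="const", scorer=lambda s: 0.7)]
        )
        assert fn(None)[0] == 0.0
        assert fn("NCC(=O")[0] == 0.0

    def test_scorer_exception_scores_zero(self):
        def broken(s):
            raise RuntimeError("boom")

        comp = ScoringComponent(name="broken", scorer=broken)
        raw, t = comp("NCC(=O)O")
        assert t == 0.0

    def test_ring_objective_ranks_cyclic_over_linear(self):
        maximize = ScoreTransform(TransformShape.SIGMOID, 0, 60)
        minimize = ScoreTransform(TransformShape.REVERSE_SIGMOID, 0, 60)
        cyc = largest_ring_size(_cyclo_ala9())
        lin = largest_ring_size(
            assemble_smiles(Peptide(residues=(ALA,) * 9))
        )
        assert maximize(cyc) > maximize(lin)
        assert minimize(cyc) < minimize(lin)

    def test_default_alerts_catch_reactive_peptide(self):
        score = make_custom_alerts(DEFAULT_ALERT_SMARTS)
        assert score("NCC(=O)Cl") == 0.0
        assert score(_cyclo_ala9()) == 1.0
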