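"""Corpus generation: distributions, quotas, stratified splits, pairs."""

import re
from collections import Counter

import numpy as np
import pytest

from pepfill.building_blocks import monomer_key
from pepfill.chuckles import (
    Topology,
    assemble_smiles,
    canonicalize,
    has_sidechain_primary_amine,
    has_sulfhydryl,
    is_valid,
    map_fillers,
)
from pepfill.datagen import (
    Dataset,
    GenConfig,
    build_eval_sets,
    build_dataset,
    compose_peptide,
    make_pair,
    make_pairs,
    read_pairs,
    sample_length,
    sample_skewed_fraction,
    write_pairs,
)


class TestSampling:
    def test_lengths_stay_in_range_with_mode_near_mean(self, rng):
        cfg = GenConfig(n_peptides=1)
        draws = [sample_length(cfg, rng) for _ in range(10_000)]
        assert min(draws) >= 6 and max(draws) <= 18
        mode = Counter(draws).most_common(1)[0][0]
        assert 11 <= mode <= 13

    def test_length_sequence_reproducible(self):
        cfg = GenConfig(n_peptides=1)
        a = [sample_length(cfg, np.random.default_rng(3)) for _ in range(50)]
        b = [sample_length(cfg, np.random.default_rng(3)) for _ in range(50)]
        assert a == b

    def test_nnaa_fraction_left_skewed_on_its_range(self, rng):
        draws = [
            sample_skewed_fraction((0.0, 0.3), rng, (5.0, 2.0))
            for _ in range(10_000)
        ]
        assert 0.0 <= min(draws) and max(draws) <= 0.3
        assert np.mean(draws) > 0.15  # mass near the upper bound

    def test_natural_mask_fraction_mean_is_point_three(self, rng):
        draws = [
            sample_skewed_fraction((0.0, 0.5), rng, (3.0, 2.0))
            for _ in range(100_000)
        ]
        assert abs(np.mean(draws) - 0.30) < 0.01

    def test_degenerate_range(self, rng):
        assert sample_skewed_fraction((0.0, 0.0), rng) == 0.0


class TestComposePeptide:
    def test_disulfide_has_two_sulfhydryl_residues(self, library, rng):
        cfg = GenConfig(n_peptides=1, seed=0)
        p = compose_peptide(cfg, Topology.DISULFIDE, library, rng)
        anchored = [r for r in p.residues if r.peptide_ring_labels()]
        assert len(anchored) == 2

    def test_sidechain_to_tail_span_at_least_five(self, library, rng):
        cfg = GenConfig(n_peptides=1, seed=0)
        for _ in range(5):
            p = compose_peptide(cfg, Topology.SIDECHAIN_TO_TAIL, library, rng)
            start = next(
                i for i, r in enumerate(p.residues) if r.peptide_ring_labels()
            )
            assert len(p) - start >= 5

    def test_nnaa_fraction_bounded(self, library, rng):
        """NNAA content applies to the drawn building blocks, before the
        stereo/N-methyl mutations, so undo those via the residue flags."""
        natural_keys = {
            monomer_key(r.chuckles, keep_stereo=False) for r in library.natural
        }

        def drawn_from_nnaa_pool(r):
            chk = r.chuckles
            if r.n_methylated:
                chk = chk.replace("N(C)", "N", 1)
            return monomer_key(chk, keep_stereo=False) not in natural_keys

        cfg = GenConfig(n_peptides=1, seed=0)
        for _ in range(10):
            p = compose_peptide(cfg, Topology.LINEAR, library, rng)
            n_nnaa = sum(1 for r in p.residues if drawn_from_nnaa_pool(r))
            assert n_nnaa / len(p) <= 0.3 + 1.0 / len(p)


class TestBuildDataset:
    def test_quota_and_split_exact(self, dataset_small):
        topo_counts = Counter(p.topology for p in dataset_small.peptides)
        assert topo_counts[Topology.LINEAR] == 160
        assert all(
            topo_counts[t] == 80
            for t in (
                Topology.HEAD_TO_TAIL,
                Topology.SIDECHAIN_TO_TAIL,
                Topology.DISULFIDE,
            )
        )
        split_counts = Counter(dataset_small.split_labels)
        assert split_counts == {"train": 360, "validation": 20, "test": 20}

    def test_unique_at_canonical_level(self, dataset_small):
        keys = {canonicalize(assemble_smiles(p)) for p in dataset_small.peptides}
        assert len(keys) == len(dataset_small.peptides)

    def test_split_preserves_length_distribution(self, dataset_small):
        """Per-split length histograms stay within 2 points of the global one
        for well-filled bins (stratification)."""
        all_lengths = np.array([len(p) for p in dataset_small.peptides])
        train_lengths = np.array(
            [
                len(p)
                for p, s in zip(
                    dataset_small.peptides, dataset_small.split_labels
                )
                if s == "train"
            ]
        )
        for L in range(6, 19):
            share_all = np.mean(all_lengths == L)
            share_train = np.mean(train_lengths == L)
            assert abs(share_all - share_train) <= 0.02

    def test_determinism(self, library, gen_config):
        a = build_dataset(gen_config, library)
        b = build_dataset(gen_config, library)
        assert [p.rho for p in a.peptides] == [p.rho for p in b.peptides]
        assert a.split_labels == b.split_labels

    def test_tsv_round_trip(self, dataset_small, tmp_path):
        path = tmp_path / "ds.tsv"
        dataset_small.to_tsv(path)
        again = Dataset.from_tsv(path)
        assert [p.rho for p in again.peptides] == [
            p.rho for p in dataset_small.peptides
        ]
        assert again.split_labels == dataset_small.split_labels


class TestPairs:
    def test_source_target_recombine_to_parent(
        self, dataset_small, library, gen_config, rng
    ):
        for p in dataset_small.peptides[:50]:
            pair = make_pair(p, library, gen_config, rng)
            masked_positions = tuple(
                i for i, s in enumerate(pair.source.split("|")) if s == "?"
            )
            assert len(masked_positions) == pair.n_masked >= 1
            rebuilt = pair.source.split("|")
            fillers = iter(pair.target.split("|"))
            rho = "|".join(
                next(fillers) if s == "?" else s for s in rebuilt
            )
            assert rho == p.rho

    def test_mean_masked_fraction_near_thirty_percent(
        self, dataset_small, library, gen_config, rng
    ):
        pairs = make_pairs(
            dataset_small.peptides, library, gen_config, rng,
            pairs_per_peptide=3,
        )
        fracs = [
            p.n_masked / len(p.source.split("|")) for p in pairs
        ]
        assert abs(np.mean(fracs) - 0.30) < 0.02

    def test_pairs_tsv_round_trip(
        self, dataset_small, library, gen_config, rng, tmp_path
    ):
        pairs = make_pairs(
            dataset_small.peptides[:20], library, gen_config, rng
        )
        path = tmp_path / "pairs.tsv"
        write_pairs(pairs, path)
        again = read_pairs(path)
        assert [(p.source, p.target, p.n_masked) for p in again] == [
            (p.source, p.target, p.n_masked) for p in pairs
        ]


class TestEvalSets:
    def test_sets_scale_down_preserving_structure(
        self, dataset_small, library, gen_config
    ):
        rng = np.random.default_rng(9)
        model_eval, topology_eval = build_eval_sets(
            dataset_small, library, gen_config, rng
        )
        assert len(model_eval) > 0 and len(topology_eval) > 0
        assert len(topology_eval) <= len(model_eval)

    def test_topology_eval_sources_leave_one_label_open(
        self, dataset_small, library, gen_config
    ):
        rng = np.random.default_rng(9)
        _, topology_eval = build_eval_sets(
            dataset_small, library, gen_config, rng
        )
        for masked in topology_eval:
            labels = re.findall(r"%\d{2}", masked.source)
            if masked.topology == Topology.LINEAR:
                assert len(labels) == 0
            else:
                assert len(labels) == 1  # the other anchor is masked
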