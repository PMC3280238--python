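"""Generators: determinism, planted invariants, round trips."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from natx import synthdata
from natx.synthdata import OUTGROUP_LABEL


class TestSimulateFamilyTree:
    def test_leaf_count_2x3(self):
        t = synthdata.simulate_family_tree(2, 3, seed=1)
        assert len(t.leaves()) == 7  # 6 ingroup + outgroup

    def test_leaf_count_14x4(self):
        t = synthdata.simulate_family_tree(14, 4, seed=7)
        assert len(t.leaves()) == 57

    def test_deterministic(self):
        a = synthdata.simulate_family_tree(3, 3, seed=1).newick()
        b = synthdata.simulate_family_tree(3, 3, seed=1).newick()
        assert a == b

    def test_different_seed_differs(self):
        a = synthdata.simulate_family_tree(3, 3, seed=1).newick()
        b = synthdata.simulate_family_tree(3, 3, seed=2).newick()
        assert a != b

    def test_planted_clades_are_monophyletic(self):
        t = synthdata.simulate_family_tree(4, 3, seed=3)
        clades = {frozenset(l.label for l in n.leaves())
                  for n in t.postorder() if not n.is_leaf}
        for i in range(1, 5):
            planted = frozenset(l for l in t.leaf_names()
                                if l.startswith(f"SF{i:02d}_"))
            assert planted in clades

    def test_positive_branch_lengths(self):
        t = synthdata.simulate_family_tree(3, 2, seed=5)
        for n in t.postorder():
            if n.parent is not None:
                assert n.length is None or n.length > 0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            synthdata.simulate_family_tree(1, 3, seed=0)
        with pytest.raises(ValueError):
            synthdata.simulate_family_tree(3, 0, seed=0)


class TestEvolve:
    def test_zero_rate_all_identical(self):
        t = synthdata.simulate_family_tree(2, 3, seed=1)
        seqs = synthdata.evolve_mature_peptides(t, sub_rate=0.0, seed=2)
        assert len(set(seqs.values())) == 1

    def test_exact_cysteine_count(self):
        t = synthdata.simulate_family_tree(3, 3, seed=1)
        seqs = synthdata.evolve_mature_peptides(t, n_cys=8, sub_rate=0.4, seed=2)
        for s in seqs.values():
            assert s.count("C") == 8

    def test_cysteine_columns_invariant(self):
        t = synthdata.simulate_family_tree(3, 3, seed=1)
        seqs = synthdata.evolve_mature_peptides(t, n_cys=6, sub_rate=0.5, seed=3)
        positions = {tuple(i for i, c in enumerate(s) if c == "C")
                     for s in seqs.values()}
        assert len(positions) == 1

    def test_within_exceeds_between_identity(self):
        t = synthdata.simulate_family_tree(2, 4, seed=4)
        seqs = synthdata.evolve_mature_peptides(t, sub_rate=0.3, seed=4)
        ingroup = {k: v for k, v in seqs.items() if k != OUTGROUP_LABEL}

        def ident(a, b):  # equal-length planted sequences: direct comparison
            return sum(x == y for x, y in zip(a, b)) / len(a)

        within, between = [], []
        for a, b in itertools.combinations(sorted(ingroup), 2):
            pair_ident = ident(ingroup[a], ingroup[b])
            if a.split("_")[0] == b.split("_")[0]:
                within.append(pair_ident)
            else:
                between.append(pair_ident)
        assert np.mean(within) > np.mean(between)

    def test_odd_cys_rejected(self):
        t = synthdata.simulate_family_tree(2, 2, seed=1)
        with pytest.raises(ValueError):
            synthdata.evolve_mature_peptides(t, n_cys=7, seed=0)

    def test_scaffold_len_bounds(self):
        t = synthdata.simulate_family_tree(2, 2, seed=1)
        with pytest.raises(ValueError):
            synthdata.evolve_mature_peptides(t, scaffold_len=40, seed=0)


class TestBuildPrecursor:
    MATURE = "KKDGYPVEYDNCAYICWNYDNAYCDKLCKDKKADSGYCYWVHILCYCYGLPDSEPTKTNGKCKS"

    def test_gkk_motif(self):
        rec = synthdata.build_precursor(self.MATURE, 20, "GKK", seed=1)
        assert rec.protein.endswith(self.MATURE + "GKK")
        assert rec.amidated

    def test_empty_motif_not_amidated(self):
        rec = synthdata.build_precursor(self.MATURE, 20, "", seed=1)
        assert not rec.amidated
        assert rec.cterm_pro is None

    def test_cds_roundtrip(self):
        rec = synthdata.build_precursor(self.MATURE, 19, "GKRK", seed=2)
        translated = str(Seq(rec.cds).translate(to_stop=True))
        assert translated == rec.protein

    def test_bad_motif(self):
        with pytest.raises(ValueError):
            synthdata.build_precursor(self.MATURE, 20, "GRRK", seed=1)

    def test_bad_signal_len(self):
        with pytest.raises(ValueError):
            synthdata.build_precursor(self.MATURE, 25, "GK", seed=1)

    def test_signal_interval(self):
        rec = synthdata.build_precursor(self.MATURE, 21, "GK", seed=3)
        assert rec.signal == (1, 21)
        assert rec.mature_seq == self.MATURE


def _random_protein(n, seed):
    import random
    rng = random.Random(seed)
    return "M" + "".join(rng.choice("ADEFGHIKLMNPQRSTVWY") for _ in range(n))


class TestFragment:
    CDS = synthdata.reverse_translate(_random_protein(76, 13))

    def test_exact_substrings_no_errors(self):
        reads = synthdata.fragment_to_ests(self.CDS, 8, 100, 0.0, seed=1)
        for r in reads:
            assert r.seq in self.CDS

    def test_zero_reads(self):
        assert synthdata.fragment_to_ests(self.CDS, 0, 100, 0.0, seed=1) == []

    def test_deterministic(self):
        a = synthdata.fragment_to_ests(self.CDS, 5, 100, 0.01, seed=9)
        b = synthdata.fragment_to_ests(self.CDS, 5, 100, 0.01, seed=9)
        assert [(r.id, r.seq, r.qual) for r in a] == [(r.id, r.seq, r.qual) for r in b]

    def test_error_rate_bounds(self):
        with pytest.raises(ValueError):
            synthdata.fragment_to_ests(self.CDS, 5, 100, 1.5, seed=1)

    def test_vector_prefix(self, vector):
        reads = synthdata.fragment_to_ests(self.CDS, 30, 120, 0.0,
                                           vector=vector, seed=4,
                                           vector_fraction=1.0)
        for r in reads:
            assert r.seq.startswith(vector[:50])

    def test_coverage_at_2x(self):
        # n_reads * read_len >= 2 * len(cds) must give contiguous coverage
        reads = synthdata.fragment_to_ests(self.CDS, 6, 100, 0.0, seed=5)
        covered = np.zeros(len(self.CDS), dtype=bool)
        for r in reads:
            start = self.CDS.index(r.seq)
            covered[start:start + len(r.seq)] = True
        assert covered.all()

    def test_quality_lengths(self):
        reads = synthdata.fragment_to_ests(self.CDS, 5, 100, 0.0, seed=6)
        for r in reads:
            assert len(r.qual) == len(r.seq)
            assert all(0 <= q <= 41 for q in r.qual)


class TestTruthBundle:
    def test_partition_and_indices(self, small_truth):
        subfams = sorted(set(small_truth.true_subfamily_of.values()))
        assert subfams == [1, 2, 3]
        tree_leaves = set(small_truth.true_tree.leaf_names()) - {OUTGROUP_LABEL}
        assert tree_leaves == set(small_truth.true_subfamily_of)

    def test_reproducible(self):
        a = synthdata.generate_truth_bundle(seed=5)
        b = synthdata.generate_truth_bundle(seed=5)
        assert a.true_tree.newick() == b.true_tree.newick()
        assert a.matures == b.matures
        assert [p.cds for p in a.true_precursors] == [p.cds for p in b.true_precursors]

    def test_amidation_flags_match_motifs(self, small_truth):
        for p in small_truth.true_precursors:
            assert p.amidated == bool(small_truth.motifs[p.id])
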