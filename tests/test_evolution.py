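import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camtakit import evolution as ev
from camtakit.models import GeneModel, ProteinRecord, ValidationError
from camtakit.synthetic import evolve_codon_pair, gen_additive_tree
from conftest import random_codon_pairs
from oracles import alignment_score_oracle, ng86_oracle


# ---------------------------------------------------------------------------
# global alignment
# ---------------------------------------------------------------------------

class TestAlignGlobal:
    def test_self_alignment(self):
        p = ProteinRecord("a", "MKVLWAALLV")
        aln = ev.align_global(p, p)
        assert aln.identity_pct == 100.0
        assert aln.coverage_pct == 100.0

    def test_score_matches_enumeration_oracle(self, rng):
        aas = list("ARNDCQEGHILKMFPSTWYV")
        for _ in range(15):
            a = "".join(rng.choice(aas, size=int(rng.integers(2, 6))))
            b = "".join(rng.choice(aas, size=int(rng.integers(2, 6))))
            aln = ev.align_global(ProteinRecord("a", a), ProteinRecord("b", b))
            expected = alignment_score_oracle(a, b, ev.BLOSUM62)
            assert aln.score == pytest.approx(expected)

    def test_coverage_definition(self):
        aln = ev.align_global(ProteinRecord("a", "AAAA"), ProteinRecord("b", "AAAAAAAA"))
        assert aln.coverage_pct == pytest.approx(50.0)

    def test_bad_symbols_rejected(self):
        with pytest.raises(ValidationError):
            ev.align_global(ProteinRecord("a", "AXA"), ProteinRecord("b", "AAA"))


class TestDetectParalogs:
    def test_identical_pair_accepted(self):
        p1 = ProteinRecord("a", "MKVLWAALLVTFLAGCQA" * 4)
        p2 = ProteinRecord("b", p1.sequence)
        assert len(ev.detect_paralogs([p1, p2])) == 1

    def test_dissimilar_pair_rejected(self):
        # swap ~45% of residues to chemically dissimilar ones -> 60% similarity
        base = "MKVLWAALLVTFLAGCQAKVEQAVETEPEPELRQQTEWQSGQRWELALGRFWDYLRWVQT"
        swap = {"A": "D", "L": "D", "V": "D", "W": "P", "K": "E", "E": "K"}
        mutated = "".join(swap.get(c, c) for c in base)
        aln = ev.align_global(ProteinRecord("a", base), ProteinRecord("b", mutated))
        assert aln.similarity_pct == pytest.approx(60.0)
        pairs = ev.detect_paralogs(
            [ProteinRecord("a", base), ProteinRecord("b", mutated)]
        )
        assert pairs == []

    def test_boundary_is_strict(self):
        assert not ev.passes_paralog_rule(70.0, 90.0)
        assert not ev.passes_paralog_rule(90.0, 70.0)
        assert ev.passes_paralog_rule(70.01, 70.01)

    def test_needs_two_proteins(self):
        with pytest.raises(ValidationError):
            ev.detect_paralogs([ProteinRecord("a", "MKVL")])


class TestRbhOrthologs:
    def test_single_members_pair(self):
        pairs, ties = ev.rbh_orthologs(
            [ProteinRecord("a", "MKVLWAALLV")], [ProteinRecord("b", "MKVLWAALIV")]
        )
        assert pairs == [("a", "b")] and ties == []

    def test_tie_yields_no_pair(self):
        a = [ProteinRecord("a", "MKVLWAALLV")]
        b = [ProteinRecord("b1", "MKVLWAALLV"), ProteinRecord("b2", "MKVLWAALLV")]
        pairs, ties = ev.rbh_orthologs(a, b)
        assert pairs == [] and ties

    def test_planted_orthology_recovered(self):
        rng = np.random.default_rng(5)
        from camtakit.synthetic import _AA_LIST, back_translate

        pairs_true = []
        set_a, set_b = [], []
        for i in range(4):
            prot = "".join(rng.choice(_AA_LIST, size=60))
            cds = back_translate(prot, rng)
            ev_pair = evolve_codon_pair(cds, 0.02, 0.2, seed=100 + i)
            set_a.append(ProteinRecord(f"a{i}", ev.translate_cds(ev_pair.seq_a)))
            set_b.append(ProteinRecord(f"b{i}", ev.translate_cds(ev_pair.seq_b)))
            pairs_true.append((f"a{i}", f"b{i}"))
        pairs, _ = ev.rbh_orthologs(set_a, set_b)
        assert sorted(pairs) == pairs_true


# ---------------------------------------------------------------------------
# duplication typing
# ---------------------------------------------------------------------------

class TestClassifyDuplication:
    def _models(self):
        return [
            GeneModel(id="g1", chromosome="chr5", strand="+", start=1000, end=5000),
            GeneModel(id="g2", chromosome="chr13", strand="+", start=1000, end=5000),
            GeneModel(id="g3", chromosome="chr5", strand="+", start=25_000, end=30_000),
            GeneModel(id="g4", chromosome="chr5", strand="+", start=505_000, end=510_000),
        ]

    def test_different_chromosomes_segmental(self):
        call = ev.classify_duplication(("g1", "g2"), self._models())
        assert call.dup_type == "segmental" and not call.same_chromosome

    def test_nearby_same_chromosome_tandem(self):
        call = ev.classify_duplication(("g1", "g3"), self._models())
        assert call.dup_type == "tandem" and call.genomic_distance == 20_000

    def test_distant_same_chromosome_segmental(self):
        call = ev.classify_duplication(("g1", "g4"), self._models())
        assert call.dup_type == "segmental" and call.same_chromosome

    def test_missing_gene_errors(self):
        with pytest.raises(ValidationError, match="missing"):
            ev.classify_duplication(("g1", "nope"), self._models())


# ---------------------------------------------------------------------------
# back-translation
# ---------------------------------------------------------------------------

class TestBacktranslate:
    def test_gapless(self):
        aln = ev.PairwiseAlignment("a", "b", "MK", "MK", 0, 100, 100, 100)
        codons = ev.backtranslate_alignment(aln, "ATGAAA", "ATGAAG")
        assert codons == [("ATG", "ATG"), ("AAA", "AAG")]

    def test_single_gap_drops_codon(self):
        aln = ev.PairwiseAlignment("a", "b", "M-K", "MFK", 0, 100, 100, 100)
        codons = ev.backtranslate_alignment(aln, "ATGAAA", "ATGTTTAAG")
        assert codons == [("ATG", "ATG"), ("AAA", "AAG")]

    def test_translation_mismatch_names_codon(self):
        aln = ev.PairwiseAlignment("a", "b", "MK", "MK", 0, 100, 100, 100)
        with pytest.raises(ValidationError, match="codon 2"):
            ev.backtranslate_alignment(aln, "ATGGGG", "ATGAAG")


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

class TestNeiGojobori:
    def test_identical_sequences(self):
        res = ev.nei_gojobori([("ATG", "ATG"), ("AAA", "AAA")])
        assert res.ka == 0.0 and res.ks == 0.0

    def test_worked_example(self):
        res = ev.nei_gojobori([("TTT", "TTC"), ("GGG", "GGG"), ("AAA", "AAA")])
        assert res.S == pytest.approx(5 / 3)
        assert res.Sd == pytest.approx(1.0)
        assert res.ps == pytest.approx(0.6)
        assert res.ks == pytest.approx(-0.75 * np.log(0.2))
        assert res.ka == 0.0

    def test_stop_codon_rejected(self):
        with pytest.raises(ValidationError, match="stop"):
            ev.nei_gojobori([("TAA", "ATG")])

    def test_matches_oracle_on_random_pairs(self, rng):
        for _ in range(60):
            pairs = random_codon_pairs(rng, 10)
            res = ev.nei_gojobori(pairs)
            exp = ng86_oracle(pairs)
            for key in ("N", "S", "Nd", "Sd"):
                assert getattr(res, key) == pytest.approx(exp[key], abs=1e-9)
            for key, prop in (("ka", "pn"), ("ks", "ps")):
                got, want = getattr(res, key), exp[key]
                if want is None and got is None:
                    continue
                if want is None or got is None:
                    assert abs(getattr(res, prop) - 0.75) < 1e-9
                else:
                    assert got == pytest.approx(want, rel=1e-6, abs=1e-9)

    def test_site_conservation(self, rng):
        for _ in range(30):
            pairs = random_codon_pairs(rng, int(rng.integers(1, 30)))
            res = ev.nei_gojobori(pairs)
            assert res.N + res.S == pytest.approx(3 * len(pairs), abs=1e-9)

    def test_parameter_recovery_smoke(self):
        # small-scale version of the 30-kb recovery acceptance criterion
        rng = np.random.default_rng(2)
        from camtakit.synthetic import _AA_LIST, back_translate

        prot = "".join(rng.choice(_AA_LIST, size=2000))
        anc = back_translate(prot, rng)
        kas, kss = [], []
        for seed in range(5):
            pair = evolve_codon_pair(anc, 0.1, 0.4, seed)
            aln = list(zip(
                (pair.seq_a[i:i + 3] for i in range(0, len(anc), 3)),
                (pair.seq_b[i:i + 3] for i in range(0, len(anc), 3)),
            ))
            res = ev.nei_gojobori(aln)
            kas.append(res.ka)
            kss.append(res.ks)
        assert np.mean(kas) == pytest.approx(0.1, rel=0.15)
        assert np.mean(kss) == pytest.approx(0.4, rel=0.15)


class TestRatioAndSelection:
    def test_printed_pair_ga5(self):
        ratio, label = ev.kaks_ratio_and_selection(0.1456, 0.4511)
        assert ratio == pytest.approx(0.3228, abs=0.005)
        assert label == "purifying"

    def test_neutral_band(self):
        ratio, label = ev.kaks_ratio_and_selection(0.2, 0.2)
        assert ratio == 1.0 and label == "neutral"

    def test_printed_pair_gr5(self):
        ratio, _ = ev.kaks_ratio_and_selection(0.1472, 0.4030)
        assert ratio == pytest.approx(0.3653, abs=0.005)

    def test_zero_ks_undefined(self):
        ratio, label = ev.kaks_ratio_and_selection(0.1, 0.0)
        assert ratio is None and label == "undefined"


class TestDateDuplication:
    def test_printed_example(self):
        assert ev.date_duplication(0.3907) == pytest.approx(13.02, abs=0.005)

    def test_zero(self):
        assert ev.date_duplication(0.0) == 0.0

    def test_second_printed_example(self):
        assert ev.date_duplication(0.4104) == pytest.approx(13.68, abs=0.005)

    def test_negative_lambda_errors(self):
        with pytest.raises(ValidationError):
            ev.date_duplication(0.4, lambda_rate=0.0)

    @given(ks=st.floats(0, 5), scale=st.floats(0.5, 4))
    @settings(max_examples=50, deadline=None)
    def test_linear_in_ks_inverse_in_lambda(self, ks, scale):
        base = ev.date_duplication(ks)
        assert ev.date_duplication(ks * scale) == pytest.approx(base * scale, rel=1e-9)
        assert ev.date_duplication(ks, ev.DEFAULT_CLOCK_RATE * scale) == pytest.approx(
            base / scale, rel=1e-9)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

class TestNjTree:
    def test_two_taxa_even_split(self):
        tree = ev.nj_tree(np.array([[0, 0.4], [0.4, 0]]), ["a", "b"])
        lengths = sorted(tree.graph.edges[e]["length"] for e in tree.graph.edges)
        assert lengths == pytest.approx([0.2, 0.2])
        assert tree.path_distance("a", "b") == pytest.approx(0.4)

    def test_additive_matrix_recovered_exactly(self):
        for seed in range(10):
            g, leaves, d = gen_additive_tree(4 + seed % 5, seed)
            tree = ev.nj_tree(d, leaves)
            for i, j in itertools.combinations(range(len(leaves)), 2):
                assert tree.path_distance(leaves[i], leaves[j]) == pytest.approx(
                    d[i, j], abs=1e-9)

    def test_topology_recovered(self):
        import networkx as nx

        g, leaves, d = gen_additive_tree(6, 42)
        tree = ev.nj_tree(d, leaves)
        ref = ev.DistanceTree(graph=g, leaves=leaves)
        assert tree.bipartitions() == ref.bipartitions()

    def test_identical_sequences_full_support(self):
        seqs = {t: "ACGTACGTACGT" for t in "abcd"}
        d, labels = ev.p_distance_matrix(seqs)
        tree = ev.nj_tree(d, labels, alignment=seqs, bootstrap_reps=20)
        assert tree.supports
        assert all(v == 100.0 for v in tree.supports.values())

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 0.1, 0.2], [0.1001, 0, 0.3], [0.2, 0.3, 0]])
        with pytest.raises(ValidationError, match="asymmetric"):
            ev.nj_tree(d, ["a", "b", "c"])


# ---------------------------------------------------------------------------
# gene structure signatures
# ---------------------------------------------------------------------------

class TestGeneStructure:
    def _gene(self, gid, exons):
        return GeneModel(id=gid, chromosome="c", strand="+", start=1,
                         end=1_000_000, exons=exons)

    def test_identical_structures_grouped(self):
        exons = [(1, 100), (201, 320), (401, 470)]
        groups = ev.group_by_structure([self._gene("a", exons), self._gene("b", exons)])
        assert ["a", "b"] in groups

    def test_different_intron_counts_split(self):
        g12 = self._gene("a", [(i * 100 + 1, i * 100 + 50) for i in range(13)])
        g15 = self._gene("b", [(i * 100 + 1, i * 100 + 50) for i in range(16)])
        groups = ev.group_by_structure([g12, g15])
        assert len(groups) == 2
        sig = ev.gene_structure_signature([g12, g15])
        assert sig["a"][0] == 12 and sig["b"][0] == 15

    def test_empty_input(self):
        assert ev.gene_structure_signature([]) == {}
        assert ev.group_by_structure([]) == []
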