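"""Conserved-element discovery: key index, word cost, growth,
clustering, matrix, motif scan."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitevol.hce import (
    HCE,
    BinaryMatrix,
    HceParams,
    Word,
    build_key_index,
    cluster_words,
    find_hces,
    grow_words,
    presence_matrix,
    revcomp,
    scan_consensus,
    word_cost,
)
from mitevol.simulate import SimulationConfig, generate

from conftest import ZERO_RATES


class FakeGenome:
    def __init__(self, accession, sequence):
        self.accession = accession
        self.sequence = sequence


# 32-mers of one real conserved element shared by four congeneric
# species; malaccensis/pigmentosa identical, thermophila three
# substitutions away
W_MAL = "AATTTAAATACTTGCATTAAGACTAATCGTGG"
W_PIG = "AATTTAAATACTTGCATTAAGACTAATCGTGG"
W_THE = "AATTTAAACACTTGCATTAAAACTAATCTTGG"


class TestKeyIndex:
    def test_shared_key_lists_both_genomes(self):
        ga = FakeGenome("A", "CCGG" + W_MAL + "GGCC")
        gb = FakeGenome("B", "TTCG" + W_THE + "CGAA")
        idx = build_key_index([ga, gb])
        # a shared 8-mer with three distinct bases (two-letter keys are
        # masked as low-complexity)
        kmer = "ACTTGCAT"
        assert kmer in W_MAL and kmer in W_THE
        key = min(kmer, revcomp(kmer))
        genomes = {occ[0] for occ in idx[key]}
        assert genomes == {"A", "B"}

    def test_high_copy_key_discarded(self):
        seq = "ACGTACGTCCAT" * 200
        g = FakeGenome("A", seq)
        idx = build_key_index([g], HceParams(max_key_repeat=100))
        assert all(len(v) <= 100 for v in idx.values())

    def test_short_genome_contributes_nothing(self):
        with pytest.warns(UserWarning, match="shorter than key length"):
            idx = build_key_index([FakeGenome("A", "ACGTAADCGA"),
                                   FakeGenome("B", "ACGTTTT")])
        assert all(occ[0] == "A" for v in idx.values() for occ in v)


class TestWordCost:
    def test_identity_is_zero(self):
        assert word_cost(W_MAL, W_PIG) == 0.0

    def test_three_substitutions_cost_three(self):
        assert word_cost(W_MAL, W_THE) == pytest.approx(3.0)

    def test_strand_agnostic(self):
        assert word_cost(W_MAL, revcomp(W_THE)) == pytest.approx(3.0)

    def test_internal_deletion_rejected_at_default(self):
        deleted = W_MAL[:15] + W_MAL[16:]
        assert word_cost(W_MAL, deleted) > HceParams().max_word_cost

    def test_internal_deletion_allowed_when_configured(self):
        deleted = W_MAL[:15] + W_MAL[16:]
        params = HceParams(max_consecutive_deletions=1)
        assert word_cost(W_MAL, deleted, params) == pytest.approx(
            params.deletion_cost)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            word_cost(W_MAL, "")

    @given(st.text(alphabet="ACGT", min_size=8, max_size=40),
           st.text(alphabet="ACGT", min_size=8, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_symmetry(self, a, b):
        assert word_cost(a, b) == pytest.approx(word_cost(b, a))


class TestGrowAndCluster:
    def test_planted_element_yields_one_word_per_genome(self):
        import numpy.random as npr

        rng = npr.default_rng(0)
        plant = "".join(rng.choice(list("ACGT"), size=32))
        genomes = []
        for i in range(4):
            left = "".join(rng.choice(list("ACGT"), size=300))
            right = "".join(rng.choice(list("ACGT"), size=300))
            genomes.append(FakeGenome(f"G{i}", left + plant + right))
        params = HceParams()
        words = grow_words(build_key_index(genomes, params), genomes, params)
        per_genome = {w.genome for w in words}
        assert per_genome == {"G0", "G1", "G2", "G3"}
        for w in words:
            assert 301 - 3 <= w.start <= 301 + 3
            assert w.length >= 24

    def test_nonoverlapping_seeds_stay_separate_words(self):
        # overlap below the merge threshold leaves two words
        import numpy.random as npr

        rng = npr.default_rng(1)
        p1 = "".join(rng.choice(list("ACGT"), size=30))
        p2 = "".join(rng.choice(list("ACGT"), size=30))
        genomes = []
        for i in range(2):
            mid = "".join(rng.choice(list("ACGT"), size=200))  # unrelated
            genomes.append(FakeGenome(f"G{i}", p1 + mid + p2))
        assert genomes[0].sequence != genomes[1].sequence
        params = HceParams()
        words = grow_words(build_key_index(genomes, params), genomes, params)
        starts = sorted(w.start for w in words if w.genome == "G0")
        assert len(starts) == 2

    def test_cluster_excludes_outlier_beyond_threshold(self):
        core = [Word(f"G{i}", "+", 10, 32, W_MAL) for i in range(4)]
        far = W_MAL[:10] + "GGGGCCCCGG" + W_MAL[20:]
        outlier = Word("G9", "+", 10, 32, far)
        params = HceParams()
        hces = cluster_words(core + [outlier], params)
        assert len(hces) == 1
        assert outlier.genome not in hces[0].genomes()
        assert len(hces[0].members) == 4

    def test_empty_word_list(self):
        assert cluster_words([]) == []

    def test_member_floor_enforced(self):
        few = [Word(f"G{i}", "+", 10, 32, W_MAL) for i in range(3)]
        assert cluster_words(few, HceParams()) == []
        assert len(cluster_words(few, HceParams(min_diff_words_word=2,
                                                min_diff_words_key=2))) == 1


class TestPresenceMatrix:
    def _hce(self, hce_id, genomes):
        return HCE(hce_id, [Word(g, "+", 1, 24, "A" * 24) for g in genomes],
                   "A" * 24)

    def test_columns_match_membership(self):
        genomes = [FakeGenome(f"G{i}", "ACGT" * 10) for i in range(6)]
        hces = [self._hce(1, ["G0", "G1", "G2", "G3"]),
                self._hce(2, [g.accession for g in genomes])]
        m = presence_matrix(hces, genomes)
        assert m.shape == (6, 2)
        col1 = [row[0] for row in m.cells]
        assert sum(col1) == 4
        assert all(row[1] == 1 for row in m.cells)

    def test_no_hces_gives_zero_columns(self):
        genomes = [FakeGenome("A", "ACGT"), FakeGenome("B", "ACGT")]
        m = presence_matrix([], genomes)
        assert m.shape == (2, 0)

    def test_all_zero_column_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            BinaryMatrix(["a", "b"], [1], [[0], [0]])


class TestStrandClosure:
    def test_reverse_complemented_genomes_same_membership(self):
        cfg = SimulationConfig(seed=21, n_genes=8, n_leaves=4,
                               event_rates=dict(ZERO_RATES),
                               n_planted_hces=3, per_base_mutation_rate=0.01)
        genomes, _ = generate(cfg)
        hces_fwd, _ = find_hces(genomes)
        flipped = [FakeGenome(g.accession, revcomp(g.sequence)) for g in genomes]
        hces_rev, _ = find_hces(flipped)
        fwd_sets = sorted(tuple(sorted(h.genomes())) for h in hces_fwd)
        rev_sets = sorted(tuple(sorted(h.genomes())) for h in hces_rev)
        assert fwd_sets == rev_sets

    def test_determinism(self, static_dataset):
        genomes, _ = static_dataset
        h1, m1 = find_hces(genomes)
        h2, m2 = find_hces(genomes)
        assert [(h.hce_id, h.members) for h in h1] == \
               [(h.hce_id, h.members) for h in h2]
        assert m1.cells == m2.cells


class TestScanConsensus:
    # printed member sequences of two promoter-bearing conserved
    # elements; the YRTA core is present except in the pyriformis copy
    SEQ_299_MAL = "GACACACCATATGAATTTAAATCATTAATAATTCAA"
    SEQ_315_PYR = "TTAACGAATTTACAATAAAAAAATAAA"
    SEQ_315_MAL = "ATAACGTATTTACAATAAAAAAATAAT"

    def test_yrta_match_at_printed_site(self):
        hits = scan_consensus(self.SEQ_299_MAL, "YRTA")
        assert (8, "CATA") in hits

    def test_substituted_site_does_not_match(self):
        assert scan_consensus(self.SEQ_315_PYR, "YRTA") == []

    def test_cgta_site_matches(self):
        assert any(h[1] == "CGTA" for h in scan_consensus(self.SEQ_315_MAL, "YRTA"))

    def test_extended_consensus(self):
        assert scan_consensus("GGYRTANNAATTYGG".replace("Y", "C")
                              .replace("R", "A").replace("N", "T"),
                              "YRTAnnAATTY")

    def test_overlapping_matches_reported(self):
        assert len(scan_consensus("TATATA", "TATA")) == 2

    def test_empty_sequence(self):
        assert scan_consensus("", "YRTA") == []

    def test_bad_pattern_rejected(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            scan_consensus("ACGT", "YRTA%")
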