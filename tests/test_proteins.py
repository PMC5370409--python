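"""Protein family clustering from the pairwise-similarity graph."""

import random

import numpy as np
import pytest

from mitevol.proteins import (
    Cluster,
    ClusteringParams,
    Hit,
    ProteinRecord,
    cluster,
    cluster_stats,
    count_differences,
    find_paralog_pairs,
    pairwise_hits,
    select_wide_clusters,
)
from mitevol.simulate import SimulationConfig, generate, proteins_from_genomes

from conftest import ZERO_RATES

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n):
    return "".join(rng.choice(AA) for _ in range(n))


def mutate(rng, seq, rate):
    out = []
    for c in seq:
        if rng.random() < rate:
            out.append(rng.choice([x for x in AA if x != c]))
        else:
            out.append(c)
    return "".join(out)


@pytest.fixture(scope="module")
def clustered_dataset():
    cfg = SimulationConfig(seed=2, n_genes=12, n_leaves=6,
                           event_rates=dict(ZERO_RATES), n_planted_hces=0)
    genomes, truth = generate(cfg)
    prots = proteins_from_genomes(genomes)
    hits = pairwise_hits(prots)
    return prots, truth, cluster(hits, prots)


class TestPairwiseHits:
    def test_identical_proteins_strong_edge(self):
        rng = random.Random(0)
        seq = random_protein(rng, 100)
        a = ProteinRecord("p1", "g1", "x", seq)
        b = ProteinRecord("p2", "g2", "x", seq)
        hits = pairwise_hits([a, b])
        assert hits and all(h.evalue < 1e-10 for h in hits)

    def test_unrelated_proteins_no_edge(self):
        rng = random.Random(1)
        misses = 0
        for trial in range(20):
            a = ProteinRecord("p1", "g1", "x", random_protein(rng, 100))
            b = ProteinRecord("p2", "g2", "y", random_protein(rng, 100))
            if pairwise_hits([a, b]):
                misses += 1
        assert misses == 0

    def test_family_at_seventy_percent_identity_fully_edged(self):
        rng = random.Random(2)
        seed_seq = random_protein(rng, 120)
        prots = [ProteinRecord(f"p{i}", f"g{i}", "fam",
                               mutate(rng, seed_seq, 0.3)) for i in range(6)]
        hits = pairwise_hits(prots)
        pairs = {frozenset((h.query, h.subject)) for h in hits}
        assert len(pairs) == 15

    def test_fewer_than_two_proteins_rejected(self):
        with pytest.raises(ValueError):
            pairwise_hits([ProteinRecord("p", "g", "x", "MKV")])


class TestCluster:
    def test_no_hits_all_singletons(self):
        prots = [ProteinRecord(f"p{i}", "g", "x", "MKVLITA") for i in range(5)]
        out = cluster([], prots)
        assert len(out) == 5 and all(not c.nontrivial for c in out)

    def test_partition_property(self, clustered_dataset):
        prots, _, clusters = clustered_dataset
        seen = [m.protein_id for c in clusters for m in c.members]
        assert sorted(seen) == sorted(p.protein_id for p in prots)

    def test_families_recovered(self, clustered_dataset):
        prots, truth, clusters = clustered_dataset
        fam = truth.family_membership
        nontrivial = [c for c in clusters if c.nontrivial]
        assert len(nontrivial) == len({fam[p.protein_id] for p in prots})
        for c in nontrivial:
            assert len({fam[m.protein_id] for m in c.members}) == 1

    def test_order_invariance(self, clustered_dataset):
        prots, _, clusters = clustered_dataset
        shuffled = list(prots)
        random.Random(9).shuffle(shuffled)
        hits = pairwise_hits(shuffled)
        again = cluster(hits, shuffled)
        as_sets = lambda cl: sorted(
            tuple(sorted(m.protein_id for m in c.members)) for c in cl)
        assert as_sets(clusters) == as_sets(again)

    def test_h_pruning_splits_bridged_families(self):
        prots = [ProteinRecord(p, p[0], "x", "M" * 10)
                 for p in ("a1", "a2", "a3", "b1", "b2", "b3")]
        strong_pairs = (("a1", "a2"), ("a2", "a3"), ("a1", "a3"),
                        ("b1", "b2"), ("b2", "b3"), ("b1", "b3"))
        strong = [Hit(q, s, 500.0, 1e-40, 1.0)
                  for a, b in strong_pairs for q, s in ((a, b), (b, a))]
        bridge = [Hit("a3", "b1", 40.0, 5e-4, 0.5),
                  Hit("b1", "a3", 40.0, 5e-4, 0.5)]
        loose = cluster(strong + bridge, prots, ClusteringParams())
        assert sum(1 for c in loose if c.nontrivial) == 1
        pruned = cluster(strong + bridge, prots,
                         ClusteringParams(H=0.5, L=0.0))
        assert sum(1 for c in pruned if c.nontrivial) == 2


class TestStatsAndSelection:
    def test_rowwise_identity(self, clustered_dataset):
        _, _, clusters = clustered_dataset
        table, hist = cluster_stats(clusters)
        assert (table["proteins"] ==
                table["in_clusters"] + table["singletons"]).all()

    def test_all_singletons_row(self):
        prots = [ProteinRecord(f"p{i}", "g1", "x", "MKVLITA") for i in range(4)]
        table, hist = cluster_stats(cluster([], prots))
        assert table.loc["g1", "in_clusters"] == 0
        assert table.loc["g1", "singletons"] == 4
        assert hist == {}

    def test_one_cluster_holding_everything(self, clustered_dataset):
        prots, _, _ = clustered_dataset
        giant = [Cluster(1, list(prots))]
        _, hist = cluster_stats(giant)
        assert hist == {6: 1}

    def test_select_wide_identity_and_empty(self, clustered_dataset):
        _, _, clusters = clustered_dataset
        assert select_wide_clusters(clusters, 1) == clusters
        assert select_wide_clusters(clusters, 99) == []
        wide = select_wide_clusters(clusters, 6)
        assert all(len(c.species_profile) >= 6 for c in wide)


class TestCountDifferences:
    def test_identical(self):
        a = ProteinRecord("a", "g", "x", "MKVLITA")
        assert count_differences(a, a) == 0

    def test_single_substitution(self):
        assert count_differences(ProteinRecord("a", "g", "x", "ACDE"),
                                 ProteinRecord("b", "g", "x", "ACDF")) == 1

    def test_gap_counts_as_difference(self):
        assert count_differences(ProteinRecord("a", "g", "x", "ACDEKLM"),
                                 ProteinRecord("b", "g", "x", "ACDKLM")) == 1

    def test_paralog_pair_report(self):
        seq = "MKVLITAGPTREALDPVRYISNHSSGKMGFAIA"
        recs = [ProteinRecord("Nad9_1", "tmal", "nad9", seq),
                ProteinRecord("Nad9_2", "tmal", "nad9", seq[:10] + "W" + seq[11:]),
                ProteinRecord("other", "tthe", "nad9", seq)]
        pairs = find_paralog_pairs([Cluster(1, recs)])
        assert pairs == [(1, "tmal", "Nad9_1", "Nad9_2", 1)]
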