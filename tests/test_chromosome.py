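"""Chromosome structures, operations and the weighted rearrangement
distance."""

import random

import pytest

from mitevol.chromosome import (
    ChromosomeStructure,
    EvolutionEvent,
    OperationCosts,
    SignedGene,
    apply_events,
    apply_operation,
    build_graph,
    distance,
    distance_matrix,
    distance_oracle,
    structures_equivalent,
)

L = ChromosomeStructure.linear
C = ChromosomeStructure.circular


def rand_structure(rng, families):
    genes = list(families)
    rng.shuffle(genes)
    chroms = []
    while genes:
        k = rng.randint(1, len(genes))
        part, genes = genes[:k], genes[k:]
        chroms.append((rng.choice("LC"),
                       [SignedGene(f, 1, rng.choice((1, -1))) for f in part]))
    return ChromosomeStructure(chroms)


COST_SETTINGS = [
    OperationCosts(),
    OperationCosts(1.7, 0.9, 1.3, 0.8, 1.4, 0.6, 2.0, 2.5),
    OperationCosts(0.8, 1.5, 0.7, 1.2, 1.0, 1.3, 2.0, 2.5),
]


class TestBreakpointGraph:
    def test_linear_counts(self):
        g = build_graph(L("a", "b", "c"))
        assert (len(g.b_edges), len(g.a_edges), len(g.telomeres)) == (3, 2, 2)

    def test_circular_counts(self):
        g = build_graph(C("a", "b"))
        assert (len(g.b_edges), len(g.a_edges), len(g.telomeres)) == (2, 2, 0)

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError):
            ChromosomeStructure([("L", [])])


class TestApplyOperation:
    def test_inversion_by_single_dcj(self):
        s = L("a", "b", "c")
        # cut (a_h,b_t) and (b_h,c_t), rejoin to invert b
        ah = (("a", 1), "h")
        bt = (("b", 1), "t")
        bh = (("b", 1), "h")
        ct = (("c", 1), "t")
        ev = EvolutionEvent("dcj", (frozenset((ah, bt)), frozenset((bh, ct)),
                                    frozenset((ah, bh)), frozenset((bt, ct))), 1.2)
        assert apply_operation(s, ev) == L("a", "*b", "c")

    def test_circularisation_by_a_insert(self):
        s = L("a", "b", "c")
        at = (("a", 1), "t")
        ch = (("c", 1), "h")
        ev = EvolutionEvent("a_insert", (at, ch), 1.0)
        assert apply_operation(s, ev) == C("a", "b", "c")

    def test_b_delete_with_healing(self):
        ev = EvolutionEvent("b_delete", (("b", 1), True), 1.0)
        assert apply_operation(L("a", "b", "c"), ev) == L("a", "c")

    def test_illegal_operand_raises(self):
        ev = EvolutionEvent("a_delete", (frozenset(((("x", 1), "h"),
                                                    (("y", 1), "t"))),), 0.9)
        with pytest.raises(ValueError, match="not present"):
            apply_operation(L("a", "b"), ev)


class TestDistance:
    def test_identical_structures(self):
        s = L("a", "b", "c")
        cost, events = distance(s, s)
        assert cost == 0.0 and events == []

    def test_single_inversion_costs_one_dcj(self):
        assert distance(L("a", "b", "c"), L("a", "*b", "c"),
                        return_events=False) == pytest.approx(1.2)

    def test_single_gene_gain_costs_one_b_insert(self):
        assert distance(L("a", "b"), L("a", "b", "c"),
                        return_events=False) == pytest.approx(0.9)

    def test_circular_to_linear_costs_one_a_delete(self):
        assert distance(C("a", "b", "c"), L("a", "b", "c"),
                        return_events=False) == pytest.approx(0.9)

    def test_disjoint_genes_need_loss_plus_gain(self):
        assert distance(L("a"), L("b"),
                        return_events=False) == pytest.approx(1.9)

    def test_oracle_values_by_hand(self):
        assert distance_oracle(C("a", "b", "c"), L("a", "b", "c")) == pytest.approx(0.9)
        assert distance_oracle(L("a"), L("b")) == pytest.approx(1.9)
        s = L("a", "b", "c")
        assert distance_oracle(s, s) == 0.0

    def test_oracle_reports_unknown_beyond_budget(self):
        with pytest.raises(LookupError, match="unknown"):
            distance_oracle(L("a"), L("b"), max_cost=0.5)

    @pytest.mark.parametrize("setting", range(3))
    def test_matches_uniform_cost_oracle_on_small_instances(self, setting):
        """Guided search equals exhaustive search on random <=5-gene
        pairs (a reduced slice of the full certification run)."""
        rng = random.Random(100 + setting)
        costs = COST_SETTINGS[setting]
        for _ in range(25):
            total = rng.randint(2, 5)
            fams = [chr(97 + i) for i in range(total)]
            s1 = rand_structure(rng, fams[:rng.randint(1, total)])
            s2 = rand_structure(rng, fams[max(0, total - rng.randint(1, total)):])
            d = distance(s1, s2, costs, return_events=False)
            assert d == pytest.approx(distance_oracle(s1, s2, costs))

    def test_replay_reaches_target(self):
        rng = random.Random(7)
        for _ in range(20):
            fams = [chr(97 + i) for i in range(rng.randint(2, 6))]
            s1 = rand_structure(rng, fams)
            s2 = rand_structure(rng, fams[:rng.randint(1, len(fams))])
            _, events = distance(s1, s2)
            assert structures_equivalent(apply_events(s1, events), s2)

    def test_zero_law_on_random_structures(self):
        rng = random.Random(3)
        for _ in range(10):
            s = rand_structure(rng, list("abcdef"))
            assert distance(s, s, return_events=False) == 0.0

    def test_upper_bound_law(self):
        """The distance never exceeds the cost of an explicitly
        constructed event sequence."""
        s = L("a", "b", "c", "d")
        ev1 = EvolutionEvent("b_delete", (("b", 1), True), 1.0)
        mid = apply_operation(s, ev1)
        ev2 = EvolutionEvent("b_delete", (("c", 1), True), 1.0)
        end = apply_operation(mid, ev2)
        assert distance(s, end, return_events=False) <= 2.0 + 1e-9

    def test_monotone_cost_scaling(self):
        s1, s2 = L("a", "b", "c", "d"), L("d", "*b", "a", "c")
        d1 = distance(s1, s2, return_events=False)
        d2 = distance(s1, s2, OperationCosts().scaled(2.5), return_events=False)
        assert d2 == pytest.approx(2.5 * d1)

    def test_special_edge_costs_honoured(self):
        # deleting gene b is special: flat special cost replaces b_delete
        dflt = distance(L("a", "b"), L("a"), return_events=False)
        spec = distance(L("a", "b"), L("a"),
                        special_b=lambda g: g[0] == "b", return_events=False)
        assert dflt == pytest.approx(1.0)
        assert spec == pytest.approx(2.5)

    def test_paralog_occurrences_matched_by_context(self):
        s1 = ChromosomeStructure([("L", ["a", "nad9#1", "b", "nad9#2", "c"])])
        s2 = ChromosomeStructure([("L", ["a", "nad9#2", "b", "nad9#1", "c"])])
        # same genome up to occurrence relabelling
        assert distance(s1, s2, return_events=False) == 0.0


class TestDistanceMatrix:
    def test_identical_inputs_zero_matrix(self):
        s = L("a", "b", "c")
        m = distance_matrix({"x": s, "y": s, "z": s})
        assert (m.d == 0).all()

    def test_mean_symmetrisation(self):
        s1, s2, s3 = L("a", "b"), L("a", "b", "c"), L("a")
        m = distance_matrix({"x": s1, "y": s2, "z": s3}, symmetrize="mean")
        dxy = distance(s1, s2, return_events=False)
        dyx = distance(s2, s1, return_events=False)
        assert m[("x", "y")] == pytest.approx((dxy + dyx) / 2)

    def test_true_scenario_upper_bounds_matrix_entries(self):
        """Leaf pairs evolved by self-inverse, equal-cost operations are
        never further apart than the event costs along the true tree
        path.  Circular genomes with dcj-only events keep every
        operation reversible at equal cost (a dcj joining two telomere
        pairs has no equal-cost reverse, so linear topologies break the
        bound); small genomes keep the distance exact."""
        from mitevol.simulate import SimulationConfig, generate

        cfg = SimulationConfig(
            seed=13, n_leaves=5, n_genes=8, n_planted_hces=0, topology="C",
            event_rates={"dcj": 1.0, "sesqui": 0.0, "a_insert": 0.0,
                         "a_delete": 0.0, "b_insert": 0.0, "b_delete": 0.0},
            events_per_edge_range=(0, 2))
        _, truth = generate(cfg)
        m = distance_matrix(truth.leaf_structures)
        tree = truth.tree
        edge_cost = {k: sum(e.cost for e in evs)
                     for k, evs in truth.edge_events.items()}

        def label(n):
            return n.taxon.label if n.taxon else n.label

        for i, a in enumerate(m.labels):
            for b in m.labels[i + 1:]:
                na = tree.find_node_with_taxon_label(a)
                nb = tree.find_node_with_taxon_label(b)
                anc_a = [na] + list(na.ancestor_iter())
                anc_b = [nb] + list(nb.ancestor_iter())
                mrca = next(x for x in anc_a if x in anc_b)

                def walk_cost(n):
                    tot = 0.0
                    while n is not mrca:
                        tot += edge_cost[(label(n.parent_node), label(n))]
                        n = n.parent_node
                    return tot

                assert m[(a, b)] <= walk_cost(na) + walk_cost(nb) + 1e-9
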