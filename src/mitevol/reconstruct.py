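"""Ancestral chromosome-structure reconstruction on a tree.

Given leaf chromosome structures and a tree, infer internal-node
structures that (locally) minimise the total edge cost under the
weighted cut-and-join model, and list the per-edge events.

The optimiser is a deterministic local search: internal nodes are
initialised with the structure of their nearest descendant leaf
(post-order), then repeatedly re-optimised one node at a time against
the sum of directed distances to the node's tree neighbours.  The
candidate set for a node is its current structure, its neighbours'
structures, and single-operation perturbations of those candidates
taken from the first steps of optimal/greedy pairwise scenarios.  A
sweep visits every internal node; the search stops when a full sweep
yields no improvement, so the total cost is non-increasing across
sweeps.  Exact Steiner/median optimality is not attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import dendropy

from mitevol.chromosome import (
    ChromosomeStructure,
    EvolutionEvent,
    OperationCosts,
    apply_events,
    distance,
    structures_equivalent,
)


@dataclass
class Scenario:
    """A reconstructed evolutionary scenario.

    ``node_structures`` maps node labels (leaf labels and internal
    ``N<i>`` labels) to structures; ``edge_events`` maps
    ``(parent_label, child_label)`` to the replayable event list of that
    edge.  Replaying each edge's events transforms the parent structure
    into the child structure, and ``total_cost`` is the sum of all
    event costs.
    """

    tree: dendropy.Tree
    node_structures: Dict[str, ChromosomeStructure]
    edge_events: Dict[Tuple[str, str], List[EvolutionEvent]]
    total_cost: float

    def check_replay(self) -> bool:
        for (p, c), events in self.edge_events.items():
            replayed = apply_events(self.node_structures[p], events)
            if not structures_equivalent(replayed, self.node_structures[c]):
                return False
        return True

    def to_table(self) -> str:
        """Appendix-style three-column listing: descendant leaves, gene
        order (L/C flag, ``*`` for complementary strand), events on the
        incident edge."""
        lines = []
        label_to_node = {}
        for node in self.tree.preorder_node_iter():
            label_to_node[_node_label(node)] = node
        incoming: Dict[str, List[EvolutionEvent]] = {}
        for (p, c), evs in self.edge_events.items():
            incoming[c] = evs
        for node in self.tree.preorder_node_iter():
            lab = _node_label(node)
            leaves = ",".join(sorted(
                x.taxon.label for x in node.leaf_iter()))
            struct = self.node_structures[lab]
            order = "; ".join(
                f"{topo} " + " ".join(g.label for g in genes)
                for topo, genes in struct.chromosomes)
            events = "; ".join(e.op_kind for e in incoming.get(lab, []))
            lines.append(f"{leaves}\t{order}\t{events}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        payload = {
            "total_cost": self.total_cost,
            "tree": self.tree.as_string(schema="newick").strip(),
            "nodes": {
                lab: [[topo, [g.label for g in genes]]
                      for topo, genes in s.chromosomes]
                for lab, s in self.node_structures.items()
            },
            "edges": {
                f"{p}->{c}": [[e.op_kind, e.cost] for e in evs]
                for (p, c), evs in self.edge_events.items()
            },
        }
        return json.dumps(payload, indent=2)


def _node_label(node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


def _resolve_polytomies(tree: dendropy.Tree) -> None:
    """Resolve multifurcations deterministically, grouping the two
    children with the smallest descendant leaf labels first."""

    def min_leaf(n):
        return min(x.taxon.label for x in n.leaf_iter())

    for node in list(tree.postorder_node_iter()):
        while len(node.child_nodes()) > 2:
            children = sorted(node.child_nodes(), key=min_leaf)
            a, b = children[0], children[1]
            node.remove_child(a)
            node.remove_child(b)
            joined = dendropy.Node()
            joined.edge.length = 0.0
            joined.add_child(a)
            joined.add_child(b)
            node.add_child(joined)


def reconstruct(
    tree: dendropy.Tree,
    leaves: Dict[str, ChromosomeStructure],
    costs: OperationCosts = OperationCosts(),
    seed: int = 0,
    max_sweeps: int = 20,
    root_at_midpoint: bool = True,
) -> Scenario:
    """Infer ancestral structures on ``tree`` from leaf structures.

    ``tree`` may be unrooted (e.g. straight from neighbor joining); it
    is midpoint-rooted by default.  Polytomies are resolved
    deterministically before reconstruction.  The search itself is
    deterministic; ``seed`` is accepted for interface stability.
    """
    tree = dendropy.Tree.get(data=tree.as_string(schema="newick"), schema="newick")
    tree_leaves = {x.taxon.label for x in tree.leaf_node_iter()}
    missing = tree_leaves - set(leaves)
    if missing:
        raise ValueError(f"no structure for leaves: {sorted(missing)}")
    if root_at_midpoint and len(tree.seed_node.child_nodes()) != 2:
        has_lengths = all(e.length is not None for e in tree.preorder_edge_iter()
                          if e.head_node is not tree.seed_node)
        if has_lengths:
            tree.reroot_at_midpoint(update_bipartitions=False)
    _resolve_polytomies(tree)

    # label internal nodes
    counter = 1
    for node in tree.postorder_node_iter():
        if node.taxon is None:
            node.label = f"N{counter}"
            counter += 1

    dist_cache: Dict[Tuple[ChromosomeStructure, ChromosomeStructure], tuple] = {}

    def dfull(a, b):
        key = (a, b)
        if key not in dist_cache:
            dist_cache[key] = distance(a, b, costs)
        return dist_cache[key]

    def d(a, b) -> float:
        return dfull(a, b)[0]

    internal = [n for n in tree.postorder_node_iter() if not n.is_leaf()]

    def neighbors(node):
        out = list(node.child_nodes())
        if node.parent_node is not None:
            out.append(node.parent_node)
        return out

    def local_cost(node, cand, struct) -> float:
        total = 0.0
        if node.parent_node is not None:
            total += d(struct[_node_label(node.parent_node)], cand)
        for ch in node.child_nodes():
            total += d(cand, struct[_node_label(ch)])
        return total

    def perturbations(cands):
        """Intermediate structures along pairwise scenarios between the
        candidates (every prefix of the event list), i.e. iterated
        single-operation perturbations that stay on optimal paths."""
        out = []
        for a in cands:
            for b in cands:
                if a == b:
                    continue
                _, events = dfull(a, b)
                cur = a
                for ev in events[:-1]:
                    cur = apply_events(cur, [ev])
                    out.append(cur)
                # commuting events can be taken in any order; try each
                # event of the path on its own as well
                for ev in events[1:]:
                    try:
                        out.append(apply_events(a, [ev]))
                    except ValueError:
                        continue
        return out

    def majority_candidate(structs):
        """Consensus structure: genes and adjacencies carried by more
        than half of the neighbour structures (adjacencies added
        greedily by support while extremities stay free)."""
        from collections import Counter
        from mitevol.chromosome import state_to_structure, structure_to_state

        k = len(structs)
        gene_votes = Counter()
        adj_votes = Counter()
        for s in structs:
            genes, adjs = structure_to_state(s)
            gene_votes.update(genes)
            adj_votes.update(adjs)
        genes = {g for g, v in gene_votes.items() if v * 2 > k}
        if not genes:
            return None
        used = set()
        adjs = set()
        for adj, v in sorted(adj_votes.items(),
                             key=lambda kv: (-kv[1], sorted(kv[0]))):
            if v * 2 <= k:
                break
            exts = set(adj)
            if any(e[0] not in genes for e in exts) or exts & used:
                continue
            adjs.add(adj)
            used |= exts
        return state_to_structure((frozenset(genes), frozenset(adjs)))

    def scenario_cost(assign) -> float:
        total = 0.0
        for node in tree.preorder_node_iter():
            for ch in node.child_nodes():
                total += d(assign[_node_label(node)], assign[_node_label(ch)])
        return total

    def sweep_to_convergence(struct):
        for _sweep in range(max_sweeps):
            improved = False
            for node in internal:
                lab = _node_label(node)
                neigh_structs = [struct[_node_label(x)] for x in neighbors(node)]
                candidates = [struct[lab]] + neigh_structs
                maj = majority_candidate(neigh_structs)
                if maj is not None:
                    candidates.append(maj)
                candidates += perturbations([struct[lab]] + neigh_structs)
                seen = set()
                best_struct, best_cost = None, None
                for cand in candidates:
                    if cand in seen:
                        continue
                    seen.add(cand)
                    c = local_cost(node, cand, struct)
                    if best_cost is None or c < best_cost - 1e-12:
                        best_struct, best_cost = cand, c
                if best_struct != struct[lab]:
                    cur_cost = local_cost(node, struct[lab], struct)
                    if best_cost < cur_cost - 1e-12:
                        struct[lab] = best_struct
                        improved = True
            if not improved:
                break
        return struct

    # start 1: nearest descendant leaf per internal node (post-order)
    init_leaf: Dict[str, ChromosomeStructure] = {}
    nearest: Dict[str, Tuple[float, str]] = {}
    for node in tree.postorder_node_iter():
        lab = _node_label(node)
        if node.is_leaf():
            init_leaf[lab] = leaves[lab]
            nearest[lab] = (0.0, lab)
        else:
            best = None
            for ch in node.child_nodes():
                cd, cleaf = nearest[_node_label(ch)]
                cd += ch.edge.length or 1.0
                cand = (cd, cleaf)
                if best is None or cand < best:
                    best = cand
            nearest[lab] = best
            init_leaf[lab] = leaves[best[1]]

    # start 2: majority consensus of the node's descendant leaves
    init_maj: Dict[str, ChromosomeStructure] = {}
    for node in tree.postorder_node_iter():
        lab = _node_label(node)
        if node.is_leaf():
            init_maj[lab] = leaves[lab]
        else:
            desc = [leaves[x.taxon.label] for x in node.leaf_iter()]
            maj = majority_candidate(desc)
            init_maj[lab] = maj if maj is not None and maj.chromosomes else init_leaf[lab]

    results = []
    for init in (init_leaf, init_maj):
        assign = sweep_to_convergence(dict(init))
        results.append((scenario_cost(assign), assign))
    results.sort(key=lambda r: r[0])
    _, struct = results[0]

    edge_events: Dict[Tuple[str, str], List[EvolutionEvent]] = {}
    total = 0.0
    for node in tree.preorder_node_iter():
        for ch in node.child_nodes():
            p, c = _node_label(node), _node_label(ch)
            cost, events = dfull(struct[p], struct[c])
            edge_events[(p, c)] = events
            total += cost
    return Scenario(tree, struct, edge_events, total)
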