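"""Synthetic genomes with a known evolutionary history.

The generator emulates the statistical shape of small organellar
genome sets: a handful of genomes with tens of genes each on one
linear or circular chromosome, AT-rich sequence, strand-signed gene
orders evolved along a tree by the weighted cut-and-join operations,
intergenic regions carrying planted conserved elements under a
point-substitution noise model, and protein families with tunable
within-family identity (including occasional recent paralogs created
by gene-gain events that duplicate an existing family).

Everything is driven by a single integer seed; the same seed yields
byte-identical output files.  The emitted :class:`GroundTruth` carries
the true tree, the true structures at every node, the per-edge event
lists (replayable with :func:`replay_truth`), the planted element
coordinates per leaf and the protein family membership, so every
pipeline stage can be scored against a known answer.

Background sequence (gene bodies and intergenic spacers) is drawn
i.i.d. per leaf, so planted elements are the only conserved sequence
features; real genomes also share coding sequence between species,
which these tests deliberately do not emulate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import dendropy
import numpy as np

from mitevol.chromosome import (
    ChromosomeStructure,
    EvolutionEvent,
    OperationCosts,
    SignedGene,
    _Engine,
    apply_events,
    structure_to_state,
)
from mitevol.genome_io import AnnotatedGenome, GeneFeature, write_genbank
from mitevol.hce import revcomp
from mitevol.proteins import ProteinRecord

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
# natural residue background (Robinson-Robinson frequencies); a uniform
# background over-represents rare high-scoring residues (W, C) and breaks
# the Karlin-Altschul significance calibration of the similarity search
_AA_FREQ = np.array([
    0.078, 0.019, 0.054, 0.063, 0.039, 0.074, 0.022, 0.051, 0.057, 0.091,
    0.022, 0.045, 0.052, 0.043, 0.051, 0.071, 0.058, 0.065, 0.013, 0.032,
])
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Event rates are expected events per unit branch length, per
    operation kind; counts per edge are Poisson draws.  Planted
    elements are inserted at the root (all leaves carry a mutated
    copy).  Defaults describe a small linear mitochondrial genome set:
    8 genomes, 20 genes, 75% A+T.
    """

    n_genes: int = 20
    topology: str = "L"
    n_leaves: int = 8
    tree: Optional[dendropy.Tree] = None
    branch_length_range: Tuple[float, float] = (0.5, 1.5)
    event_rates: Dict[str, float] = field(default_factory=lambda: {
        "dcj": 0.5, "sesqui": 0.2, "a_insert": 0.1, "a_delete": 0.1,
        "b_insert": 0.15, "b_delete": 0.15,
    })
    # When set, the total event count of each edge is drawn uniformly from
    # this inclusive range (kinds in proportion to event_rates) instead of
    # Poisson per kind; use (1, 2) to guarantee every branch is marked by
    # at least one event.
    events_per_edge_range: Optional[Tuple[int, int]] = None
    paralog_gain_prob: float = 0.3  # a gene gain duplicates an existing family
    n_planted_hces: int = 10
    hce_length_range: Tuple[int, int] = (30, 60)
    per_base_mutation_rate: float = 0.02
    n_protein_families: int = 0  # 0: every root gene family encodes a protein
    within_family_identity: float = 0.7
    protein_length_range: Tuple[int, int] = (60, 120)
    gene_length_range: Tuple[int, int] = (90, 240)
    intergenic_length_range: Tuple[int, int] = (40, 120)
    at_content: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if self.topology not in ("L", "C"):
            raise ValueError("topology must be 'L' or 'C'")
        if not 0 <= self.per_base_mutation_rate <= 1:
            raise ValueError("per_base_mutation_rate must be in [0,1]")
        if not 0 < self.within_family_identity <= 1:
            raise ValueError("within_family_identity must be in (0,1]")
        if any(r < 0 for r in self.event_rates.values()):
            raise ValueError("event rates must be non-negative")


@dataclass
class GroundTruth:
    tree: dendropy.Tree
    node_structures: Dict[str, ChromosomeStructure]
    edge_events: Dict[Tuple[str, str], List[EvolutionEvent]]
    leaf_structures: Dict[str, ChromosomeStructure]
    hce_coordinates: Dict[str, list]  # leaf -> [(plant_id, start, end, strand)]
    planted_sequences: Dict[int, str]
    family_membership: Dict[str, str]  # protein_id -> family

    def leaf_labels(self) -> List[str]:
        return sorted(self.leaf_structures)


def _random_tree(rng, n_leaves: int, bl_range) -> dendropy.Tree:
    """Random rooted binary tree over leaves G1..Gn with uniform branch
    lengths in ``bl_range``."""
    labels = [f"G{i + 1}" for i in range(n_leaves)]
    frags = {lab: lab for lab in labels}
    active = list(labels)
    while len(active) > 1:
        i = int(rng.integers(len(active)))
        a = active.pop(i)
        j = int(rng.integers(len(active)))
        b = active.pop(j)
        la = rng.uniform(*bl_range)
        lb = rng.uniform(*bl_range)
        merged = f"({frags[a]}:{la:.6f},{frags[b]}:{lb:.6f})"
        key = min(a, b)
        frags[key] = merged
        active.append(key)
    newick = frags[active[0]] + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return tree


def _rand_seq(rng, length: int, at: float) -> str:
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]  # A C G T
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _mutate_dna(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in hits:
        choices = [c for c in "ACGT" if c != out[i]]
        out[i] = choices[int(rng.integers(3))]
    return "".join(out)


def _random_protein(rng, length: int) -> str:
    return "".join(np.array(list(_AA20))[rng.choice(20, size=length, p=_AA_FREQ)])


def _mutate_protein(rng, seq: str, sub_prob: float) -> str:
    out = list(seq)
    hits = np.nonzero(rng.random(len(out)) < sub_prob)[0]
    for i in hits:
        # background-weighted substitution kernel, excluding the current
        # residue
        while True:
            c = _AA20[int(rng.choice(20, p=_AA_FREQ))]
            if c != out[i]:
                break
        out[i] = c
    return "".join(out)


def _random_event(rng, struct: ChromosomeStructure, kind: str,
                  fresh_family, costs: OperationCosts,
                  paralog_prob: float) -> Optional[EvolutionEvent]:
    """Draw one uniformly random legal operation of ``kind``."""
    state = structure_to_state(struct)
    if kind == "b_insert":
        if rng.random() < paralog_prob and state[0]:
            fams = sorted({k[0] for k in state[0]})
            fam = fams[int(rng.integers(len(fams)))]
            occs = [k[1] for k in state[0] if k[0] == fam]
            new_key = (fam, max(occs) + 1)
        else:
            new_key = (fresh_family(), 1)
        target = (frozenset(state[0] | {new_key}), state[1])
    else:
        target = state
    eng = _Engine(state, target, costs, None, None)
    candidates = [op for op in eng.ops(eng.encode(state)) if op[0] == kind]
    if not candidates:
        return None
    op = candidates[int(rng.integers(len(candidates)))]
    return eng.decode_event(op)


def generate(config: SimulationConfig):
    """Simulate one dataset; returns ``(genomes, truth)``.

    ``genomes`` is a list of :class:`AnnotatedGenome` (one per leaf
    chromosome; single-chromosome leaves yield one record named after
    the leaf).  Use :func:`write_dataset` to serialise everything.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.hce_length_range
    ig_lo, ig_hi = config.intergenic_length_range
    if lo > ig_hi:
        raise ValueError(
            "planted elements longer than the largest intergenic region")
    if config.n_planted_hces > config.n_genes + 1:
        raise ValueError("more planted elements than intergenic slots")

    # --- tree
    if config.tree is not None:
        tree = dendropy.Tree.get(data=config.tree.as_string(schema="newick"),
                                 schema="newick")
    else:
        tree = _random_tree(rng, config.n_leaves, config.branch_length_range)
    counter = 1
    for node in tree.postorder_node_iter():
        if node.taxon is None:
            node.label = f"N{counter}"
            counter += 1

    def label(node):
        return node.taxon.label if node.taxon is not None else node.label

    # --- root structure
    families = [f"g{i:02d}" for i in range(config.n_genes)]
    orient = [1 if rng.random() < 0.5 else -1 for _ in families]
    root = ChromosomeStructure([(config.topology, [
        SignedGene(f, 1, o) for f, o in zip(families, orient)
    ])])

    fresh_counter = [config.n_genes]

    def fresh_family():
        fam = f"g{fresh_counter[0]:02d}"
        fresh_counter[0] += 1
        return fam

    costs = OperationCosts()
    node_structures = {label(tree.seed_node): root}
    edge_events: Dict[Tuple[str, str], List[EvolutionEvent]] = {}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            parent_struct = node_structures[label(node)]
            bl = child.edge.length if child.edge.length is not None else 1.0
            kinds = []
            if config.events_per_edge_range is not None:
                lo_e, hi_e = config.events_per_edge_range
                n_events = int(rng.integers(lo_e, hi_e + 1))
                rate_kinds = sorted(k for k, r in config.event_rates.items() if r > 0)
                weights = np.array([config.event_rates[k] for k in rate_kinds])
                weights = weights / weights.sum()
                for _ in range(n_events):
                    kinds.append(rate_kinds[int(rng.choice(len(rate_kinds), p=weights))])
            else:
                for kind in sorted(config.event_rates):
                    k = int(rng.poisson(config.event_rates[kind] * bl))
                    kinds.extend([kind] * k)
            rng.shuffle(kinds)
            events = []
            cur = parent_struct
            for kind in kinds:
                if cur.n_genes() <= 2 and kind == "b_delete":
                    continue  # keep structures non-degenerate
                ev = _random_event(rng, cur, kind, fresh_family, costs,
                                   config.paralog_gain_prob)
                if ev is None:
                    continue
                cur = apply_events(cur, [ev])
                events.append(ev)
            node_structures[label(child)] = cur
            edge_events[(label(node), label(child))] = events

    leaf_structures = {
        label(x): node_structures[label(x)] for x in tree.leaf_node_iter()
    }

    # --- protein families: one seed per family, per-copy substitution
    # q = 1 - sqrt(identity) so expected pairwise identity between two
    # leaf copies is about the configured target
    all_families = sorted({g.family for s in node_structures.values()
                           for g in s.genes()})
    plo, phi = config.protein_length_range
    seeds = {}
    for fam in all_families:
        length = int(rng.integers(plo, phi + 1))
        seeds[fam] = _random_protein(rng, length)
    q = 1.0 - float(np.sqrt(config.within_family_identity))

    # --- planted conserved elements (inserted at the root: all leaves)
    plants = {}
    for pid in range(1, config.n_planted_hces + 1):
        plants[pid] = _rand_seq(rng, int(rng.integers(lo, hi + 1)), config.at_content)
    # fixed slot (intergenic index) per plant, same for every leaf
    n_slots = config.n_genes + 1
    slot_ids = rng.choice(n_slots, size=config.n_planted_hces, replace=False)

    genomes: List[AnnotatedGenome] = []
    hce_coords: Dict[str, list] = {}
    family_membership: Dict[str, str] = {}
    for leaf in sorted(leaf_structures):
        struct = leaf_structures[leaf]
        multi = len(struct.chromosomes) > 1
        hce_coords[leaf] = []
        # plants are tied to slot positions counted across the whole genome
        plant_by_slot = {}
        for pid, slot in zip(sorted(plants), slot_ids):
            plant_by_slot[int(slot)] = pid
        slot_counter = 0
        prot_counter = 0
        for ci, (topo, genes) in enumerate(struct.chromosomes):
            seq_parts: List[str] = []
            feats: List[GeneFeature] = []
            pos = 0
            acc = leaf if not multi else f"{leaf}.{ci + 1}"

            def add_intergenic():
                nonlocal pos, slot_counter
                ig = _rand_seq(rng, int(rng.integers(ig_lo, ig_hi + 1)),
                               config.at_content)
                pid = plant_by_slot.get(slot_counter)
                if pid is not None:
                    copy = _mutate_dna(rng, plants[pid],
                                       config.per_base_mutation_rate)
                    strand = "+"
                    if rng.random() < 0.2:
                        copy = revcomp(copy)
                        strand = "-"
                    mid = len(ig) // 2
                    start = pos + mid + 1  # 1-based
                    hce_coords[leaf].append(
                        (pid, start, start + len(copy) - 1, strand))
                    ig = ig[:mid] + copy + ig[mid:]
                seq_parts.append(ig)
                pos += len(ig)
                slot_counter += 1

            for g in genes:
                add_intergenic()
                prot = _mutate_protein(rng, seeds[g.family], q)
                gene_len = 3 * len(prot) + 3
                body = _rand_seq(rng, gene_len, config.at_content)
                start = pos + 1
                end = pos + gene_len
                pid_str = f"{leaf}_{prot_counter:03d}"
                prot_counter += 1
                feats.append(GeneFeature(
                    gene_id=g.family, start=start, end=end,
                    strand="+" if g.orientation > 0 else "-",
                    kind="protein", translation=prot))
                family_membership[pid_str] = g.family
                seq_parts.append(body)
                pos += gene_len
            add_intergenic()
            genomes.append(AnnotatedGenome(
                accession=acc,
                organism=leaf,
                sequence="".join(seq_parts),
                topology="circular" if topo == "C" else "linear",
                features=feats,
            ))

    truth = GroundTruth(
        tree=tree,
        node_structures=node_structures,
        edge_events=edge_events,
        leaf_structures=leaf_structures,
        hce_coordinates=hce_coords,
        planted_sequences=plants,
        family_membership=family_membership,
    )
    return genomes, truth


def proteins_from_genomes(genomes: List[AnnotatedGenome]) -> List[ProteinRecord]:
    """Flatten the protein complement of a set of genomes into records
    for clustering (ids are ``<organism>_<index>`` in feature order)."""
    records = []
    counters: Dict[str, int] = {}
    for g in genomes:
        for f in g.features:
            if f.kind != "protein" or not f.translation:
                continue
            idx = counters.get(g.organism, 0)
            counters[g.organism] = idx + 1
            records.append(ProteinRecord(
                protein_id=f"{g.organism}_{idx:03d}",
                genome=g.organism,
                gene_name=f.gene_id,
                sequence=f.translation))
    return records


def replay_truth(truth: GroundTruth) -> Dict[str, ChromosomeStructure]:
    """Re-apply the true per-edge events from the root down; returns the
    reconstructed leaf structures (bit-for-bit equal to the emitted ones
    when the truth is consistent)."""

    def label(node):
        return node.taxon.label if node.taxon is not None else node.label

    root_label = label(truth.tree.seed_node)
    out: Dict[str, ChromosomeStructure] = {}
    current = {root_label: truth.node_structures[root_label]}
    for node in truth.tree.preorder_node_iter():
        for child in node.child_nodes():
            p, c = label(node), label(child)
            events = truth.edge_events[(p, c)]
            current[c] = apply_events(current[p], events)
            if child.is_leaf():
                out[c] = current[c]
    return out


def verify_truth(truth: GroundTruth) -> bool:
    """True iff replaying the event lists reproduces every emitted leaf
    structure exactly (a tampered event list that is no longer legal to
    apply also fails the check)."""
    try:
        replayed = replay_truth(truth)
    except ValueError:
        return False
    return all(replayed[leaf] == truth.leaf_structures[leaf]
               for leaf in truth.leaf_structures)


def write_dataset(genomes: List[AnnotatedGenome], truth: GroundTruth,
                  out_dir) -> None:
    """Serialise a simulated dataset: one GenBank file per genome record,
    a truth JSON, and a protein FASTA."""
    from mitevol.genome_io import write_fasta, write_gene_orders

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for g in genomes:
        write_genbank(g, out / f"{g.accession}.gb")
    write_fasta(proteins_from_genomes(genomes), out / "proteins.faa")
    write_gene_orders(truth.leaf_structures, out / "gene_orders.tsv")
    payload = {
        "tree": truth.tree.as_string(schema="newick").strip(),
        "hce_coordinates": truth.hce_coordinates,
        "planted_sequences": truth.planted_sequences,
        "family_membership": truth.family_membership,
        "edge_events": {
            f"{p}->{c}": [[e.op_kind, e.cost] for e in evs]
            for (p, c), evs in sorted(truth.edge_events.items())
        },
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
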