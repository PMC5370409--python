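"""Protein family clustering from a pairwise similarity graph.

Mitochondrially encoded proteins are compared all-against-all with a
local aligner (Smith–Waterman, BLOSUM62, gap open 11 / extend 1 — the
classic protein-search defaults, so an external BLAST+ backend is
interchangeable); alignment scores are converted to E-values with the
Karlin–Altschul formula using the total residue count of the input set
as the database size.  Pairs with E below the threshold become edges;
families are the connected components of the edge graph after optional
coverage (``L``) and per-vertex strongest-fraction (``H``) filtering.
With the most relaxed settings (L=0, H=1) the method reduces to plain
connected components.  One-member clusters are *singletons*; clusters
with two or more members are *nontrivial*.

Recent paralogs (near-identical within-genome copies, e.g. duplicated
NADH dehydrogenase subunit 9 genes) stay inside their family cluster
and are reported by a post-hoc within-genome scan.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

# gapped Karlin-Altschul parameters for BLOSUM62 with 11/1 gap costs
_KA_LAMBDA = 0.267
_KA_K = 0.041

_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ClusteringParams:
    """Similarity-graph clustering parameters.

    ``e_threshold`` — maximum E-value for an edge; ``L`` — minimum
    alignment coverage (aligned length / shorter sequence length);
    ``H`` — fraction of the strongest edges kept per vertex; ``p`` is
    accepted for interface compatibility and ignored by the
    component-based clusterer (with L=0 and H=1 the method is plain
    connected components and ``p`` has no effect).
    """

    e_threshold: float = 0.001
    L: float = 0.0
    H: float = 1.0
    p: float = 1e9

    def __post_init__(self):
        if self.e_threshold <= 0:
            raise ValueError("e_threshold must be positive")
        if not (0 <= self.L <= 1 and 0 < self.H <= 1):
            raise ValueError("L in [0,1], H in (0,1] required")


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    genome: str
    gene_name: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper().rstrip("*")
        if not seq or not set(seq) <= _AA:
            bad = sorted(set(seq) - _AA)
            raise ValueError(
                f"{self.protein_id}: empty or non-amino-acid sequence (bad: {bad})")
        object.__setattr__(self, "sequence", seq)


class Hit(NamedTuple):
    query: str
    subject: str
    score: float
    evalue: float
    coverage: float


@dataclass
class Cluster:
    cluster_id: int
    members: List[ProteinRecord]
    species_profile: set = field(default_factory=set)

    def __post_init__(self):
        if not self.species_profile:
            self.species_profile = {m.genome for m in self.members}

    @property
    def nontrivial(self) -> bool:
        return len(self.members) >= 2


def _builtin_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_hits(
    proteins: Sequence[ProteinRecord],
    params: ClusteringParams = ClusteringParams(),
    backend: str = "builtin",
) -> List[Hit]:
    """All-against-all similarity search.

    Returns one :class:`Hit` per ordered pair with E-value at or below
    ``params.e_threshold``.  ``backend`` is ``"builtin"`` (Smith–
    Waterman with Karlin–Altschul E-values) or ``"blast"`` (external
    ``blastp``; same contract).
    """
    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    ids = [p.protein_id for p in proteins]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids")
    if backend == "blast":
        return _blast_hits(proteins, params)
    aligner = _builtin_aligner()
    db_size = sum(len(p.sequence) for p in proteins)
    hits: List[Hit] = []
    for i, a in enumerate(proteins):
        for j in range(i + 1, len(proteins)):
            b = proteins[j]
            aln = aligner.align(a.sequence, b.sequence)
            score = aln.score
            best = aln[0]
            aligned_a = sum(e - s for s, e in best.aligned[0])
            cov = aligned_a / min(len(a.sequence), len(b.sequence))
            for q, s in ((a, b), (b, a)):
                e = _KA_K * len(q.sequence) * db_size * math.exp(-_KA_LAMBDA * score)
                if e <= params.e_threshold:
                    hits.append(Hit(q.protein_id, s.protein_id, float(score),
                                    float(e), float(cov)))
    return hits


def _blast_hits(proteins, params) -> List[Hit]:
    """External blastp backend (requires NCBI BLAST+ on PATH)."""
    if shutil.which("blastp") is None or shutil.which("makeblastdb") is None:
        raise RuntimeError("BLAST+ not found on PATH")
    lengths = {p.protein_id: len(p.sequence) for p in proteins}
    with tempfile.TemporaryDirectory() as tmp:
        faa = Path(tmp) / "prot.faa"
        with open(faa, "w") as fh:
            for p in proteins:
                fh.write(f">{p.protein_id}\n{p.sequence}\n")
        db = Path(tmp) / "db"
        for cmd in (
            ["makeblastdb", "-in", str(faa), "-dbtype", "prot", "-out", str(db)],
        ):
            res = subprocess.run(cmd, capture_output=True, text=True)
            if res.returncode != 0:
                raise RuntimeError(f"makeblastdb failed: {res.stderr}")
        res = subprocess.run(
            ["blastp", "-query", str(faa), "-db", str(db),
             "-outfmt", "6 qseqid sseqid bitscore evalue length",
             "-evalue", str(params.e_threshold)],
            capture_output=True, text=True)
        if res.returncode != 0:
            raise RuntimeError(f"blastp failed: {res.stderr}")
        hits = []
        seen = set()
        for line in res.stdout.splitlines():
            q, s, score, e, alen = line.split("\t")
            if q == s or (q, s) in seen:
                continue
            seen.add((q, s))
            cov = int(alen) / min(lengths[q], lengths[s])
            hits.append(Hit(q, s, float(score), float(e), cov))
        return hits


def cluster(
    hits: Sequence[Hit],
    proteins: Sequence[ProteinRecord],
    params: ClusteringParams = ClusteringParams(),
) -> List[Cluster]:
    """Partition proteins into clusters from the hit graph.

    Edges are filtered by coverage >= ``L``; each vertex keeps at most
    the ``H``-fraction strongest of its edges (an edge survives if
    either endpoint keeps it); clusters are the connected components.
    With L=0 and H=1 this is plain connected components.  Cluster ids
    are assigned canonically by the smallest member protein id, so the
    partition is independent of input order.
    """
    g = nx.Graph()
    g.add_nodes_from(p.protein_id for p in proteins)
    by_vertex: Dict[str, list] = {p.protein_id: [] for p in proteins}
    for h in hits:
        if h.coverage + 1e-12 < params.L:
            continue
        by_vertex[h.query].append(h)
    kept = set()
    for v, vhits in by_vertex.items():
        vhits.sort(key=lambda h: (-h.score, h.subject))
        n_keep = len(vhits) if params.H >= 1 else int(math.ceil(params.H * len(vhits)))
        for h in vhits[:n_keep]:
            kept.add((h.query, h.subject))
    for q, s in kept:
        g.add_edge(q, s)
    by_id = {p.protein_id: p for p in proteins}
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])
    return [
        Cluster(i + 1, [by_id[pid] for pid in comp])
        for i, comp in enumerate(comps)
    ]


def cluster_stats(clusters: Sequence[Cluster]):
    """Per-genome protein counts and the cluster size histogram.

    Returns ``(table, histogram)``: the table has one row per genome
    with columns ``proteins`` (total), ``in_clusters`` (members of
    nontrivial clusters) and ``singletons``; the histogram maps
    species-profile size to the number of nontrivial clusters with that
    profile width.
    """
    rows: Dict[str, dict] = {}
    hist: Dict[int, int] = {}
    for c in clusters:
        for m in c.members:
            r = rows.setdefault(m.genome, {"proteins": 0, "in_clusters": 0,
                                           "singletons": 0})
            r["proteins"] += 1
            if c.nontrivial:
                r["in_clusters"] += 1
            else:
                r["singletons"] += 1
        if c.nontrivial:
            k = len(c.species_profile)
            hist[k] = hist.get(k, 0) + 1
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "genome"
    return table, dict(sorted(hist.items()))


def select_wide_clusters(clusters: Sequence[Cluster], min_species: int) -> List[Cluster]:
    """Clusters whose species profile covers at least ``min_species``
    genomes."""
    if min_species < 1:
        raise ValueError("min_species must be >= 1")
    return [c for c in clusters if len(c.species_profile) >= min_species]


def count_differences(a: ProteinRecord, b: ProteinRecord) -> int:
    """Number of differing columns in a unit-score global alignment
    (a gap opposite a residue counts as one difference per column)."""
    sa = a.sequence if isinstance(a, ProteinRecord) else str(a)
    sb = b.sequence if isinstance(b, ProteinRecord) else str(b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    best = aligner.align(sa, sb)[0]
    blocks_a, blocks_b = best.aligned
    mismatches = 0
    aligned_a = 0
    for (s1, e1), (s2, e2) in zip(blocks_a, blocks_b):
        aligned_a += e1 - s1
        for x, y in zip(sa[s1:e1], sb[s2:e2]):
            if x != y:
                mismatches += 1
    gaps = (len(sa) - aligned_a) + (len(sb) - aligned_a)
    return mismatches + gaps


def find_paralog_pairs(clusters: Sequence[Cluster]) -> List[tuple]:
    """Within-genome member pairs of each nontrivial cluster (recent
    paralog candidates), with their pairwise difference counts."""
    out = []
    for c in clusters:
        if not c.nontrivial:
            continue
        by_genome: Dict[str, list] = {}
        for m in c.members:
            by_genome.setdefault(m.genome, []).append(m)
        for genome, members in sorted(by_genome.items()):
            if len(members) < 2:
                continue
            members.sort(key=lambda m: m.protein_id)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    out.append((c.cluster_id, genome,
                                members[i].protein_id, members[j].protein_id,
                                count_differences(members[i], members[j])))
    return out


def family_difference_tree(members: Sequence[ProteinRecord]):
    """Descriptive NJ tree of one family from pairwise difference
    counts (a distance-based substitute for model-based trees)."""
    from mitevol.trees import DistanceMatrix, neighbor_joining

    labels = [m.protein_id for m in members]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = count_differences(members[i], members[j])
    return neighbor_joining(DistanceMatrix(labels, d))
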