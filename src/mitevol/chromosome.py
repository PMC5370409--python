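"""Chromosome structures, breakpoint graphs and the weighted cut-and-join
rearrangement distance.

A genome is abstracted as a *chromosome structure*: a set of linear (``L``)
or circular (``C``) chromosomes, each an ordered list of strand-signed gene
occurrences.  Equivalently the structure is a set of *adjacencies* between
gene extremities (head/tail per occurrence); a linear chromosome is a path
of the extremity graph, a circular one a cycle.

The evolutionary model transforms one structure into another by weighted
operations:

=================  ====================================================  =======
operation          effect on the adjacency set                           default
=================  ====================================================  =======
``dcj``            cut two adjacencies / telomere pairs, rejoin the        1.2
                   four ends in an alternative pairing (inversions,
                   translocations, fusions, fissions; the linear
                   variant is the telomere-involving case)
``sesqui``         one cut plus one join touching three ends               1.1
``a_insert``       join two telomeres (e.g. circularisation)               1.0
``a_delete``       cut one adjacency (e.g. linearisation)                  0.9
``b_insert``       gain a gene occurrence                                  0.9
``b_delete``       lose a gene occurrence (flanks optionally healed)       1.0
=================  ====================================================  =======

Deletions of adjacencies or genes marked *special* by a caller-supplied
predicate are charged at separate (higher) costs; by default no edge is
special.

``distance`` searches for a minimum-total-cost operation sequence.  A
beam search over strictly mismatch-reducing operations supplies a valid
scenario (an upper bound, tight for short scenarios); on small gene
universes the bound is refined by an A* search whose admissible
potential weighs wrong/missing adjacencies and surplus/absent genes
with coefficients from a small linear program over the per-operation
mismatch-reduction capacities, making the result exact there (and
certified against ``distance_oracle``, an independent uniform-cost
search).
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, NamedTuple, Optional, Sequence

import numpy as np
from scipy.optimize import linprog
from scipy.optimize import linear_sum_assignment


# ---------------------------------------------------------------------------
# Domain types


class SignedGene(NamedTuple):
    """A strand-signed gene occurrence.

    ``orientation`` is +1 (reading strand) or -1 (complementary strand;
    rendered with a leading ``*`` in gene-order tables).  ``occurrence``
    disambiguates paralogous copies of the same family within a structure.
    """

    family: str
    occurrence: int = 1
    orientation: int = 1

    def __neg__(self) -> "SignedGene":
        return SignedGene(self.family, self.occurrence, -self.orientation)

    @property
    def label(self) -> str:
        name = self.family if self.occurrence == 1 else f"{self.family}#{self.occurrence}"
        return ("*" + name) if self.orientation < 0 else name


class Chromosome(NamedTuple):
    topology: str  # 'L' or 'C'
    genes: tuple  # tuple[SignedGene, ...]


def _as_signed(g) -> SignedGene:
    if isinstance(g, SignedGene):
        return g
    if isinstance(g, str):
        name = g
        orient = 1
        if name.startswith("*") or name.startswith("-"):
            orient = -1
            name = name[1:]
        occ = 1
        if "#" in name:
            name, snum = name.split("#", 1)
            occ = int(snum)
        return SignedGene(name, occ, orient)
    raise TypeError(f"cannot interpret {g!r} as a signed gene")


class ChromosomeStructure:
    """An ordered-gene representation of one genome.

    Parameters
    ----------
    chromosomes:
        Iterable of ``(topology, genes)`` pairs, topology ``'L'`` or
        ``'C'``.  Genes may be :class:`SignedGene` or compact strings like
        ``"cob"``, ``"*nad9#2"``.
    """

    __slots__ = ("chromosomes",)

    def __init__(self, chromosomes: Iterable):
        chroms = []
        for topo, genes in chromosomes:
            if topo not in ("L", "C"):
                raise ValueError(f"topology must be 'L' or 'C', got {topo!r}")
            genes = tuple(_as_signed(g) for g in genes)
            if not genes:
                raise ValueError("empty chromosome")
            chroms.append(Chromosome(topo, genes))
        self.chromosomes = tuple(chroms)
        seen = set()
        for ch in self.chromosomes:
            for g in ch.genes:
                key = (g.family, g.occurrence)
                if key in seen:
                    raise ValueError(f"duplicate gene occurrence {key}")
                seen.add(key)

    # -- convenience constructors ------------------------------------
    @classmethod
    def linear(cls, *genes) -> "ChromosomeStructure":
        return cls([("L", genes)])

    @classmethod
    def circular(cls, *genes) -> "ChromosomeStructure":
        return cls([("C", genes)])

    # -----------------------------------------------------------------
    def genes(self) -> list:
        return [g for ch in self.chromosomes for g in ch.genes]

    def gene_keys(self) -> frozenset:
        return frozenset((g.family, g.occurrence) for g in self.genes())

    def n_genes(self) -> int:
        return sum(len(ch.genes) for ch in self.chromosomes)

    def canonical(self) -> "ChromosomeStructure":
        st = structure_to_state(self)
        return state_to_structure(st)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ChromosomeStructure):
            return NotImplemented
        return structure_to_state(self) == structure_to_state(other)

    def __hash__(self) -> int:
        return hash(structure_to_state(self))

    def __repr__(self) -> str:
        parts = []
        for topo, genes in self.chromosomes:
            parts.append(topo + "[" + " ".join(g.label for g in genes) + "]")
        return "ChromosomeStructure(" + " ".join(parts) + ")"


@dataclass(frozen=True)
class OperationCosts:
    """Costs of the eight operation kinds.

    ``special_a_delete``/``special_b_delete`` apply only to edges a caller
    marks special via the predicate hooks of :func:`distance`.
    """

    dcj: float = 1.2
    sesqui: float = 1.1
    a_insert: float = 1.0
    b_delete: float = 1.0
    b_insert: float = 0.9
    a_delete: float = 0.9
    special_a_delete: float = 2.0
    special_b_delete: float = 2.5

    def __post_init__(self):
        for f in ("dcj", "sesqui", "a_insert", "b_delete", "b_insert",
                  "a_delete", "special_a_delete", "special_b_delete"):
            if getattr(self, f) < 0:
                raise ValueError(f"cost {f} must be non-negative")

    def scaled(self, lam: float) -> "OperationCosts":
        return OperationCosts(*(lam * getattr(self, f) for f in (
            "dcj", "sesqui", "a_insert", "b_delete", "b_insert",
            "a_delete", "special_a_delete", "special_b_delete")))


@dataclass(frozen=True)
class EvolutionEvent:
    """One elementary operation, replayable via :func:`apply_operation`.

    ``operands`` encodes the touched extremities/genes; its layout depends
    on ``op_kind`` (see :func:`apply_operation`).
    """

    op_kind: str
    operands: tuple
    cost: float

    def __repr__(self) -> str:
        return f"EvolutionEvent({self.op_kind}, {self.operands!r}, cost={self.cost})"


# ---------------------------------------------------------------------------
# State encoding: (genes, adjacencies)
#
# An extremity is ((family, occurrence), 'h'|'t'); an adjacency is a
# frozenset of two extremities.  Telomeres are extremities in no adjacency.


def _ext(gene_key, side):
    return (gene_key, side)


def _left_right(g: SignedGene):
    key = (g.family, g.occurrence)
    if g.orientation >= 0:
        return _ext(key, "t"), _ext(key, "h")
    return _ext(key, "h"), _ext(key, "t")


def structure_to_state(s: ChromosomeStructure):
    """Return the (gene set, adjacency set) encoding of a structure."""
    genes = set()
    adjs = set()
    for topo, chain in s.chromosomes:
        ends = [_left_right(g) for g in chain]
        for g in chain:
            genes.add((g.family, g.occurrence))
        for (l1, r1), (l2, r2) in zip(ends, ends[1:]):
            adjs.add(frozenset((r1, l2)))
        if topo == "C":
            adjs.add(frozenset((ends[-1][1], ends[0][0])))
    return frozenset(genes), frozenset(adjs)


def state_to_structure(state) -> ChromosomeStructure:
    """Rebuild the canonical ordered-gene structure from a state.

    Deterministic: linear chromosomes start from the lexicographically
    smaller end, circular ones from their smallest extremity; chromosomes
    are sorted by their gene tuples.
    """
    genes, adjs = state
    partner = {}
    for adj in adjs:
        a, b = tuple(adj) if len(adj) == 2 else (next(iter(adj)), next(iter(adj)))
        partner[a] = b
        partner[b] = a

    def walk(start_ext):
        """Traverse from a starting extremity; yields SignedGenes."""
        chain = []
        ext = start_ext
        visited_local = set()
        while True:
            gk, side = ext
            orient = 1 if side == "t" else -1
            chain.append(SignedGene(gk[0], gk[1], orient))
            visited_local.add(gk)
            other = _ext(gk, "h" if side == "t" else "t")
            nxt = partner.get(other)
            if nxt is None:
                return chain, None  # linear end
            if nxt[0] in visited_local:
                return chain, nxt  # closed a cycle
            ext = nxt

    unvisited = set(genes)
    # linear chromosomes: start at telomeric extremities
    telomeres = sorted(
        _ext(gk, side)
        for gk in genes
        for side in ("h", "t")
        if _ext(gk, side) not in partner
    )
    chroms = []
    for tel in telomeres:
        if tel[0] not in unvisited:
            continue
        chain, _ = walk(tel)
        rev = tuple(-g for g in reversed(chain))
        fwd = tuple(chain)
        chroms.append(Chromosome("L", min(fwd, rev)))
        unvisited -= {(g.family, g.occurrence) for g in chain}
    # remaining components are cycles
    while unvisited:
        gk = min(unvisited)
        chain, _ = walk(_ext(gk, "t"))
        n = len(chain)
        # canonical rotation/orientation: smallest of all rotations of both
        # directions
        fwd = tuple(chain)
        rev = tuple(-g for g in reversed(chain))
        candidates = [fwd[i:] + fwd[:i] for i in range(n)]
        candidates += [rev[i:] + rev[:i] for i in range(n)]
        chroms.append(Chromosome("C", min(candidates)))
        unvisited -= {(g.family, g.occurrence) for g in chain}
    chroms.sort()
    return ChromosomeStructure(chroms)


# ---------------------------------------------------------------------------
# Breakpoint graph


@dataclass
class BreakpointGraph:
    """Extremity graph of one structure: b-edges are genes, a-edges are
    adjacencies, telomeres are unsaturated extremities of linear
    chromosomes."""

    vertices: list
    b_edges: list  # (tail_ext, head_ext) per gene occurrence
    a_edges: list  # frozensets of two extremities
    telomeres: list


def build_graph(s: ChromosomeStructure) -> BreakpointGraph:
    if not s.chromosomes:
        raise ValueError("empty structure has no breakpoint graph")
    genes, adjs = structure_to_state(s)
    vertices = sorted(_ext(gk, side) for gk in genes for side in ("h", "t"))
    in_adj = set()
    for adj in adjs:
        in_adj.update(adj)
    return BreakpointGraph(
        vertices=vertices,
        b_edges=[(_ext(gk, "t"), _ext(gk, "h")) for gk in sorted(genes)],
        a_edges=sorted(adjs, key=lambda a: tuple(sorted(a))),
        telomeres=sorted(v for v in vertices if v not in in_adj),
    )


# ---------------------------------------------------------------------------
# Operation application


def _apply_to_state(state, ev: EvolutionEvent):
    """Apply one event to a (genes, adjacencies) state; returns new state.

    Operand layouts:

    * ``a_delete``: ``(adjacency,)``
    * ``a_insert``: ``(ext_x, ext_y)``
    * ``dcj``: ``(cut1, cut2, join1, join2)`` — each a frozenset of two
      extremities; a cut that is a current adjacency is removed, otherwise
      both its extremities must be telomeres ("telomere pair"); the joins
      must re-pair the same four ends differently.
    * ``sesqui``: ``(cut_adjacency, join)`` — join pairs one freed end
      with a current telomere.
    * ``b_insert``: ``(gene_key, signed_flag, cut_or_None, joins)`` —
      gene added; optional adjacency cut; ``joins`` are new adjacencies
      using the new gene's extremities.
    * ``b_delete``: ``(gene_key, heal)`` — gene and its incident
      adjacencies removed; if ``heal`` and the gene had two adjacencies to
      other genes, the two exposed foreign ends are joined.
    """
    genes, adjs = state
    genes = set(genes)
    adjs = set(adjs)
    kind = ev.op_kind

    def ends_of(genes_):
        return {_ext(gk, s) for gk in genes_ for s in ("h", "t")}

    saturated = set()
    for adj in adjs:
        saturated.update(adj)

    def require(cond, msg):
        if not cond:
            raise ValueError(f"illegal {kind}: {msg}")

    if kind == "a_delete":
        (adj,) = ev.operands
        require(adj in adjs, f"adjacency {set(adj)} not present")
        adjs.remove(adj)
    elif kind == "a_insert":
        x, y = ev.operands
        require(x != y, "join requires two distinct extremities")
        all_ends = ends_of(genes)
        require(x in all_ends and y in all_ends, "extremity not in structure")
        require(x not in saturated and y not in saturated, "extremity not a telomere")
        adjs.add(frozenset((x, y)))
    elif kind == "dcj":
        cut1, cut2, join1, join2 = ev.operands
        require(not (cut1 & cut2), "cuts share an extremity")
        freed = set(cut1) | set(cut2)
        require(len(freed) == 4, "dcj needs four distinct ends")
        for cut in (cut1, cut2):
            if cut in adjs:
                adjs.remove(cut)
            else:
                require(
                    all(e not in saturated for e in cut),
                    f"cut {set(cut)} is neither an adjacency nor a telomere pair",
                )
        require(set(join1) | set(join2) == freed and not (join1 & join2),
                "joins must re-pair the four freed ends")
        require({join1, join2} != {cut1, cut2}, "joins must differ from cuts")
        all_ends = ends_of(genes)
        require(freed <= all_ends, "extremity not in structure")
        adjs.add(join1)
        adjs.add(join2)
    elif kind == "sesqui":
        cut, join = ev.operands
        require(cut in adjs, f"cut {set(cut)} is not an adjacency")
        inter = cut & join
        require(len(inter) == 1, "join must reuse exactly one freed end")
        (tel,) = tuple(join - cut)
        require(tel not in saturated, f"{tel} is not a telomere")
        require(tel in ends_of(genes), "extremity not in structure")
        adjs.remove(cut)
        adjs.add(join)
    elif kind == "b_insert":
        gene_key, _sign, cut, joins = ev.operands
        require(gene_key not in genes, f"gene {gene_key} already present")
        new_ends = {_ext(gene_key, "h"), _ext(gene_key, "t")}
        if cut is not None:
            require(cut in adjs, f"cut {set(cut)} is not an adjacency")
            adjs.remove(cut)
            saturated -= set(cut)
        used = set()
        for j in joins:
            require(len(j) == 2, "join must pair two extremities")
            foreign = set(j) - new_ends
            require(len(set(j) & new_ends) >= 1, "join must touch the new gene")
            for e in foreign:
                require(e in ends_of(genes), "extremity not in structure")
                require(e not in saturated, f"{e} is not free")
            require(not (set(j) & used), "extremity joined twice")
            used |= set(j)
        genes.add(gene_key)
        for j in joins:
            adjs.add(frozenset(j))
    elif kind == "b_delete":
        gene_key, heal = ev.operands
        require(gene_key in genes, f"gene {gene_key} not present")
        gene_ends = {_ext(gene_key, "h"), _ext(gene_key, "t")}
        incident = [adj for adj in adjs if adj & gene_ends]
        foreign = [e for adj in incident for e in adj if e not in gene_ends]
        for adj in incident:
            adjs.remove(adj)
        genes.remove(gene_key)
        if heal:
            require(len(foreign) == 2, "healing needs two exposed foreign ends")
            adjs.add(frozenset(foreign))
    else:
        raise ValueError(f"unknown operation kind {kind!r}")

    # invariant: each extremity in at most one adjacency
    seen = set()
    for adj in adjs:
        for e in adj:
            require(e not in seen, f"extremity {e} saturated twice")
            seen.add(e)
    return frozenset(genes), frozenset(adjs)


def apply_operation(s: ChromosomeStructure, ev: EvolutionEvent) -> ChromosomeStructure:
    """Apply one evolution event to a structure; returns the new structure.

    Raises ``ValueError`` naming the violated invariant for illegal
    operand sets.
    """
    state = structure_to_state(s)
    return state_to_structure(_apply_to_state(state, ev))


def apply_events(s: ChromosomeStructure, events: Sequence[EvolutionEvent]) -> ChromosomeStructure:
    state = structure_to_state(s)
    for ev in events:
        state = _apply_to_state(state, ev)
    return state_to_structure(state)


# ---------------------------------------------------------------------------
# Distance search machinery


def _potential_coeffs(costs: OperationCosts, weights=(1.0, 1.0, 1.0, 1.0)):
    """Admissible mismatch weights (alpha, beta, gamma_del, gamma_ins).

    Solves a small LP: maximise the ``weights``-weighted coefficient sum
    subject to "no operation reduces the weighted mismatch count by more
    than its cost".  alpha weighs a present-but-wrong adjacency, beta a
    missing target adjacency, the gammas surplus/absent gene occurrences.
    ``weights`` is normally the start state's mismatch count vector, so
    the resulting potential is the strongest admissible bound *for that
    instance*; any feasible coefficient vector is admissible throughout
    the search because the constraints are state-independent.
    """
    # constraints  a*dB + b*dM + gd*dE + gi*dI <= cost, one per maximal
    # per-operation mismatch reduction (dominated cases omitted)
    cons = [
        ((2, 2, 0, 0), costs.dcj),    # cut 2 bad adjacencies, join 2 needed
        ((1, 2, 0, 0), costs.dcj),    # cut 1 bad + telomere pair, join 2 needed
        ((0, 2, 0, 0), costs.dcj),    # two telomere pairs, join 2 needed
        ((1, 1, 0, 0), costs.sesqui),
        ((0, 1, 0, 0), costs.a_insert),
        ((1, 0, 0, 0), costs.a_delete),
        # b_insert spliced into a bad adjacency, creating 2 needed
        ((1, 2, 0, 1), costs.b_insert),
        # b_delete with heal: drop surplus gene, its 2 bad adjacencies,
        # create 1 needed
        ((2, 1, 1, 0), costs.b_delete),
    ]
    A_ub = [list(c) for c, _ in cons]
    b_ub = [c for _, c in cons]
    obj = [-(w if w > 0 else 1e-3) for w in weights]
    res = linprog(
        c=obj,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=[(0, None)] * 4,
        method="highs",
    )
    if not res.success:  # degenerate (e.g. zero costs); fall back to zeros
        return (0.0, 0.0, 0.0, 0.0)
    return tuple(res.x)


def _match_occurrences(s1: ChromosomeStructure, s2: ChromosomeStructure):
    """Relabel duplicate gene occurrences of ``s2`` to best match ``s1``.

    Occurrences of the same family are paired across the two structures by
    minimum-cost bipartite assignment on flanking-context similarity, so
    that paralogous copies line up before graph construction.  Returns the
    relabelled copy of ``s2`` and the occurrence mapping used.
    """

    def contexts(s):
        ctx = {}
        for topo, chain in s.chromosomes:
            n = len(chain)
            for i, g in enumerate(chain):
                if topo == "C":
                    left = chain[(i - 1) % n]
                    right = chain[(i + 1) % n]
                else:
                    left = chain[i - 1] if i > 0 else None
                    right = chain[i + 1] if i < n - 1 else None
                sgn = g.orientation

                def flank(x):
                    if x is None:
                        return None
                    return (x.family, x.orientation * sgn)

                ctx[(g.family, g.occurrence)] = (flank(left), flank(right))
        return ctx

    fams1 = {}
    fams2 = {}
    for g in s1.genes():
        fams1.setdefault(g.family, []).append(g.occurrence)
    for g in s2.genes():
        fams2.setdefault(g.family, []).append(g.occurrence)
    ctx1, ctx2 = contexts(s1), contexts(s2)

    mapping = {}  # (family, old_occ in s2) -> new occ
    for fam in sorted(fams2):
        occ2 = sorted(fams2[fam])
        occ1 = sorted(fams1.get(fam, []))
        if not occ1:
            # keep labels, but avoid clashing with s1 numbering space
            for o in occ2:
                mapping[(fam, o)] = o
            continue
        cost = np.zeros((len(occ2), len(occ1)))
        for i, o2 in enumerate(occ2):
            for j, o1 in enumerate(occ1):
                l2, r2 = ctx2[(fam, o2)]
                l1, r1 = ctx1[(fam, o1)]
                # orientation-insensitive flank agreement (either direction)
                direct = (l1 != l2) + (r1 != r2)
                flipped = (l1 != (r2 if r2 is None else (r2[0], -r2[1]))) + (
                    r1 != (l2 if l2 is None else (l2[0], -l2[1])))
                cost[i, j] = min(direct, flipped)
        rows, cols = linear_sum_assignment(cost)
        assigned = {}
        for i, j in zip(rows, cols):
            assigned[occ2[i]] = occ1[j]
        next_free = max(occ1 + occ2) + 1
        for o in occ2:
            if o in assigned:
                mapping[(fam, o)] = assigned[o]
            else:
                mapping[(fam, o)] = next_free
                next_free += 1

    chroms = []
    for topo, chain in s2.chromosomes:
        chroms.append((topo, [
            SignedGene(g.family, mapping.get((g.family, g.occurrence), g.occurrence),
                       g.orientation)
            for g in chain
        ]))
    return ChromosomeStructure(chroms), mapping


# ---------------------------------------------------------------------------
# Fast integer-encoded search engine
#
# Extremities of gene i (in the sorted universe of the two structures) are
# 2i (tail) and 2i+1 (head); an adjacency is a sorted int pair; a state is
# (gene bitmask, frozenset of adjacency pairs).  The engine backs the
# greedy scenario builder, the guided A* refinement and the uniform-cost
# oracle, and decodes chosen operations back into replayable
# :class:`EvolutionEvent` objects.


class _Engine:
    __slots__ = ("keys", "index", "n", "costs", "special_a", "special_b",
                 "start", "target", "tmask", "tadjs", "base_cost")

    def __init__(self, st1, st2, costs, special_a, special_b):
        self.keys = sorted(st1[0] | st2[0])
        self.index = {k: i for i, k in enumerate(self.keys)}
        self.n = len(self.keys)
        self.costs = costs
        self.special_a = special_a
        self.special_b = special_b
        self.base_cost = {
            "a_delete": costs.a_delete,
            "a_insert": costs.a_insert,
            "sesqui": costs.sesqui,
            "dcj": costs.dcj,
            "b_delete": costs.b_delete,
            "b_insert": costs.b_insert,
        }
        self.start = self.encode(st1)
        self.target = self.encode(st2)
        self.tmask, self.tadjs = self.target

    # -- encoding -----------------------------------------------------
    def encode(self, st):
        genes, adjs = st
        mask = 0
        for k in genes:
            mask |= 1 << self.index[k]
        enc = set()
        for adj in adjs:
            a, b = sorted(self._enc_ext(e) for e in adj)
            enc.add((a, b))
        return (mask, frozenset(enc))

    def _enc_ext(self, e):
        key, side = e
        return 2 * self.index[key] + (1 if side == "h" else 0)

    def _dec_ext(self, x):
        return (self.keys[x // 2], "h" if x & 1 else "t")

    def _dec_adj(self, pair):
        return frozenset(self._dec_ext(x) for x in pair)

    def decode_event(self, op) -> EvolutionEvent:
        kind, data = op
        if kind == "a_delete":
            operands = (self._dec_adj(data[0]),)
        elif kind == "a_insert":
            operands = (self._dec_ext(data[0]), self._dec_ext(data[1]))
        elif kind == "sesqui":
            adj, kept, tel = data
            operands = (self._dec_adj(adj),
                        frozenset((self._dec_ext(kept), self._dec_ext(tel))))
        elif kind == "dcj":
            c1, c2, j1, j2 = data
            operands = (self._dec_adj(c1), self._dec_adj(c2),
                        self._dec_adj(j1), self._dec_adj(j2))
        elif kind == "b_delete":
            gi, heal = data
            operands = (self.keys[gi], heal)
        elif kind == "b_insert":
            gi, cut, joins = data
            operands = (self.keys[gi], 1,
                        None if cut is None else self._dec_adj(cut),
                        tuple(self._dec_adj(j) for j in joins))
        else:
            raise ValueError(kind)
        return EvolutionEvent(kind, operands, self.cost(op))

    # -- costs --------------------------------------------------------
    def cost(self, op):
        kind, data = op
        if kind == "a_delete" and self.special_a is not None:
            if self.special_a(self._dec_adj(data[0])):
                return self.costs.special_a_delete
        if kind == "b_delete" and self.special_b is not None:
            if self.special_b(self.keys[data[0]]):
                return self.costs.special_b_delete
        return self.base_cost[kind]

    # -- state inspection ---------------------------------------------
    def mismatch(self, state):
        mask, adjs = state
        bad = len(adjs - self.tadjs)
        missing = len(self.tadjs - adjs)
        extra = (mask & ~self.tmask).bit_count()
        absent = (self.tmask & ~mask).bit_count()
        return bad, missing, extra, absent

    # -- operation enumeration -----------------------------------------
    def ops(self, state):
        """Yield (kind, data) for every legal operation, deterministically.

        Gene insertions are restricted to target gene occurrences:
        inserting any other gene can never be part of a minimum-cost
        scenario under non-negative costs, as its later deletion undoes
        it at extra cost.
        """
        mask, adjs = state
        sat = set()
        for a, b in adjs:
            sat.add(a)
            sat.add(b)
        present = [i for i in range(self.n) if mask >> i & 1]
        tel = [e for i in present for e in (2 * i, 2 * i + 1) if e not in sat]
        adj_list = sorted(adjs)
        n_tel = len(tel)

        for adj in adj_list:
            yield ("a_delete", (adj,))
        for xi in range(n_tel):
            for yi in range(xi + 1, n_tel):
                yield ("a_insert", (tel[xi], tel[yi]))
        for adj in adj_list:
            for kept in adj:
                for t in tel:
                    yield ("sesqui", (adj, kept, t))
        cut_objects = adj_list + [
            (tel[xi], tel[yi]) for xi in range(n_tel) for yi in range(xi + 1, n_tel)
        ]
        for ii in range(len(cut_objects)):
            a, b = cut_objects[ii]
            for jj in range(ii + 1, len(cut_objects)):
                c, d = cut_objects[jj]
                if a == c or a == d or b == c or b == d:
                    continue
                for j1, j2 in (
                    ((min(a, c), max(a, c)), (min(b, d), max(b, d))),
                    ((min(a, d), max(a, d)), (min(b, c), max(b, c))),
                ):
                    if (j1 == cut_objects[ii] and j2 == cut_objects[jj]) or (
                        j2 == cut_objects[ii] and j1 == cut_objects[jj]
                    ):
                        continue
                    yield ("dcj", (cut_objects[ii], cut_objects[jj], j1, j2))
        for i in present:
            t0, h0 = 2 * i, 2 * i + 1
            foreign = [
                x for adj in adj_list if t0 in adj or h0 in adj
                for x in adj if x != t0 and x != h0
            ]
            yield ("b_delete", (i, False))
            if len(foreign) == 2:
                yield ("b_delete", (i, True))
        missing_genes = self.tmask & ~mask
        for i in range(self.n):
            if not missing_genes >> i & 1:
                continue
            t0, h0 = 2 * i, 2 * i + 1
            yield ("b_insert", (i, None, ()))            # own linear chromosome
            yield ("b_insert", (i, None, ((t0, h0),)))   # own circular chromosome
            for t in tel:                                # extend at a telomere
                for e in (t0, h0):
                    yield ("b_insert", (i, None, ((min(t, e), max(t, e)),)))
            for xi in range(n_tel):                      # bridge two telomeres
                for yi in range(xi + 1, n_tel):
                    x, y = tel[xi], tel[yi]
                    yield ("b_insert", (i, None,
                                        ((min(x, t0), max(x, t0)),
                                         (min(h0, y), max(h0, y)))))
                    yield ("b_insert", (i, None,
                                        ((min(x, h0), max(x, h0)),
                                         (min(t0, y), max(t0, y)))))
            for adj in adj_list:                         # splice into an adjacency
                x, y = adj
                yield ("b_insert", (i, adj,
                                    ((min(x, t0), max(x, t0)),
                                     (min(h0, y), max(h0, y)))))
                yield ("b_insert", (i, adj,
                                    ((min(x, h0), max(x, h0)),
                                     (min(t0, y), max(t0, y)))))

    def apply(self, state, op):
        mask, adjs = state
        kind, data = op
        if kind == "a_delete":
            return (mask, adjs - {data[0]})
        if kind == "a_insert":
            x, y = data
            return (mask, adjs | {(min(x, y), max(x, y))})
        if kind == "sesqui":
            adj, kept, t = data
            return (mask, (adjs - {adj}) | {(min(kept, t), max(kept, t))})
        if kind == "dcj":
            c1, c2, j1, j2 = data
            return (mask, (adjs - {c1, c2}) | {j1, j2})
        if kind == "b_delete":
            gi, heal = data
            t0, h0 = 2 * gi, 2 * gi + 1
            incident = [adj for adj in adjs if t0 in adj or h0 in adj]
            new = set(adjs)
            for adj in incident:
                new.discard(adj)
            if heal:
                foreign = [x for adj in incident for x in adj if x != t0 and x != h0]
                a, b = foreign
                new.add((min(a, b), max(a, b)))
            return (mask & ~(1 << gi), frozenset(new))
        if kind == "b_insert":
            gi, cut, joins = data
            new = set(adjs)
            if cut is not None:
                new.discard(cut)
            for j in joins:
                new.add(j)
            return (mask | (1 << gi), frozenset(new))
        raise ValueError(kind)

    def delta(self, state, op):
        """Signed change in total mismatch count caused by ``op``;
        computed without building the successor state."""
        mask, adjs = state
        tadjs = self.tadjs
        kind, data = op

        def rm(adj):  # removing a present adjacency
            return -1 if adj not in tadjs else 1

        def ad(adj):  # adding an adjacency between free ends
            return -1 if adj in tadjs else 1

        if kind == "a_delete":
            return rm(data[0])
        if kind == "a_insert":
            x, y = data
            return ad((min(x, y), max(x, y)))
        if kind == "sesqui":
            adj, kept, t = data
            return rm(adj) + ad((min(kept, t), max(kept, t)))
        if kind == "dcj":
            c1, c2, j1, j2 = data
            d = ad(j1) + ad(j2)
            if c1 in adjs:
                d += rm(c1)
            if c2 in adjs:
                d += rm(c2)
            return d
        if kind == "b_delete":
            gi, heal = data
            t0, h0 = 2 * gi, 2 * gi + 1
            d = -1 if not self.tmask >> gi & 1 else 1
            incident = [adj for adj in adjs if t0 in adj or h0 in adj]
            for adj in incident:
                d += rm(adj)
            if heal:
                foreign = [x for adj in incident for x in adj if x != t0 and x != h0]
                a, b = foreign
                d += ad((min(a, b), max(a, b)))
            return d
        if kind == "b_insert":
            gi, cut, joins = data
            d = -1 if self.tmask >> gi & 1 else 1
            if cut is not None:
                d += rm(cut)
            for j in joins:
                d += ad(j)
            return d
        raise ValueError(kind)

    def greedy_candidates(self, state):
        """Yield (op, delta, cost) for every strictly mismatch-reducing
        operation, enumerated goal-directedly: an improving cut-and-join
        operation must create a missing target adjacency, so rearrangement
        candidates are derived from the missing-adjacency list instead of
        from all operand pairs.  The set contains every improving
        operation of :meth:`ops` (gene operations are scored directly)."""
        mask, adjs = state
        tadjs = self.tadjs
        tmask = self.tmask
        partner = {}
        for adj in adjs:
            a, b = adj
            partner[a] = adj
            partner[b] = adj
        present = [i for i in range(self.n) if mask >> i & 1]
        present_ends = {e for i in present for e in (2 * i, 2 * i + 1)}
        tel = sorted(present_ends - partner.keys())

        def rm(adj):
            return -1 if adj not in tadjs else 1

        def ad(adj):
            return -1 if adj in tadjs else 1

        def emit(kind, data, delta):
            return (kind, data), delta, self.cost((kind, data))

        # cut a wrong adjacency
        for adj in sorted(adjs):
            if adj not in tadjs:
                yield emit("a_delete", (adj,), -1)
        # gene loss (score both variants; only surplus genes usually help)
        for i in present:
            t0, h0 = 2 * i, 2 * i + 1
            incident = {partner[e] for e in (t0, h0) if e in partner}
            base = (-1 if not tmask >> i & 1 else 1) + sum(rm(a) for a in incident)
            if base < 0:
                yield emit("b_delete", (i, False), base)
            foreign = [x for adj in incident for x in adj if x != t0 and x != h0]
            if len(foreign) == 2:
                a, b = foreign
                dh = base + ad((min(a, b), max(a, b)))
                if dh < 0:
                    yield emit("b_delete", (i, True), dh)
        # gene gain variants
        missing_genes = tmask & ~mask
        for i in range(self.n):
            if not missing_genes >> i & 1:
                continue
            t0, h0 = 2 * i, 2 * i + 1
            yield emit("b_insert", (i, None, ()), -1)
            dc = -1 + ad((t0, h0))
            if dc < 0:
                yield emit("b_insert", (i, None, ((t0, h0),)), dc)
            for t in tel:
                for e in (t0, h0):
                    j = (min(t, e), max(t, e))
                    dj = -1 + ad(j)
                    if dj < 0:
                        yield emit("b_insert", (i, None, (j,)), dj)
            for xi in range(len(tel)):
                for yi in range(xi + 1, len(tel)):
                    x, y = tel[xi], tel[yi]
                    for j1, j2 in ((((min(x, t0), max(x, t0)), (min(h0, y), max(h0, y)))),
                                   (((min(x, h0), max(x, h0)), (min(t0, y), max(t0, y))))):
                        dj = -1 + ad(j1) + ad(j2)
                        if dj < 0:
                            yield emit("b_insert", (i, None, (j1, j2)), dj)
            for adj in sorted(adjs):
                x, y = adj
                for j1, j2 in ((((min(x, t0), max(x, t0)), (min(h0, y), max(h0, y)))),
                               (((min(x, h0), max(x, h0)), (min(t0, y), max(t0, y))))):
                    dj = -1 + rm(adj) + ad(j1) + ad(j2)
                    if dj < 0:
                        yield emit("b_insert", (i, adj, (j1, j2)), dj)
        # rearrangements that realise a missing target adjacency
        missing = sorted(adj for adj in tadjs - adjs
                         if adj[0] in present_ends and adj[1] in present_ends)
        free_missing = []
        for adj in missing:
            x, y = adj
            px, py = partner.get(x), partner.get(y)
            if px is None and py is None:
                yield emit("a_insert", (x, y), -1)
                free_missing.append(adj)
                continue
            if px is not None and py is None:
                bound_adj, kept, free_end = px, x, y
            elif px is None and py is not None:
                bound_adj, kept, free_end = py, y, x
            else:
                if px == py:
                    continue  # both ends in one (wrong-pairing) adjacency
                (w,) = [e for e in px if e != x]
                (z,) = [e for e in py if e != y]
                dd = rm(px) + rm(py) - 1 + ad((min(w, z), max(w, z)))
                if dd < 0:
                    yield emit("dcj", (px, py, adj,
                                       (min(w, z), max(w, z))), dd)
                continue
            # sesqui: cut the bound end loose and join it to the free end
            ds = rm(bound_adj) - 1
            if ds < 0:
                yield emit("sesqui", (bound_adj, kept, free_end), ds)
            # dcj with a telomere pair as the second cut object
            (w,) = [e for e in bound_adj if e != kept]
            for p in tel:
                if p == free_end:
                    continue
                dd = rm(bound_adj) - 1 + ad((min(w, p), max(w, p)))
                if dd < 0:
                    c2 = (min(free_end, p), max(free_end, p))
                    yield emit("dcj", (bound_adj, c2, adj,
                                       (min(w, p), max(w, p))), dd)
        # dcj realising two missing adjacencies from four telomeres
        for ai in range(len(free_missing)):
            for bi in range(ai + 1, len(free_missing)):
                a1, a2 = free_missing[ai], free_missing[bi]
                if set(a1) & set(a2):
                    continue
                c1 = (min(a1[0], a2[0]), max(a1[0], a2[0]))
                c2 = (min(a1[1], a2[1]), max(a1[1], a2[1]))
                if {c1, c2} == {a1, a2}:
                    c1 = (min(a1[0], a2[1]), max(a1[0], a2[1]))
                    c2 = (min(a1[1], a2[0]), max(a1[1], a2[0]))
                yield emit("dcj", (c1, c2, a1, a2), -2)

    # -- cheap admissible lower bound (used by the capped oracle) ------
    def cheap_bound(self, state):
        """Admissible lower bound on remaining cost, independent of the
        LP potential: gene content changes need one b-op each; wrong /
        missing adjacencies need cut / join capacity bounded per unit
        cost."""
        bad, missing, extra, absent = self.mismatch(state)
        c = self.costs
        bd = c.b_delete if self.special_b is None else min(c.b_delete, c.special_b_delete)
        ad_ = c.a_delete if self.special_a is None else min(c.a_delete, c.special_a_delete)
        gene_bound = extra * bd + absent * c.b_insert

        def rate(cap, cost):
            return cap / cost if cost > 0 else float("inf")

        kcut = max(rate(2, c.dcj), rate(1, c.sesqui), rate(1, ad_),
                   rate(2, bd), rate(1, c.b_insert))
        kjoin = max(rate(2, c.dcj), rate(1, c.sesqui), rate(1, c.a_insert),
                    rate(2, c.b_insert), rate(1, bd))
        cut_bound = bad / kcut if kcut != float("inf") else 0.0
        join_bound = missing / kjoin if kjoin != float("inf") else 0.0
        return max(gene_bound, cut_bound, join_bound)


def _greedy_scenario_engine(eng: "_Engine", beam_width: int = 2,
                            max_steps: int = 100_000):
    """Build a valid (not necessarily minimal) scenario by beam search
    over strictly mismatch-reducing operations, preferring the largest
    mismatch reduction per unit cost and ranking beam states by accrued
    cost plus an admissible bound on the remainder.  Terminates because
    a strictly mismatch-reducing operation always exists (cut a wrong
    adjacency / drop a surplus gene / insert an absent gene / join a
    missing adjacency); every path completes within the initial
    mismatch count steps."""
    target = eng.target
    frontier = [(0.0, eng.start, [])]
    best_complete = None
    for _ in range(max_steps):
        nxt = {}
        for total, cur, ops in frontier:
            if cur == target:
                if best_complete is None or total < best_complete[0]:
                    best_complete = (total, ops)
                continue
            scored = []
            for op, d, cost in eng.greedy_candidates(cur):
                scored.append(((-d / (cost + 1e-9), -cost), op, cost))
            if not scored:
                raise RuntimeError("greedy scenario stalled")
            scored.sort(key=lambda t: t[0], reverse=True)
            for _, op, cost in scored[:beam_width]:
                st = eng.apply(cur, op)
                ntotal = total + cost
                if st not in nxt or ntotal < nxt[st][0]:
                    nxt[st] = (ntotal, ops + [op])
        if not nxt:
            break
        ranked = sorted(
            ((tot + eng.cheap_bound(st), tot, st, ops)
             for st, (tot, ops) in nxt.items()),
            key=lambda t: t[0])
        if best_complete is not None:
            ranked = [r for r in ranked if r[0] < best_complete[0] - 1e-12]
        frontier = [(tot, st, ops) for _, tot, st, ops in ranked[:beam_width]]
        if not frontier:
            break
    if best_complete is None:
        raise RuntimeError("greedy scenario exceeded step budget")
    return best_complete


def _astar_engine(eng: "_Engine", coeffs, upper_bound, node_budget):
    """A* over engine states with the LP-potential heuristic; returns
    (cost, ops) or None if the node budget is exhausted first."""
    alpha, beta, gd, gi = coeffs

    def h(st):
        b, m, e, i = eng.mismatch(st)
        return alpha * b + beta * m + gd * e + gi * i

    start = eng.start
    target = eng.target
    counter = itertools.count()
    heap = [(h(start), 0.0, next(counter), start)]
    best_g = {start: 0.0}
    parent = {start: None}
    expanded = 0
    while heap:
        f, g, _, cur = heapq.heappop(heap)
        if g > best_g.get(cur, float("inf")) + 1e-12:
            continue
        if cur == target:
            ops = []
            node = cur
            while parent[node] is not None:
                prev, op = parent[node]
                ops.append(op)
                node = prev
            ops.reverse()
            return g, ops
        expanded += 1
        if expanded > node_budget:
            return None
        for op in eng.ops(cur):
            ng = g + eng.cost(op)
            if ng > upper_bound + 1e-9:
                continue
            nxt = eng.apply(cur, op)
            if ng < best_g.get(nxt, float("inf")) - 1e-12:
                hn = h(nxt)
                if ng + hn > upper_bound + 1e-9:
                    continue
                best_g[nxt] = ng
                parent[nxt] = (cur, op)
                heapq.heappush(heap, (ng + hn, ng, next(counter), nxt))
    return None


def _dijkstra_engine(eng: "_Engine", max_cost):
    """Plain uniform-cost search to the target, capped at ``max_cost``;
    states provably unable to beat the cap (by the cheap admissible
    bound) are discarded.  Returns the exact optimum or None."""
    start = eng.start
    target = eng.target
    counter = itertools.count()
    heap = [(0.0, next(counter), start)]
    dist = {start: 0.0}
    while heap:
        g, _, cur = heapq.heappop(heap)
        if g > dist.get(cur, float("inf")) + 1e-12:
            continue
        if cur == target:
            return g
        for op in eng.ops(cur):
            ng = g + eng.cost(op)
            if ng > max_cost + 1e-9:
                continue
            nxt = eng.apply(cur, op)
            if ng < dist.get(nxt, float("inf")) - 1e-12:
                if ng + eng.cheap_bound(nxt) > max_cost + 1e-9:
                    continue
                dist[nxt] = ng
                heapq.heappush(heap, (ng, next(counter), nxt))
    return None


def distance(
    s1: ChromosomeStructure,
    s2: ChromosomeStructure,
    costs: OperationCosts = OperationCosts(),
    special_a: Optional[Callable] = None,
    special_b: Optional[Callable] = None,
    node_budget: int = 200_000,
    return_events: bool = True,
):
    """Minimum-cost directed transformation of ``s1`` into ``s2``.

    Returns ``(cost, events)``; replaying ``events`` on ``s1`` with
    :func:`apply_events` yields ``s2`` (up to canonical relabelling of
    paralogous occurrence indices).  A greedy mismatch-descent scenario
    provides an upper bound; when the combined gene universe is small the
    bound is refined by an A* search guided by an admissible LP-derived
    potential, which is exact whenever it completes within
    ``node_budget`` expansions.
    """
    s2m, _ = _match_occurrences(s1, s2)
    st1 = structure_to_state(s1)
    st2 = structure_to_state(s2m)
    if st1 == st2:
        return (0.0, []) if return_events else 0.0
    eng = _Engine(st1, st2, costs, special_a, special_b)
    g_cost, g_ops = _greedy_scenario_engine(eng)
    result = (g_cost, g_ops)
    # Refine by A* when the gene universe is small enough that the state
    # space is bounded; larger instances keep the greedy scenario (an
    # upper bound, tight for short scenarios).
    if eng.n <= 9:
        coeffs = _potential_coeffs(costs, weights=eng.mismatch(eng.start))
        exact = _astar_engine(eng, coeffs, upper_bound=g_cost,
                              node_budget=node_budget)
        if exact is not None:
            result = exact
    if not return_events:
        return result[0]
    return result[0], [eng.decode_event(op) for op in result[1]]


def distance_oracle(
    s1: ChromosomeStructure,
    s2: ChromosomeStructure,
    costs: OperationCosts = OperationCosts(),
    max_cost: Optional[float] = None,
    special_a: Optional[Callable] = None,
    special_b: Optional[Callable] = None,
):
    """Exact minimum cost by uniform-cost (Dijkstra) search over the
    operation-induced state space, capped at ``max_cost``.

    When ``max_cost`` is omitted the cap is the cost of a valid greedy
    scenario — always an upper bound on the optimum, so the capped search
    still returns the exact minimum.  Intended for small instances
    (practical bound: about six total gene occurrences).  Raises
    ``LookupError`` when no scenario within the explicit cap exists
    ("unknown >= max_cost" — never a wrong number).
    """
    s2m, _ = _match_occurrences(s1, s2)
    st1 = structure_to_state(s1)
    st2 = structure_to_state(s2m)
    if st1 == st2:
        return 0.0
    eng = _Engine(st1, st2, costs, special_a, special_b)
    capped = max_cost
    if capped is None:
        capped, _ = _greedy_scenario_engine(eng)
    found = _dijkstra_engine(eng, capped)
    if found is None:
        raise LookupError(
            f"no scenario of cost <= {capped} found (unknown >= {capped})")
    return found


def structures_equivalent(a: ChromosomeStructure, b: ChromosomeStructure) -> bool:
    """Equality up to renumbering of paralogous occurrence indices.

    Occurrence labels of duplicated gene families are arbitrary
    bookkeeping; two structures that differ only by such a renumbering
    describe the same genome."""
    if a == b:
        return True
    fams_a: dict = {}
    fams_b: dict = {}
    for g in a.genes():
        fams_a.setdefault(g.family, []).append(g.occurrence)
    for g in b.genes():
        fams_b.setdefault(g.family, []).append(g.occurrence)
    if set(fams_a) != set(fams_b):
        return False
    if any(len(fams_a[f]) != len(fams_b[f]) for f in fams_a):
        return False
    multi = [f for f in fams_a if len(fams_a[f]) > 1]
    if not multi:
        return False
    if any(len(fams_a[f]) > 4 for f in multi):
        raise ValueError("too many occurrences for equivalence check")
    state_a = structure_to_state(a)
    for combo in itertools.product(*[
        itertools.permutations(sorted(fams_a[f])) for f in multi
    ]):
        remap = {}
        for f, perm in zip(multi, combo):
            for old, new in zip(sorted(fams_b[f]), perm):
                remap[(f, old)] = new
        chroms = []
        for topo, genes in b.chromosomes:
            chroms.append((topo, [
                SignedGene(g.family, remap.get((g.family, g.occurrence), g.occurrence),
                           g.orientation) for g in genes
            ]))
        if structure_to_state(ChromosomeStructure(chroms)) == state_a:
            return True
    return False


def distance_matrix(
    structures: dict,
    costs: OperationCosts = OperationCosts(),
    symmetrize: str = "mean",
    node_budget: int = 100_000,
):
    """All-pairs distance matrix over a ``label -> structure`` mapping.

    The directed distance is asymmetric when insertion and deletion costs
    differ; ``symmetrize`` chooses ``mean`` (arithmetic) or ``min``.
    Returns a :class:`mitevol.trees.DistanceMatrix`.
    """
    from mitevol.trees import DistanceMatrix

    if symmetrize not in ("mean", "min"):
        raise ValueError("symmetrize must be 'mean' or 'min'")
    labels = sorted(structures)
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        dij = distance(structures[labels[i]], structures[labels[j]], costs,
                       node_budget=node_budget, return_events=False)
        dji = distance(structures[labels[j]], structures[labels[i]], costs,
                       node_budget=node_budget, return_events=False)
        v = (dij + dji) / 2.0 if symmetrize == "mean" else min(dij, dji)
        d[i, j] = d[j, i] = v
    return DistanceMatrix(labels, d)
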