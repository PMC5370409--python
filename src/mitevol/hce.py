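"""Discovery of highly conserved elements (HCEs) across genomes.

An HCE is a cluster of near-identical genomic *words* shared between (or
repeated within) genomes, found without reference to gene annotation;
fully invariant clusters are the ultraconserved special case.  The
pipeline is seeded k-mer matching, X-drop extension, overlap merging,
and clique extraction from the word similarity graph by minimum-degree
peeling:

1. ``build_key_index`` — exact ``key_length``-mers of both strands
   (low-complexity keys masked), dropping keys above ``max_key_repeat``
   occurrences;
2. ``grow_words`` — seed pairs are extended by an X-drop scan tied to
   ``max_word_cost``; overlapping extensions on one genome merge when
   they share at least ``min_overlap`` bases, merged word ends are
   trimmed to the region supported by two or more extensions, and
   merged words must reach ``min_word_length`` and stay within
   ``max_compaction_ratio`` of their seed support;
3. ``cluster_words`` — words become vertices, pairs with
   ``word_cost <= max_word_cost`` become edges, and maximal
   threshold-cliques are peeled off; every emitted HCE has all pairwise
   member costs within the threshold.

Words are stored on their lexicographically canonical strand (the
smaller of slice and reverse complement) and compared in both
orientations, so reverse-complementing every input genome leaves HCE
membership unchanged.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class HceParams:
    """Parameters of the HCE search (defaults are the standard set).

    ``min_diff_words_word`` is the minimum number of member words per
    emitted HCE; ``min_diff_words_key`` requires that many members to
    share at least one exact key.
    """

    key_length: int = 8
    min_word_length: int = 24
    max_word_cost: float = 3.1
    min_overlap: int = 20
    max_consecutive_deletions: int = 0
    deletion_cost: float = 2.1
    max_key_repeat: int = 1000
    max_compaction_ratio: float = 2.2
    min_diff_words_word: int = 4
    min_diff_words_key: int = 3

    def __post_init__(self):
        if self.key_length > self.min_word_length:
            raise ValueError("key_length must not exceed min_word_length")
        if self.max_word_cost < 0 or self.deletion_cost < 0:
            raise ValueError("costs must be non-negative")


@dataclass(frozen=True)
class Word:
    """A candidate conserved word on one genome.

    ``start`` is the 1-based forward-strand coordinate of the leftmost
    base of the occupied interval; ``sequence`` is the canonical-strand
    reading (the genome slice for ``+``, its reverse complement for
    ``-``).
    """

    genome: str
    strand: str
    start: int
    length: int
    sequence: str

    @property
    def end(self) -> int:  # 1-based inclusive
        return self.start + self.length - 1


@dataclass
class HCE:
    hce_id: int
    members: List[Word]
    consensus: str

    def genomes(self) -> set:
        return {w.genome for w in self.members}


@dataclass
class BinaryMatrix:
    """Presence/absence of each HCE in each genome (cells 0/1)."""

    row_labels: List[str]
    col_labels: List[int]
    cells: list  # rows x cols of 0/1

    def __post_init__(self):
        arr = np.asarray(self.cells, dtype=int)
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("matrix cells must be 0/1")
        if arr.size and (arr.sum(axis=0) == 0).any():
            raise ValueError("all-zero column in presence matrix")
        self.cells = arr.tolist()

    @property
    def shape(self):
        return (len(self.row_labels), len(self.col_labels))


# ---------------------------------------------------------------------------
# Key index


def build_key_index(genomes: Sequence, params: HceParams = HceParams()) -> Dict[str, list]:
    """Index every exact k-mer of both strands of every genome.

    Keys are stored in canonical (lexicographically smaller) strand
    form; each occurrence is ``(accession, strand, pos)`` with ``pos``
    1-based on the forward strand and ``strand`` telling which strand
    reads the canonical form.  Keys occurring more than
    ``max_key_repeat`` times in total are discarded.
    """
    if not genomes:
        raise ValueError("no genomes to index")
    k = params.key_length
    index: Dict[str, list] = {}
    for g in genomes:
        seq = g.sequence.upper()
        if len(seq) < k:
            warnings.warn(f"{g.accession}: sequence shorter than key length, skipped")
            continue
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if any(c not in "ACGT" for c in kmer):
                continue
            if len(set(kmer)) < 3:
                continue  # low-complexity mask (homopolymers, 2-letter repeats)
            rc = revcomp(kmer)
            canon, strand = (kmer, "+") if kmer <= rc else (rc, "-")
            index.setdefault(canon, []).append((g.accession, strand, i + 1))
    return {
        key: occs for key, occs in index.items()
        if len(occs) <= params.max_key_repeat
    }


# ---------------------------------------------------------------------------
# Word cost


def _rl_gap_dp(x: str, y: str, dcost: float, maxrun: int) -> float:
    """Minimum cost of a global correspondence of two equal-length
    windows: mismatches cost 1, deleted bases ``dcost`` each, with at
    most ``maxrun`` consecutive deletions."""
    INF = float("inf")
    lx, ly = len(x), len(y)
    # dp state: (j, run) -> cost, rolled over i
    prev = {(0, 0): 0.0}
    for j in range(1, ly + 1):
        r = j
        prev[(j, min(r, maxrun))] = j * dcost if j <= maxrun else INF
    for i in range(1, lx + 1):
        cur = {}
        base = i * dcost if i <= maxrun else INF
        if base < INF:
            cur[(0, min(i, maxrun))] = base
        for j in range(1, ly + 1):
            best = {}
            for (r, c) in [(0, prev.get((j - 1, rr), INF) +
                            (0 if x[i - 1] == y[j - 1] else 1))
                           for rr in range(maxrun + 1)]:
                if c < best.get(r, INF):
                    best[r] = c
            for rr in range(maxrun):
                c = prev.get((j, rr), INF) + dcost
                if c < best.get(rr + 1, INF):
                    best[rr + 1] = c
                c = cur.get((j - 1, rr), INF) + dcost
                if c < best.get(rr + 1, INF):
                    best[rr + 1] = c
            for r, c in best.items():
                if c < INF:
                    cur[(j, r)] = c
        prev = cur
    return min((c for (j, r), c in prev.items() if j == ly), default=INF)


def word_cost(a, b, params: HceParams = HceParams()) -> float:
    """Cost of the best correspondence between two words.

    The two sequences are slid against each other; for each offset the
    cost is the mismatch count over the overlap window plus
    ``deletion_cost`` for every base of *refused* overlap (overlap
    shorter than the shorter sequence).  The inherent length difference
    between the words is not charged: word boundaries jitter by a few
    bases between genomes because seed extensions run into unrelated
    flanking sequence.  With ``max_consecutive_deletions`` > 0 the
    overlap windows are additionally aligned with run-limited internal
    deletions at ``deletion_cost`` per base.  Symmetric; 0 for
    identical sequences (and for an exact substring at full overlap).
    """
    sa = a.sequence if isinstance(a, Word) else str(a)
    sb = b.sequence if isinstance(b, Word) else str(b)
    if not sa or not sb:
        raise ValueError("word sequences must be non-empty")
    if sa == sb:
        return 0.0
    # orientation-agnostic: homologous words may be recorded on either
    # strand when their boundaries jitter, so try both readings of b
    return min(_oriented_cost(sa, sb, params),
               _oriented_cost(sa, revcomp(sb), params))


def _oriented_cost(sa: str, sb: str, params: HceParams) -> float:
    maxrun = params.max_consecutive_deletions
    dcost = params.deletion_cost
    xa = np.frombuffer(sa.encode(), dtype=np.uint8)
    xb = np.frombuffer(sb.encode(), dtype=np.uint8)
    la, lb = len(xa), len(xb)
    shorter = min(la, lb)
    best = float("inf")
    # visit offsets by increasing refused overlap so the deficit lower
    # bound allows early termination
    for off in sorted(range(-lb + 1, la), key=lambda o: min(la, o + lb) - max(0, o),
                      reverse=True):
        lo_a = max(0, off)
        hi_a = min(la, off + lb)
        overlap = hi_a - lo_a
        if overlap <= 0:
            continue
        deficit = shorter - overlap
        if dcost * deficit >= best:
            break
        wa = sa[lo_a:hi_a]
        wb = sb[lo_a - off:hi_a - off]
        mism = int((xa[lo_a:hi_a] != xb[lo_a - off:hi_a - off]).sum())
        cost = mism + dcost * deficit
        if maxrun > 0 and mism > 0:
            cost = min(cost, _rl_gap_dp(wa, wb, dcost, maxrun) + dcost * deficit)
        if cost < best:
            best = cost
    if maxrun > 0:
        # a run-limited global alignment of the whole sequences lets a
        # true internal deletion cost a single gap
        best = min(best, _rl_gap_dp(sa, sb, dcost, maxrun))
    return float(best)


# ---------------------------------------------------------------------------
# Word growth


def _xdrop_extend(next_pair, xdrop: float) -> int:
    """Greedy X-drop extension: +1 per matching column, -3 per mismatch
    (the standard nucleotide-search weighting, chosen so that extension
    dies quickly even in biased-composition background), stopping when
    the running score falls more than ``xdrop`` below its maximum;
    returns the extension length up to the best-scoring column (so
    trailing mismatch runs are trimmed)."""
    score = 0.0
    best = 0.0
    best_len = 0
    steps = 0
    for match in next_pair:
        steps += 1
        score += 1.0 if match else -3.0
        if score > best:
            best = score
            best_len = steps
        elif best - score > xdrop:
            break
    return best_len


def _extend_pair(seq_a: str, seq_b: str, pa: int, pb: int, same_orientation: bool,
                 k: int, xdrop: float):
    """Extend an exact seed match outward with X-drop trimming; returns
    the matched interval on each genome as 0-based [start, end)
    forward-strand coordinates.

    ``pa``/``pb`` are 0-based seed starts on the forward strands.  For
    opposite orientation the seed of b is the reverse complement of the
    seed of a, and rightward movement on a corresponds to leftward
    movement on b.
    """
    la, lb = len(seq_a), len(seq_b)
    if same_orientation:
        ext_r = _xdrop_extend(
            (seq_a[pa + k + t] == seq_b[pb + k + t]
             for t in range(min(la - pa - k, lb - pb - k))), xdrop)
        ext_l = _xdrop_extend(
            (seq_a[pa - 1 - t] == seq_b[pb - 1 - t]
             for t in range(min(pa, pb))), xdrop)
        return (pa - ext_l, pa + k + ext_r), (pb - ext_l, pb + k + ext_r)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    ext_r = _xdrop_extend(
        (comp.get(seq_a[pa + k + t]) == seq_b[pb - 1 - t]
         for t in range(min(la - pa - k, pb))), xdrop)
    ext_l = _xdrop_extend(
        (comp.get(seq_a[pa - 1 - t]) == seq_b[pb + k + t]
         for t in range(min(pa, lb - pb - k))), xdrop)
    return (pa - ext_l, pa + k + ext_r), (pb - ext_r, pb + k + ext_l)


def grow_words(index: Dict[str, list], genomes: Sequence,
               params: HceParams = HceParams()) -> List[Word]:
    """Extend seed matches around shared keys and merge overlapping
    extensions into words.

    Emitted words have length >= ``min_word_length`` and satisfy the
    compaction constraint: merged span / (number of distinct seed
    positions x key length) <= ``max_compaction_ratio``.
    """
    seqs = {g.accession: g.sequence.upper() for g in genomes}
    k = params.key_length
    xdrop = params.max_word_cost  # X-drop threshold for seed extension
    # candidate intervals per genome: interval -> set of seed positions
    segments: Dict[str, Dict[Tuple[int, int], set]] = {acc: {} for acc in seqs}

    def record(acc, interval, seed_pos):
        d = segments[acc]
        if interval in d:
            d[interval].add(seed_pos)
        else:
            d[interval] = {seed_pos}

    for key in sorted(index):
        occs = index[key]
        if len(occs) < 2:
            continue
        for x in range(len(occs)):
            ga, sa_, pa = occs[x]
            for y in range(x + 1, len(occs)):
                gb, sb_, pb = occs[y]
                if ga == gb and abs(pa - pb) < params.min_word_length:
                    continue  # self-overlapping tandem match, not a repeat locus
                same = sa_ == sb_
                (a0, a1), (b0, b1) = _extend_pair(
                    seqs[ga], seqs[gb], pa - 1, pb - 1, same, k, xdrop)
                record(ga, (a0, a1), pa - 1)
                record(gb, (b0, b1), pb - 1)

    words = []
    for acc in sorted(segments):
        ivals = sorted(segments[acc].items())
        merged: List[list] = []  # [start, end, seed set, contributing intervals]
        for (s0, s1), seeds in ivals:
            if merged and s0 <= merged[-1][1] - params.min_overlap:
                merged[-1][1] = max(merged[-1][1], s1)
                merged[-1][2] |= seeds
                merged[-1][3].append((s0, s1))
            else:
                merged.append([s0, s1, set(seeds), [(s0, s1)]])
        for s0, s1, seeds, parts in merged:
            if len(parts) >= 2:
                # trim the ends to the region covered by at least two
                # contributing extensions: a single pair's overshoot into
                # unrelated flanking sequence has support 1, the conserved
                # core is covered by every pair
                events = sorted([(a, 1) for a, _ in parts] + [(b, -1) for _, b in parts])
                depth = 0
                lo, hi = None, None
                for pos, step in events:
                    depth += step
                    if depth >= 2 and lo is None:
                        lo = pos
                    if depth >= 2:
                        hi = pos
                # extend hi to where depth drops below 2
                if lo is not None:
                    depth = 0
                    spans = []
                    cur = None
                    for pos, step in events:
                        prev_depth = depth
                        depth += step
                        if prev_depth < 2 <= depth:
                            cur = pos
                        elif prev_depth >= 2 > depth:
                            spans.append((cur, pos))
                    s0, s1 = min(sp[0] for sp in spans), max(sp[1] for sp in spans)
            span = s1 - s0
            if span < params.min_word_length:
                continue
            seeds_in = {p for p in seeds if s0 <= p < s1}
            if not seeds_in or span / (len(seeds_in) * k) > params.max_compaction_ratio:
                continue
            fwd = seqs[acc][s0:s1]
            rc = revcomp(fwd)
            seq, strand = (fwd, "+") if fwd <= rc else (rc, "-")
            words.append(Word(acc, strand, s0 + 1, span, seq))
    words.sort(key=lambda w: (w.genome, w.start, w.strand))
    return words


# ---------------------------------------------------------------------------
# Clustering


def _shared_key_support(seqs: List[str], k: int) -> int:
    """Largest number of member sequences sharing one exact k-mer
    (either strand)."""
    from collections import Counter

    best = 0
    counts: Counter = Counter()
    for idx, s in enumerate(seqs):
        kmers = set()
        for i in range(len(s) - k + 1):
            km = s[i:i + k]
            kmers.add(min(km, revcomp(km)))
        counts.update(kmers)
    if counts:
        best = max(counts.values())
    return best


def cluster_words(words: Sequence[Word],
                  params: HceParams = HceParams()) -> List[HCE]:
    """Group words into HCEs by threshold-clique peeling.

    Words are vertices; an edge joins two words with
    ``word_cost <= max_word_cost``.  Within each connected component the
    minimum-degree vertex is peeled (ties broken by genome, start,
    strand) until the remainder is a clique; peeled vertices re-enter
    the pool for further extraction.  Emitted HCEs must have at least
    ``min_diff_words_word`` members, at least ``min_diff_words_key`` of
    which share one exact key, and satisfy all pairwise cost bounds by
    construction.  HCEs are numbered in order of emission.
    """
    words = sorted(words, key=lambda w: (w.genome, w.start, w.strand))
    n = len(words)
    if n == 0:
        return []
    limit = params.max_word_cost
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if word_cost(words[i], words[j], params) <= limit + 1e-12:
                adj[i].add(j)
                adj[j].add(i)

    def components(vertices: set):
        seen = set()
        comps = []
        for v in sorted(vertices):
            if v in seen:
                continue
            stack = [v]
            comp = set()
            while stack:
                u = stack.pop()
                if u in comp:
                    continue
                comp.add(u)
                stack.extend(adj[u] & vertices - comp)
            seen |= comp
            comps.append(comp)
        return comps

    def consensus(members: List[Word]) -> str:
        L = min(len(w.sequence) for w in members)
        cols = []
        for i in range(L):
            counts: dict = {}
            for w in members:
                c = w.sequence[i]
                counts[c] = counts.get(c, 0) + 1
            cols.append(max(sorted(counts), key=lambda c: counts[c]))
        return "".join(cols)

    hces: List[HCE] = []
    pool = set(range(n))
    work = components(pool)
    while work:
        comp = work.pop(0)
        if len(comp) < 2:
            continue
        live = set(comp)
        # peel until the remainder is a clique under the cost threshold
        while live:
            if all(len(adj[v] & live) == len(live) - 1 for v in live):
                break
            v = min(live, key=lambda u: (len(adj[u] & live),
                                         (words[u].genome, words[u].start, words[u].strand)))
            live.remove(v)
        removed = comp - live
        if (len(live) >= max(2, params.min_diff_words_word)
                and _shared_key_support([words[v].sequence for v in live],
                                        params.key_length)
                >= params.min_diff_words_key):
            members = sorted((words[v] for v in live),
                             key=lambda w: (w.genome, w.start, w.strand))
            hces.append(HCE(len(hces) + 1, members, consensus(members)))
        # peeled-off vertices may still harbour further clusters
        if removed:
            work.extend(components(removed))
    return hces


def presence_matrix(hces: Sequence[HCE], genomes: Sequence) -> BinaryMatrix:
    """|genomes| x |hces| presence/absence matrix (1 = the HCE has at
    least one member word in that genome)."""
    ids = [h.hce_id for h in hces]
    if len(set(ids)) != len(ids):
        raise ValueError("HCE ids must be unique")
    rows = [g.accession if hasattr(g, "accession") else str(g) for g in genomes]
    cells = []
    for r in rows:
        cells.append([1 if r in h.genomes() else 0 for h in hces])
    return BinaryMatrix(rows, ids, cells)


def find_hces(genomes: Sequence, params: HceParams = HceParams()):
    """Full pipeline: key index -> word growth -> clustering -> matrix.

    Returns ``(hces, matrix)``.
    """
    index = build_key_index(genomes, params)
    words = grow_words(index, genomes, params)
    hces = cluster_words(words, params)
    return hces, presence_matrix(hces, genomes)


# ---------------------------------------------------------------------------
# Promoter consensus scan

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def scan_consensus(seq: str, consensus: str) -> List[Tuple[int, str]]:
    """All (1-based position, matched substring) occurrences of an IUPAC
    consensus pattern on the given strand; overlapping matches are all
    reported."""
    pat = []
    for c in consensus.upper():
        if c not in _IUPAC:
            raise ValueError(f"non-IUPAC character {c!r} in pattern")
        pat.append(_IUPAC[c])
    rx = re.compile("(?=(" + "".join(pat) + "))")
    return [(m.start() + 1, m.group(1)) for m in rx.finditer(seq.upper())]
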