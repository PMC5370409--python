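"""Distance-based phylogenetic trees.

Implements Saitou–Nei neighbor joining with deterministic tie-breaking,
row distances on binary presence/absence matrices, Robinson–Foulds
topology comparison and clade membership checks.  Trees are
:class:`dendropy.Tree` objects throughout, serialisable to Newick.
"""

from __future__ import annotations

import io
import warnings
from typing import Iterable, Sequence

import dendropy
import numpy as np


class DistanceMatrix:
    """A labeled symmetric distance matrix with zero diagonal."""

    __slots__ = ("labels", "d")

    def __init__(self, labels: Sequence[str], d):
        d = np.asarray(d, dtype=float)
        labels = list(labels)
        if len(set(labels)) != len(labels):
            raise ValueError("labels must be unique")
        if d.shape != (len(labels), len(labels)):
            raise ValueError("matrix shape does not match labels")
        if np.isnan(d).any():
            raise ValueError("NaN in distance matrix")
        if not np.allclose(d, d.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("diagonal must be zero")
        if (d < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.labels = labels
        self.d = d

    def __getitem__(self, pair):
        a, b = pair
        return self.d[self.labels.index(a), self.labels.index(b)]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(lab + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            labels = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                labels.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        if labels != header:
            raise ValueError("row labels do not match header")
        return cls(labels, np.array(rows))

    def __repr__(self) -> str:
        return f"DistanceMatrix({len(self.labels)} taxa)"


def neighbor_joining(m: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining.

    Returns an unrooted binary tree with branch lengths; negative
    lengths (possible on non-additive input) are clamped to zero with a
    warning.  Ties in the Q criterion are broken by the smallest label
    pair, so the output is reproducible.
    """
    n = len(m.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    def fmt(x: float) -> str:
        if x < 0:
            warnings.warn("negative branch length clamped to 0")
            x = 0.0
        return f"{x:.12g}"

    # active nodes: label used for tie-breaking, newick fragment
    labels = list(m.labels)
    frags = {lab: lab for lab in labels}
    d = {(a, b): m.d[i, j] for i, a in enumerate(labels) for j, b in enumerate(labels)}

    active = sorted(labels)
    while len(active) > 3:
        r = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        k = len(active)
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (k - 2) * d[(a, b)] - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        la = d[(a, b)] / 2 + (r[a] - r[b]) / (2 * (k - 2))
        lb = d[(a, b)] - la
        u = min(a, b)  # tie-break identity of the merged node
        new_frag = f"({frags[a]}:{fmt(la)},{frags[b]}:{fmt(lb)})"
        new_d = {}
        for c in active:
            if c in (a, b):
                continue
            new_d[c] = (d[(a, c)] + d[(b, c)] - d[(a, b)]) / 2
        active = sorted(c for c in active if c not in (a, b))
        for c in active:
            d[(u, c)] = d[(c, u)] = new_d[c]
        active.append(u)
        active.sort()
        frags.pop(a, None)
        frags.pop(b, None)
        frags[u] = new_frag

    a, b, c = active
    # three-point closed form
    la = (d[(a, b)] + d[(a, c)] - d[(b, c)]) / 2
    lb = (d[(a, b)] + d[(b, c)] - d[(a, c)]) / 2
    lc = (d[(a, c)] + d[(b, c)] - d[(a, b)]) / 2
    newick = f"({frags[a]}:{fmt(la)},{frags[b]}:{fmt(lb)},{frags[c]}:{fmt(lc)});"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return tree


def binary_distance(matrix, metric: str = "hamming") -> DistanceMatrix:
    """Pairwise row distances on a presence/absence matrix.

    ``hamming`` counts differing columns; ``jaccard`` is 1 minus the
    intersection/union ratio of the presence sets (0 for two all-absent
    rows).
    """
    cells = np.asarray(matrix.cells, dtype=int)
    if cells.ndim != 2 or cells.shape[1] < 1:
        raise ValueError("matrix must have at least one column")
    labels = list(matrix.row_labels)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = cells[i], cells[j]
            if metric == "hamming":
                v = float(np.sum(a != b))
            elif metric == "jaccard":
                union = np.sum((a | b) != 0)
                inter = np.sum((a & b) != 0)
                v = 0.0 if union == 0 else 1.0 - inter / union
            else:
                raise ValueError("metric must be 'hamming' or 'jaccard'")
            d[i, j] = d[j, i] = v
    return DistanceMatrix(labels, d)


def _common_namespace(t1: dendropy.Tree, t2: dendropy.Tree):
    ns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick",
                          taxon_namespace=ns)
    b = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick",
                          taxon_namespace=ns)
    a.is_rooted = False
    b.is_rooted = False
    return a, b


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson–Foulds symmetric bipartition difference (0 = identical
    unrooted topology)."""
    a, b = _common_namespace(t1, t2)
    la = {x.taxon.label for x in a.leaf_node_iter()}
    lb = {x.taxon.label for x in b.leaf_node_iter()}
    if la != lb:
        raise ValueError("trees must share an identical leaf set")
    return int(dendropy.calculate.treecompare.symmetric_difference(a, b))


def _bipartition_leafsets(tree: dendropy.Tree):
    leaves = frozenset(x.taxon.label for x in tree.leaf_node_iter())
    sets = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(x.taxon.label for x in node.leaf_iter())
        sets.add(below)
        sets.add(leaves - below)
    return leaves, sets


def clade_check(tree: dendropy.Tree, groups: dict) -> dict:
    """For each named group of leaf labels, test whether the group is a
    bipartition of the unrooted tree (i.e. forms a clade under some
    rooting).  The full leaf set is a clade by convention."""
    leaves, sets = _bipartition_leafsets(tree)
    out = {}
    for name, members in groups.items():
        g = frozenset(members)
        if not g <= leaves:
            raise ValueError(f"group {name!r} contains non-leaf labels")
        out[name] = g == leaves or g in sets
    return out
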