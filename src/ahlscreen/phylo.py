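"""Distance phylogenetics: equal-rates (Jukes-Cantor) distances,
neighbor joining, bootstrap support and outgroup rooting.

This is the machinery behind marker-gene trees of bacterial isolates:
pairwise JC distances from a concatenated alignment, a Saitou-Nei
neighbor-joining topology, column-resampling bootstrap support and
rooting on a designated outgroup taxon.  Implementation choices that the
classical method leaves open are fixed for determinism: ties in the
Q-matrix are broken by the lexicographically smallest pair of cluster
representatives, and negative branch-length estimates are clamped to zero
with the deficit moved to the sister branch so path lengths are
preserved.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError

logger = logging.getLogger(__name__)

_VALID_CHARS = set("ACGTN-")


class Alignment:
    """A multiple sequence alignment over {A, C, G, T, -, N}."""

    def __init__(self, records: Iterable[tuple[str, str]]):
        self.records = [(str(n), str(s).upper()) for n, s in records]
        if len(self.records) < 3:
            raise ValidationError("alignment needs >= 3 taxa")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            raise ValidationError("aligned sequences must have equal length")
        names = [n for n, _ in self.records]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate taxon ids")
        for n, s in self.records:
            bad = set(s) - _VALID_CHARS
            if bad:
                raise ValidationError(f"invalid characters {bad} in {n}")

    @property
    def taxa(self) -> list[str]:
        return [n for n, _ in self.records]

    @property
    def n_sites(self) -> int:
        return len(self.records[0][1])

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        """Bootstrap replicate: sample columns with replacement."""
        cols = rng.integers(0, self.n_sites, size=self.n_sites)
        return Alignment([
            (n, "".join(s[c] for c in cols)) for n, s in self.records
        ])

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from Bio import SeqIO
        return cls((rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta"))

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for n, s in self.records:
                fh.write(f">{n}\n{s}\n")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with taxon labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        if (self.values < 0).any():
            raise ValidationError("distances must be non-negative")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def jc_distance(alignment: Alignment) -> DistanceMatrix:
    """Jukes-Cantor distances, d = -(3/4) ln(1 - (4/3) p).

    p is the mismatch proportion over pairwise-complete columns (positions
    where both sequences have an unambiguous base; gaps and N are excluded
    per pair).  A pair with p >= 0.75 has no finite JC distance and raises
    an error naming the pair rather than being silently capped.
    """
    arrays = {n: np.frombuffer(s.encode(), dtype="S1") for n, s in alignment.records}
    valid = {n: np.isin(a, np.array([b"A", b"C", b"G", b"T"])) for n, a in arrays.items()}
    taxa = alignment.taxa
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = taxa[i], taxa[j]
            both = valid[a] & valid[b]
            m = int(both.sum())
            if m == 0:
                raise ValidationError(f"no comparable columns for {a}/{b}")
            p = float((arrays[a][both] != arrays[b][both]).sum()) / m
            if p >= 0.75:
                raise ValidationError(
                    f"JC distance undefined for {a}/{b}: p = {p:.3f} >= 0.75")
            d[i, j] = d[j, i] = -0.75 * math.log1p(-4.0 * p / 3.0)
    return DistanceMatrix(labels=list(taxa), values=d)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class Node:
    label: str | None = None
    length: float | None = None       # branch length to parent
    support: float | None = None      # bootstrap %, internal nodes only
    children: list["Node"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> list[str]:
        if self.is_leaf():
            return [self.label]
        out = []
        for c in self.children:
            out.extend(c.leaf_labels())
        return out


class Tree:
    """A phylogenetic tree; NJ output is stored with a trifurcating root
    (the conventional representation of an unrooted binary tree)."""

    def __init__(self, root: Node):
        self.root = root
        labels = root.leaf_labels()
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate leaf labels")

    @property
    def leaf_labels(self) -> list[str]:
        return self.root.leaf_labels()

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions as canonical leaf sets (the side not
        containing the alphabetically first leaf)."""
        all_leaves = frozenset(self.leaf_labels)
        anchor = min(all_leaves)
        out = set()

        def visit(node, is_root):
            for child in node.children:
                side = frozenset(child.leaf_labels())
                if 1 < len(side) < len(all_leaves) - 1:
                    canonical = all_leaves - side if anchor in side else side
                    out.add(canonical)
                visit(child, False)

        visit(self.root, True)
        return out

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        def find(node, target, acc):
            if node.is_leaf():
                return acc + [node] if node.label == target else None
            for c in node.children:
                r = find(c, target, acc + [node])
                if r:
                    return r
            return None

        pa = find(self.root, a, [])
        pb = find(self.root, b, [])
        if pa is None or pb is None:
            raise ValidationError("leaf not found")
        shared = 0
        for x, y in zip(pa, pb):
            if x is y:
                shared += 1
            else:
                break
        return (sum(n.length or 0.0 for n in pa[shared:])
                + sum(n.length or 0.0 for n in pb[shared:]))

    def newick(self) -> str:
        def fmt(node):
            if node.is_leaf():
                core = node.label
            else:
                inner = ",".join(fmt(c) for c in node.children)
                sup = "" if node.support is None else f"{node.support:g}"
                core = f"({inner}){sup}"
            if node.length is not None:
                core += f":{node.length:.6g}"
            return core

        return fmt(self.root) + ";"


def nj_tree(d: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimising the Q criterion is joined; ties are
    broken by the lexicographically smallest (representative-label) pair.
    Negative branch-length estimates are clamped to zero and the deficit
    moved to the sister branch, preserving the pair's summed length.
    """
    n = len(d.labels)
    if n < 3:
        raise ValidationError("neighbor joining needs >= 3 taxa")
    nodes: dict[str, Node] = {l: Node(label=l) for l in d.labels}
    reps = sorted(d.labels)
    dist = {}
    for i, a in enumerate(reps):
        for b in reps[i + 1:]:
            dist[(a, b)] = d.get(a, b)

    def get(a, b):
        return dist[(a, b) if a < b else (b, a)]

    def set_(a, b, v):
        dist[(a, b) if a < b else (b, a)] = v

    while len(reps) > 3:
        m = len(reps)
        r = {a: sum(get(a, b) for b in reps if b != a) for a in reps}
        best = min(
            (((m - 2) * get(a, b) - r[a] - r[b], a, b)
             for i, a in enumerate(reps) for b in reps[i + 1:]),
            key=lambda t: (t[0], t[1], t[2]),
        )
        _, a, b = best
        dab = get(a, b)
        va = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        vb = dab - va
        if va < 0:
            va, vb = 0.0, dab
        elif vb < 0:
            va, vb = dab, 0.0
        parent = Node(children=[nodes[a], nodes[b]])
        nodes[a].length = va
        nodes[b].length = vb
        rep = min(a, b)
        for c in reps:
            if c in (a, b):
                continue
            set_(rep, c, 0.5 * (get(a, c) + get(b, c) - dab))
        nodes[rep] = parent
        reps = [c for c in reps if c not in (a, b) or c == rep]

    # resolve the final three clusters around a trifurcating root
    a, b, c = reps
    la = 0.5 * (get(a, b) + get(a, c) - get(b, c))
    lb = 0.5 * (get(a, b) + get(b, c) - get(a, c))
    lc = 0.5 * (get(a, c) + get(b, c) - get(a, b))
    nodes[a].length = max(la, 0.0)
    nodes[b].length = max(lb, 0.0)
    nodes[c].length = max(lc, 0.0)
    return Tree(Node(children=[nodes[a], nodes[b], nodes[c]]))


def bootstrap_support(alignment: Alignment, n_reps: int = 100,
                      seed: int = 0) -> Tree:
    """JC + NJ tree with column-resampling bootstrap supports.

    Support of an internal edge is the percentage of replicates whose
    JC+NJ tree contains the same bipartition.  Replicates where a JC
    distance is undefined are counted as not containing any bipartition.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    if alignment.n_sites < 10:
        logger.warning("alignment has only %d columns; bootstrap supports "
                       "will be unstable", alignment.n_sites)
    tree = nj_tree(jc_distance(alignment))
    counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        rep = alignment.resample_columns(rng)
        try:
            rep_bps = nj_tree(jc_distance(rep)).bipartitions()
        except ValidationError:
            continue
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1

    all_leaves = frozenset(tree.leaf_labels)
    anchor = min(all_leaves)

    def annotate(node):
        for child in node.children:
            if not child.is_leaf():
                side = frozenset(child.leaf_labels())
                if 1 < len(side) < len(all_leaves) - 1:
                    canonical = all_leaves - side if anchor in side else side
                    child.support = 100.0 * counts[canonical] / n_reps
                annotate(child)

    annotate(tree.root)
    return tree


def root_at_outgroup(tree: Tree, outgroup: str) -> Tree:
    """Root the tree on the outgroup's pendant edge (midpoint of it).

    Idempotent: re-rooting an already outgroup-rooted tree returns an
    equivalent tree.
    """
    if outgroup not in tree.leaf_labels:
        raise ValidationError(f"outgroup {outgroup!r} is not a leaf of the tree")
    tree = Tree(copy.deepcopy(tree.root))  # never mutate the caller's tree

    # locate the outgroup leaf and the path from the root to it
    def path_to(node, target):
        if node.is_leaf():
            return [node] if node.label == target else None
        for c in node.children:
            p = path_to(c, target)
            if p is not None:
                return [node] + p
        return None

    path = path_to(tree.root, outgroup)
    leaf = path[-1]
    parent = path[-2]

    # already in rooted form: binary root with outgroup as one child
    if parent is tree.root and len(tree.root.children) == 2:
        return tree

    # detach the outgroup, then reverse all edges from its parent up to the
    # old root so the parent becomes the ingroup apex
    parent.children.remove(leaf)
    for upper, lower in zip(path[:-2][::-1], path[1:-1][::-1]):
        upper.children.remove(lower)
        lower.children.append(upper)
        upper.length = lower.length
    # a passed-through old root of degree 2 is redundant: splice it out
    def splice(node):
        for i, c in enumerate(list(node.children)):
            splice(c)
            if len(c.children) == 1 and c.is_leaf() is False and c.label is None:
                gc = c.children[0]
                gc.length = (gc.length or 0.0) + (c.length or 0.0)
                node.children[i] = gc
    splice(parent)

    half = (leaf.length or 0.0) / 2
    leaf.length = half
    ingroup = parent
    ingroup.length = half
    root = Node(children=[leaf, ingroup])
    return Tree(root)
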