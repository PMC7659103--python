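"""Independent oracles used by the test suite.

These deliberately do not import the counting/phylogeny code they check:
the genetic code comes from Bio.Seq, codon-pair differences are counted by
brute-force path enumeration, and additive matrices come from a local tree
builder with its own path-length traversal.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"

SENSE_CODONS = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if str(Seq(a + b + c).translate()) != "*"
]


def aa_of(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_site_counts(codon: str) -> tuple[float, float]:
    """Stop-excluded NG86 site counts, written independently."""
    s = 0.0
    for pos in range(3):
        changes = []
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if aa_of(alt) == "*":
                continue
            changes.append(aa_of(alt) == aa_of(codon))
        if changes:
            s += sum(changes) / len(changes)
    return s, 3.0 - s


def oracle_pair_diffs(a: str, b: str) -> tuple[float, float]:
    """(sd, nd) averaged over all stop-free substitution orderings."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = a, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if aa_of(nxt) == "*":
                ok = False
                break
            if aa_of(nxt) == aa_of(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        # final-state per-position fallback
        sd = nd = 0
        for pos in diff:
            alt = a[:pos] + b[pos] + a[pos + 1 :]
            if aa_of(alt) != "*" and aa_of(alt) == aa_of(a):
                sd += 1
            else:
                nd += 1
        return float(sd), float(nd)
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


# ---------------------------------------------------------------- trees


class SimpleTree:
    """Minimal rooted tree for generating additive matrices."""

    def __init__(self, name=None, children=None):
        self.name = name
        self.children = children or []  # list of (SimpleTree, length)

    def leaf_depths(self):
        if not self.children:
            return [(self.name, 0.0)]
        out = []
        for child, bl in self.children:
            out.extend((leaf, d + bl) for leaf, d in child.leaf_depths())
        return out


def random_additive_tree(n_leaves: int, rng: np.random.Generator) -> SimpleTree:
    labels = [f"T{i}" for i in range(n_leaves)]
    perm = [labels[i] for i in rng.permutation(n_leaves)]

    def build(leaves):
        if len(leaves) == 1:
            return SimpleTree(name=leaves[0])
        k = int(rng.integers(1, len(leaves)))
        return SimpleTree(
            children=[
                (build(leaves[:k]), float(rng.uniform(0.1, 1.0))),
                (build(leaves[k:]), float(rng.uniform(0.1, 1.0))),
            ]
        )

    thirds = max(1, n_leaves // 3)
    return SimpleTree(
        children=[
            (build(perm[:thirds]), float(rng.uniform(0.1, 1.0))),
            (build(perm[thirds : 2 * thirds]), float(rng.uniform(0.1, 1.0))),
            (build(perm[2 * thirds :]), float(rng.uniform(0.1, 1.0))),
        ]
    )


def additive_matrix(tree: SimpleTree) -> tuple[list[str], np.ndarray]:
    """Path-length matrix computed by recursive cross-group combination."""
    labels = sorted(leaf for leaf, _ in tree.leaf_depths())
    idx = {l: i for i, l in enumerate(labels)}
    d = np.zeros((len(labels), len(labels)))

    def walk(node):
        if not node.children:
            return [(node.name, 0.0)]
        groups = [
            [(leaf, dist + bl) for leaf, dist in walk(child)]
            for child, bl in node.children
        ]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for la, da in groups[a]:
                    for lb, db in groups[b]:
                        d[idx[la], idx[lb]] = d[idx[lb], idx[la]] = da + db
        return [x for g in groups for x in g]

    walk(tree)
    return labels, d


def oracle_splits(tree: SimpleTree) -> set[frozenset[str]]:
    leaves = {leaf for leaf, _ in tree.leaf_depths()}
    ref = min(leaves)
    out = set()

    def walk(node):
        if not node.children:
            return {node.name}
        mine = set()
        for child, _bl in node.children:
            side = walk(child)
            if 2 <= len(side) <= len(leaves) - 2:
                out.add(frozenset(side if ref not in side else leaves - side))
            mine |= side
        return mine

    walk(tree)
    return out


def mybkit_tree_matrix(tree) -> tuple[list[str], np.ndarray]:
    """Path-length matrix of a mybkit TreeNode, via an independent walk."""
    leaves = sorted(tree.leaves())
    idx = {l: i for i, l in enumerate(leaves)}
    d = np.zeros((len(leaves), len(leaves)))

    def walk(node):
        if node.is_leaf:
            return [(node.name, 0.0)]
        groups = [
            [(leaf, dist + bl) for leaf, dist in walk(child)]
            for child, bl in node.children
        ]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for la, da in groups[a]:
                    for lb, db in groups[b]:
                        d[idx[la], idx[lb]] = d[idx[lb], idx[la]] = da + db
        return [x for g in groups for x in g]

    walk(tree)
    return leaves, d


def mybkit_tree_splits(tree) -> set[frozenset[str]]:
    leaves = set(tree.leaves())
    ref = min(leaves)
    out = set()

    def walk(node):
        if node.is_leaf:
            return {node.name}
        mine = set()
        for child, _bl in node.children:
            side = walk(child)
            if 2 <= len(side) <= len(leaves) - 2:
                out.add(frozenset(side if ref not in side else leaves - side))
            mine |= side
        return mine

    walk(tree)
    return out
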