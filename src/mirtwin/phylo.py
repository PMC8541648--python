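"""Distance phylogenetics for miRNA-5p/loop/miRNA-3p alignments.

p-distances (proportion of differing sites over gap-free column pairs) feed
Saitou–Nei neighbor joining with a deterministic label-order tie-break;
bootstrap support is the percentage of column-resampled replicates whose NJ
tree contains each internal bipartition of the full-data tree.  Trees are
Bio.Phylo objects and serialize to Newick, with support values as internal
node labels.

Alignment construction itself is out of scope — the module consumes any
multiple sequence alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Phylo.BaseTree import Clade, Tree

from .io import SequenceRecord


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    #: set when negative NJ branch lengths were clamped to zero
    clamped: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (self.d < -1e-12).any():
            raise ValueError("distances must be non-negative")


def p_distance(alignment: Sequence[SequenceRecord]) -> DistanceMatrix:
    """Pairwise proportion of differing sites, ignoring columns where either
    row has a gap.  A pair with no comparable columns is an error."""
    if len(alignment) < 3:
        raise ValueError("need at least 3 rows")
    labels = [rec.id for rec in alignment]
    arr = np.array([list(rec.seq) for rec in alignment])
    gap = (arr == "-") | (arr == ".") | (arr == "N")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            usable = ~gap[i] & ~gap[j]
            total = int(usable.sum())
            if total == 0:
                raise ValueError(
                    f"rows {labels[i]!r} and {labels[j]!r} share no comparable columns"
                )
            diff = int((arr[i, usable] != arr[j, usable]).sum())
            d[i, j] = d[j, i] = diff / total
    return DistanceMatrix(labels=labels, d=d)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining with label-order tie-breaking.

    Exactly recovers additive matrices; negative branch lengths are clamped
    to zero and flagged on ``dm.clamped``.  The returned tree is unrooted
    (trifurcating root clade).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    d = dm.d.astype(float).copy()
    nodes: list[Clade] = [Clade(name=lab) for lab in dm.labels]
    # tie-break key: lexicographically smallest (sorted pair of subtree labels)
    keys: list[str] = list(dm.labels)
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        row_sums = d.sum(axis=1)
        best = None  # (Q, key_pair, i, j)
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - row_sums[i] - row_sums[j]
                key_pair = tuple(sorted((keys[i], keys[j])))
                cand = (q, key_pair, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * d[i, j] + (row_sums[i] - row_sums[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.branch_length = clamp(li)
        child_j.branch_length = clamp(lj)
        new = Clade(clades=[child_i, child_j])
        new_key = min(keys[i], keys[j])
        new_d = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d = np.vstack([d[keep][:, keep], new_d[keep][None, :]])
        d = np.hstack([d, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[x] for x in keep] + [new]
        keys = [keys[x] for x in keep] + [new_key]
    # resolve the final three nodes around an unrooted center
    (a, b, c) = nodes
    da, db, dc = (
        0.5 * (d[0, 1] + d[0, 2] - d[1, 2]),
        0.5 * (d[0, 1] + d[1, 2] - d[0, 2]),
        0.5 * (d[0, 2] + d[1, 2] - d[0, 1]),
    )
    a.branch_length = clamp(da)
    b.branch_length = clamp(db)
    c.branch_length = clamp(dc)
    dm.clamped = clamped
    return Tree(root=Clade(clades=[a, b, c]), rooted=False)


def bipartitions(tree: Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions (as the smaller-or-canonical leaf set)."""
    all_leaves = frozenset(t.name for t in tree.get_terminals())
    parts: set[frozenset[str]] = set()
    for clade in tree.get_nonterminals():
        leaves = frozenset(t.name for t in clade.get_terminals())
        if 1 < len(leaves) < len(all_leaves) - 1:
            other = all_leaves - leaves
            parts.add(min(leaves, other, key=lambda s: (len(s), sorted(s))))
    return parts


def _resample_columns(alignment: Sequence[SequenceRecord], rng: np.random.Generator) -> list[SequenceRecord]:
    ncol = len(alignment[0].seq)
    idx = rng.integers(0, ncol, size=ncol)
    return [
        SequenceRecord(rec.id, "".join(rec.seq[i] for i in idx), rec.desc)
        for rec in alignment
    ]


def bootstrap(alignment: Sequence[SequenceRecord], n: int = 1000, seed: int = 0) -> Tree:
    """NJ tree of the full alignment with bootstrap support values.

    Support of an internal bipartition = percentage of ``n`` column-resampled
    replicates whose NJ tree contains it.  Bit-for-bit reproducible given
    the seed.
    """
    if len(alignment) < 4:
        raise ValueError("need at least 4 rows to bootstrap")
    tree = neighbor_joining(p_distance(alignment))
    target = {part: 0 for part in bipartitions(tree)}
    rng = np.random.default_rng(seed)
    for _ in range(n):
        rep = _resample_columns(alignment, rng)
        try:
            rep_parts = bipartitions(neighbor_joining(p_distance(rep)))
        except ValueError:  # a replicate can lose all comparable columns
            continue
        for part in target:
            if part in rep_parts:
                target[part] += 1
    all_leaves = frozenset(t.name for t in tree.get_terminals())
    for clade in tree.get_nonterminals():
        leaves = frozenset(t.name for t in clade.get_terminals())
        if 1 < len(leaves) < len(all_leaves) - 1:
            part = min(leaves, all_leaves - leaves, key=lambda s: (len(s), sorted(s)))
            clade.confidence = 100.0 * target[part] / n if n else None
    return tree


def tree_path_lengths(tree: Tree) -> DistanceMatrix:
    """All-pairs leaf-to-leaf path lengths (for additivity checks)."""
    leaves = tree.get_terminals()
    labels = [t.name for t in leaves]
    n = len(labels)
    d = np.zeros((n, n))
    depths = tree.depths(unit_branch_lengths=False)
    for i in range(n):
        for j in range(i + 1, n):
            mrca = tree.common_ancestor(leaves[i], leaves[j])
            dist = depths[leaves[i]] + depths[leaves[j]] - 2 * depths[mrca]
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels=labels, d=d)
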