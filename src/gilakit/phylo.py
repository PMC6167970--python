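"""Uncorrected distances, neighbor joining, tree comparison, and the strict clock.

The distance-based tree is a light-weight stand-in for full likelihood or
Bayesian inference: it is enough to check monophyly of nominal groups and
concordance between datasets, which is what the downstream verdicts need.

The strict clock converts an uncorrected p-distance to a divergence time.
By default the quoted rate is interpreted as a PAIRWISE divergence rate
(2%/Myr between two lineages -> TMRCA = d / r), the usual convention for
mtDNA "percent per million years" rates; the per-lineage reading (TMRCA =
d / 2r) is available as a mode switch.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from gilakit._util import as_matrix


@dataclass
class ClockConfig:
    """Strict-clock rate: ``rate`` per Myr, pairwise or per-lineage."""

    rate: float = 0.02
    mode: str = "pairwise"  # or "per_lineage"

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("clock rate must be > 0")
        if self.mode not in ("pairwise", "per_lineage"):
            raise ValueError(f"unknown clock mode {self.mode!r}")


def read_newick(source: "str | io.TextIOBase") -> TreeNode:
    """Parse a Newick string or file handle into a tree."""
    if isinstance(source, str):
        source = io.StringIO(source)
    return TreeNode.read(source)


def p_distance_matrix(
    sequences: Mapping[str, "str | np.ndarray"],
) -> DistanceMatrix:
    """Uncorrected pairwise distance of an alignment, with pairwise deletion.

    d(a, b) = differing sites / sites where both sequences are non-gap and
    non-N.  Raises if a pair shares no comparable site.
    """
    labels = list(sequences)
    mat = as_matrix(sequences)
    if mat.ndim != 2:
        raise ValueError("sequences must be aligned (equal lengths)")
    n = len(labels)
    valid = mat >= 0
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable sites between {labels[i]!r} and {labels[j]!r}"
                )
            dm[i, j] = dm[j, i] = np.count_nonzero(mat[i][both] != mat[j][both]) / m
    return DistanceMatrix(dm, ids=labels)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a symmetric distance matrix.

    Taxa are sorted lexicographically before joining so the resulting topology
    is invariant to the input order; negative branch lengths are clamped to 0.
    Requires >= 3 taxa.
    """
    if len(dm.ids) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    order = sorted(dm.ids)
    dm = dm.filter(order)
    return nj(dm, neg_as_zero=True)


def strict_clock_time(d: float, config: ClockConfig | None = None) -> float:
    """Convert an uncorrected pairwise distance to a TMRCA in Myr."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    config = config or ClockConfig()
    divisor = config.rate if config.mode == "pairwise" else 2 * config.rate
    return d / divisor


def root_at_outgroup(tree: TreeNode, outgroup: str) -> TreeNode:
    """Root an (un)rooted tree on the branch leading to ``outgroup``."""
    tip = tree.find(outgroup)
    return tree.root_at(tip.parent, reset=True)


def check_monophyly(
    tree: TreeNode, labels: Iterable[str], outgroup: str | None = None
) -> dict:
    """Is ``labels`` a monophyletic group on (rooted) ``tree``?

    Returns the verdict and the size of the smallest clade containing all the
    labels.  If ``outgroup`` is given the tree is rooted on it first.
    """
    labels = set(labels)
    if outgroup is not None:
        tree = root_at_outgroup(tree, outgroup)
    tips = {t.name for t in tree.tips()}
    unknown = labels - tips
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)}")
    if len(labels) == 1:
        return {"monophyletic": True, "clade_size": 1}
    lca = tree.lca(sorted(labels))
    clade = {t.name for t in lca.tips()}
    return {"monophyletic": clade == labels, "clade_size": len(clade)}


def _nontrivial_splits(tree: TreeNode, taxa: frozenset) -> set[frozenset]:
    splits: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = taxa - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(min(side, other, key=lambda s: tuple(sorted(s))))
    return splits


def topology_concordance(tree_a: TreeNode, tree_b: TreeNode) -> dict:
    """Robinson-Foulds concordance between two trees on the same tip set.

    Returns the symmetric-difference RF distance over non-trivial splits, the
    RF normalized by its maximum 2(n-3), and the number of shared splits.
    """
    taxa_a = frozenset(t.name for t in tree_a.tips())
    taxa_b = frozenset(t.name for t in tree_b.tips())
    if taxa_a != taxa_b:
        raise ValueError("trees must share an identical tip set")
    sa = _nontrivial_splits(tree_a, taxa_a)
    sb = _nontrivial_splits(tree_b, taxa_b)
    rf = len(sa ^ sb)
    max_rf = 2 * (len(taxa_a) - 3)
    return {
        "rf": rf,
        "normalized_rf": rf / max_rf if max_rf > 0 else 0.0,
        "shared_splits": len(sa & sb),
        "n_splits_a": len(sa),
        "n_splits_b": len(sb),
    }
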