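"""Ultrametric dendrograms: average clustering, Newick round-trips, topology comparison.

Species-level volatilome dendrograms are built by UPGMA on the matrix of median
Euclidean distances between species' samples; the sequence-side dendrogram is
built the same way from ITS-style pairwise distances. Concordance between the two
is quantified with the Robinson-Foulds distance over internal bipartitions and
the Pearson correlation of cophenetic distances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import DistanceMatrix


@dataclass(frozen=True)
class Node:
    """One vertex of a rooted merge tree; leaves carry a label and height 0."""

    height: float
    label: str | None = None
    children: tuple["Node", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Dendrogram:
    """Rooted binary merge tree with nondecreasing heights from leaves to root."""

    root: Node
    leaf_names: list[str] = field(init=False)

    def __post_init__(self) -> None:
        names = self.root.leaves()
        if len(set(names)) != len(names):
            raise ValueError("duplicated leaf labels in dendrogram")
        self._check_monotone(self.root)
        self.leaf_names = sorted(names)

    @staticmethod
    def _check_monotone(node: Node) -> None:
        for c in node.children:
            if c.height > node.height + 1e-9:
                raise ValueError("merge heights are not monotone along a root path")
            Dendrogram._check_monotone(c)

    # -- cophenetics ---------------------------------------------------------

    def cophenetic(self) -> DistanceMatrix:
        """Tree-implied distances: twice the height of the lowest common merge."""
        names = self.leaf_names
        pos = {s: k for k, s in enumerate(names)}
        n = len(names)
        d = np.zeros((n, n))

        def visit(node: Node) -> list[str]:
            if node.is_leaf:
                return [node.label]  # type: ignore[list-item]
            groups = [visit(c) for c in node.children]
            for ga, gb in itertools.combinations(groups, 2):
                for a in ga:
                    for b in gb:
                        d[pos[a], pos[b]] = d[pos[b], pos[a]] = 2.0 * node.height
            return [x for g in groups for x in g]

        visit(self.root)
        return DistanceMatrix(names, d)

    # -- bipartitions --------------------------------------------------------

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits of the unrooted topology.

        Each split is canonicalised as the side that does not contain the
        lexicographically smallest leaf, so rooted trees with the same unrooted
        topology yield identical sets.
        """
        all_leaves = frozenset(self.leaf_names)
        anchor = min(self.leaf_names)
        splits: set[frozenset[str]] = set()

        def visit(node: Node, is_root: bool) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])  # type: ignore[list-item]
            below = frozenset().union(*(visit(c, False) for c in node.children))
            if not is_root and 1 < len(below) < len(all_leaves) - 1:
                side = below if anchor not in below else all_leaves - below
                splits.add(side)
            return below

        visit(self.root, True)
        return splits

    # -- newick --------------------------------------------------------------

    def to_newick(self) -> str:
        """Serialize with branch lengths encoding merge heights."""

        def fmt(node: Node, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{bl:.10g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{bl:.10g}"

        if self.root.is_leaf:
            return f"{self.root.label}:0;"
        inner = ",".join(fmt(c, self.root.height) for c in self.root.children)
        return f"({inner});"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def from_newick(text: str) -> Dendrogram:
    """Parse a Newick string into a :class:`Dendrogram`.

    Branch lengths are interpreted as height differences of an ultrametric tree
    (leaves at height 0). Malformed input raises :class:`ValueError` with the
    parser's position information.
    """
    import dendropy

    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises schema-specific errors with positions
        raise ValueError(f"newick parse error: {exc}") from exc

    def convert(nd) -> tuple[Node, float]:
        """Return (node, height) where height is the max leaf depth below."""
        if nd.is_leaf():
            if nd.taxon is None or nd.taxon.label is None:
                raise ValueError("newick parse error: unlabeled leaf")
            return Node(0.0, label=str(nd.taxon.label).replace(" ", "_")), 0.0
        kids = []
        height = 0.0
        for ch in nd.child_nodes():
            sub, sub_h = convert(ch)
            bl = ch.edge.length if ch.edge.length is not None else 0.0
            kids.append(sub)
            height = max(height, sub_h + bl)
        return Node(height, children=tuple(kids)), height

    root, _ = convert(tree.seed_node)
    return Dendrogram(root)


def read_newick(path: str | Path) -> Dendrogram:
    return from_newick(Path(path).read_text())


# -- clustering ---------------------------------------------------------------


def median_species_distance(d: DistanceMatrix, meta: pd.DataFrame,
                            group_col: str = "species") -> DistanceMatrix:
    """Collapse a sample-level distance matrix to species level by the median
    of all cross-pair distances between the two species' samples."""
    meta = meta.loc[[i for i in d.ids if i in meta.index]]
    groups = {}
    pos = {s: k for k, s in enumerate(d.ids)}
    for g, sub in meta.groupby(group_col, sort=True):
        groups[str(g)] = np.array([pos[i] for i in sub.index])
    names = sorted(groups)
    if not names:
        raise ValueError("no groups found in metadata")
    n = len(names)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            block = d.values[np.ix_(groups[names[a]], groups[names[b]])]
            out[a, b] = out[b, a] = float(np.median(block))
    return DistanceMatrix(names, out)


def upgma(d: DistanceMatrix, weighted: bool = True) -> Dendrogram:
    """Average-linkage agglomeration of a distance matrix.

    ``weighted=True`` is size-weighted UPGMA (inter-cluster distances are the
    mean over all cross pairs); ``weighted=False`` is WPGMA. Merge heights are
    half the merge distance, so the cophenetic distance between two leaves
    equals their inter-cluster distance at merging. Ties are broken by the
    lexicographically smallest pair of cluster representatives (the minimum
    leaf label in each cluster).
    """
    if len(d) < 2:
        raise ValueError("need at least two objects to cluster")
    if np.isnan(d.values).any():
        raise ValueError("NaN distances")

    clusters: dict[int, Node] = {k: Node(0.0, label=name) for k, name in enumerate(d.ids)}
    sizes: dict[int, int] = {k: 1 for k in clusters}
    reps: dict[int, str] = {k: name for k, name in enumerate(d.ids)}
    dist: dict[tuple[int, int], float] = {}
    for a, b in itertools.combinations(range(len(d)), 2):
        dist[(a, b)] = float(d.values[a, b])
    next_id = len(d)

    def key(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    while len(clusters) > 1:
        # smallest distance; ties -> lexicographically smallest representative pair
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted((reps[kv[0][0]], reps[kv[0][1]])))),
        )
        (a, b), dab = best
        merged = Node(dab / 2.0, children=(clusters[a], clusters[b]))
        na, nb = sizes[a], sizes[b]
        new = next_id
        next_id += 1
        for c in clusters:
            if c in (a, b):
                continue
            dac, dbc = dist[key(a, c)], dist[key(b, c)]
            if weighted:
                dist[key(new, c)] = (na * dac + nb * dbc) / (na + nb)
            else:
                dist[key(new, c)] = (dac + dbc) / 2.0
        for c in list(dist):
            if a in c or b in c:
                del dist[c]
        del clusters[a], clusters[b], sizes[a], sizes[b]
        clusters[new] = merged
        sizes[new] = na + nb
        reps[new] = min(reps.pop(a), reps.pop(b))

    return Dendrogram(next(iter(clusters.values())))


# -- comparison ---------------------------------------------------------------


@dataclass
class TreeComparison:
    rf: int
    normalized_rf: float
    cophenetic_r: float


def compare_trees(t1: Dendrogram, t2: Dendrogram) -> TreeComparison:
    """Robinson-Foulds distance over internal bipartitions plus cophenetic
    correlation; leaf sets must match."""
    if t1.leaf_names != t2.leaf_names:
        raise ValueError("trees have different leaf sets")
    b1, b2 = t1.bipartitions(), t2.bipartitions()
    rf = len(b1 ^ b2)
    n = len(t1.leaf_names)
    denom = 2 * (n - 3)
    nrf = rf / denom if denom > 0 else 0.0
    c1 = t1.cophenetic().condensed()
    c2 = t2.cophenetic().condensed()
    if np.std(c1) == 0 or np.std(c2) == 0:
        r = 1.0 if np.allclose(c1, c2) else 0.0
    else:
        r = float(np.corrcoef(c1, c2)[0, 1])
    return TreeComparison(rf=rf, normalized_rf=nrf, cophenetic_r=r)


# -- sequence distances -------------------------------------------------------

_UNAMBIGUOUS = frozenset("ACGTU")


def p_distance(fasta_path: str | Path | None = None,
               records: Sequence[tuple[str, str]] | None = None) -> DistanceMatrix:
    """Proportion of differing sites between aligned sequences.

    Sites where either sequence is a gap or an ambiguity code are excluded
    pairwise (pairwise deletion). Accepts a FASTA path or (id, sequence) pairs.
    """
    if records is None:
        if fasta_path is None:
            raise ValueError("provide a FASTA path or records")
        from Bio import SeqIO

        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(fasta_path), "fasta")]
    ids = [str(i) for i, _ in records]
    seqs = [s.upper() for _, s in records]
    if len(set(len(s) for s in seqs)) > 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    arrs = [np.frombuffer(s.encode(), dtype="S1") for s in seqs]
    ok = [np.isin(a, [c.encode() for c in _UNAMBIGUOUS]) for a in arrs]
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ok[i] & ok[j]
            m = int(comparable.sum())
            if m == 0:
                raise ValueError(f"no comparable sites between {ids[i]} and {ids[j]}")
            diff = int(((arrs[i] != arrs[j]) & comparable).sum())
            out[i, j] = out[j, i] = diff / m
    return DistanceMatrix(ids, out)
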