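"""Distance-based tree building (UPGMA, neighbor joining), bootstrap, newick I/O.

Maximum-likelihood inference is deliberately not implemented here;
neighbor joining on identity distances is the built-in tree builder and
``read_newick`` accepts trees from any external ML tool.  All
agglomeration tie-breaks are lexicographic on cluster ids (the smallest
leaf label in a cluster), so every build is deterministic.

The five-species land-plant tree used for reconciliation
((Ppatens,(Smoellendorffii,(Osativa,(Athaliana,Ptrichocarpa))))) ships
as package data.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from importlib import resources

import dendropy
import numpy as np

from .align import DistanceMatrix, Msa, identity_distance


class NewickError(ValueError):
    pass


@dataclass
class TreeNode:
    label: str | None = None
    children: list = field(default_factory=list)
    branch_length: float | None = None
    support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf()]


@dataclass
class PhyloTree:
    """A rooted or unrooted labeled tree with branch lengths.

    Unrooted trees are stored rooted at an arbitrary trivalent node with
    ``rooted=False``.
    """

    root: TreeNode
    rooted: bool = True

    def postorder(self):
        return self.root.postorder()

    def leaves(self):
        return self.root.leaves()

    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.leaves()]

    def copy(self) -> "PhyloTree":
        return _copy.deepcopy(self)

    def mrca(self, labels) -> TreeNode:
        """Most recent common ancestor of the given leaf labels."""
        wanted = set(labels)
        best = None

        def walk(node) -> set:
            below = set()
            for child in node.children:
                below |= walk(child)
            if node.is_leaf():
                below.add(node.label)
            nonlocal best
            if best is None and wanted <= below:
                best = node
            return below

        covered = walk(self.root)
        if not wanted <= covered:
            raise KeyError(f"labels not in tree: {sorted(wanted - covered)}")
        return best

    def newick(self) -> str:
        return write_newick(self)


def _format_length(value: float) -> str:
    text = f"{value:.6f}".rstrip("0").rstrip(".")
    return text if text else "0"


def write_newick(tree: PhyloTree) -> str:
    """Serialize with branch lengths (6 decimals) and support as internal label."""

    def render(node: TreeNode) -> str:
        if node.is_leaf():
            out = node.label or ""
        else:
            inner = ",".join(render(c) for c in node.children)
            label = ""
            if node.support is not None:
                label = _format_length(node.support)
            elif node.label:
                label = node.label
            out = f"({inner}){label}"
        if node.branch_length is not None:
            out += f":{_format_length(node.branch_length)}"
        return out

    return render(tree.root) + ";"


def read_newick(text: str, rooted: bool | None = None) -> PhyloTree:
    """Parse a newick string; duplicate leaf labels or bad syntax raise NewickError."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"newick parse error: {exc}") from exc

    def convert(dnode) -> TreeNode:
        children = [convert(c) for c in dnode.child_nodes()]
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
        else:
            label = dnode.label
        support = None
        if label is not None and children:
            try:
                support = float(label)
                label = None
            except ValueError:
                pass
        return TreeNode(
            label=label,
            children=children,
            branch_length=dnode.edge.length,
            support=support,
        )

    root = convert(dtree.seed_node)
    tree = PhyloTree(root=root, rooted=True)
    labels = tree.leaf_labels()
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise NewickError(f"duplicate leaf labels: {dupes}")
    if rooted is None:
        rooted = len(root.children) <= 2
    tree.rooted = rooted
    return tree


def load_species_tree() -> PhyloTree:
    """The packaged five-species land-plant tree (unit branch lengths)."""
    text = resources.files("ktfam.data").joinpath("species_tree.nwk").read_text().strip()
    return read_newick(text, rooted=True)


def _validate_matrix(D: DistanceMatrix) -> None:
    if np.any(D.d < 0):
        raise ValueError("negative distances")
    if len(D.ids) < 2:
        raise ValueError("need >= 2 taxa")


def upgma(D: DistanceMatrix) -> PhyloTree:
    """Average-linkage agglomeration; rooted ultrametric tree.

    Cluster ids are the smallest member leaf label; merge ties go to the
    lexicographically smallest (id_a, id_b) pair.
    """
    _validate_matrix(D)
    # cluster id -> (node, size, height)
    clusters: dict[str, tuple[TreeNode, int, float]] = {
        label: (TreeNode(label=label), 1, 0.0) for label in D.ids
    }
    dist: dict[frozenset, float] = {}
    for i, a in enumerate(D.ids):
        for j in range(i + 1, len(D.ids)):
            dist[frozenset((a, D.ids[j]))] = float(D.d[i][j])

    while len(clusters) > 1:
        names = sorted(clusters)
        best = min(
            ((dist[frozenset((a, b))], a, b)
             for i, a in enumerate(names) for b in names[i + 1:]),
        )
        d_ab, a, b = best
        node_a, size_a, h_a = clusters.pop(a)
        node_b, size_b, h_b = clusters.pop(b)
        height = d_ab / 2.0
        node_a.branch_length = max(height - h_a, 0.0)
        node_b.branch_length = max(height - h_b, 0.0)
        merged = TreeNode(children=[node_a, node_b])
        new_id = min(a, b)
        for other in list(clusters):
            d_new = (
                size_a * dist.pop(frozenset((a, other)))
                + size_b * dist.pop(frozenset((b, other)))
            ) / (size_a + size_b)
            dist[frozenset((new_id, other))] = d_new
        dist.pop(frozenset((a, b)), None)
        clusters[new_id] = (merged, size_a + size_b, height)

    root = next(iter(clusters.values()))[0]
    return PhyloTree(root=root, rooted=True)


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; unrooted tree (trivalent root).

    Negative branch lengths are clamped to zero.  Ties in the Q
    criterion break lexicographically on cluster ids.
    """
    _validate_matrix(D)
    if len(D.ids) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    nodes: dict[str, TreeNode] = {label: TreeNode(label=label) for label in D.ids}
    dist: dict[frozenset, float] = {}
    for i, a in enumerate(D.ids):
        for j in range(i + 1, len(D.ids)):
            dist[frozenset((a, D.ids[j]))] = float(D.d[i][j])

    active = sorted(nodes)
    while len(active) > 3:
        n = len(active)
        r = {a: sum(dist[frozenset((a, b))] for b in active if b != a) for a in active}
        best = min(
            (
                ((n - 2) * dist[frozenset((a, b))] - r[a] - r[b], a, b)
                for i, a in enumerate(active)
                for b in active[i + 1:]
            ),
        )
        _, a, b = best
        d_ab = dist[frozenset((a, b))]
        len_a = 0.5 * d_ab + (r[a] - r[b]) / (2 * (n - 2))
        len_b = d_ab - len_a
        nodes[a].branch_length = max(len_a, 0.0)
        nodes[b].branch_length = max(len_b, 0.0)
        new_id = min(a, b)
        merged = TreeNode(children=[nodes[a], nodes[b]])
        active = [x for x in active if x not in (a, b)]
        for other in active:
            d_new = 0.5 * (
                dist.pop(frozenset((a, other)))
                + dist.pop(frozenset((b, other)))
                - d_ab
            )
            dist[frozenset((new_id, other))] = max(d_new, 0.0)
        dist.pop(frozenset((a, b)), None)
        nodes.pop(a)
        nodes.pop(b)
        nodes[new_id] = merged
        active.append(new_id)
        active.sort()

    a, b, c = active
    d_ab = dist[frozenset((a, b))]
    d_ac = dist[frozenset((a, c))]
    d_bc = dist[frozenset((b, c))]
    nodes[a].branch_length = max(0.5 * (d_ab + d_ac - d_bc), 0.0)
    nodes[b].branch_length = max(0.5 * (d_ab + d_bc - d_ac), 0.0)
    nodes[c].branch_length = max(0.5 * (d_ac + d_bc - d_ab), 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root=root, rooted=False)


@dataclass(frozen=True)
class BootstrapConfig:
    replicates: int = 1000
    seed: int = 0
    builder: str = "NJ"  # NJ | UPGMA

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.builder not in ("NJ", "UPGMA"):
            raise ValueError("builder must be NJ or UPGMA")


def _build(D: DistanceMatrix, builder: str) -> PhyloTree:
    return neighbor_joining(D) if builder == "NJ" else upgma(D)


def _bipartitions(tree: PhyloTree) -> dict[int, frozenset]:
    """Canonical split (side not containing the overall smallest label) per internal node."""
    all_leaves = frozenset(tree.leaf_labels())
    anchor = min(all_leaves)
    splits: dict[int, frozenset] = {}

    def walk(node) -> frozenset:
        if node.is_leaf():
            return frozenset((node.label,))
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree.root and 1 < len(below) < len(all_leaves) - 1:
            splits[id(node)] = below if anchor not in below else all_leaves - below
        return below

    walk(tree.root)
    return splits


def _resample(msa: Msa, rng: np.random.Generator) -> Msa:
    cols = rng.integers(0, msa.n_cols, size=msa.n_cols)
    return Msa(ids=list(msa.ids), rows=["".join(row[j] for j in cols) for row in msa.rows])


def bootstrap_support(
    msa: Msa,
    config: BootstrapConfig = BootstrapConfig(),
    distance_fn=identity_distance,
    builder: str | None = None,
) -> PhyloTree:
    """Column-resampling bootstrap; support = % replicates holding each split."""
    builder = builder or config.builder
    reference = _build(distance_fn(msa), builder)
    ref_splits = _bipartitions(reference)
    counts = {split: 0 for split in ref_splits.values()}
    rng = np.random.default_rng(config.seed)
    for _ in range(config.replicates):
        rep_tree = _build(distance_fn(_resample(msa, rng)), builder)
        rep_splits = set(_bipartitions(rep_tree).values())
        for split in counts:
            if split in rep_splits:
                counts[split] += 1

    for node in reference.postorder():
        if id(node) in ref_splits:
            node.support = 100.0 * counts[ref_splits[id(node)]] / config.replicates
    return reference
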