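"""Gene-tree/species-tree reconciliation under duplication-loss parsimony.

Every gene-tree node is mapped to the lowest species-tree node that
contains all its descendant species (the LCA map).  An internal gene
node is a DUPLICATION when it shares its image with one of its children,
otherwise a SPECIATION.  Losses are the minimal set consistent with the
map: a gene edge whose endpoints map k species edges apart implies k-1
losses below a speciation and k below a duplication, each localized to
the species branch the lineage failed to enter.

``root_by_dl`` roots an unrooted gene tree by evaluating the
duplication+loss score of every branch rooting and keeping the minimum
(ties broken on the canonical newick string; all tied rootings are
reported).

Ancestral copy numbers use the "copies exiting a species node"
convention: the number of gene lineages present in that ancestral genome
after the duplications mapped to it.  This convention reproduces the
published figure-caption claims for the K+ transporter families (one
HKT and two TPK genes in the embryophyte ancestor; one Shaker-like
channel in the land-plant ancestor and two in the tracheophyte
ancestor, with the K_in copy lost toward S. moellendorffii).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import fixtures
from .trees import PhyloTree, TreeNode, load_species_tree

DUPLICATION = "DUPLICATION"
SPECIATION = "SPECIATION"
LEAF = "LEAF"


class SpeciesIndex:
    """Constant-time ancestor/LCA queries over a rooted species tree."""

    def __init__(self, tree: PhyloTree):
        if not tree.rooted:
            raise ValueError("species tree must be rooted")
        self.tree = tree
        self.parent: dict[int, TreeNode | None] = {id(tree.root): None}
        self.depth: dict[int, int] = {id(tree.root): 0}
        self.tin: dict[int, int] = {}
        self.tout: dict[int, int] = {}
        self.leaf_by_label: dict[str, TreeNode] = {}
        self.nodes: list[TreeNode] = []
        clock = 0

        def walk(node: TreeNode):
            nonlocal clock
            self.tin[id(node)] = clock
            clock += 1
            self.nodes.append(node)
            if node.is_leaf():
                if node.label in self.leaf_by_label:
                    raise ValueError(f"duplicate species leaf {node.label!r}")
                self.leaf_by_label[node.label] = node
            for child in node.children:
                self.parent[id(child)] = node
                self.depth[id(child)] = self.depth[id(node)] + 1
                walk(child)
            self.tout[id(node)] = clock
            clock += 1

        walk(tree.root)

    def is_ancestor(self, a: TreeNode, b: TreeNode) -> bool:
        """a ancestor-or-equal of b."""
        return self.tin[id(a)] <= self.tin[id(b)] and self.tout[id(b)] <= self.tout[id(a)]

    def is_proper_ancestor(self, a: TreeNode, b: TreeNode) -> bool:
        return a is not b and self.is_ancestor(a, b)

    def lca(self, a: TreeNode, b: TreeNode) -> TreeNode:
        while not self.is_ancestor(a, b):
            a = self.parent[id(a)]
        return a

    def path_down(self, a: TreeNode, b: TreeNode) -> list[TreeNode]:
        """Nodes from ancestor a down to descendant b, inclusive."""
        if not self.is_ancestor(a, b):
            raise ValueError("a must be ancestor-or-equal of b")
        path = [b]
        while path[-1] is not a:
            path.append(self.parent[id(path[-1])])
        path.reverse()
        return path

    def name(self, node: TreeNode) -> str:
        if node.label:
            return node.label
        return ",".join(sorted(leaf.label for leaf in node.leaves()))

    def node_by_name(self, name: str) -> TreeNode:
        for node in self.nodes:
            if self.name(node) == name:
                return node
        raise KeyError(f"species node {name!r} not in species tree")


@dataclass
class ReconciliationResult:
    rooted_gene_tree: PhyloTree
    species: SpeciesIndex
    mapping: dict  # id(gene node) -> species TreeNode
    events: dict   # id(gene node) -> DUPLICATION | SPECIATION | LEAF
    duplication_count: int
    loss_count: int
    losses: list   # (gene-edge child label-or-clade, species branch name)
    leaf_map: dict

    @property
    def score(self) -> int:
        return self.duplication_count + self.loss_count

    def ancestral_copies(self, species_node) -> int:
        return ancestral_copies(self, species_node)

    def loss_species_branches(self) -> list[str]:
        return sorted(branch for _, branch in self.losses)


def lca_map(
    rooted_gene_tree: PhyloTree, species: SpeciesIndex | PhyloTree, leaf_map: dict
) -> dict:
    """Map each gene node to the species-tree LCA of its leaves' species."""
    if isinstance(species, PhyloTree):
        species = SpeciesIndex(species)
    mapping: dict[int, TreeNode] = {}
    for node in rooted_gene_tree.postorder():
        if node.is_leaf():
            if node.label not in leaf_map:
                raise KeyError(f"gene leaf {node.label!r} has no species mapping")
            sp_label = leaf_map[node.label]
            if sp_label not in species.leaf_by_label:
                raise KeyError(
                    f"gene leaf {node.label!r} maps to unknown species {sp_label!r}"
                )
            mapping[id(node)] = species.leaf_by_label[sp_label]
        else:
            image = mapping[id(node.children[0])]
            for child in node.children[1:]:
                image = species.lca(image, mapping[id(child)])
            mapping[id(node)] = image
    return mapping


def annotate_events(mapping: dict, rooted_gene_tree: PhyloTree) -> tuple[dict, int]:
    """DUPLICATION iff a node shares its species image with some child."""
    events: dict[int, str] = {}
    duplications = 0
    for node in rooted_gene_tree.postorder():
        if node.is_leaf():
            events[id(node)] = LEAF
        elif any(mapping[id(c)] is mapping[id(node)] for c in node.children):
            events[id(node)] = DUPLICATION
            duplications += 1
        else:
            events[id(node)] = SPECIATION
    return events, duplications


def _gene_label(node: TreeNode) -> str:
    if node.is_leaf():
        return node.label
    return "(" + ",".join(sorted(l.label for l in node.leaves())) + ")"


def count_losses(
    mapping: dict,
    events: dict,
    rooted_gene_tree: PhyloTree,
    species: SpeciesIndex,
    species_root_constraint: bool = False,
) -> tuple[int, list]:
    """Minimal losses consistent with the LCA map, localized to species branches.

    A gene lineage descending from species node x toward its child c
    without speciating charges one loss on the branch of the other child
    of x.  Below a speciation the first descent is the speciation itself.
    With ``species_root_constraint`` the family origin is pinned to the
    species root and losses above the gene root's image are charged too.
    """
    losses: list[tuple[str, str]] = []

    def charge(u_image: TreeNode, v_image: TreeNode, skip_first: bool, gene_child: TreeNode):
        path = species.path_down(u_image, v_image)
        start = 1 if skip_first else 0
        for i in range(start, len(path) - 1):
            node, taken = path[i], path[i + 1]
            for sibling in node.children:
                if sibling is not taken:
                    losses.append((_gene_label(gene_child), species.name(sibling)))

    for node in rooted_gene_tree.postorder():
        for child in node.children:
            u_img, v_img = mapping[id(node)], mapping[id(child)]
            if u_img is v_img:
                continue
            charge(u_img, v_img, events[id(node)] == SPECIATION, child)

    if species_root_constraint:
        root_img = mapping[id(rooted_gene_tree.root)]
        if root_img is not species.tree.root:
            charge(species.tree.root, root_img, False, rooted_gene_tree.root)

    return len(losses), losses


def reconcile(
    rooted_gene_tree: PhyloTree,
    species_tree: PhyloTree,
    leaf_map: dict,
    species_root_constraint: bool = False,
) -> ReconciliationResult:
    """Full LCA reconciliation of a rooted gene tree."""
    species = SpeciesIndex(species_tree)
    mapping = lca_map(rooted_gene_tree, species, leaf_map)
    events, duplications = annotate_events(mapping, rooted_gene_tree)
    loss_count, losses = count_losses(
        mapping, events, rooted_gene_tree, species, species_root_constraint
    )
    return ReconciliationResult(
        rooted_gene_tree=rooted_gene_tree,
        species=species,
        mapping=mapping,
        events=events,
        duplication_count=duplications,
        loss_count=loss_count,
        losses=losses,
        leaf_map=dict(leaf_map),
    )


def ancestral_copies(result: ReconciliationResult, species_node) -> int:
    """Gene copies exiting an ancestral species node (post-duplication).

    Counts gene edges (u, v) — including a virtual edge above the gene
    root — whose top end is above the node (or at it via a duplication)
    and whose bottom end is below it (or at it via a speciation/leaf).
    """
    species = result.species
    if isinstance(species_node, str):
        species_node = species.node_by_name(species_node)
    if id(species_node) not in species.tin:
        raise KeyError("species node not in the reconciled species tree")

    mapping, events = result.mapping, result.events
    count = 0

    def top_ok(u: TreeNode | None) -> bool:
        if u is None:  # virtual parent above the gene root
            return True
        m = mapping[id(u)]
        if species.is_proper_ancestor(m, species_node):
            return True
        return m is species_node and events[id(u)] == DUPLICATION

    def bottom_ok(v: TreeNode) -> bool:
        m = mapping[id(v)]
        if species.is_proper_ancestor(species_node, m):
            return True
        return m is species_node and events[id(v)] in (SPECIATION, LEAF)

    parent: dict[int, TreeNode | None] = {id(result.rooted_gene_tree.root): None}
    for node in result.rooted_gene_tree.postorder():
        for child in node.children:
            parent[id(child)] = node
    for node in result.rooted_gene_tree.postorder():
        if top_ok(parent[id(node)]) and bottom_ok(node):
            count += 1
    return count


# ---------------------------------------------------------------------------
# Rooting by duplication-loss parsimony
# ---------------------------------------------------------------------------

def canonical_newick(tree: PhyloTree) -> str:
    """Topology-only newick with children sorted; a rooting fingerprint."""

    def render(node: TreeNode) -> str:
        if node.is_leaf():
            return node.label
        return "(" + ",".join(sorted(render(c) for c in node.children)) + ")"

    return render(tree.root) + ";"


def _adjacency(tree: PhyloTree):
    """Undirected edge list and adjacency of an (un)rooted tree."""
    edges = []
    adj: dict[int, list] = {}

    def walk(node: TreeNode):
        adj.setdefault(id(node), [])
        for child in node.children:
            length = child.branch_length if child.branch_length is not None else 1.0
            edges.append((node, child, length))
            adj.setdefault(id(child), [])
            adj[id(node)].append((child, length))
            adj[id(child)].append((node, length))
            walk(child)

    walk(tree.root)
    return edges, adj


def _orient(adj, node: TreeNode, parent: TreeNode | None, incoming: float | None) -> TreeNode:
    children = [
        _orient(adj, nb, node, length)
        for nb, length in adj[id(node)]
        if nb is not parent
    ]
    label = node.label if not children else None
    return TreeNode(label=label, children=children, branch_length=incoming)


def all_rootings(unrooted: PhyloTree) -> list[PhyloTree]:
    """One rooted tree per branch of the unrooted tree."""
    edges, adj = _adjacency(unrooted)
    rootings = []
    for u, v, length in edges:
        half = length / 2.0
        root = TreeNode(children=[_orient(adj, u, v, half), _orient(adj, v, u, half)])
        rootings.append(PhyloTree(root=root, rooted=True))
    return rootings


def root_by_dl(
    unrooted_gene_tree: PhyloTree, species_tree: PhyloTree, leaf_map: dict
) -> tuple[ReconciliationResult, int, list[str]]:
    """Evaluate D+L for every branch rooting; return the minimal one.

    Ties break on the lexicographically smallest canonical newick; all
    tied rootings are reported as canonical strings.
    """
    if len(unrooted_gene_tree.leaves()) < 3:
        raise ValueError("rooting search needs >= 3 leaves")
    candidates = []
    for rooted in all_rootings(unrooted_gene_tree):
        result = reconcile(rooted, species_tree, leaf_map)
        candidates.append((result.score, canonical_newick(rooted), result))
    best_score = min(score for score, _, _ in candidates)
    tied = sorted(
        (canon, result) for score, canon, result in candidates if score == best_score
    )
    # distinct topologies only (both orientations of the root edge coincide)
    tied_canons = sorted({canon for canon, _ in tied})
    return tied[0][1], best_score, tied_canons


# ---------------------------------------------------------------------------
# Fixture gene trees from the published ortholog-group structures
# ---------------------------------------------------------------------------

def _ladder(labels: list[str]) -> TreeNode:
    node = TreeNode(label=labels[0], branch_length=1.0)
    for label in labels[1:]:
        node = TreeNode(
            children=[node, TreeNode(label=label, branch_length=1.0)],
            branch_length=1.0,
        )
    return node


def _species_restricted(sp_node: TreeNode, members: dict[str, list[str]]) -> TreeNode | None:
    """Species tree restricted to represented species; same-species loci as clades."""
    if sp_node.is_leaf():
        names = members.get(sp_node.label)
        return _ladder(sorted(names)) if names else None
    subtrees = [t for t in (_species_restricted(c, members) for c in sp_node.children) if t]
    if not subtrees:
        return None
    if len(subtrees) == 1:
        return subtrees[0]
    node = subtrees[0]
    for sub in subtrees[1:]:
        node = TreeNode(children=[node, sub], branch_length=1.0)
    return node


def build_fixture_gene_tree(
    family: str, include_partial: bool = True
) -> tuple[PhyloTree, dict]:
    """Rooted gene tree + leaf->species map for a family's packaged inventory.

    One leaf per published locus; within each ortholog group the topology
    mirrors the species tree restricted to represented species; groups
    join per the packaged structure.  ``include_partial=False`` drops the
    loci flagged as partial annotations.
    """
    if family not in fixtures.GROUP_STRUCTURES:
        raise ValueError(
            f"unknown family {family!r}; valid: {sorted(fixtures.GROUP_STRUCTURES)}"
        )
    groups = fixtures.group_members(family)
    _, join = fixtures.GROUP_STRUCTURES[family]
    species_tree = load_species_tree()

    if not include_partial:
        groups = {
            g: {
                sp: [n for n in names if n not in fixtures.PARTIAL_SEQUENCES]
                for sp, names in members.items()
            }
            for g, members in groups.items()
        }

    def build(structure) -> TreeNode:
        if isinstance(structure, str):
            subtree = _species_restricted(species_tree.root, groups[structure])
            if subtree is None:
                raise ValueError(f"group {structure!r} has no members")
            return subtree
        left, right = structure
        return TreeNode(children=[build(left), build(right)], branch_length=1.0)

    root = build(join)
    root.branch_length = None
    tree = PhyloTree(root=root, rooted=True)
    leaf_map = {
        name: sp
        for members in groups.values()
        for sp, names in members.items()
        for name in names
    }
    return tree, leaf_map


def leaf_map_from_ids(gene_leaf_labels, sep: str = "|") -> dict:
    """Species-prefix naming convention: 'Species|gene' -> species."""
    mapping = {}
    for label in gene_leaf_labels:
        if sep not in label:
            raise ValueError(f"gene leaf {label!r} lacks the '{sep}' species prefix")
        mapping[label] = label.split(sep, 1)[0]
    return mapping
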