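"""LCA reconciliation, loss localization, DL rooting, ancestral copies."""

import itertools

import pytest

from ktfam.reconcile import (
    DUPLICATION,
    LEAF,
    SPECIATION,
    SpeciesIndex,
    all_rootings,
    ancestral_copies,
    annotate_events,
    build_fixture_gene_tree,
    canonical_newick,
    count_losses,
    lca_map,
    leaf_map_from_ids,
    reconcile,
    root_by_dl,
)
from ktfam.trees import PhyloTree, TreeNode, load_species_tree, read_newick

SPECIES_3 = "((A:1,B:1):1,C:1);"


def gene(newick: str) -> PhyloTree:
    return read_newick(newick)


def species_map(tree: PhyloTree) -> dict:
    return {label: label[0] for label in tree.leaf_labels()}


# ---------------------------------------------------------------------------
# Independent oracle: minimum D+L over every valid gene->species map
# ---------------------------------------------------------------------------

def oracle_min_dl(gene_tree: PhyloTree, species_tree: PhyloTree, leaf_map: dict) -> int:
    sp = SpeciesIndex(species_tree)

    def ancestors_or_self(node):
        chain = [node]
        while sp.parent[id(node)] is not None:
            node = sp.parent[id(node)]
            chain.append(node)
        return chain

    def edge_distance(top, bottom):
        return len(sp.path_down(top, bottom)) - 1

    internal = [n for n in gene_tree.postorder() if n.children]
    fixed = {
        id(n): sp.leaf_by_label[leaf_map[n.label]]
        for n in gene_tree.postorder()
        if n.is_leaf()
    }
    best = [float("inf")]

    def assign(k, images):
        if k == len(internal):
            dup_nodes = set()
            cost = 0
            for node in internal:
                lca = sp.lca(images[id(node.children[0])], images[id(node.children[1])])
                img = images[id(node)]
                if img is not lca or any(images[id(c)] is img for c in node.children):
                    dup_nodes.add(id(node))
                    cost += 1
            for node in internal:
                for child in node.children:
                    k_edges = edge_distance(images[id(node)], images[id(child)])
                    cost += k_edges if id(node) in dup_nodes else k_edges - 1
            best[0] = min(best[0], cost)
            return
        node = internal[k]
        lca = sp.lca(images[id(node.children[0])], images[id(node.children[1])])
        for choice in ancestors_or_self(lca):
            images[id(node)] = choice
            assign(k + 1, images)
        del images[id(node)]

    # children must be assigned before parents: postorder ordering guarantees it
    assign(0, dict(fixed))
    return best[0]


def brute_force_lca(species_tree: PhyloTree, leaves_a, leaves_b=None):
    """LCA by explicit root-path intersection."""
    sp = SpeciesIndex(species_tree)

    def root_path(node):
        path = [node]
        while sp.parent[id(node)] is not None:
            node = sp.parent[id(node)]
            path.append(node)
        return path

    nodes = [sp.leaf_by_label[l] for l in leaves_a]
    common = set(id(n) for n in root_path(nodes[0]))
    for node in nodes[1:]:
        common &= set(id(n) for n in root_path(node))
    # deepest common ancestor
    for node in root_path(nodes[0]):
        if id(node) in common:
            return node
    raise AssertionError


class TestLcaMap:
    def test_congruent_tree_is_isomorphism(self):
        species = read_newick(SPECIES_3)
        g = gene("((A1:1,B1:1):1,C1:1);")
        mapping = lca_map(g, species, species_map(g))
        sp = SpeciesIndex(species)
        assert mapping[id(g.root)] is species.root
        left = g.root.children[0]
        assert sorted(l.label for l in mapping[id(left)].leaves()) == ["A", "B"]

    def test_quartet_maps_to_ab_ancestor(self):
        species = read_newick("(A:1,B:1);")
        g = gene("((A1:1,B1:1):1,(A2:1,B2:1):1);")
        mapping = lca_map(g, species, species_map(g))
        for node in g.postorder():
            if node.children:
                assert mapping[id(node)] is species.root

    def test_unmapped_leaf_named(self):
        species = read_newick(SPECIES_3)
        g = gene("(A1:1,Z9:1);")
        with pytest.raises(KeyError, match="Z9"):
            lca_map(g, species, {"A1": "A"})

    def test_matches_bruteforce_path_intersection(self, rng):
        species = load_species_tree()
        tags = species.leaf_labels()
        for _ in range(25):
            n = int(rng.integers(2, 9))
            leaves = [f"{tags[rng.integers(5)]}|g{i}" for i in range(n)]
            topo = _random_rooted_topology(leaves, rng)
            g = PhyloTree(root=topo, rooted=True)
            mapping = lca_map(g, species, leaf_map_from_ids(leaves))
            for node in g.postorder():
                if node.children:
                    below = sorted({l.label.split("|")[0] for l in node.leaves()})
                    assert mapping[id(node)] is brute_force_lca(species, below)


def _random_rooted_topology(labels, rng):
    nodes = [TreeNode(label=l, branch_length=1.0) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(TreeNode(children=[a, b], branch_length=1.0))
    return nodes[0]


class TestEventsAndLosses:
    def test_congruent_tree_no_events(self):
        species = read_newick(SPECIES_3)
        g = gene("((A1:1,B1:1):1,C1:1);")
        result = reconcile(g, species, species_map(g))
        assert result.duplication_count == 0 and result.loss_count == 0

    def test_quartet_root_duplication(self):
        species = read_newick("(A:1,B:1);")
        g = gene("((A1:1,B1:1):1,(A2:1,B2:1):1);")
        mapping = lca_map(g, species, species_map(g))
        events, dups = annotate_events(mapping, g)
        assert dups == 1
        assert events[id(g.root)] == DUPLICATION
        for child in g.root.children:
            assert events[id(child)] == SPECIATION

    def test_three_leaf_dup_plus_loss(self):
        species = read_newick("(A:1,B:1);")
        g = gene("(A1:1,(A2:1,B1:1):1);")
        result = reconcile(g, species, species_map(g))
        assert result.events[id(g.root)] == DUPLICATION
        assert (result.duplication_count, result.loss_count) == (1, 1)
        assert result.loss_species_branches() == ["B"]

    def test_matches_exhaustive_map_minimum_small_sample(self, rng):
        species = read_newick(SPECIES_3)
        cases = 0
        for n in (3, 4):
            for assignment in itertools.product("ABC", repeat=n):
                if rng.random() > 0.25:
                    continue
                labels = [f"{sp}{i}" for i, sp in enumerate(assignment)]
                g = PhyloTree(root=_random_rooted_topology(labels, rng), rooted=True)
                result = reconcile(g, species, {l: l[0] for l in labels})
                assert result.score == oracle_min_dl(g, species, {l: l[0] for l in labels})
                cases += 1
        assert cases > 20


class TestRootByDl:
    def test_congruent_unrooted_scores_zero(self):
        species = read_newick(SPECIES_3)
        unrooted = read_newick("(A1:1,B1:1,C1:1);", rooted=False)
        result, score, tied = root_by_dl(unrooted, species, species_map(unrooted))
        assert score == 0

    def test_quartet_roots_on_central_edge(self):
        species = read_newick("(A:1,B:1);")
        unrooted = read_newick("((A1:1,B1:1):1,A2:1,B2:1);", rooted=False)
        result, score, tied = root_by_dl(unrooted, species, species_map(unrooted))
        assert score == 1
        assert (result.duplication_count, result.loss_count) == (1, 0)

    def test_minimum_over_all_rootings(self, rng):
        species = read_newick(SPECIES_3)
        for _ in range(10):
            labels = [f"{'ABC'[rng.integers(3)]}{i}" for i in range(6)]
            rooted = PhyloTree(root=_random_rooted_topology(labels, rng), rooted=True)
            # flatten to an unrooted view by attaching the root trivalently
            a, b = rooted.root.children
            if a.is_leaf() and b.is_leaf():
                continue
            host, other = (a, b) if a.children else (b, a)
            unrooted = PhyloTree(
                root=TreeNode(children=list(host.children) + [other]), rooted=False
            )
            lm = {l: l[0] for l in labels}
            _, score, _ = root_by_dl(unrooted, species, lm)
            explicit = [
                oracle_min_dl(r, species, lm) for r in all_rootings(unrooted)
            ]
            assert score == min(explicit)


class TestAncestralCopies:
    def test_congruent_single_copy_everywhere(self):
        species = read_newick(SPECIES_3)
        g = gene("((A1:1,B1:1):1,C1:1);")
        result = reconcile(g, species, species_map(g))
        for node in result.species.nodes:
            if node.children:
                assert ancestral_copies(result, node) == 1

    def test_quartet_two_copies_exit_root(self):
        species = read_newick("(A:1,B:1);")
        g = gene("((A1:1,B1:1):1,(A2:1,B2:1):1);")
        result = reconcile(g, species, species_map(g))
        assert ancestral_copies(result, species.root) == 2

    def test_unknown_species_node_rejected(self):
        species = read_newick(SPECIES_3)
        g = gene("((A1:1,B1:1):1,C1:1);")
        result = reconcile(g, species, species_map(g))
        with pytest.raises(KeyError):
            ancestral_copies(result, "Zebra")


class TestFixtureGeneTrees:
    def test_hkt_sixteen_leaves(self, species_tree):
        tree, leaf_map = build_fixture_gene_tree("HKT")
        assert len(tree.leaves()) == 16
        per_species = {}
        for leaf, sp in leaf_map.items():
            per_species[sp] = per_species.get(sp, 0) + 1
        assert per_species == {
            "Athaliana": 1, "Osativa": 7, "Ptrichocarpa": 1,
            "Ppatens": 1, "Smoellendorffii": 6,
        }

    def test_tpk_root_duplication_at_embryophyte_root(self, species_tree):
        tree, leaf_map = build_fixture_gene_tree("TPK")
        result = reconcile(tree, species_tree, leaf_map)
        assert result.events[id(tree.root)] == DUPLICATION
        assert result.mapping[id(tree.root)] is species_tree.root

    def test_shaker_single_smoellendorffii_leaf(self):
        tree, leaf_map = build_fixture_gene_tree("SHAKER")
        sm = [l for l, sp in leaf_map.items() if sp == "Smoellendorffii"]
        assert sm == ["Sel-moe-SmORK"]

    def test_partial_sequence_flag(self):
        full, _ = build_fixture_gene_tree("SHAKER", include_partial=True)
        trimmed, lm = build_fixture_gene_tree("SHAKER", include_partial=False)
        assert len(full.leaves()) == len(trimmed.leaves()) + 1
        assert "Pop-tri-Kc06" not in lm

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            build_fixture_gene_tree("KEA")


class TestInvariants:
    def test_leaf_copy_conservation(self, species_tree):
        for family in ("HKT", "TPK", "SHAKER", "HAK"):
            tree, leaf_map = build_fixture_gene_tree(family)
            result = reconcile(tree, species_tree, leaf_map)
            per_leaf = sum(
                ancestral_copies(result, leaf)
                for leaf in species_tree.leaves()
            )
            assert per_leaf == len(tree.leaves())

    def test_grafting_species_specific_leaf_monotone(self, species_tree):
        tree, leaf_map = build_fixture_gene_tree("HKT")
        before = reconcile(tree, species_tree, leaf_map)
        root_copies_before = ancestral_copies(before, species_tree.root)

        grafted, leaf_map2 = build_fixture_gene_tree("HKT")
        target = next(l for l in grafted.leaves() if leaf_map2[l.label] == "Osativa")
        twin = TreeNode(label="Ory-sat-HKT-extra", branch_length=1.0)
        old = TreeNode(label=target.label, branch_length=1.0)
        target.label = None
        target.children = [old, twin]
        leaf_map2["Ory-sat-HKT-extra"] = "Osativa"
        after = reconcile(grafted, species_tree, leaf_map2)
        assert after.duplication_count >= before.duplication_count
        assert ancestral_copies(after, species_tree.root) == root_copies_before

    def test_species_specific_leaf_copies_match_counts(self, species_tree):
        tree, leaf_map = build_fixture_gene_tree("TPK")
        result = reconcile(tree, species_tree, leaf_map)
        for leaf in species_tree.leaves():
            expected = sum(1 for sp in leaf_map.values() if sp == leaf.label)
            assert ancestral_copies(result, leaf) == expected
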