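"""Synthetic proteomes with planted K+ transporter families and ground truth.

Families evolve along the packaged five-species tree under a
birth-death process (per-copy duplication and loss with exponential
waiting times), sequences evolve from a family template by independent
per-site substitution, and planted motif positions are constrained to
their allowed residue sets so that every emitted family member is
guaranteed to carry its class motifs at known offsets.  Decoy proteins
(uniform-random with a matched length distribution) and near-miss decoys
(templates with one motif position broken) exercise the specificity of
screening and curation.

The substitution process is a uniform-replacement model, not an
empirical rate matrix: it is sufficient to exercise alignment, distance
and classification machinery but is not phylogenetically realistic.
Indels are not simulated, so within-family alignments are gap-free by
construction.  All randomness flows from a single seed through named
substreams, so each stage is independently reproducible.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .motifs import MotifPattern, classify, load_motif_library, scan
from .seqio import AMINO_ACIDS, ProteinRecord, write_fasta
from .trees import PhyloTree, TreeNode, load_species_tree

_AA = sorted(AMINO_ACIDS)

FAMILY_NAMES = ("HAK", "HKT", "TPK", "SHAKER")


@dataclass(frozen=True)
class FamilyTemplate:
    """A template protein with planted motif instances at fixed offsets."""

    family: str
    sequence: str
    motif_offsets: tuple  # ((motif_id, offset), ...)

    def validate(self, library: list[MotifPattern]) -> None:
        by_id = {p.motif_id: p for p in library}
        for motif_id, offset in self.motif_offsets:
            pattern = by_id[motif_id]
            if not pattern.matches_at(self.sequence, offset):
                raise ValueError(
                    f"{self.family} template: motif {motif_id} does not match at {offset}"
                )


def _planted_instance(pattern: MotifPattern, rng: np.random.Generator) -> str:
    return "".join(
        _AA[rng.integers(len(_AA))] if allowed is None else sorted(allowed)[0]
        for allowed in pattern.positions
    )


def _make_template(
    family: str,
    length: int,
    placements: list[tuple[int, int]],
    library: list[MotifPattern],
    rng: np.random.Generator,
) -> FamilyTemplate:
    by_id = {p.motif_id: p for p in library}
    for _ in range(200):
        residues = [_AA[i] for i in rng.integers(len(_AA), size=length)]
        for motif_id, offset in placements:
            inst = _planted_instance(by_id[motif_id], rng)
            residues[offset : offset + len(inst)] = inst
        seq = "".join(residues)
        template = FamilyTemplate(family, seq, tuple(placements))
        template.validate(library)
        call = classify(ProteinRecord(id="tmpl", species="tmpl", sequence=seq), library)
        expected = "CHANNEL" if family in ("TPK", "SHAKER") else family
        if call.family != expected:
            continue
        if family == "TPK" and call.channel_subtype != "TANDEM_PORE":
            continue
        if family == "SHAKER" and call.channel_subtype != "SINGLE_PORE":
            continue
        return template
    raise RuntimeError(f"could not build a clean {family} template")


def default_templates(library: list[MotifPattern] | None = None) -> dict[str, FamilyTemplate]:
    """Deterministic family templates (fixed internal stream).

    HAK carries the five HAK motifs; HKT both HKT motifs; TPK two pore
    motifs (tandem pore); SHAKER one pore motif flanked by the
    voltage-sensor- and inner-helix-like motifs.
    """
    library = library or load_motif_library()
    rng = np.random.default_rng(90417)  # fixed template stream
    # lengths are roughly half the real proteins (HAK ~780 aa, Shaker ~700,
    # HKT ~500, TPK ~370), keeping their relative order
    return {
        "HAK": _make_template(
            "HAK", 400, [(6, 30), (7, 100), (8, 170), (9, 250), (10, 330)], library, rng
        ),
        "HKT": _make_template("HKT", 280, [(4, 60), (5, 180)], library, rng),
        "TPK": _make_template("TPK", 220, [(1, 50), (1, 140)], library, rng),
        "SHAKER": _make_template("SHAKER", 340, [(2, 40), (1, 160), (3, 260)], library, rng),
    }


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic five-proteome benchmark.

    Rates are events per copy per branch-length unit on the species tree
    (unit branch lengths by default).  The defaults generate modest
    family expansion (a few duplications per family across the tree),
    ~80% within-family identity, and ten decoys per species.
    """

    species_tree: PhyloTree | None = None
    dup_rate: float = 0.2
    loss_rate: float = 0.05
    subst_rate: float = 0.03
    families: tuple = FAMILY_NAMES
    decoys_per_species: int = 10
    near_miss_fraction: float = 0.1
    seed: int = 0
    terminal_duplications_only: bool = False
    #: with terminal_duplications_only, duplications fall in the last
    #: fraction of the terminal branch (rate rescaled to keep the expected
    #: count): recent paralogs are clearly less diverged than sister
    #: species, which is what makes exact event recovery identifiable
    terminal_dup_window: float = 0.3
    retry_cap: int = 50

    def __post_init__(self):
        if min(self.dup_rate, self.loss_rate, self.subst_rate) < 0:
            raise ValueError("rates must be nonnegative")
        if self.species_tree is None:
            self.species_tree = load_species_tree()


@dataclass
class GroundTruth:
    family_labels: dict  # protein id -> family or "DECOY"
    gene_trees: dict     # family -> newick of the true gene tree
    events: dict         # family -> list of (event, species_branch)
    copy_numbers: dict   # family -> {species: true copy number}
    motif_coordinates: dict  # protein id -> [(motif_id, offset), ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "family_labels": self.family_labels,
                "gene_trees": self.gene_trees,
                "events": self.events,
                "copy_numbers": self.copy_numbers,
                "motif_coordinates": self.motif_coordinates,
            },
            indent=2,
            sort_keys=True,
        )


def _substream(seed: int, *tags) -> np.random.Generator:
    # zlib.crc32 is stable across processes (unlike hash())
    return np.random.default_rng(
        [seed % (2**31), *(zlib.crc32(str(t).encode()) % (2**31) for t in tags)]
    )


# ---------------------------------------------------------------------------
# Birth-death gene family evolution along the species tree
# ---------------------------------------------------------------------------

@dataclass
class _Lineage:
    node: TreeNode  # gene-tree node under construction


def _evolve_branch(
    entering: list[TreeNode],
    branch_length: float,
    species_label: str,
    dup_rate: float,
    loss_rate: float,
    rng: np.random.Generator,
    events: list,
) -> list[TreeNode]:
    """Duplicate/lose copies along one species branch; returns surviving tips.

    Each entering gene node gets children as events unfold; returned
    nodes are the copies reaching the bottom of the branch.
    """
    surviving = []
    stack = [(node, branch_length) for node in entering]
    total = dup_rate + loss_rate
    while stack:
        node, remaining = stack.pop()
        if total <= 0:
            node.branch_length = (node.branch_length or 0.0) + remaining
            surviving.append(node)
            continue
        wait = rng.exponential(1.0 / total)
        if wait >= remaining:
            node.branch_length = (node.branch_length or 0.0) + remaining
            surviving.append(node)
            continue
        node.branch_length = (node.branch_length or 0.0) + wait
        if rng.random() < dup_rate / total:
            events.append(("DUPLICATION", species_label))
            left = TreeNode(branch_length=0.0)
            right = TreeNode(branch_length=0.0)
            node.children = [left, right]
            stack.append((right, remaining - wait))
            stack.append((left, remaining - wait))
        else:
            events.append(("LOSS", species_label))
            node.label = "__LOST__"
    return surviving


def _prune_lost(node: TreeNode) -> TreeNode | None:
    """Remove extinct lineages; suppress unary nodes, merging branch lengths."""
    if node.is_leaf():
        return None if node.label == "__LOST__" else node
    kept = [c for c in (_prune_lost(c) for c in node.children) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        child = kept[0]
        child.branch_length = (child.branch_length or 0.0) + (node.branch_length or 0.0)
        return child
    node.children = kept
    return node


def simulate_family(config: SimulationConfig, family: str) -> tuple[PhyloTree, list]:
    """Birth-death evolution of one family; returns (true gene tree, events).

    Leaves are labeled 'Species|FAMILY_gK'.  Fully extinct families are
    re-drawn up to config.retry_cap.
    """
    rng = _substream(config.seed, "family", family)
    for attempt in range(config.retry_cap):
        events: list = []
        counters: dict[str, int] = {}

        def recurse(sp_node: TreeNode, entering: list[TreeNode]):
            length = sp_node.branch_length or 1.0
            label = sp_node.label or "internal"
            if not config.terminal_duplications_only:
                tips = _evolve_branch(
                    entering, length, label, config.dup_rate, config.loss_rate, rng, events
                )
            elif sp_node.is_leaf():
                window = config.terminal_dup_window
                tips = _evolve_branch(
                    entering, length * (1 - window), label, 0.0, config.loss_rate, rng, events
                )
                tips = _evolve_branch(
                    tips, length * window, label, config.dup_rate / window,
                    config.loss_rate, rng, events,
                )
            else:
                tips = _evolve_branch(
                    entering, length, label, 0.0, config.loss_rate, rng, events
                )
            if sp_node.is_leaf():
                for tip in tips:
                    counters[sp_node.label] = counters.get(sp_node.label, 0) + 1
                    tip.label = f"{sp_node.label}|{family}_g{counters[sp_node.label]}"
                return
            for tip in tips:
                children = [TreeNode(branch_length=0.0) for _ in sp_node.children]
                tip.children = children
                if len(children) > 1:
                    events.append(("SPECIATION", sp_node.label or "internal"))
            for k, sp_child in enumerate(sp_node.children):
                recurse(sp_child, [tip.children[k] for tip in tips])

        sp_root = config.species_tree.root
        root = TreeNode(branch_length=0.0)
        # one ancestral copy at the species root; the root branch is not evolved
        root.children = [TreeNode(branch_length=0.0) for _ in sp_root.children]
        for k, sp_child in enumerate(sp_root.children):
            recurse(sp_child, [root.children[k]])

        pruned = _prune_lost(root)
        if pruned is None:
            continue  # fully extinct: redraw
        pruned.branch_length = None
        return PhyloTree(root=pruned, rooted=True), events
    raise RuntimeError(
        f"family {family} went extinct {config.retry_cap} times; lower loss_rate"
    )


# ---------------------------------------------------------------------------
# Sequence evolution with motif-constrained sites
# ---------------------------------------------------------------------------

def _mutate(
    sequence: str,
    branch_length: float,
    subst_rate: float,
    constraints: dict,
    rng: np.random.Generator,
) -> str:
    p = 1.0 - math.exp(-subst_rate * branch_length)
    if p <= 0:
        return sequence
    residues = list(sequence)
    hits = np.nonzero(rng.random(len(residues)) < p)[0]
    for site in hits:
        allowed = constraints.get(site)
        if allowed is None:
            choices = [a for a in _AA if a != residues[site]]
        else:
            choices = [a for a in sorted(allowed) if a != residues[site]]
            if not choices:
                continue  # single-residue motif position: frozen
        residues[site] = choices[rng.integers(len(choices))]
    return "".join(residues)


def _constraints(template: FamilyTemplate, library: list[MotifPattern]) -> dict:
    by_id = {p.motif_id: p for p in library}
    constraints: dict[int, frozenset] = {}
    for motif_id, offset in template.motif_offsets:
        for k, allowed in enumerate(by_id[motif_id].positions):
            if allowed is not None:
                constraints[offset + k] = allowed
    return constraints


def evolve_sequences(
    gene_tree: PhyloTree,
    template: FamilyTemplate,
    config: SimulationConfig,
    library: list[MotifPattern] | None = None,
) -> list[ProteinRecord]:
    """Evolve the template along the gene tree; one protein per gene leaf.

    Sites inside planted motif spans only mutate within the motif's
    allowed set, so every emitted member still scans positive at the
    planted offsets.
    """
    library = library or load_motif_library()
    constraints = _constraints(template, library)
    rng = _substream(config.seed, "sequence", template.family)
    proteins = []

    def walk(node: TreeNode, sequence: str):
        seq = _mutate(sequence, node.branch_length or 0.0, config.subst_rate, constraints, rng)
        if node.is_leaf():
            species = node.label.split("|", 1)[0]
            proteins.append(
                ProteinRecord(id=node.label, species=species, sequence=seq,
                              description=f"synthetic {template.family} member")
            )
        for child in node.children:
            walk(child, seq)

    walk(gene_tree.root, template.sequence)
    return proteins


# ---------------------------------------------------------------------------
# Proteome emission: families + decoys + near-misses, with ground truth
# ---------------------------------------------------------------------------

def _random_decoy(length: int, rng: np.random.Generator) -> str:
    return "".join(_AA[i] for i in rng.integers(len(_AA), size=length))


#: planted motif instances to break so the source family's rule fails:
#: HAK needs 3 of its 5 motifs knocked out (rule: >=3 match), the others one
_NEAR_MISS_BREAKS = {"HAK": 3, "HKT": 1, "TPK": 1, "SHAKER": 1}


def _near_miss(
    template: FamilyTemplate, library: list[MotifPattern], rng: np.random.Generator
) -> str:
    """Template copy with one restricted position per broken motif instance.

    For SHAKER the broken instance is the pore motif (motif 1), the one
    whose loss defeats the channel rule.
    """
    by_id = {p.motif_id: p for p in library}
    placements = list(template.motif_offsets)
    if template.family == "SHAKER":
        targets = [p for p in placements if p[0] == 1]
    else:
        order = rng.permutation(len(placements))
        targets = [placements[i] for i in order[: _NEAR_MISS_BREAKS[template.family]]]
    residues = list(template.sequence)
    for motif_id, offset in targets:
        pattern = by_id[motif_id]
        restricted = [k for k, allowed in enumerate(pattern.positions) if allowed is not None]
        k = restricted[rng.integers(len(restricted))]
        outside = [a for a in _AA if a not in pattern.positions[k]]
        residues[offset + k] = outside[rng.integers(len(outside))]
    return "".join(residues)


def emit_proteomes(
    config: SimulationConfig,
) -> tuple[dict[str, list[ProteinRecord]], GroundTruth]:
    """Per-species protein lists plus the ground truth for every record."""
    library = load_motif_library()
    templates = default_templates(library)
    proteomes: dict[str, list[ProteinRecord]] = {
        leaf: [] for leaf in config.species_tree.leaf_labels()
    }
    labels: dict[str, str] = {}
    gene_trees: dict[str, str] = {}
    events_out: dict[str, list] = {}
    copy_numbers: dict[str, dict] = {}
    motif_coords: dict[str, list] = {}

    for family in config.families:
        template = templates[family]
        tree, events = simulate_family(config, family)
        gene_trees[family] = tree.newick()
        events_out[family] = events
        members = evolve_sequences(tree, template, config, library)
        counts = {sp: 0 for sp in proteomes}
        for protein in members:
            proteomes[protein.species].append(protein)
            labels[protein.id] = family
            counts[protein.species] += 1
            motif_coords[protein.id] = [list(t) for t in template.motif_offsets]
        copy_numbers[family] = counts

    member_lengths = [len(t.sequence) for t in templates.values()]
    decoy_rng = _substream(config.seed, "decoy")
    for species in sorted(proteomes):
        n_near = int(round(config.decoys_per_species * config.near_miss_fraction))
        for k in range(config.decoys_per_species):
            if k < n_near:
                family = sorted(config.families)[int(decoy_rng.integers(len(config.families)))]
                seq = _near_miss(templates[family], library, decoy_rng)
                desc = f"near-miss decoy ({family} template, one motif position broken)"
            else:
                length = member_lengths[int(decoy_rng.integers(len(member_lengths)))]
                length = int(length + decoy_rng.integers(-20, 21))
                seq = _random_decoy(max(length, 30), decoy_rng)
                desc = "random decoy"
            pid = f"{species}|DECOY_d{k + 1}"
            proteomes[species].append(
                ProteinRecord(id=pid, species=species, sequence=seq, description=desc)
            )
            labels[pid] = "DECOY"

    truth = GroundTruth(
        family_labels=labels,
        gene_trees=gene_trees,
        events=events_out,
        copy_numbers=copy_numbers,
        motif_coordinates=motif_coords,
    )
    return proteomes, truth


def write_proteomes(proteomes: dict, truth: GroundTruth, outdir) -> None:
    """Write <species>.fa files, truth.json and gene_trees.nwk."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for species, records in sorted(proteomes.items()):
        write_fasta(records, out / f"{species}.fa")
    (out / "truth.json").write_text(truth.to_json())
    (out / "gene_trees.nwk").write_text(
        "".join(f"{fam}\t{nwk}\n" for fam, nwk in sorted(truth.gene_trees.items()))
    )
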