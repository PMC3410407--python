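"""End-to-end screen orchestration and inventory tables.

``run_screen`` chains the pipeline over a set of proteomes: motif
classification → per-family curation against reference proteins →
progressive alignment → conserved-block filtering → neighbor-joining
tree → duplication-loss rooting and reconciliation against the species
tree.  The result is an inventory table comparable to the packaged
reference tables plus per-family artifacts for audit.

Channel calls are routed by pore count: tandem-pore subunits to TPK,
single-pore subunits with voltage-sensor-like motif evidence to the
Shaker-like family, and anything else to OTHER_VG for human review
(mirroring the similarity-based identification of BK-like channels
without a BLAST stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import fixtures
from .align import BlockFilterParams, Msa, block_filter, identity_distance, progressive_msa
from .curation import CurationParams, CurationReport, curate
from .motifs import ClassificationRules, classify, load_motif_library
from .reconcile import ReconciliationResult, leaf_map_from_ids, reconcile, root_by_dl
from .seqio import ProteinRecord
from .trees import PhyloTree, load_species_tree, neighbor_joining

VALID_FAMILIES = fixtures.FAMILIES  # HAK, HKT, TPK, SHAKER, OTHER_VG
CURATED_FAMILIES = ("HAK", "HKT", "TPK", "SHAKER")


@dataclass
class InventoryTable:
    """Rows of (species, family, locus, name); FIXTURE or COMPUTED."""

    rows: list  # of (species, family, locus, name)
    provenance: str = "COMPUTED"

    def __post_init__(self):
        seen = set()
        for species, family, locus, _name in self.rows:
            if family not in VALID_FAMILIES:
                raise ValueError(f"unknown family {family!r}; valid: {VALID_FAMILIES}")
            key = (species, locus)
            if key in seen:
                raise ValueError(f"duplicate (species, locus) row: {key}")
            seen.add(key)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["species", "family", "locus", "name"])

    @classmethod
    def fixture(cls) -> "InventoryTable":
        table = fixtures.load_all_tables()
        return cls(rows=[tuple(r) for r in table.itertuples(index=False)], provenance="FIXTURE")

    @classmethod
    def fixture_for(cls, number: int) -> "InventoryTable":
        table = fixtures.load_table(number)
        return cls(rows=[tuple(r) for r in table.itertuples(index=False)], provenance="FIXTURE")


def count_inventory(table: InventoryTable, species: str, family: str) -> int:
    """Number of rows matching (species, family)."""
    if family not in VALID_FAMILIES:
        raise ValueError(f"unknown family {family!r}; valid: {VALID_FAMILIES}")
    known_species = {row[0] for row in table.rows} | set(fixtures.LAND_PLANTS)
    if species not in known_species:
        raise ValueError(f"unknown species {species!r}; valid: {sorted(known_species)}")
    return sum(1 for row in table.rows if row[0] == species and row[1] == family)


def compare_inventories(computed: InventoryTable, fixture: InventoryTable) -> dict:
    """Per (species, family): counts, shared loci, additions, omissions."""
    comp: dict[tuple, set] = {}
    fix: dict[tuple, set] = {}
    for species, family, locus, _ in computed.rows:
        comp.setdefault((species, family), set()).add(locus)
    for species, family, locus, _ in fixture.rows:
        fix.setdefault((species, family), set()).add(locus)
    diff = {}
    for key in sorted(set(comp) | set(fix)):
        c, f = comp.get(key, set()), fix.get(key, set())
        diff[key] = {
            "computed_count": len(c),
            "fixture_count": len(f),
            "shared": sorted(c & f),
            "additions": sorted(c - f),
            "omissions": sorted(f - c),
        }
    return diff


def diff_is_empty(diff: dict) -> bool:
    return all(not d["additions"] and not d["omissions"] for d in diff.values())


@dataclass
class PipelineConfig:
    """Per-stage parameters for a screen run; unknown keys are rejected."""

    rules: ClassificationRules = field(default_factory=ClassificationRules)
    curation: CurationParams = field(default_factory=CurationParams)
    block_filter: BlockFilterParams = field(default_factory=BlockFilterParams)
    references: dict = field(default_factory=dict)  # family -> list[ProteinRecord]
    species_tree: PhyloTree | None = None
    species_root_constraint: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.species_tree is None:
            self.species_tree = load_species_tree()
        if not self.references:
            from .syndata import default_templates

            self.references = {
                family: [
                    ProteinRecord(
                        id=f"ref|{family}", species="reference", sequence=t.sequence
                    )
                ]
                for family, t in default_templates().items()
            }

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        allowed = {"rules", "curation", "block_filter", "species_root_constraint", "seed"}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        if "rules" in raw:
            kwargs["rules"] = ClassificationRules(**raw["rules"])
        if "curation" in raw:
            kwargs["curation"] = CurationParams(**raw["curation"])
        if "block_filter" in raw:
            kwargs["block_filter"] = BlockFilterParams(**raw["block_filter"])
        for key in ("species_root_constraint", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class FamilyArtifacts:
    family: str
    candidates: list          # candidate ids after classification
    curation: CurationReport | None
    members: list             # selected ids
    msa: Msa | None
    filtered_msa: Msa | None
    retained_columns: list
    gene_tree: PhyloTree | None
    reconciliation: ReconciliationResult | None
    warnings: list


@dataclass
class ScreenResult:
    inventory: InventoryTable
    families: dict  # family -> FamilyArtifacts
    manifest: dict


def _route_family(call) -> str | None:
    """Map a motif FamilyCall onto an inventory family."""
    if call.family in ("HAK", "HKT"):
        return call.family
    if call.family == "CHANNEL":
        if call.channel_subtype == "TANDEM_PORE":
            return "TPK"
        if call.channel_subtype == "SINGLE_PORE" and (
            {2, 3} & set(call.motif_ids_matched)
        ):
            return "SHAKER"
        return "OTHER_VG"
    return None


def run_screen(
    proteomes: dict[str, list[ProteinRecord]],
    config: PipelineConfig | None = None,
) -> ScreenResult:
    """Screen proteomes end to end; pure function of (inputs, config, seed)."""
    config = config or PipelineConfig()
    library = load_motif_library()
    proteins: list[ProteinRecord] = [
        p for species in sorted(proteomes) for p in proteomes[species]
    ]
    by_id = {p.id: p for p in proteins}

    candidates: dict[str, list[str]] = {f: [] for f in VALID_FAMILIES}
    for protein in proteins:
        family = _route_family(classify(protein, library, config.rules))
        if family is not None:
            candidates[family].append(protein.id)

    rows: list[tuple] = []
    artifacts: dict[str, FamilyArtifacts] = {}

    for family in CURATED_FAMILIES:
        warnings: list[str] = []
        ids = sorted(candidates[family])
        family_art = FamilyArtifacts(
            family=family, candidates=ids, curation=None, members=[], msa=None,
            filtered_msa=None, retained_columns=[], gene_tree=None,
            reconciliation=None, warnings=warnings,
        )
        artifacts[family] = family_art
        if not ids:
            continue
        references = config.references.get(family, [])
        if not references:
            warnings.append("no reference proteins; curation skipped")
            continue
        report = curate([by_id[i] for i in ids], references, library, config.curation)
        family_art.curation = report
        selected = set(report.selected_component)
        # identical paralogs are dropped from the similarity graph only;
        # the inventory retains them alongside their kept twin
        restored = {dup for dup, keeper in report.duplicate_of.items() if keeper in selected}
        members = sorted(selected | restored)
        family_art.members = members
        for mid in members:
            record = by_id[mid]
            rows.append((record.species, family, mid, mid))

        if len(members) >= 2:
            msa = progressive_msa([by_id[m] for m in members])
            family_art.msa = msa
            filtered, retained = block_filter(msa, config.block_filter)
            family_art.retained_columns = retained
            if filtered.n_cols == 0:
                warnings.append("block filter removed every column; using unfiltered MSA")
                filtered = msa
            family_art.filtered_msa = filtered
            if len(members) >= 3:
                unrooted = neighbor_joining(identity_distance(filtered))
                leaf_map = {}
                for m in members:
                    leaf_map[m] = by_id[m].species
                result, _score, _tied = root_by_dl(unrooted, config.species_tree, leaf_map)
                family_art.gene_tree = result.rooted_gene_tree
                family_art.reconciliation = result

    for pid in sorted(candidates["OTHER_VG"]):
        record = by_id[pid]
        rows.append((record.species, "OTHER_VG", pid, pid))
    artifacts["OTHER_VG"] = FamilyArtifacts(
        family="OTHER_VG", candidates=sorted(candidates["OTHER_VG"]),
        curation=None, members=sorted(candidates["OTHER_VG"]), msa=None,
        filtered_msa=None, retained_columns=[], gene_tree=None,
        reconciliation=None, warnings=["similarity-unreviewed channel calls"],
    )

    from . import __version__

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_proteins": len(proteins),
        "rules": vars(config.rules),
        "curation": vars(config.curation),
        "block_filter": vars(config.block_filter),
    }
    inventory = InventoryTable(rows=sorted(rows), provenance="COMPUTED")
    return ScreenResult(inventory=inventory, families=artifacts, manifest=manifest)
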