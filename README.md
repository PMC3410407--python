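# ktfam

Genome-wide inventories of plant potassium-transport protein families —
HAK/KT/KUP and HKT transporters, tandem-pore (TPK) channels,
voltage-gated Shaker-like channels, and BK-like channels — with the
phylogenetic machinery to turn those inventories into statements about
ancestral genomes.

`ktfam` is for comparative genomicists and plant membrane-transport
researchers who want a tested, scriptable version of the classic
inventory workflow:

1. **screen** proteomes with ten class-specific degenerate motifs
   (PROSITE-style exact positional matching, e.g. the K⁺ channel pore
   motif `[S,T]-x-x-T-x-G-[Y,F,L]-G-[D,E]`);
2. **curate** the raw hits semi-automatically — length filter against
   the reference motif span, all-vs-all global-alignment percent
   identities, removal of duplicate (identity 100) and weak (< 20)
   pairs, fragmentation into similarity groups, selection of the
   reference-like group;
3. **verify exhaustiveness** by scanning six-frame genome translations
   for the K⁺ selectivity-filter tripeptide G-Y-G inside ORFs;
4. **align** each family, filter low-quality alignment blocks
   (conserved/flank thresholds at ⌈n/2⌉, non-conserved runs ≤ 20,
   blocks ≥ 2, gaps as ordinary symbols), and build distance trees
   (UPGMA / neighbor joining, seeded bootstrap);
5. **reconcile** each gene tree against the species tree
   `(Ppatens,(Smoellendorffii,(Osativa,(Athaliana,Ptrichocarpa))))`
   under duplication–loss parsimony: LCA mapping M, duplication at node
   *u* iff M(u) = M(c) for a child *c*, minimal losses localized to
   species branches, rooting by minimal D+L, and ancestral copy numbers
   as *copies exiting* a species node.

The five published inventory tables ship as fixtures, and a synthetic
proteome generator (birth–death gene families along the species tree,
motif-constrained sequence evolution, random and near-miss decoys, full
ground truth) makes every stage testable without downloading genomes.

## Worked example: the Shaker-like channel family history

The packaged inventory lists 36 Shaker-like channel genes (9 in
*A. thaliana*, 11 in rice, 11 in poplar, 4 in *P. patens*, and the
single *S. moellendorffii* gene, the K_out channel SmORK). Building the
fixture gene tree from the published ortholog-group structure and
reconciling it against the species tree:

```python
from ktfam import build_fixture_gene_tree, load_species_tree, reconcile

species = load_species_tree()
gene_tree, leaf_map = build_fixture_gene_tree("SHAKER")
result = reconcile(gene_tree, species, leaf_map)

tracheophyte = species.mrca(["Smoellendorffii", "Athaliana"])
print("leaves:", len(gene_tree.leaves()))
print("duplications:", result.duplication_count)
print("losses:", result.loss_count, "on", result.loss_species_branches())
print("copies exiting embryophyte ancestor:", result.ancestral_copies(species.root))
print("copies exiting tracheophyte ancestor:", result.ancestral_copies(tracheophyte))
```

prints

```
leaves: 36
duplications: 29
losses: 1 on ['Smoellendorffii']
copies exiting embryophyte ancestor: 1
copies exiting tracheophyte ancestor: 2
```

Read: the land-plant ancestor carried a single Shaker-like channel
gene; the tracheophyte ancestor carried two (a K_out-type and a
K_in-type lineage); the K_in copy was lost on the branch leading to
*S. moellendorffii*, leaving SmORK as that genome's only Shaker-like
gene. The 29 duplications are the within-group amplifications implied
by the inventory (e.g. the *P. patens*-specific K_in expansion). The
same calls for the other families give one ancestral HKT gene and two
ancestral TPK genes in the embryophyte ancestor.

## Worked example: a synthetic screen with ground truth

```python
from ktfam import SimulationConfig, emit_proteomes, run_screen, PipelineConfig

proteomes, truth = emit_proteomes(SimulationConfig(seed=42))
result = run_screen(proteomes, PipelineConfig(seed=42))
for fam in ("HAK", "HKT", "TPK", "SHAKER"):
    n = sum(1 for r in result.inventory.rows if r[1] == fam)
    true_n = sum(1 for f in truth.family_labels.values() if f == fam)
    print(f"{fam}: screened {n}, simulated {true_n}")
art = result.families["HAK"]
print("HAK duplications:", art.reconciliation.duplication_count,
      "losses:", art.reconciliation.loss_count)
```

prints

```
HAK: screened 9, simulated 9
HKT: screened 3, simulated 3
TPK: screened 7, simulated 7
SHAKER: screened 8, simulated 8
HAK duplications: 4 losses: 0
```

— the screen recovered every planted family member (and none of the 50
decoys), and reconciling the inferred HAK gene tree recovered the
simulated duplication history.

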