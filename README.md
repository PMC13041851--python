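# scgenus

Cross-species comparison of single-cell transcriptomes via **evolutionarily
informed gene sets** derived from a global gene homology graph.

Comparative single-cell analyses across deeply diverged species (hundreds
of millions of years) are usually forced onto the small intersection of
one-to-one orthologs, discarding the duplicated and lineage-expanded gene
families that carry much of the evolutionary signal. `scgenus` instead:

1. **Builds a homology graph.** Pairwise protein similarity searches
   (tabular BLASTp output) are collapsed from isoforms to genes and turned
   into an undirected weighted multipartite graph: nodes are genes of the
   S species, only reciprocal cross-species alignments become edges, and
   the weight is the symmetric bit-score maximum `w_ij = max(B_ij, B_ji)`.
   Alignments with E-value ≥ 1e−6 are discarded; for each protein pair the
   best-bit HSP is used.
2. **Discovers gene sets.** The graph is partitioned by weighted Leiden
   community detection across a log-spaced resolution sweep (default 13
   points on [0.01, 100]). Resolutions where fewer than 50% of communities
   contain genes from all species are discarded, duplicate communities
   across retained resolutions are collapsed, and each gene set G_j is
   assigned an evolutionary age — the most recent common ancestor, on a
   reference species tree, of the species it covers.
3. **Transforms expression.** Per species, cells × genes becomes
   cells × gene-sets via `Z_cj = (1/|G_j ∩ genes_s|) Σ_{g} X_cg`, so
   lineage-specific expansions contribute through their mean expression
   rather than extra feature weight. The columns are identical across
   species: a shared, interpretable feature space.
4. **Compares.** On top of `Z` the package provides the bespoke
   comparative statistics: per-set **conservation scores** (mean pairwise
   Spearman ρ of pseudobulk profiles over a cell-type panel, classified at
   the 0.75 / 0.5 / 0 boundaries, with per-age ECDFs), **species-mixing
   entropy** of neighborhoods (frequency-corrected Shannon entropy
   normalized by log S, clusters flagged below median 0.55), Wilcoxon
   gene-set **markers**, **centroid L1 divergence** within versus between
   cell types in PCA space, neighbor-joining **cell-type phylogenies**
   with bootstrap **leaf stability indices**, and natural-spline F-tests
   for **branch-** and **species-dependent pseudotime dynamics**.

A first-class synthetic-fixture module generates all inputs (gene families
evolving along a species tree with duplication/loss and
divergence-decaying bit scores; expression with planted cell-type
programs, species effects and pseudotime dynamics), so the entire pipeline
is testable without downloads.

## Worked example

```python
import tempfile, pathlib
from scgenus import *
from scgenus.synthetic_fixtures import FamilySimulationConfig

# 1. simulate 50 gene families on the default 11-species vertebrate tree
sim = simulate_gene_families(FamilySimulationConfig(n_families=50, seed=0))
work = pathlib.Path(tempfile.mkdtemp())
sim.write_dir(work)

# 2. parse hit tables, collapse isoforms, build the reciprocal graph
hits = []
for path in sorted((work / "hits").glob("*.tsv")):
    qs, ss = path.stem.split("__")
    hits.extend(parse_blast_tab(path, qs, ss, evalue_max=1e-6))
maps = {sp: read_annotation_map(work / "maps" / f"{sp}.tsv")
        for sp in sim.registry.species_ids}
graph = build_homology_graph(collapse_to_gene_pairs(hits, maps), sim.registry)
print(f"graph: {graph.n_nodes} genes, {graph.n_edges} reciprocal edges")

# 3. discover gene sets across the resolution sweep and age them
catalog = discover_gene_sets(graph, sim.registry, tree=sim.tree, seed=0)
ages = {}
for gs in catalog:
    ages[gs.lca_age] = ages.get(gs.lca_age, 0) + 1
print(f"catalog: {catalog.k} gene sets; ages: {dict(sorted(ages.items()))}")

# 4. planted expression -> gene-set space -> conservation scores
cfg = ExpressionSimulationConfig(cell_types=tuple(f"t{i}" for i in range(10)),
                                 cells_per_type=30, seed=1)
mats = simulate_expression(cfg, catalog)
Zs = [transform_to_gene_sets(m, catalog) for m in mats.values()]
pb = pseudobulk_by_celltype(Zs)
cons = conservation_table(pb, catalog)
print("conservation classes:", cons["class"].value_counts().to_dict())
print("mean score: %.3f" % cons.score.mean())
```

This prints:

```
graph: 1007 genes, 11468 reciprocal edges
catalog: 48 gene sets; ages: {'Euteleostomi': 4, 'Vertebrata': 44}
conservation classes: {'highly_conserved': 48}
mean score: 0.969
```

The 50 planted families yield 48 full-coverage gene sets (two pairs of
recently split families merge/split across resolutions), almost all dated
to the tree root since loss is rare at the default settings. With one
shared program per set across species, conservation scores sit near 1, as
they should: identical pseudobulk rank profiles give ρ = 1 for every
species pair.

The same steps are available from the shell:

```sh
scgenus fixtures make --preset small --seed 0 --out fx/
scgenus graph build --hits-dir fx/hits --maps-dir fx/maps \
    --species fx/species.txt --evalue 1e-6 --out graph.tsv
scgenus sets discover --graph graph.tsv --species fx/species.txt \
    --tree fx/tree.nwk --out catalog/
scgenus catalog export-magma --catalog catalog/ --species human --out sets.magma
```

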