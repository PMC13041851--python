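# Methods

This note documents the models and procedures implemented in `scgenus`,
the defaults and the reasoning behind them, what the synthetic generators
do and do not emulate, and the numerical conventions used throughout.

## Homology graph

Input is tabular protein-level similarity output (12-column BLAST dialect
by default; column positions configurable) for every ordered species pair,
plus per-species protein→gene maps. Construction:

1. **E-value filter, then HSP selection.** Rows are retained iff
   E-value < 1e−6 (strict inequality); among the retained rows of a
   protein pair, the highest-bit HSP represents that pair. Filtering
   precedes selection: if a pair's best HSP fails the filter but a weaker
   HSP passes, the pair survives with the best *passing* bit score. The
   alternative (select first, then filter) silently drops pairs whose
   strongest local alignment happens to have a marginal E-value.
2. **Isoform collapse.** The directional gene-level score B_ab is the
   maximum bit score over all isoform hit pairs mapping to the ordered
   gene pair. Same-species pairs are discarded (the graph is multipartite
   by construction). Unmapped proteins are skipped with a logged count by
   default; an "error" policy is available.
3. **Reciprocity and weights.** An undirected edge exists iff directional
   records survive in both directions, with weight `max(B_ab, B_ba)`.
   Reciprocity is evaluated at the *gene* level, after collapsing — a gene
   pair whose forward and reverse evidence comes from different isoform
   pairs still counts as reciprocal, since isoform identity is annotation
   detail, not homology evidence.
4. **Node policy.** Only genes on at least one retained edge become nodes
   ("touched", the default); isolated genes contribute nothing to
   community detection and only bloat the graph. A "all" policy keeps
   every annotated gene.

## Gene-set discovery

Weighted Leiden community detection with the modularity objective
(RB-configuration null, linear resolution parameter) is run over a
log-spaced grid of resolutions — default 13 points on [0.01, 100]. The
point count is a package choice; the endpoints and log spacing are the
method's. CPM is available as an option but is not the default, because
the objective is stated as modularity-based. Partitions are deterministic
given (graph, resolution, seed); the seed (default 0) is recorded in
catalog provenance.

**Retention.** A resolution is kept iff at least `min_fraction` (default
0.5) of its communities contain genes from all registry species.
Singleton communities are excluded from the denominator by default: at
high resolutions singletons dominate the count and would make the rule
fail vacuously rather than informatively; `count_singletons=True`
restores the literal count-all reading. If no resolution passes, the
end-to-end driver falls back to retaining the whole sweep (recorded in
provenance) so a catalog is always produced.

**Collapse.** Communities from retained resolutions are unioned;
*redundant* means exact membership equality, and duplicates are merged
into one gene set recording all source resolutions. Overlapping but
non-identical sets are both kept — nested sets from different resolutions
are genuinely different features. Set ids are content-addressed (SHA-1 of
the sorted canonical membership), so identical sets get identical ids
across runs and machines.

**Evolutionary age.** Each set's age is the label of the most recent
common ancestor, on the reference species tree, of the species it covers;
single-species sets map to the tip itself. MRCA computation is delegated
to dendropy.

## Gene-set feature space

The provided normalization is library-size scaling to 1e4 counts per cell
followed by log1p. This is a deliberately simple, fully specified
contract — the transform accepts any pre-normalized matrix, so users can
substitute a variance-stabilizing normalization upstream; regularized
negative-binomial normalization is out of scope here.

`Z_cj` is the mean of the cell's expression over the genes of set j that
the species actually has (members ∩ matrix genes). Sets with no gene
present for a species are filled with 0 **and flagged absent** in
`Z.var["absent"]`: the zero keeps downstream matrix operations total,
while the flag lets conservation scoring exclude structural absence from
being read as "not expressed". Sparse inputs are aggregated through a
sparse membership matrix without densifying the expression matrix.
Gene-id matching is exact and case-sensitive.

Pseudobulk is the per-(species, cell type) mean of Z over cells, carried
in long format with cell counts and the presence flag.

## Conservation scoring

Per gene set: each species with the set present contributes the vector of
pseudobulk means across the cell-type panel; every species pair with two
non-constant vectors contributes a Spearman ρ (mid-rank ties; computed as
the Pearson correlation of rank vectors, with an exact 1.0 for identical
rank vectors); the conservation score is the mean ρ. Constant-vector
pairs are undefined under rank correlation and are skipped and counted
rather than imputed. With fewer than two usable species the record is
"unscored". Classes follow the fixed boundaries: highly conserved
(> 0.75), conserved (0.5–0.75, both endpoints included at the top),
weakly conserved (0–0.5 exclusive), highly divergent (≤ 0). Per-age ECDFs
are plain i/n step functions over sorted scores; groups with fewer than
two sets are flagged.

## Species-mixing entropy

Within a neighborhood, species counts are divided by global species
frequencies (so abundant datasets do not dominate), renormalized to
proportions p_s, and scored as −Σ p_s ln p_s / ln S where S is the
registry size. Dividing by ln S (rather than by the entropy of the global
composition) makes the score hit 1 exactly when the weighted composition
is uniform over *all* S species and 0 for a single-species neighborhood,
matching the intended 0-to-1 reading; the choice is configurable at the
call site via `n_species_total`. Neighborhood construction itself is
consumed as input (assignments in cell metadata); a plain kNN sampler in
PC space is provided as plumbing for fixtures only. Clusters of
neighborhoods are flagged species-enriched when their median entropy
(standard mid-rank median) falls below 0.55.

## Markers

One-vs-rest two-sided Wilcoxon rank-sum tests per (set, group) on pooled
cells, Bonferroni-corrected across sets within each group. The log2 fold
change back-transforms log-scale means through expm1 and uses pseudocount
1: `log2((expm1mean_in + 1)/(expm1mean_out + 1))` — the common
toolkit convention; the method itself delegates this detail. Default
filters: positive markers only, lfc ≥ 0.25, detection ≥ 5% in at least
one side, adjusted p < 0.05.

## Centroid divergence

Within a cell type: pool the type's cells from all species, keep the
2,000 most variable sets, run PCA, and keep the smallest number of
leading PCs whose explained-variance fractions sum to 20% (capped at
100); distances are pairwise L1 between species centroids. Between cell
types: cell-type centroid L1 distances in the shared joint PC space over
all cells (top 50 PCs) — the integrated space is the reference scale for
between-identity divergence, and applying the 20% rule there instead
would collapse a many-type configuration onto 2 PCs and destroy the
scale. Batch correction of the joint space is out of scope; the joint
uncorrected PCA stands in for an integrated embedding, which is the one
deviation from the full procedure and is the reason between-type
distances should be read as a scale, not as corrected biology. Cell types
present in one species only are flagged; their within distances are
undefined.

## Cell-type phylogenies

Tips are (sub)type centroids in the first 50 shared PCs; distances are
1 − Pearson ρ. Neighbor joining is the standard Saitou–Nei agglomeration,
implemented deterministically: Q-criterion ties are broken by the
lexicographically smallest pair of clade labels (a clade is labelled by
its smallest tip), and negative branch-length estimates are clamped to
zero with the deficit shifted to the sister branch so path lengths are
preserved where possible. NJ is exact on additive matrices (verified to
1e−9 in tests). Bootstrap replicates resample each tip's cells with
replacement (same size), recompute centroids and rebuild the tree;
default 1,000 iterations, seed-reproducible.

**Leaf stability.** For each tip t and quartet {t, a, b, c}, the three
possible resolutions are counted across bootstrap trees using the
four-point condition on topological (edge-count) distances; the quartet's
stability is the maximum frequency, and LSI(t) is the mean over quartets
(all of them, or a seeded uniform subsample of 2,000 per tip when there
are more). This is the quartet-"maximum" variant of Thorley–Wilkinson
leaf stability; the variant name is recorded in `LSI_VARIANT` since
published implementations differ in the aggregation (max vs difference vs
entropy) and the source procedure does not print a formula. Unresolved
quartets (possible at the trifurcating root) vote for no resolution; a
quartet unresolved in every tree contributes the uninformative value 1/3.

## Pseudotime regression tests

The natural cubic spline basis has df columns (default 6, no intercept):
df − 1 internal knots at evenly spaced quantiles of pseudotime, boundary
knots at the data extremes, truncated-power construction with the natural
(linear-beyond-boundary) constraint. The span matches the standard
reference construction exactly (verified against an independent
natural-spline fit in tests).

*Branch dependence*: null = intercept + shared spline on pooled cells;
alternative = branch-specific intercepts and spline coefficients (full
interaction, shared knots so the models are nested; a shared-intercept
variant is available by flag). *Species dependence*: additive
(species + pseudotime) versus interaction (species × pseudotime), linear
in pseudotime — implemented as Gaussian least squares, the linear
analogue of the toolkit GLM the procedure cites. Both use
`F = ((RSS0 − RSS1)/Δdf)/(RSS1/(n − p1))`, p from the F distribution,
Bonferroni across the sets tested in a run, significance at adjusted
p < 1e−4. Pseudotime is used as given (no rescaling). Empirical
calibration: type-I error at α = 0.05 lies within [0.03, 0.07] under both
nulls (1,000 and 500 replicates in the acceptance run), and power against
reciprocal branch dynamics (amplitude 1, noise sd 0.1, n = 300 per
branch) is ~1 at the adjusted-p rule.

## Synthetic generators

The default species tree is an 11-tip vertebrate-like topology (lamprey
sister to all; teleosts with a cypriniform pair plus cichlid; axolotl;
mammals; squamate, turtle and bird clades) with named internal nodes so
age stratification has several depth classes; branch lengths are in units
of roughly 100 Myr and the tree is ultrametric with diameter 10.6.

*Gene families* start as one lineage at the root; along each branch each
lineage is lost with probability 0.05 and duplicated with probability 0.2
(defaults). Within-family cross-species bit scores are
`base − decay × patristic distance + N(0, sd)` (defaults 400, 25/unit,
sd 5, floor 50), drawn independently per direction so reciprocal scores
differ; each gene has 1–2 isoforms whose hit bits jitter below the
gene-level score, and 10% of isoform pairs get a second, weaker HSP so
best-HSP selection is exercised. E-values are the deterministic map
10^(−bit/4): no alignment statistics are modelled, only the filter's
behavior. Spurious cross-family hits appear at low bit (30–55) with
probability 1e−4 per gene pair, and equally many sub-threshold hits
(bit 12–23) fall to the E-value filter. Linear decay is the simplest
model that makes family recovery resolution-dependent, which is what the
sweep/retention logic needs to be tested against.

*Expression* plants gene-set-level programs: every member gene of a set
carries the program value for the cell's type, times a per-(species, set)
lognormal effect (sd 0.1 by default) and per-cell lognormal noise
(sd 0.2), emitted on the normalized scale. In the zero-noise limit the
pseudobulk of the transformed data equals the program matrix exactly,
which pins the whole transform chain. Overlapping catalog sets are
resolved first-set-wins for gene assignment. A `shuffled_sets` option
permutes a set's program independently per species, producing
conservation scores near 0 for those sets.

*Trajectories* draw pseudotime uniform on [0, 1] and compose per-branch
monotone shapes (increasing, decreasing, constant) with optional
per-species amplitude multipliers and Gaussian noise.

**What the generators do not emulate:** sequence evolution (bit scores
are distances plus noise, not alignments), count noise and depth
variation (expression is emitted post-normalization), dropout, batch
structure, doublets, and realistic pseudotime inference error. Passing
tests therefore demonstrate correctness of the graph/partition/transform/
statistics machinery under the stated statistical structure — not
robustness to the full messiness of real atlases.

## Problem sizes and defaults used in the acceptance run

Planted-family recovery runs the full default fixture (11 species, 200
families, duplication 0.2, loss 0.05): ~4,200 genes and ~50,000 edges,
with adjusted Rand index and mean best-Jaccard both 1.0 at the retained
resolutions. Centroid-structure checks use 60 families with loss 0 and
the full-coverage catalog subset, 10 cell types × 50 cells × 11 species,
species effect sd 0.02 against planted type programs — within-type
distances come out ~20× smaller than between-type distances. Calibration
uses 1,000 null replicates at n = 300 per branch. The whole script
completes in well under a minute on one CPU.

## Known limitations

- Reciprocity cannot distinguish true one-way homology loss from missing
  search output; both simply produce no edge.
- The retention rule depends on the singleton-denominator policy at high
  resolutions; both policies are implemented and the default documented.
- Near-duplicate (high-Jaccard but non-identical) gene sets are kept as
  separate features by design; a τ-Jaccard merge exists behind a flag.
- The joint PC space used for between-type distances is uncorrected for
  batch/platform effects.
- LSI values depend on the chosen quartet aggregation variant; compare
  only within a variant.
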