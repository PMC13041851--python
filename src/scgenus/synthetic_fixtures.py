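"""Synthetic inputs with the statistical structure the method assumes.

Two generators make every stage testable without downloads:

* :func:`simulate_gene_families` evolves gene families along a species tree
  with per-branch duplication and loss, emits per-species proteomes (genes
  with one or more protein isoforms), protein->gene annotation maps and
  pairwise tabular hit tables in which within-family bit scores decay
  linearly with patristic distance (plus Gaussian noise) and E-values are a
  deterministic decreasing function of the bit score.  Spurious cross-family
  hits appear at low bit scores with a configurable probability, and a
  fraction of hits fall below the E-value retention threshold so the filter
  is exercised.  Planted family labels are returned for evaluation.
* :func:`simulate_expression` plants cell-type programs at the gene-set
  level: every member gene of a set carries the set's program value for the
  cell's type, times a per-(species, set) lognormal species effect and
  per-cell lognormal noise, so the gene-set transform recovers the program
  exactly in the zero-noise limit.  Values are emitted on the normalized
  log-like scale, ready for the gene-set transform.

:func:`simulate_trajectory_table` additionally produces pseudotime/branch/
species-labelled cells with configurable monotone program shapes per branch
for the trajectory regression tests.

The default species tree mirrors an 11-tip vertebrate-like topology with
named internal nodes (so evolutionary-age stratification has several depth
classes); branch lengths are in units of ~100 Myr.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from anndata import AnnData

from .feature_space import make_expression_matrix
from .geneset_discovery import GeneSetCatalog, SpeciesTree
from .homology_graph import SpeciesRegistry

DEFAULT_SPECIES_TREE_NEWICK = (
    "(lamprey:5.3,(((zebrafish:2.3,goldfish:2.3)Cypriniformes:0.6,cichlid:2.9)"
    "Teleostei:1.4,(axolotl:3.5,((human:0.9,mouse:0.9)Mammalia:2.3,"
    "(lizard:2.8,(turtle:2.5,(chicken:0.9,zebra_finch:0.9)Aves:1.6)"
    "Archelosauria:0.3)Sauropsida:0.4)Amniota:0.3)Tetrapoda:0.8)"
    "Euteleostomi:1.0)Vertebrata;"
)

DEFAULT_SPECIES = (
    "lamprey",
    "zebrafish",
    "goldfish",
    "cichlid",
    "axolotl",
    "human",
    "mouse",
    "lizard",
    "turtle",
    "chicken",
    "zebra_finch",
)


@dataclass
class FamilySimulationConfig:
    """Controls for the gene-family / hit-table generator."""

    newick: str = DEFAULT_SPECIES_TREE_NEWICK
    n_families: int = 200
    duplication_prob: float = 0.2
    loss_prob: float = 0.05
    base_bit: float = 400.0
    bit_decay_per_unit: float = 25.0
    bit_noise_sd: float = 5.0
    min_bit: float = 50.0
    isoform_extra_prob: float = 0.3
    extra_hsp_prob: float = 0.1
    cross_family_hit_prob: float = 1e-4
    subthreshold_hit_prob: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duplication_prob", "loss_prob", "cross_family_hit_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def _evalue_of_bit(bit: np.ndarray | float):
    """Deterministic decreasing map from bit score to E-value."""
    return 10.0 ** (-np.asarray(bit) / 4.0)


@dataclass
class SimulatedHomology:
    """Output bundle of :func:`simulate_gene_families`."""

    registry: SpeciesRegistry
    tree: SpeciesTree
    annotation_maps: dict[str, dict[str, str]]
    hit_tables: dict[tuple[str, str], pd.DataFrame]
    family_of: dict[tuple[str, str], int]

    def genes_of(self, species: str) -> list[str]:
        return sorted(set(self.annotation_maps[species].values()))

    def write_dir(self, path: str | Path) -> None:
        """Write hits/, maps/ and species.txt in the formats the tool reads."""
        path = Path(path)
        (path / "hits").mkdir(parents=True, exist_ok=True)
        (path / "maps").mkdir(parents=True, exist_ok=True)
        (path / "species.txt").write_text("\n".join(self.registry.species_ids) + "\n")
        (path / "tree.nwk").write_text(
            self.tree.tree.as_string(schema="newick", suppress_rooting=True)
        )
        for sp, mapping in self.annotation_maps.items():
            with open(path / "maps" / f"{sp}.tsv", "w") as fh:
                for prot, gene in sorted(mapping.items()):
                    fh.write(f"{prot}\t{gene}\n")
        for (qs, ss), table in self.hit_tables.items():
            out = pd.DataFrame(
                {
                    0: table["qprot"],
                    1: table["sprot"],
                    2: 90.0,
                    3: 100,
                    4: 5,
                    5: 0,
                    6: 1,
                    7: 100,
                    8: 1,
                    9: 100,
                    10: table["evalue"],
                    11: table["bit"],
                }
            )
            out.to_csv(path / "hits" / f"{qs}__{ss}.tsv", sep="\t", index=False, header=False)


def simulate_gene_families(cfg: FamilySimulationConfig) -> SimulatedHomology:
    """Evolve gene families along the species tree and emit hit tables."""
    rng = np.random.default_rng(cfg.seed)
    tree = SpeciesTree.from_newick(cfg.newick)
    species = tuple(sorted(tree.tip_labels))
    registry = SpeciesRegistry(species)

    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.tree.taxon_namespace}
    patristic = {
        (a, b): pdm.patristic_distance(taxa[a], taxa[b])
        for a in species
        for b in species
        if a != b
    }

    # evolve lineage counts per family along the tree (duplication / loss)
    genes: dict[str, list[tuple[str, int]]] = {sp: [] for sp in species}  # (gene, family)
    family_of: dict[tuple[str, str], int] = {}
    root = tree.tree.seed_node
    for fam in range(cfg.n_families):
        counts: dict = {root: 1}
        for node in tree.tree.preorder_node_iter():
            if node is root:
                continue
            n_parent = counts[node.parent_node]
            n_here = 0
            for _ in range(n_parent):
                if rng.random() < cfg.loss_prob:
                    continue
                n_here += 1
                if rng.random() < cfg.duplication_prob:
                    n_here += 1
            counts[node] = n_here
        for leaf in tree.tree.leaf_node_iter():
            sp = leaf.taxon.label
            for k in range(counts[leaf]):
                gene = f"{sp}_F{fam:04d}G{k}"
                genes[sp].append((gene, fam))
                family_of[(sp, gene)] = fam

    # proteomes: one or more isoforms per gene
    annotation_maps: dict[str, dict[str, str]] = {}
    isoforms: dict[str, dict[str, list[str]]] = {}
    for sp in species:
        amap: dict[str, str] = {}
        iso: dict[str, list[str]] = {}
        for gene, _fam in genes[sp]:
            n_iso = 1 + int(rng.random() < cfg.isoform_extra_prob)
            iso[gene] = [f"{gene}P{i}" for i in range(n_iso)]
            for prot in iso[gene]:
                amap[prot] = gene
        annotation_maps[sp] = amap
        isoforms[sp] = iso

    by_family: dict[str, dict[int, list[str]]] = {}
    for sp in species:
        fams: dict[int, list[str]] = {}
        for gene, fam in genes[sp]:
            fams.setdefault(fam, []).append(gene)
        by_family[sp] = fams

    hit_tables: dict[tuple[str, str], pd.DataFrame] = {}
    for qs in species:
        for ss in species:
            if qs == ss:
                continue
            dist = patristic[(qs, ss)]
            mean_bit = cfg.base_bit - cfg.bit_decay_per_unit * dist
            qprot_col: list[str] = []
            sprot_col: list[str] = []
            bit_col: list[float] = []

            def emit(qp: str, sp_: str, bit: float) -> None:
                qprot_col.append(qp)
                sprot_col.append(sp_)
                bit_col.append(round(max(bit, 1.0), 1))

            # within-family hits
            for fam, q_genes in by_family[qs].items():
                s_genes = by_family[ss].get(fam)
                if not s_genes:
                    continue
                for ga in q_genes:
                    for gb in s_genes:
                        gene_bit = max(
                            cfg.min_bit,
                            mean_bit + rng.normal(0, cfg.bit_noise_sd),
                        )
                        first = True
                        for pa in isoforms[qs][ga]:
                            for pb in isoforms[ss][gb]:
                                jitter = 0.0 if first else abs(rng.normal(0, 2.0))
                                first = False
                                emit(pa, pb, gene_bit - jitter)
                                if rng.random() < cfg.extra_hsp_prob:
                                    # a second, weaker HSP for the same pair
                                    emit(pa, pb, gene_bit - 5 - abs(rng.normal(0, 5.0)))
            # spurious cross-family hits (low bit, still passing the filter)
            n_q, n_s = len(genes[qs]), len(genes[ss])
            n_spurious = rng.binomial(n_q * n_s, cfg.cross_family_hit_prob)
            for _ in range(n_spurious):
                ga, fam_a = genes[qs][rng.integers(n_q)]
                gb, fam_b = genes[ss][rng.integers(n_s)]
                if fam_a == fam_b:
                    continue
                bit = rng.uniform(30, 55)
                emit(isoforms[qs][ga][0], isoforms[ss][gb][0], bit)
            # sub-threshold hits, removed by the E-value filter downstream
            n_weak = rng.binomial(n_q * n_s, cfg.subthreshold_hit_prob)
            for _ in range(n_weak):
                ga, _ = genes[qs][rng.integers(n_q)]
                gb, _ = genes[ss][rng.integers(n_s)]
                emit(isoforms[qs][ga][0], isoforms[ss][gb][0], rng.uniform(12, 23))

            bits = np.array(bit_col)
            hit_tables[(qs, ss)] = pd.DataFrame(
                {
                    "qprot": qprot_col,
                    "sprot": sprot_col,
                    "evalue": _evalue_of_bit(bits),
                    "bit": bits,
                }
            )
    return SimulatedHomology(
        registry=registry,
        tree=tree,
        annotation_maps=annotation_maps,
        hit_tables=hit_tables,
        family_of=family_of,
    )


# -- evaluation helpers ------------------------------------------------------


def partition_ari(partition, family_of: Mapping[tuple[str, str], int]) -> float:
    """Adjusted Rand index of a graph partition against planted families."""
    from sklearn.metrics import adjusted_rand_score

    truth, pred = [], []
    for comm_idx, comm in enumerate(partition.communities):
        for node in comm:
            if node in family_of:
                truth.append(family_of[node])
                pred.append(comm_idx)
    return float(adjusted_rand_score(truth, pred))


def mean_best_jaccard(
    catalog: GeneSetCatalog, family_of: Mapping[tuple[str, str], int], min_species: int = 2
) -> float:
    """Mean, over planted families, of the best Jaccard match in the catalog.

    Families represented in fewer than ``min_species`` species (which cannot
    form cross-species edges) are excluded.
    """
    by_fam: dict[int, set[tuple[str, str]]] = {}
    for node, fam in family_of.items():
        by_fam.setdefault(fam, set()).add(node)
    memberships = [set(gs.members) for gs in catalog.gene_sets]
    scores = []
    for fam, nodes in by_fam.items():
        if len({s for s, _ in nodes}) < min_species:
            continue
        best = max(
            (len(nodes & m) / len(nodes | m) for m in memberships), default=0.0
        )
        scores.append(best)
    if not scores:
        raise ValueError("no evaluable planted families")
    return float(np.mean(scores))


# -- expression simulation ---------------------------------------------------


@dataclass
class ExpressionSimulationConfig:
    """Controls for planted cell-type programs at the gene-set level."""

    cell_types: tuple[str, ...] = tuple(f"type{i}" for i in range(10))
    cells_per_type: int = 100
    program: pd.DataFrame | None = None  # cell_type x set_id means
    species_effect_sd: float = 0.1
    noise_sd: float = 0.2
    shuffled_sets: tuple[str, ...] = ()
    seed: int = 0


def random_program(
    cell_types: Sequence[str], set_ids: Sequence[str], rng: np.random.Generator
) -> pd.DataFrame:
    """A program matrix with one elevated marker cell type per set."""
    base = rng.uniform(0.5, 1.5, size=(len(cell_types), len(set_ids)))
    for j in range(len(set_ids)):
        marker = rng.integers(len(cell_types))
        base[marker, j] += rng.uniform(2.0, 4.0)
    return pd.DataFrame(base, index=list(cell_types), columns=list(set_ids))


def simulate_expression(
    cfg: ExpressionSimulationConfig, catalog: GeneSetCatalog
) -> dict[str, AnnData]:
    """Per-species expression matrices with planted gene-set programs.

    Every member gene of a set carries the set's program value for the
    cell's type, multiplied by a per-(species, set) lognormal species effect
    and per-cell lognormal noise.  Where a gene belongs to several
    (overlapping) catalog sets, the first set in catalog order wins.
    Values are on the normalized scale expected by the gene-set transform.
    """
    rng = np.random.default_rng(cfg.seed)
    set_ids = catalog.set_ids
    species_list = sorted({s for gs in catalog for s, _ in gs.members})
    program = cfg.program
    if program is None:
        program = random_program(cfg.cell_types, set_ids, rng)
    missing = [sid for sid in set_ids if sid not in program.columns]
    if missing:
        raise ValueError(f"program matrix lacks sets: {missing[:5]}")

    out: dict[str, AnnData] = {}
    for sp in species_list:
        gene_to_set: dict[str, str] = {}
        for gs in catalog:
            for g in gs.genes_of(sp):
                gene_to_set.setdefault(g, gs.set_id)
        gene_ids = sorted(gene_to_set)
        if not gene_ids:
            continue
        set_of_gene = np.array([set_ids.index(gene_to_set[g]) for g in gene_ids])
        # per-(species, set) multiplicative effect
        effects = np.exp(rng.normal(0, cfg.species_effect_sd, size=len(set_ids)))
        prog = program.loc[list(cfg.cell_types), set_ids].values.copy()
        for sid in cfg.shuffled_sets:
            j = set_ids.index(sid)
            prog[:, j] = rng.permutation(prog[:, j])
        n_cells = cfg.cells_per_type * len(cfg.cell_types)
        X = np.zeros((n_cells, len(gene_ids)))
        labels = []
        row = 0
        for ci, ct in enumerate(cfg.cell_types):
            means = prog[ci] * effects  # per set
            for _ in range(cfg.cells_per_type):
                noise = (
                    np.exp(rng.normal(0, cfg.noise_sd, size=len(set_ids)))
                    if cfg.noise_sd > 0
                    else np.ones(len(set_ids))
                )
                set_vals = means * noise
                X[row] = set_vals[set_of_gene]
                labels.append(ct)
                row += 1
        obs = pd.DataFrame({"cell_type": labels})
        cells = [f"{sp}_c{i}" for i in range(n_cells)]
        out[sp] = make_expression_matrix(X, cells, gene_ids, species=sp, obs=obs)
    return out


# -- trajectory fixtures -----------------------------------------------------


def _shape_value(kind: str, amp: float, t: np.ndarray) -> np.ndarray:
    if kind == "inc":
        return amp * t
    if kind == "dec":
        return amp * (1.0 - t)
    if kind == "const":
        return np.zeros_like(t)
    raise ValueError(f"unknown shape kind {kind!r}")


def simulate_trajectory_table(
    set_shapes: Mapping[str, Mapping[str, tuple[str, float]]],
    n_per_branch: int = 300,
    species: Sequence[str] = ("human", "mouse"),
    species_slope: Mapping[str, Mapping[str, float]] | None = None,
    noise_sd: float = 0.1,
    base: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Cells with pseudotime, branch and species labels plus set expression.

    ``set_shapes[set_id][branch] = (kind, amplitude)`` with kind one of
    "inc" (amplitude * t), "dec" (amplitude * (1 - t)) or "const".
    ``species_slope[set_id][species]`` optionally scales the amplitude per
    species (default 1), giving species-dependent dynamics.
    """
    rng = np.random.default_rng(seed)
    branches = sorted({b for shapes in set_shapes.values() for b in shapes})
    rows = []
    cell = 0
    for branch in branches:
        for i in range(n_per_branch):
            sp = species[i % len(species)]
            t = rng.uniform()
            row = {
                "cell_id": f"c{cell}",
                "pseudotime": t,
                "branch": branch,
                "species": sp,
            }
            cell += 1
            rows.append(row)
    table = pd.DataFrame(rows)
    t = table["pseudotime"].values
    for sid, shapes in set_shapes.items():
        y = np.full(len(table), base, dtype=float)
        for branch, (kind, amp) in shapes.items():
            mask = (table["branch"] == branch).values
            mult = np.ones(mask.sum())
            if species_slope and sid in species_slope:
                sl = species_slope[sid]
                mult = np.array(
                    [sl.get(s, 1.0) for s in table.loc[mask, "species"]]
                )
            y[mask] += mult * _shape_value(kind, amp, t[mask])
        y += rng.normal(0, noise_sd, size=len(table))
        table[sid] = y
    return table
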