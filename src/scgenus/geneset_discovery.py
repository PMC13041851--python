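"""Evolutionarily informed gene-set discovery.

The homology graph is partitioned with the Leiden algorithm at a sweep of
resolutions (default 13 points, log-spaced on [0.01, 100]).  Resolutions
whose communities rarely span all species are discarded (a resolution is
retained iff at least half of its communities — singletons excluded by
default — contain genes from every species), duplicate communities across
retained resolutions are collapsed, and each resulting gene set is assigned
an evolutionary age: the label of the most recent common ancestor, on a
reference species tree, of the species represented in the set.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

import dendropy

from .homology_graph import HomologyGraph, SpeciesRegistry

DEFAULT_RESOLUTION_MIN = 0.01
DEFAULT_RESOLUTION_MAX = 100.0
DEFAULT_RESOLUTION_COUNT = 13
DEFAULT_MIN_ALL_SPECIES_FRACTION = 0.5


def default_resolution_grid(
    lo: float = DEFAULT_RESOLUTION_MIN,
    hi: float = DEFAULT_RESOLUTION_MAX,
    n: int = DEFAULT_RESOLUTION_COUNT,
) -> list[float]:
    """Log-spaced resolution grid."""
    if lo <= 0 or hi <= lo or n < 1:
        raise ValueError("need 0 < lo < hi and n >= 1")
    return list(np.logspace(np.log10(lo), np.log10(hi), n))


@dataclass
class ResolutionPartition:
    """Community partition of the homology graph at one resolution."""

    resolution: float
    communities: list[frozenset[tuple[str, str]]]
    seed: int

    def species_coverage(self, community: frozenset[tuple[str, str]]) -> frozenset[str]:
        return frozenset(s for s, _ in community)


@dataclass
class GeneSet:
    """A community of homologous genes used as a shared cross-species feature."""

    set_id: str
    members: frozenset[tuple[str, str]]
    source_resolutions: list[float] = field(default_factory=list)
    lca_age: str | None = None

    @property
    def species_coverage(self) -> frozenset[str]:
        return frozenset(s for s, _ in self.members)

    @property
    def size(self) -> int:
        return len(self.members)

    def genes_of(self, species: str) -> list[str]:
        return sorted(g for s, g in self.members if s == species)


@dataclass
class GeneSetCatalog:
    """Collection of gene sets with provenance."""

    gene_sets: list[GeneSet]
    provenance: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.gene_sets)

    @property
    def set_ids(self) -> list[str]:
        return [gs.set_id for gs in self.gene_sets]

    def __iter__(self):
        return iter(self.gene_sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for gs in self.gene_sets:
            if gs.set_id == set_id:
                return gs
        raise KeyError(set_id)

    # -- persistence ---------------------------------------------------------

    def to_dir(self, path: str | Path) -> None:
        """Write members TSV (set_id, species, gene_id) and a JSON sidecar."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        rows = [
            {"set_id": gs.set_id, "species": s, "gene_id": g}
            for gs in self.gene_sets
            for s, g in sorted(gs.members)
        ]
        pd.DataFrame(rows, columns=["set_id", "species", "gene_id"]).to_csv(
            path / "members.tsv", sep="\t", index=False
        )
        sidecar = {
            "provenance": self.provenance,
            "sets": {
                gs.set_id: {
                    "size": gs.size,
                    "species_coverage": sorted(gs.species_coverage),
                    "source_resolutions": gs.source_resolutions,
                    "lca_age": gs.lca_age,
                }
                for gs in self.gene_sets
            },
        }
        (path / "catalog.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))

    @classmethod
    def from_dir(cls, path: str | Path) -> "GeneSetCatalog":
        path = Path(path)
        members = pd.read_csv(path / "members.tsv", sep="\t", dtype=str)
        sidecar = json.loads((path / "catalog.json").read_text())
        sets = []
        grouped = members.groupby("set_id", sort=True)
        for set_id, grp in grouped:
            meta = sidecar["sets"][set_id]
            sets.append(
                GeneSet(
                    set_id=set_id,
                    members=frozenset(zip(grp["species"], grp["gene_id"])),
                    source_resolutions=list(meta["source_resolutions"]),
                    lca_age=meta["lca_age"],
                )
            )
        return cls(gene_sets=sets, provenance=sidecar.get("provenance", {}))

    def export_magma(self, path: str | Path, species: str = "human") -> int:
        """Write a MAGMA set file: one line per set, set_id then gene ids.

        Only sets with at least one gene from ``species`` are written;
        returns the number of lines written.
        """
        n = 0
        with open(path, "w") as fh:
            for gs in self.gene_sets:
                genes = gs.genes_of(species)
                if genes:
                    fh.write(gs.set_id + " " + " ".join(genes) + "\n")
                    n += 1
        return n


def _canonical_set_id(members: frozenset[tuple[str, str]]) -> str:
    """Stable id from the sorted canonical membership."""
    canon = ";".join(f"{s}|{g}" for s, g in sorted(members))
    return "GS" + hashlib.sha1(canon.encode()).hexdigest()[:10]


def partition_at_resolution(
    graph: HomologyGraph, resolution: float, seed: int = 0, objective: str = "modularity"
) -> ResolutionPartition:
    """Weighted Leiden community detection at one resolution.

    ``objective`` is "modularity" (RB-configuration null with linear
    resolution parameter, the default) or "cpm".
    Deterministic given (graph, resolution, seed).
    """
    import leidenalg

    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    g = graph.to_igraph()
    if objective == "modularity":
        part_cls = leidenalg.RBConfigurationVertexPartition
    elif objective == "cpm":
        part_cls = leidenalg.CPMVertexPartition
    else:
        raise ValueError(f"unknown objective {objective!r}")
    part = leidenalg.find_partition(
        g,
        part_cls,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    communities = [
        frozenset((g.vs[i]["species"], g.vs[i]["gene"]) for i in comm) for comm in part
    ]
    return ResolutionPartition(resolution=resolution, communities=communities, seed=seed)


def sweep_resolutions(
    graph: HomologyGraph,
    grid: Sequence[float] | None = None,
    seed: int = 0,
    objective: str = "modularity",
) -> list[ResolutionPartition]:
    """Partition the graph at every resolution in the grid (grid order)."""
    if grid is None:
        grid = default_resolution_grid()
    grid = list(grid)
    if not grid:
        raise ValueError("empty resolution grid")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("resolution grid must be strictly increasing")
    return [partition_at_resolution(graph, r, seed=seed, objective=objective) for r in grid]


def retain_resolutions(
    partitions: list[ResolutionPartition],
    registry: SpeciesRegistry,
    min_fraction: float = DEFAULT_MIN_ALL_SPECIES_FRACTION,
    count_singletons: bool = False,
) -> list[ResolutionPartition]:
    """Keep resolutions with sufficient all-species community coverage.

    A resolution is retained iff the fraction of its communities whose
    species coverage equals the full registry is at least ``min_fraction``.
    Singleton communities are excluded from the denominator unless
    ``count_singletons`` is set.
    """
    if not partitions:
        raise ValueError("no partitions given")
    full = frozenset(registry.species_ids)
    retained = []
    for part in partitions:
        counted = [
            c for c in part.communities if count_singletons or len(c) >= 2
        ]
        if not counted:
            continue
        n_full = sum(1 for c in counted if part.species_coverage(c) == full)
        if n_full / len(counted) >= min_fraction:
            retained.append(part)
    return retained


def collapse_redundant(
    retained: list[ResolutionPartition],
    near_duplicate_jaccard: float | None = None,
) -> GeneSetCatalog:
    """Union communities across retained resolutions, merging exact duplicates.

    Overlapping but non-identical communities are both kept; duplicates are
    merged into a single gene set recording all source resolutions.  With
    ``near_duplicate_jaccard`` set (off by default), sets whose membership
    Jaccard similarity with an already-kept larger set reaches the threshold
    are absorbed into that set (membership of the representative is kept,
    source resolutions are merged).
    """
    if not retained:
        raise ValueError("no retained resolutions")
    by_members: dict[frozenset[tuple[str, str]], list[float]] = {}
    for part in retained:
        for comm in part.communities:
            by_members.setdefault(comm, []).append(part.resolution)
    sets = [
        GeneSet(
            set_id=_canonical_set_id(members),
            members=members,
            source_resolutions=sorted(res),
        )
        for members, res in by_members.items()
    ]
    if near_duplicate_jaccard is not None:
        if not 0 < near_duplicate_jaccard <= 1:
            raise ValueError("near_duplicate_jaccard must be in (0, 1]")
        kept: list[GeneSet] = []
        for gs in sorted(sets, key=lambda g: (-g.size, g.set_id)):
            home = None
            for rep in kept:
                jac = len(gs.members & rep.members) / len(gs.members | rep.members)
                if jac >= near_duplicate_jaccard:
                    home = rep
                    break
            if home is None:
                kept.append(gs)
            else:
                home.source_resolutions = sorted(
                    set(home.source_resolutions) | set(gs.source_resolutions)
                )
        sets = kept
    sets.sort(key=lambda gs: gs.set_id)
    provenance = {
        "retained_resolutions": [p.resolution for p in retained],
        "seed": retained[0].seed,
    }
    return GeneSetCatalog(gene_sets=sets, provenance=provenance)


# -- species tree / evolutionary age ----------------------------------------


@dataclass
class SpeciesTree:
    """Rooted species tree with labelled internal nodes (clade names)."""

    tree: dendropy.Tree

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick", rooting="default-rooted")
        return cls(tree=tree)

    @classmethod
    def from_file(cls, path: str | Path) -> "SpeciesTree":
        return cls.from_newick(Path(path).read_text())

    @property
    def tip_labels(self) -> set[str]:
        return {t.label for t in self.tree.taxon_namespace}

    def mrca_label(self, species: Iterable[str]) -> str:
        """Label of the MRCA node of the given tips (tip label for one tip)."""
        species = sorted(set(species))
        missing = [s for s in species if s not in self.tip_labels]
        if missing:
            raise ValueError(f"species not in tree: {missing}")
        if len(species) == 1:
            return species[0]
        node = self.tree.mrca(taxon_labels=species)
        if node.is_leaf():
            return node.taxon.label
        if node.label:
            return node.label
        # unlabelled internal node: synthesize a stable name from its tip set
        tips = sorted(leaf.taxon.label for leaf in node.leaf_iter())
        return "MRCA(" + ",".join(tips) + ")"

    def node_depth_order(self) -> list[str]:
        """Internal + tip labels ordered root-first (deep to shallow)."""
        order = []
        for node in self.tree.preorder_node_iter():
            label = node.taxon.label if node.is_leaf() else node.label
            if label:
                order.append(label)
        return order


def assign_lca_age(catalog: GeneSetCatalog, tree: SpeciesTree) -> GeneSetCatalog:
    """Fill ``lca_age`` on every gene set (in place; returns the catalog)."""
    for gs in catalog.gene_sets:
        gs.lca_age = tree.mrca_label(gs.species_coverage)
    return catalog


def discover_gene_sets(
    graph: HomologyGraph,
    registry: SpeciesRegistry,
    tree: SpeciesTree | None = None,
    grid: Sequence[float] | None = None,
    min_fraction: float = DEFAULT_MIN_ALL_SPECIES_FRACTION,
    seed: int = 0,
    count_singletons: bool = False,
    objective: str = "modularity",
) -> GeneSetCatalog:
    """End-to-end discovery: sweep, retain, collapse, and (optionally) age.

    Falls back to retaining the whole sweep if no resolution passes the
    coverage rule (with a provenance note), so a catalog is always produced.
    """
    partitions = sweep_resolutions(graph, grid=grid, seed=seed, objective=objective)
    retained = retain_resolutions(
        partitions, registry, min_fraction=min_fraction, count_singletons=count_singletons
    )
    fallback = False
    if not retained:
        retained = partitions
        fallback = True
    catalog = collapse_redundant(retained)
    catalog.provenance["grid"] = [p.resolution for p in partitions]
    catalog.provenance["min_all_species_fraction"] = min_fraction
    catalog.provenance["retention_fallback_all"] = fallback
    if tree is not None:
        assign_lca_age(catalog, tree)
    return catalog
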