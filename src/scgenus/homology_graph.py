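"""Global gene homology graph construction.

Cross-species protein similarity searches (tabular BLASTp output) are turned
into an undirected, weighted, multipartite gene graph: nodes are
(species, gene) pairs, edges connect genes of *different* species whose
proteins align reciprocally, and the edge weight is the maximum of the two
directional gene-level bit scores, ``w_ij = max(B_ij, B_ji)``.

Isoform handling: a gene may encode several proteins, so many protein-level
hits can map to one gene pair.  The directional gene-level score is the
maximum bit score over all isoform hit pairs, taken after per-alignment
E-value filtering and best-HSP selection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("scgenus")

#: default column positions (0-based) in 12-column tabular BLAST output:
#: query id, subject id, E-value, bit score.
DEFAULT_BLAST_COLUMNS = (0, 1, 10, 11)

DEFAULT_EVALUE_MAX = 1e-6


class BlastParseError(ValueError):
    """Raised when a hit-table row cannot be parsed."""


class UnmappedProteinError(KeyError):
    """Raised when a protein id is missing from the annotation map under policy 'error'."""


@dataclass(frozen=True)
class SpeciesRegistry:
    """Ordered collection of species identifiers under comparison."""

    species_ids: tuple[str, ...]

    def __init__(self, species_ids: Iterable[str]) -> None:
        ids = tuple(str(s) for s in species_ids)
        if len(ids) != len(set(ids)):
            raise ValueError("species ids must be unique")
        if any(not s for s in ids):
            raise ValueError("species ids must be non-empty")
        if len(ids) < 2:
            raise ValueError("need at least two species")
        object.__setattr__(self, "species_ids", ids)

    def __len__(self) -> int:
        return len(self.species_ids)

    def __contains__(self, species: str) -> bool:
        return species in self.species_ids

    @classmethod
    def from_file(cls, path: str | Path) -> "SpeciesRegistry":
        """Read one species id per line (blank lines and '#' comments skipped)."""
        ids = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
        return cls(ids)


@dataclass(frozen=True)
class ProteinHit:
    """A single protein-level alignment surviving filtering."""

    query_protein: str
    subject_protein: str
    evalue: float
    bit_score: float
    query_species: str
    subject_species: str


def parse_blast_tab(
    path: str | Path,
    query_species: str,
    subject_species: str,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    columns: Sequence[int] = DEFAULT_BLAST_COLUMNS,
) -> list[ProteinHit]:
    """Parse a tabular BLAST hit file into filtered protein hits.

    Rows are E-value filtered first (retained iff ``evalue < evalue_max``,
    strict inequality); then, for each (query, subject) protein pair, only
    the HSP with the highest bit score among the *passing* rows is kept.

    Parameters
    ----------
    path
        Tab-separated hit table.
    query_species, subject_species
        Species of the query and subject proteomes.
    evalue_max
        Strict upper bound on the alignment E-value.
    columns
        0-based positions of (query id, subject id, E-value, bit score).

    Returns
    -------
    list of :class:`ProteinHit`, one per surviving protein pair.
    """
    if len(columns) != 4:
        raise ValueError("columns must give 4 positions: query, subject, evalue, bit")
    qc, sc, ec, bc = columns
    need = max(columns) + 1
    best: dict[tuple[str, str], ProteinHit] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < need:
                raise BlastParseError(
                    f"{path}: line {lineno}: expected at least {need} columns, got {len(fields)}"
                )
            try:
                evalue = float(fields[ec])
                bit = float(fields[bc])
            except ValueError as exc:
                raise BlastParseError(
                    f"{path}: line {lineno}: non-numeric E-value/bit score"
                ) from exc
            if evalue < 0 or bit <= 0:
                raise BlastParseError(
                    f"{path}: line {lineno}: E-value must be >= 0 and bit score > 0"
                )
            if not evalue < evalue_max:
                continue
            key = (fields[qc], fields[sc])
            prev = best.get(key)
            if prev is None or bit > prev.bit_score:
                best[key] = ProteinHit(
                    query_protein=fields[qc],
                    subject_protein=fields[sc],
                    evalue=evalue,
                    bit_score=bit,
                    query_species=query_species,
                    subject_species=subject_species,
                )
    return list(best.values())


def read_annotation_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column protein_id<TAB>gene_id TSV into a dict."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}: line {lineno}: expected protein<TAB>gene")
        prot, gene = parts[0], parts[1]
        if prot in mapping and mapping[prot] != gene:
            raise ValueError(f"{path}: protein {prot!r} maps to multiple genes")
        mapping[prot] = gene
    return mapping


def collapse_to_gene_pairs(
    hits: Iterable[ProteinHit],
    maps: Mapping[str, Mapping[str, str]],
    unmapped: str = "skip",
) -> pd.DataFrame:
    """Collapse isoform-level hits to directional gene-pair scores.

    For each ordered cross-species gene pair, ``B_ab`` is the maximum bit
    score over all isoform hit pairs mapping to it.  Hits whose query and
    subject genes belong to the same species are discarded.

    Parameters
    ----------
    hits
        Protein hits (already E-value filtered / HSP-collapsed).
    maps
        species id -> {protein id -> gene id}.
    unmapped
        "skip" (drop hits with unmapped proteins, logging a count) or
        "error" (raise :class:`UnmappedProteinError` naming the protein).

    Returns
    -------
    DataFrame with columns gene_a, gene_b, species_a, species_b, bit
    (one row per ordered gene pair; a = query side).
    """
    if unmapped not in ("skip", "error"):
        raise ValueError(f"unknown unmapped-protein policy {unmapped!r}")
    best: dict[tuple[str, str, str, str], float] = {}
    n_skipped = 0
    for hit in hits:
        qmap = maps.get(hit.query_species, {})
        smap = maps.get(hit.subject_species, {})
        gene_a = qmap.get(hit.query_protein)
        gene_b = smap.get(hit.subject_protein)
        if gene_a is None or gene_b is None:
            missing = hit.query_protein if gene_a is None else hit.subject_protein
            if unmapped == "error":
                raise UnmappedProteinError(
                    f"protein {missing!r} absent from annotation map"
                )
            n_skipped += 1
            continue
        if hit.query_species == hit.subject_species:
            continue
        key = (hit.query_species, gene_a, hit.subject_species, gene_b)
        if best.get(key, -np.inf) < hit.bit_score:
            best[key] = hit.bit_score
    if n_skipped:
        logger.warning("collapse_to_gene_pairs: skipped %d hits with unmapped proteins", n_skipped)
    rows = [
        {"species_a": sa, "gene_a": ga, "species_b": sb, "gene_b": gb, "bit": b}
        for (sa, ga, sb, gb), b in best.items()
    ]
    return pd.DataFrame(rows, columns=["species_a", "gene_a", "species_b", "gene_b", "bit"])


@dataclass
class HomologyGraph:
    """Undirected weighted multipartite gene homology graph.

    ``edges`` holds one row per unordered cross-species gene pair with both
    directional bit scores (reciprocity is a construction invariant) and the
    symmetric weight ``weight = max(bit_fwd, bit_rev)``.
    """

    registry: SpeciesRegistry
    edges: pd.DataFrame  # species_a, gene_a, species_b, gene_b, weight, bit_fwd, bit_rev
    nodes: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def weight(self, a: tuple[str, str], b: tuple[str, str]) -> float | None:
        """Weight of the edge between nodes ``a`` and ``b`` (None if absent)."""
        e = self.edges
        m = (
            ((e.species_a == a[0]) & (e.gene_a == a[1]) & (e.species_b == b[0]) & (e.gene_b == b[1]))
            | ((e.species_a == b[0]) & (e.gene_a == b[1]) & (e.species_b == a[0]) & (e.gene_b == a[1]))
        )
        hit = e.loc[m, "weight"]
        return None if hit.empty else float(hit.iloc[0])

    def to_igraph(self):
        """Export to a python-igraph Graph with 'weight' edge attribute."""
        import igraph as ig

        index = {node: i for i, node in enumerate(self.nodes)}
        g = ig.Graph(n=len(self.nodes))
        g.vs["name"] = [f"{s}|{gid}" for s, gid in self.nodes]
        g.vs["species"] = [s for s, _ in self.nodes]
        g.vs["gene"] = [gid for _, gid in self.nodes]
        pairs = [
            (index[(r.species_a, r.gene_a)], index[(r.species_b, r.gene_b)])
            for r in self.edges.itertuples()
        ]
        g.add_edges(pairs)
        g.es["weight"] = self.edges["weight"].tolist()
        return g

    def summary(self) -> dict:
        """Node/edge counts overall and per species pair."""
        per_pair: dict[str, int] = {}
        for r in self.edges.itertuples():
            key = "--".join(sorted((r.species_a, r.species_b)))
            per_pair[key] = per_pair.get(key, 0) + 1
        per_species: dict[str, int] = {}
        for s, _ in self.nodes:
            per_species[s] = per_species.get(s, 0) + 1
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "nodes_per_species": per_species,
            "edges_per_species_pair": per_pair,
        }

    def to_tsv(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, registry: SpeciesRegistry) -> "HomologyGraph":
        edges = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
        nodes = sorted(
            {(r.species_a, str(r.gene_a)) for r in edges.itertuples()}
            | {(r.species_b, str(r.gene_b)) for r in edges.itertuples()}
        )
        return cls(registry=registry, edges=edges, nodes=nodes)


def build_homology_graph(
    pair_scores: pd.DataFrame,
    registry: SpeciesRegistry,
    node_policy: str = "touched",
    annotation_genes: Mapping[str, Iterable[str]] | None = None,
) -> HomologyGraph:
    """Build the reciprocal homology graph from directional gene-pair scores.

    An undirected edge exists for a gene pair iff directional records exist in
    both directions; its weight is the maximum of the two directional scores.

    Parameters
    ----------
    pair_scores
        Output of :func:`collapse_to_gene_pairs`.
    registry
        Species under comparison; any species in ``pair_scores`` must be listed.
    node_policy
        "touched" (default) keeps only genes on at least one retained edge;
        "all" additionally keeps isolated genes listed in ``annotation_genes``.
    annotation_genes
        species -> iterable of gene ids, required for ``node_policy="all"``.
    """
    if node_policy not in ("touched", "all"):
        raise ValueError(f"unknown node policy {node_policy!r}")
    seen_species = set(pair_scores["species_a"]) | set(pair_scores["species_b"]) if len(pair_scores) else set()
    unknown = seen_species - set(registry.species_ids)
    if unknown:
        raise ValueError(f"species absent from registry: {sorted(unknown)}")

    directional: dict[tuple[tuple[str, str], tuple[str, str]], float] = {}
    for r in pair_scores.itertuples():
        directional[((r.species_a, str(r.gene_a)), (r.species_b, str(r.gene_b)))] = float(r.bit)

    rows = []
    for (a, b), bit_fwd in directional.items():
        if a >= b:  # handle each unordered pair once, from its sorted orientation
            continue
        bit_rev = directional.get((b, a))
        if bit_rev is None:
            continue
        rows.append(
            {
                "species_a": a[0],
                "gene_a": a[1],
                "species_b": b[0],
                "gene_b": b[1],
                "weight": max(bit_fwd, bit_rev),
                "bit_fwd": bit_fwd,
                "bit_rev": bit_rev,
            }
        )
    edges = pd.DataFrame(
        rows,
        columns=["species_a", "gene_a", "species_b", "gene_b", "weight", "bit_fwd", "bit_rev"],
    )
    touched = sorted(
        {(r.species_a, r.gene_a) for r in edges.itertuples()}
        | {(r.species_b, r.gene_b) for r in edges.itertuples()}
    )
    if node_policy == "all":
        if annotation_genes is None:
            raise ValueError("node_policy='all' requires annotation_genes")
        nodes = sorted(
            set(touched)
            | {(s, str(g)) for s, genes in annotation_genes.items() for g in genes}
        )
    else:
        nodes = touched
    return HomologyGraph(registry=registry, edges=edges, nodes=nodes)


def write_graph_summary(graph: HomologyGraph, path: str | Path) -> None:
    Path(path).write_text(json.dumps(graph.summary(), indent=2, sort_keys=True))
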