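"""Shared fixtures: a small simulated homology pipeline run end to end."""

import numpy as np
import pytest

from scgenus import (
    GeneSetCatalog,
    build_homology_graph,
    collapse_to_gene_pairs,
    discover_gene_sets,
    parse_blast_tab,
    read_annotation_map,
    simulate_gene_families,
)
from scgenus.synthetic_fixtures import FamilySimulationConfig


@pytest.fixture(scope="session")
def sim_small():
    """20 planted gene families on the default 11-species tree, no loss."""
    return simulate_gene_families(
        FamilySimulationConfig(n_families=20, loss_prob=0.0, seed=0)
    )


@pytest.fixture(scope="session")
def sim_dir(sim_small, tmp_path_factory):
    d = tmp_path_factory.mktemp("fixture")
    sim_small.write_dir(d)
    return d


@pytest.fixture(scope="session")
def graph_small(sim_small, sim_dir):
    """Homology graph built through the full parse -> collapse -> build path."""
    hits = []
    for path in sorted((sim_dir / "hits").glob("*.tsv")):
        qs, ss = path.stem.split("__")
        hits.extend(parse_blast_tab(path, qs, ss))
    maps = {
        sp: read_annotation_map(sim_dir / "maps" / f"{sp}.tsv")
        for sp in sim_small.registry.species_ids
    }
    pairs = collapse_to_gene_pairs(hits, maps)
    return build_homology_graph(pairs, sim_small.registry)


@pytest.fixture(scope="session")
def catalog_small(sim_small, graph_small):
    return discover_gene_sets(
        graph_small, sim_small.registry, tree=sim_small.tree, seed=0
    )


@pytest.fixture(scope="session")
def catalog_full_coverage(sim_small, catalog_small):
    """Catalog restricted to sets covering every species (for planted programs)."""
    full = frozenset(sim_small.registry.species_ids)
    return GeneSetCatalog(
        [gs for gs in catalog_small if gs.species_coverage == full],
        provenance=dict(catalog_small.provenance),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
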