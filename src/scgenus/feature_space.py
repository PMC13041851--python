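"""Gene-set feature space: normalization, transformation, pseudobulk.

Expression matrices are carried as :class:`anndata.AnnData` objects, one per
species (``adata.uns["species"]`` holds the species id; cell metadata lives
in ``adata.obs``).  The central transform maps a cells × genes matrix X to a
cells × gene-sets matrix Z by averaging, per cell, the expression of the
genes of each set that the species actually has:

    Z_cj = mean over g in (G_j ∩ genes of species s) of X_cg

so lineage-specific gene expansions contribute through their mean expression
rather than through increased feature weight.  Sets with no gene present in
a species are filled with 0 and flagged absent (``Z.var["absent"]``) so that
downstream statistics can exclude them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .geneset_discovery import GeneSetCatalog

logger = logging.getLogger("scgenus")

DEFAULT_SCALE = 1e4


def make_expression_matrix(
    X,
    cell_ids: Sequence[str],
    gene_ids: Sequence[str],
    species: str,
    obs: pd.DataFrame | None = None,
) -> AnnData:
    """Bundle a cells × genes matrix with ids and metadata into AnnData."""
    if obs is None:
        obs = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
    else:
        obs = obs.copy()
        obs.index = pd.Index(cell_ids, name="cell_id")
    var = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("gene ids must be unique")
    adata = AnnData(X=X, obs=obs, var=var)
    adata.uns["species"] = species
    return adata


def lognormalize(adata: AnnData, scale: float = DEFAULT_SCALE) -> AnnData:
    """Library-size normalize each cell to total ``scale``, then log1p.

    Cells with zero total are left all-zero (with a warning).  Negative
    input raises.  Returns a new AnnData; the input is not modified.
    """
    X = adata.X
    if sp.issparse(X):
        if (X.data < 0).any():
            raise ValueError("negative expression values")
        totals = np.asarray(X.sum(axis=1)).ravel()
    else:
        X = np.asarray(X, dtype=float)
        if (X < 0).any():
            raise ValueError("negative expression values")
        totals = X.sum(axis=1)
    n_zero = int((totals == 0).sum())
    if n_zero:
        warnings.warn(f"{n_zero} cells have zero total counts; left as zeros")
    factors = np.where(totals > 0, scale / np.where(totals > 0, totals, 1.0), 0.0)
    if sp.issparse(X):
        Xn = sp.diags(factors) @ X.tocsr()
        Xn.data = np.log1p(Xn.data)
    else:
        Xn = np.log1p(X * factors[:, None])
    out = AnnData(X=Xn, obs=adata.obs.copy(), var=adata.var.copy())
    out.uns.update(adata.uns)
    out.uns["normalization"] = {"method": "lognorm", "scale": scale}
    return out


def transform_to_gene_sets(adata: AnnData, catalog: GeneSetCatalog) -> AnnData:
    """Transform cells × genes to cells × gene-sets by per-set means.

    Column order follows ``catalog.set_ids`` and is therefore identical for
    every species.  ``var`` carries ``n_genes`` (member genes present for
    this species) and ``absent`` (no member gene present; column is 0).
    """
    species = adata.uns.get("species")
    gene_index = {g: i for i, g in enumerate(adata.var_names)}
    set_ids = catalog.set_ids
    rows, cols, vals = [], [], []
    n_genes = np.zeros(len(set_ids), dtype=int)
    for j, gs in enumerate(catalog.gene_sets):
        present = [gene_index[g] for g in gs.genes_of(species) if g in gene_index]
        n_genes[j] = len(present)
        if present:
            w = 1.0 / len(present)
            for i in present:
                rows.append(i)
                cols.append(j)
                vals.append(w)
    M = sp.csr_matrix(
        (vals, (rows, cols)), shape=(adata.n_vars, len(set_ids)), dtype=float
    )
    X = adata.X
    Z = (X @ M) if sp.issparse(X) else np.asarray(X, dtype=float) @ M.toarray()
    if sp.issparse(Z):
        Z = np.asarray(Z.todense())
    var = pd.DataFrame(
        {"n_genes": n_genes, "absent": n_genes == 0},
        index=pd.Index(set_ids, name="set_id"),
    )
    out = AnnData(X=Z, obs=adata.obs.copy(), var=var)
    out.uns["species"] = species
    return out


@dataclass
class PseudobulkTensor:
    """Species × cell type × gene set mean expression (long format).

    ``table`` columns: species, cell_type, set_id, mean, n_cells, present
    (present = the set has at least one member gene in that species).
    """

    table: pd.DataFrame
    cell_types: list[str] = field(default_factory=list)

    def profile(self, set_id: str, species: str) -> pd.Series | None:
        """Pseudobulk vector of a set across the cell-type panel, or None if absent."""
        sub = self.table[(self.table.set_id == set_id) & (self.table.species == species)]
        if sub.empty or not sub["present"].iloc[0]:
            return None
        return sub.set_index("cell_type")["mean"].reindex(self.cell_types)

    def species_of(self, set_id: str) -> list[str]:
        sub = self.table[(self.table.set_id == set_id) & self.table.present]
        return sorted(sub.species.unique())

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PseudobulkTensor":
        table = pd.read_csv(path, sep="\t", dtype={"set_id": str})
        return cls(table=table, cell_types=sorted(table.cell_type.unique()))


def pseudobulk_by_celltype(
    Zs: Iterable[AnnData], cell_type_key: str = "cell_type"
) -> PseudobulkTensor:
    """Average gene-set expression over cells of each (species, cell type)."""
    frames = []
    cell_types: set[str] = set()
    for Z in Zs:
        if cell_type_key not in Z.obs:
            raise KeyError(f"cell metadata has no column {cell_type_key!r}")
        species = Z.uns.get("species")
        X = np.asarray(Z.X.todense()) if sp.issparse(Z.X) else np.asarray(Z.X)
        labels = Z.obs[cell_type_key].astype(str).values
        absent = (
            Z.var["absent"].values if "absent" in Z.var else np.zeros(Z.n_vars, bool)
        )
        for ct in np.unique(labels):
            mask = labels == ct
            means = X[mask].mean(axis=0)
            frames.append(
                pd.DataFrame(
                    {
                        "species": species,
                        "cell_type": ct,
                        "set_id": Z.var_names,
                        "mean": means,
                        "n_cells": int(mask.sum()),
                        "present": ~absent,
                    }
                )
            )
            cell_types.add(ct)
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["species", "cell_type", "set_id", "mean", "n_cells", "present"]
    )
    return PseudobulkTensor(table=table, cell_types=sorted(cell_types))


# -- disk I/O ----------------------------------------------------------------


def read_expression_dir(path: str | Path, species: str) -> AnnData:
    """Read a cells × genes matrix from a directory.

    Layout: either ``matrix.mtx`` (cells × genes triplets) with ``genes.tsv``
    and ``cells.tsv`` (one id per line), or ``dense.tsv`` (cells in rows,
    first column = cell id, header = gene ids).  Optional ``metadata.tsv``
    keyed by cell id provides cell annotations.
    """
    import scipy.io

    path = Path(path)
    if (path / "matrix.mtx").exists():
        X = scipy.io.mmread(path / "matrix.mtx").tocsr()
        genes = (path / "genes.tsv").read_text().split()
        cells = (path / "cells.tsv").read_text().split()
    elif (path / "dense.tsv").exists():
        df = pd.read_csv(path / "dense.tsv", sep="\t", index_col=0)
        X = df.values.astype(float)
        genes = list(df.columns)
        cells = [str(c) for c in df.index]
    else:
        raise FileNotFoundError(f"no matrix.mtx or dense.tsv under {path}")
    obs = None
    if (path / "metadata.tsv").exists():
        obs = pd.read_csv(path / "metadata.tsv", sep="\t", index_col=0, dtype=str)
        obs = obs.loc[cells]
        for col in ("pseudotime",):
            if col in obs:
                obs[col] = obs[col].astype(float)
    return make_expression_matrix(X, cells, genes, species=species, obs=obs)


def write_expression_dir(adata: AnnData, path: str | Path, dense: bool = False) -> None:
    """Write an AnnData in the directory convention of :func:`read_expression_dir`."""
    import scipy.io

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if dense:
        pd.DataFrame(
            np.asarray(adata.X.todense()) if sp.issparse(adata.X) else np.asarray(adata.X),
            index=adata.obs_names,
            columns=adata.var_names,
        ).to_csv(path / "dense.tsv", sep="\t")
    else:
        scipy.io.mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(adata.X))
        (path / "genes.tsv").write_text("\n".join(adata.var_names) + "\n")
        (path / "cells.tsv").write_text("\n".join(adata.obs_names) + "\n")
    if len(adata.obs.columns):
        adata.obs.to_csv(path / "metadata.tsv", sep="\t")
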