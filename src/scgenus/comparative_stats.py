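"""Comparative statistics over the gene-set feature space.

Four families of bespoke statistics:

* **Conservation scoring** — per gene set, the mean pairwise Spearman rank
  correlation of its pseudobulk profile (across a fixed cell-type panel)
  between species, classified as highly conserved (> 0.75), conserved
  (0.5–0.75), weakly conserved (0–0.5) or highly divergent (≤ 0), with
  per-evolutionary-age ECDFs.
* **Species-mixing entropy** — Shannon entropy of frequency-corrected
  species composition within cell neighborhoods, normalized by log S so
  that 0 means single-species dominance and 1 maximal mixing; clusters of
  neighborhoods with median entropy < 0.55 are flagged species-enriched.
* **Wilcoxon gene-set markers** — rank-sum marker tests with log2
  fold-change and detection-rate filters and Bonferroni correction.
* **Centroid L1 divergence** — per cell type, pairwise L1 distances between
  species centroids in a PCA space (2,000 most variable sets; number of PCs
  = minimum explaining 20% of variance, capped at 100), contrasted with
  between-cell-type centroid distances in a shared joint PC space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from anndata import AnnData

from .feature_space import PseudobulkTensor
from .geneset_discovery import GeneSetCatalog

logger = logging.getLogger("scgenus")

#: conservation-class boundaries (score > 0.75; 0.5 <= score <= 0.75;
#: 0 < score < 0.5; score <= 0)
HIGHLY_CONSERVED_MIN = 0.75
CONSERVED_MIN = 0.5
DEFAULT_ENTROPY_FLAG_THRESHOLD = 0.55
DEFAULT_PC_VARIANCE_TARGET = 0.20
DEFAULT_PC_CAP = 100
DEFAULT_N_HVG = 2000
DEFAULT_JOINT_N_PCS = 50


# -- conservation ------------------------------------------------------------


@dataclass
class ConservationRecord:
    set_id: str
    score: float | None
    pairwise: dict[tuple[str, str], float]
    n_species_used: int
    n_pairs_skipped: int
    label: str


def classify_conservation(score: float | None) -> str:
    """Class label for a conservation score; boundaries as printed above."""
    if score is None or not np.isfinite(score):
        return "unscored"
    if score > HIGHLY_CONSERVED_MIN:
        return "highly_conserved"
    if score >= CONSERVED_MIN:
        return "conserved"
    if score > 0:
        return "weakly_conserved"
    return "highly_divergent"


def _score_profiles(profiles: Mapping[str, np.ndarray]) -> tuple[float | None, dict, int, int]:
    """Mean pairwise Spearman rho over species profiles.

    Pairs where either vector is constant (undefined rank correlation) are
    skipped and counted.  Computed as Pearson correlation of mid-ranks,
    which equals Spearman's rho with average-rank tie handling.
    """
    species = sorted(profiles)
    ranks = {s: stats.rankdata(profiles[s]) for s in species}
    rhos: dict[tuple[str, str], float] = {}
    skipped = 0
    used: set[str] = set()
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            ra, rb = ranks[a], ranks[b]
            if ra.std() == 0 or rb.std() == 0:
                skipped += 1
                continue
            if np.array_equal(ra, rb):
                rho = 1.0  # identical rank vectors: exact by definition
            else:
                rho = float(np.clip(np.corrcoef(ra, rb)[0, 1], -1.0, 1.0))
            rhos[(a, b)] = rho
            used.update((a, b))
    score = float(np.mean(list(rhos.values()))) if rhos else None
    return score, rhos, len(used), skipped


def conservation_score(pb: PseudobulkTensor, set_id: str) -> ConservationRecord:
    """Conservation record for one gene set from pseudobulk profiles.

    Species where the set is structurally absent are excluded.  With fewer
    than two usable species the score is undefined (label "unscored").
    """
    profiles: dict[str, np.ndarray] = {}
    for species in pb.species_of(set_id):
        prof = pb.profile(set_id, species)
        if prof is not None and prof.notna().all():
            profiles[species] = prof.values.astype(float)
    if len(profiles) < 2:
        return ConservationRecord(set_id, None, {}, len(profiles), 0, "unscored")
    score, rhos, n_used, skipped = _score_profiles(profiles)
    return ConservationRecord(set_id, score, rhos, n_used, skipped, classify_conservation(score))


def conservation_table(
    pb: PseudobulkTensor, catalog: GeneSetCatalog | None = None, set_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Conservation scores for many sets; adds lca_age when a catalog is given."""
    if set_ids is None:
        set_ids = sorted(pb.table.set_id.unique())
    rows = []
    ages = {gs.set_id: gs.lca_age for gs in catalog} if catalog is not None else {}
    for sid in set_ids:
        rec = conservation_score(pb, sid)
        rows.append(
            {
                "set_id": sid,
                "score": rec.score,
                "class": rec.label,
                "n_species_used": rec.n_species_used,
                "n_pairs_skipped": rec.n_pairs_skipped,
                "lca_age": ages.get(sid),
            }
        )
    return pd.DataFrame(rows)


def ecdf_by_age(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Empirical CDFs of conservation scores grouped by evolutionary age.

    ``records`` must have columns score and lca_age; unscored rows are
    dropped.  Each group's table has sorted scores with ECDF values i/n;
    groups with fewer than two sets carry ``flagged=True``.
    """
    out: dict[str, pd.DataFrame] = {}
    usable = records.dropna(subset=["score", "lca_age"])
    for age, grp in usable.groupby("lca_age"):
        scores = np.sort(grp["score"].values.astype(float))
        n = len(scores)
        out[str(age)] = pd.DataFrame(
            {
                "score": scores,
                "ecdf": np.arange(1, n + 1) / n,
                "flagged": n < 2,
            }
        )
    return out


# -- species-mixing entropy --------------------------------------------------


@dataclass
class NeighborhoodComposition:
    neighborhood_id: str
    counts: dict[str, int]
    weights: dict[str, float]
    entropy: float
    cluster: str | None = None


def mixing_entropy(
    species_labels: Sequence[str],
    global_freqs: Mapping[str, float],
    n_species_total: int,
    neighborhood_id: str = "",
) -> NeighborhoodComposition:
    """Frequency-corrected Shannon entropy of a neighborhood's species mix.

    Counts are divided by global species frequencies, renormalized to
    proportions p_s, and the entropy −Σ p_s log p_s is divided by
    log(n_species_total) so the maximum 1 requires uniform weighted
    representation of *all* species in the registry.
    """
    if len(species_labels) == 0:
        raise ValueError("empty neighborhood")
    counts: dict[str, int] = {}
    for s in species_labels:
        counts[s] = counts.get(s, 0) + 1
    for s in counts:
        if global_freqs.get(s, 0) <= 0:
            raise ValueError(f"global frequency missing or non-positive for species {s!r}")
    weights = {s: c / global_freqs[s] for s, c in counts.items()}
    total = sum(weights.values())
    props = np.array([w / total for w in weights.values()])
    if len(props) == 1:
        ent = 0.0
    else:
        ent = float(-(props * np.log(props)).sum() / np.log(n_species_total))
    return NeighborhoodComposition(
        neighborhood_id=neighborhood_id, counts=counts, weights=weights, entropy=ent
    )


def neighborhood_entropies(
    obs: pd.DataFrame,
    registry_size: int,
    neighborhood_key: str = "neighborhood_id",
    species_key: str = "species",
) -> list[NeighborhoodComposition]:
    """Mixing entropy per neighborhood from a cell metadata table."""
    freqs = obs[species_key].value_counts(normalize=True).to_dict()
    out = []
    for nb, grp in obs.groupby(neighborhood_key, sort=True):
        out.append(
            mixing_entropy(
                grp[species_key].tolist(), freqs, registry_size, neighborhood_id=str(nb)
            )
        )
    return out


def flag_low_mixing_clusters(
    compositions: Sequence[NeighborhoodComposition],
    clusters: Mapping[str, str] | Sequence[str],
    threshold: float = DEFAULT_ENTROPY_FLAG_THRESHOLD,
) -> tuple[set[str], pd.DataFrame]:
    """Flag neighborhood clusters whose median entropy falls below threshold.

    ``clusters`` maps neighborhood id -> cluster id (or is a parallel list).
    Returns (flagged cluster ids, per-cluster median table).
    """
    if not isinstance(clusters, Mapping):
        clusters = {c.neighborhood_id: cl for c, cl in zip(compositions, clusters)}
    per_cluster: dict[str, list[float]] = {}
    for comp in compositions:
        if comp.neighborhood_id not in clusters:
            raise ValueError(f"neighborhood {comp.neighborhood_id!r} has no cluster")
        per_cluster.setdefault(str(clusters[comp.neighborhood_id]), []).append(comp.entropy)
    rows = []
    flagged = set()
    for cl, ents in sorted(per_cluster.items()):
        if not ents:
            raise ValueError(f"empty cluster {cl!r}")
        med = float(np.median(ents))
        is_flagged = med < threshold
        if is_flagged:
            flagged.add(cl)
        rows.append({"cluster": cl, "median_entropy": med, "n": len(ents), "flagged": is_flagged})
    return flagged, pd.DataFrame(rows)


def knn_neighborhoods(
    coords: np.ndarray,
    k: int = 50,
    n_neighborhoods: int | None = None,
    seed: int = 0,
) -> list[np.ndarray]:
    """Plain kNN neighborhood sampler (plumbing for fixtures).

    Samples index cells uniformly without replacement and returns, per index
    cell, the indices of its k nearest neighbors (including itself) in the
    given coordinate space.
    """
    from sklearn.neighbors import NearestNeighbors

    n = coords.shape[0]
    k = min(k, n)
    rng = np.random.default_rng(seed)
    if n_neighborhoods is None:
        n_neighborhoods = max(1, n // k)
    idx = rng.choice(n, size=min(n_neighborhoods, n), replace=False)
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    _, neigh = nn.kneighbors(coords[idx])
    return [neigh[i] for i in range(len(idx))]


# -- Wilcoxon markers --------------------------------------------------------


@dataclass
class MarkerResult:
    set_id: str
    group: str
    log2fc: float
    pct_in: float
    pct_out: float
    pvalue: float
    padj: float
    significant: bool


def _log2fc(x_in: np.ndarray, x_out: np.ndarray) -> float:
    """log2 fold change of expm1-backtransformed group means (pseudocount 1)."""
    mean_in = np.expm1(x_in).mean()
    mean_out = np.expm1(x_out).mean() if len(x_out) else 0.0
    return float(np.log2((mean_in + 1.0) / (mean_out + 1.0)))


def wilcoxon_markers(
    Zs: Iterable[AnnData] | AnnData,
    group_key: str = "cell_type",
    groups: Sequence[str] | None = None,
    lfc_min: float = 0.25,
    pct_min: float = 0.05,
    only_pos: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker tests on gene-set expression.

    Cells from all supplied matrices are pooled.  Per (set, group): two-sided
    rank-sum p-value, log2 fold change of expm1-backtransformed means
    (pseudocount 1) and detection fractions.  Results are filtered to
    ``lfc >= lfc_min`` (absolute value when ``only_pos`` is off) and
    ``max(pct_in, pct_out) >= pct_min``; p-values are Bonferroni-adjusted
    across all sets per group (before filtering).
    """
    if isinstance(Zs, AnnData):
        Zs = [Zs]
    mats, labels = [], []
    var_names = None
    for Z in Zs:
        if group_key not in Z.obs:
            raise KeyError(f"cell metadata has no column {group_key!r}")
        if var_names is None:
            var_names = list(Z.var_names)
        elif list(Z.var_names) != var_names:
            raise ValueError("gene-set columns differ between matrices")
        X = np.asarray(Z.X.todense()) if sp.issparse(Z.X) else np.asarray(Z.X, dtype=float)
        mats.append(X)
        labels.extend(Z.obs[group_key].astype(str).tolist())
    X = np.vstack(mats)
    labels = np.array(labels)
    if groups is None:
        groups = sorted(np.unique(labels))
    n_sets = X.shape[1]
    rows: list[dict] = []
    for grp in groups:
        mask = labels == grp
        if mask.sum() < 2:
            warnings.warn(f"group {grp!r} has fewer than 2 cells; skipped")
            continue
        Xin, Xout = X[mask], X[~mask]
        pvals = np.ones(n_sets)
        for j in range(n_sets):
            a, b = Xin[:, j], Xout[:, j]
            if len(b) == 0:
                continue
            if np.all(a == a[0]) and np.all(b == a[0]):
                pvals[j] = 1.0
                continue
            pvals[j] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        padj = np.minimum(pvals * n_sets, 1.0)
        for j in range(n_sets):
            a, b = Xin[:, j], Xout[:, j]
            lfc = _log2fc(a, b)
            pct_in = float((a > 0).mean())
            pct_out = float((b > 0).mean()) if len(b) else 0.0
            keep_lfc = lfc >= lfc_min if only_pos else abs(lfc) >= lfc_min
            if not keep_lfc or max(pct_in, pct_out) < pct_min:
                continue
            rows.append(
                {
                    "set_id": var_names[j],
                    "group": grp,
                    "log2fc": lfc,
                    "pct_in": pct_in,
                    "pct_out": pct_out,
                    "pvalue": pvals[j],
                    "padj": padj[j],
                    "significant": padj[j] < alpha,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["set_id", "group", "log2fc", "pct_in", "pct_out", "pvalue", "padj", "significant"],
    )


# -- centroid L1 divergence --------------------------------------------------


def select_pc_count(
    explained_variance_fractions: Sequence[float],
    target: float = DEFAULT_PC_VARIANCE_TARGET,
    cap: int = DEFAULT_PC_CAP,
) -> int:
    """Smallest number of leading PCs whose variance fractions sum to target.

    Returns ``cap`` when no prefix of length <= cap reaches the target.
    """
    fracs = np.asarray(explained_variance_fractions, dtype=float)
    if fracs.size == 0:
        raise ValueError("empty explained-variance list")
    if (fracs < 0).any():
        raise ValueError("variance fractions must be non-negative")
    csum = np.cumsum(fracs[:cap])
    hits = np.nonzero(csum >= target)[0]
    if hits.size == 0:
        return min(cap, fracs.size)
    return int(hits[0]) + 1


@dataclass
class CentroidDistanceReport:
    """Within- and between-cell-type centroid L1 distances in PC space."""

    within: pd.DataFrame  # cell_type, species_a, species_b, l1
    between: pd.DataFrame  # cell_type_a, cell_type_b, l1
    n_pcs_within: dict[str, int] = field(default_factory=dict)
    n_pcs_between: int = 0
    flagged_single_species: list[str] = field(default_factory=list)
    centroids: dict[str, pd.DataFrame] = field(default_factory=dict)


def _top_hvg(X: np.ndarray, n_hvg: int) -> np.ndarray:
    """Column indices of the n_hvg most variable features."""
    var = X.var(axis=0)
    n_hvg = min(n_hvg, X.shape[1])
    order = np.argsort(var)[::-1]
    return np.sort(order[:n_hvg])


def _pca_scores(X: np.ndarray, target: float, cap: int, seed: int = 0) -> tuple[np.ndarray, int]:
    from sklearn.decomposition import PCA

    n_comp = min(cap, X.shape[0] - 1, X.shape[1])
    if n_comp < 1:
        raise ValueError("too few cells for PCA")
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(X)
    m = select_pc_count(pca.explained_variance_ratio_, target=target, cap=cap)
    return scores[:, :m], m


def centroid_l1_analysis(
    Zs: Iterable[AnnData],
    cell_type_key: str = "cell_type",
    n_hvg: int = DEFAULT_N_HVG,
    variance_target: float = DEFAULT_PC_VARIANCE_TARGET,
    pc_cap: int = DEFAULT_PC_CAP,
    joint_n_pcs: int = DEFAULT_JOINT_N_PCS,
    seed: int = 0,
) -> CentroidDistanceReport:
    """Centroid-based L1 divergence analysis.

    Within a cell type: pool that type's cells from all species, keep the
    ``n_hvg`` most variable sets, run PCA, choose the PC count explaining
    ``variance_target`` of the variance (capped), and measure pairwise L1
    distances between per-species centroids.  Between cell types:
    cell-type centroid distances in the shared joint PC space (top
    ``joint_n_pcs`` components over all cells), the reference scale for
    divergence between distinct cell identities.
    """
    from scipy.spatial.distance import pdist, squareform

    mats, species_labels, type_labels = [], [], []
    for Z in Zs:
        X = np.asarray(Z.X.todense()) if sp.issparse(Z.X) else np.asarray(Z.X, dtype=float)
        mats.append(X)
        species_labels.extend([Z.uns.get("species")] * Z.n_obs)
        type_labels.extend(Z.obs[cell_type_key].astype(str).tolist())
    X = np.vstack(mats)
    species_labels = np.array(species_labels)
    type_labels = np.array(type_labels)

    within_rows = []
    n_pcs_within: dict[str, int] = {}
    flagged: list[str] = []
    centroids_by_type: dict[str, pd.DataFrame] = {}
    for ct in sorted(np.unique(type_labels)):
        mask = type_labels == ct
        sub = X[mask]
        sp_here = species_labels[mask]
        uniq = sorted(np.unique(sp_here))
        if len(uniq) < 2:
            flagged.append(ct)
            continue
        cols = _top_hvg(sub, n_hvg)
        scores, m = _pca_scores(sub[:, cols], variance_target, pc_cap, seed=seed)
        n_pcs_within[ct] = m
        cents = np.vstack([scores[sp_here == s].mean(axis=0) for s in uniq])
        centroids_by_type[ct] = pd.DataFrame(cents, index=uniq)
        D = squareform(pdist(cents, metric="cityblock"))
        for i, a in enumerate(uniq):
            for jj in range(i + 1, len(uniq)):
                within_rows.append(
                    {"cell_type": ct, "species_a": a, "species_b": uniq[jj], "l1": D[i, jj]}
                )

    # between-cell-type distances in the shared joint PC space
    from sklearn.decomposition import PCA

    cols = _top_hvg(X, n_hvg)
    Xj = X[:, cols]
    n_pcs_between = min(joint_n_pcs, Xj.shape[0] - 1, Xj.shape[1])
    scores = PCA(n_components=n_pcs_between, svd_solver="full", random_state=seed).fit_transform(Xj)
    types = sorted(np.unique(type_labels))
    cents = np.vstack([scores[type_labels == ct].mean(axis=0) for ct in types])
    D = squareform(pdist(cents, metric="cityblock"))
    between_rows = [
        {"cell_type_a": types[i], "cell_type_b": types[j], "l1": D[i, j]}
        for i in range(len(types))
        for j in range(i + 1, len(types))
    ]
    return CentroidDistanceReport(
        within=pd.DataFrame(within_rows, columns=["cell_type", "species_a", "species_b", "l1"]),
        between=pd.DataFrame(between_rows, columns=["cell_type_a", "cell_type_b", "l1"]),
        n_pcs_within=n_pcs_within,
        n_pcs_between=n_pcs_between,
        flagged_single_species=flagged,
        centroids=centroids_by_type,
    )
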