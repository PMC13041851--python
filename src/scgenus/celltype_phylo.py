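"""Distance-based cell-type phylogenies with bootstrap tip stability.

Cell-type (or subtype) centroids in a shared PC space are compared by
Pearson correlation; distances ``1 - rho`` feed Saitou–Nei neighbor
joining.  Topological robustness is assessed by resampling cells within
each tip with replacement, rebuilding the tree per replicate, and scoring
each tip with a quartet-based leaf stability index (LSI): for quartets
containing the tip, the stability is the maximum frequency among the three
possible quartet resolutions across bootstrap trees, and the LSI is the
mean over quartets.  LSI ranges from 0 (unstable placement) to 1 (the tip
occupies the same relative position in every replicate).

The NJ implementation is deterministic: ties in the Q-criterion are broken
by the lexicographically smallest pair of clade labels (a clade's label is
its smallest tip label), and negative branch lengths are clamped to zero
with the deficit shifted to the sister branch.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

LSI_VARIANT = "quartet-max (Thorley-Wilkinson style)"


@dataclass
class CentroidProfile:
    """A tree tip: a cell (sub)type's mean position in PC space."""

    label: str
    coords: np.ndarray


@dataclass
class PhyloDistanceMatrix:
    """Symmetric tip-tip distance matrix (1 - Pearson rho)."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if np.isnan(m).any():
            raise ValueError("distance matrix contains NaN")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        self.matrix = m


def centroid_correlation_distance(profiles: Sequence[CentroidProfile]) -> PhyloDistanceMatrix:
    """1 - Pearson correlation distances between centroid profiles."""
    if len(profiles) < 3:
        raise ValueError("need at least 3 tips")
    dim = len(profiles[0].coords)
    for p in profiles:
        if len(p.coords) != dim:
            raise ValueError("centroid vectors differ in dimensionality")
        if np.std(p.coords) == 0:
            raise ValueError(f"constant centroid vector for tip {p.label!r}")
    coords = np.vstack([p.coords for p in profiles]).astype(float)
    corr = np.corrcoef(coords)
    D = 1.0 - corr
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return PhyloDistanceMatrix(labels=[p.label for p in profiles], matrix=D)


@dataclass
class CellTypeTree:
    """Unrooted tree stored as a child list under a (trifurcating) root.

    ``children[node]`` is a list of (child, branch_length); node 0..n_tips-1
    are tips in ``tip_labels`` order, higher ids are internal.
    """

    tip_labels: list[str]
    children: dict[int, list[tuple[int, float]]]
    root: int
    lsi: dict[str, float] = field(default_factory=dict)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def _adjacency(self) -> dict[int, list[tuple[int, float]]]:
        adj: dict[int, list[tuple[int, float]]] = {}
        for parent, kids in self.children.items():
            for child, bl in kids:
                adj.setdefault(parent, []).append((child, bl))
                adj.setdefault(child, []).append((parent, bl))
        return adj

    def _tip_distances(self, topological: bool) -> np.ndarray:
        adj = self._adjacency()
        n = self.n_tips
        out = np.zeros((n, n))
        for src in range(n):
            dist = {src: 0.0}
            stack = [src]
            while stack:
                u = stack.pop()
                for v, bl in adj.get(u, []):
                    if v not in dist:
                        dist[v] = dist[u] + (1.0 if topological else bl)
                        stack.append(v)
            for dst in range(n):
                out[src, dst] = dist[dst]
        return out

    def tip_path_lengths(self) -> pd.DataFrame:
        """Sum of branch lengths along tip-to-tip paths."""
        return pd.DataFrame(
            self._tip_distances(topological=False), index=self.tip_labels, columns=self.tip_labels
        )

    def topological_distances(self) -> np.ndarray:
        """Edge counts along tip-to-tip paths (tips in tip_labels order)."""
        return self._tip_distances(topological=True)

    def newick(self, include_lsi: bool = False) -> str:
        def render(node: int) -> str:
            kids = self.children.get(node, [])
            if not kids:
                label = self.tip_labels[node]
                if include_lsi and label in self.lsi:
                    return f"{label}[&lsi={self.lsi[label]:.4f}]"
                return label
            inner = ",".join(
                f"{render(child)}:{bl:.6g}" for child, bl in kids
            )
            return f"({inner})"

        return render(self.root) + ";"


def neighbor_joining(D: PhyloDistanceMatrix) -> CellTypeTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Exact on additive distance matrices.  Negative branch-length estimates
    are clamped to zero and the deficit moved to the sister branch.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("need at least 3 tips")
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D.matrix[i, j])

    def d(i: int, j: int) -> float:
        if i == j:
            return 0.0
        return dist[(min(i, j), max(i, j))]

    active = list(range(n))
    # clade sort key: smallest tip label in the clade, for tie-breaking
    key: dict[int, str] = {i: D.labels[i] for i in range(n)}
    children: dict[int, list[tuple[int, float]]] = {}
    next_id = n

    while len(active) > 3:
        r = len(active)
        rowsum = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        best_q = np.inf
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (r - 2) * d(i, j) - rowsum[i] - rowsum[j]
                pair_key = tuple(sorted((key[i], key[j])))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and (best is None or pair_key < best[1])
                ):
                    best_q = q
                    best = ((i, j), pair_key)
        (i, j), _ = best
        li = 0.5 * d(i, j) + (rowsum[i] - rowsum[j]) / (2 * (r - 2))
        lj = d(i, j) - li
        # clamp negatives, shifting the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        u = next_id
        next_id += 1
        children[u] = [(i, li), (j, lj)]
        key[u] = min(key[i], key[j])
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
            dist[(min(u, k), max(u, k))] = duk
        active = [k for k in active if k not in (i, j)] + [u]

    # final trifurcation via the three-point formulas
    a, b, c = sorted(active, key=lambda x: key[x])
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    root = next_id
    children[root] = [(a, max(la, 0.0)), (b, max(lb, 0.0)), (c, max(lc, 0.0))]
    return CellTypeTree(tip_labels=list(D.labels), children=children, root=root)


def bootstrap_trees(
    cells: Mapping[str, np.ndarray], n_boot: int = 1000, seed: int = 0
) -> list[CellTypeTree]:
    """Bootstrap NJ trees by resampling each tip's cells with replacement.

    ``cells`` maps tip label -> (n_cells, n_dims) coordinate array.  Per
    iteration each tip's cells are resampled (same size), centroids are
    recomputed, and an NJ tree is built from 1 - Pearson distances.
    """
    labels = sorted(cells)
    for lab in labels:
        arr = np.asarray(cells[lab], dtype=float)
        if arr.ndim != 2 or arr.shape[0] == 0:
            raise ValueError(f"tip {lab!r} has no cells")
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(n_boot):
        profiles = []
        for lab in labels:
            arr = np.asarray(cells[lab], dtype=float)
            idx = rng.integers(0, arr.shape[0], size=arr.shape[0])
            profiles.append(CentroidProfile(label=lab, coords=arr[idx].mean(axis=0)))
        trees.append(neighbor_joining(centroid_correlation_distance(profiles)))
    return trees


def point_estimate_tree(cells: Mapping[str, np.ndarray]) -> CellTypeTree:
    """NJ tree from the full-sample centroids (no resampling)."""
    profiles = [
        CentroidProfile(label=lab, coords=np.asarray(cells[lab], dtype=float).mean(axis=0))
        for lab in sorted(cells)
    ]
    return neighbor_joining(centroid_correlation_distance(profiles))


def _quartet_resolution(dt: np.ndarray, t: int, a: int, b: int, c: int) -> int | None:
    """Resolution of quartet {t,a,b,c}: 0 = ta|bc, 1 = tb|ac, 2 = tc|ab.

    Uses the four-point condition on topological distances; returns None
    when unresolved (all pairings tie, e.g. a star local topology).
    """
    sums = (
        dt[t, a] + dt[b, c],
        dt[t, b] + dt[a, c],
        dt[t, c] + dt[a, b],
    )
    m = min(sums)
    winners = [k for k, s in enumerate(sums) if s == m]
    return winners[0] if len(winners) == 1 else None


def leaf_stability_index(
    boot: Sequence[CellTypeTree],
    max_quartets_per_tip: int = 2000,
    seed: int = 0,
) -> dict[str, float]:
    """Quartet-based leaf stability per tip, from a set of bootstrap trees.

    For each tip t and quartet {t, a, b, c} (all such quartets, or a
    uniform subsample of ``max_quartets_per_tip`` when there are more), the
    quartet's stability is the maximum frequency of its three possible
    resolutions across the bootstrap trees; LSI(t) is the mean over
    quartets.  Values lie in [0, 1].
    """
    if not boot:
        raise ValueError("no bootstrap trees")
    labels = boot[0].tip_labels
    n = len(labels)
    if n < 4:
        raise ValueError("need at least 4 tips")
    for tree in boot:
        if tree.tip_labels != labels:
            raise ValueError("bootstrap trees have differing tip sets")
    dts = [tree.topological_distances() for tree in boot]
    rng = np.random.default_rng(seed)
    lsi: dict[str, float] = {}
    others_all = list(range(n))
    for t in range(n):
        others = [x for x in others_all if x != t]
        all_triples = list(itertools.combinations(others, 3))
        if len(all_triples) > max_quartets_per_tip:
            pick = rng.choice(len(all_triples), size=max_quartets_per_tip, replace=False)
            triples = [all_triples[i] for i in sorted(pick)]
        else:
            triples = all_triples
        stabilities = []
        for a, b, c in triples:
            counts = [0, 0, 0]
            n_resolved = 0
            for dt in dts:
                res = _quartet_resolution(dt, t, a, b, c)
                if res is not None:
                    counts[res] += 1
                    n_resolved += 1
            if n_resolved == 0:
                stabilities.append(1.0 / 3.0)
            else:
                stabilities.append(max(counts) / len(dts))
        lsi[labels[t]] = float(np.mean(stabilities))
    return lsi
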