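"""Conservation scoring, mixing entropy, markers, PC selection, centroids."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scgenus import (
    classify_conservation,
    conservation_score,
    ecdf_by_age,
    flag_low_mixing_clusters,
    make_expression_matrix,
    mixing_entropy,
    select_pc_count,
    centroid_l1_analysis,
    wilcoxon_markers,
)
from scgenus.feature_space import PseudobulkTensor


def pb_from_profiles(profiles, set_id="S0"):
    """profiles: species -> vector over cell types t0..tn."""
    rows = []
    for sp, vec in profiles.items():
        for i, v in enumerate(vec):
            rows.append(
                {"species": sp, "cell_type": f"t{i}", "set_id": set_id,
                 "mean": float(v), "n_cells": 10, "present": True}
            )
    table = pd.DataFrame(rows)
    return PseudobulkTensor(table=table, cell_types=sorted(table.cell_type.unique()))


class TestConservationScore:
    def test_identical_profiles_score_one(self):
        v = [1.0, 3.0, 2.0, 5.0]
        rec = conservation_score(pb_from_profiles({"a": v, "b": v, "c": v}), "S0")
        assert rec.score == pytest.approx(1.0)
        assert rec.label == "highly_conserved"

    def test_reversed_ranks_score_minus_one(self):
        rec = conservation_score(
            pb_from_profiles({"a": [1, 2, 3, 4], "b": [4, 3, 2, 1]}), "S0"
        )
        assert rec.score == pytest.approx(-1.0)
        assert rec.label == "highly_divergent"

    def test_three_species_mean_of_pairwise_spearman(self, rng):
        profiles = {s: rng.normal(size=8) for s in "abc"}
        rec = conservation_score(pb_from_profiles(profiles), "S0")
        expected = np.mean(
            [stats.spearmanr(profiles[x], profiles[y]).statistic
             for x, y in itertools.combinations("abc", 2)]
        )
        assert rec.score == pytest.approx(expected, abs=1e-12)

    def test_constant_profile_pairs_skipped(self):
        rec = conservation_score(
            pb_from_profiles({"a": [1, 1, 1], "b": [1, 2, 3], "c": [3, 2, 1]}), "S0"
        )
        assert rec.n_pairs_skipped == 2
        assert rec.score == pytest.approx(-1.0)  # only the b-c pair remains

    def test_single_species_unscored(self):
        rec = conservation_score(pb_from_profiles({"a": [1, 2, 3]}), "S0")
        assert rec.score is None and rec.label == "unscored"

    def test_absent_species_excluded(self):
        pb = pb_from_profiles({"a": [1, 2, 3], "b": [1, 2, 3], "c": [3, 2, 1]})
        pb.table.loc[pb.table.species == "c", "present"] = False
        rec = conservation_score(pb, "S0")
        assert rec.score == pytest.approx(1.0)
        assert rec.n_species_used == 2

    def test_random_profiles_mean_near_zero(self):
        rng = np.random.default_rng(0)
        scores = []
        for _ in range(300):
            profiles = {s: rng.normal(size=10) for s in "abcde"}
            scores.append(conservation_score(pb_from_profiles(profiles), "S0").score)
        assert abs(np.mean(scores)) < 0.05


class TestClassification:
    @pytest.mark.parametrize(
        "score,label",
        [
            (0.8, "highly_conserved"),
            (0.76, "highly_conserved"),
            (0.75, "conserved"),
            (0.5, "conserved"),
            (0.49, "weakly_conserved"),
            (1e-9, "weakly_conserved"),
            (0.0, "highly_divergent"),
            (-0.1, "highly_divergent"),
            (None, "unscored"),
        ],
    )
    def test_boundaries_exact(self, score, label):
        assert classify_conservation(score) == label


class TestEcdf:
    def test_two_point_group(self):
        records = pd.DataFrame(
            {"score": [0.2, 0.8], "lca_age": ["Root", "Root"]}
        )
        ecdf = ecdf_by_age(records)["Root"]
        assert list(ecdf.ecdf) == [0.5, 1.0]
        assert list(ecdf.score) == [0.2, 0.8]

    def test_matches_sort_rank_oracle(self, rng):
        scores = rng.uniform(-1, 1, size=40)
        records = pd.DataFrame({"score": scores, "lca_age": "A"})
        ecdf = ecdf_by_age(records)["A"]
        order = np.sort(scores)
        for s, e in zip(ecdf.score, ecdf.ecdf):
            assert e == pytest.approx(np.searchsorted(order, s, side="right") / 40)

    def test_small_group_flagged(self):
        records = pd.DataFrame({"score": [0.5], "lca_age": ["B"]})
        assert ecdf_by_age(records)["B"].flagged.all()


class TestMixingEntropy:
    FREQS = {f"s{i}": 1 / 11 for i in range(11)}

    def test_single_species_entropy_zero(self):
        comp = mixing_entropy(["s0"] * 20, self.FREQS, 11)
        assert comp.entropy == 0.0

    def test_uniform_all_species_entropy_one(self):
        labels = [f"s{i}" for i in range(11)] * 3
        comp = mixing_entropy(labels, self.FREQS, 11)
        assert comp.entropy == pytest.approx(1.0, abs=1e-12)

    def test_two_species_closed_form(self):
        comp = mixing_entropy(["s0"] * 5 + ["s1"] * 5, self.FREQS, 11)
        assert comp.entropy == pytest.approx(np.log(2) / np.log(11), abs=1e-12)

    def test_frequency_correction_rebalances_counts(self):
        # species s0 is globally 9x more common; a 9:1 neighborhood is
        # maximally mixed after correction
        freqs = {"s0": 0.9, "s1": 0.1}
        comp = mixing_entropy(["s0"] * 9 + ["s1"], freqs, 2)
        assert comp.entropy == pytest.approx(1.0, abs=1e-12)

    def test_entropy_bounded(self, rng):
        for _ in range(50):
            k = rng.integers(1, 12)
            labels = [f"s{rng.integers(0, k)}" for _ in range(rng.integers(1, 40))]
            comp = mixing_entropy(labels, self.FREQS, 11)
            assert 0.0 <= comp.entropy <= 1.0 + 1e-12

    def test_empty_neighborhood_rejected(self):
        with pytest.raises(ValueError):
            mixing_entropy([], self.FREQS, 11)

    def test_entropy_bounds_property(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=200, deadline=None, derandomize=True)
        @given(
            counts=st.lists(st.integers(0, 50), min_size=11, max_size=11),
            freqs=st.lists(st.floats(0.01, 1.0), min_size=11, max_size=11),
        )
        def check(counts, freqs):
            if sum(counts) == 0:
                return
            total = sum(freqs)
            gf = {f"s{i}": f / total for i, f in enumerate(freqs)}
            labels = [f"s{i}" for i, c in enumerate(counts) for _ in range(c)]
            comp = mixing_entropy(labels, gf, 11)
            assert -1e-12 <= comp.entropy <= 1 + 1e-12

        check()


class TestKnnNeighborhoods:
    def test_neighborhoods_have_k_members_and_are_deterministic(self, rng):
        from scgenus import knn_neighborhoods

        coords = rng.normal(size=(120, 5))
        nb1 = knn_neighborhoods(coords, k=10, n_neighborhoods=6, seed=0)
        nb2 = knn_neighborhoods(coords, k=10, n_neighborhoods=6, seed=0)
        assert len(nb1) == 6
        assert all(len(n) == 10 for n in nb1)
        assert all(np.array_equal(a, b) for a, b in zip(nb1, nb2))


class TestClusterFlagging:
    def comps(self, entropies):
        from scgenus.comparative_stats import NeighborhoodComposition

        return [
            NeighborhoodComposition(str(i), {}, {}, e) for i, e in enumerate(entropies)
        ]

    def test_median_below_threshold_flagged(self):
        comps = self.comps([0.4, 0.5, 0.6])
        flagged, table = flag_low_mixing_clusters(comps, ["k"] * 3)
        assert flagged == {"k"}
        assert table.median_entropy.iloc[0] == pytest.approx(0.5)

    def test_median_above_threshold_not_flagged(self):
        comps = self.comps([0.5, 0.6, 0.7])
        flagged, _ = flag_low_mixing_clusters(comps, ["k"] * 3)
        assert flagged == set()

    def test_singleton_cluster_median_is_value(self):
        comps = self.comps([0.3])
        flagged, table = flag_low_mixing_clusters(comps, ["solo"])
        assert flagged == {"solo"} and table.median_entropy.iloc[0] == 0.3


def zmat(X, groups, species="spA"):
    obs = pd.DataFrame({"cell_type": groups})
    Z = make_expression_matrix(np.asarray(X, float),
                               [f"c{i}" for i in range(len(groups))],
                               [f"S{j}" for j in range(np.asarray(X).shape[1])],
                               species, obs=obs)
    return Z


class TestWilcoxonMarkers:
    def test_exclusive_expression_is_top_marker(self, rng):
        n = 60
        X = np.zeros((2 * n, 2))
        X[:n, 0] = rng.uniform(1, 2, n)  # set 0 exclusive to group A
        X[:, 1] = rng.uniform(1, 2, 2 * n)
        res = wilcoxon_markers(zmat(X, ["A"] * n + ["B"] * n), lfc_min=0.25)
        a = res[(res.group == "A") & (res.set_id == "S0")]
        assert len(a) == 1
        assert a.log2fc.iloc[0] > 0 and a.significant.iloc[0]

    def test_identical_distributions_not_significant(self, rng):
        X = np.tile(rng.uniform(1, 2, size=(30, 1)), (2, 1))
        res = wilcoxon_markers(zmat(X, ["A"] * 30 + ["B"] * 30), lfc_min=0.0)
        assert not res.significant.any()

    def test_pvalue_matches_exact_rank_sum_enumeration(self, rng):
        # 20-cell toy data, no ties: compare against full enumeration of the
        # rank-sum null distribution
        a = rng.normal(size=8)
        b = rng.normal(loc=1.0, size=12)
        X = np.concatenate([a, b])[:, None]
        res = wilcoxon_markers(
            zmat(X, ["A"] * 8 + ["B"] * 12), lfc_min=-np.inf, pct_min=0.0, only_pos=False
        )
        p_pkg = res[res.group == "A"].pvalue.iloc[0]
        ranks = stats.rankdata(X.ravel())
        observed = ranks[:8].sum()
        null = [
            sum(comb)
            for comb in itertools.combinations(ranks, 8)
        ]
        null = np.array(null)
        mean = null.mean()
        p_exact = np.mean(np.abs(null - mean) >= abs(observed - mean) - 1e-9)
        assert p_pkg == pytest.approx(p_exact, abs=1e-9)

    def test_detection_fraction_filter(self):
        X = np.zeros((100, 1))
        X[0, 0] = 0.1  # detected in 2% of either group
        res = wilcoxon_markers(zmat(X, ["A"] * 50 + ["B"] * 50),
                               lfc_min=-np.inf, pct_min=0.05, only_pos=False)
        assert res.empty

    def test_tiny_group_skipped_with_warning(self):
        X = np.ones((3, 1))
        with pytest.warns(UserWarning, match="fewer than 2"):
            res = wilcoxon_markers(zmat(X, ["A", "B", "B"]), lfc_min=-np.inf, pct_min=0)
        assert set(res.group) == {"B"}


class TestSelectPcCount:
    def test_cumulative_threshold(self):
        fracs = [0.15, 0.04, 0.02, 0.01]
        assert select_pc_count(fracs, target=0.20) == 3

    def test_first_component_sufficient(self):
        assert select_pc_count([0.25, 0.1], target=0.20) == 1

    def test_cap_returned_when_target_unreachable(self):
        fracs = [0.001] * 150
        assert select_pc_count(fracs, target=0.20, cap=100) == 100

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_pc_count([])


class TestCentroidL1:
    def make_Zs(self, rng, species_shift=0.05, type_sep=5.0, n=40, k=30):
        Zs = []
        type_means = {f"t{i}": rng.normal(scale=type_sep, size=k) for i in range(3)}
        for sp in ["a", "b", "c"]:
            shift = rng.normal(scale=species_shift, size=k)
            X, groups = [], []
            for ct, mu in type_means.items():
                X.append(mu + shift + rng.normal(scale=0.1, size=(n, k)))
                groups += [ct] * n
            Zs.append(zmat(np.vstack(X), groups, species=sp))
        return Zs

    def test_within_distances_smaller_than_between(self, rng):
        rep = centroid_l1_analysis(self.make_Zs(rng), n_hvg=30)
        assert rep.within.l1.max() < rep.between.l1.min()

    def test_distances_nonnegative_and_symmetric_pairs_unique(self, rng):
        rep = centroid_l1_analysis(self.make_Zs(rng), n_hvg=30)
        assert (rep.within.l1 >= 0).all() and (rep.between.l1 >= 0).all()
        pairs = set(map(tuple, rep.within[["cell_type", "species_a", "species_b"]].values))
        assert len(pairs) == len(rep.within)

    def test_l1_triangle_inequality_on_centroids(self, rng):
        rep = centroid_l1_analysis(self.make_Zs(rng), n_hvg=30)
        for ct, cents in rep.centroids.items():
            labels = list(cents.index)
            arr = cents.values
            for i, j, k in itertools.permutations(range(len(labels)), 3):
                dij = np.abs(arr[i] - arr[j]).sum()
                djk = np.abs(arr[j] - arr[k]).sum()
                dik = np.abs(arr[i] - arr[k]).sum()
                assert dik <= dij + djk + 1e-9

    def test_single_species_cell_type_flagged(self, rng):
        Zs = self.make_Zs(rng)
        # give species "a" an extra private cell type
        extra = zmat(rng.normal(size=(10, 30)), ["private"] * 10, species="a")
        rep = centroid_l1_analysis(Zs + [extra], n_hvg=30)
        assert "private" in rep.flagged_single_species
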