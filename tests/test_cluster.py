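"""Poisson-deviance K-means, consensus assignment and the library tree."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from _oracles import poisson_deviance_oracle
from sagekit.cluster import (
    PoissonCKMeans,
    amalgamate_groups,
    build_library_tree,
    consensus_cluster,
    dispersion_curve,
    has_clade,
    poissonc_distance,
    select_clustering_tags,
    tree_from_distances,
)
from sagekit.tagproc import TagCountTable, TagMap


class TestDeviance:
    def test_perfect_fit_is_zero(self):
        assert poissonc_distance([2, 2, 2], [1 / 3, 1 / 3, 1 / 3]) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        assert poissonc_distance([4, 0], [0.5, 0.5]) == pytest.approx(4 * np.log(2), rel=1e-12)

    def test_matches_transcription_oracle_on_random_grid(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            x = rng.integers(0, 50, size=3)
            if x.sum() == 0:
                x[0] = 1
            c = rng.dirichlet([1, 1, 1])
            assert poissonc_distance(x, c) == pytest.approx(
                poisson_deviance_oracle(list(x), list(c)), rel=1e-10, abs=1e-12
            )

    def test_scaling_matches_oracle(self):
        x = np.array([3, 7, 1])
        c = np.array([0.3, 0.5, 0.2])
        assert poissonc_distance(10 * x, c) == pytest.approx(
            poisson_deviance_oracle(list(10 * x), list(c)), rel=1e-10
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            poissonc_distance([0, 0, 0], [1 / 3, 1 / 3, 1 / 3])
        with pytest.raises(ValueError):
            poissonc_distance([1, 2, 3], [0.5, 0.4, 0.4])


def _two_group_profiles(n=200, scale=100, seed=0):
    rng = np.random.default_rng(seed)
    groups = np.repeat([0, 1], n // 2)
    shapes = np.array([[0.90, 0.05, 0.05], [0.05, 0.05, 0.90]])
    X = rng.poisson(scale * shapes[groups])
    X[X.sum(axis=1) == 0, 0] = 1
    return X.astype(float), groups


class TestPoissonCKMeans:
    def test_k_equals_n_gives_zero_dispersion(self):
        X, _ = _two_group_profiles(n=30)
        model = PoissonCKMeans(n_clusters=30, random_state=0).fit(X)
        assert model.inertia_ == pytest.approx(0.0, abs=1e-8)

    def test_dispersion_monotone_within_run(self):
        X, _ = _two_group_profiles(n=300, seed=2)
        model = PoissonCKMeans(n_clusters=4, random_state=1).fit(X)
        path = np.asarray(model.inertia_path_)
        assert np.all(np.diff(path) <= 1e-8)
        assert path[-1] <= path[0]

    def test_two_planted_groups_recovered_exactly(self):
        X, groups = _two_group_profiles()
        labels = PoissonCKMeans(n_clusters=2, n_init=3, random_state=0).fit_predict(X)
        assert adjusted_rand_score(groups, labels) == 1.0

    def test_predict_matches_training_assignment(self):
        X, _ = _two_group_profiles(seed=4)
        model = PoissonCKMeans(n_clusters=2, random_state=0).fit(X)
        assert np.array_equal(model.predict(X), model.labels_)

    def test_sklearn_param_interface(self):
        model = PoissonCKMeans(n_clusters=3)
        assert model.get_params()["n_clusters"] == 3
        model.set_params(n_clusters=5)
        assert model.n_clusters == 5

    def test_k_out_of_range(self):
        X, _ = _two_group_profiles(n=10)
        with pytest.raises(ValueError):
            PoissonCKMeans(n_clusters=11).fit(X)


class TestDispersionCurve:
    def test_zero_at_k_equals_n(self):
        X, _ = _two_group_profiles(n=12, seed=5)
        curve, _ = dispersion_curve(X, k_range=[2, 12], seed=0, n_init=2)
        assert curve[12] == pytest.approx(0.0, abs=1e-8)

    def test_elbow_near_planted_k(self):
        rng = np.random.default_rng(6)
        shapes = np.array([
            [0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8],
        ])
        groups = np.repeat([0, 1, 2], 100)
        X = rng.poisson(200 * shapes[groups]).astype(float)
        X[X.sum(axis=1) == 0, 0] = 1
        _, elbow = dispersion_curve(X, k_range=range(2, 8), seed=1, n_init=3)
        assert elbow in (2, 3, 4)


class TestConsensus:
    def test_single_run_equals_plain_fit(self):
        X, _ = _two_group_profiles(seed=7)
        res = consensus_cluster(X, 2, n_runs=1, seed=123)
        assert np.all(res.stability == 1.0)

    def test_separated_groups_fully_stable(self):
        X, groups = _two_group_profiles(seed=8)
        res = consensus_cluster(X, 2, n_runs=20, seed=0)
        assert np.all(res.stability == 1.0)
        assert adjusted_rand_score(groups, res.labels) == 1.0

    def test_consensus_invariant_to_run_label_permutation(self):
        """Alignment undoes arbitrary cluster numbering, so different seeds
        (hence different init orderings) give identical partitions."""
        X, groups = _two_group_profiles(seed=9)
        a = consensus_cluster(X, 2, n_runs=10, seed=1)
        b = consensus_cluster(X, 2, n_runs=10, seed=99)
        assert adjusted_rand_score(a.labels, b.labels) == 1.0


class TestAmalgamation:
    @pytest.mark.parametrize(
        "centroid,group",
        [
            ((0.20, 0.30, 0.50), 1),
            ((0.50, 0.30, 0.20), 2),
            ((0.20, 0.60, 0.20), 3),
            ((0.34, 0.33, 0.33), 4),
            ((0.45, 0.10, 0.45), 5),
        ],
    )
    def test_rule_table(self, centroid, group):
        assert amalgamate_groups([centroid])[0] == group


class TestLibraryTree:
    def test_three_point_branch_lengths(self):
        d = pd.DataFrame(
            [[0.0, 0.2, 0.4], [0.2, 0.0, 0.4], [0.4, 0.4, 0.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        tree = tree_from_distances(d)
        lengths = {t.name: t.length for t in tree.tree.tips()}
        assert lengths["A"] == pytest.approx(0.1, abs=1e-9)
        assert lengths["B"] == pytest.approx(0.1, abs=1e-9)
        assert lengths["C"] == pytest.approx(0.3, abs=1e-9)
        assert tree.newick.endswith(";")

    def test_identical_libraries_zero_distance(self):
        counts = {f"t{i:016d}": 10 + i for i in range(30)}
        other = {f"t{i:016d}": 10 + (i * 7) % 23 for i in range(30)}
        libs = [
            TagCountTable("A", dict(counts)),
            TagCountTable("B", dict(counts)),
            TagCountTable("C", other),
        ]
        tree = build_library_tree(libs)
        assert tree.distances.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)
        assert (tree.distances.values <= 2 + 1e-9).all()
        assert (tree.distances.values >= -1e-9).all()

    def test_constant_library_rejected(self):
        libs = [
            TagCountTable("A", {"T" * 17: 5, "G" * 17: 5}),
            TagCountTable("B", {"T" * 17: 3, "G" * 17: 9}),
            TagCountTable("C", {"T" * 17: 1, "G" * 17: 2}),
        ]
        with pytest.raises(ValueError, match="constant"):
            build_library_tree(libs)

    def test_same_stage_libraries_form_clades(self, balanced_atlas):
        libs = [t for _, t in sorted(balanced_atlas.libraries.items())]
        tree = build_library_tree(libs)
        for stage in balanced_atlas.config.stages:
            members = [
                t.library_id for (_, s), t in balanced_atlas.libraries.items()
                if s == stage
            ]
            assert has_clade(tree.tree, members), stage


class TestSelection:
    def _map(self, classes):
        tmap = TagMap()
        for t, c in classes.items():
            tmap.mapping_class[t] = c
            tmap.hits[t] = [("G_" + t, "+")] if c == "unique_sense" else []
        return tmap

    def test_combined_count_and_mapping_rules(self):
        counts = pd.DataFrame(
            {"AS": [3, 4, 100], "RAD": [3, 4, 100], "CR": [4, 4, 100]},
            index=["at_threshold", "above", "antisense_tag"],
        )
        tmap = self._map({
            "at_threshold": "unique_sense",
            "above": "unique_sense",
            "antisense_tag": "antisense",
        })
        sel = select_clustering_tags(counts, tmap)
        assert list(sel.index) == ["above"]    # sum=10 excluded (strict >10)
        assert sel.loc["above", ["pct_AS", "pct_RAD", "pct_CR"]].sum() == pytest.approx(100.0)
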