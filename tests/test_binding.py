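"""The similarity-based binding predictor and its building blocks."""

import numpy as np
import pytest

from protex.binding import (
    ALL_CATEGORIES,
    DistanceCategory,
    SimilarityBindingClassifier,
    UndecidablePairError,
    category_distance,
    k_nearest,
    related_items,
)


class TestKNearest:
    def test_exact_match_ranks_first(self, rng):
        ids = [f"x{i}" for i in range(10)]
        matrix = rng.normal(size=(10, 4))
        assert k_nearest(matrix[3], ids, matrix, 1, "euclidean") == ["x3"]

    def test_k_equal_store_returns_all(self, rng):
        ids = ["a", "b", "c"]
        matrix = rng.normal(size=(3, 2))
        assert set(k_nearest(np.zeros(2), ids, matrix, 3, "manhattan")) == set(ids)

    def test_k_larger_than_store_errors(self):
        with pytest.raises(ValueError):
            k_nearest(np.zeros(2), ["a"], np.zeros((1, 2)), 2, "euclidean")

    @pytest.mark.parametrize("metric", ["euclidean", "manhattan"])
    def test_matches_full_sort_brute_force(self, rng, metric):
        ids = [f"v{i:02d}" for i in range(50)]
        matrix = rng.normal(size=(50, 6))
        for _ in range(20):
            q = rng.normal(size=6)
            if metric == "euclidean":
                d = np.linalg.norm(matrix - q, axis=1)
            else:
                d = np.abs(matrix - q).sum(axis=1)
            expected = [ids[i] for i in np.argsort(d, kind="stable")[:3]]
            assert k_nearest(q, ids, matrix, 3, metric) == expected

    def test_ties_break_by_stable_id_order(self):
        matrix = np.zeros((4, 2))
        assert k_nearest(np.zeros(2), ["d", "c", "b", "a"], matrix, 2, "euclidean") == ["d", "c"]


class TestRelatedItems:
    def test_one_to_one_pairing_is_bijective(self):
        pairs = [(f"p{i}", f"l{i}") for i in range(5)]
        out = related_items(["p1", "p3"], pairs, "protein")
        assert out == ["l1", "l3"]

    def test_anchor_without_pairs_gives_empty(self):
        assert related_items(["p9"], [("p0", "l0")], "protein") == []

    def test_matches_join_oracle_and_dedupes(self, rng):
        proteins = [f"p{i}" for i in range(8)]
        ligands = [f"l{i}" for i in range(8)]
        pairs = [
            (proteins[rng.integers(8)], ligands[rng.integers(8)]) for _ in range(30)
        ]
        anchors = ["p0", "p3", "p5"]
        out = related_items(anchors, pairs, "protein")
        expected = set(l for p, l in pairs if p in anchors)
        assert set(out) == expected
        assert len(out) == len(set(out))
        # ligand side mirror
        mirror = related_items(["l0", "l1"], pairs, "ligand")
        assert set(mirror) == set(p for p, l in pairs if l in ("l0", "l1"))


class TestCategoryDistance:
    def test_self_distance_is_zero_everywhere(self, rng):
        q = rng.normal(size=5)
        for metric in ("euclidean", "manhattan"):
            for agg in ("cluster_mean", "mean_of_distances"):
                assert category_distance(q, q[None, :], metric, agg) == pytest.approx(0.0)

    def test_singleton_set_makes_aggregations_agree(self, rng):
        q, r = rng.normal(size=4), rng.normal(size=4)
        for metric in ("euclidean", "manhattan"):
            a = category_distance(q, r[None, :], metric, "cluster_mean")
            b = category_distance(q, r[None, :], metric, "mean_of_distances")
            assert a == pytest.approx(b)

    def test_matches_direct_loop_oracle(self, rng):
        q = rng.normal(size=6)
        related = rng.normal(size=(10, 6))
        centroid = related.mean(axis=0)
        assert category_distance(q, related, "euclidean", "cluster_mean") == pytest.approx(
            np.linalg.norm(q - centroid)
        )
        assert category_distance(q, related, "manhattan", "cluster_mean") == pytest.approx(
            np.abs(q - centroid).sum()
        )
        assert category_distance(q, related, "euclidean", "mean_of_distances") == pytest.approx(
            np.mean([np.linalg.norm(q - r) for r in related])
        )
        assert category_distance(q, related, "manhattan", "mean_of_distances") == pytest.approx(
            np.mean([np.abs(q - r).sum() for r in related])
        )

    def test_empty_related_set_errors(self):
        with pytest.raises(ValueError):
            category_distance(np.zeros(3), np.empty((0, 3)), "euclidean", "cluster_mean")


def _toy_binding_problem(rng, offset=40.0, n_per_group=5):
    """Two planted groups in feature space; positives are within-group."""
    pstore, lstore = {}, {}
    pairs, labels = [], []
    for g in range(2):
        for i in range(n_per_group):
            pstore[f"p{g}{i}"] = rng.normal(size=6) + g * offset
            lstore[f"l{g}{i}"] = rng.normal(size=6) + g * offset
    for g in range(2):
        for i in range(n_per_group):
            pairs.append((f"p{g}{i}", f"l{g}{i}"))
            labels.append(1)
    # cross-group negatives
    for i in range(n_per_group):
        pairs.append((f"p0{i}", f"l1{i}"))
        labels.append(0)
        pairs.append((f"p1{i}", f"l0{i}"))
        labels.append(0)
    return pstore, lstore, pairs, np.array(labels)


class TestClassifier:
    def test_eight_categories_exist(self):
        assert len(ALL_CATEGORIES) == 8
        assert len({(c.side, c.metric, c.aggregation) for c in ALL_CATEGORIES}) == 8

    def test_identical_vectors_fit_zero_thresholds(self):
        pstore = {f"p{i}": np.ones(3) for i in range(4)}
        lstore = {f"l{i}": np.ones(3) for i in range(4)}
        pairs = [(f"p{i}", f"l{i}") for i in range(4)]
        y = [1, 1, 1, 0]
        model = SimilarityBindingClassifier(k=3).fit(pairs, y, pstore, lstore)
        assert all(t == pytest.approx(0.0) for t in model.thresholds_.values())

    def test_thresholds_sit_between_within_and_between_scales(self, rng):
        pstore, lstore, pairs, y = _toy_binding_problem(rng)
        model = SimilarityBindingClassifier(k=3).fit(pairs, y, pstore, lstore)
        lvecs = np.array([lstore[l] for l in sorted(lstore)])
        groups = np.array([0] * 5 + [1] * 5)
        d = np.linalg.norm(lvecs[:, None] - lvecs[None, :], axis=2)
        within = d[(groups[:, None] == groups[None, :]) & (d > 0)].mean()
        between = d[groups[:, None] != groups[None, :]].mean()
        for cat, thr in model.thresholds_.items():
            if cat.side == "ligand" and cat.metric == "euclidean":
                assert within < thr < between

    def test_fit_is_deterministic(self, rng):
        pstore, lstore, pairs, y = _toy_binding_problem(rng)
        t1 = SimilarityBindingClassifier(k=3).fit(pairs, y, pstore, lstore).thresholds_
        t2 = SimilarityBindingClassifier(k=3).fit(pairs, y, pstore, lstore).thresholds_
        assert t1 == t2

    def test_stored_positive_pair_predicts_positive(self, rng):
        pstore, lstore, pairs, y = _toy_binding_problem(rng)
        model = SimilarityBindingClassifier(k=3).fit(pairs, y, pstore, lstore)
        assert model.predict_pair(("p00", "l00")) == 1

    def test_far_away_query_predicts_negative(self, rng):
        pstore, lstore, pairs, y = _toy_binding_problem(rng)
        pstore["pfar"] = np.full(6, 1e6)
        lstore["lfar"] = np.full(6, -1e6)
        model = SimilarityBindingClassifier(k=3).fit(pairs, y, pstore, lstore)
        assert model.predict_pair(("pfar", "lfar")) == 0

    def test_heldout_recovery_on_separated_groups(self, rng):
        pstore, lstore, pairs, y = _toy_binding_problem(rng, n_per_group=8)
        model = SimilarityBindingClassifier(k=3).fit(pairs, y, pstore, lstore)
        # unseen within-group pairs should bind, unseen cross-group not
        pos = [(f"p0{i}", f"l0{j}") for i in range(8) for j in range(8) if i != j][:20]
        neg = [(f"p0{i}", f"l1{j}") for i in range(4) for j in range(4, 8)][:20]
        assert np.mean(model.predict(pos) == 1) > 0.8
        assert np.mean(model.predict(neg) == 0) > 0.8

    def test_raising_thresholds_only_flips_toward_positive(self, rng):
        pstore, lstore, pairs, y = _toy_binding_problem(rng)
        model = SimilarityBindingClassifier(k=3).fit(pairs, y, pstore, lstore)
        queries = [(f"p0{i}", f"l1{i}") for i in range(5)] + [(f"p0{i}", f"l0{(i + 1) % 5}") for i in range(5)]
        before = model.predict(queries)
        model.thresholds_ = {c: t * 3.0 for c, t in model.thresholds_.items()}
        after = model.predict(queries)
        assert not ((before == 1) & (after == 0)).any()

    def test_uniform_feature_scaling_leaves_votes_unchanged(self, rng):
        pstore, lstore, pairs, y = _toy_binding_problem(rng)
        queries = [(f"p{g}{i}", f"l{1 - g}{i}") for g in range(2) for i in range(5)]
        m1 = SimilarityBindingClassifier(k=3).fit(pairs, y, pstore, lstore)
        scale = 7.5
        m2 = SimilarityBindingClassifier(k=3).fit(
            pairs, y, {k: v * scale for k, v in pstore.items()}, {k: v * scale for k, v in lstore.items()}
        )
        np.testing.assert_array_equal(m1.predict(queries), m2.predict(queries))
        for cat in m1.thresholds_:
            assert m2.thresholds_[cat] == pytest.approx(scale * m1.thresholds_[cat])

    def test_undecidable_when_no_side_has_related_structures(self, rng):
        # the only positive protein/ligand is far from the query's neighbors
        pstore = {"p0": np.zeros(2), "p1": np.full(2, 100.0), "p2": np.full(2, 101.0), "p3": np.full(2, 102.0)}
        lstore = {"l0": np.zeros(2), "l1": np.full(2, 100.0), "l2": np.full(2, 101.0), "l3": np.full(2, 102.0)}
        pairs = [("p0", "l0"), ("p1", "l1"), ("p2", "l2"), ("p3", "l3")]
        y = [1, 0, 0, 0]
        model = SimilarityBindingClassifier(k=3).fit(pairs, y, pstore, lstore)
        pstore["pq"] = np.full(2, 101.5)
        lstore["lq"] = np.full(2, 101.5)
        model._protein_features["pq"] = pstore["pq"]
        model._ligand_features["lq"] = lstore["lq"]
        with pytest.raises(UndecidablePairError):
            model.predict_pair(("pq", "lq"))
        np.testing.assert_array_equal(model.predict([("pq", "lq")], undecidable=0), [0])

    def test_two_vote_side_scheme_supported(self, rng):
        pstore, lstore, pairs, y = _toy_binding_problem(rng)
        model = SimilarityBindingClassifier(k=3, vote_scheme="sides").fit(pairs, y, pstore, lstore)
        assert model.predict_pair(("p00", "l00")) in (0, 1)

    def test_opposite_label_protocol_requires_negatives(self, rng):
        pstore, lstore, pairs, y = _toy_binding_problem(rng)
        only_pos = [p for p, lab in zip(pairs, y) if lab == 1]
        with pytest.raises(ValueError, match="negative"):
            SimilarityBindingClassifier(threshold_protocol="opposite").fit(
                only_pos, np.ones(len(only_pos)), pstore, lstore
            )

    def test_category_validation(self):
        with pytest.raises(ValueError):
            DistanceCategory("ligand", "cosine", "cluster_mean")
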