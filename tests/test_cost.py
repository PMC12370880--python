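import numpy as np
import pandas as pd
import pytest

from scalemap import (
    NicheAssignment,
    SignalMatrix,
    build_cost_stack,
    composition_similarity,
    cost_diagnostics,
    custom_similarity,
    feature_similarity,
    filter_candidates,
    frequency_aware_jaccard,
    label_similarity,
    niche_similarity,
    pair_poc,
    parse_metrics,
    territory_similarity,
)
from scalemap import expression_signal, extract_niches, niche_signal, territory_signal

from conftest import make_dataset


def signal(values, features=None, level="cell"):
    values = np.asarray(values, dtype=float)
    features = features or [f"g{i}" for i in range(values.shape[0])]
    return SignalMatrix(
        level=level,
        values=values,
        feature_ids=features,
        barcodes=[f"c{i}" for i in range(values.shape[1])],
    )


def pearson_two_pass(x, y):
    """Textbook two-pass correlation, independent of the implementation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


class TestFeatureSimilarity:
    def test_identical_vectors_score_one(self):
        s = feature_similarity(signal([[1], [2], [3]]), signal([[1], [2], [3]]))
        assert s.scores[0, 0] == pytest.approx(1.0)

    def test_reversed_vector_scores_minus_one(self):
        s = feature_similarity(signal([[1], [2], [3]]), signal([[3], [2], [1]]))
        assert s.scores[0, 0] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        q, r = [1.0, 2.0, 3.0], [1.0, 2.0, 4.0]
        s = feature_similarity(signal(np.array([q]).T), signal(np.array([r]).T))
        assert s.scores[0, 0] == pytest.approx(pearson_two_pass(q, r), abs=1e-12)

    def test_random_matrix_matches_pairwise_oracle(self, rng):
        qv, rv = rng.normal(size=(6, 4)), rng.normal(size=(6, 5))
        s = feature_similarity(signal(qv), signal(rv))
        for i in range(4):
            for j in range(5):
                assert s.scores[i, j] == pytest.approx(
                    pearson_two_pass(qv[:, i], rv[:, j]), abs=1e-10
                )

    def test_shared_feature_intersection_used(self, rng):
        qv = signal(rng.normal(size=(4, 3)), features=["a", "b", "c", "d"])
        rv = signal(rng.normal(size=(3, 3)), features=["d", "b", "z"])
        s = feature_similarity(qv, rv)
        oq = qv.restrict_features(["b", "d"]).values
        orf = rv.restrict_features(["b", "d"]).values
        assert s.scores[0, 0] == pytest.approx(
            pearson_two_pass(oq[:, 0], orf[:, 0]), abs=1e-10
        )

    def test_too_few_shared_features_fails(self):
        with pytest.raises(ValueError, match="shared features"):
            feature_similarity(
                signal(np.ones((2, 1)), features=["a", "b"]),
                signal(np.ones((2, 1)), features=["c", "d"]),
            )

    def test_constant_column_scores_zero_with_warning(self, rng):
        qv = np.column_stack([np.full(5, 3.0), rng.normal(size=5)])
        with pytest.warns(RuntimeWarning, match="constant"):
            s = feature_similarity(signal(qv), signal(rng.normal(size=(5, 2))))
        np.testing.assert_allclose(s.scores[0], 0.0)


class TestDerivedSimilarities:
    def test_niche_similarity_is_feature_similarity_of_niche_signals(self, rng):
        q = make_dataset(n_genes=8, n_cells=12, normalized=True, seed=1)
        r = make_dataset(n_genes=8, n_cells=10, normalized=True, seed=2)
        qn = niche_signal(q, extract_niches(q, k=3), expression_signal(q))
        rn = niche_signal(r, extract_niches(r, k=3), expression_signal(r))
        s = niche_similarity(qn, rn)
        oracle = feature_similarity(qn, rn)
        np.testing.assert_allclose(s.scores, oracle.scores)
        assert s.metric == "niche"

    def test_territory_similarity_block_constant(self, rng):
        q = make_dataset(n_genes=8, n_cells=9, normalized=True, seed=3)
        r = make_dataset(n_genes=8, n_cells=9, normalized=True, seed=4)
        qlab = rng.choice(["A", "B"], 9).astype(object)
        rlab = rng.choice(["X", "Y", "Z"], 9).astype(object)
        q = q.with_(territory_labels=qlab)
        r = r.with_(territory_labels=rlab)
        s = territory_similarity(
            territory_signal(q, expression_signal(q)),
            territory_signal(r, expression_signal(r)),
        )
        # score depends only on the (query territory, ref territory) pair
        for tq in np.unique(qlab):
            for tr in np.unique(rlab):
                block = s.scores[np.ix_(qlab == tq, rlab == tr)]
                np.testing.assert_allclose(block, block.flat[0])

    def test_single_territory_pair_is_constant_matrix(self):
        q = make_dataset(n_genes=5, n_cells=4, normalized=True, seed=5)
        r = make_dataset(n_genes=5, n_cells=6, normalized=True, seed=6)
        q = q.with_(territory_labels=np.array(["T"] * 4, dtype=object))
        r = r.with_(territory_labels=np.array(["U"] * 6, dtype=object))
        s = territory_similarity(
            territory_signal(q, expression_signal(q)),
            territory_signal(r, expression_signal(r)),
        )
        assert np.unique(np.round(s.scores, 12)).size == 1


class TestFrequencyAwareJaccard:
    def test_identical_multisets(self):
        assert frequency_aware_jaccard(["A", "A", "B"], ["B", "A", "A"]) == 1.0

    def test_disjoint_label_sets(self):
        assert frequency_aware_jaccard(["A", "A"], ["B", "C"]) == 0.0

    def test_hand_enumerated_uniquification_rule(self):
        # {A,A,B} -> {A, A.1, B}; {A,B,B} -> {A, B, B.1}; |∩|=2, |∪|=4
        assert frequency_aware_jaccard(["A", "A", "B"], ["A", "B", "B"]) == pytest.approx(0.5)

    def test_semimetric_properties(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        labels = st.lists(st.sampled_from("ABC"), min_size=1, max_size=6)

        @settings(max_examples=50, derandomize=True)
        @given(a=labels, b=labels)
        def check(a, b):
            j = frequency_aware_jaccard(a, b)
            assert 0.0 <= j <= 1.0
            assert j == pytest.approx(frequency_aware_jaccard(b, a))
            if sorted(a) == sorted(b):
                assert j == pytest.approx(1.0)

        check()

    def test_matches_counter_oracle(self, rng):
        from collections import Counter

        for _ in range(20):
            a = list(rng.choice(list("ABCD"), rng.integers(1, 8)))
            b = list(rng.choice(list("ABCD"), rng.integers(1, 8)))
            ca, cb = Counter(a), Counter(b)
            keys = set(ca) | set(cb)
            inter = sum(min(ca[k], cb[k]) for k in keys)
            union = sum(max(ca[k], cb[k]) for k in keys)
            assert frequency_aware_jaccard(a, b) == pytest.approx(inter / union)


class TestCompositionAndLabel:
    def composition_pair(self):
        q = make_dataset(n_cells=3, seed=1).with_(
            cell_labels=np.array(["A", "A", "B"], dtype=object)
        )
        r = make_dataset(n_cells=3, seed=2).with_(
            cell_labels=np.array(["A", "B", "B"], dtype=object)
        )
        # every niche covers the whole 3-cell sample
        full = NicheAssignment("knn", 2, [[1, 2], [0, 2], [0, 1]], include_center=True)
        return q, r, full

    def test_whole_sample_niches_score_hand_value(self):
        q, r, full = self.composition_pair()
        s = composition_similarity(q, r, full, full)
        np.testing.assert_allclose(s.scores, 0.5)

    def test_missing_labels_fail(self):
        q, r, full = self.composition_pair()
        with pytest.raises(ValueError):
            composition_similarity(q.with_(cell_labels=None), r, full, full)

    def test_label_similarity_matches_outer_equality(self, rng):
        q = make_dataset(n_cells=7, with_labels=True, seed=1)
        r = make_dataset(n_cells=5, with_labels=True, seed=2)
        s = label_similarity(q, r)
        oracle = np.equal.outer(q.cell_labels, r.cell_labels).astype(float)
        np.testing.assert_array_equal(s.scores, oracle)


class TestCostStack:
    def stack_from(self, score_list, nq=2, nr=2):
        mats = [
            custom_similarity(np.full((nq, nr), s), (-1.0, 1.0), metric=f"m{i}")
            for i, s in enumerate(score_list)
        ]
        return build_cost_stack(
            mats, [f"q{i}" for i in range(nq)], [f"r{j}" for j in range(nr)]
        )

    def test_perfect_scores_give_zero_cost(self):
        assert self.stack_from([1.0, 1.0, 1.0]).total_cost.max() == 0.0

    def test_zero_scores_cost_equals_matrix_count(self):
        np.testing.assert_allclose(self.stack_from([0.0] * 4).total_cost, 4.0)

    def test_mixed_scores_sum_reciprocals(self):
        np.testing.assert_allclose(self.stack_from([0.4, 1.0]).total_cost, 0.6)

    def test_dimension_mismatch_fails(self):
        a = custom_similarity(np.zeros((2, 2)), (0, 1), "a")
        b = custom_similarity(np.zeros((2, 3)), (0, 1), "b")
        with pytest.raises(ValueError):
            build_cost_stack([a, b], ["q0", "q1"], ["r0", "r1"])

    def test_total_recomputable_from_matrices(self, rng):
        mats = [
            custom_similarity(rng.uniform(-1, 1, (4, 5)), (-1, 1), f"m{i}")
            for i in range(3)
        ]
        stack = build_cost_stack(
            mats, [f"q{i}" for i in range(4)], [f"r{j}" for j in range(5)]
        )
        recomputed = sum(1.0 - m.scores for m in stack.matrices.values())
        np.testing.assert_allclose(stack.total_cost, recomputed, atol=1e-12)

    def test_parse_metrics_letterwise(self):
        assert parse_metrics("fncty") == [
            "feature",
            "niche",
            "composition",
            "territory",
            "label",
        ]
        with pytest.raises(ValueError):
            parse_metrics("fx")


class TestFiltering:
    def make_stack(self, scores, labels=None):
        mats = [custom_similarity(np.asarray(scores), (-1, 1), "feature")]
        if labels is not None:
            mats.append(custom_similarity(np.asarray(labels), (0, 1), "label"))
        nq, nr = np.asarray(scores).shape
        return build_cost_stack(
            mats, [f"q{i}" for i in range(nq)], [f"r{j}" for j in range(nr)]
        )

    def test_low_threshold_removes_nothing(self):
        stack = self.make_stack([[0.5, 0.2], [0.3, 0.4]])
        out = filter_candidates(stack, threshold=0.1)
        assert list(out.active_query) == [0, 1]

    def test_label_absent_from_reference_dropped(self):
        # query 1's label matches no reference cell (row of zeros)
        stack = self.make_stack(
            [[0.99, 0.99], [0.99, 0.99]], labels=[[1.0, 0.0], [0.0, 0.0]]
        )
        out = filter_candidates(stack, threshold=0.9, use_label_filter=True)
        assert list(out.active_query) == [0]

    def test_removal_matches_row_max_oracle(self, rng):
        scores = rng.uniform(0, 1, (20, 10))
        stack = self.make_stack(scores)
        out = filter_candidates(stack, threshold=0.9)
        expected = np.flatnonzero(scores.max(axis=1) > 0.9)
        np.testing.assert_array_equal(out.active_query, expected)

    def test_all_queries_filtered_fails(self):
        stack = self.make_stack([[0.1, 0.2], [0.1, 0.2]])
        with pytest.raises(ValueError, match="every query"):
            filter_candidates(stack, threshold=0.95)


class TestDiagnostics:
    def pairs(self, n=2):
        return pd.DataFrame(
            {
                "query_barcode": [f"q{i}" for i in range(n)],
                "ref_barcode": [f"r{i}" for i in range(n)],
            }
        )

    def test_single_metric_poc_is_one(self):
        mats = [custom_similarity(np.array([[0.5, 0.9], [0.2, 0.8]]), (0, 1), "feature")]
        stack = build_cost_stack(mats, ["q0", "q1"], ["r0", "r1"])
        poc = pair_poc(stack, self.pairs())
        np.testing.assert_allclose(poc["poc_feature"], 1.0)

    def test_constant_matrix_cv_zero(self):
        mats = [custom_similarity(np.full((2, 2), 0.4), (0, 1), "feature")]
        stack = build_cost_stack(mats, ["q0", "q1"], ["r0", "r1"])
        diag = cost_diagnostics(stack, self.pairs())
        assert diag.loc[0, "cv"] == pytest.approx(0.0)

    def test_contribution_ratios(self):
        # pair (q0, r0): contributions 0.3 and 0.1 -> POCs 0.75 / 0.25
        a = custom_similarity(np.array([[0.7]]), (0, 1), "feature")
        b = custom_similarity(np.array([[0.9]]), (0, 1), "niche")
        stack = build_cost_stack([a, b], ["q0"], ["r0"])
        poc = pair_poc(stack, self.pairs(1))
        assert poc["poc_feature"][0] == pytest.approx(0.75)
        assert poc["poc_niche"][0] == pytest.approx(0.25)

    def test_zero_cost_pairs_excluded_with_count(self):
        a = custom_similarity(np.array([[1.0, 0.5], [0.6, 1.0]]), (0, 1), "feature")
        stack = build_cost_stack([a], ["q0", "q1"], ["r0", "r1"])
        diag = cost_diagnostics(stack, self.pairs())  # both pairs on the diagonal
        assert diag.loc[0, "n_zero_cost_excluded"] == 2

    def test_poc_sums_to_one_on_random_stacks(self, rng):
        mats = [
            custom_similarity(rng.uniform(-1, 0.99, (6, 7)), (-1, 1), f"m{i}")
            for i in range(4)
        ]
        stack = build_cost_stack(
            mats, [f"q{i}" for i in range(6)], [f"r{j}" for j in range(7)]
        )
        pairs = pd.DataFrame(
            {
                "query_barcode": [f"q{i}" for i in range(6)],
                "ref_barcode": [f"r{j}" for j in rng.integers(0, 7, 6)],
            }
        )
        poc = pair_poc(stack, pairs)
        sums = poc[[c for c in poc.columns if c.startswith("poc_")]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
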