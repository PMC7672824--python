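import io
import math

import numpy as np
import pytest

from goknn.ontology import ancestors, close_annotations
from goknn.predictor import (
    KnnConfig,
    Neighbor,
    TermScores,
    TrainingIndex,
    blast_baseline,
    dynamic_distance_threshold,
    funoverlap_weight,
    hybrid_neighbors,
    naive_baseline,
    nearest_neighbors_dynamic,
    nearest_neighbors_fixed,
    normalize_scores,
    predict,
    predict_all,
    propagate_scores,
    read_cafa_predictions,
    read_funfam_assignments,
    vote,
    voting_weight,
    write_cafa_predictions,
)
from goknn.reduction import ReducedVector

from conftest import GO, random_dag


def make_index(rng, n, dim=3):
    vecs = [
        ReducedVector(f"t{i:03d}", rng.normal(size=dim)) for i in range(n)
    ]
    return vecs, TrainingIndex(vecs)


def brute_force_sorted(query, vectors):
    pairs = [
        (float(np.linalg.norm(v.coordinates - query.coordinates)), v.protein_id)
        for v in vectors
    ]
    return sorted(pairs)


def assert_neighbors_match(neighbors, expected_pairs, atol=1e-9):
    assert [n.protein_id for n in neighbors] == [p for _, p in expected_pairs]
    np.testing.assert_allclose(
        [n.distance for n in neighbors], [d for d, _ in expected_pairs], atol=atol
    )


def propagate_oracle(raw, dag, mode):
    """Memoized recursion over direct children, independent of module order."""
    memo = {}

    def score(term):
        if term in memo:
            return memo[term]
        own = raw.get(term, 0.0)
        kids = [score(c) for c in dag.children(term)]
        kids = [k for k in kids if k > 0]
        value = max([own, *kids]) if mode == "max" else own + sum(kids)
        memo[term] = value
        return value

    return {t: score(t) for t in dag.terms if score(t) > 0}


class TestFixedKnn:
    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vecs, index = make_index(rng, int(rng.integers(2, 30)))
        query = ReducedVector("q", rng.normal(size=3))
        k = int(rng.integers(1, len(vecs) + 1))
        result = nearest_neighbors_fixed(query, index, k)
        assert_neighbors_match(result, brute_force_sorted(query, vecs)[:k])

    def test_k1_equals_one_nn(self):
        rng = np.random.default_rng(0)
        vecs, index = make_index(rng, 10)
        query = ReducedVector("q", rng.normal(size=3))
        assert (
            nearest_neighbors_fixed(query, index, 1)[0].protein_id
            == brute_force_sorted(query, vecs)[0][1]
        )

    def test_ties_broken_by_ascending_protein_id(self):
        vecs = [
            ReducedVector("b", np.array([1.0, 0.0])),
            ReducedVector("a", np.array([-1.0, 0.0])),
            ReducedVector("c", np.array([0.0, 1.0])),
        ]
        result = nearest_neighbors_fixed(
            ReducedVector("q", np.zeros(2)), TrainingIndex(vecs), 2
        )
        assert [n.protein_id for n in result] == ["a", "b"]

    def test_k_too_large_rejected(self):
        rng = np.random.default_rng(1)
        _, index = make_index(rng, 3)
        with pytest.raises(ValueError):
            nearest_neighbors_fixed(ReducedVector("q", np.zeros(3)), index, 4)


class TestDynamicThreshold:
    def test_constant_nn_distances_give_that_constant(self):
        # four points on a unit-spaced line wrapped far apart pairwise:
        # use two tight pairs so every nearest-neighbor distance is 1
        vecs = [
            ReducedVector("a", np.array([0.0])),
            ReducedVector("b", np.array([1.0])),
            ReducedVector("c", np.array([100.0])),
            ReducedVector("d", np.array([101.0])),
        ]
        index = TrainingIndex(vecs)
        for q in ("Q1", "Q2", "Q3"):
            assert dynamic_distance_threshold(index, q) == pytest.approx(1.0)

    def test_linear_interpolation_quantile(self):
        # NN-distance multiset {1, 2, 3, 4} -> Q2 = 2.5
        vecs = [
            ReducedVector("a", np.array([0.0, 0.0])),
            ReducedVector("b", np.array([1.0, 0.0])),
            ReducedVector("c", np.array([0.0, 50.0])),
            ReducedVector("d", np.array([2.0, 50.0])),
            ReducedVector("e", np.array([100.0, 0.0])),
            ReducedVector("f", np.array([103.0, 0.0])),
            ReducedVector("g", np.array([100.0, 50.0])),
            ReducedVector("h", np.array([104.0, 50.0])),
        ]
        index = TrainingIndex(vecs)
        nn = sorted(
            min(
                np.linalg.norm(v.coordinates - w.coordinates)
                for w in vecs
                if w.protein_id != v.protein_id
            )
            for v in vecs
        )
        assert nn == [1, 1, 2, 2, 3, 3, 4, 4]
        assert dynamic_distance_threshold(index, "Q2") == pytest.approx(2.5)

    def test_requires_two_proteins(self):
        index = TrainingIndex([ReducedVector("a", np.zeros(2))])
        with pytest.raises(ValueError):
            dynamic_distance_threshold(index, "Q2")


class TestDynamicKnn:
    @pytest.mark.parametrize("seed", range(25))
    def test_matches_strict_filter_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vecs, index = make_index(rng, int(rng.integers(2, 30)))
        query = ReducedVector("q", rng.normal(size=3))
        threshold = float(rng.uniform(0.5, 3.0))
        result = nearest_neighbors_dynamic(query, index, threshold)
        expected = [p for p in brute_force_sorted(query, vecs) if p[0] < threshold]
        assert_neighbors_match(result, expected)

    def test_threshold_below_all_distances_gives_empty(self):
        rng = np.random.default_rng(2)
        _, index = make_index(rng, 5)
        query = ReducedVector("q", rng.normal(size=3) + 100)
        assert nearest_neighbors_dynamic(query, index, 0.01) == []

    def test_five_points_inside_radius_selected(self):
        # five tight points around the query plus distant ones
        vecs = [ReducedVector(f"n{i}", np.array([0.1 * i, 0.0])) for i in range(5)]
        vecs += [ReducedVector(f"f{i}", np.array([50.0 + i, 0.0])) for i in range(4)]
        result = nearest_neighbors_dynamic(
            ReducedVector("q", np.zeros(2)), TrainingIndex(vecs), 1.0
        )
        assert sorted(n.protein_id for n in result) == [f"n{i}" for i in range(5)]


class TestHybridKnn:
    def test_dense_query_equals_dynamic(self):
        rng = np.random.default_rng(3)
        vecs, index = make_index(rng, 20)
        query = ReducedVector("q", vecs[0].coordinates + 0.01)
        threshold = 2.0
        dyn = nearest_neighbors_dynamic(query, index, threshold)
        assert dyn
        assert hybrid_neighbors(query, index, 3, threshold) == dyn

    def test_isolated_query_falls_back_to_fixed(self):
        rng = np.random.default_rng(4)
        vecs, index = make_index(rng, 20)
        query = ReducedVector("q", rng.normal(size=3) + 1000)
        assert hybrid_neighbors(query, index, 3, 0.5) == nearest_neighbors_fixed(
            query, index, 3
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_hybrid_covers_every_query_dynamic_does_not(self, seed):
        rng = np.random.default_rng(seed)
        vecs, index = make_index(rng, 15)
        queries = [ReducedVector(f"q{i}", rng.normal(size=3) * 5) for i in range(10)]
        threshold = dynamic_distance_threshold(index, "Q1")
        dyn_cov = sum(bool(nearest_neighbors_dynamic(q, index, threshold)) for q in queries)
        hyb_cov = sum(bool(hybrid_neighbors(q, index, 3, threshold)) for q in queries)
        assert hyb_cov == len(queries)
        assert dyn_cov <= hyb_cov


class TestVotingWeight:
    def test_printed_formulas(self):
        assert voting_weight(7.3, "equal") == 1.0
        assert voting_weight(2.0, "inverse") == 0.5
        assert voting_weight(4.0, "sqrt_inverse") == 0.5

    def test_zero_distance_clamped_finite(self):
        w = voting_weight(0.0, "inverse")
        assert math.isfinite(w) and w == pytest.approx(1e9)


class TestFunOverlap:
    def test_identical_sets_give_one(self):
        assert funoverlap_weight({"f1", "f2"}, {"f1", "f2"}) == 1.0

    def test_disjoint_or_empty_excluded(self):
        assert funoverlap_weight({"f1"}, {"f2"}) is None
        assert funoverlap_weight(set(), {"f1"}) is None
        assert funoverlap_weight({"f1"}, set()) is None

    def test_jaccard_and_asymmetric_variants(self):
        assert funoverlap_weight({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)
        assert funoverlap_weight({"a", "b"}, {"b", "c"}, asymmetric=True) == 0.5

    def test_assignment_reader_applies_evalue_filter(self):
        text = "p1\tf1\t1e-9\np1\tf2\t1e-3\np2\tf3\t1e-5\n"
        ff = read_funfam_assignments(io.StringIO(text))
        assert ff == {"p1": {"f1"}, "p2": {"f3"}}


class TestVote:
    def test_single_neighbor_scores_all_its_terms(self):
        ann = {"n1": {GO[4], GO[5]}}
        scores = vote([Neighbor("n1", 0.5, 1.0)], ann)
        assert scores.scores == {GO[4]: 1.0, GO[5]: 1.0}

    def test_toy_child_weights_feeding_the_parent(self):
        # three neighbors voting leaves under GO:2 with weights summing to
        # 2.3 on GO:4 and 1.2 on GO:5
        neighbors = [
            Neighbor("n1", 1.0, 1.1),
            Neighbor("n2", 1.0, 1.2),
            Neighbor("n3", 1.0, 1.2),
        ]
        ann = {"n1": {GO[4]}, "n2": {GO[4]}, "n3": {GO[5]}}
        scores = vote(neighbors, ann)
        assert scores.scores[GO[4]] == pytest.approx(2.3)
        assert scores.scores[GO[5]] == pytest.approx(1.2)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_nested_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        terms = [f"GO:{i:07d}" for i in range(1, 20)]
        ann = {
            f"n{i}": {str(t) for t in rng.choice(terms, size=rng.integers(1, 6))}
            for i in range(8)
        }
        neighbors = [
            Neighbor(f"n{i}", float(rng.uniform(0.1, 2)), float(rng.uniform(0.1, 3)))
            for i in range(8)
        ]
        result = vote(neighbors, ann).scores
        expected = {}
        for nb in neighbors:
            for t in ann[nb.protein_id]:
                expected[t] = expected.get(t, 0.0) + nb.weight
        assert set(result) == set(expected)
        for t in expected:
            assert result[t] == pytest.approx(expected[t], abs=1e-12)

    def test_unknown_neighbor_named_in_error(self):
        with pytest.raises(KeyError, match="ghost"):
            vote([Neighbor("ghost", 1.0, 1.0)], {})


class TestPropagation:
    def test_sum_merges_children_weights(self, toy_dag):
        raw = TermScores({GO[4]: 2.3, GO[5]: 1.2})
        out = propagate_scores(raw, toy_dag, "sum")
        assert out.scores[GO[2]] == pytest.approx(3.5)

    def test_max_takes_strongest_child(self, toy_dag):
        raw = TermScores({GO[4]: 2.3, GO[5]: 1.2})
        out = propagate_scores(raw, toy_dag, "max")
        assert out.scores[GO[2]] == pytest.approx(2.3)

    def test_flat_dag_unchanged_below_root(self, toy_dag):
        raw = TermScores({GO[4]: 1.0, GO[6]: 2.0})
        for mode in ("sum", "max"):
            out = propagate_scores(raw, toy_dag, mode)
            assert out.scores[GO[4]] == 1.0
            assert out.scores[GO[6]] == 2.0

    @pytest.mark.parametrize("mode", ["sum", "max"])
    @pytest.mark.parametrize("seed", range(13))
    def test_matches_recursive_oracle_on_random_dags(self, mode, seed):
        rng = np.random.default_rng(seed)
        dag = random_dag(rng, int(rng.integers(5, 50)))
        ids = list(dag.terms)
        raw = {
            str(t): float(rng.uniform(0.1, 3))
            for t in rng.choice(ids, size=min(8, len(ids)), replace=False)
        }
        out = propagate_scores(TermScores(raw), dag, mode).scores
        expected = propagate_oracle(raw, dag, mode)
        assert set(out) == set(expected)
        for t in expected:
            assert out[t] == pytest.approx(expected[t], abs=1e-9)

    @pytest.mark.parametrize("mode", ["sum", "max"])
    def test_hierarchy_consistency_parent_geq_child(self, mode):
        rng = np.random.default_rng(99)
        for _ in range(100):
            dag = random_dag(rng, int(rng.integers(5, 40)))
            ids = list(dag.terms)
            raw = {
                str(t): float(rng.uniform(0.1, 3))
                for t in rng.choice(ids, size=min(6, len(ids)), replace=False)
            }
            out = propagate_scores(TermScores(raw), dag, mode).scores
            for term, score in out.items():
                for parent in dag.parents(term):
                    assert out[parent] >= score - 1e-12

    def test_unique_descendants_counts_diamond_once(self):
        from goknn.ontology import GoDag, GoTerm

        ns = "BPO"
        diamond = GoDag(
            [
                GoTerm(id=GO[1], namespace=ns),
                GoTerm(id=GO[2], namespace=ns, parents=frozenset({GO[1]})),
                GoTerm(id=GO[3], namespace=ns, parents=frozenset({GO[1]})),
                GoTerm(id=GO[4], namespace=ns, parents=frozenset({GO[2], GO[3]})),
            ]
        )
        raw = TermScores({GO[4]: 1.0})
        per_path = propagate_scores(raw, diamond, "sum")
        once = propagate_scores(raw, diamond, "sum", unique_descendants=True)
        assert per_path.scores[GO[1]] == pytest.approx(2.0)  # both paths
        assert once.scores[GO[1]] == pytest.approx(1.0)

    def test_unknown_scored_term_rejected(self, toy_dag):
        with pytest.raises(KeyError):
            propagate_scores(TermScores({"GO:0009999": 1.0}), toy_dag, "sum")


class TestNormalize:
    def test_equal_scores_all_become_one(self):
        out = normalize_scores(TermScores({GO[2]: 2.0, GO[3]: 2.0}))
        assert out.scores == {GO[2]: 1.0, GO[3]: 1.0}

    def test_division_by_maximum(self):
        out = normalize_scores(TermScores({GO[2]: 3.5, GO[4]: 2.3, GO[5]: 1.2}))
        assert out.scores[GO[2]] == 1.0
        assert out.scores[GO[4]] == pytest.approx(2.3 / 3.5)
        assert out.scores[GO[5]] == pytest.approx(1.2 / 3.5)

    def test_idempotent(self):
        once = normalize_scores(TermScores({GO[2]: 3.5, GO[4]: 2.3}))
        twice = normalize_scores(once)
        assert twice.scores == once.scores

    def test_all_zero_warns_and_empties(self):
        with pytest.warns(UserWarning):
            out = normalize_scores(TermScores({GO[2]: 0.0}))
        assert out.scores == {}


class TestPredict:
    def setup_benchmark(self, rng, toy_dag):
        centers = {0: np.array([0.0, 0.0]), 1: np.array([10.0, 10.0])}
        leaves = {0: GO[4], 1: GO[6]}
        vecs, ann = [], {}
        for i in range(10):
            c = i % 2
            pid = f"t{i:03d}"
            vecs.append(ReducedVector(pid, centers[c] + rng.normal(0, 0.1, 2)))
            ann[pid] = {leaves[c]}
        return vecs, close_annotations(toy_dag, ann)

    def test_one_nn_transfers_closed_set_with_score_one(self, toy_dag):
        rng = np.random.default_rng(0)
        vecs, closed = self.setup_benchmark(rng, toy_dag)
        index = TrainingIndex(vecs)
        query = ReducedVector("q", np.array([0.05, 0.0]))
        scores = predict(query, index, closed, toy_dag, KnnConfig(mode="one_nn"))
        nearest = nearest_neighbors_fixed(query, index, 1)[0]
        assert set(scores.scores) == closed[nearest.protein_id]
        assert all(v == 1.0 for v in scores.scores.values())

    def test_fixed_k1_equal_weights_reproduces_one_nn_terms(self, toy_dag):
        rng = np.random.default_rng(1)
        vecs, closed = self.setup_benchmark(rng, toy_dag)
        index = TrainingIndex(vecs)
        query = ReducedVector("q", np.array([9.9, 10.2]))
        one = predict(query, index, closed, toy_dag, KnnConfig(mode="one_nn"))
        fixed = predict(
            query, index, closed, toy_dag,
            KnnConfig(mode="fixed", k=1, weight_scheme="equal"),
        )
        assert set(fixed.scores) == set(one.scores)

    def test_dynamic_empty_neighborhood_returns_none(self, toy_dag):
        rng = np.random.default_rng(2)
        vecs, closed = self.setup_benchmark(rng, toy_dag)
        query = ReducedVector("q", np.array([500.0, 500.0]))
        scores = predict(
            query, TrainingIndex(vecs), closed, toy_dag,
            KnnConfig(mode="dynamic", quartile="Q2"), threshold=0.5,
        )
        assert scores is None

    def test_predictions_exclude_roots_and_max_is_one(self, toy_dag):
        rng = np.random.default_rng(3)
        vecs, closed = self.setup_benchmark(rng, toy_dag)
        query = ReducedVector("q", np.array([0.0, 0.1]))
        scores = predict(
            query, TrainingIndex(vecs), closed, toy_dag,
            KnnConfig(mode="fixed", k=5, weight_scheme="inverse"),
        )
        assert GO[1] not in scores.scores
        assert max(scores.scores.values()) == 1.0
        assert all(0 < v <= 1 for v in scores.scores.values())

    def test_pipeline_composes_individual_operations(self, toy_dag):
        """End-to-end fixed-KNN equals chaining the step oracles by hand."""
        rng = np.random.default_rng(4)
        vecs, closed = self.setup_benchmark(rng, toy_dag)
        index = TrainingIndex(vecs)
        query = ReducedVector("q", np.array([0.1, -0.1]))
        cfg = KnnConfig(mode="fixed", k=4, weight_scheme="inverse", propagation="sum")
        got = predict(query, index, closed, toy_dag, cfg).scores

        neighbors = nearest_neighbors_fixed(query, index, 4)
        raw = {}
        for nb in neighbors:
            w = 1.0 / max(nb.distance, 1e-9)
            for t in closed[nb.protein_id]:
                raw[t] = raw.get(t, 0.0) + w
        merged = propagate_oracle(raw, toy_dag, "sum")
        merged.pop(GO[1], None)
        top = max(merged.values())
        expected = {t: v / top for t, v in merged.items()}
        assert set(got) == set(expected)
        for t in expected:
            assert got[t] == pytest.approx(expected[t], abs=1e-9)

    def test_funoverlap_requires_dynamic_mode(self):
        with pytest.raises(ValueError):
            KnnConfig(mode="fixed", weight_scheme="funoverlap")

    def test_funoverlap_weighting_drops_nonoverlapping_neighbors(self, toy_dag):
        rng = np.random.default_rng(5)
        vecs, closed = self.setup_benchmark(rng, toy_dag)
        funfams = {"q": {"f1"}, "t000": {"f1"}}  # only t000 overlaps
        query = ReducedVector("q", np.array([0.0, 0.0]))
        scores = predict(
            query, TrainingIndex(vecs), closed, toy_dag,
            KnnConfig(mode="dynamic", quartile="Q3", weight_scheme="funoverlap"),
            threshold=100.0, funfams=funfams,
        )
        assert set(scores.scores) == closed["t000"]


class TestBaselines:
    def test_naive_term_frequencies(self, toy_dag):
        ann = close_annotations(
            toy_dag,
            {"a": {GO[4]}, "b": {GO[4]}, "c": {GO[6]}, "d": {GO[7]}},
        )
        scores = naive_baseline(ann)
        assert scores.scores[GO[4]] == 0.5
        assert scores.scores[GO[2]] == 0.5
        assert scores.scores[GO[3]] == 0.5
        assert scores.scores[GO[6]] == 0.25

    def test_naive_identical_for_every_query(self, toy_dag):
        ann = close_annotations(toy_dag, {"a": {GO[4]}, "b": {GO[6]}})
        assert naive_baseline(ann).scores == naive_baseline(ann).scores

    def test_naive_empty_training_rejected(self):
        with pytest.raises(ValueError):
            naive_baseline({})

    def blast_row(self, q, s, evalue):
        return f"{q}\t{s}\t98.0\t100\t2\t0\t1\t100\t1\t100\t{evalue}\t200.0"

    def test_single_hit_scores_one(self, toy_dag):
        ann = close_annotations(toy_dag, {"s1": {GO[4]}})
        preds = blast_baseline(self.blast_row("q1", "s1", "1e-20"), ann)
        assert preds["q1"].scores == {GO[4]: 1.0, GO[2]: 1.0}

    def test_stronger_hit_wins_before_normalization(self, toy_dag):
        ann = close_annotations(toy_dag, {"s1": {GO[4]}, "s2": {GO[4], GO[6]}})
        hits = "\n".join(
            [self.blast_row("q1", "s1", "1e-10"), self.blast_row("q1", "s2", "1e-5")]
        )
        preds = blast_baseline(hits, ann)
        # GO:4 carried by the 1e-10 hit (w=10); GO:6 only by the 1e-5 hit (w=5)
        assert preds["q1"].scores[GO[4]] == 1.0
        assert preds["q1"].scores[GO[6]] == pytest.approx(0.5)

    def test_prediction_includes_closed_ancestors(self, toy_dag):
        ann = close_annotations(toy_dag, {"s1": {GO[4]}})
        preds = blast_baseline(self.blast_row("q1", "s1", "1e-8"), ann)
        assert GO[2] in preds["q1"].scores

    def test_malformed_row_reports_line(self, toy_dag):
        ann = close_annotations(toy_dag, {"s1": {GO[4]}})
        with pytest.raises(ValueError, match="line 1"):
            blast_baseline("q1\ts1\tonly-three", ann)

    def test_query_without_hits_absent(self, toy_dag):
        ann = close_annotations(toy_dag, {"s1": {GO[4]}})
        preds = blast_baseline(self.blast_row("q1", "unknown", "1e-8"), ann)
        assert preds == {}


def test_cafa_prediction_roundtrip():
    preds = {
        "p1": TermScores({GO[4]: 1.0, GO[2]: 0.66}, normalized=True),
        "p2": TermScores({GO[6]: 0.25}, normalized=True),
    }
    buf = io.StringIO()
    write_cafa_predictions(preds, buf)
    text = buf.getvalue()
    assert text.startswith("AUTHOR") and text.rstrip().endswith("END")
    again = read_cafa_predictions(text)
    assert again["p1"].scores == {GO[4]: 1.0, GO[2]: 0.66}
    assert again["p2"].scores == {GO[6]: 0.25}
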