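"""Label co-occurrence graph, community detection, and the NLSP ensemble."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from substrate_nlsp.labelstats import label_pair_table
from substrate_nlsp.nlsp import (
    CommunityPartition,
    NLSPModel,
    build_label_graph,
    detect_communities,
    fit_label_powerset,
    fit_nlsp,
    make_learner,
    predict_label_scores,
    predict_nlsp,
    rakeld_partition,
)


def toy_problem(n=24, m=3, seed=0):
    """Separable features: each labelset cluster sits at its own corner."""
    rng = np.random.default_rng(seed)
    labelsets = [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0)]
    rows, feats = [], []
    for i in range(n):
        ls = labelsets[i % len(labelsets)]
        rows.append(ls)
        feats.append(np.array(ls) * 2.0 + rng.normal(0, 0.05, size=m))
    Y = pd.DataFrame(rows, columns=["A", "B", "C"])
    return np.array(feats), Y


class TestLabelGraph:
    def test_single_label_rows_give_no_edges(self):
        Y = pd.DataFrame([[1, 0], [0, 1]], columns=["A", "B"])
        g = build_label_graph(Y)
        assert g.number_of_edges() == 0
        assert set(g.nodes) == {"A", "B"}

    def test_hand_tallied_weights(self):
        Y = pd.DataFrame(
            [[1, 1, 0], [1, 0, 0], [0, 1, 1]], columns=["A", "B", "C"]
        )
        g = build_label_graph(Y)
        assert g["A"]["B"]["weight"] == 1
        assert g["B"]["C"]["weight"] == 1
        assert not g.has_edge("A", "C")

    def test_weight_equals_pair_table_cell(self, small_dataset):
        Y = small_dataset.labels
        g = build_label_graph(Y)
        for i, j in itertools.combinations(Y.columns, 2):
            co = int(label_pair_table(Y, i, j).counts[1, 1])
            if co > 0:
                assert g[i][j]["weight"] == co
            else:
                assert not g.has_edge(i, j)

    def test_unweighted_flag(self):
        Y = pd.DataFrame([[1, 1], [1, 1]], columns=["A", "B"])
        assert build_label_graph(Y, weighted=False)["A"]["B"]["weight"] == 1


def all_partitions(items):
    """Every set partition of ``items`` (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1:]
        yield part + [[first]]


class TestDetectCommunities:
    def test_edgeless_graph_gives_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abcd")
        part = detect_communities(g)
        assert sorted(map(sorted, part.communities)) == [["a"], ["b"], ["c"], ["d"]]

    def test_two_triangles_match_exhaustive_modularity_optimum(self):
        g = nx.Graph()
        tri1 = [("A", "B"), ("B", "C"), ("A", "C")]
        tri2 = [("D", "E"), ("E", "F"), ("D", "F")]
        g.add_edges_from(tri1 + tri2, weight=1)
        part = detect_communities(g, method="greedy_modularity")
        got = sorted(map(sorted, part.communities))
        assert got == [["A", "B", "C"], ["D", "E", "F"]]
        # independent oracle: exhaustive search over all 203 partitions
        best = max(
            all_partitions(g.nodes),
            key=lambda p: nx.community.modularity(g, [set(c) for c in p]),
        )
        assert sorted(map(sorted, best)) == got

    def test_greedy_beats_trivial_partition(self, small_dataset):
        g = build_label_graph(small_dataset.labels)
        core = g.subgraph([n for n in g if g.degree(n) > 0])
        part = detect_communities(g)
        comms = [set(c) & set(core.nodes) for c in part.communities]
        comms = [c for c in comms if c]
        assert nx.community.modularity(core, comms) >= nx.community.modularity(
            core, [set(core.nodes)]
        )

    @pytest.mark.parametrize("method", ["greedy_modularity", "async_label_propagation"])
    def test_deterministic_given_seed(self, small_dataset, method):
        g = build_label_graph(small_dataset.labels)
        p1 = detect_communities(g, method=method, seed=5)
        p2 = detect_communities(g, method=method, seed=5)
        assert p1.communities == p2.communities

    def test_unknown_method_raises(self):
        g = nx.Graph()
        g.add_node("A")
        with pytest.raises(ValueError, match="unknown community method"):
            detect_communities(g, method="louvain-ish")


class TestRakeld:
    def test_k_equals_m_gives_singletons(self):
        part = rakeld_partition(list("ABCD"), k=4)
        assert sorted(len(c) for c in part.communities) == [1, 1, 1, 1]

    def test_k_one_gives_single_community(self):
        part = rakeld_partition(list("ABCD"), k=1)
        assert part.communities == [frozenset("ABCD")]

    def test_balanced_split_13_into_4(self):
        labels = [f"L{i}" for i in range(13)]
        part = rakeld_partition(labels, k=4, seed=3)
        assert sorted(len(c) for c in part.communities) == [3, 3, 3, 4]
        assert set().union(*part.communities) == set(labels)
        # disjoint
        assert sum(len(c) for c in part.communities) == 13

    def test_deterministic_and_seed_sensitive(self):
        labels = [f"L{i}" for i in range(8)]
        assert rakeld_partition(labels, 3, seed=1).communities == rakeld_partition(
            labels, 3, seed=1
        ).communities

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            rakeld_partition(list("AB"), k=3)


class TestLabelPowerset:
    def test_distinct_rows_become_classes(self):
        X, Y = toy_problem()
        unit = fit_label_powerset(X, Y, make_learner("knn1"))
        assert len(unit.codebook) == 4  # {A},{B},{C},{A,B}

    def test_constant_labels_warn_and_predict_constantly(self, caplog):
        X = np.zeros((5, 2))
        Y = pd.DataFrame([[1, 0]] * 5, columns=["A", "B"])
        with caplog.at_level("WARNING"):
            unit = fit_label_powerset(X, Y, make_learner("knn1"))
        assert "single distinct labelset" in caplog.text
        assert unit.decode(unit.learner.predict(np.ones((1, 2)))[0]) == {"A"}

    def test_class_count_bounded(self, small_dataset):
        Y = small_dataset.labels
        X = np.random.default_rng(0).normal(size=(len(Y), 4))
        unit = fit_label_powerset(X, Y, make_learner("knn1"))
        assert len(unit.codebook) <= min(len(Y), 2 ** Y.shape[1])

    def test_empty_labelset_is_a_class(self):
        X = np.arange(4, dtype=float).reshape(-1, 1)
        Y = pd.DataFrame([[0], [1], [0], [1]], columns=["A"])
        unit = fit_label_powerset(X, Y, make_learner("knn1"))
        assert frozenset() in {frozenset(v) for v in unit.codebook.values()}


class TestNLSPEnsemble:
    def test_single_community_equals_plain_label_powerset(self):
        X, Y = toy_problem()
        part = CommunityPartition([frozenset(Y.columns)], method="manual")
        model = fit_nlsp(X, Y, part, lambda s: make_learner("knn1"))
        pred = predict_nlsp(model, X)
        lp = fit_label_powerset(X, Y, make_learner("knn1"))
        lp_pred = np.zeros_like(Y.to_numpy())
        for r, cid in enumerate(lp.learner.predict(X)):
            for lab in lp.decode(cid):
                lp_pred[r, list(Y.columns).index(lab)] = 1
        np.testing.assert_array_equal(pred.to_numpy(), lp_pred)

    def test_singleton_communities_equal_binary_relevance(self):
        X, Y = toy_problem()
        part = CommunityPartition(
            [frozenset([c]) for c in Y.columns], method="manual"
        )
        model = fit_nlsp(X, Y, part, lambda s: make_learner("knn1"))
        pred = predict_nlsp(model, X)
        for lab in Y.columns:
            clf = make_learner("knn1")
            clf.fit(X, Y[lab].to_numpy())
            np.testing.assert_array_equal(pred[lab].to_numpy(), clf.predict(X))

    def test_overlapping_communities_share_label(self):
        X, Y = toy_problem()
        part = CommunityPartition(
            [frozenset({"A", "B"}), frozenset({"B", "C"})], method="manual"
        )
        model = fit_nlsp(X, Y, part, lambda s: make_learner("knn1"))
        assert len(model.units) == 2
        owners = [u for u in model.units if "B" in u.labels]
        assert len(owners) == 2

    def test_memorizing_learner_recovers_training_labels(self):
        X, Y = toy_problem()
        part = CommunityPartition(
            [frozenset({"A", "B"}), frozenset({"C"})], method="manual"
        )
        model = fit_nlsp(X, Y, part, lambda s: make_learner("knn1"))
        pred = predict_nlsp(model, X)
        np.testing.assert_array_equal(pred.to_numpy(), Y.to_numpy())

    def test_union_monotonicity(self):
        X, Y = toy_problem()
        part = CommunityPartition([frozenset({"A", "B"})], method="manual")
        base = fit_nlsp(X, Y[["A", "B"]], part, lambda s: make_learner("knn1"))
        part2 = CommunityPartition(
            [frozenset({"A", "B"}), frozenset({"C"})], method="manual"
        )
        grown = fit_nlsp(X, Y, part2, lambda s: make_learner("knn1"))
        p_base = predict_nlsp(base, X)
        p_grown = predict_nlsp(grown, X)
        assert (p_grown[["A", "B"]].to_numpy() >= p_base.to_numpy()).all()

    def test_seed_determinism_with_random_forest(self):
        X, Y = toy_problem(n=32)
        part = CommunityPartition([frozenset(Y.columns)], method="manual")

        def run():
            model = fit_nlsp(
                X, Y, part,
                lambda s: make_learner("rf", seed=s, n_estimators=20),
                seed=9,
            )
            return predict_nlsp(model, X)

        np.testing.assert_array_equal(run().to_numpy(), run().to_numpy())

    def test_feature_width_mismatch_raises(self):
        X, Y = toy_problem()
        part = CommunityPartition([frozenset(Y.columns)], method="manual")
        model = fit_nlsp(
            X, Y, part, lambda s: make_learner("knn1"),
            feature_names=[f"f{i}" for i in range(X.shape[1])],
        )
        with pytest.raises(ValueError, match="feature width"):
            predict_nlsp(model, X[:, :2])

    def test_partition_must_cover_labels(self):
        X, Y = toy_problem()
        part = CommunityPartition([frozenset({"A"})], method="manual")
        with pytest.raises(ValueError, match="does not cover"):
            fit_nlsp(X, Y, part, lambda s: make_learner("knn1"))


class TestLabelScores:
    def test_deterministic_proba_scores_are_binary(self):
        X, Y = toy_problem()
        part = CommunityPartition(
            [frozenset({"A", "B"}), frozenset({"C"})], method="manual"
        )
        model = fit_nlsp(X, Y, part, lambda s: make_learner("knn1"))
        scores = predict_label_scores(model, X)
        assert ((scores.to_numpy() == 0) | (scores.to_numpy() == 1)).all()

    def test_thresholded_scores_reproduce_predictions_for_disjoint_communities(self):
        X, Y = toy_problem()
        part = CommunityPartition(
            [frozenset({"A", "B"}), frozenset({"C"})], method="manual"
        )
        model = fit_nlsp(X, Y, part, lambda s: make_learner("knn1"))
        pred = predict_nlsp(model, X)
        scores = predict_label_scores(model, X)
        np.testing.assert_array_equal(
            (scores.to_numpy() > 0.5).astype(int), pred.to_numpy()
        )

    def test_label_absent_from_support_scores_zero(self):
        X = np.arange(6, dtype=float).reshape(-1, 1)
        Y = pd.DataFrame({"A": [1] * 6, "B": [0] * 6})
        part = CommunityPartition([frozenset({"A", "B"})], method="manual")
        model = fit_nlsp(X, Y, part, lambda s: make_learner("knn1"))
        scores = predict_label_scores(model, X)
        assert (scores["B"] == 0).all()

    def test_learner_without_proba_raises_capability_error(self):
        X, Y = toy_problem()

        class Bare:
            def fit(self, X, y):
                self.y = np.asarray(y)
                return self

            def predict(self, X):
                return np.zeros(len(X), dtype=int)

        part = CommunityPartition([frozenset(Y.columns)], method="manual")
        model = fit_nlsp(X, Y, part, lambda s: Bare())
        with pytest.raises(AttributeError, match="predict_proba"):
            predict_label_scores(model, X)


class TestSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path):
        X, Y = toy_problem()
        part = CommunityPartition([frozenset(Y.columns)], method="manual")
        model = fit_nlsp(X, Y, part, lambda s: make_learner("knn1"))
        path = tmp_path / "model.bin"
        model.save(path)
        again = NLSPModel.load(path)
        np.testing.assert_array_equal(
            predict_nlsp(model, X).to_numpy(), predict_nlsp(again, X).to_numpy()
        )

    def test_non_model_file_rejected(self, tmp_path):
        path = tmp_path / "junk.bin"
        import pickle

        path.write_bytes(pickle.dumps({"something": "else"}))
        with pytest.raises(ValueError, match="not an NLSP model"):
            NLSPModel.load(path)
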