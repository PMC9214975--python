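"""GCN forward/backward, pooling, training and evaluation metrics."""

import math

import numpy as np
import pytest

from pankinet.featurize import CompoundGraph, featurize_compound
from pankinet.gcn import (EMBEDDING_DIM, KERNELS, TrainConfig, evaluate,
                          forward, forward_batch, global_average_pool,
                          graph_conv, init_params, metrics_from_scores,
                          predict_scores, train)
from pankinet.pkfi import ACTIVE, INACTIVE, DataSplit


class TestGraphConv:
    def test_identity_propagation(self):
        F = np.arange(12.0).reshape(4, 3)
        out = graph_conv(F, np.eye(4), np.eye(3), activation="linear")
        assert np.allclose(out, F)

    def test_lone_atom_row(self):
        rng = np.random.default_rng(0)
        F = np.zeros((5, 4))
        F[0] = rng.normal(size=4)
        L = np.zeros((5, 5))
        L[0, 0] = 1.0
        W = rng.normal(size=(4, 2))
        out = graph_conv(F, L, W, activation="linear")
        assert np.allclose(out[0], F[0] @ W)
        assert np.all(out[1:] == 0)

    def test_two_atom_hand_computation(self):
        L = np.array([[0.5, 0.5], [0.5, 0.5]])
        F = np.array([[1.0, 2.0], [3.0, 4.0]])
        W = np.array([[1.0, 0.0], [1.0, -1.0]])
        # L @ F = [[2,3],[2,3]]; (L@F) @ W = [[5,-3],[5,-3]]
        linear = graph_conv(F, L, W, activation="linear")
        assert np.allclose(linear, [[5, -3], [5, -3]])
        relu = graph_conv(F, L, W, activation="relu")
        assert np.allclose(relu, [[5, 0], [5, 0]])

    def test_matches_neighborhood_sum_oracle_on_small_graphs(self, rng):
        for _ in range(10):
            n, d_in, d_out = 6, 5, 3
            L = rng.normal(size=(n, n))
            L = (L + L.T) / 2
            F = rng.normal(size=(n, d_in))
            W = rng.normal(size=(d_in, d_out))
            out = graph_conv(F, L, W, activation="linear")
            # explicit per-atom weighted-sum: out[i] = sum_j L[i,j] F[j] W
            expected = np.array([
                sum(L[i, j] * F[j] for j in range(n)) @ W for i in range(n)])
            assert np.allclose(out, expected)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            graph_conv(np.ones((4, 3)), np.eye(5), np.ones((3, 2)))


class TestGlobalAveragePool:
    def test_zero_map(self):
        assert np.allclose(global_average_pool(np.zeros((50, 16))), 0)

    def test_single_nonzero_row_divided_by_padded_dim(self):
        F = np.zeros((50, 8))
        F[3] = np.arange(8.0)
        assert np.allclose(global_average_pool(F), np.arange(8.0) / 50)

    def test_masked_divisor_option(self):
        F = np.zeros((50, 4))
        F[0] = 10.0
        assert np.allclose(global_average_pool(F, n_atoms=5), 2.0)

    def test_output_lengths_match_kernel_widths(self):
        g = featurize_compound("c1ccccc1")
        params = init_params(seed=0)
        _, fmaps = forward(g, params)
        for F, d in zip(fmaps, KERNELS):
            assert global_average_pool(F).shape == (d,)


class TestForward:
    def test_zero_classifier_gives_uniform_probabilities(self):
        g = featurize_compound("CCO")
        params = init_params(seed=0)
        params.classifier_w[:] = 0.0
        params.classifier_b[:] = 0.0
        probs, _ = forward(g, params)
        assert np.allclose(probs, [0.5, 0.5])

    def test_embedding_dimension_is_112(self):
        assert EMBEDDING_DIM == 112
        g = featurize_compound("c1ccncc1")
        params = init_params(seed=1)
        probs, fmaps, cache = forward_batch(g.AF, g.L, params, keep_cache=True)
        assert cache["h"].shape == (EMBEDDING_DIM,)

    def test_probabilities_normalized(self, probe_smiles):
        params = init_params(seed=2)
        for smiles in probe_smiles:
            probs, _ = forward(featurize_compound(smiles), params)
            assert abs(probs.sum() - 1.0) < 1e-9
            assert np.all(probs >= 0)

    def test_padded_rows_stay_zero(self):
        g = featurize_compound("c1ccccc1")
        params = init_params(seed=3)
        _, fmaps = forward(g, params)
        for F in fmaps:
            assert np.all(F[g.n_atoms:] == 0)

    def test_padding_only_rescales_pooling(self):
        """Forward on the trimmed graph equals the padded forward up to the
        fixed-N pooling factor."""
        g = featurize_compound("Cn1cnc2c1c(=O)n(C)c(=O)n2C")
        n = g.n_atoms
        params = init_params(seed=4)
        _, fmaps_padded = forward(g, params)
        F = g.AF[:n]
        L = g.L[:n, :n]
        for W, F_pad in zip(params.weights, fmaps_padded):
            F = graph_conv(F, L, W)
            assert np.allclose(F, F_pad[:n])
            assert np.allclose(global_average_pool(F, n_atoms=50),
                               global_average_pool(F_pad))


def toy_split(graphs, seed=0):
    ids = sorted(graphs)
    labels = [ACTIVE if i % 2 == 0 else INACTIVE for i in range(len(ids))]
    items = list(zip(ids, labels))
    return DataSplit(train=items, test=items, seed=seed)


class TestTrain:
    def test_zero_epochs_returns_initialization(self, small_benchmark,
                                                small_graphs):
        from pankinet.pkfi import split_set
        split = split_set(small_benchmark.pkfi_set, 0.8, seed=0)
        cfg = TrainConfig(epochs=0, seed=11)
        params = train(split, small_graphs, cfg)
        ref = init_params(11)
        for a, b in zip(params.weights, ref.weights):
            assert np.array_equal(a, b)

    def test_deterministic_given_seed(self, small_benchmark, small_graphs):
        from pankinet.pkfi import split_set
        split = split_set(small_benchmark.pkfi_set, 0.8, seed=0)
        cfg = TrainConfig(epochs=3, seed=5)
        a = train(split, small_graphs, cfg)
        b = train(split, small_graphs, cfg)
        assert a.train_loss == b.train_loss
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_single_class_training_set_rejected(self, small_graphs):
        ids = sorted(small_graphs)[:10]
        split = DataSplit(train=[(i, ACTIVE) for i in ids],
                          test=[(ids[0], ACTIVE)], seed=0)
        with pytest.raises(ValueError):
            train(split, small_graphs, TrainConfig(epochs=1))

    def test_learns_separable_planted_motif(self, small_trained,
                                            small_benchmark, small_graphs):
        params, split = small_trained
        metrics = evaluate(params, split.train, small_graphs)
        assert metrics.acc >= 0.95


def mcc_oracle(tp, fp, fn, tn):
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return 0.0 if denom == 0 else (tp * tn - fp * fn) / denom


def auroc_oracle(y_true, scores):
    """Rank statistic: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for y, s in zip(y_true, scores) if y == 1]
    neg = [s for y, s in zip(y_true, scores) if y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics_from_scores([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2])
        assert (m.acc, m.mcc, m.auroc) == (1.0, 1.0, 1.0)

    def test_mcc_closed_form_example(self):
        # TP=2, FP=1, FN=1, TN=2 -> MCC = 1/3
        y_true = [1, 1, 1, 0, 0, 0]
        scores = [0.9, 0.9, 0.1, 0.9, 0.1, 0.1]
        m = metrics_from_scores(y_true, scores)
        assert m.mcc == pytest.approx(1 / 3)

    def test_matches_closed_form_oracles_on_random_tables(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 40))
            y_true = rng.integers(0, 2, size=n)
            if len(set(y_true.tolist())) < 2:
                continue
            scores = rng.random(size=n)
            m = metrics_from_scores(y_true, scores)
            y_pred = (scores >= 0.5).astype(int)
            tp = int(np.sum((y_true == 1) & (y_pred == 1)))
            fp = int(np.sum((y_true == 0) & (y_pred == 1)))
            fn = int(np.sum((y_true == 1) & (y_pred == 0)))
            tn = int(np.sum((y_true == 0) & (y_pred == 0)))
            assert m.acc == pytest.approx((tp + tn) / n)
            assert m.mcc == pytest.approx(mcc_oracle(tp, fp, fn, tn))
            assert m.auroc == pytest.approx(auroc_oracle(y_true, scores))
            assert m.confusion.tolist() == [[tn, fp], [fn, tp]]

    def test_random_scores_near_chance(self, rng):
        y_true = np.repeat([0, 1], 500)
        scores = rng.random(1000)
        m = metrics_from_scores(y_true, scores)
        assert abs(m.auroc - 0.5) < 0.06

    def test_single_class_flags_undefined_auroc(self):
        m = metrics_from_scores([1, 1, 1], [0.9, 0.8, 0.7])
        assert math.isnan(m.auroc) and m.flag

    def test_empty_test_set_rejected(self, small_graphs):
        with pytest.raises(ValueError):
            evaluate(init_params(0), [], small_graphs)
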