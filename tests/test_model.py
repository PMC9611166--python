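"""Network forward pass, gradients, training loop, and metric oracles."""

import numpy as np
import pytest

from cocrystal_gcn import (
    Hyperparameters,
    LabeledPair,
    ModelParams,
    PairDataset,
    SyntheticSpec,
    bce_loss,
    build_pair_graph,
    cross_validate,
    evaluate,
    forward_pair,
    gc_step,
    generate_dataset,
    global_pool,
    node_embed,
    predict,
    train,
)
from cocrystal_gcn.model import (
    Metrics,
    _backward_batch,
    _forward_batch,
    _pack_batch,
    batch_probabilities,
    forward_logit,
    load_params,
    pair_graphs,
    roc_auc,
    save_params,
)
from cocrystal_gcn.molgraph import PairGraph


def brute_force_logit(params, x_in, a_c, a_nc):
    """Entry-by-entry re-evaluation of the whole network with python loops."""
    def mat(a, b):
        out = [[0.0] * len(b[0]) for _ in range(len(a))]
        for i in range(len(a)):
            for j in range(len(b[0])):
                out[i][j] = sum(a[i][k] * b[k][j] for k in range(len(b)))
        return out

    def relu(m):
        return [[max(v, 0.0) for v in row] for row in m]

    def add_bias(m, b):
        return [[v + b[j] for j, v in enumerate(row)] for row in m]

    def add(m, n):
        return [[u + v for u, v in zip(r1, r2)] for r1, r2 in zip(m, n)]

    hp = params.hp
    h = relu(add_bias(mat(relu(add_bias(mat(x_in.tolist(), params.W1.tolist()), params.b1)),
                          params.W2.tolist()), params.b2))
    if hp.use_covalent:
        h = add(h, relu(mat(mat(a_c.tolist(), h), params.W_C.tolist())))
    if hp.use_noncovalent:
        h = add(h, relu(mat(mat(a_nc.tolist(), h), params.W_NC.tolist())))
    g = [sum(col) for col in zip(*h)]
    if hp.mean_pool:
        g = [v / len(h) for v in g]
    hidden = [max(v + b, 0.0) for v, b in zip(mat([g], params.W_FC1.tolist())[0], params.b_FC1)]
    return sum(u * w for u, w in zip(hidden, params.W_FC2[:, 0])) + float(params.b_FC2[0])


class TestForwardOps:
    def test_node_embed_zero_parameters_give_zero(self, tiny_params):
        p = tiny_params.copy()
        for w in p.weights().values():
            w[...] = 0.0
        x = np.ones((3, p.hp.feature_dim))
        assert np.all(node_embed(x, p) == 0)

    def test_node_embed_identity_passes_nonnegative_input(self):
        hp = Hyperparameters(feature_dim=4, embed_dim1=4, embed_dim2=4, fc_hidden=4)
        p = ModelParams.initialize(hp, seed=0)
        p.W1[...] = np.eye(4)
        p.W2[...] = np.eye(4)
        p.b1[...] = 0
        p.b2[...] = 0
        x = np.abs(np.random.default_rng(0).normal(size=(5, 4)))
        assert np.allclose(node_embed(x, p), x)

    def test_node_embed_hand_computed(self):
        hp = Hyperparameters(feature_dim=2, embed_dim1=2, embed_dim2=2, fc_hidden=2)
        p = ModelParams.initialize(hp, seed=0)
        p.W1[...] = np.eye(2)
        p.b1[...] = 0
        p.W2[...] = np.ones((2, 2))
        p.b2[...] = 0
        # inner relu([1, -1]) = [1, 0]; times all-ones -> [1, 1]
        assert np.allclose(node_embed(np.array([[1.0, -1.0]]), p), [[1.0, 1.0]])

    def test_gc_step_no_edges_returns_residual(self):
        h = np.array([[1.0], [2.0]])
        assert np.allclose(gc_step(h, np.zeros((2, 2)), np.eye(1), h), h)

    def test_gc_step_two_node_path(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        h = np.array([[1.0], [2.0]])
        out = gc_step(h, a, np.eye(1), h)
        assert np.allclose(out, [[3.0], [3.0]])

    def test_gc_step_relu_clips_negative_messages(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        h = np.array([[1.0], [-2.0]])
        out = gc_step(h, a, np.eye(1), h)
        assert np.allclose(out, [[1.0], [-1.0]])

    def test_gc_step_shape_mismatch(self):
        with pytest.raises(ValueError):
            gc_step(np.ones((3, 2)), np.zeros((2, 2)), np.eye(2), np.ones((3, 2)))

    def test_global_pool_examples(self):
        assert np.allclose(global_pool(np.array([[1.0, 2.0], [3.0, 4.0]])), [4.0, 6.0])
        row = np.array([[2.0, 5.0]])
        assert np.allclose(global_pool(row), row[0])

    def test_global_pool_permutation_invariant(self):
        h = np.random.default_rng(1).normal(size=(6, 3))
        assert np.allclose(global_pool(h), global_pool(h[::-1]))

    def test_global_pool_rejects_empty_mask(self):
        with pytest.raises(ValueError):
            global_pool(np.ones((2, 2)), mask=np.zeros(2))

    def test_predict_zero_head_gives_half(self, tiny_params):
        p = tiny_params.copy()
        p.W_FC1[...] = 0
        p.b_FC1[...] = 0
        p.W_FC2[...] = 0
        p.b_FC2[...] = 0
        assert predict(np.ones(p.hp.embed_dim2), p) == pytest.approx(0.5)

    def test_predict_saturates_with_large_bias(self, tiny_params):
        p = tiny_params.copy()
        p.b_FC2[...] = 50.0
        assert predict(np.ones(p.hp.embed_dim2), p) == pytest.approx(1.0)

    def test_forward_matches_brute_force_oracle(self, tiny_params):
        pg = build_pair_graph("CCO", "c1ccncc1")
        assert forward_logit(tiny_params, pg) == pytest.approx(
            brute_force_logit(tiny_params, pg.x_in, pg.a_c, pg.a_nc), abs=1e-6
        )


class TestSymmetries:
    def _permute(self, pg: PairGraph, perm: np.ndarray) -> PairGraph:
        return PairGraph(
            api=pg.api, coformer=pg.coformer, m=pg.m,
            x_in=pg.x_in[perm],
            a_c=pg.a_c[np.ix_(perm, perm)],
            a_nc=pg.a_nc[np.ix_(perm, perm)],
        )

    def test_atom_relabeling_within_molecules(self, tiny_params, random_pairs):
        rng = np.random.default_rng(0)
        for pg in random_pairs[:20]:
            na = pg.api.atom_count
            perm = np.concatenate([rng.permutation(na), na + rng.permutation(pg.m - na)])
            assert forward_pair(tiny_params, self._permute(pg, perm)) == pytest.approx(
                forward_pair(tiny_params, pg), abs=1e-6
            )

    def test_api_coformer_swap(self, tiny_params, random_pairs):
        for pg in random_pairs[:20]:
            swapped = build_pair_graph(pg.coformer, pg.api)
            assert forward_pair(tiny_params, swapped) == pytest.approx(
                forward_pair(tiny_params, pg), abs=1e-6
            )

    def test_batched_padding_matches_unbatched(self, tiny_params, random_pairs):
        graphs = random_pairs[:12]
        batched = batch_probabilities(tiny_params, graphs)
        single = [forward_pair(tiny_params, g) for g in graphs]
        assert np.allclose(batched, single, atol=1e-5)

    def test_ablation_flags_skip_their_convolution(self, random_pairs):
        pg = random_pairs[0]
        hp_nc = Hyperparameters(embed_dim1=8, embed_dim2=8, fc_hidden=8, use_covalent=False)
        p = ModelParams.initialize(hp_nc, seed=3)
        # with the covalent step disabled, zeroing A_C must not change the output
        no_cov = PairGraph(api=pg.api, coformer=pg.coformer, m=pg.m,
                           x_in=pg.x_in, a_c=np.zeros_like(pg.a_c), a_nc=pg.a_nc)
        assert forward_logit(p, pg) == pytest.approx(forward_logit(p, no_cov))
        hp_c = Hyperparameters(embed_dim1=8, embed_dim2=8, fc_hidden=8, use_noncovalent=False)
        p2 = ModelParams.initialize(hp_c, seed=3)
        no_nc = PairGraph(api=pg.api, coformer=pg.coformer, m=pg.m,
                          x_in=pg.x_in, a_c=pg.a_c, a_nc=np.zeros_like(pg.a_nc))
        assert forward_logit(p2, pg) == pytest.approx(forward_logit(p2, no_nc))

    def test_both_convolutions_disabled_rejected(self):
        with pytest.raises(ValueError):
            Hyperparameters(use_covalent=False, use_noncovalent=False)


class TestLossAndMetrics:
    def test_bce_perfect_prediction_tends_to_zero(self):
        assert bce_loss([1.0], [1.0]) < 1e-6

    def test_bce_half_is_ln2(self):
        assert bce_loss([1.0], [0.5]) == pytest.approx(np.log(2), abs=1e-9)

    def test_bce_hand_arithmetic(self):
        expected = -(np.log(0.9) + np.log(0.8)) / 2
        assert bce_loss([1, 0], [0.9, 0.2]) == pytest.approx(expected, abs=1e-9)

    def test_bce_empty_raises(self):
        with pytest.raises(ValueError):
            bce_loss([], [])

    def test_worked_confusion_case(self):
        m = Metrics(tp=3, fp=1, tn=4, fn=2, auc=None)
        assert m.recall == pytest.approx(0.6)
        assert m.precision == pytest.approx(0.75)
        assert m.acc == pytest.approx(0.7)

    def test_undefined_metrics_are_none_not_zero(self):
        m = Metrics(tp=0, fp=0, tn=5, fn=0, auc=None)
        assert m.precision is None and m.recall is None

    def test_auc_perfect_and_tied(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_auc_matches_sklearn_on_random_sets(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            s = np.round(rng.random(n), 1)  # coarse scores force ties
            assert roc_auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_evaluate_counts_sum_to_dataset_size(self, tiny_params):
        ds = generate_dataset(SyntheticSpec(n_molecules=40, n_pos=20, n_neg=20, seed=2))
        m = evaluate(tiny_params, ds)
        assert m.tp + m.fp + m.tn + m.fn == len(ds)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        hp = Hyperparameters(embed_dim1=5, embed_dim2=5, fc_hidden=4, epochs=1)
        params = ModelParams.initialize(hp, seed=8)
        for w in params.weights().values():
            w *= 0.3  # keep predictions off the clipping bounds, where the
            # analytic sigmoid+BCE gradient and the clipped loss diverge
        graphs = pair_graphs(generate_dataset(SyntheticSpec(n_molecules=30, n_pos=4, n_neg=4, seed=3)))
        y = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        x, ac, anc, mask = _pack_batch(graphs, False)
        probs = _forward_batch(params, x, ac, anc, mask)["prob"]
        assert np.all((probs > hp.clip_eps) & (probs < 1 - hp.clip_eps))
        grads = _backward_batch(params, _forward_batch(params, x, ac, anc, mask), y)

        def loss_at(p):
            return bce_loss(y, _forward_batch(p, x, ac, anc, mask)["prob"])

        rng = np.random.default_rng(0)
        for name, w in params.weights().items():
            flat = w.reshape(-1)
            for idx in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                eps = 1e-6
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_at(params)
                flat[idx] = orig - eps
                down = loss_at(params)
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert grads[name].reshape(-1)[idx] == pytest.approx(numeric, abs=1e-6), name


@pytest.fixture(scope="module")
def tiny_training_sets():
    ds = generate_dataset(SyntheticSpec(n_molecules=60, n_pos=120, n_neg=120, label_noise=0.0, seed=6))
    from cocrystal_gcn.data import split_dataset

    return split_dataset(ds, (0.8, 0.1, 0.1), seed=1)


class TestTraining:
    HP = Hyperparameters(embed_dim1=16, embed_dim2=16, fc_hidden=32, epochs=8, batch_size=32)

    def test_loss_decreases_on_planted_rule_data(self, tiny_training_sets):
        tr, va, _ = tiny_training_sets
        _, log = train(tr, va, hp=self.HP, seed=2)
        assert log.train_loss.iloc[-1] < log.train_loss.iloc[0]

    def test_same_seed_gives_bitwise_identical_checkpoints(self, tiny_training_sets):
        tr, va, _ = tiny_training_sets
        hp = Hyperparameters(embed_dim1=8, embed_dim2=8, fc_hidden=8, epochs=2, batch_size=32)
        p1, _ = train(tr, va, hp=hp, seed=4)
        p2, _ = train(tr, va, hp=hp, seed=4)
        for k in p1.weights():
            assert np.array_equal(p1.weights()[k], p2.weights()[k])

    def test_zero_learning_rate_keeps_initialization(self, tiny_training_sets):
        tr, va, _ = tiny_training_sets
        hp = Hyperparameters(embed_dim1=8, embed_dim2=8, fc_hidden=8, epochs=1,
                             learning_rate=0.0, batch_size=32)
        p, _ = train(tr, va, hp=hp, seed=4)
        init = ModelParams.initialize(hp, seed=4)
        for k in p.weights():
            assert np.array_equal(p.weights()[k], init.weights()[k])

    def test_single_class_training_set_rejected(self, tiny_training_sets):
        _, va, _ = tiny_training_sets
        only_pos = PairDataset([p for p in va if p.label == 1])
        with pytest.raises(ValueError, match="both classes"):
            train(only_pos, va, hp=self.HP, seed=0)

    def test_checkpoint_round_trip(self, tiny_training_sets, tmp_path):
        tr, va, te = tiny_training_sets
        hp = Hyperparameters(embed_dim1=8, embed_dim2=8, fc_hidden=8, epochs=1, batch_size=32)
        p, _ = train(tr, va, hp=hp, seed=4)
        save_params(p, tmp_path / "model.npz")
        loaded = load_params(tmp_path / "model.npz")
        assert loaded.hp == p.hp
        assert evaluate(loaded, te).as_dict() == evaluate(p, te).as_dict()

    def test_cross_validate_reports_folds_and_mean(self, tiny_training_sets):
        tr, va, te = tiny_training_sets
        ds = PairDataset(tr.pairs + va.pairs + te.pairs)
        hp = Hyperparameters(embed_dim1=8, embed_dim2=8, fc_hidden=16, epochs=3, batch_size=32)
        report = cross_validate(ds, k=2, hp=hp, seed=0)
        assert len(report) == 3
        folds = report[report.fold != "mean"]
        mean = report[report.fold == "mean"].iloc[0]
        assert float(mean.test_acc) == pytest.approx(folds.test_acc.astype(float).mean())
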