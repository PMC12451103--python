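import copy

import numpy as np
import pytest

from mvsite import ModelConfig, MultiViewSiteModel
from mvsite.features import NodeFeatureMatrix
from mvsite.graphs import MultiViewGraph, ViewGraph
from mvsite.model import classify, gcn_propagate, multi_scale_fuse, view_fuse
from mvsite.nn import Tensor
from mvsite import nn

from oracles import oracle_forward


def _rand_graph(n=5, d_init=6, seed=0, views=("P", "S", "T")):
    rng = np.random.default_rng(seed)
    nfm = NodeFeatureMatrix(rng.normal(size=(n, d_init)),
                            {"all": (0, d_init)}, np.ones(d_init, dtype=bool))
    graphs = {}
    for v in views:
        edges = set()
        while len(edges) < n:
            i, j = rng.integers(0, n, size=2)
            if i != j:
                edges.add((min(i, j), max(i, j)))
        graphs[v] = ViewGraph(v, n, edges)
    y = rng.integers(0, 2, size=n)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    return MultiViewGraph("r", nfm, graphs, y)


class TestGcnPropagate:
    def test_identity_adjacency_identity_weight(self):
        x = np.abs(np.random.default_rng(0).normal(size=(4, 3)))
        out = gcn_propagate(np.eye(4), x, Tensor(np.eye(3)))
        np.testing.assert_allclose(out.data, x)

    def test_single_edge_averages_rows(self):
        a = np.full((2, 2), 0.5)
        x = np.array([[2.0, 0.0], [4.0, 8.0]])
        out = gcn_propagate(a, x, Tensor(np.eye(2)))
        np.testing.assert_allclose(out.data, [[3, 4], [3, 4]])

    def test_zero_input_zero_output(self):
        out = gcn_propagate(np.eye(3), np.zeros((3, 2)), Tensor(np.ones((2, 2))))
        assert (out.data == 0).all()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            gcn_propagate(np.eye(3), np.zeros((4, 2)), Tensor(np.eye(2)))


def _mhvf_params(d, ffn_mult=2, rng=None, zero_value=False):
    rng = rng or np.random.default_rng(0)
    p = {}
    for w in ("Wq", "Wk", "Wv", "Wo"):
        p[w] = Tensor(rng.normal(size=(d, d)) * 0.3)
    if zero_value:
        p["Wv"] = Tensor(np.zeros((d, d)))
    p["W1"] = Tensor(rng.normal(size=(d, ffn_mult * d)) * 0.3)
    p["b1"] = Tensor(np.zeros(ffn_mult * d))
    p["W2"] = Tensor(rng.normal(size=(ffn_mult * d, d)) * 0.3)
    p["b2"] = Tensor(np.zeros(d))
    for ln in ("ln1", "ln2"):
        p[f"{ln}_g"] = Tensor(np.ones(d))
        p[f"{ln}_b"] = Tensor(np.zeros(d))
    return p


class TestViewFuse:
    def test_identical_views_give_identical_tokens(self):
        d = 4
        p = _mhvf_params(d)
        v = np.random.default_rng(1).normal(size=(3, d))
        out = view_fuse([Tensor(v)] * 3, p, n_heads=1).data.reshape(3, 3, d)
        np.testing.assert_allclose(out[:, 0], out[:, 1])
        np.testing.assert_allclose(out[:, 1], out[:, 2])

    def test_zero_value_and_ffn_is_pure_residual(self):
        d = 4
        p = _mhvf_params(d, zero_value=True)
        p["W2"] = Tensor(np.zeros((2 * d, d)))          # FFN output = 0
        hs = [Tensor(np.random.default_rng(2).normal(size=(2, d)))
              for _ in range(3)]
        out = view_fuse(hs, p, n_heads=2).data.reshape(2, 3, d)
        tokens = np.stack([h.data for h in hs], axis=1)
        expect = np.empty_like(tokens)
        for i in range(2):
            for t in range(3):
                x = tokens[i, t]
                for _ in range(2):                      # LN(LN(x))
                    mu, var = x.mean(), x.var()
                    x = (x - mu) / np.sqrt(var + 1e-5)
                expect[i, t] = x
        np.testing.assert_allclose(out, expect, atol=1e-12)

    def test_width_mismatch_raises(self):
        p = _mhvf_params(4)
        hs = [Tensor(np.zeros((2, 6))) for _ in range(3)]
        with pytest.raises(ValueError):
            view_fuse(hs, p, n_heads=1)


class TestMultiScaleFuse:
    def test_identical_tokens_identity_projections(self):
        d = 5
        rng = np.random.default_rng(3)
        p = {"Wq": Tensor(rng.normal(size=(d, d))),
             "Wk": Tensor(rng.normal(size=(d, d))),
             "Wv": Tensor(np.eye(d)), "Wo": Tensor(np.eye(d))}
        v = rng.normal(size=(2, d))
        z_f, enhanced = multi_scale_fuse([Tensor(v)] * 4, p)
        for za in enhanced:
            np.testing.assert_allclose(za.data, v)
        np.testing.assert_allclose(z_f.data, v)

    def test_attention_rows_sum_to_one(self):
        d = 4
        rng = np.random.default_rng(4)
        p = {w: Tensor(rng.normal(size=(d, d)))
             for w in ("Wq", "Wk", "Wv", "Wo")}
        maps = {}
        multi_scale_fuse([Tensor(rng.normal(size=(3, d))) for _ in range(4)],
                         p, attn_out=maps)
        np.testing.assert_allclose(maps["msf"].sum(axis=-1), 1.0, atol=1e-6)


class TestClassify:
    def _params(self, d, seed=0):
        rng = np.random.default_rng(seed)
        return {"W1": Tensor(rng.normal(size=(d, 3))), "b1": Tensor(np.zeros(3)),
                "W2": Tensor(rng.normal(size=(3, 1))), "b2": Tensor(np.zeros(1))}

    def test_zero_logit_is_positive_call(self):
        p = self._params(2)
        p["W1"] = Tensor(np.zeros((2, 3)))
        p["W2"] = Tensor(np.zeros((3, 1)))
        logits = classify(Tensor(np.ones((2, 2))), p)
        probs = nn.sigmoid(logits).data
        assert (probs == 0.5).all()
        assert ((probs >= 0.5).astype(int) == 1).all()

    def test_identical_rows_identical_probability(self):
        p = self._params(3)
        z = np.tile(np.array([[0.3, -0.2, 1.0]]), (4, 1))
        logits = classify(Tensor(z), p).data
        assert np.ptp(logits) == 0


class TestForward:
    def test_matches_straight_line_oracle(self):
        g = _rand_graph(n=5, d_init=6, seed=7)
        cfg = ModelConfig(d_init=6, d_hidden=8, d_scale=6, n_heads=2,
                          clf_hidden=4, dropout=0.0, seed=9)
        model = MultiViewSiteModel(cfg)
        p_vec = model.forward(g).p
        p_oracle = oracle_forward(model, g)
        np.testing.assert_allclose(p_vec, p_oracle, atol=1e-5)

    def test_permutation_equivariance(self, small_graph, small_model):
        g = small_graph
        p1 = small_model.forward(g).p
        rng = np.random.default_rng(0)
        perm = rng.permutation(g.n)
        inv = np.argsort(perm)
        nfm = NodeFeatureMatrix(g.features.X[perm], dict(g.features.blocks),
                                g.features.continuous)
        graphs = {v: ViewGraph(v, g.n, {(int(inv[i]), int(inv[j]))
                                        for i, j in vg.edges})
                  for v, vg in g.graphs.items()}
        g2 = MultiViewGraph(g.chain_id, nfm, graphs, g.y[perm])
        p2 = small_model.forward(g2).p
        np.testing.assert_allclose(p2, p1[perm], atol=1e-7)

    def test_zero_weights_constant_probability(self, small_graph):
        cfg = ModelConfig(d_init=small_graph.features.d_init, d_hidden=8,
                          d_scale=6, n_heads=2, clf_hidden=4, dropout=0.0)
        model = MultiViewSiteModel(cfg)
        for k, p in model.params.items():
            if not (k.endswith("ln1_g") or k.endswith("ln2_g")):
                p.data[:] = 0.0
        p_vec = model.forward(small_graph).p
        assert np.ptp(p_vec) == 0

    def test_seeded_forward_is_bit_identical(self, small_graph):
        cfg = ModelConfig(d_init=small_graph.features.d_init, d_hidden=8,
                          d_scale=6, n_heads=2, clf_hidden=4, seed=21)
        z1 = MultiViewSiteModel(cfg).forward(small_graph).Z_f
        z2 = MultiViewSiteModel(cfg).forward(small_graph).Z_f
        assert (z1 == z2).all()

    def test_attention_rows_stochastic_everywhere(self, small_graph, small_model):
        emb = small_model.forward(small_graph, collect_attention=True)
        assert set(emb.attention) == {"mhvf1", "mhvf2", "mhvf3", "msf"}
        for a in emb.attention.values():
            np.testing.assert_allclose(a.sum(axis=-1), 1.0, atol=1e-6)


class TestGradients:
    def test_gradient_flow_reaches_every_parameter(self):
        g = _rand_graph(n=6, d_init=5, seed=3)
        cfg = ModelConfig(d_init=5, d_hidden=8, d_scale=6, n_heads=2,
                          clf_hidden=4, dropout=0.0, seed=5)
        model = MultiViewSiteModel(cfg)
        emb = model.forward(g)
        loss = nn.bce_with_logits(emb._logits_tensor, g.y).mean()
        loss.backward()
        for name, p in model.params.items():
            assert p.grad is not None, f"no gradient for {name}"
            assert np.abs(p.grad).max() > 0, f"dead gradient for {name}"

    def test_gradients_match_finite_differences(self):
        g = _rand_graph(n=4, d_init=3, seed=11)
        cfg = ModelConfig(d_init=3, d_hidden=4, d_scale=4, n_heads=2,
                          clf_hidden=3, dropout=0.0, seed=13)
        model = MultiViewSiteModel(cfg)

        def loss_value():
            emb = model.forward(g)
            return float(nn.bce_with_logits(emb._logits_tensor, g.y).mean().data)

        emb = model.forward(g)
        loss = nn.bce_with_logits(emb._logits_tensor, g.y).mean()
        loss.backward()
        rng = np.random.default_rng(1)
        eps = 1e-6
        for name in ("gcn1.P.W", "mhvf2.Wq", "msf.Wv", "clf.W1", "node.W"):
            p = model.params[name]
            idx = tuple(rng.integers(0, s) for s in p.data.shape)
            orig = p.data[idx]
            p.data[idx] = orig + eps
            up = loss_value()
            p.data[idx] = orig - eps
            down = loss_value()
            p.data[idx] = orig
            numeric = (up - down) / (2 * eps)
            assert p.grad[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-8), name


class TestAblationStructure:
    def test_removing_view_drops_its_parameters(self):
        full = MultiViewSiteModel(ModelConfig(d_init=5, d_hidden=8, d_scale=6,
                                              n_heads=2))
        wo_t = MultiViewSiteModel(ModelConfig(d_init=5, d_hidden=8, d_scale=6,
                                              n_heads=2, views=("P", "S")))
        assert set(wo_t.params) < set(full.params)
        assert not any(".T." in k for k in wo_t.params)

    def test_two_view_model_runs(self):
        g = _rand_graph(n=5, d_init=5, seed=2, views=("P", "S"))
        cfg = ModelConfig(d_init=5, d_hidden=8, d_scale=6, n_heads=2,
                          views=("P", "S"), dropout=0.0)
        p = MultiViewSiteModel(cfg).forward(g).p
        assert p.shape == (5,)

    def test_alternative_node_tokenization_runs_and_is_equivariant(self):
        g = _rand_graph(n=5, d_init=5, seed=4)
        cfg = ModelConfig(d_init=5, d_hidden=8, d_scale=6, n_heads=2,
                          mhvf_tokens="nodes", dropout=0.0, seed=6)
        model = MultiViewSiteModel(cfg)
        p1 = model.forward(g).p
        assert p1.shape == (5,)
        perm = np.random.default_rng(1).permutation(5)
        inv = np.argsort(perm)
        nfm = NodeFeatureMatrix(g.features.X[perm], dict(g.features.blocks),
                                g.features.continuous)
        graphs = {v: ViewGraph(v, 5, {(int(inv[i]), int(inv[j]))
                                      for i, j in vg.edges})
                  for v, vg in g.graphs.items()}
        p2 = model.forward(MultiViewGraph("r", nfm, graphs, g.y[perm])).p
        np.testing.assert_allclose(p2, p1[perm], atol=1e-7)

    def test_msf_off_concatenates_scales(self):
        g = _rand_graph(n=5, d_init=5, seed=2)
        cfg = ModelConfig(d_init=5, d_hidden=8, d_scale=6, n_heads=2,
                          use_msf=False, dropout=0.0)
        model = MultiViewSiteModel(cfg)
        emb = model.forward(g)
        assert emb.Z_f.shape == (5, 4 * 6)
        assert emb.Z_enhanced is None
        assert "msf.Wq" not in model.params


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path, small_graph, small_model):
        path = tmp_path / "ckpt.npz"
        small_model.save(path)
        loaded = MultiViewSiteModel.load(path)
        np.testing.assert_array_equal(loaded.forward(small_graph).p,
                                      small_model.forward(small_graph).p)
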