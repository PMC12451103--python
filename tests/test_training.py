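import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mvsite import (ModelConfig, TrainConfig, ablate, compute_metrics,
                    roc_auc, split_dataset, train)
from mvsite.synthetic import DatasetSpec, _simulate_one
from mvsite.training import (apply_ablation_to_model_config,
                             apply_feature_ablation, batch_loss,
                             ABLATION_VARIANTS)
from mvsite.model import MultiViewSiteModel

from oracles import brute_auc, brute_metrics


class TestSplitDataset:
    def test_sixty_chains_nine_to_one(self):
        train_c, val_c = split_dataset(list(range(60)), 0.1, seed=0)
        assert len(train_c) == 54 and len(val_c) == 6

    def test_deterministic_given_seed(self):
        a = split_dataset(list(range(17)), 0.1, seed=5)
        b = split_dataset(list(range(17)), 0.1, seed=5)
        assert a == b

    def test_two_chains_half(self):
        train_c, val_c = split_dataset([0, 1], 0.5, seed=0)
        assert len(train_c) == 1 and len(val_c) == 1

    def test_fewer_than_two_raises(self):
        with pytest.raises(ValueError):
            split_dataset([0], 0.1, seed=0)

    def test_partition_is_disjoint_and_complete(self):
        chains = list(range(23))
        tr, va = split_dataset(chains, 0.25, seed=2)
        assert sorted(tr + va) == chains


class TestMetrics:
    def test_perfect_prediction(self):
        rep = compute_metrics([0, 1, 1, 0], [0.1, 0.9, 0.8, 0.2])
        assert (rep.precision, rep.recall, rep.mcc, rep.auc) == (1, 1, 1, 1)

    def test_worked_confusion_example(self):
        # TP=2 FP=1 TN=3 FN=1 -> MCC = 5 / sqrt(3*3*4*4) = 5/12
        y = [1, 1, 1, 0, 0, 0, 0]
        p = [0.9, 0.8, 0.1, 0.7, 0.2, 0.2, 0.1]
        rep = compute_metrics(y, p)
        assert (rep.TP, rep.FP, rep.TN, rep.FN) == (2, 1, 3, 1)
        assert rep.mcc == pytest.approx(5 / 12)

    def test_constant_scores_auc_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5] * 4) == pytest.approx(0.5)

    def test_single_class_auc_missing(self):
        assert compute_metrics([1, 1], [0.2, 0.9]).auc is None

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            compute_metrics([1, 0], [0.5])

    def test_mcc_invariant_under_class_swap(self):
        y = np.array([1, 0, 1, 1, 0, 0, 1, 0])
        p = np.array([0.9, 0.6, 0.2, 0.7, 0.1, 0.55, 0.8, 0.3])
        a = compute_metrics(y, p).mcc
        b = compute_metrics(1 - y, 1 - p + 1e-9).mcc
        assert a == pytest.approx(b)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        y = rng.integers(0, 2, size=n)
        p = np.round(rng.uniform(size=n), 2)        # force score ties
        rep = compute_metrics(y, p)
        tp, fp, tn, fn, prec, rec, mcc = brute_metrics(y, p)
        assert (rep.TP, rep.FP, rep.TN, rep.FN) == (tp, fp, tn, fn)
        assert rep.precision == pytest.approx(prec, abs=1e-12)
        assert rep.recall == pytest.approx(rec, abs=1e-12)
        assert rep.mcc == pytest.approx(mcc, abs=1e-12)
        expected_auc = brute_auc(y, p)
        if expected_auc is None:
            assert rep.auc is None
        else:
            assert rep.auc == pytest.approx(expected_auc, abs=1e-12)

    def test_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=200)
        p = np.round(rng.uniform(size=200), 2)
        assert roc_auc(y, p) == pytest.approx(roc_auc_score(y, p), abs=1e-12)


class TestAblate:
    def test_returns_flagged_config(self):
        cfg = ablate(TrainConfig(), "ter_str")
        assert cfg.ablation == "ter_str"

    def test_unknown_variant_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            ablate(TrainConfig(), "everything")

    @pytest.mark.parametrize("variant,view", [("prim_str", "P"),
                                              ("sec_str", "S"),
                                              ("ter_str", "T")])
    def test_structure_variants_drop_the_view(self, variant, view):
        mcfg = apply_ablation_to_model_config(
            ModelConfig(d_init=4), variant)
        assert view not in mcfg.views and len(mcfg.views) == 2

    def test_msf_variant_disables_scale_attention(self):
        mcfg = apply_ablation_to_model_config(ModelConfig(d_init=4), "msf")
        assert not mcfg.use_msf

    def test_feature_variants_zero_the_block(self, small_graph):
        out = apply_feature_ablation([small_graph], "sec_feat")[0]
        assert (out.features.block("secondary") == 0).all()
        assert not (small_graph.features.block("secondary") == 0).all()
        assert out.graphs["S"].edges == small_graph.graphs["S"].edges

    def test_full_model_parameters_superset_of_every_variant(self):
        base = ModelConfig(d_init=4, d_hidden=8, d_scale=6, n_heads=2)
        full = set(MultiViewSiteModel(base).params)
        for variant in ABLATION_VARIANTS:
            mcfg = apply_ablation_to_model_config(base, variant)
            assert set(MultiViewSiteModel(mcfg).params) <= full


def _tiny_dataset(n_rnas=6, seed=3, signal=2.0, epochs=None):
    dspec = DatasetSpec(length_range=(18, 24), d_emb=6, msa_depth=12,
                        pocket_signal_strength=signal, seed=seed)
    rng = np.random.default_rng(seed)
    return [_simulate_one(dspec, i, rng) for i in range(n_rnas)]


class TestTrainLoop:
    def test_batch_loss_is_mean_of_per_node_bce(self):
        graphs = _tiny_dataset(2)
        cfg = ModelConfig(d_init=graphs[0].features.d_init, d_hidden=8,
                          d_scale=6, n_heads=2, dropout=0.0, seed=1)
        model = MultiViewSiteModel(cfg)
        loss = float(batch_loss(model, graphs).data)
        terms = []
        for g in graphs:
            p = model.predict_proba(g)
            terms.extend(-(g.y * np.log(p) + (1 - g.y) * np.log(1 - p)))
        assert loss == pytest.approx(np.mean(terms), rel=1e-9)

    def test_loss_decreases_on_learnable_data(self):
        graphs = _tiny_dataset(6, signal=3.0)
        mcfg = ModelConfig(d_init=graphs[0].features.d_init, d_hidden=8,
                           d_scale=8, n_heads=2, dropout=0.0, seed=2)
        result = train(graphs[:5], graphs[5:], mcfg,
                       TrainConfig(seed=2, epochs=10))
        losses = [h["train_loss"] for h in result.history]
        assert losses[-1] < losses[0]

    def test_single_class_labels_raise(self):
        graphs = _tiny_dataset(3)
        for g in graphs:
            g.y[:] = 0
        mcfg = ModelConfig(d_init=graphs[0].features.d_init)
        with pytest.raises(ValueError, match="one class"):
            train(graphs[:2], graphs[2:], mcfg, TrainConfig(epochs=1))

    def test_sensitivity_sweep_reports_both_axes(self):
        from mvsite.training import sensitivity_sweep, sweep_to_tsv
        graphs = _tiny_dataset(8)
        mcfg = ModelConfig(d_init=graphs[0].features.d_init, d_hidden=8,
                           d_scale=6, n_heads=2, seed=1)
        tcfg = TrainConfig(seed=1, epochs=2)
        rows = sensitivity_sweep(graphs[:6], graphs[6:7], graphs[7:],
                                 mcfg, tcfg, k_values=[4, 8], sweep="k")
        assert [r["value"] for r in rows] == [4, 8]
        rows += sensitivity_sweep(graphs[:6], graphs[6:7], graphs[7:],
                                  mcfg, tcfg, layer_values=[1], sweep="layers")
        text = sweep_to_tsv(rows)
        assert text.startswith("sweep\tvalue") and len(text.splitlines()) == 4

    def test_identical_seed_identical_history(self):
        graphs = _tiny_dataset(5)
        mcfg = ModelConfig(d_init=graphs[0].features.d_init, d_hidden=8,
                           d_scale=6, n_heads=2, seed=7)
        tcfg = TrainConfig(seed=7, epochs=4)
        r1 = train(graphs[:4], graphs[4:], mcfg, tcfg)
        r2 = train(graphs[:4], graphs[4:], mcfg, tcfg)
        assert r1.history_text() == r2.history_text()
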