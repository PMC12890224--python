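"""Model wiring, training behaviour, evaluation harness and feature analysis."""

import dataclasses

import numpy as np
import pytest

from survformer import (
    ModelConfig,
    SimConfig,
    build_model,
    concordance_index,
    feature_correlation_analysis,
    fit,
    fit_pipeline,
    repeated_holdout,
    select_K,
    simulate_cohort,
)
from survformer.train import FittedPipeline


def _tiny_cfg(**kw):
    base = dict(epochs=30, d_latent=8, d_c=4, d_head_out=4, d_attn=8, d_h=4,
                K=5, seed=0)
    base.update(kw)
    return ModelConfig(**base)


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(SimConfig(n=80, p=(10, 8), seed=1))


class TestBuildModel:
    def test_cross_only_has_no_inter_sample_weights(self):
        m = build_model("cross_only", [10, 8], d_latent=8, d_c=4)
        assert "W_Q" not in m.params and "W_V" not in m.params
        assert "W_Qc_0" in m.params

    def test_single_graph_ignores_other_omics(self, cohort):
        omics, surv, _ = cohort
        cfg = _tiny_cfg(variant="single_graph", omics_index=0)
        pipe = fit_pipeline(omics, surv, cfg)
        base = pipe.training_scores()
        # perturb the second layer: scores must not move
        X2 = pipe.X_train[1].copy()
        pipe.X_train[1] = pipe.X_train[1] + 100.0
        np.testing.assert_array_equal(pipe.training_scores(), base)
        pipe.X_train[1] = X2

    @pytest.mark.parametrize("variant", ["full", "single_graph", "concat_graph",
                                         "cross_only", "cross_gcn", "cross_attn"])
    def test_forward_smoke_all_variants(self, cohort, variant):
        omics, surv, _ = cohort
        idx = np.arange(10)
        pipe = fit_pipeline([m.subset(idx) for m in omics], surv.subset(idx),
                            _tiny_cfg(variant=variant, epochs=2, K=3))
        s = pipe.training_scores()
        assert s.shape == (10,) and np.isfinite(s).all()

    def test_unknown_variant_fatal(self):
        with pytest.raises(ValueError, match="unknown variant"):
            build_model("nope", [4, 4])


class TestFit:
    def test_loss_decreases(self, cohort):
        omics, surv, _ = cohort
        pipe = fit_pipeline(omics, surv, _tiny_cfg(epochs=60))
        assert np.isfinite(pipe.loss_trace).all()
        assert pipe.loss_trace[-1] <= pipe.loss_trace[0]

    def test_zero_learning_rate_leaves_parameters(self, cohort):
        omics, surv, _ = cohort
        cfg = _tiny_cfg(lr=0.0, epochs=5)
        from survformer.train import Model
        from survformer.io import Preprocessor

        X = [Preprocessor().fit_transform(m).values for m in omics]
        model = Model(cfg, [x.shape[1] for x in X])
        before = {k: p.data.copy() for k, p in model.params.items()}
        from survformer.graph import build_fused_graph
        g = build_fused_graph(X, K=cfg.K)
        fit(model, X, surv, g)
        for k, p in model.params.items():
            np.testing.assert_array_equal(p.data, before[k])

    def test_training_requires_events(self, cohort):
        omics, surv, _ = cohort
        from survformer.io import SurvivalTable

        no_events = SurvivalTable(surv.time, np.zeros_like(surv.event))
        with pytest.raises(ValueError, match="at least one"):
            fit_pipeline(omics, no_events, _tiny_cfg())

    def test_fixed_seed_reproducible_trace(self, cohort):
        omics, surv, _ = cohort
        t1 = fit_pipeline(omics, surv, _tiny_cfg(epochs=10)).loss_trace
        t2 = fit_pipeline(omics, surv, _tiny_cfg(epochs=10)).loss_trace
        assert t1 == t2

    def test_strong_signal_training_discrimination(self):
        omics, surv, truth = simulate_cohort(SimConfig(n=200, seed=2))
        oracle_c, _ = concordance_index(truth["eta"], surv)
        assert oracle_c > 0.85  # generator's benchmark, computed first
        pipe = fit_pipeline(omics, surv, ModelConfig(epochs=400, seed=0))
        train_c, _ = concordance_index(pipe.training_scores(), surv)
        assert train_c > 0.8


class TestRepeatedHoldout:
    def test_split_sizes_and_result_count(self, cohort):
        omics, surv, _ = cohort
        results, summary = repeated_holdout(omics, surv, _tiny_cfg(epochs=5),
                                            n_repeats=3)
        assert len(results) == 3
        assert summary["n_repeats"] == 3
        assert 0 <= summary["c_index_mean"] <= 1

    def test_same_master_seed_is_deterministic(self, cohort):
        omics, surv, _ = cohort
        _, s1 = repeated_holdout(omics, surv, _tiny_cfg(epochs=5), n_repeats=2,
                                 seed=9)
        _, s2 = repeated_holdout(omics, surv, _tiny_cfg(epochs=5), n_repeats=2,
                                 seed=9)
        assert s1 == s2

    def test_test_labels_never_influence_training(self, cohort):
        """Taint check: permuting held-out outcomes changes no trained weight."""
        omics, surv, _ = cohort
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(surv))
        tr, te = idx[:64], idx[64:]
        cfg = _tiny_cfg(epochs=10)

        pipe1 = fit_pipeline([m.subset(tr) for m in omics], surv.subset(tr), cfg)

        # permute the held-out survival rows; training inputs are untouched
        from survformer.io import SurvivalTable

        perm = rng.permutation(len(te))
        tainted_time = surv.time.copy()
        tainted_event = surv.event.copy()
        tainted_time[te] = tainted_time[te][perm]
        tainted_event[te] = tainted_event[te][perm]
        tainted = SurvivalTable(tainted_time, tainted_event, surv.sample_ids)
        pipe2 = fit_pipeline([m.subset(tr) for m in omics], tainted.subset(tr),
                             cfg)
        for k in pipe1.model.params:
            np.testing.assert_array_equal(pipe1.model.params[k].data,
                                          pipe2.model.params[k].data)


class TestSelectK:
    def test_single_value_grid(self, cohort):
        omics, surv, _ = cohort
        best, _ = select_K(omics, surv, [7], _tiny_cfg())
        assert best == 7

    def test_tie_prefers_smaller_K(self, cohort):
        # both K values exceed n-1 within folds and are clipped to the same
        # effective neighbourhood, so their scores tie exactly
        omics, surv, _ = cohort
        best, curve = select_K(omics, surv, [200, 300], _tiny_cfg(epochs=3),
                               folds=2)
        assert curve[200] == curve[300]
        assert best == 200

    def test_empty_grid_rejected(self, cohort):
        omics, surv, _ = cohort
        with pytest.raises(ValueError, match="empty"):
            select_K(omics, surv, [], _tiny_cfg())


class TestSerialization:
    def test_round_trip_reproduces_predictions(self, cohort, tmp_path):
        omics, surv, _ = cohort
        idx = np.arange(len(surv))
        tr, te = idx[:64], idx[64:]
        pipe = fit_pipeline([m.subset(tr) for m in omics], surv.subset(tr),
                            _tiny_cfg(epochs=10))
        test_omics = [m.subset(te) for m in omics]
        expected = pipe.predict_risk(test_omics)

        path = tmp_path / "model.npz"
        pipe.save(path)
        loaded = FittedPipeline.load(path)
        np.testing.assert_array_equal(loaded.predict_risk(test_omics), expected)
        assert loaded.cfg == pipe.cfg
        assert loaded.loss_trace == pipe.loss_trace


class TestFeatureCorrelation:
    def test_feature_equal_to_hidden_node_ranks_first(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 5))
        Zh = np.column_stack([X[:, 2], rng.normal(size=30)])
        table = feature_correlation_analysis(X, Zh, top_m=3)
        top = table[(table.hidden_node == 0) & (table["rank"] == 1)].iloc[0]
        assert top.feature_id == "f2"
        assert top.r == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        z = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        table = feature_correlation_analysis(x[:, None], z[:, None], top_m=1)
        xc, zc = x - x.mean(), z - z.mean()
        expected = (xc @ zc) / np.sqrt((xc @ xc) * (zc @ zc))
        assert table.iloc[0].r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_hidden_node_skipped(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 3))
        Zh = np.column_stack([np.ones(10), X[:, 0]])
        with pytest.warns(UserWarning, match="zero variance"):
            table = feature_correlation_analysis(X, Zh, top_m=2)
        assert set(table.hidden_node) == {1}

    def test_independent_noise_has_small_correlation(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(2000, 4))
        Zh = rng.normal(size=(2000, 1))
        table = feature_correlation_analysis(X, Zh, top_m=4)
        assert table.r.abs().max() < 0.1
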