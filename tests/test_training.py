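"""Training loop: stopping rule, leakage guard, determinism, ensemble,
grid search. Uses a reduced 24-slide cohort with 64-d bags for speed."""

import numpy as np
import pytest

from conftest import small_cohort, tiny_model_cfg, tiny_train_cfg
from milpath.config import LossConfig, OversampleConfig, TrainConfig
from milpath.training import (MILEnsembleClassifier, MILResponseClassifier,
                              assert_no_leakage, grid_search)


class TestLeakageGuard:
    def test_disjoint_ids_pass(self):
        assert_no_leakage(["a", "b"], ["c"], ["d"])

    def test_shared_id_raises(self):
        with pytest.raises(RuntimeError, match="leakage"):
            assert_no_leakage(["a", "b"], ["b"])

    def test_fit_rejects_overlapping_cohorts(self, sep6_small):
        train, val, _ = sep6_small
        clf = MILResponseClassifier(model=tiny_model_cfg(),
                                    train=tiny_train_cfg(max_epochs=2,
                                                         patience=1))
        with pytest.raises(RuntimeError, match="leakage"):
            clf.fit(train, val_bags=train[:2])


class TestEarlyStopping:
    def test_constant_metric_stops_after_patience(self, sep0_small):
        train, val, _ = sep0_small
        # separation 0 ⇒ validation metric flat almost immediately
        clf = MILResponseClassifier(
            model=tiny_model_cfg(),
            train=tiny_train_cfg(max_epochs=30, patience=1, n_members=1),
            oversample=OversampleConfig(method="none"))
        clf.fit(train, val_bags=val)
        n_epochs = len(clf.history_.table)
        assert n_epochs < 30
        assert clf.history_.best_epoch <= n_epochs

    def test_history_and_steps_recorded(self, sep6_small):
        train, val, _ = sep6_small
        clf = MILResponseClassifier(model=tiny_model_cfg(),
                                    train=tiny_train_cfg(max_epochs=3))
        clf.fit(train, val_bags=val)
        table = clf.history_.table
        assert {"epoch", "val_accuracy", "val_macro_f1"} <= set(table.columns)
        steps_per_epoch = int(np.ceil(len(train) / 8))
        assert clf.history_.total_steps == steps_per_epoch * len(table)


class TestDeterminism:
    def test_same_seed_reproduces_metrics(self, sep6_small):
        train, val, _ = sep6_small

        def run():
            clf = MILResponseClassifier(model=tiny_model_cfg(),
                                        train=tiny_train_cfg(max_epochs=3),
                                        seed=11)
            clf.fit(train, val_bags=val)
            return clf

        a, b = run(), run()
        assert np.allclose(
            a.history_.table["val_macro_f1"].to_numpy(),
            b.history_.table["val_macro_f1"].to_numpy(), atol=1e-6)
        assert np.allclose(a.predict_proba(val), b.predict_proba(val),
                           atol=1e-6)

    def test_different_seeds_differ(self, sep6_small):
        train, val, _ = sep6_small
        probs = []
        for seed in (0, 1):
            clf = MILResponseClassifier(model=tiny_model_cfg(),
                                        train=tiny_train_cfg(max_epochs=2,
                                                             patience=1),
                                        seed=seed)
            clf.fit(train, val_bags=val)
            probs.append(clf.predict_proba(val))
        assert not np.allclose(probs[0], probs[1])


class TestDecisionModes:
    @pytest.mark.parametrize("decision", ["cascade", "joint", "vote"])
    def test_all_modes_emit_valid_distributions(self, sep6_small, decision):
        train, val, _ = sep6_small
        clf = MILResponseClassifier(
            model=tiny_model_cfg(),
            train=tiny_train_cfg(max_epochs=2, patience=1,
                                 decision=decision))
        clf.fit(train, val_bags=val)
        probs = clf.predict_proba(val)
        assert probs.shape == (len(val), 3)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(probs >= 0)


class TestEnsemble:
    def test_single_member_no_bootstrap_equals_member(self, sep6_small):
        train, val, _ = sep6_small
        cfg = tiny_train_cfg(max_epochs=2, patience=1, n_members=1,
                             bootstrap=False)
        ens = MILEnsembleClassifier(model=tiny_model_cfg(), train=cfg,
                                    seed=4)
        ens.fit(train, val_bags=val)
        single = MILResponseClassifier(model=tiny_model_cfg(), train=cfg,
                                       seed=4)
        single.fit(train, val_bags=val)
        assert np.allclose(ens.predict_proba(val),
                           single.predict_proba(val), atol=1e-9)

    def test_weights_normalized_and_convexity(self, sep6_small):
        train, val, _ = sep6_small
        ens = MILEnsembleClassifier(
            model=tiny_model_cfg(),
            train=tiny_train_cfg(max_epochs=2, patience=1, n_members=3),
            seed=0)
        ens.fit(train, val_bags=val)
        assert ens.weights_.sum() == pytest.approx(1.0)
        member_probs = np.stack([m.predict_proba(val)
                                 for m in ens.members_])
        combined = ens.predict_proba(val)
        assert np.all(combined <= member_probs.max(axis=0) + 1e-9)
        assert np.all(combined >= member_probs.min(axis=0) - 1e-9)

    def test_checkpoint_round_trip(self, sep6_small, tmp_path):
        train, val, _ = sep6_small
        clf = MILResponseClassifier(model=tiny_model_cfg(),
                                    train=tiny_train_cfg(max_epochs=2,
                                                         patience=1))
        clf.fit(train, val_bags=val)
        clf.save(tmp_path / "member.npz")
        loaded = MILResponseClassifier.load(tmp_path / "member.npz")
        assert np.allclose(loaded.predict_proba(val),
                           clf.predict_proba(val), atol=1e-12)


class TestGridSearch:
    def test_single_point_grid_returns_it(self, sep6_small):
        train, val, _ = sep6_small
        best, table = grid_search(
            train, val, {"init_lr": [1e-4]}, model=tiny_model_cfg(),
            train=tiny_train_cfg(max_epochs=2, patience=1))
        assert best == {"init_lr": 1e-4}
        assert len(table) == 1

    def test_divergent_learning_rate_loses(self, sep6_small):
        train, val, _ = sep6_small
        best, table = grid_search(
            train, val, {"init_lr": [1e-4, 10.0]}, model=tiny_model_cfg(),
            train=tiny_train_cfg(max_epochs=3, patience=2))
        assert best["init_lr"] == 1e-4

    def test_table_is_exhaustive_product(self, sep6_small):
        train, val, _ = sep6_small
        grid = {"init_lr": [1e-4, 1e-3], "batch_size": [4, 8]}
        _, table = grid_search(train, val, grid, model=tiny_model_cfg(),
                               train=tiny_train_cfg(max_epochs=2,
                                                    patience=1))
        assert len(table) == 4

    def test_empty_grid_rejected(self, sep6_small):
        train, val, _ = sep6_small
        with pytest.raises(ValueError):
            grid_search(train, val, {})


class TestOversamplingIntegration:
    @pytest.mark.parametrize("method", ["smote", "adasyn"])
    def test_methods_run_and_fit(self, sep6_small, method):
        train, val, _ = sep6_small
        clf = MILResponseClassifier(
            model=tiny_model_cfg(),
            train=tiny_train_cfg(max_epochs=2, patience=1),
            oversample=OversampleConfig(method=method))
        clf.fit(train, val_bags=val)
        assert hasattr(clf, "model_")

    def test_dann_branch_trains_with_external_domain_bags(self, sep6_small):
        train, val, ext = sep6_small
        clf = MILResponseClassifier(
            model=tiny_model_cfg(),
            train=tiny_train_cfg(max_epochs=2, patience=1),
            loss=LossConfig(dann_use_unlabeled_external=True))
        clf.fit(train, val_bags=val, domain_bags=ext)
        assert hasattr(clf, "model_")
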