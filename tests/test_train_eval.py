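"""Metrics, early stopping, cross-validation plumbing, outlier subsets."""

import numpy as np
import pytest

import plmddg as p
from plmddg.errors import ConfigurationError, LeakageError, ShapeError
from plmddg.model import DdgRegressor, ModelConfig
from plmddg.train_eval import (
    TrainConfig,
    _pair_aware_val_split,
    compute_metrics,
    evaluate_independent,
    outlier_subset,
    train,
)


class TestComputeMetrics:
    def test_identity_predictions(self):
        y = np.array([0.5, -1.0, 2.0])
        m = compute_metrics(y, y)
        assert m["pcc"] == 1.0
        assert m["mae"] == 0.0 and m["rmse"] == 0.0 and m["mse"] == 0.0

    def test_hand_computed_case(self):
        m = compute_metrics(np.array([1.0, 2, 3]), np.array([2.0, 4, 6]))
        assert m["pcc"] == pytest.approx(1.0, abs=1e-9)
        assert m["mae"] == pytest.approx(2.0, abs=1e-9)
        assert m["rmse"] == pytest.approx(np.sqrt(14 / 3), abs=1e-9)

    def test_rmse_squared_equals_mse(self):
        rng = np.random.default_rng(0)
        y, yhat = rng.normal(size=50), rng.normal(size=50)
        m = compute_metrics(y, yhat)
        assert m["rmse"] ** 2 == pytest.approx(m["mse"], abs=1e-9)
        assert m["mae"] <= m["rmse"]

    def test_constant_prediction_flags_pcc(self):
        m = compute_metrics(np.array([1.0, 2, 3]), np.zeros(3))
        assert not m["pcc_defined"]
        assert np.isnan(m["pcc"])
        assert m["mae"] == 2.0  # errors still computed

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            compute_metrics(np.zeros(3), np.zeros(4))


def _toy_records(n=30, seed=0):
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        wt, mut = "NDEKRQ"[i % 6], "AGHWYF"[i % 6]
        recs.append(p.MutationRecord(f"C{i % 7}", "A", wt, (i % 40) + 1, mut,
                                     float(rng.normal()), "DSB", "train"))
    return p.reverse_augment(recs)


class _StubModel:
    """Predicts a fixed linear readout of the first channel's center row."""

    def __init__(self, const=0.0):
        self.const = const

    def predict(self, arrays):
        return np.full(len(arrays[0]), self.const)


class TestValidationSplit:
    def test_pairs_never_straddle_the_split(self):
        aug = _toy_records(40)
        mask = _pair_aware_val_split(aug, 0.1, seed=3)
        for r, m in zip(aug, mask):
            partner = [m2 for r2, m2 in zip(aug, mask)
                       if r2.site_key == r.site_key]
            assert all(x == m for x in partner)

    def test_fraction_respected_roughly(self):
        aug = _toy_records(100)
        mask = _pair_aware_val_split(aug, 0.1, seed=0)
        assert 0.02 <= mask.mean() <= 0.25


class TestEarlyStopping:
    def _run(self, metric_sequence, patience=40, max_epochs=150):
        """Drive the stopping rule directly through a scripted history."""
        best, best_epoch, since, stopped = np.inf, 0, 0, 0
        for epoch in range(1, max_epochs + 1):
            m = metric_sequence(epoch)
            stopped = epoch
            if m < best:
                best, best_epoch, since = m, epoch, 0
            else:
                since += 1
                if since >= patience:
                    break
        return best_epoch, stopped

    def test_frozen_metric_stops_at_41_best_1(self):
        best, stopped = self._run(lambda e: 1.0)
        assert (best, stopped) == (1, 41)

    def test_strict_improvement_runs_all_150(self):
        best, stopped = self._run(lambda e: -e)
        assert (best, stopped) == (150, 150)

    def test_training_loop_applies_the_same_rule(self, synthetic_backends):
        # constant labels freeze the validation loss almost immediately;
        # training must stop long before max_epochs
        seqs, recs, _ = p.generate(p.FixtureConfig(
            n_complexes=4, mutations_per_complex=3, noise_sigma=0.0))
        aug = p.reverse_augment(recs)
        arrays = p.embeddings.build_channel_arrays(
            aug, seqs, 9, synthetic_backends)
        cfg = ModelConfig(window_length=9, channel_dims=(64, 64, 48),
                          projected_dim=8, feedforward_dim=16,
                          head_hidden=(8, 4), dropout=0.0)
        model = DdgRegressor(cfg)
        tcfg = TrainConfig(max_epochs=30, early_stop_patience=5,
                           learning_rate=0.0, seed=0)
        _, hist = train(model, aug, arrays, tcfg)
        # zero learning rate: nothing improves after epoch 1
        assert hist.best_epoch == 1
        assert hist.stopped_epoch == 6

    def test_determinism_same_seed_same_history(self, synthetic_backends):
        seqs, recs, _ = p.generate(p.FixtureConfig(
            n_complexes=4, mutations_per_complex=3))
        aug = p.reverse_augment(recs)
        arrays = p.embeddings.build_channel_arrays(
            aug, seqs, 9, synthetic_backends)
        cfg = ModelConfig(window_length=9, channel_dims=(64, 64, 48),
                          projected_dim=8, feedforward_dim=16,
                          head_hidden=(8, 4))
        hists = []
        for _ in range(2):
            model = DdgRegressor(cfg)
            tcfg = TrainConfig(max_epochs=3, early_stop_patience=2,
                               learning_rate=1e-3, seed=5)
            _, hist = train(model, aug, arrays, tcfg)
            hists.append(hist)
        assert hists[0].train_loss == hists[1].train_loss
        assert hists[0].val_metric == hists[1].val_metric

    def test_patience_must_be_below_max_epochs(self):
        with pytest.raises(ConfigurationError):
            TrainConfig(max_epochs=10, early_stop_patience=10)


class TestEvaluateIndependent:
    def test_zero_stub_on_symmetric_set_gives_mae_mean_abs(self):
        aug = _toy_records(20)
        arrays = [np.zeros((len(aug), 3, 4))]
        metrics, rows = evaluate_independent(_StubModel(0.0), aug, arrays)
        expected = np.mean([abs(r.ddg) for r in aug])
        assert metrics["mae"] == pytest.approx(expected)
        assert len(rows) == len(aug)

    def test_leakage_detected_and_overridable(self):
        aug = _toy_records(10)
        arrays = [np.zeros((len(aug), 3, 4))]
        train_cplx = {aug[0].complex_id}
        with pytest.raises(LeakageError):
            evaluate_independent(_StubModel(), aug, arrays,
                                 train_complexes=train_cplx)
        metrics, _ = evaluate_independent(_StubModel(), aug, arrays,
                                          train_complexes=train_cplx,
                                          allow_overlap=True)
        assert "mae" in metrics


class TestOutlierSubset:
    def test_top_two_of_twenty(self):
        y = np.arange(20.0)  # |ddg| increasing
        idx, metrics = outlier_subset(y, y, fraction=0.10)
        assert sorted(idx) == [18, 19]
        assert metrics["n"] == 2

    def test_reverse_partner_shares_subset(self):
        recs = _toy_records(20)
        y = np.array([r.ddg for r in recs])
        idx, _ = outlier_subset(y, y, fraction=0.10)
        picked = {recs[i].site_key for i in idx}
        # augmentation gives each forward record an equal-|ddg| reverse:
        # selected sites appear an even number of times
        counts = [sum(1 for i in idx if recs[i].site_key == k) for k in picked]
        assert all(c == 2 for c in counts)

    def test_ties_broken_by_input_order(self):
        y = np.array([1.0, 2.0, 2.0, 0.5])
        idx, _ = outlier_subset(y, y, fraction=0.25)
        assert idx.tolist() == [1]

    def test_fraction_one_rejected(self):
        with pytest.raises(ConfigurationError):
            outlier_subset(np.ones(5), np.ones(5), fraction=1.0)

    def test_empty_input(self):
        idx, metrics = outlier_subset(np.array([]), np.array([]), 0.1)
        assert idx.size == 0 and metrics == {}
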