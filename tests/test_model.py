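"""Batching, validation split, metrics, and the training loop contract."""

import inspect

import numpy as np
import pytest

from eegadapt.model import (
    AdaptationConfig,
    Metrics,
    TDANN,
    leave_one_domain_out,
    make_domain_batches,
    _stratified_val_split,
)


def tiny_config(**kw):
    defaults = dict(
        preset="compact",
        n_classes=2,
        batch_source=20,
        batch_target=20,
        max_epochs=2,
        patience=2,
        seed=0,
    )
    defaults.update(kw)
    return AdaptationConfig(**defaults)


def tiny_data(rng, n_s=80, n_t=40, hw=16):
    xs = rng.normal(size=(n_s, 5, hw, hw))
    ys = rng.integers(0, 2, n_s)
    xt = rng.normal(size=(n_t, 5, hw, hw))
    return xs, ys, xt


class TestMakeDomainBatches:
    def test_800_by_800_split_80_gives_10_batches(self, rng):
        batches = list(make_domain_batches(800, 800, 80, 80, rng))
        assert len(batches) == 10
        assert all(len(s) == 80 and len(t) == 80 for s, t in batches)

    def test_same_seed_identical_composition(self):
        a = list(make_domain_batches(100, 60, 20, 20, np.random.default_rng(5)))
        b = list(make_domain_batches(100, 60, 20, 20, np.random.default_rng(5)))
        for (sa, ta), (sb, tb) in zip(a, b):
            np.testing.assert_array_equal(sa, sb)
            np.testing.assert_array_equal(ta, tb)

    def test_source_samples_cover_pool_exactly_once(self, rng):
        batches = list(make_domain_batches(120, 80, 30, 20, rng))
        src = np.concatenate([s for s, _ in batches])
        # multiset equality with the full pool
        assert sorted(src.tolist()) == list(range(120))

    def test_target_draws_without_replacement_within_cycle(self, rng):
        batches = list(make_domain_batches(200, 100, 20, 50, rng))
        tgt = np.concatenate([t for _, t in batches])
        # 10 batches x 50 = 500 draws = 5 full cycles of 100
        counts = np.bincount(tgt, minlength=100)
        assert set(counts) == {5}

    def test_pool_smaller_than_batch_raises(self, rng):
        with pytest.raises(ValueError, match="smaller than one batch"):
            list(make_domain_batches(10, 50, 20, 20, rng))
        with pytest.raises(ValueError, match="target pool"):
            list(make_domain_batches(50, 10, 20, 20, rng))


class TestValidationSplit:
    def test_85_15_proportions_per_domain(self, rng):
        labels = np.tile([0, 1], 100)
        domains = np.repeat([0, 1], 100)
        train, val = _stratified_val_split(labels, domains, 0.15, rng)
        for d in (0, 1):
            n_val = (val & (domains == d)).sum()
            assert abs(n_val - 15) <= 1
        assert not np.any(train & val)

    def test_stratified_by_class(self, rng):
        labels = np.r_[np.zeros(60, int), np.ones(60, int)]
        domains = np.zeros(120, int)
        _, val = _stratified_val_split(labels, domains, 0.15, rng)
        assert abs(val[labels == 0].sum() - val[labels == 1].sum()) <= 1


class TestMetrics:
    def test_constant_classifier_accuracy_is_prevalence(self):
        y = np.array([0, 0, 0, 1, 1])
        m = Metrics.from_predictions(y, np.zeros(5, int), 2)
        assert m.accuracy == pytest.approx(0.6)

    def test_confusion_trace_over_total_is_accuracy(self, rng):
        y = rng.integers(0, 3, 50)
        p = rng.integers(0, 3, 50)
        m = Metrics.from_predictions(y, p, 3)
        assert np.trace(m.confusion) / m.confusion.sum() == pytest.approx(m.accuracy)
        np.testing.assert_array_equal(m.confusion.sum(axis=1), np.bincount(y, minlength=3))

    def test_class_permutation_leaves_accuracy_unchanged(self, rng):
        y = rng.integers(0, 3, 40)
        p = rng.integers(0, 3, 40)
        perm = np.array([2, 0, 1])
        a = Metrics.from_predictions(y, p, 3).accuracy
        b = Metrics.from_predictions(perm[y], perm[p], 3).accuracy
        assert a == pytest.approx(b)


class TestAdaptationConfig:
    def test_invalid_values_raise(self):
        with pytest.raises(ValueError):
            AdaptationConfig(val_fraction=0.6)
        with pytest.raises(ValueError):
            AdaptationConfig(lambda_d=-0.1)
        with pytest.raises(ValueError):
            AdaptationConfig(gp_eval_points="bogus")

    def test_variants(self):
        cfg = AdaptationConfig()
        assert cfg.variant("mmd_only").lambda_d == 0.0
        assert cfg.variant("dann_only").lambda_m == 0.0
        src = cfg.variant("source_only")
        assert not src.use_target and not src.adaptive_norm
        assert cfg.variant("tdann") == cfg
        with pytest.raises(ValueError):
            cfg.variant("bogus")

    def test_hash_stable_and_sensitive(self):
        a, b = AdaptationConfig(seed=1), AdaptationConfig(seed=1)
        assert a.hash() == b.hash()
        assert a.hash() != AdaptationConfig(seed=2).hash()

    def test_reference_defaults(self):
        cfg = AdaptationConfig()
        assert (cfg.lambda_d, cfg.lambda_m, cfg.lambda_z, cfg.lambda_L) == (0.1, 0.1, 0.01, 10.0)
        assert cfg.batch_source == cfg.batch_target == 80
        assert cfg.learning_rate == 5e-4


class TestTrainingContract:
    def test_target_labels_are_not_accepted_anywhere(self):
        # the training path cannot read test labels: the API has no slot for them
        params = inspect.signature(TDANN.__init__).parameters
        assert "target_labels" not in params
        assert all("target" not in p or "label" not in p for p in params)

    def test_fit_runs_without_target_labels_and_is_seed_deterministic(self, rng):
        xs, ys, xt = tiny_data(rng)
        cfg = tiny_config()
        r1 = TDANN(xs, ys, xt, cfg).fit()
        r2 = TDANN(xs, ys, xt, cfg).fit()
        assert r1.history.equals(r2.history)
        p1 = r1.predict_proba(xt, domain=1)
        p2 = r2.predict_proba(xt, domain=1)
        np.testing.assert_array_equal(p1, p2)

    def test_source_only_ignores_target(self, rng):
        xs, ys, _ = tiny_data(rng)
        cfg = tiny_config().variant("source_only")
        res = TDANN(xs, ys, None, cfg).fit()
        m = res.evaluate(xs, ys, domain=0)
        assert 0.0 <= m.accuracy <= 1.0

    def test_use_target_without_target_pool_raises(self, rng):
        xs, ys, _ = tiny_data(rng)
        with pytest.raises(ValueError, match="target pool"):
            TDANN(xs, ys, None, tiny_config())

    def test_evaluate_unseen_domain_without_adapt_raises(self, rng):
        xs, ys, xt = tiny_data(rng)
        cfg = tiny_config()
        res = TDANN(xs, ys, xt, cfg).fit()
        with pytest.raises(KeyError, match="domain 5"):
            res.evaluate(xt, np.zeros(len(xt), int), domain=5)

    def test_loss_history_columns_and_finiteness(self, rng):
        xs, ys, xt = tiny_data(rng)
        res = TDANN(xs, ys, xt, tiny_config()).fit()
        for col in ("L_C", "L_MMD", "H", "L_G", "val_loss"):
            assert col in res.history.columns
            assert np.isfinite(res.history[col]).all()
        assert res.history["L_C"].iloc[-1] >= 0

    def test_summary_mentions_config(self, rng):
        xs, ys, xt = tiny_data(rng)
        res = TDANN(xs, ys, xt, tiny_config()).fit()
        text = res.summary()
        assert "compact" in text and "lambda_d" in text


class TestLeaveOneDomainOut:
    def _images(self, rng, n_domains=3, per_domain=60, hw=16):
        x = rng.normal(size=(n_domains * per_domain, 5, hw, hw))
        labels = rng.integers(0, 2, n_domains * per_domain)
        domains = np.repeat(np.arange(n_domains), per_domain)
        return x, labels, domains

    def test_each_domain_tested_exactly_once(self, rng):
        x, labels, domains = self._images(rng)
        res = leave_one_domain_out(x, labels, domains, tiny_config(batch_source=16, batch_target=16))
        assert sorted(res.fold_domains) == [0, 1, 2]
        assert len(res.folds) == 3

    def test_summary_mean_is_arithmetic_mean(self, rng):
        x, labels, domains = self._images(rng, n_domains=2)
        res = leave_one_domain_out(x, labels, domains, tiny_config(batch_source=16, batch_target=16))
        assert res.mean_accuracy == pytest.approx(res.accuracies.mean())
        assert "mean" in res.summary()

    def test_single_domain_raises(self, rng):
        x, labels, domains = self._images(rng, n_domains=1)
        with pytest.raises(ValueError, match="at least 2 domains"):
            leave_one_domain_out(x, labels, domains, tiny_config())
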