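"""Weighted metrics, early stopping and hyperparameter search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hinttok.search import (
    Categorical,
    FloatRange,
    IntRange,
    SearchError,
    SearchSpace,
    tpe_search,
)
from hinttok.training import (
    EarlyStopper,
    TrainConfig,
    absolute_improvement,
    evaluate_weighted_metrics,
    fit_with_early_stopping,
    relative_improvement,
)


def brute_force_weighted(y_true, y_pred):
    """Independent per-class computation straight from the confusion counts."""
    labels = sorted(set(y_true) | set(y_pred))
    n = len(y_true)
    wf1 = wp = wr = 0.0
    for c in labels:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        support = tp + fn
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / support if support else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        w = support / n
        wf1 += w * f1
        wp += w * prec
        wr += w * rec
    return wf1, wp, wr


class TestWeightedMetrics:
    def test_perfect_predictions(self):
        y = ["a", "b", "c", "a"]
        rep = evaluate_weighted_metrics(y, y)
        assert rep.weighted_f1 == rep.weighted_precision == rep.weighted_recall == 1.0

    def test_hand_confusion_matrix(self):
        rep = evaluate_weighted_metrics(list("AABB"), list("ABBB"))
        assert rep.weighted_recall == pytest.approx(0.75)  # equals accuracy
        wf1, wp, wr = brute_force_weighted(list("AABB"), list("ABBB"))
        assert rep.weighted_f1 == pytest.approx(wf1)
        assert rep.weighted_precision == pytest.approx(wp)

    def test_majority_class_collapse(self):
        """A constant predictor on a 90/10 binary set scores exactly the
        brute-force per-class value (the no-HTL collapse failure mode)."""
        y_true = ["maj"] * 90 + ["min"] * 10
        y_pred = ["maj"] * 100
        rep = evaluate_weighted_metrics(y_true, y_pred)
        wf1, wp, wr = brute_force_weighted(y_true, y_pred)
        assert rep.weighted_f1 == pytest.approx(wf1, abs=1e-12)
        assert rep.weighted_recall == pytest.approx(0.9)
        assert rep.per_class["min"]["f1"] == 0.0

    def test_oracle_equivalence_1000_random_confusions(self):
        """Weighted F1/precision/recall match the brute-force computation to
        1e-12, and weighted recall equals accuracy, on 1000 random label
        vectors of 2-4 classes."""
        rng = np.random.default_rng(11)
        for _ in range(1000):
            k = int(rng.integers(2, 5))
            n = int(rng.integers(2, 40))
            y_true = rng.integers(0, k, size=n).tolist()
            y_pred = rng.integers(0, k, size=n).tolist()
            rep = evaluate_weighted_metrics(y_true, y_pred)
            wf1, wp, wr = brute_force_weighted(y_true, y_pred)
            acc = float(np.mean(np.array(y_true) == np.array(y_pred)))
            assert abs(rep.weighted_f1 - wf1) < 1e-12
            assert abs(rep.weighted_precision - wp) < 1e-12
            assert abs(rep.weighted_recall - wr) < 1e-12
            assert abs(rep.weighted_recall - acc) < 1e-12

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            evaluate_weighted_metrics([], [])

    def test_rounding_policy(self):
        rep = evaluate_weighted_metrics(list("AABB"), list("ABBB"))
        assert rep.rounded()["weighted_recall"] == 0.75
        assert isinstance(rep.to_json(), str)


class TestImprovements:
    @pytest.mark.parametrize(
        "htl,ctrl,expected",
        [(0.64, 0.25, 156.0), (0.56, 0.35, 60.0), (0.5, 0.5, 0.0)],
    )
    def test_relative(self, htl, ctrl, expected):
        assert relative_improvement(htl, ctrl) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "htl,ctrl,expected", [(0.58, 0.41, 17.0), (0.3, 0.3, 0.0), (0.71, 0.70, 1.0)]
    )
    def test_absolute(self, htl, ctrl, expected):
        assert absolute_improvement(htl, ctrl) == pytest.approx(expected)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            relative_improvement(0.5, 0.0)


class _ScriptedModel:
    """Stub model whose validation F1 follows a scripted sequence."""

    def __init__(self, scores):
        self.scores = list(scores)
        self.epoch = 0

    def train_epoch(self, ids, y, rng, lr, batch_size, dropout):
        self.epoch += 1
        return 0.0

    def predict(self, ids):
        # Return predictions matching y at the scripted accuracy so that
        # weighted F1 equals the scripted score for binary alternating y.
        score = self.scores[min(self.epoch - 1, len(self.scores) - 1)]
        n = len(ids)
        correct = int(round(score * n))
        y = np.arange(n) % 2
        pred = y.copy()
        pred[correct:] = 1 - pred[correct:]
        return pred

    def state_dict(self):
        return {"epoch": self.epoch}

    def load_state_dict(self, state):
        self.restored = state["epoch"]


def _run_scripted(scores, max_epochs=50, patience=15):
    model = _ScriptedModel(scores)
    n = 20
    X = np.zeros((n, 4))
    y = np.arange(n) % 2
    cfg = TrainConfig(max_epochs=max_epochs, patience=patience, seed=0)
    fit = fit_with_early_stopping(model, (X, y), (X, y), cfg, class_labels=[0, 1])
    return fit, model


def stopping_epoch_oracle(scores, max_epochs, patience):
    """Hand-stepped counter over a score sequence."""
    best = -np.inf
    stale = 0
    for epoch in range(1, max_epochs + 1):
        s = scores[min(epoch - 1, len(scores) - 1)]
        if s > best:
            best, stale = s, 0
        else:
            stale += 1
        if stale >= patience:
            return epoch
    return max_epochs


class TestEarlyStopping:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(max_epochs=10, patience=11)
        with pytest.raises(ValueError):
            TrainConfig(patience=0)

    def test_constant_score_stops_after_patience_plus_one(self):
        fit, _ = _run_scripted([0.5] * 60)
        assert fit.stopping_epoch == 16
        assert fit.best_epoch == 1

    def test_patience_one_immediate_stop(self):
        fit, _ = _run_scripted([0.5, 0.4, 0.4, 0.4], patience=1)
        assert fit.stopping_epoch == 2

    def test_restores_best_checkpoint(self):
        fit, model = _run_scripted([0.2, 0.8, 0.3] + [0.3] * 30)
        assert fit.best_epoch == 2
        assert model.restored == 2

    def test_counter_matches_oracle_on_random_sequences(self):
        """Early stopping equals a reference counter simulation for arbitrary
        score ladders, honoring the 50-epoch cap and patience 15."""
        rng = np.random.default_rng(4)
        for _ in range(60):
            scores = np.round(rng.random(60), 2).tolist()
            patience = int(rng.integers(1, 16))
            max_epochs = int(rng.integers(patience, 51))
            stopper = EarlyStopper(patience)
            stopped = max_epochs
            for ep in range(1, max_epochs + 1):
                if stopper.update(ep, scores[ep - 1]):
                    stopped = ep
                    break
            assert stopped == stopping_epoch_oracle(scores, max_epochs, patience)
            assert stopped <= max_epochs


class TestSearch:
    def test_space_validation(self):
        with pytest.raises(SearchError):
            SearchSpace({}, n_trials=5)
        with pytest.raises(SearchError):
            SearchSpace({"x": FloatRange(0, 1)}, n_trials=0)
        with pytest.raises(SearchError):
            FloatRange(1.0, 1.0)
        with pytest.raises(SearchError):
            Categorical(())

    def test_constant_objective_returns_first_trial(self):
        space = SearchSpace({"x": FloatRange(0, 1)}, n_trials=10, seed=0)
        res = tpe_search(space, lambda p: 1.0)
        assert res.best_trial.number == 0
        assert len(res.trials) == 10

    def test_single_trial_is_one_random_draw(self):
        space_t = SearchSpace({"x": FloatRange(0, 1)}, n_trials=1, sampler="tpe", seed=3)
        space_r = SearchSpace({"x": FloatRange(0, 1)}, n_trials=1, sampler="random", seed=3)
        rt = tpe_search(space_t, lambda p: p["x"])
        rr = tpe_search(space_r, lambda p: p["x"])
        assert rt.best_params == rr.best_params

    def test_seed_reproducibility(self):
        space = SearchSpace(
            {"x": FloatRange(0, 1), "c": Categorical((1, 2, 3)), "k": IntRange(1, 9)},
            n_trials=10,
            seed=5,
        )
        f = lambda p: -((p["x"] - 0.3) ** 2) + 0.01 * p["k"]
        a = tpe_search(space, f)
        b = tpe_search(space, f)
        assert [t.params for t in a.trials] == [t.params for t in b.trials]

    def test_startup_equals_trials_degenerates_to_random(self):
        from hinttok.search import TPESampler, RandomSampler, Trial

        params = {"x": FloatRange(0, 1), "c": Categorical(("a", "b"))}
        history = []
        rng1, rng2 = np.random.default_rng(8), np.random.default_rng(8)
        tpe = TPESampler(n_startup=10)
        rnd = RandomSampler()
        for t in range(10):
            p1 = tpe.suggest(rng1, params, history)
            p2 = rnd.suggest(rng2, params, history)
            assert p1 == p2
            history.append(Trial(t, p1, float(t)))
            history.pop()  # keep history empty-equivalent (below startup anyway)

    def test_all_nonfinite_trials_error(self):
        space = SearchSpace({"x": FloatRange(0, 1)}, n_trials=3, seed=0)
        with pytest.raises(SearchError):
            tpe_search(space, lambda p: float("nan"))

    def test_tpe_beats_random_on_quadratic(self):
        """Median |best_x − 0.7| over 200 seeds is smaller for TPE than for
        pure random search on −(x − 0.7)² with 10 trials."""
        errs = {"tpe": [], "random": []}
        for sampler in ("tpe", "random"):
            for seed in range(200):
                space = SearchSpace(
                    {"x": FloatRange(0.0, 1.0)}, n_trials=10, sampler=sampler, seed=seed
                )
                res = tpe_search(space, lambda p: -((p["x"] - 0.7) ** 2))
                errs[sampler].append(abs(res.best_params["x"] - 0.7))
        assert np.median(errs["tpe"]) < np.median(errs["random"])


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    st.lists(st.integers(0, 3), min_size=1, max_size=30),
    st.lists(st.integers(0, 3), min_size=1, max_size=30),
)
def test_weighted_recall_is_accuracy(y_true, y_pred):
    """The support-weighted recall identity holds for every input."""
    n = min(len(y_true), len(y_pred))
    y_true, y_pred = y_true[:n], y_pred[:n]
    rep = evaluate_weighted_metrics(y_true, y_pred)
    acc = sum(t == p for t, p in zip(y_true, y_pred)) / n
    assert rep.weighted_recall == pytest.approx(acc, abs=1e-12)
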