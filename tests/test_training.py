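"""Splits, training schedule, ensemble inference, metrics, aggregation."""

import numpy as np
import pytest

from lsfgdl.networks import BorylationNet, ModelConfig
from lsfgdl.surf import binarize_outcome
from lsfgdl.training import (
    MetricsReport,
    SplitPlan,
    TrainConfig,
    featurize_reactions,
    fscore_from_rates,
    make_split,
    metric_classification,
    metric_regression,
    predict_ensemble,
    roc_auc,
    run_repeats,
    train,
    train_val_split,
)
from lsfgdl.conditions import fit_vocabulary

from conftest import make_record, small_config


# --------------------------------------------------------------------- splits


def _toy_records(n=100, n_substrates=10):
    subs = [f"{'C' * (i + 1)}c1ccccc1" for i in range(n_substrates)]
    return [make_record(f"r{i:03d}", substrate=subs[i % n_substrates]) for i in range(n)]


def test_random_kfold_balanced_and_deterministic():
    recs = _toy_records(101)
    folds = make_split(recs, SplitPlan("random_kfold", k=4), seed=7)
    sizes = sorted(len(te) for _, te in folds)
    assert max(sizes) - min(sizes) <= 1
    all_test = np.sort(np.concatenate([te for _, te in folds]))
    np.testing.assert_array_equal(all_test, np.arange(101))  # folds partition
    again = make_split(recs, SplitPlan("random_kfold", k=4), seed=7)
    for (a, b), (c, d) in zip(folds, again):
        np.testing.assert_array_equal(a, c)
        np.testing.assert_array_equal(b, d)


def test_substrate_holdout_never_leaks():
    recs = _toy_records(120, 12)
    folds = make_split(recs, SplitPlan("substrate_holdout", k=4), seed=0)
    for train_idx, test_idx in folds:
        tr = {recs[i].substrate for i in train_idx}
        te = {recs[i].substrate for i in test_idx}
        assert not tr & te


def test_explicit_substrate_holdout_collects_all_plate_reactions():
    recs = _toy_records(96, 4)  # 24 reactions per substrate
    held = recs[0].substrate
    ((train_idx, test_idx),) = [
        make_split(recs, SplitPlan("substrate_holdout", holdout_substrates=[held]), 0)[0]
    ]
    assert len(test_idx) == 24
    assert all(recs[i].substrate == held for i in test_idx)


def test_k_larger_than_n_is_an_error():
    with pytest.raises(ValueError):
        make_split(_toy_records(3), SplitPlan("random_kfold", k=5), 0)


def test_train_val_split_partitions():
    tr, val = train_val_split(np.arange(40), 0.25, seed=1)
    assert len(val) == 10 and len(tr) == 30
    assert not set(tr) & set(val)


# ------------------------------------------------------------------- training


@pytest.fixture(scope="module")
def tiny_fit():
    """A short real fit on 40 synthetic-style records (2D GNN, yield)."""
    recs = []
    rng = np.random.default_rng(0)
    subs = ["Cc1ccccc1", "CCc1ccccc1", "COc1ccccc1", "Cc1ccncc1"]
    for i in range(40):
        recs.append(
            make_record(
                f"t{i:02d}",
                substrate=subs[i % 4],
                ligand=f"L{i % 3}",
                solvent=f"S{i % 2}",
                yield_percent=float(rng.uniform(5, 95)),
            )
        )
    cfg = small_config(architecture="GNN", graph_variant="2D", task="yield")
    vocab = fit_vocabulary(recs)
    items = featurize_reactions(recs, cfg, vocab, seed=0)
    net = BorylationNet(cfg, condition_width=vocab.width, seed=0)
    tcfg = TrainConfig(learning_rate=1e-3, max_epochs=12, lr_decay_epochs=5, seed=0)
    info = train(net, items[:32], items[32:], tcfg)
    return net, items, tcfg, info


def test_lr_step_decay_schedule(tiny_fit):
    _, _, tcfg, info = tiny_fit
    lrs = {h["epoch"]: h["lr"] for h in info["history"]}
    # decay factor applied after each lr_decay_epochs block
    assert lrs[1] == tcfg.learning_rate
    assert lrs[tcfg.lr_decay_epochs + 1] == tcfg.learning_rate * tcfg.lr_decay_factor
    assert lrs[2 * tcfg.lr_decay_epochs + 1] == tcfg.learning_rate * tcfg.lr_decay_factor**2


def test_early_stop_returns_argmin_of_smoothed_series(tiny_fit):
    _, _, _, info = tiny_fit
    series = [h["smoothed_val_mae"] for h in info["history"]]
    assert info["best_epoch"] == int(np.argmin(series)) + 1


def test_smoothing_is_exponential(tiny_fit):
    _, _, tcfg, info = tiny_fit
    h = info["history"]
    for prev, cur in zip(h, h[1:]):
        expected = (
            tcfg.smoothing_factor * prev["smoothed_val_mae"]
            + (1 - tcfg.smoothing_factor) * cur["val_mae"]
        )
        assert cur["smoothed_val_mae"] == pytest.approx(expected)


def test_training_reduces_loss(tiny_fit):
    _, _, _, info = tiny_fit
    losses = [h["train_loss"] for h in info["history"]]
    assert losses[-1] < losses[0]


# ---------------------------------------------------------------- ensembles


class _StubModel:
    """Predict a fixed sequence of values, one per conformer call."""

    def __init__(self, values, is_3d=True):
        self.values = list(values)
        self.config = ModelConfig(
            architecture="GNN", graph_variant="3D" if is_3d else "2D", task="yield"
        )
        self._i = 0

    def forward_reaction(self, batch, cond):
        from lsfgdl.autodiff import Tensor

        v = self.values[self._i]
        self._i += 1
        return Tensor(np.array([[v]]))


class _StubItem:
    def __init__(self, n_graphs):
        from lsfgdl.graphs import MolGraph

        g = MolGraph(np.zeros((1, 20)), np.zeros((0, 2), int), "2D")
        self.graphs = [g] * n_graphs
        self.condition = np.zeros(1)


def test_ensemble_mean_std_hand_calculation():
    values = [0.9] * 9 + [0.4]
    mean, std = predict_ensemble(_StubModel(values), _StubItem(10))
    assert mean == pytest.approx(np.mean(values))
    assert std == pytest.approx(np.std(values))  # population std


def test_ensemble_constant_outputs():
    mean, std = predict_ensemble(_StubModel([0.7] * 10), _StubItem(10))
    assert (mean, std) == (pytest.approx(0.7), 0.0)


def test_2d_model_ensemble_std_is_zero(tiny_fit):
    net, items, _, _ = tiny_fit
    mean, std = predict_ensemble(net, items[0])
    assert std == 0.0


def test_conformer_count_mismatch_raises():
    with pytest.raises(ValueError, match="conformer count"):
        predict_ensemble(_StubModel([0.5] * 7), _StubItem(7), expected_n=10)


# ------------------------------------------------------------------- metrics


def test_regression_metric_identities():
    y = np.array([3.0, 10.0, 55.0, 70.0, 91.0])
    r, mae = metric_regression(y, y)
    assert (r, mae) == (pytest.approx(1.0), 0.0)
    r_neg, _ = metric_regression(-(y - y.mean()), y - y.mean())
    assert r_neg == pytest.approx(-1.0)


def test_regression_metric_against_closed_form():
    pred = np.array([1.0, 4.0, 2.0, 8.0, 6.0])
    true = np.array([2.0, 5.0, 1.0, 7.0, 9.0])
    r, mae = metric_regression(pred, true)
    # brute-force formula evaluation
    px, tx = pred - pred.mean(), true - true.mean()
    r_hand = float((px * tx).sum() / np.sqrt((px**2).sum() * (tx**2).sum()))
    assert r == pytest.approx(r_hand)
    assert mae == pytest.approx(np.abs(pred - true).mean())


def test_regression_zero_variance_reports_missing_r():
    r, mae = metric_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert r is None and mae == pytest.approx(1.0)


def test_fscore_is_harmonic_mean_of_ppv_and_tpr():
    # printed regioselectivity rows fix the semantics: PPV 62 / TPR 59
    # give F = 60 (rounded); the arithmetic mean (60.5 vs 43) would not
    # match the second row (PPV 56 / TPR 30 -> printed 38 +/- 5)
    assert round(fscore_from_rates(62, 59)) == 60
    f2 = fscore_from_rates(56, 30)
    assert abs(f2 - 38) <= 5
    arithmetic = (56 + 30) / 2
    assert abs(f2 - 38) < abs(arithmetic - 38)  # harmonic fits the table better


def test_classification_report_counts_and_rates():
    pred = np.array([1, 1, 0, 0, 1, 0, 1, 0], bool)
    true = np.array([1, 0, 0, 1, 1, 0, 0, 0], bool)
    rep = metric_classification(pred, true)
    assert (rep.tp, rep.fp, rep.tn, rep.fn) == (2, 2, 3, 1)
    assert rep.tp + rep.fp + rep.tn + rep.fn == rep.n
    assert rep.ppv == pytest.approx(50.0)
    assert rep.tpr == pytest.approx(100 * 2 / 3)
    assert rep.balanced_accuracy == pytest.approx((100 * 2 / 3 + 60.0) / 2)
    assert rep.accuracy == pytest.approx(100 * 5 / 8)


def test_perfect_predictions_hit_every_metric():
    rep = metric_classification([1, 0, 1, 0], [1, 0, 1, 0])
    assert (
        rep.ppv == rep.tpr == rep.f_score == rep.balanced_accuracy == rep.accuracy == 100.0
    )


def test_empty_positive_class_reports_missing():
    rep = metric_classification([0, 0, 0], [0, 0, 0])
    assert rep.ppv is None and rep.tpr is None and rep.f_score is None
    assert roc_auc([0.1, 0.2, 0.3], [0, 0, 0]) is None


def test_confusion_mismatch_rejected():
    with pytest.raises(ValueError):
        MetricsReport(n=5, tp=1, fp=1, tn=1, fn=1)


# ----------------------------------------------------- thresholds & repeats


def test_threshold_label_composition():
    yields = [0.0, 0.5, 1.0, 20.0]
    assert [binarize_outcome(y, 1) for y in yields] == [False, False, True, True]
    assert [binarize_outcome(y, 20) for y in yields] == [False, False, False, False]


def test_threshold_positive_fraction_matches_analytic(rng):
    # uniform yields on [0, 40]: P(y >= 1) = 39/40, P(y > 5) = 35/40, ...
    yields = rng.uniform(0, 40, size=4000)
    for th, p in [(1, 39 / 40), (5, 35 / 40), (10, 30 / 40), (20, 20 / 40)]:
        frac = np.mean([binarize_outcome(y, th) for y in yields])
        assert frac == pytest.approx(p, abs=3 * np.sqrt(p * (1 - p) / 4000))


def test_run_repeats_aggregation():
    out = run_repeats(lambda s: {"m": float(s)}, seeds=(1, 2, 3))
    assert out["m"] == (pytest.approx(2.0), pytest.approx(1.0))  # sample std
    const = run_repeats(lambda s: {"m": 5.0}, seeds=(1, 2, 3))
    assert const["m"][1] == 0.0
    with pytest.raises(ValueError):
        run_repeats(lambda s: {"m": 1.0}, seeds=(1, 1))
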