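import numpy as np
import pytest

from lmppm.architectures import OMNetConfig, build_omnet
from lmppm.train_eval import (TrainConfig, compute_metrics, evaluate,
                              grid_experiment, load_image_folder, train)


def _micro_graph(classes=3):
    return build_omnet(OMNetConfig(
        stem_channels=4, stage_widths=(4, 4, 8, 8),
        residual_repeats=(0, 0, 0, 0), head_channels=16, pool_output=1,
        num_classes=classes, input_size=32))


# --------------------------------------------------------------- metrics

def _brute_force_counts(y, pred, k):
    """Exhaustive one-vs-rest pair counting: the independent oracle."""
    out = {}
    for c in range(k):
        tp = sum(1 for t, p in zip(y, pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y, pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y, pred) if t == c and p != c)
        tn = sum(1 for t, p in zip(y, pred) if t != c and p != c)
        out[c] = (tp, fp, fn, tn)
    return out


def test_metrics_agree_with_brute_force_oracle(rng):
    k, n = 5, 200
    y = rng.integers(0, k, n)
    probs = rng.dirichlet(np.ones(k), n)
    m = compute_metrics(y, probs, k)
    pred = probs.argmax(axis=1)
    oracle = _brute_force_counts(y, pred, k)
    precs, recs, f1s = [], [], []
    for c in range(k):
        tp, fp, fn, tn = oracle[c]
        row = m.per_class.loc[c]
        assert (row.TP, row.FP, row.FN, row.TN) == (tp, fp, fn, tn)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        precs.append(p)
        recs.append(r)
        f1s.append(2 * p * r / (p + r) if p + r else 0.0)
    assert m.macro_precision == pytest.approx(np.mean(precs))
    assert m.macro_recall == pytest.approx(np.mean(recs))
    assert m.macro_f1 == pytest.approx(np.mean(f1s))
    assert m.accuracy == pytest.approx(np.mean(pred == y))
    assert m.confusion.sum() == n


def test_metrics_printed_toy_counts():
    """TP=8, FP=2, FN=4, TN=86 -> precision .8, recall 2/3, F1 ~.727."""
    y = np.array([0] * 12 + [1] * 88)
    pred = np.array([0] * 8 + [1] * 4 + [0] * 2 + [1] * 86)
    probs = np.eye(2)[pred] * 0.9 + 0.05
    m = compute_metrics(y, probs, 2)
    row = m.per_class.loc[0]
    assert (row.TP, row.FP, row.FN, row.TN) == (8, 2, 4, 86)
    assert row.precision == pytest.approx(0.8)
    assert row.recall == pytest.approx(2 / 3)
    assert row.f1 == pytest.approx(2 * 0.8 * (2 / 3) / (0.8 + 2 / 3))


def test_perfect_predictions_give_unit_metrics(rng):
    y = rng.integers(0, 4, 50)
    probs = np.eye(4)[y]
    m = compute_metrics(y, probs, 4)
    assert m.accuracy == m.macro_precision == m.macro_recall == m.macro_f1 == 1.0
    for c in range(4):
        assert m.roc[c]["auc"] == pytest.approx(1.0)


def test_random_scores_auc_near_half(rng):
    y = rng.integers(0, 2, 4000)
    probs = rng.dirichlet(np.ones(2), 4000)
    m = compute_metrics(y, probs, 2)
    assert m.roc[0]["auc"] == pytest.approx(0.5, abs=0.05)


def test_f1_is_harmonic_mean_per_class(rng):
    y = rng.integers(0, 3, 120)
    probs = rng.dirichlet(np.ones(3), 120)
    m = compute_metrics(y, probs, 3)
    for _, row in m.per_class.iterrows():
        if row.precision + row.recall > 0:
            assert row.f1 == pytest.approx(
                2 * row.precision * row.recall / (row.precision + row.recall))


# -------------------------------------------------------------- training

def test_zero_epoch_returns_initial_weights_and_empty_log(tiny_dataset):
    out, spec, _ = tiny_dataset
    cfg = TrainConfig(epochs=0, image_size=32, seed=5)
    res = train(_micro_graph(), out, cfg)
    assert len(res.log) == 0
    assert list(res.log.columns) == ["epoch", "train_loss", "train_acc",
                                     "val_loss", "val_acc"]


def test_identical_seed_reproduces_epoch0_loss(tiny_dataset):
    out, _, _ = tiny_dataset
    cfg = TrainConfig(epochs=1, image_size=32, seed=5, batch_size=8)
    a = train(_micro_graph(), out, cfg)
    b = train(_micro_graph(), out, cfg)
    assert a.log.train_loss[0] == b.log.train_loss[0]
    c = train(_micro_graph(), out, TrainConfig(epochs=1, image_size=32,
                                               seed=6, batch_size=8))
    assert c.log.train_loss[0] != a.log.train_loss[0]


def test_class_mismatch_between_model_and_data_rejected(tiny_dataset):
    out, _, _ = tiny_dataset
    with pytest.raises(ValueError, match="classes"):
        train(_micro_graph(classes=7), out, TrainConfig(epochs=1,
                                                        image_size=32))


def test_missing_split_rejected(tmp_path):
    with pytest.raises(FileNotFoundError):
        load_image_folder(tmp_path, "train")


def test_config_yaml_roundtrip():
    cfg = TrainConfig(epochs=23, batch_size=7, seed=99,
                      learning_rate=3e-4)
    again = TrainConfig.from_yaml(cfg.to_yaml())
    assert again == cfg


def test_train_writes_log_and_checkpoint(tiny_dataset, tmp_path):
    out, _, _ = tiny_dataset
    cfg = TrainConfig(epochs=1, image_size=32, seed=5, batch_size=8)
    res = train(_micro_graph(), out, cfg, out_dir=tmp_path)
    assert (tmp_path / "log.csv").exists()
    assert (tmp_path / "best.npz").exists()
    assert len(res.log) == 1


def test_grid_degenerate_cell_matches_plain_run(tiny_dataset):
    out, _, _ = tiny_dataset
    cfg = TrainConfig(epochs=1, image_size=32, seed=5, batch_size=8)
    df = grid_experiment(_micro_graph(), [1], [1], out, cfg,
                         depthwise=False)
    res = train(_micro_graph(), out, cfg)
    m = evaluate(res.network, out, "test", image_size=32)
    assert df.loc[0, "test_acc"] == pytest.approx(m.accuracy)
    from lmppm.cost import count_params
    assert df.loc[0, "parameters"] == count_params(_micro_graph())
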