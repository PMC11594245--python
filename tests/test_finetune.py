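"""Dice/combined losses, episodic fine-tuning, full training, checkpoints."""

import numpy as np
import pytest

from protods import (
    EmbeddingNetwork,
    FinetuneConfig,
    InstanceRecord,
    NetworkConfig,
    PredictionBatch,
    ProtoDSModel,
    SSLConfig,
    combined_loss,
    dice_loss,
    evaluate_model,
    finetune,
    train_protods,
)
from protods.errors import InputError
from protods.network import Adam


def _onehot(idx, c):
    out = np.zeros((len(idx), c))
    out[np.arange(len(idx)), idx] = 1.0
    return out


class TestDiceLoss:
    def test_perfect_predictions_give_zero(self):
        y = _onehot([0, 1, 0, 1], 2)
        assert dice_loss(PredictionBatch(probs=y, onehot=y)) == pytest.approx(0.0)

    def test_single_uniform_sample_closed_form(self):
        batch = PredictionBatch(probs=[[0.5, 0.5]], onehot=[[1.0, 0.0]])
        # class 1: 1 - 2*0.5/(0.25+1) = 0.2; class 2 (absent, denom 0.25): 1
        assert dice_loss(batch) == pytest.approx(0.6, abs=1e-12)

    def test_hard_predictions_reproduce_f1(self):
        # TP=2, FP=1, FN=1 on the positive class -> DSC = 2*2/(4+1+1) = 2/3
        y_true = [1, 1, 1, 0, 0]
        y_pred = [1, 1, 0, 1, 0]
        probs = _onehot(y_pred, 2)  # column order (neg, pos)
        onehot = _onehot(y_true, 2)
        a = (probs * onehot).sum(axis=0)
        b = (probs**2).sum(axis=0) + (onehot**2).sum(axis=0)
        dsc_pos = 2 * a[1] / b[1]
        assert dsc_pos == pytest.approx(2 / 3, abs=1e-12)

    def test_bounded_and_order_invariant(self, rng):
        probs = rng.dirichlet(np.ones(3), size=20)
        onehot = _onehot(rng.integers(0, 3, 20), 3)
        loss = dice_loss(PredictionBatch(probs=probs, onehot=onehot))
        assert 0.0 <= loss <= 1.0
        perm = rng.permutation(20)
        loss_p = dice_loss(PredictionBatch(probs=probs[perm], onehot=onehot[perm]))
        assert loss == pytest.approx(loss_p, abs=1e-12)

    def test_dice_term_equals_f1_on_random_hard_batches(self, rng):
        """Per-class 1 - Dice equals one-vs-rest F1 from TP/FP/FN counts."""
        from protods.finetune import _dice_and_grad

        for _ in range(200):
            n, c = int(rng.integers(2, 30)), int(rng.integers(2, 5))
            y_true = rng.integers(0, c, n)
            y_pred = rng.integers(0, c, n)
            probs = _onehot(y_pred, c)
            onehot = _onehot(y_true, c)
            _, _ = _dice_and_grad(probs, onehot)
            a = (probs * onehot).sum(axis=0)
            b = (probs**2).sum(axis=0) + (onehot**2).sum(axis=0)
            for k in range(c):
                tp = int(np.sum((y_true == k) & (y_pred == k)))
                fp = int(np.sum((y_true != k) & (y_pred == k)))
                fn = int(np.sum((y_true == k) & (y_pred != k)))
                if b[k] > 0:
                    dsc = 2 * a[k] / b[k]
                    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
                    assert abs(dsc - f1) <= 1e-12

    def test_invalid_batches_rejected(self):
        with pytest.raises(InputError):
            PredictionBatch(probs=[[0.7, 0.7]], onehot=[[1, 0]])
        with pytest.raises(InputError):
            PredictionBatch(probs=[[0.5, 0.5]], onehot=[[1, 1]])


class TestCombinedLoss:
    def test_perfect_probabilities_give_zero(self):
        y = _onehot([0, 1], 2)
        assert combined_loss(PredictionBatch(probs=y, onehot=y)) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_zero_dice_weight_reduces_to_cross_entropy(self, rng):
        probs = rng.dirichlet(np.ones(3), size=10)
        onehot = _onehot(rng.integers(0, 3, 10), 3)
        batch = PredictionBatch(probs=probs, onehot=onehot)
        expected = -np.log((probs * onehot).sum(axis=1)).mean()
        assert combined_loss(batch, lambda_dice=0.0) == pytest.approx(
            expected, abs=1e-12
        )

    def test_uniform_binary_ce_is_ln2(self):
        probs = np.full((7, 2), 0.5)
        onehot = _onehot([0, 1, 0, 1, 0, 1, 0], 2)
        batch = PredictionBatch(probs=probs, onehot=onehot)
        assert combined_loss(batch, lambda_dice=0.0) == pytest.approx(
            np.log(2), abs=1e-12
        )

    def test_nonnegative(self, rng):
        probs = rng.dirichlet(np.ones(4), size=12)
        onehot = _onehot(rng.integers(0, 4, 12), 4)
        assert combined_loss(PredictionBatch(probs=probs, onehot=onehot)) >= 0


def _tiny_records(rng, per_class=(4, 2), d=8, n_pixels=5):
    records = []
    for cls, count in enumerate(per_class, start=1):
        centre = rng.random(d) + cls
        for j in range(count):
            records.append(
                InstanceRecord(
                    instance_id=f"c{cls}_{j}", label=cls,
                    spectra=centre + 0.05 * rng.standard_normal((n_pixels, d)),
                    pixel_coords=np.stack(
                        [np.arange(n_pixels), np.zeros(n_pixels, int)], axis=1
                    ),
                )
            )
    return records


class TestFinetune:
    def test_singleton_minority_class_trains(self, rng):
        records = _tiny_records(rng, per_class=(4, 1))
        net = EmbeddingNetwork(NetworkConfig(input_dim=8, hidden_dim=8, n_blocks=1))
        net, log = finetune(net, records, FinetuneConfig(epochs=2, batch_size=16))
        assert len(log) == 2
        assert all(np.isfinite(row["total"]) for row in log)

    def test_seeded_epoch_reproducible(self, rng):
        records = _tiny_records(rng)

        def run():
            net = EmbeddingNetwork(
                NetworkConfig(input_dim=8, hidden_dim=8, n_blocks=1), seed=3
            )
            net, log = finetune(net, records, FinetuneConfig(epochs=2, seed=3))
            return net.state_dict(), log

        s1, l1 = run()
        s2, l2 = run()
        assert l1 == l2
        for k in s1:
            np.testing.assert_array_equal(s1[k], s2[k])

    def test_training_improves_query_accuracy(self, rng):
        records = _tiny_records(rng, per_class=(6, 6), d=8)
        cfg = NetworkConfig(input_dim=8, hidden_dim=16, n_blocks=2)
        ssl = SSLConfig(epochs=0)
        short, _ = train_protods(records, cfg, ssl,
                                 FinetuneConfig(epochs=1, seed=0, use_ssl_init=False,
                                                learning_rate=1e-3))
        long, _ = train_protods(records, cfg, ssl,
                                FinetuneConfig(epochs=30, seed=0, use_ssl_init=False,
                                               learning_rate=1e-3))

        def train_acc(model):
            rep = evaluate_model(model, records)
            return rep.balanced_accuracy

        assert train_acc(long) >= train_acc(short)


class TestTrainProtoDS:
    def test_ablation_flags_skip_pretraining(self, rng):
        records = _tiny_records(rng)
        cfg = NetworkConfig(input_dim=8, hidden_dim=8, n_blocks=1)
        model, hist = train_protods(
            records, cfg, SSLConfig(epochs=2),
            FinetuneConfig(epochs=1, use_ssl_init=False, use_dice=False),
        )
        assert hist["ssl_trace"] == []
        assert model.prototypes.n_classes == 2

    def test_checkpoint_round_trip_identical_predictions(self, rng, tmp_path):
        records = _tiny_records(rng)
        cfg = NetworkConfig(input_dim=8, hidden_dim=8, n_blocks=1)
        model, _ = train_protods(
            records, cfg, SSLConfig(epochs=1), FinetuneConfig(epochs=1)
        )
        path = str(tmp_path / "ckpt.npz")
        model.save(path)
        back = ProtoDSModel.load(path)
        from protods import classify_instance

        for rec in records:
            p1 = classify_instance(model.net, rec, model.prototypes)[1]
            p2 = classify_instance(back.net, rec, back.prototypes)[1]
            np.testing.assert_array_equal(p1, p2)

    def test_label_permutation_collapses_balanced_accuracy(self, small_dataset):
        """Random labels destroy the class signal: B.Acc falls toward 1/C."""
        _, train, test, band_idx = small_dataset
        rng = np.random.default_rng(11)
        shuffled = []
        labels = [r.label for r in train]
        rng.shuffle(labels)
        for rec, lab in zip(train, labels):
            shuffled.append(
                InstanceRecord(instance_id=rec.instance_id, label=lab,
                               spectra=rec.spectra, pixel_coords=rec.pixel_coords)
            )
        cfg = NetworkConfig(input_dim=band_idx.size, hidden_dim=16, n_blocks=2)
        ft = FinetuneConfig(epochs=20, learning_rate=1e-3, use_ssl_init=False)
        shuffled_model, _ = train_protods(shuffled, cfg, SSLConfig(epochs=0), ft)
        true_model, _ = train_protods(train, cfg, SSLConfig(epochs=0), ft)
        bacc_shuffled = evaluate_model(shuffled_model, test).balanced_accuracy
        bacc_true = evaluate_model(true_model, test).balanced_accuracy
        assert bacc_true >= 0.9  # separable data is learned
        assert bacc_shuffled < bacc_true  # label signal destroyed
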