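"""Canonical end-to-end experiments on synthetic data.

These functions fix the study conditions for the package's two headline
sanity experiments so that tests, scripts and documentation all run the
same protocol:

* ``ssl_structure_experiment`` — does contrastive pretraining alone recover
  instance structure?  Pretrain on 40 unlabeled instances, then compare
  mean same-instance vs cross-instance embedding distances on held-out
  instances.
* ``imbalance_experiment`` — with 100 majority / 5 minority training
  instances and moderate noise, does the full two-step method beat (or at
  least match) a vanilla prototypical network on balanced accuracy?

Cubes are kept small (64 bands, 7 x 7 pixels) so a full multi-seed run
finishes in minutes on one CPU core; the generator's noise structure is the
same as at full scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .contrastive import SSLConfig, pretrain
from .evaluation import evaluate_model
from .finetune import FinetuneConfig, train_protods
from .network import EmbeddingNetwork, NetworkConfig
from .synthetic import SignatureModel, SimConfig, dataset_to_records, simulate_dataset

__all__ = ["ssl_structure_experiment", "imbalance_experiment"]

_SIGNATURE_MODEL = dict(n_classes=2, n_bands=64)


def _make_records(seed: int, n_majority: int, n_minority: int, n_test: int):
    model = SignatureModel(**_SIGNATURE_MODEL)
    cfg = SimConfig(
        seed=seed, n_majority=n_majority, n_minority=(n_minority,),
        n_test_per_class=n_test, height=7, width=7,
    )
    ds = simulate_dataset(model, cfg)
    return dataset_to_records(ds)


def ssl_structure_experiment(seed: int, epochs: int = 50) -> dict:
    """Pretrain on 40 instances; measure embedding structure on held-out ones.

    Returns mean same-instance and cross-instance pairwise embedding
    distances over the held-out instances and whether the same-instance mean
    is smaller (``win``), plus the first/last epoch losses.
    """
    train, test, band_idx = _make_records(seed, n_majority=20, n_minority=20, n_test=8)
    net = EmbeddingNetwork(NetworkConfig(input_dim=int(band_idx.size)), seed=seed)
    net, trace = pretrain(net, train, SSLConfig(epochs=epochs, seed=seed))

    rng = np.random.default_rng(seed)
    embs = [net.embed(r.spectra) for r in test]
    same, cross = [], []
    for i, e in enumerate(embs):
        idx = rng.choice(e.shape[0], size=(20, 2))
        same.extend(np.linalg.norm(e[idx[:, 0]] - e[idx[:, 1]], axis=1))
        j = (i + 1 + int(rng.integers(len(embs) - 1))) % len(embs)
        o = embs[j]
        cross.extend(
            np.linalg.norm(
                e[rng.integers(0, e.shape[0], 20)] - o[rng.integers(0, o.shape[0], 20)],
                axis=1,
            )
        )
    same_mean, cross_mean = float(np.mean(same)), float(np.mean(cross))
    return {
        "same_instance_mean_dist": same_mean,
        "cross_instance_mean_dist": cross_mean,
        "win": same_mean < cross_mean,
        "first_epoch_loss": trace[0],
        "last_epoch_loss": trace[-1],
    }


def imbalance_experiment(
    seeds=(1, 2, 3, 4, 5),
    variants=("full", "no_ssl_no_dice"),
    ssl_epochs: int = 60,
    finetune_epochs: int = 50,
) -> pd.DataFrame:
    """Train the requested variants on 100-majority / 5-minority data per seed.

    Each seed draws a fresh dataset (new signatures, new instances) and
    trains every variant from scratch; the result is a long-format frame of
    test balanced accuracies.
    """
    from .evaluation import ABLATION_VARIANTS

    rows = []
    for seed in seeds:
        train, test, band_idx = _make_records(
            int(seed), n_majority=100, n_minority=5, n_test=25
        )
        net_cfg = NetworkConfig(input_dim=int(band_idx.size))
        for variant in variants:
            flags = ABLATION_VARIANTS[variant]
            model, _ = train_protods(
                train,
                net_cfg,
                SSLConfig(epochs=ssl_epochs, seed=int(seed)),
                FinetuneConfig(epochs=finetune_epochs, seed=int(seed), **flags),
            )
            report = evaluate_model(model, test)
            rows.append(
                {
                    "seed": int(seed),
                    "variant": variant,
                    "balanced_accuracy": report.balanced_accuracy,
                    "macro_f1": report.macro_f1,
                    "macro_auroc": report.macro_auroc,
                    "macro_ap": report.macro_ap,
                }
            )
    return pd.DataFrame(rows)
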