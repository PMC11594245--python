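"""Step 2: episodic supervised fine-tuning with the Dice + cross-entropy loss.

Every epoch re-enacts a prototypical episode: a random subset of each class's
training instances supplies the support pixels whose mean embedding forms the
class prototype; *all* training pixel spectra then act as queries, classified
by softmax over negative distances to the prototypes.  The objective is

    L = lambda_CE * CE(p, y) + lambda_D * Dice(p, y),

where the soft Dice loss per class c is ``1 - 2*sum_i p_ic y_ic /
(sum_i p_ic^2 + sum_i y_ic^2)`` averaged over classes.  One minus the Dice
term is the Dice-Sorensen coefficient, algebraically the class F1 for hard
predictions; because it ignores true negatives, the majority class cannot
drown out the minority's contribution the way plain cross-entropy lets it.

After fine-tuning, the deployment prototypes are recomputed from *all*
training pixels with the final network in inference mode.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .cube import InstanceRecord
from .errors import InputError, SupportError, TrainingError
from .network import Adam, EmbeddingNetwork, NetworkConfig
from .prototypes import PrototypeSet, pairwise_sq_dists
from .contrastive import SSLConfig, pretrain

__all__ = [
    "PredictionBatch",
    "FinetuneConfig",
    "dice_loss",
    "combined_loss",
    "finetune_epoch",
    "finetune",
    "train_protods",
    "ProtoDSModel",
]

_EPS = 1e-12


@dataclass
class PredictionBatch:
    """Predicted probabilities and one-hot ground truth, both N x C."""

    probs: np.ndarray
    onehot: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.atleast_2d(np.asarray(self.probs, dtype=float))
        self.onehot = np.atleast_2d(np.asarray(self.onehot, dtype=float))
        if self.probs.shape != self.onehot.shape:
            raise InputError("probs and onehot must share a shape")
        if self.probs.shape[0] == 0:
            raise InputError("empty prediction batch")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise InputError("probability rows must sum to 1")
        row_sums = self.onehot.sum(axis=1)
        if not (
            np.all((self.onehot == 0) | (self.onehot == 1)) and np.all(row_sums == 1)
        ):
            raise InputError("onehot rows must be valid one-hot indicators")


@dataclass
class FinetuneConfig:
    epochs: int = 50
    learning_rate: float = 1e-4
    support_fraction: float = 0.5  # of each class's instances, per epoch
    support_pixels_per_class: int = 256
    batch_size: int = 256  # query pixel spectra per update
    lambda_ce: float = 1.0
    lambda_dice: float = 1.0
    use_ssl_init: bool = True
    use_dice: bool = True
    distance: str = "squared_euclidean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise InputError("epochs must be >= 1")
        lam_d = self.lambda_dice if self.use_dice else 0.0
        if self.lambda_ce < 0 or self.lambda_dice < 0:
            raise InputError("loss weights must be >= 0")
        if self.lambda_ce == 0 and lam_d == 0:
            raise InputError("at least one loss weight must be positive")


def _dice_and_grad(probs: np.ndarray, onehot: np.ndarray):
    """Soft Dice loss (mean over classes) and its gradient w.r.t. probs.

    A class whose denominator sum(p^2) + sum(y^2) is exactly 0 contributes 0.
    """
    c = probs.shape[1]
    a = (probs * onehot).sum(axis=0)  # per-class overlap
    b = (probs**2).sum(axis=0) + (onehot**2).sum(axis=0)
    nonzero = b > 0
    terms = np.where(nonzero, 1.0 - 2.0 * a / np.where(nonzero, b, 1.0), 0.0)
    loss = terms.mean()
    # gradient: columns whose denominator would underflow when squared carry a
    # vanishing term (all probabilities saturated near 0) and get zero gradient
    stable = b > 1e-150
    bz = np.where(stable, b, 1.0)
    grad = (2.0 / c) * (2.0 * a[None, :] * probs - onehot * bz[None, :]) / bz[None, :] ** 2
    grad[:, ~stable] = 0.0
    return loss, grad


def dice_loss(batch: PredictionBatch) -> float:
    """Mean soft Dice loss over classes; in [0, 1], 0 iff probs == onehot."""
    loss, _ = _dice_and_grad(batch.probs, batch.onehot)
    return float(loss)


def _ce_and_grad(probs: np.ndarray, onehot: np.ndarray):
    n = probs.shape[0]
    p_true = np.clip((probs * onehot).sum(axis=1), _EPS, None)
    loss = float(-np.log(p_true).mean())
    grad = -onehot / (n * np.clip(probs, _EPS, None))
    grad[onehot == 0] = 0.0
    return loss, grad


def combined_loss(
    batch: PredictionBatch, lambda_ce: float = 1.0, lambda_dice: float = 1.0
) -> float:
    """lambda_CE * mean cross-entropy + lambda_D * Dice loss."""
    ce, _ = _ce_and_grad(batch.probs, batch.onehot)
    d, _ = _dice_and_grad(batch.probs, batch.onehot)
    return float(lambda_ce * ce + lambda_dice * d)


def _softmax_neg_dist(dists: np.ndarray):
    logits = -dists
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def _episode_step(
    net: EmbeddingNetwork,
    support_x: np.ndarray,
    support_cls: np.ndarray,  # class index 0..C-1 per support row
    query_x: np.ndarray,
    query_onehot: np.ndarray,
    cfg: FinetuneConfig,
    adam: Adam,
) -> tuple[float, float]:
    """One combined-loss update; returns (ce, dice) components."""
    n_cls = query_onehot.shape[1]
    zs, tape_s = net.forward_train(support_x)
    counts = np.bincount(support_cls, minlength=n_cls).astype(float)
    protos = np.zeros((n_cls, zs.shape[1]))
    np.add.at(protos, support_cls, zs)
    protos /= counts[:, None]

    zq, tape_q = net.forward_train(query_x)
    d = pairwise_sq_dists(zq, protos)
    if cfg.distance == "euclidean":
        d_sq = d
        d = np.sqrt(d_sq + _EPS)
    probs = _softmax_neg_dist(d)

    lam_d = cfg.lambda_dice if cfg.use_dice else 0.0
    ce, g_ce = _ce_and_grad(probs, query_onehot)
    dl, g_d = _dice_and_grad(probs, query_onehot)
    g_p = cfg.lambda_ce * g_ce + lam_d * g_d

    # softmax backward: dlogits = p * (g - sum(g * p))
    inner = (g_p * probs).sum(axis=1, keepdims=True)
    d_logits = probs * (g_p - inner)
    dd = -d_logits
    if cfg.distance == "euclidean":
        dd = dd / (2.0 * d)
    diff = zq[:, None, :] - protos[None, :, :]
    dzq = 2.0 * (dd[:, :, None] * diff).sum(axis=1)
    dprotos = -2.0 * (dd[:, :, None] * diff).sum(axis=0)
    dzs = dprotos[support_cls] / counts[support_cls][:, None]

    net.zero_grads()
    net.backward(dzq, tape_q)
    net.backward(dzs, tape_s)
    adam.step(net.parameters(), net.grads)
    return ce, dl


def _grouped(records: list[InstanceRecord]):
    groups: dict[int, list[InstanceRecord]] = {}
    for r in records:
        groups.setdefault(r.label, []).append(r)
    return dict(sorted(groups.items()))


def finetune_epoch(
    net: EmbeddingNetwork,
    records: list[InstanceRecord],
    cfg: FinetuneConfig,
    rng: np.random.Generator,
    adam: Adam,
) -> tuple[float, float]:
    """One episodic epoch; returns (mean CE, mean Dice) over the updates.

    Per epoch a support subset of instances is drawn per class (fraction
    ``support_fraction``, minimum one instance — a singleton minority class
    is always its own support); all training pixels act as queries in
    shuffled mini-batches, with one Adam update per mini-batch.
    """
    groups = _grouped(records)
    if not groups:
        raise SupportError("no training records")
    class_ids = np.array(list(groups.keys()))
    n_cls = class_ids.size

    support_x, support_cls = [], []
    for ci, (label, recs) in enumerate(groups.items()):
        n_sup = max(1, int(round(cfg.support_fraction * len(recs))))
        picks = rng.choice(len(recs), size=n_sup, replace=False)
        pix = np.concatenate([recs[i].spectra for i in picks])
        if pix.shape[0] > cfg.support_pixels_per_class:
            sel = rng.choice(pix.shape[0], cfg.support_pixels_per_class, replace=False)
            pix = pix[sel]
        support_x.append(pix)
        support_cls.append(np.full(pix.shape[0], ci))
    support_x = np.concatenate(support_x)
    support_cls = np.concatenate(support_cls)

    query_x = np.concatenate([r.spectra for r in records])
    query_ci = np.concatenate(
        [np.full(r.n_pixels, int(np.nonzero(class_ids == r.label)[0][0])) for r in records]
    )
    order = rng.permutation(query_x.shape[0])

    ces, dices = [], []
    for start in range(0, order.size, cfg.batch_size):
        sel = order[start:start + cfg.batch_size]
        onehot = np.zeros((sel.size, n_cls))
        onehot[np.arange(sel.size), query_ci[sel]] = 1.0
        ce, dl = _episode_step(
            net, support_x, support_cls, query_x[sel], onehot, cfg, adam
        )
        if not (np.isfinite(ce) and np.isfinite(dl)):
            raise TrainingError("non-finite fine-tuning loss")
        ces.append(ce)
        dices.append(dl)
    return float(np.mean(ces)), float(np.mean(dices))


def finetune(
    net: EmbeddingNetwork,
    records: list[InstanceRecord],
    cfg: FinetuneConfig,
) -> tuple[EmbeddingNetwork, list[dict]]:
    """Run ``cfg.epochs`` episodic epochs; returns the net and a loss log."""
    rng = np.random.default_rng(cfg.seed)
    adam = Adam(net.parameters(), lr=cfg.learning_rate)
    log = []
    lam_d = cfg.lambda_dice if cfg.use_dice else 0.0
    for epoch in range(cfg.epochs):
        ce, dl = finetune_epoch(net, records, cfg, rng, adam)
        log.append(
            {"epoch": epoch, "ce": ce, "dice": dl,
             "total": cfg.lambda_ce * ce + lam_d * dl}
        )
    return net, log


@dataclass
class ProtoDSModel:
    """A trained network plus its deployment prototypes."""

    net: EmbeddingNetwork
    prototypes: PrototypeSet
    distance: str = "squared_euclidean"

    def save(self, path: str) -> None:
        import json

        state = {f"net.{k}": v for k, v in self.net.state_dict().items()}
        state["proto.class_ids"] = self.prototypes.class_ids
        state["proto.vectors"] = self.prototypes.vectors
        np.savez(path, **state)
        sidecar = {
            "config": asdict(self.net.config),
            "input_dim": self.net.config.input_dim,
            "embedding_dim": self.net.config.embedding_dim,
            "distance": self.distance,
            "class_ids": self.prototypes.class_ids.tolist(),
            "prototypes": self.prototypes.vectors.tolist(),
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "ProtoDSModel":
        import json

        with open(str(path) + ".json") as fh:
            sidecar = json.load(fh)
        net = EmbeddingNetwork(NetworkConfig(**sidecar["config"]))
        with np.load(path if str(path).endswith(".npz") else str(path)) as archive:
            net.load_state_dict(
                {k[4:]: archive[k] for k in archive.files if k.startswith("net.")}
            )
            protos = PrototypeSet(
                class_ids=archive["proto.class_ids"], vectors=archive["proto.vectors"]
            )
        return cls(net=net, prototypes=protos, distance=sidecar["distance"])


def extract_prototypes(
    net: EmbeddingNetwork, records: list[InstanceRecord]
) -> PrototypeSet:
    """Deployment prototypes from all training pixels, inference mode."""
    from .prototypes import compute_prototypes

    emb = np.concatenate([net.embed(r.spectra) for r in records])
    labels = np.concatenate([np.full(r.n_pixels, r.label) for r in records])
    return compute_prototypes(emb, labels)


def train_protods(
    records: list[InstanceRecord],
    net_cfg: NetworkConfig,
    ssl_cfg: SSLConfig,
    ft_cfg: FinetuneConfig,
) -> tuple[ProtoDSModel, dict]:
    """Full two-step training (or an ablated variant per the config flags).

    Flag combinations reproduce the ablation variants: both on (full method),
    ``use_dice`` off (no Dice), ``use_ssl_init`` off (no pretraining), both
    off (vanilla prototypical network).  Returns the model and a history dict
    with the pretraining loss trace and per-epoch fine-tuning losses.
    """
    net = EmbeddingNetwork(net_cfg, seed=ft_cfg.seed)
    history: dict = {"ssl_trace": [], "finetune_log": []}
    if ft_cfg.use_ssl_init:
        net, trace = pretrain(net, records, ssl_cfg)
        history["ssl_trace"] = trace
    net, log = finetune(net, records, ft_cfg)
    history["finetune_log"] = log
    protos = extract_prototypes(net, records)
    return ProtoDSModel(net=net, prototypes=protos, distance=ft_cfg.distance), history
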