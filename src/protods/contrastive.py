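"""Step 1: instance-wise spectral contrastive pretraining.

The pretext task uses no labels.  Two effective-pixel spectra drawn from the
same physical instance form a positive pair; negatives are drawn from the
pixel pool of other instances.  With similarity s (default the negative
squared Euclidean distance between embeddings) and temperature tau, each
query incurs the InfoNCE loss

    l = -log  exp(s+/tau) / ( exp(s+/tau) + sum_{j=1..B} exp(s-_j/tau) ),

which pulls same-instance spectra together and pushes different-instance
spectra apart.  The learned embedding then seeds the supervised fine-tuning
stage: same-instance pixels differ only by illumination and noise, so an
embedding that identifies instances already discards much nuisance variation
before any label is seen.

Defaults: B = 16 negatives, tau = 1, Adam at learning rate 1e-4, 200 epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cube import InstanceRecord
from .errors import DatasetError, NumericError, TrainingError
from .network import Adam, EmbeddingNetwork

__all__ = ["SSLConfig", "ContrastiveBatch", "sample_contrastive_batch",
           "contrastive_loss", "pretrain"]


@dataclass
class SSLConfig:
    n_negatives: int = 16  # B
    temperature: float = 1.0  # tau
    epochs: int = 200
    learning_rate: float = 1e-4
    instances_per_step: int = 16
    similarity: str = "neg_sq_euclidean"  # or "cosine"
    negatives_include_own_instance: bool = False
    positive_pool_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_negatives < 1:
            raise DatasetError("n_negatives must be >= 1")
        if self.temperature <= 0:
            raise DatasetError("temperature must be > 0")
        if self.epochs < 0:
            raise DatasetError("epochs must be >= 0")
        if self.positive_pool_size < 1:
            raise DatasetError("positive_pool_size must be >= 1")


@dataclass
class ContrastiveBatch:
    """Sampled raw spectra for one optimization step (labels never touched)."""

    queries: np.ndarray  # (K, D)
    positives: np.ndarray  # (K, D)
    negatives: np.ndarray  # (K, B, D)
    instance_ids: list[str]


def _usable(records: list[InstanceRecord]) -> list[InstanceRecord]:
    usable = [r for r in records if r.n_pixels >= 2]
    skipped = len(records) - len(usable)
    if skipped:
        warnings.warn(
            f"skipping {skipped} instance(s) with fewer than 2 effective pixels "
            "from contrastive sampling",
            stacklevel=3,
        )
    if len(usable) < 2:
        raise DatasetError(
            "contrastive pretraining needs at least 2 instances with >= 2 "
            f"effective pixels each; got {len(usable)}"
        )
    return usable


def sample_contrastive_batch(
    records: list[InstanceRecord],
    cfg: SSLConfig,
    rng: np.random.Generator,
    instance_subset: np.ndarray | None = None,
) -> ContrastiveBatch:
    """Draw queries, same-instance positives and cross-instance negatives.

    One query per sampled instance.  The positive is a distinct pixel of the
    query's instance (or a mean of ``positive_pool_size`` distinct pixels).
    Negatives are uniform over the pixel pool of the *other* instances;
    ``negatives_include_own_instance`` widens that pool to the query's own
    instance (query pixel excluded).
    """
    usable = _usable(records)
    if instance_subset is None:
        k = min(cfg.instances_per_step, len(usable))
        instance_subset = rng.choice(len(usable), size=k, replace=False)
    queries, positives, negatives, ids = [], [], [], []
    for idx in instance_subset:
        rec = usable[int(idx)]
        n_pool = min(cfg.positive_pool_size, rec.n_pixels - 1)
        picks = rng.choice(rec.n_pixels, size=1 + n_pool, replace=False)
        queries.append(rec.spectra[picks[0]])
        positives.append(rec.spectra[picks[1:]].mean(axis=0))
        ids.append(rec.instance_id)

        neg_rows = []
        for _ in range(cfg.n_negatives):
            if cfg.negatives_include_own_instance:
                j = int(rng.integers(len(usable)))
            else:
                j = int(rng.integers(len(usable) - 1))
                if j >= int(idx):
                    j += 1
            other = usable[j]
            if j == int(idx):
                # own instance allowed: any pixel except the query pixel
                r = int(rng.integers(other.n_pixels - 1))
                if r >= picks[0]:
                    r += 1
            else:
                r = int(rng.integers(other.n_pixels))
            neg_rows.append(other.spectra[r])
        negatives.append(np.stack(neg_rows))
    return ContrastiveBatch(
        queries=np.stack(queries),
        positives=np.stack(positives),
        negatives=np.stack(negatives),
        instance_ids=ids,
    )


def _similarities(q, keys, kind):
    """s(q_i, key_{i,j}) for q (K, M) against keys (K, J, M) -> (K, J)."""
    if kind == "neg_sq_euclidean":
        diff = keys - q[:, None, :]
        return -np.einsum("kjm,kjm->kj", diff, diff), diff
    if kind == "cosine":
        qn = np.linalg.norm(q, axis=1, keepdims=True)
        kn = np.linalg.norm(keys, axis=2)
        return np.einsum("km,kjm->kj", q, keys) / (qn * kn + 1e-12), None
    raise NumericError(f"unknown similarity {kind!r}")


def contrastive_loss(
    q_emb: np.ndarray,
    pos_emb: np.ndarray,
    neg_embs: np.ndarray,
    temperature: float = 1.0,
    similarity: str = "neg_sq_euclidean",
) -> float:
    """Mean InfoNCE loss of queries against their positives and negatives.

    ``q_emb``/``pos_emb`` are (K, M) (a single M-vector is promoted);
    ``neg_embs`` is (K, B, M) or (B, M) for a single query.
    """
    loss, _ = _loss_and_grads(
        np.atleast_2d(q_emb),
        np.atleast_2d(pos_emb),
        np.asarray(neg_embs, dtype=float).reshape(
            (np.atleast_2d(q_emb).shape[0], -1, np.atleast_2d(q_emb).shape[1])
        ),
        temperature,
        similarity,
    )
    return float(loss)


def _loss_and_grads(q, pos, negs, tau, kind):
    if not (np.all(np.isfinite(q)) and np.all(np.isfinite(pos)) and np.all(np.isfinite(negs))):
        raise NumericError("non-finite embeddings in contrastive loss")
    k_n, b, _ = negs.shape
    keys = np.concatenate([pos[:, None, :], negs], axis=1)  # (K, 1+B, M)
    s, diff = _similarities(q, keys, kind)
    z = s / tau
    zmax = z.max(axis=1, keepdims=True)
    logsumexp = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
    losses = logsumexp - z[:, 0]
    loss = losses.mean()

    # d loss / d s: softmax weights, minus 1 on the positive slot
    w = np.exp(z - zmax)
    w /= w.sum(axis=1, keepdims=True)
    ds = w.copy()
    ds[:, 0] -= 1.0
    ds /= tau * k_n  # mean over the K queries

    if kind == "neg_sq_euclidean":
        # s = -||q - key||^2, diff = key - q
        dkeys = ds[:, :, None] * (-2.0 * diff)
        dq = (ds[:, :, None] * (2.0 * diff)).sum(axis=1)
    else:  # cosine
        qn = np.linalg.norm(q, axis=1, keepdims=True) + 1e-12
        kn = np.linalg.norm(keys, axis=2, keepdims=True) + 1e-12
        dkeys = ds[:, :, None] * (q[:, None, :] / (qn[:, None, :] * kn)
                                  - s[:, :, None] * keys / kn**2)
        dq = (ds[:, :, None] * (keys / (qn[:, None, :] * kn)
                                - (s[:, :, None] * q[:, None, :] / qn[:, None, :] ** 2))).sum(axis=1)
    return loss, (dq, dkeys[:, 0, :], dkeys[:, 1:, :])


def pretrain(
    net: EmbeddingNetwork,
    records: list[InstanceRecord],
    cfg: SSLConfig,
) -> tuple[EmbeddingNetwork, list[float]]:
    """Optimize the network on the contrastive pretext task.

    One epoch visits every usable training instance once as a query source,
    in shuffled chunks of ``instances_per_step``.  Returns the network
    (updated in place) and the per-epoch mean loss trace.  Labels are never
    read, so the result is invariant to any relabeling of the records.
    """
    usable = _usable(records)
    rng = np.random.default_rng(cfg.seed)
    adam = Adam(net.parameters(), lr=cfg.learning_rate)
    trace: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(usable))
        losses = []
        for start in range(0, len(order), cfg.instances_per_step):
            chunk = order[start:start + cfg.instances_per_step]
            batch = sample_contrastive_batch(usable, cfg, rng, instance_subset=chunk)
            k, b = batch.negatives.shape[:2]
            x = np.concatenate(
                [batch.queries, batch.positives, batch.negatives.reshape(k * b, -1)]
            )
            emb, tape = net.forward_train(x)
            m = emb.shape[1]
            q, pos = emb[:k], emb[k:2 * k]
            negs = emb[2 * k:].reshape(k, b, m)
            loss, (dq, dpos, dnegs) = _loss_and_grads(
                q, pos, negs, cfg.temperature, cfg.similarity
            )
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite contrastive loss at epoch {epoch}")
            demb = np.concatenate([dq, dpos, dnegs.reshape(k * b, m)])
            net.zero_grads()
            net.backward(demb, tape)
            adam.step(net.parameters(), net.grads)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return net, trace
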