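"""Class prototypes, softmax-distance posteriors, set pooling.

A class prototype is the arithmetic mean of the class's support embeddings.
A query embedding q is classified by a softmax over negative distances to
the prototypes,

    p(y = k | q) = exp(-d(q, c_k)) / sum_k' exp(-d(q, c_k')),

with d the squared Euclidean distance by default (plain Euclidean available
via ``distance="euclidean"``).  At test time all pixel embeddings of one
physical instance are averaged by a set-pooling layer into a single vector
before classification, making the decision invariant to the number of pixels
the instance happens to contribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cube import CalibratedCube, InstanceRecord
from .errors import DegenerateInstanceError, InputError, SupportError
from .network import EmbeddingNetwork

__all__ = [
    "PrototypeSet",
    "compute_prototypes",
    "pairwise_sq_dists",
    "posteriors",
    "set_pool",
    "classify_instance",
    "pixel_probability_map",
]


@dataclass
class PrototypeSet:
    """One prototype vector per class, with the class ids they belong to."""

    class_ids: np.ndarray  # (C,) int
    vectors: np.ndarray  # (C, M)

    def __post_init__(self) -> None:
        self.class_ids = np.asarray(self.class_ids, dtype=int).ravel()
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if self.class_ids.size != self.vectors.shape[0]:
            raise InputError("one class id per prototype row required")
        if not np.all(np.isfinite(self.vectors)):
            raise InputError("prototype vectors must be finite")

    @property
    def n_classes(self) -> int:
        return self.class_ids.size


def compute_prototypes(embeddings: np.ndarray, labels: np.ndarray) -> PrototypeSet:
    """Mean embedding per class present in ``labels``.

    Classes are ordered by ascending class id.  Raises SupportError if any
    label value appears zero times (cannot happen when classes are taken
    from ``labels`` itself, but empty inputs are rejected).
    """
    embeddings = np.atleast_2d(np.asarray(embeddings, dtype=float))
    labels = np.asarray(labels, dtype=int).ravel()
    if labels.size == 0:
        raise SupportError("no support samples given")
    if labels.size != embeddings.shape[0]:
        raise InputError("labels and embeddings disagree in length")
    class_ids = np.unique(labels)
    vectors = np.stack([embeddings[labels == k].mean(axis=0) for k in class_ids])
    return PrototypeSet(class_ids=class_ids, vectors=vectors)


def pairwise_sq_dists(queries: np.ndarray, protos: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, (N, M) x (C, M) -> (N, C)."""
    diff = queries[:, None, :] - protos[None, :, :]
    return np.einsum("ncm,ncm->nc", diff, diff)


def posteriors(
    query_emb: np.ndarray,
    protos: PrototypeSet,
    distance: str = "squared_euclidean",
) -> np.ndarray:
    """Softmax over negative prototype distances; rows sum to 1.

    Accepts a single M-vector (returns shape (C,)) or an N x M matrix
    (returns N x C).  Numerically stabilized by subtracting the row max
    logit before exponentiation.
    """
    q = np.asarray(query_emb, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    if q.shape[1] != protos.vectors.shape[1]:
        raise InputError(
            f"query dim {q.shape[1]} != prototype dim {protos.vectors.shape[1]}"
        )
    d = pairwise_sq_dists(q, protos.vectors)
    if distance == "euclidean":
        d = np.sqrt(d)
    elif distance != "squared_euclidean":
        raise InputError(f"unknown distance {distance!r}")
    logits = -d
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    p = e / e.sum(axis=1, keepdims=True)
    return p[0] if single else p


def set_pool(embeddings: np.ndarray) -> np.ndarray:
    """Average N x M pixel embeddings of one instance into one M-vector."""
    embeddings = np.atleast_2d(np.asarray(embeddings, dtype=float))
    if embeddings.shape[0] == 0:
        raise DegenerateInstanceError("cannot pool an empty embedding set")
    return embeddings.mean(axis=0)


def classify_instance(
    net: EmbeddingNetwork,
    instance: InstanceRecord,
    protos: PrototypeSet,
    distance: str = "squared_euclidean",
) -> tuple[int, np.ndarray]:
    """Predict the class of one instance by set-pooled embedding.

    Returns (predicted class id, posterior vector over protos.class_ids).
    Ties break toward the lowest class id.
    """
    pooled = set_pool(net.embed(instance.spectra))
    post = posteriors(pooled, protos, distance=distance)
    return int(protos.class_ids[int(np.argmax(post))]), post


def pixel_probability_map(
    net: EmbeddingNetwork,
    cube: CalibratedCube,
    band_idx: np.ndarray,
    protos: PrototypeSet,
    class_id: int,
    distance: str = "squared_euclidean",
) -> np.ndarray:
    """Per-pixel posterior of ``class_id`` over a masked cube.

    Returns an H x W float map with the class posterior at effective pixels
    and NaN at non-effective ones.
    """
    if cube.mask is None:
        raise InputError("cube has no mask; call effective_mask first")
    matches = np.nonzero(protos.class_ids == class_id)[0]
    if matches.size == 0:
        raise InputError(f"class {class_id} has no prototype")
    k = int(matches[0])
    rows, cols = np.nonzero(cube.mask)
    out = np.full(cube.shape[:2], np.nan)
    if rows.size == 0:
        return out
    spectra = cube.reflectance[rows, cols][:, np.asarray(band_idx, dtype=int)]
    p = posteriors(net.embed(spectra), protos, distance=distance)
    out[rows, cols] = p[:, k]
    return out
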