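"""Metrics, the imbalance experiment protocol, ablations, and separability.

Imbalanced problems make plain accuracy misleading, so the report centres on
prevalence-immune quantities: balanced accuracy (mean per-class recall,
equal to (sensitivity + specificity)/2 in the binary case), macro-averaged
F1, one-vs-rest macro AUROC and macro average precision, plus per-class
sensitivity/specificity.  The split protocol holds the majority class fixed
and downsamples minority *training* counts to a ladder n in {1, 5, 10, 15,
20}; with several minority classes the least-represented one is set to n and
the others scaled by their original ratios (half-up rounding).  The test set
is carved out first and is identical across all n for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.decomposition import PCA
from sklearn.metrics import average_precision_score, roc_auc_score

from .cube import InstanceRecord
from .errors import InputError, UndefinedMetricError
from .finetune import FinetuneConfig, ProtoDSModel, train_protods
from .contrastive import SSLConfig
from .network import NetworkConfig
from .prototypes import classify_instance

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "ImbalanceSpec",
    "confusion",
    "balanced_accuracy",
    "macro_f1",
    "sens_spec",
    "macro_auroc",
    "macro_ap",
    "evaluate_model",
    "build_imbalanced_split",
    "run_ablation",
    "separability_iou",
    "ABLATION_VARIANTS",
]

ABLATION_VARIANTS = {
    "full": {"use_ssl_init": True, "use_dice": True},
    "no_dice": {"use_ssl_init": True, "use_dice": False},
    "no_ssl": {"use_ssl_init": False, "use_dice": True},
    "no_ssl_no_dice": {"use_ssl_init": False, "use_dice": False},
}


@dataclass
class ConfusionCounts:
    """C x C confusion matrix (rows = true class, columns = predicted)."""

    class_ids: np.ndarray
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.class_ids = np.asarray(self.class_ids, dtype=int).ravel()
        self.matrix = np.asarray(self.matrix, dtype=int)
        c = self.class_ids.size
        if self.matrix.shape != (c, c) or np.any(self.matrix < 0):
            raise InputError("confusion matrix must be C x C nonnegative")

    def one_vs_rest(self, k: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) treating class index k as positive."""
        m = self.matrix
        tp = int(m[k, k])
        fp = int(m[:, k].sum() - tp)
        fn = int(m[k, :].sum() - tp)
        tn = int(m.sum() - tp - fp - fn)
        return tp, fp, fn, tn


def confusion(true_labels, predicted_labels, class_ids=None) -> ConfusionCounts:
    """Count a confusion matrix over the union of observed class ids."""
    t = np.asarray(true_labels, dtype=int).ravel()
    p = np.asarray(predicted_labels, dtype=int).ravel()
    if t.size != p.size:
        raise InputError("true and predicted label vectors differ in length")
    if class_ids is None:
        class_ids = np.unique(np.concatenate([t, p]))
    else:
        class_ids = np.asarray(class_ids, dtype=int).ravel()
        observed = set(t.tolist()) | set(p.tolist())
        if not observed <= set(class_ids.tolist()):
            raise InputError(f"labels outside class set {class_ids.tolist()}")
    index = {k: i for i, k in enumerate(class_ids.tolist())}
    m = np.zeros((class_ids.size, class_ids.size), dtype=int)
    for ti, pi in zip(t, p):
        m[index[ti], index[pi]] += 1
    return ConfusionCounts(class_ids=class_ids, matrix=m)


def _check_rows(cm: ConfusionCounts) -> None:
    empty = np.nonzero(cm.matrix.sum(axis=1) == 0)[0]
    if empty.size:
        raise UndefinedMetricError(
            f"class {cm.class_ids[empty[0]]} has no true instances; "
            "per-class recall undefined"
        )


def balanced_accuracy(cm: ConfusionCounts) -> float:
    """Mean per-class recall."""
    _check_rows(cm)
    recalls = np.diag(cm.matrix) / cm.matrix.sum(axis=1)
    return float(recalls.mean())


def macro_f1(cm: ConfusionCounts) -> float:
    """Mean one-vs-rest F1 (a class with no predictions and no truth gets 0)."""
    _check_rows(cm)
    f1s = []
    for k in range(cm.class_ids.size):
        tp, fp, fn, _ = cm.one_vs_rest(k)
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom > 0 else 0.0)
    return float(np.mean(f1s))


def sens_spec(cm: ConfusionCounts) -> dict[int, tuple[float, float]]:
    """Per-class (sensitivity, specificity) in one-vs-rest framing."""
    _check_rows(cm)
    out = {}
    for k, cid in enumerate(cm.class_ids.tolist()):
        tp, fp, fn, tn = cm.one_vs_rest(k)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
        out[cid] = (float(sens), float(spec))
    return out


def _ovr_targets(labels: np.ndarray, class_ids: np.ndarray) -> np.ndarray:
    return (labels[:, None] == class_ids[None, :]).astype(int)


def _macro_score(scores, labels, class_ids, fn, name):
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels, dtype=int).ravel()
    if not np.all(np.isfinite(scores)):
        raise InputError("scores must be finite")
    if class_ids is None:
        class_ids = np.unique(labels)
    class_ids = np.asarray(class_ids, dtype=int)
    targets = _ovr_targets(labels, class_ids)
    vals = []
    for j, cid in enumerate(class_ids.tolist()):
        pos = targets[:, j].sum()
        if pos == 0 or pos == labels.size:
            raise UndefinedMetricError(
                f"{name} undefined for class {cid}: needs >= 1 positive and "
                ">= 1 negative"
            )
        vals.append(fn(targets[:, j], scores[:, j]))
    return float(np.mean(vals))


def macro_auroc(scores, labels, class_ids=None) -> float:
    """One-vs-rest AUROC averaged over classes with equal weight (midrank ties)."""
    return _macro_score(scores, labels, class_ids, roc_auc_score, "AUROC")


def macro_ap(scores, labels, class_ids=None) -> float:
    """One-vs-rest average precision averaged over classes."""
    return _macro_score(scores, labels, class_ids, average_precision_score, "AP")


@dataclass
class EvalReport:
    balanced_accuracy: float
    macro_f1: float
    macro_auroc: float
    macro_ap: float
    sens_spec: dict[int, tuple[float, float]]
    confusion: ConfusionCounts
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "balanced_accuracy": self.balanced_accuracy,
            "macro_f1": self.macro_f1,
            "macro_auroc": self.macro_auroc,
            "macro_ap": self.macro_ap,
            "sens_spec": {str(k): list(v) for k, v in self.sens_spec.items()},
            "confusion": self.confusion.matrix.tolist(),
            "class_ids": self.confusion.class_ids.tolist(),
            **{f"meta_{k}": v for k, v in self.metadata.items()},
        }


def evaluate_model(
    model: ProtoDSModel, records: list[InstanceRecord], metadata: dict | None = None
) -> EvalReport:
    """Instance-level evaluation: set-pooled prediction per test instance."""
    true, pred, scores = [], [], []
    for rec in records:
        yhat, post = classify_instance(
            model.net, rec, model.prototypes, distance=model.distance
        )
        true.append(rec.label)
        pred.append(yhat)
        scores.append(post)
    class_ids = model.prototypes.class_ids
    cm = confusion(true, pred, class_ids=class_ids)
    scores = np.stack(scores)
    labels = np.asarray(true)
    return EvalReport(
        balanced_accuracy=balanced_accuracy(cm),
        macro_f1=macro_f1(cm),
        macro_auroc=macro_auroc(scores, labels, class_ids),
        macro_ap=macro_ap(scores, labels, class_ids),
        sens_spec=sens_spec(cm),
        confusion=cm,
        metadata=metadata or {},
    )


@dataclass
class ImbalanceSpec:
    """Protocol for one imbalance setting.

    ``n`` is the training count of the least-represented minority class;
    other minority classes scale as round_half_up(n * orig_k / orig_least).
    The majority class trains at full size.  The test split is drawn once
    from ``seed`` and is identical for every ``n``.
    """

    n: int
    train_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InputError("n must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise InputError("train_fraction must be in (0, 1)")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def build_imbalanced_split(
    manifest: pd.DataFrame, spec: ImbalanceSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split, then minority-training downsampling.

    The per-class shuffle is derived from ``spec.seed`` only, so the test
    rows are invariant to ``n``.  Training counts per class: the majority
    (largest original count) is kept whole, the least minority becomes
    exactly ``n``, intermediate minorities scale by original ratio with
    half-up rounding.
    """
    if not {"instance_id", "label"} <= set(manifest.columns):
        raise InputError("manifest needs instance_id and label columns")
    counts = manifest["label"].value_counts()
    majority = int(counts.idxmax())
    least = int(counts.idxmin())
    train_parts, test_parts = [], []
    for label, group in manifest.groupby("label", sort=True):
        rng = np.random.default_rng([spec.seed, int(label)])
        order = rng.permutation(len(group))
        # half-up on the training side keeps the full minority ladder feasible
        # (e.g. 197 instances at 50/50 -> 99 in training, matching n=20 scaling)
        n_train_full = _round_half_up(spec.train_fraction * len(group))
        train_g = group.iloc[order[:n_train_full]]
        test_g = group.iloc[order[n_train_full:]]
        if int(label) == majority and int(label) != least:
            n_keep = len(train_g)
        elif int(label) == least:
            n_keep = spec.n
        else:
            n_keep = _round_half_up(spec.n * counts[label] / counts[least])
        if n_keep > len(train_g):
            raise InputError(
                f"class {label}: requested {n_keep} training instances but only "
                f"{len(train_g)} available before downsampling"
            )
        train_parts.append(train_g.iloc[:n_keep])
        test_parts.append(test_g)
    return (
        pd.concat(train_parts, ignore_index=True),
        pd.concat(test_parts, ignore_index=True),
    )


def run_ablation(
    train_records: list[InstanceRecord],
    test_records: list[InstanceRecord],
    net_cfg: NetworkConfig,
    ssl_cfg: SSLConfig,
    ft_cfg: FinetuneConfig,
    variants: list[str] = ("full", "no_ssl_no_dice"),
    seeds: list[int] = (0,),
) -> pd.DataFrame:
    """Train each ablation variant from scratch per seed and evaluate.

    Returns a long-format DataFrame (variant, seed, metrics...).  A failed
    cell is recorded with NaN metrics and the error message; the grid
    continues.
    """
    from dataclasses import replace

    rows = []
    for variant in variants:
        flags = ABLATION_VARIANTS[variant]
        for seed in seeds:
            row = {"variant": variant, "seed": int(seed)}
            try:
                ss = replace(ssl_cfg, seed=int(seed))
                ft = replace(ft_cfg, seed=int(seed), **flags)
                model, _ = train_protods(train_records, net_cfg, ss, ft)
                report = evaluate_model(
                    model, test_records, metadata={"variant": variant, "seed": seed}
                )
                row.update(
                    balanced_accuracy=report.balanced_accuracy,
                    macro_f1=report.macro_f1,
                    macro_auroc=report.macro_auroc,
                    macro_ap=report.macro_ap,
                    error="",
                )
            except Exception as exc:  # record the failure, keep going
                row.update(
                    balanced_accuracy=np.nan,
                    macro_f1=np.nan,
                    macro_auroc=np.nan,
                    macro_ap=np.nan,
                    error=str(exc),
                )
            rows.append(row)
    return pd.DataFrame(rows)


def separability_iou(
    embeddings: np.ndarray,
    labels: np.ndarray,
    resolution: int = 200,
    level: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise overlap of per-class Gaussian confidence ellipses in 2-D.

    Embeddings are projected to 2 principal components; each class gets a
    mean + covariance Gaussian whose ``level`` confidence ellipse (Mahalanobis
    radius from the chi-square quantile with 2 df) is rasterized on a common
    ``resolution x resolution`` grid.  Returns (C x C IOU matrix, N x 2
    projection).  A singular class covariance is ridge-regularized with a
    warning.
    """
    import warnings

    embeddings = np.atleast_2d(np.asarray(embeddings, dtype=float))
    labels = np.asarray(labels, dtype=int).ravel()
    class_ids = np.unique(labels)
    if class_ids.size < 2:
        raise InputError("separability needs >= 2 classes")
    for k in class_ids:
        if (labels == k).sum() < 3:
            raise InputError(f"class {k} needs >= 3 samples for a 2-D Gaussian")
    proj = PCA(n_components=2).fit_transform(embeddings)
    r2 = chi2.ppf(level, df=2)

    params = []
    for k in class_ids:
        pts = proj[labels == k]
        mu = pts.mean(axis=0)
        cov = np.cov(pts.T)
        if np.linalg.matrix_rank(cov) < 2 or np.linalg.det(cov) < 1e-300:
            warnings.warn(f"singular covariance for class {k}; regularizing")
            cov = cov + 1e-6 * np.eye(2)
        params.append((mu, np.linalg.inv(cov)))

    # common grid covering every ellipse with a margin
    extents = []
    for (mu, cov_inv) in params:
        cov = np.linalg.inv(cov_inv)
        radius = np.sqrt(r2 * np.linalg.eigvalsh(cov).max())
        extents.append((mu - radius, mu + radius))
    lo = np.min([e[0] for e in extents], axis=0)
    hi = np.max([e[1] for e in extents], axis=0)
    xs = np.linspace(lo[0], hi[0], resolution)
    ys = np.linspace(lo[1], hi[1], resolution)
    gx, gy = np.meshgrid(xs, ys)
    grid = np.stack([gx.ravel(), gy.ravel()], axis=1)

    members = []
    for (mu, cov_inv) in params:
        d = grid - mu
        members.append(np.einsum("ni,ij,nj->n", d, cov_inv, d) <= r2)

    c = class_ids.size
    iou = np.eye(c)
    for i in range(c):
        for j in range(i + 1, c):
            union = np.logical_or(members[i], members[j]).sum()
            inter = np.logical_and(members[i], members[j]).sum()
            iou[i, j] = iou[j, i] = inter / union if union else 0.0
    return iou, proj
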