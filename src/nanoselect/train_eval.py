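"""Training loop, evaluation metrics, and cross-validation harnesses.

Training is plain mini-batch Adam on softmax cross-entropy, fully
deterministic given the config seed (deterministic initialisation and data
order). Evaluation centres on the ROC: the AUC is computed both as the
trapezoid area under the empirical ROC and as the Mann-Whitney probability
that a random target outranks a random host (ties counted half) — the two
agree exactly and the test suite asserts it.

Two cross-validation modes mirror standard practice for this kind of
classifier: stratified k-fold over chunks, and leave-one-species-out, which
holds out every chunk of one microbial species to measure generalisation to
unseen taxa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import confusion_matrix, roc_curve

from . import nn
from .errors import DatasetImbalanceError, InvalidArgumentError
from .model import CLASS_LABELS, ClassifierSpec, SquiggleClassifier
from .preprocess import ChunkDataset

__all__ = [
    "TrainConfig",
    "EvalReport",
    "CVPlan",
    "train",
    "auc_mann_whitney",
    "evaluate_scores",
    "evaluate",
    "kfold_cv",
    "leave_one_species_out_cv",
    "stratified_fold_assignments",
]


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise InvalidArgumentError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise InvalidArgumentError("learning_rate must be >= 0")
        if self.batch_size < 1:
            raise InvalidArgumentError("batch_size must be >= 1")


def train(
    spec: ClassifierSpec,
    train_set: ChunkDataset,
    cfg: TrainConfig | None = None,
) -> SquiggleClassifier:
    """Fit the classifier; returns the fitted model carrying epoch curves.

    The returned model's ``history`` maps "loss" and "accuracy" to per-epoch
    training values; ``training_meta`` records the seed, epochs, and final
    loss/accuracy. Reproducible bit-for-bit for a fixed config seed.
    """
    cfg = cfg or TrainConfig()
    counts = train_set.class_counts()
    if min(counts.values()) == 0:
        raise DatasetImbalanceError(f"training set must contain both classes: {counts}")

    model = SquiggleClassifier(spec, seed=cfg.seed)
    optimiser = nn.Adam(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    X = train_set.X.astype(float)
    y = train_set.y

    loss_curve: list[float] = []
    acc_curve: list[float] = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(train_set))
        losses: list[float] = []
        correct = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = X[idx][:, None, :]
            logits = model.net.forward(xb, training=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y[idx])
            optimiser.zero_grad()
            model.net.backward(dlogits)
            optimiser.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        loss_curve.append(float(np.mean(losses)))
        acc_curve.append(correct / len(order))

    model.history = {"loss": loss_curve, "accuracy": acc_curve}
    model.training_meta = {
        "seed": cfg.seed,
        "epochs": cfg.epochs,
        "batch_size": cfg.batch_size,
        "learning_rate": cfg.learning_rate,
        "final_loss": loss_curve[-1],
        "final_accuracy": acc_curve[-1],
        "n_train": len(train_set),
    }
    return model


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney probability that a random positive (label 1)
    outranks a random negative, ties counted one half.

    Equals the trapezoid area under the empirical ROC of the same scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise InvalidArgumentError("both labels must be present")
    ranks = rankdata(scores)  # midranks handle ties as 1/2
    rank_sum_pos = ranks[labels == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class EvalReport:
    """Classification metrics on one evaluation set.

    ``roc_points`` runs monotonically from (0, 0) to (1, 1); ``auc`` is its
    trapezoid area; ``precision`` takes "target" as the positive class.
    """

    accuracy: float
    precision: float
    auc: float
    roc_points: np.ndarray  # (m, 2) columns FPR, TPR
    confusion: np.ndarray  # rows true, cols predicted, host=0/target=1
    per_species_recall: dict[str, float] = field(default_factory=dict)
    n: int = 0

    def summary(self) -> str:
        lines = [
            f"n = {self.n}",
            f"accuracy  = {self.accuracy:.4f}",
            f"precision = {self.precision:.4f} (positive = target)",
            f"AUC       = {self.auc:.4f}",
            f"confusion (rows true host/target, cols predicted):\n{self.confusion}",
        ]
        for sp, rec in sorted(self.per_species_recall.items()):
            lines.append(f"recall[{sp}] = {rec:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "auc": self.auc,
            "confusion": self.confusion.tolist(),
            "per_species_recall": self.per_species_recall,
        }

    def plot_roc(self, ax=None):
        """ROC curve on a matplotlib axis (created if not given)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.roc_points[:, 0], self.roc_points[:, 1], label=f"AUC={self.auc:.3f}")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax


def evaluate_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    species: list[str] | None = None,
    threshold: float = 0.5,
) -> EvalReport:
    """Build an EvalReport from target-class scores and true labels.

    Predictions are score >= threshold -> target (ties to target, matching
    the classifier's tie-break).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise InvalidArgumentError("both classes must be present in evaluation")
    pred = (scores >= threshold).astype(int)
    acc = float((pred == labels).mean())
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    fpr, tpr, _ = roc_curve(labels, scores)
    roc_points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    conf = confusion_matrix(labels, pred, labels=[0, 1])
    per_species: dict[str, float] = {}
    if species is not None:
        for sp in sorted(set(species)):
            mask = np.array([s == sp for s in species])
            per_species[sp] = float((pred[mask] == labels[mask]).mean())
    return EvalReport(
        accuracy=acc,
        precision=precision,
        auc=auc,
        roc_points=roc_points,
        confusion=conf,
        per_species_recall=per_species,
        n=len(labels),
    )


def evaluate(model: SquiggleClassifier, eval_set: ChunkDataset) -> EvalReport:
    probs = model.predict_proba(eval_set.X.astype(float))
    return evaluate_scores(probs[:, 1], eval_set.y, species=eval_set.species)


@dataclass
class CVPlan:
    mode: str  # "kfold" or "leave_one_species_out"
    assignments: dict[str, int | str]


def stratified_fold_assignments(labels: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold ids.

    Within each class the (shuffled) items are dealt cyclically across folds,
    carrying the dealing offset between classes, so per-class counts are as
    even as possible AND total fold sizes differ by at most one.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise InvalidArgumentError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds = np.full(len(labels), -1, dtype=int)
    offset = 0
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        for j, i in enumerate(idx):
            folds[i] = (offset + j) % k
        offset = (offset + len(idx)) % k
    return folds


def kfold_cv(
    chunks: ChunkDataset,
    k: int = 5,
    spec: ClassifierSpec | None = None,
    cfg: TrainConfig | None = None,
    score_fn=None,
) -> tuple[list[EvalReport], CVPlan]:
    """Stratified k-fold cross-validation; every chunk validates exactly once.

    Trains one model per fold on the other k-1 folds. ``score_fn(train_set,
    eval_set) -> target scores`` replaces training when given (e.g. an oracle
    for testing the harness itself).
    """
    cfg = cfg or TrainConfig()
    counts = chunks.class_counts()
    if min(counts.values()) < k:
        raise InvalidArgumentError(f"need >= {k} chunks per class, have {counts}")
    folds = stratified_fold_assignments(chunks.y, k, seed=cfg.seed)
    reports: list[EvalReport] = []
    for fold in range(k):
        train_idx = np.flatnonzero(folds != fold)
        val_idx = np.flatnonzero(folds == fold)
        train_set = chunks.subset(train_idx)
        val_set = chunks.subset(val_idx)
        if score_fn is not None:
            scores = np.asarray(score_fn(train_set, val_set), dtype=float)
            reports.append(evaluate_scores(scores, val_set.y, species=val_set.species))
        else:
            model = train(spec or ClassifierSpec(), train_set, cfg)
            reports.append(evaluate(model, val_set))
    plan = CVPlan(
        mode="kfold",
        assignments={chunks.read_ids[i]: int(folds[i]) for i in range(len(chunks))},
    )
    return reports, plan


def leave_one_species_out_cv(
    chunks: ChunkDataset,
    spec: ClassifierSpec | None = None,
    cfg: TrainConfig | None = None,
    species: list[str] | None = None,
    score_fn=None,
) -> tuple[dict[str, EvalReport], CVPlan]:
    """Leave-one-species-out cross-validation over the target class.

    For each target species s, trains on host plus all other target species
    and evaluates on the held-out s chunks mixed with an equal-sized sample
    of host chunks that were likewise excluded from that run's training, so
    the evaluation set contains both classes and neither side was seen.
    """
    cfg = cfg or TrainConfig()
    target_species = sorted(
        {chunks.species[i] for i in range(len(chunks)) if chunks.y[i] == 1}
    )
    if len(target_species) < 2:
        raise InvalidArgumentError("need at least 2 target species")
    if species is not None:
        requested = list(species)
        missing = [s for s in requested if s not in target_species]
        for s in missing:
            warnings.warn(f"species {s!r} has zero chunks; skipped", stacklevel=2)
        target_species = [s for s in requested if s in target_species]

    species_arr = np.array(chunks.species)
    host_idx = np.flatnonzero(chunks.y == 0)
    rng = np.random.default_rng(cfg.seed)
    host_order = host_idx[rng.permutation(len(host_idx))]

    reports: dict[str, EvalReport] = {}
    assignments: dict[str, str] = {}
    cursor = 0
    for sp in target_species:
        held_idx = np.flatnonzero((chunks.y == 1) & (species_arr == sp))
        n_host = min(len(held_idx), len(host_order) - cursor)
        if n_host == 0:
            warnings.warn(f"no unseen host chunks left for {sp!r}; skipped", stacklevel=2)
            continue
        host_eval = host_order[cursor : cursor + n_host]
        cursor += n_host
        eval_idx = np.concatenate([held_idx, host_eval])
        train_mask = np.ones(len(chunks), dtype=bool)
        train_mask[eval_idx] = False
        train_set = chunks.subset(np.flatnonzero(train_mask))
        eval_set = chunks.subset(eval_idx)
        if score_fn is not None:
            scores = np.asarray(score_fn(train_set, eval_set), dtype=float)
            reports[sp] = evaluate_scores(scores, eval_set.y, species=eval_set.species)
        else:
            model = train(spec or ClassifierSpec(), train_set, cfg)
            reports[sp] = evaluate(model, eval_set)
        for i in eval_idx:
            assignments[chunks.read_ids[i]] = sp
    plan = CVPlan(mode="leave_one_species_out", assignments=assignments)
    return reports, plan
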