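"""Downstream benchmark construction and cross-validated classification.

Two benchmark families:

* Pair classification — decide whether a heavy/light pair is natively paired
  or a shuffled (random) pairing. Negatives are built by a seeded derangement
  of the light chains, so no light chain keeps its native heavy partner and
  the label balance is exactly 50/50. Each example also carries a mutation
  subset — mutated (both chains mutated), unmutated (both naive), or
  different (one of each) — for stratified reporting.

* Specificity classification — balanced multi-class antigen-specificity
  labels (e.g. healthy donor vs influenza vs coronavirus). Classes are
  deduplicated by greedy identity clustering, downsampled to the smallest
  class, and split with stratified k-fold cross-validation. The unpaired
  variant keeps only the heavy chain of each record.

Classifier scoring reports accuracy, F1, AUC, AUPR and MCC as a mean with a
standard error across folds (sample SD / sqrt(k)).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from sklearn import metrics as skmetrics
from sklearn.model_selection import StratifiedKFold

from .errors import TaskError
from .prep import SeparatorPolicy, Vocabulary, encode_record, filter_and_dedup
from .repertoire import AntibodySequence, PairedRecord

TaskInput = Union[PairedRecord, AntibodySequence]


@dataclasses.dataclass
class TaskExample:
    input: TaskInput
    label: int
    subset: Optional[str] = None  # mutated | unmutated | different
    fold: int = -1


@dataclasses.dataclass
class MetricSummary:
    mean: float
    se: float


@dataclasses.dataclass
class ClassifierMetrics:
    accuracy: MetricSummary
    f1: MetricSummary
    auc: MetricSummary
    aupr: MetricSummary
    mcc: MetricSummary

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {name: {"mean": s.mean, "se": s.se}
                for name, s in dataclasses.asdict(self).items()}


def assign_mutation_subset(pair: PairedRecord) -> str:
    """mutated if both chains carry mutations, unmutated if neither, else different."""
    h, l = pair.heavy.mutation_count > 0, pair.light.mutation_count > 0
    if h and l:
        return "mutated"
    if not h and not l:
        return "unmutated"
    return "different"


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """A uniformly-shuffled permutation with no fixed points (n >= 2)."""
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def build_pair_classification(pairs: Sequence[PairedRecord], seed: int = 0,
                              k_folds: int = 5) -> list[TaskExample]:
    """Native pairs (label 1) plus an equal number of shuffled pairs (label 0)."""
    if len(pairs) < 2:
        raise TaskError("need at least 2 native pairs to build shuffled negatives")
    rng = np.random.default_rng(seed)
    perm = _derangement(len(pairs), rng)
    examples: list[TaskExample] = []
    for pair in pairs:
        examples.append(TaskExample(input=pair, label=1,
                                    subset=assign_mutation_subset(pair)))
    for i, pair in enumerate(pairs):
        shuffled = PairedRecord(heavy=pair.heavy, light=pairs[perm[i]].light,
                                pair_id=f"{pair.pair_id}xR{i}", is_native=False)
        examples.append(TaskExample(input=shuffled, label=0,
                                    subset=assign_mutation_subset(shuffled)))
    labels = np.array([e.label for e in examples])
    folds = stratified_kfold(labels, k=k_folds, seed=seed)
    for ex, fold in zip(examples, folds):
        ex.fold = int(fold)
    return examples


def build_specificity_dataset(class_pools: Mapping[str, Sequence[TaskInput]],
                              identity_threshold: float = 0.99, seed: int = 0,
                              k_folds: int = 5,
                              heavy_only: bool = False) -> list[TaskExample]:
    """Cluster per class, balance to the smallest class, assign stratified folds.

    ``heavy_only`` builds the unpaired variant of the task, keeping only the
    heavy chain of each paired record. Class labels are integers in the order
    the mapping iterates.
    """
    if len(class_pools) < 2:
        raise TaskError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    clustered: dict[str, list[TaskInput]] = {}
    for cls, pool in class_pools.items():
        kept = filter_and_dedup(list(pool), identity_threshold)
        if not kept:
            raise TaskError(f"class {cls!r} is empty after clustering")
        clustered[cls] = kept
    n_per_class = min(len(v) for v in clustered.values())
    examples: list[TaskExample] = []
    for label, (cls, pool) in enumerate(clustered.items()):
        chosen = rng.choice(len(pool), size=n_per_class, replace=False)
        for i in sorted(chosen):
            item = pool[i]
            if heavy_only and isinstance(item, PairedRecord):
                item = item.heavy
            examples.append(TaskExample(input=item, label=label))
    labels = np.array([e.label for e in examples])
    folds = stratified_kfold(labels, k=k_folds, seed=seed)
    for ex, fold in zip(examples, folds):
        ex.fold = int(fold)
    return examples


def stratified_kfold(labels: Sequence[int], k: int = 5, seed: int = 0
                     ) -> np.ndarray:
    """Per-example fold ids with per-class counts balanced to within 1."""
    labels = np.asarray(labels)
    if k < 2:
        raise TaskError("k must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise TaskError(f"smallest class has {counts.min()} members, fewer than k={k}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.full(len(labels), -1, dtype=np.int64)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(labels)), labels)):
        folds[test_idx] = fold
    return folds


def _fold_metrics(y_true: np.ndarray, scores: np.ndarray) -> dict[str, float]:
    """One fold's metric battery from per-class probability scores."""
    n_classes = scores.shape[1]
    y_pred = scores.argmax(1)
    out = {
        "accuracy": skmetrics.accuracy_score(y_true, y_pred),
        "mcc": skmetrics.matthews_corrcoef(y_true, y_pred),
    }
    if n_classes == 2:
        out["f1"] = skmetrics.f1_score(y_true, y_pred, zero_division=0)
    else:
        out["f1"] = skmetrics.f1_score(y_true, y_pred, average="macro",
                                       zero_division=0)
    if len(np.unique(y_true)) < 2:
        out["auc"] = out["aupr"] = float("nan")  # undefined on one-class folds
        return out
    if n_classes == 2:
        out["auc"] = skmetrics.roc_auc_score(y_true, scores[:, 1])
        out["aupr"] = skmetrics.average_precision_score(y_true, scores[:, 1])
    else:
        y_onehot = np.eye(n_classes)[y_true]
        out["auc"] = skmetrics.roc_auc_score(y_onehot, scores, average="macro",
                                             multi_class="ovr")
        out["aupr"] = skmetrics.average_precision_score(y_onehot, scores,
                                                        average="macro")
    return out


def classification_metrics(y_true: Sequence[int], scores: np.ndarray,
                           folds: Sequence[int]) -> ClassifierMetrics:
    """Per-fold metrics summarized as mean and standard error across folds.

    ``scores`` holds per-class probabilities (n_examples, n_classes). Folds
    on which AUC/AUPR are undefined (a single class present) are excluded
    from those two means only.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores)
    folds = np.asarray(folds)
    per_fold: dict[str, list[float]] = {m: [] for m in
                                        ("accuracy", "f1", "auc", "aupr", "mcc")}
    for fold in np.unique(folds):
        sel = folds == fold
        fm = _fold_metrics(y_true[sel], scores[sel])
        for name, value in fm.items():
            per_fold[name].append(value)

    def summarize(values: list[float]) -> MetricSummary:
        arr = np.array([v for v in values if np.isfinite(v)])
        if arr.size == 0:
            return MetricSummary(float("nan"), float("nan"))
        se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
        return MetricSummary(float(arr.mean()), se)

    return ClassifierMetrics(**{m: summarize(v) for m, v in per_fold.items()})


def subset_metrics(examples: Sequence[TaskExample], scores: np.ndarray
                   ) -> dict[str, ClassifierMetrics]:
    """Pair-classification metrics recomputed within each mutation subset."""
    out = {}
    subsets = np.array([e.subset for e in examples])
    labels = np.array([e.label for e in examples])
    folds = np.array([e.fold for e in examples])
    for subset in ("mutated", "unmutated", "different"):
        sel = subsets == subset
        if sel.sum() == 0:
            continue
        out[subset] = classification_metrics(labels[sel], scores[sel], folds[sel])
    return out


# ---------------------------------------------------------------------------
# Classifier head and fine-tuning

class _SoftmaxHead:
    """Two-layer classification head (dense -> tanh -> dense -> softmax)."""

    def __init__(self, n_features: int, n_classes: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(n_features)
        self.W1 = rng.standard_normal((n_features, n_features)) * scale
        self.b1 = np.zeros(n_features)
        self.W2 = rng.standard_normal((n_features, n_classes)) * scale
        self.b2 = np.zeros(n_classes)

    def probs(self, X: np.ndarray) -> np.ndarray:
        hidden = np.tanh(X @ self.W1 + self.b1)
        z = hidden @ self.W2 + self.b2
        z = z - z.max(1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(1, keepdims=True)

    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int, lr: float,
            batch_size: int, rng: np.random.Generator,
            warmup_ratio: float = 0.1) -> None:
        n = len(X)
        n_steps = max(1, epochs * ((n + batch_size - 1) // batch_size))
        warmup = max(1, int(warmup_ratio * n_steps))
        step = 0
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                Xb, yb = X[idx], y[idx]
                hidden = np.tanh(Xb @ self.W1 + self.b1)
                z = hidden @ self.W2 + self.b2
                z = z - z.max(1, keepdims=True)
                p = np.exp(z)
                p /= p.sum(1, keepdims=True)
                dz = p.copy()
                dz[np.arange(len(yb)), yb] -= 1.0
                dz /= len(yb)
                dW2 = hidden.T @ dz
                db2 = dz.sum(0)
                dhid = (dz @ self.W2.T) * (1 - hidden**2)
                dW1 = Xb.T @ dhid
                db1 = dhid.sum(0)
                if step < warmup:
                    cur_lr = lr * (step + 1) / warmup
                else:
                    cur_lr = lr * (n_steps - step) / max(1, n_steps - warmup)
                self.W1 -= cur_lr * dW1
                self.b1 -= cur_lr * db1
                self.W2 -= cur_lr * dW2
                self.b2 -= cur_lr * db2
                step += 1


def pooled_features(model, examples: Sequence[TaskExample], vocab: Vocabulary,
                    policy: SeparatorPolicy = SeparatorPolicy(),
                    batch_size: int = 64) -> np.ndarray:
    """Mean-pooled final hidden states over non-pad positions, per example."""
    feats = []
    encoded = [encode_record(e.input, vocab, policy) for e in examples]
    for i in range(0, len(encoded), batch_size):
        chunk = encoded[i:i + batch_size]
        ids = np.stack([c.ids for c in chunk])
        mask = np.stack([c.attention_mask for c in chunk])
        longest = int(mask.sum(1).max())
        h = model.encode(ids[:, :longest], mask[:, :longest])
        m = mask[:, :longest, None]
        feats.append((h * m).sum(1) / m.sum(1))
    return np.concatenate(feats).astype(np.float64)


@dataclasses.dataclass
class FinetuneConfig:
    epochs: int = 5
    peak_lr: float = 5e-2  # head-only training tolerates a far higher LR
    batch_size: int = 32
    warmup_ratio: float = 0.1
    seed: int = 0


def finetune_classifier(model, task: Sequence[TaskExample], vocab: Vocabulary,
                        cfg: FinetuneConfig = FinetuneConfig(),
                        policy: SeparatorPolicy = SeparatorPolicy(),
                        ) -> tuple[np.ndarray, ClassifierMetrics]:
    """Cross-validated classification on pooled encoder representations.

    For each fold, a fresh two-layer softmax head is trained on the pooled
    features of the other folds and scored on the held-out fold. The encoder
    itself stays frozen (linear-probe style), which keeps desk-scale runs in
    seconds; the head, batch size, warmup ratio and peak LR are configurable.
    Returns the out-of-fold probability matrix and the fold-summarized
    metric battery.
    """
    if any(e.fold < 0 for e in task):
        raise TaskError("task examples are missing fold assignments")
    labels = np.array([e.label for e in task])
    folds = np.array([e.fold for e in task])
    n_classes = int(labels.max()) + 1
    X = pooled_features(model, task, vocab, policy)
    # standardize features; statistics from the training folds only
    scores = np.zeros((len(task), n_classes))
    for fold in np.unique(folds):
        train_sel = folds != fold
        mu, sd = X[train_sel].mean(0), X[train_sel].std(0) + 1e-8
        Xtr = (X[train_sel] - mu) / sd
        Xte = (X[~train_sel & (folds == fold)] - mu) / sd
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed % (2**31), int(fold)]))
        head = _SoftmaxHead(X.shape[1], n_classes, rng)
        if cfg.epochs > 0:
            head.fit(Xtr, labels[train_sel], cfg.epochs, cfg.peak_lr,
                     cfg.batch_size, rng, cfg.warmup_ratio)
        scores[folds == fold] = head.probs(Xte)
    return scores, classification_metrics(labels, scores, folds)
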