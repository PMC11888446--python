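"""Pair/specificity task construction and the classifier metric battery."""

import itertools

import numpy as np
import pytest

from ablm_curriculum.encoder import EncoderConfig, build_encoder
from ablm_curriculum.errors import TaskError
from ablm_curriculum.repertoire import (generate_repertoire,
                                        generate_specificity_pools)
from ablm_curriculum.tasks import (FinetuneConfig, assign_mutation_subset,
                                   build_pair_classification,
                                   build_specificity_dataset,
                                   classification_metrics, finetune_classifier,
                                   stratified_kfold)


@pytest.fixture(scope="module")
def native_pairs():
    pairs, _ = generate_repertoire(100, 0, 0, mutation_rate=5.0,
                                   naive_fraction=0.4, seed=21)
    return pairs


def test_pair_task_balance_and_counts(native_pairs):
    examples = build_pair_classification(native_pairs, seed=0)
    assert len(examples) == 200
    labels = [e.label for e in examples]
    assert labels.count(1) == 100 and labels.count(0) == 100


def test_pair_task_derangement(native_pairs):
    examples = build_pair_classification(native_pairs, seed=1)
    native_light = {p.pair_id: p.light.sequence for p in native_pairs}
    for ex in examples:
        if ex.label == 0:
            source_id = ex.input.pair_id.split("xR")[0]
            assert ex.input.light.sequence != native_light[source_id]
            assert not ex.input.is_native


def test_pair_task_deterministic(native_pairs):
    a = build_pair_classification(native_pairs, seed=2)
    b = build_pair_classification(native_pairs, seed=2)
    assert [e.input.pair_id for e in a] == [e.input.pair_id for e in b]
    assert [e.fold for e in a] == [e.fold for e in b]


def test_pair_task_needs_two_pairs(native_pairs):
    with pytest.raises(TaskError):
        build_pair_classification(native_pairs[:1], seed=0)


@pytest.mark.parametrize("h,l,expected", [(3, 2, "mutated"), (0, 0, "unmutated"),
                                          (3, 0, "different"), (0, 5, "different")])
def test_mutation_subsets(native_pairs, h, l, expected):
    import dataclasses
    pair = native_pairs[0]
    modified = dataclasses.replace(
        pair,
        heavy=dataclasses.replace(pair.heavy, mutation_count=h),
        light=dataclasses.replace(pair.light, mutation_count=l))
    assert assign_mutation_subset(modified) == expected


def test_subset_assignment_total(native_pairs):
    examples = build_pair_classification(native_pairs, seed=3)
    assert all(e.subset in ("mutated", "unmutated", "different")
               for e in examples)


def test_specificity_balancing():
    # unbalanced input pools are downsampled to the smallest clustered class
    pools = generate_specificity_pools(n_per_class=40, seed=4)
    unbalanced = {"HD": pools["HD"][:40], "Flu": pools["Flu"][:30],
                  "CoV": pools["CoV"][:35]}
    examples = build_specificity_dataset(unbalanced, identity_threshold=1.0,
                                         seed=5, k_folds=5)
    labels = [e.label for e in examples]
    assert labels.count(0) == labels.count(1) == labels.count(2)
    assert labels.count(0) <= 30
    assert len(examples) == 3 * labels.count(0)


def test_specificity_heavy_only_variant():
    pools = generate_specificity_pools(n_per_class=25, seed=6)
    examples = build_specificity_dataset(pools, identity_threshold=1.0,
                                         seed=7, heavy_only=True)
    from ablm_curriculum.repertoire import AntibodySequence
    assert all(isinstance(e.input, AntibodySequence) and e.input.chain == "heavy"
               for e in examples)


def test_stratified_kfold_exact_counts():
    labels = np.array([0] * 100 + [1] * 100)
    folds = stratified_kfold(labels, k=5, seed=8)
    for fold in range(5):
        sel = folds == fold
        assert (labels[sel] == 0).sum() == 20
        assert (labels[sel] == 1).sum() == 20


def test_stratified_kfold_uneven_counts():
    labels = np.array([0] * 103 + [1] * 97)
    folds = stratified_kfold(labels, k=5, seed=9)
    for fold in range(5):
        sel = folds == fold
        assert (labels[sel] == 0).sum() in (20, 21)
        assert (labels[sel] == 1).sum() in (19, 20)
    assert np.all(folds >= 0)


def test_stratified_kfold_small_class_rejected():
    labels = np.array([0] * 10 + [1] * 3)
    with pytest.raises(TaskError):
        stratified_kfold(labels, k=5, seed=10)


def test_perfect_classifier_metrics():
    y = np.array([0, 1] * 20)
    scores = np.eye(2)[y]
    folds = np.repeat(np.arange(5), 8)
    metrics = classification_metrics(y, scores, folds)
    for summary in (metrics.accuracy, metrics.f1, metrics.auc, metrics.aupr,
                    metrics.mcc):
        assert summary.mean == pytest.approx(1.0)
        assert summary.se == pytest.approx(0.0)


def test_constant_classifier_on_balanced_task():
    y = np.array([0, 1] * 20)
    scores = np.tile([0.9, 0.1], (40, 1))  # always predicts class 0
    folds = np.repeat(np.arange(5), 8)
    metrics = classification_metrics(y, scores, folds)
    assert metrics.accuracy.mean == pytest.approx(0.5)
    assert metrics.mcc.mean == pytest.approx(0.0)


def _closed_form(tp, fp, fn, tn):
    n = tp + fp + fn + tn
    acc = (tp + tn) / n
    denom = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
    mcc = ((tp * tn - fp * fn) / denom) if denom else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return acc, mcc, f1


def test_hand_built_confusion_matrix():
    # TP=3, FP=1, FN=1, TN=3 -> accuracy 0.75, MCC 0.5
    y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    pred = np.array([1, 1, 1, 0, 1, 0, 0, 0])
    scores = np.stack([1 - pred, pred], axis=1).astype(float)
    metrics = classification_metrics(y, scores, np.zeros(8, int))
    assert metrics.accuracy.mean == pytest.approx(0.75)
    assert metrics.mcc.mean == pytest.approx(0.5)


def test_metrics_agree_with_closed_form_small_matrices():
    # exhaustive 2x2 confusion matrices with cells <= 3 and both classes present
    for tp, fp, fn, tn in itertools.product(range(4), repeat=4):
        n_pos, n_neg = tp + fn, fp + tn
        if n_pos == 0 or n_neg == 0:
            continue
        y = np.array([1] * n_pos + [0] * n_neg)
        pred = np.array([1] * tp + [0] * fn + [1] * fp + [0] * tn)
        scores = np.stack([1 - pred, pred], axis=1).astype(float)
        metrics = classification_metrics(y, scores, np.zeros(len(y), int))
        acc, mcc, f1 = _closed_form(tp, fp, fn, tn)
        assert metrics.accuracy.mean == pytest.approx(acc)
        assert metrics.mcc.mean == pytest.approx(mcc)
        assert metrics.f1.mean == pytest.approx(f1)


def test_single_class_fold_excluded_from_auc():
    y = np.array([0, 0, 0, 0, 0, 1, 0, 1])
    scores = np.tile([0.6, 0.4], (8, 1))
    folds = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    metrics = classification_metrics(y, scores, folds)
    assert np.isfinite(metrics.auc.mean)  # fold 0 dropped, fold 1 kept
    assert np.isfinite(metrics.accuracy.mean)


@pytest.fixture(scope="module")
def tiny_model():
    return build_encoder(EncoderConfig(n_layers=1, n_heads=2, hidden_size=16,
                                       intermediate_size=32), seed=30)


def test_finetune_zero_epochs_near_chance(tiny_model, vocab):
    pools = generate_specificity_pools(n_per_class=30, motif_strength=0.9, seed=31)
    task = build_specificity_dataset(pools, identity_threshold=1.0, seed=32)
    _, metrics = finetune_classifier(tiny_model, task, vocab,
                                     FinetuneConfig(epochs=0, seed=33))
    assert 0.1 < metrics.accuracy.mean < 0.6  # untrained head ~ chance (1/3)


def test_finetune_learns_injected_specificity_signal(tiny_model, vocab):
    pools = generate_specificity_pools(n_per_class=60, motif_strength=0.9,
                                       seed=34)
    task = build_specificity_dataset(pools, identity_threshold=1.0, seed=35)
    _, metrics = finetune_classifier(tiny_model, task, vocab,
                                     FinetuneConfig(epochs=30, seed=36))
    assert metrics.accuracy.mean > 1 / 3 + 0.15  # clearly above chance


def test_finetune_deterministic(tiny_model, vocab):
    pools = generate_specificity_pools(n_per_class=20, motif_strength=0.9, seed=37)
    task = build_specificity_dataset(pools, identity_threshold=1.0, seed=38)
    s1, m1 = finetune_classifier(tiny_model, task, vocab,
                                 FinetuneConfig(epochs=3, seed=39))
    s2, m2 = finetune_classifier(tiny_model, task, vocab,
                                 FinetuneConfig(epochs=3, seed=39))
    assert np.array_equal(s1, s2)
    assert m1 == m2
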