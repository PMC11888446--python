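"""MLM evaluation: CE and accuracy over labeled positions, per-region CE, and
CDRH3 accuracy by single-position masking.

All metrics are computed only at labeled (predicted) positions, so structural
tokens — separator, cls, eos, padding — can never influence a reported
number: they are simply never labeled, and per-region/CDRH3 scoring masks
residue positions one at a time with the rest of the sequence visible.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np

from .errors import EvaluationError
from .prep import IGNORE_INDEX, TokenizedExample, Vocabulary
from .sampler import collate

REGION_NAMES = tuple(f"{c}-{r}" for c in "HL"
                     for r in ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4"))


@dataclasses.dataclass
class EvalReport:
    ce_loss: float
    accuracy: float
    n_positions: int
    per_region: dict[str, float] | None = None


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(-1, keepdims=True)
    return z - np.log(np.exp(z).sum(-1, keepdims=True))


def _score_labeled(model, examples: Sequence[TokenizedExample],
                   batch_size: int = 64):
    """Yield (nll, correct) per labeled position across the dataset."""
    nlls, hits = [], []
    for i in range(0, len(examples), batch_size):
        ids, mask, labels = collate(examples[i:i + batch_size])
        longest = int(mask.sum(1).max())  # pads are masked: cropping is exact
        ids, mask, labels = ids[:, :longest], mask[:, :longest], labels[:, :longest]
        logits = model.forward(ids, mask)
        labeled = labels != IGNORE_INDEX
        rows = np.where(labeled)
        if rows[0].size == 0:
            continue
        true = labels[rows]
        logp = _log_softmax(logits.astype(np.float64))
        nlls.append(-logp[rows[0], rows[1], true])
        hits.append(logits[rows].argmax(-1) == true)
    if not nlls:
        return np.empty(0), np.empty(0, bool)
    return np.concatenate(nlls), np.concatenate(hits)


def masked_eval(model, examples: Sequence[TokenizedExample],
                batch_size: int = 64) -> EvalReport:
    """CE and accuracy averaged over labeled positions only."""
    nll, hit = _score_labeled(model, examples, batch_size)
    if nll.size == 0:
        raise EvaluationError("dataset has no labeled positions")
    return EvalReport(ce_loss=float(nll.mean()), accuracy=float(hit.mean()),
                      n_positions=int(nll.size))


def _single_mask_scores(model, example: TokenizedExample, positions: np.ndarray,
                        vocab: Vocabulary, batch_size: int = 128):
    """Mask each listed position individually; return (nll, correct) arrays."""
    nlls, hits = [], []
    longest = int(example.attention_mask.sum())
    for i in range(0, len(positions), batch_size):
        chunk = positions[i:i + batch_size]
        ids = np.repeat(example.ids[None, :longest], len(chunk), axis=0)
        mask = np.repeat(example.attention_mask[None, :longest], len(chunk), axis=0)
        rows = np.arange(len(chunk))
        true = ids[rows, chunk].copy()
        ids[rows, chunk] = vocab.mask_id
        logits = model.forward(ids, mask)
        at = logits[rows, chunk]
        logp = _log_softmax(at.astype(np.float64))
        nlls.append(-logp[rows, true])
        hits.append(at.argmax(-1) == true)
    return np.concatenate(nlls), np.concatenate(hits)


def per_region_loss(model, examples: Sequence[TokenizedExample],
                    vocab: Vocabulary) -> dict[str, float]:
    """Mean CE per region via per-position masking.

    Each position of each region is masked one at a time (the rest of the
    sequence stays visible), predicted, and its CE accumulated; the mean is
    over all (sequence, position) pairs of that region across the dataset.
    Regions absent from every example are omitted with a warning.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for ex in examples:
        for region, (start, end) in ex.token_regions.items():
            if end <= start:
                continue
            positions = np.arange(start, end)
            nll, _ = _single_mask_scores(model, ex, positions, vocab)
            sums[region] = sums.get(region, 0.0) + float(nll.sum())
            counts[region] = counts.get(region, 0) + len(positions)
    if not sums:
        raise EvaluationError("no region annotations in the dataset")
    missing = [r for r in REGION_NAMES if r not in sums]
    if missing:
        warnings.warn(f"regions absent from all examples, omitted: {missing}")
    return {region: sums[region] / counts[region] for region in sums}


def cdrh3_accuracy(model, examples: Sequence[TokenizedExample],
                   vocab: Vocabulary, average: str = "micro") -> float:
    """Accuracy of single-position masked predictions in the heavy CDR3.

    ``micro`` pools every (sequence, position) pair into one mean; ``macro``
    averages per-sequence accuracies.
    """
    if average not in ("micro", "macro"):
        raise ValueError("average must be 'micro' or 'macro'")
    all_hits: list[np.ndarray] = []
    for ex in examples:
        interval = ex.token_regions.get("H-CDR3")
        if interval is None or interval[1] <= interval[0]:
            continue
        positions = np.arange(interval[0], interval[1])
        _, hit = _single_mask_scores(model, ex, positions, vocab)
        all_hits.append(hit)
    if not all_hits:
        raise EvaluationError("no H-CDR3 annotations in the dataset")
    if average == "micro":
        return float(np.concatenate(all_hits).mean())
    return float(np.mean([h.mean() for h in all_hits]))
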