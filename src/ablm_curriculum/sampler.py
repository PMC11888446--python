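"""Per-step batch composition and MLM collation.

Each training step draws its batch from two pools — unpaired and paired —
according to the schedule's unpaired probability at that step. The unpaired
count is a binomial draw (each slot in the batch is independently unpaired
with probability P(step)), which is unbiased for any probability. Within a
pool, examples are drawn without replacement from a per-epoch permutation
that reshuffles when exhausted, with the reshuffle seed derived
deterministically from (base seed, pool name, epoch number) so runs are
reproducible across restarts.

The MLM collator selects 15% of eligible positions for prediction; of those,
80% become the mask token, 10% a random residue token, and 10% are left
unchanged. Structural tokens (cls/sep/eos/pad) are never selected and random
replacement never draws a special token.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .errors import SamplingError
from .prep import IGNORE_INDEX, TokenizedExample, Vocabulary
from .schedule import SchedulePlan


@dataclasses.dataclass
class MLMConfig:
    select_rate: float = 0.15
    mask_rate: float = 0.8
    random_rate: float = 0.1
    keep_rate: float = 0.1

    def __post_init__(self):
        if not 0.0 < self.select_rate < 1.0:
            raise ValueError("select_rate must lie in (0, 1)")
        if abs(self.mask_rate + self.random_rate + self.keep_rate - 1.0) > 1e-12:
            raise ValueError("mask_rate + random_rate + keep_rate must equal 1")


class Pool:
    """A named example pool cycled without replacement across epochs."""

    def __init__(self, name: str, examples: Sequence, base_seed: int = 0):
        self.name = name
        self.examples = list(examples)
        self.base_seed = int(base_seed)
        self.epoch = 0
        self._cursor = 0
        self._perm = self._permutation(0) if self.examples else np.empty(0, int)

    def __len__(self) -> int:
        return len(self.examples)

    def _permutation(self, epoch: int) -> np.ndarray:
        # pool name folded into the seed as a stable small integer
        name_code = sum(ord(c) for c in self.name) % (2**16)
        seq = np.random.SeedSequence([self.base_seed % (2**31), name_code, epoch])
        return np.random.default_rng(seq).permutation(len(self.examples))

    def draw_indices(self, n: int) -> np.ndarray:
        """Next n indices of the current epoch permutation, cycling epochs."""
        if n == 0:
            return np.empty(0, dtype=np.int64)
        if not self.examples:
            raise SamplingError(f"pool {self.name!r} is empty")
        out = []
        while n > 0:
            available = len(self._perm) - self._cursor
            take = min(n, available)
            out.append(self._perm[self._cursor:self._cursor + take])
            self._cursor += take
            n -= take
            if self._cursor == len(self._perm):
                self.epoch += 1
                self._perm = self._permutation(self.epoch)
                self._cursor = 0
        return np.concatenate(out).astype(np.int64)

    def take(self, indices: np.ndarray) -> list:
        return [self.examples[i] for i in indices]


@dataclasses.dataclass
class BatchPlan:
    """Composition of one training batch: which pool, which indices."""

    step: int
    n_unpaired: int
    n_paired: int
    unpaired_indices: np.ndarray
    paired_indices: np.ndarray

    @property
    def batch_size(self) -> int:
        return self.n_unpaired + self.n_paired


def plan_batch(schedule: SchedulePlan, step: int, batch_size: int,
               rng: np.random.Generator, unpaired_pool: Pool,
               paired_pool: Pool) -> BatchPlan:
    """Draw one batch's composition from the schedule's P(step)."""
    if not 0 <= step < schedule.total_steps:
        raise ValueError(f"step {step} outside [0, {schedule.total_steps})")
    if batch_size <= 0:
        raise ValueError("batch_size must be positive")
    p = schedule.probability_fn(step)
    n_unpaired = int(rng.binomial(batch_size, p))
    n_paired = batch_size - n_unpaired
    if n_unpaired > 0 and len(unpaired_pool) == 0:
        raise SamplingError("unpaired pool is empty but unpaired examples requested")
    if n_paired > 0 and len(paired_pool) == 0:
        raise SamplingError("paired pool is empty but paired examples requested")
    return BatchPlan(
        step=step, n_unpaired=n_unpaired, n_paired=n_paired,
        unpaired_indices=unpaired_pool.draw_indices(n_unpaired),
        paired_indices=paired_pool.draw_indices(n_paired))


def apply_mlm(example: TokenizedExample, cfg: MLMConfig, vocab: Vocabulary,
              rng: np.random.Generator) -> TokenizedExample:
    """Return a copy with MLM corruption applied and labels filled in.

    Only residue-token positions under the attention mask are eligible; each
    is selected independently with probability select_rate. Selected
    positions carry the original id as label; their input id becomes the mask
    token w.p. mask_rate, a uniformly random residue token w.p. random_rate,
    and stays unchanged otherwise. Unselected labels remain IGNORE.
    """
    ids = example.ids.copy()
    labels = np.full_like(ids, IGNORE_INDEX)
    residue_ids = np.array(vocab.residue_ids)
    eligible = np.isin(ids, residue_ids) & (example.attention_mask == 1)
    selected = eligible & (rng.random(len(ids)) < cfg.select_rate)
    labels[selected] = ids[selected]
    action = rng.random(len(ids))
    mask_here = selected & (action < cfg.mask_rate)
    random_here = selected & (action >= cfg.mask_rate) & \
        (action < cfg.mask_rate + cfg.random_rate)
    ids[mask_here] = vocab.mask_id
    n_random = int(random_here.sum())
    if n_random:
        ids[random_here] = rng.choice(residue_ids, size=n_random)
    return TokenizedExample(ids=ids, attention_mask=example.attention_mask.copy(),
                            labels=labels, origin=example.origin,
                            token_regions=dict(example.token_regions))


def collate(examples: Sequence[TokenizedExample]
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack examples into (ids, attention_mask, labels) batch arrays."""
    ids = np.stack([e.ids for e in examples])
    mask = np.stack([e.attention_mask for e in examples])
    labels = np.stack([e.labels for e in examples])
    return ids, mask, labels
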