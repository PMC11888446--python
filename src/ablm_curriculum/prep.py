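"""Vocabulary, separator placement, tokenization, dedup and data splits.

The vocabulary is the 33-token ESM-2 alphabet. When a dedicated chain
separator is requested, the base vocabulary's unused ``<null_1>`` placeholder
is replaced by ``<sep>`` so the size stays exactly 33 and every residue and
special token keeps its id. Separator placement follows one convention for
all inputs: between the chains of a paired sequence, at the end of an
unpaired heavy chain, and at the beginning of an unpaired light chain — so a
model can always tell which side of the separator a chain sits on.

Inputs are padded to a fixed 320 tokens, long enough for the longest paired
heavy+light sequence plus the structural tokens.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .errors import LengthError, SplitError, TokenizationError
from .repertoire import CANONICAL_AA, AntibodySequence, PairedRecord

MAX_LEN = 320
IGNORE_INDEX = -100

# ESM-2 token order; <null_1> is the placeholder swapped for <sep>.
_BASE_TOKENS = (
    "<cls>", "<pad>", "<eos>", "<unk>",
    "L", "A", "G", "V", "S", "E", "R", "T", "I", "D", "P", "K",
    "Q", "N", "F", "Y", "M", "H", "W", "C",
    "X", "B", "U", "Z", "O", ".", "-",
    "<null_1>", "<mask>",
)


class SeparatorMode(str, enum.Enum):
    """How the chain separator is realized.

    unique_sep : a dedicated ``<sep>`` token replaces the placeholder token.
    reuse_cls  : the ``<cls>`` token doubles as the separator.
    none       : no separator is emitted anywhere.
    """

    unique_sep = "sep"
    reuse_cls = "cls"
    none = "none"


@dataclasses.dataclass(frozen=True)
class SeparatorPolicy:
    separator: SeparatorMode = SeparatorMode.unique_sep

    @classmethod
    def from_name(cls, name: str) -> "SeparatorPolicy":
        return cls(SeparatorMode(name))


@dataclasses.dataclass(frozen=True)
class Vocabulary:
    """Fixed 33-token vocabulary with special-token bookkeeping."""

    tokens: tuple[str, ...]
    index: dict[str, int]
    cls_token: str = "<cls>"
    pad_token: str = "<pad>"
    eos_token: str = "<eos>"
    unk_token: str = "<unk>"
    mask_token: str = "<mask>"
    sep_token: Optional[str] = None  # None when <cls> is reused or no separator

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def cls_id(self) -> int:
        return self.index[self.cls_token]

    @property
    def pad_id(self) -> int:
        return self.index[self.pad_token]

    @property
    def eos_id(self) -> int:
        return self.index[self.eos_token]

    @property
    def mask_id(self) -> int:
        return self.index[self.mask_token]

    @property
    def residue_ids(self) -> tuple[int, ...]:
        return tuple(self.index[aa] for aa in CANONICAL_AA)

    def encode_token(self, token: str) -> int:
        return self.index[token]

    def decode_id(self, token_id: int) -> str:
        return self.tokens[token_id]


def build_vocabulary(policy: SeparatorPolicy = SeparatorPolicy()) -> Vocabulary:
    """Build the 33-token vocabulary for a separator policy."""
    tokens = list(_BASE_TOKENS)
    sep_token = None
    if policy.separator is SeparatorMode.unique_sep:
        tokens[tokens.index("<null_1>")] = "<sep>"
        sep_token = "<sep>"
    vocab = Vocabulary(tokens=tuple(tokens),
                       index={t: i for i, t in enumerate(tokens)},
                       sep_token=sep_token)
    assert len(vocab) == 33
    return vocab


@dataclasses.dataclass
class TokenizedExample:
    """A fixed-length model input: ids, mask, MLM labels and region map."""

    ids: np.ndarray            # (320,) int64
    attention_mask: np.ndarray  # (320,) int64, 1 on real tokens
    labels: np.ndarray          # (320,) int64, IGNORE_INDEX where unpredicted
    origin: str                 # paired | unpaired_heavy | unpaired_light
    token_regions: dict[str, tuple[int, int]] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if not (len(self.ids) == len(self.attention_mask) == len(self.labels) == MAX_LEN):
            raise ValueError(f"all arrays must have length {MAX_LEN}")

    @property
    def length(self) -> int:
        return int(self.attention_mask.sum())


Record = Union[PairedRecord, AntibodySequence]


def _separator_tokens(policy: SeparatorPolicy) -> list[str]:
    if policy.separator is SeparatorMode.unique_sep:
        return ["<sep>"]
    if policy.separator is SeparatorMode.reuse_cls:
        return ["<cls>"]
    return []


def _check_residues(sequence: str, where: str) -> None:
    for pos, ch in enumerate(sequence):
        if ch not in CANONICAL_AA:
            raise TokenizationError(
                f"unknown residue {ch!r} at position {pos} of {where}")


def format_tokens(record: Record, policy: SeparatorPolicy = SeparatorPolicy()
                  ) -> list[str]:
    """Lay out one record as an unpadded token-string list.

    paired          -> [<cls>] H.. [sep] L.. [<eos>]
    unpaired heavy  -> [<cls>] H.. [sep] [<eos>]
    unpaired light  -> [<cls>] [sep] L.. [<eos>]
    """
    sep = _separator_tokens(policy)
    if isinstance(record, PairedRecord):
        _check_residues(record.heavy.sequence, "heavy chain")
        _check_residues(record.light.sequence, "light chain")
        return (["<cls>"] + list(record.heavy.sequence) + sep
                + list(record.light.sequence) + ["<eos>"])
    _check_residues(record.sequence, f"{record.chain} chain")
    if record.chain == "heavy":
        return ["<cls>"] + list(record.sequence) + sep + ["<eos>"]
    return ["<cls>"] + sep + list(record.sequence) + ["<eos>"]


def origin_of(record: Record) -> str:
    if isinstance(record, PairedRecord):
        return "paired"
    return "unpaired_heavy" if record.chain == "heavy" else "unpaired_light"


def token_region_map(record: Record, policy: SeparatorPolicy = SeparatorPolicy()
                     ) -> dict[str, tuple[int, int]]:
    """Region intervals in token coordinates (H-/L- prefixed).

    Residue coordinates shift by 1 for the leading cls token; light-chain
    regions in paired inputs shift additionally by the heavy length and the
    separator (if any).
    """
    n_sep = len(_separator_tokens(policy))
    out: dict[str, tuple[int, int]] = {}
    if isinstance(record, PairedRecord):
        h_off = 1
        l_off = 1 + len(record.heavy.sequence) + n_sep
        for name, (a, b) in record.heavy.regions.items():
            out[f"H-{name}"] = (a + h_off, b + h_off)
        for name, (a, b) in record.light.regions.items():
            out[f"L-{name}"] = (a + l_off, b + l_off)
        return out
    if record.chain == "heavy":
        off, prefix = 1, "H"
    else:
        off, prefix = 1 + n_sep, "L"
    for name, (a, b) in record.regions.items():
        out[f"{prefix}-{name}"] = (a + off, b + off)
    return out


def tokenize_and_pad(tokens: Sequence[str], vocab: Vocabulary,
                     origin: str = "paired",
                     token_regions: Optional[dict[str, tuple[int, int]]] = None,
                     ) -> TokenizedExample:
    """Map token strings to ids and pad to the fixed 320-token length."""
    if len(tokens) > MAX_LEN:
        raise LengthError(f"token stream of length {len(tokens)} exceeds {MAX_LEN}")
    ids = np.full(MAX_LEN, vocab.pad_id, dtype=np.int64)
    for i, tok in enumerate(tokens):
        try:
            ids[i] = vocab.index[tok]
        except KeyError:
            raise TokenizationError(f"unknown token {tok!r} at position {i}") from None
    mask = np.zeros(MAX_LEN, dtype=np.int64)
    mask[:len(tokens)] = 1
    labels = np.full(MAX_LEN, IGNORE_INDEX, dtype=np.int64)
    return TokenizedExample(ids=ids, attention_mask=mask, labels=labels,
                            origin=origin, token_regions=dict(token_regions or {}))


def encode_record(record: Record, vocab: Vocabulary,
                  policy: SeparatorPolicy = SeparatorPolicy()) -> TokenizedExample:
    """format_tokens + region mapping + tokenize_and_pad in one call."""
    return tokenize_and_pad(format_tokens(record, policy), vocab,
                            origin=origin_of(record),
                            token_regions=token_region_map(record, policy))


# ---------------------------------------------------------------------------
# Filtering / dedup / splitting

def _sequence_of(item) -> str:
    if isinstance(item, PairedRecord):
        return item.heavy.sequence + item.light.sequence
    if isinstance(item, AntibodySequence):
        return item.sequence
    return str(item)


def pairwise_identity(a: str, b: str) -> float:
    """Exact matches over aligned leading positions, divided by max length.

    A deliberately simple, alignment-free identity used by the greedy
    clustering stand-in; it supports dedup semantics at desk scale but is not
    a replacement for CD-HIT/AntiRef-style clustering of real repertoires.
    """
    if not a or not b:
        return 0.0
    matches = sum(x == y for x, y in zip(a, b))
    return matches / max(len(a), len(b))


def filter_and_dedup(sequences: Iterable, identity_threshold: float = 0.9) -> list:
    """Remove malformed records, then greedy centroid clustering.

    Records containing the literal substring ``"nan"`` (case-insensitive) or
    characters outside the canonical alphabet are dropped. The survivors are
    scanned in input order: a sequence joins the first existing centroid with
    identity >= threshold, otherwise it founds a new centroid. Returns the
    centroids (first representatives), preserving first-occurrence order.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must lie in (0, 1]")
    centroids: list = []
    centroid_seqs: list[str] = []
    for item in sequences:
        seq = _sequence_of(item)
        if "nan" in seq.lower() or set(seq) - set(CANONICAL_AA):
            continue
        for cs in centroid_seqs:
            if pairwise_identity(seq, cs) >= identity_threshold:
                break
        else:
            centroids.append(item)
            centroid_seqs.append(seq)
    return centroids


def split_train_eval_test(items: Sequence, train_fraction: float = 0.96,
                          seed: int = 0) -> tuple[list, list, list]:
    """Seeded shuffle, then split; eval/test each take half of the holdout."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    if len(items) < 3:
        raise SplitError(f"need at least 3 items to split, got {len(items)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    n_train = round(train_fraction * len(items))
    n_train = min(max(n_train, 1), len(items) - 2)
    holdout = len(items) - n_train
    n_eval = holdout // 2
    train = [items[i] for i in order[:n_train]]
    eval_ = [items[i] for i in order[n_train:n_train + n_eval]]
    test = [items[i] for i in order[n_train + n_eval:]]
    return train, eval_, test
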