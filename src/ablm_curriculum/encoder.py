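"""A small bidirectional transformer encoder for masked language modeling.

Pure NumPy, forward and backward passes written out explicitly, with an Adam
optimizer — sized for CPU experiments (the default configuration is 2 layers
with hidden size 64). The architecture is a standard pre-norm encoder:
embedding, per-layer multi-head self-attention and GELU MLP blocks with
residual connections and layer norm, a final layer norm, and an output
projection tied to the input embedding. Positional information is either
rotary (queries and keys rotated by position-dependent angles, so attention
depends only on relative distance) or a learned absolute position table.

Float32 by default; a float64 mode exists for gradient checking.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy.special import erf

from .errors import ConfigurationError, DivergenceError
from .prep import IGNORE_INDEX, TokenizedExample
from .sampler import MLMConfig, Pool, apply_mlm, collate, plan_batch
from .schedule import LRScheduleConfig, SchedulePlan, lr_at

_NEG_INF = -1e9
_LN_EPS = 1e-5


@dataclasses.dataclass
class EncoderConfig:
    n_layers: int = 2
    n_heads: int = 4
    hidden_size: int = 64
    intermediate_size: int = 256
    pe_type: str = "rope"  # "rope" | "absolute"
    vocab_size: int = 33
    max_positions: int = 320
    rope_base: float = 10_000.0
    dtype: str = "float32"

    def __post_init__(self):
        if self.hidden_size % self.n_heads != 0:
            raise ConfigurationError(
                f"hidden_size {self.hidden_size} not divisible by n_heads {self.n_heads}")
        if (self.hidden_size // self.n_heads) % 2 != 0:
            raise ConfigurationError("head dimension must be even for rotary embeddings")
        if self.pe_type not in ("rope", "absolute"):
            raise ConfigurationError(f"unknown pe_type {self.pe_type!r}")
        if self.pe_type == "absolute" and self.max_positions < 320:
            raise ConfigurationError("absolute PE requires max_positions >= 320")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


# ---------------------------------------------------------------------------
# Rotary position embedding

def _rope_angles(n_positions: int, dim: int, base: float) -> tuple[np.ndarray, np.ndarray]:
    half = dim // 2
    inv_freq = base ** (-2.0 * np.arange(half) / dim)  # (half,)
    angles = np.arange(n_positions)[:, None] * inv_freq[None, :]  # (L, half)
    return np.cos(angles), np.sin(angles)


def rope_rotate(x: np.ndarray, position: int | np.ndarray,
                base: float = 10_000.0) -> np.ndarray:
    """Rotate a vector (last axis, even dimension d) by its position.

    Coordinate pair i = (x[i], x[i + d/2]) is rotated by the angle
    position * base^(-2 i / d). The map is orthogonal, so norms are
    preserved, and the dot product of two rotated vectors depends only on
    the difference of their positions.
    """
    x = np.asarray(x)
    d = x.shape[-1]
    if d % 2 != 0:
        raise ValueError(f"rope_rotate requires an even dimension, got {d}")
    half = d // 2
    inv_freq = base ** (-2.0 * np.arange(half) / d)
    angles = np.asarray(position)[..., None] * inv_freq
    cos, sin = np.cos(angles), np.sin(angles)
    x1, x2 = x[..., :half], x[..., half:]
    return np.concatenate([x1 * cos - x2 * sin, x1 * sin + x2 * cos], axis=-1)


def _rope_apply(x: np.ndarray, cos: np.ndarray, sin: np.ndarray) -> np.ndarray:
    # x: (B, H, L, dh); cos/sin: (L, dh/2)
    half = x.shape[-1] // 2
    x1, x2 = x[..., :half], x[..., half:]
    return np.concatenate([x1 * cos - x2 * sin, x1 * sin + x2 * cos], axis=-1)


def _rope_apply_inverse(x: np.ndarray, cos: np.ndarray, sin: np.ndarray) -> np.ndarray:
    half = x.shape[-1] // 2
    x1, x2 = x[..., :half], x[..., half:]
    return np.concatenate([x1 * cos + x2 * sin, -x1 * sin + x2 * cos], axis=-1)


# ---------------------------------------------------------------------------
# Primitive layers

def _gelu(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # returns (gelu(x), Phi(x)); Phi is cached for the backward pass
    cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
    return x * cdf, cdf


def _gelu_grad(x: np.ndarray, cdf: np.ndarray) -> np.ndarray:
    phi = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
    return cdf + x * phi


def _outer_grad(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # sum_{batch,pos} a[..., i] b[..., j] via one BLAS gemm
    return a.reshape(-1, a.shape[-1]).T @ b.reshape(-1, b.shape[-1])


def _ln_forward(x, g, b):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv_std
    return g * xhat + b, (xhat, inv_std)


def _ln_backward(dy, g, cache):
    xhat, inv_std = cache
    dgamma = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    dbeta = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv_std * (dxhat - dxhat.mean(-1, keepdims=True)
                    - xhat * (dxhat * xhat).mean(-1, keepdims=True))
    return dx, dgamma, dbeta


def _softmax(x: np.ndarray) -> np.ndarray:
    x = x - x.max(-1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(-1, keepdims=True)


class TransformerEncoder:
    """Parameters live in a flat dict of NumPy arrays; see :meth:`forward`."""

    def __init__(self, cfg: EncoderConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        dt = cfg.np_dtype
        d, inter, V = cfg.hidden_size, cfg.intermediate_size, cfg.vocab_size

        def w(*shape, scale=0.02):
            return (rng.standard_normal(shape) * scale).astype(dt)

        p: dict[str, np.ndarray] = {"E": w(V, d), "b_out": np.zeros(V, dt)}
        if cfg.pe_type == "absolute":
            p["P"] = w(cfg.max_positions, d)
        for layer in range(cfg.n_layers):
            pre = f"l{layer}."
            p[pre + "ln1_g"] = np.ones(d, dt)
            p[pre + "ln1_b"] = np.zeros(d, dt)
            for name in ("q", "k", "v", "o"):
                p[pre + f"W{name}"] = w(d, d)
                p[pre + f"b{name}"] = np.zeros(d, dt)
            p[pre + "ln2_g"] = np.ones(d, dt)
            p[pre + "ln2_b"] = np.zeros(d, dt)
            p[pre + "W1"] = w(d, inter)
            p[pre + "b1"] = np.zeros(inter, dt)
            p[pre + "W2"] = w(inter, d)
            p[pre + "b2"] = np.zeros(d, dt)
        p["lnf_g"] = np.ones(d, dt)
        p["lnf_b"] = np.zeros(d, dt)
        self.params = p

    # -- forward ------------------------------------------------------------

    def _split_heads(self, x):
        B, L, d = x.shape
        H = self.cfg.n_heads
        return x.reshape(B, L, H, d // H).transpose(0, 2, 1, 3)

    def _merge_heads(self, x):
        B, H, L, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, L, H * dh)

    def _hidden(self, ids: np.ndarray, attention_mask: np.ndarray,
                want_cache: bool):
        cfg, p = self.cfg, self.params
        B, L = ids.shape
        dh = cfg.hidden_size // cfg.n_heads
        x = p["E"][ids]
        if cfg.pe_type == "absolute":
            x = x + p["P"][:L]
        x = np.ascontiguousarray(x)
        key_bias = ((1 - attention_mask) * _NEG_INF).astype(x.dtype)[:, None, None, :]
        if cfg.pe_type == "rope":
            cos, sin = _rope_angles(L, dh, cfg.rope_base)
            cos, sin = cos.astype(x.dtype), sin.astype(x.dtype)
        else:
            cos = sin = None
        caches = []
        for layer in range(cfg.n_layers):
            pre = f"l{layer}."
            a_in, ln1_cache = _ln_forward(x, p[pre + "ln1_g"], p[pre + "ln1_b"])
            q = self._split_heads(a_in @ p[pre + "Wq"] + p[pre + "bq"])
            k = self._split_heads(a_in @ p[pre + "Wk"] + p[pre + "bk"])
            v = self._split_heads(a_in @ p[pre + "Wv"] + p[pre + "bv"])
            if cfg.pe_type == "rope":
                q = _rope_apply(q, cos, sin)
                k = _rope_apply(k, cos, sin)
            scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(dh) + key_bias
            att = _softmax(scores)
            ctx = self._merge_heads(att @ v)
            attn_out = ctx @ p[pre + "Wo"] + p[pre + "bo"]
            x_attn = x + attn_out
            m_in, ln2_cache = _ln_forward(x_attn, p[pre + "ln2_g"], p[pre + "ln2_b"])
            hpre = m_in @ p[pre + "W1"] + p[pre + "b1"]
            hact, hcdf = _gelu(hpre)
            x_out = x_attn + hact @ p[pre + "W2"] + p[pre + "b2"]
            if want_cache:
                caches.append(dict(a_in=a_in, ln1=ln1_cache, q=q, k=k, v=v,
                                   att=att, ctx=ctx, m_in=m_in, ln2=ln2_cache,
                                   hpre=hpre, hact=hact, hcdf=hcdf))
            x = x_out
        h, lnf_cache = _ln_forward(x, p["lnf_g"], p["lnf_b"])
        cache = dict(ids=ids, L=L, layers=caches, lnf=lnf_cache, h=h,
                     cos=cos, sin=sin, dh=dh) if want_cache else None
        return h, cache

    def encode(self, ids: np.ndarray, attention_mask: np.ndarray) -> np.ndarray:
        """Final hidden states (batch, length, hidden)."""
        h, _ = self._hidden(ids, attention_mask, want_cache=False)
        return h

    def forward(self, ids: np.ndarray, attention_mask: np.ndarray) -> np.ndarray:
        """Per-position logits over the vocabulary (batch, length, vocab)."""
        h, _ = self._hidden(ids, attention_mask, want_cache=False)
        return h @ self.params["E"].T + self.params["b_out"]

    # -- backward -----------------------------------------------------------

    def loss_and_grads(self, ids: np.ndarray, attention_mask: np.ndarray,
                       labels: np.ndarray):
        """Mean CE over labeled positions, its gradients, and metrics."""
        cfg, p = self.cfg, self.params
        h, cache = self._hidden(ids, attention_mask, want_cache=True)
        logits = h @ p["E"].T + p["b_out"]
        labeled = labels != IGNORE_INDEX
        n_labeled = int(labeled.sum())
        if n_labeled == 0:
            raise ValueError("no labeled positions in batch")
        probs = _softmax(logits.astype(np.float64))
        rows = np.where(labeled)
        true = labels[rows]
        logp = np.log(np.maximum(probs[rows[0], rows[1], true], 1e-30))
        loss = float(-logp.mean())
        acc = float((probs[rows].argmax(-1) == true).mean())

        dlogits = probs.astype(h.dtype)
        dlogits[rows[0], rows[1], true] -= 1.0
        dlogits *= labeled[..., None].astype(h.dtype) / n_labeled

        grads = {name: np.zeros_like(arr) for name, arr in p.items()}
        grads["E"] += _outer_grad(dlogits, h)
        grads["b_out"] += dlogits.sum((0, 1))
        dh = dlogits @ p["E"]
        dx, dg, db = _ln_backward(dh, p["lnf_g"], cache["lnf"])
        grads["lnf_g"] += dg
        grads["lnf_b"] += db
        dh_half = cache["dh"]
        cos, sin = cache["cos"], cache["sin"]
        for layer in reversed(range(cfg.n_layers)):
            pre = f"l{layer}."
            c = cache["layers"][layer]
            # MLP block
            d_mlp_out = dx
            grads[pre + "W2"] += _outer_grad(c["hact"], d_mlp_out)
            grads[pre + "b2"] += d_mlp_out.sum((0, 1))
            dhact = d_mlp_out @ p[pre + "W2"].T
            dhpre = dhact * _gelu_grad(c["hpre"], c["hcdf"])
            grads[pre + "W1"] += _outer_grad(c["m_in"], dhpre)
            grads[pre + "b1"] += dhpre.sum((0, 1))
            dm_in = dhpre @ p[pre + "W1"].T
            dx_attn, dg2, db2 = _ln_backward(dm_in, p[pre + "ln2_g"], c["ln2"])
            grads[pre + "ln2_g"] += dg2
            grads[pre + "ln2_b"] += db2
            dx = dx + dx_attn  # residual + LN path into the attention output
            # attention block
            d_attn_out = dx
            grads[pre + "Wo"] += _outer_grad(c["ctx"], d_attn_out)
            grads[pre + "bo"] += d_attn_out.sum((0, 1))
            dctx = self._split_heads(d_attn_out @ p[pre + "Wo"].T)
            datt = dctx @ c["v"].transpose(0, 1, 3, 2)
            dv = c["att"].transpose(0, 1, 3, 2) @ dctx
            dscores = c["att"] * (datt - (datt * c["att"]).sum(-1, keepdims=True))
            dscores /= np.sqrt(dh_half)
            dq = dscores @ c["k"]
            dk = dscores.transpose(0, 1, 3, 2) @ c["q"]
            if cfg.pe_type == "rope":
                dq = _rope_apply_inverse(dq, cos, sin)
                dk = _rope_apply_inverse(dk, cos, sin)
            dq_f, dk_f, dv_f = (self._merge_heads(z) for z in (dq, dk, dv))
            a_in = c["a_in"]
            grads[pre + "Wq"] += _outer_grad(a_in, dq_f)
            grads[pre + "bq"] += dq_f.sum((0, 1))
            grads[pre + "Wk"] += _outer_grad(a_in, dk_f)
            grads[pre + "bk"] += dk_f.sum((0, 1))
            grads[pre + "Wv"] += _outer_grad(a_in, dv_f)
            grads[pre + "bv"] += dv_f.sum((0, 1))
            da_in = dq_f @ p[pre + "Wq"].T + dk_f @ p[pre + "Wk"].T \
                + dv_f @ p[pre + "Wv"].T
            dx_in, dg1, db1 = _ln_backward(da_in, p[pre + "ln1_g"], c["ln1"])
            grads[pre + "ln1_g"] += dg1
            grads[pre + "ln1_b"] += db1
            dx = dx + dx_in
        if cfg.pe_type == "absolute":
            grads["P"][:cache["L"]] += dx.sum(0)
        np.add.at(grads["E"], cache["ids"], dx)
        return loss, grads, {"n_labeled": n_labeled, "accuracy": acc}

    def checksum(self) -> float:
        return float(sum(np.abs(v).sum() for v in self.params.values()))


def build_encoder(cfg: EncoderConfig, seed: int = 0) -> TransformerEncoder:
    """Deterministically initialized encoder for a config and seed."""
    return TransformerEncoder(cfg, seed=seed)


# ---------------------------------------------------------------------------
# Optimizer and training loop

class Adam:
    """Adam with decoupled weight decay on matrix-shaped parameters."""

    def __init__(self, params: dict[str, np.ndarray], beta1: float = 0.9,
                 beta2: float = 0.98, eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             lr: float) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1 ** self.t
        bc2 = 1.0 - self.beta2 ** self.t
        for name, value in params.items():
            g = grads[name]
            self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
            self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g * g
            update = (self.m[name] / bc1) / (np.sqrt(self.v[name] / bc2) + self.eps)
            if self.weight_decay and value.ndim >= 2:
                update = update + self.weight_decay * value
            value -= (lr * update).astype(value.dtype)


@dataclasses.dataclass
class TrainRunConfig:
    total_steps: int
    batch_size: int
    lr_schedule: LRScheduleConfig
    mlm: MLMConfig
    schedule: SchedulePlan
    seed: int = 0
    eval_interval: int = 200
    eval_batch_size: int = 64
    crop_multiple: int = 8  # batches are cropped to the longest real length

    def __post_init__(self):
        if self.total_steps != self.schedule.total_steps:
            raise ConfigurationError(
                "total_steps must match the schedule's total_steps")


@dataclasses.dataclass
class TrainLog:
    steps: list[dict]
    evals: list[dict]

    def realized_unpaired_fraction(self) -> float:
        n_un = sum(r["n_unpaired"] for r in self.steps)
        n_total = sum(r["n_unpaired"] + r["n_paired"] for r in self.steps)
        return n_un / n_total if n_total else float("nan")


def _crop(ids, mask, labels, multiple: int):
    longest = int(mask.sum(1).max())
    L = min(ids.shape[1], max(multiple, -(-longest // multiple) * multiple))
    return ids[:, :L], mask[:, :L], labels[:, :L]


def _eval_ce(model: TransformerEncoder, examples: Sequence[TokenizedExample],
             batch_size: int, crop_multiple: int) -> tuple[float, float]:
    """Mean CE and accuracy over labeled positions of pre-masked examples."""
    total_nll, total_correct, total_n = 0.0, 0.0, 0
    for i in range(0, len(examples), batch_size):
        ids, mask, labels = collate(examples[i:i + batch_size])
        ids, mask, labels = _crop(ids, mask, labels, crop_multiple)
        logits = model.forward(ids, mask)
        labeled = labels != IGNORE_INDEX
        rows = np.where(labeled)
        true = labels[rows]
        probs = _softmax(logits.astype(np.float64))
        logp = np.log(np.maximum(probs[rows[0], rows[1], true], 1e-30))
        total_nll += float(-logp.sum())
        total_correct += float((probs[rows].argmax(-1) == true).sum())
        total_n += len(true)
    return total_nll / total_n, total_correct / total_n


def train(model: TransformerEncoder, pools: dict, run_cfg: TrainRunConfig,
          vocab) -> TrainLog:
    """Run the MLM training loop over mixed paired/unpaired pools.

    ``pools`` maps "unpaired"/"paired" to lists of TokenizedExample (clean,
    un-corrupted) and optionally "eval_unpaired"/"eval_paired" to held-out
    lists evaluated at every eval interval (each with fixed, seeded MLM
    corruption so eval CE is comparable across the run). Every random draw —
    batch composition, pool order, MLM corruption — derives from
    ``run_cfg.seed``. Raises DivergenceError on a non-finite loss.
    """
    seed = run_cfg.seed % (2**31)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    eval_rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    unpaired_pool = Pool("unpaired", pools["unpaired"], base_seed=seed)
    paired_pool = Pool("paired", pools["paired"], base_seed=seed)
    eval_sets = {}
    for name in ("eval_unpaired", "eval_paired"):
        if pools.get(name):
            eval_sets[name] = [apply_mlm(e, run_cfg.mlm, vocab, eval_rng)
                               for e in pools[name]]
    optimizer = Adam(model.params)
    log = TrainLog(steps=[], evals=[])

    def run_eval(step: int) -> None:
        row = {"step": step}
        for name, examples in eval_sets.items():
            ce, acc = _eval_ce(model, examples, run_cfg.eval_batch_size,
                               run_cfg.crop_multiple)
            key = name.removeprefix("eval_")
            row[f"ce_{key}"] = ce
            row[f"acc_{key}"] = acc
        log.evals.append(row)

    run_eval(0)
    for step in range(run_cfg.total_steps):
        plan = plan_batch(run_cfg.schedule, step, run_cfg.batch_size, rng,
                          unpaired_pool, paired_pool)
        batch = (unpaired_pool.take(plan.unpaired_indices)
                 + paired_pool.take(plan.paired_indices))
        batch = [apply_mlm(e, run_cfg.mlm, vocab, rng) for e in batch]
        ids, mask, labels = _crop(*collate(batch), run_cfg.crop_multiple)
        loss, grads, metrics = model.loss_and_grads(ids, mask, labels)
        if not np.isfinite(loss):
            raise DivergenceError(step)
        lr = lr_at(run_cfg.lr_schedule, step)
        optimizer.step(model.params, grads, lr)
        log.steps.append({
            "step": step, "lr": lr,
            "p_unpaired": run_cfg.schedule.probability_fn(step),
            "n_unpaired": plan.n_unpaired, "n_paired": plan.n_paired,
            "train_ce": loss, "train_acc": metrics["accuracy"]})
        if run_cfg.eval_interval and (step + 1) % run_cfg.eval_interval == 0:
            run_eval(step + 1)
    if not log.evals or log.evals[-1]["step"] != run_cfg.total_steps:
        run_eval(run_cfg.total_steps)
    return log
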