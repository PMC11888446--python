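"""Unpaired-probability curves, shift calibration, and LR schedules.

The curriculum is a sigmoid decay of the probability that a training example
is drawn from the unpaired pool:

    P(t) = B - A / (1 + exp(-k * (t - shift)))

with t = step / total_steps in [0, 1]. B is the curve's upper bound, A its
height (so the curve decays from near B toward near B - A), k sets the slope
of the transition, and shift places the midpoint. The shift is not a free
parameter: it is solved so that the discrete mean of P over all training
steps equals a requested total unpaired fraction — i.e. so the model sees
exactly the intended overall share of unpaired data.

A stated probability range "a to b" maps to B = a and A = a - b; the range
refers to the sigmoid's asymptotic bounds, so the values actually reached at
t = 0 and t = 1 are near (not exactly) a and b for moderate k.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Callable

import numpy as np

from .errors import CalibrationError

_BISECT_TOL = 1e-9
_BISECT_MAX_ITER = 200
_SHIFT_LO, _SHIFT_HI = -1.0, 2.0


@dataclasses.dataclass
class CurriculumConfig:
    """Symbols of the unpaired-probability curve plus its calibration target."""

    B: float
    A: float
    k: float
    shift: float = 0.5
    total_steps: int = 100_000
    target_unpaired_fraction: float = 0.625

    def __post_init__(self):
        if not 0.0 <= self.B <= 1.0:
            raise ValueError("B must lie in [0, 1]")
        if not 0.0 <= self.A <= self.B:
            raise ValueError("A must lie in [0, B]")
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.total_steps <= 0:
            raise ValueError("total_steps must be positive")

    @classmethod
    def from_range(cls, upper: float, lower: float, k: float,
                   total_steps: int = 100_000,
                   target_unpaired_fraction: float = 0.625) -> "CurriculumConfig":
        """Build from a probability range "upper to lower" (B=upper, A=upper-lower)."""
        return cls(B=upper, A=upper - lower, k=k, total_steps=total_steps,
                   target_unpaired_fraction=target_unpaired_fraction)


def unpaired_probability(cfg: CurriculumConfig, t: float | np.ndarray
                         ) -> float | np.ndarray:
    """Evaluate P(t) = B - A / (1 + exp(-k (t - shift))) for t in [0, 1]."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > 1):
        raise ValueError("t must lie in [0, 1]")
    value = cfg.B - cfg.A / (1.0 + np.exp(-cfg.k * (t_arr - cfg.shift)))
    return float(value) if np.isscalar(t) or t_arr.ndim == 0 else value


def schedule_mean(cfg: CurriculumConfig) -> float:
    """Discrete mean of P over steps s = 0 .. total_steps-1, t = s/total_steps."""
    t = np.arange(cfg.total_steps) / cfg.total_steps
    return float(np.mean(unpaired_probability(cfg, t)))


def solve_shift(B: float, A: float, k: float, total_steps: int,
                target_unpaired_fraction: float) -> float:
    """Solve for the shift that makes the schedule mean hit the target.

    Uses bisection on shift in [-1, 2] (the mean is strictly increasing in
    shift); saturated curves at the interval ends cover any attainable target
    in (B - A, B). Raises CalibrationError, naming the attainable interval,
    when the target cannot be reached.
    """
    if A == 0.0:
        # zero-height curve: P is constant B regardless of shift
        if abs(target_unpaired_fraction - B) > _BISECT_TOL:
            raise CalibrationError(
                f"A=0 makes the schedule constant at {B}; target "
                f"{target_unpaired_fraction} is unattainable")
        return 0.5

    def mean_at(shift: float) -> float:
        cfg = CurriculumConfig(B=B, A=A, k=k, shift=shift,
                               total_steps=total_steps,
                               target_unpaired_fraction=target_unpaired_fraction)
        return schedule_mean(cfg)

    lo_mean, hi_mean = mean_at(_SHIFT_LO), mean_at(_SHIFT_HI)
    if not lo_mean - _BISECT_TOL <= target_unpaired_fraction <= hi_mean + _BISECT_TOL:
        raise CalibrationError(
            f"target {target_unpaired_fraction} outside the attainable mean "
            f"interval [{lo_mean:.6f}, {hi_mean:.6f}] for B={B}, A={A}, k={k}")
    lo, hi = _SHIFT_LO, _SHIFT_HI
    for _ in range(_BISECT_MAX_ITER):
        mid = 0.5 * (lo + hi)
        m = mean_at(mid)
        if abs(m - target_unpaired_fraction) <= _BISECT_TOL:
            return mid
        if m < target_unpaired_fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate(cfg: CurriculumConfig) -> CurriculumConfig:
    """Return a copy of cfg with shift solved against its own target."""
    shift = solve_shift(cfg.B, cfg.A, cfg.k, cfg.total_steps,
                        cfg.target_unpaired_fraction)
    return dataclasses.replace(cfg, shift=shift)


class ScheduleKind(str, enum.Enum):
    curriculum = "curriculum"
    constant = "constant"
    finetuned = "finetuned"
    unpaired_only = "unpaired_only"
    paired_only = "paired_only"


@dataclasses.dataclass
class SchedulePlan:
    """A per-step unpaired probability function for one training strategy."""

    kind: ScheduleKind
    probability_fn: Callable[[int], float]
    total_steps: int
    config: CurriculumConfig | None = None

    def probabilities(self) -> np.ndarray:
        return np.array([self.probability_fn(s) for s in range(self.total_steps)])

    def mean(self) -> float:
        return float(self.probabilities().mean())


def make_schedule(kind: ScheduleKind | str, total_steps: int,
                  target_unpaired_fraction: float = 0.625,
                  B: float = 0.7, A: float = 0.4, k: float = 15.0,
                  ) -> SchedulePlan:
    """Build the unpaired-probability plan for one of the five strategies.

    All mixed strategies (curriculum, constant, finetuned) are matched on the
    same total unpaired fraction, so with equal step budgets they consume the
    same total amount of unpaired and paired data; unpaired_only and
    paired_only are the degenerate constants 1 and 0.
    """
    kind = ScheduleKind(kind)
    if not 0.0 <= target_unpaired_fraction <= 1.0:
        raise ValueError("target_unpaired_fraction must lie in [0, 1]")
    if kind is ScheduleKind.curriculum:
        cfg = calibrate(CurriculumConfig(
            B=B, A=A, k=k, total_steps=total_steps,
            target_unpaired_fraction=target_unpaired_fraction))

        def fn(step: int, _cfg=cfg, _n=total_steps) -> float:
            return float(unpaired_probability(_cfg, step / _n))

        return SchedulePlan(kind, fn, total_steps, config=cfg)
    if kind is ScheduleKind.constant:
        return SchedulePlan(kind, lambda s: target_unpaired_fraction, total_steps)
    if kind is ScheduleKind.finetuned:
        switch = round(target_unpaired_fraction * total_steps)
        return SchedulePlan(kind, lambda s, _sw=switch: 1.0 if s < _sw else 0.0,
                            total_steps)
    if kind is ScheduleKind.unpaired_only:
        return SchedulePlan(kind, lambda s: 1.0, total_steps)
    return SchedulePlan(kind, lambda s: 0.0, total_steps)


# ---------------------------------------------------------------------------
# Learning-rate schedules

class LRKind(str, enum.Enum):
    linear = "linear"
    wsd = "wsd"
    sgdr = "sgdr"


@dataclasses.dataclass
class LRScheduleConfig:
    """Learning-rate schedule: linear decay, warmup-stable-decay, or cosine
    annealing with warm restarts."""

    kind: LRKind = LRKind.linear
    peak_lr: float = 4e-4
    warmup_steps: int = 6000
    total_steps: int = 100_000
    wsd_decay_fraction: float = 0.2
    sgdr_cycles: int = 3

    def __post_init__(self):
        self.kind = LRKind(self.kind)
        if self.peak_lr <= 0:
            raise ValueError("peak_lr must be positive")
        if not 0 <= self.warmup_steps < self.total_steps:
            raise ValueError("warmup_steps must be < total_steps")
        if not 0.0 < self.wsd_decay_fraction < 1.0:
            raise ValueError("wsd_decay_fraction must lie in (0, 1)")
        if self.sgdr_cycles < 1:
            raise ValueError("sgdr_cycles must be >= 1")


def lr_at(cfg: LRScheduleConfig, step: int) -> float:
    """Learning rate at an integer step in [0, total_steps)."""
    if not 0 <= step < cfg.total_steps:
        raise ValueError(f"step {step} outside [0, {cfg.total_steps})")
    if cfg.warmup_steps > 0 and step <= cfg.warmup_steps:
        return cfg.peak_lr * step / cfg.warmup_steps
    if cfg.kind is LRKind.linear:
        span = cfg.total_steps - cfg.warmup_steps
        return cfg.peak_lr * (cfg.total_steps - step) / span
    if cfg.kind is LRKind.wsd:
        decay_start = cfg.total_steps * (1.0 - cfg.wsd_decay_fraction)
        if step < decay_start:
            return cfg.peak_lr
        return cfg.peak_lr * (cfg.total_steps - step) / (cfg.total_steps - decay_start)
    # sgdr: cosine annealing with warm restarts over equal-length cycles
    span = cfg.total_steps - cfg.warmup_steps
    cycle_len = span / cfg.sgdr_cycles
    pos = (step - cfg.warmup_steps) % cycle_len
    return cfg.peak_lr * 0.5 * (1.0 + np.cos(np.pi * pos / cycle_len))
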