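"""Hierarchical experiment configuration and the end-to-end runner.

One YAML file declares every stage — repertoire generation, tokenization and
splitting, the curriculum and LR schedules, encoder training, evaluation and
downstream tasks — with per-module seeds. ``run_experiment`` executes the
declared stages in order and writes a manifest (config snapshot, seeds,
package version, checksums of written files) sufficient to re-run the
deterministic stages bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .encoder import EncoderConfig, TrainRunConfig, build_encoder, train
from .errors import ConfigurationError
from .evaluation import cdrh3_accuracy, masked_eval
from .prep import (SeparatorPolicy, build_vocabulary, encode_record,
                   split_train_eval_test)
from .repertoire import generate_repertoire, generate_specificity_pools, write_csv
from .sampler import MLMConfig, apply_mlm
from .schedule import (CurriculumConfig, LRScheduleConfig, ScheduleKind,
                       lr_at, make_schedule)
from .tasks import (FinetuneConfig, build_pair_classification,
                    build_specificity_dataset, finetune_classifier)

_DEFAULTS: dict[str, dict[str, Any]] = {
    "data": dict(n_paired=400, n_unpaired_heavy=1500, n_unpaired_light=1500,
                 mutation_rate=6.0, naive_fraction=0.5, seed=11,
                 train_fraction=0.96, split_seed=12),
    "tokenizer": dict(separator_mode="sep"),
    "schedule": dict(kind="curriculum", B=0.7, A=0.4, k=15.0,
                     target_unpaired_fraction=0.625),
    "lr": dict(kind="linear", peak_lr=1e-3, warmup_steps=100,
               wsd_decay_fraction=0.2, sgdr_cycles=3),
    "mlm": dict(select_rate=0.15, mask_rate=0.8, random_rate=0.1, keep_rate=0.1),
    "model": dict(n_layers=2, n_heads=4, hidden_size=64, intermediate_size=256,
                  pe_type="rope", seed=21),
    "train": dict(total_steps=500, batch_size=16, seed=31, eval_interval=100),
    "tasks": dict(enabled=False, n_per_class=150, identity_threshold=0.99,
                  motif_strength=0.8, k_folds=5, epochs=5, seed=41),
}


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a YAML config, fill defaults, and validate with field paths."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigurationError("config root must be a mapping")
    cfg: dict[str, Any] = {}
    for section, defaults in _DEFAULTS.items():
        block = dict(defaults)
        extra = user.get(section, {})
        if not isinstance(extra, dict):
            raise ConfigurationError(f"{section}: expected a mapping")
        for key, value in extra.items():
            if key not in defaults:
                raise ConfigurationError(f"{section}.{key}: unknown field")
            block[key] = value
        cfg[section] = block
    unknown = set(user) - set(_DEFAULTS)
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
    _validate(cfg)
    return cfg


def _validate(cfg: dict[str, Any]) -> None:
    sched = cfg["schedule"]
    if ScheduleKind(sched["kind"]) is ScheduleKind.curriculum:
        lo, hi = sched["B"] - sched["A"], sched["B"]
        target = sched["target_unpaired_fraction"]
        if not lo <= target <= hi:
            raise ConfigurationError(
                f"schedule.target_unpaired_fraction: {target} outside the "
                f"attainable interval [{lo}, {hi}]")
    if cfg["train"]["total_steps"] <= cfg["lr"]["warmup_steps"]:
        raise ConfigurationError(
            "train.total_steps: must exceed lr.warmup_steps")
    if cfg["data"]["n_paired"] < 3:
        raise ConfigurationError("data.n_paired: need at least 3 for splitting")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_experiment(config_path: str | Path, out_dir: str | Path) -> dict[str, Any]:
    """Execute generate -> prep -> schedule -> train -> eval (-> tasks).

    Writes the generated repertoire, a per-step training log, an evaluation
    report and a manifest under ``out_dir`` and returns the manifest.
    """
    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    data_cfg = cfg["data"]
    pairs, unpaired = generate_repertoire(
        n_paired=data_cfg["n_paired"],
        n_unpaired_heavy=data_cfg["n_unpaired_heavy"],
        n_unpaired_light=data_cfg["n_unpaired_light"],
        mutation_rate=data_cfg["mutation_rate"],
        naive_fraction=data_cfg["naive_fraction"],
        seed=data_cfg["seed"])
    write_csv(out / "repertoire.csv", pairs, unpaired)

    policy = SeparatorPolicy.from_name(cfg["tokenizer"]["separator_mode"])
    vocab = build_vocabulary(policy)
    paired_tok = [encode_record(p, vocab, policy) for p in pairs]
    unpaired_tok = [encode_record(u, vocab, policy) for u in unpaired]
    split_seed = data_cfg["split_seed"]
    p_train, p_eval, p_test = split_train_eval_test(
        paired_tok, data_cfg["train_fraction"], seed=split_seed)
    u_train, u_eval, u_test = split_train_eval_test(
        unpaired_tok, data_cfg["train_fraction"], seed=split_seed + 1)

    sched_cfg = cfg["schedule"]
    total_steps = cfg["train"]["total_steps"]
    plan = make_schedule(sched_cfg["kind"], total_steps,
                         sched_cfg["target_unpaired_fraction"],
                         B=sched_cfg["B"], A=sched_cfg["A"], k=sched_cfg["k"])
    lr_cfg = LRScheduleConfig(kind=cfg["lr"]["kind"],
                              peak_lr=cfg["lr"]["peak_lr"],
                              warmup_steps=cfg["lr"]["warmup_steps"],
                              total_steps=total_steps,
                              wsd_decay_fraction=cfg["lr"]["wsd_decay_fraction"],
                              sgdr_cycles=cfg["lr"]["sgdr_cycles"])
    mlm_cfg = MLMConfig(**cfg["mlm"])

    model_cfg = cfg["model"]
    enc_cfg = EncoderConfig(n_layers=model_cfg["n_layers"],
                            n_heads=model_cfg["n_heads"],
                            hidden_size=model_cfg["hidden_size"],
                            intermediate_size=model_cfg["intermediate_size"],
                            pe_type=model_cfg["pe_type"])
    model = build_encoder(enc_cfg, seed=model_cfg["seed"])

    run_cfg = TrainRunConfig(total_steps=total_steps,
                             batch_size=cfg["train"]["batch_size"],
                             lr_schedule=lr_cfg, mlm=mlm_cfg, schedule=plan,
                             seed=cfg["train"]["seed"],
                             eval_interval=cfg["train"]["eval_interval"])
    pools = {"unpaired": u_train, "paired": p_train,
             "eval_unpaired": u_eval, "eval_paired": p_eval}
    log = train(model, pools, run_cfg, vocab)

    step_rows = pd.DataFrame(log.steps)
    step_rows.to_csv(out / "train_log.csv", index=False)
    pd.DataFrame(log.evals).to_csv(out / "eval_log.csv", index=False)

    eval_rng = np.random.default_rng(np.random.SeedSequence(
        [cfg["train"]["seed"] % (2**31), 77]))
    test_masked = [apply_mlm(e, mlm_cfg, vocab, eval_rng)
                   for e in (p_test + u_test)]
    report = masked_eval(model, test_masked)
    results: dict[str, Any] = {
        "test_ce": report.ce_loss, "test_accuracy": report.accuracy,
        "n_test_positions": report.n_positions,
        "realized_unpaired_fraction": log.realized_unpaired_fraction(),
        "schedule_mean": plan.mean(),
        "initial_eval": log.evals[0], "final_eval": log.evals[-1],
    }
    if len(p_test) >= 3:
        results["cdrh3_accuracy"] = cdrh3_accuracy(model, p_test[:20], vocab)

    tasks_cfg = cfg["tasks"]
    if tasks_cfg["enabled"]:
        pools_spec = generate_specificity_pools(
            n_per_class=tasks_cfg["n_per_class"],
            motif_strength=tasks_cfg["motif_strength"],
            seed=tasks_cfg["seed"])
        spec_task = build_specificity_dataset(
            pools_spec, identity_threshold=tasks_cfg["identity_threshold"],
            seed=tasks_cfg["seed"], k_folds=tasks_cfg["k_folds"])
        _, spec_metrics = finetune_classifier(
            model, spec_task, vocab,
            FinetuneConfig(epochs=tasks_cfg["epochs"], seed=tasks_cfg["seed"]),
            policy)
        pair_task = build_pair_classification(pairs[:200] if len(pairs) > 200
                                              else pairs, seed=tasks_cfg["seed"],
                                              k_folds=tasks_cfg["k_folds"])
        _, pair_metrics = finetune_classifier(
            model, pair_task, vocab,
            FinetuneConfig(epochs=tasks_cfg["epochs"], seed=tasks_cfg["seed"]),
            policy)
        results["specificity_metrics"] = spec_metrics.as_dict()
        results["pair_classification_metrics"] = pair_metrics.as_dict()

    (out / "results.json").write_text(json.dumps(results, indent=2, default=float))

    manifest = {
        "version": __version__,
        "config": cfg,
        "seeds": {"data": data_cfg["seed"], "split": split_seed,
                  "model": model_cfg["seed"], "train": cfg["train"]["seed"],
                  "tasks": tasks_cfg["seed"]},
        "outputs": {name: _checksum(out / name)
                    for name in ("repertoire.csv", "train_log.csv",
                                 "eval_log.csv", "results.json")},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
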