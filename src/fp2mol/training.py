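"""Training: cyclic decayed learning-rate schedule, token batching, NLL.

The learning-rate schedule ramps linearly from the floor to the peak over
the warm-up steps of each cycle, then decays geometrically so that it
reaches the floor exactly at the cycle end, and repeats with period
``cycle_steps`` at a constant per-cycle maximum.  Batches are sized by
token count: pairs are bucketed by source length and packed greedily so
that (max source length + max target length) x pairs stays within the
token budget.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import autodiff as ad
from .model import Transformer


@dataclass(frozen=True)
class SchedulerConfig:
    peak_lr: float = 1e-3
    floor_lr: float = 3.9e-12
    warmup_steps: int = 5000
    cycle_steps: int = 25000
    constant_factor: float = 5.0  # retained for provenance of the cyclic schedule

    def __post_init__(self):
        if not 0 < self.floor_lr < self.peak_lr:
            raise ValueError("need 0 < floor_lr < peak_lr")
        if not 0 < self.warmup_steps < self.cycle_steps:
            raise ValueError("need 0 < warmup_steps < cycle_steps")


@dataclass(frozen=True)
class TrainConfig:
    tokens_per_batch: int = 8000
    max_steps: int = 500_000
    checkpoint_every: int = 25_000
    seed: int = 0


@dataclass
class TrainState:
    step: int = 0
    losses: list[float] = field(default_factory=list)
    lr: float = 0.0
    best_checkpoint: str | None = None


def lr_at(step: int, cfg: SchedulerConfig) -> float:
    """Learning rate at optimizer step ``step`` (1-based)."""
    if step < 1:
        raise ValueError("step must be >= 1")
    s = (step - 1) % cfg.cycle_steps + 1
    if s <= cfg.warmup_steps:
        return cfg.floor_lr + (cfg.peak_lr - cfg.floor_lr) * s / cfg.warmup_steps
    frac = (s - cfg.warmup_steps) / (cfg.cycle_steps - cfg.warmup_steps)
    return cfg.peak_lr * (cfg.floor_lr / cfg.peak_lr) ** frac


@dataclass(frozen=True)
class EncodedPair:
    """One translation example: encoded source and target index sequences."""
    src: tuple[int, ...]
    tgt: tuple[int, ...]  # without bos/eos
    id: str = ""

    @property
    def footprint(self) -> int:
        return len(self.src) + len(self.tgt) + 2  # bos/eos on the target side


def make_batches(pairs: Sequence[EncodedPair], tokens_per_batch: int,
                 seed: int) -> list[list[EncodedPair]]:
    """Token-budgeted batches, bucketed by source length, order shuffled."""
    for p in pairs:
        if p.footprint > tokens_per_batch:
            raise ValueError(
                f"pair {p.id or p.src[:4]} footprint {p.footprint} exceeds "
                f"tokens_per_batch={tokens_per_batch}"
            )
    ordered = sorted(pairs, key=lambda p: (len(p.src), len(p.tgt)))
    batches: list[list[EncodedPair]] = []
    cur: list[EncodedPair] = []
    max_s = max_t = 0
    for p in ordered:
        ns = max(max_s, len(p.src))
        nt = max(max_t, len(p.tgt) + 2)
        if cur and (ns + nt) * (len(cur) + 1) > tokens_per_batch:
            batches.append(cur)
            cur, max_s, max_t = [], 0, 0
            ns, nt = len(p.src), len(p.tgt) + 2
        cur.append(p)
        max_s, max_t = ns, nt
    if cur:
        batches.append(cur)
    random.Random(seed).shuffle(batches)
    return batches


def pad_batch(batch: Sequence[EncodedPair], bos: int, eos: int, pad: int = 0):
    """Pad a batch to arrays: src, tgt_in (bos+tgt), tgt_out (tgt+eos), mask."""
    n = len(batch)
    max_s = max(len(p.src) for p in batch)
    max_t = max(len(p.tgt) for p in batch) + 1
    src = np.full((n, max_s), pad, dtype=np.int64)
    tgt_in = np.full((n, max_t), pad, dtype=np.int64)
    tgt_out = np.full((n, max_t), pad, dtype=np.int64)
    mask = np.zeros((n, max_t), dtype=np.float32)
    for i, p in enumerate(batch):
        src[i, : len(p.src)] = p.src
        seq = list(p.tgt)
        tgt_in[i, : len(seq) + 1] = [bos] + seq
        tgt_out[i, : len(seq) + 1] = seq + [eos]
        mask[i, : len(seq) + 1] = 1.0
    return src, tgt_in, tgt_out, mask


class Adam:
    def __init__(self, params: dict[str, ad.Tensor], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / bias1
            vhat = self.v[k] / bias2
            p.data -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def batch_loss(model: Transformer, batch: Sequence[EncodedPair],
               bos: int, eos: int, train: bool = True) -> ad.Tensor:
    """Mean per-token NLL over the batch, padding excluded."""
    src, tgt_in, tgt_out, mask = pad_batch(batch, bos, eos)
    log_probs = model.forward(src, tgt_in, train=train)
    return ad.masked_nll(log_probs, tgt_out, mask)


def train(
    model: Transformer,
    pairs: Sequence[EncodedPair],
    train_cfg: TrainConfig,
    sched_cfg: SchedulerConfig,
    bos: int = 1,
    eos: int = 2,
    out_dir: str | Path | None = None,
    checkpoint_hook: Callable[[Transformer, TrainState], None] | None = None,
    stop_condition: Callable[[Transformer, TrainState], bool] | None = None,
    log_every: int = 0,
) -> TrainState:
    """Optimize mean per-token NLL with the cyclic decayed schedule.

    Writes a checkpoint (and calls ``checkpoint_hook``) every
    ``checkpoint_every`` steps when ``out_dir`` is given.  A
    ``stop_condition`` evaluated at checkpoint boundaries allows early
    termination (e.g. once a memorization target is reached).
    """
    state = TrainState()
    if train_cfg.max_steps == 0 or not pairs:
        return state
    opt = Adam(model.params)
    epoch = 0
    log_fh = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        log_fh = open(out_dir / "train.log", "w")
    try:
        while state.step < train_cfg.max_steps:
            batches = make_batches(pairs, train_cfg.tokens_per_batch,
                                   seed=train_cfg.seed + epoch)
            epoch += 1
            for batch in batches:
                if state.step >= train_cfg.max_steps:
                    break
                state.step += 1
                state.lr = lr_at(state.step, sched_cfg)
                opt.zero_grad()
                loss = batch_loss(model, batch, bos, eos, train=True)
                value = float(loss.data)
                if not math.isfinite(value):
                    raise FloatingPointError(
                        f"non-finite loss {value} at step {state.step}"
                    )
                loss.backward()
                opt.step(state.lr)
                state.losses.append(value)
                if log_fh and (log_every and state.step % log_every == 0):
                    log_fh.write(json.dumps(
                        {"step": state.step, "lr": state.lr, "loss": value}) + "\n")
                    log_fh.flush()
                at_checkpoint = state.step % train_cfg.checkpoint_every == 0
                if at_checkpoint:
                    if out_dir is not None:
                        ckpt = out_dir / f"step{state.step:08d}.npz"
                        model.save(ckpt)
                        state.best_checkpoint = str(ckpt)
                    if checkpoint_hook is not None:
                        checkpoint_hook(model, state)
                    if stop_condition is not None and stop_condition(model, state):
                        return state
    finally:
        if log_fh:
            log_fh.close()
    return state
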