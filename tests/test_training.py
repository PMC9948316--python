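"""Learning-rate schedule, token batching and the training loop."""

import math

import numpy as np
import pytest

from fp2mol import autodiff as ad
from fp2mol import training
from fp2mol.model import ModelConfig, Transformer
from fp2mol.training import (
    EncodedPair,
    SchedulerConfig,
    TrainConfig,
    batch_loss,
    lr_at,
    make_batches,
    pad_batch,
    train,
)

SCHED = SchedulerConfig()


class TestSchedule:
    def test_peak_at_warmup_end(self):
        assert lr_at(5000, SCHED) == pytest.approx(1e-3, rel=1e-9)

    def test_floor_at_cycle_end(self):
        assert lr_at(25000, SCHED) == pytest.approx(3.9e-12, rel=1e-9)

    def test_halfway_up_the_ramp(self):
        expected = SCHED.floor_lr + (SCHED.peak_lr - SCHED.floor_lr) * 0.5
        assert lr_at(2500, SCHED) == pytest.approx(expected, rel=1e-9)

    def test_periodic_with_cycle_length(self):
        for s in (1, 137, 5000, 12345, 25000):
            assert lr_at(s, SCHED) == pytest.approx(lr_at(s + 25000, SCHED), rel=1e-12)

    def test_continuous_at_ramp_decay_junction(self):
        left = lr_at(5000, SCHED)
        right = lr_at(5001, SCHED)
        assert abs(right - left) / left < 1e-2

    def test_maximum_attained_exactly_at_warmup(self):
        cycle = [lr_at(s, SCHED) for s in range(1, 25001)]
        assert int(np.argmax(cycle)) + 1 == 5000

    def test_geometric_decay_is_log_linear(self):
        s1, s2, s3 = 10000, 15000, 20000
        r1 = math.log(lr_at(s2, SCHED)) - math.log(lr_at(s1, SCHED))
        r2 = math.log(lr_at(s3, SCHED)) - math.log(lr_at(s2, SCHED))
        assert r1 == pytest.approx(r2, rel=1e-6)

    def test_step_below_one_raises(self):
        with pytest.raises(ValueError):
            lr_at(0, SCHED)


def _pairs(n, src_len, tgt_len):
    return [EncodedPair(tuple(range(4, 4 + src_len)), tuple(range(4, 4 + tgt_len)),
                        id=f"p{i}") for i in range(n)]


class TestBatching:
    def test_small_corpus_single_batch(self):
        batches = make_batches(_pairs(10, 50, 48), tokens_per_batch=8000, seed=0)
        assert len(batches) == 1 and len(batches[0]) == 10

    def test_oversized_pair_raises(self):
        with pytest.raises(ValueError, match="p0"):
            make_batches(_pairs(1, 200, 100), tokens_per_batch=64, seed=0)

    def test_footprints_within_budget(self, toy_encoded):
        budget = 600
        batches = make_batches(toy_encoded, budget, seed=1)
        assert sum(len(b) for b in batches) == len(toy_encoded)
        for batch in batches:
            max_s = max(len(p.src) for p in batch)
            max_t = max(len(p.tgt) + 2 for p in batch)
            assert (max_s + max_t) * len(batch) <= budget

    def test_shuffle_is_seeded(self, toy_encoded):
        a = make_batches(toy_encoded, 500, seed=5)
        b = make_batches(toy_encoded, 500, seed=5)
        assert a == b


class TestLoss:
    def test_padding_excluded(self, toy_model, toy_encoded):
        batch = toy_encoded[:4]
        src, tgt_in, tgt_out, mask = pad_batch(batch, bos=1, eos=2)
        with ad.no_grad():
            base = training.batch_loss(toy_model, batch, 1, 2, train=False).data
        # append pure padding columns on both sides
        src2 = np.pad(src, ((0, 0), (0, 3)))
        tgt_in2 = np.pad(tgt_in, ((0, 0), (0, 2)))
        tgt_out2 = np.pad(tgt_out, ((0, 0), (0, 2)))
        mask2 = np.pad(mask, ((0, 0), (0, 2)))
        with ad.no_grad():
            lp = toy_model.forward(src2, tgt_in2).data
        n = mask2.sum()
        idx = np.indices(tgt_out2.shape)
        manual = -(lp[(*idx, tgt_out2)] * mask2).sum() / n
        assert manual == pytest.approx(float(base), abs=1e-4)


class TestTrainLoop:
    def test_zero_steps_leaves_model_unchanged(self, toy_model, toy_encoded):
        before = {k: t.data.copy() for k, t in toy_model.params.items()}
        state = train(toy_model, toy_encoded, TrainConfig(max_steps=0), SCHED)
        assert state.step == 0
        for k, t in toy_model.params.items():
            assert np.array_equal(before[k], t.data)

    def test_fixed_seed_identical_loss_traces(self, toy_vocabs, toy_encoded):
        sv, tv = toy_vocabs
        sched = SchedulerConfig(warmup_steps=10, cycle_steps=50)
        traces = []
        for _ in range(2):
            cfg = ModelConfig(src_vocab_size=len(sv), tgt_vocab_size=len(tv),
                              n_layers=1, n_heads=2, d_model=16, d_ff=32,
                              dropout=0.1, max_src_len=128, max_tgt_len=64)
            m = Transformer(cfg, seed=9)
            state = train(m, toy_encoded, TrainConfig(tokens_per_batch=2000,
                                                      max_steps=8, seed=4), sched)
            traces.append(state.losses)
        assert traces[0] == traces[1]

    def test_single_pair_loss_decreases(self, toy_vocabs, toy_encoded):
        sv, tv = toy_vocabs
        cfg = ModelConfig(src_vocab_size=len(sv), tgt_vocab_size=len(tv),
                          n_layers=1, n_heads=2, d_model=16, d_ff=32,
                          dropout=0.0, max_src_len=128, max_tgt_len=64)
        m = Transformer(cfg, seed=2)
        sched = SchedulerConfig(peak_lr=1e-2, warmup_steps=5, cycle_steps=200)
        state = train(m, toy_encoded[:1], TrainConfig(tokens_per_batch=2000,
                                                      max_steps=120, seed=0), sched)
        # allow small noise but require a mostly monotone decreasing trace
        diffs = np.diff(state.losses)
        assert state.losses[-1] < state.losses[0] * 0.5
        assert (diffs < 1e-3).mean() > 0.8

    def test_state_lr_matches_schedule(self, toy_model, toy_encoded):
        sched = SchedulerConfig(warmup_steps=10, cycle_steps=50)
        state = train(toy_model, toy_encoded, TrainConfig(tokens_per_batch=2000,
                                                          max_steps=3, seed=0), sched)
        assert state.step == 3
        assert state.lr == pytest.approx(lr_at(3, sched))
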