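"""Top-1 decoding: beam search over the translator's target vocabulary."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import autodiff as ad
from . import codecs
from .codecs import Vocabulary
from .fingerprints import PRIMARY_METRIC, tanimoto_smiles
from .model import Transformer


@dataclass(frozen=True)
class PredictionRecord:
    id: str
    ground_truth: str
    prediction: str
    representation: str
    valid: bool
    tc_primary: float


def _beam_search(model: Transformer, src_ids: np.ndarray, beam_size: int,
                 max_len: int, length_normalize: bool = False):
    """Returns (token index list, terminated flag) of the best hypothesis."""
    bos, eos = 1, 2
    with ad.no_grad():
        src = np.asarray(src_ids)[None, :]
        src_mask = model.src_padding_mask(src)
        memory = model.encode(model.src_token_embeddings(src), src_mask)
        hyps: list[tuple[list[int], float]] = [([bos], 0.0)]
        done: list[tuple[list[int], float]] = []
        for _ in range(max_len):
            if not hyps:
                break
            n = len(hyps)
            tgt = np.array([h[0] for h in hyps], dtype=np.int64)
            mem = ad.Tensor(np.repeat(memory.data, n, axis=0))
            mask = np.repeat(src_mask, n, axis=0)
            log_probs = model.decode(mem, mask, tgt).data[:, -1, :]
            log_probs[:, 0] = -np.inf  # never emit pad
            log_probs[:, bos] = -np.inf
            cand: list[tuple[list[int], float]] = []
            for (seq, score), lp in zip(hyps, log_probs):
                top = np.argsort(lp)[::-1][: beam_size]
                for tok in top:
                    cand.append((seq + [int(tok)], score + float(lp[tok])))
            cand.sort(key=lambda h: h[1], reverse=True)
            hyps = []
            for seq, score in cand:
                if seq[-1] == eos:
                    done.append((seq, score))
                elif len(hyps) < beam_size:
                    hyps.append((seq, score))
                if len(done) >= beam_size and len(hyps) >= beam_size:
                    break
            if len(done) >= beam_size:
                break

    def key(h):
        seq, score = h
        return score / max(len(seq) - 1, 1) if length_normalize else score

    if done:
        best = max(done, key=key)
        return best[0][1:-1], True
    if not hyps:
        return [], False
    best = max(hyps, key=key)
    return best[0][1:], False


def translate_top1(model: Transformer, src_tokens, src_vocab: Vocabulary,
                   tgt_vocab: Vocabulary, beam_size: int = 5,
                   max_len: int = 256, length_normalize: bool = False) -> str:
    """Highest log-probability completed hypothesis, detokenized.

    ``beam_size=1`` is exactly greedy argmax decoding.  Unknown source
    feature tokens map to the unk index.
    """
    tokens = src_tokens.tokens if hasattr(src_tokens, "tokens") else src_tokens
    if len(tokens) == 0:
        raise ValueError("empty source sequence")
    src_ids = np.array(src_vocab.encode(tokens), dtype=np.int64)
    out_ids, _ = _beam_search(model, src_ids, beam_size, max_len, length_normalize)
    return "".join(tgt_vocab.decode(out_ids))


def _score(prediction: str, ground_truth: str, representation: str,
           terminated: bool = True) -> tuple[bool, float]:
    if representation == codecs.SELFIES:
        pred_smiles = codecs.selfies_to_smiles(prediction)
        gt_smiles = codecs.selfies_to_smiles(ground_truth)
        valid = terminated and codecs.is_valid(prediction, representation)
    else:
        pred_smiles, gt_smiles = prediction, ground_truth
        valid = terminated and codecs.is_valid(prediction, representation)
    if not valid:
        return False, 0.0
    return True, tanimoto_smiles(pred_smiles, gt_smiles, PRIMARY_METRIC)


def translate_batch(model: Transformer, srcs: Sequence, src_vocab: Vocabulary,
                    tgt_vocab: Vocabulary, ground_truths: Sequence[str],
                    representation: str = codecs.SMILES, ids: Sequence[str] | None = None,
                    beam_size: int = 5, max_len: int = 256) -> list[PredictionRecord]:
    """Order-preserving per-record translation with validity and Tc scores."""
    records = []
    for i, (src, gt) in enumerate(zip(srcs, ground_truths)):
        rid = ids[i] if ids is not None else f"P{i + 1:06d}"
        tokens = src.tokens if hasattr(src, "tokens") else src
        try:
            src_ids = np.array(src_vocab.encode(tokens), dtype=np.int64)
            out_ids, terminated = _beam_search(model, src_ids, beam_size, max_len)
            pred = "".join(tgt_vocab.decode(out_ids))
            valid, tc = _score(pred, gt, representation, terminated)
        except Exception:
            pred, valid, tc = "", False, 0.0
        records.append(PredictionRecord(rid, gt, pred, representation, valid, tc))
    return records


def greedy_decode_batch(model: Transformer, src_ids_list: Sequence[Sequence[int]],
                        max_len: int = 256) -> list[list[int]]:
    """Vectorized greedy decoding of many sources at once.

    Equivalent to per-item ``beam_size=1`` decoding (padding never changes
    results); used for fast periodic evaluation during training.
    """
    bos, eos, pad = 1, 2, 0
    n = len(src_ids_list)
    if n == 0:
        return []
    max_s = max(len(s) for s in src_ids_list)
    src = np.full((n, max_s), pad, dtype=np.int64)
    for i, s in enumerate(src_ids_list):
        src[i, : len(s)] = s
    with ad.no_grad():
        src_mask = model.src_padding_mask(src)
        memory = model.encode(model.src_token_embeddings(src), src_mask)
        tgt = np.full((n, 1), bos, dtype=np.int64)
        finished = np.zeros(n, dtype=bool)
        for _ in range(max_len):
            log_probs = model.decode(memory, src_mask, tgt).data[:, -1, :]
            log_probs[:, pad] = -np.inf  # never emit pad/bos
            log_probs[:, bos] = -np.inf
            nxt = log_probs.argmax(axis=-1)
            nxt[finished] = pad
            tgt = np.concatenate([tgt, nxt[:, None]], axis=1)
            finished |= nxt == eos
            if finished.all():
                break
    out = []
    for row in tgt:
        seq = []
        for tok in row[1:]:
            if tok in (eos, pad):
                break
            seq.append(int(tok))
        out.append(seq)
    return out
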