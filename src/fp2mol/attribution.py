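"""Attribution maps: integrated gradients and cross-attention weights.

Both methods produce a matrix with one row per target token of the
prediction and one column per source feature token.  Integrated gradients
attribute the log-probability of each predicted token (under teacher
forcing) to the source token embeddings along a straight path from a
baseline; the baseline is the padding-token embedding, matching the
"absent feature" semantics of fingerprints as feature sets.  Attention
maps expose the decoder's cross-attention, aggregated over a chosen layer
and over heads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .model import Transformer


@dataclass(frozen=True)
class AttributionMatrix:
    target_tokens: tuple[str, ...]
    source_tokens: tuple[str, ...]
    values: np.ndarray  # shape (|tgt|, |src|)
    method: str  # integrated_gradients | attention
    ig_steps: int = 0
    baseline: str = ""


def _target_logprob_endpoints(model: Transformer, src_ids, tgt_ids) -> np.ndarray:
    """F_t(x) per target position for the true source embeddings."""
    with ad.no_grad():
        lp = model.forward(np.asarray(src_ids)[None], _tgt_in(tgt_ids)[None]).data[0]
    return lp[np.arange(len(tgt_ids)), tgt_ids]


def _tgt_in(tgt_ids) -> np.ndarray:
    bos = 1
    return np.concatenate([[bos], np.asarray(tgt_ids)[:-1]]) if len(tgt_ids) else np.array([bos])


def integrated_gradients(
    model: Transformer,
    src_ids,
    tgt_ids,
    m_steps: int = 64,
    src_tokens: tuple[str, ...] | None = None,
    tgt_tokens: tuple[str, ...] | None = None,
) -> AttributionMatrix:
    """Path-integral attribution of each predicted token to each source token.

    For target position t, the attribution of source token i is
    ``(x_i - x'_i) . (1/m) sum_k dF_t(x' + (k/m)(x - x')) / dx_i`` summed
    over embedding dimensions, with F_t the log-probability of the target
    token at t and x' the padding-embedding baseline.  Rows satisfy the
    completeness identity ``sum_i A[t, i] ~= F_t(x) - F_t(x')``.
    """
    if m_steps < 1:
        raise ValueError("m_steps must be >= 1")
    src_ids = np.asarray(src_ids)
    tgt_ids = np.asarray(tgt_ids)
    x = model.params["src_embed"].data[src_ids]  # (Ts, d)
    x_base = np.broadcast_to(model.params["src_embed"].data[Transformer.PAD],
                             x.shape).copy()
    diff = x - x_base
    alphas = (np.arange(1, m_steps + 1, dtype=np.float32) / m_steps)[:, None, None]
    interp = x_base[None] + alphas * diff[None]  # (m, Ts, d)
    src_batch = np.repeat(src_ids[None], m_steps, axis=0)
    tgt_in = np.repeat(_tgt_in(tgt_ids)[None], m_steps, axis=0)
    n_t = len(tgt_ids)
    values = np.zeros((n_t, len(src_ids)), dtype=np.float64)
    for t in range(n_t):
        emb = ad.Tensor(interp, requires_grad=True)
        log_probs = model.forward_from_embeddings(emb, src_batch, tgt_in[:, : t + 1])
        grad = np.zeros_like(log_probs.data)
        grad[:, t, tgt_ids[t]] = 1.0  # select F_t across the interpolation batch
        log_probs.backward(grad)
        avg_grad = emb.grad.mean(axis=0)  # (Ts, d)
        values[t] = (diff * avg_grad).sum(axis=-1)
        for p in model.params.values():  # drop incidental weight gradients
            p.grad = None
    return AttributionMatrix(
        target_tokens=tuple(tgt_tokens or map(str, tgt_ids)),
        source_tokens=tuple(src_tokens or map(str, src_ids)),
        values=values,
        method="integrated_gradients",
        ig_steps=m_steps,
        baseline="pad-embedding",
    )


def completeness_residual(model: Transformer, src_ids, tgt_ids,
                          matrix: AttributionMatrix) -> np.ndarray:
    """Per-row |row-sum - (F_t(x) - F_t(x'))| of an IG matrix."""
    src_ids = np.asarray(src_ids)
    tgt_ids = np.asarray(tgt_ids)
    f_x = _target_logprob_endpoints(model, src_ids, tgt_ids)
    base_ids = np.full_like(src_ids, Transformer.PAD)
    with ad.no_grad():
        x_base = ad.Tensor(np.broadcast_to(
            model.params["src_embed"].data[Transformer.PAD],
            (1, len(src_ids), model.config.d_model)).copy())
        lp = model.forward_from_embeddings(x_base, src_ids[None], _tgt_in(tgt_ids)[None]).data[0]
    f_base = lp[np.arange(len(tgt_ids)), tgt_ids]
    return np.abs(matrix.values.sum(axis=1) - (f_x - f_base))


def attention_map(
    model: Transformer,
    src_ids,
    tgt_ids,
    layer: int | str = "last",
    head_agg: str = "mean",
    src_tokens: tuple[str, ...] | None = None,
    tgt_tokens: tuple[str, ...] | None = None,
) -> AttributionMatrix:
    """Cross-attention weights of the decoder, aggregated over heads.

    Default aggregation: final decoder layer, arithmetic mean over heads.
    Rows are indexed by target positions and sum to 1.
    """
    src_ids = np.asarray(src_ids)
    tgt_ids = np.asarray(tgt_ids)
    with ad.no_grad():
        model.forward(src_ids[None], _tgt_in(tgt_ids)[None], collect_attention=True)
    layers = model.last_cross_attention  # list of (1, h, Tt, Ts)
    idx = len(layers) - 1 if layer == "last" else int(layer)
    attn = layers[idx][0]  # (h, Tt, Ts)
    if head_agg == "mean":
        values = attn.mean(axis=0)
    elif head_agg == "max":
        values = attn.max(axis=0)
    else:
        raise ValueError(f"unknown head aggregation {head_agg!r}")
    return AttributionMatrix(
        target_tokens=tuple(tgt_tokens or map(str, tgt_ids)),
        source_tokens=tuple(src_tokens or map(str, src_ids)),
        values=values,
        method="attention",
    )


def raw_attention(model: Transformer) -> list[np.ndarray]:
    """Captured per-layer cross-attention tensors from the last forward."""
    if model.last_cross_attention is None:
        raise RuntimeError("run a forward pass with collect_attention=True first")
    return model.last_cross_attention
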