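"""Transformer encoder–decoder for fingerprint-to-string translation.

Pre-layer-norm residual blocks with final norms after both stacks,
sinusoidal positional encoding on both sides, untied source/target
embeddings scaled by sqrt(d_model), and an output projection to
per-position log-probabilities.  Cross-attention probabilities of every
decoder layer are captured on request for attribution maps.

The network runs on the NumPy autodiff engine in :mod:`fp2mol.autodiff`;
evaluation-mode forwards are deterministic, training-mode forwards draw
dropout masks from an explicit generator.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from . import autodiff as ad

NEG_INF = np.float32(-1e9)


@dataclass(frozen=True)
class ModelConfig:
    src_vocab_size: int
    tgt_vocab_size: int
    n_layers: int = 6
    n_heads: int = 8
    d_model: int = 512
    d_ff: int = 2048
    dropout: float = 0.1
    pre_layer_norm: bool = True
    positional_encoding: bool = True
    max_src_len: int = 512
    max_tgt_len: int = 256

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def sinusoidal_encoding(max_len: int, d_model: int) -> np.ndarray:
    pos = np.arange(max_len)[:, None]
    dim = np.arange(0, d_model, 2)[None, :]
    angle = pos / np.power(10000.0, dim / d_model)
    pe = np.zeros((max_len, d_model), dtype=np.float32)
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


class Transformer:
    PAD = 0  # padding index contract shared with codecs.Vocabulary

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.params: dict[str, ad.Tensor] = {}
        self._dropout_rng = np.random.default_rng(seed + 1)
        rng = np.random.default_rng(seed)
        c = config
        self._pe_src = sinusoidal_encoding(c.max_src_len, c.d_model)
        self._pe_tgt = sinusoidal_encoding(c.max_tgt_len, c.d_model)
        self.last_cross_attention: list[np.ndarray] | None = None

        def p(name, *shape, kind="linear"):
            if kind == "zeros":
                data = np.zeros(shape, dtype=np.float32)
            elif kind == "ones":
                data = np.ones(shape, dtype=np.float32)
            elif kind == "embed":
                data = rng.standard_normal(shape).astype(np.float32) / math.sqrt(shape[-1])
            else:  # xavier
                fan_in, fan_out = shape[-2], shape[-1]
                lim = math.sqrt(6.0 / (fan_in + fan_out))
                data = rng.uniform(-lim, lim, shape).astype(np.float32)
            self.params[name] = ad.Tensor(data, requires_grad=True)

        p("src_embed", c.src_vocab_size, c.d_model, kind="embed")
        p("tgt_embed", c.tgt_vocab_size, c.d_model, kind="embed")
        for stack, n in (("enc", c.n_layers), ("dec", c.n_layers)):
            for i in range(n):
                pre = f"{stack}{i}"
                heads = ["self"] if stack == "enc" else ["self", "cross"]
                for h in heads:
                    for w in ("q", "k", "v", "o"):
                        p(f"{pre}.{h}.W{w}", c.d_model, c.d_model)
                        p(f"{pre}.{h}.b{w}", c.d_model, kind="zeros")
                    p(f"{pre}.{h}.ln_g", c.d_model, kind="ones")
                    p(f"{pre}.{h}.ln_b", c.d_model, kind="zeros")
                p(f"{pre}.ff.W1", c.d_model, c.d_ff)
                p(f"{pre}.ff.b1", c.d_ff, kind="zeros")
                p(f"{pre}.ff.W2", c.d_ff, c.d_model)
                p(f"{pre}.ff.b2", c.d_model, kind="zeros")
                p(f"{pre}.ff.ln_g", c.d_model, kind="ones")
                p(f"{pre}.ff.ln_b", c.d_model, kind="zeros")
        p("enc.final_ln_g", c.d_model, kind="ones")
        p("enc.final_ln_b", c.d_model, kind="zeros")
        p("dec.final_ln_g", c.d_model, kind="ones")
        p("dec.final_ln_b", c.d_model, kind="zeros")
        p("out.W", c.d_model, c.tgt_vocab_size)
        p("out.b", c.tgt_vocab_size, kind="zeros")

    # ------------------------------------------------------------------
    def count_parameters(self) -> int:
        return sum(int(np.prod(t.data.shape)) for t in self.params.values())

    def _maybe_dropout(self, x: ad.Tensor, train: bool) -> ad.Tensor:
        if train and self.config.dropout > 0.0:
            return ad.dropout(x, self.config.dropout, self._dropout_rng)
        return x

    def _attention(self, prefix: str, q_in, k_in, v_in, mask, train, capture=False):
        c = self.config
        P = self.params
        dk = c.d_model // c.n_heads

        def split(x):
            b, t = x.data.shape[0], x.data.shape[1]
            return ad.transpose(ad.reshape(x, (b, t, c.n_heads, dk)), (0, 2, 1, 3))

        q = split(ad.add(ad.matmul(q_in, P[f"{prefix}.Wq"]), P[f"{prefix}.bq"]))
        k = split(ad.add(ad.matmul(k_in, P[f"{prefix}.Wk"]), P[f"{prefix}.bk"]))
        v = split(ad.add(ad.matmul(v_in, P[f"{prefix}.Wv"]), P[f"{prefix}.bv"]))
        scores = ad.scale(ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))), 1.0 / math.sqrt(dk))
        if mask is not None:
            scores = ad.add(scores, ad.Tensor(mask))
        probs = ad.softmax(scores, axis=-1)
        if capture and self.last_cross_attention is not None:
            self.last_cross_attention.append(probs.data.copy())
        probs = self._maybe_dropout(probs, train)
        ctx = ad.matmul(probs, v)
        b, t = q_in.data.shape[0], q_in.data.shape[1]
        merged = ad.reshape(ad.transpose(ctx, (0, 2, 1, 3)), (b, t, c.d_model))
        return ad.add(ad.matmul(merged, P[f"{prefix}.Wo"]), P[f"{prefix}.bo"])

    def _sublayer(self, prefix, x, fn, train):
        P = self.params
        if self.config.pre_layer_norm:
            y = fn(ad.layer_norm(x, P[f"{prefix}.ln_g"], P[f"{prefix}.ln_b"]))
            return ad.add(x, self._maybe_dropout(y, train))
        y = self._maybe_dropout(fn(x), train)
        return ad.layer_norm(ad.add(x, y), P[f"{prefix}.ln_g"], P[f"{prefix}.ln_b"])

    def _ff(self, prefix, x):
        P = self.params
        h = ad.relu(ad.add(ad.matmul(x, P[f"{prefix}.W1"]), P[f"{prefix}.b1"]))
        return ad.add(ad.matmul(h, P[f"{prefix}.W2"]), P[f"{prefix}.b2"])

    # ------------------------------------------------------------------
    def src_token_embeddings(self, src_ids: np.ndarray) -> ad.Tensor:
        """Raw (unscaled, position-free) source token embeddings; IG input."""
        return ad.embedding(self.params["src_embed"], np.asarray(src_ids))

    def _prepare_src(self, emb_raw: ad.Tensor, train: bool) -> ad.Tensor:
        c = self.config
        x = ad.scale(emb_raw, math.sqrt(c.d_model))
        if c.positional_encoding:
            x = ad.add(x, ad.Tensor(self._pe_src[: x.data.shape[1]]))
        return self._maybe_dropout(x, train)

    def encode(self, src_emb_raw: ad.Tensor, src_mask: np.ndarray, train: bool = False):
        P = self.params
        x = self._prepare_src(src_emb_raw, train)
        for i in range(self.config.n_layers):
            pre = f"enc{i}"
            x = self._sublayer(f"{pre}.self", x,
                               lambda y: self._attention(f"{pre}.self", y, y, y,
                                                         src_mask, train), train)
            x = self._sublayer(f"{pre}.ff", x, lambda y: self._ff(f"{pre}.ff", y), train)
        return ad.layer_norm(x, P["enc.final_ln_g"], P["enc.final_ln_b"])

    def decode(self, memory: ad.Tensor, src_mask, tgt_ids: np.ndarray,
               train: bool = False, collect_attention: bool = False):
        c = self.config
        P = self.params
        tgt_ids = np.asarray(tgt_ids)
        b, t = tgt_ids.shape
        x = ad.scale(ad.embedding(P["tgt_embed"], tgt_ids), math.sqrt(c.d_model))
        if c.positional_encoding:
            x = ad.add(x, ad.Tensor(self._pe_tgt[:t]))
        x = self._maybe_dropout(x, train)
        causal = np.triu(np.full((t, t), NEG_INF, dtype=np.float32), k=1)
        tgt_pad = np.where(tgt_ids == self.PAD, NEG_INF, np.float32(0.0))
        tgt_mask = causal[None, None] + tgt_pad[:, None, None, :]
        self.last_cross_attention = [] if collect_attention else None
        for i in range(c.n_layers):
            pre = f"dec{i}"
            x = self._sublayer(f"{pre}.self", x,
                               lambda y: self._attention(f"{pre}.self", y, y, y,
                                                         tgt_mask, train), train)
            x = self._sublayer(f"{pre}.cross", x,
                               lambda y: self._attention(f"{pre}.cross", y, memory, memory,
                                                         src_mask, train,
                                                         capture=collect_attention), train)
            x = self._sublayer(f"{pre}.ff", x, lambda y: self._ff(f"{pre}.ff", y), train)
        x = ad.layer_norm(x, P["dec.final_ln_g"], P["dec.final_ln_b"])
        logits = ad.add(ad.matmul(x, P["out.W"]), P["out.b"])
        return ad.log_softmax(logits, axis=-1)

    @staticmethod
    def src_padding_mask(src_ids: np.ndarray) -> np.ndarray:
        src_ids = np.asarray(src_ids)
        return np.where(src_ids == Transformer.PAD, NEG_INF,
                        np.float32(0.0))[:, None, None, :]

    def forward(self, src_ids: np.ndarray, tgt_in_ids: np.ndarray,
                train: bool = False, collect_attention: bool = False) -> ad.Tensor:
        """Teacher-forced per-position log-probabilities, shape (B, T, V)."""
        src_ids = np.asarray(src_ids)
        tgt_in_ids = np.asarray(tgt_in_ids)
        c = self.config
        if src_ids.max(initial=0) >= c.src_vocab_size or tgt_in_ids.max(initial=0) >= c.tgt_vocab_size:
            raise IndexError("token index out of vocabulary range")
        if src_ids.shape[1] > c.max_src_len or tgt_in_ids.shape[1] > c.max_tgt_len:
            raise ValueError("sequence length exceeds model maximum")
        src_mask = self.src_padding_mask(src_ids)
        memory = self.encode(self.src_token_embeddings(src_ids), src_mask, train)
        return self.decode(memory, src_mask, tgt_in_ids, train, collect_attention)

    def forward_from_embeddings(self, src_emb_raw: ad.Tensor, src_ids: np.ndarray,
                                tgt_in_ids: np.ndarray) -> ad.Tensor:
        """Evaluation forward from explicit source embeddings (for attribution)."""
        src_mask = self.src_padding_mask(src_ids)
        memory = self.encode(src_emb_raw, src_mask, train=False)
        return self.decode(memory, src_mask, tgt_in_ids, train=False)

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        arrays = {name: t.data for name, t in self.params.items()}
        np.savez(path, __config__=np.frombuffer(self.config.to_json().encode(), dtype=np.uint8),
                 __digest__=np.frombuffer(self.config.digest().encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "Transformer":
        with np.load(path) as archive:
            cfg_json = archive["__config__"].tobytes().decode()
            digest = archive["__digest__"].tobytes().decode()
            config = ModelConfig(**json.loads(cfg_json))
            if config.digest() != digest:
                raise ValueError("checkpoint config hash mismatch")
            model = cls(config)
            for name in model.params:
                model.params[name].data = archive[name].astype(np.float32)
        return model


def count_parameters(config: ModelConfig) -> int:
    """Total trainable parameter count of a model with this configuration."""
    return Transformer(config, seed=0).count_parameters()
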