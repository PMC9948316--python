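"""Building translation pairs: fingerprint token sequences -> target strings."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from . import codecs
from .codecs import Vocabulary
from .corpus import MoleculeRecord
from .fingerprints import featurize
from .training import EncodedPair


@dataclass(frozen=True)
class TranslationPair:
    id: str
    src_tokens: tuple[str, ...]  # fingerprint feature tokens
    tgt_string: str              # SMILES or robust bracket string
    representation: str


def build_pairs(records: Sequence[MoleculeRecord], spec_name: str,
                representation: str = codecs.SMILES) -> list[TranslationPair]:
    """Featurize every record and pair it with its target string."""
    out = []
    for rec in records:
        seq = featurize(rec.smiles, spec_name)
        if representation == codecs.SMILES:
            tgt = rec.smiles
        elif representation == codecs.SELFIES:
            tgt = codecs.smiles_to_selfies(rec.smiles)
        else:
            raise ValueError(f"unknown representation {representation!r}")
        out.append(TranslationPair(rec.id, tuple(seq.tokens), tgt, representation))
    return out


def write_pairs(pairs: Sequence[TranslationPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{' '.join(p.src_tokens)}\t{p.tgt_string}\t{p.id}\n")


def read_pairs(path: str | Path,
               representation: str = codecs.SMILES) -> list[TranslationPair]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{i + 1}: expected at least two columns")
            pid = parts[2] if len(parts) > 2 else f"P{i + 1:06d}"
            out.append(TranslationPair(pid, tuple(parts[0].split()), parts[1],
                                       representation))
    return out


def build_vocabularies(pairs: Sequence[TranslationPair]) -> tuple[Vocabulary, Vocabulary]:
    """Source vocabulary over feature tokens, target over string tokens."""
    src_vocab = codecs.build_vocab([p.src_tokens for p in pairs])
    rep = pairs[0].representation
    tgt_vocab = codecs.build_vocab(
        [codecs.tokenize(p.tgt_string, rep).tokens for p in pairs]
    )
    return src_vocab, tgt_vocab


def encode_pairs(pairs: Sequence[TranslationPair], src_vocab: Vocabulary,
                 tgt_vocab: Vocabulary) -> list[EncodedPair]:
    out = []
    for p in pairs:
        tgt_tokens = codecs.tokenize(p.tgt_string, p.representation).tokens
        out.append(EncodedPair(
            src=tuple(src_vocab.encode(p.src_tokens)),
            tgt=tuple(tgt_vocab.encode(tgt_tokens)),
            id=p.id,
        ))
    return out
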