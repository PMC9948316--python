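"""Tokenization, canonicalization and vocabularies for molecular strings.

Two target representations are supported: SMILES, tokenized atom-wise with
the standard chemistry-NLP segmentation (bracket atoms, two-letter
elements, ``%nn`` ring closures as single tokens), and the robust
bracket-token representation of :mod:`fp2mol.robust`, tokenized one
bracketed unit at a time.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

from rdkit import Chem

from . import robust

SMILES = "SMILES"
SELFIES = "SELFIES"  # the robust bracket-token representation

PAD, BOS, EOS, UNK = "<pad>", "<bos>", "<eos>", "<unk>"
SPECIALS = (PAD, BOS, EOS, UNK)

_SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|%\d{2}|[BCNOSPFIbcnosp]|[0-9()=#\-+/\\@.:~$*])"
)


class TokenizationError(ValueError):
    pass


@dataclass(frozen=True)
class TokenSequence:
    representation: str
    tokens: tuple[str, ...]

    def text(self) -> str:
        return "".join(self.tokens)


def tokenize_smiles(s: str) -> TokenSequence:
    """Atom-wise SMILES segmentation; concatenating the tokens restores ``s``."""
    if not s:
        raise TokenizationError("empty SMILES string")
    tokens = _SMILES_TOKEN_RE.findall(s)
    if "".join(tokens) != s:
        raise TokenizationError(f"cannot segment SMILES {s!r}")
    depth = 0
    for t in tokens:
        if t == "(":
            depth += 1
        elif t == ")":
            depth -= 1
            if depth < 0:
                raise TokenizationError(f"unbalanced parentheses in {s!r}")
    return TokenSequence(SMILES, tuple(tokens))


def tokenize_selfies(s: str) -> TokenSequence:
    """One token per bracketed unit; stray characters raise."""
    try:
        return TokenSequence(SELFIES, tuple(robust.tokenize(s)))
    except robust.RobustDecodeError as exc:
        raise TokenizationError(str(exc)) from exc


def tokenize(s: str, representation: str) -> TokenSequence:
    if representation == SMILES:
        return tokenize_smiles(s)
    if representation == SELFIES:
        return tokenize_selfies(s)
    raise ValueError(f"unknown representation {representation!r}")


def canonicalize(s: str, keep_stereo: bool = True) -> str:
    """Canonical SMILES with aromaticity perception.

    With ``keep_stereo=False`` all stereo annotations (tetrahedral tags and
    double-bond directions) are removed before canonicalization, so the two
    enantiomers of a molecule map to one string.
    """
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise ValueError(f"unparseable SMILES {s!r}")
    if not keep_stereo:
        Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def is_valid(s: str, representation: str = SMILES) -> bool:
    """SMILES: sanitization succeeds; robust strings: tokenizable ⇒ decodable."""
    if not s:
        return False
    if representation == SMILES:
        return Chem.MolFromSmiles(s) is not None
    try:
        tokens = robust.tokenize(s)
    except robust.RobustDecodeError:
        return False
    # every alphabet-token sequence decodes (possibly to the empty molecule)
    return all(robust.is_token(t) for t in tokens)


def selfies_to_smiles(s: str) -> str:
    """Decode a robust string to canonical SMILES ('' when undecodable)."""
    try:
        return robust.decode_to_smiles(robust.tokenize(s))
    except robust.RobustDecodeError:
        return ""


def smiles_to_selfies(s: str) -> str:
    """Encode a SMILES into the robust representation (round-trip verified)."""
    return "".join(robust.encode(s))


class Vocabulary:
    """Bijective token↔index map with pad/bos/eos/unk at indices 0..3."""

    def __init__(self, tokens: list[str]):
        for sp in SPECIALS:
            if sp in tokens:
                raise ValueError(f"special token {sp!r} in token list")
        self._itos: list[str] = list(SPECIALS) + list(tokens)
        self._stoi = {t: i for i, t in enumerate(self._itos)}

    pad_index, bos_index, eos_index, unk_index = 0, 1, 2, 3

    def __len__(self) -> int:
        return len(self._itos)

    def __contains__(self, token: str) -> bool:
        return token in self._stoi

    def encode(self, tokens) -> list[int]:
        unk = self.unk_index
        return [self._stoi.get(t, unk) for t in tokens]

    def decode(self, indices) -> list[str]:
        out = []
        for i in indices:
            t = self._itos[i]
            if t not in SPECIALS:
                out.append(t)
        return out

    def token(self, index: int) -> str:
        return self._itos[index]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"tokens": self._itos[len(SPECIALS):]}))

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        return cls(json.loads(Path(path).read_text())["tokens"])


def build_vocab(sequences) -> Vocabulary:
    """Vocabulary over all observed tokens, ordered by frequency then lexicographically."""
    counts: dict[str, int] = {}
    empty = True
    for seq in sequences:
        empty = False
        tokens = seq.tokens if hasattr(seq, "tokens") else seq
        for t in tokens:
            counts[t] = counts.get(t, 0) + 1
    if empty:
        raise ValueError("empty corpus")
    ordered = sorted(counts, key=lambda t: (-counts[t], t))
    return Vocabulary(ordered)
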