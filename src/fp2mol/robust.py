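"""Robust bracket-token molecular strings.

A small SELFIES-style line notation in which every unit is enclosed in
square brackets and *any* sequence of alphabet tokens decodes to a valid
molecule.  Robustness comes from valence-capped decoding: bond orders are
clipped to the remaining valence of both partners, impossible tokens are
skipped, unmatched branch tokens are forgiven, and out-of-range ring
closures are ignored.  The grammar mirrors the structure of SMILES:

* atom tokens ``[C]``, ``[=O]``, ``[#N]``, ``[/C]``, ``[\\C]`` carry the
  bond (order or direction) to the previously placed atom;
* chiral-atom tokens ``[C@H]``, ``[C@@]`` etc. carry a tetrahedral tag and
  an optional explicit hydrogen;
* ``[Branch]`` / ``[EndBranch]`` open and close a side chain rooted at the
  current atom;
* ``[Ring3]`` (or ``[=Ring3]``) bonds the current atom to the atom placed
  three positions earlier, closing a ring.

The codec is intentionally restricted to neutral organic-subset atoms
(C, N, O, S, P and the halogens, with S and P kept at their lowest
valence) so that decoding can never produce a sanitisation failure.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

ELEMENTS = ("Cl", "Br", "C", "N", "O", "S", "P", "F", "I")

#: maximum total valence assumed during decoding (lowest common valence,
#: so every decoded graph is sanitisable)
MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3, "F": 1, "Cl": 1, "Br": 1, "I": 1}

_BOND_ORDER = {"": 1, "-": 1, "=": 2, "#": 3, "/": 1, "\\": 1}
_BOND_TYPE = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}

MAX_RING_SPAN = 64

_TOKEN_RE = re.compile(r"\[[^\[\]]*\]")
_ATOM_RE = re.compile(
    r"\[(?P<bond>[-=#/\\]?)(?P<elem>Cl|Br|C|N|O|S|P|F|I)"
    r"(?P<chiral>@@|@)?(?P<h>H)?\]"
)
_RING_RE = re.compile(r"\[(?P<bond>[-=#]?)Ring(?P<n>[1-9][0-9]?)\]")

BRANCH = "[Branch]"
END_BRANCH = "[EndBranch]"


class RobustDecodeError(ValueError):
    """Raised when a string is not a concatenation of alphabet tokens."""


class RobustEncodeError(ValueError):
    """Raised when a molecule cannot be expressed in the restricted alphabet."""


def alphabet(max_ring: int = 9) -> list[str]:
    """The sampling alphabet: atom, branch and small-ring tokens."""
    toks: list[str] = []
    for bond in ("", "=", "#"):
        for elem in ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I"):
            toks.append(f"[{bond}{elem}]")
    toks += [BRANCH, END_BRANCH]
    toks += [f"[Ring{n}]" for n in range(1, max_ring + 1)]
    return toks


def tokenize(s: str) -> list[str]:
    """Split a robust string into bracket tokens; raises on stray characters."""
    tokens = _TOKEN_RE.findall(s)
    if "".join(tokens) != s:
        raise RobustDecodeError(f"stray characters outside bracket tokens in {s!r}")
    return tokens


def is_token(tok: str) -> bool:
    return (
        tok in (BRANCH, END_BRANCH)
        or _ATOM_RE.fullmatch(tok) is not None
        or (_RING_RE.fullmatch(tok) is not None
            and int(_RING_RE.fullmatch(tok)["n"]) <= MAX_RING_SPAN)
    )


def decode(tokens: Sequence[str] | str) -> Chem.Mol | None:
    """Decode a token sequence into a sanitised molecule.

    Never fails on alphabet tokens: chemically impossible instructions are
    skipped.  Returns ``None`` for a sequence that places no atoms.
    """
    if isinstance(tokens, str):
        tokens = tokenize(tokens)
    rw = Chem.RWMol()
    rem: list[int] = []  # remaining valence per atom index
    prev: int | None = None
    stack: list[int] = []
    for tok in tokens:
        if tok == BRANCH:
            if prev is not None:
                stack.append(prev)
            continue
        if tok == END_BRANCH:
            if stack:
                prev = stack.pop()
            continue
        m = _RING_RE.fullmatch(tok)
        if m is not None:
            if prev is None:
                continue
            j = prev - int(m["n"])
            if j < 0 or j == prev or int(m["n"]) > MAX_RING_SPAN:
                continue
            if rw.GetBondBetweenAtoms(prev, j) is not None:
                continue
            order = min(_BOND_ORDER[m["bond"]], rem[prev], rem[j])
            if order < 1:
                continue
            rw.AddBond(prev, j, _BOND_TYPE[order])
            rem[prev] -= order
            rem[j] -= order
            continue
        m = _ATOM_RE.fullmatch(tok)
        if m is None:
            raise RobustDecodeError(f"unknown token {tok!r}")
        elem, bond, chiral, hcount = m["elem"], m["bond"], m["chiral"], m["h"]
        nh = 1 if hcount else 0
        cap = MAX_VALENCE[elem] - nh
        atom = Chem.Atom(elem)
        if nh:
            atom.SetNumExplicitHs(nh)
        if chiral == "@":
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
        elif chiral == "@@":
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CW)
        if prev is None:
            if cap < 0:
                continue
            idx = rw.AddAtom(atom)
            rem.append(cap)
            prev = idx
            continue
        order = min(_BOND_ORDER[bond], rem[prev], cap)
        if order < 1:
            # previous atom saturated: re-root at the most recent atom with
            # spare valence (never triggered by encoder output, where bonds
            # always fit; keeps random strings growing instead of dying)
            for j in range(len(rem) - 1, -1, -1):
                if rem[j] >= 1:
                    prev = j
                    break
            else:
                continue
            order = min(_BOND_ORDER[bond], rem[prev], cap)
            if order < 1:
                continue
        idx = rw.AddAtom(atom)
        rem.append(cap - order)
        rem[prev] -= order
        rw.AddBond(prev, idx, _BOND_TYPE[order])
        if bond in ("/", "\\") and order == 1:
            b = rw.GetBondBetweenAtoms(prev, idx)
            b.SetBondDir(
                Chem.BondDir.ENDUPRIGHT if bond == "/" else Chem.BondDir.ENDDOWNRIGHT
            )
        prev = idx
    if rw.GetNumAtoms() == 0:
        return None
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    Chem.DetectBondStereochemistry(mol)
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    return mol


def decode_to_smiles(tokens: Sequence[str] | str) -> str:
    """Decode to a canonical isomeric SMILES ('' for an atom-free sequence)."""
    mol = decode(tokens)
    return "" if mol is None else Chem.MolToSmiles(mol)


def _kekule_smiles(mol: Chem.Mol) -> str:
    mol = Chem.Mol(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    return Chem.MolToSmiles(mol, kekuleSmiles=True)


_SMI_ATOM = re.compile(
    r"(?P<bracket>\[[^\]]+\])|(?P<organic>Cl|Br|C|N|O|S|P|F|I)"
)
_BRACKET_ATOM = re.compile(
    r"\[(?P<isotope>\d+)?(?P<elem>[A-Z][a-z]?)(?P<chiral>@@|@)?"
    r"(?P<h>H\d*)?(?P<charge>[+-]\d*)?\]"
)


def _encode_once(smiles: str) -> list[str]:
    """Translate one Kekulé SMILES into robust tokens, mirroring its layout."""
    tokens: list[str] = []
    open_rings: dict[str, tuple[int, str]] = {}
    atom_count = 0
    pending_bond = ""
    i = 0
    n = len(smiles)
    while i < n:
        c = smiles[i]
        if c in "-=#/\\":
            pending_bond = c if c != "-" else ""
            i += 1
            continue
        if c == "(":
            tokens.append(BRANCH)
            i += 1
            continue
        if c == ")":
            tokens.append(END_BRANCH)
            i += 1
            continue
        if c.isdigit() or c == "%":
            if c == "%":
                label, i = smiles[i + 1 : i + 3], i + 3
            else:
                label, i = c, i + 1
            if label in open_rings:
                j, obond = open_rings.pop(label)
                bond = pending_bond or obond
                if bond in ("/", "\\"):
                    raise RobustEncodeError("directional ring-closure bond")
                span = atom_count - j
                if span > MAX_RING_SPAN:
                    raise RobustEncodeError(f"ring span {span} out of range")
                tokens.append(f"[{bond}Ring{span}]")
            else:
                open_rings[label] = (atom_count, pending_bond)
            pending_bond = ""
            continue
        m = _SMI_ATOM.match(smiles, i)
        if m is None:
            raise RobustEncodeError(f"unsupported SMILES syntax at {smiles[i:]!r}")
        i = m.end()
        if m["organic"]:
            elem, chiral, nh = m["organic"], "", ""
        else:
            bm = _BRACKET_ATOM.fullmatch(m["bracket"])
            if bm is None or bm["isotope"] or bm["charge"]:
                raise RobustEncodeError(f"unsupported atom {m.group(0)!r}")
            elem, chiral = bm["elem"], bm["chiral"] or ""
            h = bm["h"]
            if h is None:
                nh = ""
            elif h in ("H", "H1"):
                nh = "H"
            else:
                raise RobustEncodeError(f"unsupported H count in {m.group(0)!r}")
            if not chiral and nh:
                # e.g. [NH] written explicitly: treat as the plain atom
                nh = ""
        if elem not in MAX_VALENCE:
            raise RobustEncodeError(f"element {elem!r} outside alphabet")
        tokens.append(f"[{pending_bond}{elem}{chiral}{nh}]")
        pending_bond = ""
        atom_count += 1
    if open_rings:
        raise RobustEncodeError("unclosed ring bond in input")
    return tokens


def _stereo_variants(tokens: list[str], cap: int = 1024) -> Iterable[list[str]]:
    """All sign-flips of chiral tags and bond directions, nearest-first."""
    sites = [
        k
        for k, t in enumerate(tokens)
        if "@" in t or t.startswith("[/") or t.startswith("[\\")
    ]
    n_sites = len(sites)
    count = 0
    for mask in range(1 << min(n_sites, 10)):
        if count >= cap:
            return
        variant = list(tokens)
        for b, k in enumerate(sites):
            if mask >> b & 1:
                t = variant[k]
                if t.startswith("[/"):
                    t = "[\\" + t[2:]
                elif t.startswith("[\\"):
                    t = "[/" + t[2:]
                elif "@@" in t:
                    t = t.replace("@@", "@")
                else:
                    t = t.replace("@", "@@")
                variant[k] = t
        count += 1
        yield variant


def encode(smiles_or_mol: str | Chem.Mol) -> list[str]:
    """Encode a molecule as robust tokens such that decoding round-trips.

    The token layout mirrors the molecule's canonical Kekulé SMILES.  Because
    tetrahedral parity and cis/trans direction are order-sensitive, the
    encoder verifies the round trip and searches sign-flips of the stereo
    tokens until the decoded canonical SMILES matches; a molecule outside
    the restricted alphabet raises :class:`RobustEncodeError`.
    """
    if isinstance(smiles_or_mol, str):
        mol = Chem.MolFromSmiles(smiles_or_mol)
        if mol is None:
            raise RobustEncodeError(f"unparseable SMILES {smiles_or_mol!r}")
    else:
        mol = smiles_or_mol
    target = Chem.MolToSmiles(mol)
    base = _encode_once(_kekule_smiles(mol))
    for variant in _stereo_variants(base):
        if decode_to_smiles(variant) == target:
            return variant
    raise RobustEncodeError(
        f"could not find a round-tripping encoding for {target!r}"
    )
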