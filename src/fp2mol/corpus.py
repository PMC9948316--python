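"""Synthetic drug-like molecule corpus: generate, filter, diversify, split.

The generator emulates a large training corpus of small/medium organic
molecules at desk scale.  Molecules are produced by sampling random token
strings in the robust bracket-token alphabet and decoding them (decoding is
total, so every sample is a valid molecule), filtering to a heavy-atom cap,
de-duplicating by canonical isomeric SMILES, and then enriching
stereochemistry molecule-by-molecule until roughly the target fraction of
records carries stereo annotations.  Every admitted record round-trips
through the robust codec, so the same corpus can serve SMILES- and
SELFIES-style translation experiments.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem
from rdkit.Chem.EnumerateStereoisomers import (
    EnumerateStereoisomers,
    StereoEnumerationOptions,
)

from . import robust
from .fingerprints import morgan_sparse_keys


@dataclass(frozen=True)
class MoleculeRecord:
    id: str
    smiles: str  # canonical isomeric SMILES
    heavy_atoms: int
    has_stereo: bool


@dataclass(frozen=True)
class CorpusConfig:
    n_molecules: int
    heavy_atom_cap: int = 50
    stereo_fraction_target: float = 0.3
    max_generation_attempts: int = 0  # 0 → 200 × n_molecules
    seed: int = 0
    min_tokens: int = 8
    max_tokens: int = 40

    def __post_init__(self):
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be non-negative")
        if not 0.0 <= self.stereo_fraction_target <= 1.0:
            raise ValueError("stereo_fraction_target must lie in [0, 1]")

    @property
    def attempts(self) -> int:
        return self.max_generation_attempts or 200 * max(self.n_molecules, 1)


@dataclass(frozen=True)
class CorpusSplit:
    train: list[MoleculeRecord] = field(default_factory=list)
    test: list[MoleculeRecord] = field(default_factory=list)
    seed: int = 0


class GenerationExhausted(RuntimeError):
    pass


def _has_stereo(smiles: str) -> bool:
    return "@" in smiles or "/" in smiles or "\\" in smiles


def _record(idx: int, smiles: str, mol: Chem.Mol) -> MoleculeRecord:
    return MoleculeRecord(
        id=f"M{idx:06d}",
        smiles=smiles,
        heavy_atoms=mol.GetNumHeavyAtoms(),
        has_stereo=_has_stereo(smiles),
    )


def _encodable(smiles: str) -> bool:
    try:
        return robust.decode_to_smiles(robust.encode(smiles)) == smiles
    except robust.RobustEncodeError:
        return False


# heavier weight on carbon and single bonds gives organic, drug-like skeletons
def _alphabet_weights(alpha: list[str]) -> list[float]:
    weights = []
    for t in alpha:
        if t == "[C]":
            w = 30.0
        elif t in ("[N]", "[O]"):
            w = 6.0
        elif t in ("[=C]", "[=N]", "[=O]"):
            w = 4.0
        elif t in (robust.BRANCH, robust.END_BRANCH):
            w = 6.0
        elif t.startswith("[Ring"):
            w = 1.5
        elif t.startswith("[#"):
            w = 0.3
        else:
            w = 1.0
        weights.append(w)
    return weights


def generate_molecules(config: CorpusConfig) -> list[MoleculeRecord]:
    """Generate ``config.n_molecules`` unique valid molecules, seeded.

    Raises :class:`GenerationExhausted` with a diagnostic if the attempt
    budget runs out before enough unique records exist.
    """
    if config.n_molecules == 0:
        return []
    rng = random.Random(config.seed)
    alpha = robust.alphabet()
    weights = _alphabet_weights(alpha)
    seen: set[str] = set()
    mols: list[tuple[str, Chem.Mol]] = []
    attempts = 0
    while len(mols) < config.n_molecules:
        if attempts >= config.attempts:
            raise GenerationExhausted(
                f"exhausted {attempts} attempts with only "
                f"{len(mols)}/{config.n_molecules} unique molecules"
            )
        attempts += 1
        length = rng.randint(config.min_tokens, config.max_tokens)
        tokens = rng.choices(alpha, weights=weights, k=length)
        mol = robust.decode(tokens)
        if mol is None or mol.GetNumHeavyAtoms() > config.heavy_atom_cap:
            continue
        smiles = Chem.MolToSmiles(mol)
        if smiles in seen or not _encodable(smiles):
            continue
        seen.add(smiles)
        mols.append((smiles, mol))

    # stereo enrichment: assign unresolved stereocenters molecule-by-molecule
    # until the stereo fraction approaches the target
    n_target = round(config.stereo_fraction_target * config.n_molecules)
    have = sum(1 for s, _ in mols if _has_stereo(s))
    order = list(range(len(mols)))
    rng.shuffle(order)
    for i in order:
        if have >= n_target:
            break
        smiles, mol = mols[i]
        if _has_stereo(smiles):
            continue
        opts = StereoEnumerationOptions(maxIsomers=8, rand=rng.randrange(2**31))
        isomers = [Chem.MolToSmiles(m) for m in EnumerateStereoisomers(mol, options=opts)]
        stereo = [s for s in isomers if _has_stereo(s)]
        rng.shuffle(stereo)
        for cand in stereo:
            if cand in seen or not _encodable(cand):
                continue
            cand_mol = Chem.MolFromSmiles(cand)
            if cand_mol is None or cand_mol.GetNumHeavyAtoms() > config.heavy_atom_cap:
                continue
            seen.discard(smiles)
            seen.add(cand)
            mols[i] = (cand, cand_mol)
            have += 1
            break
    return [_record(i + 1, s, m) for i, (s, m) in enumerate(mols)]


def filter_by_heavy_atoms(mols: list[MoleculeRecord], cap: int) -> list[MoleculeRecord]:
    """Keep records with ``heavy_atoms <= cap`` (inclusive), preserving order."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    return [m for m in mols if m.heavy_atoms <= cap]


def select_diverse_by_atom_types(
    candidates: list[MoleculeRecord],
    base: list[MoleculeRecord],
    budget: int,
) -> list[MoleculeRecord]:
    """Greedy atom-type coverage selection.

    Atom types are the radius-0 sparse circular features.  At each step the
    candidate contributing the most features not yet covered by
    ``base ∪ selected`` is picked (ties broken by input order); selection
    stops early when no candidate adds a new feature.
    """
    if budget < 0:
        raise ValueError("budget must be >= 0")
    covered: set[int] = set()
    for rec in base:
        covered |= morgan_sparse_keys(rec.smiles, 0)
    cand_keys = [morgan_sparse_keys(rec.smiles, 0) for rec in candidates]
    remaining = list(range(len(candidates)))
    selected: list[MoleculeRecord] = []
    while len(selected) < budget and remaining:
        gains = [len(cand_keys[i] - covered) for i in remaining]
        best_gain = max(gains)
        if best_gain == 0:
            break
        best = remaining[gains.index(best_gain)]
        selected.append(candidates[best])
        covered |= cand_keys[best]
        remaining.remove(best)
    return selected


def split_corpus(mols: list[MoleculeRecord], test_size: int, seed: int) -> CorpusSplit:
    """Uniform random train/test split without replacement, seeded."""
    if not 0 <= test_size <= len(mols):
        raise ValueError(f"test_size {test_size} out of range [0, {len(mols)}]")
    rng = random.Random(seed)
    idx = list(range(len(mols)))
    rng.shuffle(idx)
    test_idx = set(idx[:test_size])
    train = [m for i, m in enumerate(mols) if i not in test_idx]
    test = [m for i, m in enumerate(mols) if i in test_idx]
    return CorpusSplit(train=train, test=test, seed=seed)


def write_smiles_file(records: list[MoleculeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.smiles}\t{rec.id}\n")


def read_smiles_file(path: str | Path) -> list[MoleculeRecord]:
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            smiles = parts[0]
            rid = parts[1] if len(parts) > 1 else f"M{i + 1:06d}"
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                raise ValueError(f"{path}:{i + 1}: unparseable SMILES {smiles!r}")
            canonical = Chem.MolToSmiles(mol)
            records.append(MoleculeRecord(rid, canonical, mol.GetNumHeavyAtoms(),
                                          _has_stereo(canonical)))
    return records


def write_manifest(config: CorpusConfig, records: list[MoleculeRecord],
                   path: str | Path) -> None:
    n = len(records)
    manifest = {
        "config": {
            "n_molecules": config.n_molecules,
            "heavy_atom_cap": config.heavy_atom_cap,
            "stereo_fraction_target": config.stereo_fraction_target,
            "seed": config.seed,
        },
        "n_records": n,
        "stereo_fraction": (sum(r.has_stereo for r in records) / n) if n else 0.0,
        "mean_heavy_atoms": (sum(r.heavy_atoms for r in records) / n) if n else 0.0,
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
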