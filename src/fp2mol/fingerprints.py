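"""The thirteen structural-fingerprint featurizers and Tanimoto similarity.

Each featurizer renders a molecule either as an ordered sequence of feature
tokens (the source "sentence" for translation) or as a set of integer
features (for similarity metrics).  All fingerprints are computed with
RDKit; binary variants are hashed to 2048 bits except MACCS (166 keys) and
Avalon (512 bits).  Presence-only (set) semantics are used throughout,
including for the sparse topological-torsion (TT) and atom-environment
(AEs) fingerprints.

Similarity metrics additionally include ``ECFP2*`` and ``ECFP4*``, the
explicit-bit (unhashed sparse) variants of the radius-1 and radius-2
circular fingerprints, for a total of 15 metric fingerprints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

from rdkit import Chem
from rdkit.Avalon import pyAvalonTools
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

MoleculeLike = Union[str, Chem.Mol, "object"]


@dataclass(frozen=True)
class FingerprintSpec:
    """One registered featurizer with all parameters fixed."""

    name: str
    family: str  # predefined | paths-and-features | path-based | 4-atom-paths | circular
    hashed: bool
    n_bits: int | str  # bit-vector size, or "sparse"
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FeatureTokenSequence:
    """Ordered fingerprint-feature tokens (set semantics, ascending IDs)."""

    spec_name: str
    tokens: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class FeatureSet:
    """Integer feature set used for Tanimoto similarity."""

    spec_name: str
    features: frozenset[int]


_REGISTRY: tuple[FingerprintSpec, ...] = (
    FingerprintSpec("MACCS", "predefined", True, 166, {}),
    FingerprintSpec("Avalon", "paths-and-features", True, 512, {}),
    FingerprintSpec("HashAP", "path-based", True, 2048, {"minLength": 1, "maxLength": 6}),
    FingerprintSpec("RDK4", "path-based", True, 2048,
                    {"minPath": 2, "maxPath": 4, "branched": True}),
    FingerprintSpec("RDK4-L", "path-based", True, 2048,
                    {"minPath": 2, "maxPath": 4, "branched": False}),
    FingerprintSpec("TT", "4-atom-paths", False, "sparse", {"torsionAtomCount": 4}),
    FingerprintSpec("HashTT", "4-atom-paths", True, 2048, {"torsionAtomCount": 4}),
    FingerprintSpec("AEs", "circular", False, "sparse", {"radius": 1}),
    FingerprintSpec("ECFP0", "circular", True, 2048, {"radius": 0}),
    FingerprintSpec("ECFP2", "circular", True, 2048, {"radius": 1}),
    FingerprintSpec("ECFP4", "circular", True, 2048, {"radius": 2}),
    FingerprintSpec("FCFP2", "circular", True, 2048, {"radius": 1, "features": True}),
    FingerprintSpec("FCFP4", "circular", True, 2048, {"radius": 2, "features": True}),
)

#: metric-only sparse circular variants (explicit-bit ECFP2/ECFP4)
_METRIC_EXTRAS: tuple[FingerprintSpec, ...] = (
    FingerprintSpec("ECFP2*", "circular", False, "sparse", {"radius": 1}),
    FingerprintSpec("ECFP4*", "circular", False, "sparse", {"radius": 2}),
)

METRIC_NAMES: tuple[str, ...] = tuple(s.name for s in _REGISTRY) + tuple(
    s.name for s in _METRIC_EXTRAS
)

#: primary similarity metric of the whole pipeline: sparse circular radius 1
PRIMARY_METRIC = "AEs"


def registry_list() -> list[FingerprintSpec]:
    """The 13 registered featurizers, in registry (table) order."""
    return list(_REGISTRY)


def get_spec(name: str) -> FingerprintSpec:
    for spec in _REGISTRY + _METRIC_EXTRAS:
        if spec.name == name:
            return spec
    raise KeyError(f"unknown fingerprint spec {name!r}")


def _as_mol(mol: MoleculeLike) -> Chem.Mol:
    if isinstance(mol, Chem.Mol):
        return mol
    smiles = mol if isinstance(mol, str) else getattr(mol, "smiles", None)
    if smiles is None:
        raise TypeError(f"cannot interpret {mol!r} as a molecule")
    parsed = Chem.MolFromSmiles(smiles)
    if parsed is None:
        raise ValueError(f"unparseable molecule {smiles!r}")
    return parsed


_GEN_CACHE: dict[str, object] = {}


def _generator(name: str):
    gen = _GEN_CACHE.get(name)
    if gen is not None:
        return gen
    g = rdFingerprintGenerator
    if name == "HashAP":
        gen = g.GetAtomPairGenerator(minDistance=1, maxDistance=6, fpSize=2048)
    elif name == "RDK4":
        gen = g.GetRDKitFPGenerator(minPath=2, maxPath=4, fpSize=2048, branchedPaths=True)
    elif name == "RDK4-L":
        gen = g.GetRDKitFPGenerator(minPath=2, maxPath=4, fpSize=2048, branchedPaths=False)
    elif name in ("TT", "HashTT"):
        gen = g.GetTopologicalTorsionGenerator(torsionAtomCount=4, fpSize=2048)
    elif name in ("AEs", "ECFP2*"):
        gen = g.GetMorganGenerator(radius=1)
    elif name == "ECFP4*":
        gen = g.GetMorganGenerator(radius=2)
    elif name.startswith("ECFP"):
        radius = {"ECFP0": 0, "ECFP2": 1, "ECFP4": 2}[name]
        gen = g.GetMorganGenerator(radius=radius, fpSize=2048)
    elif name.startswith("FCFP"):
        radius = {"FCFP2": 1, "FCFP4": 2}[name]
        gen = g.GetMorganGenerator(
            radius=radius, fpSize=2048,
            atomInvariantsGenerator=g.GetMorganFeatureAtomInvGen(),
        )
    else:
        raise KeyError(name)
    _GEN_CACHE[name] = gen
    return gen


def _feature_ids(mol: Chem.Mol, name: str) -> list[int]:
    """Sorted on-bit indices (hashed) or sparse feature IDs for one spec."""
    if name == "MACCS":
        # RDKit's MACCS vector is 167 long with bit 0 unused (keys 1..166);
        # shift to the 0-based key range [0, 166)
        bits = MACCSkeys.GenMACCSKeys(mol).GetOnBits()
        return sorted(b - 1 for b in bits)
    if name == "Avalon":
        return sorted(pyAvalonTools.GetAvalonFP(mol, nBits=512).GetOnBits())
    gen = _generator(name)
    if name in ("TT", "AEs", "ECFP2*", "ECFP4*"):
        counts = gen.GetSparseCountFingerprint(mol).GetNonzeroElements()
        return sorted(counts)
    return sorted(gen.GetFingerprint(mol).GetOnBits())


def morgan_sparse_keys(mol: MoleculeLike, radius: int) -> frozenset[int]:
    """Sparse circular feature identifiers up to ``radius`` (atom types at 0)."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    keys = gen.GetSparseCountFingerprint(_as_mol(mol)).GetNonzeroElements()
    return frozenset(keys)


def featurize(mol: MoleculeLike, spec: FingerprintSpec | str) -> FeatureTokenSequence:
    """Render a molecule as an ascending sequence of feature-ID tokens."""
    if isinstance(spec, str):
        spec = get_spec(spec)
    ids = _feature_ids(_as_mol(mol), spec.name)
    if spec.hashed and ids and not (0 <= ids[0] and ids[-1] < int(spec.n_bits)):
        raise AssertionError(f"{spec.name} emitted a feature outside [0, {spec.n_bits})")
    return FeatureTokenSequence(spec.name, tuple(str(i) for i in ids))


def to_feature_set(mol: MoleculeLike, spec_name: str) -> FeatureSet:
    """Integer feature set of a molecule under one of the 15 metric fingerprints."""
    if spec_name not in METRIC_NAMES:
        raise KeyError(f"unknown fingerprint spec {spec_name!r}")
    return FeatureSet(spec_name, frozenset(_feature_ids(_as_mol(mol), spec_name)))


def tanimoto(a: FeatureSet, b: FeatureSet) -> float:
    """|a ∩ b| / |a ∪ b|; 1.0 when both sets are empty."""
    if a.spec_name != b.spec_name:
        raise ValueError(f"mismatched specs {a.spec_name!r} vs {b.spec_name!r}")
    union = a.features | b.features
    if not union:
        return 1.0
    return len(a.features & b.features) / len(union)


def tanimoto_smiles(s1: str, s2: str, spec_name: str = PRIMARY_METRIC) -> float:
    """Convenience: Tanimoto between two SMILES under one metric fingerprint."""
    return tanimoto(to_feature_set(s1, spec_name), to_feature_set(s2, spec_name))
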