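"""Evaluation metrics: Tanimoto exactness, accuracy breakdown, fingerprint
bias matrix, significance thresholds and stereo-error profiling.

The accuracy breakdown classifies each prediction by the first matching
rule: invalid -> not Tc-exact (under the primary sparse radius-1 circular
metric) -> string exact -> non-canonical (same molecule, different string)
-> stereo (same molecule once stereo is stripped) -> others.  The four
exact categories partition the Tc-exact total.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from rdkit import Chem

from . import codecs
from .decode import PredictionRecord
from .fingerprints import (
    METRIC_NAMES,
    PRIMARY_METRIC,
    get_spec,
    tanimoto,
    to_feature_set,
)

CATEGORIES = ("string_exact", "non_canonical", "stereo", "others",
              "not_exact", "invalid")


@dataclass(frozen=True)
class BreakdownReport:
    n_total: int
    pct_tc_exact: float
    pct_string_exact: float
    pct_stereo: float
    pct_noncanonical: float
    pct_others: float
    pct_invalid: float
    mean_tc: float


@dataclass(frozen=True)
class SignificanceThreshold:
    spec_name: str
    p_value: float
    tc_threshold: float
    n_pairs: int
    seed: int


def _to_smiles(s: str, representation: str) -> str | None:
    """Underlying SMILES of a prediction/ground truth, None when invalid."""
    if representation == codecs.SELFIES:
        if not codecs.is_valid(s, representation):
            return None
        return codecs.selfies_to_smiles(s)  # may be '' (the empty molecule)
    return s if codecs.is_valid(s, representation) else None


def _tc_exact(pred_smiles: str, gt_smiles: str, metric: str) -> bool:
    # Tc == 1 iff the feature sets are identical: compare sets exactly
    return (to_feature_set(pred_smiles, metric).features
            == to_feature_set(gt_smiles, metric).features)


def tanimoto_exactness(records: Sequence[PredictionRecord],
                       metric_spec: str = PRIMARY_METRIC) -> float:
    """Percentage of valid predictions with Tc = 1 under ``metric_spec``.

    Invalid predictions count in the denominator only.
    """
    get_spec(metric_spec)
    if not records:
        raise ValueError("empty record list")
    hits = 0
    for rec in records:
        if not rec.valid:
            continue
        pred = _to_smiles(rec.prediction, rec.representation)
        gt = _to_smiles(rec.ground_truth, rec.representation)
        if pred is not None and gt is not None and _tc_exact(pred, gt, metric_spec):
            hits += 1
    return 100.0 * hits / len(records)


def classify(rec: PredictionRecord) -> str:
    """First-matching-rule category of one prediction."""
    pred = _to_smiles(rec.prediction, rec.representation) if rec.valid else None
    if pred is None:
        return "invalid"
    gt = _to_smiles(rec.ground_truth, rec.representation)
    if gt is None:
        raise ValueError(f"record {rec.id}: unparseable ground truth")
    if not _tc_exact(pred, gt, PRIMARY_METRIC):
        return "not_exact"
    if rec.prediction == rec.ground_truth:
        return "string_exact"
    if codecs.canonicalize(pred) == codecs.canonicalize(gt):
        return "non_canonical"
    if codecs.canonicalize(pred, keep_stereo=False) == codecs.canonicalize(gt, keep_stereo=False):
        return "stereo"
    return "others"


def breakdown(records: Sequence[PredictionRecord]) -> BreakdownReport:
    if not records:
        raise ValueError("empty record list")
    counts = {c: 0 for c in CATEGORIES}
    tc_sum = 0.0
    for rec in records:
        counts[classify(rec)] += 1
        tc_sum += rec.tc_primary if rec.valid else 0.0
    n = len(records)
    pct = lambda c: 100.0 * counts[c] / n
    return BreakdownReport(
        n_total=n,
        pct_tc_exact=pct("string_exact") + pct("non_canonical") + pct("stereo") + pct("others"),
        pct_string_exact=pct("string_exact"),
        pct_stereo=pct("stereo"),
        pct_noncanonical=pct("non_canonical"),
        pct_others=pct("others"),
        pct_invalid=pct("invalid"),
        mean_tc=tc_sum / n,
    )


def bias_matrix(per_model_records: dict[str, Sequence[PredictionRecord]]) -> pd.DataFrame:
    """Tanimoto exactness of each model's predictions under all 15 metrics."""
    if not per_model_records:
        raise ValueError("at least one model's records required")
    rows = {
        model: {m: tanimoto_exactness(records, m) for m in METRIC_NAMES}
        for model, records in per_model_records.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(METRIC_NAMES))


def significance_threshold(corpus: Sequence, spec_name: str, p: float = 0.01,
                           n_pairs: int = 10_000, seed: int = 0) -> SignificanceThreshold:
    """Empirical (1-p) quantile of random-pair Tanimoto similarities.

    Samples ``n_pairs`` unordered molecule pairs (no self-pairs) from the
    corpus, computes Tc under ``spec_name`` and returns the similarity
    value exceeded by at most a fraction ``p`` of random pairs.
    """
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    smiles = [getattr(m, "smiles", m) for m in corpus]
    if len(smiles) < 2:
        raise ValueError("corpus must contain at least 2 molecules")
    rng = random.Random(seed)
    fps = [to_feature_set(s, spec_name) for s in smiles]
    values = []
    for _ in range(n_pairs):
        i, j = rng.sample(range(len(fps)), 2)
        values.append(tanimoto(fps[i], fps[j]))
    values.sort()
    idx = min(int((1.0 - p) * n_pairs), n_pairs - 1)
    return SignificanceThreshold(spec_name, p, values[idx], n_pairs, seed)


def _stereo_descriptors(smiles: str) -> dict:
    """Stereo descriptors keyed by canonical ranks of the stereo-stripped form."""
    mol = Chem.MolFromSmiles(smiles)
    stripped = Chem.Mol(mol)
    Chem.RemoveStereochemistry(stripped)
    ranks = list(Chem.CanonicalRankAtoms(stripped, breakTies=True))
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    desc = {}
    for atom in mol.GetAtoms():
        if atom.HasProp("_CIPCode"):
            desc[("atom", ranks[atom.GetIdx()])] = atom.GetProp("_CIPCode")
    for bond in mol.GetBonds():
        st = bond.GetStereo()
        if st != Chem.BondStereo.STEREONONE:
            key = ("bond", tuple(sorted((ranks[bond.GetBeginAtomIdx()],
                                         ranks[bond.GetEndAtomIdx()]))))
            desc[key] = str(st)
    return desc


def stereo_error_profile(records: Sequence[PredictionRecord]) -> dict[str, int]:
    """Partition stereo-category records by the nature of the stereo error.

    ``reversed``: every shared stereo element has an opposite descriptor;
    ``missing``: the prediction lacks elements the ground truth has;
    ``spurious``: the prediction has elements the ground truth lacks;
    ``mixed``: any other combination.
    """
    out = {"reversed": 0, "missing": 0, "spurious": 0, "mixed": 0}
    for rec in records:
        if classify(rec) != "stereo":
            continue
        pred = _to_smiles(rec.prediction, rec.representation)
        gt = _to_smiles(rec.ground_truth, rec.representation)
        d_gt = _stereo_descriptors(gt)
        d_pr = _stereo_descriptors(pred)
        missing = set(d_gt) - set(d_pr)
        spurious = set(d_pr) - set(d_gt)
        flipped = {k for k in set(d_gt) & set(d_pr) if d_gt[k] != d_pr[k]}
        if flipped and not missing and not spurious:
            out["reversed"] += 1
        elif missing and not spurious and not flipped:
            out["missing"] += 1
        elif spurious and not missing and not flipped:
            out["spurious"] += 1
        else:
            out["mixed"] += 1
    return out
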