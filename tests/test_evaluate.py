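"""Evaluation metrics: exactness, breakdown partition, bias matrix, thresholds."""

import random

import pytest

from fp2mol import codecs, evaluate
from fp2mol.decode import PredictionRecord
from fp2mol.evaluate import (
    breakdown,
    bias_matrix,
    classify,
    significance_threshold,
    stereo_error_profile,
    tanimoto_exactness,
)
from fp2mol.fingerprints import METRIC_NAMES, PRIMARY_METRIC, tanimoto_smiles


def rec(gt, pred, rid="r", rep=codecs.SMILES):
    valid = codecs.is_valid(pred, rep)
    tc = tanimoto_smiles(pred, gt) if valid else 0.0
    return PredictionRecord(rid, gt, pred, rep, valid, tc)


PERFECT = [rec("CCO", "CCO"), rec("c1ccccc1", "c1ccccc1")]
ALL_INVALID = [rec("CCO", "C(("), rec("CCO", "")]

# an adversarial toy set covering every category
TOY = [
    rec("CCO", "CCO", "string"),                    # string exact
    rec("OCC", "CCO", "weird"),                     # same molecule, raw strings differ
    rec("C/C=C/C", "C/C=C\\C", "stereo1"),          # flipped double-bond stereo
    rec("C[C@H](N)C(=O)O", "C[C@@H](N)C(=O)O", "stereo2"),  # flipped center
    rec("CCO", "CCC", "miss"),                      # wrong molecule
    rec("CCO", "C((", "inv"),                       # invalid
]


class TestTanimotoExactness:
    def test_perfect_predictions_are_100_under_every_metric(self):
        for name in METRIC_NAMES:
            assert tanimoto_exactness(PERFECT, name) == 100.0

    def test_all_invalid_is_zero(self):
        assert tanimoto_exactness(ALL_INVALID, PRIMARY_METRIC) == 0.0

    def test_matches_hand_count(self):
        # hand enumeration: string/enumeration/stereo records are exact under
        # the stereo-insensitive primary metric (4 of 6); the wrong molecule
        # and the invalid prediction are not, but count in the denominator
        assert tanimoto_exactness(TOY, PRIMARY_METRIC) == pytest.approx(100 * 4 / 6)

    def test_empty_records_raise(self):
        with pytest.raises(ValueError):
            tanimoto_exactness([], PRIMARY_METRIC)


class TestBreakdown:
    def test_category_assignments(self):
        assert classify(rec("CCO", "CCO")) == "string_exact"
        assert classify(rec("OCC", "CCO")) in ("string_exact", "non_canonical")
        # force a genuinely non-canonical writing of ethanol
        r = PredictionRecord("x", "CCO", "C(O)C", codecs.SMILES, True, 1.0)
        assert classify(r) == "non_canonical"
        assert classify(rec("C/C=C/C", "C/C=C\\C")) == "stereo"
        assert classify(rec("CCO", "C((")) == "invalid"
        assert classify(rec("CCO", "CCC")) == "not_exact"

    def test_partition_identity(self):
        rep = breakdown(TOY)
        parts = (rep.pct_string_exact + rep.pct_stereo + rep.pct_noncanonical
                 + rep.pct_others)
        assert parts == pytest.approx(rep.pct_tc_exact)
        not_exact = 100.0 - rep.pct_tc_exact - rep.pct_invalid
        assert not_exact >= 0
        assert rep.n_total == len(TOY)

    def test_mean_tc_counts_invalid_as_zero(self):
        rep = breakdown([rec("CCO", "CCO"), rec("CCO", "C((")])
        expected = (1.0 + 0.0) / 2
        assert rep.mean_tc == pytest.approx(expected)

    def test_exactness_lower_bounded_by_string_exact(self, small_corpus):
        recs = [rec(r.smiles, r.smiles) for r in small_corpus[:10]]
        recs.append(rec("CCO", "CCC"))
        rep = breakdown(recs)
        for name in METRIC_NAMES:
            assert tanimoto_exactness(recs, name) >= rep.pct_string_exact - 1e-9


class TestBiasMatrix:
    def test_perfect_row_is_all_100(self):
        df = bias_matrix({"perfect": PERFECT})
        assert list(df.columns) == list(METRIC_NAMES)
        assert (df.loc["perfect"] == 100.0).all()

    def test_cells_match_independent_exactness(self):
        df = bias_matrix({"toy": TOY})
        for name in METRIC_NAMES:
            assert df.loc["toy", name] == pytest.approx(
                tanimoto_exactness(TOY, name))

    def test_requires_at_least_one_model(self):
        with pytest.raises(ValueError):
            bias_matrix({})


class TestSignificanceThreshold:
    def test_identical_corpus_threshold_is_one(self):
        thr = significance_threshold(["CCO"] * 5, "AEs", p=0.01, n_pairs=100, seed=0)
        assert thr.tc_threshold == 1.0

    def test_p_one_gives_minimum(self, small_corpus):
        smiles = [r.smiles for r in small_corpus[:30]]
        thr = significance_threshold(smiles, "AEs", p=1.0, n_pairs=200, seed=1)
        rng = random.Random(1)
        from fp2mol.fingerprints import tanimoto, to_feature_set
        fps = [to_feature_set(s, "AEs") for s in smiles]
        vals = []
        for _ in range(200):
            i, j = rng.sample(range(len(fps)), 2)
            vals.append(tanimoto(fps[i], fps[j]))
        assert thr.tc_threshold == min(vals)

    def test_matches_bruteforce_quantile(self, small_corpus):
        smiles = [r.smiles for r in small_corpus[:40]]
        thr = significance_threshold(smiles, "ECFP4", p=0.01, n_pairs=1000, seed=7)
        rng = random.Random(7)
        from fp2mol.fingerprints import tanimoto, to_feature_set
        fps = [to_feature_set(s, "ECFP4") for s in smiles]
        vals = sorted(tanimoto(*rng.sample(fps, 2)) for _ in range(1000))
        assert thr.tc_threshold == vals[990]

    def test_monotone_non_increasing_in_p(self, small_corpus):
        smiles = [r.smiles for r in small_corpus[:30]]
        thresholds = [
            significance_threshold(smiles, "AEs", p=p, n_pairs=500, seed=3).tc_threshold
            for p in (0.01, 0.05, 0.25, 1.0)
        ]
        assert thresholds == sorted(thresholds, reverse=True)

    def test_exceedance_bounded_by_p(self, small_corpus):
        smiles = [r.smiles for r in small_corpus[:40]]
        thr = significance_threshold(smiles, "AEs", p=0.05, n_pairs=1000, seed=9)
        rng = random.Random(9)
        from fp2mol.fingerprints import tanimoto, to_feature_set
        fps = [to_feature_set(s, "AEs") for s in smiles]
        vals = [tanimoto(*rng.sample(fps, 2)) for _ in range(1000)]
        exceed = sum(v > thr.tc_threshold for v in vals) / len(vals)
        assert exceed <= 0.05 + 0.01

    def test_tiny_corpus_raises(self):
        with pytest.raises(ValueError):
            significance_threshold(["CCO"], "AEs")


class TestStereoErrorProfile:
    def test_reversed_double_bond(self):
        prof = stereo_error_profile([rec("C/C=C/C", "C/C=C\\C")])
        assert prof["reversed"] == 1

    def test_reversed_center(self):
        prof = stereo_error_profile([rec("C[C@H](N)C(=O)O", "C[C@@H](N)C(=O)O")])
        assert prof["reversed"] == 1

    def test_missing_stereo_in_prediction(self):
        prof = stereo_error_profile([rec("C[C@H](N)C(=O)O", "CC(N)C(=O)O")])
        assert prof["missing"] == 1

    def test_spurious_stereo_in_prediction(self):
        prof = stereo_error_profile([rec("CC(N)C(=O)O", "C[C@H](N)C(=O)O")])
        assert prof["spurious"] == 1

    def test_ignores_non_stereo_records(self):
        prof = stereo_error_profile([rec("CCO", "CCO"), rec("CCO", "CCC")])
        assert sum(prof.values()) == 0
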