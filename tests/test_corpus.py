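"""Synthetic corpus: generation, filtering, diversity selection, splitting."""

import pytest
from rdkit import Chem

from fp2mol import corpus
from fp2mol.corpus import CorpusConfig, MoleculeRecord
from fp2mol.fingerprints import morgan_sparse_keys


def _rec(smiles, rid="X"):
    mol = Chem.MolFromSmiles(smiles)
    can = Chem.MolToSmiles(mol)
    return MoleculeRecord(rid, can, mol.GetNumHeavyAtoms(),
                          "@" in can or "/" in can or "\\" in can)


class TestGenerate:
    def test_empty_request(self):
        assert corpus.generate_molecules(CorpusConfig(n_molecules=0)) == []

    def test_fixed_seed_determinism(self):
        cfg = CorpusConfig(n_molecules=100, seed=7)
        assert corpus.generate_molecules(cfg) == corpus.generate_molecules(cfg)

    def test_records_are_valid_and_canonical(self, small_corpus):
        for rec in small_corpus[:50]:
            mol = Chem.MolFromSmiles(rec.smiles)
            assert mol is not None
            assert Chem.MolToSmiles(mol) == rec.smiles
            assert mol.GetNumHeavyAtoms() == rec.heavy_atoms
            has = "@" in rec.smiles or "/" in rec.smiles or "\\" in rec.smiles
            assert rec.has_stereo == has

    def test_stereo_fraction_near_target(self, small_corpus):
        frac = sum(r.has_stereo for r in small_corpus) / len(small_corpus)
        assert abs(frac - 0.3) <= 0.1

    def test_respects_heavy_atom_cap(self, small_corpus):
        assert corpus.filter_by_heavy_atoms(small_corpus, 50) == small_corpus

    def test_unique_canonical_smiles(self, small_corpus):
        smiles = [r.smiles for r in small_corpus]
        assert len(set(smiles)) == len(smiles)

    def test_exhaustion_raises(self):
        cfg = CorpusConfig(n_molecules=500, max_generation_attempts=10, seed=0)
        with pytest.raises(corpus.GenerationExhausted):
            corpus.generate_molecules(cfg)


class TestHeavyAtomFilter:
    def test_cap_is_inclusive(self):
        at_cap = _rec("C" * 50)
        assert at_cap.heavy_atoms == 50
        assert corpus.filter_by_heavy_atoms([at_cap], 50) == [at_cap]

    def test_above_cap_removed(self):
        over = _rec("C" * 51)
        assert corpus.filter_by_heavy_atoms([over], 50) == []

    def test_empty_input(self):
        assert corpus.filter_by_heavy_atoms([], 50) == []

    def test_preserves_order(self, small_corpus):
        kept = corpus.filter_by_heavy_atoms(small_corpus, 15)
        assert kept == [r for r in small_corpus if r.heavy_atoms <= 15]


class TestDiversitySelection:
    def test_identical_candidates_add_nothing(self):
        base = [_rec("CCO")]
        cands = [_rec("CCO", f"C{i}") for i in range(5)]
        assert corpus.select_diverse_by_atom_types(cands, base, 5) == []

    def test_matches_bruteforce_greedy(self, small_corpus):
        base, cands = small_corpus[:5], small_corpus[5:25]
        got = corpus.select_diverse_by_atom_types(cands, base, 10)

        # independent greedy recomputation of marginal coverage
        covered = set()
        for r in base:
            covered |= morgan_sparse_keys(r.smiles, 0)
        pool = list(cands)
        expect = []
        for _ in range(10):
            gains = [len(morgan_sparse_keys(r.smiles, 0) - covered) for r in pool]
            if not pool or max(gains) == 0:
                break
            best = pool[gains.index(max(gains))]
            expect.append(best)
            covered |= morgan_sparse_keys(best.smiles, 0)
            pool.remove(best)
        assert got == expect

    def test_coverage_beats_random_subsets(self, small_corpus):
        import itertools
        cands = small_corpus[:8]
        k = 3
        sel = corpus.select_diverse_by_atom_types(cands, [], k)

        def coverage(rs):
            cov = set()
            for r in rs:
                cov |= morgan_sparse_keys(r.smiles, 0)
            return len(cov)

        best_random = max(coverage(c) for c in itertools.combinations(cands, min(k, len(sel))))
        assert coverage(sel) >= best_random or len(sel) < k


class TestSplit:
    def test_zero_test_size(self, small_corpus):
        sp = corpus.split_corpus(small_corpus, 0, seed=1)
        assert sp.train == small_corpus and sp.test == []

    def test_deterministic(self, small_corpus):
        a = corpus.split_corpus(small_corpus, 15, seed=3)
        b = corpus.split_corpus(small_corpus, 15, seed=3)
        assert a.train == b.train and a.test == b.test

    def test_partitions_disjoint_and_complete(self, small_corpus):
        sp = corpus.split_corpus(small_corpus, 30, seed=5)
        train_s = {r.smiles for r in sp.train}
        test_s = {r.smiles for r in sp.test}
        assert not train_s & test_s
        assert len(sp.train) + len(sp.test) == len(small_corpus)

    def test_out_of_range_raises(self, small_corpus):
        with pytest.raises(ValueError):
            corpus.split_corpus(small_corpus, len(small_corpus) + 1, seed=0)


def test_smiles_file_roundtrip(tmp_path, small_corpus):
    path = tmp_path / "corpus.smi"
    corpus.write_smiles_file(small_corpus[:20], path)
    back = corpus.read_smiles_file(path)
    assert [r.smiles for r in back] == [r.smiles for r in small_corpus[:20]]
    assert [r.id for r in back] == [r.id for r in small_corpus[:20]]
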