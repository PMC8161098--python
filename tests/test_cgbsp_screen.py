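from decimal import Decimal, getcontext

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cgbscreen.cgbfp import CGBFP, TargetPanel
from cgbscreen.cgbsp_screen import (
    compare_profiles,
    cosine,
    mean_structural_similarity,
    morgan_fingerprint,
    nn_score,
    rank_library,
    tanimoto,
)
from cgbscreen.chem_io import Compound, FingerprintMatrix


def cosine_oracle(a, b):
    """Arbitrary-precision cosine for integer vectors."""
    getcontext().prec = 60
    dot = sum(int(x) * int(y) for x, y in zip(a, b))
    aa = sum(int(x) * int(x) for x in a)
    bb = sum(int(y) * int(y) for y in b)
    if aa == 0 or bb == 0:
        return 0.0
    return float(Decimal(dot) / (Decimal(aa).sqrt() * Decimal(bb).sqrt()))


def _panel(n):
    ids = tuple(f"t{i}" for i in range(n))
    return TargetPanel(ids, dict.fromkeys(ids, 1), 1)


def _fp(cid, values, panel=None):
    values = np.asarray(values, dtype=float)
    return CGBFP(cid, panel or _panel(len(values)), values)


class TestCosine:
    def test_orthogonal(self):
        assert cosine(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_scale_invariance(self):
        assert cosine(np.array([2.0, 2.0]), np.array([1.0, 1.0])) == pytest.approx(1.0)

    def test_zero_vector_scores_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert cosine(np.zeros(3), np.ones(3)) == 0.0
        assert any("zero-norm" in r.message for r in caplog.records)

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError):
            cosine(np.ones(2), np.ones(3))

    def test_matches_arbitrary_precision_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            a = rng.integers(0, 1000, n)
            b = rng.integers(0, 1000, n)
            assert cosine(a.astype(float), b.astype(float)) == pytest.approx(
                cosine_oracle(a, b), abs=1e-12
            )

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=2, max_size=50),
        st.floats(0.1, 10.0),
    )
    def test_symmetry_bounds_and_scaling(self, vals, scale):
        a = np.array(vals)
        b = np.roll(a, 1)
        s1, s2 = cosine(a, b), cosine(b, a)
        assert s1 == s2
        assert -1e-12 <= s1 <= 1 + 1e-12
        assert cosine(scale * a, b) == pytest.approx(s1, abs=1e-9)


class TestNnScore:
    def test_identical_reference_wins(self):
        q = _fp("q", [0.1, 0.9, 0.3])
        refs = [_fp("r1", [0.9, 0.1, 0.2]), _fp("r2", [0.1, 0.9, 0.3])]
        score, rid = nn_score(q, refs)
        assert score == pytest.approx(1.0)
        assert rid == "r2"

    def test_single_reference_equals_cosine(self):
        q = _fp("q", [0.5, 0.5])
        r = _fp("r", [0.2, 0.9])
        score, rid = nn_score(q, [r])
        assert score == pytest.approx(cosine(q.values, r.values))

    def test_tie_breaks_to_smallest_id(self):
        q = _fp("q", [1.0, 0.0])
        refs = [_fp("zz", [0.5, 0.0]), _fp("aa", [0.7, 0.0])]
        _, rid = nn_score(q, refs)
        assert rid == "aa"

    def test_matches_brute_force_max(self):
        rng = np.random.default_rng(2)
        panel = _panel(30)
        refs = [_fp(f"r{i:02d}", rng.random(30), panel) for i in range(20)]
        q = _fp("q", rng.random(30), panel)
        score, _ = nn_score(q, refs)
        assert score == pytest.approx(max(cosine(q.values, r.values) for r in refs))

    def test_no_references_error(self):
        with pytest.raises(ValueError):
            nn_score(_fp("q", [1.0]), [])

    def test_panel_mismatch_error(self):
        q = _fp("q", [1.0, 0.0])
        other = TargetPanel(("x", "y"), {"x": 1, "y": 1}, 1)
        with pytest.raises(ValueError, match="panel"):
            nn_score(q, [_fp("r", [1.0, 0.0], other)])


class TestRankLibrary:
    def _library(self, rng, n, p=10):
        vals = rng.random((n, p))
        return FingerprintMatrix([f"c{i:04d}" for i in range(n)], [f"t{i}" for i in range(p)], vals)

    def test_references_rank_first_when_present(self):
        rng = np.random.default_rng(3)
        lib = self._library(rng, 50)
        panel = _panel(10)
        refs = [_fp("r", lib.values[7], panel)]
        hits = rank_library(lib, refs, top_k=5)
        assert hits[0].compound_id == "c0007"
        assert hits[0].cgbsp_score == pytest.approx(1.0)
        assert [h.rank for h in hits] == [1, 2, 3, 4, 5]

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(4)
        lib = self._library(rng, 100)
        panel = _panel(10)
        refs = [_fp(f"r{i}", rng.random(10), panel) for i in range(5)]
        hits = rank_library(lib, refs, top_k=40)
        brute = []
        for i, cid in enumerate(lib.row_ids):
            s = max(cosine(lib.values[i], r.values) for r in refs)
            brute.append((cid, s))
        brute.sort(key=lambda t: (-t[1], t[0]))
        assert [h.compound_id for h in hits] == [cid for cid, _ in brute[:40]]
        for h, (_, s) in zip(hits, brute):
            assert h.cgbsp_score == pytest.approx(s, abs=1e-12)

    def test_tied_scores_ordered_by_id(self):
        panel = _panel(2)
        lib = FingerprintMatrix(["b", "a"], ["t0", "t1"], np.array([[0.5, 0.5], [0.5, 0.5]]))
        hits = rank_library(lib, [_fp("r", [1.0, 1.0], panel)], top_k=2)
        assert [h.compound_id for h in hits] == ["a", "b"]

    def test_top_k_exceeding_library_returns_all(self, caplog):
        rng = np.random.default_rng(5)
        lib = self._library(rng, 10)
        panel = _panel(10)
        with caplog.at_level("WARNING"):
            hits = rank_library(lib, [_fp("r", rng.random(10), panel)], top_k=99)
        assert len(hits) == 10


class TestMorganTanimoto:
    def test_identical_molecules_identical_bits(self):
        a = morgan_fingerprint(Compound.from_smiles("a", "CC(=O)O"))
        b = morgan_fingerprint(Compound.from_smiles("b", "OC(C)=O"))
        assert a == b
        assert tanimoto(a, b) == 1.0

    def test_different_molecules_differ(self):
        a = morgan_fingerprint(Compound.from_smiles("a", "C"))
        b = morgan_fingerprint(Compound.from_smiles("b", "CCO"))
        assert tanimoto(a, b) < 1.0

    def test_radius_zero_counts_atom_environments(self):
        # all six benzene atoms share one radius-0 environment;
        # butane has exactly two (terminal and inner carbons)
        from rdkit.Chem import rdFingerprintGenerator

        gen = rdFingerprintGenerator.GetMorganGenerator(radius=0, fpSize=2048)
        benzene = gen.GetCountFingerprintAsNumPy(Compound.from_smiles("b", "c1ccccc1").mol())
        assert (benzene > 0).sum() == 1 and benzene.sum() == 6
        butane = gen.GetCountFingerprintAsNumPy(Compound.from_smiles("u", "CCCC").mol())
        assert (butane > 0).sum() == 2 and sorted(butane[butane > 0]) == [2, 2]

    def test_tanimoto_matches_popcount_oracle(self):
        from rdkit.DataStructs import ExplicitBitVect

        rng = np.random.default_rng(6)
        for _ in range(1000):
            a_bits = rng.random(256) < 0.1
            b_bits = rng.random(256) < 0.1
            a, b = ExplicitBitVect(256), ExplicitBitVect(256)
            for i in np.flatnonzero(a_bits):
                a.SetBit(int(i))
            for i in np.flatnonzero(b_bits):
                b.SetBit(int(i))
            union = np.sum(a_bits | b_bits)
            expected = 0.0 if union == 0 else np.sum(a_bits & b_bits) / union
            assert tanimoto(a, b) == pytest.approx(expected, abs=1e-12)

    def test_both_empty_scores_zero(self):
        from rdkit.DataStructs import ExplicitBitVect

        assert tanimoto(ExplicitBitVect(16), ExplicitBitVect(16)) == 0.0


class TestCompareProfiles:
    def test_self_comparison_is_one_one(self):
        c = Compound.from_smiles("c", "c1ccccc1O")
        fp = _fp("c", [0.2, 0.8, 0.4])
        out = compare_profiles(c, fp, c, fp)
        assert out.cgbsp_score == pytest.approx(1.0)
        assert out.morgan_tanimoto == 1.0

    def test_orthogonal_and_disjoint_is_zero_zero(self):
        a = Compound.from_smiles("a", "CCCC")
        b = Compound.from_smiles("b", "c1ccncc1")
        out = compare_profiles(a, _fp("a", [1.0, 0.0]), b, _fp("b", [0.0, 1.0]))
        assert out.cgbsp_score == 0.0
        assert out.morgan_tanimoto == 0.0

    def test_scaffold_hop_pair_profile_beats_structure(self, toy_model, toy_universe, toy_panel):
        """A binder sharing the target's preferred substituents on a different
        scaffold should look similar in profile space but not in Morgan space."""
        from cgbscreen import synthetic_data

        bench = synthetic_data.make_scaffold_hop_benchmark(
            toy_universe, seed=11, library_size=80, n_hops=10, n_lookalikes=10, n_references=5
        )
        from cgbscreen.cgbfp import fingerprint

        ref = bench.references[0]
        hop = next(c for c in bench.library if bench.roles[c.id] == "hop")
        ref_fp = fingerprint(toy_model, ref, toy_panel, toy_universe.targets)
        hop_fp = fingerprint(toy_model, hop, toy_panel, toy_universe.targets)
        out = compare_profiles(hop, hop_fp, ref, ref_fp)
        assert out.cgbsp_score > out.morgan_tanimoto


class TestProfilePlot:
    def test_plot_written(self, tmp_path):
        from cgbscreen.cgbsp_screen import plot_profile_comparison

        hit = Compound.from_smiles("h", "CCO")
        ref = Compound.from_smiles("r", "CCN")
        hfp, rfp = _fp("h", [0.2, 0.9, 0.1]), _fp("r", [0.3, 0.8, 0.2])
        out = compare_profiles(hit, hfp, ref, rfp)
        path = tmp_path / "cmp.png"
        plot_profile_comparison(out, hfp, rfp, path)
        assert path.stat().st_size > 0


class TestMeanStructuralSimilarity:
    def test_self_library(self):
        c = Compound.from_smiles("c", "CCO")
        assert mean_structural_similarity(c, [c]) == 1.0

    def test_average_of_two(self):
        ref = Compound.from_smiles("r", "CCO")
        twin = Compound.from_smiles("t", "OCC")
        other = Compound.from_smiles("o", "c1ccncc1")
        got = mean_structural_similarity(ref, [twin, other])
        s_other = tanimoto(morgan_fingerprint(ref), morgan_fingerprint(other))
        assert got == pytest.approx((1.0 + s_other) / 2)

    def test_matches_looped_oracle(self):
        rng = np.random.default_rng(8)
        from cgbscreen.synthetic_data import SCAFFOLDS, make_compound

        names = list(SCAFFOLDS)
        lib = [
            make_compound(
                f"m{i}",
                names[int(rng.integers(0, len(names)))],
                [int(s) for s in rng.choice(16, size=2, replace=False)],
                rng,
            )
            for i in range(100)
        ]
        ref = lib[0]
        expected = np.mean(
            [tanimoto(morgan_fingerprint(ref), morgan_fingerprint(c)) for c in lib]
        )
        assert mean_structural_similarity(ref, lib) == pytest.approx(expected, abs=1e-12)
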