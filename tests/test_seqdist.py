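"""Distance computation, concatenation frame, and NJ utilities."""

import math

import numpy as np
import pytest

from endosym import seqdist
from endosym.mlst import WOLBACHIA_SCHEME
from endosym.seqdist import (
    DistanceMatrix,
    SaturationError,
    concatenate,
    distance_matrix,
    jc_correct,
    mean_pairwise,
    nj_tree,
    p_distance,
)

LOCUS_ORDER = [(d.name, d.length) for d in WOLBACHIA_SCHEME]


class TestPDistance:
    @pytest.mark.parametrize(
        "a, b, p, valid",
        [
            ("ACGT", "ACGA", 0.25, 4),
            ("AC-T", "ACGT", 0.0, 3),  # gap excluded pairwise
            ("ACNT", "ACGT", 0.0, 3),  # ambiguity excluded
            ("AAAA", "AAAA", 0.0, 4),
        ],
    )
    def test_examples(self, a, b, p, valid):
        pd = p_distance(a, b)
        assert pd.p == pytest.approx(p)
        assert pd.valid_sites == valid

    def test_matches_site_loop_oracle(self, rng):
        alphabet = list("ACGT-N")
        a = "".join(rng.choice(alphabet, size=1000))
        b = "".join(rng.choice(alphabet, size=1000))
        mism = valid = 0
        for x, y in zip(a, b):
            if x in "ACGT" and y in "ACGT":
                valid += 1
                mism += x != y
        pd = p_distance(a, b)
        assert pd.valid_sites == valid
        assert pd.p == pytest.approx(mism / valid)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            p_distance("ACGT", "ACG")

    def test_all_invalid_rejected(self):
        with pytest.raises(ValueError, match="valid"):
            p_distance("NN--", "ACGT")


class TestJukesCantor:
    def test_zero(self):
        assert jc_correct(0.0) == 0.0

    def test_closed_form_value(self):
        # -(3/4) ln(1 - 0.4/3) evaluated to high precision
        assert jc_correct(0.10) == pytest.approx(0.1073256327, abs=1e-9)

    def test_saturation_boundary(self):
        with pytest.raises(SaturationError):
            jc_correct(0.75)

    def test_strictly_increasing_and_convex(self):
        grid = np.linspace(0, 0.74, 200)
        d = np.array([jc_correct(p) for p in grid])
        assert np.all(np.diff(d) > 0)
        assert np.all(np.diff(d, 2) > -1e-12)
        # d >= p everywhere, d -> p as p -> 0
        assert np.all(d >= grid - 1e-15)
        assert jc_correct(1e-6) == pytest.approx(1e-6, rel=1e-3)


class TestConcatenation:
    def test_scheme_frame(self):
        per_locus = {
            name: {"s": "A" * length} for name, length in LOCUS_ORDER
        }
        concat, cmap = concatenate(per_locus, LOCUS_ORDER)
        assert len(concat["s"]) == 2079
        assert cmap.total_length == 2079
        assert cmap.spans["coxA"] == (370, 771)

    def test_single_locus_identity(self):
        concat, cmap = concatenate({"x": {"s": "ACGT"}}, [("x", 4)])
        assert concat["s"] == "ACGT"
        assert cmap.spans["x"] == (1, 4)

    def test_coordinate_round_trip_exhaustive(self):
        _, cmap = concatenate(
            {name: {"s": "A" * length} for name, length in LOCUS_ORDER},
            LOCUS_ORDER,
        )
        for pos in range(1, cmap.total_length + 1):
            locus, off = cmap.locus_of(pos)
            assert cmap.to_concat(locus, off) == pos

    def test_missing_locus_named(self):
        with pytest.raises(ValueError, match="coxA"):
            concatenate({"gatB": {"s": "A" * 369}}, LOCUS_ORDER[:2])


class TestDistanceMatrix:
    def test_identical_set_zero(self):
        dm = distance_matrix({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        assert np.all(dm.values == 0)

    def test_hand_computed(self):
        seqs = {"a": "AAAAAAAAAA", "b": "AAAAACAAAA", "c": "CCAAACAAAA"}
        dm = distance_matrix(seqs, model="p")
        assert dm.pair("a", "b") == pytest.approx(0.1)
        assert dm.pair("a", "c") == pytest.approx(0.3)
        assert dm.pair("b", "c") == pytest.approx(0.2)

    def test_jc_dominates_p(self, rng):
        seqs = {
            f"s{i}": "".join(rng.choice(list("ACGT"), size=300))
            for i in range(4)
        }
        p = distance_matrix(seqs, model="p")
        jc = distance_matrix(seqs, model="jc")
        ok = ~np.isnan(jc.values)
        assert np.all(jc.values[ok] >= p.values[ok] - 1e-12)

    def test_order_invariance(self, rng):
        base = rng.choice(list("ACGT"), size=120)
        seqs = {}
        for i in range(5):  # related sequences, no saturated pairs
            s = base.copy()
            hit = rng.choice(120, size=20, replace=False)
            s[hit] = rng.choice(list("ACGT"), size=20)
            seqs[f"s{i}"] = "".join(s)
        a = distance_matrix(seqs)
        b = distance_matrix(dict(reversed(list(seqs.items()))))
        for x in seqs:
            for y in seqs:
                if x != y:
                    assert a.pair(x, y) == pytest.approx(b.pair(x, y))

    def test_saturated_pair_flagged(self):
        # maximally divergent pair: p = 1 > 0.75
        dm = distance_matrix({"a": "A" * 40, "b": "C" * 40, "c": "A" * 40})
        assert ("a", "b") in dm.invalid_pairs
        assert math.isnan(dm.pair("a", "b"))


class TestMeanPairwise:
    def test_identical_pair_zero(self):
        dm = distance_matrix({"a": "ACGT", "b": "ACGT"})
        assert mean_pairwise(dm) == 0.0

    def test_arithmetic_identity(self):
        vals = np.array(
            [[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]]
        )
        dm = DistanceMatrix(["a", "b", "c"], vals)
        assert mean_pairwise(dm) == pytest.approx(0.2)

    def test_matches_brute_force(self, rng):
        n = 7
        m = np.round(rng.random((n, n)), 3)
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        dm = DistanceMatrix([f"t{i}" for i in range(n)], m)
        expected = sum(
            m[i, j] for i in range(n) for j in range(i + 1, n)
        ) / (n * (n - 1) / 2)
        assert mean_pairwise(dm) == pytest.approx(expected)

    def test_invalid_entries_guarded(self):
        dm = distance_matrix({"a": "A" * 40, "b": "C" * 40, "c": "A" * 40})
        with pytest.raises(ValueError, match="saturated"):
            mean_pairwise(dm)
        with pytest.warns(UserWarning):
            assert mean_pairwise(dm, exclude_invalid=True) >= 0


class TestNeighborJoining:
    def test_additive_four_taxon_recovery(self):
        # tree: ((a:2,b:3):1,(c:4,d:5)); additive distances below
        labels = ["a", "b", "c", "d"]
        vals = np.array(
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 0, 0],
            ],
            dtype=float,
        )
        vals[2, 3] = vals[3, 2] = 9.0
        dm = DistanceMatrix(labels, vals)
        tree = nj_tree(dm)
        # NJ must reproduce the additive input exactly
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                if i < j:
                    d = tree.find(x).distance(tree.find(y))
                    assert d == pytest.approx(vals[i, j])

    def test_three_taxa(self):
        vals = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], vals))
        assert {t.name for t in tree.tips()} == {"a", "b", "c"}

    def test_label_permutation_invariance(self, rng):
        n = 6
        pts = rng.random((n, 2))
        m = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(n)]
        t1 = nj_tree(DistanceMatrix(labels, m))
        perm = rng.permutation(n)
        t2 = nj_tree(
            DistanceMatrix([labels[i] for i in perm], m[np.ix_(perm, perm)])
        )
        for i in range(n):
            for j in range(i + 1, n):
                a, b = labels[i], labels[j]
                assert t1.find(a).distance(t1.find(b)) == pytest.approx(
                    t2.find(a).distance(t2.find(b))
                )

    def test_too_few_labels(self):
        dm = distance_matrix({"a": "ACGT", "b": "AGGT"})
        with pytest.raises(ValueError):
            nj_tree(dm)
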