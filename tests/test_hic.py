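"""Contact-matrix I/O, backgrounds, normalization, correlation, clustering."""

import numpy as np
import pytest

from oracles import brute_overall_background, brute_pearson
from schpipe.errors import AnalysisError, FormatError
from schpipe.hic import (
    diagonal_normalize,
    gene_level_background,
    gene_pair_contact,
    hic_cluster,
    overall_background,
    pcc_matrix,
    proximity_test,
    read_contact_matrix,
    write_contact_matrix,
)

from conftest import make_contact, toy_annotation


class TestContactIO:
    def test_coo_single_triple_masks_unseen_bin(self, tmp_path):
        p = tmp_path / "c.coo.tsv"
        p.write_text("0\t1\t5\n")
        cm = read_contact_matrix(p, "coo", n_bins=3)
        assert cm.mask.tolist() == [False, False, True]
        assert cm.matrix[0, 1] == 5 and cm.matrix[1, 0] == 5
        assert np.isnan(cm.matrix[2, 2])

    def test_dense_asymmetric_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("0\t1\n2\t0\n")
        with pytest.raises(FormatError, match="symmetric"):
            read_contact_matrix(p, "dense")

    def test_coo_bad_index_rejected(self, tmp_path):
        p = tmp_path / "c.coo.tsv"
        p.write_text("0\t9\t5\n")
        with pytest.raises(FormatError, match="out of range"):
            read_contact_matrix(p, "coo", n_bins=3)

    def test_dense_coo_round_trip(self, tmp_path, rng):
        m = rng.poisson(5, (6, 6)).astype(float)
        m = np.triu(m) + np.triu(m, 1).T
        cm = make_contact(m)
        write_contact_matrix(cm, tmp_path / "d.tsv", "dense")
        write_contact_matrix(cm, tmp_path / "c.tsv", "coo")
        dense = read_contact_matrix(tmp_path / "d.tsv", "dense")
        coo = read_contact_matrix(tmp_path / "c.tsv", "coo", n_bins=6)
        np.testing.assert_allclose(dense.matrix, cm.matrix)
        # COO omits zeros; compare where the original was nonzero
        nz = cm.matrix != 0
        np.testing.assert_allclose(coo.matrix[nz], cm.matrix[nz])


class TestOverallBackground:
    def test_hand_values(self):
        cm = make_contact([[1, 2, 3], [2, 4, 5], [3, 5, 6]])
        bg = overall_background(cm)
        assert bg.at(1) == pytest.approx(3.5)  # mean(2, 5)
        assert bg.at(2) == pytest.approx(3.0)
        assert bg.counts[1] == 2 and bg.counts[2] == 1

    def test_constant_matrix(self):
        bg = overall_background(make_contact(np.full((4, 4), 7.0)))
        assert all(bg.at(d) == 7.0 for d in range(4))

    def test_matches_brute_force_on_random_matrices(self, rng):
        """Exact agreement with a double-loop oracle on 30 random 50x50
        matrices, including masked columns."""
        for k in range(30):
            m = rng.poisson(4, (50, 50)).astype(float)
            m = np.triu(m) + np.triu(m, 1).T
            mask = np.zeros(50, dtype=bool)
            if k % 3 == 0:
                mask[rng.choice(50, 4, replace=False)] = True
                m[mask, :] = np.nan
                m[:, mask] = np.nan
            bg = overall_background(make_contact(m, mask=mask))
            expect = brute_overall_background(m)
            for d in range(50):
                if d in expect:
                    assert bg.at(d) == pytest.approx(expect[d], abs=0)
                else:
                    assert np.isnan(bg.at(d))


class TestGeneLevelBackground:
    def test_two_genes_single_pair(self):
        cm = make_contact([[1, 2, 3], [2, 4, 5], [3, 5, 6]])
        ann = toy_annotation([("g1", "chr1", 100), ("g2", "chr1", 80_100)])
        bg = gene_level_background(cm, ann)  # bins 0 and 2, entry [0, 2] = 3
        assert bg.at(2) == pytest.approx(3.0)
        assert bg.counts.sum() == 1

    def test_all_genes_one_bin_only_d0(self):
        cm = make_contact([[1, 2], [2, 8]])
        ann = toy_annotation([("g1", "chr1", 100), ("g2", "chr1", 200)])
        bg = gene_level_background(cm, ann)
        assert bg.at(0) == pytest.approx(1.0)
        assert np.isnan(bg.at(1))

    def test_equals_overall_when_bins_fully_covered(self, rng):
        n = 6
        m = rng.poisson(5, (n, n)).astype(float)
        m = np.triu(m) + np.triu(m, 1).T
        cm = make_contact(m, bin_size=1000)
        ann = toy_annotation([(f"g{b}", "chr1", b * 1000 + 10) for b in range(n)])
        ov = overall_background(cm)
        gl = gene_level_background(cm, ann)
        # every off-diagonal entry carries exactly one gene pair (d >= 1)
        for d in range(1, n):
            assert gl.at(d) == pytest.approx(ov.at(d))


class TestGenePairContact:
    ANN = toy_annotation(
        [("g1", "chr1", 100_000), ("g2", "chr1", 180_000), ("g3", "chr2", 100)]
    )

    def test_floor_arithmetic(self):
        m = np.zeros((6, 6))
        m[2, 4] = m[4, 2] = 9.0
        cm = make_contact(m)
        v, d = gene_pair_contact(cm, self.ANN, "g1", "g2")
        assert (v, d) == (9.0, 2)

    def test_identity_pair_is_diagonal(self):
        m = np.diag([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        v, d = gene_pair_contact(make_contact(m), self.ANN, "g1", "g1")
        assert d == 0 and v == 3.0

    def test_cross_chromosome_rejected(self):
        with pytest.raises(AnalysisError, match="inter-chromosomal"):
            gene_pair_contact(make_contact(np.zeros((6, 6))), self.ANN, "g1", "g3")

    def test_masked_bin_flagged_nan(self):
        m = np.zeros((6, 6))
        mask = np.zeros(6, dtype=bool)
        mask[4] = True
        m[:, 4] = m[4, :] = np.nan
        v, d = gene_pair_contact(make_contact(m, mask=mask), self.ANN, "g1", "g2")
        assert np.isnan(v) and d == 2


class TestProximityTest:
    def test_null_when_contacts_equal_background(self):
        cm = make_contact(np.full((5, 5), 4.0), bin_size=1000)
        ann = toy_annotation([(f"g{b}", "chr1", b * 1000 + 10) for b in range(5)])
        pairs = [("g0", "g2"), ("g1", "g3"), ("g0", "g4")]
        rep = proximity_test(pairs, {"chr1": cm}, ann)
        assert rep.p_vs_overall == pytest.approx(1.0)
        assert rep.mean_comut == pytest.approx(rep.mean_overall)

    def test_single_pair_rejected(self):
        cm = make_contact(np.full((5, 5), 4.0), bin_size=1000)
        ann = toy_annotation([("g0", "chr1", 10), ("g1", "chr1", 2010)])
        with pytest.raises(AnalysisError):
            proximity_test([("g0", "g1")], {"chr1": cm}, ann)

    def test_planted_pairs_above_background(self, small_dataset):
        from schpipe.comut import build_matrix, comutated_pairs

        m = build_matrix(small_dataset.mutation_records())
        rep = proximity_test(
            comutated_pairs(m), small_dataset.contact_maps, small_dataset.annotation
        )
        assert rep.p_vs_overall < 0.01 and rep.p_vs_gene_level < 0.01
        assert rep.mean_comut > rep.mean_overall
        assert rep.mean_comut > rep.mean_gene_level


class TestDiagonalNormalize:
    def test_constant_matrix_becomes_ones(self):
        nm = diagonal_normalize(make_contact(np.full((4, 4), 5.0)))
        np.testing.assert_allclose(nm.aprime, 1.0)

    def test_hand_example(self):
        nm = diagonal_normalize(make_contact([[1, 2], [2, 8]]))
        assert nm.aprime[0, 1] == pytest.approx(1.0)  # 2 / mean(2)
        assert nm.aprime[0, 0] == pytest.approx(1 / 4.5)

    def test_every_off_diagonal_has_unit_mean(self, rng):
        """Machine-precision normalization identity on 30 random matrices."""
        for _ in range(30):
            n = int(rng.integers(5, 40))
            m = rng.poisson(6, (n, n)).astype(float) + 0.5
            m = np.triu(m) + np.triu(m, 1).T
            nm = diagonal_normalize(make_contact(m))
            for d in range(n):
                diag = np.diagonal(nm.aprime, offset=d)
                assert np.nanmean(diag) == pytest.approx(1.0, abs=1e-12)


class TestPccMatrix:
    def test_duplicate_and_negated_columns(self):
        base = np.array(
            [[1.0, 1.0, -1.0, 0.3],
             [2.0, 2.0, -2.0, 0.1],
             [0.5, 0.5, -0.5, 0.9],
             [1.5, 1.5, -1.5, 0.2]]
        )
        nm = diagonal_normalize(make_contact(np.ones((4, 4))))
        nm.aprime = base
        out = pcc_matrix(nm)
        assert out.pcc[0, 1] == pytest.approx(1.0)
        assert out.pcc[0, 2] == pytest.approx(-1.0)

    def test_matches_textbook_oracle(self, rng):
        n = 8
        m = rng.poisson(9, (n, n)).astype(float)
        m = np.triu(m) + np.triu(m, 1).T
        nm = pcc_matrix(diagonal_normalize(make_contact(m)))
        for i in range(n):
            for j in range(i + 1, n):
                expect = brute_pearson(nm.aprime[:, i], nm.aprime[:, j])
                assert nm.pcc[i, j] == pytest.approx(expect, abs=1e-12)

    def test_masked_column_stays_masked(self):
        m = np.ones((5, 5)) + np.eye(5)
        mask = np.zeros(5, dtype=bool)
        mask[2] = True
        m[:, 2] = m[2, :] = np.nan
        out = pcc_matrix(diagonal_normalize(make_contact(m, mask=mask)))
        assert out.pcc_mask[2]
        assert np.isnan(out.pcc[2, 3])


class TestHicCluster:
    def _blocky(self, rng, n=60, blocks=((5, 15), (35, 45))):
        """Matrix with two high-contact blocks over a decaying background."""
        idx = np.arange(n)
        d = np.abs(idx[:, None] - idx[None, :])
        mu = 50.0 / (d + 1.0)
        for lo, hi in blocks:
            mu[lo:hi, lo:hi] *= 6.0
        m = rng.poisson(mu).astype(float)
        m = np.triu(m) + np.triu(m, 1).T
        return make_contact(m, bin_size=1000)

    def test_recovers_two_planted_blocks(self, rng):
        cm = self._blocky(rng)
        ann = toy_annotation(
            [(f"a{b}", "chr1", b * 1000 + 10) for b in range(6, 14)]
            + [(f"b{b}", "chr1", b * 1000 + 10) for b in range(36, 44)]
        )
        cs = hic_cluster(pcc_matrix(diagonal_normalize(cm)), ann)
        big = sorted([sorted(c) for c in cs.clusters if len(c) >= 2], key=len)[-2:]
        assert {g[0] for g in big[0]} | {g[0] for g in big[1]} == {"a", "b"}
        by_prefix = {c[0][0]: set(c) for c in big}
        assert by_prefix["a"] == {f"a{b}" for b in range(6, 14)}
        assert by_prefix["b"] == {f"b{b}" for b in range(36, 44)}

    def test_single_gene_is_singleton(self, rng):
        cm = self._blocky(rng)
        ann = toy_annotation([("g1", "chr1", 10_010)])
        cs = hic_cluster(pcc_matrix(diagonal_normalize(cm)), ann)
        assert cs.clusters == [["g1"]]

    def test_invariant_to_gene_input_order(self, rng):
        cm = self._blocky(rng)
        ann = toy_annotation(
            [(f"g{b}", "chr1", b * 1000 + 10) for b in (6, 40, 8, 37, 12, 40)]
            [: 5]
        )
        nm = pcc_matrix(diagonal_normalize(cm))
        a = hic_cluster(nm, ann)
        b = hic_cluster(nm, ann.iloc[::-1].reset_index(drop=True))
        assert sorted(map(sorted, a.clusters)) == sorted(map(sorted, b.clusters))
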