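"""Gene-sample matrix construction and Hamming seed clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import brute_hamming_similarity, brute_seed_cluster
from schpipe.comut import (
    GeneSampleMatrix,
    MutationRecord,
    build_matrix,
    hamming_similarity,
    read_mutations,
    seed_cluster,
    select_threshold,
)
from schpipe.errors import AnalysisError, DimensionError, FormatError

from conftest import make_contact, toy_annotation


def rec(sample, gene, pos=100, ref="A", alt="C", chrom="chr1"):
    return MutationRecord(sample, gene, chrom, pos, ref, alt)


class TestReadMutations:
    HEADER = "Tumor_Sample_Barcode\tHugo_Symbol\tChromosome\tStart_Position\tReference_Allele\tTumor_Seq_Allele2\n"

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(self.HEADER)
        assert read_mutations(p) == []

    def test_invalid_rows_dropped(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            self.HEADER
            + "s1\tg1\tchr1\t100\tA\tA\n"  # ref == alt
            + "s1\tg2\tchr1\t-5\tA\tC\n"  # bad position
            + "s1\tg3\tchr1\t100\tN\tC\n"  # ambiguous base
            + "s1\tg4\tchr1\t100\tA\tC\n"
        )
        records = read_mutations(p)
        assert [r.gene_id for r in records] == ["g4"]

    def test_missing_column_is_named(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("Tumor_Sample_Barcode\tHugo_Symbol\n")
        with pytest.raises(FormatError, match="Chromosome"):
            read_mutations(p)

    def test_synthetic_cohort_round_trip(self, small_dataset, tmp_path):
        p = tmp_path / "m.tsv"
        small_dataset.mutations.to_csv(p, sep="\t", index=False)
        assert len(read_mutations(p)) == len(small_dataset.mutations)


class TestBuildMatrix:
    def test_single_record(self):
        m = build_matrix([rec("s1", "g1")])
        assert m.matrix.tolist() == [[1]]
        assert m.gene_ids == ["g1"] and m.sample_ids == ["s1"]

    def test_duplicates_collapse_to_one(self):
        m = build_matrix([rec("s1", "g1", pos=10), rec("s1", "g1", pos=20)])
        assert m.matrix.tolist() == [[1]]

    def test_rank_order_by_mutated_sample_count(self):
        records = (
            [rec(f"s{i}", "gx") for i in range(5)]
            + [rec("s0", "gb"), rec("s1", "gb")]
            + [rec("s2", "ga"), rec("s3", "ga")]
        )
        m = build_matrix(records)
        # most-mutated first, count ties broken lexicographically
        assert m.gene_ids == ["gx", "ga", "gb"]

    def test_empty_input_rejected(self):
        with pytest.raises(AnalysisError):
            build_matrix([])


class TestHammingSimilarity:
    def test_hand_cases(self):
        assert hamming_similarity([1, 0, 1], [1, 0, 1]) == 1.0
        assert hamming_similarity([1, 1, 0, 0], [0, 0, 1, 1]) == 0.0
        assert hamming_similarity([1, 0, 1, 0], [1, 1, 1, 0], 4) == 0.75

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            hamming_similarity([1, 0], [1, 0, 1])

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(st.integers(0, 1), min_size=1, max_size=30),
        st.randoms(use_true_random=False),
    )
    def test_bounded_symmetric_and_identity(self, a, r):
        b = [r.randint(0, 1) for _ in a]
        s = hamming_similarity(a, b)
        assert 0.0 <= s <= 1.0
        assert s == hamming_similarity(b, a)
        assert (s == 1.0) == (a == b)


def _random_gsm(rng, n_genes=20, n_samples=10):
    mat = (rng.random((n_genes, n_samples)) < 0.3).astype(np.uint8)
    mat[mat.sum(axis=1) == 0, 0] = 1  # no all-zero rows
    records = [
        rec(f"s{j:02d}", f"g{i:02d}")
        for i in range(n_genes)
        for j in range(n_samples)
        if mat[i, j]
    ]
    return build_matrix(records)


class TestSeedCluster:
    def test_matches_independent_oracle_on_random_matrices(self, rng):
        """Greedy clustering equals a from-scratch reimplementation exactly,
        for every grid threshold on 20 random matrices."""
        for _ in range(20):
            m = _random_gsm(rng)
            rows = m.matrix.tolist()
            for t in [round(0.1 * k, 1) for k in range(1, 11)]:
                ours = seed_cluster(m, t).clusters
                expect = [
                    [m.gene_ids[i] for i in cl] for cl in brute_seed_cluster(rows, t)
                ]
                assert ours == expect

    def test_partition_property(self, rng):
        m = _random_gsm(rng)
        for t in (0.2, 0.5, 0.9):
            cs = seed_cluster(m, t)
            flat = [g for c in cs.clusters for g in c]
            assert sorted(flat) == sorted(m.gene_ids)
            assert len(flat) == len(set(flat))

    def test_all_singletons_when_no_pair_qualifies(self):
        m = build_matrix([rec("s1", "g1"), rec("s2", "g2"), rec("s3", "g3")])
        # rows differ pairwise; threshold 1.0 admits only identical rows
        cs = seed_cluster(m, 1.0)
        assert all(len(c) == 1 for c in cs.clusters)

    def test_two_identical_pairs_form_two_clusters(self):
        records = (
            [rec(s, "g1") for s in ("s1", "s2", "s3")]
            + [rec(s, "g2") for s in ("s1", "s2", "s3")]
            + [rec(s, "g3") for s in ("s4", "s5")]
            + [rec(s, "g4") for s in ("s4", "s5")]
        )
        m = build_matrix(records)
        cs = seed_cluster(m, 0.9)
        assert sorted(map(sorted, cs.clusters)) == [["g1", "g2"], ["g3", "g4"]]

    def test_invariant_to_sample_column_permutation(self, rng):
        m = _random_gsm(rng)
        perm = rng.permutation(m.n_sp)
        m2 = GeneSampleMatrix(m.matrix[:, perm], m.gene_ids, [m.sample_ids[p] for p in perm])
        assert seed_cluster(m, 0.7).clusters == seed_cluster(m2, 0.7).clusters


class TestSelectThreshold:
    def _setup(self, contact):
        # two tight co-mutation pairs on one chromosome
        records = (
            [rec(s, "g1") for s in ("s1", "s2", "s3")]
            + [rec(s, "g2") for s in ("s1", "s2", "s3")]
            + [rec(s, "g3") for s in ("s4", "s5")]
            + [rec(s, "g4") for s in ("s4", "s5")]
        )
        m = build_matrix(records)
        ann = toy_annotation(
            [("g1", "chr1", 100), ("g2", "chr1", 40_100),
             ("g3", "chr1", 120_100), ("g4", "chr1", 160_100)]
        )
        return m, {"chr1": contact}, ann

    def test_uninformative_contacts_give_p_one(self):
        cm = make_contact(np.full((5, 5), 3.0))
        m, maps, ann = self._setup(cm)
        _, grid = select_threshold(m, maps, ann)
        ok = grid.dropna(subset=["p"])
        assert (ok["p"] > 0.99).all()

    def test_informative_contacts_select_clustering_threshold(self):
        mat = np.full((5, 5), 1.0)
        mat[0, 1] = mat[1, 0] = 50.0  # g1-g2 pair in contact
        mat[3, 4] = mat[4, 3] = 50.0  # g3-g4 pair in contact
        m, maps, ann = self._setup(make_contact(mat))
        thr, grid = select_threshold(m, maps, ann)
        # at the selected threshold the pairs must be intra-cluster
        best = grid[grid["threshold"] == thr].iloc[0]
        assert best["mean_intra"] > best["mean_inter"]

    def test_planted_data_recovers_clusters(self, small_dataset):
        from schpipe.sch import gene_pairs

        m = build_matrix(small_dataset.mutation_records())
        thr, _ = select_threshold(
            m, small_dataset.contact_maps, small_dataset.annotation
        )
        clusters = seed_cluster(m, thr).clusters
        truth_pairs = gene_pairs(small_dataset.truth.truth_groups())
        found_pairs = gene_pairs(clusters)
        assert truth_pairs <= found_pairs
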