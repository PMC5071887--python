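"""Generator contracts: planted structure, determinism, statistical shape."""

import numpy as np
import pytest
from scipy import stats

from schpipe.config import SyntheticConfig
from schpipe.errors import ConfigError
from schpipe.signatures import TYPE_ORDER, mutation_type_of
from schpipe.synthetic import (
    generate_annotation,
    generate_contact_matrices,
    generate_ctcf_track,
    generate_mutation_cohort,
    generate_reference,
    simulate,
    write_dataset,
)


def cfg(**kw):
    base = dict(
        seed=0,
        n_chromosomes=2,
        bins_per_chromosome=60,
        bin_size=5_000,
        n_genes=40,
        n_samples=10,
        n_planted_hotspots=2,
        hotspot_size_min=4,
        hotspot_size_max=4,
        hotspot_block_bins=6,
        background_mut_prob=0.05,
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestConfigValidation:
    def test_probability_out_of_range(self):
        with pytest.raises(ConfigError):
            cfg(comut_prob=1.5)

    def test_hotspots_must_fit_gene_budget(self):
        with pytest.raises(ConfigError):
            cfg(n_genes=6, n_planted_hotspots=2, hotspot_size_min=4, hotspot_size_max=4)


class TestAnnotation:
    def test_zero_genes_zero_truth(self):
        ann, truth = generate_annotation(cfg(n_genes=0, n_planted_hotspots=0))
        assert len(ann) == 0 and truth.hotspots == []

    def test_forced_hotspot_membership(self):
        ann, truth = generate_annotation(cfg())
        assert len(truth.hotspots) == 2
        sets = [set(h.genes) for h in truth.hotspots]
        assert all(len(s) == 4 for s in sets)
        assert sets[0].isdisjoint(sets[1])

    def test_planted_genes_lie_in_their_block(self):
        _, truth = generate_annotation(cfg())
        for h in truth.hotspots:
            for g in h.genes:
                assert h.bin_lo <= truth.gene_bin(g) <= h.bin_hi

    def test_unique_ids_and_valid_tss(self):
        ann, _ = generate_annotation(cfg())
        assert ann["gene_id"].is_unique
        assert (ann["tss"] >= 1).all()
        assert (ann["strand"] == "+").all()

    def test_same_seed_same_bytes(self, tmp_path):
        from schpipe.io import write_annotation_bed

        for i, name in enumerate(("a.bed", "b.bed")):
            ann, _ = generate_annotation(cfg())
            write_annotation_bed(ann, tmp_path / name)
        assert (tmp_path / "a.bed").read_bytes() == (tmp_path / "b.bed").read_bytes()


class TestContacts:
    def test_symmetric_and_nonnegative(self):
        c = cfg()
        _, truth = generate_annotation(c)
        for cm in generate_contact_matrices(c, truth).values():
            np.testing.assert_array_equal(cm.matrix, cm.matrix.T)
            assert np.nanmin(cm.matrix) >= 0

    def test_flat_limit_without_noise(self):
        c = cfg(contact_boost=1.0, decay_exponent=0.0)
        _, truth = generate_annotation(c)
        cm = generate_contact_matrices(c, truth, noise="none")["chr1"]
        np.testing.assert_allclose(cm.matrix, c.contact_depth)

    def test_boosted_block_raised_before_noise(self):
        c = cfg(contact_boost=4.0)
        _, truth = generate_annotation(c)
        cm = generate_contact_matrices(c, truth, noise="none")[truth.hotspots[0].chrom]
        h = truth.hotspots[0]
        inside = cm.matrix[h.bin_lo, h.bin_hi]
        d = h.bin_hi - h.bin_lo
        outside_expected = c.contact_depth * (d + 1.0) ** (-c.decay_exponent)
        assert inside == pytest.approx(4.0 * outside_expected)

    def test_decay_matches_power_law_within_monte_carlo_error(self):
        """Mean off-diagonal decay over replicates tracks c*(d+1)^-1."""
        c = cfg(
            n_chromosomes=1, bins_per_chromosome=200, n_genes=10,
            n_planted_hotspots=0, decay_exponent=1.0,
        )
        _, truth = generate_annotation(c)
        reps = []
        for k in range(20):
            ck = SyntheticConfig(**{**c.to_dict(), "seed": k})
            cm = generate_contact_matrices(ck, truth)["chr1"]
            reps.append(
                [np.diagonal(cm.matrix, offset=d).mean() for d in range(0, 120, 10)]
            )
        reps = np.array(reps)
        mean = reps.mean(axis=0)
        ds = np.arange(0, 120, 10)
        expected = c.contact_depth * (ds + 1.0) ** (-1.0)
        # analytic Poisson Monte-Carlo SE of each grand mean
        n_entries = (200 - ds) * len(reps)
        se = np.sqrt(expected / n_entries)
        assert np.all(np.abs(mean - expected) <= 3 * se)

    def test_missing_fraction_masks_columns(self):
        c = cfg(missing_bin_fraction=0.1)
        _, truth = generate_annotation(c)
        cm = generate_contact_matrices(c, truth)["chr1"]
        assert cm.mask.sum() == round(0.1 * c.bins_per_chromosome)
        assert np.isnan(cm.matrix[cm.mask]).all()

    def test_too_few_bins_rejected(self):
        c = cfg()
        _, truth = generate_annotation(c)
        c.bins_per_chromosome = 1  # degrade after placement
        with pytest.raises(ConfigError):
            generate_contact_matrices(c, truth)


class TestCohort:
    def test_forced_record_count(self):
        c = cfg(
            n_genes=20, n_planted_hotspots=1, hotspot_size_min=3, hotspot_size_max=3,
            comut_prob=1.0, background_mut_prob=0.0, n_samples=5,
        )
        _, truth = generate_annotation(c)
        ref = generate_reference(c, truth)
        ann, truth = generate_annotation(c)  # regenerate consistently
        ref = generate_reference(c, truth)
        muts = generate_mutation_cohort(c, truth, ref, ann)
        assert len(muts) == 15  # 3 genes x 5 samples

    def test_empty_table_when_all_rates_zero(self):
        c = cfg(comut_prob=0.0, background_mut_prob=0.0)
        ann, truth = generate_annotation(c)
        ref = generate_reference(c, truth)
        muts = generate_mutation_cohort(c, truth, ref, ann)
        assert len(muts) == 0

    def test_full_concordance_forces_single_type_per_hotspot(self):
        c = cfg(signature_concordance=1.0, comut_prob=1.0, background_mut_prob=0.0)
        ann, truth = generate_annotation(c)
        ref = generate_reference(c, truth)
        muts = generate_mutation_cohort(c, truth, ref, ann)
        for h in truth.hotspots:
            sub = muts[muts["Hugo_Symbol"].isin(h.genes)]
            types = {
                mutation_type_of(r, a)
                for r, a in zip(sub["Reference_Allele"], sub["Tumor_Seq_Allele2"])
            }
            assert types == {h.mut_type}

    def test_ref_allele_matches_reference_and_alt_differs(self):
        ds = simulate(cfg())
        view = ds.reference_view()
        for r in ds.mutations.itertuples(index=False):
            base = view[r.Chromosome][r.Start_Position - 1 : r.Start_Position]
            assert base == r.Reference_Allele
            assert r.Reference_Allele != r.Tumor_Seq_Allele2


class TestTracksAndSets:
    def test_unboosted_signal_indistinguishable_at_hotspot_tss(self):
        c = cfg(ctcf_boost=1.0, bins_per_chromosome=100)
        _, truth = generate_annotation(c)
        t = generate_ctcf_track(c, truth)
        starts, ends, vals = t.data["chr1"]
        rng = np.random.default_rng(0)
        near = np.zeros(len(starts), dtype=bool)
        for g in truth.planted_genes:
            chrom, tss = truth.gene_tss[g]
            if chrom == "chr1":
                near |= (ends > tss - 2000) & (starts < tss + 2000)
        a = vals[near]
        b = rng.choice(vals[~near], size=200, replace=False)
        assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_flank_conservation_one_plants_exact_motifs(self):
        c = cfg(flank_conservation=1.0)
        _, truth = generate_annotation(c)
        ref = generate_reference(c, truth)
        for h in truth.hotspots:
            seq = ref[h.chrom]
            for g in h.genes:
                site = truth.gene_site[g]
                window = seq[site - 11 : site + 10].decode()
                assert window == h.motif

    def test_pathways_embed_hotspots(self):
        c = cfg(pathway_fraction=1.0)
        ds = simulate(c)
        for h in ds.truth.hotspots:
            assert any(set(h.genes) <= p for p in ds.pathways.values())


class TestDeterminism:
    def test_identical_seed_writes_identical_files(self, tmp_path):
        for name in ("runA", "runB"):
            write_dataset(simulate(cfg()), tmp_path / name)
        a, b = tmp_path / "runA", tmp_path / "runB"
        files = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
        assert files
        for f in files:
            assert (a / f).read_bytes() == (b / f).read_bytes(), f

    def test_different_seed_differs(self, tmp_path):
        a = simulate(cfg(seed=1))
        b = simulate(cfg(seed=2))
        assert not a.mutations.equals(b.mutations)
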