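"""Plate simulator: occupancy law, class signatures, determinism, spiking."""

import numpy as np
import pytest
from scipy import stats

from wellmut.simulate import (CLASS_ARTEFACT, CLASS_CLONAL,
                              CLASS_CLONE_SPECIFIC, CLASS_HET_SNP, SimConfig,
                              double_occupancy_poisson_limit,
                              double_occupancy_probability,
                              expected_occupied_wells, high_confidence_clonal_ids,
                              partition_locus, simulate_plate, simulate_variant,
                              spike_utds)
from wellmut.welldata import parse_joint_vcf, well_counts


class TestPartitioning:
    def test_exact_and_poisson_limit_agree(self):
        exact = double_occupancy_probability(60, 384)
        limit = double_occupancy_poisson_limit(60, 384)
        assert limit == pytest.approx(0.0761, abs=5e-4)
        assert exact == pytest.approx(limit, abs=2e-3)
        assert exact < 0.10  # the design target of the template load

    def test_monte_carlo_matches_closed_form(self, rng):
        n_trials = 20000
        occ = dbl = 0
        for _ in range(n_trials // 500):
            counts = rng.multinomial(60, np.full(384, 1 / 384), size=500)
            occ += int((counts >= 1).sum())
            dbl += int((counts >= 2).sum())
        p_hat = dbl / occ
        p = double_occupancy_probability(60, 384)
        se = np.sqrt(p * (1 - p) / occ)
        assert abs(p_hat - p) < 3 * se

    def test_copies_conserved_and_zero_case(self, rng):
        counts = partition_locus(60, 384, rng)
        assert counts.sum() == 60
        assert partition_locus(0, 384, rng).sum() == 0

    def test_occupancy_expectation(self, rng):
        expect = expected_occupied_wells(30, 384)
        assert expect == pytest.approx(28.9, abs=0.1)
        occupied = [(partition_locus(30, 384, rng) > 0).sum() for _ in range(500)]
        assert np.mean(occupied) == pytest.approx(expect, abs=3 * np.std(occupied) / np.sqrt(500))

    def test_occupancy_chi2_goodness_of_fit(self, rng):
        """Per-well counts follow Binomial(copies, 1/n) under multinomial."""
        counts = rng.multinomial(60, np.full(384, 1 / 384), size=30).ravel()
        k = np.arange(counts.max() + 1)
        expected = stats.binom.pmf(k, 60, 1 / 384) * counts.size
        observed = np.bincount(counts, minlength=k.size)
        keep = expected > 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 1e-3


class TestVariantClasses:
    def test_artefact_is_dual_allelic_single_well(self, rng):
        cfg = SimConfig(artefact_contaminated_fraction=0.0,
                        artefact_mismapped_fraction=0.0)
        for _ in range(20):
            v, t = simulate_variant(CLASS_ARTEFACT, cfg, rng)
            assert t.true_class == CLASS_ARTEFACT
            wc = well_counts(v)
            assert wc.Vw <= 1
            if wc.Vw == 1:
                assert v.var_reads[t.artefact_origin_well] > 0

    def test_artefact_strand_fraction_splits_origin_reads(self, rng):
        cfg = SimConfig(artefact_contaminated_fraction=0.0,
                        artefact_mismapped_fraction=0.0,
                        mean_reads_per_well_per_locus=30.0,
                        locus_efficiency_shape=0.0,
                        well_amplification_shape=0.0)
        fracs = []
        for _ in range(40):
            v, t = simulate_variant(CLASS_ARTEFACT, cfg, rng)
            o = t.artefact_origin_well
            depth = v.ref_reads[o] + v.var_reads[o]
            if depth > 0:
                fracs.append(v.var_reads[o] / depth)
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.05)

    def test_het_snp_spans_many_wells(self, rng):
        cfg = SimConfig()
        vws = [well_counts(simulate_variant(CLASS_HET_SNP, cfg, rng)[0]).Vw
               for _ in range(50)]
        assert np.median(vws) > 10

    def test_full_fraction_clone_equals_clonal_distribution(self, rng):
        cfg = SimConfig(clone_cell_fraction=1.0)
        vw_cs = [well_counts(simulate_variant(CLASS_CLONE_SPECIFIC, cfg, rng)[0]).Vw
                 for _ in range(60)]
        vw_cl = [well_counts(simulate_variant(CLASS_CLONAL, cfg, rng)[0]).Vw
                 for _ in range(60)]
        assert stats.mannwhitneyu(vw_cs, vw_cl).pvalue > 0.01

    def test_partial_clone_fraction_scales_variant_wells(self, rng):
        lo = SimConfig(clone_cell_fraction=0.2)
        hi = SimConfig(clone_cell_fraction=1.0)
        vw_lo = np.median([well_counts(simulate_variant(CLASS_CLONE_SPECIFIC, lo, rng)[0]).Vw
                           for _ in range(40)])
        vw_hi = np.median([well_counts(simulate_variant(CLASS_CLONE_SPECIFIC, hi, rng)[0]).Vw
                           for _ in range(40)])
        assert vw_lo < vw_hi


class TestPlate:
    def test_training_pool_bookkeeping(self):
        cfg = SimConfig(n_artefacts=80, n_het_snps=120, n_clone_specific=0,
                        n_clonal_somatic=10, seed=4)
        plate = simulate_plate(cfg)
        assert len(plate.ids_with_label(0)) == 80
        assert len(plate.ids_with_label(1)) == 120
        assert len(plate.ids_with_label(None)) == 10
        utd_classes = {plate.truths[i].true_class for i in plate.ids_with_label(0)}
        assert utd_classes == {CLASS_ARTEFACT}

    def test_most_artefacts_have_low_well_support(self):
        plate = simulate_plate(SimConfig(n_artefacts=1000, n_het_snps=10, seed=9))
        vws = np.array([well_counts(v).Vw for v in plate.variants
                        if plate.truths[v.variant_id].true_class == CLASS_ARTEFACT])
        assert (vws <= 2).mean() >= 0.95

    def test_artefact_wells_more_often_dual_allelic_than_snp_wells(self):
        plate = simulate_plate(SimConfig(n_artefacts=500, n_het_snps=500, seed=3))
        dual_frac = {CLASS_ARTEFACT: [], CLASS_HET_SNP: []}
        for v in plate.variants:
            cls = plate.truths[v.variant_id].true_class
            var_wells = v.var_reads > 0
            if var_wells.any():
                dual_frac[cls].append(
                    float((var_wells & (v.ref_reads > 0)).sum() / var_wells.sum()))
        mw = stats.mannwhitneyu(dual_frac[CLASS_ARTEFACT], dual_frac[CLASS_HET_SNP],
                                alternative="greater")
        assert mw.pvalue < 0.01
        # and artefacts support the variant in far fewer wells
        vw = {cls: [well_counts(v).Vw for v in plate.variants
                    if plate.truths[v.variant_id].true_class == cls]
              for cls in (CLASS_ARTEFACT, CLASS_HET_SNP)}
        assert np.median(vw[CLASS_ARTEFACT]) < np.median(vw[CLASS_HET_SNP])

    def test_same_seed_reproduces_plate_exactly(self):
        cfg = SimConfig(n_artefacts=30, n_het_snps=30, seed=11)
        p1, p2 = simulate_plate(cfg), simulate_plate(cfg)
        assert [v.variant_id for v in p1.variants] == [v.variant_id for v in p2.variants]
        for a, b in zip(p1.variants, p2.variants):
            np.testing.assert_array_equal(a.var_reads, b.var_reads)
            np.testing.assert_array_equal(a.ref_reads, b.ref_reads)
            assert a.qual_fields == b.qual_fields

    def test_distinct_seeds_statistically_indistinguishable(self):
        vws = []
        for seed in (21, 22):
            plate = simulate_plate(SimConfig(n_artefacts=0, n_het_snps=400, seed=seed))
            vws.append([well_counts(v).Vw for v in plate.variants])
        assert stats.ks_2samp(*vws).pvalue > 0.01

    def test_vcf_round_trip_preserves_well_counts(self, tmp_path):
        plate = simulate_plate(SimConfig(n_artefacts=15, n_het_snps=15, seed=6))
        path = str(tmp_path / "plate.vcf")
        plate.write_vcf(path)
        back = {v.variant_id: v for v in parse_joint_vcf(path, "Merged")}
        assert len(back) == 30
        for v in plate.variants:
            assert well_counts(back[v.variant_id]) == well_counts(v)


@pytest.fixture(scope="module")
def spiking_plate():
    return simulate_plate(SimConfig(n_artefacts=200, n_het_snps=100,
                                    n_clonal_somatic=150, seed=8))


class TestSpiking:
    @pytest.fixture
    def plate(self, spiking_plate):
        return spiking_plate

    def test_eligibility_rule_is_strict(self, plate):
        by_id = plate.variants_by_id()
        for vid in high_confidence_clonal_ids(plate):
            wc = well_counts(by_id[vid])
            assert wc.Tw > 6 and wc.Vw / wc.Tw > 0.45

    def test_spike_counts_follow_ratio(self, plate):
        n_utd = len(plate.ids_with_label(0))
        sets = spike_utds(plate, ratios=[0.0, 0.1], n_replicates=3, seed=0)
        assert len(sets) == 6
        for s in sets:
            expect = int(np.floor(s.ratio * n_utd))
            assert len(s.utd_star_ids) == expect
        assert all(len(s.utd_star_ids) == 0 for s in sets if s.ratio == 0.0)

    def test_replicates_differ_but_are_seed_stable(self, plate):
        a = spike_utds(plate, ratios=[0.1], n_replicates=2, seed=5)
        b = spike_utds(plate, ratios=[0.1], n_replicates=2, seed=5)
        assert a == b
        assert a[0].utd_star_ids != a[1].utd_star_ids

    def test_shortfall_raises_with_count(self, plate):
        with pytest.raises(ValueError, match="short by"):
            spike_utds(plate, ratios=[0.9], n_replicates=1, seed=0)
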