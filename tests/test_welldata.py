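"""Well-level parsing, filtering and labelling."""

import numpy as np
import pytest

from wellmut.plate import PlateLayout
from wellmut.welldata import (GT_HET, GT_HOMALT, GT_HOMREF, GT_MISSING,
                              LABEL_HET_SNP, LABEL_OTHER, LABEL_UTD, BulkCall,
                              CandidateVariant, WellCounts, label_variants,
                              mappability_mask, parse_joint_vcf,
                              quality_filter, well_counts, well_filter,
                              write_joint_vcf)

from .conftest import random_variant
from .naive import naive_quality_filter, naive_well_counts, naive_well_filter


def _variant(ref=None, var=None, gt=None, qual=None, **kw):
    layout = PlateLayout()
    n = layout.n_wells
    ref_arr = np.zeros(n, dtype=int)
    var_arr = np.zeros(n, dtype=int)
    gt_arr = np.full(n, GT_MISSING, dtype=np.int8)
    for i, r in (ref or {}).items():
        ref_arr[i] = r
    for i, v in (var or {}).items():
        var_arr[i] = v
    for i, g in (gt or {}).items():
        gt_arr[i] = g
    qf = dict(QUAL=100.0, FR=0.5, HP=1.0, QD=20.0, SbPval=0.1)
    if qual:
        qf.update(qual)
    return CandidateVariant(chrom="chr1", pos=100, ref_allele="A", alt_allele="T",
                            qual_fields=qf, ref_reads=ref_arr, var_reads=var_arr,
                            genotypes=gt_arr, context21="A" * 21, **kw)


class TestQualityFilter:
    def test_all_thresholds_pass(self):
        v = _variant(qual=dict(QUAL=61, FR=0.2, HP=4, QD=11, SbPval=0.9))
        assert quality_filter(v)

    @pytest.mark.parametrize("field,value", [
        ("QUAL", 60.0),    # strict >
        ("FR", 0.1),       # strict >
        ("HP", 4.5),       # <= 4
        ("QD", 10.0),      # strict >
        ("SbPval", 0.96),  # <= 0.95
    ])
    def test_boundary_fails(self, field, value):
        v = _variant(qual={field: value})
        assert not quality_filter(v)

    def test_sbpval_at_bound_passes(self):
        assert quality_filter(_variant(qual=dict(SbPval=0.95)))

    @pytest.mark.parametrize("field", ["QUAL", "FR", "HP", "QD", "SbPval"])
    def test_missing_annotation_fails(self, field):
        v = _variant(qual={field: None})
        assert not quality_filter(v)


class TestWellCounts:
    def test_mixed_plate(self):
        ref = {i: 2 for i in range(10)}
        ref.update({i: 1 for i in range(10, 14)})
        var = {i: 3 for i in range(10, 14)}
        wc = well_counts(_variant(ref=ref, var=var))
        assert (wc.Tw, wc.Vw) == (14, 4)

    def test_empty_plate(self):
        assert well_counts(_variant()) == WellCounts(0, 0)

    def test_var_only_well(self):
        assert well_counts(_variant(var={5: 5})) == WellCounts(1, 1)

    def test_min_reads_threshold(self):
        wc = well_counts(_variant(ref={0: 1}, var={1: 1}), min_reads=2)
        assert (wc.Tw, wc.Vw) == (0, 0)


class TestWellFilter:
    @pytest.mark.parametrize("tw,vw,expect", [
        (6, 3, True),
        (5, 5, False),    # Tw not > 5
        (40, 4, False),   # ratio exactly 0.1 fails (strict)
        (40, 5, True),
        (10, 2, False),   # Vw not > 2
        (0, 0, False),
    ])
    def test_thresholds(self, tw, vw, expect):
        assert well_filter(WellCounts(tw, vw)) is expect


class TestFilterProperties:
    def test_agrees_with_naive_on_random_plates(self, rng):
        for _ in range(100):
            v = random_variant(rng)
            wc = well_counts(v)
            assert (wc.Tw, wc.Vw) == naive_well_counts(list(v.wells))
            assert well_filter(wc) == naive_well_filter(wc.Tw, wc.Vw)
            assert quality_filter(v) == naive_quality_filter(v.qual_fields)

    def test_raising_thresholds_never_gains_survivors(self, rng):
        variants = [random_variant(rng) for _ in range(60)]
        base = sum(well_filter(well_counts(v)) for v in variants)
        for kw in (dict(min_tw=8), dict(min_vw=4), dict(min_ratio=0.2)):
            tightened = sum(well_filter(well_counts(v), **kw) for v in variants)
            assert tightened <= base
        qbase = sum(quality_filter(v) for v in variants)
        for kw in (dict(min_qual=80), dict(min_qd=30), dict(min_fr=0.3)):
            assert sum(quality_filter(v, **kw) for v in variants) <= qbase


class TestMappabilityMask:
    def _mask(self, tmp_path, lines):
        p = tmp_path / "mask.bed"
        p.write_text("".join(f"{c}\t{s}\t{e}\n" for c, s, e in lines))
        return str(p)

    @pytest.mark.parametrize("interval,kept", [
        ((99, 100), False),   # 0-based 99 covers 1-based pos 100
        ((100, 200), False),
        ((50, 99), True),     # half-open: ends just before pos
    ])
    def test_coordinate_convention(self, tmp_path, interval, kept):
        v = _variant()  # pos 100
        mask = self._mask(tmp_path, [("chr1", *interval)])
        out = list(mappability_mask([v], mask))
        assert (len(out) == 1) is kept

    def test_contig_absent_retained(self, tmp_path):
        mask = self._mask(tmp_path, [("chr2", 0, 10**9)])
        assert len(list(mappability_mask([_variant()], mask))) == 1


class TestLabelling:
    def _bulk(self, gt=GT_HOMREF, depth=30, var_reads=0, gq=99.0):
        return {("chr1", 100, "A", "T"): BulkCall(gt, depth, var_reads, gq)}

    def test_unsupported_in_both_bulks_is_utd(self):
        out = list(label_variants([_variant()], self._bulk(), self._bulk(depth=28)))
        assert out[0].label == LABEL_UTD and out[0].train_label == 0

    def test_blood_het_is_snp(self):
        out = list(label_variants(
            [_variant()], self._bulk(GT_HET, var_reads=14),
            self._bulk(GT_HET, var_reads=15, gq=99)))
        assert out[0].label == LABEL_HET_SNP and out[0].train_label == 1

    def test_tumor_het_is_other(self):
        out = list(label_variants(
            [_variant()], self._bulk(GT_HET, var_reads=10), self._bulk()))
        assert out[0].label == LABEL_OTHER and out[0].train_label is None

    def test_low_depth_blocks_utd(self):
        out = list(label_variants([_variant()], self._bulk(depth=5), self._bulk()))
        assert out[0].label == LABEL_OTHER

    def test_low_gq_blocks_snp(self):
        out = list(label_variants(
            [_variant()], self._bulk(GT_HET, var_reads=12, gq=10),
            self._bulk(GT_HET, var_reads=12, gq=10)))
        assert out[0].label == LABEL_OTHER

    def test_absent_site_is_other(self):
        out = list(label_variants([_variant()], {}, self._bulk()))
        assert out[0].label == LABEL_OTHER

    def test_labels_partition(self, rng):
        variants = [random_variant(rng) for _ in range(20)]
        bulk = {v.variant_id: BulkCall(GT_HOMREF, 30, 0, 99) for v in variants[::2]}
        out = list(label_variants(variants, bulk, bulk))
        assert len(out) == len(variants)
        assert all(lv.label in {LABEL_UTD, LABEL_HET_SNP, LABEL_OTHER} for lv in out)


class TestVcfRoundTrip:
    def test_counts_and_genotypes_survive(self, tmp_path, rng):
        layout = PlateLayout()
        variants = [random_variant(rng, pos=100 * (i + 1)) for i in range(8)]
        path = str(tmp_path / "joint.vcf")
        write_joint_vcf(variants, path, merged_sample="Merged", layout=layout)
        back = list(parse_joint_vcf(path, "Merged", layout=layout))
        assert len(back) == len(variants)
        for orig, rt in zip(variants, back):
            assert rt.variant_id == orig.variant_id
            assert well_counts(rt) == well_counts(orig)
            np.testing.assert_array_equal(rt.ref_reads, orig.ref_reads)
            np.testing.assert_array_equal(rt.var_reads, orig.var_reads)
            covered = (orig.ref_reads + orig.var_reads) > 0
            np.testing.assert_array_equal(rt.genotypes[covered],
                                          orig.genotypes[covered])
            for k, val in orig.qual_fields.items():
                if val is not None:
                    assert rt.qual_fields[k] == pytest.approx(val, rel=1e-5)

    def test_unknown_merged_sample_fatal(self, tmp_path, rng):
        path = str(tmp_path / "joint.vcf")
        write_joint_vcf([random_variant(rng)], path, merged_sample="Merged")
        with pytest.raises(ValueError, match="merged sample"):
            next(parse_joint_vcf(path, "NotThere"))
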