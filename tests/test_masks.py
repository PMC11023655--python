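"""Collapsing-mask membership, MAF filtering and carrier collapsing."""

import numpy as np
import pandas as pd
import pytest

from bwburden import (
    VariantAnnotation,
    build_custom_mask,
    collapse,
    compute_maf,
    leave_one_out,
    missense_ptv_mask,
    ptv_mask,
    qualifies,
)
from bwburden.cohort import MISSING, GenotypeMatrix
from bwburden.masks import GeneBurdenSet, build_burden_set, collapse_all, collapse_set


def ann(key="1:100:A:G", consequence="stop_gained", loftee="HC", cadd=None, gene="G1"):
    return VariantAnnotation(key, gene, consequence, loftee, cadd)


class TestQualifies:
    @pytest.mark.parametrize(
        "consequence,loftee,cadd,expected",
        [
            ("stop_gained", "HC", None, True),
            ("splice_donor", "HC", None, True),
            ("frameshift", "HC", None, True),
            ("stop_gained", "LC", None, False),   # LOFTEE high confidence required
            ("stop_gained", "none", None, False),
            ("start_lost", "HC", None, False),    # discovery PTV excludes start/stop-lost
            ("missense", "none", 40.0, False),
            ("splice_region", "HC", 40.0, False),
            ("synonymous", "HC", 40.0, False),
        ],
    )
    def test_discovery_ptv(self, consequence, loftee, cadd, expected):
        assert qualifies(ann(consequence=consequence, loftee=loftee, cadd=cadd),
                         ptv_mask()) is expected

    @pytest.mark.parametrize(
        "consequence,loftee,cadd,expected",
        [
            ("stop_gained", "HC", None, True),     # PTV clause carries over
            ("missense", "none", 25.0, True),      # CADD threshold is inclusive
            ("missense", "none", 24.9, False),
            ("missense", "none", None, False),     # missing CADD cannot qualify
            ("inframe_indel", "none", 30.0, False),  # discovery dialect: no indels
            ("synonymous", "none", 40.0, False),
        ],
    )
    def test_discovery_missense_ptv(self, consequence, loftee, cadd, expected):
        assert qualifies(ann(consequence=consequence, loftee=loftee, cadd=cadd),
                         missense_ptv_mask()) is expected

    def test_regenie_admits_inframe_indels(self):
        mask = missense_ptv_mask("regenie")
        assert qualifies(ann(consequence="inframe_indel", loftee="none", cadd=25.0), mask)
        assert not qualifies(ann(consequence="inframe_indel", loftee="none", cadd=24.0), mask)

    def test_decode_lof_includes_start_stop_lost(self):
        mask = ptv_mask("decode")
        for cons in ("start_lost", "stop_lost", "stop_gained", "splice_acceptor"):
            assert qualifies(ann(consequence=cons, loftee="HC"), mask)
        assert not qualifies(ann(consequence="splice_region", loftee="HC"), mask)

    def test_ptv_subset_of_missense_ptv(self):
        """Mask monotonicity within each dialect."""
        for dialect in ("discovery", "regenie", "decode"):
            narrow, wide = ptv_mask(dialect), missense_ptv_mask(dialect)
            for cons in ("stop_gained", "splice_donor", "splice_acceptor",
                         "frameshift", "start_lost", "stop_lost", "missense",
                         "inframe_indel", "splice_region", "synonymous"):
                for loftee in ("HC", "LC", "none"):
                    a = ann(consequence=cons, loftee=loftee, cadd=30.0)
                    if qualifies(a, narrow):
                        assert qualifies(a, wide)


class TestCustomMask:
    def test_exact_membership(self):
        mask = build_custom_mask(["1:1:A:G", "1:2:A:G", "1:3:A:G"])
        assert qualifies(ann(key="1:2:A:G", consequence="synonymous", loftee="none"), mask)
        assert not qualifies(ann(key="1:4:A:G"), mask)

    def test_duplicates_collapse(self):
        mask = build_custom_mask(["1:1:A:G", "1:1:A:G"])
        assert len(mask.explicit_variant_list) == 1

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            build_custom_mask([])


class TestMaf:
    def test_strict_boundary(self):
        # 2 het carriers / 1000 samples = exactly 0.001 -> not rare enough
        gts = np.zeros(1000, dtype=int)
        gts[:2] = 1
        assert compute_maf(gts) == pytest.approx(0.001)

    def test_folding(self):
        gts = np.full(1000, 2, dtype=int)
        gts[0] = 1  # 1999 alt alleles of 2000
        assert compute_maf(gts) == pytest.approx(0.0005)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            compute_maf(np.full(5, MISSING))


def _matrix(gt_rows, samples=None):
    gt = np.asarray(gt_rows, dtype=np.int8)
    n_var, n_samp = gt.shape
    samples = samples or [f"S{i}" for i in range(n_samp)]
    variants = pd.DataFrame(
        {"chrom": "1", "pos": np.arange(1, n_var + 1) * 10, "ref": "A", "alt": "G"}
    )
    return GenotypeMatrix(variants, samples, gt)


class TestCollapse:
    def annotations(self, gm, gene="G1"):
        return [ann(key=k, gene=gene) for k in gm.variants.key]

    def test_indicator_caps_at_one(self):
        gm = _matrix([[1, 0, 0, 0], [1, 0, 0, 0]])
        cv = collapse("G1", ptv_mask(), gm, self.annotations(gm), maf_max=0.5)
        assert cv.status[0] == 1
        assert cv.n_carriers == 1

    def test_count_coding(self):
        gm = _matrix([[1, 0, 0, 0], [1, 0, 0, 0]])
        cv = collapse("G1", ptv_mask(), gm, self.annotations(gm), maf_max=0.5,
                      coding="count")
        assert cv.status[0] == 2

    def test_all_missing_sample_is_missing(self):
        gm = _matrix([[MISSING, 1, 0, 0], [MISSING, 0, 0, 0]])
        cv = collapse("G1", ptv_mask(), gm, self.annotations(gm), maf_max=0.5)
        assert cv.status[0] == MISSING
        assert cv.n_carriers == 1

    def test_order_invariant(self):
        gm1 = _matrix([[1, 0, 0, 0], [0, 1, 0, 0]])
        gm2 = gm1.subset_variants(np.array([1, 0]))
        anns = self.annotations(gm1)
        cv1 = collapse("G1", ptv_mask(), gm1, anns, maf_max=0.5)
        cv2 = collapse("G1", ptv_mask(), gm2, list(reversed(anns)), maf_max=0.5)
        assert np.array_equal(cv1.status, cv2.status)
        assert cv1.qualifying_variant_keys == cv2.qualifying_variant_keys

    def test_carrier_threshold_excludes(self):
        # 9 carriers of a qualifying variant among 100 samples
        gt = np.zeros((1, 100), dtype=np.int8)
        gt[0, :9] = 1
        gm = _matrix(gt)
        anns = self.annotations(gm)
        kept = collapse_all([ptv_mask()], gm, anns, maf_max=0.5, min_carriers=10)
        assert kept == []
        gt[0, 9] = 1
        kept = collapse_all([ptv_mask()], _matrix(gt), anns, maf_max=0.5,
                            min_carriers=10)
        assert len(kept) == 1 and kept[0].n_carriers == 10

    def test_adding_variant_never_decreases_carriers(self):
        gt = np.zeros((2, 50), dtype=np.int8)
        gt[0, :5] = 1
        gt[1, 5:8] = 1
        gm = _matrix(gt)
        anns = self.annotations(gm)
        one = collapse_set(GeneBurdenSet("G1", "PTV", (gm.variants.key[0],)), gm)
        both = collapse_set(GeneBurdenSet("G1", "PTV", tuple(gm.variants.key)), gm)
        assert both.n_carriers >= one.n_carriers


class TestLeaveOneOut:
    def setup_method(self):
        self.bset = GeneBurdenSet("G1", "PTV", ("1:10:A:G", "1:20:A:G"))

    def test_removes_named_variant(self):
        out = leave_one_out(self.bset, "1:10:A:G")
        assert out.variant_keys == ("1:20:A:G",)

    def test_absent_key_is_identity(self):
        assert leave_one_out(self.bset, "1:99:A:G") == self.bset

    def test_removing_last_variant_empties(self):
        out = leave_one_out(leave_one_out(self.bset, "1:10:A:G"), "1:20:A:G")
        assert out.variant_keys == ()
        gm = _matrix([[1, 0], [0, 1]])
        cv = collapse_set(out, gm)
        assert cv.n_carriers == 0 and cv.n_missing == gm.n_samples
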