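import numpy as np
import pandas as pd
import pytest

import epiretscore as e
from epiretscore import ConfigError, Signature, SignatureRegion
from epiretscore.dmr import DMR
from tests.conftest import make_matrix


def dmr(chrom, start, end, direction="hyper", delta=0.3):
    if direction == "hypo":
        delta = -abs(delta)
    return DMR(chrom, start, end, 10, delta, 0.01, direction)


class TestDeriveSignature:
    def test_partial_overlap_retained_with_degeneration_coordinates(self):
        deg = [dmr("chr1", 100, 300, "hyper")]
        trt = [dmr("chr1", 250, 400, "hypo")]
        got = e.derive_signature(deg, trt)
        assert [(d.chrom, d.start, d.end, d.direction) for d in got] == \
               [("chr1", 100, 300, "hyper")]

    def test_disjoint_lists_give_empty_signature_with_warning(self):
        with pytest.warns(UserWarning, match="empty signature"):
            got = e.derive_signature([dmr("chr1", 100, 300)],
                                     [dmr("chr1", 500, 700)])
        assert got == []

    def test_multiple_partners_emit_once(self):
        deg = [dmr("chr1", 100, 300)]
        trt = [dmr("chr1", 120, 150), dmr("chr1", 200, 250)]
        assert len(e.derive_signature(deg, trt)) == 1

    def test_min_overlap_bp_gate(self):
        deg = [dmr("chr1", 100, 200)]
        trt = [dmr("chr1", 199, 300)]
        assert len(e.derive_signature(deg, trt, min_overlap_bp=1)) == 1
        with pytest.warns(UserWarning):
            assert e.derive_signature(deg, trt, min_overlap_bp=2) == []


def anchor_matrix():
    """4 CpGs in two 2-CpG regions; two P21 and two P60 samples.

    Region A ("chr1", 999, 1100) drifts 0.2 -> 0.6 (hyper); region B
    ("chr1", 1999, 2100) drifts 0.7 -> 0.3 (hypo).
    """
    pos = [1000, 1100, 2000, 2100]
    beta = np.array([
        [0.2, 0.2, 0.6, 0.6],
        [0.2, 0.2, 0.6, 0.6],
        [0.7, 0.7, 0.3, 0.3],
        [0.7, 0.7, 0.3, 0.3],
    ])
    return make_matrix(["chr1"] * 4, pos, beta, ["p21a", "p21b", "p60a", "p60b"])


class TestComputeAnchors:
    def test_anchors_from_group_means(self):
        m = anchor_matrix()
        regs = [dmr("chr1", 999, 1100, "hyper"), dmr("chr1", 1999, 2100, "hypo")]
        sig = e.compute_anchors(regs, m, ["p21a", "p21b"], ["p60a", "p60b"])
        assert len(sig) == 2
        assert sig.regions[0].anchor_p21 == pytest.approx(0.2)
        assert sig.regions[0].anchor_p60 == pytest.approx(0.6)
        assert sig.regions[1].anchor_p21 == pytest.approx(0.7)
        assert sig.regions[1].anchor_p60 == pytest.approx(0.3)

    def test_narrow_span_dropped(self):
        m = anchor_matrix()
        beta = m.beta.copy()
        beta.loc[("chr1", 1000), :] = [0.5, 0.5, 0.505, 0.505]
        beta.loc[("chr1", 1100), :] = [0.5, 0.5, 0.505, 0.505]
        m2 = e.MethylationMatrix(beta)
        regs = [dmr("chr1", 999, 1100, "hyper")]
        sig = e.compute_anchors(regs, m2, ["p21a", "p21b"], ["p60a", "p60b"],
                                min_anchor_span=0.01)
        assert len(sig) == 0

    def test_direction_inconsistent_region_dropped(self):
        m = anchor_matrix()
        regs = [dmr("chr1", 999, 1100, "hypo")]  # data drift up, label hypo
        assert len(e.compute_anchors(regs, m, ["p21a", "p21b"],
                                     ["p60a", "p60b"])) == 0

    def test_region_without_cpgs_dropped(self):
        m = anchor_matrix()
        regs = [dmr("chr5", 0, 100, "hyper")]
        assert len(e.compute_anchors(regs, m, ["p21a"], ["p60a"])) == 0

    def test_empty_anchor_group_rejected(self):
        with pytest.raises(ConfigError):
            e.compute_anchors([], anchor_matrix(), [], ["p60a"])


def two_region_signature():
    return Signature((
        SignatureRegion("chr1", 999, 1100, "hyper", 0.2, 0.6),
        SignatureRegion("chr1", 1999, 2100, "hypo", 0.7, 0.3)), sex=None)


class TestScore:
    def test_midpoint_symmetry(self):
        # hyper anchors (0.2, 0.6) with beta 0.4 and hypo anchors (0.7, 0.3)
        # with beta 0.5 both normalize to 0.5.
        sig = two_region_signature()
        m = make_matrix(["chr1"] * 2, [1000, 2000],
                        [[0.4], [0.5]], ["s"])
        score, n = e.score_sample(m, sig, "s")
        assert n == 2
        assert score == pytest.approx(0.5)

    @pytest.mark.parametrize("normalization", ["per_region", "stratum"])
    def test_anchor_identities(self, normalization):
        sig = two_region_signature()
        m = make_matrix(["chr1"] * 2, [1000, 2000],
                        [[0.2, 0.6], [0.7, 0.3]], ["at21", "at60"])
        rep = e.score_samples(m, sig, normalization=normalization)
        assert rep.score_of("at21") == 0.0
        assert rep.score_of("at60") == 1.0

    def test_scores_are_not_clipped(self):
        sig = two_region_signature()
        m = make_matrix(["chr1"] * 2, [1000, 2000],
                        [[0.1, 0.8], [0.8, 0.1]], ["healthier", "worse"])
        rep = e.score_samples(m, sig)
        assert rep.score_of("healthier") < 0
        assert rep.score_of("worse") > 1

    def test_direction_flip_invariance(self):
        # Replacing a region's betas b by 1-b everywhere (sample and anchors)
        # and flipping its label leaves every normalized value unchanged.
        sig = two_region_signature()
        m = make_matrix(["chr1"] * 2, [1000, 2000], [[0.45], [0.52]], ["s"])
        flipped_sig = Signature((
            SignatureRegion("chr1", 999, 1100, "hypo", 0.8, 0.4),
            sig.regions[1]), sex=None)
        m_flip = make_matrix(["chr1"] * 2, [1000, 2000],
                             [[0.55], [0.52]], ["s"])
        assert e.score_sample(m, sig, "s")[0] == pytest.approx(
            e.score_sample(m_flip, flipped_sig, "s")[0])

    def test_region_order_invariance(self):
        sig = two_region_signature()
        reordered = Signature(tuple(reversed(sig.regions)), sex=None)
        m = make_matrix(["chr1"] * 2, [1000, 2000], [[0.33], [0.61]], ["s"])
        assert e.score_sample(m, sig, "s")[0] == pytest.approx(
            e.score_sample(m, reordered, "s")[0])

    def test_no_computable_region_gives_nan_and_zero_count(self):
        sig = two_region_signature()
        m = make_matrix(["chr1"] * 2, [1000, 2000],
                        [[np.nan, 0.4], [np.nan, 0.5]], ["empty", "ok"])
        rep = e.score_samples(m, sig)
        row = rep.per_sample.set_index("sample_id")
        assert np.isnan(row.loc["empty", "score"])
        assert row.loc["empty", "n_regions_used"] == 0
        assert row.loc["ok", "n_regions_used"] == 2

    def test_cross_sex_scoring_refused_unless_forced(self):
        sig = Signature(two_region_signature().regions, sex="female")
        m = make_matrix(["chr1"] * 2, [1000, 2000], [[0.4], [0.5]], ["m1"])
        meta = [e.SampleMeta("m1", "male", 60, "sham")]
        with pytest.raises(ConfigError, match="sex"):
            e.score_samples(m, sig, meta=meta)
        rep = e.score_samples(m, sig, meta=meta, force_cross_sex=True)
        assert rep.score_of("m1") == pytest.approx(0.5)

    def test_empty_signature_rejected(self):
        m = make_matrix(["chr1"], [1000], [[0.4]], ["s"])
        with pytest.raises(ConfigError):
            e.score_samples(m, Signature((), sex=None))


class TestScoreCfdna:
    def test_subset_restriction(self):
        sig = two_region_signature()
        m = make_matrix(["chr1"] * 2, [1000, 2000], [[0.4], [0.5]], ["p"])
        detectable = e.RegionSet([("chr1", 950, 1050)])  # only the hyper region
        rep = e.score_cfdna(m, sig, detectable)
        assert rep.per_sample["n_regions_used"].iloc[0] == 1
        assert rep.score_of("p") == pytest.approx(0.5)  # (0.4-0.2)/0.4

    def test_empty_subset_rejected(self):
        sig = two_region_signature()
        m = make_matrix(["chr1"] * 2, [1000, 2000], [[0.4], [0.5]], ["p"])
        with pytest.raises(ConfigError):
            e.score_cfdna(m, sig, e.RegionSet([("chr9", 0, 10)]))
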