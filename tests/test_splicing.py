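"""Splice-event filters, STR-event pairing and positional geometry."""

import numpy as np
import pandas as pd
import pytest

from splicestr.genotypes import StrLocus
from splicestr.splicing import (
    GeneModel,
    SpliceEvent,
    candidate_pairs,
    filter_samples,
    filter_splice_events,
    isoform_relative_abundance,
    match_intron_events,
    nearest_splice_site_distance,
    scaled_gene_position,
)


def make_event(event_id="ev1", strand="+", psi=None, reads=None, chrom="chr1",
               constitutive=((1000, 1100), (9000, 9100)), target=((5000, 5100),),
               etype="SE"):
    n = 100
    if psi is None:
        psi = np.linspace(10, 90, n)
    if reads is None:
        reads = np.full(n, 50.0)
    return SpliceEvent(id=event_id, event_type=etype, gene="g1", chrom=chrom,
                       strand=strand, constitutive_exons=[tuple(c) for c in constitutive],
                       target_exons=[tuple(t) for t in target], psi=np.asarray(psi, float),
                       read_counts=np.asarray(reads, float))


def make_str(start, end, chrom="chr1", sid="str1", unit="AC"):
    return StrLocus(sid, chrom, start, end, unit, end - start)


class TestEventFilters:
    def test_extreme_psi_excluded(self):
        psi = np.zeros(100)
        psi[:5] = 50.0  # PSI is 0 in 95% of samples
        assert filter_splice_events([make_event(psi=psi)]) == []

    def test_read_support_rule(self):
        reads = np.full(100, 50.0)
        reads[:15] = 5.0  # >= 10 reads in 85% of samples -> kept
        ev = make_event(reads=reads)
        assert filter_splice_events([ev]) == [ev]
        reads2 = np.full(100, 50.0)
        reads2[:25] = 5.0  # >= 10 reads in only 75% -> dropped
        assert filter_splice_events([make_event(reads=reads2)]) == []

    def test_segdup_single_base_overlap_excludes(self):
        ev = make_event()
        segdups = {"chr1": [(5099, 6000)]}  # overlaps target [5000,5100) by 1 bp
        assert filter_splice_events([ev], segdups) == []
        segdups_away = {"chr1": [(5100, 6000)]}  # abuts, half-open: no overlap
        assert filter_splice_events([ev], segdups_away) == [ev]


class TestSampleFilter:
    def test_thresholds(self):
        psi = np.zeros((100, 3))
        psi[:25, 0] = np.nan  # 25% missing -> dropped
        psi[:20, 1] = np.nan  # exactly 20% -> kept (strict inequality)
        keep = filter_samples(psi)
        assert list(keep) == [False, True, True]


class TestCandidatePairs:
    def test_window_rules(self):
        ev = make_event()
        near = make_str(1000 - 50_000, 1000 - 50_000 + 20, sid="near")
        far = make_str(9100 + 150_000, 9100 + 150_000 + 20, sid="far")
        inside = make_str(5010, 5030, sid="inside")
        pairs = candidate_pairs([ev], [near, far, inside])
        assert ("ev1", "near") in pairs
        assert ("ev1", "inside") in pairs
        assert all(s != "far" for _, s in pairs)

    def test_boundary_inclusive(self):
        ev = make_event()
        edge = make_str(9100 + 100_000, 9100 + 100_000 + 20, sid="edge")
        assert ("ev1", "edge") in candidate_pairs([ev], [edge])

    def test_enumeration_order_independent(self):
        evs = [make_event(event_id=f"e{i}", constitutive=((i * 1000, i * 1000 + 100),
                                                          (i * 1000 + 500, i * 1000 + 600)),
                          target=((i * 1000 + 200, i * 1000 + 300),))
               for i in range(5)]
        strs = [make_str(j * 700, j * 700 + 20, sid=f"s{j}") for j in range(8)]
        p1 = set(candidate_pairs(evs, strs, window_bp=2000))
        p2 = set()
        for s in strs:
            p2 |= {(e, sid) for e, sid in candidate_pairs(evs, [s], window_bp=2000)}
        assert p1 == p2


class TestSpliceSiteDistance:
    def test_plus_strand_upstream(self):
        # STR ends 80 bp before the target exon start on a + gene
        ev = make_event(strand="+")
        s = make_str(4900, 4920)  # ends at 4920, exon starts 5000 -> gap 80
        d, _ = nearest_splice_site_distance(s, ev)
        assert d == -80

    def test_minus_strand_flip(self):
        # same genomic offset past the exon's genomic end, on a - gene,
        # is upstream in transcript orientation
        ev = make_event(strand="-")
        s = make_str(5180, 5200)  # starts 80 bp after exon end 5100
        d, _ = nearest_splice_site_distance(s, ev)
        assert d == -80

    def test_overlap_zero(self):
        ev = make_event()
        s = make_str(5050, 5070)
        assert nearest_splice_site_distance(s, ev)[0] == 0

    def test_strand_reversal_mirror(self):
        ev_p = make_event(strand="+")
        ev_m = make_event(strand="-")
        s_left = make_str(4800, 4820)
        s_right = make_str(5280, 5300)
        d_p, _ = nearest_splice_site_distance(s_left, ev_p)
        d_m, _ = nearest_splice_site_distance(s_right, ev_m)
        assert d_p == d_m  # mirrored geometry, flipped strand

    def test_mxe_nearest_exon_reported(self):
        ev = make_event(etype="MXE", target=((5000, 5100), (7000, 7100)))
        s = make_str(7150, 7170)
        d, idx = nearest_splice_site_distance(s, ev)
        assert idx == 1
        assert d == 50


class TestScaledGenePosition:
    def test_tss_and_tes_anchors(self):
        g = GeneModel("g", "chr1", "+", tss=1000, tes=11000)
        assert scaled_gene_position(make_str(995, 1005), g) == pytest.approx(0.0)
        assert scaled_gene_position(make_str(10995, 11005), g) == pytest.approx(1.0)

    def test_minus_strand_upstream_negative(self):
        # minus-strand gene: TSS at the genomically larger coordinate
        g = GeneModel("g", "chr1", "-", tss=11000, tes=1000)
        # STR 10% of span genomically downstream of the genomic end (= past TSS)
        s = make_str(11995, 12005)
        assert scaled_gene_position(s, g) == pytest.approx(-0.1)

    def test_zero_span_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("g", "chr1", "+", tss=5, tes=5)


class TestIsoformRatios:
    def test_ratios_and_degenerate_sample(self):
        tpm = pd.DataFrame({"s1": [30.0, 70.0], "s2": [0.0, 0.0]},
                           index=["t1", "t2"])
        ratios = isoform_relative_abundance(tpm, {"t1": "g", "t2": "g"})
        assert ratios.loc["t1", "s1"] == pytest.approx(0.3)
        assert ratios.loc["t2", "s1"] == pytest.approx(0.7)
        assert ratios["s2"].isna().all()  # 0/0 -> missing, not 0

    def test_single_isoform_ratio_one(self):
        tpm = pd.DataFrame({"s1": [5.0]}, index=["t1"])
        ratios = isoform_relative_abundance(tpm, {"t1": "g"})
        assert ratios.loc["t1", "s1"] == pytest.approx(1.0)

    def test_unexpressed_transcript_dropped_and_sums_to_one(self):
        tpm = pd.DataFrame({"s1": [3.0, 7.0, 0.0], "s2": [2.0, 2.0, 0.0]},
                           index=["t1", "t2", "t3"])
        ratios = isoform_relative_abundance(tpm, dict.fromkeys(tpm.index, "g"))
        assert "t3" not in ratios.index
        assert ratios.sum(axis=0).values == pytest.approx([1.0, 1.0], abs=1e-9)


class TestIntronMatching:
    def test_ratio_bounds_and_sign_flip(self):
        ev = make_event()  # constitutive intron [1100, 9000) -> length 7900
        recs = pd.DataFrame({
            "str_id": ["s1", "s1", "s1"],
            "intron_length": [7900, int(7900 * 0.94), int(7900 * 1.05)],
            "beta": [0.4, 0.2, -0.1],
        })
        m = match_intron_events(ev, recs)
        assert list(m.index) == [0, 2]  # 0.94 ratio falls below the bound
        assert m.loc[0, "beta_flipped"] == pytest.approx(-0.4)
        assert m.loc[2, "beta_flipped"] == pytest.approx(0.1)
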