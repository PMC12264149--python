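import numpy as np
import pandas as pd
import pytest

from m6akit import retro as rt
from m6akit.core import AnnotationBundle, GeneModel, Peak, RepeatLocus, TranscriptModel
from m6akit.signal import BinnedTrack

from .oracles import max_per_base

CONSENSUS = {"L1X": 6000, "ALUX": 300, "LTRX": 400, "INTX": 3000}


def repeat_row(locus_id, subfamily, repclass, start, end, strand="+",
               family=".", part=".", chrom="chr1"):
    return {"locus_id": locus_id, "subfamily": subfamily, "repclass": repclass,
            "chrom": chrom, "start": start, "end": end, "strand": strand,
            "family": family, "part": part}


def empty_bundle(size=100_000):
    return AnnotationBundle(genes={}, transcripts=[], chrom_sizes={"chr1": size})


def locus(start, end, strand="+", subfamily="L1X", lid="L1", chrom="chr1"):
    return RepeatLocus(lid, subfamily, "LINE", chrom, start, end, strand,
                       completeness=1.0)


class TestFiltering:
    def test_completeness_boundary_closed_at_090(self):
        rows = pd.DataFrame([
            repeat_row("a", "L1X", "LINE", 0, 5400),      # 5400/6000 = 0.90 kept
            repeat_row("b", "L1X", "LINE", 10_000, 15_399),  # 0.8998 dropped
        ])
        kept = rt.filter_repeat_loci(rows, CONSENSUS, empty_bundle())
        assert [l.locus_id for l in kept] == ["a"]
        assert kept[0].completeness == pytest.approx(0.9)

    def test_full_length_triplet_assembled(self):
        rows = pd.DataFrame([
            repeat_row("l1", "LTRX", "LTR", 0, 400, family="HERV", part="ltr"),
            repeat_row("i1", "INTX", "LTR", 500, 3500, family="HERV", part="internal"),
            repeat_row("l2", "LTRX", "LTR", 3600, 4000, family="HERV", part="ltr"),
        ])
        kept = rt.filter_repeat_loci(rows, CONSENSUS, empty_bundle())
        assert len(kept) == 1
        fl = kept[0]
        assert fl.architecture == "full_length_ERV"
        assert (fl.start, fl.end) == (0, 4000)

    def test_ltr_pair_without_internal_stays_solo(self):
        rows = pd.DataFrame([
            repeat_row("l1", "LTRX", "LTR", 0, 400, family="HERV", part="ltr"),
            repeat_row("l2", "LTRX", "LTR", 500, 900, family="HERV", part="ltr"),
        ])
        kept = rt.filter_repeat_loci(rows, CONSENSUS, empty_bundle())
        assert {l.architecture for l in kept} == {"solo"}
        assert len(kept) == 2

    def test_gap_above_tolerance_blocks_assembly(self):
        rows = pd.DataFrame([
            repeat_row("l1", "LTRX", "LTR", 0, 400, family="HERV", part="ltr"),
            repeat_row("i1", "INTX", "LTR", 1000, 4000, family="HERV", part="internal"),
            repeat_row("l2", "LTRX", "LTR", 4100, 4500, family="HERV", part="ltr"),
        ])
        kept = rt.filter_repeat_loci(rows, CONSENSUS, empty_bundle(), fl_gap=500)
        assert all(l.architecture != "full_length_ERV" for l in kept)
        kept = rt.filter_repeat_loci(rows, CONSENSUS, empty_bundle(), fl_gap=700)
        assert any(l.architecture == "full_length_ERV" for l in kept)

    def test_exon_overlap_removed(self):
        tx = TranscriptModel("g.t1", "g", "chr1", "+", exons=[(100, 2000)])
        bundle = AnnotationBundle(genes={"g": GeneModel("g", "chr1", "+", 100, 2000)},
                                  transcripts=[tx], chrom_sizes={"chr1": 100_000})
        rows = pd.DataFrame([
            repeat_row("in_exon", "L1X", "LINE", 1990, 7990),
            repeat_row("clear", "L1X", "LINE", 10_000, 16_000),
        ])
        kept = rt.filter_repeat_loci(rows, CONSENSUS, bundle)
        assert [l.locus_id for l in kept] == ["clear"]

    def test_missing_consensus_error(self):
        rows = pd.DataFrame([repeat_row("a", "NEW", "LINE", 0, 100)])
        with pytest.raises(ValueError, match="NEW"):
            rt.filter_repeat_loci(rows, CONSENSUS, empty_bundle())


def track(values, label="t"):
    return BinnedTrack(10, {"chr1": np.asarray(values, float)}, label=label)


class TestScoring:
    def test_max_over_bins(self):
        t = track([0.5, 2.5, 1.0, 0.0])
        scores = rt.score_repeat_loci([locus(0, 30)], {"GV": [t]}, {"GV": [t]})
        assert scores.iloc[0]["expression"] == pytest.approx(2.5)

    def test_negative_signal_max(self):
        sig = track([-0.3, 0.8])
        inp = track([1.0, 1.0])
        scores = rt.score_repeat_loci([locus(0, 20)], {"GV": [inp]}, {"GV": [sig]})
        assert scores.iloc[0]["m6a_signal"] == pytest.approx(0.8)
        assert scores.iloc[0]["modified"]

    def test_replicate_mean(self):
        t1, t2 = track([2.0]), track([4.0])
        scores = rt.score_repeat_loci([locus(0, 10)], {"GV": [t1, t2]},
                                      {"GV": [t1, t2]})
        assert scores.iloc[0]["expression"] == pytest.approx(3.0)

    def test_zero_coverage_not_expressed(self):
        t = track([0.0, 0.0])
        scores = rt.score_repeat_loci([locus(0, 20)], {"GV": [t]}, {"GV": [t]})
        assert not scores.iloc[0]["expressed"]

    def test_matches_per_base_oracle_random(self, rng):
        vals = rng.uniform(0, 10, 200)
        t = track(vals)
        loci = []
        for i in range(100):
            s = int(rng.integers(0, 1990))
            e = int(rng.integers(s + 1, min(s + 300, 2000) + 1))
            loci.append(locus(s, e, lid=f"r{i}"))
        scores = rt.score_repeat_loci(loci, {"GV": [t]}, {"GV": [t]})
        for l, (_, row) in zip(loci, scores.iterrows()):
            assert row["expression"] == max_per_base(vals, 10, l.start, l.end)

    def test_shrinking_never_increases_score(self, rng):
        vals = rng.uniform(0, 10, 100)
        t = track(vals)
        full = rt.score_repeat_loci([locus(100, 900)], {"GV": [t]}, {"GV": [t]})
        small = rt.score_repeat_loci([locus(200, 800)], {"GV": [t]}, {"GV": [t]})
        assert small.iloc[0]["expression"] <= full.iloc[0]["expression"]

    def test_locus_outside_track_error(self):
        t = track([1.0])
        with pytest.raises(ValueError):
            rt.score_repeat_loci([locus(0, 500)], {"GV": [t]}, {"GV": [t]})


class TestSummary:
    def scores(self, n_expr, n_mod, n_silent=0):
        rows = []
        for i in range(n_expr):
            rows.append({"locus_id": f"r{i}", "subfamily": "L1X", "stage": "GV",
                         "expressed": True, "modified": i < n_mod,
                         "expression": 1.0, "m6a_signal": 1.0 if i < n_mod else -1.0})
        for i in range(n_silent):
            rows.append({"locus_id": f"s{i}", "subfamily": "L1X", "stage": "GV",
                         "expressed": False, "modified": False,
                         "expression": 0.0, "m6a_signal": 0.0})
        return pd.DataFrame(rows)

    def test_percentage(self):
        out = rt.subfamily_summary(self.scores(10, 5), "GV")
        assert out.iloc[0]["pct_modified"] == pytest.approx(50.0)

    def test_no_expressed_missing_percent(self):
        out = rt.subfamily_summary(self.scores(0, 0, n_silent=4), "GV")
        assert np.isnan(out.iloc[0]["pct_modified"])
        assert out.iloc[0]["n_expressed"] == 0


class TestElementProfile:
    def test_constant_signal(self):
        t = track(np.ones(100))
        prof = rt.element_profile([locus(0, 1000)], t, n_bins=10)
        np.testing.assert_allclose(prof.mean, 1.0)
        np.testing.assert_allclose(prof.sd, 0.0)

    def test_single_locus_sd_zero(self, rng):
        t = track(rng.uniform(0, 5, 100))
        prof = rt.element_profile([locus(0, 1000)], t, n_bins=20)
        np.testing.assert_allclose(prof.sd, 0.0)

    def test_minus_strand_reversed(self):
        ramp = np.arange(100, dtype=float)  # rises toward genomic end
        t = track(ramp)
        plus = rt.element_profile([locus(0, 1000, "+")], t, n_bins=10)
        minus = rt.element_profile([locus(0, 1000, "-")], t, n_bins=10)
        assert plus.mean[-1] > plus.mean[0]
        assert minus.mean[0] > minus.mean[-1]
        np.testing.assert_allclose(minus.mean, plus.mean[::-1])

    def test_empty_error(self):
        with pytest.raises(ValueError):
            rt.element_profile([], track([1.0]))


class TestConditionComparison:
    def peaks(self, n, start=0):
        return [Peak("chr1", start + i * 100, start + i * 100 + 50,
                     start + i * 100 + 25, name=f"p{i}") for i in range(n)]

    def test_identical_sets_zero_reduction(self):
        loci = [locus(0, 20_000)]
        p = self.peaks(10)
        comp = rt.condition_peak_comparison(p, p, loci)
        assert comp.pct_reduction == pytest.approx(0.0)

    def test_partial_reduction_arithmetic(self):
        loci = [locus(0, 20_000)]
        comp = rt.condition_peak_comparison(self.peaks(100), self.peaks(53), loci)
        assert comp.n_associated_ctrl == 100
        assert comp.n_associated_treated == 53
        assert comp.pct_reduction == pytest.approx(47.0)

    def test_no_overlap_counts_zero_reduction_undefined(self):
        loci = [locus(50_000, 60_000)]
        comp = rt.condition_peak_comparison(self.peaks(5), self.peaks(5), loci)
        assert comp.n_associated_ctrl == comp.n_associated_treated == 0
        assert comp.pct_reduction is None

    def test_per_subfamily_wilcoxon(self, rng):
        def scores(shift):
            return pd.DataFrame({
                "subfamily": ["L1X"] * 30,
                "m6a_signal": rng.normal(loc=shift, scale=0.1, size=30),
            })
        loci = [locus(0, 20_000)]
        comp = rt.condition_peak_comparison(self.peaks(5), self.peaks(2), loci,
                                            scores(2.0), scores(0.5))
        row = comp.per_subfamily.iloc[0]
        assert row["p_value"] < 0.01
        assert row["median_ctrl"] > row["median_treated"]
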