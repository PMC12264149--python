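import numpy as np
import pandas as pd
import pytest

from m6akit import annotate as ann
from m6akit.core import AnnotationBundle, GeneModel, Peak, TranscriptModel

from .conftest import make_bundle
from .oracles import gene_call_brute, rrach_scan


def peak(start, end, summit=None, chrom="chr1", name="p"):
    return Peak(chrom, start, end, summit if summit is not None else (start + end) // 2,
                name=name)


class TestFeatureAssignment:
    """geneA (+): exons [100,300)+[400,700), stop codon [550,553)."""

    def setup_method(self):
        self.bundle = make_bundle()
        self.masks = ann.build_feature_masks(self.bundle)

    def test_peak_within_200bp_of_stop_is_stop_codon(self):
        # 100 bp downstream of the stop codon end
        assert ann.assign_peak_feature(peak(650, 660), self.masks) == "stop_codon"

    def test_peak_past_window_in_3utr(self):
        # geneB 3'UTR is [2000,2097); its stop window is [1897,2300) -> use a
        # dedicated gene with a long 3'UTR instead
        tx = TranscriptModel("gL.t1", "gL", "chr1", "+",
                             exons=[(7000, 8000)], cds=[(7050, 7300)],
                             stop_codon=(7300, 7303))
        bundle = AnnotationBundle(
            genes={"gL": GeneModel("gL", "chr1", "+", 7000, 8000)},
            transcripts=[tx], chrom_sizes={"chr1": 10_000})
        masks = ann.build_feature_masks(bundle)
        # 300 bp past the stop codon, inside the annotated 3'UTR
        assert ann.assign_peak_feature(peak(7600, 7620), masks) == "3UTR"

    def test_intergenic(self):
        assert ann.assign_peak_feature(peak(9000, 9100), self.masks) == "intergenic"

    def test_intron(self):
        # geneA intron [300,400); stay left of the stop-codon window [350,753)
        assert ann.assign_peak_feature(peak(305, 345), self.masks) == "intron"

    def test_noncoding_exon(self):
        assert ann.assign_peak_feature(peak(5100, 5150), self.masks) == "exon"

    def test_partition_every_peak_gets_one_label(self, rng):
        peaks = [peak(int(s), int(s) + 50, name=f"p{i}")
                 for i, s in enumerate(rng.integers(0, 9900, 300))]
        df = ann.annotate_peaks(peaks, self.bundle)
        assert len(df) == 300
        assert df["feature"].isin(ann.FEATURE_ORDER).all()


class TestEnrichment:
    def test_masked_lengths_partition_genome(self):
        bundle = make_bundle()
        lengths = ann.hierarchy_masked_lengths(bundle)
        assert sum(lengths.values()) == bundle.genome_length()
        assert all(v >= 0 for v in lengths.values())

    def test_expected_sums_to_total_peaks(self, rng):
        bundle = make_bundle()
        peaks = [peak(int(s), int(s) + 30, name=f"p{i}")
                 for i, s in enumerate(rng.integers(0, 9900, 200))]
        table = ann.feature_enrichment(peaks, bundle).table
        assert table["observed"].sum() == 200
        assert table["expected"].sum() == pytest.approx(200, abs=1e-9)

    def test_single_feature_spanning_genome_scores_zero(self):
        tx = TranscriptModel("t.t1", "g", "chr1", "+", exons=[(0, 1000)])
        bundle = AnnotationBundle(genes={"g": GeneModel("g", "chr1", "+", 0, 1000)},
                                  transcripts=[tx], chrom_sizes={"chr1": 1000})
        peaks = [peak(i * 100, i * 100 + 50, name=f"p{i}") for i in range(8)]
        table = ann.feature_enrichment(peaks, bundle)
        assert table.score("exon") == pytest.approx(0.0)

    def test_observed_eight_expected_two_gives_two(self):
        # exon feature occupies 1/4 of the genome; all 8 peaks inside it
        tx = TranscriptModel("t.t1", "g", "chr1", "+", exons=[(0, 250)])
        bundle = AnnotationBundle(genes={"g": GeneModel("g", "chr1", "+", 0, 250)},
                                  transcripts=[tx], chrom_sizes={"chr1": 1000})
        peaks = [peak(i * 30, i * 30 + 20, name=f"p{i}") for i in range(8)]
        table = ann.feature_enrichment(peaks, bundle)
        assert table.score("exon") == pytest.approx(2.0)  # log2(8/2)

    def test_empty_peak_list_is_error(self):
        with pytest.raises(ValueError):
            ann.feature_enrichment([], make_bundle())

    def test_zero_observed_reported_missing(self):
        bundle = make_bundle()
        peaks = [peak(9000, 9050)]
        table = ann.feature_enrichment(peaks, bundle).table
        assert np.isnan(table.loc["5UTR", "enrichment"])


class TestMetagene:
    def setup_method(self):
        self.bundle = make_bundle()

    def test_first_utr5_base_is_zero(self):
        tx = self.bundle.transcripts_of("geneA")[0]
        assert ann.metagene_coordinate(100, tx) == pytest.approx(0.0)

    def test_first_stop_base_is_two(self):
        tx = self.bundle.transcripts_of("geneA")[0]
        assert ann.metagene_coordinate(550, tx) == pytest.approx(2.0)

    def test_cds_midpoint_is_one_point_five(self):
        # geneA: 5'UTR 50 nt, CDS 300 nt; CDS midpoint = tx position 200,
        # which lies at genomic 400 (first base of exon 2)
        tx = self.bundle.transcripts_of("geneA")[0]
        assert ann.metagene_coordinate(400, tx) == pytest.approx(1.5)

    def test_minus_strand_first_stop_base_is_two(self):
        # geneB (-): stop codon [2097,2100); first stop base 5'->3' is 2099
        tx = self.bundle.transcripts_of("geneB")[0]
        assert ann.metagene_coordinate(2099, tx) == pytest.approx(2.0)

    def test_minus_strand_first_utr5_base_is_zero(self):
        tx = self.bundle.transcripts_of("geneB")[0]
        assert ann.metagene_coordinate(2599, tx) == pytest.approx(0.0)

    def test_noncoding_summit_skipped(self):
        prof = ann.metagene_profile([("chr1", 5100)], self.bundle)
        assert prof.n_used == 0 and prof.n_skipped == 1

    def test_density_sums_to_one(self):
        prof = ann.metagene_profile([("chr1", 550), ("chr1", 400), ("chr1", 100)],
                                    self.bundle)
        assert prof.density.sum() == pytest.approx(1.0)
        assert ((prof.coords >= 0) & (prof.coords < 3)).all()


class TestRepresentativeTranscript:
    def test_highest_tpm_wins_then_length_then_id(self):
        tx1 = TranscriptModel("g.t1", "g", "chr1", "+", exons=[(0, 100)])
        tx2 = TranscriptModel("g.t2", "g", "chr1", "+", exons=[(0, 300)])
        tx3 = TranscriptModel("g.t3", "g", "chr1", "+", exons=[(0, 300)])
        bundle = AnnotationBundle(genes={"g": GeneModel("g", "chr1", "+", 0, 300)},
                                  transcripts=[tx1, tx2, tx3],
                                  chrom_sizes={"chr1": 1000})
        expr = pd.Series({"g.t1": 9.0, "g.t2": 1.0, "g.t3": 1.0})
        assert ann.representative_transcript(bundle, expr)["g"].transcript_id == "g.t1"
        # no expression: longer first, then lexicographic
        assert ann.representative_transcript(bundle)["g"].transcript_id == "g.t2"


class TestGeneCalls:
    def test_union_rule_single_replicate_hit(self, toy_bundle):
        peaks = {"rep1": [peak(150, 250)], "rep2": []}
        calls = {c.gene_id: c for c in ann.call_m6a_genes(peaks, toy_bundle)}
        assert calls["geneA"].status == "m6A+"
        assert calls["geneB"].status == "m6A-"

    def test_no_overlap_negative(self, toy_bundle):
        calls = {c.gene_id: c.status
                 for c in ann.call_m6a_genes({"rep1": [peak(9000, 9100)]}, toy_bundle)}
        assert set(calls.values()) == {"m6A-"}

    def test_intronic_peak_negative_at_exon_level(self, toy_bundle):
        peaks = {"rep1": [peak(310, 390)]}  # inside geneA's intron
        calls = {c.gene_id: c.status for c in ann.call_m6a_genes(peaks, toy_bundle)}
        assert calls["geneA"] == "m6A-"
        calls = {c.gene_id: c.status
                 for c in ann.call_m6a_genes(peaks, toy_bundle, exon_level=False)}
        assert calls["geneA"] == "m6A+"

    def test_expression_floor_flags_not_expressed(self, toy_bundle):
        expr = pd.Series({"geneA": 0.2, "geneB": 5.0, "geneC": 5.0})
        calls = {c.gene_id: c.status
                 for c in ann.call_m6a_genes({"rep1": [peak(150, 250)]}, toy_bundle,
                                             expression=expr, tpm_floor=1.0)}
        assert calls["geneA"] == "not_expressed"

    def test_matches_brute_force_on_random_instance(self, rng):
        genes = {}
        transcripts = []
        gene_exons = {}
        for i in range(200):
            gid = f"g{i}"
            s = int(rng.integers(0, 95_000))
            exons = [(s, s + 200), (s + 400, s + 600)]
            genes[gid] = GeneModel(gid, "chr1", "+", s, s + 600)
            transcripts.append(TranscriptModel(f"{gid}.t", gid, "chr1", "+", exons))
            gene_exons[gid] = [("chr1", a, b) for a, b in exons]
        bundle = AnnotationBundle(genes=genes, transcripts=transcripts,
                                  chrom_sizes={"chr1": 100_000})
        peaks_by_rep = {}
        raw = {}
        for rep in ("rep1", "rep2"):
            ps = []
            for j in range(250):
                s = int(rng.integers(0, 99_000))
                ps.append(peak(s, s + int(rng.integers(20, 400)), name=f"{rep}_{j}"))
            peaks_by_rep[rep] = ps
            raw[rep] = [(p.chrom, p.start, p.end) for p in ps]
        calls = {c.gene_id: c.status == "m6A+"
                 for c in ann.call_m6a_genes(peaks_by_rep, bundle)}
        assert calls == gene_call_brute(gene_exons, raw)


class TestRRACH:
    def bundle_with(self, seq):
        tx = TranscriptModel("g.t1", "g", "chr1", "+", exons=[(0, len(seq))])
        return AnnotationBundle(genes={"g": GeneModel("g", "chr1", "+", 0, len(seq))},
                                transcripts=[tx], chrom_sizes={"chr1": len(seq)},
                                sequence={"chr1": seq})

    def test_ggact_counts_one(self):
        count, density = ann.count_rrach(self.bundle_with("GGACT"), "g")
        assert count == 1
        assert density == pytest.approx(200.0)  # 1 per 5 bp

    def test_no_match(self):
        assert ann.count_rrach(self.bundle_with("CCCCCCCC"), "g")[0] == 0

    def test_overlapping_matches_counted(self):
        # GGAACT? use GAGGACT-like overlap: 'GGACAC...'? construct AAACA GGACA
        seq = "GGACAGGACT"
        assert ann.count_rrach(self.bundle_with(seq), "g")[0] == rrach_scan(seq)

    def test_matches_scan_oracle_on_random_sequences(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=1000))
            assert ann.count_rrach(self.bundle_with(seq), "g")[0] == rrach_scan(seq)

    def test_minus_strand_uses_sense_sequence(self):
        # genomic minus-strand gene: sense sequence is the reverse complement
        seq = "A" * 20
        tx = TranscriptModel("g.t1", "g", "chr1", "-", exons=[(0, 20)])
        bundle = AnnotationBundle(genes={"g": GeneModel("g", "chr1", "-", 0, 20)},
                                  transcripts=[tx], chrom_sizes={"chr1": 20},
                                  sequence={"chr1": "AGTCC" + "A" * 15})
        # revcomp("AGTCC"...) ends with "GGACT"
        assert ann.count_rrach(bundle, "g")[0] == 1

    def test_missing_sequence_errors_with_gene(self, toy_bundle):
        with pytest.raises(ValueError, match="geneA"):
            ann.count_rrach(toy_bundle, "geneA")
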