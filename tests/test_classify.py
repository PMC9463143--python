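"""Classification rules, multimapper weighting, and normalization."""

import math

import pytest

from pirnakit.classify import (
    CountTable,
    build_count_table,
    classify_alignments,
    classify_read,
    filter_and_weight,
    length_histogram,
    normalize,
    WeightedAlignment,
)
from pirnakit.core import AlignmentRecord, GenomicInterval
from pirnakit.errors import DataError


def _aln(chrom, start, length, strand, nt="G", n_loci=1, rid="r"):
    return AlignmentRecord(
        rid, length, nt, GenomicInterval(chrom, start, start + length, strand), n_loci
    )


class TestFilterAndWeight:
    @pytest.mark.parametrize(
        "length,kept", [(16, False), (17, True), (40, True), (41, False)]
    )
    def test_length_filter_boundaries(self, length, kept):
        out = list(filter_and_weight([_aln("chr1", 0, length, "+")]))
        assert bool(out) == kept

    def test_multimapper_weight(self):
        out = list(filter_and_weight([_aln("chr1", 0, 22, "+", n_loci=4)]))
        assert out[0].weight == 0.25

    def test_unique_read_weight_one(self):
        out = list(filter_and_weight([_aln("chr1", 0, 22, "+")]))
        assert out[0].weight == 1.0


class TestClassifyRead:
    def _cls(self, aln, index):
        return classify_read(WeightedAlignment(aln, 1.0), index)

    def test_g22_antisense_to_protein_coding(self, tiny_index):
        cr = self._cls(_aln("chr1", 1100, 22, "-", "G"), tiny_index)
        assert cr.read_class == "g22_antisense"
        assert cr.assigned_features == ("geneA",)

    def test_five_prime_a_not_g22(self, tiny_index):
        cr = self._cls(_aln("chr1", 1100, 22, "-", "A"), tiny_index)
        assert cr.read_class == "other"

    def test_length_24_not_g22(self, tiny_index):
        cr = self._cls(_aln("chr1", 1100, 24, "-", "G"), tiny_index)
        assert cr.read_class == "other"

    def test_g22_antisense_to_transposon(self, tiny_index):
        cr = self._cls(_aln("chr2", 200, 21, "-", "G"), tiny_index)
        assert cr.read_class == "g22_antisense"
        assert cr.assigned_features == ("tn1",)

    def test_mature_pirna_exact_locus(self, tiny_index):
        cr = self._cls(_aln("chr1", 9500, 21, "+", "T"), tiny_index)
        assert cr.read_class == "mature_piRNA"

    def test_pirna_with_overhang_not_mature(self, tiny_index):
        # one nucleotide past the annotated 3' end
        cr = self._cls(_aln("chr1", 9501, 21, "+", "T"), tiny_index)
        assert cr.read_class != "mature_piRNA"

    def test_sense_read_in_rrna_is_structural(self, tiny_index):
        cr = self._cls(_aln("chr1", 7100, 22, "+", "G"), tiny_index)
        assert cr.read_class == "structural_sense"

    def test_sense_read_on_gene(self, tiny_index):
        cr = self._cls(_aln("chr1", 1100, 25, "+", "A"), tiny_index)
        assert cr.read_class == "sense_feature"

    def test_order_independent(self, tiny_index):
        alns = [
            _aln("chr1", 1100, 22, "-", "G", rid="a"),
            _aln("chr1", 7100, 22, "+", "G", rid="b"),
            _aln("chr1", 9500, 21, "+", "T", rid="c"),
        ]
        fwd = classify_alignments(alns, tiny_index)
        rev = classify_alignments(alns[::-1], tiny_index)
        assert sorted((c.alignment.read_id, c.read_class) for c in fwd) == sorted(
            (c.alignment.read_id, c.read_class) for c in rev
        )


class TestCountTable:
    def test_two_unique_reads_count_two(self, tiny_features, tiny_index):
        alns = [
            _aln("chr1", 1100, 22, "-", "G", rid="r1"),
            _aln("chr1", 1400, 22, "-", "G", rid="r2"),
        ]
        t = build_count_table(
            classify_alignments(alns, tiny_index), tiny_features
        )
        assert t.get("geneA", "g22_antisense", "antisense") == 2.0

    def test_duplicated_locus_read_splits_weight(self, tiny_features, tiny_index):
        alns = [
            _aln("chr1", 1100, 22, "-", "G", n_loci=2, rid="r1"),
            _aln("chr2", 200, 22, "-", "G", n_loci=2, rid="r1"),
        ]
        t = build_count_table(
            classify_alignments(alns, tiny_index), tiny_features
        )
        assert t.get("geneA", "g22_antisense", "antisense") == 0.5
        assert t.get("tn1", "g22_antisense", "antisense") == 0.5
        assert t.total_mapped == 1.0

    def test_structural_only_library_degenerate(self, tiny_features, tiny_index):
        alns = [_aln("chr1", 7100, 22, "+", "A", rid="r1")]
        t = build_count_table(
            classify_alignments(alns, tiny_index), tiny_features
        )
        assert t.degenerate
        with pytest.raises(DataError, match="denominator|degenerate"):
            normalize(t, "srna-rpm")

    def test_tsv_round_trip(self, tiny_features, tiny_index, tmp_path):
        alns = [
            _aln("chr1", 1100, 22, "-", "G", rid="r1"),
            _aln("chr1", 7100, 22, "+", "A", rid="r2"),
        ]
        t = build_count_table(classify_alignments(alns, tiny_index), tiny_features, "s1")
        t.to_tsv(tmp_path / "c.tsv")
        back = CountTable.from_tsv(tmp_path / "c.tsv")
        assert back.sample == "s1"
        assert back.total_mapped == t.total_mapped
        assert back.counts.equals(t.counts)


class TestNormalize:
    def test_rpm_formula(self):
        t = CountTable.from_gene_counts({"g": 15.0}, "s", total_mapped=1.5e6)
        assert normalize(t, "srna-rpm").series()["g"] == 10.0

    def test_rpm_structural_excluded_from_denominator(self):
        t = CountTable.from_gene_counts(
            {"g": 10.0}, "s", total_mapped=2.5e6, structural_sense=0.5e6
        )
        assert normalize(t, "srna-rpm").series()["g"] == 5.0

    def test_rpkm_formula(self, tiny_features):
        import pandas as pd

        t = CountTable(
            counts=pd.DataFrame(
                {
                    "feature_id": ["geneA"],
                    "read_class": ["sense_feature"],
                    "orientation": ["sense"],
                    "count": [100.0],
                }
            ),
            sample="m",
            total_mapped=1e6,
            structural_sense=0.0,
            protein_coding_mapped=1e6,
        )
        # geneA spans 1 kb
        norm = normalize(t, "mrna-rpkm", tiny_features)
        assert norm.series("sense_feature", "sense")["geneA"] == 100.0

    def test_zero_count_feature_rpm_zero(self):
        t = CountTable.from_gene_counts({"g": 0.0}, "s", total_mapped=1e6)
        assert normalize(t, "srna-rpm").series()["g"] == 0.0


class TestLengthHistogram:
    def test_mass_at_21_for_pirnas(self, tiny_index):
        alns = [_aln("chr1", 9500, 21, "+", "T", rid=f"r{i}") for i in range(5)]
        h = length_histogram(classify_alignments(alns, tiny_index), "mature_piRNA")
        assert h[21] == 5.0 and h.sum() == 5.0

    def test_empty_class_all_zero(self, tiny_index):
        h = length_histogram([], "g22_antisense")
        assert (h == 0).all()

    def test_histogram_sum_matches_weighted_total(self, std_bundle):
        h = length_histogram(std_bundle.classified, "g22_antisense")
        total = math.fsum(
            c.weight for c in std_bundle.classified if c.read_class == "g22_antisense"
        )
        assert h.sum() == pytest.approx(total, rel=1e-12)


class TestTruthRecovery:
    def test_rpm_correlates_with_truth(self, std_bundle):
        """Per-gene 22G RPM tracks the generator's abundance (Spearman >= 0.95)."""
        from scipy.stats import spearmanr

        norm = normalize(std_bundle.table, "srna-rpm")
        rpm = norm.series()
        mu = std_bundle.truth.mean_counts("wildtype", "total", std_bundle.spec.depth)
        genes = [g for g in mu.index if mu[g] > 0]
        rho = spearmanr(rpm.reindex(genes).fillna(0).values, mu[genes].values).statistic
        assert rho >= 0.95

    def test_generated_classes_match_biotype(self, std_bundle):
        """>= 99.9% of reads classify under their generating feature's rule."""
        from collections import Counter

        counts = Counter(c.read_class for c in std_bundle.classified)
        n_other = counts.get("other", 0) + counts.get("sense_feature", 0)
        assert n_other / sum(counts.values()) <= 0.001
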