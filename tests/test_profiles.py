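"""Depth tracks, metagene binning, tail enrichment, site windows."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pirnakit.classify import ClassifiedRead
from pirnakit.core import AlignmentRecord, GenomicInterval, TargetSite
from pirnakit.errors import DataError
from pirnakit.profiles import (
    metagene_profile,
    per_base_depth,
    site_window_profile,
    tail_enrichment,
)


def _g22(feature, start, length=22, weight=1.0, rid="r"):
    strand = "-" if feature.strand == "+" else "+"
    aln = AlignmentRecord(
        rid, length, "G", GenomicInterval(feature.chrom, start, start + length, strand)
    )
    return ClassifiedRead(aln, "g22_antisense", (feature.feature_id,), weight)


class TestPerBaseDepth:
    def test_single_read_covers_its_span(self, tiny_features):
        f = tiny_features["geneA"]  # plus strand, 1000..2000
        track = per_base_depth([_g22(f, 1010)], f, denominator=1e6)
        assert track[10:32].tolist() == [1.0] * 22
        assert track.sum() == 22.0

    def test_no_reads_all_zero(self, tiny_features):
        f = tiny_features["geneA"]
        assert per_base_depth([], f, 1e6).sum() == 0.0

    def test_overlapping_reads_add(self, tiny_features):
        f = tiny_features["geneA"]
        track = per_base_depth(
            [_g22(f, 1010, rid="a"), _g22(f, 1020, rid="b")], f, 1e6
        )
        assert track[20:32].tolist() == [2.0] * 12

    def test_minus_strand_flipped_to_transcript_orientation(self, tiny_features):
        f = tiny_features["geneB"]  # minus strand, 3000..3500
        # read at genomic 3478..3500 covers transcript positions 0..21
        track = per_base_depth([_g22(f, 3478)], f, 1e6)
        assert track[:22].sum() == 22.0 and track[22:].sum() == 0.0

    def test_spliced_two_exon_mapping(self, tiny_features):
        f = tiny_features["geneC"]  # minus strand, exons 5000-5100, 5200-5300
        # read spanning the intron genomically: covers 5090..5112;
        # only the 10 exonic bases 5090..5100 count, transcript pos 100..109
        track = per_base_depth([_g22(f, 5090)], f, 1e6)
        assert track.sum() == 10.0
        assert track[100:110].tolist() == [1.0] * 10


def _brute_force_bins(track, n_bins=100):
    """Independent per-position assignment: loop, no bincount."""
    bins = [0.0] * n_bins
    L = len(track)
    for p, v in enumerate(track):
        bins[(p * n_bins) // L] += v
    return np.array(bins)


class TestMetagene:
    def test_uniform_depth_exact_bins(self):
        prof = metagene_profile([np.ones(1000)])
        assert np.allclose(prof.bins, 10.0)

    def test_length_150_matches_brute_force(self):
        track = np.ones(150)
        prof = metagene_profile([track])
        assert prof.bins.sum() == 150.0
        assert set(np.unique(prof.bins)) == {1.0, 2.0}
        assert np.array_equal(prof.bins, _brute_force_bins(track))

    def test_tail_concentrated_mass_lands_in_last_bins(self):
        track = np.zeros(1000)
        track[900:] = 1.0
        prof = metagene_profile([track])
        assert prof.bins[90:].sum() == track.sum()

    @given(st.integers(1, 5000), st.integers(0, 10_000))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_mass_conserved_any_length(self, length, seed):
        """Sum over 100 bins equals per-base mass, any gene length."""
        rng = np.random.default_rng(seed)
        track = rng.exponential(1.0, size=length)
        prof = metagene_profile([track])
        assert prof.bins.sum() == pytest.approx(track.sum(), rel=1e-9)
        assert np.allclose(prof.bins, _brute_force_bins(track), rtol=1e-9)

    def test_empty_gene_set_rejected(self):
        with pytest.raises(DataError):
            metagene_profile([])


class TestTailEnrichment:
    @pytest.mark.parametrize(
        "head,tail,cls",
        [(9, 1, "non_enriched"), (8, 2, "medium"), (13, 7, "high"),
         (17, 3, "non_enriched"), (7, 3, "medium")],
    )
    def test_class_boundaries(self, head, tail, cls):
        # point masses make the tail fraction exact in floating point
        track = np.zeros(1000)
        track[0] = head
        track[999] = tail
        te = tail_enrichment(track)
        assert te.tail_fraction == tail / (head + tail)
        assert te.enrichment_class == cls

    @pytest.mark.parametrize("length", [997, 1000, 150, 23])
    def test_uniform_depth_is_non_enriched(self, length):
        te = tail_enrichment(np.ones(length))
        assert te.tail_fraction == pytest.approx(
            np.floor(0.15 * length) / length
        )
        assert te.enrichment_class == "non_enriched"

    def test_zero_track_undefined(self):
        te = tail_enrichment(np.zeros(100))
        assert np.isnan(te.tail_fraction) and te.enrichment_class is None


def _site(fid, anchor):
    return TargetSite(
        f"pi_{fid}_{anchor}", fid, anchor, GenomicInterval("chr1", 1, 2, "+")
    )


class TestSiteWindow:
    def test_delta_at_anchor(self):
        track = np.zeros(500)
        track[200] = 1.0
        prof = site_window_profile({"g": track}, [_site("g", 200)])
        assert prof.mean_depth[50] == 1.0  # position 0 of the window
        assert np.nansum(prof.mean_depth) == 1.0

    def test_out_of_transcript_positions_excluded_not_zero(self):
        track = np.ones(60)
        prof = site_window_profile({"g": track}, [_site("g", 10)])
        # positions before the transcript start have no data
        assert np.isnan(prof.mean_depth[: 50 - 10]).all()
        assert np.nanmean(prof.mean_depth) == 1.0

    def test_site_order_invariance(self):
        rng = np.random.default_rng(1)
        tracks = {f"g{i}": rng.random(400) for i in range(5)}
        sites = [_site(f"g{i}", 100 + 13 * i) for i in range(5)]
        a = site_window_profile(tracks, sites)
        b = site_window_profile(tracks, sites[::-1])
        assert np.array_equal(a.mean_depth, b.mean_depth, equal_nan=True)

    def test_no_usable_sites_rejected(self):
        with pytest.raises(DataError):
            site_window_profile({}, [_site("g", 10)])

    def test_planted_bumps_localize_to_anchor(self, std_bundle):
        """Simulated site bumps put the profile maximum within 3 nt of 0."""
        prof = site_window_profile(std_bundle.tracks, std_bundle.sites)
        peak = prof.positions[int(np.nanargmax(prof.mean_depth))]
        assert abs(peak) <= 3

    def test_null_profile_flat(self, null_bundle):
        prof = site_window_profile(null_bundle.tracks, null_bundle.sites)
        ratio = np.nanmax(prof.mean_depth) / np.nanmin(prof.mean_depth)
        assert ratio <= 1.2


class TestTailRecovery:
    def test_high_tau_genes_classified_high(self, std_bundle):
        """tau=0.40 genes (>= 100 expected reads) classify 'high' >= 95%."""
        truth = std_bundle.truth
        mu = truth.mean_counts("wildtype", "total", std_bundle.spec.depth)
        sited = {s.target_feature_id for s in std_bundle.sites}
        genes = [
            g
            for g in truth.genes.index
            if truth.genes.at[g, "tau"] == 0.40 and mu[g] >= 100 and g not in sited
        ]
        assert len(genes) >= 40
        hits = [
            tail_enrichment(std_bundle.tracks[g]).enrichment_class == "high"
            for g in genes
        ]
        assert np.mean(hits) >= 0.95

    def test_low_tau_genes_classified_non_enriched(self, lowtau_bundle):
        """tau=0.10 genes (>= 100 expected reads) classify 'non_enriched' >= 95%."""
        truth = lowtau_bundle.truth
        mu = truth.mean_counts("wildtype", "total", lowtau_bundle.spec.depth)
        sited = {s.target_feature_id for s in lowtau_bundle.sites}
        genes = [
            g
            for g in truth.genes.index
            if truth.genes.at[g, "tau"] == 0.10 and mu[g] >= 100 and g not in sited
        ]
        assert len(genes) >= 100
        hits = [
            tail_enrichment(lowtau_bundle.tracks[g]).enrichment_class
            == "non_enriched"
            for g in genes
        ]
        assert np.mean(hits) >= 0.95
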