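"""Shared fixtures: small synthetic bundles generated once per session."""

from __future__ import annotations

import dataclasses

import pytest

import pirnakit as pk
from pirnakit.classify import build_count_table, classify_alignments, FeatureIndex
from pirnakit.profiles import depth_tracks


@dataclasses.dataclass
class Bundle:
    """A simulated library taken through classification, with its truth."""

    config: pk.SimConfig
    features: dict
    cmap: pk.TargetClassMap
    sites: list
    truth: pk.SimTruth
    spec: pk.SampleSpec
    alignments: list
    classified: list
    table: object
    tracks: dict


def _make_bundle(config: pk.SimConfig, seed: int, spec: pk.SampleSpec) -> Bundle:
    features, cmap, sites, truth = pk.build_truth(config, seed)
    alns = pk.simulate_srna_library(truth, spec, features, sites)
    classified = classify_alignments(alns, FeatureIndex(features))
    table = build_count_table(classified, features, sample=spec.label)
    pc = {
        fid: f
        for fid, f in features.items()
        if f.biotype in ("protein_coding", "pseudogene", "transposon")
    }
    tracks = depth_tracks(classified, pc, table.denominator_srna)
    return Bundle(
        config, features, cmap, sites, truth, spec, alns, classified, table, tracks
    )


@pytest.fixture(scope="session")
def std_bundle() -> Bundle:
    """Default structure: site bumps, 3'-tails on CSR-1 targets, duplicated loci."""
    cfg = pk.SimConfig(
        n_protein_coding=300, n_duplicated_pairs=10, sites_per_targeted_gene=2
    )
    return _make_bundle(cfg, seed=11, spec=pk.SampleSpec("wildtype", "total", 3e5, 1))


@pytest.fixture(scope="session")
def lowtau_bundle() -> Bundle:
    """Genes with tail weight 0.10 (below the uniform 0.15 expectation)."""
    cfg = pk.SimConfig(n_protein_coding=300, n_duplicated_pairs=0, tau_default=0.10)
    return _make_bundle(cfg, seed=12, spec=pk.SampleSpec("wildtype", "total", 3e5, 1))


@pytest.fixture(scope="session")
def null_bundle() -> Bundle:
    """Positional null: no site bumps, flat tails everywhere."""
    cfg = pk.SimConfig(
        n_protein_coding=300,
        n_duplicated_pairs=0,
        site_bump_beta=0.0,
        tau_csr1=0.15,
        tau_enhanced=0.15,
    )
    return _make_bundle(cfg, seed=13, spec=pk.SampleSpec("wildtype", "total", 3e5, 2))


@pytest.fixture
def tiny_features() -> dict[str, pk.FeatureRecord]:
    """Hand-built features covering the classification rules."""
    I = pk.GenomicInterval
    F = pk.FeatureRecord
    feats = [
        F("geneA", (I("chr1", 1000, 2000, "+"),), "protein_coding"),
        F("geneB", (I("chr1", 3000, 3500, "-"),), "protein_coding"),
        # two-exon minus-strand gene for spliced-coordinate checks
        F("geneC", (I("chr1", 5000, 5100, "-"), I("chr1", 5200, 5300, "-")), "protein_coding"),
        F("rrna1", (I("chr1", 7000, 8000, "+"),), "rRNA"),
        F("mir1", (I("chr1", 9000, 9022, "+"),), "miRNA"),
        F("pi1", (I("chr1", 9500, 9521, "+"),), "piRNA"),
        F("tn1", (I("chr2", 100, 1100, "+"),), "transposon"),
    ]
    return {f.feature_id: f for f in feats}


@pytest.fixture
def tiny_index(tiny_features) -> FeatureIndex:
    return FeatureIndex(tiny_features)
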