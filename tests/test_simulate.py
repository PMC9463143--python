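"""Generator contracts: determinism, config forcing, and moment recovery."""

import math

import numpy as np
import pytest

import pirnakit as pk
from pirnakit.errors import ConfigError


class TestBuildTruth:
    def test_config_forces_class_counts(self):
        cfg = pk.SimConfig(n_protein_coding=300, wago_fraction=0.3)
        _, cmap, _, _ = pk.build_truth(cfg, seed=0)
        assert len(cmap.wago) == 90

    def test_subsets_within_parent_class(self, std_bundle):
        cmap = std_bundle.cmap
        assert cmap.prg1_dependent <= cmap.wago
        assert cmap.reduced_hrde1 <= cmap.wago
        assert cmap.enhanced_hrde1 <= cmap.csr1

    def test_same_seed_identical_truth(self):
        cfg = pk.SimConfig(n_protein_coding=50)
        f1, c1, s1, t1 = pk.build_truth(cfg, seed=9)
        f2, c2, s2, t2 = pk.build_truth(cfg, seed=9)
        assert f1 == f2 and s1 == s2
        assert c1.classes == c2.classes
        assert t1.genes.equals(t2.genes)

    def test_truth_serialization_round_trip(self, tmp_path, std_bundle):
        std_bundle.truth.to_dir(tmp_path / "truth")
        back = pk.SimTruth.from_dir(tmp_path / "truth")
        assert back.seed == std_bundle.truth.seed
        assert back.config == std_bundle.truth.config
        got = back.mean_counts("mutant", "ip_hrde1", 1e5)
        want = std_bundle.truth.mean_counts("mutant", "ip_hrde1", 1e5)
        assert np.allclose(got.values, want.values)

    def test_duplicated_loci_share_abundance(self, std_bundle):
        g = std_bundle.truth.genes
        dups = g[g.dup_partner.notna()]
        assert len(dups) == 20
        for fid, row in dups.iterrows():
            assert g.at[row.dup_partner, "lam"] == row.lam

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ConfigError):
            pk.SimConfig(wago_fraction=0.7, csr1_fraction=0.7)
        with pytest.raises(ConfigError):
            pk.SimConfig(tau_default=1.5)


class TestLibrarySimulation:
    def test_same_seed_identical_library(self, std_bundle):
        again = pk.simulate_srna_library(
            std_bundle.truth, std_bundle.spec, std_bundle.features, std_bundle.sites
        )
        assert again == std_bundle.alignments

    def test_unknown_condition_rejected(self):
        with pytest.raises(ConfigError):
            pk.SampleSpec("scrambled", "total")

    def test_count_moments_match_generator(self):
        """Observed weighted count stays within 3 sampling SD of lambda*phi."""
        cfg = pk.SimConfig(n_protein_coding=200, n_duplicated_pairs=0)
        _, _, _, truth = pk.build_truth(cfg, seed=2)
        depth = cfg.reference_depth
        mu = truth.mean_counts("wildtype", "total", depth)
        gene = mu.index[int(np.argmin(np.abs(mu.values - 100)))]
        m = mu[gene]
        var = m + cfg.dispersion * m * m
        obs = [
            pk.simulate_gene_counts(
                truth, pk.SampleSpec("wildtype", "total", depth, seed=s)
            )[gene]
            for s in range(20)
        ]
        assert abs(np.mean(obs) - m) <= 3 * math.sqrt(var / 20)

    def test_fourfold_fold_effect_recovered(self):
        """Planted phi=0.25 genes show median log2(mut/wt) ~ -2."""
        cfg = pk.SimConfig(n_protein_coding=500, n_duplicated_pairs=0)
        _, cmap, _, truth = pk.build_truth(cfg, seed=3)
        depth = 1e6
        wt = pk.simulate_gene_counts(truth, pk.SampleSpec("wildtype", "total", depth, 1))
        mut = pk.simulate_gene_counts(truth, pk.SampleSpec("mutant", "total", depth, 1))
        mu = truth.mean_counts("wildtype", "total", depth)
        genes = [g for g in sorted(cmap.prg1_dependent) if mu[g] >= 200][:50]
        lfc = np.log2((mut[genes] + 0.5) / (wt[genes] + 0.5))
        assert np.median(lfc) == pytest.approx(-2.0, abs=0.3)

    def test_g22_reads_have_g22_geometry(self, std_bundle):
        g22 = [
            c.alignment
            for c in std_bundle.classified
            if c.read_class == "g22_antisense"
        ]
        assert g22, "no 22G reads simulated"
        assert all(a.length in (21, 22, 23) for a in g22)
        assert all(a.five_prime_nt == "G" for a in g22)

    def test_pirna_reads_are_21nt_5u_sense(self, std_bundle):
        pis = [
            c.alignment
            for c in std_bundle.classified
            if c.read_class == "mature_piRNA"
        ]
        assert pis
        assert all(a.length == 21 and a.five_prime_nt == "T" for a in pis)

    def test_multimapper_fraction_present(self, std_bundle):
        multi = [a for a in std_bundle.alignments if a.n_loci > 1]
        assert multi and all(a.n_loci == 2 for a in multi)


class TestMrnaCounts:
    def test_psi_effect_recovered(self):
        """Planted mRNA doubling (psi=2) recovered as a ~2x mean ratio."""
        cfg = pk.SimConfig(n_protein_coding=500, n_duplicated_pairs=0)
        _, cmap, _, truth = pk.build_truth(cfg, seed=4)
        depth = 1e6
        wt = pk.simulate_mrna_counts(
            truth, pk.SampleSpec("wildtype", "mrna", depth, 1)
        ).set_index("feature_id")["count"]
        mut = pk.simulate_mrna_counts(
            truth, pk.SampleSpec("mutant", "mrna", depth, 1)
        ).set_index("feature_id")["count"]
        genes = [g for g in sorted(cmap.prg1_dependent) if wt[g] >= 100][:50]
        ratio = (mut[genes] / wt[genes]).mean()
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_zero_expression_gene_always_zero(self):
        cfg = pk.SimConfig(n_protein_coding=50, n_duplicated_pairs=0)
        _, _, _, truth = pk.build_truth(cfg, seed=5)
        truth.genes.loc[truth.genes.index[0], "mu_mrna"] = 0.0
        c = pk.simulate_mrna_counts(truth, pk.SampleSpec("wildtype", "mrna", 1e5, 1))
        assert c.set_index("feature_id")["count"][truth.genes.index[0]] == 0

    def test_same_seed_identical_table(self):
        cfg = pk.SimConfig(n_protein_coding=50, n_duplicated_pairs=0)
        _, _, _, truth = pk.build_truth(cfg, seed=6)
        spec = pk.SampleSpec("wildtype", "mrna", 1e5, 3)
        a = pk.simulate_mrna_counts(truth, spec)
        b = pk.simulate_mrna_counts(truth, spec)
        assert a.equals(b)


class TestGranuleImages:
    def test_full_overlap_recovered_noiselessly(self):
        from pirnakit.imaging import measure_colocalization
        from pirnakit.simulate import dog_spot_response

        stack, _ = pk.simulate_granule_images(
            overlap_fraction=1.0, noise_sigma=0.0, seed=1
        )
        thr = 0.25 * dog_spot_response(100.0)
        assert measure_colocalization(stack[0], stack[1], thr, thr) > 0.99

    def test_zero_overlap_separated_spots(self):
        from pirnakit.imaging import measure_colocalization
        from pirnakit.simulate import dog_spot_response

        stack, _ = pk.simulate_granule_images(
            overlap_fraction=0.0, noise_sigma=0.0, seed=2
        )
        thr = 0.25 * dog_spot_response(100.0)
        assert measure_colocalization(stack[0], stack[1], thr, thr) < 0.01

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            pk.simulate_granule_images(overlap_fraction=1.2)

    def test_deterministic(self):
        a, ta = pk.simulate_granule_images(seed=9)
        b, tb = pk.simulate_granule_images(seed=9)
        assert np.array_equal(a, b) and ta == tb
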