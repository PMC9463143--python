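"""Metagene, 3'-tail, and piRNA-site-centered density profiles.

CSR-1 targets are simulated with 40% of their 22G coverage in the last 15%
of the transcript; WAGO targets carry localized density bumps at piRNA
target sites. This script recovers both signatures.
"""

import numpy as np

import pirnakit as pk
from pirnakit.profiles import (
    depth_tracks,
    metagene_profile,
    site_window_profile,
    tail_enrichment_table,
)

config = pk.SimConfig(n_protein_coding=300, n_duplicated_pairs=0)
features, classes, sites, truth = pk.build_truth(config, seed=2)
spec = pk.SampleSpec("wildtype", "total", depth=300_000, seed=1)
alignments = pk.simulate_srna_library(truth, spec, features, sites)
classified = pk.classify_alignments(alignments, pk.FeatureIndex(features))
table = pk.build_count_table(classified, features)

gene_features = {
    fid: f for fid, f in features.items()
    if f.biotype in ("protein_coding", "pseudogene", "transposon")
}
tracks = depth_tracks(classified, gene_features, table.denominator_srna)

# metagene: 100 bins, mass-conserving floor binning
csr1 = sorted(classes.csr1 - classes.enhanced_hrde1)
prof = metagene_profile([tracks[g] for g in csr1])
last15 = prof.bins[85:].sum() / prof.bins.sum()
print(f"CSR-1 targets metagene: {100 * last15:.1f}% of depth in last 15 bins "
      "(planted 3'-tail weight 0.40)")

# 3'-tail classes per gene
tail = tail_enrichment_table({g: tracks[g] for g in csr1})
print("tail classes among CSR-1 targets:",
      tail.enrichment_class.value_counts().to_dict())

# piRNA-site window: mean RPM per position, anchor (piRNA nt 10) at 0
site_prof = site_window_profile(tracks, sites)
peak = site_prof.positions[int(np.nanargmax(site_prof.mean_depth))]
enrich = np.nanmax(site_prof.mean_depth) / np.nanmedian(site_prof.mean_depth)
print(f"site-centered profile: peak at {peak:+d} nt from the anchor, "
      f"{enrich:.1f}x over the window median ({site_prof.n_sites} sites)")
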