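"""End-to-end orchestration: simulate -> classify -> normalize -> analytics.

A run is driven by a :class:`RunConfig` (single YAML file); every output
table is deterministic given (config, seed) and the run manifest records the
config hash, the seed, and the SHA-256 of every artifact.  The manifest is
written last: its absence marks partial outputs as stale.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .classify import CountTable, FeatureIndex, classify_alignments, build_count_table, normalize
from .differential import PriorSpec, call_differential, quadrant_analysis, summarize_directions
from .errors import ConfigError, PirnakitError
from .ipratio import compute_ratio
from .profiles import depth_tracks, metagene_profile, site_window_profile, tail_enrichment_table
from .simulate import SampleSpec, SimConfig, build_truth, simulate_mrna_counts, simulate_srna_library


@dataclasses.dataclass
class RunConfig:
    """Whole-pipeline configuration with per-module parameter blocks."""

    outdir: str = "pirnakit_run"
    seed: int = 0
    depth_total: float = 300_000.0
    depth_ip: float = 300_000.0
    depth_mrna: float = 300_000.0
    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    diff_alpha: float = 0.05
    diff_fold_threshold: float = 2.0
    diff_pseudocount: float = 1.0
    prior_a: float = 1.0
    prior_b: float = 1.0
    ratio_pseudocount: float = 0.1
    metagene_bins: int = 100
    site_halfwidth: int = 50

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        if "sim" in data and isinstance(data["sim"], dict):
            sim_known = {f.name for f in dataclasses.fields(SimConfig)}
            sim_unknown = set(data["sim"]) - sim_known
            if sim_unknown:
                raise ConfigError(f"unknown sim config keys: {sorted(sim_unknown)}")
            data["sim"] = SimConfig(**data["sim"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_canonical_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=True)

    @property
    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output path excluded)."""
        d = dataclasses.asdict(self)
        d.pop("outdir")
        return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full synthetic pipeline and return the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    stage = "setup"
    try:
        stage = "simulate"
        features, cmap, sites, truth = build_truth(config.sim, config.seed)
        pio.write_annotations_gff3(features.values(), outdir / "annotation.gff3")
        pio.write_target_classes(cmap, outdir / "target_classes.tsv")
        pio.write_target_sites(sites, outdir / "sites.bed", outdir / "sites_anchor.tsv")
        truth.to_dir(outdir / "truth")
        artifacts += [
            outdir / "annotation.gff3",
            outdir / "target_classes.tsv",
            outdir / "sites.bed",
            outdir / "sites_anchor.tsv",
        ]

        specs = {
            "wt_total": SampleSpec("wildtype", "total", config.depth_total, 1),
            "mut_total": SampleSpec("mutant", "total", config.depth_total, 2),
            "wt_ip_hrde1": SampleSpec("wildtype", "ip_hrde1", config.depth_ip, 3),
            "wt_ip_csr1": SampleSpec("wildtype", "ip_csr1", config.depth_ip, 4),
            "mut_ip_hrde1": SampleSpec("mutant", "ip_hrde1", config.depth_ip, 5),
        }
        stage = "classify"
        index = FeatureIndex(features)
        tables: dict[str, CountTable] = {}
        norms = {}
        classified = {}
        for name, spec in specs.items():
            alns = simulate_srna_library(truth, spec, features, sites)
            pio.write_alignments_bed(alns, outdir / f"{name}.bed")
            artifacts.append(outdir / f"{name}.bed")
            cl = classify_alignments(alns, index)
            classified[name] = cl
            table = build_count_table(cl, features, sample=name)
            table.to_tsv(outdir / f"{name}_counts.tsv")
            artifacts.append(outdir / f"{name}_counts.tsv")
            tables[name] = table
            norm = normalize(table, "srna-rpm")
            norms[name] = norm
            pio.write_table(norm.values, outdir / f"{name}_rpm.tsv")
            artifacts.append(outdir / f"{name}_rpm.tsv")

        stage = "differential"
        prior = PriorSpec(config.prior_a, config.prior_b)
        diff = call_differential(
            tables["wt_total"],
            tables["mut_total"],
            cmap.wago,
            prior=prior,
            alpha=config.diff_alpha,
            fold_threshold=config.diff_fold_threshold,
            pseudocount=config.diff_pseudocount,
        )
        pio.write_table(diff, outdir / "diff_wago.tsv")
        artifacts.append(outdir / "diff_wago.tsv")
        diff_summary = summarize_directions(diff)

        stage = "quadrants"
        mrna = {}
        for cond, sd in (("wildtype", 6), ("mutant", 7)):
            counts = simulate_mrna_counts(
                truth, SampleSpec(cond, "mrna", config.depth_mrna, sd)
            )
            mrna[cond] = counts.set_index("feature_id")["count"]
        lengths = pd.Series(
            {fid: features[fid].spliced_length for fid in mrna["wildtype"].index}
        )
        rpkm = {
            c: v * 1e6 / (lengths / 1000.0 * v.sum()) for c, v in mrna.items()
        }
        mrna_lfc = np.log2((rpkm["mutant"] + 1) / (rpkm["wildtype"] + 1))
        srna_lfc = diff.set_index("feature_id")["log2_fold_change"]
        prg1 = sorted(cmap.prg1_dependent)
        quad = quadrant_analysis(mrna_lfc, srna_lfc, prg1)
        pio.write_table(
            pd.DataFrame([quad]), outdir / "quadrants_prg1_dependent.tsv"
        )
        artifacts.append(outdir / "quadrants_prg1_dependent.tsv")

        stage = "profiles"
        pc_features = {
            fid: f for fid, f in features.items()
            if f.biotype in ("protein_coding", "pseudogene", "transposon")
        }
        tracks = depth_tracks(
            classified["wt_total"], pc_features, tables["wt_total"].denominator_srna
        )
        meta = metagene_profile(
            [tracks[g] for g in sorted(cmap.wago)], config.metagene_bins
        )
        pio.write_table(
            pd.DataFrame(
                {"bin": np.arange(config.metagene_bins), "depth": meta.bins}
            ),
            outdir / "metagene_wago.tsv",
        )
        artifacts.append(outdir / "metagene_wago.tsv")

        csr_tracks = depth_tracks(
            classified["wt_ip_csr1"], pc_features, tables["wt_ip_csr1"].denominator_srna
        )
        tail = tail_enrichment_table(
            {g: csr_tracks[g] for g in sorted(cmap.csr1)}
        )
        pio.write_table(tail, outdir / "tail_enrichment_csr1.tsv")
        artifacts.append(outdir / "tail_enrichment_csr1.tsv")

        site_prof = site_window_profile(tracks, sites, config.site_halfwidth)
        pio.write_table(
            pd.DataFrame(
                {"position": site_prof.positions, "mean_depth": site_prof.mean_depth}
            ),
            outdir / "site_profile_wago.tsv",
        )
        artifacts.append(outdir / "site_profile_wago.tsv")

        stage = "ratio"
        ratio = compute_ratio(
            norms["wt_ip_hrde1"],
            norms["wt_ip_csr1"],
            cmap.csr1,
            pseudocount=config.ratio_pseudocount,
        )
        pio.write_table(ratio, outdir / "ratio_csr1.tsv")
        artifacts.append(outdir / "ratio_csr1.tsv")

        stage = "manifest"
        manifest = {
            "config_hash": config.config_hash,
            "seed": config.seed,
            "config": yaml.safe_load(config.to_canonical_yaml()),
            "diff_summary": diff_summary,
            "artifacts": {
                str(p.relative_to(outdir)): _sha256(p) for p in sorted(artifacts)
            },
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except PirnakitError as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc
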