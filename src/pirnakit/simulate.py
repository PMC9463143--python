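"""Synthetic annotation, small-RNA/mRNA library, and image generation.

The generator builds a synthetic genome of non-overlapping single-exon
features (deliberate duplicated gene pairs excepted), a target-class map
(WAGO / CSR-1 targets with prg1-dependent, reduced-HRDE-1 and
enhanced-HRDE-1 subsets), piRNA target sites on WAGO targets, and ground
truth (:class:`SimTruth`) from which small-RNA libraries, IP libraries,
mRNA count tables, and two-channel granule images are simulated.

Statistical structure:

* per-gene 22G counts are gamma-Poisson (negative binomial) around
  ``lambda_g * phi_{g,cond} * eps_{g,ab} * depth / reference_depth`` with a
  single global dispersion (variance = mu + dispersion * mu^2);
* read positions are a mixture of uniform coverage, a 3'-tail component
  whose total tail mass is the recoverable parameter ``tau_g``, and
  Gaussian bumps at piRNA target-site anchors (mass ``beta`` per site,
  half-width-at-half-max ``site_halfwidth``);
* 22G reads are 21–23 nt, 5'G, antisense to their gene; piRNA-locus reads
  are 21 nt, 5'U, sense; miRNA reads are mature sense reads; structural
  features shed sense degradation fragments;
* reads from a duplicated gene pair are reported at both loci with
  ``n_loci = 2``;
* every output is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .core import (
    AlignmentRecord,
    FeatureRecord,
    GenomicInterval,
    TargetClassMap,
    TargetSite,
)
from .errors import ConfigError
from . import io as pio

CONDITIONS = ("wildtype", "mutant")
KINDS = ("total", "ip_hrde1", "ip_csr1", "mrna")

_HWHM_TO_SIGMA = 1.0 / math.sqrt(2.0 * math.log(2.0))


@dataclasses.dataclass
class SimConfig:
    """Generator configuration; defaults define the simulated study conditions."""

    # genome composition
    n_protein_coding: int = 2000
    n_pseudogene: int = 30
    n_transposon: int = 40
    n_rrna: int = 4
    n_trna: int = 20
    n_snorna: int = 10
    n_mirna: int = 30
    n_pirna: int = 60
    gene_length_min: int = 500
    gene_length_max: int = 3000
    n_duplicated_pairs: int = 20

    # target classes
    wago_fraction: float = 0.3
    csr1_fraction: float = 0.3
    prg1_dependent_fraction: float = 0.5  # of WAGO targets
    reduced_hrde1_fraction: float = 0.3  # of WAGO targets
    enhanced_hrde1_fraction: float = 0.15  # of CSR-1 targets

    # abundance & noise
    reference_depth: float = 1_000_000.0
    lambda_sigma: float = 1.2  # lognormal spread of baseline abundance
    dispersion: float = 0.005  # NB: var = mu + dispersion * mu^2

    # library composition (fractions of total reads)
    frac_structural: float = 0.15
    frac_pirna: float = 0.05
    frac_mirna: float = 0.03

    # positional structure
    tau_default: float = 0.15  # uniform expectation of the last-15% mass
    tau_csr1: float = 0.40  # CSR-1 targets are 3'-end concentrated
    tau_enhanced: float = 0.15  # enhanced-HRDE-1 genes lose that concentration
    sites_per_targeted_gene: int = 2
    site_bump_beta: float = 0.10  # read-mass fraction per site bump
    site_halfwidth: int = 10  # half-width at half max, nt

    # condition fold effects
    phi_prg1_mutant: float = 0.25  # prg1-dependent WAGO 22Gs, mutant
    phi_enhanced_hrde1_mutant: float = 4.0  # enhanced genes in HRDE-1 IP, mutant
    phi_reduced_hrde1_mutant: float = 0.25  # reduced genes in HRDE-1 IP, mutant
    psi_prg1_mutant: float = 2.0  # mRNA of prg1-dependent genes, mutant
    psi_enhanced_mutant: float = 0.5  # mRNA of enhanced genes, mutant

    # IP enrichment factors (per antibody, per target class)
    eps_hrde_wago: float = 8.0
    eps_hrde_csr1: float = 0.5
    eps_hrde_enhanced: float = 2.0
    eps_hrde_none: float = 1.0
    eps_csr_csr1: float = 8.0
    eps_csr_wago: float = 2.0
    eps_csr_none: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "wago_fraction",
            "csr1_fraction",
            "prg1_dependent_fraction",
            "reduced_hrde1_fraction",
            "enhanced_hrde1_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.wago_fraction + self.csr1_fraction > 1.0 + 1e-9:
            raise ConfigError("wago_fraction + csr1_fraction exceeds 1")
        if self.frac_structural + self.frac_pirna + self.frac_mirna >= 1.0:
            raise ConfigError("library composition fractions sum to >= 1")
        if not 0.0 <= self.tau_default <= 1.0:
            raise ConfigError("tau_default outside [0, 1]")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclasses.dataclass
class SampleSpec:
    """One library to simulate."""

    condition: str
    kind: str  # total | ip_hrde1 | ip_csr1 | mrna
    depth: float = 1_000_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ConfigError(f"unknown condition {self.condition!r}")
        if self.kind not in KINDS:
            raise ConfigError(f"unknown library kind {self.kind!r}")
        if self.depth <= 0:
            raise ConfigError("depth must be > 0")

    @property
    def label(self) -> str:
        return f"{self.condition}_{self.kind}_s{self.seed}"


@dataclasses.dataclass
class SimTruth:
    """Ground truth: per-gene parameters, effect structure, and the seed."""

    genes: pd.DataFrame  # feature_id-indexed: biotype, target_class, subsets,
    #                      lam, tau, length, dup_partner
    other_weights: dict[str, pd.Series]  # structural / pirna / mirna shares
    config: SimConfig
    seed: int

    def mean_counts(self, condition: str, kind: str, depth: float) -> pd.Series:
        """Expected weighted 22G read count per gene for one library."""
        if condition not in CONDITIONS:
            raise ConfigError(f"unknown condition {condition!r}")
        if kind not in KINDS:
            raise ConfigError(f"unknown library kind {kind!r}")
        cfg = self.config
        g = self.genes
        mu = g["lam"].astype(float).copy()
        if condition == "mutant":
            mu[g["prg1_dependent"]] *= cfg.phi_prg1_mutant
        if kind == "ip_hrde1":
            eps = pd.Series(cfg.eps_hrde_none, index=g.index)
            eps[g["target_class"] == "WAGO"] = cfg.eps_hrde_wago
            eps[g["target_class"] == "CSR1"] = cfg.eps_hrde_csr1
            eps[g["enhanced_hrde1"]] = cfg.eps_hrde_enhanced
            mu *= eps
            if condition == "mutant":
                mu[g["enhanced_hrde1"]] *= cfg.phi_enhanced_hrde1_mutant
                mu[g["reduced_hrde1"]] *= cfg.phi_reduced_hrde1_mutant
        elif kind == "ip_csr1":
            eps = pd.Series(cfg.eps_csr_none, index=g.index)
            eps[g["target_class"] == "WAGO"] = cfg.eps_csr_wago
            eps[g["target_class"] == "CSR1"] = cfg.eps_csr_csr1
            mu *= eps
        return mu * (depth / cfg.reference_depth)

    def mrna_means(self, condition: str, depth: float) -> pd.Series:
        """Expected mRNA count per gene (protein-coding only)."""
        cfg = self.config
        g = self.genes
        pc = g[g["biotype"] == "protein_coding"]
        mu = pc["mu_mrna"].astype(float).copy()
        if condition == "mutant":
            mu[pc["prg1_dependent"]] *= cfg.psi_prg1_mutant
            mu[pc["enhanced_hrde1"]] *= cfg.psi_enhanced_mutant
        return mu * (depth / cfg.reference_depth)

    # -- serialization ------------------------------------------------------

    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pio.write_table(
            self.genes.reset_index().rename(columns={"index": "feature_id"}),
            outdir / "truth_genes.tsv",
        )
        for name, series in self.other_weights.items():
            pio.write_table(
                series.rename("weight").rename_axis("feature_id").reset_index(),
                outdir / f"truth_{name}_weights.tsv",
            )
        meta = {"seed": self.seed, "config": dataclasses.asdict(self.config)}
        with open(outdir / "truth_meta.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)

    @classmethod
    def from_dir(cls, outdir: str | Path) -> "SimTruth":
        outdir = Path(outdir)
        with open(outdir / "truth_meta.yaml") as fh:
            meta = yaml.safe_load(fh)
        genes = pio.read_table(outdir / "truth_genes.tsv", index_col="feature_id")
        for col in ("prg1_dependent", "reduced_hrde1", "enhanced_hrde1"):
            genes[col] = genes[col].astype(bool)
        weights = {}
        for name in ("structural", "pirna", "mirna"):
            p = outdir / f"truth_{name}_weights.tsv"
            if p.exists():
                df = pio.read_table(p, index_col="feature_id")
                weights[name] = df["weight"]
        return cls(
            genes=genes,
            other_weights=weights,
            config=SimConfig(**meta["config"]),
            seed=meta["seed"],
        )


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson counts: variance = mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion > 0:
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mean[pos] * dispersion)
    else:
        lam = mean[pos]
    out[pos] = rng.poisson(lam)
    return out


# ---------------------------------------------------------------------------
# truth construction


def build_truth(
    config: SimConfig = SimConfig(), seed: int = 0
) -> tuple[dict[str, FeatureRecord], TargetClassMap, list[TargetSite], SimTruth]:
    """Build the annotation + target classes + piRNA sites + ground truth.

    Features are laid out non-overlapping on synthetic chromosomes (gap 100
    nt, ~400 features per chromosome); duplicated pairs are equal-length
    protein-coding genes whose reads multimap across both loci.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11CE]))

    specs: list[tuple[str, str, int]] = []  # (feature_id, biotype, length)
    for i in range(config.n_protein_coding):
        L = int(rng.integers(config.gene_length_min, config.gene_length_max + 1))
        specs.append((f"gene{i:05d}", "protein_coding", L))
    for i in range(config.n_pseudogene):
        specs.append((f"pseudo{i:03d}", "pseudogene",
                      int(rng.integers(300, 1500))))
    for i in range(config.n_transposon):
        specs.append((f"tn{i:03d}", "transposon", int(rng.integers(500, 4000))))
    for i in range(config.n_rrna):
        specs.append((f"rrna{i:02d}", "rRNA", int(rng.integers(1500, 3500))))
    for i in range(config.n_trna):
        specs.append((f"trna{i:02d}", "tRNA", int(rng.integers(70, 90))))
    for i in range(config.n_snorna):
        specs.append((f"sno{i:02d}", "snoRNA", int(rng.integers(60, 200))))
    for i in range(config.n_mirna):
        specs.append((f"mir{i:02d}", "miRNA", 22))
    for i in range(config.n_pirna):
        specs.append((f"21ur-{i:03d}", "piRNA", 21))

    # duplicated pairs: clone the first n_duplicated_pairs protein-coding genes
    n_dup = min(config.n_duplicated_pairs, config.n_protein_coding)
    dup_partner: dict[str, str] = {}
    for i in range(n_dup):
        src_id = f"gene{i:05d}"
        twin_id = f"gene{i:05d}dup"
        src_len = next(L for fid, bt, L in specs if fid == src_id)
        specs.append((twin_id, "protein_coding", src_len))
        dup_partner[src_id] = twin_id
        dup_partner[twin_id] = src_id

    order = rng.permutation(len(specs))
    features: dict[str, FeatureRecord] = {}
    per_chrom = 400
    gap = 100
    pos = gap
    chrom_idx = 0
    for rank, oi in enumerate(order):
        if rank and rank % per_chrom == 0:
            chrom_idx += 1
            pos = gap
        fid, biotype, L = specs[oi]
        strand = "+" if rng.random() < 0.5 else "-"
        iv = GenomicInterval(f"sim{chrom_idx + 1}", pos, pos + L, strand)
        features[fid] = FeatureRecord(fid, (iv,), biotype)
        pos += L + gap

    # target classes over protein-coding genes (duplicated twins excluded so
    # multimapping and differential effects stay orthogonal)
    pc_ids = [f"gene{i:05d}" for i in range(config.n_protein_coding)
              if f"gene{i:05d}" not in dup_partner]
    pc_ids = list(rng.permutation(pc_ids))
    n_wago = int(round(config.wago_fraction * config.n_protein_coding))
    n_csr1 = int(round(config.csr1_fraction * config.n_protein_coding))
    n_wago = min(n_wago, len(pc_ids))
    n_csr1 = min(n_csr1, len(pc_ids) - n_wago)
    wago = pc_ids[:n_wago]
    csr1 = pc_ids[n_wago : n_wago + n_csr1]
    cmap = TargetClassMap()
    for g in wago:
        cmap.classes[g] = "WAGO"
    for g in csr1:
        cmap.classes[g] = "CSR1"
    for fid, _, _ in specs:
        if features[fid].biotype == "protein_coding" and fid not in cmap.classes:
            cmap.classes[fid] = "none"
    cmap.prg1_dependent = set(
        wago[: int(round(config.prg1_dependent_fraction * len(wago)))]
    )
    cmap.reduced_hrde1 = set(
        wago[len(wago) - int(round(config.reduced_hrde1_fraction * len(wago))) :]
    )
    cmap.enhanced_hrde1 = set(
        csr1[: int(round(config.enhanced_hrde1_fraction * len(csr1)))]
    )
    cmap.validate()

    # per-gene truth table over all 22G-producing features
    g22_ids = [
        fid
        for fid, bt, _ in specs
        if bt in ("protein_coding", "pseudogene", "transposon")
    ]
    raw = rng.lognormal(mean=0.0, sigma=config.lambda_sigma, size=len(g22_ids))
    lam = pd.Series(raw, index=g22_ids)
    for src, twin in dup_partner.items():
        if src < twin:  # assign once per pair: identical loci, identical abundance
            lam[twin] = lam[src]
    g22_budget = (
        1.0 - config.frac_structural - config.frac_pirna - config.frac_mirna
    )
    lam = lam / lam.sum() * g22_budget * config.reference_depth

    genes = pd.DataFrame(index=pd.Index(g22_ids, name="feature_id"))
    genes["biotype"] = [features[f].biotype for f in g22_ids]
    genes["target_class"] = [cmap.target_class(f) for f in g22_ids]
    genes["prg1_dependent"] = [f in cmap.prg1_dependent for f in g22_ids]
    genes["reduced_hrde1"] = [f in cmap.reduced_hrde1 for f in g22_ids]
    genes["enhanced_hrde1"] = [f in cmap.enhanced_hrde1 for f in g22_ids]
    genes["length"] = [features[f].spliced_length for f in g22_ids]
    genes["lam"] = lam
    tau = pd.Series(config.tau_default, index=g22_ids)
    tau[genes["target_class"] == "CSR1"] = config.tau_csr1
    tau[genes["enhanced_hrde1"]] = config.tau_enhanced
    genes["tau"] = tau
    genes["dup_partner"] = [dup_partner.get(f) for f in g22_ids]
    mrna_raw = rng.lognormal(mean=0.0, sigma=1.0, size=len(g22_ids))
    mrna_mu = pd.Series(mrna_raw, index=g22_ids)
    mrna_mu[genes["biotype"] != "protein_coding"] = 0.0
    genes["mu_mrna"] = mrna_mu / mrna_mu.sum() * config.reference_depth

    # piRNA target sites on WAGO targets
    sites: list[TargetSite] = []
    for g in sorted(cmap.wago):
        f = features[g]
        L = f.spliced_length
        for j in range(config.sites_per_targeted_gene):
            anchor = int(rng.integers(60, max(61, L - 60)))
            gpos = _transcript_to_genomic(f, anchor)
            loc = GenomicInterval(
                f.chrom, max(0, gpos - 10), gpos + 11, "-" if f.strand == "+" else "+"
            )
            sites.append(
                TargetSite(
                    pirna_id=f"site_{g}_{j}",
                    target_feature_id=g,
                    anchor=anchor,
                    location=loc,
                )
            )

    weights = {}
    for name, biotype in (
        ("structural", None),
        ("pirna", "piRNA"),
        ("mirna", "miRNA"),
    ):
        if name == "structural":
            ids = [f for f, bt, _ in specs if bt in ("rRNA", "tRNA", "snoRNA")]
        else:
            ids = [f for f, bt, _ in specs if bt == biotype]
        w = rng.lognormal(0.0, 1.0, size=len(ids)) if ids else np.array([])
        s = pd.Series(w, index=ids)
        weights[name] = s / s.sum() if len(s) else s

    truth = SimTruth(genes=genes, other_weights=weights, config=config, seed=seed)
    return features, cmap, sites, truth


def _transcript_to_genomic(feature: FeatureRecord, t: int) -> int:
    """Inverse of FeatureRecord.genomic_to_transcript for single/multi exon."""
    L = feature.spliced_length
    if not 0 <= t < L:
        raise ConfigError(f"transcript position {t} outside feature")
    fwd = t if feature.strand == "+" else L - 1 - t
    offset = 0
    for iv in feature.intervals:
        if fwd < offset + len(iv):
            return iv.start + (fwd - offset)
        offset += len(iv)
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# library simulation


def simulate_gene_counts(
    truth: SimTruth, spec: SampleSpec, rng: np.random.Generator | None = None
) -> pd.Series:
    """Negative-binomial per-gene weighted 22G counts for one library.

    This is the count-level marginal of :func:`simulate_srna_library`;
    duplicated-pair multimapping leaves these weighted counts unchanged in
    expectation (each read contributes 1/2 at both loci of equal abundance).
    """
    if rng is None:
        rng = _sample_rng(truth, spec)
    mu = truth.mean_counts(spec.condition, spec.kind, spec.depth)
    counts = _nb_counts(rng, mu.values, truth.config.dispersion)
    return pd.Series(counts, index=mu.index, name="count")


def _sample_rng(truth: SimTruth, spec: SampleSpec) -> np.random.Generator:
    kind_id = KINDS.index(spec.kind)
    cond_id = CONDITIONS.index(spec.condition)
    return np.random.default_rng(
        np.random.SeedSequence([truth.seed, spec.seed, cond_id, kind_id])
    )


def simulate_srna_library(
    truth: SimTruth,
    spec: SampleSpec,
    features: Mapping[str, FeatureRecord],
    sites: Iterable[TargetSite] = (),
) -> list[AlignmentRecord]:
    """Simulate one aligned small-RNA library as alignment records.

    Gene-antisense 22G reads follow the per-gene positional mixture
    (uniform / 3'-tail / site bumps); structural, mature piRNA, and mature
    miRNA sense reads fill their configured library fractions.  Reads from
    duplicated loci are reported at both loci with ``n_loci = 2``.
    """
    if spec.kind == "mrna":
        raise ConfigError("use simulate_mrna_counts for mRNA libraries")
    cfg = truth.config
    rng = _sample_rng(truth, spec)
    out: list[AlignmentRecord] = []
    label = spec.label
    serial = 0

    site_map: dict[str, list[TargetSite]] = {}
    for s in sites:
        site_map.setdefault(s.target_feature_id, []).append(s)

    counts = simulate_gene_counts(truth, spec, rng)
    sigma_bump = cfg.site_halfwidth * _HWHM_TO_SIGMA
    for fid, n in counts.items():
        if n == 0:
            continue
        f = features[fid]
        L = f.spliced_length
        tau = float(truth.genes.at[fid, "tau"])
        gsites = site_map.get(fid, [])
        centers = _sample_positions(rng, int(n), L, tau, gsites, cfg.site_bump_beta,
                                    sigma_bump)
        lengths = rng.integers(21, 24, size=int(n))
        starts_t = np.clip(centers - lengths // 2, 0, np.maximum(L - lengths, 0))
        twin = truth.genes.at[fid, "dup_partner"]
        twin_f = features[twin] if isinstance(twin, str) else None
        n_loci = 2 if twin_f is not None else 1
        for st, ln in zip(starts_t, lengths):
            rid = f"{label}:r{serial}"
            serial += 1
            out.append(_antisense_record(rid, f, int(st), int(ln), n_loci))
            if twin_f is not None:
                out.append(_antisense_record(rid, twin_f, int(st), int(ln), n_loci))

    # structural / mature piRNA / mature miRNA sense reads
    comp = {
        "structural": cfg.frac_structural,
        "pirna": cfg.frac_pirna,
        "mirna": cfg.frac_mirna,
    }
    for name, frac in comp.items():
        weights = truth.other_weights.get(name)
        if weights is None or not len(weights):
            continue
        mu = weights.values * frac * spec.depth
        ns = _nb_counts(rng, mu, cfg.dispersion)
        for fid, n in zip(weights.index, ns):
            if n == 0:
                continue
            f = features[fid]
            L = f.spliced_length
            for _ in range(int(n)):
                rid = f"{label}:r{serial}"
                serial += 1
                if name == "structural":
                    ln = int(rng.integers(17, 36))
                    ln = min(ln, L)
                    st = int(rng.integers(0, L - ln + 1))
                    nt = "ACGT"[rng.integers(4)]
                else:
                    ln, st = L, 0  # mature read spans the annotated locus
                    nt = "T" if name == "pirna" else "ACGT"[rng.integers(4)]
                gstart = _transcript_to_genomic(f, st + ln - 1 if f.strand == "-" else st)
                out.append(
                    AlignmentRecord(
                        read_id=rid,
                        length=ln,
                        five_prime_nt=nt,
                        location=GenomicInterval(f.chrom, gstart, gstart + ln, f.strand),
                        n_loci=1,
                    )
                )
    return out


def _antisense_record(
    rid: str, f: FeatureRecord, start_t: int, length: int, n_loci: int
) -> AlignmentRecord:
    """An antisense read covering transcript positions [start_t, start_t+len)."""
    if f.strand == "+":
        gstart = f.start + start_t
        strand = "-"
    else:
        gstart = f.end - start_t - length
        strand = "+"
    return AlignmentRecord(
        read_id=rid,
        length=length,
        five_prime_nt="G",
        location=GenomicInterval(f.chrom, gstart, gstart + length, strand),
        n_loci=n_loci,
    )


def _sample_positions(
    rng: np.random.Generator,
    n: int,
    length: int,
    tau: float,
    gsites: list[TargetSite],
    beta: float,
    sigma_bump: float,
) -> np.ndarray:
    """Sample read-center transcript positions from the positional mixture."""
    tail_len = max(1, math.floor(0.15 * length))
    bump_mass = beta * len(gsites)
    rest = max(0.0, 1.0 - bump_mass)
    # within the non-bump component, mix uniform and tail/head so that the
    # last-15% mass equals tau
    if tau >= 0.15:
        w_tail = (tau - 0.15) / 0.85
        probs = [rest * (1 - w_tail), rest * w_tail, bump_mass]
        comps = rng.choice(3, size=n, p=np.array(probs) / sum(probs))
        pos = np.empty(n, dtype=np.int64)
        m = comps == 0
        pos[m] = rng.integers(0, length, size=int(m.sum()))
        m = comps == 1
        pos[m] = rng.integers(length - tail_len, length, size=int(m.sum()))
    else:
        w_head = 1.0 - tau / 0.15
        probs = [rest * (1 - w_head), rest * w_head, bump_mass]
        comps = rng.choice(3, size=n, p=np.array(probs) / sum(probs))
        pos = np.empty(n, dtype=np.int64)
        m = comps == 0
        pos[m] = rng.integers(0, length, size=int(m.sum()))
        m = comps == 1
        pos[m] = rng.integers(0, length - tail_len, size=int(m.sum()))
    m = comps == 2
    if m.any():
        anchors = np.array([s.anchor for s in gsites])
        which = rng.integers(0, len(gsites), size=int(m.sum()))
        bump = rng.normal(anchors[which], sigma_bump)
        pos[m] = np.clip(np.rint(bump), 0, length - 1).astype(np.int64)
    return pos


def simulate_mrna_counts(truth: SimTruth, spec: SampleSpec) -> pd.DataFrame:
    """Per-gene mRNA counts (negative binomial around mu_g * psi_{g,cond})."""
    if spec.kind != "mrna":
        raise ConfigError("SampleSpec.kind must be 'mrna'")
    rng = _sample_rng(truth, spec)
    mu = truth.mrna_means(spec.condition, spec.depth)
    counts = _nb_counts(rng, mu.values, truth.config.dispersion)
    return pd.DataFrame({"feature_id": mu.index, "count": counts})


# ---------------------------------------------------------------------------
# granule images


def simulate_granule_images(
    shape: tuple[int, int, int] = (3, 128, 128),
    n_puncta: int = 30,
    overlap_fraction: float = 0.5,
    noise_sigma: float = 1.0,
    amplitude: float = 100.0,
    spot_sigma: float = 2.0,
    background: float = 10.0,
    min_separation: int = 8,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Two-channel stack with a planted fraction of coincident puncta.

    A fraction ``overlap_fraction`` of channel-A spot centers coincide with
    channel-B centers; the rest are kept >= ``min_separation`` px from every
    B center.  Spots are in-plane Gaussians (sigma ``spot_sigma``) on a
    noisy background.  Returns the (2, z, y, x) stack and the truth dict.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ConfigError("overlap_fraction outside [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1BA6E]))
    nz, ny, nx = shape
    margin = 4 * int(math.ceil(spot_sigma)) + 1

    def rand_center() -> tuple[int, int, int]:
        return (
            int(rng.integers(0, nz)),
            int(rng.integers(margin, ny - margin)),
            int(rng.integers(margin, nx - margin)),
        )

    centers_b: list[tuple[int, int, int]] = []
    while len(centers_b) < n_puncta:
        c = rand_center()
        if all(_xy_dist(c, o) >= min_separation for o in centers_b):
            centers_b.append(c)

    n_coloc = int(round(overlap_fraction * n_puncta))
    picked = rng.choice(n_puncta, size=n_coloc, replace=False)
    centers_a = [centers_b[i] for i in picked]
    while len(centers_a) < n_puncta:
        c = rand_center()
        if all(_xy_dist(c, o) >= min_separation for o in centers_b) and all(
            _xy_dist(c, o) >= min_separation for o in centers_a
        ):
            centers_a.append(c)

    stack = np.full((2, nz, ny, nx), background, dtype=float)
    for ch, centers in ((0, centers_a), (1, centers_b)):
        for z, y, x in centers:
            _render_spot(stack[ch, z], y, x, amplitude, spot_sigma)
    stack += rng.normal(0.0, noise_sigma, size=stack.shape)

    truth = {
        "overlap_fraction": overlap_fraction,
        "n_puncta": n_puncta,
        "centers_a": centers_a,
        "centers_b": centers_b,
        "amplitude": amplitude,
        "spot_sigma": spot_sigma,
        "seed": seed,
    }
    return stack, truth


def _xy_dist(a: tuple[int, int, int], b: tuple[int, int, int]) -> float:
    return math.hypot(a[1] - b[1], a[2] - b[2])


def _render_spot(plane: np.ndarray, y: int, x: int, amp: float, sigma: float) -> None:
    r = int(math.ceil(4 * sigma))
    y0, y1 = max(0, y - r), min(plane.shape[0], y + r + 1)
    x0, x1 = max(0, x - r), min(plane.shape[1], x + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    plane[y0:y1, x0:x1] += amp * np.exp(
        -((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2)
    )


def dog_spot_response(
    amplitude: float, spot_sigma: float = 2.0,
    sigma_small: float = 1.0, sigma_large: float = 4.0,
) -> float:
    """Peak DoG response of a planted Gaussian spot (threshold calibration).

    Blurring a 2-D Gaussian of variance s^2 with a filter of variance f^2
    scales its peak by s^2/(s^2+f^2).
    """
    s2 = spot_sigma**2
    return amplitude * s2 * (1.0 / (s2 + sigma_small**2) - 1.0 / (s2 + sigma_large**2))
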