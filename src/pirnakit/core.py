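"""Core domain types shared across the pipeline.

All genomic coordinates are internally 0-based, half-open, on explicitly
stranded intervals; conversions to/from 1-based conventions happen only at
file boundaries (see :mod:`pirnakit.io`).  The 5' nucleotide of an alignment
is always expressed in *read* orientation (reverse-complemented for
minus-strand alignments), because small-RNA identity rules (5'G for 22G-RNAs,
5'U for piRNAs) are properties of the read, not of the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

BIOTYPES = frozenset(
    {
        "protein_coding",
        "pseudogene",
        "transposon",
        "rRNA",
        "tRNA",
        "snoRNA",
        "miRNA",
        "piRNA",
        "simple_repeat",
        "satellite",
    }
)

#: biotypes whose sense-mapping fragments are treated as degradation products
#: and excluded from the RPM denominator
STRUCTURAL_BIOTYPES = frozenset({"rRNA", "tRNA", "snoRNA"})

#: biotypes eligible to be 22G-RNA (antisense siRNA) targets
G22_TARGET_BIOTYPES = frozenset({"protein_coding", "pseudogene", "transposon"})

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A", "N": "N"}


def complement(nt: str) -> str:
    return _COMPLEMENT[nt.upper()]


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class FeatureRecord:
    """An annotated genomic feature — the unit of read counting.

    ``intervals`` are the exon intervals in genomic order (sorted by start),
    all on one chromosome and strand, pairwise disjoint.  ``spliced_length``
    is the summed exon length, i.e. the transcript length used for metagene
    and 3'-tail computations.
    """

    feature_id: str
    intervals: tuple[GenomicInterval, ...]
    biotype: str

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError(f"{self.feature_id}: feature needs >= 1 interval")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.feature_id}: unknown biotype {self.biotype!r}")
        chrom = self.intervals[0].chrom
        strand = self.intervals[0].strand
        prev_end = -1
        for iv in self.intervals:
            if iv.chrom != chrom or iv.strand != strand:
                raise ValueError(f"{self.feature_id}: intervals span chrom/strand")
            if iv.start < prev_end:
                raise ValueError(f"{self.feature_id}: intervals overlap or unsorted")
            prev_end = iv.end

    @property
    def chrom(self) -> str:
        return self.intervals[0].chrom

    @property
    def strand(self) -> str:
        return self.intervals[0].strand

    @property
    def start(self) -> int:
        return self.intervals[0].start

    @property
    def end(self) -> int:
        return self.intervals[-1].end

    @property
    def spliced_length(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def genomic_to_transcript(self, pos: int) -> int | None:
        """Map a genomic position to a 5'->3' transcript coordinate.

        Returns ``None`` for intronic/outside positions.  For minus-strand
        features the transcript runs right-to-left on the genome.
        """
        offset = 0
        for iv in self.intervals:
            if iv.start <= pos < iv.end:
                fwd = offset + (pos - iv.start)
                if self.strand == "+":
                    return fwd
                return self.spliced_length - 1 - fwd
            offset += len(iv)
        return None


@dataclass(frozen=True)
class AlignmentRecord:
    """One reported alignment of a small-RNA read.

    ``n_loci`` is the number of equally-best loci the read aligned to
    (the multimapper penalty divides the read's count by this).
    ``five_prime_nt`` is in read orientation; T and U are interchangeable.
    """

    read_id: str
    length: int
    five_prime_nt: str
    location: GenomicInterval
    n_loci: int = 1

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError(f"{self.read_id}: n_loci must be >= 1")
        if self.length != len(self.location):
            raise ValueError(
                f"{self.read_id}: length {self.length} != interval span "
                f"{len(self.location)} (ungapped small-RNA alignments only)"
            )
        nt = self.five_prime_nt.upper().replace("U", "T")
        if nt not in "ACGTN":
            raise ValueError(f"{self.read_id}: bad 5' nucleotide {self.five_prime_nt!r}")
        object.__setattr__(self, "five_prime_nt", nt)

    @property
    def strand(self) -> str:
        return self.location.strand


@dataclass
class TargetClassMap:
    """Gene -> target-class assignment with named subsets.

    A gene is a WAGO target (silenced via WAGO-bound 22G-RNAs), a CSR-1
    target (licensed via CSR-1-bound 22G-RNAs), or neither.  Subsets:
    ``prg1_dependent`` (WAGO targets whose 22G-RNAs require the piRNA
    pathway), ``reduced_hrde1`` (WAGO targets with reduced HRDE-1 22Gs in
    the mutant), ``enhanced_hrde1`` (CSR-1 targets that gain HRDE-1 22Gs).
    """

    classes: dict[str, str] = field(default_factory=dict)
    prg1_dependent: set[str] = field(default_factory=set)
    reduced_hrde1: set[str] = field(default_factory=set)
    enhanced_hrde1: set[str] = field(default_factory=set)

    _SUBSET_PARENT = {
        "prg1_dependent": "WAGO",
        "reduced_hrde1": "WAGO",
        "enhanced_hrde1": "CSR1",
    }

    def __post_init__(self) -> None:
        for cls in self.classes.values():
            if cls not in ("WAGO", "CSR1", "none"):
                raise ValueError(f"unknown target class {cls!r}")
        self.validate()

    def validate(self) -> None:
        for name, parent in self._SUBSET_PARENT.items():
            for g in getattr(self, name):
                if self.classes.get(g) != parent:
                    raise ValueError(
                        f"subset {name} member {g!r} is not a {parent} target"
                    )

    def target_class(self, feature_id: str) -> str:
        return self.classes.get(feature_id, "none")

    def genes_in(self, cls: str) -> set[str]:
        return {g for g, c in self.classes.items() if c == cls}

    @property
    def wago(self) -> set[str]:
        return self.genes_in("WAGO")

    @property
    def csr1(self) -> set[str]:
        return self.genes_in("CSR1")


@dataclass(frozen=True)
class TargetSite:
    """A predicted piRNA target site on an mRNA.

    ``anchor`` is the transcript coordinate paired to piRNA nucleotide 10 —
    the position site-centered density windows are centered on.
    """

    pirna_id: str
    target_feature_id: str
    anchor: int
    location: GenomicInterval

    def __post_init__(self) -> None:
        if self.anchor < 0:
            raise ValueError(f"{self.pirna_id}: anchor must be >= 0")


def index_features(features: Iterable[FeatureRecord]) -> dict[str, FeatureRecord]:
    """Index features by id, rejecting duplicates."""
    out: dict[str, FeatureRecord] = {}
    for f in features:
        if f.feature_id in out:
            raise ValueError(f"duplicate feature_id {f.feature_id!r}")
        out[f.feature_id] = f
    return out
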