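"""Read classification, multimapper weighting, and count normalization.

Class rules, applied in precedence order (first match wins):

1. ``structural_sense`` — sense overlap with rRNA/tRNA/snoRNA; such fragments
   are treated as degradation products and excluded from the RPM denominator.
2. ``mature_miRNA`` / ``mature_piRNA`` — sense read lying fully within the
   annotated locus (reads with overhangs are not mature species).
3. ``g22_antisense`` — 21–23 nt read with a 5' G, antisense to a
   protein-coding gene, pseudogene, or transposon (the 22G-RNA definition).
4. ``sense_feature`` — any remaining sense overlap with an annotated feature.
5. ``other`` — everything else, including antisense reads failing the 22G
   rule.

Reads are length-filtered to 17–40 nt before classification, and each read
carries weight ``1/n_loci`` (multimapper penalty), so a read reported at k
equally-best loci contributes total weight <= 1 across the library.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import (
    G22_TARGET_BIOTYPES,
    STRUCTURAL_BIOTYPES,
    AlignmentRecord,
    FeatureRecord,
)
from .errors import DataError
from .io import FLOAT_FORMAT, NA_REP

MIN_LEN, MAX_LEN = 17, 40
G22_LENGTHS = frozenset({21, 22, 23})

READ_CLASSES = (
    "structural_sense",
    "mature_miRNA",
    "mature_piRNA",
    "g22_antisense",
    "sense_feature",
    "other",
)


@dataclasses.dataclass(frozen=True)
class WeightedAlignment:
    alignment: AlignmentRecord
    weight: float


@dataclasses.dataclass(frozen=True)
class ClassifiedRead:
    alignment: AlignmentRecord
    read_class: str
    assigned_features: tuple[str, ...]
    weight: float


class FeatureIndex:
    """Interval index over feature spans for overlap queries."""

    def __init__(self, features: Mapping[str, FeatureRecord] | Iterable[FeatureRecord]):
        if not isinstance(features, Mapping):
            features = {f.feature_id: f for f in features}
        self.features: dict[str, FeatureRecord] = dict(features)
        self._trees: dict[str, IntervalTree] = {}
        for f in self.features.values():
            tree = self._trees.setdefault(f.chrom, IntervalTree())
            tree.addi(f.start, f.end, f)

    def overlapping(self, chrom: str, start: int, end: int) -> list[FeatureRecord]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


def filter_and_weight(
    alignments: Iterable[AlignmentRecord],
) -> Iterator[WeightedAlignment]:
    """Drop reads outside 17–40 nt and attach the 1/n_loci weight."""
    for aln in alignments:
        if MIN_LEN <= aln.length <= MAX_LEN:
            yield WeightedAlignment(aln, 1.0 / aln.n_loci)


def classify_read(wa: WeightedAlignment, index: FeatureIndex) -> ClassifiedRead:
    """Assign one weighted alignment to its small-RNA class."""
    aln = wa.alignment
    loc = aln.location
    hits = index.overlapping(loc.chrom, loc.start, loc.end)
    sense = [f for f in hits if f.strand == loc.strand]
    antisense = [f for f in hits if f.strand != loc.strand]

    structural = [f for f in sense if f.biotype in STRUCTURAL_BIOTYPES]
    if structural:
        return ClassifiedRead(
            aln, "structural_sense", _ids(structural), wa.weight
        )

    for biotype, cls in (("miRNA", "mature_miRNA"), ("piRNA", "mature_piRNA")):
        mature = [
            f
            for f in sense
            if f.biotype == biotype and f.start <= loc.start and loc.end <= f.end
        ]
        if mature:
            return ClassifiedRead(aln, cls, _ids(mature), wa.weight)

    if aln.length in G22_LENGTHS and aln.five_prime_nt == "G":
        targets = [f for f in antisense if f.biotype in G22_TARGET_BIOTYPES]
        if targets:
            return ClassifiedRead(aln, "g22_antisense", _ids(targets), wa.weight)

    if sense:
        return ClassifiedRead(aln, "sense_feature", _ids(sense), wa.weight)

    return ClassifiedRead(aln, "other", (), wa.weight)


def _ids(features: Sequence[FeatureRecord]) -> tuple[str, ...]:
    return tuple(sorted(f.feature_id for f in features))


def classify_alignments(
    alignments: Iterable[AlignmentRecord], index: FeatureIndex
) -> list[ClassifiedRead]:
    """Length-filter, weight, and classify a whole library."""
    return [classify_read(wa, index) for wa in filter_and_weight(alignments)]


_ORIENTATION = {
    "structural_sense": "sense",
    "mature_miRNA": "sense",
    "mature_piRNA": "sense",
    "g22_antisense": "antisense",
    "sense_feature": "sense",
}


@dataclasses.dataclass
class CountTable:
    """Weighted per-(feature, class, orientation) counts plus library totals.

    ``total_mapped`` and ``structural_sense`` count each read once (by its
    weight), regardless of how many features it was assigned to, so
    ``denominator_srna = total_mapped - structural_sense`` is the
    reads-per-million denominator with structural-RNA degradation excluded.
    ``protein_coding_mapped`` is the sense protein-coding total used as the
    RPKM depth for poly(A)-selected mRNA libraries.
    """

    counts: pd.DataFrame  # columns: feature_id, read_class, orientation, count
    sample: str
    total_mapped: float
    structural_sense: float
    protein_coding_mapped: float

    @property
    def denominator_srna(self) -> float:
        return self.total_mapped - self.structural_sense

    @property
    def degenerate(self) -> bool:
        """True when no non-structural reads remain to normalize against."""
        return self.denominator_srna <= 0

    def class_counts(self, read_class: str, orientation: str) -> pd.Series:
        df = self.counts
        sel = df[(df.read_class == read_class) & (df.orientation == orientation)]
        return sel.set_index("feature_id")["count"]

    def get(self, feature_id: str, read_class: str, orientation: str) -> float:
        s = self.class_counts(read_class, orientation)
        return float(s.get(feature_id, 0.0))

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#sample={self.sample}\n")
            fh.write(f"#total_mapped={self.total_mapped!r}\n")
            fh.write(f"#structural_sense={self.structural_sense!r}\n")
            fh.write(f"#protein_coding_mapped={self.protein_coding_mapped!r}\n")
            self.counts.to_csv(
                fh, sep="\t", na_rep=NA_REP, float_format=FLOAT_FORMAT, index=False
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        meta: dict[str, str] = {}
        skip = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].rstrip("\n").partition("=")
                meta[key] = val
                skip += 1
        df = pd.read_csv(
            path, sep="\t", skiprows=skip, na_values=[NA_REP], keep_default_na=False
        )
        df["count"] = df["count"].astype(float)
        return cls(
            counts=df,
            sample=meta.get("sample", ""),
            total_mapped=float(meta["total_mapped"]),
            structural_sense=float(meta["structural_sense"]),
            protein_coding_mapped=float(meta["protein_coding_mapped"]),
        )

    @classmethod
    def from_gene_counts(
        cls,
        gene_counts: Mapping[str, float] | pd.Series,
        sample: str,
        total_mapped: float,
        structural_sense: float = 0.0,
        read_class: str = "g22_antisense",
        orientation: str = "antisense",
    ) -> "CountTable":
        """Build a table directly from per-gene counts of one class.

        This is the count-level entry point used when gene counts are
        simulated or imported without read-level records.
        """
        s = pd.Series(gene_counts, dtype=float)
        df = pd.DataFrame(
            {
                "feature_id": s.index,
                "read_class": read_class,
                "orientation": orientation,
                "count": s.values,
            }
        )
        return cls(
            counts=df,
            sample=sample,
            total_mapped=float(total_mapped),
            structural_sense=float(structural_sense),
            protein_coding_mapped=0.0,
        )


def build_count_table(
    classified: Iterable[ClassifiedRead],
    features: Mapping[str, FeatureRecord],
    sample: str = "",
) -> CountTable:
    """Total each read's weight into its assigned features.

    A read assigned to several features under its winning rule contributes
    its full weight to each (interval-intersection counting); library totals
    count it once.
    """
    acc: dict[tuple[str, str, str], float] = {}
    total = 0.0
    structural = 0.0
    pc_mapped = 0.0
    for cr in classified:
        total += cr.weight
        if cr.read_class == "structural_sense":
            structural += cr.weight
        orientation = _ORIENTATION.get(cr.read_class)
        saw_pc = False
        for fid in cr.assigned_features:
            if fid not in features:
                raise DataError(
                    f"classified read assigned to {fid!r}, absent from annotation"
                )
            key = (fid, cr.read_class, orientation)
            acc[key] = acc.get(key, 0.0) + cr.weight
            if orientation == "sense" and features[fid].biotype == "protein_coding":
                saw_pc = True
        if saw_pc:
            pc_mapped += cr.weight
    rows = [
        {"feature_id": k[0], "read_class": k[1], "orientation": k[2], "count": v}
        for k, v in sorted(acc.items())
    ]
    df = pd.DataFrame(rows, columns=["feature_id", "read_class", "orientation", "count"])
    return CountTable(
        counts=df,
        sample=sample,
        total_mapped=total,
        structural_sense=structural,
        protein_coding_mapped=pc_mapped,
    )


@dataclasses.dataclass
class NormalizedTable:
    """Per-feature RPM (small-RNA) or RPKM (mRNA) values.

    sRNA: ``RPM = weighted_count * 1e6 / (total_mapped - structural_sense)``.
    mRNA: ``RPKM = count * 1e6 / (kb_length * protein_coding_total)``.
    """

    values: pd.DataFrame  # feature_id, read_class, orientation, value
    mode: str  # "srna-rpm" | "mrna-rpkm"
    denominator: float
    sample: str = ""

    def series(
        self, read_class: str = "g22_antisense", orientation: str = "antisense"
    ) -> pd.Series:
        df = self.values
        sel = df[(df.read_class == read_class) & (df.orientation == orientation)]
        return sel.set_index("feature_id")["value"]


def normalize(
    table: CountTable,
    mode: str = "srna-rpm",
    features: Mapping[str, FeatureRecord] | None = None,
) -> NormalizedTable:
    """Normalize a count table to RPM (sRNA) or RPKM (mRNA).

    A zero denominator is an explicit error, never a silent NaN.
    """
    if mode == "srna-rpm":
        denom = table.denominator_srna
        if denom <= 0:
            raise DataError(
                f"sample {table.sample!r}: non-structural denominator is "
                f"{denom}; cannot compute RPM (degenerate library)"
            )
        out = table.counts.copy()
        out["value"] = out.pop("count") * 1e6 / denom
        return NormalizedTable(out, mode, denom, table.sample)
    if mode == "mrna-rpkm":
        if features is None:
            raise DataError("mrna-rpkm normalization requires feature lengths")
        denom = table.protein_coding_mapped
        if denom <= 0:
            raise DataError(
                f"sample {table.sample!r}: protein-coding total is {denom}; "
                "cannot compute RPKM"
            )
        out = table.counts.copy()
        kb = out["feature_id"].map(
            lambda fid: features[fid].spliced_length / 1000.0
        )
        out["value"] = out.pop("count") * 1e6 / (kb * denom)
        return NormalizedTable(out, mode, denom, table.sample)
    raise DataError(f"unknown normalization mode {mode!r}")


def length_histogram(
    classified: Iterable[ClassifiedRead], read_class: str | None = None
) -> pd.Series:
    """Weighted read counts per length 17..40 (each read counted once)."""
    hist = np.zeros(MAX_LEN - MIN_LEN + 1)
    for cr in classified:
        if read_class is not None and cr.read_class != read_class:
            continue
        hist[cr.alignment.length - MIN_LEN] += cr.weight
    return pd.Series(hist, index=range(MIN_LEN, MAX_LEN + 1), name="count")
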