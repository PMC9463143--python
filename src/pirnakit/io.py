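"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions are converted exactly once, here: GFF3 is 1-based
inclusive on disk, BED and SAM-via-pysam are 0-based half-open; internally
everything is 0-based half-open (:mod:`pirnakit.core`).

Alignment ingestion supports SAM/BAM (via pysam; multi-hit count from the
``NH`` tag, else inferred by read-name grouping) and a 7-column BED dialect
``chrom start end read_id n_loci strand five_prime_nt`` as written by the
synthetic-data generator.

Tables are tab-delimited TSV with a header row and ``.`` for missing values;
floats are written with 12 significant digits so write-then-read is identity
at that precision.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import pysam

from .core import (
    AlignmentRecord,
    FeatureRecord,
    GenomicInterval,
    TargetClassMap,
    TargetSite,
    complement,
)
from .errors import DataError, ParseError, SchemaError

FLOAT_FORMAT = "%.12g"
NA_REP = "."


# ---------------------------------------------------------------------------
# annotations


@dataclasses.dataclass
class AnnotationResult:
    """Parsed annotation plus a report of skipped records."""

    features: dict[str, FeatureRecord]
    skipped: list[tuple[str, str]]  # (feature_id, unmapped biotype token)


def _validate_gff3_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise ParseError(f"{path}:{lineno}: bad GFF3 coordinates {start}-{end}")
            if cols[6] not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: strand must be + or -")


def read_annotations(
    path: str | Path, biotype_map: Mapping[str, str]
) -> AnnotationResult:
    """Read genomic features from GFF3 or BED12.

    ``biotype_map`` translates source biotype tokens into the controlled
    vocabulary.  For GFF3 the token is the ``biotype`` attribute when present,
    else the feature type (column 3); ``exon`` records are attached to their
    ``Parent``.  For BED12 the token is the part of the name after the last
    ``|``, else the map's ``"*"`` default.  Records whose token has no mapping
    are skipped and reported, not an error.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return _read_annotations_bed12(path, biotype_map)
    return _read_annotations_gff3(path, biotype_map)


def _read_annotations_gff3(
    path: Path, biotype_map: Mapping[str, str]
) -> AnnotationResult:
    _validate_gff3_lines(path)
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="error",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises various types
        raise ParseError(f"{path}: {exc}") from exc

    features: dict[str, FeatureRecord] = {}
    skipped: list[tuple[str, str]] = []
    for f in db.all_features():
        if f.featuretype == "exon":
            continue
        token = f.attributes.get("biotype", [f.featuretype])[0]
        fid = f.id
        if token not in biotype_map:
            skipped.append((fid, token))
            continue
        exons = list(db.children(f, featuretype="exon", order_by="start"))
        if exons:
            intervals = tuple(
                GenomicInterval(e.seqid, e.start - 1, e.end, e.strand) for e in exons
            )
        else:
            intervals = (GenomicInterval(f.seqid, f.start - 1, f.end, f.strand),)
        if fid in features:
            raise ParseError(f"{path}: duplicate feature_id {fid!r}")
        features[fid] = FeatureRecord(fid, intervals, biotype_map[token])
    return AnnotationResult(features, skipped)


def _read_annotations_bed12(
    path: Path, biotype_map: Mapping[str, str]
) -> AnnotationResult:
    features: dict[str, FeatureRecord] = {}
    skipped: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 BED columns")
            try:
                chrom, start, end = cols[0], int(cols[1]), int(cols[2])
                name, strand = cols[3], cols[5]
                if len(cols) >= 12:
                    n_blocks = int(cols[9])
                    sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
                    starts = [int(x) for x in cols[11].rstrip(",").split(",")]
                else:
                    n_blocks, sizes, starts = 1, [end - start], [0]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed BED fields") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ParseError(f"{path}:{lineno}: blockCount mismatch")
            if "|" in name:
                fid, token = name.rsplit("|", 1)
            else:
                fid, token = name, "*"
            if token not in biotype_map:
                skipped.append((fid, token))
                continue
            intervals = tuple(
                GenomicInterval(chrom, start + s0, start + s0 + sz, strand)
                for s0, sz in zip(starts, sizes)
            )
            if fid in features:
                raise ParseError(f"{path}:{lineno}: duplicate feature_id {fid!r}")
            features[fid] = FeatureRecord(fid, intervals, biotype_map[token])
    return AnnotationResult(features, skipped)


def write_annotations_gff3(
    features: Iterable[FeatureRecord], path: str | Path, source: str = "pirnakit"
) -> None:
    """Write features as GFF3 (1-based inclusive), exons as children."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in sorted(features, key=lambda x: (x.chrom, x.start, x.feature_id)):
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        source,
                        f.biotype,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        f"ID={f.feature_id};biotype={f.biotype}",
                    ]
                )
                + "\n"
            )
            if len(f.intervals) > 1:
                for i, iv in enumerate(f.intervals, 1):
                    fh.write(
                        "\t".join(
                            [
                                iv.chrom,
                                source,
                                "exon",
                                str(iv.start + 1),
                                str(iv.end),
                                ".",
                                iv.strand,
                                ".",
                                f"ID={f.feature_id}.e{i};Parent={f.feature_id}",
                            ]
                        )
                        + "\n"
                    )


def write_annotations_bed12(
    features: Iterable[FeatureRecord], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for f in sorted(features, key=lambda x: (x.chrom, x.start, x.feature_id)):
            sizes = ",".join(str(len(iv)) for iv in f.intervals)
            starts = ",".join(str(iv.start - f.start) for iv in f.intervals)
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        str(f.start),
                        str(f.end),
                        f"{f.feature_id}|{f.biotype}",
                        "0",
                        f.strand,
                        str(f.start),
                        str(f.end),
                        "0",
                        str(len(f.intervals)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# alignments


def read_alignments(path: str | Path) -> list[AlignmentRecord]:
    """Read small-RNA alignments from SAM/BAM or the 7-column BED dialect.

    Returns one :class:`AlignmentRecord` per reported alignment.  The
    multi-hit count comes from the ``NH`` tag (SAM) or the score column
    (BED); when absent it is inferred by grouping identical read names.
    """
    path = Path(path)
    if path.suffix.lower() in (".sam", ".bam"):
        return _read_alignments_sam(path)
    return _read_alignments_bed(path)


def _read_alignments_sam(path: Path) -> list[AlignmentRecord]:
    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    raw: list[tuple[str, str, int, int, str, str, int | None]] = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            seq = aln.query_sequence
            if not seq:
                raise DataError(
                    f"{path}: read {aln.query_name} has no sequence; "
                    "cannot determine 5' nucleotide"
                )
            strand = "-" if aln.is_reverse else "+"
            # stored sequence is reference-forward; the read's 5' base is the
            # complement of the stored 3'-most base on the minus strand
            nt = complement(seq[-1]) if aln.is_reverse else seq[0]
            nh = aln.get_tag("NH") if aln.has_tag("NH") else None
            raw.append(
                (
                    aln.query_name,
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end,
                    strand,
                    nt,
                    nh,
                )
            )
    return _assemble_alignments(raw, str(path))


def _read_alignments_bed(path: Path) -> list[AlignmentRecord]:
    raw: list[tuple[str, str, int, int, str, str, int | None]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 7:
                raise DataError(
                    f"{path}:{lineno}: alignment BED needs 7 columns "
                    "(chrom start end read_id n_loci strand five_prime_nt); "
                    "no 5'-nt source otherwise"
                )
            try:
                chrom, start, end = cols[0], int(cols[1]), int(cols[2])
                name, strand, nt = cols[3], cols[5], cols[6]
                nh = None if cols[4] in (".", "0") else int(cols[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed fields") from exc
            raw.append((name, chrom, start, end, strand, nt, nh))
    return _assemble_alignments(raw, str(path))


def _assemble_alignments(
    raw: list[tuple[str, str, int, int, str, str, int | None]], source: str
) -> list[AlignmentRecord]:
    if any(r[6] is None for r in raw):
        counts: dict[str, int] = {}
        for r in raw:
            counts[r[0]] = counts.get(r[0], 0) + 1
        raw = [(r[0], r[1], r[2], r[3], r[4], r[5], counts[r[0]]) for r in raw]
    seen: dict[str, int] = {}
    out: list[AlignmentRecord] = []
    for name, chrom, start, end, strand, nt, nh in raw:
        assert nh is not None
        if name in seen and seen[name] != nh:
            raise DataError(
                f"{source}: read {name} has inconsistent multi-hit counts "
                f"({seen[name]} vs {nh})"
            )
        seen[name] = nh
        out.append(
            AlignmentRecord(
                read_id=name,
                length=end - start,
                five_prime_nt=nt,
                location=GenomicInterval(chrom, start, end, strand),
                n_loci=nh,
            )
        )
    return out


def write_alignments_bed(
    alignments: Iterable[AlignmentRecord], path: str | Path
) -> None:
    """Write alignments in the 7-column BED dialect read back by this module."""
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(
                "\t".join(
                    [
                        a.location.chrom,
                        str(a.location.start),
                        str(a.location.end),
                        a.read_id,
                        str(a.n_loci),
                        a.location.strand,
                        a.five_prime_nt,
                    ]
                )
                + "\n"
            )


def write_alignments_sam(
    alignments: Sequence[AlignmentRecord],
    path: str | Path,
    chrom_lengths: Mapping[str, int],
) -> None:
    """Write alignments as SAM with NH tags.

    Read sequences carry only the informative 5' nucleotide (rest ``N``),
    reverse-complemented into reference orientation for minus-strand records.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()],
    }
    tid = {c: i for i, c in enumerate(chrom_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for a in alignments:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = a.read_id
            seg.reference_id = tid[a.location.chrom]
            seg.reference_start = a.location.start
            seg.cigarstring = f"{a.length}M"
            seg.mapping_quality = 255
            if a.location.strand == "+":
                seg.flag = 0
                seg.query_sequence = a.five_prime_nt + "N" * (a.length - 1)
            else:
                seg.flag = 16
                seg.query_sequence = "N" * (a.length - 1) + complement(a.five_prime_nt)
            seg.set_tag("NH", a.n_loci)
            fh.write(seg)


# ---------------------------------------------------------------------------
# tables


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a TSV table: header row, '.' for missing, 12-digit floats."""
    df.to_csv(path, sep="\t", na_rep=NA_REP, float_format=FLOAT_FORMAT, index=index)


def read_table(
    path: str | Path,
    schema: Mapping[str, type] | None = None,
    index_col: str | None = None,
) -> pd.DataFrame:
    """Read a TSV table written by :func:`write_table`.

    When ``schema`` is given the header must match its keys exactly and
    columns are coerced to the declared dtypes; a mismatch raises
    :class:`SchemaError`.
    """
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP], keep_default_na=False)
    if schema is not None:
        if list(df.columns) != list(schema.keys()):
            raise SchemaError(
                f"{path}: header {list(df.columns)} does not match declared "
                f"schema {list(schema.keys())}"
            )
        for col, dtype in schema.items():
            df[col] = df[col].astype(dtype)
    if index_col is not None:
        df = df.set_index(index_col)
    return df


# ---------------------------------------------------------------------------
# target classes and sites


def write_target_classes(cmap: TargetClassMap, path: str | Path) -> None:
    rows = []
    for gene, cls in sorted(cmap.classes.items()):
        subsets = [
            s
            for s in ("prg1_dependent", "reduced_hrde1", "enhanced_hrde1")
            if gene in getattr(cmap, s)
        ]
        rows.append(
            {"feature_id": gene, "target_class": cls, "subsets": ",".join(subsets) or None}
        )
    write_table(pd.DataFrame(rows, columns=["feature_id", "target_class", "subsets"]), path)


def read_target_classes(path: str | Path) -> TargetClassMap:
    df = read_table(path)
    cmap = TargetClassMap()
    for _, row in df.iterrows():
        cmap.classes[row["feature_id"]] = row["target_class"]
        if isinstance(row.get("subsets"), str):
            for s in row["subsets"].split(","):
                getattr(cmap, s).add(row["feature_id"])
    cmap.validate()
    return cmap


def write_target_sites(
    sites: Iterable[TargetSite], bed_path: str | Path, anchor_path: str | Path
) -> None:
    """Write sites as BED6 (name = piRNA id) plus a paired anchor TSV."""
    sites = list(sites)
    with open(bed_path, "w") as fh:
        for s in sites:
            fh.write(
                "\t".join(
                    [
                        s.location.chrom,
                        str(s.location.start),
                        str(s.location.end),
                        s.pirna_id,
                        "0",
                        s.location.strand,
                    ]
                )
                + "\n"
            )
    anchors = pd.DataFrame(
        [
            {
                "pirna_id": s.pirna_id,
                "target_feature_id": s.target_feature_id,
                "anchor": s.anchor,
            }
            for s in sites
        ],
        columns=["pirna_id", "target_feature_id", "anchor"],
    )
    write_table(anchors, anchor_path)


def read_target_sites(
    bed_path: str | Path, anchor_path: str | Path
) -> list[TargetSite]:
    anchors = read_table(anchor_path)
    by_id = {
        row["pirna_id"]: (row["target_feature_id"], int(row["anchor"]))
        for _, row in anchors.iterrows()
    }
    sites: list[TargetSite] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ParseError(f"{bed_path}:{lineno}: expected BED6")
            pid = cols[3]
            if pid not in by_id:
                raise DataError(f"{bed_path}:{lineno}: no anchor entry for {pid!r}")
            target, anchor = by_id[pid]
            sites.append(
                TargetSite(
                    pirna_id=pid,
                    target_feature_id=target,
                    anchor=anchor,
                    location=GenomicInterval(cols[0], int(cols[1]), int(cols[2]), cols[5]),
                )
            )
    return sites
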