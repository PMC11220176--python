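"""Sequence and annotation I/O with consistent coordinate conventions.

All in-memory coordinates are 0-based, half-open ``[start, end)``.  GFF3 uses
1-based closed intervals; the conversion happens here, at the file boundary,
and nowhere else.  Minus-strand cDNA is always returned 5'->3' of the
transcript (i.e. reverse-complemented), which is the orientation in which
overlap identities are computed downstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_RE = re.compile(r"^[ACGTN]*$")
_NON_ACGTN_RE = re.compile(r"[^ACGTN]")


class FastaFormatError(ValueError):
    """Malformed FASTA input (e.g. duplicate record identifiers)."""


class Gff3FormatError(ValueError):
    """Malformed GFF3 input (broken Parent links, exons outside spans...)."""


class CoordinateError(ValueError):
    """A feature lies outside the sequence it is addressed on."""


class AlphabetError(ValueError):
    """A nucleotide string contains characters outside {A,C,G,T,N}."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open stranded interval on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
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

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """Distance between interval edges; 0 if overlapping; None across chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass
class TranscriptModel:
    """An annotated transcript: locus, ordered exons, biotype."""

    transcript_id: str
    gene_id: str
    locus: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    biotype: str = "unclassified"
    family_label: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            self.exons = [self.locus]
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = None
        for exon in self.exons:
            if exon.chrom != self.locus.chrom or exon.strand != self.locus.strand:
                raise ValueError(
                    f"{self.transcript_id}: exon {exon} not on locus chrom/strand"
                )
            if exon.start < self.locus.start or exon.end > self.locus.end:
                raise Gff3FormatError(
                    f"{self.transcript_id}: exon {exon} outside locus {self.locus}"
                )
            if prev_end is not None and exon.start < prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = exon.end

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def cdna_to_genomic(self, cdna_pos: int) -> int:
        """Map a 0-based position on the spliced cDNA to a genomic offset."""
        if not 0 <= cdna_pos < self.spliced_length:
            raise CoordinateError(
                f"cDNA position {cdna_pos} outside transcript "
                f"{self.transcript_id} (length {self.spliced_length})"
            )
        if self.locus.strand == "-":
            cdna_pos = self.spliced_length - 1 - cdna_pos
        offset = cdna_pos
        for exon in self.exons:
            if offset < len(exon):
                return exon.start + offset
            offset -= len(exon)
        raise AssertionError("unreachable")

    def cdna_interval_exonic(self, start: int, end: int) -> bool:
        """True when the cDNA interval [start, end) projects into exons.

        Spliced coordinates lie in exons by construction, so this is a sanity
        projection rather than a filter; it raises if the interval is out of
        range.
        """
        self.cdna_to_genomic(start)
        self.cdna_to_genomic(end - 1)
        return True


@dataclass(frozen=True)
class SplicedSequence:
    """A transcript's spliced cDNA, 5'->3'."""

    transcript_id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; raises AlphabetError otherwise."""
    if not _VALID_RE.match(seq):
        bad = _NON_ACGTN_RE.search(seq)
        raise AlphabetError(f"non-ACGTN character {bad.group()!r} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def sanitize_sequence(seq: str, *, context: str = "") -> str:
    """Uppercase and replace any non-ACGTN character by N (logged)."""
    seq = seq.upper().replace("U", "T")
    if not _VALID_RE.match(seq):
        n_bad = len(_NON_ACGTN_RE.findall(seq))
        logger.warning(
            "replaced %d non-ACGTN character(s) with N%s",
            n_bad,
            f" in {context}" if context else "",
        )
        seq = _NON_ACGTN_RE.sub("N", seq)
    return seq


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping.

    IDs are the first whitespace-delimited token of each header.  Sequences
    are uppercased; characters outside {A,C,G,T,N} become N with a warning.
    Duplicate IDs raise :class:`FastaFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise FastaFormatError(f"duplicate FASTA identifier {record.id!r}")
        out[record.id] = sanitize_sequence(str(record.seq), context=record.id)
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    """Write sequences as multi-record FASTA wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def spliced_cdna(model: TranscriptModel, genome: Mapping[str, str]) -> SplicedSequence:
    """Concatenate exon subsequences; reverse-complement for minus strand."""
    if model.locus.chrom not in genome:
        raise CoordinateError(f"chromosome {model.locus.chrom!r} not in genome")
    chrom_seq = genome[model.locus.chrom]
    parts = []
    for exon in model.exons:
        if exon.end > len(chrom_seq):
            raise CoordinateError(
                f"{model.transcript_id}: exon {exon} beyond chromosome end "
                f"({len(chrom_seq)})"
            )
        parts.append(chrom_seq[exon.start : exon.end])
    seq = "".join(parts)
    if model.locus.strand == "-":
        seq = reverse_complement(seq)
    return SplicedSequence(model.transcript_id, seq)


_BIOTYPE_BY_FEATURE = {"mRNA": "coding", "lnc_RNA": "lncRNA", "transcript": "unclassified"}
_FEATURE_BY_BIOTYPE = {"coding": "mRNA", "lncRNA": "lnc_RNA", "unclassified": "transcript"}


def read_gff3(path: str | Path) -> list[TranscriptModel]:
    """Parse gene/mRNA-or-lnc_RNA/exon features into transcript models.

    Coordinates convert from GFF3 1-based closed to 0-based half-open.
    Transcripts without exon children get a single exon spanning their locus.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[TranscriptModel] = []
    for ftype in ("mRNA", "lnc_RNA", "transcript"):
        for feat in db.features_of_type(ftype, order_by=("seqid", "start")):
            parents = list(db.parents(feat, featuretype="gene"))
            gene_id = parents[0].id if parents else feat.id
            locus = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            exons = []
            for exon in db.children(feat, featuretype="exon", order_by="start"):
                if exon.start - 1 < locus.start or exon.end > locus.end:
                    raise Gff3FormatError(
                        f"exon {exon.id or exon.start} outside transcript {feat.id}"
                    )
                exons.append(
                    GenomicInterval(exon.seqid, exon.start - 1, exon.end, exon.strand)
                )
            family = feat.attributes.get("family", [None])[0]
            biotype = feat.attributes.get(
                "biotype", [_BIOTYPE_BY_FEATURE.get(ftype, "unclassified")]
            )[0]
            models.append(
                TranscriptModel(
                    transcript_id=feat.id,
                    gene_id=gene_id,
                    locus=locus,
                    exons=exons,
                    biotype=biotype,
                    family_label=family,
                )
            )
    return models


def write_gff3(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Emit gene/transcript/exon features (1-based closed on disk)."""
    lines = ["##gff-version 3"]
    for m in models:
        loc = m.locus
        ftype = _FEATURE_BY_BIOTYPE.get(m.biotype, "transcript")
        attrs = f"ID={m.gene_id}_gene"
        lines.append(
            "\t".join(
                [loc.chrom, "ectlnc", "gene", str(loc.start + 1), str(loc.end),
                 ".", loc.strand, ".", attrs]
            )
        )
        tx_attrs = f"ID={m.transcript_id};Parent={m.gene_id}_gene;biotype={m.biotype}"
        if m.family_label:
            tx_attrs += f";family={m.family_label}"
        lines.append(
            "\t".join(
                [loc.chrom, "ectlnc", ftype, str(loc.start + 1), str(loc.end),
                 ".", loc.strand, ".", tx_attrs]
            )
        )
        for i, exon in enumerate(m.exons, 1):
            lines.append(
                "\t".join(
                    [exon.chrom, "ectlnc", "exon", str(exon.start + 1), str(exon.end),
                     ".", exon.strand, ".",
                     f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")
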