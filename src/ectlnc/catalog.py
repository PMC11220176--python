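"""Transcript cataloguing: lncRNA/coding classification and cis/trans mode.

The biotype call is a deliberately simple, fully documented heuristic: a
transcript is *coding* when any forward reading frame contains an
ATG-initiated, stop-terminated open reading frame longer than ``max_orf_aa``
codons, and *lncRNA* when it is at least ``min_lnc_length`` nucleotides with
no such ORF.  Biotype labels carried by the input annotation override the
heuristic.  Regulation mode (cis vs trans) is assigned by genomic distance:
pairs on the same chromosome closer than ``cis_window`` are cis, everything
else trans.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .seqio import SplicedSequence, TranscriptModel

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class CatalogParams:
    """Thresholds for biotype classification and cis/trans assignment.

    min_lnc_length: minimum lncRNA length in nt (the field's 200-nt floor).
    max_orf_aa: longest tolerated ORF, in amino acids, for a non-coding call.
    cis_window: maximum genomic gap, in nt, for a cis relationship.
    """

    min_lnc_length: int = 200
    max_orf_aa: int = 100
    cis_window: int = 10_000

    def __post_init__(self) -> None:
        if self.min_lnc_length < 1 or self.max_orf_aa < 1 or self.cis_window < 0:
            raise ValueError("invalid catalog parameters")


def longest_orf_aa(seq: str) -> int:
    """Length (aa) of the longest ATG..stop ORF across the 3 forward frames.

    The count includes the initiator Met and excludes the stop codon.  ORFs
    that run off the 3' end without a stop are not counted.
    """
    seq = seq.upper()
    best = 0
    for frame in range(3):
        start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                best = max(best, (i - start) // 3)
                start = None
    return best


def classify_transcript(cdna: SplicedSequence | str, params: CatalogParams | None = None) -> str:
    """Return 'coding', 'lncRNA' or 'unclassified' for a spliced sequence."""
    params = params or CatalogParams()
    seq = cdna.seq if isinstance(cdna, SplicedSequence) else cdna
    if not seq:
        raise ValueError("empty sequence")
    orf = longest_orf_aa(seq)
    if orf > params.max_orf_aa:
        return "coding"
    if len(seq) >= params.min_lnc_length:
        return "lncRNA"
    return "unclassified"


def regulation_mode(
    lnc: TranscriptModel, target: TranscriptModel, params: CatalogParams | None = None
) -> str:
    """'cis' when loci are on one chromosome within cis_window nt, else 'trans'."""
    params = params or CatalogParams()
    gap = lnc.locus.gap_to(target.locus)
    if gap is not None and gap <= params.cis_window:
        return "cis"
    return "trans"


def build_catalog(
    entries: Iterable[tuple[TranscriptModel, SplicedSequence]],
    params: CatalogParams | None = None,
) -> pd.DataFrame:
    """Tabulate transcripts with length, longest ORF and final biotype.

    Annotation biotypes ('coding'/'lncRNA') override the heuristic; transcripts
    annotated 'unclassified' are classified from sequence.
    """
    params = params or CatalogParams()
    rows = []
    for model, cdna in entries:
        heuristic = classify_transcript(cdna, params)
        biotype = model.biotype if model.biotype != "unclassified" else heuristic
        rows.append(
            {
                "transcript_id": model.transcript_id,
                "length": len(cdna),
                "longest_orf_aa": longest_orf_aa(cdna.seq),
                "biotype": biotype,
            }
        )
    return pd.DataFrame(
        rows, columns=["transcript_id", "length", "longest_orf_aa", "biotype"]
    )


def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    catalog.to_csv(path, sep="\t", index=False)
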