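"""The ECT-lncRNA screen.

For every (trans-lncRNA, candidate target mRNA) pair the screen finds the
best local alignment between the lncRNA cDNA and the target cDNA in both
orientations (the "overlap region"), computes two identity statistics —

* overlap identity   = 100 * matches / alignment columns (gap columns count
  against identity), and
* global identity    = 100 * matches / lncRNA cDNA length —

and keeps the pair when the overlap identity exceeds a threshold (default
>80%) over at least a minimum number of columns (default 100 nt).  A pair
whose overlap aligns in the sense orientation is flagged '+' (consistency);
one aligning against the reverse complement of the target is flagged '-'
(complementarity), i.e. a trans-acting natural antisense transcript.

Scoring defaults (+2/-3, gap -5/-2) favour ungapped, high-identity blocks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Align import PairwiseAligner

from .catalog import CatalogParams, regulation_mode
from .seqio import SplicedSequence, TranscriptModel, reverse_complement

# Bounded enumeration of co-optimal alignments when resolving ties.
_MAX_CO_OPTIMAL = 16


def _shares_kmer(a: str, b: str, k: int) -> bool:
    """True when a and b share an exact k-mer in either orientation of b."""
    if len(a) < k or len(b) < k:
        return True  # too short to prefilter; always align
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    for seq in (b, reverse_complement(b)):
        if any(seq[i : i + k] in kmers for i in range(len(seq) - k + 1)):
            return True
    return False


@dataclass(frozen=True)
class ScreenParams:
    """Thresholds and alignment scoring for the overlap screen."""

    min_overlap_identity_pct: float = 80.0
    min_overlap_length: int = 100
    match_score: int = 2
    mismatch_score: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    require_exonic_overlap: bool = True
    # skip alignment when no exact k-mer is shared in either orientation
    # (heuristic speedup; None disables)
    prefilter_k: int | None = 12

    def __post_init__(self) -> None:
        if not 0 <= self.min_overlap_identity_pct <= 100:
            raise ValueError("min_overlap_identity_pct must be in [0, 100]")
        if self.min_overlap_length < 1:
            raise ValueError("min_overlap_length must be >= 1")


@dataclass(frozen=True)
class OverlapAlignment:
    """Best local alignment between a lncRNA cDNA and a target cDNA."""

    lnc_id: str
    target_id: str
    lnc_start: int
    lnc_end: int
    tgt_start: int  # forward cDNA coordinates even for antisense hits
    tgt_end: int
    orientation: str  # 'sense' | 'antisense'
    matches: int
    aligned_cols: int
    score: float

    def __post_init__(self) -> None:
        if self.matches > self.aligned_cols:
            raise ValueError("matches cannot exceed aligned columns")


@dataclass(frozen=True)
class ECTPair:
    """A screened pair: alignment, identities and the +/- consistency flag."""

    alignment: OverlapAlignment
    overlap_identity_pct: float
    global_identity_pct: float
    consistency_flag: str  # '+' sense (consistency), '-' antisense (trans-NAT)
    exonic: bool


@dataclass(frozen=True)
class ScreenSummary:
    n_lncrna: int
    n_trans: int
    n_pairs: int
    fraction_pct: float
    nat_count: int
    overlap_identity_min: float | None
    overlap_identity_max: float | None
    global_identity_min: float | None
    global_identity_max: float | None


# Scores are scaled by this factor with +1 added per match, so the aligner
# maximizes (score, matches) lexicographically: among all maximum-score local
# alignments the one with the most identities is found.  Valid as long as the
# match count stays below the scale.
_LEX_SCALE = 1_000_000


def _make_aligner(params: ScreenParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match_score * _LEX_SCALE + 1
    aligner.mismatch_score = params.mismatch_score * _LEX_SCALE
    aligner.open_gap_score = params.gap_open * _LEX_SCALE
    aligner.extend_gap_score = params.gap_extend * _LEX_SCALE
    return aligner


def _alignment_stats(aln, seq_a: str, seq_b: str) -> tuple[int, int, int, int, int, int]:
    """(matches, cols, a_start, a_end, b_start, b_end) from aligned blocks."""
    blocks_a, blocks_b = aln.aligned
    matches = 0
    matched_cols = 0
    for (a_s, a_e), (b_s, b_e) in zip(blocks_a, blocks_b):
        matched_cols += a_e - a_s
        for k in range(a_e - a_s):
            if seq_a[a_s + k] == seq_b[b_s + k]:
                matches += 1
    gap_cols = 0
    for i in range(len(blocks_a) - 1):
        gap_cols += blocks_a[i + 1][0] - blocks_a[i][1]
        gap_cols += blocks_b[i + 1][0] - blocks_b[i][1]
    a_start, a_end = int(blocks_a[0][0]), int(blocks_a[-1][1])
    b_start, b_end = int(blocks_b[0][0]), int(blocks_b[-1][1])
    return matches, matched_cols + gap_cols, a_start, a_end, b_start, b_end


def _best_local(aligner: PairwiseAligner, lnc: str, tgt: str):
    """Best alignment resolving co-optimal ties by (matches desc, leftmost)."""
    alignments = aligner.align(lnc, tgt)
    best = None
    best_key = None
    for aln in itertools.islice(alignments, _MAX_CO_OPTIMAL):
        if len(aln.aligned[0]) == 0:  # empty local alignment
            continue
        stats = _alignment_stats(aln, lnc, tgt)
        key = (-stats[0], stats[2], stats[4])
        if best_key is None or key < best_key:
            best, best_key = (aln.score, stats), key
    return best


def align_overlap(
    lnc_cdna: str | SplicedSequence,
    tgt_cdna: str | SplicedSequence,
    params: ScreenParams | None = None,
    *,
    lnc_id: str = "lnc",
    target_id: str = "target",
) -> OverlapAlignment | None:
    """Best-scoring local alignment of lncRNA vs target cDNA, both orientations.

    The target is also aligned reverse-complemented; the higher-scoring
    orientation wins, ties going to sense.  Antisense coordinates are reported
    on the forward target cDNA.  Returns None when the sequences admit no
    positive-scoring local alignment at all.
    """
    params = params or ScreenParams()
    lnc = lnc_cdna.seq if isinstance(lnc_cdna, SplicedSequence) else lnc_cdna
    tgt = tgt_cdna.seq if isinstance(tgt_cdna, SplicedSequence) else tgt_cdna
    if not lnc or not tgt:
        raise ValueError("empty sequence passed to align_overlap")
    aligner = _make_aligner(params)
    sense = _best_local(aligner, lnc, tgt)
    anti = _best_local(aligner, lnc, reverse_complement(tgt))
    if sense is None and anti is None:
        return None
    if anti is None or (sense is not None and sense[0] >= anti[0]):
        score, (matches, cols, ls, le, ts, te) = sense
        orientation = "sense"
    else:
        score, (matches, cols, ls, le, ts_rc, te_rc) = anti
        orientation = "antisense"
        ts, te = len(tgt) - te_rc, len(tgt) - ts_rc
    score = (score - matches) / _LEX_SCALE  # undo the lexicographic embedding
    return OverlapAlignment(
        lnc_id=lnc_id,
        target_id=target_id,
        lnc_start=ls,
        lnc_end=le,
        tgt_start=ts,
        tgt_end=te,
        orientation=orientation,
        matches=matches,
        aligned_cols=cols,
        score=float(score),
    )


def overlap_identity(aln: OverlapAlignment) -> float:
    """Percent identical bases over alignment columns (gaps count as errors)."""
    if aln.aligned_cols <= 0:
        raise ValueError("alignment has zero columns")
    return 100.0 * aln.matches / aln.aligned_cols


def global_identity(aln: OverlapAlignment, lnc_length: int) -> float:
    """Percent of the full lncRNA cDNA covered by identical aligned bases."""
    if lnc_length <= 0:
        raise ValueError("lncRNA length must be positive")
    return 100.0 * aln.matches / lnc_length


def screen_pairs(
    lncrnas: Sequence[tuple[TranscriptModel, SplicedSequence]],
    targets: Sequence[tuple[TranscriptModel, SplicedSequence]],
    params: ScreenParams | None = None,
    mode_params: CatalogParams | None = None,
) -> list[ECTPair]:
    """Screen every trans (lncRNA, target) combination through align_overlap.

    Pairs pass when overlap identity is strictly above the threshold, the
    alignment spans at least ``min_overlap_length`` columns and (optionally)
    the target-side overlap is exonic.  One lncRNA may pair with several
    paralogous targets.  Output is sorted by (lnc_id, overlap identity desc).
    """
    params = params or ScreenParams()
    mode_params = mode_params or CatalogParams()
    pairs: list[ECTPair] = []
    for lnc_model, lnc_cdna in lncrnas:
        for tgt_model, tgt_cdna in targets:
            if regulation_mode(lnc_model, tgt_model, mode_params) != "trans":
                continue
            if params.prefilter_k and not _shares_kmer(
                lnc_cdna.seq, tgt_cdna.seq, params.prefilter_k
            ):
                continue
            aln = align_overlap(
                lnc_cdna,
                tgt_cdna,
                params,
                lnc_id=lnc_model.transcript_id,
                target_id=tgt_model.transcript_id,
            )
            if aln is None or aln.aligned_cols < params.min_overlap_length:
                continue
            ov_id = overlap_identity(aln)
            if ov_id <= params.min_overlap_identity_pct:
                continue
            exonic = True
            if params.require_exonic_overlap:
                exonic = tgt_model.cdna_interval_exonic(aln.tgt_start, aln.tgt_end)
                if not exonic:
                    continue
            pairs.append(
                ECTPair(
                    alignment=aln,
                    overlap_identity_pct=ov_id,
                    global_identity_pct=global_identity(aln, len(lnc_cdna)),
                    consistency_flag="+" if aln.orientation == "sense" else "-",
                    exonic=exonic,
                )
            )
    pairs.sort(
        key=lambda p: (
            p.alignment.lnc_id,
            -p.overlap_identity_pct,
            p.alignment.target_id,
        )
    )
    return pairs


def round_half_up(value: float, ndigits: int = 1) -> float:
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def summarize_records(
    records: Iterable[tuple[float, float, str]],
    n_lncrna: int,
    n_trans: int,
) -> ScreenSummary:
    """Aggregate (overlap_identity, global_identity, flag) records.

    Used both for screen output and for externally transcribed pair tables.
    """
    records = list(records)
    n_pairs = len(records)
    if n_trans == 0 and n_pairs > 0:
        raise ValueError("pairs present but n_trans is zero")
    fraction = round_half_up(100.0 * n_pairs / n_trans, 1) if n_trans else 0.0
    overlaps = [r[0] for r in records]
    globals_ = [r[1] for r in records]
    return ScreenSummary(
        n_lncrna=n_lncrna,
        n_trans=n_trans,
        n_pairs=n_pairs,
        fraction_pct=fraction,
        nat_count=sum(1 for r in records if r[2] == "-"),
        overlap_identity_min=min(overlaps) if overlaps else None,
        overlap_identity_max=max(overlaps) if overlaps else None,
        global_identity_min=min(globals_) if globals_ else None,
        global_identity_max=max(globals_) if globals_ else None,
    )


def summarize_screen(pairs: Sequence[ECTPair], n_lncrna: int, n_trans: int) -> ScreenSummary:
    return summarize_records(
        ((p.overlap_identity_pct, p.global_identity_pct, p.consistency_flag) for p in pairs),
        n_lncrna,
        n_trans,
    )


PAIR_COLUMNS = [
    "lnc_id", "target_id", "lnc_start", "lnc_end", "tgt_start", "tgt_end",
    "orientation", "matches", "aligned_cols", "overlap_identity_pct",
    "global_identity_pct", "consistency_flag", "exonic",
]


def pairs_to_dataframe(pairs: Sequence[ECTPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        a = p.alignment
        rows.append(
            {
                "lnc_id": a.lnc_id,
                "target_id": a.target_id,
                "lnc_start": a.lnc_start,
                "lnc_end": a.lnc_end,
                "tgt_start": a.tgt_start,
                "tgt_end": a.tgt_end,
                "orientation": a.orientation,
                "matches": a.matches,
                "aligned_cols": a.aligned_cols,
                "overlap_identity_pct": round(p.overlap_identity_pct, 2),
                "global_identity_pct": round(p.global_identity_pct, 2),
                "consistency_flag": p.consistency_flag,
                "exonic": p.exonic,
            }
        )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def write_pairs(pairs: Sequence[ECTPair], path: str | Path) -> None:
    pairs_to_dataframe(pairs).to_csv(path, sep="\t", index=False)
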