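"""Cross-species conservation ("bait") search.

The overlap-region subsequence of each screened pair is used as a bait to
find orthologous lncRNAs in other species' lncRNA sets; each candidate
ortholog is then re-screened against that species' mRNAs to rebuild the
pair, giving one conservation-table row per (ortholog lncRNA, target) plus
target-less rows when no target qualifies.  The same identity thresholds
govern the bait search and the in-species re-pairing.

A shared-k-mer prefilter (default k=12, both orientations) skips alignments
that cannot plausibly reach the identity threshold; it is a heuristic
shortcut, validated against full alignment on the divergence regimes the
simulator produces.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .catalog import CatalogParams
from .screen import (
    ECTPair,
    OverlapAlignment,
    ScreenParams,
    align_overlap,
    overlap_identity,
    screen_pairs,
)
from .seqio import SplicedSequence, TranscriptModel

DEFAULT_PREFILTER_K = 12


@dataclass(frozen=True)
class OrthologHit:
    """One conservation-table row (the cross-species analogue of a pair row)."""

    seed_lnc_id: str
    species: str
    ortholog_lnc_id: str
    target_id: str | None
    bait_identity_pct: float
    overlap_identity_pct: float | None
    global_identity_pct: float | None
    consistency_flag: str | None


def shares_kmer(bait: str, candidate: str, k: int = DEFAULT_PREFILTER_K) -> bool:
    """True when bait and candidate share an exact k-mer in either orientation."""
    from .screen import _shares_kmer

    return _shares_kmer(bait, candidate, k)


def seed_overlap_sequence(seed: ECTPair, lnc_cdna: str | SplicedSequence) -> str:
    """The bait: the lncRNA cDNA subsequence under the seed's overlap region."""
    seq = lnc_cdna.seq if isinstance(lnc_cdna, SplicedSequence) else lnc_cdna
    return seq[seed.alignment.lnc_start : seed.alignment.lnc_end]


def bait_search(
    seed_overlap_seq: str,
    species_lncrnas: Sequence[tuple[TranscriptModel, SplicedSequence]],
    params: ScreenParams | None = None,
    *,
    prefilter_k: int | None = DEFAULT_PREFILTER_K,
) -> list[tuple[TranscriptModel, SplicedSequence, float, OverlapAlignment]]:
    """Candidate ortholog lncRNAs with bait identity above the threshold.

    Returns (model, cdna, bait_identity_pct, alignment) sorted by descending
    identity, then id for stability.
    """
    params = params or ScreenParams()
    hits = []
    for model, cdna in species_lncrnas:
        if prefilter_k and not shares_kmer(seed_overlap_seq, cdna.seq, prefilter_k):
            continue
        aln = align_overlap(
            seed_overlap_seq, cdna, params,
            lnc_id="bait", target_id=model.transcript_id,
        )
        if aln is None or aln.aligned_cols < params.min_overlap_length:
            continue
        identity = overlap_identity(aln)
        if identity > params.min_overlap_identity_pct:
            hits.append((model, cdna, identity, aln))
    hits.sort(key=lambda h: (-h[2], h[0].transcript_id))
    return hits


def build_conservation_table(
    seeds: Sequence[ECTPair],
    seed_cdnas: Mapping[str, str | SplicedSequence],
    species_data: Mapping[
        str,
        tuple[
            Sequence[tuple[TranscriptModel, SplicedSequence]],
            Sequence[tuple[TranscriptModel, SplicedSequence]],
        ],
    ],
    params: ScreenParams | None = None,
    mode_params: CatalogParams | None = None,
    *,
    prefilter_k: int | None = DEFAULT_PREFILTER_K,
) -> tuple[list[OrthologHit], dict[str, bool]]:
    """Bait-search every seed in every species and re-derive pairs there.

    Returns the table rows and a per-seed ``conserved`` flag (True when at
    least one species yields an ortholog hit).
    """
    params = params or ScreenParams()
    rows: list[OrthologHit] = []
    conserved: dict[str, bool] = {}
    # each ortholog is re-paired against its species' targets once, not per seed
    pair_cache: dict[tuple[str, str], list[ECTPair]] = {}
    for seed in seeds:
        seed_id = seed.alignment.lnc_id
        bait = seed_overlap_sequence(seed, seed_cdnas[seed_id])
        found = False
        for species, (lncrnas, targets) in species_data.items():
            for model, cdna, bait_identity, _ in bait_search(
                bait, lncrnas, params, prefilter_k=prefilter_k
            ):
                found = True
                cache_key = (species, model.transcript_id)
                if cache_key not in pair_cache:
                    pair_cache[cache_key] = screen_pairs(
                        [(model, cdna)], targets, params, mode_params
                    )
                pairs = pair_cache[cache_key]
                if not pairs:
                    rows.append(
                        OrthologHit(
                            seed_lnc_id=seed_id,
                            species=species,
                            ortholog_lnc_id=model.transcript_id,
                            target_id=None,
                            bait_identity_pct=bait_identity,
                            overlap_identity_pct=None,
                            global_identity_pct=None,
                            consistency_flag=None,
                        )
                    )
                for pair in pairs:
                    rows.append(
                        OrthologHit(
                            seed_lnc_id=seed_id,
                            species=species,
                            ortholog_lnc_id=model.transcript_id,
                            target_id=pair.alignment.target_id,
                            bait_identity_pct=bait_identity,
                            overlap_identity_pct=pair.overlap_identity_pct,
                            global_identity_pct=pair.global_identity_pct,
                            consistency_flag=pair.consistency_flag,
                        )
                    )
        conserved[seed_id] = found
    return rows, conserved


TABLE_COLUMNS = [
    "seed_lnc_id", "species", "ortholog_lnc_id", "target_id",
    "bait_identity_pct", "overlap_identity_pct", "global_identity_pct",
    "consistency_flag", "conserved",
]


def table_to_dataframe(
    rows: Sequence[OrthologHit], conserved: Mapping[str, bool]
) -> pd.DataFrame:
    records = [
        {
            "seed_lnc_id": r.seed_lnc_id,
            "species": r.species,
            "ortholog_lnc_id": r.ortholog_lnc_id,
            "target_id": r.target_id if r.target_id is not None else ".",
            "bait_identity_pct": round(r.bait_identity_pct, 2),
            "overlap_identity_pct": (
                round(r.overlap_identity_pct, 2)
                if r.overlap_identity_pct is not None else "."
            ),
            "global_identity_pct": (
                round(r.global_identity_pct, 2)
                if r.global_identity_pct is not None else "."
            ),
            "consistency_flag": r.consistency_flag if r.consistency_flag else ".",
            "conserved": conserved.get(r.seed_lnc_id, False),
        }
        for r in rows
    ]
    return pd.DataFrame(records, columns=TABLE_COLUMNS)


def write_conservation_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
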