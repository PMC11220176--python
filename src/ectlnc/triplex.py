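"""Simplified RNA-DNA triplex (TFO/TTS) prediction.

A triplex target site (TTS) is a polypurine tract in duplex DNA; a
triplex-forming oligonucleotide (TFO) is an RNA window pairing with the
purine strand through Hoogsteen triplets:

* Y motif (pyrimidine TFO, parallel):    U/T . A:T   and  C . G:C
* R motif (purine TFO, antiparallel):    G . G:C    and  A . A:T
* M motif (G/T mixed TFO, parallel):     G . G:C    and  T . A:T

Pairing is ungapped.  Parallel motifs compare the RNA window 5'->3' against
the purine strand 5'->3'; the antiparallel R motif compares the RNA window
reversed.  Candidate sites are every ungapped window of at least
``min_length`` columns whose error fraction (triplets outside the code) is
at most ``max_error_rate``; overlapping candidates on the same motif and
purine strand are then collapsed to the best one — lowest error rate, then
longest, then leftmost — so a perfect core is never shadowed by a sloppier
extension.  DNA coordinates are always reported on the forward strand with
an explicit purine-strand attribute.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import reverse_complement

PARALLEL_MOTIFS = frozenset({"Y", "M"})
# (RNA base, purine-strand DNA base) pairs allowed per motif
MOTIF_CODE = {
    "Y": {("T", "A"), ("C", "G")},
    "R": {("G", "G"), ("A", "A")},
    "M": {("G", "G"), ("T", "A")},
}

_EPS = 1e-9


@dataclass(frozen=True)
class TriplexParams:
    min_length: int = 15
    max_error_rate: float = 0.10
    motifs: frozenset[str] = frozenset({"Y", "R", "M"})

    def __post_init__(self) -> None:
        if self.min_length < 5:
            raise ValueError("min_length must be >= 5")
        if not 0 <= self.max_error_rate < 0.5:
            raise ValueError("max_error_rate must be in [0, 0.5)")
        if not set(self.motifs) <= {"Y", "R", "M"}:
            raise ValueError(f"unknown motifs: {set(self.motifs) - {'Y', 'R', 'M'}}")


@dataclass(frozen=True)
class TTSCandidate:
    """A maximal polypurine window, forward DNA coordinates."""

    start: int
    end: int
    purine_strand: str  # '+' forward strand is the purine strand, '-' its complement
    purine_fraction: float


@dataclass(frozen=True)
class TriplexSite:
    tts_start: int
    tts_end: int
    purine_strand: str
    tfo_start: int
    tfo_end: int
    motif: str
    length: int
    errors: int

    @property
    def error_rate(self) -> float:
        return self.errors / self.length


@dataclass(frozen=True)
class TriplexProbe:
    """The three oligos an EMSA needs: RNA TFO plus the DNA duplex strands."""

    tfo_seq: str
    purine_seq: str
    pyrimidine_seq: str
    tfo_start: int
    tfo_end: int
    tts_start: int
    tts_end: int
    errors: int


def _max_errors(length: int, rate: float) -> int:
    return int(np.floor(rate * length + _EPS))


def _qualifying_windows(err: np.ndarray, min_length: int, max_error_rate: float) -> list[tuple[int, int]]:
    """All windows [a, b) of length >= min_length with error fraction <= rate.

    ``err`` is a 0/1 array (1 = error position).  Enumerates lengths with
    cumulative sums; a cheap density prefilter skips arrays that cannot hold
    a qualifying window.
    """
    n = err.size
    if n < min_length:
        return []
    csum = np.concatenate([[0], np.cumsum(err)])
    # prefilter: any qualifying window contains a min_length window with at
    # least (1 - 2*rate) * min_length matches (averaging over disjoint blocks)
    need = int(np.floor((1 - 2 * max_error_rate) * min_length + _EPS))
    win_match = (min_length - (csum[min_length:] - csum[:-min_length]))
    if win_match.size and win_match.max() < need:
        return []
    windows: list[tuple[int, int]] = []
    for length in range(min_length, n + 1):
        errors = csum[length:] - csum[:-length]
        ok = np.nonzero(errors <= _max_errors(length, max_error_rate))[0]
        windows.extend((int(a), int(a) + length) for a in ok)
    return windows


def _maximal_windows(err: np.ndarray, min_length: int, max_error_rate: float) -> list[tuple[int, int]]:
    """Containment-maximal qualifying windows (used for TTS discovery)."""
    return _drop_contained(_qualifying_windows(err, min_length, max_error_rate))


def _drop_contained(windows: list[tuple[int, int]]) -> list[tuple[int, int]]:
    windows = sorted(set(windows), key=lambda w: (w[0], -w[1]))
    kept: list[tuple[int, int]] = []
    max_end = -1
    for a, b in windows:
        if b > max_end:
            kept.append((a, b))
            max_end = b
    return kept


def _purine_mask(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return (arr == ord("A")) | (arr == ord("G"))


def find_tts(dna: str, params: TriplexParams | None = None) -> list[TTSCandidate]:
    """Maximal windows whose purine content meets 1 - max_error_rate.

    Both strands are scanned; reverse-strand windows are reported on forward
    coordinates with purine_strand '-'.
    """
    params = params or TriplexParams()
    n = len(dna)
    out: list[TTSCandidate] = []
    for strand in ("+", "-"):
        purine = dna if strand == "+" else reverse_complement(dna)
        err = (~_purine_mask(purine)).astype(np.int8)
        for a, b in _maximal_windows(err, params.min_length, params.max_error_rate):
            if strand == "+":
                start, end = a, b
            else:
                start, end = n - b, n - a
            frac = 1 - float(err[a:b].mean())
            out.append(TTSCandidate(start, end, strand, round(frac, 4)))
    out.sort(key=lambda t: (t.start, t.end, t.purine_strand))
    return out


def _motif_match(p: np.ndarray, r: np.ndarray, motif: str) -> np.ndarray:
    """Elementwise triplet-code match between purine-strand and RNA arrays."""
    ok = np.zeros(p.shape, dtype=bool)
    for rna_b, dna_b in MOTIF_CODE[motif]:
        ok |= (r == ord(rna_b)) & (p == ord(dna_b))
    return ok


def match_triplex(rna: str, dna: str, params: TriplexParams | None = None) -> list[TriplexSite]:
    """All maximal, merged triplex sites between an RNA and duplex DNA."""
    params = params or TriplexParams()
    if not rna or not dna:
        raise ValueError("empty sequence")
    n = len(dna)
    r_len = len(rna)
    rna_arr = np.frombuffer(rna.upper().replace("U", "T").encode(), dtype=np.uint8)
    raw: list[TriplexSite] = []
    for strand in ("+", "-"):
        purine = dna if strand == "+" else reverse_complement(dna)
        p_arr = np.frombuffer(purine.encode(), dtype=np.uint8)
        for motif in sorted(params.motifs):
            r_cmp = rna_arr if motif in PARALLEL_MOTIFS else rna_arr[::-1]
            # slide along diagonals of the (purine, rna) pairing grid
            for d in range(-(r_len - 1), len(purine)):
                i0 = max(d, 0)
                j0 = i0 - d
                span = min(len(purine) - i0, r_len - j0)
                if span < params.min_length:
                    continue
                match = _motif_match(p_arr[i0 : i0 + span], r_cmp[j0 : j0 + span], motif)
                err = (~match).astype(np.int8)
                for a, b in _qualifying_windows(err, params.min_length, params.max_error_rate):
                    raw.append(
                        _make_site(
                            strand, motif, i0 + a, i0 + b, j0 + a, j0 + b,
                            int(err[a:b].sum()), n, r_len,
                        )
                    )
    return merge_sites(raw)


def _make_site(
    strand: str, motif: str,
    p_start: int, p_end: int, rc_start: int, rc_end: int,
    errors: int, dna_len: int, rna_len: int,
) -> TriplexSite:
    """Convert purine-frame / comparison-frame coords to forward coordinates."""
    if strand == "+":
        tts = (p_start, p_end)
    else:
        tts = (dna_len - p_end, dna_len - p_start)
    if motif in PARALLEL_MOTIFS:
        tfo = (rc_start, rc_end)
    else:  # RNA was reversed for the antiparallel comparison
        tfo = (rna_len - rc_end, rna_len - rc_start)
    return TriplexSite(
        tts_start=tts[0], tts_end=tts[1], purine_strand=strand,
        tfo_start=tfo[0], tfo_end=tfo[1], motif=motif,
        length=p_end - p_start, errors=errors,
    )


def merge_sites(sites: Iterable[TriplexSite]) -> list[TriplexSite]:
    """Collapse DNA-overlapping sites per (motif, purine strand) to the best.

    Best = lowest error rate, then longest, then leftmost TTS, then leftmost
    TFO.  Overlap grouping is transitive on TTS intervals.
    """
    by_key: dict[tuple[str, str], list[TriplexSite]] = {}
    for s in sites:
        by_key.setdefault((s.motif, s.purine_strand), []).append(s)
    out: list[TriplexSite] = []
    for group in by_key.values():
        group.sort(key=lambda s: (s.tts_start, s.tts_end))
        cluster: list[TriplexSite] = []
        cluster_end = -1
        for s in group:
            if cluster and s.tts_start >= cluster_end:
                out.append(_best_site(cluster))
                cluster = []
                cluster_end = -1
            cluster.append(s)
            cluster_end = max(cluster_end, s.tts_end)
        if cluster:
            out.append(_best_site(cluster))
    out.sort(key=lambda s: (s.tts_start, s.tts_end, s.motif, s.purine_strand))
    return out


def _best_site(cluster: Sequence[TriplexSite]) -> TriplexSite:
    return min(
        cluster,
        key=lambda s: (s.error_rate, -s.length, s.tts_start, s.tfo_start),
    )


def _site_frames(site: TriplexSite, rna: str, dna: str) -> tuple[str, str]:
    """(purine-frame DNA window, comparison-frame RNA window) for a site."""
    n = len(dna)
    purine = dna if site.purine_strand == "+" else reverse_complement(dna)
    if site.purine_strand == "+":
        p_win = purine[site.tts_start : site.tts_end]
    else:
        p_win = purine[n - site.tts_end : n - site.tts_start]
    r_win = rna[site.tfo_start : site.tfo_end]
    if site.motif not in PARALLEL_MOTIFS:
        r_win = r_win[::-1]
    return p_win, r_win


def design_probe(site: TriplexSite, rna: str, dna: str, probe_len: int = 20) -> TriplexProbe:
    """Pick the lowest-error probe_len sub-window of a site (tie: leftmost).

    Returns the RNA TFO and both DNA duplex strands for that window.
    """
    if site.length < probe_len:
        raise ValueError(
            f"site length {site.length} is shorter than probe length {probe_len}"
        )
    p_win, r_win = _site_frames(site, rna, dna)
    code = MOTIF_CODE[site.motif]
    err = np.array(
        [0 if (r, p) in code else 1 for r, p in zip(r_win, p_win)], dtype=np.int8
    )
    csum = np.concatenate([[0], np.cumsum(err)])
    window_err = csum[probe_len:] - csum[:-probe_len]
    k0 = int(np.argmin(window_err))  # argmin takes the leftmost tie
    purine_seq = p_win[k0 : k0 + probe_len]
    if site.motif in PARALLEL_MOTIFS:
        tfo_start = site.tfo_start + k0
    else:
        tfo_start = site.tfo_end - k0 - probe_len
    if site.purine_strand == "+":
        tts_start = site.tts_start + k0
    else:
        tts_start = site.tts_end - k0 - probe_len
    return TriplexProbe(
        tfo_seq=rna[tfo_start : tfo_start + probe_len],
        purine_seq=purine_seq,
        pyrimidine_seq=reverse_complement(purine_seq),
        tfo_start=tfo_start,
        tfo_end=tfo_start + probe_len,
        tts_start=tts_start,
        tts_end=tts_start + probe_len,
        errors=int(window_err[k0]),
    )


SITE_COLUMNS = [
    "lnc_id", "target_id", "tfo_start", "tfo_end", "tts_start", "tts_end",
    "purine_strand", "motif", "length", "errors", "error_rate",
]


def sites_to_dataframe(
    sites: Sequence[TriplexSite], lnc_id: str = ".", target_id: str = "."
) -> pd.DataFrame:
    rows = [
        {
            "lnc_id": lnc_id,
            "target_id": target_id,
            "tfo_start": s.tfo_start,
            "tfo_end": s.tfo_end,
            "tts_start": s.tts_start,
            "tts_end": s.tts_end,
            "purine_strand": s.purine_strand,
            "motif": s.motif,
            "length": s.length,
            "errors": s.errors,
            "error_rate": round(s.error_rate, 4),
        }
        for s in sites
    ]
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def write_sites(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
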