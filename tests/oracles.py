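"""Independent reference implementations used only by the test suite.

These are deliberately naive: an affine-gap local-alignment DP over score
tuples, a window-enumeration triplex search built on an explicit pairing
matrix, and an all-pairs transitive-closure clusterer.  They share no code
with the package implementations they check.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# --- local alignment -------------------------------------------------------

def sw_affine(
    a: str,
    b: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = -5,
    gap_extend: int = -2,
) -> tuple[int, int]:
    """Best local alignment (score, matches), affine gaps (open + (L-1)*ext).

    DP over (score, matches) tuples compared lexicographically, so among all
    maximum-score local alignments the reported match count is the maximum
    achievable.
    """
    n, m = len(a), len(b)
    neg = (-(10 ** 9), 0)
    zero = (0, 0)
    h_prev = [zero] * (m + 1)
    e_row = [neg] * (m + 1)
    f_prev = [neg] * (m + 1)
    best = zero
    for i in range(1, n + 1):
        h_cur = [zero] * (m + 1)
        f_cur = [neg] * (m + 1)
        e = neg
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = max(
                (h_cur[j - 1][0] + gap_open, h_cur[j - 1][1]),
                (e[0] + gap_extend, e[1]),
            )
            f_cur[j] = max(
                (h_prev[j][0] + gap_open, h_prev[j][1]),
                (f_prev[j][0] + gap_extend, f_prev[j][1]),
            )
            if ai == b[j - 1]:
                diag = (h_prev[j - 1][0] + match, h_prev[j - 1][1] + 1)
            else:
                diag = (h_prev[j - 1][0] + mismatch, h_prev[j - 1][1])
            h_cur[j] = max(zero, diag, e, f_cur[j])
            if h_cur[j] > best:
                best = h_cur[j]
        h_prev = h_cur
        f_prev = f_cur
    return best


def sw_affine_both_orientations(lnc: str, tgt: str, **scores) -> tuple[int, int, str]:
    """(score, matches, orientation) with score ties preferring sense."""
    s_score, s_matches = sw_affine(lnc, tgt, **scores)
    a_score, a_matches = sw_affine(lnc, revcomp(tgt), **scores)
    if (s_score, s_matches) >= (a_score, a_matches):
        return s_score, s_matches, "sense"
    return a_score, a_matches, "antisense"


# --- triplex ---------------------------------------------------------------

ORACLE_CODE = {
    "Y": {("T", "A"), ("C", "G")},
    "R": {("G", "G"), ("A", "A")},
    "M": {("G", "G"), ("T", "A")},
}
ORACLE_PARALLEL = {"Y", "M"}


def _pair_matrix(purine: str, rna: str, motif: str) -> np.ndarray:
    code = ORACLE_CODE[motif]
    mat = np.zeros((len(purine), len(rna)), dtype=bool)
    for i, p in enumerate(purine):
        for j, r in enumerate(rna):
            mat[i, j] = (r, p) in code
    return mat


def _diagonal_windows(
    err: np.ndarray, min_length: int, max_rate: float
) -> list[tuple[int, int]]:
    """All [a, b) windows along one diagonal meeting length and rate."""
    out = []
    pre = np.concatenate([[0], np.cumsum(err)])
    L = err.size
    for length in range(min_length, L + 1):
        for a in range(L - length + 1):
            errors = int(pre[a + length] - pre[a])
            if errors <= int(np.floor(max_rate * length + 1e-9)):
                out.append((a, a + length))
    return out


def brute_triplex(
    rna: str,
    dna: str,
    min_length: int,
    max_error_rate: float,
    motifs=("M", "R", "Y"),
) -> list[tuple]:
    """Exhaustive qualifying-window enumeration + naive overlap merge.

    Returns sorted tuples (tts_start, tts_end, purine_strand, tfo_start,
    tfo_end, motif, length, errors).
    """
    n, m = len(dna), len(rna)
    raw: list[tuple] = []
    for strand in ("+", "-"):
        purine = dna if strand == "+" else revcomp(dna)
        for motif in motifs:
            mat = _pair_matrix(purine, rna, motif)
            if motif in ORACLE_PARALLEL:
                # window: purine[i+k] pairs rna[j+k]
                for d in range(-(m - 1), n):
                    i0, j0 = max(d, 0), max(-d, 0)
                    span = min(n - i0, m - j0)
                    if span < min_length:
                        continue
                    err = ~np.array([mat[i0 + k, j0 + k] for k in range(span)])
                    for a, b in _diagonal_windows(err, min_length, max_error_rate):
                        p_s, p_e = i0 + a, i0 + b
                        r_s, r_e = j0 + a, j0 + b
                        raw.append(_convert(strand, motif, p_s, p_e, r_s, r_e,
                                            int(err[a:b].sum()), n, m))
            else:
                # antiparallel: purine[i+k] pairs rna[c - (i+k)] on anti-diagonal c
                for c in range(n + m - 1):
                    i_lo = max(0, c - (m - 1))
                    i_hi = min(n - 1, c)
                    span = i_hi - i_lo + 1
                    if span < min_length:
                        continue
                    err = ~np.array(
                        [mat[i_lo + k, c - (i_lo + k)] for k in range(span)]
                    )
                    for a, b in _diagonal_windows(err, min_length, max_error_rate):
                        p_s, p_e = i_lo + a, i_lo + b
                        r_s, r_e = c - (p_e - 1), c - p_s + 1
                        raw.append(_convert(strand, motif, p_s, p_e, r_s, r_e,
                                            int(err[a:b].sum()), n, m))
    return merge_naive(raw)


def _convert(strand, motif, p_s, p_e, r_s, r_e, errors, n, m):
    if strand == "+":
        tts = (p_s, p_e)
    else:
        tts = (n - p_e, n - p_s)
    return (tts[0], tts[1], strand, r_s, r_e, motif, p_e - p_s, errors)


def merge_naive(raw: list[tuple]) -> list[tuple]:
    """Transitive overlap clusters per (motif, strand); best site per cluster."""
    remaining = list(raw)
    out = []
    while remaining:
        seed = remaining.pop()
        cluster = [seed]
        changed = True
        while changed:
            changed = False
            for site in remaining[:]:
                if any(_same_group_overlap(site, member) for member in cluster):
                    cluster.append(site)
                    remaining.remove(site)
                    changed = True
        out.append(
            min(cluster, key=lambda s: (s[7] / s[6], -s[6], s[0], s[3]))
        )
    return sorted(out)


def _same_group_overlap(x: tuple, y: tuple) -> bool:
    return (
        x[5] == y[5]
        and x[2] == y[2]
        and x[0] < y[1]
        and y[0] < x[1]
    )


def brute_tts(dna: str, min_length: int, max_error_rate: float) -> list[tuple]:
    """All containment-maximal purine windows per strand (naive)."""
    n = len(dna)
    out = []
    for strand in ("+", "-"):
        purine = dna if strand == "+" else revcomp(dna)
        qualifying = []
        for a in range(n):
            for b in range(a + min_length, n + 1):
                errors = sum(1 for ch in purine[a:b] if ch not in "AG")
                if errors <= int(np.floor(max_error_rate * (b - a) + 1e-9)):
                    qualifying.append((a, b))
        maximal = [
            w for w in qualifying
            if not any(
                (v[0] <= w[0] and w[1] <= v[1] and v != w) for v in qualifying
            )
        ]
        for a, b in maximal:
            if strand == "+":
                out.append((a, b, strand))
            else:
                out.append((n - b, n - a, strand))
    return sorted(out)


# --- clusters --------------------------------------------------------------

def brute_clusters(genes, max_gap: int, min_members: int):
    """All-pairs transitive closure; returns frozensets of member ids."""
    items = list(genes)
    parent = list(range(len(items)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            gi, fi, li = items[i]
            gj, fj, lj = items[j]
            if fi != fj or li.chrom != lj.chrom:
                continue
            if li.start < lj.end and lj.start < li.end:
                gap = 0
            else:
                gap = max(li.start, lj.start) - min(li.end, lj.end)
            if gap <= max_gap:
                union(i, j)
    groups: dict[int, set[str]] = {}
    for i, (gid, _, _) in enumerate(items):
        groups.setdefault(find(i), set()).add(gid)
    return {
        frozenset(members)
        for members in groups.values()
        if len(members) >= min_members
    }
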