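"""Tandem gene-cluster detection and chromosome organization reports.

A tandem cluster is a maximal single-linkage chain of same-family genes on
one chromosome whose successive gaps do not exceed ``max_gap`` (default
250 kb).  Distances between clusters are measured between span edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .screen import ECTPair
from .seqio import GenomicInterval, TranscriptModel


@dataclass(frozen=True)
class GeneCluster:
    family_label: str
    chrom: str
    members: tuple[str, ...]
    span: GenomicInterval

    @property
    def size(self) -> int:
        return len(self.members)


def detect_clusters(
    genes: Iterable[tuple[str, str, GenomicInterval]],
    max_gap: int = 250_000,
    min_members: int = 2,
) -> tuple[list[GeneCluster], list[GeneCluster]]:
    """Chain same-family genes by genomic gap; return (clusters, singletons).

    Clusters have >= min_members members; smaller chains are reported as
    singleton "clusters" so downstream reports can still place them.
    """
    by_group: dict[tuple[str, str], list[tuple[str, GenomicInterval]]] = {}
    for gene_id, family, locus in genes:
        by_group.setdefault((family, locus.chrom), []).append((gene_id, locus))
    clusters: list[GeneCluster] = []
    singletons: list[GeneCluster] = []
    for (family, chrom), members in sorted(by_group.items()):
        members.sort(key=lambda m: (m[1].start, m[1].end, m[0]))
        chain: list[tuple[str, GenomicInterval]] = []
        chain_end = None
        for gene_id, locus in members:
            if chain and locus.start - chain_end > max_gap:
                _emit(chain, family, chrom, min_members, clusters, singletons)
                chain = []
                chain_end = None
            chain.append((gene_id, locus))
            chain_end = locus.end if chain_end is None else max(chain_end, locus.end)
        if chain:
            _emit(chain, family, chrom, min_members, clusters, singletons)
    return clusters, singletons


def _emit(
    chain: list[tuple[str, GenomicInterval]],
    family: str,
    chrom: str,
    min_members: int,
    clusters: list[GeneCluster],
    singletons: list[GeneCluster],
) -> None:
    span = GenomicInterval(
        chrom, min(l.start for _, l in chain), max(l.end for _, l in chain)
    )
    cluster = GeneCluster(family, chrom, tuple(g for g, _ in chain), span)
    (clusters if cluster.size >= min_members else singletons).append(cluster)


def cluster_distance(a: GeneCluster, b: GeneCluster) -> int | None:
    """Edge-to-edge distance; 0 when spans overlap; None across chromosomes."""
    return a.span.gap_to(b.span)


def adjacency_report(
    pairs: Sequence[ECTPair],
    clusters: Sequence[GeneCluster],
    models: Mapping[str, TranscriptModel],
) -> pd.DataFrame:
    """One row per (lncRNA cluster, target cluster) linked by >= 1 ECT pair."""
    cluster_of: dict[str, GeneCluster] = {}
    for c in clusters:
        for gene_id in c.members:
            cluster_of[gene_id] = c
    seen: dict[tuple[str, str], tuple[GeneCluster, GeneCluster, int]] = {}
    for p in pairs:
        lnc_model = models.get(p.alignment.lnc_id)
        tgt_model = models.get(p.alignment.target_id)
        if lnc_model is None or tgt_model is None:
            missing = p.alignment.lnc_id if lnc_model is None else p.alignment.target_id
            raise KeyError(f"unresolvable transcript id {missing!r}")
        lnc_cluster = cluster_of.get(lnc_model.gene_id) or _singleton(lnc_model)
        tgt_cluster = cluster_of.get(tgt_model.gene_id) or _singleton(tgt_model)
        key = (_label(lnc_cluster), _label(tgt_cluster))
        if key not in seen:
            seen[key] = (lnc_cluster, tgt_cluster, 1)
        else:
            a, b, n = seen[key]
            seen[key] = (a, b, n + 1)
    rows = []
    for (lnc_label, tgt_label), (a, b, n_pairs) in sorted(seen.items()):
        dist = cluster_distance(a, b)
        rows.append(
            {
                "lnc_cluster": lnc_label,
                "target_cluster": tgt_label,
                "lnc_chrom": a.chrom,
                "target_chrom": b.chrom,
                "n_pairs": n_pairs,
                "same_chrom": a.chrom == b.chrom,
                "distance": dist if dist is not None else ".",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "lnc_cluster", "target_cluster", "lnc_chrom", "target_chrom",
            "n_pairs", "same_chrom", "distance",
        ],
    )


def _singleton(model: TranscriptModel) -> GeneCluster:
    return GeneCluster(
        model.family_label or model.gene_id,
        model.locus.chrom,
        (model.gene_id,),
        GenomicInterval(model.locus.chrom, model.locus.start, model.locus.end),
    )


def _label(cluster: GeneCluster) -> str:
    return f"{cluster.family_label}:{cluster.chrom}:{cluster.span.start}-{cluster.span.end}"


def clusters_to_dataframe(
    clusters: Sequence[GeneCluster], singletons: Sequence[GeneCluster] = ()
) -> pd.DataFrame:
    rows = []
    for c in list(clusters) + list(singletons):
        rows.append(
            {
                "family_label": c.family_label,
                "chrom": c.chrom,
                "span_start": c.span.start,
                "span_end": c.span.end,
                "n_members": c.size,
                "is_cluster": c.size >= 2,
                "members": ",".join(c.members),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "family_label", "chrom", "span_start", "span_end",
            "n_members", "is_cluster", "members",
        ],
    )
    return df.sort_values(["chrom", "span_start"]).reset_index(drop=True)
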