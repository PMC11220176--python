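"""Synthetic transcriptomes with planted ground truth.

The generator emulates the genomic situation the screen assumes:

* a tandem family of paralogous coding genes (multi-exon, intron-separated)
  mutated from a common ancestor;
* lncRNA loci created by partial duplication of a paralog's 5' exons —
  intronless, diverged, inserted in sense or antisense orientation, placed as
  a cluster at a configurable distance from the family (modelling lncRNA
  clusters arising as incomplete residues of a gene-cluster duplication);
* a mirror-symmetric polypurine tract planted in one paralog's 5' exons (and
  propagated intact into lncRNAs copied from it) for triplex testing;
* decoy lncRNAs of matched length with no relationship to the family;
* a second species derived by whole-genome substitution at a fixed rate.

Everything planted is recorded in a truth manifest; the manifest's realized
substitution counts — not analytic expectations — are the per-replicate
oracle for identity arithmetic.  Substitutions only by default (an indel
rate exists but defaults to 0) so that
expected overlap identity = 100 * (1 - realized substitutions / length)
holds exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .seqio import (
    GenomicInterval,
    SplicedSequence,
    TranscriptModel,
    reverse_complement,
    spliced_cdna,
    write_fasta,
    write_gff3,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_PURINES = np.frombuffer(b"AG", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.int64)  # A/C/G/T -> 0..3 (others fold to 0)
for _i, _b in enumerate(_BASES):
    _BASE_INDEX[_b] = _i

FAMILY_LABEL = "famA"
LNC_FAMILY_LABEL = "lncA"


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the synthetic dataset (defaults are the baseline)."""

    rng_seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 500_000
    family_size: int = 4
    paralog_divergence: float = 0.05
    gene_exons: int = 5
    exon_length: int = 250
    intron_length: int = 150
    gene_spacing: int = 5_000
    lnc_copied_exons: int = 3
    lnc_divergence: float = 0.05
    lnc_antisense_prob: float = 0.5
    lnc_cluster_size: int = 5
    lnc_cluster_distance: int = 2_000_000  # capped to fit the chromosome
    lnc_spacing: int = 1_000
    lnc_keep_intron: bool = False
    triplex_tract_length: int = 20
    species2_divergence: float = 0.05
    n_decoy_lncrnas: int = 50
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        for rate in (
            self.paralog_divergence, self.lnc_divergence,
            self.species2_divergence, self.indel_rate,
        ):
            if not 0 <= rate <= 0.5:
                raise ValueError("substitution/indel rates must lie in [0, 0.5]")
        if not 0 <= self.lnc_antisense_prob <= 1:
            raise ValueError("lnc_antisense_prob must be a probability")
        for count in (
            self.n_chromosomes, self.chrom_length, self.family_size,
            self.gene_exons, self.exon_length, self.lnc_copied_exons,
            self.lnc_cluster_size, self.triplex_tract_length,
        ):
            if count < 1:
                raise ValueError("counts and lengths must be >= 1")
        if self.lnc_copied_exons > self.gene_exons:
            raise ValueError("cannot copy more exons than the gene has")


@dataclass
class SyntheticTruth:
    """Ground-truth manifest for one generated dataset."""

    rng_seed: int
    params: dict
    family: dict
    planted_lncrnas: list[dict]
    triplex: dict
    lnc_cluster: dict
    species2: dict
    decoy_ids: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SpeciesData:
    name: str
    genome: dict[str, str]
    models: list[TranscriptModel]

    def transcripts(self, biotype: str) -> list[tuple[TranscriptModel, SplicedSequence]]:
        return [
            (m, spliced_cdna(m, self.genome))
            for m in self.models
            if m.biotype == biotype
        ]

    def lncrnas(self) -> list[tuple[TranscriptModel, SplicedSequence]]:
        return self.transcripts("lncRNA")

    def mrnas(self) -> list[tuple[TranscriptModel, SplicedSequence]]:
        return self.transcripts("coding")

    def model_index(self) -> dict[str, TranscriptModel]:
        return {m.transcript_id: m for m in self.models}


@dataclass
class SyntheticDataset:
    species: list[SpeciesData]
    truth: SyntheticTruth


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def mutate_sequence(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    protected: np.ndarray | None = None,
) -> tuple[str, int]:
    """Substitute each position with probability ``rate`` to a different base.

    ``protected`` is an optional boolean mask of positions never mutated.
    Returns the mutated sequence and the realized substitution count.
    """
    if not 0 <= rate <= 0.5:
        raise ValueError("rate must lie in [0, 0.5]")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    if protected is not None:
        hit &= ~protected
    idx = np.nonzero(hit)[0]
    if idx.size:
        # shift each hit base by 1-3 positions in A/C/G/T order: always a
        # different base, uniform over the three alternatives
        base_index = _BASE_INDEX[arr[idx]]
        arr[idx] = _BASES[(base_index + rng.integers(1, 4, idx.size)) % 4]
    return arr.tobytes().decode(), int(idx.size)


def _apply_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = []
    for ch in seq:
        r = rng.random()
        if r < rate / 2:
            continue  # deletion
        out.append(ch)
        if rate / 2 <= r < rate:
            out.append(chr(rng.choice(_BASES)))  # insertion
    return "".join(out)


def _mirror_purine_tract(rng: np.random.Generator, length: int) -> str:
    """A polypurine tract equal to its own reversal.

    Mirror symmetry makes the planted triplex geometry orientation-independent:
    both the sense copy (R motif, antiparallel) and the antisense copy
    (Y motif, parallel) of a derived lncRNA pair perfectly with the tract.
    """
    half = rng.choice(_PURINES, size=length // 2).tobytes().decode()
    mid = chr(rng.choice(_PURINES)) if length % 2 else ""
    return half + mid + half[::-1]


def generate_ect_dataset(params: SimParams | None = None) -> SyntheticDataset:
    """Generate the two-species dataset with its truth manifest."""
    params = params or SimParams()
    rng = np.random.default_rng(params.rng_seed)

    gene_span = (
        params.gene_exons * params.exon_length
        + (params.gene_exons - 1) * params.intron_length
    )
    margin = 10_000
    family_start = margin
    family_end = family_start + params.family_size * gene_span + (
        params.family_size - 1
    ) * params.gene_spacing
    if family_end + margin > params.chrom_length:
        raise ValueError("chromosome too short for the tandem family")

    genome = {
        f"chr{i + 1}": random_sequence(rng, params.chrom_length)
        for i in range(params.n_chromosomes)
    }
    chrom1 = "chr1"
    chrom1_arr = bytearray(genome[chrom1].encode())

    # --- tandem paralog family -------------------------------------------
    ancestor = random_sequence(rng, gene_span)
    tract = _mirror_purine_tract(rng, params.triplex_tract_length)
    tract_exon = min(1, params.lnc_copied_exons - 1)  # 2nd exon when copied
    tract_offset_in_exon = max(0, min(50, params.exon_length - params.triplex_tract_length))
    tract_gene_offset = (
        tract_exon * (params.exon_length + params.intron_length) + tract_offset_in_exon
    )

    models: list[TranscriptModel] = []
    gene_seqs: list[str] = []
    gene_starts: list[int] = []
    for g in range(params.family_size):
        start = family_start + g * (gene_span + params.gene_spacing)
        seq, _ = mutate_sequence(ancestor, params.paralog_divergence, rng)
        if g == 0:  # the tract-bearing paralog; overwrite post-mutation
            seq = (
                seq[:tract_gene_offset]
                + tract
                + seq[tract_gene_offset + len(tract):]
            )
        chrom1_arr[start : start + gene_span] = seq.encode()
        gene_seqs.append(seq)
        gene_starts.append(start)
        exons = [
            GenomicInterval(
                chrom1,
                start + e * (params.exon_length + params.intron_length),
                start + e * (params.exon_length + params.intron_length) + params.exon_length,
            )
            for e in range(params.gene_exons)
        ]
        models.append(
            TranscriptModel(
                transcript_id=f"g{g + 1}.t1",
                gene_id=f"g{g + 1}",
                locus=GenomicInterval(chrom1, start, start + gene_span),
                exons=exons,
                biotype="coding",
                family_label=FAMILY_LABEL,
            )
        )

    # --- planted lncRNA cluster ------------------------------------------
    copied_exon_len = params.lnc_copied_exons * params.exon_length
    if params.lnc_keep_intron and params.lnc_copied_exons >= 2:
        copied_exon_len += params.intron_length
    cluster_span = params.lnc_cluster_size * (copied_exon_len + params.lnc_spacing)
    max_distance = params.chrom_length - margin - cluster_span - family_end
    if max_distance <= 0:
        raise ValueError("chromosome too short for the lncRNA cluster")
    realized_distance = min(params.lnc_cluster_distance, max_distance)
    cluster_start = family_end + realized_distance

    planted: list[dict] = []
    tract_lnc_coords: dict[str, list[int]] = {}
    for j in range(params.lnc_cluster_size):
        src = 0 if j == 0 else int(rng.integers(params.family_size))
        src_seq = gene_seqs[src]
        pieces = []
        for e in range(params.lnc_copied_exons):
            off = e * (params.exon_length + params.intron_length)
            pieces.append(src_seq[off : off + params.exon_length])
            if params.lnc_keep_intron and e == 0 and params.lnc_copied_exons >= 2:
                pieces.append(
                    src_seq[off + params.exon_length : off + params.exon_length + params.intron_length]
                )
        copied = "".join(pieces)
        # spliced-frame position of the tract inside the copy, if present
        tract_spliced = None
        if src == 0 and tract_exon < params.lnc_copied_exons:
            shift = params.intron_length if (params.lnc_keep_intron and tract_exon >= 1) else 0
            tract_spliced = tract_exon * params.exon_length + shift + tract_offset_in_exon
        protected = None
        if tract_spliced is not None:
            protected = np.zeros(len(copied), dtype=bool)
            protected[tract_spliced : tract_spliced + len(tract)] = True
        mutated, n_sub = mutate_sequence(copied, params.lnc_divergence, rng, protected)
        mutated = _apply_indels(mutated, params.indel_rate, rng)
        antisense = bool(rng.random() < params.lnc_antisense_prob)
        inserted = reverse_complement(mutated) if antisense else mutated
        start = cluster_start + j * (copied_exon_len + params.lnc_spacing)
        if start + len(inserted) + margin > params.chrom_length:
            raise ValueError("lncRNA locus exceeds chromosome")
        chrom1_arr[start : start + len(inserted)] = inserted.encode()
        lnc_id = f"lnc{j + 1}"
        models.append(
            TranscriptModel(
                transcript_id=f"{lnc_id}.t1",
                gene_id=lnc_id,
                locus=GenomicInterval(chrom1, start, start + len(inserted)),
                exons=[GenomicInterval(chrom1, start, start + len(inserted))],
                biotype="lncRNA",
                family_label=LNC_FAMILY_LABEL,
            )
        )
        planted.append(
            {
                "lnc_id": f"{lnc_id}.t1",
                "gene_id": lnc_id,
                "source_gene": f"g{src + 1}",
                "source_transcript": f"g{src + 1}.t1",
                "copied_exons": params.lnc_copied_exons,
                "orientation": "antisense" if antisense else "sense",
                "copied_length": len(copied),
                "realized_substitutions": n_sub,
                "expected_overlap_identity_pct": 100.0 * (1 - n_sub / len(copied)),
            }
        )
        if tract_spliced is not None:
            if antisense:
                lo = len(mutated) - (tract_spliced + len(tract))
                tract_lnc_coords[f"{lnc_id}.t1"] = [lo, lo + len(tract)]
            else:
                tract_lnc_coords[f"{lnc_id}.t1"] = [tract_spliced, tract_spliced + len(tract)]

    genome[chrom1] = chrom1_arr.decode()

    # --- decoy lncRNAs ----------------------------------------------------
    decoy_chrom = "chr2" if params.n_chromosomes >= 2 else chrom1
    decoy_start0 = margin if params.n_chromosomes >= 2 else (
        cluster_start + cluster_span + margin
    )
    decoy_arr = bytearray(genome[decoy_chrom].encode())
    decoy_ids = []
    for d in range(params.n_decoy_lncrnas):
        start = decoy_start0 + d * (copied_exon_len + 2_000)
        if start + copied_exon_len + margin > params.chrom_length:
            raise ValueError("decoy lncRNA exceeds chromosome")
        seq = random_sequence(rng, copied_exon_len)
        decoy_arr[start : start + copied_exon_len] = seq.encode()
        decoy_id = f"decoy{d + 1}"
        models.append(
            TranscriptModel(
                transcript_id=f"{decoy_id}.t1",
                gene_id=decoy_id,
                locus=GenomicInterval(decoy_chrom, start, start + copied_exon_len),
                exons=[GenomicInterval(decoy_chrom, start, start + copied_exon_len)],
                biotype="lncRNA",
            )
        )
        decoy_ids.append(f"{decoy_id}.t1")
    genome[decoy_chrom] = decoy_arr.decode()

    species1 = SpeciesData("species1", genome, models)

    # --- species 2: whole-genome divergence ------------------------------
    genome2 = {}
    for chrom, seq in genome.items():
        genome2[chrom], _ = mutate_sequence(seq, params.species2_divergence, rng)
    models2 = [
        TranscriptModel(
            transcript_id=f"s2_{m.transcript_id}",
            gene_id=f"s2_{m.gene_id}",
            locus=m.locus,
            exons=list(m.exons),
            biotype=m.biotype,
            family_label=m.family_label,
        )
        for m in models
    ]
    species2 = SpeciesData("species2", genome2, models2)
    homolog_map = {m.transcript_id: f"s2_{m.transcript_id}" for m in models}

    truth = SyntheticTruth(
        rng_seed=params.rng_seed,
        params=dataclasses.asdict(params),
        family={
            "gene_ids": [f"g{g + 1}" for g in range(params.family_size)],
            "chrom": chrom1,
            "span": [gene_starts[0], gene_starts[-1] + gene_span],
            "tract_gene": "g1",
        },
        planted_lncrnas=planted,
        triplex={
            "gene_id": "g1",
            "transcript_id": "g1.t1",
            "tract_seq": tract,
            "tract_gene_start": gene_starts[0] + tract_gene_offset,
            "tract_gene_end": gene_starts[0] + tract_gene_offset + len(tract),
            "tract_offset_in_gene": tract_gene_offset,
            "tract_lnc_coords": tract_lnc_coords,
        },
        lnc_cluster={
            "chrom": chrom1,
            "span": [cluster_start, cluster_start + cluster_span],
            "realized_distance_to_family": realized_distance,
        },
        species2={
            "divergence": params.species2_divergence,
            "homolog_map": homolog_map,
        },
        decoy_ids=decoy_ids,
    )
    return SyntheticDataset(species=[species1, species2], truth=truth)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write speciesN.fa / speciesN.gff3 / truth.json (byte-deterministic)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, sp in enumerate(dataset.species, 1):
        write_fasta(sp.genome, outdir / f"species{i}.fa")
        write_gff3(sp.models, outdir / f"species{i}.gff3")
    dataset.truth.to_json(outdir / "truth.json")


def load_species(fasta: str | Path, gff3: str | Path, name: str = "species") -> SpeciesData:
    from .seqio import read_fasta, read_gff3

    return SpeciesData(name, read_fasta(fasta), read_gff3(gff3))
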