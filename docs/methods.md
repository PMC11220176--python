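# Methods

## The screen

A candidate ECT pair is a (trans-lncRNA, mRNA) couple whose spliced cDNAs
share a high-identity local alignment — the *overlap region*. For each
couple the lncRNA is aligned locally against the target cDNA and against its
reverse complement (Smith–Waterman with affine gaps; defaults +2 match,
−3 mismatch, −5 gap open, −2 gap extend, chosen to favour long ungapped
high-identity blocks). The higher-scoring orientation wins, ties going to
sense. Two statistics are reported:

* **overlap identity** = 100 · matches / alignment columns. Gap columns
  count against identity.
* **global identity** = 100 · matches / lncRNA cDNA length — how much of the
  whole lncRNA the conserved block explains.

A pair is emitted when overlap identity is *strictly* greater than the
threshold (default 80%, a literal reading of the published “>80%” rule) over
at least `min_overlap_length` columns. No minimum was published; the default
of 100 nt excludes trivially short high-identity hits while admitting the
shortest reported lncRNA of this class (227 bp). The two identity
denominators are likewise not spelled out in the literature; the definitions
above are this package's declared convention and reproduce the published
pattern (overlap identity ≫ global identity). One lncRNA may pair with
several paralogous targets; no best-hit collapsing is performed. Because of
this, the summary's pair fraction (100 · n_pairs / n_trans) can exceed 100%
on paralog-rich data; in the published table every pair has a distinct
lncRNA, so the same formula yields the printed 0.8% (24 / 2904).

**Alignment backend and tie-breaking.** Alignment is delegated to
Biopython's `PairwiseAligner` (C implementation) with all scores scaled by
10⁶ and +1 added to the match score. This embeds the identity count
lexicographically into the score, so the aligner maximizes (score, matches):
among all maximum-score local alignments the reported matches value is the
maximum achievable, a well-defined quantity independent of traceback order.
Residual coordinate ties are resolved by enumerating up to 16 co-optimal
tracebacks and taking the leftmost (lncRNA start, then target start). The
test suite checks score, matches and orientation against an independent
affine-gap DP oracle that optimizes the same lexicographic objective.

**k-mer prefilter.** Pairs sharing no exact 12-mer in either orientation are
skipped without alignment. This is a heuristic: 80% identity over 100
columns only guarantees exact runs of ~4 nt in the adversarial worst case,
but at the substitution-style divergence this screen targets the probability
of losing a qualifying pair is negligible, and the tests verify on the
generator's regimes that the filtered and unfiltered screens agree. Set
`prefilter_k: null` to disable.

## Biotype and regulation mode

The published lncRNA identification used a stack of external
coding-potential tools; this package substitutes a documented heuristic: a
transcript is *coding* if any forward frame contains an ATG-initiated,
stop-terminated ORF longer than 100 aa (count includes the initiator Met),
*lncRNA* if ≥200 nt with no such ORF, *unclassified* otherwise. Only forward
frames are scanned — transcripts are directional. Biotype labels present in
the input annotation override the heuristic, so a curated lncRNA set passes
through unchanged. The cis/trans assignment rule was also not published;
here a pair is *cis* when both loci are on one chromosome within a 10 kb
window (overlap counts as distance 0), *trans* otherwise. Both thresholds
are configuration keys. Consequently the published cis/trans split counts
are not reproduction targets; only the screen's behaviour downstream of the
trans set is.

## Cross-species bait search

The bait is the overlap-region subsequence of the lncRNA (not the full
lncRNA; a full-length mode exists behind a flag). Candidates in another
species' lncRNA set qualify under exactly the same identity/length
thresholds as the in-species screen — no separate cross-species cutoff was
published. Each candidate ortholog is then re-screened against that
species' mRNAs to rebuild pairs; orthologs with no qualifying target are
still reported as target-less rows (nulls written as `.`), mirroring the
published table's blank entries. A seed is `conserved` when at least one
species yields a hit.

## Triplex prediction

Full Triplexator scoring is deliberately not reimplemented (no parameters
were published; the one validated probe sets a 20-bp working scale).
Instead the canonical Hoogsteen triplet codes are applied directly:

| motif | TFO alphabet | orientation | code (RNA · DNA purine strand) |
|-------|--------------|-------------|--------------------------------|
| Y     | U/T, C       | parallel    | T·A, C·G                       |
| R     | G, A         | antiparallel| G·G, A·A                       |
| M     | G, T         | parallel    | G·G, T·A                       |

Sites are **ungapped** (triplex helices do not accommodate gaps, and this
keeps the brute-force oracle exact). Both strands of the DNA are scanned as
potential purine strands; coordinates are always reported forward-strand
with a purine-strand attribute, 0-based half-open, matching the rest of the
package. A candidate site is any window of ≥ `min_length` columns (default
15) with a triplet-code error fraction ≤ `max_error_rate` (default 0.10).
Overlapping candidates on the same (motif, purine strand) are collapsed
transitively to the single best site — lowest error rate, then longest,
then leftmost — so a perfect core is never shadowed by a longer, sloppier
extension (this selection rule, rather than containment-maximality, is what
guarantees a planted perfect tract is reported at error rate 0). TTS
discovery (`find_tts`) reports containment-maximal purine windows per
strand. `design_probe` picks the lowest-error sub-window of a site
(leftmost tie-break) and returns the RNA TFO plus both DNA duplex strands —
the three oligos an EMSA needs.

## Tandem clusters

Genes of one family on one chromosome are chained single-linkage while
successive edge-to-edge gaps stay ≤ `max_gap` (default 250 kb — the
literature states no numeric criterion for “tandem”, so this is a declared,
configurable substitute). Chains of ≥2 members are clusters; the rest are
reported as singletons so the adjacency report can still place them.
Cluster distances are measured between span edges (deterministic and
convention-stable), 0 for overlapping spans, null across chromosomes.

## The synthetic generator

The generator emulates the genomic situation the screen assumes, with every
random choice driven by one seeded NumPy generator (identical parameters
and seed give byte-identical FASTA/GFF3/manifest):

* **Tandem family** — `family_size` (4) paralogs, each `gene_exons` (5)
  exons of 250 nt separated by 150-nt introns, mutated independently from a
  common random ancestor at `paralog_divergence` (0.05), laid out in tandem
  on chromosome 1.
* **lncRNA cluster** — `lnc_cluster_size` (5) loci, each the intronless
  concatenation of the first `lnc_copied_exons` (3) exons of a source
  paralog (a flag can retain the first intron), mutated at `lnc_divergence`
  (0.05) and inserted in sense or antisense orientation with probability
  0.5, as a cluster placed `lnc_cluster_distance` downstream of the family
  (capped to fit the chromosome; the realized distance is recorded).
  Substitutions only by default — an indel flag exists but defaults to 0 —
  so the manifest identity law is exact: expected overlap identity =
  100 · (1 − realized substitutions / copied length), and the manifest's
  realized counts, not the analytic value, are the per-replicate oracle.
* **Triplex tract** — a 20-nt polypurine tract overwritten post-mutation
  into the first paralog's second exon and protected from mutation in
  lncRNAs copied from it. The tract is generated *mirror-symmetric*
  (u + reverse(u)), which makes the planted geometry orientation-independent
  under the positional triplet codes: a sense lncRNA copy pairs perfectly as
  an antiparallel R-motif TFO and an antisense copy as a parallel Y-motif
  TFO. The first lncRNA always derives from the tract-bearing paralog so
  every dataset contains at least one plantable TFO.
* **Decoys and species 2** — `n_decoy_lncrnas` (50) length-matched random
  lncRNAs on chromosome 2, and a second species obtained by whole-genome
  substitution at `species2_divergence` (0.05) with identical coordinates,
  giving known homolog mappings.

Background composition is uniform; the screen is composition-agnostic.
What the generator does **not** model: indel-driven divergence (off by
default), rate heterogeneity or codon structure, transcription noise,
incomplete transcript models, and assembly artifacts. Passing tests
therefore demonstrate correctness of the screening logic under
substitution-style divergence with exact ground truth — not robustness to
every failure mode of real transcriptome assemblies.

## Numerical and determinism choices

* Coordinates are 0-based half-open everywhere in memory; GFF3 (1-based
  closed) converts at the file boundary only. Minus-strand cDNA is emitted
  5'→3'.
* Ambiguity codes beyond N are normalized to N on input (tolerant ingestion)
  with a logged warning; N never matches anything in alignment or triplet
  codes.
* Error-rate comparisons use `errors ≤ floor(rate · length + 1e-9)` to keep
  float thresholds exact at grid values.
* All output tables have fixed column orders and documented sort keys; JSON
  is written with sorted keys; logs carry no timestamps — a re-run with the
  same config and seed is byte-identical.
* Summary fractions round half-up to one decimal.

## Problem sizes used by the test suite and acceptance script

Oracle-equivalence tests run 50 random pairs ≤300 nt against the alignment
DP oracle, 20 RNA/DNA pairs (DNA ≤110 nt) over a 3×3 triplex parameter grid,
and 10 random layouts against the clustering closure oracle. Recovery tests
use the generator's default study conditions over 10 seeds at divergences
0.05/0.10/0.40, and a 6-level divergence sweep (0–0.40) with 30 replicates
per level using a reduced background (150 kb chromosomes, 5 decoys) since
only planted-pair alignments are measured there. The acceptance script uses
3 seeds per statistic with the same defaults. These sizes are the package's
chosen balance between coverage and turnaround on a single CPU.

## Known limitations

* The identity-denominator conventions, the minimum overlap length, the
  cis/trans window and the tandem gap threshold are declared substitutes for
  unpublished choices; all are configurable, and conclusions that depend on
  them should be checked for sensitivity.
* The bait search is not true orthology inference — no synteny or
  reciprocal-best-hit logic; it finds sequence-conserved overlap regions.
* Triplex prediction is a motif screen, not a thermodynamic model; published
  tools disagree between species on these sites, and this implementation
  makes no stability claims.
* The all-vs-all screen is quadratic in transcript counts beyond the k-mer
  prefilter; whole-transcriptome scaling optimizations are out of scope.
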