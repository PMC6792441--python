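# Methods

This note documents the models, defaults and numerical choices behind
`fragmito`, and what the synthetic-data experiments do and do not show.

## Sequence primitives

Translation uses NCBI codon tables; the organism's mitochondrial genetic
code is unknown for an uncultured single cell, so the table is a
parameter throughout. Defaults: table 1 (standard) for nuclear genes,
table 4 (TGA → Trp) for organellar contigs — the absence of internal
stops in organellar reading frames is itself one of the quantities the
pipeline reports, so a mistaken table choice is visible in the output
rather than silently absorbed.

Local alignment is affine-gap Smith–Waterman (Biopython's
`PairwiseAligner` engine behind the `seqcore` interface). A gap of length
L costs `gap_open + L·gap_extend`. Defaults are BLAST-like: BLOSUM62 with
11/1 for proteins; match +1, mismatch −2, gap 5/2 for nucleotides. N
never matches and is excluded from GC. When no positive-scoring residue
pair exists the score is 0 with an empty alignment. Heuristic seeded
search and E-value statistics are deliberately out of scope: assemblies
at single-cell scale are small enough for exact alignment.

In-silico PCR reports a product wherever the forward primer matches the
plus strand and the reverse complement of the reverse primer matches
downstream, each within a Hamming-mismatch budget; product length
includes both primer sites. Only this convergent orientation is
searched; callers wanting the mirrored orientation swap the primers.

## Organellar contig classification

Three lines of evidence:

* **Coverage.** Organellar genomes are high-copy; the classification
  ratio uses the assembly *median* coverage as denominator because
  whole-genome amplification yields heavy-tailed coverage (sd larger than
  the mean), making the mean non-robust. Default ratio threshold
  `r_min = 3.0`.
* **GC.** Absolute deviation from the length-weighted assembly GC,
  threshold `gc_delta = 0.05`. Both defaults are chosen so that a bin
  with ~4.7-fold coverage and ΔGC ≈ 0.10 — the separation the generator
  emulates — classifies positive with a wide margin.
* **Tetranucleotides.** Canonical 4-mer frequencies (4-mer and reverse
  complement collapsed to the lexicographically smaller key; 136
  classes; N-containing windows skipped) feed a self-organizing map:
  rectangular toroidal grid (default 20×12), Gaussian neighbourhood,
  learning rate 0.5 → 0.01 and radius max(w,h)/2 → 1, both decaying
  linearly over 10 epochs, weights initialized from sampled data points.
  No installed package provides a SOM, so the classic online update is
  implemented directly; it is deterministic under a fixed seed. The SOM
  is used for *seeded admission* (contigs mapping to nodes dominated by
  known organellar seeds) and for U-matrix visualization; the default
  rule is coverage AND GC, with "ambiguous" when exactly one criterion
  holds. Contigs under 500 bp are excluded from SOM training (too few
  4-mer windows).

N50 is the largest length L such that contigs ≥ L contain at least half
of the assembly bases.

## Module detection

Each reference protein (queries may carry a `gene|taxon` id; hits from
different taxa are deduplicated per contig keeping the best score) is
aligned against all six frame translations of each contig. Because a
single optimal local alignment will happily chain two distant modules
through a long affine gap, each alignment path is decomposed into
**gap-free high-scoring segments**: split at every gap, reduced to
maximal-scoring subsegments (recursive Kadane), then trimmed so each end
sits on a run of ≥ 3 consecutive exact matches. The trim rule is what
makes exact boundary recovery possible: a chance positive-scoring residue
beyond a true module boundary almost never arrives in a run of three.
On noisy data the same rule costs at most a residue or two at module
ends, which recall-level statistics absorb. Defaults: `min_score 55`
(BLOSUM62 units), `min_identity 0.35`, minimum 5 aa.

Minus-strand hits are mapped back to forward-strand bp intervals; for a
gap-free module `bp_len = 3·aa_len` exactly.

`merge_hsps` re-joins collinear same-diagonal fragments (same contig,
gene, strand, frame; protein gap ≤ `max_gap_aa`, nucleotide gap exactly
3× the protein gap), summing scores — the analogue of merging split HSPs.

**Bona fide vs putative contigs.** A contig with ≥ 1 module is bona fide.
Remaining contigs > 500 bp are screened against bona fide contigs for
shared non-coding cassettes: nucleotide local alignment of ≥ 80 bp with
identity in [0.75, 0.995]. The ceiling excludes exact repeats (identical
copies are indistinguishable from assembly duplicates); "similar but not
identical" has no published number, so 0.995 operationalizes it. Since
cassettes sit near chromosome ends, only a 250 bp window at each contig
end is compared by default (`search_window=None` scans whole contigs).
External annotation services are not consulted; translated homology is
the sole bona fide criterion.

## Transcript assembly

Transcript order is defined by reference-protein coordinates; genomic
order by (contig id, contig start). Contig order in an assembly is
arbitrary, so placement on more than one contig by itself implies
trans-splicing, as does a permuted order or mixed strands.

* **Chaining**: dynamic programming over modules sorted by protein start
  maximizing (covered residues, then summed score, then fewer modules),
  with pairwise overlaps ≤ 5 aa; verified against exhaustive subset
  search in tests. Chains advance strictly (non-decreasing ends), which
  bounds all pairwise overlaps by the adjacent ones.
* **Overlap refinement**: each overlapping junction is split at the
  point maximizing the summed per-residue substitution score of the two
  trimmed modules against the reference (ties resolved toward the
  right-hand module).
* **Gap extension**: a flanking module is extended along its contig
  through a residual gap only when the extension reproduces the missing
  reference residues *exactly* and closes the gap entirely. Junction
  gaps whose residues are all phenylalanine (≤ 4 aa) are never extended:
  they are exactly the poly-U-appendage candidates, and genomic DNA
  cannot distinguish a true genomic TTT run from an edited junction
  without RNA data — the package sides with the editing hypothesis and
  records it as such.
* **Short-module collapse** (`collapse_short=True`, off by default): a
  short internal module whose span is also encoded — possibly weakly but
  stop-free and with positive substitution score — as a continuation of
  its left neighbour is removed and flagged. This models the "possible
  short module" ambiguity, where a small extension of the neighbour
  through a poorly conserved region renders the module unnecessary. It
  is opt-in because, applied blindly, chance stop-free continuations
  would erode genuine modules.
* **Poly-U junctions**: for a junction with residual gap g ≤ 4 aa, the
  solver finds the minimal k ≤ 12 such that inserting k U's — plus at
  most two leftover genomic nucleotides per flank (partial codons) —
  restores the reading frame and the reference residues exactly. k = 0
  for clean abutments; junctions with no U-only solution are annotated
  `unresolved`; gaps > 4 aa are `missing_modules`. k_max = 12 covers the
  largest appendage reported in this gene family (6 U) with margin.
* **Substitution-editing check**: the assembled CDS is translated under
  the configured code; verdict "none required" iff no internal stop,
  otherwise stop positions are listed as candidate editing or
  code-reassignment sites.

## Splice-boundary comparison

Module boundaries are positions in each taxon's mature protein. Taxon A's
boundaries are projected into taxon B coordinates through a global
protein alignment (BLOSUM62, 12/1, cheap terminal gaps — chains may cover
slightly different extents); a boundary is conserved when a B boundary
lies within 1 aa of the projection (0 is too strict under alignment
jitter; the criterion in the literature is qualitative). Boundaries
falling in alignment gaps are flagged unmapped. The summary counts
boundaries conserved in all compared taxa, in some, and in none.

## Introns and U1

Canonical GT–AG introns are called between consecutive homology blocks of
a nuclear gene: blocks are first reduced to the largest collinear chain
(protein and genomic coordinates both increasing — this discards chance
mini-hits inside introns), then each inter-block insertion is searched
for a GT…AG placement within ±6 bp of the homology-implied breakpoints
(handling intron phase and chance block over-extension by up to 2 aa),
keeping the placement that maximizes the spliced-translation score, ties
toward the homology-implied breakpoints, and requiring the spliced score
to be at least the unspliced block baseline. Only canonical GT–AG introns
are modelled; non-canonical intron classes found in related lineages are
out of scope.

U1 binding: the recognition region is, by default, the 9 nt at offset 2
from the U1 5′ end (the active-site extent is only approximately known,
so both offset and length are configurable). It is paired antiparallel
against the −3..+6 donor window; the score counts Watson–Crick pairs plus
G:U wobbles, with T ≡ U. U1 candidates are located by nucleotide homology
on both strands (identity ≥ 0.7 over ≥ 80 nt).

## The synthetic-data generator

The generator's defaults are the study conditions the analysis assumes:

| quantity | default | rationale |
|---|---|---|
| nuclear GC / mito GC | 0.457 / 0.361 | typical nuclear-vs-organellar separation for this lineage class |
| nuclear coverage | log-normal, mean 41.6×, sd 62.6× | heavy-tailed single-cell amplification; log-normal allows sd > mean |
| mito coverage | log-normal, mean 196×, sd 49× | ~4.7-fold copy-number excess |
| genes | 3 proteins (510/450/380 aa), 5 modules each | fragmented-gene regime; modules capped at 135 aa, min 25 aa |
| contigs | 176 nuclear + 8 coding + 16 cassette-only mito | 200-contig assembly with the 8/16 bona-fide/putative split |
| cassettes | 100 bp, ≥1 substitution per copy at 5% rate, within 50 bp of ends | similar-but-never-identical shared regions |
| mito composition | CpG depletion factor 0.5 | makes tetranucleotide binning informative beyond GC alone |
| introns | Poisson(2) per nuclear gene, 60–300 bp, GTAAGT…CAG | canonical donors pair with the planted U1 recognition region |
| noise | 0 substitutions by default | exact-recovery regime; `noise_sub_rate` adds coding substitutions |

Reverse translation draws synonymous codons with a GC tilt whose
parameter is solved by bisection so the expected coding GC matches the
bin target — without this, module-dense contigs drift toward nuclear GC
and blur the classification margin.

Three generator policies make *exact* recovery a well-posed target rather
than a statistical one:

* **Boundary cleaning**: the background codon adjacent to each planted
  module (in the module's own frame and orientation) is resampled until
  it does not translate to the next reference residue, so homology search
  cannot extend a module by chance.
* **Junction decodability**: background flanking an edited junction is
  resampled until the planted k is the unique minimal solution of the
  junction-fill equation and neither flank can absorb a gap residue.
* **Exon spacing**: intron insertion points are kept ≥ 60 bp apart so
  every internal exon anchors a homology block.

Poly-U omissions are taken in whole codons when k is a multiple of 3
(split as evenly as possible between the two flanks); other k are taken
from the left module's tail, leaving a partial codon on the contig.
Junction residues are written as phenylalanines (TTT) because UUU is the
only U-only codon. Nuclear genes are planted on the plus strand; the
intron caller itself is strand-aware and is tested on reverse-complement
input.

**What passing tests show — and don't.** Noise-free recovery tests prove
the inference chain is lossless when the signal is intact: they validate
coordinate arithmetic, chaining optimality and junction decoding, not
robustness. Real SAG data add assembly fragmentation and chimerism,
amplification dropout, sequencing error, diverged (not identical)
reference proteomes, and genuinely ambiguous module boundaries — the
generator models none of these beyond an optional uniform substitution
rate, under which module recall (not exactness) is the tested guarantee.
NUMT discrimination, read-level simulation and guide-RNA editing are out
of scope.

## Problem sizes

Default experiments use 200-contig assemblies (~0.4 Mb), three genes ×
five modules, five replicate seeds for binning, 100 junctions for poly-U
decoding and 1000 random windows for the U1 rank-sum comparison; these
sizes keep the full test suite and the acceptance script to a few minutes
on one CPU while leaving every statistical margin wide.

## Known limitations

* The cassette screen compares contig end windows by default; cassettes
  placed mid-contig require `search_window=None`.
* `in_silico_pcr` searches one convergent orientation (forward primer on
  the plus strand).
* Cross-taxon boundary projection assumes chains cover most of the
  protein; for sparse chains the global alignment can misplace
  boundaries near its ends.
* The U1 "active site" extent is configurable rather than inferred; no
  secondary-structure model is fitted.
* With substitution noise, the exact-match gap-extension rule almost
  never fires, so small genuine gaps in noisy data are reported as
  unresolved junctions rather than extended through.
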