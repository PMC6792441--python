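"""Sequence primitives: complementation, six-frame translation, local alignment, in-silico PCR.

These are the building blocks of the organellar-gene pipeline.  Translated
homology search (:mod:`fragmito.modulefind`) and cassette screening run on
top of the local aligners defined here, which wrap Biopython's
Smith-Waterman implementation with BLAST-like affine-gap conventions: a gap
of length ``L`` costs ``gap_open + L * gap_extend``.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

__all__ = [
    "GeneticCode",
    "LocalAlignment",
    "PcrProduct",
    "get_code",
    "reverse_complement",
    "translate",
    "six_frame_translations",
    "load_matrix",
    "local_align_protein",
    "local_align_nt",
    "in_silico_pcr",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Default scoring follows BLAST defaults for protein (BLOSUM62, 11/1) and
#: nucleotide (+1/-2, gap 5/2) searches.
DEFAULT_PROTEIN_GAP_OPEN = 11
DEFAULT_PROTEIN_GAP_EXTEND = 1
DEFAULT_NT_MATCH = 1
DEFAULT_NT_MISMATCH = -2
DEFAULT_NT_GAP_OPEN = 5
DEFAULT_NT_GAP_EXTEND = 2

FRAMES = (1, 2, 3, -1, -2, -3)


class SequenceError(ValueError):
    """Raised for malformed sequence input (bad alphabet, bad frame, ...)."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A, C, G, T, N}."""
    bad = set(seq) - set("ACGTN")
    if bad:
        raise SequenceError(
            f"reverse_complement: illegal symbol(s) {sorted(bad)!r}; expected A/C/G/T/N"
        )
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneticCode:
    """A codon translation table (NCBI numbering).

    The organism's mitochondrial code is unknown a priori for an
    environmental single cell, so the table is a parameter throughout the
    package; table 4 (TGA = Trp) is the conventional default for organellar
    sequence, table 1 for nuclear genes.
    """

    table_id: int
    codons: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.codons) != 64:
            raise SequenceError(f"genetic code table must have 64 codons, got {len(self.codons)}")
        if "*" not in self.codons.values():
            raise SequenceError("genetic code table must contain at least one stop codon")

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codons.items() if aa == "*")


@functools.lru_cache(maxsize=None)
def get_code(table_id: int = 1) -> GeneticCode:
    """Look up an NCBI translation table by id."""
    try:
        tbl = CodonTable.unambiguous_dna_by_id[table_id]
    except KeyError as exc:
        raise SequenceError(f"unknown genetic code table id {table_id}") from exc
    codons = dict(tbl.forward_table)
    for stop in tbl.stop_codons:
        codons[stop] = "*"
    return GeneticCode(table_id=table_id, codons=codons)


def translate(seq: str, frame: int = 1, table_id: int = 1) -> str:
    """Translate ``seq`` in one of the six frames; stops rendered ``*``.

    Frames +1/+2/+3 read the forward strand with offsets 0/1/2; -1/-2/-3
    read the reverse complement likewise.  Codons containing N translate
    to ``X``.
    """
    if frame not in FRAMES:
        raise SequenceError(f"frame must be one of {FRAMES}, got {frame}")
    code = get_code(table_id)
    if frame < 0:
        seq = reverse_complement(seq)
    offset = abs(frame) - 1
    s = seq[offset:]
    n = len(s) // 3
    out = []
    for i in range(n):
        codon = s[3 * i : 3 * i + 3]
        out.append(code.codons.get(codon, "X"))
    return "".join(out)


def six_frame_translations(seq: str, table_id: int = 1) -> dict[int, str]:
    return {f: translate(seq, f, table_id) for f in FRAMES}


@functools.lru_cache(maxsize=None)
def load_matrix(name: str = "BLOSUM62"):
    """Load a substitution matrix by name, or from an NCBI-format file path."""
    try:
        return substitution_matrices.load(name)
    except Exception:
        return substitution_matrices.read(name)


@dataclass
class LocalAlignment:
    """A best local alignment between a query and a target.

    Intervals are 0-based half-open.  ``blocks`` holds the gap-free pieces
    as ``(query_start, query_end, target_start, target_end)`` tuples;
    ``pairs`` enumerates the aligned index pairs.  ``identity`` is the
    fraction of alignment columns (gap columns included) with identical
    residues.
    """

    query_start: int
    query_end: int
    target_start: int
    target_end: int
    score: float
    identity: float
    blocks: list[tuple[int, int, int, int]] = field(default_factory=list)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return [
            (q, t)
            for qs, qe, ts, te in self.blocks
            for q, t in zip(range(qs, qe), range(ts, te))
        ]

    @property
    def n_columns(self) -> int:
        if not self.blocks:
            return 0
        aligned = sum(qe - qs for qs, qe, ts, te in self.blocks)
        gaps = 0
        for (aqs, aqe, ats, ate), (bqs, bqe, bts, bte) in zip(self.blocks, self.blocks[1:]):
            gaps += (bqs - aqe) + (bts - ate)
        return aligned + gaps

    @property
    def is_empty(self) -> bool:
        return not self.blocks


_EMPTY = LocalAlignment(0, 0, 0, 0, 0.0, 0.0, [])


def _finish(query: str, target: str, aln, score: float) -> LocalAlignment:
    qblocks, tblocks = aln.aligned
    blocks = [
        (int(qs), int(qe), int(ts), int(te))
        for (qs, qe), (ts, te) in zip(qblocks, tblocks)
    ]
    matches = sum(
        1
        for qs, qe, ts, te in blocks
        for q, t in zip(range(qs, qe), range(ts, te))
        if query[q] == target[t]
    )
    la = LocalAlignment(
        query_start=blocks[0][0],
        query_end=blocks[-1][1],
        target_start=blocks[0][2],
        target_end=blocks[-1][3],
        score=float(score),
        identity=0.0,
        blocks=blocks,
    )
    la.identity = matches / la.n_columns if la.n_columns else 0.0
    return la


_ALIGNER_CACHE: dict[tuple, Align.PairwiseAligner] = {}


def _make_aligner(matrix, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    key = (id(matrix), gap_open, gap_extend)
    aligner = _ALIGNER_CACHE.get(key)
    if aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = matrix
        aligner.open_gap_score = -(gap_open + gap_extend)
        aligner.extend_gap_score = -gap_extend
        _ALIGNER_CACHE[key] = aligner
    return aligner


def local_score_protein(
    query: str,
    target: str,
    matrix="BLOSUM62",
    gap_open: float = DEFAULT_PROTEIN_GAP_OPEN,
    gap_extend: float = DEFAULT_PROTEIN_GAP_EXTEND,
) -> float:
    """Optimal local alignment score only (no traceback; fast prescreen)."""
    if isinstance(matrix, str):
        matrix = load_matrix(matrix)
    return float(_make_aligner(matrix, gap_open, gap_extend).score(query, target))


def local_align_protein(
    query: str,
    target: str,
    matrix="BLOSUM62",
    gap_open: float = DEFAULT_PROTEIN_GAP_OPEN,
    gap_extend: float = DEFAULT_PROTEIN_GAP_EXTEND,
) -> LocalAlignment:
    """Optimal Smith-Waterman local protein alignment under affine gaps.

    Returns a zero-score empty alignment when no positive-scoring residue
    pair exists.  Residues absent from the matrix alphabet raise an error.
    """
    if not query or not target:
        raise SequenceError("local_align_protein: sequences must be non-empty")
    if isinstance(matrix, str):
        matrix = load_matrix(matrix)
    alphabet = set(str(matrix.alphabet))
    unknown = (set(query) | set(target)) - alphabet
    if unknown:
        raise SequenceError(f"residue(s) {sorted(unknown)!r} absent from substitution matrix")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    results = aligner.align(query, target)
    if results.score <= 0:
        return _EMPTY
    return _finish(query, target, results[0], results.score)


@functools.lru_cache(maxsize=None)
def _nt_matrix(match: float, mismatch: float):
    """Match/mismatch matrix over ACGTN where N never matches anything."""
    alphabet = "ACGTN"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            mat[a, b] = match if (a == b and a != "N") else mismatch
    return mat


def local_align_nt(
    query: str,
    target: str,
    match: float = DEFAULT_NT_MATCH,
    mismatch: float = DEFAULT_NT_MISMATCH,
    gap_open: float = DEFAULT_NT_GAP_OPEN,
    gap_extend: float = DEFAULT_NT_GAP_EXTEND,
) -> LocalAlignment:
    """Optimal local nucleotide alignment; N counts as a mismatch."""
    if not query or not target:
        raise SequenceError("local_align_nt: sequences must be non-empty")
    bad = (set(query) | set(target)) - set("ACGTN")
    if bad:
        raise SequenceError(f"local_align_nt: illegal symbol(s) {sorted(bad)!r}")
    aligner = _make_aligner(_nt_matrix(match, mismatch), gap_open, gap_extend)
    results = aligner.align(query, target)
    if results.score <= 0:
        return _EMPTY
    return _finish(query, target, results[0], results.score)


@dataclass(frozen=True)
class PcrProduct:
    contig_id: str
    start: int  # 0-based, start of forward primer site
    end: int  # half-open, end of reverse primer site
    length: int
    fwd_mismatches: int
    rev_mismatches: int


def _primer_sites(seq: str, primer: str, max_mismatches: int) -> list[tuple[int, int]]:
    hits = []
    k = len(primer)
    for i in range(len(seq) - k + 1):
        mm = sum(1 for a, b in zip(seq[i : i + k], primer) if a != b)
        if mm <= max_mismatches:
            hits.append((i, mm))
    return hits


def in_silico_pcr(
    contigs: dict[str, str],
    forward_primer: str,
    reverse_primer: str,
    max_mismatches: int = 0,
    max_product_bp: int = 20000,
) -> list[PcrProduct]:
    """Predict amplicons from a convergent primer pair.

    A product is reported wherever the forward primer matches the plus
    strand and the reverse complement of the reverse primer matches
    downstream on the same strand, each within the mismatch budget.
    The product length includes both primer sites.
    """
    for name, p in (("forward", forward_primer), ("reverse", reverse_primer)):
        if len(p) < 15:
            raise SequenceError(f"{name} primer must be >= 15 nt, got {len(p)}")
    rc_rev = reverse_complement(reverse_primer)
    products = []
    for cid, seq in contigs.items():
        fwd_hits = _primer_sites(seq, forward_primer, max_mismatches)
        rev_hits = _primer_sites(seq, rc_rev, max_mismatches)
        for fstart, fmm in fwd_hits:
            for rstart, rmm in rev_hits:
                rend = rstart + len(rc_rev)
                if rstart >= fstart + len(forward_primer) and rend - fstart <= max_product_bp:
                    products.append(
                        PcrProduct(cid, fstart, rend, rend - fstart, fmm, rmm)
                    )
    return products
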