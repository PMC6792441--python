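"""Canonical GT-AG introns and U1 snRNA splice-site complementarity.

Nuclear genes are scanned for spliceosomal introns by homology: where a
reference protein aligns to a contig in two separated blocks, the
intervening genomic insertion is tested for a GT...AG excision that
restores the reading frame and the missing residues.  The 5' splice site
is then scored for antiparallel base pairing against the recognition
region of a U1 snRNA candidate (Watson-Crick pairs plus G:U wobbles),
the physical basis of donor-site selection.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import seqcore
from .modulefind import Module, find_modules

__all__ = [
    "IntronCall",
    "U1Match",
    "U1Locus",
    "find_canonical_introns",
    "u1_binding_score",
    "find_u1_candidate",
    "donor_window",
]


class IntronError(ValueError):
    pass


@dataclass
class IntronCall:
    contig_id: str
    start: int  # 0-based half-open, forward strand
    end: int
    strand: str
    gene: str
    donor: str  # first two intron nt (transcript sense)
    acceptor: str  # last two intron nt
    score_gain: float  # positional score of the residues restored by splicing
    source: str = "homology"


@dataclass
class U1Match:
    window: str  # 9-nt donor window, -3..+6 around the donor site
    recognition: str
    pairing: str  # '|' Watson-Crick, ':' G:U wobble, '.' unpaired
    score: int


@dataclass
class U1Locus:
    contig_id: str
    start: int
    end: int
    strand: str
    identity: float
    score: float
    length: int


def _blocks_for_gene(
    seq: str, ref_protein: str, gene: str, table_id: int, min_block_score: float
) -> dict[str, list[Module]]:
    hits = find_modules(
        {"_contig": seq}, {gene: ref_protein},
        min_score=min_block_score, min_identity=0.35, min_aa=5,
        table_id=table_id,
    )
    by_strand: dict[str, list[Module]] = {}
    for h in hits:
        by_strand.setdefault(h.strand, []).append(h)
    for group in by_strand.values():
        group.sort(key=lambda m: m.prot_start)
    return by_strand


def _select_collinear(blocks: list[Module], t_coords) -> list[Module]:
    """Largest-coverage chain of blocks collinear in both protein and
    (transcript-sense) genomic coordinates; drops spurious chance hits
    that fall inside introns or out of order."""
    blocks = sorted(blocks, key=lambda m: (m.prot_start, m.prot_end))
    n = len(blocks)
    best: list[tuple[int, float]] = []
    parent: list[int | None] = []
    for i, bi in enumerate(blocks):
        obj = (bi.prot_end - bi.prot_start, bi.score)
        par: int | None = None
        for j in range(i):
            bj = blocks[j]
            if bj.prot_end - bi.prot_start > 2 or bj.prot_end > bi.prot_end:
                continue
            if t_coords(bi)[0] < t_coords(bj)[1] - 6:
                continue
            gain = bi.prot_end - max(bi.prot_start, bj.prot_end)
            cand = (best[j][0] + gain, best[j][1] + bi.score)
            if cand > obj:
                obj, par = cand, j
        best.append(obj)
        parent.append(par)
    k: int | None = max(range(n), key=lambda i: best[i])
    out = []
    while k is not None:
        out.append(blocks[k])
        k = parent[k]
    out.reverse()
    return out


def find_canonical_introns(
    contig_id: str,
    seq: str,
    ref_protein: str,
    gene: str = "",
    table_id: int = 1,
    max_intron_bp: int = 2000,
    search_bp: int = 6,
    min_block_score: float = 25.0,
    matrix_name: str = "BLOSUM62",
) -> list[IntronCall]:
    """Call GT-AG introns between homology blocks of one gene.

    For each pair of consecutive alignment blocks on the same strand the
    GT...AG placement is searched within +-``search_bp`` bp of the
    homology-implied breakpoints; the placement maximizing the spliced
    translation score is accepted (ties broken toward the
    homology-implied breakpoints), provided the residues restored by
    splicing score non-negatively against the reference.  Insertions
    without any frame-consistent GT...AG placement yield no call.
    """
    matrix = seqcore.load_matrix(matrix_name)
    calls: list[IntronCall] = []
    for strand, blocks in _blocks_for_gene(
        seq, ref_protein, gene or "gene", table_id, min_block_score
    ).items():
        if len(blocks) < 2:
            continue
        work = seq if strand == "+" else seqcore.reverse_complement(seq)
        L = len(seq)

        def t_coords(m: Module) -> tuple[int, int]:
            if strand == "+":
                return m.contig_start, m.contig_end
            return L - m.contig_end, L - m.contig_start

        blocks = _select_collinear(blocks, t_coords)
        if len(blocks) < 2:
            continue

        for b1, b2 in zip(blocks, blocks[1:]):
            s1, e1 = t_coords(b1)
            s2, e2 = t_coords(b2)
            if s2 <= e1:
                continue
            insertion = s2 - e1
            gap_aa = b2.prot_start - b1.prot_end
            # small negative gaps happen when a block over-extends by a
            # chance residue match into the intron
            if gap_aa < -2 or insertion - 3 * gap_aa > max_intron_bp + 2 * search_bp:
                continue
            need = 3 * (b2.prot_end - b1.prot_start)
            ref_seg = ref_protein[b1.prot_start : b2.prot_end]
            best = None
            for ds in range(-search_bp, search_bp + 1):
                for de in range(-search_bp, search_bp + 1):
                    istart, iend = e1 + ds, s2 + de
                    if istart < s1 + 3 or iend > e2 - 3:
                        continue
                    ilen = iend - istart
                    if ilen < 4 or ilen > max_intron_bp:
                        continue
                    if (istart - s1) + (e2 - iend) != need:
                        continue
                    if work[istart : istart + 2] != "GT":
                        continue
                    if work[iend - 2 : iend] != "AG":
                        continue
                    spliced = work[s1:istart] + work[iend:e2]
                    trans = seqcore.translate(spliced, 1, table_id)
                    if len(trans) != len(ref_seg):
                        continue
                    score = sum(
                        float(matrix[a, b]) for a, b in zip(trans, ref_seg)
                    )
                    key = (score, -(abs(ds) + abs(de)))
                    if best is None or key > best[0]:
                        best = (key, istart, iend)
            if best is None:
                continue
            (score, _), istart, iend = best
            # unspliced baseline: the two blocks alone, counting any
            # overlapped reference residues once
            t1 = seqcore.translate(work[s1:e1], 1, table_id)
            t2 = seqcore.translate(work[s2:e2], 1, table_id)
            unspliced = sum(
                float(matrix[a, b])
                for a, b in zip(t1, ref_protein[b1.prot_start : b1.prot_end])
            )
            skip = max(0, b1.prot_end - b2.prot_start)
            unspliced += sum(
                float(matrix[a, b])
                for a, b in zip(t2[skip:],
                                ref_protein[b2.prot_start + skip : b2.prot_end])
            )
            if score < unspliced:
                continue
            if strand == "+":
                f_start, f_end = istart, iend
            else:
                f_start, f_end = L - iend, L - istart
            calls.append(
                IntronCall(
                    contig_id=contig_id,
                    start=f_start,
                    end=f_end,
                    strand=strand,
                    gene=gene,
                    donor=work[istart : istart + 2],
                    acceptor=work[iend - 2 : iend],
                    score_gain=score - unspliced,
                )
            )
    calls.sort(key=lambda c: (c.contig_id, c.start))
    return calls


def donor_window(seq: str, intron_start: int, strand: str = "+",
                 exon_nt: int = 3, intron_nt: int = 6) -> str:
    """The -3..+6 window around a 5' splice site (transcript sense)."""
    if strand == "+":
        a = intron_start - exon_nt
        b = intron_start + intron_nt
        if a < 0 or b > len(seq):
            raise IntronError("donor window out of contig bounds")
        return seq[a:b]
    a = intron_start - intron_nt
    b = intron_start + exon_nt
    if a < 0 or b > len(seq):
        raise IntronError("donor window out of contig bounds")
    return seqcore.reverse_complement(seq[a:b])


_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


def u1_binding_score(
    u1_seq: str,
    donor_win: str,
    recognition_offset: int = 2,
    recognition_len: int = 9,
) -> U1Match:
    """Score antiparallel pairing of the U1 recognition region against a
    donor window.

    The recognition region is ``u1_seq[offset : offset+len]`` (the
    active-site extent is configurable because it is only approximately
    known); T and U are equivalent.  Score counts Watson-Crick pairs plus
    G:U wobbles.
    """
    u1 = u1_seq.upper().replace("U", "T")
    win = donor_win.upper().replace("U", "T")
    recog = u1[recognition_offset : recognition_offset + recognition_len]
    if len(recog) < recognition_len:
        raise IntronError("U1 sequence shorter than its recognition window")
    if len(win) != recognition_len:
        raise IntronError(
            f"donor window must be {recognition_len} nt, got {len(win)}"
        )
    pairing = []
    score = 0
    for i, b in enumerate(win):
        partner = recog[recognition_len - 1 - i]
        if (b, partner) in _PAIRS:
            pairing.append("|")
            score += 1
        elif (b, partner) in _WOBBLE:
            pairing.append(":")
            score += 1
        else:
            pairing.append(".")
    return U1Match(window=win, recognition=recog,
                   pairing="".join(pairing), score=score)


def find_u1_candidate(
    contigs: dict[str, str],
    u1_query: str,
    min_identity: float = 0.7,
    min_len: int = 80,
) -> list[U1Locus]:
    """Locate U1 snRNA candidates by nucleotide homology on both strands.

    Hits with identity >= ``min_identity`` over >= ``min_len`` aligned
    columns are returned ranked by alignment score.
    """
    query = u1_query.upper().replace("U", "T")
    if len(query) < 50:
        raise IntronError(f"U1 query must be >= 50 nt, got {len(query)}")
    loci = []
    for cid, seq in contigs.items():
        for strand in "+-":
            target = seq if strand == "+" else seqcore.reverse_complement(seq)
            aln = seqcore.local_align_nt(query, target)
            if aln.is_empty:
                continue
            if aln.n_columns < min_len or aln.identity < min_identity:
                continue
            if strand == "+":
                start, end = aln.target_start, aln.target_end
            else:
                start = len(seq) - aln.target_end
                end = len(seq) - aln.target_start
            loci.append(
                U1Locus(cid, start, end, strand, aln.identity, aln.score,
                        aln.n_columns)
            )
    loci.sort(key=lambda u: -u.score)
    return loci
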