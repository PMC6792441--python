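"""Detection of mitochondrial gene modules by translated homology.

Reference mitochondrial proteins are aligned (Smith-Waterman, BLOSUM62)
against all six frame translations of each contig.  Because fragmented
organellar genes place several short coding modules on one contig - often
far apart, out of order, or on opposite strands - a single optimal local
alignment can chain distant modules through long gaps.  Hits are therefore
post-processed into gap-free high-scoring segments ("HSPs"): the alignment
path is split at every gap, each gap-free block is reduced to its
maximal-scoring subsegments, and segment ends are trimmed back to exact
residue matches.  Each surviving segment is one candidate module.

Contigs carrying at least one module are *bona fide* organellar contigs;
the remainder are screened for shared-but-not-identical non-coding
"cassette" regions near the ends of bona fide contigs, which flags
*putative* organellar contigs that carry no coding module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import seqcore
from .seqcore import LocalAlignment

__all__ = ["Module", "MitoContigCall", "find_modules", "merge_hsps",
           "call_mito_contigs"]


@dataclass
class Module:
    """A translated-homology hit mapped back to forward-strand bp."""

    contig_id: str
    contig_start: int  # 0-based half-open, forward strand
    contig_end: int
    strand: str  # '+' or '-'
    frame: int  # 1-3 within the strand
    gene: str
    prot_start: int  # 0-based half-open on the reference protein
    prot_end: int
    score: float
    identity: float
    taxon: str = ""

    @property
    def aa_len(self) -> int:
        return self.prot_end - self.prot_start

    @property
    def bp_len(self) -> int:
        return self.contig_end - self.contig_start


@dataclass
class MitoContigCall:
    contig_id: str
    status: str  # bona_fide | putative | none
    module_count: int = 0
    cassette_partner: str | None = None
    cassette_start: int | None = None
    cassette_end: int | None = None
    cassette_identity: float | None = None
    cassette_length: int | None = None


def _column_scores(query: str, target: str, aln: LocalAlignment, matrix):
    """Per-column (q_idx, t_idx, score, is_match) for each gap-free block."""
    blocks = []
    for qs, qe, ts, te in aln.blocks:
        cols = []
        for q, t in zip(range(qs, qe), range(ts, te)):
            s = float(matrix[query[q], target[t]])
            cols.append((q, t, s, query[q] == target[t]))
        blocks.append(cols)
    return blocks


def _max_subsegments(cols, min_score: float):
    """Recursive Kadane: non-overlapping maximal-scoring runs of columns."""
    if not cols:
        return []
    best_sum = best_i = best_j = None
    cur = 0.0
    start = 0
    for i, (_, _, s, _) in enumerate(cols):
        if cur <= 0:
            cur = s
            start = i
        else:
            cur += s
        if best_sum is None or cur > best_sum:
            best_sum, best_i, best_j = cur, start, i + 1
    if best_sum is None or best_sum < min_score:
        return []
    out = _max_subsegments(cols[:best_i], min_score)
    out.append(cols[best_i:best_j])
    out.extend(_max_subsegments(cols[best_j:], min_score))
    return out


def _trim_to_matches(cols, run: int = 3):
    """Trim segment ends back to a run of ``run`` consecutive exact matches.

    A true module boundary is flanked by identities; chance positive-scoring
    columns beyond it almost never come in runs, so this anchors segment
    ends on solid matches without disturbing interior mismatches.
    """
    a, b = 0, len(cols)
    while b - a >= run and not all(c[3] for c in cols[a : a + run]):
        a += 1
    while b - a >= run and not all(c[3] for c in cols[b - run : b]):
        b -= 1
    if b - a < run:
        return [] if not all(c[3] for c in cols[a:b]) else cols[a:b]
    return cols[a:b]


def _segments_from_alignment(query, target, aln, matrix, min_score):
    segs = []
    for block_cols in _column_scores(query, target, aln, matrix):
        for seg in _max_subsegments(block_cols, min_score):
            seg = _trim_to_matches(seg)
            if seg:
                segs.append(seg)
    return segs


def _frame_to_bp(contig_len: int, strand: str, frame: int,
                 aa_start: int, aa_end: int) -> tuple[int, int]:
    off = frame - 1
    if strand == "+":
        return off + 3 * aa_start, off + 3 * aa_end
    return contig_len - (off + 3 * aa_end), contig_len - (off + 3 * aa_start)


def _search_segment(
    protein: str, trans: str, lo: int, hi: int, matrix,
    min_score: float, hits: list,
) -> None:
    if hi - lo < 5:
        return
    if seqcore.local_score_protein(protein, trans[lo:hi], matrix=matrix) < min_score:
        return
    aln = seqcore.local_align_protein(protein, trans[lo:hi], matrix=matrix)
    if aln.is_empty or aln.score < min_score:
        return
    for seg in _segments_from_alignment(protein, trans[lo:hi], aln, matrix,
                                        min_score):
        score = sum(c[2] for c in seg)
        if score < min_score:
            continue
        matches = sum(1 for c in seg if c[3])
        hits.append(
            {
                "q": (seg[0][0], seg[-1][0] + 1),
                "t": (lo + seg[0][1], lo + seg[-1][1] + 1),
                "score": score,
                "identity": matches / len(seg),
            }
        )
    _search_segment(protein, trans, lo, lo + aln.target_start, matrix,
                    min_score, hits)
    _search_segment(protein, trans, lo + aln.target_end, hi, matrix,
                    min_score, hits)


def _gene_and_taxon(ref_id: str) -> tuple[str, str]:
    gene, _, taxon = ref_id.partition("|")
    return gene, taxon


def find_modules(
    contigs: dict[str, str],
    ref_proteins: dict[str, str],
    min_score: float = 55.0,
    min_identity: float = 0.35,
    min_aa: int = 5,
    table_id: int = 4,
    matrix_name: str = "BLOSUM62",
    deduplicate: bool = True,
) -> list[Module]:
    """Find gene modules on contigs by six-frame translated homology.

    Reference ids may carry a taxon suffix after ``|`` (``cox1|Dpap``);
    hits from different reference taxa for the same gene that overlap on
    the contig are deduplicated keeping the highest score.
    """
    if not ref_proteins:
        raise ValueError("find_modules: reference protein set is empty")
    matrix = seqcore.load_matrix(matrix_name)
    modules: list[Module] = []
    for cid, seq in contigs.items():
        L = len(seq)
        if L < 3 * min_aa:
            continue
        for frame in seqcore.FRAMES:
            trans = seqcore.translate(seq, frame, table_id)
            if len(trans) < min_aa:
                continue
            strand = "+" if frame > 0 else "-"
            f = abs(frame)
            for ref_id, protein in ref_proteins.items():
                gene, taxon = _gene_and_taxon(ref_id)
                hits: list[dict] = []
                _search_segment(protein, trans, 0, len(trans), matrix,
                                min_score, hits)
                for h in hits:
                    if h["identity"] < min_identity:
                        continue
                    qa, qb = h["q"]
                    ta, tb = h["t"]
                    if qb - qa < min_aa:
                        continue
                    bs, be = _frame_to_bp(L, strand, f, ta, tb)
                    modules.append(
                        Module(
                            contig_id=cid,
                            contig_start=bs,
                            contig_end=be,
                            strand=strand,
                            frame=f,
                            gene=gene,
                            prot_start=qa,
                            prot_end=qb,
                            score=h["score"],
                            identity=h["identity"],
                            taxon=taxon,
                        )
                    )
    if deduplicate:
        modules = _dedupe(modules)
    modules.sort(key=lambda m: (m.contig_id, m.contig_start, m.gene))
    return modules


def _overlap_frac(a: Module, b: Module) -> float:
    ov = min(a.contig_end, b.contig_end) - max(a.contig_start, b.contig_start)
    if ov <= 0:
        return 0.0
    return ov / min(a.bp_len, b.bp_len)


def _dedupe(modules: list[Module]) -> list[Module]:
    """Keep the best-scoring hit per (contig, gene) overlapping interval."""
    kept: list[Module] = []
    for m in sorted(modules, key=lambda m: -m.score):
        if any(
            k.contig_id == m.contig_id and k.gene == m.gene
            and _overlap_frac(k, m) >= 0.5
            for k in kept
        ):
            continue
        kept.append(m)
    return kept


def _transcript_pos(m: Module) -> tuple[int, int]:
    """Contig coordinate in transcript reading direction (start, end)."""
    if m.strand == "+":
        return m.contig_start, m.contig_end
    return -m.contig_end, -m.contig_start


def merge_hsps(modules: list[Module], max_gap_aa: int = 10) -> list[Module]:
    """Merge collinear same-diagonal hits separated by at most
    ``max_gap_aa`` in both protein and contig coordinates.

    Hits must share contig, gene, strand and frame to be mergeable; scores
    are summed and identities length-averaged.  Everything else passes
    through unchanged.
    """
    groups: dict[tuple, list[Module]] = {}
    for m in modules:
        groups.setdefault(
            (m.contig_id, m.gene, m.strand, m.frame, m.taxon), []
        ).append(m)
    out: list[Module] = []
    for group in groups.values():
        group.sort(key=lambda m: m.prot_start)
        cur = group[0]
        for nxt in group[1:]:
            prot_gap = nxt.prot_start - cur.prot_end
            nt_gap = _transcript_pos(nxt)[0] - _transcript_pos(cur)[1]
            if 0 <= prot_gap <= max_gap_aa and nt_gap == 3 * prot_gap:
                total_aa = cur.aa_len + nxt.aa_len
                cur = Module(
                    contig_id=cur.contig_id,
                    contig_start=min(cur.contig_start, nxt.contig_start),
                    contig_end=max(cur.contig_end, nxt.contig_end),
                    strand=cur.strand,
                    frame=cur.frame,
                    gene=cur.gene,
                    prot_start=cur.prot_start,
                    prot_end=nxt.prot_end,
                    score=cur.score + nxt.score,
                    identity=(cur.identity * cur.aa_len
                              + nxt.identity * nxt.aa_len) / total_aa,
                    taxon=cur.taxon,
                )
            else:
                out.append(cur)
                cur = nxt
        out.append(cur)
    out.sort(key=lambda m: (m.contig_id, m.contig_start, m.gene))
    return out


def call_mito_contigs(
    contigs: dict[str, str],
    modules: list[Module],
    *,
    min_len: int = 500,
    cassette_min_len: int = 80,
    cassette_min_ident: float = 0.75,
    cassette_max_ident: float = 0.995,
    search_window: int | None = 250,
) -> list[MitoContigCall]:
    """Classify contigs as bona fide / putative organellar, or neither.

    A contig with at least one coding module is *bona fide*.  Remaining
    contigs longer than ``min_len`` bp are screened for cassette sharing:
    a nucleotide local alignment against a bona fide contig of length >=
    ``cassette_min_len`` with identity within
    [``cassette_min_ident``, ``cassette_max_ident``] makes the contig
    *putative*.  The upper identity bound excludes exact repeats, which
    are indistinguishable from assembly duplicates.  Because cassettes sit
    near chromosome ends, only ``search_window`` bp at each contig end are
    compared (pass None to scan whole contigs).
    """
    per_contig: dict[str, int] = {}
    for m in modules:
        per_contig[m.contig_id] = per_contig.get(m.contig_id, 0) + 1
    bona_fide = sorted(per_contig)
    calls = []

    def windows(seq: str) -> list[tuple[int, str]]:
        if search_window is None or len(seq) <= 2 * search_window:
            return [(0, seq)]
        return [(0, seq[:search_window]),
                (len(seq) - search_window, seq[-search_window:])]

    bf_windows = {
        b: [w for _, w in windows(contigs[b])] for b in bona_fide
    }
    for cid, seq in contigs.items():
        if cid in per_contig:
            calls.append(MitoContigCall(cid, "bona_fide",
                                        module_count=per_contig[cid]))
            continue
        if len(seq) <= min_len:
            calls.append(MitoContigCall(cid, "none"))
            continue
        best = None
        for offset, win in windows(seq):
            for b in bona_fide:
                for target in bf_windows[b]:
                    aln = seqcore.local_align_nt(win, target)
                    if aln.is_empty:
                        continue
                    if (aln.n_columns >= cassette_min_len
                            and cassette_min_ident <= aln.identity
                            <= cassette_max_ident):
                        if best is None or aln.score > best[0]:
                            best = (aln.score, b, offset + aln.query_start,
                                    offset + aln.query_end, aln.identity,
                                    aln.n_columns)
        if best is not None:
            _, partner, qs, qe, ident, length = best
            calls.append(
                MitoContigCall(
                    cid, "putative",
                    cassette_partner=partner,
                    cassette_start=qs, cassette_end=qe,
                    cassette_identity=ident, cassette_length=length,
                )
            )
        else:
            calls.append(MitoContigCall(cid, "none"))
    calls.sort(key=lambda c: c.contig_id)
    return calls
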