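"""Reassembly of scattered gene modules into a mature coding sequence.

In diplonemid-like mitochondrial genomes a gene's coding sequence is split
into modules that may sit on different chromosomes, out of order, and on
either strand; the mature mRNA is produced by trans-splicing the module
transcripts in reference-protein order, occasionally completed by a
poly-U appendage at a junction.  This module reconstructs that mature CDS
from detected modules:

* :func:`chain_modules` selects the module subset that tiles the
  reference protein best (dynamic programming, bounded pairwise overlap);
* :func:`refine_junctions` settles overlapping boundaries and attempts
  bounded extension of modules across residual gaps;
* :func:`infer_u_appendage` decodes junctions whose missing residues can
  be restored by inserting U's;
* :func:`scramble_report` quantifies how scrambled the genomic layout is
  and whether trans-splicing is required at all;
* :func:`check_substitution_editing` asks whether the assembled CDS
  translates without internal stops, i.e. whether substitution editing
  would additionally be needed.

Transcript order is defined by reference-protein coordinates; genomic
order by (contig id, contig start).  Contig order in an assembly is
arbitrary, so placement on more than one contig by itself already forces
trans-splicing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from . import seqcore
from .junctions import solve_junction_fill
from .modulefind import Module

__all__ = [
    "ModuleChain",
    "Junction",
    "ScrambleReport",
    "chain_modules",
    "refine_junctions",
    "scramble_report",
    "infer_u_appendage",
    "check_substitution_editing",
    "EditingReport",
    "module_cds",
    "assemble_chain_seqs",
    "render_module_diagram",
]


class ChainError(ValueError):
    pass


@dataclass
class Junction:
    left_index: int  # positions within the chain's transcript-ordered list
    right_index: int
    gap_aa: int
    status: str = "pending"  # abut|gap|u_appendage|flank_fill|unresolved|missing_modules
    k_u: int | None = None
    ext_left: int = 0
    ext_right: int = 0
    genomic: str = ""  # cis_possible | trans
    conserved: bool | None = None  # slot filled by splice comparison


@dataclass
class ScrambleReport:
    gene: str
    n_modules: int
    n_contigs: int
    permutation: list[int]  # transcript indices in genomic order
    n_breakpoints: int
    strand_mix: bool
    permuted_order: bool
    trans_splicing_required: bool
    rationale: list[str]


@dataclass
class ModuleChain:
    gene: str
    ref_protein: str
    modules: list[Module]  # transcript order (ascending prot_start)
    junctions: list[Junction] = field(default_factory=list)
    cds: str = ""
    protein: str = ""
    notes: list[str] = field(default_factory=list)

    @property
    def coverage_fraction(self) -> float:
        covered = sum(m.aa_len for m in self.modules)
        for j in self.junctions:
            if j.status in {"u_appendage", "flank_fill"}:
                covered += j.gap_aa
        return covered / len(self.ref_protein) if self.ref_protein else 0.0

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "ref_protein": self.ref_protein,
            "modules": [dataclasses.asdict(m) for m in self.modules],
            "junctions": [dataclasses.asdict(j) for j in self.junctions],
            "cds": self.cds,
            "protein": self.protein,
            "coverage_fraction": self.coverage_fraction,
            "notes": list(self.notes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModuleChain":
        return cls(
            gene=d["gene"],
            ref_protein=d["ref_protein"],
            modules=[Module(**m) for m in d["modules"]],
            junctions=[Junction(**j) for j in d["junctions"]],
            cds=d.get("cds", ""),
            protein=d.get("protein", ""),
            notes=list(d.get("notes", [])),
        )


def module_cds(contigs: dict[str, str], m: Module) -> str:
    """Transcript-sense coding DNA of a module."""
    s = contigs[m.contig_id][m.contig_start : m.contig_end]
    return s if m.strand == "+" else seqcore.reverse_complement(s)


# ---------------------------------------------------------------------------
# chaining


def chain_modules(
    modules: list[Module],
    ref_protein: str,
    max_overlap_aa: int = 5,
) -> ModuleChain:
    """Select the module subset that maximizes covered reference residues.

    Dynamic programming over modules sorted by protein start; consecutive
    selected modules may overlap by at most ``max_overlap_aa`` in protein
    coordinates.  Ties go to higher summed score, then to fewer modules.
    Returns the chain in transcript order, junctions not yet refined.
    """
    if not modules:
        raise ChainError("chain_modules: no modules given")
    genes = {m.gene for m in modules}
    if len(genes) > 1:
        raise ChainError(f"chain_modules: modules from several genes {genes}")
    mods = sorted(modules, key=lambda m: (m.prot_start, m.prot_end, -m.score))
    n = len(mods)
    NEG = (-1, 0.0, 0)
    best = []
    parent: list[int | None] = []
    for i, mi in enumerate(mods):
        obj = (mi.aa_len, mi.score, -1)
        par: int | None = None
        for j in range(i):
            mj = mods[j]
            if mj.prot_end > mi.prot_end:
                continue
            if mj.prot_end - mi.prot_start > max_overlap_aa:
                continue
            gain = mi.prot_end - max(mi.prot_start, mj.prot_end)
            cand = (best[j][0] + gain, best[j][1] + mi.score, best[j][2] - 1)
            if cand > obj:
                obj, par = cand, j
        best.append(obj)
        parent.append(par)
    end = max(range(n), key=lambda i: best[i])
    chain_idx = []
    k: int | None = end
    while k is not None:
        chain_idx.append(k)
        k = parent[k]
    chain_idx.reverse()
    selected = [mods[i] for i in chain_idx]
    chain = ModuleChain(gene=mods[0].gene, ref_protein=ref_protein,
                        modules=selected)
    _rebuild_junctions(chain)
    return chain


def _rebuild_junctions(chain: ModuleChain) -> None:
    old = {(j.left_index, j.right_index): j for j in chain.junctions}
    chain.junctions = []
    for i in range(len(chain.modules) - 1):
        left, right = chain.modules[i], chain.modules[i + 1]
        gap = right.prot_start - left.prot_end
        j = old.get((i, i + 1)) or Junction(i, i + 1, gap_aa=max(gap, 0))
        j.gap_aa = max(gap, 0)
        if gap < 0:
            j.status = "pending"
        elif gap == 0:
            j.status = "abut"
        else:
            j.status = "gap"
        j.genomic = _genomic_context(left, right)
        chain.junctions.append(j)


def _genomic_context(left: Module, right: Module) -> str:
    if left.contig_id == right.contig_id and left.strand == right.strand:
        if left.strand == "+" and left.contig_end <= right.contig_start:
            return "cis_possible"
        if left.strand == "-" and right.contig_end <= left.contig_start:
            return "cis_possible"
    return "trans"


# ---------------------------------------------------------------------------
# junction refinement


def _trim_module(m: Module, from_start: int = 0, from_end: int = 0) -> Module:
    """Trim aa off the transcript-sense start/end, keeping bp in sync."""
    new = dataclasses.replace(m)
    new.prot_start += from_start
    new.prot_end -= from_end
    if m.strand == "+":
        new.contig_start += 3 * from_start
        new.contig_end -= 3 * from_end
    else:
        new.contig_end -= 3 * from_start
        new.contig_start += 3 * from_end
    return new


def _extend_module(m: Module, at_start: int = 0, at_end: int = 0) -> Module:
    return _trim_module(m, from_start=-at_start, from_end=-at_end)


def _flank_codons_after(contigs, m: Module, n_codons: int) -> str:
    """Up to ``n_codons`` in-frame codons following the module
    (transcript sense); truncated at the contig edge."""
    seq = contigs[m.contig_id]
    if m.strand == "+":
        return seq[m.contig_end : m.contig_end + 3 * n_codons]
    a = max(0, m.contig_start - 3 * n_codons)
    return seqcore.reverse_complement(seq[a : m.contig_start])


def _flank_codons_before(contigs, m: Module, n_codons: int) -> str:
    seq = contigs[m.contig_id]
    if m.strand == "+":
        a = max(0, m.contig_start - 3 * n_codons)
        return seq[a : m.contig_start]
    return seqcore.reverse_complement(
        seq[m.contig_end : m.contig_end + 3 * n_codons]
    )


def _flank_nt_after(contigs, m: Module, n: int) -> str:
    seq = contigs[m.contig_id]
    if m.strand == "+":
        return seq[m.contig_end : m.contig_end + n]
    a = max(0, m.contig_start - n)
    return seqcore.reverse_complement(seq[a : m.contig_start])


def _flank_nt_before(contigs, m: Module, n: int) -> str:
    seq = contigs[m.contig_id]
    if m.strand == "+":
        a = max(0, m.contig_start - n)
        return seq[a : m.contig_start]
    return seqcore.reverse_complement(seq[m.contig_end : m.contig_end + n])


def refine_junctions(
    chain: ModuleChain,
    contigs: dict[str, str],
    *,
    max_overlap_aa: int = 5,
    extend_max_aa: int = 10,
    u_gap_max_aa: int = 4,
    collapse_short: bool = False,
    collapse_max_aa: int = 20,
    table_id: int = 4,
    matrix_name: str = "BLOSUM62",
) -> ModuleChain:
    """Settle module boundaries: split overlaps, extend through gaps.

    Overlapping pairs are split at the point that maximizes the summed
    substitution score of the two trimmed modules against the reference.
    Gapped pairs are bridged by extending the flanking modules along
    their contigs, but only when the extension reproduces the missing
    reference residues exactly and closes the gap; gaps whose residues
    are all phenylalanine (and small enough) are left untouched as
    poly-U appendage candidates.  With ``collapse_short``, a short module
    whose span is also encoded - possibly weakly - as a continuation of
    its left neighbour is removed and flagged: a short internal module
    can be an artefact of forcing a contiguous tiling.
    """
    matrix = seqcore.load_matrix(matrix_name)
    ref = chain.ref_protein
    chain = ModuleChain(chain.gene, ref, list(chain.modules),
                        [dataclasses.replace(j) for j in chain.junctions],
                        chain.cds, chain.protein, list(chain.notes))
    mods = chain.modules

    # 1) split overlaps
    for i in range(len(mods) - 1):
        left, right = mods[i], mods[i + 1]
        overlap = left.prot_end - right.prot_start
        if overlap <= 0:
            continue
        if overlap > max_overlap_aa:
            raise ChainError(
                f"junction overlap {overlap} aa exceeds max_overlap_aa "
                f"({max_overlap_aa}); re-chain first"
            )
        lt = seqcore.translate(module_cds(contigs, left), 1, table_id)
        rt = seqcore.translate(module_cds(contigs, right), 1, table_id)
        lo, hi = right.prot_start, left.prot_end
        best_b, best_score = hi, None
        for b in range(lo, hi + 1):
            s = 0.0
            for p in range(lo, b):
                s += float(matrix[lt[p - left.prot_start], ref[p]])
            for p in range(b, hi):
                s += float(matrix[rt[p - right.prot_start], ref[p]])
            if best_score is None or s > best_score:
                best_score, best_b = s, b
        mods[i] = _trim_module(left, from_end=hi - best_b)
        mods[i + 1] = _trim_module(right, from_start=best_b - lo)
    _rebuild_junctions(chain)

    # 2) optional collapse of short modules encodable as an extension of
    #    the left neighbour (the "possible short module" scenario)
    if collapse_short:
        changed = True
        while changed:
            changed = False
            for i in range(1, len(mods)):
                m = mods[i]
                left = mods[i - 1]
                span = m.prot_end - left.prot_end
                if m.aa_len > collapse_max_aa or span <= 0 or span > \
                        collapse_max_aa + extend_max_aa:
                    continue
                ext = _flank_codons_after(contigs, left, span)
                if len(ext) < 3 * span:
                    continue
                trans = seqcore.translate(ext, 1, table_id)
                if "*" in trans:
                    continue
                score = sum(
                    float(matrix[a, b])
                    for a, b in zip(trans, ref[left.prot_end : m.prot_end])
                )
                if score <= 0:
                    continue
                mods[i - 1] = _extend_module(left, at_end=span)
                del mods[i]
                chain.notes.append(
                    f"module {i} ({m.prot_start}-{m.prot_end} aa) removed: "
                    f"span encodable as extension of its left neighbour "
                    f"(score {score:.1f})"
                )
                changed = True
                break
        _rebuild_junctions(chain)

    # 3) exact-match extension through residual gaps
    for i in range(len(mods) - 1):
        left, right = mods[i], mods[i + 1]
        gap = right.prot_start - left.prot_end
        if gap <= 0:
            continue
        gap_res = ref[left.prot_end : right.prot_start]
        if gap <= u_gap_max_aa and set(gap_res) == {"F"}:
            continue  # poly-U appendage candidate; leave for inference
        if gap > 2 * extend_max_aa:
            continue
        lext = _flank_codons_after(contigs, left, min(gap, extend_max_aa))
        lt = seqcore.translate(lext, 1, table_id) if len(lext) >= 3 else ""
        n_l = 0
        while n_l < len(lt) and lt[n_l] == gap_res[n_l]:
            n_l += 1
        rem = gap - n_l
        n_r = 0
        if rem > 0:
            rext = _flank_codons_before(contigs, right,
                                        min(rem, extend_max_aa))
            rt = seqcore.translate(rext, 1, table_id) if len(rext) >= 3 else ""
            while (n_r < len(rt) and n_r < rem
                   and rt[len(rt) - 1 - n_r] == gap_res[gap - 1 - n_r]):
                n_r += 1
        if n_l + n_r >= gap:
            # close the junction (avoid double-counting if both close it)
            n_r = gap - n_l
            mods[i] = _extend_module(left, at_end=n_l)
            mods[i + 1] = _extend_module(right, at_start=n_r)
            chain.notes.append(
                f"gap of {gap} aa at junction {i}/{i + 1} closed by "
                f"genomic extension ({n_l}+{n_r} aa)"
            )
    _rebuild_junctions(chain)
    return chain


# ---------------------------------------------------------------------------
# scrambling / trans-splicing


def scramble_report(chain: ModuleChain) -> ScrambleReport:
    """Compare transcript order with genomic order.

    Trans-splicing is required when the gene spans several contigs, when
    the genomic order is a non-identity permutation of transcript order,
    or when modules sit on both strands.
    """
    mods = chain.modules
    genomic = sorted(range(len(mods)),
                     key=lambda i: (mods[i].contig_id, mods[i].contig_start))
    permutation = list(genomic)
    contigs_used = {m.contig_id for m in mods}
    strand_mix = len({m.strand for m in mods}) > 1
    permuted = permutation != sorted(permutation)
    pos = {t: g for g, t in enumerate(permutation)}
    n_break = 0
    for i in range(len(mods) - 1):
        same_contig = mods[i].contig_id == mods[i + 1].contig_id
        if not (same_contig and pos[i + 1] == pos[i] + 1):
            n_break += 1
    rationale = []
    if len(contigs_used) > 1:
        rationale.append("multi_contig")
    if permuted:
        rationale.append("permuted_order")
    if strand_mix:
        rationale.append("strand_mix")
    return ScrambleReport(
        gene=chain.gene,
        n_modules=len(mods),
        n_contigs=len(contigs_used),
        permutation=permutation,
        n_breakpoints=n_break,
        strand_mix=strand_mix,
        permuted_order=permuted,
        trans_splicing_required=bool(rationale),
        rationale=rationale,
    )


# ---------------------------------------------------------------------------
# uracil appendage inference


def infer_u_appendage(
    chain: ModuleChain,
    contigs: dict[str, str],
    k_max: int = 12,
    u_gap_max_aa: int = 4,
    table_id: int = 4,
) -> ModuleChain:
    """Decode residual junction gaps as poly-U appendages.

    For each junction with a residual reference gap of at most
    ``u_gap_max_aa`` residues, reports the minimal number k <= ``k_max``
    of inserted U's (with up to two leftover genomic nucleotides per
    flank) that restores the reading frame and the reference residues
    exactly.  Junctions that abut get k = 0; gaps with no U-only solution
    are annotated unresolved; larger gaps are reported as missing
    modules.
    """
    for j in chain.junctions:
        left, right = chain.modules[j.left_index], chain.modules[j.right_index]
        if j.gap_aa == 0:
            j.k_u, j.status = 0, "abut"
            continue
        if j.gap_aa > u_gap_max_aa:
            j.status = "missing_modules"
            continue
        gap_res = chain.ref_protein[left.prot_end : right.prot_start]
        fill = solve_junction_fill(
            _flank_nt_after(contigs, left, 2),
            _flank_nt_before(contigs, right, 2),
            gap_res, table_id=table_id, k_max=k_max,
        )
        if fill is None:
            j.status = "unresolved"
        else:
            j.k_u = fill.k
            j.ext_left, j.ext_right = fill.ext_left, fill.ext_right
            j.status = "u_appendage" if fill.k > 0 else "flank_fill"
    return chain


def assemble_chain_seqs(
    chain: ModuleChain, contigs: dict[str, str], table_id: int = 4
) -> ModuleChain:
    """Concatenate module CDSs and junction fills into the mature CDS and
    its translation."""
    parts = []
    for i, m in enumerate(chain.modules):
        if i > 0:
            j = chain.junctions[i - 1]
            if j.status in {"u_appendage", "flank_fill"}:
                parts.append(_flank_nt_after(contigs, chain.modules[i - 1],
                                             j.ext_left)[: j.ext_left])
                parts.append("T" * (j.k_u or 0))
                if j.ext_right:
                    parts.append(_flank_nt_before(contigs, m, j.ext_right))
        parts.append(module_cds(contigs, m))
    chain.cds = "".join(parts)
    chain.protein = seqcore.translate(chain.cds, 1, table_id)
    return chain


# ---------------------------------------------------------------------------
# substitution editing check


@dataclass
class EditingReport:
    gene: str
    internal_stops: list[int]  # aa positions in the assembled protein
    identity_to_ref: float
    verdict: str  # "none required" | "candidate editing sites"


def check_substitution_editing(
    chain: ModuleChain, table_id: int = 4
) -> EditingReport:
    """Would substitution editing be needed to make the mRNA translatable?

    Verdict is "none required" iff the assembled CDS has no internal stop
    under the configured code; otherwise the stop positions are candidate
    editing or code-reassignment sites.
    """
    if not chain.cds:
        raise ChainError("assemble the chain CDS first")
    prot = seqcore.translate(chain.cds, 1, table_id)
    stops = [i for i, aa in enumerate(prot[:-1]) if aa == "*"]
    matched = 0
    total = 0
    pos = 0
    for i, m in enumerate(chain.modules):
        if i > 0:
            j = chain.junctions[i - 1]
            if j.status in {"u_appendage", "flank_fill"}:
                pos += j.gap_aa
        for p in range(m.prot_start, m.prot_end):
            if pos < len(prot):
                total += 1
                if prot[pos] == chain.ref_protein[p]:
                    matched += 1
            pos += 1
    return EditingReport(
        gene=chain.gene,
        internal_stops=stops,
        identity_to_ref=matched / total if total else 0.0,
        verdict="none required" if not stops else "candidate editing sites",
    )


# ---------------------------------------------------------------------------
# text diagram (module maps in contig coordinates)


def render_module_diagram(chain: ModuleChain, contigs: dict[str, str],
                          width: int = 72) -> str:
    """Per-gene text diagram: modules drawn along each contig with their
    transcript indices, mimicking a gene-architecture figure."""
    lines = [f"gene {chain.gene}: {len(chain.modules)} modules"]
    by_contig: dict[str, list[tuple[int, Module]]] = {}
    for t, m in enumerate(chain.modules):
        by_contig.setdefault(m.contig_id, []).append((t, m))
    for cid in sorted(by_contig):
        L = len(contigs[cid])
        scale = (width - 1) / max(L, 1)
        row = ["-"] * width
        labels = []
        for t, m in sorted(by_contig[cid], key=lambda x: x[1].contig_start):
            a = int(m.contig_start * scale)
            b = max(a + 1, int(m.contig_end * scale))
            for x in range(a, min(b, width)):
                row[x] = "="
            mid = min((a + b) // 2, width - 1)
            row[mid] = str((t + 1) % 10)
            labels.append(
                f"m{t + 1}({m.strand}) {m.contig_start}-{m.contig_end}"
            )
        lines.append(f"  {cid} ({L} bp)")
        lines.append("  " + "".join(row))
        lines.append("  " + "; ".join(labels))
    return "\n".join(lines)
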