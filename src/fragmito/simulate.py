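"""Synthetic single-cell assemblies with a planted fragmented mitochondrial genome.

The generator emulates the statistical structure a single-cell amplified
genome (SAG) of a deep-branching euglenozoan presents to the analysis:

* a nuclear background (GC ~ 0.457, heavy-tailed log-normal coverage,
  mean 41.6x / sd 62.6x, optional GT-AG introns in planted genes);
* a small mitochondrial bin (GC ~ 0.361, ~5x higher coverage, CpG-depleted
  composition so tetranucleotide binning is non-trivial);
* protein-coding genes shattered into modules of at most ~135 aa,
  scattered - and, when ``scramble`` is on, reordered and strand-mixed -
  across contigs;
* ~100 bp "cassette" regions, similar but never identical between copies,
  within 50 bp of mitochondrial contig ends;
* optional junctions that require a poly-U appendage to restore the
  reading frame.

Everything is emitted together with a :class:`TruthManifest` so that
downstream recovery can be scored exactly.  All randomness flows from a
single seeded generator: a fixed config yields byte-identical output.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from . import io as fio
from . import seqcore
from .junctions import solve_junction_fill

__all__ = [
    "SimConfig",
    "SimConfigError",
    "GenePlan",
    "TruthManifest",
    "fragment_gene",
    "plant_u_appendage",
    "simulate_assembly",
    "U1_QUERY",
    "U1_RECOGNITION",
    "DONOR_CONSENSUS",
]

BASES = np.array(list("ACGT"))

#: 5' splice-donor consensus used when planting canonical introns.
DONOR_CONSENSUS = "GTAAGT"
#: The U1 snRNA active-site region pairs antiparallel with the 9-nt donor
#: window (-3..+6); this string is its perfect pairing partner for the
#: consensus ``CAG|GTAAGT``.
U1_RECOGNITION = "ACTTACCTG"
#: Synthetic U1 small nuclear RNA query (DNA sense).  The recognition
#: region sits at positions [2:11]; the remainder is an arbitrary fixed
#: stem-loop-like tail so that homology search has something to find.
U1_QUERY = (
    "AT" + U1_RECOGNITION + "GCAGGGGAGATACCATGATCACGAAGGTGGTTTTCCCAGGGCGAGGC"
    "TTATCCATTGCACTCCGGATGTGCTGACCCCTGCGATTTCCCCAAATGTGGGAAACTCGACTGCATAAT"
)


class SimConfigError(ValueError):
    """A simulation-config invariant was violated; names the field."""


@dataclass
class SimConfig:
    """Simulation parameters.

    Defaults are the study conditions the analysis is meant to operate
    under: nuclear GC 0.457 vs mitochondrial 0.361, assembly-wide coverage
    41.6x (sd 62.6x, log-normal) vs mitochondrial 196x, three
    mitochondrial genes in five modules each capped at 135 aa, 100-bp
    cassettes diverged at 5% per copy, eight module-bearing plus sixteen
    cassette-only mitochondrial contigs.
    """

    seed: int = 1
    # nuclear bin
    n_nuclear_contigs: int = 176
    nuclear_len_range: tuple[int, int] = (800, 3000)
    nuclear_gc: float = 0.457
    nuclear_cov_mean: float = 41.6
    nuclear_cov_sd: float = 62.6
    # mitochondrial bin
    mito_gc: float = 0.361
    mito_cov_mean: float = 196.0
    mito_cov_sd: float = 49.0
    n_mito_contigs: int = 8
    n_cassette_only: int = 16
    mito_cpg_factor: float = 0.5
    # gene fragmentation
    ref_proteins: list[tuple[str, str]] | None = None
    modules_per_gene: tuple[int, int] = (5, 5)
    max_module_aa: int = 135
    min_module_aa: int = 25
    scramble: bool = True
    minus_strand_prob: float = 0.5
    spacer_range: tuple[int, int] = (60, 240)
    # cassettes
    cassette_len: int = 100
    cassette_divergence: float = 0.05
    # editing
    u_appendage_sites: list[tuple[str, int, int]] = field(default_factory=list)
    # nuclear genes / introns / U1
    n_nuclear_genes: int = 3
    intron_rate: float = 2.0
    intron_len_range: tuple[int, int] = (60, 300)
    include_u1: bool = True
    # noise
    noise_sub_rate: float = 0.0
    # genetic codes
    mito_table_id: int = 4
    nuclear_table_id: int = 1

    def validate(self) -> None:
        for name in ("nuclear_gc", "mito_gc", "cassette_divergence", "noise_sub_rate",
                     "minus_strand_prob", "mito_cpg_factor"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimConfigError(f"{name} must be in [0,1], got {v}")
        for name in ("n_nuclear_contigs", "n_mito_contigs", "n_cassette_only",
                     "n_nuclear_genes"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be non-negative")
        for name in ("cassette_len", "max_module_aa", "min_module_aa"):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be positive")
        for name in ("nuclear_len_range", "modules_per_gene", "spacer_range",
                     "intron_len_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise SimConfigError(f"{name} must be a positive (lo, hi) interval")
        if self.modules_per_gene[1] > 12:
            raise SimConfigError("modules_per_gene upper bound must be <= 12")
        for name in ("nuclear_cov_mean", "nuclear_cov_sd", "mito_cov_mean",
                     "mito_cov_sd", "intron_rate"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be non-negative")
        if self.min_module_aa > self.max_module_aa:
            raise SimConfigError("min_module_aa exceeds max_module_aa")


# ---------------------------------------------------------------------------
# gene fragmentation plans


@dataclass
class PlannedModule:
    transcript_index: int  # 0-based position along the mature mRNA
    prot_start: int
    prot_end: int


@dataclass
class GenePlan:
    """Fragmentation of one reference protein into an ordered module plan."""

    protein: str
    modules: list[PlannedModule]  # transcript order
    placement_order: list[int]  # transcript indices in genomic placement order
    edits: dict[int, int] = field(default_factory=dict)  # junction index -> k
    forced_codons: dict[int, str] = field(default_factory=dict)  # residue -> codon

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    @property
    def permutation(self) -> list[int]:
        return list(self.placement_order)


def _partition_lengths(
    total: int, n: int, min_len: int, max_len: int, rng: np.random.Generator
) -> list[int]:
    if n * min_len > total or n * max_len < total:
        raise SimConfigError(
            f"cannot split {total} aa into {n} modules of {min_len}-{max_len} aa"
        )
    lengths = []
    remaining = total
    for i in range(n):
        left = n - i - 1
        lo = max(min_len, remaining - left * max_len)
        hi = min(max_len, remaining - left * min_len)
        L = int(rng.integers(lo, hi + 1)) if i < n - 1 else remaining
        lengths.append(L)
        remaining -= L
    return lengths


def fragment_gene(
    ref_protein: str,
    n_modules: int,
    max_module_aa: int | None = None,
    scramble: bool = False,
    seed: int = 0,
    min_module_aa: int = 1,
) -> GenePlan:
    """Partition a protein into <= ``max_module_aa`` modules and pick a
    genomic placement order.

    The protein intervals tile ``[0, len)`` without overlap.  With
    ``scramble`` the placement order is a non-identity permutation of
    transcript order whenever there are at least two modules.
    """
    L = len(ref_protein)
    if n_modules < 1:
        raise SimConfigError("n_modules must be >= 1")
    if n_modules > L:
        raise SimConfigError(
            f"protein of {L} aa is too short for {n_modules} modules"
        )
    rng = np.random.default_rng(seed)
    cap = max_module_aa if max_module_aa is not None else L
    lengths = _partition_lengths(L, n_modules, min_module_aa, cap, rng)
    modules, pos = [], 0
    for i, ln in enumerate(lengths):
        modules.append(PlannedModule(i, pos, pos + ln))
        pos += ln
    order = list(range(n_modules))
    if scramble and n_modules >= 2:
        while order == list(range(n_modules)):
            order = list(rng.permutation(n_modules))
        order = [int(x) for x in order]
    return GenePlan(protein=ref_protein, modules=modules, placement_order=order)


def _u_split(k: int) -> tuple[int, int]:
    """How many of the k omitted T's come off the left / right module.

    Multiples of three are split as whole codons, as evenly as possible;
    other k are taken entirely from the left module's tail (a partial
    codon stays behind on the contig).
    """
    if k % 3 == 0:
        a = 3 * ((k // 3 + 1) // 2)
        return a, k - a
    return k, 0


def u_junction_residue_span(k: int) -> tuple[int, int]:
    """(left, right) count of reference residues consumed by a k-U junction."""
    a, b = _u_split(k)
    return math.ceil(a / 3), b // 3


def plant_u_appendage(plan: GenePlan, junction_index: int, k: int) -> GenePlan:
    """Mark a junction of a gene plan as requiring a k-U appendage.

    The reference residues consumed by the omitted nucleotides must be
    encodable entirely by U's in mRNA sense, i.e. they must be
    phenylalanines (UUU); otherwise the junction is rejected.
    """
    if k < 1:
        raise SimConfigError(f"u appendage k must be >= 1, got {k}")
    if not (1 <= junction_index < plan.n_modules):
        raise SimConfigError(
            f"junction index must be in [1, {plan.n_modules}), got {junction_index}"
        )
    n_left, n_right = u_junction_residue_span(k)
    p = plan.modules[junction_index].prot_start
    left_mod = plan.modules[junction_index - 1]
    right_mod = plan.modules[junction_index]
    if n_left > left_mod.prot_end - left_mod.prot_start or \
            n_right > right_mod.prot_end - right_mod.prot_start:
        raise SimConfigError("u appendage consumes an entire flanking module")
    span = plan.protein[p - n_left : p + n_right]
    if any(aa != "F" for aa in span):
        raise SimConfigError(
            f"junction {junction_index} residues {span!r} cannot be written with "
            "U-only codons (UUU=F); choose a junction flanked by phenylalanines"
        )
    new_edits = dict(plan.edits)
    new_edits[junction_index] = k
    forced = dict(plan.forced_codons)
    for r in range(p - n_left, p + n_right):
        forced[r] = "TTT"
    return dataclasses.replace(plan, edits=new_edits, forced_codons=forced)


# ---------------------------------------------------------------------------
# sequence generation helpers


def _iid_background(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _cpg_gc_drop(gc: float, factor: float) -> float:
    """Expected GC loss from CpG depletion, used to pre-compensate."""
    cpg = (gc / 2) ** 2
    replaced = cpg * (1 - factor)
    p_c_given_not_g = (gc / 2) / (1 - gc / 2)
    return replaced * (1 - p_c_given_not_g)


def random_background(
    n: int, gc: float, rng: np.random.Generator, cpg_factor: float = 1.0
) -> str:
    """Order-0 background with target GC; optional CpG depletion.

    With ``cpg_factor`` < 1, the G of a fraction (1 - factor) of CpG
    dinucleotides is resampled from {A, C, T}; the base GC is raised
    beforehand so the realized GC still matches the target.
    """
    if n <= 0:
        return ""
    gc_base = gc + (_cpg_gc_drop(gc, cpg_factor) if cpg_factor < 1.0 else 0.0)
    codes = _iid_background(n, gc_base, rng)
    if cpg_factor < 1.0 and n > 1:
        is_cpg = np.where((codes[:-1] == 1) & (codes[1:] == 2))[0] + 1
        hit = is_cpg[rng.random(is_cpg.size) < (1 - cpg_factor)]
        if hit.size:
            q = np.array([(1 - gc_base) / 2, gc_base / 2, 0.0, (1 - gc_base) / 2])
            q = q / q.sum()
            codes[hit] = rng.choice(4, size=hit.size, p=q)
    return "".join(BASES[codes])


def _synonymous_codons(table_id: int) -> dict[str, list[str]]:
    code = seqcore.get_code(table_id)
    syn: dict[str, list[str]] = {}
    for codon, aa in code.codons.items():
        if aa != "*":
            syn.setdefault(aa, []).append(codon)
    for aa in syn:
        syn[aa].sort()
    return syn


def reverse_translate(
    protein: str,
    table_id: int,
    gc: float,
    rng: np.random.Generator,
    forced_codons: dict[int, str] | None = None,
    offset: int = 0,
) -> str:
    """Choose synonymous codons, tilting the choice toward a target GC.

    ``forced_codons`` maps absolute residue indices (``offset`` + local
    index) to fixed codons (used to guarantee U-appendage junctions are
    written as TTT).
    """
    syn = _synonymous_codons(table_id)
    forced_codons = forced_codons or {}
    p = _solve_codon_tilt(protein, syn, gc)
    out = []
    for i, aa in enumerate(protein):
        if (offset + i) in forced_codons:
            out.append(forced_codons[offset + i])
            continue
        codons = syn[aa]
        w = np.array([p ** _gc3(c) * (1 - p) ** (3 - _gc3(c)) for c in codons])
        out.append(codons[rng.choice(len(codons), p=w / w.sum())])
    return "".join(out)


def _gc3(codon: str) -> int:
    return sum(b in "GC" for b in codon)


def _solve_codon_tilt(protein: str, syn: dict[str, list[str]],
                      target_gc: float) -> float:
    """Tilt parameter p such that the expected GC of the chosen codons
    matches the target (bisection; clamped when the protein's amino-acid
    composition cannot reach the target)."""

    def expected_gc(p: float) -> float:
        tot = 0.0
        for aa in protein:
            codons = syn[aa]
            w = [p ** _gc3(c) * (1 - p) ** (3 - _gc3(c)) for c in codons]
            s = sum(w)
            tot += sum(wi * _gc3(c) for wi, c in zip(w, codons)) / s
        return tot / (3 * len(protein))

    lo, hi = 0.01, 0.99
    if expected_gc(lo) >= target_gc:
        return lo
    if expected_gc(hi) <= target_gc:
        return hi
    for _ in range(30):
        mid = (lo + hi) / 2
        if expected_gc(mid) < target_gc:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def random_protein(n: int, rng: np.random.Generator) -> str:
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    return "".join(aas[rng.integers(0, 20, size=n)])


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.where(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _diverge_cassette(master: str, rate: float, rng: np.random.Generator,
                      seen: set[str]) -> str:
    """A copy of the cassette, similar but never identical to the master
    or to any previously emitted copy."""
    for _ in range(100):
        n_sub = max(1, rng.binomial(len(master), rate))
        positions = rng.choice(len(master), size=n_sub, replace=False)
        arr = list(master)
        for p in positions:
            choices = [b for b in "ACGT" if b != arr[p]]
            arr[p] = choices[rng.integers(0, 3)]
        copy = "".join(arr)
        if copy != master and copy not in seen:
            seen.add(copy)
            return copy
    raise RuntimeError("could not produce a diverged cassette copy")


# ---------------------------------------------------------------------------
# truth manifest


@dataclass
class PlantedModuleRecord:
    gene: str
    module_index: int  # transcript order, 0-based
    contig: str
    strand: str
    contig_start: int
    contig_end: int
    prot_start: int
    prot_end: int


@dataclass
class JunctionEditRecord:
    gene: str
    junction_index: int
    k: int
    gap_residues: str  # reference residues restored by the U appendage


@dataclass
class PlantedIntronRecord:
    contig: str
    gene: str
    start: int
    end: int
    donor_pos: int
    acceptor_pos: int


@dataclass
class TruthManifest:
    """Ground truth for one simulated assembly (all coordinates 0-based
    half-open on the forward strand)."""

    seed: int
    bins: dict[str, str]
    modules: list[PlantedModuleRecord]
    junction_edits: list[JunctionEditRecord]
    introns: list[PlantedIntronRecord]
    cassettes: list[tuple[str, int, int]]
    mito_refs: dict[str, str]
    nuclear_refs: dict[str, str]
    permutations: dict[str, list[int]]
    u1_locus: tuple[str, int, int, str] | None
    u1_seq: str | None

    def to_json(self, path) -> None:
        fio.write_report(dataclasses.asdict(self), path)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        d = fio.read_report(path)
        d["modules"] = [PlantedModuleRecord(**m) for m in d["modules"]]
        d["junction_edits"] = [JunctionEditRecord(**j) for j in d["junction_edits"]]
        d["introns"] = [PlantedIntronRecord(**i) for i in d["introns"]]
        d["cassettes"] = [tuple(c) for c in d["cassettes"]]
        if d.get("u1_locus"):
            d["u1_locus"] = tuple(d["u1_locus"])
        return cls(**d)


# ---------------------------------------------------------------------------
# assembly construction


_DEFAULT_GENES = (("cox1", 510), ("nad5", 450), ("cob", 380))
_DEFAULT_NUCLEAR_GENES = (("atg2", 420), ("h4", 360), ("d2hgdh", 400))


@dataclass
class _EmittedModule:
    gene: str
    transcript_index: int
    dna: str  # transcript-sense DNA actually emitted (after U omissions)
    prot_start: int  # findable (complete-codon) protein interval
    prot_end: int
    left_clean: str | None  # ref residue that must NOT continue leftward
    right_clean: str | None


def _emit_gene_modules(
    gene: str,
    plan: GenePlan,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[_EmittedModule], list[JunctionEditRecord]]:
    cds = reverse_translate(
        plan.protein, cfg.mito_table_id, cfg.mito_gc, rng,
        forced_codons=plan.forced_codons,
    )
    emitted, edits = [], []
    for m in plan.modules:
        dna = cds[3 * m.prot_start : 3 * m.prot_end]
        ps, pe = m.prot_start, m.prot_end
        j_right = m.transcript_index + 1  # junction after this module
        if j_right in plan.edits:
            a, _ = _u_split(plan.edits[j_right])
            dna = dna[: len(dna) - a]
            pe -= math.ceil(a / 3)
        j_left = m.transcript_index  # junction before this module
        if j_left in plan.edits:
            _, b = _u_split(plan.edits[j_left])
            dna = dna[b:]
            ps += b // 3
        emitted.append(
            _EmittedModule(
                gene=gene,
                transcript_index=m.transcript_index,
                dna=_mutate(dna, cfg.noise_sub_rate, rng),
                prot_start=ps,
                prot_end=pe,
                left_clean=plan.protein[ps - 1] if ps > 0 else None,
                right_clean=plan.protein[pe] if pe < len(plan.protein) else None,
            )
        )
    for j, k in sorted(plan.edits.items()):
        n_left, n_right = u_junction_residue_span(k)
        p = plan.modules[j].prot_start
        edits.append(
            JunctionEditRecord(
                gene=gene,
                junction_index=j,
                k=k,
                gap_residues=plan.protein[p - n_left : p + n_right],
            )
        )
    return emitted, edits


def _interleave(per_gene: dict[str, list[_EmittedModule]],
                rng: np.random.Generator) -> list[_EmittedModule]:
    """Random merge preserving each gene's internal (permuted) order."""
    keys = sorted(per_gene)
    queues = {g: list(per_gene[g]) for g in keys}
    out = []
    while any(queues.values()):
        weights = np.array([len(queues[g]) for g in keys], dtype=float)
        g = keys[rng.choice(len(keys), p=weights / weights.sum())]
        out.append(queues[g].pop(0))
    return out


def _resample_window(
    contig: list[str], start: int, n: int, gc: float, rng: np.random.Generator
) -> None:
    seg = random_background(n, gc, rng)
    for i, b in enumerate(seg):
        contig[start + i] = b


def _clean_module_flanks(
    contig: list[str], start: int, end: int, strand: str,
    em: _EmittedModule, cfg: SimConfig, rng: np.random.Generator,
) -> None:
    """Make module boundaries locally unambiguous.

    The background codon adjacent to a planted module (in the module's own
    frame and orientation) is resampled until it does not translate to the
    next reference residue, so that a homology search cannot extend a
    module by chance and recovery of the exact planted interval is a
    well-posed problem.
    """
    tid = cfg.mito_table_id

    def fix(pos: int, revcomp: bool, residue: str | None) -> None:
        if residue is None or pos < 0 or pos + 3 > len(contig):
            return
        for _ in range(50):
            codon = "".join(contig[pos : pos + 3])
            aa = seqcore.translate(
                seqcore.reverse_complement(codon) if revcomp else codon, 1, tid
            )
            if aa != residue:
                return
            _resample_window(contig, pos, 3, cfg.mito_gc, rng)

    if strand == "+":
        fix(end, False, em.right_clean)
        fix(start - 3, False, em.left_clean)
    else:
        fix(start - 3, True, em.right_clean)
        fix(end, True, em.left_clean)


def _ensure_junction_decodable(
    contig_seqs: dict[str, list[str]],
    records: list[PlantedModuleRecord],
    edits: list[JunctionEditRecord],
    manifest_refs: dict[str, str],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> None:
    """Resample background next to edited junctions until the planted k is
    the unique minimal solution of the junction fill equation."""
    by_key = {(r.gene, r.module_index): r for r in records}
    for e in edits:
        left = by_key[(e.gene, e.junction_index - 1)]
        right = by_key[(e.gene, e.junction_index)]
        for attempt in range(100):
            lf = _flank_after(contig_seqs, left)
            rf = _flank_before(contig_seqs, right)
            fill = solve_junction_fill(lf, rf, e.gap_residues, cfg.mito_table_id)
            # the flanking in-frame codons must also not extend the modules
            # into the gap by chance (keeps module boundaries unambiguous)
            next_l = seqcore.translate(_flank_after(contig_seqs, left, 3), 1,
                                       cfg.mito_table_id)
            prev_r = seqcore.translate(_flank_before(contig_seqs, right, 3)[-3:],
                                       1, cfg.mito_table_id)
            if (fill is not None and fill.k == e.k
                    and next_l != e.gap_residues[0]
                    and prev_r != e.gap_residues[-1]):
                break
            _resample_flanks(contig_seqs, left, right, cfg, rng)
        else:
            raise RuntimeError(
                f"could not make junction {e.gene}:{e.junction_index} decodable"
            )


def _flank_after(contig_seqs, rec: PlantedModuleRecord, n: int = 2) -> str:
    """Transcript-sense nucleotides following the module's complete-codon
    (findable) interval; includes any partial-codon leftovers."""
    seq = contig_seqs[rec.contig]
    aligned = 3 * (rec.prot_end - rec.prot_start)
    if rec.strand == "+":
        a = rec.contig_start + aligned
        return "".join(seq[a : a + n])
    a = rec.contig_end - aligned
    return seqcore.reverse_complement("".join(seq[max(0, a - n) : a]))


def _flank_before(contig_seqs, rec: PlantedModuleRecord, n: int = 2) -> str:
    seq = contig_seqs[rec.contig]
    if rec.strand == "+":
        return "".join(seq[max(0, rec.contig_start - n) : rec.contig_start])
    return seqcore.reverse_complement(
        "".join(seq[rec.contig_end : rec.contig_end + n])
    )


def _resample_flanks(contig_seqs, left: PlantedModuleRecord,
                     right: PlantedModuleRecord, cfg: SimConfig,
                     rng: np.random.Generator) -> None:
    for rec in (left, right):
        seq = contig_seqs[rec.contig]
        if rec.strand == "+":
            a = rec.contig_end if rec is left else max(0, rec.contig_start - 3)
        else:
            a = max(0, rec.contig_start - 3) if rec is left else rec.contig_end
        n = min(3, len(seq) - a)
        if n > 0:
            _resample_window(seq, a, n, cfg.mito_gc, rng)


def _lognormal_cov(mean: float, sd: float, n: int, rng: np.random.Generator
                   ) -> np.ndarray:
    if mean <= 0:
        return np.zeros(n)
    sigma2 = math.log(1 + (sd / mean) ** 2) if sd > 0 else 0.0
    mu = math.log(mean) - sigma2 / 2
    return rng.lognormal(mu, math.sqrt(sigma2), size=n)


def simulate_assembly(
    config: SimConfig,
) -> tuple[dict[str, str], dict[str, float], TruthManifest]:
    """Generate contigs, a per-contig coverage table and the ground truth.

    Deterministic for a fixed config.  See the module docstring for what
    is emulated.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # --- reference proteins and fragmentation plans
    if cfg.ref_proteins is not None:
        refs = [(g, p.upper()) for g, p in cfg.ref_proteins]
    else:
        refs = [(g, random_protein(n, rng)) for g, n in _DEFAULT_GENES]
    if cfg.u_appendage_sites and not refs:
        raise SimConfigError("u_appendage_sites requested but no ref_proteins")
    mito_refs = dict(refs)

    u_sites_by_gene: dict[str, list[tuple[int, int]]] = {}
    for gene, j, k in cfg.u_appendage_sites:
        if gene not in mito_refs:
            raise SimConfigError(f"u_appendage_sites names unknown gene {gene!r}")
        u_sites_by_gene.setdefault(gene, []).append((j, k))

    plans: dict[str, GenePlan] = {}
    for gene, protein in refs:
        n_mod = int(rng.integers(cfg.modules_per_gene[0], cfg.modules_per_gene[1] + 1))
        n_mod = min(n_mod, max(1, len(protein) // cfg.min_module_aa))
        n_mod = max(n_mod, math.ceil(len(protein) / cfg.max_module_aa))
        plan = fragment_gene(
            protein, n_mod, cfg.max_module_aa, cfg.scramble,
            seed=int(rng.integers(0, 2**31)), min_module_aa=cfg.min_module_aa,
        )
        for j, k in u_sites_by_gene.get(gene, []):
            if not (1 <= j < plan.n_modules):
                raise SimConfigError(
                    f"u appendage junction {j} out of range for {gene} "
                    f"({plan.n_modules} modules)"
                )
            # The generator owns the reference: write phenylalanines at the
            # junction so a U-only fill is constructible, then re-plan.
            n_left, n_right = u_junction_residue_span(k)
            p = plan.modules[j].prot_start
            prot = list(plan.protein)
            for r in range(p - n_left, p + n_right):
                prot[r] = "F"
            plan = dataclasses.replace(plan, protein="".join(prot))
            plan = plant_u_appendage(plan, j, k)
        mito_refs[gene] = plan.protein
        plans[gene] = plan

    # --- emit module DNA
    per_gene_emitted: dict[str, list[_EmittedModule]] = {}
    all_edits: list[JunctionEditRecord] = []
    for gene in sorted(plans):
        emitted, edits = _emit_gene_modules(gene, plans[gene], cfg, rng)
        # genomic placement order
        order = plans[gene].placement_order
        per_gene_emitted[gene] = [emitted[i] for i in order]
        all_edits.extend(edits)

    if cfg.scramble:
        placement = _interleave(per_gene_emitted, rng)
        strands = [
            "-" if rng.random() < cfg.minus_strand_prob else "+" for _ in placement
        ]
    else:
        placement = [m for g in sorted(per_gene_emitted) for m in per_gene_emitted[g]]
        strands = ["+"] * len(placement)

    n_modules_total = len(placement)
    n_coding = (
        min(cfg.n_mito_contigs, n_modules_total)
        if cfg.scramble
        else len([g for g in per_gene_emitted if per_gene_emitted[g]])
    )

    # quotas per coding contig (>= 1 module each)
    if cfg.scramble and n_coding > 0:
        quotas = np.ones(n_coding, dtype=int)
        extra = n_modules_total - n_coding
        if extra > 0:
            quotas += rng.multinomial(extra, np.ones(n_coding) / n_coding)
    elif not cfg.scramble:
        quotas = np.array(
            [len(per_gene_emitted[g]) for g in sorted(per_gene_emitted)
             if per_gene_emitted[g]],
            dtype=int,
        )
    else:
        quotas = np.array([], dtype=int)

    # --- build mitochondrial contigs
    contigs: dict[str, list[str]] = {}
    bins: dict[str, str] = {}
    module_records: list[PlantedModuleRecord] = []
    cassette_records: list[tuple[str, int, int]] = []
    master_cassette = random_background(cfg.cassette_len, cfg.mito_gc, rng,
                                        cfg.mito_cpg_factor)
    seen_cassettes: set[str] = set()

    def bg(n: int) -> str:
        return random_background(n, cfg.mito_gc, rng, cfg.mito_cpg_factor)

    idx = 0
    total_mito = n_coding + cfg.n_cassette_only
    width = max(2, len(str(total_mito)))
    mito_bodies: list[tuple[str, list[tuple[str, _EmittedModule | None, str]]]] = []
    for ci in range(n_coding):
        cid = f"mito_{ci + 1:0{width}d}"
        parts: list[tuple[str, _EmittedModule | None, str]] = []
        parts.append(("pad", None, bg(int(rng.integers(5, 46)))))
        parts.append(("cassette", None,
                      _diverge_cassette(master_cassette, cfg.cassette_divergence,
                                        rng, seen_cassettes)))
        parts.append(("spacer", None, bg(int(rng.integers(*cfg.spacer_range)))))
        for _ in range(quotas[ci]):
            em = placement[idx]
            strand = strands[idx]
            dna = em.dna if strand == "+" else seqcore.reverse_complement(em.dna)
            parts.append(("module" + strand, em, dna))
            parts.append(("spacer", None, bg(int(rng.integers(*cfg.spacer_range)))))
            idx += 1
        # keep cassettes near the very ends: pad the interior, not the tail,
        # so every mitochondrial contig could hold a maximal (135 aa) module
        min_len = 3 * cfg.max_module_aa + 2 * (cfg.cassette_len + 50) + 100
        body_len = sum(len(s) for _, _, s in parts)
        tail_len = cfg.cassette_len + 45
        if body_len + tail_len < min_len:
            parts.append(("spacer", None, bg(min_len - body_len - tail_len)))
        parts.append(("cassette", None,
                      _diverge_cassette(master_cassette, cfg.cassette_divergence,
                                        rng, seen_cassettes)))
        parts.append(("pad", None, bg(int(rng.integers(5, 46)))))
        mito_bodies.append((cid, parts))

    for cid, parts in mito_bodies:
        seq: list[str] = []
        local_modules: list[tuple[int, int, str, _EmittedModule]] = []
        for kind, em, s in parts:
            start = len(seq)
            seq.extend(s)
            if kind.startswith("module"):
                local_modules.append((start, len(seq), kind[-1], em))
            elif kind == "cassette":
                cassette_records.append((cid, start, len(seq)))
        contigs[cid] = seq
        bins[cid] = "mitochondrial"
        for start, end, strand, em in local_modules:
            _clean_module_flanks(seq, start, end, strand, em, cfg, rng)
            module_records.append(
                PlantedModuleRecord(
                    gene=em.gene,
                    module_index=em.transcript_index,
                    contig=cid,
                    strand=strand,
                    contig_start=start,
                    contig_end=end,
                    prot_start=em.prot_start,
                    prot_end=em.prot_end,
                )
            )

    for ci in range(cfg.n_cassette_only):
        cid = f"mito_{n_coding + ci + 1:0{width}d}"
        body_len = int(rng.integers(600, 1601))
        seq = list(bg(int(rng.integers(5, 46))))
        c1 = _diverge_cassette(master_cassette, cfg.cassette_divergence, rng,
                               seen_cassettes)
        cassette_records.append((cid, len(seq), len(seq) + len(c1)))
        seq.extend(c1)
        seq.extend(bg(body_len))
        c2 = _diverge_cassette(master_cassette, cfg.cassette_divergence, rng,
                               seen_cassettes)
        cassette_records.append((cid, len(seq), len(seq) + len(c2)))
        seq.extend(c2)
        seq.extend(bg(int(rng.integers(5, 46))))
        contigs[cid] = seq
        bins[cid] = "mitochondrial"

    _ensure_junction_decodable(contigs, module_records, all_edits, mito_refs,
                               cfg, rng)

    # --- nuclear contigs: plain background, planted genes (with introns), U1
    nuclear_refs: dict[str, str] = {}
    intron_records: list[PlantedIntronRecord] = []
    u1_locus = None
    nwidth = max(3, len(str(cfg.n_nuclear_contigs)))

    n_gene_contigs = min(cfg.n_nuclear_genes, cfg.n_nuclear_contigs)
    gene_specs = list(_DEFAULT_NUCLEAR_GENES)
    while len(gene_specs) < n_gene_contigs:
        gene_specs.append((f"nucgene{len(gene_specs) + 1}", 400))

    for ni in range(cfg.n_nuclear_contigs):
        cid = f"nuc_{ni + 1:0{nwidth}d}"
        if ni < n_gene_contigs:
            gene, plen = gene_specs[ni]
            protein = random_protein(plen, rng)
            nuclear_refs[gene] = protein
            cds = reverse_translate(protein, cfg.nuclear_table_id,
                                    cfg.nuclear_gc, rng)
            n_introns = int(rng.poisson(cfg.intron_rate))
            pieces: list[str] = []
            intron_pos: list[tuple[int, int]] = []  # offsets within gene body
            # keep insertion points >= 60 bp apart so every internal exon
            # stays long enough (>= 20 aa) to anchor a homology block
            cut_points: list[int] = []
            for _ in range(200):
                if len(cut_points) >= n_introns:
                    break
                c = int(rng.integers(60, len(cds) - 60))
                if all(abs(c - x) >= 60 for x in cut_points):
                    cut_points.append(c)
            cut_points.sort()
            prev = 0
            offset = 0
            for cut in cut_points:
                pieces.append(cds[prev:cut])
                offset += cut - prev
                ilen = int(rng.integers(*cfg.intron_len_range))
                mid = random_background(ilen - len(DONOR_CONSENSUS) - 3,
                                        cfg.nuclear_gc, rng)
                intron = DONOR_CONSENSUS + mid + "CAG"
                pieces.append(intron)
                intron_pos.append((offset, offset + len(intron)))
                offset += len(intron)
                prev = cut
            pieces.append(cds[prev:])
            body = "".join(pieces)
            lead = random_background(int(rng.integers(100, 400)),
                                     cfg.nuclear_gc, rng)
            tail = random_background(int(rng.integers(100, 400)),
                                     cfg.nuclear_gc, rng)
            seq_str = lead + body + tail
            for s, e in intron_pos:
                intron_records.append(
                    PlantedIntronRecord(
                        contig=cid, gene=gene,
                        start=len(lead) + s, end=len(lead) + e,
                        donor_pos=len(lead) + s,
                        acceptor_pos=len(lead) + e - 2,
                    )
                )
            contigs[cid] = list(seq_str)
        elif ni == n_gene_contigs and cfg.include_u1:
            lead = random_background(int(rng.integers(200, 600)),
                                     cfg.nuclear_gc, rng)
            tail = random_background(int(rng.integers(200, 600)),
                                     cfg.nuclear_gc, rng)
            contigs[cid] = list(lead + U1_QUERY + tail)
            u1_locus = (cid, len(lead), len(lead) + len(U1_QUERY), "+")
        else:
            L = int(rng.integers(*cfg.nuclear_len_range))
            contigs[cid] = list(random_background(L, cfg.nuclear_gc, rng))
        bins[cid] = "nuclear"

    contig_strs = {cid: "".join(s) for cid, s in contigs.items()}

    # --- coverage
    coverage: dict[str, float] = {}
    mito_ids = [c for c in contig_strs if bins[c] == "mitochondrial"]
    nuc_ids = [c for c in contig_strs if bins[c] == "nuclear"]
    mito_cov = _lognormal_cov(cfg.mito_cov_mean, cfg.mito_cov_sd,
                              len(mito_ids), rng)
    nuc_cov = _lognormal_cov(cfg.nuclear_cov_mean, cfg.nuclear_cov_sd,
                             len(nuc_ids), rng)
    for cid, c in zip(mito_ids, mito_cov):
        coverage[cid] = float(c)
    for cid, c in zip(nuc_ids, nuc_cov):
        coverage[cid] = float(c)
    coverage = {cid: coverage[cid] for cid in contig_strs}

    manifest = TruthManifest(
        seed=cfg.seed,
        bins=bins,
        modules=module_records,
        junction_edits=all_edits,
        introns=intron_records,
        cassettes=cassette_records,
        mito_refs=mito_refs,
        nuclear_refs=nuclear_refs,
        permutations={g: plans[g].permutation for g in sorted(plans)},
        u1_locus=u1_locus,
        u1_seq=U1_QUERY if cfg.include_u1 else None,
    )
    return contig_strs, coverage, manifest
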