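"""Cross-taxon comparison of module boundaries (splice sites).

Module junctions are positions in each taxon's mature protein; to ask
whether two taxa split a gene at homologous points, boundaries are
projected through a global protein alignment into a shared coordinate
system and matched within a small tolerance (alignment jitter makes an
exact-position criterion too strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

from . import seqcore
from .assemble import ModuleChain

__all__ = ["BoundaryEntry", "BoundaryMap", "chain_boundaries",
           "project_boundaries", "conservation_summary"]


class SpliceCompareError(ValueError):
    pass


@dataclass
class BoundaryEntry:
    a_pos: int  # boundary position in taxon A protein coordinates
    b_proj: int | None  # projected position in taxon B coordinates
    nearest_b: int | None
    offset: int | None
    conserved: bool
    mapped: bool


@dataclass
class BoundaryMap:
    taxon_a: str
    taxon_b: str
    tolerance_aa: int
    entries: list[BoundaryEntry] = field(default_factory=list)

    @property
    def n_conserved(self) -> int:
        return sum(e.conserved for e in self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "taxon_a": self.taxon_a,
                    "taxon_b": self.taxon_b,
                    "a_pos": e.a_pos,
                    "b_proj": e.b_proj,
                    "nearest_b": e.nearest_b,
                    "offset_aa": e.offset,
                    "conserved": e.conserved,
                    "mapped": e.mapped,
                }
                for e in self.entries
            ]
        )


def chain_boundaries(chain: ModuleChain) -> list[int]:
    """Internal module boundaries in the chain's assembled-protein
    coordinates (a boundary sits immediately before the residue it
    indexes)."""
    bounds = []
    pos = 0
    for i, m in enumerate(chain.modules):
        if i > 0 and i - 1 < len(chain.junctions):
            j = chain.junctions[i - 1]
            if j.status in {"u_appendage", "flank_fill"}:
                pos += j.gap_aa
        pos += m.aa_len
        if i < len(chain.modules) - 1:
            bounds.append(pos)
    return bounds


def _chain_protein(chain: ModuleChain) -> str:
    return chain.protein or chain.ref_protein


def _global_align(a: str, b: str, matrix_name: str = "BLOSUM62"):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = seqcore.load_matrix(matrix_name)
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    # terminal gaps are cheap: chains may cover slightly different extents
    try:
        aligner.open_end_gap_score = -1
        aligner.extend_end_gap_score = -0.5
    except AttributeError:
        aligner.end_open_gap_score = -1
        aligner.end_extend_gap_score = -0.5
    results = aligner.align(a, b)
    if results.score <= 0:
        raise SpliceCompareError(
            "proteins share no significant global alignment"
        )
    return results[0]


def _position_map(aln, len_a: int) -> dict[int, int]:
    """Map each aligned A residue index to its B residue index."""
    qblocks, tblocks = aln.aligned
    out: dict[int, int] = {}
    for (qs, qe), (ts, te) in zip(qblocks, tblocks):
        for q, t in zip(range(qs, qe), range(ts, te)):
            out[int(q)] = int(t)
    return out


def project_boundaries(
    chain_a: ModuleChain,
    chain_b: ModuleChain,
    tolerance_aa: int = 1,
    taxon_a: str = "A",
    taxon_b: str = "B",
) -> BoundaryMap:
    """Project taxon A's module boundaries into taxon B coordinates.

    A boundary is conserved when a B boundary lies within
    ``tolerance_aa`` of its projected position; boundaries falling in
    alignment gaps are flagged unmapped (and not conserved).
    """
    prot_a, prot_b = _chain_protein(chain_a), _chain_protein(chain_b)
    aln = _global_align(prot_a, prot_b)
    amap = _position_map(aln, len(prot_a))
    b_bounds = chain_boundaries(chain_b)
    out = BoundaryMap(taxon_a, taxon_b, tolerance_aa)
    for a_pos in chain_boundaries(chain_a):
        # project the residue that starts the right-hand module
        proj = amap.get(a_pos)
        if proj is None:
            out.entries.append(
                BoundaryEntry(a_pos, None, None, None, False, False)
            )
            continue
        if b_bounds:
            nearest = min(b_bounds, key=lambda b: abs(b - proj))
            offset = proj - nearest
            conserved = abs(offset) <= tolerance_aa
        else:
            nearest, offset, conserved = None, None, False
        out.entries.append(
            BoundaryEntry(a_pos, proj, nearest, offset, conserved, True)
        )
    return out


def conservation_summary(
    maps: list[BoundaryMap],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Incidence of reference-taxon boundaries across compared taxa.

    All maps must share the same reference taxon A.  Returns a boundary x
    taxon boolean incidence matrix and counts of boundaries conserved in
    every taxon (universal), in some but not all (partial), and in none
    (private to the reference).
    """
    if not maps:
        raise SpliceCompareError("conservation_summary: no boundary maps")
    ref = {m.taxon_a for m in maps}
    if len(ref) > 1:
        raise SpliceCompareError(
            f"maps compare different reference taxa: {sorted(ref)}"
        )
    taxa = [m.taxon_b for m in maps]
    positions = sorted({e.a_pos for m in maps for e in m.entries})
    data = {}
    for m in maps:
        by_pos = {e.a_pos: e.conserved for e in m.entries}
        data[m.taxon_b] = [bool(by_pos.get(p, False)) for p in positions]
    frame = pd.DataFrame(data, index=pd.Index(positions, name="boundary_aa"),
                         columns=taxa)
    shared = frame.sum(axis=1)
    counts = {
        "universal": int((shared == len(taxa)).sum()),
        "partial": int(((shared > 0) & (shared < len(taxa))).sum()),
        "private": int((shared == 0).sum()),
    }
    return frame, counts
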