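"""Uridine-appendage junction arithmetic.

Diplonemid-style mitochondria complete some open reading frames
post-transcriptionally by appending a run of U residues between two gene
modules.  On the genome this shows up as coding nucleotides that are
simply absent at a module junction: only inserting k U's (k T's in DNA
sense) restores the reading frame and the reference residues.

The solver below asks, for one junction: what is the minimal number k of
inserted U's - optionally combined with up to two leftover genomic
nucleotides on either flank (partial codons left behind on the contig) -
that reconstructs the reference residues missing between the two modules?
It is used both to decode junctions during transcript assembly and to
verify, at simulation time, that a planted junction is uniquely decodable.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import seqcore


@dataclass(frozen=True)
class JunctionFill:
    k: int  # inserted U count (T's in DNA sense)
    ext_left: int  # genomic nt taken from the left flank (0-2)
    ext_right: int  # genomic nt taken from the right flank (0-2)

    @property
    def insert_dna(self) -> str:
        return "T" * self.k


def solve_junction_fill(
    left_flank: str,
    right_flank: str,
    gap_residues: str,
    table_id: int = 4,
    k_max: int = 12,
) -> JunctionFill | None:
    """Minimal-k fill for a module junction with a residual reference gap.

    ``left_flank``: contig nucleotides immediately following the left
    module in transcript orientation (at most 2 are ever used).
    ``right_flank``: nucleotides immediately preceding the right module in
    transcript orientation (its *last* nucleotides are adjacent to the
    module).  ``gap_residues``: the reference residues between the two
    modules' protein intervals.  Returns None when no fill with k <= k_max
    reproduces the gap exactly.
    """
    g = len(gap_residues)
    if g == 0:
        return JunctionFill(0, 0, 0)
    need = 3 * g
    for k in range(0, k_max + 1):
        rem = need - k
        if rem < 0:
            break
        if rem > 4:
            continue
        for e_l in range(0, min(2, len(left_flank)) + 1):
            e_r = rem - e_l
            if e_r < 0 or e_r > min(2, len(right_flank)):
                continue
            cand = left_flank[:e_l] + "T" * k + (right_flank[-e_r:] if e_r else "")
            if seqcore.translate(cand, 1, table_id) == gap_residues:
                return JunctionFill(k, e_l, e_r)
    return None
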