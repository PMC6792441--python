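"""Independent reference implementations used only to check results.

These are deliberately plain, slow re-implementations (full Gotoh DP in
pure Python, exhaustive subset search) kept separate from the package so
that tests compare two independently written routes to the same answer.
"""

from __future__ import annotations

import itertools

NEG = float("-inf")


def brute_local_align_score(
    query: str,
    target: str,
    score_fn,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Optimal local alignment score by full Gotoh dynamic programming.

    A gap of length L costs ``gap_open + L * gap_extend``.  Pure-Python,
    O(nm); intended for sequences of length <= ~12 in tests.
    """
    n, m = len(query), len(target)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in target
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query
    best = 0.0
    go = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            prev = max(0.0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = prev + score_fn(query[i - 1], target[j - 1])
            X[i][j] = max(M[i - 1][j] - go, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - go)
            Y[i][j] = max(M[i][j - 1] - go, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - go)
            best = max(best, M[i][j])
    return best


def brute_chain_objective(modules, max_overlap_aa: int):
    """Best (coverage, score, -count) over all valid module subsets.

    A subset is valid when, ordered by protein start, ends are
    non-decreasing and adjacent overlaps are at most ``max_overlap_aa``
    (which bounds all pairwise overlaps).
    """
    best = (0, 0.0, 0)
    n = len(modules)
    for r in range(1, n + 1):
        for combo in itertools.combinations(range(n), r):
            sel = sorted((modules[i] for i in combo),
                         key=lambda m: (m.prot_start, m.prot_end))
            ok = True
            for a, b in zip(sel, sel[1:]):
                if b.prot_end < a.prot_end or \
                        a.prot_end - b.prot_start > max_overlap_aa:
                    ok = False
                    break
            if not ok:
                continue
            coverage = 0
            prev_end = None
            for m in sel:
                coverage += m.prot_end - max(
                    m.prot_start, prev_end if prev_end is not None else m.prot_start
                )
                prev_end = m.prot_end
            cand = (coverage, sum(m.score for m in sel), -len(sel))
            if cand > best:
                best = cand
    return best


def chain_objective(chain):
    """(coverage, score, -count) of a returned chain, recomputed naively."""
    coverage = 0
    prev_end = None
    for m in chain.modules:
        coverage += m.prot_end - max(
            m.prot_start, prev_end if prev_end is not None else m.prot_start
        )
        prev_end = m.prot_end
    return (coverage, sum(m.score for m in chain.modules), -len(chain.modules))


def n50_oracle(lengths) -> int:
    """N50 by literal definition: largest L such that contigs >= L hold at
    least half the total bases."""
    total = sum(lengths)
    for L in sorted(set(lengths), reverse=True):
        if sum(x for x in lengths if x >= L) * 2 >= total:
            return L
    return min(lengths)
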