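"""Independent reference implementations used only by the test suite.

These deliberately re-derive results through different code paths than the
package (full-matrix or enumeration algorithms), sharing only the scoring
conventions and tie-break rules that define the problem.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from numba import njit

from temine._dna import encode, revcomp
from temine.search import (DNA_MATRIX, GAP_EXTEND, GAP_OPEN, Hit,
                           min_alignment_score)

NEG = -(10 ** 7)


# ---------------------------------------------------------------------------
# local alignment: exhaustive scan of the whole genome (no seeding)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sw_best(q, t, mat, go, ge):
    """Score-only Gotoh scan of the full target; first-maximum tie-break
    (ascending target index, then ascending query index)."""
    n = q.shape[0]
    m = t.shape[0]
    hp = np.zeros(n + 1, np.int64)
    ep = np.full(n + 1, NEG, np.int64)
    hc = np.zeros(n + 1, np.int64)
    ec = np.full(n + 1, NEG, np.int64)
    best = 0
    bi = 0
    bj = 0
    for j in range(1, m + 1):
        f = NEG
        tj = t[j - 1]
        for i in range(1, n + 1):
            e = max(ep[i] + ge, hp[i] + go + ge)
            f = max(f + ge, hc[i - 1] + go + ge)
            h = hp[i - 1] + mat[q[i - 1], tj]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            hc[i] = h
            ec[i] = e
            if h > best:
                best = h
                bi = i
                bj = j
        hp, hc = hc, hp
        ep, ec = ec, ep
    return best, bi, bj


@njit(cache=True)
def _sw_trace(q, t, mat, go, ge):
    """Full-matrix local alignment with traceback (small slices only).

    Same tie-break rules as the package kernels: diagonal first, then gap
    in query, then gap in target; gap closes (open) before it extends.
    """
    n = q.shape[0]
    m = t.shape[0]
    H = np.zeros((n + 1, m + 1), np.int64)
    E = np.full((n + 1, m + 1), NEG, np.int64)
    F = np.full((n + 1, m + 1), NEG, np.int64)
    best = 0
    bi = 0
    bj = 0
    for j in range(1, m + 1):
        tj = t[j - 1]
        for i in range(1, n + 1):
            E[i, j] = max(E[i, j - 1] + ge, H[i, j - 1] + go + ge)
            F[i, j] = max(F[i - 1, j] + ge, H[i - 1, j] + go + ge)
            h = H[i - 1, j - 1] + mat[q[i - 1], tj]
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    i = bi
    j = bj
    matches = 0
    cols = 0
    state = 0
    while i > 0 and j > 0:
        if state == 0:
            if H[i, j] == 0:
                break
            if H[i, j] == H[i - 1, j - 1] + mat[q[i - 1], t[j - 1]]:
                cols += 1
                if q[i - 1] == t[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            cols += 1
            if E[i, j] == H[i, j - 1] + go + ge:
                state = 0
            j -= 1
        else:
            cols += 1
            if F[i, j] == H[i - 1, j] + go + ge:
                state = 0
            i -= 1
    return best, i, bi, j, bj, matches, cols


def oracle_search(query: str, genome: dict[str, str],
                  min_identity: float = 0.8, min_length: int = 1000
                  ) -> list[Hit]:
    """Exhaustive (seed-free) version of the search protocol: repeatedly
    take the best local alignment anywhere in the genome, mask it, stop
    below the score floor; then apply the identity/length filter and the
    locus-merging rule."""
    from temine.search import _merge_hits

    min_score = min_alignment_score(min_identity, min_length)
    raw = []
    for strand in ("+", "-"):
        q = encode(query if strand == "+" else revcomp(query))
        for contig, seq in genome.items():
            t = encode(seq)
            while True:
                score, bi, bj = _sw_best(q, t, DNA_MATRIX, GAP_OPEN,
                                         GAP_EXTEND)
                if score < min_score:
                    break
                w0 = max(0, bj - (2 * q.size + 64))
                (s2, qi0, qi1, tj0, tj1, matches, cols) = _sw_trace(
                    q[:bi], t[w0:bj], DNA_MATRIX, GAP_OPEN, GAP_EXTEND)
                ts, te = w0 + tj0, w0 + tj1
                ident = 100.0 * matches / cols
                if cols >= min_length and ident >= 100.0 * min_identity:
                    raw.append(Hit(contig=contig, start=ts, end=te,
                                   strand=strand, identity=ident,
                                   length=cols, score=int(s2),
                                   query_start=qi0, query_end=qi1))
                t[ts:te] = 4
    return _merge_hits(raw)


# ---------------------------------------------------------------------------
# global alignment score by exhaustive recursion (tiny strings)
# ---------------------------------------------------------------------------

def oracle_global_score(a: str, b: str, match=1, mismatch=-1,
                        gap_open=-4, gap_extend=-1) -> float:
    """Optimal affine-gap global alignment score by memoised recursion
    over (i, j, state); a gap of length L costs gap_open + L*gap_extend."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            options.append(s + rec(i + 1, j + 1, 0))
        if i < len(a):
            cost = gap_extend if state == 1 else gap_open + gap_extend
            options.append(cost + rec(i + 1, j, 1))
        if j < len(b):
            cost = gap_extend if state == 2 else gap_open + gap_extend
            options.append(cost + rec(i, j + 1, 2))
        return max(options)

    return rec(0, 0, 0)


# ---------------------------------------------------------------------------
# exhaustive TIR search
# ---------------------------------------------------------------------------

def oracle_tir(seq: str, min_len=10, max_len=100, max_mismatch_frac=0.15,
               search_window=120, allow_offset=False):
    """Naive enumeration over every (left offset, right offset, length)
    triple; same scoring (L - 3*mm) and tie rules as the detector."""
    n = len(seq)
    max_len = min(max_len, n // 2)
    offsets = range(search_window) if allow_offset else (0,)
    best_key, best = None, None
    for length in range(min_len, max_len + 1):
        for lo in offsets:
            if lo + length > min(search_window, n):
                continue
            left = seq[lo:lo + length]
            rc_positions = []
            for ro in offsets:
                if ro + length > min(search_window, n):
                    continue
                right = seq[n - ro - length:n - ro]
                rc = revcomp(right)
                mm = sum(1 for x, y in zip(left, rc) if x != y)
                if mm > int(max_mismatch_frac * length):
                    continue
                key = (length - 3 * mm, length, -lo, -ro)
                if best_key is None or key > best_key:
                    best_key = key
                    best = (lo, lo + length, n - ro - length, n - ro,
                            length, mm)
    return best


# ---------------------------------------------------------------------------
# Dollo parsimony by loss-set enumeration
# ---------------------------------------------------------------------------

def oracle_dollo(presence: dict[str, bool], tree) -> int:
    """Minimum loss count by enumerating every subset of edges under the
    MRCA of the present species as candidate loss placements."""
    present = {sp for sp, p in presence.items() if p}

    def subtree(node):
        tips = {leaf.name for leaf in node.leaves()}
        if present <= tips:
            for child in node.children:
                deeper = subtree(child)
                if deeper is not None:
                    return deeper
            return node
        return None

    mrca = subtree(tree.root)
    edges = []       # node below each candidate loss edge

    def collect(node):
        for child in node.children:
            edges.append(child)
            collect(child)

    collect(mrca)
    tips_below = {id(n): {leaf.name for leaf in n.leaves()} for n in edges}
    all_tips = {leaf.name for leaf in mrca.leaves()}
    best = None
    for r in range(len(edges) + 1):
        if best is not None and best <= r - 1:
            break
        for combo in itertools.combinations(edges, r):
            lost = set()
            for node in combo:
                lost |= tips_below[id(node)]
            pattern = {tip: tip not in lost for tip in all_tips}
            target = {tip: tip in present for tip in all_tips}
            if pattern == target:
                best = r
                break
        if best is not None:
            break
    return best
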