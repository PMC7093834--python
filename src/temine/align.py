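"""Pairwise/multiple alignment, consensus, identity matrices, clustering.

Pairwise global alignment is delegated to Biopython's ``PairwiseAligner``
(affine gaps, same scoring as the search engine); the center-star multiple
alignment, majority-rule consensus reconstruction and percent-identity
matrices are implemented here, and cluster assignment uses average-linkage
hierarchical clustering on the identity matrix (a distance-based stand-in
for tree-based cluster reading — downstream stages consume memberships,
not branch support).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._dna import IUPAC

__all__ = [
    "PairwiseAlignment",
    "MultipleAlignment",
    "IdentityMatrix",
    "global_align",
    "center_star_msa",
    "consensus",
    "pairwise_identity",
    "identity_matrix",
    "assign_clusters",
]

GAP = "-"


def _make_aligner(match: float = 1, mismatch: float = -1,
                  gap_open: float = -4, gap_extend: float = -1
                  ) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # Biopython's open_gap_score is the cost of the first gap position
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    return aligner


@dataclass(frozen=True)
class PairwiseAlignment:
    a: str          # gapped rows, equal length
    b: str
    score: float

    @property
    def columns(self) -> int:
        return len(self.a)

    def identity(self, gap_policy: str = "count_gaps") -> float:
        """Percent identity; see :func:`identity_matrix` for policies."""
        pairs = list(zip(self.a, self.b))
        matches = sum(1 for x, y in pairs
                      if x == y and x != GAP)
        if gap_policy == "count_gaps":
            denom = sum(1 for x, y in pairs if not (x == GAP and y == GAP))
        elif gap_policy == "exclude_gaps":
            denom = sum(1 for x, y in pairs if x != GAP and y != GAP)
        else:
            raise ValueError(f"unknown gap_policy {gap_policy!r}")
        return 100.0 * matches / denom if denom else 0.0


def global_align(a: str, b: str, match: float = 1, mismatch: float = -1,
                 gap_open: float = -4, gap_extend: float = -1
                 ) -> PairwiseAlignment:
    """Optimal global alignment under affine-gap scoring (gap of length L
    costs gap_open + L * gap_extend); deterministic first optimal path."""
    if not a or not b:
        raise ValueError("empty input sequence")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    alignment = aligner.align(a, b)[0]
    return PairwiseAlignment(a=str(alignment[0]), b=str(alignment[1]),
                             score=float(alignment.score))


@dataclass
class MultipleAlignment:
    """Gapped rows of equal length; degapping row i recovers input i."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self):
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def to_fasta(self) -> str:
        return "".join(f">{lab}\n{row}\n"
                       for lab, row in zip(self.labels, self.rows))


def center_star_msa(seqs: Sequence[str], labels: Sequence[str] | None = None
                    ) -> MultipleAlignment:
    """Center-star progressive multiple alignment.

    The center is the sequence maximising summed pairwise identity to the
    others; every other sequence is pairwise aligned to the center and the
    alignments are merged column-wise ('once a gap, always a gap').
    """
    if len(seqs) < 2:
        raise ValueError("center_star_msa needs >= 2 sequences")
    seqs = [s.upper() for s in seqs]
    labels = list(labels) if labels is not None \
        else [f"seq{i}" for i in range(len(seqs))]
    n = len(seqs)
    pair: dict[tuple[int, int], PairwiseAlignment] = {}
    total = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(seqs[i], seqs[j])
            pair[(i, j)] = aln
            ident = aln.identity()
            total[i] += ident
            total[j] += ident
    center = int(np.argmax(total))

    order = [center] + [i for i in range(n) if i != center]
    rows = [seqs[center]]
    for idx in order[1:]:
        i, j = (center, idx) if center < idx else (idx, center)
        aln = pair[(i, j)]
        c_row, o_row = (aln.a, aln.b) if i == center else (aln.b, aln.a)
        rows = _merge(rows, c_row, o_row)
    out_rows = [None] * n
    for pos, idx in enumerate(order):
        out_rows[idx] = rows[pos]
    return MultipleAlignment(labels=labels, rows=out_rows)


def _merge(rows: list[str], c_row: str, o_row: str) -> list[str]:
    """Merge a (center, other) pairwise alignment into rows already aligned
    to the center ('once a gap, always a gap'); rows[0] is the center with
    accumulated gaps, c_row the raw center as gapped in the new alignment."""
    merged: list[list[str]] = [[] for _ in range(len(rows) + 1)]
    center_row = rows[0]
    i = j = 0
    n_old, n_new = len(center_row), len(c_row)
    while i < n_old or j < n_new:
        old_is_gap = i < n_old and center_row[i] == GAP
        new_is_gap = j < n_new and c_row[j] == GAP
        if i < n_old and old_is_gap:
            # gap previously inserted into the center: keep old columns
            for r in range(len(rows)):
                merged[r].append(rows[r][i])
            merged[-1].append(GAP)
            i += 1
        elif j < n_new and new_is_gap:
            # new gap in the center from this pairwise alignment
            for r in range(len(rows)):
                merged[r].append(GAP)
            merged[-1].append(o_row[j])
            j += 1
        else:
            for r in range(len(rows)):
                merged[r].append(rows[r][i])
            merged[-1].append(o_row[j])
            i += 1
            j += 1
    return ["".join(m) for m in merged]


def consensus(msa: MultipleAlignment, min_frac: float = 0.5) -> str:
    """Majority-rule consensus of a multiple alignment.

    Per column: the most frequent non-gap symbol if its frequency among
    non-gap rows reaches ``min_frac``, otherwise the IUPAC ambiguity code of
    the top-tied symbols; columns where gaps are the majority are dropped.
    """
    if not msa.rows:
        raise ValueError("empty alignment")
    out = []
    n = len(msa.rows)
    for c in range(msa.columns):
        column = [row[c] for row in msa.rows]
        residues = [x for x in column if x != GAP]
        if len(residues) * 2 < n:
            continue
        symbols, counts = np.unique(residues, return_counts=True)
        top = counts.max()
        if top / len(residues) >= min_frac:
            winners = sorted(symbols[counts == top])
            if len(winners) == 1:
                out.append(winners[0])
            else:
                out.append(IUPAC.get(tuple(winners), "N"))
        else:
            winners = tuple(sorted(symbols[counts == top]))
            out.append(IUPAC.get(winners, "N"))
    return "".join(out)


def pairwise_identity(a: str, b: str, gap_policy: str = "count_gaps") -> float:
    return global_align(a.upper(), b.upper()).identity(gap_policy)


@dataclass
class IdentityMatrix:
    """Symmetric percent-identity matrix with summary statistics."""

    labels: list[str]
    values: np.ndarray
    gap_policy: str = "count_gaps"

    @property
    def mean(self) -> float:
        iu = np.triu_indices(len(self.labels), k=1)
        return float(self.values[iu].mean())

    @property
    def sd(self) -> float:
        iu = np.triu_indices(len(self.labels), k=1)
        return float(self.values[iu].std(ddof=1)) if len(iu[0]) > 1 else 0.0

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.values, index=self.labels,
                            columns=self.labels)


def identity_matrix(seqs: Sequence[str], labels: Sequence[str] | None = None,
                    gap_policy: str = "count_gaps") -> IdentityMatrix:
    """All-pairs global-alignment percent identities.

    gap_policy='count_gaps' (default): identical columns / columns with at
    least one residue (gaps count as differences).  'exclude_gaps':
    identical columns / columns where both rows have a residue.
    """
    if len(seqs) < 2:
        raise ValueError("identity_matrix needs >= 2 sequences")
    labels = list(labels) if labels is not None \
        else [f"seq{i}" for i in range(len(seqs))]
    n = len(seqs)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_identity(seqs[i], seqs[j], gap_policy)
            values[i, j] = values[j, i] = ident
    return IdentityMatrix(labels=labels, values=values, gap_policy=gap_policy)


def assign_clusters(matrix: IdentityMatrix | np.ndarray,
                    k: int | None = None, cutoff: float | None = None,
                    labels: Sequence[str] | None = None) -> dict[str, str]:
    """Average-linkage hierarchical clustering of an identity matrix.

    Cut at ``k`` clusters or at a percent-identity ``cutoff`` (members of a
    cluster are linked at identity >= cutoff).  Cluster names 'A', 'B', ...
    are assigned by decreasing size, ties by lexicographically smallest
    member, so labelling is deterministic.
    """
    if isinstance(matrix, IdentityMatrix):
        labels = matrix.labels
        dist = 100.0 - matrix.values
    else:
        dist = np.asarray(matrix, dtype=float)
        if labels is None:
            labels = [f"seq{i}" for i in range(len(dist))]
    n = len(labels)
    if k is not None and k > n:
        raise ValueError("k exceeds the number of sequences")
    np.fill_diagonal(dist, 0.0)
    link = linkage(squareform(dist, checks=False), method="average")
    if k is not None:
        assignment = fcluster(link, t=k, criterion="maxclust")
    elif cutoff is not None:
        assignment = fcluster(link, t=100.0 - cutoff, criterion="distance")
    else:
        raise ValueError("provide k or cutoff")
    groups: dict[int, list[str]] = {}
    for lab, grp in zip(labels, assignment):
        groups.setdefault(int(grp), []).append(lab)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), sorted(g)[0]))
    out: dict[str, str] = {}
    for idx, members in enumerate(ordered):
        name = chr(ord("A") + idx) if idx < 26 else f"C{idx}"
        for member in members:
            out[member] = name
    return out
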