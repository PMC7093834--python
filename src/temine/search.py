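"""Homology search: k-mer seeded, affine-gap extended, BLAST-like in spirit.

The engine finds candidate transposon copies in genome sequences from a
nucleotide consensus (``seed_and_extend``) or a transposase protein query
(``translated_scan``, a six-frame scan).  Hits feed the copy-number filter
(alignments > 1,000 bp at >= 80% identity) and the contamination check based
on flank mappability.

Identity convention: identical columns / all alignment columns (gap columns
count as differences; dual-gap columns cannot occur in a pairwise alignment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from ._align_kernels import best_local_cell, local_traceback
from ._dna import encode, encode_protein, revcomp, translate

MATCH = 1
MISMATCH = -1
GAP_OPEN = -4               # nucleotide: gap of length L costs -4 - L
GAP_EXTEND = -1
PROT_GAP_OPEN = -10         # protein: BLOSUM62 with 11/1 gap costs
PROT_GAP_EXTEND = -1
_DNA_MASK = np.int8(4)      # mask code: matches nothing, ever
_PROT_MASK = np.int8(0)     # NUL, never a residue


def _dna_matrix() -> np.ndarray:
    mat = np.full((5, 5), MISMATCH, dtype=np.int64)
    for i in range(4):
        mat[i, i] = MATCH
    mat[4, :] = mat[:, 4] = MISMATCH    # mask/N never matches
    return mat


def _protein_matrix() -> np.ndarray:
    """BLOSUM62 indexed by ASCII code (TBlastN-style scoring)."""
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    mat = np.full((128, 128), -4, dtype=np.int64)
    alpha = blosum.alphabet
    for a in alpha:
        for b in alpha:
            mat[ord(a), ord(b)] = int(blosum[a, b])
    mat[0, :] = mat[:, 0] = -10         # mask
    return mat


DNA_MATRIX = _dna_matrix()
PROTEIN_MATRIX = _protein_matrix()

__all__ = [
    "Hit",
    "KmerIndex",
    "build_kmer_index",
    "seed_and_extend",
    "translated_scan",
    "count_copies",
    "contamination_check",
    "min_alignment_score",
]


@dataclass
class Hit:
    """One merged local-alignment hit (locus-level, strand-aware)."""

    contig: str
    start: int          # 0-based half-open genomic interval
    end: int
    strand: str
    identity: float     # percent over alignment columns
    length: int         # alignment columns
    score: int
    query_start: int = 0
    query_end: int = 0

    def overlap_frac(self, other: "Hit") -> float:
        if self.contig != other.contig:
            return 0.0
        inter = min(self.end, other.end) - max(self.start, other.start)
        if inter <= 0:
            return 0.0
        shorter = min(self.end - self.start, other.end - other.start)
        return inter / shorter


class KmerIndex:
    """Exact k-mer index over a set of contigs (forward strand).

    Reverse-strand queries are handled at search time by scanning the
    reverse complement of the query.
    """

    def __init__(self, contigs: Mapping[str, str], k: int):
        if not 4 <= k <= 31:
            raise ValueError("k must be in [4, 31]")
        self.k = k
        self.contigs = dict(contigs)
        self._table: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.contigs.items():
            seq = seq.upper()
            self.contigs[name] = seq
            for pos in range(len(seq) - k + 1):
                self._table.setdefault(seq[pos:pos + k], []).append((name, pos))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._table.get(kmer.upper(), [])

    @property
    def n_positions(self) -> int:
        return sum(len(v) for v in self._table.values())


def build_kmer_index(genome: Mapping[str, str] | str, k: int = 11) -> KmerIndex:
    if isinstance(genome, str):
        genome = {"seq": genome}
    return KmerIndex(genome, k)


def min_alignment_score(min_identity: float, min_length: int) -> int:
    """Score floor for the iterative hit-extraction loop.

    A hit of ``min_length`` columns at ``min_identity`` scores at least
    about length * (2 * identity - 1) minus gap-open costs; half that value
    is a safe floor that still terminates quickly on random sequence.
    """
    return max(25, int(0.5 * min_length * (2.0 * min_identity - 1.0)))


def _extract_window_hits(qenc: np.ndarray, tenc: np.ndarray, min_score: int,
                         mask_code: np.int8, xdrop: int,
                         submat: np.ndarray, gap_open: int, gap_extend: int
                         ) -> list[tuple[int, int, int, int, int, int, int]]:
    """All local alignments >= min_score in a target slice, best-first.

    Returns tuples (t_start, t_end, q_start, q_end, score, matches, cols)
    — masking each found hit before re-scanning, so hits never overlap.
    """
    t = tenc.copy()
    out = []
    span = 2 * qenc.size + 64
    while True:
        score, bi, bj = best_local_cell(qenc, t, submat, gap_open,
                                        gap_extend, xdrop)
        if score < min_score:
            break
        w0 = max(0, bj - span)
        (s2, qi0, qi1, tj0, tj1, matches, cols) = local_traceback(
            qenc[:bi], t[w0:bj], submat, gap_open, gap_extend)
        t_start, t_end = w0 + tj0, w0 + tj1
        out.append((t_start, t_end, qi0, qi1, int(s2), matches, cols))
        t[t_start:t_end] = mask_code
    return out


def _merge_hits(hits: list[Hit], max_overlap: float = 0.5) -> list[Hit]:
    """Merge hits sharing > max_overlap of the shorter interval on the same
    strand, keeping the best score (the analysis counts loci, not HSPs)."""
    hits = sorted(hits, key=lambda h: (-h.score, h.contig, h.start))
    kept: list[Hit] = []
    for h in hits:
        if any(k.strand == h.strand and h.overlap_frac(k) > max_overlap
               for k in kept):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (h.contig, h.start, h.strand))
    return kept


def _cluster_positions(positions: list[int], gap: int) -> list[tuple[int, int]]:
    positions = sorted(positions)
    clusters = []
    lo = hi = positions[0]
    for p in positions[1:]:
        if p - hi > gap:
            clusters.append((lo, hi))
            lo = p
        hi = p
    clusters.append((lo, hi))
    return clusters


def seed_and_extend(query: str, index: KmerIndex, min_identity: float = 0.8,
                    min_length: int = 1000, xdrop: int = 10_000
                    ) -> list[Hit]:
    """Find all genomic hits of a nucleotide query meeting the thresholds.

    Exact k-mer seeds are clustered into candidate windows, each window is
    exhaustively aligned (affine-gap local DP, iteratively masking each hit),
    and hits with >= min_identity over >= min_length alignment columns are
    reported; overlapping hits at one locus are merged, best score kept.
    An exact copy of the query of sufficient length is always reported with
    identity 100.
    """
    if not query:
        raise ValueError("empty query")
    query = query.upper()
    k = index.k
    min_score = min_alignment_score(min_identity, min_length)
    raw: list[Hit] = []
    for strand in ("+", "-"):
        q = query if strand == "+" else revcomp(query)
        qenc = encode(q)
        seeds: dict[str, list[int]] = {}
        for qpos in range(len(q) - k + 1):
            for contig, tpos in index.lookup(q[qpos:qpos + k]):
                seeds.setdefault(contig, []).append(tpos)
        for contig, positions in seeds.items():
            tseq = index.contigs[contig]
            for lo, hi in _cluster_positions(positions, gap=len(q)):
                w0 = max(0, lo - len(q))
                w1 = min(len(tseq), hi + k + len(q))
                tenc = encode(tseq[w0:w1])
                for (ts, te, qs, qe, score, matches, cols) in \
                        _extract_window_hits(qenc, tenc, min_score,
                                             _DNA_MASK, xdrop, DNA_MATRIX,
                                             GAP_OPEN, GAP_EXTEND):
                    identity = 100.0 * matches / cols
                    if cols >= min_length and identity >= 100.0 * min_identity:
                        raw.append(Hit(contig=contig, start=w0 + ts,
                                       end=w0 + te, strand=strand,
                                       identity=identity, length=cols,
                                       score=score, query_start=qs,
                                       query_end=qe))
    return _merge_hits(raw)


def translated_scan(protein_query: str, genome: Mapping[str, str] | str,
                    min_aa_identity: float = 0.4, min_aa_length: int = 100,
                    k: int = 4, xdrop: int = 10_000,
                    min_score: int = 60) -> list[Hit]:
    """Six-frame translated search of a protein query against a genome.

    Each frame is split at stop codons; segments are aligned to the query
    with the seeded local-DP engine under BLOSUM62 (TBlastN-style), so
    distant transposase homologs align even below 50% identity.  Hit
    coordinates are the nucleotide interval of the matched frame segment;
    ``length`` is reported in bp (3 x aligned aa columns).
    """
    if not protein_query:
        raise ValueError("empty protein query")
    if isinstance(genome, str):
        genome = {"seq": genome}
    pq = protein_query.upper()
    qenc = encode_protein(pq)
    qkmers: dict[str, list[int]] = {}
    for i in range(len(pq) - k + 1):
        qkmers.setdefault(pq[i:i + k], []).append(i)
    raw: list[Hit] = []
    for contig, seq in genome.items():
        seq = seq.upper()
        L = len(seq)
        for strand in ("+", "-"):
            sseq = seq if strand == "+" else revcomp(seq)
            for frame in range(3):
                aa = translate(sseq[frame:])
                # segments between stops
                off = 0
                for segment in aa.split("*"):
                    if len(segment) >= k:
                        hit_positions = [
                            p for p in range(len(segment) - k + 1)
                            if segment[p:p + k] in qkmers]
                        if hit_positions:
                            senc = encode_protein(segment)
                            for lo, hi in _cluster_positions(
                                    hit_positions, gap=len(pq)):
                                w0 = max(0, lo - len(pq))
                                w1 = min(len(segment), hi + k + len(pq))
                                for (ts, te, qs, qe, score, matches, cols) \
                                        in _extract_window_hits(
                                            qenc, senc[w0:w1], min_score,
                                            _PROT_MASK, xdrop,
                                            PROTEIN_MATRIX, PROT_GAP_OPEN,
                                            PROT_GAP_EXTEND):
                                    ident = 100.0 * matches / cols
                                    if (cols >= min_aa_length
                                            and ident >= 100.0 * min_aa_identity):
                                        aa_s = off + w0 + ts
                                        aa_e = off + w0 + te
                                        nt_s = frame + 3 * aa_s
                                        nt_e = frame + 3 * aa_e
                                        if strand == "-":
                                            nt_s, nt_e = L - nt_e, L - nt_s
                                        raw.append(Hit(
                                            contig=contig, start=nt_s,
                                            end=nt_e, strand=strand,
                                            identity=ident, length=3 * cols,
                                            score=score, query_start=qs,
                                            query_end=qe))
                    off += len(segment) + 1
    return _merge_hits(raw)


def count_copies(hits: Iterable[Hit], min_length: int = 1000,
                 min_identity: float = 80.0) -> int:
    """Copy number under the published filter: alignment strictly longer
    than ``min_length`` bp AND identity >= ``min_identity`` percent."""
    return sum(1 for h in hits
               if h.length > min_length and h.identity >= min_identity)


def contamination_check(left_flank: str, right_flank: str,
                        genomes: Mapping[str, Mapping[str, str]],
                        home: tuple[str, str, int, int] | None = None,
                        min_identity: float = 0.9, k: int = 11,
                        min_flank: int = 100) -> str:
    """Classify a low-copy insertion as 'genuine' or 'contamination'.

    A copy is genuine if either flank maps (at ``min_identity`` over at
    least half the flank) to any provided genome outside the copy's own
    locus; otherwise it is flagged as likely assembly contamination.
    ``home`` = (genome_name, contig, start, end) marks the locus to exclude,
    padded by the flank lengths.
    """
    flanks = [f for f in (left_flank, right_flank) if len(f) >= min_flank]
    if not flanks:
        if max(len(left_flank), len(right_flank)) < k:
            raise ValueError("both flanks shorter than the seed length")
        flanks = [f for f in (left_flank, right_flank) if len(f) >= k]
    for name, contigs in genomes.items():
        index = build_kmer_index(contigs, k)
        for flank in flanks:
            min_len = max(k, len(flank) // 2)
            for hit in seed_and_extend(flank, index,
                                       min_identity=min_identity,
                                       min_length=min_len):
                if home is not None and name == home[0] \
                        and hit.contig == home[1]:
                    pad = max(len(left_flank), len(right_flank))
                    if hit.start < home[3] + pad and hit.end > home[2] - pad:
                        continue
                return "genuine"
    return "contamination"
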