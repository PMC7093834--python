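"""Structural annotation of candidate transposon copies.

Turns raw homology hits into annotated elements: flank extraction, multiple-
alignment boundary refinement, terminal-inverted-repeat (TIR) and TA
target-site-duplication (TSD) detection, ORF and catalytic-motif (DDE triad,
GRPR) identification, and the intact / full-length / truncated
classification used throughout Tc1/mariner family descriptions:

* full-length (FL): both TIRs detectable and both flanking TSDs equal TA;
* intact: FL and a single ORF encoding a transposase in the family length
  range whose catalytic triad matches the family's D2-E spacing;
* truncated: anything else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from ._dna import revcomp, translate

__all__ = [
    "TriadSpec",
    "TirAnnotation",
    "TsdAnnotation",
    "OrfAnnotation",
    "TECopy",
    "extract_with_flanks",
    "refine_boundaries",
    "detect_tir",
    "detect_tsd",
    "find_orf",
    "detect_dde",
    "detect_grpr",
    "classify_element",
    "annotate_copy",
]

DEFAULT_AA_RANGE = (303, 350)        # widest printed intact-transposase range
DEFAULT_FAMILY_SPACING = 35          # DD35E
DEFAULT_SPACINGS = frozenset({34, 35, 36, 37, 38, 39, 41})


@dataclass(frozen=True)
class TriadSpec:
    """DDE catalytic triad: 1-based residue indices of D1 < D2 < E.

    The family label counts the residues strictly between D2 and E
    (DD34E = Tc1-like, DD35E etc.).
    """

    d1: int
    d2: int
    e: int

    def __post_init__(self):
        if not self.d1 < self.d2 < self.e:
            raise ValueError("triad positions must satisfy D1 < D2 < E")

    @property
    def spacing(self) -> int:
        return self.e - self.d2 - 1

    @property
    def label(self) -> str:
        return f"DD{self.spacing}E"


@dataclass(frozen=True)
class TirAnnotation:
    """TIR arm pair in element coordinates (0-based half-open)."""

    left_start: int
    left_end: int
    right_start: int
    right_end: int
    length: int
    mismatches: int
    pentamer: str


@dataclass(frozen=True)
class TsdAnnotation:
    left: str | None
    right: str | None
    match: bool


@dataclass(frozen=True)
class OrfAnnotation:
    """ORF in element coordinates; the interval includes the stop codon."""

    start: int
    end: int
    protein: str
    triad: TriadSpec | None = None
    grpr_position: int | None = None


@dataclass
class TECopy:
    """One genomic copy with flanks and structural annotations.

    ``element_sequence`` and the flanks are in element orientation: for a
    minus-strand locus the element is reverse complemented and the left
    flank of the element is the reverse complement of the genomic right
    flank.
    """

    contig: str
    start: int
    end: int
    strand: str
    element_sequence: str
    left_flank: str = ""
    right_flank: str = ""
    species: str | None = None
    tir: TirAnnotation | None = None
    tsd: TsdAnnotation | None = None
    orf: OrfAnnotation | None = None
    classification: str | None = None


def extract_with_flanks(contigs: Mapping[str, str] | str, hit,
                        flank: int = 1000) -> TECopy:
    """Extract a hit's sequence with up to ``flank`` bp of genomic context.

    Flanks are clipped at contig ends; minus-strand hits are returned in
    element orientation with flanks swapped and reverse complemented.
    """
    if isinstance(contigs, str):
        contigs = {getattr(hit, "contig", "seq"): contigs}
    seq = contigs[hit.contig]
    if not (0 <= hit.start < hit.end <= len(seq)):
        raise ValueError(f"hit {hit.start}..{hit.end} outside contig "
                         f"{hit.contig} (length {len(seq)})")
    element = seq[hit.start:hit.end]
    left = seq[max(0, hit.start - flank):hit.start]
    right = seq[hit.end:hit.end + flank]
    if hit.strand == "-":
        element = revcomp(element)
        left, right = revcomp(right), revcomp(left)
    return TECopy(contig=hit.contig, start=hit.start, end=hit.end,
                  strand=hit.strand, element_sequence=element,
                  left_flank=left, right_flank=right,
                  species=getattr(hit, "species", None))


# ---------------------------------------------------------------------------
# boundary refinement
# ---------------------------------------------------------------------------

def _column_agreement(rows: list[str]) -> np.ndarray:
    """Fraction of non-gap rows sharing the majority residue per column;
    columns where fewer than half the rows have a residue score 0 (so
    truncated copies do not drag boundaries inward, while sparse columns
    cannot extend them)."""
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8)
    arr = arr.reshape(len(rows), -1)
    n, width = arr.shape
    agree = np.full(width, np.nan)
    min_rows = max(2, n // 2)
    for c in range(width):
        col = arr[:, c]
        col = col[col != ord("-")]
        if col.size < min_rows:
            continue          # sparse column (indel): uninformative, NaN
        _, counts = np.unique(col, return_counts=True)
        agree[c] = counts.max() / col.size
    return agree


def _inward_mean(agree: np.ndarray, c: int, step: int, count: int,
                 width: int) -> float:
    vals = []
    pos = c
    while 0 <= pos < width and len(vals) < count:
        if not np.isnan(agree[pos]):
            vals.append(agree[pos])
        pos += step
    return float(np.mean(vals)) if vals else 1.0


def refine_boundaries(copies: Sequence[TECopy], boundary_frac: float = 0.6,
                      edge_frac: float = 0.8, window: int = 8,
                      flank_window: int | None = None,
                      tsd: str | None = None) -> list[TECopy]:
    """Refine element boundaries by multiple alignment of copies + flanks.

    Copies are center-star aligned over flank+element+flank; scanning
    outward from the middle of the hit core, the boundary is placed where
    per-column agreement collapses (conserved interior vs divergent flank).
    A coarse scan uses a ``window``-column moving average against
    ``boundary_frac``; the edge is then refined to the outermost pair of
    consecutive columns with agreement >= ``edge_frac``.

    ``flank_window`` restricts the alignment to that many bp of flank on
    each side (boundary corrections are local; aligning kilobase flanks is
    wasted work).  ``tsd`` (e.g. "TA") trims a target-site duplication from
    both refined ends when present on both: TSDs are identical across
    copies, so conservation alone cannot separate them from the element.

    Note: if copies share flanking sequence beyond the element (e.g. a
    segmental duplication), the boundary extends into the shared flank —
    an inherent limitation of alignment-based boundary calling.
    """
    if len(copies) < 2:
        warnings.warn("refine_boundaries needs >= 2 copies; returning input")
        return list(copies)
    from .align import center_star_msa

    if flank_window is not None:
        lf = [c.left_flank[len(c.left_flank) - min(flank_window,
                                                   len(c.left_flank)):]
              for c in copies]
        rf = [c.right_flank[:flank_window] for c in copies]
    else:
        lf = [c.left_flank for c in copies]
        rf = [c.right_flank for c in copies]
    ext = [lf[i] + c.element_sequence + rf[i]
           for i, c in enumerate(copies)]
    cores = [(len(lf[i]), len(lf[i]) + len(c.element_sequence))
             for i, c in enumerate(copies)]
    msa = center_star_msa(ext, labels=[str(i) for i in range(len(ext))])
    rows = msa.rows
    width = len(rows[0])
    agree = _column_agreement(rows)

    # per-row map: column -> number of residues consumed before that column
    consumed = np.zeros((len(rows), width + 1), dtype=np.int64)
    for r, row in enumerate(rows):
        gaps = np.frombuffer(row.encode(), dtype=np.uint8) != ord("-")
        consumed[r, 1:] = np.cumsum(gaps)

    def col_of(row_idx: int, residue_idx: int) -> int:
        return int(np.searchsorted(consumed[row_idx], residue_idx + 1))

    core_cols = [(col_of(r, cores[r][0]), col_of(r, cores[r][1] - 1))
                 for r in range(len(rows))]
    mid = int(np.median([(a + b) // 2 for a, b in core_cols]))

    def smoothed(c: int, direction: int) -> float:
        """Mean agreement over the nearest ``window`` informative columns
        inward of c (NaN/indel columns are skipped, not penalised)."""
        vals = []
        pos = c
        step = 1 if direction < 0 else -1      # inward
        while 0 <= pos < width and len(vals) < window:
            if not np.isnan(agree[pos]):
                vals.append(agree[pos])
            pos += step
        return float(np.mean(vals)) if vals else 1.0

    def solid(c: int) -> bool:
        return 0 <= c < width and not np.isnan(agree[c]) \
            and agree[c] >= edge_frac

    # a column is an acceptable edge only if it and its inward neighbour
    # are individually conserved AND the inward neighbourhood is strongly
    # conserved on average — global alignment matches random flanks at well
    # above background, so isolated agreeing flank columns must be rejected
    inner_frac = min(0.95, edge_frac + 0.05)

    def edge_ok(c: int, direction: int) -> bool:
        inward = 1 if direction < 0 else -1
        return (solid(c) and solid(c + inward)
                and _inward_mean(agree, c, inward, 10, width) >= inner_frac)

    left = mid
    while left > 0 and smoothed(left - 1, -1) >= boundary_frac:
        left -= 1
    while left < mid and not edge_ok(left, -1):
        left += 1
    right = mid
    while right < width - 1 and smoothed(right + 1, +1) >= boundary_frac:
        right += 1
    while right > mid and not edge_ok(right, +1):
        right -= 1

    # column-level boundaries -> per-copy residue offsets
    deltas: list[tuple[int, int]] = []
    for r, copy in enumerate(copies):
        new_s = int(consumed[r, left])              # residues before column
        new_e = int(consumed[r, right + 1])         # residues through column
        dl = len(lf[r]) - new_s                     # >0: grew into left flank
        dr = new_e - (len(lf[r]) + len(copy.element_sequence))
        deltas.append((dl, dr))

    # per-copy realignment to the family edge consensus: gap wander in the
    # MSA shifts individual rows by a few bp, so re-anchor each copy's
    # boundary on the majority sequence of the outermost element columns
    def column_consensus(start_col: int, step: int, length: int) -> str:
        out = []
        c = start_col
        while 0 <= c < width and len(out) < length:
            col = [row[c] for row in rows]
            col = [x for x in col if x != "-"]
            if len(col) >= max(2, len(rows) // 2):
                out.append(max(set(col), key=col.count))
            c += step
        return "".join(out)

    anchor_len = 12
    left_anchor = column_consensus(left, +1, anchor_len)
    right_anchor = column_consensus(right, -1, anchor_len)[::-1]

    anchored_left = [False] * len(copies)
    anchored_right = [False] * len(copies)

    def realign(r: int, dl: int, dr: int) -> tuple[int, int]:
        full = lf[r] + copies[r].element_sequence + rf[r]
        s = len(lf[r]) - dl
        e = len(lf[r]) + len(copies[r].element_sequence) + dr
        best = (4, 0)
        for shift in sorted(range(-6, 7), key=abs):
            cand = full[s + shift:s + shift + anchor_len]
            if len(cand) == anchor_len:
                mm = sum(1 for x, y in zip(cand, left_anchor) if x != y)
                if mm < best[0]:
                    best = (mm, shift)
        anchored_left[r] = best[0] <= 3
        dl -= best[1]
        best = (4, 0)
        for shift in sorted(range(-6, 7), key=abs):
            cand = full[e + shift - anchor_len:e + shift]
            if len(cand) == anchor_len:
                mm = sum(1 for x, y in zip(cand, right_anchor) if x != y)
                if mm < best[0]:
                    best = (mm, shift)
        anchored_right[r] = best[0] <= 3
        dr += best[1]
        return dl, dr

    deltas = [realign(r, dl, dr) for r, (dl, dr) in enumerate(deltas)]

    # Residue-level edge polish.  Column agreement degrades at the element
    # ends: truncated copies' random flanks get glued onto the outermost
    # conserved columns by the aligner, and random flanks of intact copies
    # match each other well above background.  So the edges are re-walked
    # on raw residues, voting only over rows that anchored cleanly to the
    # family edge consensus, with a maximal-scoring-segment rule (each
    # step scores majority_fraction - 0.7; the boundary moves to the
    # argmax, a 1.5 x-drop bounds the walk).
    def edge_base(r: int, side: int, offset: int) -> str | None:
        """Residue ``offset`` bases outward of row r's current boundary
        (offset >= 1), or inward for offset <= 0."""
        dl, dr = deltas[r]
        full = lf[r] + copies[r].element_sequence + rf[r]
        if side < 0:
            pos = len(lf[r]) - dl - offset
        else:
            pos = (len(lf[r]) + len(copies[r].element_sequence)
                   + dr - 1 + offset)
        return full[pos] if 0 <= pos < len(full) else None

    cut, xdrop, max_walk = 0.7, 1.5, 400
    min_voters = max(2, int(np.ceil(0.3 * len(copies))))
    for side in (-1, +1):
        voters = [r for r in range(len(copies))
                  if (anchored_left if side < 0 else anchored_right)[r]]
        if len(voters) < min_voters:
            continue

        def walk(direction: int) -> int:
            """Best shift in ``direction`` (+1 outward, -1 inward)."""
            score = best = 0.0
            best_step = 0
            for step in range(1, max_walk):
                off = step if direction > 0 else 1 - step
                bases = [edge_base(r, side, off) for r in voters]
                bases = [b for b in bases if b is not None]
                if len(bases) < min_voters:
                    break
                frac = max(bases.count(b) for b in set(bases)) / len(bases)
                score += (frac - cut) if direction > 0 else (cut - frac)
                if score > best:
                    best = score
                    best_step = step
                if score < best - xdrop:
                    break
            return best_step

        shift = walk(+1)
        if shift == 0:
            shift = -walk(-1)
        if shift:
            for r in voters:
                dl, dr = deltas[r]
                if side < 0:
                    deltas[r] = (dl + shift, dr)
                else:
                    deltas[r] = (dl, dr + shift)

    if tsd:
        # snap boundaries so the target-site duplication abuts them: TSDs
        # are the family's boundary definition, and being shared sequence
        # they defeat pure conservation-based calling.  The shift is chosen
        # collectively (the copies vote) so a chance TA in one copy's flank
        # cannot displace that copy's boundary.
        w = len(tsd)
        shift_range = range(-(w + 2), w + 3)

        def tsd_match(r: int, side: int, shift: int) -> bool:
            copy = copies[r]
            full = copy.left_flank + copy.element_sequence + copy.right_flank
            dl, dr = deltas[r]
            if side < 0:
                pos = len(copy.left_flank) - dl + shift
                return pos - w >= 0 and full[pos - w:pos] == tsd
            pos = (len(copy.left_flank) + len(copy.element_sequence)
                   + dr + shift)
            return pos + w <= len(full) and full[pos:pos + w] == tsd

        min_support = max(2, round(0.3 * len(copies)))
        for side in (-1, +1):
            support = {sh: sum(tsd_match(r, side, sh)
                               for r in range(len(copies)))
                       for sh in shift_range}
            best_shift = max(shift_range,
                             key=lambda sh: (support[sh], -abs(sh)))
            if support[best_shift] >= min_support:
                for r in range(len(copies)):
                    if tsd_match(r, side, best_shift):
                        dl, dr = deltas[r]
                        if side < 0:
                            deltas[r] = (dl - best_shift, dr)
                        else:
                            deltas[r] = (dl, dr + best_shift)

    refined: list[TECopy] = []
    for r, copy in enumerate(copies):
        dl, dr = deltas[r]
        full = copy.left_flank + copy.element_sequence + copy.right_flank
        s_full = len(copy.left_flank) - dl
        e_full = len(copy.left_flank) + len(copy.element_sequence) + dr
        if copy.strand == "-":
            g_start, g_end = copy.start - dr, copy.end + dl
        else:
            g_start, g_end = copy.start - dl, copy.end + dr
        refined.append(replace(
            copy, start=g_start, end=g_end,
            element_sequence=full[s_full:e_full],
            left_flank=full[:s_full], right_flank=full[e_full:],
            tir=None, tsd=None, orf=None, classification=None))
    return refined


# ---------------------------------------------------------------------------
# TIR / TSD detection
# ---------------------------------------------------------------------------

def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def detect_tir(copy: TECopy | str, min_len: int = 10, max_len: int = 100,
               max_mismatch_frac: float = 0.15, search_window: int = 120,
               allow_offset: bool = False) -> TirAnnotation | None:
    """Find the terminal-inverted-repeat arm pair of an element.

    Scores every candidate (left offset, right offset, arm length) with
    arm_length - 3 * mismatches, requiring mismatches <= max_mismatch_frac *
    length; by default arms are anchored at the element termini (offset 0,
    TIRs abut the TSDs), with an offset search inside ``search_window``
    available via ``allow_offset``.  Ties prefer the longer arm, then the
    leftmost offsets.  Returns None when no acceptable pair exists.
    """
    seq = copy.element_sequence if isinstance(copy, TECopy) else copy
    n = len(seq)
    if n < 2 * min_len:
        raise ValueError("element shorter than twice the minimum arm length")
    max_len = min(max_len, n // 2)
    offsets = range(search_window) if allow_offset else (0,)
    best = None
    best_key = None
    for length in range(min_len, max_len + 1):
        allowed = int(max_mismatch_frac * length)
        for lo in offsets:
            if lo + length > min(search_window, n):
                break
            left_arm = seq[lo:lo + length]
            for ro in offsets:
                if ro + length > min(search_window, n):
                    break
                right_arm = seq[n - ro - length:n - ro]
                mm = _mismatches(left_arm, revcomp(right_arm))
                if mm > allowed:
                    continue
                key = (length - 3 * mm, length, -lo, -ro)
                if best_key is None or key > best_key:
                    best_key = key
                    best = TirAnnotation(
                        left_start=lo, left_end=lo + length,
                        right_start=n - ro - length, right_end=n - ro,
                        length=length, mismatches=mm,
                        pentamer=left_arm[:5])
    return best


def detect_tsd(copy: TECopy, expected: str = "TA") -> TsdAnnotation:
    """Read the putative TSDs: last 2 bp of the left flank and first 2 bp of
    the right flank; match iff both equal ``expected``."""
    w = len(expected)
    left = copy.left_flank[-w:] if len(copy.left_flank) >= w else None
    right = copy.right_flank[:w] if len(copy.right_flank) >= w else None
    match = left == expected and right == expected
    return TsdAnnotation(left=left, right=right, match=match)


# ---------------------------------------------------------------------------
# ORF and protein motifs
# ---------------------------------------------------------------------------

def _orfs_in_frame(seq: str, frame: int):
    """Yield (start, end, protein) for ATG..stop spans in one frame; the
    interval includes the stop codon."""
    n = len(seq)
    start = None
    for pos in range(frame, n - 2, 3):
        codon = seq[pos:pos + 3]
        aa = translate(codon)
        if start is None:
            if codon == "ATG":
                start = pos
        elif aa == "*":
            yield start, pos + 3, translate(seq[start:pos])
            start = None


def find_orf(element_sequence: str, min_aa: int = 100,
             both_strands: bool = False) -> OrfAnnotation | None:
    """Longest ATG-initiated, stop-terminated reading frame on the element
    strand (ties broken by leftmost start); None if below ``min_aa``."""
    if not element_sequence:
        raise ValueError("empty element sequence")
    seq = element_sequence.upper()
    candidates = []
    for frame in range(3):
        for start, end, protein in _orfs_in_frame(seq, frame):
            if len(protein) >= min_aa:
                candidates.append((len(protein), -start, start, end,
                                   protein, "+"))
    if both_strands:
        rc = revcomp(seq)
        for frame in range(3):
            for start, end, protein in _orfs_in_frame(rc, frame):
                if len(protein) >= min_aa:
                    g_start, g_end = len(seq) - end, len(seq) - start
                    candidates.append((len(protein), -g_start, g_start,
                                       g_end, protein, "-"))
    if not candidates:
        return None
    candidates.sort(reverse=True)
    _, _, start, end, protein, _ = candidates[0]
    return OrfAnnotation(start=start, end=end, protein=protein)


def detect_dde(protein: str, family_spacing: int = DEFAULT_FAMILY_SPACING,
               d2_e_spacings_allowed: frozenset[int] = DEFAULT_SPACINGS,
               d1_d2_window: tuple[int, int] = (60, 110),
               region_frac: float = 0.6) -> TriadSpec | None:
    """Locate a D..D..E catalytic triad in the C-terminal region.

    The glutamate must lie within the C-terminal ``region_frac`` of the
    protein; the D2-E spacing (residues strictly between) must be in
    ``d2_e_spacings_allowed`` (sister-family labels included so DD34E/Tc1
    -like triads are reported as such), and the D1-D2 spacing within
    ``d1_d2_window``.  Among candidates the requested family spacing wins,
    then the closest spacing, then the most N-terminal glutamate; D1 is the
    aspartate closest to D2.  Requires >= 100 residues.
    """
    if len(protein) < 100:
        return None
    protein = protein.upper()
    n = len(protein)
    region_start = n - int(np.ceil(region_frac * n))
    lo, hi = d1_d2_window
    candidates: list[TriadSpec] = []
    for e_idx, aa in enumerate(protein):
        if aa != "E" or e_idx < region_start:
            continue
        for spacing in sorted(d2_e_spacings_allowed):
            d2_idx = e_idx - spacing - 1
            if d2_idx < 1 or protein[d2_idx] != "D":
                continue
            for d1_idx in range(d2_idx - lo - 1, d2_idx - hi - 2, -1):
                if d1_idx < 0:
                    break
                if protein[d1_idx] == "D":
                    candidates.append(TriadSpec(d1=d1_idx + 1, d2=d2_idx + 1,
                                                e=e_idx + 1))
                    break
    if not candidates:
        return None
    candidates.sort(key=lambda tr: (tr.spacing != family_spacing,
                                    abs(tr.spacing - family_spacing), tr.e))
    return candidates[0]


def detect_grpr(protein: str) -> int | None:
    """Leftmost exact GRPR motif, if it falls in the N-terminal half
    (0-based residue index); None otherwise."""
    idx = protein.upper().find("GRPR")
    if idx == -1 or idx >= len(protein) / 2:
        return None
    return idx


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_element(copy: TECopy,
                     aa_range: tuple[int, int] = DEFAULT_AA_RANGE,
                     family_spacing: int = DEFAULT_FAMILY_SPACING) -> str:
    """Classify an annotated copy as intact / full_length / truncated.

    full_length: both TIR arms detected and both TSDs match TA.
    intact: full_length and the ORF encodes a transposase within
    ``aa_range`` whose triad has the family D2-E spacing.
    """
    full_length = (copy.tir is not None and copy.tsd is not None
                   and copy.tsd.match)
    intact = False
    if full_length and copy.orf is not None:
        n_aa = len(copy.orf.protein)
        triad = copy.orf.triad
        intact = (aa_range[0] <= n_aa <= aa_range[1]
                  and triad is not None and triad.spacing == family_spacing)
    copy.classification = ("intact" if intact
                           else "full_length" if full_length
                           else "truncated")
    return copy.classification


def annotate_copy(copy: TECopy, min_orf_aa: int = 100,
                  aa_range: tuple[int, int] = DEFAULT_AA_RANGE,
                  family_spacing: int = DEFAULT_FAMILY_SPACING,
                  **tir_params) -> TECopy:
    """Run the full structural annotation on one copy, in place."""
    try:
        copy.tir = detect_tir(copy, **tir_params)
    except ValueError:
        copy.tir = None
    copy.tsd = detect_tsd(copy)
    orf = find_orf(copy.element_sequence, min_aa=min_orf_aa)
    if orf is not None:
        triad = detect_dde(orf.protein, family_spacing=family_spacing)
        grpr = detect_grpr(orf.protein)
        orf = replace(orf, triad=triad, grpr_position=grpr)
    copy.orf = orf
    classify_element(copy, aa_range=aa_range, family_spacing=family_spacing)
    return copy
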