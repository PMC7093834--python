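"""Kimura two-parameter distances and repeat divergence landscapes.

The landscape (coverage in kb per 1% divergence bin between each copy and
the family consensus) is the standard way to read a repeat family's
amplification history: a unimodal low-divergence peak marks a single recent
wave, multiple modes mark repeated invasions.  Species with fewer than ten
copies are excluded, matching common practice for these plots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .align import global_align

__all__ = [
    "SiteCounts",
    "SaturatedDistanceError",
    "DivergenceLandscape",
    "count_site_differences",
    "kimura2p",
    "k2p_from_pair",
    "landscape",
    "recent_invasion_call",
]

_VALID = frozenset("ACGT")
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class SaturatedDistanceError(ValueError):
    """The K2P distance is undefined (log argument <= 0): the pair is
    saturated and no finite distance can be reported."""


@dataclass(frozen=True)
class SiteCounts:
    """Transition (P) / transversion (Q) difference fractions over the
    comparable (both-residue, unambiguous) columns of an aligned pair."""

    p: float
    q: float
    n_sites: int

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("no comparable sites")
        if self.p < 0 or self.q < 0 or self.p + self.q > 1 + 1e-12:
            raise ValueError("invalid site fractions")


def count_site_differences(row_a: str, row_b: str) -> SiteCounts:
    """Count transition/transversion differences between two aligned rows.

    Transitions are A<->G and C<->T; all other differing pairs are
    transversions.  Columns containing a gap or any ambiguity code are
    excluded from both numerator and denominator.
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows differ in length")
    n = ts = tv = 0
    for x, y in zip(row_a.upper(), row_b.upper()):
        if x not in _VALID or y not in _VALID:
            continue
        n += 1
        if x != y:
            if (x, y) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise ValueError("zero comparable columns")
    return SiteCounts(p=ts / n, q=tv / n, n_sites=n)


def kimura2p(counts: SiteCounts) -> float:
    """Kimura 2-parameter distance K = -1/2 ln[(1-2P-Q) sqrt(1-2Q)].

    Raises :class:`SaturatedDistanceError` when the correction diverges
    (1-2P-Q <= 0 or 1-2Q <= 0).
    """
    w1 = 1.0 - 2.0 * counts.p - counts.q
    w2 = 1.0 - 2.0 * counts.q
    if w1 <= 0 or w2 <= 0:
        raise SaturatedDistanceError(
            f"saturated pair: P={counts.p:.4f}, Q={counts.q:.4f}")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_from_pair(seq_a: str, seq_b: str, aligned: bool = False) -> float:
    """K2P distance between two sequences (globally aligned first unless
    ``aligned`` is set)."""
    if aligned:
        return kimura2p(count_site_differences(seq_a, seq_b))
    aln = global_align(seq_a.upper(), seq_b.upper())
    return kimura2p(count_site_differences(aln.a, aln.b))


@dataclass
class DivergenceLandscape:
    """Coverage (kb) per Kimura-divergence bin for one species."""

    species: str
    bin_edges: np.ndarray          # percent K, len = n_bins + 1
    coverage_kb: np.ndarray        # kb per bin
    total_copies: int
    excluded: bool
    n_saturated: int = 0
    copy_divergences: list[float] = field(default_factory=list)  # K per copy
    copy_lengths_kb: list[float] = field(default_factory=list)

    @property
    def total_kb(self) -> float:
        return float(self.coverage_kb.sum())

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "bin_low": self.bin_edges[:-1],
            "bin_high": self.bin_edges[1:],
            "coverage_kb": self.coverage_kb,
        })

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.bar(self.bin_edges[:-1], self.coverage_kb,
               width=np.diff(self.bin_edges), align="edge", **kwargs)
        ax.set_xlabel("Kimura divergence (%)")
        ax.set_ylabel("coverage (kb)")
        ax.set_title(self.species)
        return ax


def landscape(copies: Sequence, reference: str, species: str = "",
              bin_width: float = 1.0, min_copies: int = 10
              ) -> DivergenceLandscape:
    """Divergence landscape of a copy set against its consensus.

    Each copy is globally aligned to the reference; its K2P divergence bin
    (percent, ``bin_width`` wide) receives the copy's length in kb.
    Species with fewer than ``min_copies`` copies are marked excluded
    (their histogram is still computed).  Saturated copies are counted but
    contribute no coverage.
    """
    if not reference:
        raise ValueError("empty reference")
    seqs = [c.element_sequence if hasattr(c, "element_sequence") else c
            for c in copies]
    ks: list[float] = []
    lens: list[float] = []
    n_saturated = 0
    for seq in seqs:
        try:
            k = k2p_from_pair(seq, reference)
        except SaturatedDistanceError:
            n_saturated += 1
            continue
        ks.append(k)
        lens.append(len(seq) / 1000.0)
    top = max([100.0 * k for k in ks], default=0.0)
    n_bins = max(1, int(math.floor(top / bin_width)) + 1)
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    coverage = np.zeros(n_bins)
    for k, kb in zip(ks, lens):
        coverage[min(int(100.0 * k // bin_width), n_bins - 1)] += kb
    return DivergenceLandscape(
        species=species, bin_edges=edges, coverage_kb=coverage,
        total_copies=len(seqs), excluded=len(seqs) < min_copies,
        n_saturated=n_saturated, copy_divergences=ks, copy_lengths_kb=lens)


def recent_invasion_call(land: DivergenceLandscape,
                         threshold: float = 0.05) -> bool:
    """True iff the coverage-weighted median copy divergence is below
    ``threshold`` (substitutions/site; 0.05 = the '<5%' convention)."""
    if land.excluded:
        raise ValueError(f"landscape for {land.species!r} is excluded "
                         f"(fewer than the minimum copies)")
    order = np.argsort(land.copy_divergences)
    ks = np.asarray(land.copy_divergences)[order]
    weights = np.asarray(land.copy_lengths_kb)[order]
    cum = np.cumsum(weights)
    median_k = float(ks[np.searchsorted(cum, cum[-1] / 2.0)])
    return median_k < threshold
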