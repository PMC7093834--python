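"""Horizontal-transfer inference from TE vs host-gene distance contrasts.

The signal: transposon copies moving horizontally between long-diverged
hosts show cross-species TE distances far below the distance of a slowly
evolving single-copy host gene (a RAG1-like yardstick), which tracks the
hosts' divergence time.  A pair is flagged when the hosts split at least
``min_time_ma`` ago and d_TE < alpha * d_host.  Patchy presence/absence on
the species tree (many Dollo losses required under vertical inheritance)
is scored as corroborating evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .divergence import SaturatedDistanceError, count_site_differences, kimura2p
from .simulate import SpeciesTree, TreeNode

__all__ = [
    "DistanceContrast",
    "pairwise_distance_matrix",
    "ht_test",
    "patchiness_score",
    "ht_report",
]


@dataclass(frozen=True)
class DistanceContrast:
    """Per species pair: TE distance, host-gene distance, divergence time.

    ``ht_flag`` is None when any of the three quantities is missing or the
    TE pair is saturated (the pair is still reported).
    """

    species_a: str
    species_b: str
    d_te: float | None
    d_host: float | None
    divergence_time_ma: float | None
    ht_flag: bool | None
    cluster: str | None = None

    @property
    def ratio(self) -> float | None:
        if self.d_te is None or not self.d_host:
            return None
        return self.d_te / self.d_host


def pairwise_distance_matrix(seqs: Mapping[str, str] | Sequence[str],
                             labels: Sequence[str] | None = None,
                             aligned: bool = True) -> pd.DataFrame:
    """Symmetric K2P distance matrix with pairwise deletion of gap and
    ambiguous columns; saturated pairs are NaN.

    ``seqs`` maps labels to rows of one multiple alignment (equal length)
    unless ``aligned`` is False, in which case each pair is globally
    aligned first.
    """
    if isinstance(seqs, Mapping):
        labels = list(seqs)
        rows = [seqs[lab] for lab in labels]
    else:
        rows = list(seqs)
        labels = list(labels) if labels is not None \
            else [f"seq{i}" for i in range(len(rows))]
    if len(rows) < 2:
        raise ValueError("need >= 2 sequences")
    n = len(rows)
    mat = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        try:
            if aligned:
                if len(rows[i]) != len(rows[j]):
                    raise ValueError("aligned rows differ in length; pass "
                                     "aligned=False for unaligned input")
                d = kimura2p(count_site_differences(rows[i], rows[j]))
            else:
                from .divergence import k2p_from_pair
                d = k2p_from_pair(rows[i], rows[j])
        except SaturatedDistanceError:
            d = np.nan
        mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


def ht_test(d_te: pd.DataFrame, d_host: pd.DataFrame, times: pd.DataFrame,
            alpha: float = 0.5, min_time_ma: float = 100.0,
            clusters: Mapping[str, str] | None = None
            ) -> list[DistanceContrast]:
    """Flag species pairs whose TE distance contradicts vertical descent.

    A pair is flagged iff divergence_time >= min_time_ma AND
    d_TE < alpha * d_host.  All pairs over the TE matrix's label set are
    reported; pairs with a missing host-gene entry or saturated TE distance
    get ht_flag None.  ``alpha`` and ``min_time_ma`` are analysis defaults
    of this package, not published constants; report them with results.
    """
    species = list(d_te.index)
    out: list[DistanceContrast] = []
    for a, b in combinations(species, 2):
        dte = float(d_te.loc[a, b])
        dte_v = None if np.isnan(dte) else dte
        dhost = None
        if a in d_host.index and b in d_host.columns:
            val = float(d_host.loc[a, b])
            dhost = None if np.isnan(val) else val
        t = None
        if a in times.index and b in times.columns:
            tv = float(times.loc[a, b])
            t = None if np.isnan(tv) else tv
        if dte_v is None or dhost is None or t is None:
            flag = None
        else:
            flag = t >= min_time_ma and dte_v < alpha * dhost
        cluster = None
        if clusters is not None:
            ca, cb = clusters.get(a), clusters.get(b)
            cluster = ca if ca == cb else None
        out.append(DistanceContrast(
            species_a=a, species_b=b, d_te=dte_v, d_host=dhost,
            divergence_time_ma=t, ht_flag=flag, cluster=cluster))
    return out


def patchiness_score(presence: Mapping[str, bool],
                     tree: SpeciesTree) -> int:
    """Dollo-parsimony loss count for a presence/absence pattern.

    Assumes a single gain at the MRCA of all present species and counts the
    minimum number of loss events (maximal absent clades within that MRCA's
    clade) required to explain the absences.  Higher = patchier = harder to
    reconcile with vertical inheritance.
    """
    unknown = set(presence) - set(tree.species)
    if unknown:
        raise KeyError(f"species not in tree: {sorted(unknown)}")
    present = {sp for sp in tree.species if presence.get(sp, False)}
    if not present:
        raise ValueError("no species with the family present")

    def find_mrca(node: TreeNode) -> TreeNode | None:
        tips = {leaf.name for leaf in node.leaves()}
        if not present <= tips:
            return None
        for child in node.children:
            deeper = find_mrca(child)
            if deeper is not None:
                return deeper
        return node

    mrca = find_mrca(tree.root)

    def losses(node: TreeNode) -> int:
        tips = {leaf.name for leaf in node.leaves()}
        if not tips & present:
            return 1          # one loss explains this whole absent clade
        if node.is_leaf:
            return 0
        return sum(losses(child) for child in node.children)

    return losses(mrca)


def ht_report(contrasts: Sequence[DistanceContrast]
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate distance contrasts: per-pair rows sorted by d_TE/d_host
    ratio, and mean +/- sd summaries overall and per cluster.

    Returns (pairs, summary).
    """
    if not contrasts:
        raise ValueError("no contrasts to report")
    rows = []
    for c in contrasts:
        rows.append({
            "species_a": c.species_a, "species_b": c.species_b,
            "d_te": c.d_te, "d_host": c.d_host,
            "divergence_time_ma": c.divergence_time_ma,
            "ratio": c.ratio, "ht_flag": c.ht_flag, "cluster": c.cluster,
        })
    pairs = pd.DataFrame(rows)
    pairs = pairs.sort_values(
        ["ratio", "species_a", "species_b"], na_position="last",
        kind="mergesort").reset_index(drop=True)

    def summarize(df: pd.DataFrame, name: str) -> dict:
        return {
            "group": name,
            "n_pairs": len(df),
            "d_te_mean": df["d_te"].mean(), "d_te_sd": df["d_te"].std(),
            "d_host_mean": df["d_host"].mean(),
            "d_host_sd": df["d_host"].std(),
            "n_flagged": int((df["ht_flag"] == True).sum()),  # noqa: E712
        }

    groups = [summarize(pairs, "overall")]
    for cluster, sub in sorted(pairs.groupby("cluster", dropna=True)):
        groups.append(summarize(sub, f"cluster_{cluster}"))
    return pairs, pd.DataFrame(groups)
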