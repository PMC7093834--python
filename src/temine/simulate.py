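"""Synthetic multi-species genomes with planted transposon invasions.

The generator emulates the data regime a Tc1/mariner family study assumes:
species related by a dated ultrametric tree; a ~1.5 kb master element with
terminal inverted repeats (TIRs), CAGTC-type terminal pentamer, TA target-site
duplications and a transposase ORF carrying a DD35E catalytic triad; per-copy
neutral divergence under a Kimura two-rate (transition/transversion)
substitution process; random truncation/decay; and a slower-evolving
single-copy host gene (RAG1-like) per species used as the vertical-inheritance
yardstick.  Every planted copy is recorded in a ground-truth ledger.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._dna import decode, encode, random_dna, revcomp, translate
from .annotate import TriadSpec

__all__ = [
    "SpeciesTree",
    "TreeNode",
    "SubstitutionParams",
    "MasterElementConfig",
    "TEMasterElement",
    "InvasionEvent",
    "SimulationConfig",
    "PlantedCopy",
    "SimTruth",
    "make_species_tree",
    "evolve_sequence",
    "make_master_element",
    "simulate_invasion",
]

# stop codons in all three reading frames; placed around the planted ORF so
# that the ORF finder cannot extend it through flanking sequence
_ORF_GUARD = "TTAATTAATTAA"

_CODONS: dict[str, list[str]] = {}
for _b1 in "TCAG":
    for _b2 in "TCAG":
        for _b3 in "TCAG":
            _codon = _b1 + _b2 + _b3
            _aa = translate(_codon)
            _CODONS.setdefault(_aa, []).append(_codon)
_AA20 = "".join(sorted(set(_CODONS) - {"*"}))


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of an ultrametric species tree; ``age`` in Ma (tips at 0)."""

    age: float
    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out


class SpeciesTree:
    """Rooted, ultrametric, binary tree over species with node ages in Ma.

    The pairwise divergence time of two species is the age of their most
    recent common ancestor.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self.species = [leaf.name for leaf in root.leaves()]
        if len(self.species) != len(set(self.species)):
            raise ValueError("duplicate species labels in tree")

    @property
    def root_age(self) -> float:
        return self.root.age

    def divergence_times(self) -> pd.DataFrame:
        """Symmetric species x species matrix of MRCA ages (Ma)."""
        labels = self.species
        mat = pd.DataFrame(0.0, index=labels, columns=labels)

        def fill(node: TreeNode) -> list[str]:
            if node.is_leaf:
                return [node.name]
            groups = [fill(child) for child in node.children]
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    for a in groups[i]:
                        for b in groups[j]:
                            mat.loc[a, b] = node.age
                            mat.loc[b, a] = node.age
            return [name for grp in groups for name in grp]

        fill(self.root)
        return mat

    def mrca_age(self, names) -> float:
        """Age (Ma) of the most recent common ancestor of ``names``."""
        wanted = set(names)
        unknown = wanted - set(self.species)
        if unknown:
            raise KeyError(f"unknown species: {sorted(unknown)}")

        best: list[float] = []

        def visit(node: TreeNode) -> set[str]:
            tips = set()
            if node.is_leaf:
                tips.add(node.name)
            for child in node.children:
                tips |= visit(child)
            if wanted <= tips and not best:
                best.append(node.age)
            return tips

        visit(self.root)
        return best[0]

    def to_newick(self) -> str:
        def render(node: TreeNode, parent_age: float | None) -> str:
            if node.is_leaf:
                body = node.name
            else:
                body = "(" + ",".join(
                    render(c, node.age) for c in node.children) + ")"
            if parent_age is None:
                return body
            return f"{body}:{parent_age - node.age:g}"

        return render(self.root, None) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        import dendropy

        dtree = dendropy.Tree.get(data=text, schema="newick")
        dtree.calc_node_root_distances()
        depth = max(leaf.root_distance for leaf in dtree.leaf_node_iter())

        def convert(dnode) -> TreeNode:
            age = depth - (dnode.root_distance or 0.0)
            node = TreeNode(age=max(age, 0.0),
                            name=dnode.taxon.label if dnode.taxon else None)
            node.children = [convert(c) for c in dnode.child_nodes()]
            return node

        return cls(convert(dtree.seed_node))


def make_species_tree(n_species: int, root_age: float,
                      seed: int = 0) -> SpeciesTree:
    """Random ultrametric binary tree with ``n_species`` tips.

    Internal-node ages shrink geometrically from the root (each child clade's
    MRCA sits at a uniform fraction of its parent's age), which yields trees
    with both deep and shallow splits.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if root_age <= 0:
        raise ValueError("root_age must be positive")
    rng = np.random.default_rng([int(seed), zlib.crc32(b"tree")])
    names = [f"sp{i + 1:02d}" for i in range(n_species)]

    def build(tips: list[str], age: float) -> TreeNode:
        if len(tips) == 1:
            return TreeNode(age=0.0, name=tips[0])
        perm = [tips[i] for i in rng.permutation(len(tips))]
        split = int(rng.integers(1, len(tips)))
        sides = [sorted(perm[:split]), sorted(perm[split:])]
        node = TreeNode(age=age)
        for side in sides:
            child_age = 0.0 if len(side) == 1 else age * rng.uniform(0.3, 0.85)
            node.children.append(build(side, child_age))
        return node

    return SpeciesTree(build(names, float(root_age)))


# ---------------------------------------------------------------------------
# Kimura two-parameter sequence evolution
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionParams:
    """Parameters of the two-rate (transition/transversion) process.

    kappa       transition/transversion rate ratio (alpha/beta), > 0
    k_target    expected substitutions per site, >= 0
    indel_rate  per-site probability of an indel event, in [0, 1)
    seed        used only when no generator is passed to evolve_sequence
    """

    kappa: float = 2.0
    k_target: float = 0.0
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.k_target < 0:
            raise ValueError("k_target must be >= 0")
        if not 0 <= self.indel_rate < 1:
            raise ValueError("indel_rate must be in [0, 1)")

    def site_probabilities(self) -> tuple[float, float]:
        """Expected transition (P) and transversion (Q) difference fractions.

        With transition rate alpha and per-transversion rate beta over
        exposure t, and K = (alpha + 2 beta) t:

            P = 1/4 + 1/4 e^{-4 beta t} - 1/2 e^{-2 (alpha+beta) t}
            Q = 1/2 - 1/2 e^{-4 beta t}
        """
        bt = self.k_target / (self.kappa + 2.0)
        at = self.kappa * bt
        p = 0.25 + 0.25 * math.exp(-4 * bt) - 0.5 * math.exp(-2 * (at + bt))
        q = 0.5 - 0.5 * math.exp(-4 * bt)
        return p, q


def evolve_sequence(seq: str, params: SubstitutionParams,
                    rng: np.random.Generator | None = None) -> str:
    """Mutate ``seq`` under the K2P process to expected depth ``k_target``.

    Transitions are A<->G and C<->T; the two transversion targets of each
    base are equally likely.  Length changes only through ``indel_rate``.
    """
    if not seq:
        raise ValueError("empty sequence")
    enc = encode(seq)
    if np.any(enc > 3):
        raise ValueError("sequence must be strictly A/C/G/T")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if params.k_target == 0 and params.indel_rate == 0:
        return seq

    p, q = params.site_probabilities()
    u = rng.random(enc.size)
    out = enc.copy()
    out[u < p] = (enc[u < p] + 2) % 4                      # transition
    m1 = (u >= p) & (u < p + q / 2)
    out[m1] = (enc[m1] + 1) % 4                            # transversion
    m2 = (u >= p + q / 2) & (u < p + q)
    out[m2] = (enc[m2] + 3) % 4                            # transversion

    r = params.indel_rate
    if r > 0:
        keep = rng.random(out.size) >= r / 2.0
        out = out[keep]
        ins_at = np.flatnonzero(rng.random(out.size + 1) < r / 2.0)
        if ins_at.size:
            pieces, prev = [], 0
            for pos in ins_at:
                pieces.append(out[prev:pos])
                ln = min(int(rng.geometric(0.5)), 10)
                pieces.append(rng.integers(0, 4, size=ln).astype(np.int8))
                prev = int(pos)
            pieces.append(out[prev:])
            out = np.concatenate(pieces)
    return decode(out)


# ---------------------------------------------------------------------------
# master element
# ---------------------------------------------------------------------------

@dataclass
class MasterElementConfig:
    """Blueprint for a family master element (defaults follow the family's
    published structural ranges: ~1.5 kb element, 304-350 aa transposase,
    13-68 bp TIRs, CAGTC terminus, DD35E triad, TA TSD)."""

    total_length: int = 1550
    length_range: tuple[int, int] = (1072, 2191)
    tir_length: int = 25
    tir_range: tuple[int, int] = (13, 68)
    terminal_pentamer: str = "CAGTC"
    transposase_length: int = 340
    transposase_range: tuple[int, int] = (304, 350)
    d1_d2_spacing: int = 90      # residues strictly between D1 and D2
    d2_e_spacing: int = 35       # residues strictly between D2 and E -> DD35E
    grpr_frac: float = 0.25      # GRPR position as a fraction of protein length
    seed: int = 0


@dataclass
class TEMasterElement:
    """A family master element with fully known structure."""

    full_sequence: str
    tir_length: int
    terminal_pentamer: str
    orf_start: int               # 0-based, includes the stop codon at the end
    orf_end: int
    transposase: str
    triad: TriadSpec
    grpr_position: int           # 0-based residue index
    tsd: str = "TA"

    @property
    def tir_left(self) -> str:
        return self.full_sequence[: self.tir_length]

    @property
    def tir_right(self) -> str:
        return self.full_sequence[-self.tir_length:]

    def validate(self) -> None:
        if self.tir_right != revcomp(self.tir_left):
            raise AssertionError("TIR arms are not reverse complements")
        if not self.tir_left.startswith(self.terminal_pentamer):
            raise AssertionError("left TIR does not start with the pentamer")
        coding = self.full_sequence[self.orf_start:self.orf_end]
        if translate(coding) != self.transposase + "*":
            raise AssertionError("ORF does not translate to the transposase")


def make_master_element(config: MasterElementConfig | None = None,
                        ) -> TEMasterElement:
    """Construct a master element satisfying the family's structural spec.

    The transposase is random except for planted landmarks: an initial M, a
    GRPR motif in the N-terminal region, and a D..D..E catalytic triad in the
    C-terminal region with the configured spacings.  No other D/E residues
    occur in the catalytic region, so triad detection is unambiguous by
    construction.  Stop codons in all frames are placed immediately around
    the ORF so the planted ORF is the element's unique long reading frame.
    """
    cfg = config or MasterElementConfig()
    rng = np.random.default_rng([int(cfg.seed), zlib.crc32(b"master")])

    lo, hi = cfg.tir_range
    if not lo <= cfg.tir_length <= hi:
        raise ValueError(f"tir_length {cfg.tir_length} outside {cfg.tir_range}")
    if cfg.tir_length < len(cfg.terminal_pentamer):
        raise ValueError("TIR shorter than the terminal pentamer")
    if cfg.tir_length > cfg.total_length // 2:
        raise ValueError("TIR longer than half the element")
    lo, hi = cfg.transposase_range
    if not lo <= cfg.transposase_length <= hi:
        raise ValueError("transposase_length outside transposase_range")
    lo, hi = cfg.length_range
    if not lo <= cfg.total_length <= hi:
        raise ValueError("total_length outside length_range")

    n_aa = cfg.transposase_length
    region_start = int(math.floor(0.4 * n_aa))
    e_pos = n_aa - 12
    d2_pos = e_pos - cfg.d2_e_spacing - 1
    d1_pos = d2_pos - cfg.d1_d2_spacing - 1
    if d1_pos <= region_start:
        raise ValueError("triad spacings do not fit the catalytic region")

    aa_all = np.frombuffer(_AA20.encode(), dtype=np.uint8)
    aa_no_de = np.frombuffer(_AA20.replace("D", "").replace("E", "").encode(),
                             dtype=np.uint8)
    prot = np.empty(n_aa, dtype=np.uint8)
    prot[:region_start] = aa_all[rng.integers(0, aa_all.size,
                                              size=region_start)]
    prot[region_start:] = aa_no_de[rng.integers(0, aa_no_de.size,
                                                size=n_aa - region_start)]
    prot[0] = ord("M")
    grpr_pos = int(cfg.grpr_frac * n_aa)
    if not 1 <= grpr_pos <= n_aa // 2 - 4:
        raise ValueError("grpr_frac places GRPR outside the N-terminal half")
    prot[grpr_pos:grpr_pos + 4] = np.frombuffer(b"GRPR", dtype=np.uint8)
    prot[d1_pos] = ord("D")
    prot[d2_pos] = ord("D")
    prot[e_pos] = ord("E")
    protein = prot.tobytes().decode()
    # scrub accidental GRPR occurrences left of the planted one
    while True:
        hit = protein.find("GRPR")
        if hit == grpr_pos:
            break
        protein = protein[:hit] + "A" + protein[hit + 1:]

    codons = [_CODONS[aa][int(rng.integers(0, len(_CODONS[aa])))]
              for aa in protein]
    codons[0] = "ATG"
    orf_nt = "".join(codons) + _CODONS["*"][int(rng.integers(0, 3))]

    core_len = 2 * len(_ORF_GUARD) + len(orf_nt)
    budget = cfg.total_length - 2 * cfg.tir_length - core_len
    if budget < 0:
        raise ValueError("ORF plus guards longer than the element interior")
    utr5 = budget // 2
    utr3 = budget - utr5

    tir_left = cfg.terminal_pentamer + random_dna(
        cfg.tir_length - len(cfg.terminal_pentamer), rng)
    full = (tir_left + random_dna(utr5, rng) + _ORF_GUARD + orf_nt
            + _ORF_GUARD + random_dna(utr3, rng) + revcomp(tir_left))
    orf_start = cfg.tir_length + utr5 + len(_ORF_GUARD)

    triad = TriadSpec(d1=d1_pos + 1, d2=d2_pos + 1, e=e_pos + 1)
    element = TEMasterElement(
        full_sequence=full,
        tir_length=cfg.tir_length,
        terminal_pentamer=cfg.terminal_pentamer,
        orf_start=orf_start,
        orf_end=orf_start + len(orf_nt),
        transposase=protein,
        triad=triad,
        grpr_position=grpr_pos,
    )
    element.validate()
    return element


# ---------------------------------------------------------------------------
# invasion scenarios
# ---------------------------------------------------------------------------

@dataclass
class InvasionEvent:
    """One invasion: copies planted in each recipient species.

    kind='vertical' models inheritance of an ancestral invasion (recipients
    should be the tips of a clade, time_ma at or before their MRCA age);
    kind='ht' models a horizontal transfer into the recipients at time_ma
    (several recipients = one element spreading at that time across hosts).

    ``burst_time_ma`` places the amplification burst: insertions happen
    shortly after that time on each species' terminal branch (default: right
    after the element enters the lineage).  An anciently inherited element
    can thus amplify recently, which is what a low-divergence landscape of
    an old family records.
    """

    recipients: tuple[str, ...]
    time_ma: float
    copies: int
    kind: str = "vertical"          # 'vertical' | 'ht'
    label: str | None = None
    burst_time_ma: float | None = None

    def __post_init__(self):
        if self.copies < 0:
            raise ValueError("negative copy count")
        if self.kind not in ("vertical", "ht"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.label is None:
            self.label = "vertical" if self.kind == "vertical" else "ht"


@dataclass
class SimulationConfig:
    """Genome/invasion simulation parameters.

    Rates are substitutions/site/Ma.  The TE rate default (1.4e-3) and host
    ratio (0.3) put RAG1-like pairwise distances near 0.25 for splits around
    300 Ma, the magnitude regime of published vertebrate host-gene yardsticks.
    """

    contig_length: int = 60_000
    te_rate: float = 1.4e-3
    host_rate_ratio: float = 0.3
    host_gene_length: int = 3000
    kappa: float = 2.0
    indel_rate: float = 5e-4
    p_trunc: float = 0.3
    burst_scale_ma: float = 5.0
    min_retained: int = 100


@dataclass
class PlantedCopy:
    """Ground-truth record of one planted insertion.

    ``age_k`` is the copy's expected substitution depth from the master
    element (lineage drift since the invasion plus dead-copy drift — the
    quantity a master-query search sees).  ``insertion_time_ma`` is when the
    copy stopped moving; te_rate * insertion_time_ma is its expected
    divergence from the species' contemporary element lineage, the quantity
    a divergence landscape reads.
    """

    species: str
    contig: str
    start: int                    # 0-based half-open, element only (no TSD)
    end: int
    strand: str
    age_k: float
    insertion_time_ma: float
    truncated: bool
    retained_start: int           # retained interval in untruncated-copy coords
    retained_end: int
    scenario: str


class SimTruth:
    """Ledger of all planted copies, with tabular export."""

    def __init__(self, records: list[PlantedCopy]):
        self.records = records

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def for_species(self, species: str) -> list[PlantedCopy]:
        return [r for r in self.records if r.species == species]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])

    def to_bed(self) -> str:
        lines = []
        for r in self.records:
            lines.append(f"{r.contig}\t{r.start}\t{r.end}\t"
                         f"{r.species}:{r.scenario}\t0\t{r.strand}")
        return "\n".join(lines) + ("\n" if lines else "")


def _species_rng(seed: int, species: str) -> np.random.Generator:
    return np.random.default_rng([int(seed),
                                  zlib.crc32(species.encode("ascii"))])


def _evolve_host_gene(tree: SpeciesTree, root_seq: str, rate: float,
                      kappa: float, rng: np.random.Generator
                      ) -> dict[str, str]:
    out: dict[str, str] = {}

    def descend(node: TreeNode, seq: str) -> None:
        for child in node.children:
            k = rate * (node.age - child.age)
            child_seq = evolve_sequence(
                seq, SubstitutionParams(kappa=kappa, k_target=k), rng)
            if child.is_leaf:
                out[child.name] = child_seq
            else:
                descend(child, child_seq)

    descend(tree.root, root_seq)
    return out


def _repair_functional(child: str, parent: str, master: "TEMasterElement",
                       rng: np.random.Generator,
                       aa_revert: float = 0.7) -> str:
    """Crude purifying selection on an active element lineage.

    Lineage (not dead-copy) evolution reverts substitutions that would
    inactivate the element: every in-frame stop codon in the transposase
    ORF, loss of the start codon, changes to the catalytic-triad or GRPR
    codons, changes to the terminal pentamer of either TIR arm — and a
    fraction ``aa_revert`` of all other amino-acid-changing codons, since
    most nonsynonymous changes in a protein kept active are purged.  The
    right TIR arm is kept the reverse complement of the (drifting) left
    arm: transposase binding maintains arm complementarity.  Everything
    else drifts neutrally.  Requires child/parent of equal length (lineage
    steps are substitution-only).
    """
    seq = list(child)
    n = len(seq)
    p = len(master.terminal_pentamer)
    seq[:p] = parent[:p]
    seq[n - p:] = parent[n - p:]
    t = master.tir_length
    seq[n - t:] = revcomp("".join(seq[:t]))
    o = master.orf_start
    seq[o:o + 3] = parent[o:o + 3]                      # ATG
    protected = [master.triad.d1 - 1, master.triad.d2 - 1,
                 master.triad.e - 1]
    protected += list(range(master.grpr_position, master.grpr_position + 4))
    for aa_idx in protected:
        s = o + 3 * aa_idx
        seq[s:s + 3] = parent[s:s + 3]
    for s in range(o, master.orf_end - 3, 3):           # internal codons
        codon = "".join(seq[s:s + 3])
        if codon == parent[s:s + 3]:
            continue
        if codon in ("TAA", "TAG", "TGA"):
            seq[s:s + 3] = parent[s:s + 3]
        elif translate(codon) != translate(parent[s:s + 3]) \
                and rng.random() < aa_revert:
            seq[s:s + 3] = parent[s:s + 3]
    return "".join(seq)


def _parent_ages(tree: SpeciesTree) -> dict[str, float]:
    """Age of each tip's parent node (top of its terminal branch)."""
    out: dict[str, float] = {}

    def visit(node: TreeNode) -> None:
        for child in node.children:
            if child.is_leaf:
                out[child.name] = node.age
            else:
                visit(child)

    visit(tree.root)
    return out


def _vertical_entry_points(tree: SpeciesTree, ev: InvasionEvent,
                           master: TEMasterElement, rate: float,
                           kappa: float, rng: np.random.Generator
                           ) -> dict[str, tuple[float, str]]:
    """Element lineage states for a vertical (inherited) invasion.

    The element enters the stem of the recipients' MRCA clade at
    ``ev.time_ma`` as the master sequence and drifts along the tree's
    internal branches (shared between descendant species); each recipient's
    entry point is (parent-node age, lineage state at that node) — the top
    of the species-private terminal branch.
    """
    wanted = set(ev.recipients)

    def find_mrca(node: TreeNode) -> TreeNode | None:
        tips = {leaf.name for leaf in node.leaves()}
        if not wanted <= tips:
            return None
        for child in node.children:
            deeper = find_mrca(child)
            if deeper is not None:
                return deeper
        return node

    mrca = find_mrca(tree.root)
    if not mrca.is_leaf and ev.time_ma < mrca.age:
        raise ValueError(
            f"vertical event at {ev.time_ma} Ma predates its recipients: "
            f"their MRCA is at {mrca.age:.1f} Ma")
    out: dict[str, tuple[float, str]] = {}
    if mrca.is_leaf:
        out[mrca.name] = (ev.time_ma, master.full_sequence)
        return out

    def step(state: str, dt: float) -> str:
        nxt = evolve_sequence(state, SubstitutionParams(
            kappa=kappa, k_target=rate * dt), rng)
        return _repair_functional(nxt, state, master, rng)

    stem_state = step(master.full_sequence, ev.time_ma - mrca.age) \
        if ev.time_ma > mrca.age else master.full_sequence

    def descend(node: TreeNode, state: str) -> None:
        for child in node.children:
            if child.is_leaf:
                if child.name in wanted:
                    out[child.name] = (node.age, state)
            else:
                descend(child, step(state, node.age - child.age))

    descend(mrca, stem_state)
    return out


def simulate_invasion(tree: SpeciesTree, master: TEMasterElement,
                      events: list[InvasionEvent],
                      config: SimulationConfig | None = None,
                      seed: int = 0):
    """Plant TE invasions on a species tree; return genomes + truth.

    Returns ``(genomes, host_genes, truth)`` where genomes maps species ->
    {contig: sequence}, host_genes maps species -> sequence, and truth is
    the complete :class:`SimTruth` ledger.

    The element lineage of a vertical event drifts along the species tree
    from the invasion time (shared across descendants until each split);
    a horizontal-transfer event delivers the master directly into each
    recipient's terminal lineage at the transfer time.  Within a species,
    copies branch off the still-active lineage at exponential-burst
    insertion times after the entry point and then decay as dead copies, so
    two species that split T Ma ago carry copies ~2 * te_rate * T apart
    (matching the host gene scaled by the rate ratio) under vertical
    descent, while a recent transfer leaves cross-species copies nearly
    identical.

    Species-private randomness (backgrounds, insertion times, decay,
    truncation, placement) comes from per-species streams derived from the
    master seed, so adding a species leaves other genomes byte-identical;
    the shared lineage drift of a vertical event uses a per-event stream.
    """
    cfg = config or SimulationConfig()
    species_set = set(tree.species)
    for ev in events:
        unknown = set(ev.recipients) - species_set
        if unknown:
            raise KeyError(f"scenario references unknown species: "
                           f"{sorted(unknown)}")

    host_rng = np.random.default_rng([int(seed), zlib.crc32(b"host")])
    host_root = random_dna(cfg.host_gene_length, host_rng)
    host_rate = cfg.host_rate_ratio * cfg.te_rate
    host_genes = _evolve_host_gene(tree, host_root, host_rate,
                                   cfg.kappa, host_rng)

    parent_ages = _parent_ages(tree)
    # entry point per (event, species): (branch_top_age, lineage state)
    entries: list[dict[str, tuple[float, str]]] = []
    for idx, ev in enumerate(events):
        if ev.kind == "vertical" and len(ev.recipients) > 1:
            ev_rng = np.random.default_rng(
                [int(seed), zlib.crc32(f"event{idx}".encode())])
            entries.append(_vertical_entry_points(
                tree, ev, master, cfg.te_rate, cfg.kappa, ev_rng))
        else:
            # single-recipient vertical or horizontal transfer: the element
            # enters each recipient's terminal lineage independently
            entries.append({
                sp: (min(ev.time_ma, parent_ages[sp]),
                     master.full_sequence)
                for sp in ev.recipients})

    genomes: dict[str, dict[str, str]] = {}
    records: list[PlantedCopy] = []
    for sp in tree.species:
        rng = _species_rng(seed, sp)
        background = random_dna(cfg.contig_length, rng)
        contig = f"{sp}_ctg1"

        inserts = []           # (position, genomic_seq, record fields)
        for ev, entry in zip(events, entries):
            if sp not in ev.recipients or ev.copies == 0:
                continue
            branch_top, state = entry[sp]
            burst_at = branch_top if ev.burst_time_ma is None \
                else min(ev.burst_time_ma, branch_top)
            t_ins = burst_at - rng.exponential(cfg.burst_scale_ma,
                                               size=ev.copies)
            t_ins = np.sort(np.clip(t_ins, 0.0, burst_at))[::-1]
            cur_age = branch_top
            for t in t_ins:
                # lineage drift (shared by later copies, under purifying
                # selection on functional sites), then dead decay
                if cur_age > t:
                    nxt = evolve_sequence(
                        state, SubstitutionParams(
                            kappa=cfg.kappa,
                            k_target=cfg.te_rate * (cur_age - t)), rng)
                    state = _repair_functional(nxt, state, master, rng)
                    cur_age = float(t)
                age_k = cfg.te_rate * ev.time_ma
                params = SubstitutionParams(kappa=cfg.kappa,
                                            k_target=cfg.te_rate * float(t),
                                            indel_rate=cfg.indel_rate)
                copy_seq = evolve_sequence(state, params, rng)
                ret_lo, ret_hi = 0, len(copy_seq)
                truncated = rng.random() < cfg.p_trunc
                if truncated:
                    mode = rng.integers(0, 3)   # 0 left, 1 right, 2 both
                    max_cut = (len(copy_seq) - cfg.min_retained) // 2
                    if max_cut < 1:
                        truncated = False
                    else:
                        if mode in (0, 2):
                            ret_lo = int(rng.integers(1, max_cut + 1))
                        if mode in (1, 2):
                            ret_hi = len(copy_seq) - int(
                                rng.integers(1, max_cut + 1))
                body = copy_seq[ret_lo:ret_hi]
                strand = "+" if rng.random() < 0.5 else "-"
                has_left_tsd = ret_lo == 0
                has_right_tsd = ret_hi == len(copy_seq)
                if strand == "-":
                    body = revcomp(body)
                    has_left_tsd, has_right_tsd = has_right_tsd, has_left_tsd
                pos = int(rng.integers(0, len(background)))
                inserts.append((pos, body, has_left_tsd, has_right_tsd,
                                strand, age_k, float(t), truncated,
                                ret_lo, ret_hi, ev.label))

        inserts.sort(key=lambda item: item[0])
        pieces, prev, offset = [], 0, 0
        for (pos, body, ltsd, rtsd, strand, age_k, t_ma, truncated,
             ret_lo, ret_hi, label) in inserts:
            pieces.append(background[prev:pos])
            offset += pos - prev
            if ltsd:
                pieces.append("TA")
                offset += 2
            start = offset
            pieces.append(body)
            offset += len(body)
            records.append(PlantedCopy(
                species=sp, contig=contig, start=start, end=offset,
                strand=strand, age_k=age_k, insertion_time_ma=t_ma,
                truncated=truncated,
                retained_start=ret_lo, retained_end=ret_hi, scenario=label))
            if rtsd:
                pieces.append("TA")
                offset += 2
            prev = pos
        pieces.append(background[prev:])
        genomes[sp] = {contig: "".join(pieces)}

    return genomes, host_genes, SimTruth(records)
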