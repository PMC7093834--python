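"""File formats: FASTA, BED6/GFF3 annotations, TSV tables.

Conventions: BED intervals are 0-based half-open; GFF3 is 1-based
inclusive; FASTA labels are the full header line (spaces included),
sequences are upper-cased on read.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import pandas as pd

from .annotate import TECopy
from .search import Hit

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_annotations",
    "read_gff_intervals",
    "hits_to_frame",
    "write_hits",
    "read_hits",
]


def read_fasta(path) -> dict[str, str]:
    """Read a (possibly line-wrapped, CRLF-tolerant) FASTA file.

    The record label is the full header line after '>'.  Raises ValueError
    naming the offending line on malformed input; returns an empty mapping
    (with a warning) for an empty file.
    """
    out: dict[str, list[str]] = {}
    label = None
    with open(path, "r", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                label = line[1:].strip()
                if not label:
                    raise ValueError(f"{path}: empty FASTA header "
                                     f"at line {lineno}")
                if label in out:
                    raise ValueError(f"{path}: duplicate record {label!r} "
                                     f"at line {lineno}")
                out[label] = []
            else:
                if label is None:
                    raise ValueError(f"{path}: sequence before any header "
                                     f"at line {lineno}")
                out[label].append(line.strip().upper())
    if not out:
        warnings.warn(f"{path}: empty FASTA file")
    return {lab: "".join(parts) for lab, parts in out.items()}


def write_fasta(seqs: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for label, seq in seqs.items():
            fh.write(f">{label}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_annotations(copies: Iterable[TECopy], path,
                      fmt: str = "gff3") -> None:
    """Write annotated copies as GFF3 (1-based inclusive, nested features)
    or BED6 (0-based half-open); identical loci under either convention."""
    copies = list(copies)
    if fmt == "bed":
        with open(path, "w") as fh:
            for i, c in enumerate(copies):
                name = f"te{i + 1}:{c.classification or 'unclassified'}"
                fh.write(f"{c.contig}\t{c.start}\t{c.end}\t{name}\t0\t"
                         f"{c.strand}\n")
        return
    if fmt != "gff3":
        raise ValueError(f"unknown annotation format {fmt!r}")
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(copies):
            te_id = f"te{i + 1}"
            attrs = f"ID={te_id};classification={c.classification}"
            fh.write(f"{c.contig}\ttemine\ttransposable_element\t"
                     f"{c.start + 1}\t{c.end}\t.\t{c.strand}\t.\t{attrs}\n")
            if c.tir is not None:
                for arm, (s, e) in (("left", (c.tir.left_start,
                                              c.tir.left_end)),
                                    ("right", (c.tir.right_start,
                                               c.tir.right_end))):
                    gs, ge = _element_to_genomic(c, s, e)
                    fh.write(f"{c.contig}\ttemine\tterminal_inverted_repeat"
                             f"\t{gs + 1}\t{ge}\t.\t{c.strand}\t.\t"
                             f"ID={te_id}.tir_{arm};Parent={te_id}\n")
            if c.orf is not None:
                gs, ge = _element_to_genomic(c, c.orf.start, c.orf.end)
                label = c.orf.triad.label if c.orf.triad else "none"
                fh.write(f"{c.contig}\ttemine\tORF\t{gs + 1}\t{ge}\t.\t"
                         f"{c.strand}\t.\tID={te_id}.orf;Parent={te_id};"
                         f"triad={label}\n")
            if c.tsd is not None and c.tsd.match:
                for side, (gs, ge) in (("left", (c.start - 2, c.start)),
                                       ("right", (c.end, c.end + 2))):
                    fh.write(f"{c.contig}\ttemine\ttarget_site_duplication"
                             f"\t{gs + 1}\t{ge}\t.\t{c.strand}\t.\t"
                             f"ID={te_id}.tsd_{side};Parent={te_id}\n")


def _element_to_genomic(copy: TECopy, s: int, e: int) -> tuple[int, int]:
    """Map an element-orientation interval to genomic coordinates."""
    if copy.strand == "-":
        length = copy.end - copy.start
        return copy.start + (length - e), copy.start + (length - s)
    return copy.start + s, copy.start + e


def read_gff_intervals(path) -> pd.DataFrame:
    """Parse a GFF3 file back to 0-based half-open intervals."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            rows.append({
                "contig": parts[0], "type": parts[2],
                "start": int(parts[3]) - 1, "end": int(parts[4]),
                "strand": parts[6], "attributes": parts[8],
            })
    return pd.DataFrame(rows)


def hits_to_frame(hits: Iterable[Hit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "contig": h.contig, "start": h.start, "end": h.end,
        "strand": h.strand, "identity": h.identity, "length": h.length,
        "score": h.score,
    } for h in hits])


def write_hits(hits: Iterable[Hit], path, fmt: str = "tsv") -> None:
    """Write hits as a TSV (identity/length columns) or BED6
    (score column = integer alignment score)."""
    hits = list(hits)
    if fmt == "tsv":
        hits_to_frame(hits).to_csv(path, sep="\t", index=False)
    elif fmt == "bed":
        with open(path, "w") as fh:
            for i, h in enumerate(hits):
                fh.write(f"{h.contig}\t{h.start}\t{h.end}\thit{i + 1}\t"
                         f"{int(h.score)}\t{h.strand}\n")
    else:
        raise ValueError(f"unknown hit format {fmt!r}")


def read_hits(path) -> list[Hit]:
    df = pd.read_csv(path, sep="\t")
    return [Hit(contig=row.contig, start=int(row.start), end=int(row.end),
                strand=row.strand, identity=float(row.identity),
                length=int(row.length), score=int(row.score))
            for row in df.itertuples()]
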