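"""Core genomic types and readers/writers for the pipeline's file formats.

Coordinates are 0-based, half-open (BED convention) everywhere.  The types
here — intervals, peaks with summits and read-count scores, ortholog-paired
gene records, chromatin-state segments and FPKM expression tables — are the
substrate of every downstream conservation and modeling operation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "GenomeInterval",
    "Peak",
    "GeneRecord",
    "StateSegment",
    "ExpressionTable",
    "read_peaks",
    "write_peaks",
    "read_gene_table",
    "write_gene_table",
    "read_segmentation",
    "write_segmentation",
    "read_expression",
    "write_expression",
    "merge_intervals",
    "intersect_length",
    "intersect_intervals",
    "total_length",
]


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A half-open genomic span ``[start, end)`` on one chromosome.

    ``strand`` is '+', '-' or '.' (unspecified).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(f"start < end required, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of + - . , got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomeInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def expanded(self, pad: int) -> "GenomeInterval":
        return GenomeInterval(self.chrom, max(0, self.start - pad), self.end + pad, self.strand)


@dataclass
class Peak:
    """A TF occupancy site or mark enrichment peak.

    ``summit`` is an absolute genome position inside the interval; ``score``
    is the total number of mapped reads in the peak region.
    """

    interval: GenomeInterval
    summit: int
    score: float = 0.0
    factor: str = ""
    sample: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.score < 0:
            raise ValueError(f"score must be >= 0, got {self.score}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class GeneRecord:
    """A gene with TSS/TES and an optional one-to-one ortholog partner."""

    gene_id: str
    ortholog_id: str | None
    interval: GenomeInterval
    tss: int
    tes: int
    strand: str

    def __post_init__(self) -> None:
        iv = self.interval
        for pos, label in ((self.tss, "tss"), (self.tes, "tes")):
            if not (iv.start <= pos < iv.end):
                raise ValueError(
                    f"{label} {pos} of {self.gene_id} outside [{iv.start}, {iv.end})"
                )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if self.strand == "-" and self.tss < self.tes:
            raise ValueError(
                f"negative-strand gene {self.gene_id} must have tss >= tes"
            )
        if self.strand == "+" and self.tss > self.tes:
            raise ValueError(
                f"positive-strand gene {self.gene_id} must have tss <= tes"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def body_length(self) -> int:
        return abs(self.tes - self.tss) + 1


@dataclass(frozen=True)
class StateSegment:
    """One chromatin-state interval (state label in ``1..n_states``)."""

    interval: GenomeInterval
    state: int

    def __post_init__(self) -> None:
        if self.state < 1:
            raise ValueError(f"state labels start at 1, got {self.state}")


class ExpressionTable:
    """FPKM values keyed by (gene_id, stage, replicate).

    Thin wrapper over a long-format DataFrame with columns
    ``gene_id, stage, replicate, fpkm``.
    """

    COLUMNS = ("gene_id", "stage", "replicate", "fpkm")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"expression table missing columns: {sorted(missing)}")
        if (df["fpkm"] < 0).any():
            bad = df.loc[df["fpkm"] < 0].iloc[0]
            raise ValueError(f"negative FPKM for gene {bad['gene_id']}")
        # every gene must report every stage it appears in consistently
        counts = df.groupby(["stage"])["gene_id"].nunique()
        if counts.nunique() > 1:
            raise ValueError("every gene_id must be present for every stage")
        self.df = df.reset_index(drop=True)

    @property
    def stages(self) -> list[str]:
        return list(pd.unique(self.df["stage"]))

    @property
    def gene_ids(self) -> list[str]:
        return list(pd.unique(self.df["gene_id"]))

    def stage_means(self, log2: bool = False) -> pd.DataFrame:
        """Genes x stages matrix of replicate-averaged FPKM (optionally log2(1+x))."""
        wide = self.df.pivot_table(
            index="gene_id", columns="stage", values="fpkm", aggfunc="mean"
        )
        wide = wide[self.stages]
        if log2:
            wide = np.log2(1.0 + wide)
        return wide

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# Interval utilities
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[GenomeInterval]) -> list[GenomeInterval]:
    """Union of intervals as a sorted list of disjoint intervals."""
    by_chrom: dict[str, list[GenomeInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomeInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomeInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomeInterval(chrom, cur_s, cur_e))
    return out


def total_length(intervals: Iterable[GenomeInterval]) -> int:
    """Number of distinct bases covered by the intervals."""
    return sum(iv.length for iv in merge_intervals(intervals))


def intersect_intervals(
    a: Iterable[GenomeInterval], b: Iterable[GenomeInterval]
) -> list[GenomeInterval]:
    """Base-wise intersection of two interval sets, as disjoint intervals."""
    am = merge_intervals(a)
    bm = merge_intervals(b)
    out: list[GenomeInterval] = []
    b_by_chrom: dict[str, list[GenomeInterval]] = {}
    for iv in bm:
        b_by_chrom.setdefault(iv.chrom, []).append(iv)
    a_by_chrom: dict[str, list[GenomeInterval]] = {}
    for iv in am:
        a_by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(a_by_chrom):
        avs = a_by_chrom[chrom]
        bvs = b_by_chrom.get(chrom, [])
        i = j = 0
        while i < len(avs) and j < len(bvs):
            s = max(avs[i].start, bvs[j].start)
            e = min(avs[i].end, bvs[j].end)
            if s < e:
                out.append(GenomeInterval(chrom, s, e))
            if avs[i].end <= bvs[j].end:
                i += 1
            else:
                j += 1
    return sorted(out)


def intersect_length(a: Iterable[GenomeInterval], b: Iterable[GenomeInterval]) -> int:
    return sum(iv.length for iv in intersect_intervals(a, b))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_error(path, lineno: int, msg: str) -> ValueError:
    return ValueError(f"{path}:{lineno}: {msg}")


def read_peaks(path, dialect: str = "narrowPeak") -> list[Peak]:
    """Read peaks from a narrowPeak or BED6+summit file.

    narrowPeak column 10 is the summit offset from ``start``; an offset of -1
    (no summit) falls back to the interval midpoint with a logged warning.
    The ``bed6+summit`` dialect carries an absolute summit position in
    column 7.
    """
    if dialect not in ("narrowPeak", "bed6+summit"):
        raise ValueError(f"unknown peak dialect {dialect!r}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else ""
                if dialect == "narrowPeak":
                    if len(fields) < 10:
                        raise ValueError("narrowPeak requires 10 columns")
                    score = float(fields[6])  # signalValue = mapped reads
                    offset = int(fields[9])
                    if offset < 0:
                        summit = (start + end) // 2
                        log.warning(
                            "%s:%d: no summit offset; using interval midpoint",
                            path, lineno,
                        )
                    else:
                        summit = start + offset
                else:
                    if len(fields) < 7:
                        raise ValueError("bed6+summit requires 7 columns")
                    score = float(fields[4])
                    summit = int(fields[6])
                strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
                iv = GenomeInterval(chrom, start, end, strand)
                peaks.append(Peak(iv, summit=summit, score=score, name=name))
            except (ValueError, IndexError) as exc:
                raise _parse_error(path, lineno, str(exc)) from exc
    return peaks


def write_peaks(path, peaks: Sequence[Peak], dialect: str = "narrowPeak") -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            name = p.name or "."
            if dialect == "narrowPeak":
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}"
                    f"\t{p.score:g}\t-1\t-1\t{p.summit - iv.start}\n"
                )
            elif dialect == "bed6+summit":
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{p.score:g}"
                    f"\t{iv.strand}\t{p.summit}\n"
                )
            else:
                raise ValueError(f"unknown peak dialect {dialect!r}")


GENE_TABLE_COLUMNS = ["gene_id", "ortholog_id", "chrom", "start", "end", "strand", "tss", "tes"]


def read_gene_table(path) -> list[GeneRecord]:
    """Read a TSV gene table (header per :data:`GENE_TABLE_COLUMNS`)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "ortholog_id": str})
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: gene table missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    genes = []
    for row in df.itertuples(index=False):
        ortho = None if pd.isna(row.ortholog_id) or row.ortholog_id in ("", ".") else str(row.ortholog_id)
        genes.append(
            GeneRecord(
                gene_id=str(row.gene_id),
                ortholog_id=ortho,
                interval=GenomeInterval(str(row.chrom), int(row.start), int(row.end), str(row.strand)),
                tss=int(row.tss),
                tes=int(row.tes),
                strand=str(row.strand),
            )
        )
    return genes


def write_gene_table(path, genes: Sequence[GeneRecord]) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "ortholog_id": g.ortholog_id if g.ortholog_id is not None else ".",
            "chrom": g.chrom,
            "start": g.interval.start,
            "end": g.interval.end,
            "strand": g.strand,
            "tss": g.tss,
            "tes": g.tes,
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def paired_orthologs(
    a: Sequence[GeneRecord], b: Sequence[GeneRecord]
) -> list[tuple[GeneRecord, GeneRecord]]:
    """One-to-one ortholog pairs present in both tables.

    Genes whose declared partner is absent from the other table are excluded
    with a warning (they cannot enter cross-species analyses).
    """
    b_by_id = {g.gene_id: g for g in b}
    pairs = []
    n_dropped = 0
    for g in a:
        if g.ortholog_id is None:
            continue
        partner = b_by_id.get(g.ortholog_id)
        if partner is None:
            n_dropped += 1
            continue
        pairs.append((g, partner))
    if n_dropped:
        log.warning("%d genes had ortholog_ids absent from the partner table", n_dropped)
    return pairs


def read_segmentation(path, n_states: int | None = None) -> list[StateSegment]:
    """Read a 4-column segmentation BED (chrom, start, end, state).

    State labels may be bare integers or ``E<k>``.  Segments on a chromosome
    must not overlap; labels must lie in ``1..n_states`` when given.
    """
    segs: list[StateSegment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                label = fields[3]
                state = int(label[1:]) if label[:1] in ("E", "U") else int(label)
                segs.append(StateSegment(GenomeInterval(chrom, start, end), state))
            except (ValueError, IndexError) as exc:
                raise _parse_error(path, lineno, str(exc)) from exc
    if n_states is not None:
        for seg in segs:
            if seg.state > n_states:
                raise ValueError(
                    f"{path}: state {seg.state} exceeds declared n_states={n_states}"
                )
    by_chrom: dict[str, list[StateSegment]] = {}
    for seg in segs:
        by_chrom.setdefault(seg.interval.chrom, []).append(seg)
    for chrom, chrom_segs in by_chrom.items():
        chrom_segs.sort(key=lambda s: s.interval.start)
        for prev, nxt in zip(chrom_segs, chrom_segs[1:]):
            if nxt.interval.start < prev.interval.end:
                raise ValueError(
                    f"{path}: overlapping segments on {chrom} at {nxt.interval.start}"
                )
    return segs


def write_segmentation(path, segs: Sequence[StateSegment]) -> None:
    with open(path, "w") as fh:
        for seg in sorted(segs, key=lambda s: s.interval):
            iv = seg.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tE{seg.state}\n")


def read_expression(path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "stage": str})
    return ExpressionTable(df)


def write_expression(path, table: ExpressionTable) -> None:
    table.df.to_csv(path, sep="\t", index=False, columns=list(ExpressionTable.COLUMNS))


def read_tags(path) -> list[GenomeInterval]:
    """Read a BED3/BED6 tag (aligned-read) file as stranded intervals."""
    tags: list[GenomeInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            try:
                strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
                tags.append(
                    GenomeInterval(fields[0], int(fields[1]), int(fields[2]), strand)
                )
            except (ValueError, IndexError) as exc:
                raise _parse_error(path, lineno, str(exc)) from exc
    return tags


def write_tags(path, tags: Sequence[GenomeInterval]) -> None:
    with open(path, "w") as fh:
        for t in tags:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t.\t0\t{t.strand}\n")
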