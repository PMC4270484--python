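"""Combinatorial TF co-occupancy regions and their cross-species transfer.

Peak summits from a TF panel (e.g. GATA1, TAL1, KLF1 -> 7 non-empty
combinations) are clustered by single linkage at +/- 1000 bp into
co-occupancy regions (candidate cis-regulatory modules).  Regions are then
lifted to the other genome and assigned to the combinatorial group of the
destination region they land in, yielding a row-stochastic transfer
matrix whose diagonal carries group retention (e.g. the triple-occupied
regions conserved as triples).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chain_lift import ChainAlignment, ChainIndex, lift_interval
from .genome_model import GeneRecord, GenomeInterval, Peak

__all__ = [
    "CoRegion",
    "TransferMatrix",
    "build_regions",
    "transfer_regions",
    "assign_regions_to_genes",
    "group_label",
]

ABSENT = "absent"


def group_label(tf_set: Iterable[str]) -> str:
    return "+".join(sorted(tf_set))


@dataclass
class CoRegion:
    """A summit cluster spanning one or more TFs."""

    interval: GenomeInterval
    tf_set: frozenset[str]
    summits: list[int]
    member_peaks: list[Peak] = field(default_factory=list)

    @property
    def label(self) -> str:
        return group_label(self.tf_set)

    @property
    def median_summit(self) -> int:
        return int(np.median(self.summits))


@dataclass
class TransferMatrix:
    """Counts of source regions per group landing in each destination group.

    ``counts`` has one row per source group and one column per destination
    group plus :data:`ABSENT`; ``n`` is the mapped-region denominator per
    source group (rows sum to it).
    """

    counts: pd.DataFrame
    n_unmapped: pd.Series

    @property
    def n(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def proportions(self) -> pd.DataFrame:
        n = self.n
        return self.counts.div(n.where(n > 0), axis=0)

    def retention(self, group: str) -> float:
        """Proportion of mapped source regions of a group landing in the
        same group."""
        if group not in self.counts.index or group not in self.counts.columns:
            return math.nan
        n = self.counts.loc[group].sum()
        return self.counts.loc[group, group] / n if n else math.nan


def build_regions(
    peaks_by_tf: Mapping[str, Sequence[Peak]],
    radius: int = 1000,
    flank: int = 50,
) -> list[CoRegion]:
    """Single-linkage clustering of summits across TFs at distance <= radius.

    The region interval spans ``[min summit - flank, max summit + flank)``;
    its TF set lists every factor contributing at least one summit.
    """
    entries: list[tuple[str, int, str, Peak]] = []
    for tf, peaks in peaks_by_tf.items():
        for p in peaks:
            entries.append((p.chrom, p.summit, tf, p))
    entries.sort(key=lambda e: (e[0], e[1]))
    regions: list[CoRegion] = []
    cluster: list[tuple[str, int, str, Peak]] = []

    def flush():
        if not cluster:
            return
        chrom = cluster[0][0]
        summits = [c[1] for c in cluster]
        tfs = frozenset(c[2] for c in cluster)
        iv = GenomeInterval(chrom, max(0, min(summits) - flank), max(summits) + flank)
        regions.append(CoRegion(iv, tfs, summits, [c[3] for c in cluster]))

    for e in entries:
        if cluster and (e[0] != cluster[-1][0] or e[1] - cluster[-1][1] > radius):
            flush()
            cluster = []
        cluster.append(e)
    flush()
    return regions


def _representative_window(region: CoRegion, flank: int, span_cap: int) -> GenomeInterval:
    """Window actually lifted: the full span when short, else the narrow
    summit window around the median summit (keeps mapping behavior close to
    single-peak summit windows)."""
    if region.interval.length < span_cap:
        return region.interval
    m = region.median_summit
    return GenomeInterval(region.interval.chrom, max(0, m - flank), m + flank + 1)


def transfer_regions(
    src_regions: Sequence[CoRegion],
    dst_regions: Sequence[CoRegion],
    chains: Iterable[ChainAlignment] | ChainIndex,
    flank: int = 50,
    min_match: float = 0.10,
    span_cap: int = 500,
) -> TransferMatrix:
    """Lift source regions and tabulate the destination groups they land in.

    Mapped regions overlapping no destination region count as
    :data:`ABSENT`; ambiguous overlaps resolve to the larger overlap, ties
    to the destination region with the nearer median summit.  Unmapped
    regions are excluded from the denominators.
    """
    index = chains if isinstance(chains, ChainIndex) else ChainIndex(chains)
    src_groups = sorted({r.label for r in src_regions})
    dst_groups = sorted({r.label for r in dst_regions})
    cols = dst_groups + [ABSENT]
    counts = pd.DataFrame(0, index=src_groups, columns=cols, dtype=int)
    unmapped = pd.Series(0, index=src_groups, dtype=int)

    dst_by_chrom: dict[str, list[CoRegion]] = {}
    for r in dst_regions:
        dst_by_chrom.setdefault(r.interval.chrom, []).append(r)
    for rs in dst_by_chrom.values():
        rs.sort(key=lambda r: r.interval.start)

    for region in src_regions:
        window = _representative_window(region, flank, span_cap)
        res = lift_interval(window, index, min_match=min_match)
        if not res.is_mapped:
            unmapped[region.label] += 1
            continue
        iv = res.mapped_interval
        best = None
        best_key = None
        for cand in dst_by_chrom.get(iv.chrom, ()):
            ov = cand.interval.overlap_length(iv)
            if ov <= 0:
                continue
            dist = abs(cand.median_summit - iv.midpoint)
            key = (-ov, dist, cand.label)
            if best_key is None or key < best_key:
                best, best_key = cand, key
        target = best.label if best is not None else ABSENT
        counts.loc[region.label, target] += 1
    return TransferMatrix(counts, unmapped)


def assign_regions_to_genes(
    regions: Sequence[CoRegion],
    genes: Sequence[GeneRecord],
    max_distance: int = 50000,
) -> list[str | None]:
    """Assign each region to the nearest TSS within ``max_distance``.

    Distance is measured from the region midpoint; equidistant TSSs break
    ties by lexicographic gene_id.  Returns one gene_id (or None) per
    region, in order.
    """
    genes_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    for lst in genes_by_chrom.values():
        lst.sort()
    out: list[str | None] = []
    for region in regions:
        mid = region.interval.midpoint
        best: tuple[int, str] | None = None
        for tss, gid in genes_by_chrom.get(region.interval.chrom, ()):
            d = abs(tss - mid)
            if d > max_distance:
                continue
            if best is None or (d, gid) < best:
                best = (d, gid)
        out.append(best[1] if best else None)
    return out
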