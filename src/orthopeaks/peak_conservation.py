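"""Five-way conservation classification of TF occupancy sites.

Summit windows of source-species peaks are lifted to the destination
genome and intersected with destination peaks:

* conserved   — mapped window overlaps a destination peak (>= 1 bp);
* lost        — mapped but no overlap (source/species-A-specific);
* compensatory— a destination peak within +/- 5 kb of a lost site's
                mapped window (a new nearby site replacing the lost one);
* gained      — destination peak neither conserved nor compensatory
                (destination/species-B-specific);
* strongly_gained — the top 10% of gained peaks by read score.

Unmapped source peaks are excluded from all rate denominators: the
denominator is always the number of successfully mapped source windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .chain_lift import ChainAlignment, ChainIndex, lift_summit_window
from .genome_model import GenomeInterval, Peak

__all__ = [
    "ConservationSummary",
    "SourceClassification",
    "classify_source_peaks",
    "classify_target_peaks",
    "rank_filter_peaks",
    "assign_gene_categories",
    "CATEGORY_PRIORITY",
]

# a gene near sites of several classes takes the highest-priority one
CATEGORY_PRIORITY = ("conserved", "strongly_gained", "compensatory", "gained", "lost")

SOURCE_LABELS = ("conserved", "lost", "unmapped")
TARGET_LABELS = ("conserved", "compensatory", "gained", "strongly_gained")


@dataclass
class ConservationSummary:
    """Counts and rates from one source->destination comparison."""

    n_source_peaks: int
    n_mapped: int
    n_conserved: int
    n_lost: int
    n_lost_with_compensatory: int
    n_compensatory_sites: int

    @property
    def rate_conserved(self) -> float:
        return self.n_conserved / self.n_mapped if self.n_mapped else math.nan

    @property
    def rate_compensatory(self) -> float:
        """Fraction of lost sites with a compensatory destination site."""
        return self.n_lost_with_compensatory / self.n_lost if self.n_lost else math.nan

    def to_dict(self) -> dict:
        d = {
            "n_source_peaks": self.n_source_peaks,
            "n_mapped": self.n_mapped,
            "n_conserved": self.n_conserved,
            "n_lost": self.n_lost,
            "n_lost_with_compensatory": self.n_lost_with_compensatory,
            "n_compensatory_sites": self.n_compensatory_sites,
            "rate_conserved": self.rate_conserved,
            "rate_compensatory": self.rate_compensatory,
        }
        return d


@dataclass
class SourceClassification:
    """Per-peak source labels plus destination-side conservation flags."""

    labels: list[str]                      # per source peak: conserved|lost|unmapped
    lifted: list[GenomeInterval | None]    # mapped summit window per source peak
    conserved_dst: set[int]                # indices of destination peaks
    compensatory_dst: set[int]
    summary: ConservationSummary


def _dst_index(dst: Sequence[Peak]) -> dict[str, list[tuple[int, int, int]]]:
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, p in enumerate(dst):
        by_chrom.setdefault(p.chrom, []).append((p.interval.start, p.interval.end, i))
    for spans in by_chrom.values():
        spans.sort()
    return by_chrom


def _overlapping(by_chrom, chrom: str, start: int, end: int) -> list[int]:
    hits = []
    for s, e, i in by_chrom.get(chrom, ()):
        if s >= end:
            break
        if e > start:
            hits.append(i)
    return hits


def classify_source_peaks(
    src: Sequence[Peak],
    dst: Sequence[Peak],
    chains: Iterable[ChainAlignment] | ChainIndex,
    flank: int = 50,
    comp_window: int = 5000,
    min_match: float = 0.10,
) -> SourceClassification:
    """Classify each source peak as conserved/lost (or unmapped).

    Lost peaks are additionally scanned for compensatory destination peaks
    within ``comp_window`` of the lifted window.  A destination peak that is
    conserved for any source peak keeps the conserved flag with priority
    over compensatory, so the destination partition stays disjoint.
    """
    index = chains if isinstance(chains, ChainIndex) else ChainIndex(chains)
    dst_idx = _dst_index(dst)
    labels: list[str] = []
    lifted: list[GenomeInterval | None] = []
    conserved_dst: set[int] = set()
    compensatory_dst: set[int] = set()
    n_lost_with_comp = 0

    lost_windows: list[GenomeInterval] = []
    for p in src:
        res = lift_summit_window(p, index, flank=flank, min_match=min_match)
        if not res.is_mapped:
            labels.append("unmapped")
            lifted.append(None)
            continue
        iv = res.mapped_interval
        lifted.append(iv)
        hits = _overlapping(dst_idx, iv.chrom, iv.start, iv.end)
        if hits:
            labels.append("conserved")
            conserved_dst.update(hits)
        else:
            labels.append("lost")
            lost_windows.append(iv)

    for iv in lost_windows:
        hits = _overlapping(
            dst_idx, iv.chrom, max(0, iv.start - comp_window), iv.end + comp_window
        )
        comp = [i for i in hits if i not in conserved_dst]
        if comp:
            n_lost_with_comp += 1
            compensatory_dst.update(comp)
    compensatory_dst -= conserved_dst

    n_mapped = sum(1 for l in labels if l != "unmapped")
    n_conserved = sum(1 for l in labels if l == "conserved")
    n_lost = n_mapped - n_conserved
    summary = ConservationSummary(
        n_source_peaks=len(src),
        n_mapped=n_mapped,
        n_conserved=n_conserved,
        n_lost=n_lost,
        n_lost_with_compensatory=n_lost_with_comp,
        n_compensatory_sites=len(compensatory_dst),
    )
    return SourceClassification(labels, lifted, conserved_dst, compensatory_dst, summary)


def classify_target_peaks(
    dst: Sequence[Peak],
    conserved_dst: set[int],
    compensatory_dst: set[int],
    strong_fraction: float = 0.10,
) -> list[str]:
    """Label destination peaks, relabeling the top-scoring gained decile.

    Destination peaks that are neither conserved nor compensatory are
    gained; the ``ceil(strong_fraction * n_gained)`` highest-score gained
    peaks become strongly_gained.  Score ties at the cutoff break by
    genomic order (chrom, start) so the labeling is deterministic.
    """
    if not (0 <= strong_fraction <= 1):
        raise ValueError("strong_fraction must be in [0, 1]")
    labels = []
    gained: list[int] = []
    for i, p in enumerate(dst):
        if i in conserved_dst:
            labels.append("conserved")
        elif i in compensatory_dst:
            labels.append("compensatory")
        else:
            labels.append("gained")
            gained.append(i)
    k = math.ceil(strong_fraction * len(gained))
    order = sorted(
        gained, key=lambda i: (-dst[i].score, dst[i].chrom, dst[i].interval.start)
    )
    for i in order[:k]:
        labels[i] = "strongly_gained"
    return labels


def rank_filter_peaks(peaks: Sequence[Peak], top_fraction: float) -> list[Peak]:
    """Retain the ceil(top_fraction * n) highest-score peaks.

    Mirrors top-percentile filtering by total mapped reads in the peak
    region; ties break by genomic order for determinism.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    k = math.ceil(top_fraction * len(peaks))
    order = sorted(
        range(len(peaks)),
        key=lambda i: (-peaks[i].score, peaks[i].chrom, peaks[i].interval.start),
    )
    keep = sorted(order[:k])
    return [peaks[i] for i in keep]


def assign_gene_categories(
    genes: Sequence["object"],
    intervals_by_label: dict[str, Sequence[GenomeInterval]],
    window: int = 10000,
) -> dict[str, str]:
    """Per-gene conservation category from proximity to labeled sites.

    A gene is flagged for a category when any site of that label lies
    within ``window`` of the gene body; genes near several classes take
    the highest-priority one (:data:`CATEGORY_PRIORITY`).  ``genes`` are
    :class:`~orthopeaks.genome_model.GeneRecord` objects; "lost" sites are
    typically the lifted windows of lost source peaks so all intervals
    live on one genome.  Genes near no site map to ``"none"``.
    """
    by_label_chrom: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for label, ivs in intervals_by_label.items():
        d: dict[str, list[tuple[int, int]]] = {}
        for iv in ivs:
            d.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for spans in d.values():
            spans.sort()
        by_label_chrom[label] = d

    out: dict[str, str] = {}
    for g in genes:
        lo = g.interval.start - window
        hi = g.interval.end + window
        category = "none"
        for label in CATEGORY_PRIORITY:
            spans = by_label_chrom.get(label, {}).get(g.chrom, ())
            if any(s < hi and e > lo for s, e in spans):
                category = label
                break
        out[g.gene_id] = category
    return out
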