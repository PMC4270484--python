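"""Permutation-based genomic association, chromatin-state overlap
enrichment, and 2x2 occupancy odds ratios.

The permutation test follows the Genomic Association Tester idea: the
observed base overlap between a query interval set and a reference set is
compared with the overlap obtained when the query segments are re-placed
uniformly at random inside a workspace, preserving their lengths and
forbidding overlap among the placed segments.  Fold enrichment is
observed/expected and the permutation p-value uses the add-one rule so it
can never be zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .genome_model import (
    GenomeInterval,
    StateSegment,
    intersect_length,
    merge_intervals,
    total_length,
)

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "StateEnrichment",
    "permutation_enrichment",
    "state_overlap_enrichment",
    "category_gene_odds",
    "rank_sum_compare",
]

UNASSIGNED_STATE = 0


@dataclass
class EnrichmentResult:
    observed_overlap: int
    expected_overlap: float
    p_greater: float
    p_less: float
    p_two_sided: float
    n_perm: int

    @property
    def fold(self) -> float:
        if self.expected_overlap > 0:
            return self.observed_overlap / self.expected_overlap
        return math.nan

    def to_dict(self) -> dict:
        return {
            "observed_overlap": self.observed_overlap,
            "expected_overlap": self.expected_overlap,
            "fold": self.fold,
            "p_greater": self.p_greater,
            "p_less": self.p_less,
            "p_two_sided": self.p_two_sided,
            "n_perm": self.n_perm,
        }


def _globalize(
    interval_sets: Sequence[Sequence[GenomeInterval]],
) -> list[list[tuple[int, int]]]:
    """Map interval sets onto one linear coordinate axis (chrom offsets)."""
    extents: dict[str, int] = {}
    for ivs in interval_sets:
        for iv in ivs:
            extents[iv.chrom] = max(extents.get(iv.chrom, 0), iv.end)
    offsets: dict[str, int] = {}
    off = 0
    for chrom in sorted(extents):
        offsets[chrom] = off
        off += extents[chrom] + 1
    out = []
    for ivs in interval_sets:
        out.append([(offsets[iv.chrom] + iv.start, offsets[iv.chrom] + iv.end) for iv in ivs])
    return out


class _CoverageLookup:
    """Prefix-sum lookup of bases covered by a merged interval set below x."""

    def __init__(self, spans: Sequence[tuple[int, int]]):
        spans = sorted(spans)
        self.starts = np.array([s for s, _ in spans], dtype=np.int64)
        self.ends = np.array([e for _, e in spans], dtype=np.int64)
        lens = self.ends - self.starts
        self.cum = np.concatenate([[0], np.cumsum(lens)])

    def covered_below(self, x: np.ndarray) -> np.ndarray:
        j = np.searchsorted(self.starts, x, side="right") - 1
        j_clip = np.clip(j, 0, None)
        inside = np.clip(np.minimum(x, self.ends[j_clip]) - self.starts[j_clip], 0, None)
        return np.where(j < 0, 0, self.cum[j_clip] + inside)

    def overlap(self, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        return self.covered_below(ends) - self.covered_below(starts)


def permutation_enrichment(
    query: Sequence[GenomeInterval],
    reference: Sequence[GenomeInterval],
    workspace: Sequence[GenomeInterval],
    n_perm: int = 100000,
    seed: int | np.random.Generator = 0,
    max_rounds: int = 1000,
    batch: int = 20000,
) -> EnrichmentResult:
    """Permutation test of base overlap between query and reference.

    Each permutation re-places every query segment uniformly at random
    within the workspace (each segment entirely inside one workspace
    interval, no overlap among placed segments).  Raises when a segment
    cannot be placed or the rejection sampler fails to find a
    non-overlapping configuration.
    """
    if not query:
        raise ValueError("empty query")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    (g_query, g_ref, g_ws) = _globalize([list(query), list(reference), list(workspace)])

    observed = intersect_length(query, reference)
    ref_merged = merge_intervals(reference)
    (g_ref_m,) = _globalize_like(ref_merged, query, reference, workspace)
    ref_lookup = _CoverageLookup(g_ref_m)

    ws = sorted(merge_spans(g_ws))
    ws_starts = np.array([s for s, _ in ws], dtype=np.int64)
    ws_lens = np.array([e - s for s, e in ws], dtype=np.int64)
    seg_lens = np.array([e - s for s, e in g_query], dtype=np.int64)
    n_seg = len(seg_lens)

    # per segment length: cumulative valid-start capacity over workspace pieces
    caps = np.maximum(0, ws_lens[None, :] - seg_lens[:, None] + 1)  # (n_seg, n_ws)
    totals = caps.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("workspace too small to place a query segment")
    cumcaps = np.cumsum(caps, axis=1)

    perm_stats = np.empty(n_perm, dtype=np.int64)
    done = 0
    while done < n_perm:
        m = min(batch, n_perm - done)
        starts = _sample_starts(rng, m, seg_lens, ws_starts, caps, cumcaps, totals)
        bad = _rows_with_overlap(starts, seg_lens)
        rounds = 0
        while bad.any():
            rounds += 1
            if rounds > max_rounds:
                raise RuntimeError(
                    "could not place query segments without overlap; "
                    "workspace too crowded"
                )
            resampled = _sample_starts(
                rng, int(bad.sum()), seg_lens, ws_starts, caps, cumcaps, totals
            )
            starts[bad] = resampled
            bad_idx = np.flatnonzero(bad)
            still = _rows_with_overlap(starts[bad_idx], seg_lens)
            bad = np.zeros(m, dtype=bool)
            bad[bad_idx[still]] = True
        ov = ref_lookup.overlap(starts, starts + seg_lens[None, :])
        perm_stats[done : done + m] = ov.sum(axis=1)
        done += m

    expected = float(perm_stats.mean())
    p_greater = (1 + int((perm_stats >= observed).sum())) / (1 + n_perm)
    p_less = (1 + int((perm_stats <= observed).sum())) / (1 + n_perm)
    p_two = min(1.0, 2.0 * min(p_greater, p_less))
    return EnrichmentResult(observed, expected, p_greater, p_less, p_two, n_perm)


def _globalize_like(target, *context_sets):
    """Globalize ``target`` using offsets derived from the context sets."""
    sets = [list(target)] + [list(s) for s in context_sets]
    return _globalize(sets)[:1]


def merge_spans(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    spans = sorted(spans)
    out: list[tuple[int, int]] = []
    for s, e in spans:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _sample_starts(rng, m, seg_lens, ws_starts, caps, cumcaps, totals):
    """Uniform valid start positions, shape (m, n_seg)."""
    n_seg = len(seg_lens)
    u = (rng.random((m, n_seg)) * totals[None, :]).astype(np.int64)
    starts = np.empty((m, n_seg), dtype=np.int64)
    for j in range(n_seg):
        i = np.searchsorted(cumcaps[j], u[:, j], side="right")
        prev = np.where(i > 0, cumcaps[j][i - 1], 0)
        starts[:, j] = ws_starts[i] + (u[:, j] - prev)
    return starts


def _rows_with_overlap(starts: np.ndarray, seg_lens: np.ndarray) -> np.ndarray:
    if starts.shape[1] < 2:
        return np.zeros(starts.shape[0], dtype=bool)
    order = np.argsort(starts, axis=1, kind="stable")
    s_sorted = np.take_along_axis(starts, order, axis=1)
    l_sorted = seg_lens[order]
    gaps = s_sorted[:, 1:] - (s_sorted[:, :-1] + l_sorted[:, :-1])
    return (gaps < 0).any(axis=1)


@dataclass
class StateEnrichment:
    """Per-state fold enrichment of a query over a workspace baseline."""

    folds: dict[int, float]
    query_fraction: dict[int, float]
    workspace_fraction: dict[int, float]
    query_bases: int
    workspace_bases: int

    def scaled(self) -> dict[int, float]:
        """Folds scaled to sum to 1 across states (display convenience)."""
        tot = sum(v for v in self.folds.values() if not math.isnan(v))
        return {s: (v / tot if tot else math.nan) for s, v in self.folds.items()}


def state_overlap_enrichment(
    segments: Sequence[StateSegment],
    query: Sequence[GenomeInterval],
    workspace: Sequence[GenomeInterval] | None = None,
) -> StateEnrichment:
    """Fold enrichment of each chromatin state within the query intervals.

    ``fold_s = (query bases in state s / query bases) /
    (workspace bases in state s / workspace bases)``.  Query bases outside
    the segmentation are tallied under state 0 ("unassigned") with a
    warning.
    """
    seg_ivs = [s.interval for s in segments]
    if workspace is None:
        workspace = merge_intervals(seg_ivs)
    states = sorted({s.state for s in segments})
    by_state: dict[int, list[GenomeInterval]] = {s: [] for s in states}
    for s in segments:
        by_state[s.state].append(s.interval)

    q_total = total_length(query)
    w_total = total_length(workspace)
    if q_total == 0 or w_total == 0:
        raise ValueError("query and workspace must be non-empty")

    q_by_state = {s: intersect_length(query, ivs) for s, ivs in by_state.items()}
    w_by_state = {s: intersect_length(workspace, ivs) for s, ivs in by_state.items()}
    q_unassigned = q_total - sum(q_by_state.values())
    if q_unassigned > 0:
        log.warning("%d query bases outside the segmentation (state 0)", q_unassigned)
        q_by_state[UNASSIGNED_STATE] = q_unassigned
        w_by_state[UNASSIGNED_STATE] = w_total - sum(w_by_state.values())

    folds, qf, wf = {}, {}, {}
    for s in q_by_state:
        qf[s] = q_by_state[s] / q_total
        wf[s] = w_by_state[s] / w_total
        folds[s] = qf[s] / wf[s] if wf[s] > 0 else math.nan
    return StateEnrichment(folds, qf, wf, q_total, w_total)


def category_gene_odds(
    genes_special: set[str],
    genes_rest: set[str],
    occupied: Mapping[str, bool] | set[str],
) -> tuple[float, float]:
    """log2 odds ratio (and Fisher p) of occupancy in special vs rest genes.

    With counts a/n1 occupied among special and b/n2 among rest,
    ``OR = [a/(n1-a)] / [b/(n2-b)]``; a Haldane-Anscombe 0.5 correction is
    applied to every cell when any cell is zero.
    """
    if genes_special & genes_rest:
        raise ValueError("special and rest gene sets must be disjoint")
    n1, n2 = len(genes_special), len(genes_rest)
    if n1 == 0 or n2 == 0:
        raise ValueError("both gene sets must be non-empty")
    is_occ = (lambda g: bool(occupied.get(g, False))) if isinstance(occupied, Mapping) else (lambda g: g in occupied)
    a = sum(1 for g in genes_special if is_occ(g))
    b = sum(1 for g in genes_rest if is_occ(g))
    table = np.array([[a, n1 - a], [b, n2 - b]], dtype=float)
    _, p = stats.fisher_exact(table.astype(int))
    if (table == 0).any():
        table = table + 0.5
    odds = (table[0, 0] / table[0, 1]) / (table[1, 0] / table[1, 1])
    return float(np.log2(odds)), float(p)


def rank_sum_compare(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney rank-sum p-value.

    Exact for small tie-free samples, otherwise the normal approximation
    with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and max(x.size, y.size) <= 20) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)
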