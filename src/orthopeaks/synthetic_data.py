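"""Paired-species synthetic fixtures with planted ground truth.

The generator emulates the statistical structure of a two-species
comparative ChIP-seq study: two genomes linked by a block/gap chain
alignment with a configurable unmappable fraction, one-to-one ortholog
gene pairs at chain-corresponding positions, per-TF peak sets with
planted conservation, compensatory and gain rates, promoter mark
intensities feeding a planted linear expression model
(``y = intercept + X @ beta + noise``, exported as ``FPKM = 2^y - 1``
floored at 0 so the log response inverts it exactly), tag files whose
pileup recovers the planted intensities, and a chromatin-state
segmentation with an active state enriched at conserved and strong
species-specific sites.

Peak placement reserves an exclusion neighbourhood around every mapped
source site on the destination genome, so a lost site has a destination
peak within the compensatory window if and only if one was planted —
classification rates then estimate the planted Bernoulli rates without
cross-talk between neighbouring sites.  Everything is deterministic
under the supplied seed.

The source species is called "mouse" and the destination "human",
mirroring the mouse-to-human lift the conservation scheme is defined
for; nothing depends on the names.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .chain_lift import ChainAlignment, ChainIndex, lift_summit_window, write_chain
from .genome_model import (
    ExpressionTable,
    GeneRecord,
    GenomeInterval,
    Peak,
    StateSegment,
    write_expression,
    write_gene_table,
    write_peaks,
    write_segmentation,
)
from .peak_conservation import assign_gene_categories

__all__ = [
    "TFConfig",
    "CoOccupancyConfig",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_genome_pair",
    "generate_peaks",
    "generate_marks_expression",
    "generate_segmentation",
    "generate_coregion_peaks",
    "generate_all",
    "random_chain",
    "make_regression_fixture",
]

MARKS = (
    "H3K4me1", "H3K4me2", "H3K4me3", "H3K9ac", "H3K27me3", "H3K36me3",
    "GATA1", "TAL1", "KLF1", "NFE2",
)

# planted effect of each promoter mark on log2 expression; repressive
# H3K27me3 is negative, five marks carry no signal at all
DEFAULT_BETA = {
    "H3K9ac": 3.0,
    "H3K4me3": 2.0,
    "H3K27me3": -1.5,
    "H3K36me3": 1.0,
    "GATA1": 0.5,
}


@dataclass
class TFConfig:
    """Planted rates for one transcription factor's peak sets."""

    n_peaks: int = 2000         # mapped source peaks
    p_cons: float = 0.25        # planted conservation rate
    p_comp: float = 0.25        # compensatory fraction among lost sites
    n_gain: int = 1000          # destination-only peaks
    score_cons_boost: float = 0.5  # lognormal-mu boost for conserved sites


@dataclass
class CoOccupancyConfig:
    """Planted combinatorial regions for the co-occupancy transfer test."""

    panel: tuple[str, ...] = ("GATA1", "TAL1", "KLF1")
    n_triple: int = 400
    n_pair: int = 800           # split over the three pairs
    n_single: int = 1600        # split over the three singles
    retention_triple: float = 0.35
    retention_pair: float = 0.15
    retention_single: float = 0.05


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic two-species experiment."""

    # genomes & chain
    n_chromosomes: int = 2
    chrom_length: int = 20_000_000
    block_size: tuple[int, int] = (2000, 20000)
    unmappable_fraction: float = 0.20
    insertion_prob: float = 0.3
    insertion_size: tuple[int, int] = (1, 2000)
    # genes
    n_genes: int = 2000
    gene_length: tuple[int, int] = (2000, 20000)
    # peaks
    tf_panel: dict = field(
        default_factory=lambda: {
            "GATA1": TFConfig(p_cons=0.25),
            "TAL1": TFConfig(p_cons=0.25),
            "NFE2": TFConfig(p_cons=0.25),
            "KLF1": TFConfig(p_cons=0.60),
        }
    )
    peak_width: tuple[int, int] = (200, 600)
    score_mu: float = math.log(50.0)
    score_sigma: float = 1.0
    flank: int = 50
    comp_window: int = 5000
    comp_gap: tuple[int, int] = (200, 4300)
    min_separation: int = 11500  # destination-side exclusion between sites
    # promoter marks & expression model
    marks: tuple[str, ...] = MARKS
    beta_true: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    mark_shape: float = 2.0
    mark_gamma_scale: float = 0.5
    mark_scale: float = 10.0     # rpm scale of promoter signals
    mark_coupling_sd: float = 0.2  # between-species jitter of mark intensity
    target_r2: float = 0.60
    sigma: float | None = None   # overrides target_r2 when set
    expr_intercept: float = 5.0
    specific_fraction: float = 0.10
    specific_shift: float = 8.0  # planted log2 expression shift via marks
    plant_category_offsets: bool = True
    category_offsets: dict = field(
        default_factory=lambda: {
            "conserved": 2.0,
            "strongly_gained": 1.5,
            "compensatory": 1.0,
            "gained": 0.5,
            "lost": 0.0,
        }
    )
    proximity_window: int = 10000
    # expression time series
    stages_human: tuple[str, ...] = ("ProE", "eBasoE", "lBasoE", "PolyE", "OrthoE")
    stages_mouse: tuple[str, ...] = ("ProE", "BasoE", "PolyE", "OrthoE")
    n_replicates: int = 3
    replicate_sd: float = 0.25
    stage_drift_sd: float = 0.15
    # promoter windows / tags
    promoter_upstream: int = 2000
    promoter_downstream: int = 2000
    fragment_length: int = 200
    n_reads: int = 150_000       # per mark, per species
    n_input_reads: int = 150_000
    # segmentation
    n_states: int = 15
    active_state: int = 5
    active_fraction: float = 0.05
    state_odds: float = 5.0
    state_bin: int = 200
    # co-occupancy planting
    cooccupancy: CoOccupancyConfig = field(default_factory=CoOccupancyConfig)


def config_from_dict(overrides: dict | None) -> SyntheticConfig:
    """Build a :class:`SyntheticConfig` from a plain (e.g. JSON) dict.

    Nested ``tf_panel`` and ``cooccupancy`` blocks may be plain dicts and
    are coerced to their dataclasses; tuple-valued fields accept lists.
    """
    d = dict(overrides or {})
    panel = d.get("tf_panel")
    if panel is not None:
        d["tf_panel"] = {
            tf: (v if isinstance(v, TFConfig) else TFConfig(**v))
            for tf, v in panel.items()
        }
    co = d.get("cooccupancy")
    if co is not None and not isinstance(co, CoOccupancyConfig):
        co = dict(co)
        if "panel" in co:
            co["panel"] = tuple(co["panel"])
        d["cooccupancy"] = CoOccupancyConfig(**co)
    for key in ("block_size", "insertion_size", "gene_length", "peak_width",
                "comp_gap", "marks", "stages_human", "stages_mouse"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return SyntheticConfig(**d)


# ---------------------------------------------------------------------------
# genome pair + chain
# ---------------------------------------------------------------------------

@dataclass
class GenomePair:
    chains: list[ChainAlignment]
    chrom_sizes_src: dict[str, int]
    chrom_sizes_dst: dict[str, int]
    genes_src: list[GeneRecord]
    genes_dst: list[GeneRecord]
    pairs: list[tuple[str, str]]  # (src gene_id, dst gene_id)

    @property
    def index(self) -> ChainIndex:
        return ChainIndex(self.chains)


def random_chain(
    rng: np.random.Generator,
    t_name: str = "chrT",
    q_name: str = "chrQ",
    n_blocks: int = 8,
    block_size: tuple[int, int] = (50, 500),
    gap_size: tuple[int, int] = (0, 300),
    q_strand: str = "+",
    chain_id: int = 1,
) -> ChainAlignment:
    """A random multi-block chain for oracle-equivalence testing."""
    sizes = rng.integers(block_size[0], block_size[1] + 1, n_blocks)
    dts = rng.integers(gap_size[0], gap_size[1] + 1, n_blocks)
    dqs = rng.integers(gap_size[0], gap_size[1] + 1, n_blocks)
    dts[-1] = dqs[-1] = 0
    t_start = int(rng.integers(0, 1000))
    q_start = int(rng.integers(0, 1000))
    t_span = int(sizes.sum() + dts.sum())
    q_span = int(sizes.sum() + dqs.sum())
    t_size = t_start + t_span + int(rng.integers(0, 1000))
    q_size = q_start + q_span + int(rng.integers(0, 1000))
    blocks = [(int(s), int(dt), int(dq)) for s, dt, dq in zip(sizes, dts, dqs)]
    return ChainAlignment(
        score=float(rng.integers(100, 10000)),
        t_name=t_name, t_size=t_size, t_strand="+",
        t_start=t_start, t_end=t_start + t_span,
        q_name=q_name, q_size=q_size, q_strand=q_strand,
        q_start=q_start, q_end=q_start + q_span,
        blocks=blocks, chain_id=chain_id,
    )


def generate_genome_pair(cfg: SyntheticConfig, rng: np.random.Generator) -> GenomePair:
    """Two genomes linked by one chain per chromosome, plus gene tables.

    The chain's aligned blocks cover ``1 - unmappable_fraction`` of the
    source genome in expectation; ortholog genes sit at the
    chain-corresponding positions of source genes whose TSS maps.
    """
    chains = []
    sizes_src, sizes_dst = {}, {}
    f = cfg.unmappable_fraction
    mean_block = (cfg.block_size[0] + cfg.block_size[1]) / 2
    max_dt = int(2 * mean_block * f / (1 - f)) if f > 0 else 0
    for ci in range(cfg.n_chromosomes):
        t_name = f"chrT{ci + 1}"
        q_name = f"chrQ{ci + 1}"
        blocks = []
        t = 0
        q_len = 0
        while t < cfg.chrom_length:
            size = int(rng.integers(cfg.block_size[0], cfg.block_size[1] + 1))
            dt = int(rng.integers(0, max_dt + 1)) if max_dt else 0
            dq = (
                int(rng.integers(cfg.insertion_size[0], cfg.insertion_size[1] + 1))
                if rng.random() < cfg.insertion_prob
                else 0
            )
            blocks.append((size, dt, dq))
            t += size + dt
            q_len += size + dq
        blocks[-1] = (blocks[-1][0], 0, 0)
        t_span = sum(b[0] + b[1] for b in blocks)
        q_span = sum(b[0] + b[2] for b in blocks)
        t_size = t_span
        q_size = q_span
        chains.append(
            ChainAlignment(
                score=1000.0,
                t_name=t_name, t_size=t_size, t_strand="+",
                t_start=0, t_end=t_span,
                q_name=q_name, q_size=q_size, q_strand="+",
                q_start=0, q_end=q_span,
                blocks=blocks, chain_id=ci + 1,
            )
        )
        sizes_src[t_name] = t_size
        sizes_dst[q_name] = q_size

    index = ChainIndex(chains)
    genes_src, genes_dst, pairs = [], [], []
    src_names = sorted(sizes_src)
    per_chrom = -(-cfg.n_genes // len(src_names))
    gid = 0
    for t_name in src_names:
        chain = index.by_chrom[t_name][0]
        L = sizes_src[t_name]
        n_here = min(per_chrom, cfg.n_genes - gid)
        tss_positions = np.sort(
            rng.integers(cfg.gene_length[1] + 1, L - cfg.gene_length[1] - 1, n_here)
        )
        for tss in tss_positions:
            tss = int(tss)
            length = int(rng.integers(cfg.gene_length[0], cfg.gene_length[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            tes = tss + length if strand == "+" else tss - length
            lo, hi = min(tss, tes), max(tss, tes) + 1
            iv = GenomeInterval(t_name, lo, hi, strand)
            src_id = f"gM{gid:05d}"
            g = GeneRecord(src_id, None, iv, tss, tes, strand)
            genes_src.append(g)
            q_tss = chain.map_base(tss)
            if q_tss is not None:
                q_size = sizes_dst[chain.q_name]
                q_tes = q_tss + length if strand == "+" else q_tss - length
                if 0 <= q_tes < q_size and 0 <= q_tss < q_size:
                    dst_id = f"gH{gid:05d}"
                    lo2, hi2 = min(q_tss, q_tes), max(q_tss, q_tes) + 1
                    genes_dst.append(
                        GeneRecord(
                            dst_id, src_id,
                            GenomeInterval(chain.q_name, lo2, hi2, strand),
                            q_tss, q_tes, strand,
                        )
                    )
                    g.ortholog_id = dst_id
                    pairs.append((src_id, dst_id))
            gid += 1
    return GenomePair(chains, sizes_src, sizes_dst, genes_src, genes_dst, pairs)


# ---------------------------------------------------------------------------
# peaks with planted conservation
# ---------------------------------------------------------------------------

@dataclass
class TFPeakSet:
    src_peaks: list[Peak]
    dst_peaks: list[Peak]
    src_labels: list[str]   # planted: conserved | lost | unmapped
    dst_roles: list[str]    # planted: conserved | compensatory | gain | strong_gain


class _ExclusionMap:
    """Sorted per-chromosome reserved positions with a minimum separation."""

    def __init__(self, min_sep: int):
        self.min_sep = min_sep
        self.by_chrom: dict[str, list[int]] = {}

    def conflicts(self, chrom: str, pos: int, sep: int | None = None) -> bool:
        import bisect

        sep = self.min_sep if sep is None else sep
        lst = self.by_chrom.get(chrom)
        if not lst:
            return False
        i = bisect.bisect_left(lst, pos)
        for j in (i - 1, i):
            if 0 <= j < len(lst) and abs(lst[j] - pos) < sep:
                return True
        return False

    def add(self, chrom: str, pos: int) -> None:
        import bisect

        lst = self.by_chrom.setdefault(chrom, [])
        bisect.insort(lst, pos)


def _draw_peak(
    rng: np.random.Generator,
    chrom: str,
    summit: int,
    size: int,
    cfg: SyntheticConfig,
    factor: str,
    sample: str,
    mu_boost: float = 0.0,
) -> Peak:
    w = int(rng.integers(cfg.peak_width[0], cfg.peak_width[1] + 1))
    start = max(0, summit - w // 2)
    end = min(size, summit + (w - w // 2))
    end = max(end, summit + 1)
    score = float(np.round(np.exp(rng.normal(cfg.score_mu + mu_boost, cfg.score_sigma)), 1))
    return Peak(GenomeInterval(chrom, start, end), summit, score, factor=factor, sample=sample)


def generate_peaks(
    cfg: SyntheticConfig, genome: GenomePair, rng: np.random.Generator
) -> dict[str, TFPeakSet]:
    """Per-TF peak sets with planted conservation/compensatory/gain truth.

    Mapped source summits are accepted only when their lifted position is
    at least ``min_separation`` from every other accepted site of the same
    TF on the destination genome, so planted labels are recovered free of
    neighbour cross-talk.  Destination-only gain peaks stay clear of every
    source site's compensatory window.
    """
    index = genome.index
    src_names = sorted(genome.chrom_sizes_src)
    out: dict[str, TFPeakSet] = {}
    for tf in sorted(cfg.tf_panel):
        tfc = cfg.tf_panel[tf]
        excl = _ExclusionMap(cfg.min_separation)
        src_peaks: list[Peak] = []
        src_labels: list[str] = []
        dst_peaks: list[Peak] = []
        dst_roles: list[str] = []
        n_mapped = 0
        n_unmapped = 0
        attempts = 0
        max_attempts = 60 * tfc.n_peaks
        while n_mapped < tfc.n_peaks and attempts < max_attempts:
            attempts += 1
            chrom = src_names[int(rng.integers(len(src_names)))]
            size = genome.chrom_sizes_src[chrom]
            summit = int(rng.integers(cfg.flank + 1, size - cfg.flank - 1))
            probe = Peak(
                GenomeInterval(chrom, summit, summit + 1), summit, 0.0, factor=tf
            )
            res = lift_summit_window(probe, index, flank=cfg.flank)
            if not res.is_mapped:
                # keep a share of unmapped source sites (they exercise the
                # mapped-only denominator); cap at the natural rate
                if n_unmapped >= 0.5 * tfc.n_peaks:
                    continue
                n_unmapped += 1
                src_peaks.append(
                    _draw_peak(rng, chrom, summit, size, cfg, tf, "mouse")
                )
                src_labels.append("unmapped")
                continue
            q_iv = res.mapped_interval
            q_center = q_iv.midpoint
            if excl.conflicts(q_iv.chrom, q_center):
                continue
            excl.add(q_iv.chrom, q_center)
            n_mapped += 1
            conserved = rng.random() < tfc.p_cons
            boost = tfc.score_cons_boost if conserved else 0.0
            src_peaks.append(
                _draw_peak(rng, chrom, summit, size, cfg, tf, "mouse", mu_boost=boost)
            )
            q_size = genome.chrom_sizes_dst[q_iv.chrom]
            if conserved:
                src_labels.append("conserved")
                jitter = int(rng.integers(-cfg.flank, cfg.flank + 1))
                dst_summit = min(max(q_center + jitter, q_iv.start), q_iv.end - 1)
                dst_peaks.append(
                    _draw_peak(
                        rng, q_iv.chrom, int(dst_summit), q_size, cfg, tf, "human",
                        mu_boost=tfc.score_cons_boost,
                    )
                )
                dst_roles.append("conserved")
            else:
                src_labels.append("lost")
                if rng.random() < tfc.p_comp:
                    gap = int(rng.integers(cfg.comp_gap[0], cfg.comp_gap[1] + 1))
                    w_half = cfg.peak_width[1] // 2 + 1
                    if rng.random() < 0.5:
                        dst_summit = q_iv.end + gap + w_half
                    else:
                        dst_summit = q_iv.start - gap - w_half
                    if 0 < dst_summit < q_size:
                        dst_peaks.append(
                            _draw_peak(
                                rng, q_iv.chrom, int(dst_summit), q_size, cfg, tf, "human"
                            )
                        )
                        dst_roles.append("compensatory")
        if n_mapped < tfc.n_peaks:
            raise RuntimeError(
                f"could not place {tfc.n_peaks} mapped {tf} peaks; "
                "genome too small for the requested separation"
            )
        # destination-only gains, clear of every source site's window
        dst_names = sorted(genome.chrom_sizes_dst)
        gain_sep = cfg.comp_window + cfg.peak_width[1] + 2 * cfg.flank + 100
        n_gain = 0
        attempts = 0
        while n_gain < tfc.n_gain and attempts < 60 * tfc.n_gain:
            attempts += 1
            chrom = dst_names[int(rng.integers(len(dst_names)))]
            q_size = genome.chrom_sizes_dst[chrom]
            pos = int(rng.integers(cfg.peak_width[1], q_size - cfg.peak_width[1]))
            if excl.conflicts(chrom, pos, sep=gain_sep):
                continue
            excl.add(chrom, pos)
            dst_peaks.append(_draw_peak(rng, chrom, pos, q_size, cfg, tf, "human"))
            dst_roles.append("gain")
            n_gain += 1
        # planted strong gains: top decile of gains by score (the rule the
        # classifier applies)
        gains = [i for i, r in enumerate(dst_roles) if r == "gain"]
        k = math.ceil(0.10 * len(gains))
        order = sorted(
            gains,
            key=lambda i: (
                -dst_peaks[i].score, dst_peaks[i].chrom, dst_peaks[i].interval.start
            ),
        )
        for i in order[:k]:
            dst_roles[i] = "strong_gain"
        out[tf] = TFPeakSet(src_peaks, dst_peaks, src_labels, dst_roles)
    return out


# ---------------------------------------------------------------------------
# co-occupancy regions with planted retention
# ---------------------------------------------------------------------------

@dataclass
class PlantedRegions:
    src_peaks_by_tf: dict[str, list[Peak]]
    dst_peaks_by_tf: dict[str, list[Peak]]
    groups: list[frozenset]     # planted group per source region
    retained: list[bool]


def generate_coregion_peaks(
    cfg: SyntheticConfig, genome: GenomePair, rng: np.random.Generator
) -> PlantedRegions:
    """Plant combinatorial co-occupancy regions with group-specific
    cross-species retention (full group retained or absent)."""
    co = cfg.cooccupancy
    panel = list(co.panel)
    singles = [frozenset([t]) for t in panel]
    import itertools

    pairs = [frozenset(c) for c in itertools.combinations(panel, 2)]
    triple = frozenset(panel)
    plan: list[tuple[frozenset, float]] = []
    plan += [(triple, co.retention_triple)] * co.n_triple
    for i in range(co.n_pair):
        plan.append((pairs[i % len(pairs)], co.retention_pair))
    for i in range(co.n_single):
        plan.append((singles[i % len(singles)], co.retention_single))
    # retention planted as an exact per-group count (shuffled), so the
    # planted proportion is the configured rate, not a Bernoulli draw
    by_group: dict[frozenset, list[int]] = {}
    for i, (g, _) in enumerate(plan):
        by_group.setdefault(g, []).append(i)
    keep_flags = np.zeros(len(plan), dtype=bool)
    for g, idx in by_group.items():
        rate = next(r for gg, r in plan if gg == g)
        k = int(round(rate * len(idx)))
        chosen = rng.permutation(len(idx))[:k]
        for c in chosen:
            keep_flags[idx[c]] = True

    index = genome.index
    src_names = sorted(genome.chrom_sizes_src)
    excl = _ExclusionMap(6000)
    src_by_tf: dict[str, list[Peak]] = {t: [] for t in panel}
    dst_by_tf: dict[str, list[Peak]] = {t: [] for t in panel}
    groups: list[frozenset] = []
    retained: list[bool] = []
    attempts = 0
    max_attempts = 80 * len(plan)
    i_plan = 0
    while i_plan < len(plan) and attempts < max_attempts:
        attempts += 1
        group, _ = plan[i_plan]
        chrom = src_names[int(rng.integers(len(src_names)))]
        size = genome.chrom_sizes_src[chrom]
        center = int(rng.integers(1000, size - 1000))
        probe = Peak(GenomeInterval(chrom, center, center + 1), center, 0.0)
        res = lift_summit_window(probe, index, flank=cfg.flank)
        if not res.is_mapped:
            continue
        q_iv = res.mapped_interval
        if excl.conflicts(q_iv.chrom, q_iv.midpoint):
            continue
        if excl.conflicts(chrom, center):  # also keep source side separated
            continue
        excl.add(q_iv.chrom, q_iv.midpoint)
        excl.add(chrom, center)
        offsets = rng.integers(-400, 401, len(group))
        keep = bool(keep_flags[i_plan])
        for tf, off in zip(sorted(group), offsets):
            s = int(center + off)
            src_by_tf[tf].append(
                _draw_peak(rng, chrom, s, size, cfg, tf, "mouse")
            )
            if keep:
                q_size = genome.chrom_sizes_dst[q_iv.chrom]
                d = min(max(q_iv.midpoint + int(off), 1), q_size - 2)
                dst_by_tf[tf].append(
                    _draw_peak(rng, q_iv.chrom, d, q_size, cfg, tf, "human")
                )
        groups.append(group)
        retained.append(keep)
        i_plan += 1
    if i_plan < len(plan):
        raise RuntimeError("could not place all planted co-occupancy regions")
    return PlantedRegions(src_by_tf, dst_by_tf, groups, retained)


# ---------------------------------------------------------------------------
# promoter marks, expression, tags
# ---------------------------------------------------------------------------

@dataclass
class MarksExpression:
    X_src: pd.DataFrame          # planted log2(1+rpm) promoter matrix, mouse
    X_dst: pd.DataFrame          # human
    y_src: pd.Series             # planted ProE log2 expression (pre-floor)
    y_dst: pd.Series
    expr_src: ExpressionTable
    expr_dst: ExpressionTable
    beta: pd.Series
    sigma: float
    human_specific: list[str]    # dst gene ids
    mouse_specific: list[str]
    gene_categories_dst: dict[str, str]


def _beta_vector(cfg: SyntheticConfig) -> pd.Series:
    return pd.Series({m: float(cfg.beta_true.get(m, 0.0)) for m in cfg.marks})


def generate_marks_expression(
    cfg: SyntheticConfig,
    genome: GenomePair,
    peaks: dict[str, TFPeakSet] | None,
    rng: np.random.Generator,
) -> MarksExpression:
    """Planted promoter matrices and the expression they generate.

    Ortholog pairs share a latent mark intensity with small per-species
    jitter; a planted fraction of pairs receives a mark shift along the
    positive model coefficients (species-specific genes).  Expression is
    ``intercept + X beta + category offset + N(0, sigma^2)`` with sigma
    set from the target coefficient of determination
    (``sigma^2 = Var(X beta) (1 - R2) / R2``).
    """
    beta = _beta_vector(cfg)
    marks = list(cfg.marks)
    nm = len(marks)

    src_ids = [g.gene_id for g in genome.genes_src]
    dst_ids = [g.gene_id for g in genome.genes_dst]
    pair_src = {a for a, _ in genome.pairs}
    dst_of = dict(genome.pairs)

    def raw_to_log(x):
        return np.log2(1.0 + cfg.mark_scale * (np.exp2(x) - 1.0))

    X_src = pd.DataFrame(index=src_ids, columns=marks, dtype=float)
    X_dst = pd.DataFrame(index=dst_ids, columns=marks, dtype=float)
    for sid in src_ids:
        base = rng.gamma(cfg.mark_shape, cfg.mark_gamma_scale, nm)
        X_src.loc[sid] = raw_to_log(base)
        if sid in pair_src:
            jitter = rng.normal(0, cfg.mark_coupling_sd, nm)
            X_dst.loc[dst_of[sid]] = np.maximum(0.0, raw_to_log(base) + jitter)
    # destination-only genes (none by construction, but keep general)
    for did in dst_ids:
        if X_dst.loc[did].isna().any():
            base = rng.gamma(cfg.mark_shape, cfg.mark_gamma_scale, nm)
            X_dst.loc[did] = raw_to_log(base)

    # planted species-specific genes: mark shift along positive coefficients
    n_pairs = len(genome.pairs)
    k = int(n_pairs * cfg.specific_fraction)
    perm = rng.permutation(n_pairs)
    hs_pairs = [genome.pairs[i] for i in perm[:k]]
    ms_pairs = [genome.pairs[i] for i in perm[k : 2 * k]]
    pos = beta.clip(lower=0.0)
    denom = float((pos**2).sum())
    shift_vec = (cfg.specific_shift * pos / denom).to_numpy()
    for _, did in hs_pairs:
        X_dst.loc[did] += shift_vec
    for sid, _ in ms_pairs:
        X_src.loc[sid] += shift_vec

    bx = beta.to_numpy()
    signal_src = X_src.to_numpy() @ bx
    if cfg.sigma is not None:
        sigma = cfg.sigma
    else:
        var_signal = float(np.var(signal_src))
        sigma = math.sqrt(var_signal * (1.0 - cfg.target_r2) / cfg.target_r2)

    cat_offsets = {}
    gene_categories: dict[str, str] = {}
    if peaks is not None:
        intervals_by_label: dict[str, list[GenomeInterval]] = {
            "conserved": [], "strongly_gained": [], "compensatory": [],
            "gained": [], "lost": [],
        }
        index = genome.index
        for tf, ps in peaks.items():
            role_map = {
                "conserved": "conserved", "compensatory": "compensatory",
                "gain": "gained", "strong_gain": "strongly_gained",
            }
            for p, role in zip(ps.dst_peaks, ps.dst_roles):
                intervals_by_label[role_map[role]].append(p.interval)
            for p, lab in zip(ps.src_peaks, ps.src_labels):
                if lab == "lost":
                    res = lift_summit_window(p, index, flank=cfg.flank)
                    if res.is_mapped:
                        intervals_by_label["lost"].append(res.mapped_interval)
        gene_categories = assign_gene_categories(
            genome.genes_dst, intervals_by_label, window=cfg.proximity_window
        )
        if cfg.plant_category_offsets:
            cat_offsets = dict(cfg.category_offsets)

    src_of = {b: a for a, b in genome.pairs}

    def category_offset_dst(did: str) -> float:
        return cat_offsets.get(gene_categories.get(did, "none"), 0.0)

    def category_offset_src(sid: str) -> float:
        did = dst_of.get(sid)
        return category_offset_dst(did) if did else 0.0

    eps_src = rng.normal(0, sigma, len(src_ids))
    eps_dst = rng.normal(0, sigma, len(dst_ids))
    y_src = pd.Series(
        cfg.expr_intercept
        + signal_src
        + np.array([category_offset_src(s) for s in src_ids])
        + eps_src,
        index=src_ids,
    )
    y_dst = pd.Series(
        cfg.expr_intercept
        + X_dst.to_numpy() @ bx
        + np.array([category_offset_dst(d) for d in dst_ids])
        + eps_dst,
        index=dst_ids,
    )

    def expression_table(y: pd.Series, stages: Sequence[str]) -> ExpressionTable:
        rows = []
        drift = np.zeros(len(y))
        for si, stage in enumerate(stages):
            if si > 0:
                drift = drift + rng.normal(0, cfg.stage_drift_sd, len(y))
            for rep in range(1, cfg.n_replicates + 1):
                noise = rng.normal(0, cfg.replicate_sd, len(y))
                fpkm = np.maximum(0.0, np.exp2(y.to_numpy() + drift + noise) - 1.0)
                rows.append(
                    pd.DataFrame(
                        {
                            "gene_id": y.index,
                            "stage": stage,
                            "replicate": rep,
                            "fpkm": np.round(fpkm, 4),
                        }
                    )
                )
        return ExpressionTable(pd.concat(rows, ignore_index=True))

    expr_src = expression_table(y_src, cfg.stages_mouse)
    expr_dst = expression_table(y_dst, cfg.stages_human)
    return MarksExpression(
        X_src, X_dst, y_src, y_dst, expr_src, expr_dst, beta, sigma,
        [d for _, d in hs_pairs], [s for s, _ in ms_pairs], gene_categories,
    )


def generate_tags(
    cfg: SyntheticConfig,
    genes: Sequence[GeneRecord],
    X: pd.DataFrame,
    chrom_sizes: dict[str, int],
    rng: np.random.Generator,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Tag (read) tables per mark plus one shared input-control table.

    Promoter tags are Poisson-thinned from the planted rpm intensities so
    the pileup/normalize/promoter-matrix path recovers the planted matrix;
    the remaining depth is uniform background, and the input control is a
    uniform library of its own.
    """
    W = cfg.promoter_upstream + cfg.promoter_downstream
    read_len = 36
    chroms = sorted(chrom_sizes)
    totals = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = totals / totals.sum()

    def uniform_tags(n: int) -> pd.DataFrame:
        counts = rng.multinomial(n, probs)
        frames = []
        for c, k in zip(chroms, counts):
            hi = chrom_sizes[c] - cfg.fragment_length
            starts = rng.integers(0, hi, k)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": c,
                        "start": starts,
                        "end": starts + read_len,
                        "strand": np.where(rng.random(k) < 0.5, "+", "-"),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    windows = []
    for g in genes:
        if g.strand == "+":
            s, e = g.tss - cfg.promoter_upstream, g.tss + cfg.promoter_downstream
        else:
            s, e = g.tss + 1 - cfg.promoter_downstream, g.tss + 1 + cfg.promoter_upstream
        size = chrom_sizes[g.chrom]
        windows.append((g.chrom, max(0, s), min(e, size)))

    out: dict[str, pd.DataFrame] = {}
    for mark in X.columns:
        rpm = np.exp2(X[mark].to_numpy(float)) - 1.0
        lam = rpm * (W / cfg.fragment_length) * (cfg.n_reads / 1e6)
        counts = rng.poisson(lam)
        frames = []
        for (chrom, s, e), k in zip(windows, counts):
            if k == 0:
                continue
            lo = max(0, s - cfg.fragment_length + read_len)
            starts = rng.integers(lo, max(lo + 1, e - read_len), k)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": starts + read_len,
                        "strand": "+",
                    }
                )
            )
        n_promoter = int(counts.sum())
        n_bg = max(0, cfg.n_reads - n_promoter)
        frames.append(uniform_tags(n_bg))
        df = pd.concat(frames, ignore_index=True)
        out[mark] = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    input_df = uniform_tags(cfg.n_input_reads)
    input_df = input_df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return out, input_df


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def generate_segmentation(
    cfg: SyntheticConfig,
    chrom_sizes: dict[str, int],
    enriched_sites: Sequence[GenomeInterval],
    rng: np.random.Generator,
) -> list[StateSegment]:
    """Chromatin-state tiling with the active state enriched at given sites.

    Bins overlapping an enriched site draw the active state with a
    probability chosen so the *measured* fold enrichment of the active
    state at the sites, relative to its genome-wide fraction (which the
    hot bins themselves inflate), equals ``state_odds``.  All other bins
    draw from the background distribution.  The segmentation tiles each
    chromosome exactly.
    """
    p_bg = cfg.active_fraction
    # hot-bin share of the genome, to solve
    # p_site = F * (h*p_site + (1-h)*p_bg) for the target fold F
    n_total = sum(-(-s // cfg.state_bin) for s in chrom_sizes.values())
    hot_bins = set()
    for iv in enriched_sites:
        b0 = iv.start // cfg.state_bin
        b1 = -(-iv.end // cfg.state_bin)
        hot_bins.update((iv.chrom, b) for b in range(b0, b1))
    h = len(hot_bins) / n_total if n_total else 0.0
    F = cfg.state_odds
    if F * h >= 1.0:
        raise ValueError("enriched sites cover too much genome for the target fold")
    p_site = min(1.0, F * (1.0 - h) * p_bg / (1.0 - F * h))
    other_states = [s for s in range(1, cfg.n_states + 1) if s != cfg.active_state]
    # background mass over non-active states, heavier on the last
    # ("quiescent") state as in real segmentations
    w = np.ones(len(other_states))
    w[-1] = len(other_states)
    w = w / w.sum()
    segs: list[StateSegment] = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        nb = -(-size // cfg.state_bin)
        hot = np.zeros(nb, dtype=bool)
        for iv in enriched_sites:
            if iv.chrom != chrom:
                continue
            b0 = iv.start // cfg.state_bin
            b1 = -(-iv.end // cfg.state_bin)
            hot[b0:b1] = True
        p_active = np.where(hot, p_site, p_bg)
        active = rng.random(nb) < p_active
        states = np.array(other_states)[rng.choice(len(other_states), nb, p=w)]
        states[active] = cfg.active_state
        # merge equal-state runs
        change = np.flatnonzero(np.diff(states)) + 1
        bounds = np.concatenate([[0], change, [nb]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            start = int(a) * cfg.state_bin
            end = min(int(b) * cfg.state_bin, size)
            segs.append(StateSegment(GenomeInterval(chrom, start, end), int(states[a])))
    return segs


# ---------------------------------------------------------------------------
# regression fixture (model-recovery testing without FPKM round-trips)
# ---------------------------------------------------------------------------

def make_regression_fixture(
    n: int = 2000,
    beta: dict | None = None,
    marks: Sequence[str] = MARKS,
    target_r2: float = 0.60,
    sigma: float | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, np.ndarray, pd.Series, float]:
    """Design matrix and response from the planted linear model.

    Noise is tuned so the population coefficient of determination equals
    ``target_r2`` given the realized Var(X beta):
    ``sigma^2 = Var(X beta) (1 - R2) / R2``.  Returns (X, y, beta, sigma).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    beta = dict(DEFAULT_BETA) if beta is None else beta
    bvec = pd.Series({m: float(beta.get(m, 0.0)) for m in marks})
    raw = rng.gamma(2.0, 0.5, size=(n, len(marks)))
    X = pd.DataFrame(
        np.log2(1.0 + 10.0 * (np.exp2(raw) - 1.0)),
        columns=list(marks),
        index=[f"g{i:05d}" for i in range(n)],
    )
    signal = X.to_numpy() @ bvec.to_numpy()
    if sigma is None:
        var_signal = float(np.var(signal))
        sigma = math.sqrt(var_signal * (1.0 - target_r2) / target_r2) if target_r2 < 1 else 0.0
    y = signal + rng.normal(0.0, sigma, n) if sigma > 0 else signal.copy()
    return X, y, bvec, sigma


# ---------------------------------------------------------------------------
# orchestration + file output
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    cfg: SyntheticConfig
    genome: GenomePair
    peaks: dict[str, TFPeakSet]
    regions: PlantedRegions
    marks_expr: MarksExpression
    segmentation: list[StateSegment]

    def ground_truth_summary(self) -> dict:
        gt = {
            "beta_true": {k: float(v) for k, v in self.marks_expr.beta.items()},
            "sigma": self.marks_expr.sigma,
            "n_ortholog_pairs": len(self.genome.pairs),
            "n_human_specific": len(self.marks_expr.human_specific),
            "n_mouse_specific": len(self.marks_expr.mouse_specific),
            "tf": {},
            "cooccupancy": {},
        }
        for tf, ps in self.peaks.items():
            gt["tf"][tf] = {
                "planted_p_cons": self.cfg.tf_panel[tf].p_cons,
                "planted_p_comp": self.cfg.tf_panel[tf].p_comp,
                "n_src": len(ps.src_peaks),
                "n_src_mapped": sum(1 for l in ps.src_labels if l != "unmapped"),
                "n_src_conserved": ps.src_labels.count("conserved"),
                "n_dst": len(ps.dst_peaks),
            }
        from collections import Counter

        counts = Counter()
        kept = Counter()
        from .cooccupancy import group_label

        for g, r in zip(self.regions.groups, self.regions.retained):
            counts[group_label(g)] += 1
            if r:
                kept[group_label(g)] += 1
        gt["cooccupancy"] = {
            lab: {"n": counts[lab], "retained": kept[lab]} for lab in sorted(counts)
        }
        return gt

    def write(self, outdir: str | os.PathLike, write_tags: bool = True,
              rng: np.random.Generator | None = None) -> None:
        """Emit the full fixture directory (text formats only)."""
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        write_chain(os.path.join(outdir, "alignment.chain"), self.genome.chains)
        write_gene_table(os.path.join(outdir, "genes_mouse.tsv"), self.genome.genes_src)
        write_gene_table(os.path.join(outdir, "genes_human.tsv"), self.genome.genes_dst)
        for tf, ps in self.peaks.items():
            write_peaks(os.path.join(outdir, f"peaks_mouse_{tf}.narrowPeak"), ps.src_peaks)
            write_peaks(os.path.join(outdir, f"peaks_human_{tf}.narrowPeak"), ps.dst_peaks)
        write_expression(
            os.path.join(outdir, "expression_mouse.tsv"), self.marks_expr.expr_src
        )
        write_expression(
            os.path.join(outdir, "expression_human.tsv"), self.marks_expr.expr_dst
        )
        self.marks_expr.X_src.to_csv(
            os.path.join(outdir, "promoter_marks_mouse.tsv"), sep="\t"
        )
        self.marks_expr.X_dst.to_csv(
            os.path.join(outdir, "promoter_marks_human.tsv"), sep="\t"
        )
        write_segmentation(os.path.join(outdir, "segmentation_human.bed"), self.segmentation)
        if write_tags:
            assert rng is not None, "tag output needs the generator rng"
            for species, genes, X, sizes in (
                ("mouse", self.genome.genes_src, self.marks_expr.X_src,
                 self.genome.chrom_sizes_src),
                ("human", self.genome.genes_dst, self.marks_expr.X_dst,
                 self.genome.chrom_sizes_dst),
            ):
                tag_tables, input_df = generate_tags(self.cfg, genes, X, sizes, rng)
                for mark, df in tag_tables.items():
                    _write_tag_df(
                        os.path.join(outdir, f"tags_{species}_{mark}.bed"), df
                    )
                _write_tag_df(os.path.join(outdir, f"input_{species}.bed"), input_df)
        sizes = {
            "mouse": self.genome.chrom_sizes_src,
            "human": self.genome.chrom_sizes_dst,
        }
        with open(os.path.join(outdir, "chrom_sizes.json"), "w") as fh:
            json.dump(sizes, fh, indent=1, sort_keys=True)
        with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
            json.dump(self.ground_truth_summary(), fh, indent=1, sort_keys=True)


def _write_tag_df(path, df: pd.DataFrame) -> None:
    out = df.copy()
    out["name"] = "."
    out["score"] = 0
    out[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def generate_all(cfg: SyntheticConfig, seed: int) -> tuple[SyntheticDataset, np.random.Generator]:
    """Run every generation stage under one seeded rng."""
    rng = np.random.default_rng(seed)
    genome = generate_genome_pair(cfg, rng)
    peaks = generate_peaks(cfg, genome, rng)
    regions = generate_coregion_peaks(cfg, genome, rng)
    marks_expr = generate_marks_expression(cfg, genome, peaks, rng)
    enriched = [
        p.interval
        for ps in peaks.values()
        for p, role in zip(ps.dst_peaks, ps.dst_roles)
        if role in ("conserved", "strong_gain")
    ]
    segmentation = generate_segmentation(cfg, genome.chrom_sizes_dst, enriched, rng)
    return SyntheticDataset(cfg, genome, peaks, regions, marks_expr, segmentation), rng
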