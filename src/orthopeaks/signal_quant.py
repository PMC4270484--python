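"""Tag pileup, input-normalized signal tracks, promoter matrices and
metagene profiles.

Signal follows the standard ChIP-seq quantification recipe: aligned tags
are extended 3'-ward to the library fragment length (200 bp default),
piled up into fixed-width bins, scaled to reads-per-million, and the
matched input control (also in RPM) is subtracted with flooring at zero.
Quantitative summaries are log2(1 + x) scaled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import GeneRecord, GenomeInterval

log = logging.getLogger(__name__)

__all__ = [
    "SignalTrack",
    "extend_and_pileup",
    "normalize_subtract",
    "promoter_matrix",
    "metagene_profile",
    "promoter_mark_class",
    "matrix_correlation",
]


@dataclass
class SignalTrack:
    """Per-chromosome binned coverage.

    Each bin holds the *mean per-base* coverage within the bin, so values
    are comparable across bin widths and a bin width of 1 is exact per-base
    coverage.
    """

    bin_width: int
    chrom_sizes: dict[str, int]
    data: dict[str, np.ndarray] = field(default_factory=dict)
    n_tags: int = 0

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.bin_width)

    def values(self, chrom: str) -> np.ndarray:
        if chrom not in self.data:
            self.data[chrom] = np.zeros(self.n_bins(chrom), dtype=np.float64)
        return self.data[chrom]

    def base_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end), clipped to the chromosome."""
        size = self.chrom_sizes[chrom]
        start = max(0, start)
        end = min(end, size)
        if start >= end:
            return np.zeros(0)
        vals = self.values(chrom)
        idx = np.arange(start, end) // self.bin_width
        return vals[idx]

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        v = self.base_values(chrom, start, end)
        return float(v.mean()) if v.size else 0.0

    def total_mass(self) -> float:
        """Sum of per-base coverage over the genome."""
        return float(
            sum(
                (vals * self._bin_base_counts(chrom)).sum()
                for chrom, vals in self.data.items()
            )
        )

    def _bin_base_counts(self, chrom: str) -> np.ndarray:
        size = self.chrom_sizes[chrom]
        nb = self.n_bins(chrom)
        counts = np.full(nb, self.bin_width, dtype=np.float64)
        rem = size - (nb - 1) * self.bin_width
        counts[-1] = rem
        return counts


def extend_and_pileup(
    tags: Iterable[GenomeInterval],
    chrom_sizes: Mapping[str, int],
    fragment_length: int = 200,
    bin_width: int = 25,
) -> SignalTrack:
    """Extend each tag to the fragment length from its 5' end and pile up.

    A '+' tag covers ``[start, start + L)``; a '-' tag covers
    ``[end - L, end)``.  Unstranded tags are treated as '+' with a warning.
    Fragments are clipped at chromosome boundaries.
    """
    track = SignalTrack(bin_width=bin_width, chrom_sizes=dict(chrom_sizes))
    starts_by_chrom: dict[str, list[tuple[int, int]]] = {}
    n_unstranded = 0
    n = 0
    for t in tags:
        n += 1
        strand = t.strand
        if strand == ".":
            n_unstranded += 1
            strand = "+"
        if strand == "+":
            s = t.start
            e = t.start + fragment_length
        else:
            e = t.end
            s = t.end - fragment_length
        size = track.chrom_sizes[t.chrom]
        s = max(0, s)
        e = min(e, size)
        if s < e:
            starts_by_chrom.setdefault(t.chrom, []).append((s, e))
    if n_unstranded:
        log.warning("%d unstranded tags treated as '+'", n_unstranded)
    track.n_tags = n
    for chrom, spans in starts_by_chrom.items():
        size = track.chrom_sizes[chrom]
        arr = np.array(spans, dtype=np.int64)
        diff = np.zeros(size + 1, dtype=np.float64)
        np.add.at(diff, arr[:, 0], 1.0)
        np.add.at(diff, arr[:, 1], -1.0)
        per_base = np.cumsum(diff[:-1])
        nb = track.n_bins(chrom)
        padded = np.zeros(nb * bin_width)
        padded[:size] = per_base
        binned = padded.reshape(nb, bin_width).sum(axis=1)
        binned /= track._bin_base_counts(chrom)
        track.data[chrom] = binned
    return track


def pileup_tag_frame(
    df: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    fragment_length: int = 200,
    bin_width: int = 25,
) -> SignalTrack:
    """Vectorized :func:`extend_and_pileup` for a tag table.

    ``df`` needs columns chrom/start/end/strand; unstranded rows count as
    '+'.  Used for large tag files where building per-tag objects would
    dominate runtime.
    """
    track = SignalTrack(bin_width=bin_width, chrom_sizes=dict(chrom_sizes))
    track.n_tags = len(df)
    plus = (df["strand"].to_numpy() != "-")
    s = np.where(plus, df["start"].to_numpy(), df["end"].to_numpy() - fragment_length)
    e = s + fragment_length
    chroms = df["chrom"].to_numpy()
    for chrom in track.chrom_sizes:
        size = track.chrom_sizes[chrom]
        sel = chroms == chrom
        if not sel.any():
            continue
        cs = np.clip(s[sel], 0, size)
        ce = np.clip(e[sel], 0, size)
        diff = np.zeros(size + 1, dtype=np.float64)
        np.add.at(diff, cs, 1.0)
        np.add.at(diff, ce, -1.0)
        per_base = np.cumsum(diff[:-1])
        nb = track.n_bins(chrom)
        padded = np.zeros(nb * bin_width)
        padded[:size] = per_base
        binned = padded.reshape(nb, bin_width).sum(axis=1)
        binned /= track._bin_base_counts(chrom)
        track.data[chrom] = binned
    return track


def normalize_subtract(
    treat: SignalTrack, input_ctrl: SignalTrack, n_treat: int, n_input: int
) -> SignalTrack:
    """Input-subtracted reads-per-million: max(0, treat_RPM - input_RPM)."""
    if n_treat <= 0 or n_input <= 0:
        raise ValueError("library sizes must be positive")
    if treat.bin_width != input_ctrl.bin_width:
        raise ValueError("treat and input tracks must share a bin width")
    out = SignalTrack(bin_width=treat.bin_width, chrom_sizes=dict(treat.chrom_sizes))
    for chrom in treat.chrom_sizes:
        t = treat.values(chrom) * (1e6 / n_treat)
        c = input_ctrl.values(chrom) * (1e6 / n_input) if chrom in input_ctrl.chrom_sizes else 0.0
        out.data[chrom] = np.maximum(0.0, t - c)
    return out


def _promoter_window(gene: GeneRecord, upstream: int, downstream: int) -> tuple[int, int]:
    """Strand-aware promoter window around the TSS, half-open."""
    if gene.strand == "+":
        return gene.tss - upstream, gene.tss + downstream
    return gene.tss + 1 - downstream, gene.tss + 1 + upstream


def promoter_matrix(
    tracks: Mapping[str, SignalTrack],
    genes: Sequence[GeneRecord],
    upstream: int = 2000,
    downstream: int = 2000,
) -> pd.DataFrame:
    """Genes x marks matrix of log2(1 + mean promoter-window signal).

    The window spans ``upstream`` bases 5' and ``downstream`` bases 3' of
    the TSS, oriented by gene strand and clipped at chromosome ends.
    """
    gene_ids = [g.gene_id for g in genes]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene_ids in promoter matrix")
    out = pd.DataFrame(index=gene_ids, columns=list(tracks), dtype=float)
    out.index.name = "gene_id"
    for mark, track in tracks.items():
        col = np.empty(len(genes))
        for i, g in enumerate(genes):
            s, e = _promoter_window(g, upstream, downstream)
            col[i] = track.mean_over(g.chrom, s, e)
        out[mark] = np.log2(1.0 + col)
    return out


def metagene_profile(
    track: SignalTrack,
    genes: Sequence[GeneRecord],
    flank: int = 2000,
    body_bins: int = 100,
) -> np.ndarray:
    """Average signal profile over genes: 5' flank, length-normalized body,
    3' flank.

    Flanks are reported at the track's native bin resolution
    (``flank // bin_width`` points each); the gene body (TSS..TES) is
    resampled to ``body_bins`` equal-width points.  Profiles of '-'-strand
    genes are reversed so all run 5'->3'.  Genes with body length below
    ``body_bins`` are skipped; with no eligible gene an error is raised.
    """
    if flank % track.bin_width:
        raise ValueError("flank must be a multiple of the track bin width")
    fb = flank // track.bin_width
    profiles = []
    for g in genes:
        if g.body_length < body_bins:
            continue
        lo = min(g.tss, g.tes)
        hi = max(g.tss, g.tes) + 1
        up = track.base_values(g.chrom, lo - flank, lo)
        body = track.base_values(g.chrom, lo, hi)
        down = track.base_values(g.chrom, hi, hi + flank)
        if up.size < flank:
            up = np.concatenate([np.zeros(flank - up.size), up])
        if down.size < flank:
            down = np.concatenate([down, np.zeros(flank - down.size)])
        # resample per-base arrays: flanks to native bins, body to body_bins
        up_r = up.reshape(fb, -1).mean(axis=1) if fb else np.zeros(0)
        down_r = down.reshape(fb, -1).mean(axis=1) if fb else np.zeros(0)
        edges = np.linspace(0, body.size, body_bins + 1).astype(int)
        body_r = np.array([body[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
        prof = np.concatenate([up_r, body_r, down_r])
        if g.strand == "-":
            prof = prof[::-1]
        profiles.append(prof)
    if not profiles:
        raise ValueError("no genes with body length >= body_bins")
    return np.mean(profiles, axis=0)


def promoter_mark_class(
    pm: pd.DataFrame,
    k4me3_min: float = 1.0,
    k27me3_min: float = 0.5,
    k4me3_col: str = "H3K4me3",
    k27me3_col: str = "H3K27me3",
) -> pd.Series:
    """Classify promoters as active/repressed/bivalent/neither.

    Thresholds are on the input-normalized RPM scale (>1 rpm H3K4me3 marks
    expressed genes, >0.5 rpm H3K27me3 marks repressed ones); matrix values
    are log2(1 + rpm) and are inverted before thresholding.
    """
    for col in (k4me3_col, k27me3_col):
        if col not in pm.columns:
            raise ValueError(f"promoter matrix lacks required column {col!r}")
    k4 = np.exp2(pm[k4me3_col]) - 1.0 > k4me3_min
    k27 = np.exp2(pm[k27me3_col]) - 1.0 > k27me3_min
    labels = np.where(
        k4 & k27, "bivalent", np.where(k4, "active", np.where(k27, "repressed", "neither"))
    )
    return pd.Series(labels, index=pm.index, name="promoter_class")


def matrix_correlation(a: pd.Series, b: pd.Series, method: str = "pearson") -> float:
    """Correlation between two promoter-matrix columns over shared genes.

    Returns NaN when either column has zero variance over the shared rows.
    """
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared genes")
    x = a.loc[shared].to_numpy(float)
    y = b.loc[shared].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")
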