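"""Interval mapping between genomes over UCSC chain alignments.

A chain describes a gapped pairwise alignment as an ordered list of
ungapped blocks ``(size, dt, dq)`` where ``dt``/``dq`` are the gaps that
follow the block on the target/query side.  Query coordinates of '-'-strand
chains are stored in the reverse-complement frame, exactly as the chain
format does; they are converted to forward-strand coordinates only when an
interval is actually mapped.

Mapping follows the classic liftOver semantics used for cross-species peak
transfer: an interval maps if at least ``min_match`` of its bases fall in
aligned blocks of a single best chain, and is rejected as split/ambiguous
if a second chain also reaches that threshold (one:one matching).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome_model import GenomeInterval, Peak

__all__ = [
    "ChainAlignment",
    "LiftResult",
    "read_chain",
    "write_chain",
    "lift_interval",
    "lift_summit_window",
    "ChainIndex",
]


@dataclass
class ChainAlignment:
    """One chain: target span, query span, and gap-separated blocks."""

    score: float
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    blocks: list[tuple[int, int, int]]  # (size, dt, dq); final block has dt=dq=0
    chain_id: int

    def __post_init__(self) -> None:
        if self.t_strand != "+":
            raise ValueError(f"chain {self.chain_id}: target strand must be '+'")
        sizes = sum(b[0] for b in self.blocks)
        dts = sum(b[1] for b in self.blocks)
        dqs = sum(b[2] for b in self.blocks)
        if any(b[0] <= 0 for b in self.blocks):
            raise ValueError(f"chain {self.chain_id}: block sizes must be > 0")
        if any(b[1] < 0 or b[2] < 0 for b in self.blocks):
            raise ValueError(f"chain {self.chain_id}: gaps must be >= 0")
        if sizes + dts != self.t_end - self.t_start:
            raise ValueError(
                f"chain {self.chain_id}: target block sum {sizes + dts} != "
                f"span {self.t_end - self.t_start}"
            )
        if sizes + dqs != self.q_end - self.q_start:
            raise ValueError(
                f"chain {self.chain_id}: query block sum {sizes + dqs} != "
                f"span {self.q_end - self.q_start}"
            )
        # precompute block start positions (target frame / query chain frame)
        t_starts, q_starts = [], []
        t, q = self.t_start, self.q_start
        for size, dt, dq in self.blocks:
            t_starts.append(t)
            q_starts.append(q)
            t += size + dt
            q += size + dq
        self._t_starts = t_starts
        self._q_starts = q_starts
        self._sizes = [b[0] for b in self.blocks]

    def map_base(self, t_pos: int) -> int | None:
        """Forward-strand query position of one target base, or None."""
        i = bisect.bisect_right(self._t_starts, t_pos) - 1
        if i < 0:
            return None
        off = t_pos - self._t_starts[i]
        if off >= self._sizes[i]:
            return None
        q = self._q_starts[i] + off
        if self.q_strand == "-":
            return self.q_size - 1 - q
        return q

    def _block_range(self, start: int, end: int) -> range:
        """Indices of blocks that can overlap target [start, end)."""
        i = max(0, bisect.bisect_right(self._t_starts, start) - 1)
        j = bisect.bisect_left(self._t_starts, end)
        return range(i, j)

    def aligned_bases_in(self, start: int, end: int) -> int:
        """Number of bases of target [start, end) inside aligned blocks."""
        n = 0
        for k in self._block_range(start, end):
            bs, size = self._t_starts[k], self._sizes[k]
            lo = max(start, bs)
            hi = min(end, bs + size)
            if lo < hi:
                n += hi - lo
        return n

    def swapped(self, chain_id: int | None = None) -> "ChainAlignment":
        """The reverse chain (query becomes target), for round-trip mapping."""
        if self.q_strand == "+":
            blocks = [(size, dq, dt) for size, dt, dq in self.blocks]
            return ChainAlignment(
                self.score, self.q_name, self.q_size, "+", self.q_start, self.q_end,
                self.t_name, self.t_size, "+", self.t_start, self.t_end,
                blocks, chain_id if chain_id is not None else self.chain_id,
            )
        # '-' strand: reverse block order; new target is the query in forward
        # frame, new query is stored in reverse-complement frame of old target.
        rev = list(reversed(self.blocks))
        blocks = []
        for i, (size, dt, dq) in enumerate(rev):
            # gaps that followed block i-1 in the original now follow block i
            if i + 1 < len(rev):
                _, pdt, pdq = rev[i + 1]
            else:
                pdt = pdq = 0
            blocks.append((size, pdq, pdt))
        return ChainAlignment(
            self.score,
            self.q_name, self.q_size, "+",
            self.q_size - self.q_end, self.q_size - self.q_start,
            self.t_name, self.t_size, "-",
            self.t_size - self.t_end, self.t_size - self.t_start,
            blocks, chain_id if chain_id is not None else self.chain_id,
        )


@dataclass
class LiftResult:
    """Outcome of mapping one interval across genomes."""

    status: str  # mapped | unmapped_low_match | unmapped_split | unmapped_no_chain
    mapped_interval: GenomeInterval | None
    match_fraction: float
    chain_id: int | None = None

    @property
    def is_mapped(self) -> bool:
        return self.status == "mapped"


def read_chain(path) -> list[ChainAlignment]:
    """Parse a UCSC chain file, validating block-sum consistency."""
    chains: list[ChainAlignment] = []
    header: list[str] | None = None
    blocks: list[tuple[int, int, int]] = []

    def finish():
        nonlocal header, blocks
        if header is None:
            return
        if not blocks:
            raise ValueError(f"chain {header[-1]}: truncated (no blocks)")
        h = header
        chains.append(
            ChainAlignment(
                score=float(h[1]),
                t_name=h[2], t_size=int(h[3]), t_strand=h[4],
                t_start=int(h[5]), t_end=int(h[6]),
                q_name=h[7], q_size=int(h[8]), q_strand=h[9],
                q_start=int(h[10]), q_end=int(h[11]),
                blocks=blocks, chain_id=int(h[12]),
            )
        )
        header, blocks = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                if header is not None and blocks and blocks[-1][1:] == (0, 0):
                    finish()
                elif header is not None:
                    raise ValueError(f"{path}:{lineno}: previous chain truncated")
                header = line.split()
                if len(header) != 13:
                    raise ValueError(f"{path}:{lineno}: chain header needs 13 fields")
            else:
                if header is None:
                    raise ValueError(f"{path}:{lineno}: block outside a chain")
                parts = line.split()
                if len(parts) == 1:
                    blocks.append((int(parts[0]), 0, 0))
                elif len(parts) == 3:
                    blocks.append((int(parts[0]), int(parts[1]), int(parts[2])))
                else:
                    raise ValueError(f"{path}:{lineno}: malformed block line")
    if header is not None:
        if not blocks or blocks[-1][1:] != (0, 0):
            raise ValueError(f"{path}: truncated final chain")
        finish()
    return chains


def write_chain(path, chains: Sequence[ChainAlignment]) -> None:
    with open(path, "w") as fh:
        for c in chains:
            fh.write(
                f"chain {c.score:g} {c.t_name} {c.t_size} {c.t_strand} "
                f"{c.t_start} {c.t_end} {c.q_name} {c.q_size} {c.q_strand} "
                f"{c.q_start} {c.q_end} {c.chain_id}\n"
            )
            for i, (size, dt, dq) in enumerate(c.blocks):
                if i + 1 == len(c.blocks):
                    fh.write(f"{size}\n\n")
                else:
                    fh.write(f"{size} {dt} {dq}\n")


class ChainIndex:
    """Chains grouped by target chromosome for repeated lifting."""

    def __init__(self, chains: Iterable[ChainAlignment]):
        self.by_chrom: dict[str, list[ChainAlignment]] = {}
        for c in chains:
            self.by_chrom.setdefault(c.t_name, []).append(c)

    def chrom_size(self, chrom: str) -> int | None:
        chains = self.by_chrom.get(chrom)
        return chains[0].t_size if chains else None


def lift_interval(
    iv: GenomeInterval,
    chains: Iterable[ChainAlignment] | ChainIndex,
    min_match: float = 0.10,
    require_unique: bool = True,
) -> LiftResult:
    """Map a target-genome interval to the query genome.

    The lifted interval is the bounding span of the images of the first and
    last aligned base (internal gaps are spanned, not excised), on
    forward-strand query coordinates.  ``match_fraction`` is the fraction of
    the interval's bases inside aligned blocks of the single
    best-overlapping chain; with ``require_unique`` the lift is rejected as
    ``unmapped_split`` when a second chain also reaches ``min_match``.
    """
    if not (0 < min_match <= 1):
        raise ValueError(f"min_match must be in (0, 1], got {min_match}")
    index = chains if isinstance(chains, ChainIndex) else ChainIndex(chains)
    candidates = index.by_chrom.get(iv.chrom)
    if not candidates:
        return LiftResult("unmapped_no_chain", None, 0.0)

    scored = []
    for c in candidates:
        n_aligned = c.aligned_bases_in(iv.start, iv.end)
        if n_aligned > 0:
            scored.append((n_aligned, c.score, -c.chain_id, c))
    if not scored:
        return LiftResult("unmapped_low_match", None, 0.0)
    scored.sort(key=lambda t: t[:3], reverse=True)
    best_aligned, _, _, best = scored[0]
    frac = best_aligned / iv.length
    if frac < min_match:
        return LiftResult("unmapped_low_match", None, frac, best.chain_id)
    if require_unique:
        for n_aligned, _, _, other in scored[1:]:
            if other is not best and n_aligned / iv.length >= min_match:
                return LiftResult("unmapped_split", None, frac, best.chain_id)

    first = last = None
    for k in best._block_range(iv.start, iv.end):
        bs, size = best._t_starts[k], best._sizes[k]
        lo = max(iv.start, bs)
        hi = min(iv.end, bs + size)
        if lo < hi:
            if first is None:
                first = lo
            last = hi - 1
    q1 = best.map_base(first)
    q2 = best.map_base(last)
    lo, hi = min(q1, q2), max(q1, q2)
    strand = "+" if best.q_strand == "+" else "-"
    mapped = GenomeInterval(best.q_name, lo, hi + 1, strand)
    return LiftResult("mapped", mapped, frac, best.chain_id)


def lift_summit_window(
    peak: Peak,
    chains: Iterable[ChainAlignment] | ChainIndex,
    flank: int = 50,
    min_match: float = 0.10,
    require_unique: bool = True,
) -> LiftResult:
    """Lift the narrow window summit +/- ``flank`` of a peak.

    The window ``[summit - flank, summit + flank + 1)`` is clipped at
    chromosome bounds (size taken from the chains when available).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    index = chains if isinstance(chains, ChainIndex) else ChainIndex(chains)
    start = max(0, peak.summit - flank)
    end = peak.summit + flank + 1
    size = index.chrom_size(peak.chrom)
    if size is not None:
        end = min(end, size)
    if start >= end:  # summit beyond declared chromosome end
        return LiftResult("unmapped_no_chain", None, 0.0)
    window = GenomeInterval(peak.chrom, start, end)
    return lift_interval(window, index, min_match=min_match, require_unique=require_unique)
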