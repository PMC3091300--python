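"""Aligned-read containers and the shared preprocessing steps.

All ChIP-seq callers in this package consume the same three primitives:
a strand-aware set of 5' alignment positions (:class:`ReadDataset`), a
per-position duplicate cap derived from a Poisson model of the uniquely
mappable genome (:func:`cap_duplicates`), and overlapping extended-read
counts on an interleaved bin tiling (:func:`extend_reads` /
:func:`bin_counts`).

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ReadDataset",
    "BinnedCounts",
    "PoissonCap",
    "cap_duplicates",
    "extend_reads",
    "bin_counts",
]


@dataclass
class ReadDataset:
    """Strand-aware aligned 5' positions per chromosome.

    Parameters
    ----------
    chrom_lengths
        Mapping chromosome name -> length in bp.
    positions
        Mapping chromosome -> int64 array of 0-based 5' positions.
    strands
        Mapping chromosome -> int8 array aligned with ``positions``;
        ``+1`` for forward reads, ``-1`` for reverse reads.
    """

    chrom_lengths: dict[str, int]
    positions: dict[str, np.ndarray] = field(default_factory=dict)
    strands: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, L in self.chrom_lengths.items():
            pos = np.asarray(self.positions.get(chrom, np.empty(0, dtype=np.int64)), dtype=np.int64)
            strand = np.asarray(self.strands.get(chrom, np.empty(0, dtype=np.int8)), dtype=np.int8)
            if pos.size != strand.size:
                raise ValueError(f"{chrom}: positions and strands differ in length")
            if pos.size and (pos.min() < 0 or pos.max() >= L):
                raise ValueError(f"{chrom}: read position outside [0, {L})")
            order = np.lexsort((strand, pos))
            self.positions[chrom] = pos[order]
            self.strands[chrom] = strand[order]
        for chrom in self.positions:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"reads on unknown chromosome {chrom!r}")

    @property
    def total(self) -> int:
        return int(sum(p.size for p in self.positions.values()))

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    def subset(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.positions.get(chrom, np.empty(0, dtype=np.int64)),
            self.strands.get(chrom, np.empty(0, dtype=np.int8)),
        )


@dataclass
class BinnedCounts:
    """Overlapping extended-read counts on a strided bin tiling.

    Bin ``i`` of a chromosome spans ``[i * offset, i * offset + width)``.
    ``offset < width`` produces the interleaved tiling used by the event
    caller (50-bp bins every 25 bp).  Counts may be non-integer when a
    channel has been depth-scaled.
    """

    width: int
    offset: int
    counts: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("bin width must be positive")
        if not (0 < self.offset <= self.width):
            raise ValueError("bin offset must satisfy 0 < offset <= width")

    def n_bins(self, chrom: str) -> int:
        return self.counts[chrom].size

    def bin_start(self, i: int | np.ndarray) -> int | np.ndarray:
        return i * self.offset

    def genome_mean(self) -> float:
        total = sum(float(c.sum()) for c in self.counts.values())
        n = sum(c.size for c in self.counts.values())
        return total / n if n else 0.0

    def scaled(self, factor: float) -> "BinnedCounts":
        return BinnedCounts(
            self.width,
            self.offset,
            {c: v * factor for c, v in self.counts.items()},
            self.chrom_lengths,
        )


@dataclass(frozen=True)
class PoissonCap:
    """Duplicate cap from a per-base Poisson model of mappable positions."""

    rate: float
    p_threshold: float
    cap: int


def poisson_cap(rate: float, p_threshold: float = 1e-7) -> int:
    """Largest c >= 1 whose Poisson upper tail P(X >= c) is still >= threshold.

    Reads stacking deeper than expected at this probability from a per-base
    Poisson model are treated as amplification artifacts and truncated.
    The cap is clamped at 1 so that sparse data never discard everything.
    """
    if not (0.0 < p_threshold < 1.0):
        raise ValueError("p_threshold must lie in (0, 1)")
    if rate <= 0:
        return 1
    c = 1
    # P(X >= c) = sf(c - 1); walk up while the tail stays above threshold
    while stats.poisson.sf(c, rate) >= p_threshold:
        c += 1
        if c > 10_000_000:  # pragma: no cover - pathological rate
            raise RuntimeError("duplicate cap search did not terminate")
    return max(c, 1)


def cap_duplicates(
    reads: ReadDataset,
    mappable_bases: int,
    p_threshold: float = 1e-7,
    *,
    strand_aware: bool = True,
) -> tuple[ReadDataset, PoissonCap]:
    """Discard reads stacked at one position beyond the Poisson-expected depth.

    The per-base rate is ``total reads / mappable_bases``; the cap is the
    deepest stack still compatible with that rate at ``p_threshold``.
    Duplicates are counted per (position, strand) by default because 5'
    alignment coordinates of opposite-strand reads refer to different
    fragment ends; set ``strand_aware=False`` for the strand-blind variant.
    """
    if mappable_bases <= 0:
        raise ValueError("mappable_bases must be positive")
    rate = reads.total / mappable_bases
    cap = poisson_cap(rate, p_threshold)
    new_pos: dict[str, np.ndarray] = {}
    new_strand: dict[str, np.ndarray] = {}
    for chrom in reads.chroms():
        pos, strand = reads.subset(chrom)
        if pos.size == 0:
            new_pos[chrom] = pos
            new_strand[chrom] = strand
            continue
        key = pos * 2 + (strand > 0) if strand_aware else pos
        # data are sorted by (pos, strand): rank within each run of equal keys
        change = np.empty(key.size, dtype=bool)
        change[0] = True
        change[1:] = key[1:] != key[:-1]
        run_start = np.maximum.accumulate(np.where(change, np.arange(key.size), 0))
        rank = np.arange(key.size) - run_start
        keep = rank < cap
        new_pos[chrom] = pos[keep]
        new_strand[chrom] = strand[keep]
    capped = ReadDataset(dict(reads.chrom_lengths), new_pos, new_strand)
    return capped, PoissonCap(rate=rate, p_threshold=p_threshold, cap=cap)


def extend_reads(
    reads: ReadDataset, extension: tuple[int, int]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Extend each read into an interval mirroring the binding-model shape.

    ``extension = (eL, eR)`` are the absolute offsets where the binding
    model's density crosses the uniform density over the same support.  A
    forward read at p becomes ``[p - eL, p + eR)``; a reverse read is the
    exact coordinate reflection, ``[p - eR + 1, p + eL + 1)``.  Intervals
    are clipped to chromosome bounds.  Returns per-chromosome
    (starts, ends) arrays aligned with the dataset's read order.
    """
    eL, eR = extension
    if eL < 0 or eR < 0:
        raise ValueError("extension offsets must be non-negative")
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in reads.chroms():
        pos, strand = reads.subset(chrom)
        fwd = strand > 0
        starts = np.where(fwd, pos - eL, pos - eR + 1)
        ends = np.where(fwd, pos + eR, pos + eL + 1)
        L = reads.chrom_lengths[chrom]
        np.clip(starts, 0, L, out=starts)
        np.clip(ends, 0, L, out=ends)
        out[chrom] = (starts, ends)
    return out


def bin_counts(
    intervals: dict[str, tuple[np.ndarray, np.ndarray]],
    chrom_lengths: dict[str, int],
    width: int = 50,
    offset: int = 25,
    scale: float = 1.0,
) -> BinnedCounts:
    """Count intervals overlapping each bin of a strided tiling.

    An interval [a, b) overlaps bin [x, y) iff a < y and x < b (half-open
    semantics on both sides).  Counts are multiplied by ``scale`` so a
    depth-scaled control channel can be represented directly.
    """
    if width <= 0 or not (0 < offset <= width):
        raise ValueError("invalid bin geometry")
    counts: dict[str, np.ndarray] = {}
    for chrom, L in chrom_lengths.items():
        n_bins = max((L - 1) // offset + 1, 1)
        diff = np.zeros(n_bins + 1, dtype=np.float64)
        if chrom in intervals:
            starts, ends = intervals[chrom]
            valid = ends > starts
            starts, ends = starts[valid], ends[valid]
            # bin i overlaps [a,b) iff i*offset < b and i*offset + width > a
            lo = np.maximum((starts - width) // offset + 1, 0)
            hi = np.minimum((ends - 1) // offset, n_bins - 1)
            ok = hi >= lo
            np.add.at(diff, lo[ok], scale)
            np.add.at(diff, hi[ok] + 1, -scale)
        counts[chrom] = np.cumsum(diff[:-1])
    return BinnedCounts(width, offset, counts, dict(chrom_lengths))
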