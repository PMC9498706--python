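"""Genomic interval arithmetic on 0-based half-open coordinates.

All coordinates in this package follow the BED convention: an interval
``[start, end)`` covers bases ``start .. end-1``. A CpG site at position
``pos`` (the C of the CG dinucleotide) occupies the 2-bp interval
``[pos, pos+2)``. Windowing a CpG by ``w`` extends that 2-bp interval by
``w // 2`` on each flank.

Overlap between interval sets is measured in covered base pairs: by
default both sets are implicitly merged first, so a base covered by two
overlapping windows is counted once (see :func:`overlap_bp`).
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChromSizes",
    "ClockCpG",
    "GenomicInterval",
    "IntervalSet",
    "make_windows",
    "merge",
    "overlap_bp",
    "count_overlapping",
]


class ChromSizes(Mapping):
    """Mapping from chromosome name to length in bp.

    Lengths must be positive integers and names unique; the mapping
    preserves insertion order, which fixes the chromosome order used by
    every :class:`IntervalSet` bound to it.
    """

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = list(sizes.items()) if isinstance(sizes, Mapping) else list(sizes)
        self._sizes: dict[str, int] = {}
        for name, length in items:
            name = str(name)
            if name in self._sizes:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            if not float(length).is_integer() or int(length) <= 0:
                raise ValueError(
                    f"chromosome {name!r} has non-positive or non-integer "
                    f"length {length!r}"
                )
            self._sizes[name] = int(length)
        if not self._sizes:
            raise ValueError("chromosome sizes mapping is empty")

    def __getitem__(self, name: str) -> int:
        return self._sizes[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ChromSizes):
            return self._sizes == other._sizes
        return NotImplemented

    def __repr__(self) -> str:
        return f"ChromSizes({self._sizes!r})"

    @property
    def total_bp(self) -> int:
        return sum(self._sizes.values())


@dataclass(frozen=True)
class ClockCpG:
    """One ageing-clock CpG site.

    ``pos`` is the 0-based position of the C of the CG dinucleotide.
    ``direction`` is the signed methylation-with-age coefficient
    (> 0 hypermethylated, < 0 hypomethylated).
    """

    chrom: str
    pos: int
    direction: float = 0.0
    clock_name: str = ""

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"CpG position must be >= 0, got {self.pos}")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval with optional BED annotation columns."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class _ChromIntervals:
    starts: np.ndarray
    ends: np.ndarray
    extras: list[tuple[str | None, float | None, str | None]] | None = None


class IntervalSet:
    """A set of genomic intervals grouped by chromosome, bound to a genome.

    Intervals are stored per chromosome as sorted ``(start, end)`` NumPy
    arrays; optional name/score/strand annotations are carried alongside
    but ignored by all statistics. Every interval is validated against
    the bound :class:`ChromSizes`.
    """

    #: number of input records dropped on read (set by genome_io.read_bed)
    dropped_count: int = 0

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        chrom_sizes: ChromSizes,
    ):
        self.chrom_sizes = chrom_sizes
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            if iv.chrom not in chrom_sizes:
                raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
            if iv.end > chrom_sizes[iv.chrom]:
                raise ValueError(
                    f"interval [{iv.start}, {iv.end}) exceeds length "
                    f"{chrom_sizes[iv.chrom]} of chromosome {iv.chrom!r}"
                )
            by_chrom.setdefault(iv.chrom, []).append(iv)
        self._data: dict[str, _ChromIntervals] = {}
        for chrom in chrom_sizes:
            ivs = by_chrom.get(chrom)
            if not ivs:
                continue
            ivs.sort(key=lambda iv: (iv.start, iv.end))
            starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            ends = np.array([iv.end for iv in ivs], dtype=np.int64)
            extras = [(iv.name, iv.score, iv.strand) for iv in ivs]
            if all(e == (None, None, None) for e in extras):
                extras = None
            self._data[chrom] = _ChromIntervals(starts, ends, extras)
        self.dropped_count = 0

    @classmethod
    def from_arrays(
        cls,
        data: Mapping[str, tuple[np.ndarray, np.ndarray]],
        chrom_sizes: ChromSizes,
    ) -> "IntervalSet":
        """Build from per-chromosome (starts, ends) arrays without per-interval
        Python objects; used on hot paths (shuffling, window construction)."""
        self = cls.__new__(cls)
        self.chrom_sizes = chrom_sizes
        self._data = {}
        self.dropped_count = 0
        for chrom in chrom_sizes:
            if chrom not in data:
                continue
            starts = np.asarray(data[chrom][0], dtype=np.int64)
            ends = np.asarray(data[chrom][1], dtype=np.int64)
            if starts.size == 0:
                continue
            if starts.shape != ends.shape:
                raise ValueError("starts and ends must have equal length")
            if (starts < 0).any() or (starts >= ends).any():
                raise ValueError(f"invalid interval bounds on {chrom!r}")
            if (ends > chrom_sizes[chrom]).any():
                raise ValueError(f"interval beyond end of chromosome {chrom!r}")
            order = np.lexsort((ends, starts))
            self._data[chrom] = _ChromIntervals(starts[order], ends[order])
        unknown = set(data) - set(chrom_sizes)
        if unknown:
            raise ValueError(f"unknown chromosomes: {sorted(unknown)}")
        return self

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return sum(ci.starts.size for ci in self._data.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom, ci in self._data.items():
            extras = ci.extras or [(None, None, None)] * ci.starts.size
            for s, e, (name, score, strand) in zip(ci.starts, ci.ends, extras):
                yield GenomicInterval(chrom, int(s), int(e), name, score, strand)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if self.chrom_sizes != other.chrom_sizes:
            return False
        if set(self._data) != set(other._data):
            return False
        return all(
            np.array_equal(self._data[c].starts, other._data[c].starts)
            and np.array_equal(self._data[c].ends, other._data[c].ends)
            for c in self._data
        )

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    @property
    def total_bp(self) -> int:
        """Sum of interval lengths (overlaps counted with multiplicity)."""
        return int(
            sum((ci.ends - ci.starts).sum() for ci in self._data.values())
        )

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        ci = self._data.get(chrom)
        if ci is None:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty
        return ci.starts, ci.ends

    @property
    def lengths(self) -> np.ndarray:
        """Interval lengths in iteration order (the length multiset)."""
        if not self._data:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(
            [ci.ends - ci.starts for ci in self._data.values()]
        )

    def merge(self) -> "IntervalSet":
        return merge(self)

    def to_records(self) -> list[tuple]:
        """BED-style records (chrom, start, end[, name, score, strand])."""
        out = []
        for iv in self:
            rec: tuple = (iv.chrom, iv.start, iv.end)
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                rec = rec + (
                    iv.name if iv.name is not None else ".",
                    iv.score if iv.score is not None else 0,
                    iv.strand if iv.strand is not None else ".",
                )
            out.append(rec)
        return out

    def __repr__(self) -> str:
        return (
            f"<IntervalSet: {len(self)} intervals on {len(self._data)} "
            f"chromosomes, {self.total_bp} bp>"
        )


def _merge_arrays(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge sorted-by-start intervals; touching intervals are joined."""
    if starts.size == 0:
        return starts, ends
    # running maximum of ends identifies chain breaks
    run_max = np.maximum.accumulate(ends)
    new_group = np.empty(starts.size, dtype=bool)
    new_group[0] = True
    new_group[1:] = starts[1:] > run_max[:-1]
    idx = np.flatnonzero(new_group)
    m_starts = starts[idx]
    bounds = np.append(idx[1:], starts.size)
    # run_max is non-decreasing within a group, so its last element is the max
    m_ends = run_max[bounds - 1]
    return m_starts, m_ends


def merge(s: IntervalSet) -> IntervalSet:
    """Minimal disjoint interval set covering the same bases.

    Touching intervals (``[0,5)``, ``[5,9)``) are joined. Annotation
    columns are dropped.
    """
    data = {}
    for chrom in s.chroms:
        starts, ends = s.arrays(chrom)
        data[chrom] = _merge_arrays(starts, ends)
    return IntervalSet.from_arrays(data, s.chrom_sizes)


def _depth_at(starts: np.ndarray, ends: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Coverage depth of an interval multiset at each query point."""
    return np.searchsorted(starts, points, side="right") - np.searchsorted(
        np.sort(ends), points, side="right"
    )


def overlap_bp(a: IntervalSet, b: IntervalSet, merge_inputs: bool = True) -> int:
    """Base pairs shared between two interval sets.

    With ``merge_inputs=True`` (default) both sets are implicitly merged,
    so the result is ``|bases(a) ∩ bases(b)|`` — the covered-sequence
    overlap, symmetric and free of double counting. With
    ``merge_inputs=False`` the result is the sum of all pairwise
    interval intersections (a base covered k times in ``a`` and m times
    in ``b`` contributes k·m), which is what a plain pairwise intersect
    of unmerged files reports.
    """
    if a.chrom_sizes != b.chrom_sizes:
        raise ValueError("interval sets are bound to different chromosome sizes")
    total = 0
    for chrom in a.chroms:
        a_s, a_e = a.arrays(chrom)
        b_s, b_e = b.arrays(chrom)
        if a_s.size == 0 or b_s.size == 0:
            continue
        bounds = np.unique(np.concatenate([a_s, a_e, b_s, b_e]))
        seg_left = bounds[:-1]
        seg_len = np.diff(bounds)
        depth_a = _depth_at(a_s, a_e, seg_left)
        depth_b = _depth_at(b_s, b_e, seg_left)
        if merge_inputs:
            weight = ((depth_a > 0) & (depth_b > 0)).astype(np.int64)
        else:
            weight = depth_a.astype(np.int64) * depth_b
        total += int((seg_len * weight).sum())
    return total


def _as_position_arrays(
    points: Iterable[ClockCpG] | Mapping[str, np.ndarray],
) -> dict[str, np.ndarray]:
    if isinstance(points, Mapping):
        return {c: np.asarray(p, dtype=np.int64) for c, p in points.items()}
    by_chrom: dict[str, list[int]] = {}
    for cpg in points:
        by_chrom.setdefault(cpg.chrom, []).append(cpg.pos)
    return {c: np.array(p, dtype=np.int64) for c, p in by_chrom.items()}


def _window_bounds(
    positions: np.ndarray, window: int, chrom_len: int
) -> tuple[np.ndarray, np.ndarray]:
    half = window // 2
    ws = np.clip(positions - half, 0, chrom_len)
    we = np.clip(positions + 2 + half, 0, chrom_len)
    return ws, we


def make_windows(
    cpgs: Iterable[ClockCpG], window: int, chrom_sizes: ChromSizes
) -> IntervalSet:
    """Symmetric windows around CpG sites.

    Each CpG's 2-bp interval ``[pos, pos+2)`` is extended by
    ``window // 2`` on both flanks, then clipped to the chromosome.
    The output is *not* merged; merging is the caller's explicit choice.
    """
    if window < 0:
        raise ValueError(f"window must be >= 0, got {window}")
    by_chrom = _as_position_arrays(cpgs)
    data = {}
    for chrom, positions in by_chrom.items():
        if chrom not in chrom_sizes:
            raise ValueError(f"CpG on unknown chromosome {chrom!r}")
        clen = chrom_sizes[chrom]
        if (positions >= clen).any():
            raise ValueError(f"CpG position beyond end of chromosome {chrom!r}")
        ws, we = _window_bounds(np.sort(positions), window, clen)
        keep = ws < we
        data[chrom] = (ws[keep], we[keep])
    return IntervalSet.from_arrays(data, chrom_sizes)


def count_overlapping(
    points: Iterable[ClockCpG] | Mapping[str, np.ndarray],
    s: IntervalSet,
    window: int,
) -> int:
    """Number of CpGs whose window overlaps ``s`` by at least one base.

    ``points`` may be a list of :class:`ClockCpG` or a per-chromosome
    mapping of sorted position arrays (the catalog fast path). Each CpG
    is counted at most once; overlap uses half-open semantics, so a
    window abutting an interval does not count.
    """
    if window < 0:
        raise ValueError(f"window must be >= 0, got {window}")
    by_chrom = _as_position_arrays(points)
    merged = merge(s)
    total = 0
    for chrom, positions in by_chrom.items():
        m_s, m_e = merged.arrays(chrom)
        if m_s.size == 0 or positions.size == 0:
            continue
        clen = s.chrom_sizes[chrom] if chrom in s.chrom_sizes else None
        if clen is None:
            continue
        ws, we = _window_bounds(positions, window, clen)
        # first merged interval ending strictly after the window start;
        # the window hits iff that interval starts before the window end
        idx = np.searchsorted(m_e, ws, side="right")
        inside = idx < m_s.size
        hit = inside & (m_s[np.minimum(idx, m_s.size - 1)] < we) & (ws < we)
        total += int(hit.sum())
    return total
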