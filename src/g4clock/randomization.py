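"""Empirical-null construction by random interval relocation.

The shuffle null keeps the observed feature count and length multiset
and relocates every interval uniformly at random. In the default
genome-wide mode the destination chromosome is drawn with probability
proportional to its length and the start uniformly on
``[0, chrom_len - len]``; the per-chromosome mode keeps each interval on
its own chromosome. Shuffled intervals may overlap one another, as the
randomisation routines used for this class of analysis allow by default.

Determinism contract: one master ``seed`` plus a ``replicate_index``
yields an independent, reproducible stream per shuffle, so the replicate
set is order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import ChromSizes, IntervalSet, merge

__all__ = ["ShuffleConfig", "shuffle_intervals", "subsample_intervals"]


@dataclass(frozen=True)
class ShuffleConfig:
    """Parameters of the empirical null."""

    n_shuffles: int = 30
    seed: int = 0
    placement: str = "genome-wide"  # or "per-chromosome"
    exclusion_mask: IntervalSet | None = None
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if self.placement not in ("genome-wide", "per-chromosome"):
            raise ValueError(
                "placement must be 'genome-wide' or 'per-chromosome'"
            )


def _rng(seed: int, replicate_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(replicate_index,))
    )


def _mask_hits(
    mask_starts: np.ndarray,
    mask_ends: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
) -> np.ndarray:
    """Boolean: does each [start, end) overlap the merged mask by >= 1 bp."""
    if mask_starts.size == 0 or starts.size == 0:
        return np.zeros(starts.size, dtype=bool)
    idx = np.searchsorted(mask_ends, starts, side="right")
    inside = idx < mask_starts.size
    return inside & (mask_starts[np.minimum(idx, mask_starts.size - 1)] < ends)


def shuffle_intervals(
    s: IntervalSet,
    chrom_sizes: ChromSizes,
    config: ShuffleConfig,
    replicate_index: int = 0,
) -> IntervalSet:
    """One shuffled replicate of ``s``.

    The output has exactly the same number of intervals and the same
    multiset of lengths; every interval lies within its destination
    chromosome. Raises if an interval is longer than every chromosome,
    or if a placement outside ``config.exclusion_mask`` cannot be found
    within ``config.max_retries`` rounds.
    """
    rng = _rng(config.seed, replicate_index)
    chrom_names = list(chrom_sizes)
    chrom_lens = np.array([chrom_sizes[c] for c in chrom_names], dtype=np.int64)
    mask = merge(config.exclusion_mask) if config.exclusion_mask is not None else None

    if config.placement == "per-chromosome":
        per_chrom_lengths = {
            chrom: (s.arrays(chrom)[1] - s.arrays(chrom)[0])
            for chrom in s.chroms
        }
        chrom_idx_parts = []
        length_parts = []
        for chrom, lens in per_chrom_lengths.items():
            ci = chrom_names.index(chrom)
            if (lens > chrom_lens[ci]).any():
                bad = int(lens[lens > chrom_lens[ci]][0])
                raise ValueError(
                    f"interval of length {bad} does not fit on {chrom!r}"
                )
            chrom_idx_parts.append(np.full(lens.size, ci, dtype=np.int64))
            length_parts.append(lens)
        if not length_parts:
            return IntervalSet.from_arrays({}, chrom_sizes)
        chrom_idx = np.concatenate(chrom_idx_parts)
        lengths = np.concatenate(length_parts)
    else:
        lengths = s.lengths
        if lengths.size == 0:
            return IntervalSet.from_arrays({}, chrom_sizes)
        if lengths.max() > chrom_lens.max():
            raise ValueError(
                f"interval of length {int(lengths.max())} is longer than "
                "every chromosome"
            )
        chrom_idx = _draw_chroms(rng, lengths, chrom_lens)

    starts = rng.integers(0, chrom_lens[chrom_idx] - lengths + 1)
    if mask is not None:
        pending = np.arange(lengths.size)
        for _ in range(config.max_retries):
            hits = np.zeros(pending.size, dtype=bool)
            for ci, chrom in enumerate(chrom_names):
                sel = chrom_idx[pending] == ci
                if not sel.any():
                    continue
                m_s, m_e = mask.arrays(chrom)
                sub = pending[sel]
                hits[sel] = _mask_hits(
                    m_s, m_e, starts[sub], starts[sub] + lengths[sub]
                )
            pending = pending[hits]
            if pending.size == 0:
                break
            if config.placement == "genome-wide":
                chrom_idx[pending] = _draw_chroms(
                    rng, lengths[pending], chrom_lens
                )
            starts[pending] = rng.integers(
                0, chrom_lens[chrom_idx[pending]] - lengths[pending] + 1
            )
        else:
            i = int(pending[0])
            raise RuntimeError(
                f"could not place interval of length {int(lengths[i])} "
                f"outside the exclusion mask after {config.max_retries} retries"
            )

    data = {}
    for ci, chrom in enumerate(chrom_names):
        sel = chrom_idx == ci
        if sel.any():
            data[chrom] = (starts[sel], starts[sel] + lengths[sel])
    return IntervalSet.from_arrays(data, chrom_sizes)


def _draw_chroms(
    rng: np.random.Generator, lengths: np.ndarray, chrom_lens: np.ndarray
) -> np.ndarray:
    """Destination chromosomes, probability proportional to length, among
    chromosomes long enough to hold each interval."""
    p_all = chrom_lens / chrom_lens.sum()
    if lengths.max() <= chrom_lens.min():
        # fast path: every chromosome is feasible for every interval
        return rng.choice(chrom_lens.size, size=lengths.size, p=p_all)
    out = np.empty(lengths.size, dtype=np.int64)
    for i, ln in enumerate(lengths):
        feasible = chrom_lens >= ln
        w = chrom_lens * feasible
        out[i] = rng.choice(chrom_lens.size, p=w / w.sum())
    return out


def subsample_intervals(s: IntervalSet, k: int, seed: int = 0) -> IntervalSet:
    """Draw ``k`` intervals uniformly without replacement, coordinates
    unchanged; used to match feature counts across species."""
    n = len(s)
    if k <= 0 or k > n:
        raise ValueError(f"k must satisfy 0 < k <= {n}, got {k}")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=k, replace=False))
    keep_set = set(keep.tolist())
    chosen = [iv for i, iv in enumerate(s) if i in keep_set]
    return IntervalSet(chosen, s.chrom_sizes)
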