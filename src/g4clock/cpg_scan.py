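"""Genome-wide CG-dinucleotide catalogue.

The global-CpG enrichment test needs, as its background population, every
CG dinucleotide in the reference genome. Only the forward-strand literal
``CG`` is scanned: the CpG dinucleotide is its own reverse complement, so
a reverse-strand scan would count every site twice. Soft-masked
(lowercase) sequence is treated as ordinary sequence; ``N`` never matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .intervals import ChromSizes, ClockCpG, IntervalSet, count_overlapping

__all__ = ["CpGCatalog", "find_cpg_sites", "cpg_g4_fraction"]

_ALPHABET = frozenset(b"ACGTNacgtn")


@dataclass
class CpGCatalog:
    """Sorted 0-based positions of the C of every CG, per chromosome."""

    positions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            if pos.size and (np.diff(pos) <= 0).any():
                raise ValueError(
                    f"CpG positions on {chrom!r} not strictly increasing"
                )
            self.positions[chrom] = pos

    @property
    def N(self) -> int:
        """Total number of CG sites in the genome."""
        return int(sum(p.size for p in self.positions.values()))

    def count(self, chrom: str) -> int:
        return int(self.positions.get(chrom, np.empty(0)).size)

    def to_clock_cpgs(self, clock_name: str = "") -> list[ClockCpG]:
        return [
            ClockCpG(chrom, int(p), 0.0, clock_name)
            for chrom, pos in self.positions.items()
            for p in pos
        ]

    def to_intervals(self, chrom_sizes: ChromSizes) -> IntervalSet:
        """Export as 2-bp intervals (BED-ready via genome_io.write_bed)."""
        data = {
            chrom: (pos, pos + 2) for chrom, pos in self.positions.items()
        }
        return IntervalSet.from_arrays(data, chrom_sizes)


def find_cpg_sites(genome: Mapping[str, str]) -> CpGCatalog:
    """Scan every chromosome for CG dinucleotides (case-insensitive).

    Raises on any character outside ``{A,C,G,T,N}`` (either case),
    naming the chromosome and offset of the first offender.
    """
    positions: dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        valid = np.isin(arr, np.frombuffer(bytes(_ALPHABET), dtype=np.uint8))
        if not valid.all():
            offset = int(np.argmin(valid))
            raise ValueError(
                f"invalid character {seq[offset]!r} at {chrom}:{offset}"
            )
        upper = np.where(arr >= ord("a"), arr - 32, arr)
        is_c = upper[:-1] == ord("C")
        is_g = upper[1:] == ord("G")
        positions[chrom] = np.flatnonzero(is_c & is_g).astype(np.int64)
    return CpGCatalog(positions)


def cpg_g4_fraction(catalog: CpGCatalog, g4s: IntervalSet, window: int = 0) -> float:
    """Fraction f of genome CpGs whose window overlaps the G4 set.

    ``window=0`` tests the bare 2-bp CpG interval against the G4
    intervals; a positive window applies the same symmetric extension
    used for clock CpGs, keeping the background and the clock strictly
    comparable.
    """
    if catalog.N == 0:
        raise ValueError("CpG catalog is empty")
    k = count_overlapping(catalog.positions, g4s, window)
    return k / catalog.N
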