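"""Readers and writers for the external formats the pipeline touches.

BED3+ interval files, UCSC-style ``chrom.sizes`` tables, FASTA genomes,
delimited ageing-clock CpG tables (with a declarative column/base-convention
format spec) and the TSV results tables. All coordinates are converted to
0-based half-open on read; validation is strict by default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .intervals import ChromSizes, ClockCpG, GenomicInterval, IntervalSet

__all__ = [
    "ChromSizes",
    "ClockCpG",
    "ClockTableFormat",
    "ClockTableRead",
    "read_bed",
    "read_chrom_sizes",
    "read_clock_table",
    "read_fasta",
    "write_fasta",
    "write_bed",
    "write_chrom_sizes",
    "write_results",
    "read_results",
]


class BedParseError(ValueError):
    """A BED line that cannot be parsed; the message names the line number."""


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    """Read a two-column ``name <TAB> length`` chromosome-sizes table."""
    pairs: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'name<TAB>length', got {line!r}"
                )
            name = fields[0]
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            seen.add(name)
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer length {fields[1]!r}"
                ) from exc
            pairs.append((name, length))
    return ChromSizes(pairs)


def read_bed(
    path: str | Path,
    chrom_sizes: ChromSizes,
    on_unknown_chrom: str = "error",
) -> IntervalSet:
    """Read a BED3+ file into a validated, sorted :class:`IntervalSet`.

    Parameters
    ----------
    on_unknown_chrom
        ``"error"`` (default) raises on a record whose chromosome is not
        in ``chrom_sizes``; ``"drop"`` discards such records and reports
        their number on the returned set's ``dropped_count`` attribute.

    Extra BED columns (name, score, strand) are carried on the intervals
    but ignored by every statistic.
    """
    if on_unknown_chrom not in ("error", "drop"):
        raise ValueError("on_unknown_chrom must be 'error' or 'drop'")
    intervals: list[GenomicInterval] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: fewer than 3 tab-separated columns"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{fields[1]!r}, {fields[2]!r}"
                ) from exc
            if start < 0 or start >= end:
                raise BedParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            if chrom not in chrom_sizes:
                if on_unknown_chrom == "drop":
                    dropped += 1
                    continue
                raise ValueError(
                    f"{path}:{lineno}: unknown chromosome {chrom!r} "
                    "(use on_unknown_chrom='drop' to discard such records)"
                )
            if end > chrom_sizes[chrom]:
                raise BedParseError(
                    f"{path}:{lineno}: interval end {end} beyond chromosome "
                    f"{chrom!r} length {chrom_sizes[chrom]}"
                )
            name = fields[3] if len(fields) > 3 else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            strand = fields[5] if len(fields) > 5 else None
            intervals.append(
                GenomicInterval(chrom, start, end, name, score, strand)
            )
    iset = IntervalSet(intervals, chrom_sizes)
    iset.dropped_count = dropped
    return iset


def write_bed(s: IntervalSet, path: str | Path) -> None:
    """Write an interval set as BED (3 or 6 columns as annotated)."""
    with open(path, "w") as fh:
        for iv in s:
            if iv.name is None and iv.score is None and iv.strand is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = iv.name if iv.name is not None else "."
                score = iv.score if iv.score is not None else 0
                strand = iv.strand if iv.strand is not None else "."
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{strand}\n"
                )


def write_chrom_sizes(chrom_sizes: ChromSizes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in chrom_sizes.items():
            fh.write(f"{name}\t{length}\n")


# -- clock tables ------------------------------------------------------------


@dataclass(frozen=True)
class ClockTableFormat:
    """Declarative description of one clock table's layout.

    Published clock coordinate tables differ in column names, delimiter
    and base convention, so the mapping is declared rather than guessed.
    ``position_base`` is 1 for 1-based coordinates (converted to the
    internal 0-based convention on read) or 0.
    """

    chrom_col: str
    pos_col: str
    direction_col: str | None = None
    delimiter: str = ","
    position_base: int = 1
    clock_name: str = ""

    def __post_init__(self) -> None:
        if self.position_base not in (0, 1):
            raise ValueError("position_base must be 0 or 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ClockTableFormat":
        return cls(**d)


@dataclass
class ClockTableRead:
    """A parsed clock table plus its bookkeeping counts."""

    cpgs: list[ClockCpG]
    n_input: int
    n_retained: int
    n_dropped_missing: int
    n_duplicates: int

    def __iter__(self):
        return iter(self.cpgs)

    def __len__(self):
        return len(self.cpgs)


def read_clock_table(
    path: str | Path,
    format_spec: ClockTableFormat,
    chrom_sizes: ChromSizes | None = None,
    on_unknown_chrom: str = "error",
) -> ClockTableRead:
    """Read an ageing-clock CpG coordinate table.

    Rows with a missing chromosome or position are dropped (counted);
    duplicate ``(chrom, pos)`` rows are reduced to one. Positions are
    converted to 0-based per ``format_spec.position_base``. When
    ``chrom_sizes`` is given, positions are bounds-checked and unknown
    chromosomes follow ``on_unknown_chrom`` ('error' or 'drop').
    """
    df = pd.read_csv(path, sep=format_spec.delimiter, dtype=str)
    for col in (format_spec.chrom_col, format_spec.pos_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    n_input = len(df)
    pos = pd.to_numeric(df[format_spec.pos_col], errors="coerce")
    chrom = df[format_spec.chrom_col]
    valid = pos.notna() & chrom.notna() & (chrom.astype(str).str.strip() != "")
    n_dropped_missing = int((~valid).sum())
    df = df[valid]
    pos = pos[valid].astype(np.int64) - format_spec.position_base
    chrom = chrom[valid].astype(str)
    if (pos < 0).any():
        bad = int(pos[pos < 0].iloc[0])
        raise ValueError(f"{path}: position {bad} below 0 after base conversion")
    if format_spec.direction_col is not None:
        if format_spec.direction_col not in df.columns:
            raise ValueError(
                f"{path}: missing column {format_spec.direction_col!r}"
            )
        # tolerate unicode minus signs common in publication tables
        direction = pd.to_numeric(
            df[format_spec.direction_col]
            .astype(str)
            .str.replace("−", "-", regex=False),
            errors="coerce",
        ).fillna(0.0)
    else:
        direction = pd.Series(0.0, index=df.index)

    cpgs: list[ClockCpG] = []
    seen: set[tuple[str, int]] = set()
    n_duplicates = 0
    n_unknown = 0
    for c, p, d in zip(chrom, pos, direction):
        if chrom_sizes is not None:
            if c not in chrom_sizes:
                if on_unknown_chrom == "drop":
                    n_unknown += 1
                    continue
                raise ValueError(f"{path}: unknown chromosome {c!r}")
            if p >= chrom_sizes[c] - 1:
                raise ValueError(
                    f"{path}: CpG position {p} too close to end of {c!r} "
                    f"(length {chrom_sizes[c]})"
                )
        key = (c, int(p))
        if key in seen:
            n_duplicates += 1
            continue
        seen.add(key)
        cpgs.append(ClockCpG(c, int(p), float(d), format_spec.clock_name))
    return ClockTableRead(
        cpgs=cpgs,
        n_input=n_input,
        n_retained=len(cpgs),
        n_dropped_missing=n_dropped_missing + n_unknown,
        n_duplicates=n_duplicates,
    )


# -- FASTA -------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into a ``{name: sequence}`` mapping.

    The record name is the first whitespace-delimited token of the
    header; duplicate names and empty sequences are errors. Case is
    preserved.
    """
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise ValueError(f"{path}: duplicate FASTA record {record.id!r}")
        seq = str(record.seq)
        if not seq:
            raise ValueError(f"{path}: empty sequence for record {record.id!r}")
        genome[record.id] = seq
    if not genome:
        raise ValueError(f"{path}: no FASTA records found")
    return genome


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# -- results tables ----------------------------------------------------------

_FLOAT_FMT = "%.10g"

SHUFFLE_RESULT_COLUMNS = [
    "target", "window", "c", "t", "sd", "F", "z", "p", "log10_p",
    "n_shuffles", "shuffle_counts",
]
CPG_RESULT_COLUMNS = [
    "target", "window", "N", "K", "f", "n_clock", "n_obs", "expected",
    "fold", "p", "log10_p",
]


def _results_to_frame(results: Iterable) -> pd.DataFrame:
    rows = []
    kinds = set()
    for r in results:
        row = r.to_row()
        kinds.add(type(r).__name__)
        rows.append(row)
    if len(kinds) > 1:
        raise ValueError(
            f"cannot mix result types in one table: {sorted(kinds)}"
        )
    if not rows:
        return pd.DataFrame(columns=SHUFFLE_RESULT_COLUMNS)
    columns = list(rows[0].keys())
    return pd.DataFrame(rows, columns=columns)


def write_results(results: Sequence, path: str | Path) -> None:
    """Write enrichment results as a TSV table.

    One row per result (target set / window), fixed column order, floats
    rendered with 10 significant digits so the table round-trips through
    :func:`read_results`. An empty collection yields a header-only file
    with the shuffle-result columns.
    """
    df = _results_to_frame(results)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")
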