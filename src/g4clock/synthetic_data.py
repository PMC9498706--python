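"""Synthetic scenarios with a known, planted G4/clock association.

A scenario is a complete, downloadable-data-free stand-in for the real
inputs: a multi-chromosome genome FASTA whose CG dinucleotides are
planted at a controlled rate, a designated "ageing clock" subset of
those CpGs, and a G4 interval set consisting of a uniform background
plus, for a fraction ``rho`` of clock CpGs, one G4 whose start is
uniform within ``±d`` bp of the CpG. Every generator is a pure function
of the truth parameters and seed, so scenarios are byte-reproducible.

The default sequence background is drawn from {A, T}, which makes the
planted CG set the *complete* CG set by construction — exact ground
truth for the catalog. A realistic {A,C,G,T} background is available,
in which case the catalog is defined post hoc by scanning the sequence.

``SimulationTruth.true_fold_estimate`` gives the closed-form expected
fold enrichment under the planted model (see docs/methods.md for the
derivation), the reference value for parameter-recovery checks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from . import genome_io
from .cpg_scan import CpGCatalog, find_cpg_sites
from .genome_io import ClockTableFormat
from .intervals import ChromSizes, ClockCpG, GenomicInterval, IntervalSet

__all__ = [
    "SimulationTruth",
    "Scenario",
    "CLOCK_CSV_FORMAT",
    "simulate_genome",
    "simulate_clock",
    "simulate_g4s",
    "generate_scenario",
    "write_scenario",
    "load_truth",
    "small_truth",
    "null_truth",
    "planted_truth",
]

#: layout of the clock.csv a scenario writes (1-based positions, so the
#: reader's base-conversion path is exercised end to end)
CLOCK_CSV_FORMAT = ClockTableFormat(
    chrom_col="chrom",
    pos_col="position",
    direction_col="coefficient",
    delimiter=",",
    position_base=1,
    clock_name="synthetic",
)

_GENOME_STREAM, _CLOCK_STREAM, _G4_STREAM = 0, 1, 2


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(stream,))
    )


@dataclass(frozen=True)
class SimulationTruth:
    """Planted parameters of one synthetic scenario."""

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    background_cpg_rate: float = 0.01
    n_clock_cpgs: int = 600
    n_g4_background: int = 80
    g4_length_min: int = 20
    g4_length_max: int = 60
    planted_fraction: float = 1.0
    association_radius: int = 500
    hyper_fraction: float = 0.5
    realistic_background: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValueError("planted_fraction must be in [0, 1]")
        if self.association_radius < 0:
            raise ValueError("association_radius must be >= 0")
        if min(self.n_chroms, self.chrom_length, self.n_clock_cpgs) <= 0:
            raise ValueError("counts and lengths must be positive")
        if self.n_g4_background < 0:
            raise ValueError("n_g4_background must be >= 0")
        if not 0 < self.g4_length_min <= self.g4_length_max:
            raise ValueError("need 0 < g4_length_min <= g4_length_max")
        if not 0.0 <= self.background_cpg_rate <= 0.4:
            raise ValueError("background_cpg_rate must be in [0, 0.4]")

    # -- derived quantities --------------------------------------------------

    @property
    def genome_length(self) -> int:
        return self.n_chroms * self.chrom_length

    @property
    def n_planted(self) -> int:
        return int(self.planted_fraction * self.n_clock_cpgs)

    @property
    def mean_g4_length(self) -> float:
        return (self.g4_length_min + self.g4_length_max) / 2.0

    def expected_planted_overlap(self, window: int) -> float:
        """Expected bp overlap of one planted G4 with its own CpG window,
        exact discrete expectation over start offset and length."""
        d = self.association_radius
        w2 = window // 2
        offsets = np.arange(-d, d + 1)
        lengths = np.arange(self.g4_length_min, self.g4_length_max + 1)
        ov = np.minimum(offsets[:, None] + lengths[None, :], 2 + w2)
        ov = ov - np.maximum(offsets[:, None], -w2)
        return float(np.maximum(ov, 0).mean())

    def expected_window_coverage(self, window: int) -> float:
        """Expected merged coverage (bp) of the clock windows, Poisson
        approximation for uniformly placed clock CpGs."""
        W = window + 2
        G = self.genome_length
        return G * (1.0 - math.exp(-self.n_clock_cpgs * W / G))

    def true_fold_estimate(self, window: int | None = None) -> float:
        """Closed-form expected fold enrichment at ``window``.

        Defaults to window = 2·d, where the planted G4s are fully
        captured. With T the expected merged window coverage, the
        observed overlap decomposes into each planted G4's overlap with
        its own CpG window (E_ov), the remaining planted bases falling
        in *other* windows at the background coverage rate T/G, and the
        uniform background:

            E[c] = P·(E_ov + (l̄ − E_ov)·T/G) + B·l̄·T/G
            E[t] = (B + P)·l̄·T/G
            F    = E[c] / (1 + E[t])

        The same value is the recovery target for the global-CpG fold.
        """
        if window is None:
            window = 2 * self.association_radius
        G = self.genome_length
        P = self.n_planted
        B = self.n_g4_background
        lbar = self.mean_g4_length
        cov = self.expected_window_coverage(window) / G
        e_own = self.expected_planted_overlap(window)
        e_c = P * (e_own + (lbar - e_own) * cov) + B * lbar * cov
        e_t = (B + P) * lbar * cov
        return e_c / (1.0 + e_t)

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        return cls(**d)


class Scenario(NamedTuple):
    """An in-memory scenario: every input the pipeline needs."""

    truth: SimulationTruth
    genome: dict[str, str]
    chrom_sizes: ChromSizes
    catalog: CpGCatalog
    clock: list[ClockCpG]
    g4s: IntervalSet


def _sample_min_gap2(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n sorted positions on [0, length-2] pairwise >= 2 apart, uniform over
    all such sets (shift construction)."""
    m = length - n - 1
    if n > 0 and m < n:
        raise ValueError(
            f"cannot place {n} non-overlapping CG sites on a {length} bp "
            "chromosome"
        )
    if n == 0:
        return np.empty(0, dtype=np.int64)
    x = np.sort(rng.choice(m, size=n, replace=False))
    return x + np.arange(n, dtype=np.int64)


def simulate_genome(
    truth: SimulationTruth,
) -> tuple[dict[str, str], ChromSizes, CpGCatalog]:
    """Generate the genome FASTA mapping, its sizes and its CG catalog.

    Per-chromosome CG counts are Poisson(rate · length); in the default
    {A,T}-background mode the returned catalog is exactly the planted
    set and equals ``find_cpg_sites`` of the sequence.
    """
    rng = _rng(truth.seed, _GENOME_STREAM)
    genome: dict[str, str] = {}
    positions: dict[str, np.ndarray] = {}
    L = truth.chrom_length
    for i in range(truth.n_chroms):
        chrom = f"chr{i + 1}"
        n_cg = int(rng.poisson(truth.background_cpg_rate * L))
        if truth.realistic_background:
            arr = rng.choice(
                np.frombuffer(b"ACGT", dtype=np.uint8), size=L
            ).copy()
        else:
            arr = rng.choice(
                np.frombuffer(b"AT", dtype=np.uint8), size=L
            ).copy()
        pos = _sample_min_gap2(rng, n_cg, L)
        arr[pos] = ord("C")
        arr[pos + 1] = ord("G")
        genome[chrom] = arr.tobytes().decode("ascii")
        positions[chrom] = pos
    chrom_sizes = ChromSizes({c: len(s) for c, s in genome.items()})
    if truth.realistic_background:
        catalog = find_cpg_sites(genome)
    else:
        catalog = CpGCatalog(positions)
    return genome, chrom_sizes, catalog


def simulate_clock(
    catalog: CpGCatalog,
    n: int,
    hyper_fraction: float = 0.5,
    seed: int = 0,
    clock_name: str = "synthetic",
) -> list[ClockCpG]:
    """Sample ``n`` clock CpGs uniformly without replacement from the
    catalog; direction +1 with probability ``hyper_fraction``, else -1."""
    N = catalog.N
    if n > N:
        raise ValueError(f"cannot sample {n} clock CpGs from {N} catalog CpGs")
    rng = _rng(seed, _CLOCK_STREAM)
    chroms = list(catalog.positions)
    counts = np.array([catalog.positions[c].size for c in chroms])
    offsets = np.concatenate([[0], np.cumsum(counts)])
    flat_idx = np.sort(rng.choice(N, size=n, replace=False))
    directions = np.where(rng.random(n) < hyper_fraction, 1.0, -1.0)
    clock = []
    for idx, direction in zip(flat_idx, directions):
        ci = int(np.searchsorted(offsets, idx, side="right") - 1)
        pos = int(catalog.positions[chroms[ci]][idx - offsets[ci]])
        clock.append(ClockCpG(chroms[ci], pos, float(direction), clock_name))
    return clock


def simulate_g4s(
    truth: SimulationTruth,
    catalog: CpGCatalog,
    clock: list[ClockCpG],
    chrom_sizes: ChromSizes,
) -> IntervalSet:
    """Background G4s placed uniformly genome-wide plus one planted G4
    near each of a ``planted_fraction`` subset of clock CpGs.

    Interval names mark provenance (``bg_*`` / ``planted_*``); planted
    starts are uniform on ``[pos - d, pos + d]``, clipped to the
    chromosome.
    """
    rng = _rng(truth.seed, _G4_STREAM)
    chrom_names = list(chrom_sizes)
    chrom_lens = np.array([chrom_sizes[c] for c in chrom_names], dtype=np.int64)
    lo, hi = truth.g4_length_min, truth.g4_length_max
    intervals: list[GenomicInterval] = []

    n_bg = truth.n_g4_background
    if n_bg:
        lens = rng.integers(lo, hi + 1, size=n_bg)
        cidx = rng.choice(
            len(chrom_names), size=n_bg, p=chrom_lens / chrom_lens.sum()
        )
        starts = rng.integers(0, chrom_lens[cidx] - lens + 1)
        for j in range(n_bg):
            intervals.append(
                GenomicInterval(
                    chrom_names[cidx[j]],
                    int(starts[j]),
                    int(starts[j] + lens[j]),
                    name=f"bg_{j:05d}",
                )
            )

    n_planted = truth.n_planted
    if n_planted:
        chosen = rng.choice(len(clock), size=n_planted, replace=False)
        lens = rng.integers(lo, hi + 1, size=n_planted)
        offsets = rng.integers(
            -truth.association_radius, truth.association_radius + 1,
            size=n_planted,
        )
        for j, (ci, ln, off) in enumerate(zip(chosen, lens, offsets)):
            cpg = clock[int(ci)]
            clen = chrom_sizes[cpg.chrom]
            start = int(np.clip(cpg.pos + off, 0, clen - ln))
            intervals.append(
                GenomicInterval(
                    cpg.chrom, start, start + int(ln), name=f"planted_{j:05d}"
                )
            )
    return IntervalSet(intervals, chrom_sizes)


def generate_scenario(truth: SimulationTruth) -> Scenario:
    """Generate the complete scenario in memory."""
    genome, chrom_sizes, catalog = simulate_genome(truth)
    clock = simulate_clock(
        catalog, truth.n_clock_cpgs, truth.hyper_fraction, truth.seed
    )
    g4s = simulate_g4s(truth, catalog, clock, chrom_sizes)
    return Scenario(truth, genome, chrom_sizes, catalog, clock, g4s)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_scenario(truth: SimulationTruth, outdir: str | Path) -> dict:
    """Write the scenario files and return a manifest with checksums.

    Files written: ``genome.fa``, ``genome.chrom.sizes``, ``clock.csv``
    (1-based positions, layout per :data:`CLOCK_CSV_FORMAT`), ``g4.bed``
    and ``truth.json``. The scenario is fully reconstructable from
    ``truth.json`` alone.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = generate_scenario(truth)

    genome_io.write_fasta(scenario.genome, outdir / "genome.fa")
    genome_io.write_chrom_sizes(scenario.chrom_sizes, outdir / "genome.chrom.sizes")
    with open(outdir / "clock.csv", "w") as fh:
        fh.write("cpg_id,chrom,position,coefficient\n")
        for i, cpg in enumerate(scenario.clock):
            fh.write(
                f"syn{i:06d},{cpg.chrom},{cpg.pos + 1},{cpg.direction:g}\n"
            )
    genome_io.write_bed(scenario.g4s, outdir / "g4.bed")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    files = ["genome.fa", "genome.chrom.sizes", "clock.csv", "g4.bed", "truth.json"]
    return {
        "outdir": str(outdir),
        "files": {name: _sha256(outdir / name) for name in files},
        "clock_format": CLOCK_CSV_FORMAT.to_dict(),
        "true_fold_estimate": truth.true_fold_estimate(),
    }


def load_truth(path: str | Path) -> SimulationTruth:
    """Reload the truth parameters of a written scenario."""
    with open(path) as fh:
        return SimulationTruth.from_dict(json.load(fh))


# -- study presets -----------------------------------------------------------


def small_truth(seed: int = 0) -> SimulationTruth:
    """Small 2 x 1 Mb planted scenario; same per-bp densities as the
    full planted preset, so the expected fold is the same (fold
    enrichment is scale-invariant)."""
    return SimulationTruth(
        n_chroms=2, chrom_length=1_000_000, background_cpg_rate=0.01,
        n_clock_cpgs=600, n_g4_background=80, planted_fraction=1.0,
        association_radius=500, seed=seed,
    )


def null_truth(seed: int = 0) -> SimulationTruth:
    """10 Mb scenario with no planted association (rho = 0): the G4 set
    is pure uniform background, so both fold statistics should sit near 1."""
    return SimulationTruth(
        n_chroms=2, chrom_length=5_000_000, background_cpg_rate=0.01,
        n_clock_cpgs=1000, n_g4_background=2000, planted_fraction=0.0,
        association_radius=500, seed=seed,
    )


def planted_truth(seed: int = 0) -> SimulationTruth:
    """10 Mb scenario with one planted G4 within ±500 bp of every clock
    CpG over a sparse uniform background."""
    return SimulationTruth(
        n_chroms=2, chrom_length=5_000_000, background_cpg_rate=0.01,
        n_clock_cpgs=3000, n_g4_background=400, planted_fraction=1.0,
        association_radius=500, seed=seed,
    )
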