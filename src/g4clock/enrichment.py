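"""Enrichment statistics for G-quadruplex intervals at ageing-clock CpGs.

Two complementary statistics are provided, each as a small model object
whose ``fit()`` returns a results object with the estimate, its
uncertainty and a ``summary()`` table:

``ShuffleEnrichment``
    Fold enrichment against an empirical shuffle null. The observed
    base-pair overlap ``c`` between the G4 set and the (windowed) target
    set is compared with the overlaps ``t_1..t_m`` of ``m`` shuffled
    replicates of the G4 set. The statistic is ``F = c / (1 + t)`` with
    ``t`` the shuffle mean — the constant 1 keeps F finite when the
    expected random overlap is below one base — and significance comes
    from an upper one-tailed Z-test treating the shuffle overlaps as a
    normal null population.

``GlobalCpGEnrichment``
    Fold enrichment against the genome-wide CpG background. With ``f``
    the fraction of all ``N`` genome CpGs whose window overlaps a G4,
    the expected number of overlapping clock CpGs is ``E[n] = f·n_clock``
    and the statistic is ``n / E[n]``, tested with the hypergeometric
    upper tail (population N, successes K = f·N, draws n_clock). This
    controls for the natural enrichment of G4s around CpGs in general
    (CpG islands, promoters).

``window_scan`` evaluates both along a grid of window sizes around each
clock CpG. No multiple-testing correction is applied across windows; raw
p-values (and their log10, computed in log space since genome-scale runs
fall far below double-precision underflow) are reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .cpg_scan import CpGCatalog
from .intervals import (
    ChromSizes,
    ClockCpG,
    IntervalSet,
    count_overlapping,
    make_windows,
    merge,
    overlap_bp,
)
from .randomization import ShuffleConfig, shuffle_intervals

__all__ = [
    "ALPHA",
    "DEFAULT_WINDOWS",
    "ShuffleEnrichment",
    "ShuffleEnrichmentResult",
    "GlobalCpGEnrichment",
    "CpGEnrichmentResult",
    "WindowScanResult",
    "hypergeom_upper_tail",
    "z_test_upper",
    "enrich_vs_shuffle",
    "enrich_vs_global_cpg",
    "protein_site_enrichment",
    "window_scan",
    "stratify_by_direction",
    "DirectionStrata",
]

#: significance threshold used throughout (uncorrected)
ALPHA = 0.01

#: decade grid spanning the analysed window-size range, 10 bp to 1 Mb
DEFAULT_WINDOWS = (10, 100, 1_000, 10_000, 100_000, 1_000_000)

_LN10 = math.log(10.0)


def hypergeom_upper_tail(n_obs: int, N: int, K: int, n_draws: int) -> tuple[float, float]:
    """P(X >= n_obs) for X ~ Hypergeometric(N, K, n_draws).

    Returns ``(p, log10_p)``; the tail is computed in log space so that
    genome-scale inputs far below double underflow still report a finite
    log10 p. This is the significance test behind the global-CpG fold.
    """
    if not (0 <= K <= N and 0 <= n_draws <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N} K={K} n={n_draws}")
    logp = stats.hypergeom.logsf(n_obs - 1, N, K, n_draws)
    return float(math.exp(logp)), float(logp / _LN10)


def z_test_upper(c: float, shuffle_counts: Sequence[float]) -> tuple[float, float]:
    """Upper one-tailed Z-test of ``c`` against the shuffle population.

    The shuffle overlaps are treated as a normal null sample with the
    sample (n-1) standard deviation. Returns ``(z, p)``. Degenerate
    ``sd = 0``: p is 0 if c exceeds the mean, else 1.
    """
    z, p, _ = _z_test_upper_log(c, shuffle_counts)
    return z, p


def _z_test_upper_log(
    c: float, shuffle_counts: Sequence[float]
) -> tuple[float, float, float]:
    counts = np.asarray(shuffle_counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 shuffle counts for the Z-test")
    mean = counts.mean()
    sd = counts.std(ddof=1)
    if sd == 0.0:
        warnings.warn(
            "all shuffle overlaps identical (sd = 0); p-value degenerates "
            "to a step at the mean",
            RuntimeWarning,
            stacklevel=3,
        )
        if c > mean:
            return math.inf, 0.0, -math.inf
        return (-math.inf if c < mean else 0.0), 1.0, 0.0
    z = (c - mean) / sd
    logp = stats.norm.logsf(z)
    return float(z), float(math.exp(logp)), float(logp / _LN10)


@dataclass
class ShuffleEnrichmentResult:
    """Fold enrichment of one G4 set at one target set vs the shuffle null.

    ``F = c / (1 + t)`` where ``c`` is the observed overlap in bp and
    ``t`` the mean overlap over the shuffled replicates.
    """

    c: int
    t: float
    sd: float
    F: float
    z: float
    p: float
    log10_p: float
    n_shuffles: int
    shuffle_counts: np.ndarray
    window: int | None = None
    target: str = ""
    empty_inputs: bool = False

    def __post_init__(self) -> None:
        self.shuffle_counts = np.asarray(self.shuffle_counts)

    @property
    def significant(self) -> bool:
        return self.p < ALPHA

    def to_row(self) -> dict:
        return {
            "target": self.target,
            "window": -1 if self.window is None else self.window,
            "c": self.c,
            "t": self.t,
            "sd": self.sd,
            "F": self.F,
            "z": self.z,
            "p": self.p,
            "log10_p": self.log10_p,
            "n_shuffles": self.n_shuffles,
            "shuffle_counts": ",".join(
                str(int(x)) for x in np.asarray(self.shuffle_counts)
            ),
        }

    def summary(self) -> str:
        lines = [
            "Shuffle-null enrichment",
            "=======================",
            f"target:            {self.target or '-'}",
            f"window:            {self.window if self.window is not None else '-'} bp",
            f"observed overlap c {self.c} bp",
            f"shuffle mean t:    {self.t:.4f} bp  (sd {self.sd:.4f}, "
            f"n = {self.n_shuffles})",
            f"fold F = c/(1+t):  {self.F:.4f}",
            f"z:                 {self.z:.4f}",
            f"p (upper tail):    {self.p:.4g}   log10 p = {self.log10_p:.4f}",
            f"significant at {ALPHA}: {self.significant}",
        ]
        if self.empty_inputs:
            lines.append("warning: empty G4 or target set; statistic degenerate")
        return "\n".join(lines)


class ShuffleEnrichment:
    """Model: G4 fold enrichment at a fixed target set vs shuffled G4s.

    The G4 set is shuffled (targets held fixed), preserving feature
    count and length multiset; each replicate's base-pair overlap with
    the merged targets forms the empirical null.
    """

    def __init__(
        self,
        g4s: IntervalSet,
        targets: IntervalSet,
        chrom_sizes: ChromSizes | None = None,
        config: ShuffleConfig | None = None,
        window: int | None = None,
        target_name: str = "",
    ):
        self.g4s = g4s
        self.targets = merge(targets)
        self.chrom_sizes = chrom_sizes or g4s.chrom_sizes
        self.config = config or ShuffleConfig()
        self.window = window
        self.target_name = target_name

    @classmethod
    def from_clock(
        cls,
        g4s: IntervalSet,
        clock: Iterable[ClockCpG],
        window: int,
        chrom_sizes: ChromSizes,
        config: ShuffleConfig | None = None,
        target_name: str = "",
    ) -> "ShuffleEnrichment":
        """Build the target set by windowing clock CpGs."""
        targets = make_windows(clock, window, chrom_sizes)
        return cls(
            g4s, targets, chrom_sizes, config, window=window,
            target_name=target_name,
        )

    def fit(self) -> ShuffleEnrichmentResult:
        if len(self.g4s) == 0 or len(self.targets) == 0:
            warnings.warn(
                "empty G4 or target set: returning degenerate result "
                "(c = 0, F = 0, p = 1)",
                RuntimeWarning,
                stacklevel=2,
            )
            return ShuffleEnrichmentResult(
                c=0, t=0.0, sd=0.0, F=0.0, z=0.0, p=1.0, log10_p=0.0,
                n_shuffles=0, shuffle_counts=np.empty(0, dtype=np.int64),
                window=self.window, target=self.target_name, empty_inputs=True,
            )
        c = overlap_bp(self.g4s, self.targets)
        counts = np.array(
            [
                overlap_bp(
                    shuffle_intervals(
                        self.g4s, self.chrom_sizes, self.config, i
                    ),
                    self.targets,
                )
                for i in range(self.config.n_shuffles)
            ],
            dtype=np.int64,
        )
        t = float(counts.mean())
        sd = float(counts.std(ddof=1)) if counts.size > 1 else 0.0
        F = c / (1.0 + t)
        z, p, log10_p = _z_test_upper_log(c, counts)
        return ShuffleEnrichmentResult(
            c=int(c), t=t, sd=sd, F=float(F), z=z, p=p, log10_p=log10_p,
            n_shuffles=int(counts.size), shuffle_counts=counts,
            window=self.window, target=self.target_name,
        )


@dataclass
class CpGEnrichmentResult:
    """Fold enrichment of clock CpGs among G4-overlapping CpGs genome-wide.

    ``fold = n_obs / (f · n_clock)`` with the hypergeometric upper-tail
    p-value for drawing ``n_obs`` G4-overlapping sites in ``n_clock``
    draws from a population of ``N`` CpGs containing ``K`` successes.
    """

    N: int
    K: int
    f: float
    n_clock: int
    n_obs: int
    expected: float
    fold: float
    p: float
    log10_p: float
    window: int | None = None
    target: str = ""
    fold_infinite: bool = False
    n_absent: int = 0

    @property
    def significant(self) -> bool:
        return self.p < ALPHA

    def to_row(self) -> dict:
        return {
            "target": self.target,
            "window": -1 if self.window is None else self.window,
            "N": self.N,
            "K": self.K,
            "f": self.f,
            "n_clock": self.n_clock,
            "n_obs": self.n_obs,
            "expected": self.expected,
            "fold": self.fold,
            "p": self.p,
            "log10_p": self.log10_p,
        }

    def summary(self) -> str:
        fold = "inf" if self.fold_infinite else f"{self.fold:.4f}"
        lines = [
            "Global-CpG enrichment",
            "=====================",
            f"target:                 {self.target or '-'}",
            f"window:                 {self.window if self.window is not None else '-'} bp",
            f"genome CpGs N:          {self.N}",
            f"G4-overlapping CpGs K:  {self.K}   (f = K/N = {self.f:.6f})",
            f"clock CpGs:             {self.n_clock}",
            f"observed overlapping n: {self.n_obs}",
            f"expected E[n] = f*n:    {self.expected:.4f}",
            f"fold = n/E[n]:          {fold}",
            f"p (hypergeometric):     {self.p:.4g}   log10 p = {self.log10_p:.4f}",
            f"significant at {ALPHA}:  {self.significant}",
        ]
        if self.n_absent:
            lines.append(
                f"warning: {self.n_absent} clock CpGs absent from the catalog"
            )
        return "\n".join(lines)


class GlobalCpGEnrichment:
    """Model: clock-CpG G4 overlap against the genome-wide CpG background."""

    def __init__(
        self,
        g4s: IntervalSet,
        clock: Iterable[ClockCpG],
        catalog: CpGCatalog,
        window: int = 0,
        target_name: str = "",
    ):
        if catalog.N == 0:
            raise ValueError("CpG catalog is empty")
        self.g4s = g4s
        self.clock = _dedup_clock(clock)
        self.catalog = catalog
        self.window = window
        self.target_name = target_name

    def fit(self) -> CpGEnrichmentResult:
        n_absent = _count_absent(self.clock, self.catalog)
        if n_absent:
            warnings.warn(
                f"{n_absent} clock CpGs are not in the genome CpG catalog",
                RuntimeWarning,
                stacklevel=2,
            )
        N = self.catalog.N
        K = count_overlapping(self.catalog.positions, self.g4s, self.window)
        n_clock = len(self.clock)
        n_obs = count_overlapping(self.clock, self.g4s, self.window)
        f = K / N
        expected = f * n_clock
        fold_infinite = expected == 0.0 and n_obs > 0
        fold = math.inf if fold_infinite else (
            n_obs / expected if expected > 0 else 0.0
        )
        p, log10_p = hypergeom_upper_tail(n_obs, N, K, n_clock)
        return CpGEnrichmentResult(
            N=N, K=int(K), f=float(f), n_clock=n_clock, n_obs=int(n_obs),
            expected=float(expected), fold=float(fold),
            p=p, log10_p=log10_p,
            window=self.window, target=self.target_name,
            fold_infinite=fold_infinite, n_absent=n_absent,
        )


def _dedup_clock(clock: Iterable[ClockCpG]) -> list[ClockCpG]:
    seen: set[tuple[str, int]] = set()
    out = []
    for cpg in clock:
        key = (cpg.chrom, cpg.pos)
        if key not in seen:
            seen.add(key)
            out.append(cpg)
    return out


def _count_absent(clock: Sequence[ClockCpG], catalog: CpGCatalog) -> int:
    absent = 0
    for cpg in clock:
        pos = catalog.positions.get(cpg.chrom)
        if pos is None or pos.size == 0:
            absent += 1
            continue
        i = np.searchsorted(pos, cpg.pos)
        if i >= pos.size or pos[i] != cpg.pos:
            absent += 1
    return absent


# -- convenience functions mirroring the pipeline operations -----------------


def enrich_vs_shuffle(
    g4s: IntervalSet,
    targets: IntervalSet,
    chrom_sizes: ChromSizes | None = None,
    config: ShuffleConfig | None = None,
    window: int | None = None,
    target_name: str = "",
) -> ShuffleEnrichmentResult:
    """Fold enrichment of ``g4s`` at ``targets`` against the shuffle null."""
    return ShuffleEnrichment(
        g4s, targets, chrom_sizes, config, window, target_name
    ).fit()


def protein_site_enrichment(
    g4s: IntervalSet,
    peaks: IntervalSet,
    chrom_sizes: ChromSizes | None = None,
    config: ShuffleConfig | None = None,
    target_name: str = "",
) -> ShuffleEnrichmentResult:
    """Shuffle-null enrichment with ChIP-seq peaks as targets, used as-is
    (no windowing)."""
    return ShuffleEnrichment(
        g4s, peaks, chrom_sizes, config, window=None, target_name=target_name
    ).fit()


def enrich_vs_global_cpg(
    g4s: IntervalSet,
    clock: Iterable[ClockCpG],
    catalog: CpGCatalog,
    window: int = 0,
    target_name: str = "",
) -> CpGEnrichmentResult:
    """Clock-CpG G4 enrichment relative to the global CpG background."""
    return GlobalCpGEnrichment(g4s, clock, catalog, window, target_name).fit()


class DirectionStrata(NamedTuple):
    hyper: list[ClockCpG]
    hypo: list[ClockCpG]
    n_zero: int


def stratify_by_direction(clock: Iterable[ClockCpG]) -> DirectionStrata:
    """Partition clock CpGs into hyper- (direction > 0) and hypomethylated
    (direction < 0) strata; zero-direction sites are excluded and counted."""
    hyper, hypo, n_zero = [], [], 0
    for cpg in clock:
        if cpg.direction > 0:
            hyper.append(cpg)
        elif cpg.direction < 0:
            hypo.append(cpg)
        else:
            n_zero += 1
    if n_zero:
        warnings.warn(
            f"{n_zero} clock CpGs with direction 0 excluded from strata",
            RuntimeWarning,
            stacklevel=2,
        )
    return DirectionStrata(hyper, hypo, n_zero)


@dataclass
class WindowScanResult:
    """Both enrichment statistics along a grid of window sizes."""

    windows: list[int]
    shuffle_results: list[ShuffleEnrichmentResult]
    cpg_results: list[CpGEnrichmentResult] | None = None
    alpha: float = ALPHA

    @property
    def argmax_F(self) -> int:
        """Window with the highest shuffle fold enrichment F."""
        i = int(np.argmax([r.F for r in self.shuffle_results]))
        return self.windows[i]

    @property
    def argmax_cpg_fold(self) -> int | None:
        if not self.cpg_results:
            return None
        i = int(np.argmax([r.fold for r in self.cpg_results]))
        return self.windows[i]

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, w in enumerate(self.windows):
            r = self.shuffle_results[i]
            row = {
                "window": w,
                "c": r.c,
                "t": r.t,
                "F": r.F,
                "z": r.z,
                "p_shuffle": r.p,
                "log10_p_shuffle": r.log10_p,
                "significant_shuffle": r.p < self.alpha,
            }
            if self.cpg_results:
                g = self.cpg_results[i]
                row.update(
                    {
                        "f": g.f,
                        "n_obs": g.n_obs,
                        "expected": g.expected,
                        "fold_cpg": g.fold,
                        "p_cpg": g.p,
                        "log10_p_cpg": g.log10_p,
                        "significant_cpg": g.p < self.alpha,
                    }
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def plot(self, ax=None):
        """Fold enrichment vs window size (log-x), both statistics."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.windows, [r.F for r in self.shuffle_results],
                "o-", color="black", label="vs shuffled")
        if self.cpg_results:
            ax.plot(self.windows, [r.fold for r in self.cpg_results],
                    "s-", color="tab:blue", label="vs global CpG")
        ax.axhline(1.0, color="grey", linestyle=":", linewidth=1)
        ax.set_xscale("log")
        ax.set_xlabel("window size (bp)")
        ax.set_ylabel("fold enrichment")
        ax.legend()
        return ax

    def summary(self) -> str:
        df = self.to_frame()
        with np.printoptions(precision=4):
            body = df.to_string(index=False, float_format=lambda x: f"{x:.4g}")
        head = [
            "Window scan",
            "===========",
            f"windows: {self.windows}",
            f"max F at window {self.argmax_F} bp",
        ]
        if self.cpg_results:
            head.append(f"max global-CpG fold at window {self.argmax_cpg_fold} bp")
        return "\n".join(head) + "\n" + body


def window_scan(
    g4s: IntervalSet,
    clock: Iterable[ClockCpG],
    chrom_sizes: ChromSizes,
    catalog: CpGCatalog | None = None,
    windows: Sequence[int] = DEFAULT_WINDOWS,
    config: ShuffleConfig | None = None,
    target_name: str = "",
) -> WindowScanResult:
    """Evaluate enrichment along a strictly increasing window-size grid.

    The shuffle statistic is always computed; the global-CpG statistic is
    added when a CpG catalog is supplied. Per-window significance is
    flagged at the uncorrected 0.01 threshold.
    """
    windows = [int(w) for w in windows]
    if not windows:
        raise ValueError("windows list is empty")
    if any(w <= 0 for w in windows):
        raise ValueError("window sizes must be positive")
    if any(b <= a for a, b in zip(windows, windows[1:])):
        raise ValueError("window sizes must be strictly increasing")
    clock = _dedup_clock(clock)
    config = config or ShuffleConfig()
    shuffle_results = []
    cpg_results = [] if catalog is not None else None
    for w in windows:
        shuffle_results.append(
            ShuffleEnrichment.from_clock(
                g4s, clock, w, chrom_sizes, config, target_name
            ).fit()
        )
        if catalog is not None:
            cpg_results.append(
                GlobalCpGEnrichment(g4s, clock, catalog, w, target_name).fit()
            )
    return WindowScanResult(windows, shuffle_results, cpg_results)
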