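import numpy as np
import pytest

import g4clock as g4


@pytest.fixture(scope="session")
def toy_sizes() -> g4.ChromSizes:
    return g4.ChromSizes({"chr1": 10_000, "chr2": 8_000})


@pytest.fixture(scope="session")
def small_scenario() -> g4.Scenario:
    """A 2 x 1 Mb planted scenario shared across tests (read-only)."""
    return g4.generate_scenario(g4.small_truth(seed=7))


def random_interval_set(
    rng: np.random.Generator,
    chrom_sizes: g4.ChromSizes,
    n: int,
    max_len: int = 200,
) -> g4.IntervalSet:
    """Uniform random intervals for oracle comparisons."""
    chroms = list(chrom_sizes)
    data = {}
    counts = rng.multinomial(n, [1 / len(chroms)] * len(chroms))
    for chrom, k in zip(chroms, counts):
        if k == 0:
            continue
        clen = chrom_sizes[chrom]
        lengths = rng.integers(1, min(max_len, clen) + 1, size=k)
        starts = rng.integers(0, clen - lengths + 1)
        data[chrom] = (starts, starts + lengths)
    return g4.IntervalSet.from_arrays(data, chrom_sizes)


def coverage_mask(s: g4.IntervalSet, chrom: str) -> np.ndarray:
    """Per-base boolean coverage — the independent overlap oracle."""
    mask = np.zeros(s.chrom_sizes[chrom], dtype=bool)
    starts, ends = s.arrays(chrom)
    for a, b in zip(starts, ends):
        mask[a:b] = True
    return mask


def mask_overlap_bp(a: g4.IntervalSet, b: g4.IntervalSet) -> int:
    """Covered-base overlap counted position by position."""
    total = 0
    for chrom in a.chrom_sizes:
        total += int((coverage_mask(a, chrom) & coverage_mask(b, chrom)).sum())
    return total
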