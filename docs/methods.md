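# Methods

`g4clock` quantifies the colocalization of G-quadruplex (G4) interval
sets with ageing-clock CpG sites. This note records the statistical
model, the conventions and defaults, the design of the synthetic
scenarios used for validation, and the known limits of both.

## Coordinates and overlap semantics

All internal coordinates are 0-based, half-open (BED convention). A CpG
site is the 2-bp interval `[pos, pos+2)` covering the C and G of the
dinucleotide. A window of size `w` extends that interval by `⌊w/2⌋` on
each flank — `[pos − ⌊w/2⌋, pos + 2 + ⌊w/2⌋)` — clipped to the
chromosome, so an even window `w` yields a `w+2` bp interval.

Base-pair overlap between two interval sets merges both sets first and
counts the bases of the intersection of their covered sequence. A base
covered by two overlapping clock windows therefore counts once: the
statistic measures covered sequence, not window multiplicity. The
unmerged alternative (sum of all pairwise intersections, what a naive
intersect of unmerged files reports) is available through
`overlap_bp(..., merge_inputs=False)` for sensitivity analysis. Overlap
requires at least one shared base; abutting intervals do not overlap.
Strand is read from BED input but ignored everywhere: the CG
dinucleotide is its own reverse complement and G4 maps report both
strands.

## Enrichment relative to a shuffle null

For a G4 set and a target set (windowed clock CpGs, or ChIP-seq peaks
used as-is), the observed overlap `c` (bp) is compared against `m`
shuffled replicates of the G4 set with overlaps `t_1..t_m`:

    F = c / (1 + t),   t = mean(t_i)

The constant 1 in the denominator keeps F finite and conservative when
the expected random overlap is below one base; it is applied always,
which biases F slightly toward zero when `t` is large — a deliberate,
uniform convention. Significance is an upper one-tailed Z-test treating
the shuffle overlaps as a normal null sample:

    z = (c − mean(t_i)) / sd(t_i),   p = 1 − Φ(z)

with the sample (n−1) standard deviation. Normality of shuffle overlaps
is an *assumption*, reasonable for overlap sums over many intervals but
not guaranteed on sparse toy inputs; when all shuffle overlaps are
identical (sd = 0, common on tiny data) the p-value degenerates to a
step — 0 if `c` exceeds the mean, else 1 — and a warning is raised.
Because genome-scale runs produce p far below double-precision
underflow, the normal tail is evaluated in log space and `log10_p` is
reported alongside `p`.

Shuffling relocates each G4 interval independently, preserving the
feature count and length multiset. By default placement is genome-wide:
the destination chromosome is drawn with probability proportional to
its length and the start uniformly on `[0, chrom_len − len]`; shuffled
intervals may overlap one another (enforcing disjointness would bias
`t` downward). A per-chromosome mode and an optional exclusion mask
(e.g. assembly gaps) are provided for sensitivity analyses; neither is
used by default. One master seed plus the replicate index give each
shuffle an independent, reproducible stream, so replicates are
order-independent.

Defaults: 30 shuffles, significance threshold 0.01, no
multiple-testing correction across windows or target sets — raw p (and
log10 p) are reported so users can correct downstream.

## Enrichment relative to the global CpG background

CpGs cluster in CpG islands and promoters, which are themselves G-rich;
enrichment over a shuffle null therefore partly reflects CpG context
rather than anything specific to clock sites. The second statistic
controls for this. With `N` the number of CG dinucleotides in the
genome (forward-strand literal scan; soft-masked lowercase counts, `N`
bases never match), `K` of which have a window overlapping a G4, and
`n` of the `n_clock` clock CpGs overlapping at the same window:

    f = K / N,   E[n] = f · n_clock,   fold = n / E[n]

tested with the hypergeometric upper tail `P(X ≥ n)` for `X ~
Hypergeom(N, K, n_clock)` (computed in log space). Note the denominator
here is `E[n]` exactly, with no +1 — intentionally asymmetric with F.
The same window is applied to background CpGs and clock CpGs so the two
populations stay strictly comparable; window 0 tests the bare 2-bp
sites.

`window_scan` evaluates both statistics on a strictly increasing window
grid, by default the decade grid 10, 100, 1000, 10^4, 10^5, 10^6 bp.
Hyper- and hypomethylated clock CpGs (sign of the supplied coefficient)
can be stratified and analysed separately; zero coefficients are
excluded with a count.

## Synthetic scenarios and the analytic fold

A scenario plants every quantity the pipeline estimates:

* a genome of `n_chroms × chrom_length` bp whose CG dinucleotides are
  placed at rate `background_cpg_rate` per bp (per-chromosome counts
  Poisson, positions uniform with a 2-bp minimum gap). The sequence
  background is drawn from {A, T}, so the planted CG set is provably
  the complete CG set; a realistic {A,C,G,T} mode exists, with the
  catalog then defined by scanning the sequence;
* a clock of `n_clock_cpgs` CpGs sampled uniformly from the catalog,
  direction ±1 with probability `hyper_fraction`;
* a G4 set of `n_g4_background` intervals placed uniformly genome-wide
  plus, for a fraction `ρ` of clock CpGs, one interval whose start is
  uniform within ±`d` bp of the CpG (`association_radius`). Lengths are
  uniform on 20–60 bp, the footprint scale of experimentally mapped G4
  intervals; the law is configurable.

Everything is a pure function of the truth parameters and a seed;
written scenarios are byte-reproducible and fully reconstructable from
their `truth.json`.

The expected fold at window `w` follows in closed form. Write `G` for
genome length, `P = ⌊ρ·n_clock⌋` planted and `B` background G4s, `l̄`
the mean G4 length, `W = w + 2`, and `T = G·(1 − exp(−n_clock·W/G))`
the expected merged window coverage (Poisson approximation for
uniformly placed CpGs). Each planted G4 overlaps its own window by
`E_ov(w)`, the exact discrete expectation over the uniform offset and
the length law; its remaining `l̄ − E_ov` bases fall in *other* windows
at the coverage rate `T/G`, and uniform intervals overlap the windows
by `l̄·T/G` on average:

    E[c] = P·(E_ov + (l̄ − E_ov)·T/G) + B·l̄·T/G
    E[t] = (B + P)·l̄·T/G
    F*   = E[c] / (1 + E[t])

`true_fold_estimate` evaluates `F*` at `w = 2d` by default. It is the
recovery target for both statistics; because every term scales with
per-bp densities, it is invariant under scaling the genome and all
counts together, which is also a property test of the pipeline. At the
preset densities, simulations recover `F*` within a few percent with
the shuffle statistic and within ~10% with the global-CpG fold (whose
Poisson-coverage background term is the roughest approximation).

Presets (the conditions used throughout the validation suite):

| preset    | genome   | CpG rate | n_clock | background G4s | ρ | d (bp) |
|-----------|----------|----------|---------|----------------|---|--------|
| `small`   | 2 × 1 Mb | 0.01/bp  | 600     | 80             | 1 | 500    |
| `null`    | 2 × 5 Mb | 0.01/bp  | 1000    | 2000           | 0 | 500    |
| `planted` | 2 × 5 Mb | 0.01/bp  | 3000    | 400            | 1 | 500    |

`small` keeps the same per-bp densities as `planted` (same expected
fold) at a fifth of the size, for fast end-to-end and CLI tests.
`planted` uses 3000 clock CpGs so replicate noise on the recovered fold
is ~2%. The null calibration runs 100 replicates of `null`; the
validation suite and the acceptance script finish in well under a
minute of compute for these sizes.

### The window profile of the planted model

With a *uniform* offset law, the planted signal captured by a window of
width `W` grows linearly in `W` up to `W ≈ 2d`, exactly as the shuffle
mean does, so the expected F is flat across windows below `2d` and
declines beyond, where windows merge and the statistic relaxes toward
1. Second-order effects (planted G4s acting as background for other
windows; saturation of `E_ov`; window merging) in fact tilt the flat
region slightly toward the *smallest* windows. Real G4 maps show fold
curves that rise with window size up to ~1 kb, which implies a G4
offset distribution depleted near the CpG itself; reproducing that
shape would require a non-uniform offset law (e.g. an annular one).
The generator deliberately keeps the uniform law — it is the simplest
model with a known closed-form fold — so passing the recovery tests
demonstrates correct *magnitude* estimation at any one window, not the
rising-to-peak shape of the curve seen with real data. Tests of curve
shape on synthetic data therefore check the decline at large windows,
not the position of the maximum.

Other features of real data the generator does not emulate: CpG
islands (CpGs are uniform, not clustered), G4 sequence motifs (planted
intervals are coordinates, not G-rich sequence), chromatin context,
assembly gaps, and inter-species count differences (`subsample_intervals`
exists for the latter but no preset uses it).

## Numerical and degenerate-input conventions

* `argmax` over windows takes the first maximum (ties broken toward
  smaller windows).
* Empty G4 or target sets yield a flagged degenerate result
  (`c = 0, F = 0, p = 1`) with a warning rather than an error.
* `expected = 0` with `n > 0` in the global-CpG statistic flags the
  fold as infinite; p is still computed.
* Clock tables declare their column mapping, delimiter and base
  convention explicitly (`ClockTableFormat`); positions are converted
  to 0-based on read, duplicates dropped with counts. Tables keyed only
  by array probe ID cannot be resolved here — coordinates must be
  supplied.
* Unknown chromosomes in interval or clock input are an error by
  default; an explicit drop mode reports the dropped count. Silent
  record loss is the classic source of irreproducible enrichment
  numbers.
* Results tables render floats with 10 significant digits and
  round-trip losslessly through the paired reader.

## Limitations

The shuffle null is uniform: it is not matched on GC content, chromatin
state or gap structure, so enrichment against it conflates G4-specific
signal with any sequence-composition bias of the targets — that is
precisely why the global-CpG statistic is computed alongside. Assembly
conversion (liftOver) is out of scope; all inputs must share one genome
build. The Z-test inherits its normality assumption from the shuffle
overlap distribution and degenerates on very sparse inputs, where the
hypergeometric test is the more trustworthy of the two.
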