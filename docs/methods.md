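# Methods

## Coordinate conventions

A segmented cell is reduced to its long-axis length `ℓ` (µm) and the axial
coordinates of its fluorescent foci, measured from one pole. Two derived
coordinate systems are used:

* **Relative (unfolded)**: `x/ℓ ∈ [0, 1]`. Used for cell-quarter occupancy
  and for the midcell-division simulator, where the quarters and the septum
  are physical regions of the cell.
* **Folded (half-cell)**: `min(x/ℓ, 1 − x/ℓ) ∈ [0, 0.5]`, the fractional
  distance to the nearest pole. Used for the five-slice distributions and
  the polar fraction.

Which pole a micrograph calls "first" is arbitrary, so every statistic is
defined to be invariant under the per-cell flip `x → ℓ − x`; the folded
coordinate is invariant by construction, quarter occupancy and the
one-sided classification are symmetric in the two halves, and tests assert
this invariance explicitly.

Bins are equal-width and half-open `[a, b)` with the final bin closed (at
0.5 folded, or at 1.0 unfolded). No convention is forced by the data; one
is fixed so that results are bit-reproducible. The polar fraction counts
folded values strictly below its threshold (default 0.1), consistent with
that convention.

## Occupancy null and tests

The null model for focus placement is `n` independent uniform points on
`[0, 1]`. The probability that they leave none of `k` equal-width bins
empty is computed exactly by inclusion–exclusion over the set of empty
bins,

    P(n, k) = Σ_{j=0}^{k} (−1)^j C(k, j) ((k − j)/k)^n,

which equals the surjection count `k!·S(n, k)` over `k^n` (S = Stirling
numbers of the second kind); the test suite checks the formula against
direct enumeration of all `k^n` assignments for `n ≤ 10, k ≤ 4`. `P = 0`
for `n < k` (pigeonhole), `P = k!/k^k` at `n = k`, and `P → 1` as `n → ∞`.

The occupancy test is run per focus-count stratum (cells with exactly `n`
foci): the observed all-quarters-occupied fraction is compared to
`P(n, 4)` by a χ² goodness-of-fit on the binary (occupied, not-occupied)
outcome, df = 1. Whether the original analysis pooled strata is not
determinable; per-stratum testing is the more conservative reading and
matches reporting of separate p-values per stratum. When an expected
category count falls below 5 the asymptotic χ² is unreliable: the result is
flagged and an exact binomial p-value is reported alongside.

Between-genotype comparisons of binned distributions use the Pearson χ²
test of homogeneity on the 2×m table of counts (never fractions), without
continuity correction so the statistic equals the textbook formula
`Σ (O − E)²/E` exactly. A contiguous bin subset can be selected (e.g. the
three central half-cell slices, 0.2–0.5) to localize where two
distributions differ. Bins empty in both samples carry no information and
are dropped before testing. Five-slice fractions are computed per focus,
pooled over cells, rather than per cell then averaged; with hundreds of
cells the two differ negligibly and the pooled form is the natural one for
count-based χ².

## Loss-rate estimation

Serial passage without selection is modelled as geometric decay of the
plasmid-positive fraction, `F(g) = F(0)·(1 − L)^g`, with `L` the
probability per generation that a plasmid-bearing lineage yields a
plasmid-free daughter. Retention at each checkpoint is scored by
replica-picking a fixed number of colonies, so `colonies_positive` is
binomial around `F(g)`.

* `log_linear` (default): least-squares fit of `ln F(g)` on `g` over all
  checkpoints with `F > 0`, `L = 1 − exp(slope)`. Uses every checkpoint and
  is the default because it is robust to colony-sampling noise.
* `endpoint`: `L = 1 − (F_t/F_s)^{1/(t−s)}` between the first and last
  informative checkpoints.

Both reduce to the same value on noiseless geometric data (asserted in the
tests). Zero-retention checkpoints are excluded from the log fit rather
than pseudocounted — a pseudocount would bias `L` by an amount that depends
on the arbitrary constant — and the number dropped is recorded. If every
post-zero checkpoint shows zero retention, `L` is only bounded below (the
plasmid was lost faster than one detectable colony per checkpoint); the
estimate is then the bound implied by total loss before the first
checkpoint and is flagged.

Uncertainty is a parametric bootstrap: colony counts are redrawn as
binomials around the fitted retention curve (1000 replicates, seeded) and
the estimator reapplied; the 95% interval is the 2.5–97.5 percentile range.
Estimates are clamped to `[0, 1]`; a rate of exactly 0 is reported as 0
with its interval rather than as a detection floor. Biological replicates
are aggregated as mean ± sd (ddof = 1) across series, matching the
convention of error bars over ≥4 independent assays.

## Conjugation frequency

Frequency is transconjugants per donor, `T/D`, after multiplying each plate
count by its dilution factor; it is scale-invariant in the dilutions. With
`T = 0` the assay gives only a detection limit, reported as the upper bound
`1/D` and flagged; fold changes propagate bounds (upper-bound numerator →
upper-bound ratio; upper-bound denominator → lower-bound ratio).

## Segregation simulator

The division model is deliberately minimal: the septum is exactly at
midcell, foci do not move or replicate during division, and each focus is
inherited by the daughter whose half it occupies (a focus exactly at 0.5 is
assigned by a fair seeded coin — a measure-zero event for continuous
models). A plasmid-bearing mother whose foci all lie on one side therefore
produces one plasmid-free daughter. The predicted loss rate is the fraction
of plasmid-free daughters among all daughters of plasmid-bearing mothers —
the quantity a replica-picking assay estimates. Under independent 50/50
side assignment of `n` foci this is `(1/2)^n` per generation; a single-copy
plasmid segregates to one daughter only, giving the `0.5` floor.

Lineages are memoryless between generations: a surviving daughter re-draws
its focus positions from the same localization model each generation, since
no intergenerational focus-tracking information is assumed. A focus stands
for `copies_per_focus` plasmid copies, but inheritance of one focus makes a
daughter plasmid-positive regardless — presence/absence is what
replica-picking scores. The number of foci per cell is
`copy_number / copies_per_focus`, rounded, with a minimum of one.

The simulator intentionally exposes a gap rather than hiding it: a
population in which ~33% of focus-bearing cells are one-sided predicts a
far higher loss rate than the ~5% per generation measured for the unstable
mutant. Real cells presumably rescue some of those divisions (septum
placement noise, focus movement, re-replication before septation); the
simulator quantifies the counterfactual "no rescue" bound, and parameter
studies over copy number and model family explore how much rescue is
needed.

## Synthetic-data generator

The generator exists so that every downstream statistic is testable without
external data. It emulates:

* cell lengths: log-normal with arithmetic mean 3 µm and log-sd 0.25
  (most cells 2–6 µm). No empirical length distribution is available to
  reconstruct; this is a convention typical of exponential-phase rods.
* focus counts: explicit discrete distributions per preset. `wt` averages
  ≈6 foci/cell with 64% of cells at 4–6 and ≈2% focus-free; `stbB`
  averages 5.6; `stbA` and `stbABC` average ≈2 with 85%/78% of cells at
  1–3 foci and 11% focus-free. Counts are independent of cell length; the
  real positive length–count correlation is not modelled, so per-length
  regressions are out of scope for what passing tests demonstrate.
* positions: `uniform` (flat on [0, 1]); `polar_cluster`/`mixture`
  (weighted Gaussians reflected into [0, 1] — reflection rather than
  truncation so that a component centred at 0.05 keeps its mass near, not
  piled onto, the pole); `pole_excluded` (flat on
  `[exclusion_width, 1 − exclusion_width]`, default width 0.1).

The `stbA` preset's mixture (pole 0.35 / pole 0.35 / center 0.30, sd 0.05
fractional) was chosen to reproduce the aggregate one-sided-cell fraction
of ≈33% under its focus-count distribution. The per-count conditional
placement pattern reported for such mutants (a 2-focus cell's second focus
opposite the first 48% of the time, central 38%, same pole ~14%) cannot be
realized by any symmetric mixture sampled independently per focus — it
would require `a² + b² < 2ab` for component weights `a, b` — so foci are
drawn iid and the aggregate, which is what the segregation model and the
one-sided classifier consume, is matched instead. Cells drawn from these
presets show the qualitative genotype contrasts (flat vs clustered
profiles, polar exclusion, stability ordering) but are not reconstructions
of any real image set.

Every generator takes an explicit integer seed and creates its own
`numpy.random.Generator`; no global RNG state is read or written, and equal
seeds give byte-identical outputs.

## Numerical and interface choices

* χ² machinery is scipy's (`chisquare`, `chi2_contingency` with
  `correction=False`, `binomtest`); the inclusion–exclusion null, the
  folding/binning conventions, the estimators and the simulator are this
  package's own.
* p-values are reported as computed; values below representable resolution
  print as upper bounds in the CLI output.
* Tables are single-dialect TSV (UTF-8, `.` decimal separator). Focus
  positions are comma-joined within one column; an empty field is a
  plasmid-free cell, which is valid data, not an error.
* CLI exit codes: 0 success, 2 validation error, 3 format error. Every
  subcommand is a pure function of (inputs, options, seed).

## Problem sizes used in the checked claims

Estimator coverage is checked at L ∈ {0, 0.001, 0.01, 0.05} over 200
seeded passages of 80 generations with 10⁴ colonies per checkpoint; the
occupancy-test calibration on uniform populations of 10⁴ cells over 100
seeds per stratum (n = 4, 5, 6); the genotype ordering on 20 seeds of
2000-cell populations and 4000-lineage segregation runs; focus conservation
on 10⁵ divided cells. These sizes give Monte-Carlo standard errors an order
of magnitude below the effect sizes being asserted.

## Known limitations

Only the long axis is analysed; radial position, nucleoid geometry and
focus intensity (hence copies per focus beyond a preset constant) are not
modelled. The generator draws focus positions independently within a cell,
so it cannot reproduce ordered, evenly *spaced* patterns — its uniform
preset matches the uniform marginal distribution, not any spacing
statistic. The loss-rate bootstrap conditions on the fitted curve
(parametric), so model misspecification (non-geometric decay, e.g. from
fitness costs) widens neither the interval nor any flag.
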