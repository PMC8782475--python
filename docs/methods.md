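# Methods

## Model and assumptions

A process yields a fixed phase-I reference sample `X` of size `m`
(in control by assumption) and a stream of phase-II subgroups `Y_t` of
common size `n`. Both phases share one continuous distribution `F`; an
out-of-control state is a sustained location shift of `delta`
population standard deviations (`sigma_F`) in the test subgroups. Each
subgroup is reduced to the rank sum `W_t` of its observations in the
combined ordering with the reference. Under the in-control null, all
`(m+n choose n)` rank placements are equally likely, giving
`mu_W = n(m+n+1)/2` and `sigma_W^2 = mn(m+n+1)/12` regardless of `F` —
the source of the charts' distribution-freeness.

Ranking is ascending with midranks for ties. The moments above assume
no ties (almost sure for continuous data); when ties occur the package
midranks them, keeps the no-tie moments, and emits a `TiesWarning`
rather than applying a tie correction.

## Charting statistics and limits

All smoothing recursions start from the zero state
`Wbar_0 = Hbar_0 = mu_W`:

- HWMA: `H_t = lambda W_t + (1-lambda) Wbar_{t-1}`, where `Wbar_{t-1}`
  is the arithmetic mean of `W_1..W_{t-1}`.
- DHWMA: `DH_t = lambda H_t + (1-lambda) Hbar_{t-1}`, with `Hbar_{t-1}`
  the mean of the inner statistics `H_1..H_{t-1}`.
- HHWMA: the inner statistic uses `lambda_2`, the outer step
  `lambda_1`; equal parameters reduce it to DHWMA (bit-for-bit in this
  implementation, since the DHWMA variance factor delegates to the
  hybrid one).
- Competitors: EWMA (`Z_t = lambda W_t + (1-lambda) Z_{t-1}`), DEWMA
  (the same smoothing applied twice), and a two-sided tabular CUSUM
  with reference value `k` (in `sigma_W` units, default 0.5) and
  decision interval `h = L sigma_W`.

Two-sided limits are `mu_W ± L sigma_W sqrt(f_t)`, where `f_t` is the
variance of the plotted statistic in units of `sigma_W^2` under the
working assumption of i.i.d. `W_t`. A statistic exactly on a limit is
in control (strict-inequality signal rule); limits are not truncated at
the attainable range of the statistic.

### Variance factors and the coefficient oracle

Every statistic above is a linear combination
`sum_s c_s W_s + c_0 mu_W` with `sum c_s + c_0 = 1`. The package
carries two independent routes to `f_t = sum_s c_s^2`:

1. closed forms — the HWMA piecewise expression, and for the
   double/hybrid schemes an expression whose `t > 2` branch contains
   `sum_{u=1}^{t-2} (B + C (Hm_{t-2} - Hm_{u-1}))^2` with harmonic
   numbers `Hm`, `A = lambda_1 lambda_2`,
   `B = lambda_1 + lambda_2 - 2 lambda_1 lambda_2`,
   `C = (1-lambda_1)(1-lambda_2)`. Expanding the square reduces the
   sum to prefix sums of `Hm` and `Hm^2`, so the whole factor sequence
   up to `t_max` costs O(`t_max`) — this is what lets the run-length
   engine use exact time-varying limits out to a cap of 100,000 without
   quadratic cost. EWMA/DEWMA factors use geometric and
   quadratic-geometric sums.
2. `coefficient_vector`/`coefficient_oracle` — numerical propagation of
   each recursion into its explicit weight vector.

Unit and acceptance tests require route 1 = route 2 to 1e-10 relative
error for `t <= 50` across the studied smoothing grids (observed
agreement is at machine precision), and `sum c_s + c_0 = 1` throughout.

## Run-length simulation

Zero-state protocol, per replication: draw one fresh reference sample,
hold it fixed; stream independent test subgroups (shifted by
`delta * sigma_F` from the first subgroup on); compute each `W_t`
against that same reference (O(n log m) via a sorted reference and
`searchsorted`, valid because continuous draws are tie-free almost
surely); update the chart from the zero state; record the first `t`
whose statistic falls outside the limits. Runs are censored at a cap of
100,000 subgroups (200x the nominal ARL0 of 500); censored runs enter
the mean at the cap, are counted in the summary, and trigger a warning
above 1% — at the defaults the induced bias is far below Monte Carlo
error. Each replication gets an independent child stream of a single
`SeedSequence`, so studies are reproducible from one integer seed and
replications are provably non-overlapping.

Note one deliberate subtlety: because the reference is shared within a
replication, the `W_t` of one run are positively correlated (they load
on the same reference), while the variance factors `f_t` assume
independent `W_t`. That combination is intrinsic to the scheme design
being studied and is retained, not "corrected". One consequence is that
the in-control run-length distribution is strongly skewed: a
replication whose reference sits near the centre of `F` signals slowly,
one in a tail signals fast, so SDRL can exceed the ARL several-fold and
ARL estimates converge slowly.

Families: standard normal, Student t(5) (`sigma_F = sqrt(5/3)`),
Gamma(3,1) (`sigma_F = sqrt(3)`), used on their natural scales; because
shifts are specified in `sigma_F` units and the charts are rank-based,
in-control results are invariant to any standardisation.

Performance metrics: ARL, SDRL, run-length percentiles {5, 25, 50, 75,
95}, Monte Carlo standard error `sdrl/sqrt(reps)`, and EARL/ESDRL —
the means of per-shift ARL/SDRL over a grid `(delta_min, delta_max]`
in steps of 0.1.

## Calibration

`calibrate_limit` bisects `L` on a user bracket (default [0.5, 5.0])
against a target ARL0, evaluating every iterate with common random
numbers so the estimated ARL0(L) curve is monotone enough to bisect;
it stops at `|attained - target| <= tolerance` (default 2 at >= 20,000
replications) or bracket width 1e-4, then confirms the selected
constant with a fresh seed. For discrete-statistic edge cases (e.g. a
`lambda = 1` Shewhart-type chart at tiny `m, n`) the attained ARL is a
step function of `L` and the tolerance may be unattainable; the result
then reports `tolerance_met = False` with the diagnostic values.

## Synthetic data and what the tests show

`make_illustration_fixture` emulates only the *shape* of the motivating
silica-in-iron-ore monitoring problem — 520 reference values, 78
subgroups of 5, right-skewed marginal (Gamma(3,1) by default), a
location shift at a configurable changepoint — because the raw
flotation-process measurements are not public. Its defaults (shift
0.75 sigma at subgroup 40) produce streams on which all three schemes
typically signal shortly after the changepoint. Passing tests on these
fixtures demonstrates correct chart arithmetic and calibrated
false-alarm behaviour under i.i.d. sampling; they say nothing about
autocorrelation, measurement error, or drifting shifts, none of which
the generator models.

The published per-subgroup monitoring table for that application is
kept as a text fixture (`tests/data/silica_reference_table.csv`) and
the underlying rank sums are recovered by inverting the HWMA recursion
from the printed statistics (snapping to the half-integer grid rank
sums live on). Print rounding at 2 decimals accumulates through the
running mean, so recomputed statistics are checked at 0.15 absolute
tolerance while limits are checked at print precision.

## Documented discrepancies in the reference tables

Two parts of the published reference material are internally
inconsistent with the defining recursions, and this package follows the
recursions:

1. The published DHWMA/HHWMA statistic columns of the worked example
   freeze the running mean `Hbar_{t-1}` at its initial value `mu_W` for
   all `t` (e.g. the printed `DH_5 = 1397.00` equals
   `0.5 H_5 + 0.5 mu_W`, not `0.5 H_5 + 0.5 Hbar_4 = 1518.25`), and the
   published HHWMA limit columns depart from the stated variance for
   `t >= 3`. Tests therefore verify the worked example on its
   self-consistent parts: all 78 HWMA statistics, limits and signal
   flags (first signal at subgroup 14), all DHWMA limits, HHWMA limits
   at `t <= 2`, and all first-subgroup statistics.
2. The published in-control calibrations of the double schemes are not
   reproducible from the published equations under any protocol variant
   we tested (frozen running mean, swapped smoothing parameters, fresh
   reference per period, alternative outer recursions, a range of
   censoring caps): with the published constants the defined DHWMA
   chart at `lambda = 0.05` attains ARL0 near 750 rather than 500, and
   the hybrid chart with `(lambda_1, lambda_2) = (0.1, 0.5)` near 1000.
   The HWMA chart, by contrast, reproduces its published attained ARL0
   under both normal and t(5) data and its published shift profiles,
   which validates the engine itself. The acceptance checks for the
   double-scheme run lengths are left failing by design — they record
   the genuine behaviour of the charts as defined rather than tuning
   toward unreproducible values.

## Problem sizes

Default study sizes used by the test suite and acceptance script:
10,000–20,000 replications for in-control ARLs, 2,000 per shift for
EARL profiles, `(m, n) = (100, 5)` for run-length studies and
`(520, 5)` for the worked example — the full suite runs in under two
minutes on one CPU, and estimates carry their Monte Carlo standard
errors so all comparisons are made in units of simulation uncertainty.

## Known limitations

- Zero-state run lengths only; steady-state analysis is out of scope.
- No fast-initial-response or variance-monitoring variants.
- Competitor (EWMA/DEWMA/CUSUM) designs are internally consistent but
  their published calibration constants depend on unstated choices
  (asymptotic vs time-varying limits, CUSUM reference value), so their
  absolute run lengths are best-effort.
- The moments of `W` are used without tie correction; heavily
  discretised data would need a tie-aware variance.
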