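# Methods

This note documents the estimators, the synthetic data model, the numerical
choices and the known limitations of `mobstates`.

## Entropy and predictability estimators

**Uncorrelated entropy.** `H_u = −Σ p(x) log₂ p(x)` over the empirical
visitation frequencies of the scored (sub)sequence, with `0 log 0 = 0`.
All logarithms in the package are base 2; entropies are in bits.

**Lempel–Ziv entropy rate.** `H_c = N log₂ N / Σ Λ_i`, where `Λ_i` is the
length of the shortest substring starting at position `i` that does not
occur as a contiguous substring within positions `1..i−1`.  Boundary
conventions (fixed here because the estimator's definition leaves them
open): the match window is the full growing history `1..i−1`; candidate
substrings may run to the end of the sequence; when every substring from
`i` to the end has been seen, `Λ_i` saturates at `(N − i + 1) + 1`; and
`Λ_1 = 1`.  These choices make `Σ Λ = N` for an all-distinct sequence, so
`H_c = log₂ N` exactly — a convenient closed form used in the tests.

The match lengths are computed with an incrementally grown suffix
automaton: before appending symbol `i`, the automaton (which then contains
exactly the history) is walked along the suffix starting at `i`.  Total
cost is the build (linear) plus the sum of match lengths — near-linear for
realistic sequences and comfortably fast at `N = 50 000`, versus the cubic
cost of naive substring scanning.  A brute-force enumeration oracle lives
in the test suite only and the two are checked for exact agreement on
thousands of random sequences.

**Fano bound.** Given `H` and the number of distinct locations `S`, the
predictability bound solves `H = B(Π) + (1 − Π) log₂(S − 1)` on the
decreasing branch `Π ∈ [1/S, 1]`.  The left endpoint evaluates to `log₂ S`
and the right endpoint to 0, so the root is bracketed; it is found with
Brent's method at near machine precision (`xtol = 1e-14`), which keeps the
round-trip error `|B(Π̂) + (1−Π̂)log₂(S−1) − H|` below 1e-9 even where the
curve is steep (Π near 1).  Degenerate cases: `S = 1` or `H = 0` give
`Π = 1`; `H ≥ log₂ S` clamps to the uniform guess rate `1/S`.  The branch
`Π < 1/S` also satisfies the inequality but is meaningless for an upper
bound and is never returned.  `S` is always counted on the exact
(sub)sequence being scored — a slot, a window bin, a category-restricted
trajectory — not the user's global alphabet.

## Hour-of-week states

Check-ins are pooled across weeks into 168 hourly slots (Monday 00:00
origin, half-open intervals).  Slot predictability uses the uncorrelated
form `Π_u` only: single-hour subsequences are short, so ordering
information is both scarce and unreliable there.  Slots a user never
observed are missing (NaN) and excluded from all averages — zero-filling
would fabricate high confidence exactly where data are absent (night
slots).  Slots with a single distinct venue get `Π = 1` (the Fano bound is
degenerate at `S = 1`).

Window sizes `w` tile the weekly cycle into `ceil(168/w)` half-open bins;
`w` not dividing 168 leaves a shorter final bin (e.g. `w = 72` gives
72 h + 72 h + 24 h).  The per-user summary is the mean over the user's
non-empty bins, and `w = 168` reduces bit-exactly to the whole-trajectory
baseline.  Population distributions over users are summarised by their
histogram mode (default width 0.02 on [0, 1], ties toward the higher bin).

Activity metrics: `S` (distinct venues), radius of gyration `r_g` (root
mean square great-circle distance from the 3-D Cartesian centroid of the
check-in coordinates projected back to the sphere, in km, Earth radius
6371.0088 km) and the monthly rate `f̄_c` (check-ins per 30.44-day month
over the observation span, with a one-day floor so single-day users are
defined).  Stratified profiles use half-open metric bands; the defaults
include the commonly discussed ranges (`S` 10–20 and > 60; `r_g` < 10 km
and > 100 km) and are configurable.

Timestamps are assumed already local to the user.  Hour-of-week analysis
is meaningless across mixed timezones, so this assumption is explicit, and
an optional flag applies a crude `round(lon/15)`-hour offset for
nominally-UTC sources.  Duplicate (user, timestamp) rows are kept in file
order: rapid successive check-ins are real behaviour, and dropping them
would silently change `N`.

## Wavelet modes

Each user's series is their 168-point hour-of-week `Π_u` profile — the
only per-user periodic series the analysis constructs — with missing runs
of at most 3 slots interpolated linearly (circularly across the week
boundary); sparser users are skipped and counted.  168 hourly points
resolve periods up to 42 h, which covers the 24/12/6 h bands of interest.

The continuous wavelet transform uses the analytic Morlet wavelet with
`ω₀ = 6`, computed in the Fourier domain on a zero-padded (next power of
two) copy of the mean-removed, variance-normalised series.  Scales are
geometric with 12 sub-octaves per octave from a 2 h period up to half the
series length.  The normalisation is chosen so unit-variance white noise
has expected power 1 at every scale (verified empirically in the tests).
The global spectrum is the time average of `|W(s,t)|²` per scale; points
inside the cone of influence (scales `s > d/√2` at distance `d` from the
nearest edge) are excluded, with a fall-back to the plain average — and a
recorded usable fraction — at scales where no point survives.

Significance uses an AR(1) ("red noise") background with coefficient equal
to the series' lag-1 autocorrelation (negative values treated as white):
background spectrum `(1−a²)/(1+a²−2a cos(2π·dt/P))`, threshold
`background · χ²_{1−α,ν}/ν` with `ν = 2√(1 + (n_a·dt/(γ s))²)`, `γ = 2.32`
for the Morlet, `n_a` the number of time points averaged.  The AR(1)
false-positive rate of the threshold at a fixed period is verified ≤ 10%
at `α = 0.05` by simulation.

The dominant mode is the global-spectrum argmax restricted to periods
≤ 42 h, labelled 24/12/6 h when within ±20% of the nominal period and
"other" otherwise; the ±20% bands do not overlap.  Labels are invariant to
positive rescaling of the series and deterministic given the series.

## Location context

Venue categories default to the eight standard tags (Home/Work, Education,
Entertainment, Food, Travel, Shops, Outdoors, Nightlife).  Category
restriction preserves order, and scoring a restricted sequence is
bit-identical to running the entropy pipeline on that subsequence.
Distribution comparisons exclude users with fewer than 10 check-ins in the
category (configurable); counts of exclusions are reported.

The context model regresses whole-trajectory `Π_c` on the user's relative
category frequencies (which sum to 1 over categorised check-ins) by OLS
with an intercept and one reference category dropped — the identifiable
standard form for compositional regressors; fitted values are invariant to
which category is dropped, and this invariance is tested.  Rank-deficient
designs raise an error naming the most collinear column pair.  Residual
diagnostics report moments and the D'Agostino–Pearson normality test.

## Synthetic data model

The generator produces the structure the analysis assumes, with recorded
ground truth, so recovery tests are meaningful end to end.

**Schedule users.** Check-ins sit on an hourly lattice (at most one per
user-hour, matching the slot resolution); each hour is attended with a
per-user probability.  At an attended hour the user follows their routine
with probability `base + a₂₄cos(2π(h−4)/24) + a₁₂cos(2π(h−4)/12) +
a₆cos(2π(h−4)/6)` (clipped to [0, 1]; the phase puts the routine peak at
04:00).  Routine means home at night and the workplace on weekday
daytimes; weekend daytimes are outings regardless (check-in services log
little at-home daytime activity).  Non-routine hours draw a leisure venue
with Zipf-distributed popularity whose ranking rotates with the day of
week — people concentrate on different venues on different days — so
pooling several days genuinely mixes alphabets; without the rotation,
multi-day windows would be almost as predictable as daily ones.  A small
`noise` probability substitutes a uniformly random venue.  Defaults:
100 users, 16 weeks, attendance 0.35/h, routine base 0.55, amplitudes
(0.35, 0.06, 0.02), Zipf exponent 1.2, noise 0.05.  Attendance rates are
deliberately denser than typical public check-in feeds so that hour-of-week
slots accumulate enough observations at desk scale; the *structure*
(circadian routine, heavy-tailed heterogeneity), not the volume, is what
the analyses consume.

**Heterogeneity.** Venue-pool size, spatial spread (km) and attendance
rate are log-normal across users — the simplest family consistent with the
right-skewed, heavy-tailed activity metrics seen in check-in services.
Designed dominant periods (e.g. 75/20/5% for 24/12/6 h) are apportioned
exactly by largest remainder and realised by making the corresponding
harmonic's amplitude the major one (0.35 vs 0.06).

**Markov oracles.** 2+-state stationary chains provide sequences with the
closed-form entropy rate `Σ_i π_i Σ_j P_ij(−log₂ P_ij)` for validating the
LZ estimator.

**Periodic series.** Sinusoid mixtures plus Gaussian noise feed the
wavelet tests with known spectral content.

**Regression cohort.** Each user draws a Dirichlet(2) category mixture
`f`, and a target `Π* = Σ β_k f_k + ε` is realised by construction, so OLS
recovery of `β` is a genuine end-to-end test rather than a tautology.
Sequences have a fixed length (720 check-ins) and consist of runs: each
run repeats a freshly drawn (category, venue) pair — categories following
the largest-remainder composition of `f` in random order, venues uniform
among 6 per category — with deterministic (Bresenham) run lengths.  The
entropy rate of this process is `(H(f) + log₂ 6)·n_runs/N`, so the run
count is the single concentration knob.  A monotone lookup from run count
to *measured* `Π_c` (and measured `H_c`) is calibrated once per cohort at
the uniform mixture, with the sequence length held fixed so the LZ
small-sample bias is common to calibration and cohort.  Each user's target
is converted to a target entropy rate through the Fano identity at the
user's own expected alphabet size (concentrated mixtures reach fewer
venues; ignoring this compresses the response at the extremes and shrinks
recovered coefficients), the rate calibration is inverted in log run
count, and the count is rescaled by `(H(f₀)+log₂ 6)/(H(f)+log₂ 6)` to
match rates.  The designed noise `ε` is Gaussian with variance chosen so
the population `R²` equals the design value (0.42 by default) after
subtracting the measurement variance of the `Π_c` estimator, estimated
from the calibration replicates.  Designed coefficients place
routine-bound categories high (Home/Work 0.88, Travel 0.78, Shops 0.72)
and leisure categories low (Food 0.45, Nightlife 0.38).

**What the generator does not emulate.** Real check-in feeds are far
sparser and burstier, have social structure, venue turnover, travel and
relocation, and category noise; coordinates here are Gaussian scatter, not
street networks.  Passing recovery tests therefore demonstrates that the
estimators and pipelines are correct and internally consistent under the
assumed structure — not that real populations have any particular
predictability level.  Quantities like the cohort's median `H_u` depend on
the synthetic alphabet sizes and are not comparable to values measured on
services with tens of thousands of users and venues.

## Numerical choices and degenerate inputs

* Bisection-free Fano inversion via Brent, `xtol = 1e-14`.
* Histogram mode ties break toward the higher bin; the last bin is closed
  so `Π = 1` is counted.
* Empty slots/bins/strata are missing, never zero; empty strata yield
  all-missing profiles with `n = 0`.
* A constant series has zero wavelet power (mean removal first); a series
  with > 20% missing or fewer than 48 points is rejected.
* Malformed check-in rows are dropped and counted; a file over 50%
  malformed, an unknown dialect, or an unreadable file is fatal.
* Month length is fixed at 30.44 days; week starts Monday 00:00.

## Problem sizes

The test suite and the acceptance script run cohorts of 30–300 users
(16–20 weeks) for the profile/window/spectral analyses, 2000 users for
regression recovery, and `N = 50 000` sequences for LZ consistency —
sizes at which every stochastic tolerance in the tests was chosen to hold
with wide margin while the whole suite stays fast on one CPU.

## Known limitations

* The LZ estimator is biased upward at small `N`; no finite-sample
  correction or confidence interval is provided.
* The wavelet cone-of-influence exclusion leaves scales near half the
  series length with few or no usable time points on a 168-point profile;
  those periods fall back to edge-biased averages and are outside the
  ≤ 42 h classification range anyway.
* The red-noise significance assumes an AR(1) background; strongly
  non-AR(1) series (e.g. long-memory) will mis-state significance.
* The context model is a plain linear model on compositional regressors;
  no regularisation, interactions or nonlinearity.
* Timezone handling is the user's responsibility beyond the crude
  longitude offset option.
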