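# Methods

## Arena and wind

The arena is a 2.0 m × 1.0 m rectangle; the odor source sits at (0, 0.5) on
the upwind edge and navigators are released at (2.0, 0.5) on the downwind
edge. A trial succeeds when the navigator comes within 0.15 m of the
source.

The wind is spatially uniform: `u = A + β`, `v = B sin(ωt + φ) + β` with
mean speed A = 1 m/s, meandering amplitude B (treatment variable,
0.05–0.2 m/s; 0.15 m/s when held fixed), meandering rate ω = 0.1 rad/s
(period ≈ 63 s) and white-noise amplitude β = 0 in the benchmark (when
enabled, each component draws independently from U[−β, β] per step). The
wind is evaluated once per timestep and held constant across it
(zero-order hold), matching the explicit-Euler puff advection.

Because the wind has no spatial structure, the instantaneous plume is, to
first order in ω·(transit time), a straight trail pivoting slowly about the
source with slope `B sin(ωt)/A`. This is the central simplification of the
framework: it produces a meandering, thresholded, intermittent odor ribbon
at a tiny computational cost, but it does not reproduce the filament-level
stochastic dispersion of a turbulent plume (see Limitations).

## Plume

Puffs are released at f_r = 100 puffs/s (admissible range 50–200; the
release accumulator carries fractional puffs across steps so that exactly
f_r·T puffs are emitted over any horizon). Each puff starts at radius
r_0 = 1 mm and its squared radius grows linearly at the spread rate σ
(treatment variable, 1–4 × 10⁻⁴ m²/s; σ is dimensionally a diffusivity, so
linear growth of r² is the consistent reading). A puff is a 2-D Gaussian of
mass m_p = 1 (a.u.) whose width is tied to its squared radius,
`C(d) = m_p/(2s) · exp(−d²/2s)` with `s = r_p²`; a single state variable
keeps the sensed disc and the concentration field consistent. Puffs are
pruned once their center leaves the arena by more than their radius.

Since all puffs ride the same spatially uniform wind, the state stores one
running displacement integral and per-puff birth records; advection and
growth are O(1) per step and the binary sensor query is a windowed search
over puffs sorted by birth. A compiled (numba) twin of this update runs the
benchmark campaigns; it is equivalence-tested against the object-level
reference step for step.

The table-level transverse diffusivity R = 0.5 m²/s is carried in the
configuration for fidelity but enters no equation of this model: as a
literal Brownian diffusivity of puff centers it would disperse the plume
beyond the arena within a puff lifetime, so it is stored unused.

## Sensor

The navigator's sensor fires where total concentration ≥ C_0, implemented
per puff as the disc `r_det²(s) = 2s ln(m_p/(2s C_0))`; a puff becomes
undetectable once its peak m_p/(2s) falls below C_0, which bounds the
detectable trail length to `A·(m_p/(2C_0) − r_0²)/σ`. The benchmark
threshold C_0 = 620 a.u. (admissible 500–2400) was calibrated once and
frozen: it is the largest round threshold for which the fastest-spreading
treatment (σ = 4 × 10⁻⁴ m²/s) still reaches the release point
(trail ≈ 2.0 m), which the spread-rate campaign requires; it also places
that treatment in the end-of-trail regime where faster spreading visibly
helps the adaptive models.

## Navigators

All four models share the repertoire: fly upwind while the sensor is on
(*detecting*; the contiguous on-time is the detection time t_c), keep
flying upwind for a surge budget λ after losing the signal (*surging*),
then fly alternating crosswind legs of half-period δ₁ (*casting*); strategy
B adds a long crosswind *sweep* of duration δ₂ in a uniformly random
direction after four casting half-cycles. Headings are unit vectors
relative to the instantaneous local wind; ground speed is constant at
0.4 m/s; a zero wind vector holds the previous heading. The navigator
senses at its pre-move position each step, so navigation time is counted
from the start of the step in which odor is first sensed — this makes
τ = T/T̂ ≥ 1 exact, with T̂ = (|start − source| − 0.15 m)/0.4 m/s = 4.625 s
the straight-flight time to the success disc (using the full distance
instead would let a perfectly straight flight score τ < 1, which the
efficiency ratio is defined to exclude).

Strategy A: λ = t_c; δ₁ = α·t_c with α = 1.5 (A1) or δ₁ = α·g^k·t_c
growing geometrically with the half-cycle index k, g = 1.1 (A2). Strategy
B: fixed λ = 0.5 s and δ₁ = 1.5 s (calibrated once, see below) with
δ₂ = 7δ₁ (B1) or 3δ₁ (B2). The first casting direction of a bout is
random (±1, 50:50), as is each sweep direction; these, plus the trial's
meandering phase, are the only stochastic elements of a benchmark trial.

Trials are capped at 50·(straight-line distance/ground speed) = 250 s;
navigators that leave the arena fail, and navigators that never detect
odor are excluded from the success-rate denominator.

## Campaigns and trial randomness

A treatment sweeps one variable (meandering amplitude or spread rate) over
four levels with 250 navigators per model per level. Navigators are
independent; each trial draws its random stream from
`SeedSequence(master_seed, spawn_key=(variable, model, level, trial))`, so
campaigns are pure functions of (configuration, master seed) and trial
order is irrelevant.

Navigators are released sequentially into the *ongoing* meandering wind.
With β = 0 the wind and plume are otherwise deterministic, so this is
modelled by giving each trial a uniformly random meandering phase
φ ~ U[0, 2π): each navigator meets the plume at a different point of its
63 s cycle. Without this, strategy-A cohorts would be 2-point degenerate
(the initial cast sign being their only randomness) and cohort success
rates could only take values near {0, 50, 100}%. A shared-realization mode
(one phase per level) is available as an option.

## Statistics

All procedures use mid-ranks for ties and are implemented from their
standard definitions:

* **G²**: `2 Σ O ln(O/E)` over non-empty cells, df = k−1, upper chi-square
  tail; uniform expectation by default.
* **Fisher exact r×c**: 2×2 tables are solved by hypergeometric
  enumeration (two-sided: sum of probabilities ≤ the observed table's).
  Larger tables get a Monte-Carlo estimate of the exact p: rows are drawn
  from the multivariate hypergeometric distribution of the remaining
  column totals (the uniform fixed-margins null), and p is the
  (hits+1)/(n+1) proportion of tables at most as probable as the observed
  one, reported with its binomial standard error. Degenerate margins give
  p = 1, flagged. Default 10⁵ samples.
* **Holm–Bonferroni**: step-down `adj_i = max_{j≤i} min(1, (m−j+1) p_(j))`
  in sorted order, returned in input order.
* **Scheirer–Ray–Hare**: two-way ANOVA sums of squares on the joint
  mid-ranks; H = SS_effect/(SS_total/(N−1)), chi-square with the effect's
  df. The rank-based MS_total carries the tie correction, and with a
  single-level second factor the statistic reduces exactly to
  Kruskal–Wallis H (tested). The interaction is reported NaN when a cell
  has fewer than 2 observations.
* **Dunn**: `z_ij = (R̄_i − R̄_j)/√[(N(N+1)/12 − ΣT/(12(N−1)))(1/n_i + 1/n_j)]`
  with T = t³−t per tie group; two-sided normal p, Holm-adjusted by
  default. For two untied groups z² equals the Kruskal–Wallis H (tested).

The package's own implementations are cross-checked in the test suite
against independent routes only (brute-force table enumeration,
`scipy.stats.fisher_exact`/`kruskal`/`power_divergence`, statsmodels'
Holm) — the cross-checking library is never the implementation.

## Numerical choices

Timestep dt = 0.01 s (a navigator moves 4 mm per step, well under the
centimeter-scale detection discs; puff crossing times of order 0.01–0.1 s
are resolved). Mode budgets are compared with `mode_clock > budget` after
accrual, so a budget of k·dt lasts exactly k steps. Success is evaluated
after the move, domain exit after success. The campaign kernel and the
object-level reference share every update order and random draw, and are
asserted to produce identical flights.

## Calibration and frozen defaults

The benchmark pins A, ω, β, r_0, σ's ladder and the admissible ranges of
f_r and C_0, but not f_r's and C_0's point values, the strategy-B constants, or
m_p. These were calibrated once against the benchmark's qualitative
profile — all models succeed at weak meandering; strategy B collapses to
single-digit percentages under strong meandering and in the spread
campaign; spreading helps the adaptive models — and then frozen:
f_r = 100/s, C_0 = 620 a.u., m_p = 1, λ = 0.5 s, δ₁ = 1.5 s. They are the
package defaults and are not tuned per experiment.

## What the generator does and does not emulate

The synthetic environment emulates a thresholded, meandering, intermittent
odor ribbon with realistic scales (centimeter-wide detectable discs,
~2.5 s plume transit, minute-scale meander). It does **not** emulate
filament-scale turbulent dispersion: puff centers follow the mean wind
exactly, so the plume is spatially coherent and substantially easier to
re-acquire than a turbulent plume. Consequently the adaptive strategy-A
models retain ~50% success even at the strongest meandering, where a
stochastically dispersed plume yields single-digit success; conclusions
drawn from passing tests about *relative* model ranking and about the
direction of the meandering effect transfer to real plumes better than
absolute success percentages do. The mid-ladder response to the spread
rate is nearly flat in this plume (disc width depends only weakly on σ
below the end-of-trail regime), so monotone spread-rate ladders should not
be over-interpreted.

## Known limitations

* 2-D kinematics only: no flight dynamics, inertia, or altitude.
* No neural processing or memory-based strategies (by design).
* The Monte-Carlo Fisher test is an estimator; near a decision boundary
  its standard error must be taken into account (it is reported).
* The compiled kernel covers noise-free wind; noisy-wind studies fall back
  to the slower object-level engine.
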