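# Methods

## The competitive-aging model

A competition well holds two subpopulations aging together: a mutant
carrying one fluorophore and a wild-type reference carrying the other.
Viability in stationary phase is assumed to decay exponentially, so after
*T* days the viable inoculum of a strain with death rate *r* is
proportional to exp(−*r·T*). During an outgrowth read at hour *t*, each
viable subpopulation has regrown by a factor exp(*g·t*) while growth is
still exponential. With channel signals linear in population size, the
log signal ratio is linear in both *T* and *t*:

ln(RFP/CFP) = A_w + S_w·T_i + G_w·t_j + C_{Ti,tj}

with S_w = r_ref − r_mut (per day) and G_w = g_mut − g_ref (per hour).
The batch term C captures plate-wide drift of the measurement at each
(day, hour) read; it is the deviation from zero change that the wild-type
vs wild-type reference competitions exhibit, and is shared by all wells of
the plate. Reference wells therefore carry structural zeros for S and G —
they are not fit and post-hoc zeroed — and any coherent drift they show is
attributed to C. Real wild-type pairs can differ in death and growth rate;
that pair-specific baseline is absorbed into C (and A), so the fitted S of
a mutant well is its survivorship relative to the reference pair's
behavior, which is exactly the anchored quantity the assay defines.

### Assumptions

- Exponential viability decay in stationary phase (no Gompertz-style
  age-dependent hazard).
- Dead cells contribute no fluorescence at read time: the signal comes
  from regrown live cells, and outgrowth dilution makes carcass
  fluorescence negligible.
- Channel signal = gain × population + additive autofluorescence
  background; no spectral crosstalk between channels.
- The G·t term is exact only while both subpopulations grow exponentially;
  near saturation it is an approximation (see *Validity filtering*).

### Identifiability and the constraint

A constant can shift freely between the A block and the C block. The fit
imposes the single linear constraint Σ C = 0 over observed (day, hour)
cells, making A_w interpretable as the well's mean-batch-corrected
intercept. Any single linear constraint on C yields identical S and G;
only A and C change by a common offset. The constraint is eliminated by
reparametrising the last batch coefficient as minus the sum of the others;
the reduced system is solved by ordinary least squares (numpy lstsq), and
the covariance is mapped back through the reduction. The fit is joint —
one linear system over all wells — rather than "fit references, then
mutants", so reference noise propagates coherently into mutant
uncertainties. Rank deficiency beyond the known A/C aliasing (e.g. a
mutant well observed at a single hour) is detected by pivoted QR and
reported with the aliased parameter names.

### Sign conventions

y is always ln(corrected RFP / corrected CFP). The S and G regressors
carry the well's channel orientation (+T, +t when the mutant is the RFP
subpopulation; negated when it is the CFP one), so positive S always
means the mutant outlives the reference. Consequences, both
property-tested: negating every y negates every fitted parameter; swapping
the channels in the data *and* the mutant-channel labels (a physical
relabeling of the fluorophores) leaves S and G unchanged while negating A
and C.

## Preprocessing

Autofluorescence backgrounds are estimated per (plate, day, hour) read —
they scale with culture density, which changes over the outgrowth — as the
mean RFP of CFP-only monoculture wells and vice versa. A log-ratio point
is usable only if both corrected signals are strictly positive and exceed
`min_signal_factor` (default 1.0) times their background estimate; early
low-signal reads are dominated by background noise and excluded
reproducibly by this rule. Points, not wells, are dropped: a well leaves
the fit only when it has fewer than 3 valid points or valid points on
fewer than 2 distinct days, in which case its survivorship slope is not
estimable. The default threshold rule also serves as the stand-in for an
explicit outgrowth-phase window, which the assay does not otherwise
define; saturated late reads survive the filter, and the shared batch
terms absorb most of the common saturation deviation.

## Monoculture outgrowth kinetics

The comparison method and the source of the wild-type death rate r_wt.
The time shift Δt to reach OD600 = 0.35 (linear interpolation between
neighboring reads; log-OD interpolation behind a flag) converts to percent
viability via V = 100·2^(−Δt/δ). The doubling time δ is the least-squares
slope of ln OD vs hours restricted to OD ∈ [0.05, 0.30] on the first
sampling day — below the crossing threshold, so δ and the crossing stay
independent. Δt is referenced to the first sampling day's crossing, which
makes V invariant to any consistent baseline bias in the series. Death
rate comes from a nonlinear least-squares fit of V_T = V₀·exp(−r·T)
(scipy curve_fit, initialized at V₀ = 100, r = ln 2 / median T); V₀ is
free rather than pinned at 100 so first-day noise is absorbed. Half-life
is ln(2)/r, +∞ when r ≤ 0. r_wt defaults to the mean fitted decay rate of
the total OD600 of the plate's reference-competition wells — both
subpopulations there are wild type, so the total culture decays at the
wild-type rate; dedicated wild-type monoculture wells can be supplied
instead via the `wells` argument.

## Rescaled survivorship and reference testing

S is bounded above by r_wt (a strain cannot beat "not dying at all"), so
raw S values are incomparable between conditions whose wild types die at
different rates. rS = −ln(1 − S/r_wt) removes the ceiling: 0 for neutral,
ln 2 at half the wild-type death rate, −ln 2 at twice it, diverging as
S → r_wt where the assay saturates and only semi-quantitative statements
remain (values there can be clamped at (1−ε)·r_wt with an explicit flag).

The model pins reference S at zero, so the empirical wild-type spread
needed for significance calls is produced by leave-one-out relabeling:
each reference well in turn is declared a mutant and the plate refit,
yielding the S a wild-type well exhibits under the fitted model. Mutant
replicates are compared to that distribution with a two-sample t-test.
The pooled-variance Student form is the default: both groups are wells of
the same plate measured identically, and with as few as six mutant
replicates the Welch–Satterthwaite approximation measurably inflates the
type-I error (≈1.6% at a nominal 1% in 20 000 null draws) while the
pooled test is exact under the shared-variance null; Welch remains
available behind `equal_var=False`. No multiple-testing correction is
applied by default (nominal p-values are reported); a Benjamini–Hochberg
step can be added downstream.

## Interaction scoring

Per strain, replicate rS values in two conditions are compared with a
paired t-test when replicate indices match across conditions (replicate
plates run in both media) and Welch's test otherwise; pairing is
auto-detected and overridable. Significant strains are classified
relative to the neutral rS = 0 line: *alleviated* (phenotype moves toward
zero, or lands within a ±0.05 neutral band), *aggravated* (further from
zero, same sign), *reverted* (sign change). The band width is a
reporting convention, not part of the test. Orthogonal validation
statistics: a two-sided Wilcoxon rank-sum comparison of half-life groups
(exact when untied) and a two-way fixed-effects ANOVA of death rates whose
genotype × treatment p-value scores the interaction (statsmodels
`anova_lm`). Degenerate inputs (identical constants, empty design cells)
yield explicit markers or errors rather than spurious calls.

## The simulator

The generator emulates one screening plate end to end: 96 wells (31
reference competitions, 12 mutant strains × 5 replicate wells, two
autofluorescence controls per channel, one blank), stationary-phase
sampling at days 0, 1, 3, 5, 7, 9, 12, 15 and outgrowth reads every 2 h
from 0 to 18 h. Defaults: wild-type death rate 0.0648/day (half-life
10.7 days), mutant death rates log-normal around it (log-sd 0.4, a
realistic mix of short- and long-lived strains), doubling time 2 h with
~3% growth-rate variation, 2:1 mutant:reference mixing with 10% log
jitter, fluorescence gains 2000/1500 units per OD with backgrounds 80/120,
5% multiplicative log-normal measurement noise, and per-read batch offsets
of sd 0.1 on the log-ratio scale, centered to sum exactly to zero. The
null-pair generator reuses one truth table for two conditions; a uniform
multiplicative death-rate scale on condition B mimics a lifespan-extending
drug without interaction (rS is exactly invariant under it; scale 0.69
moves the wild-type half-life from 10.7 to 15.5 days).

Outgrowth has two modes. The default, *competitive_logistic*, integrates
the shared-resource system dN_i/dt = g_i·N_i·(1 − ΣN/K) (RK45, rtol
1e−10; closed form when the rates are equal), so late reads saturate the
way real plates do and the G·t model term is — deliberately — only an
approximation of the simulated dynamics. The *exponential* mode removes
the capacity and generates data that satisfy the linear model exactly.
Noise-free exact-recovery checks use equal growth rates (under which the
log-ratio is exactly A + S·T even with saturation); noisy recovery runs
use the logistic mode with growth variation, which is the harder, more
realistic case.

What the simulator does **not** model: spectral bleed-through between
channels, spatial plate effects (edge evaporation), cross-feeding between
strains, age-dependent (non-exponential) hazards, and carcass
fluorescence. Passing tests therefore demonstrate correctness of the
estimation machinery under the stated generative assumptions, not
robustness to these real-data phenomena.

## Numerical choices and scales

- Fits use dense least squares; a 7 680-observation, ~290-parameter plate
  solves in well under a second, so the leave-one-out reference
  distribution (31 refits) and the reference-count downsampling analysis
  (up to 61 refits) complete in seconds to half a minute.
- Test calibration (type-I error at 1000 null replicates per test) runs on
  record-level nulls — replicate S/rS/death-rate draws with identical
  truth across groups — which is the level the statistical tests consume;
  full-plate nulls exist (`make_null_pair`) for end-to-end studies where a
  handful of replicates suffices.
- The reference-count analysis summarises, per grid point, the sd of each
  mutant's S across random reference subsets (averaged over mutants) plus
  the mean 95%-CI width of mutant S. With all references retained every
  draw is the identical full fit and the across-draw sd is exactly zero.
- Crossing interpolation is linear in OD by default; at 1–3 h read
  spacing the difference from log-OD interpolation is negligible, and the
  log variant is exact on noise-free exponential outgrowths (used by the
  exactness tests).
- Well names are strictly "A1".."H12" (no zero padding); days and hours
  are real-valued throughout, with no integer-grid assumption.

## Known limitations

- Unweighted OLS: no variance model across reads; heteroscedasticity is
  handled only through the validity filter.
- The saturation mismatch between logistic outgrowth and the linear G·t
  term biases G noticeably more than S; G should be read as a nuisance
  correction, not a growth-rate measurement.
- δ estimation inherits a small bias from logistic slowdown inside the
  fitting window and from first-read baseline subtraction; in simulation
  this propagates to ~5% bias in absolute death rates from OD kinetics
  (relative quantities cancel most of it).
- For strains near the saturation limit S ≈ r_wt, rS is undefined or
  clamped; only semi-quantitative statements are possible there.
- Multi-plate experiments are fit per plate (C is a per-plate object);
  cross-plate aggregation happens at the replicate level.
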