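# Methods

## Model

The simulator is an individual-based, spatially explicit removal-trapping
model. Its state is a set of animals with fixed circular home ranges and
a grid of traps with finite capture capacity; its dynamics are nightly
Bernoulli-type capture events over a fixed trapping period.

**Detection.** The nightly capture probability of animal *i* in trap *j*
is the half-normal detection function `P_ij = g0·exp(−d_ij²/(2σ²))`,
with `d_ij` the distance (m) from the animal's home-range centre to the
trap. `g0` is the probability of capture for a trap at the centre of the
home range and σ (m) scales home-range size; 2.45σ is the radius holding
≈95% of activity under the implied circular bivariate-normal utilisation
distribution. Both parameters are species-level constants: no individual
heterogeneity, no behavioural response (trap-shyness or -happiness), no
trap-type differences in g0.

**Arena.** Traps form a `traps_per_line × n_lines` rectangular grid;
animals are placed uniformly over the grid span plus a buffer on all four
sides, wide enough that edge animals keep full home ranges. Coordinates
are continuous metres; there is no toroidal wrapping. The resident count
is `round(density × buffered_area)` where `buffered_area` is the
layout's nominal (published) area in hectares. The nominal area is kept
as an explicit field rather than recomputed from grid spans because the
standard published layouts round their areas; using the nominal value
reproduces their stated population sizes exactly, while placement uses
the exact geometric rectangle. The few-percent mismatch between the two
areas (e.g. 1134 geometric vs 1140 nominal ha for the possum layout) is
a property of the published layouts, not of the simulator.

**Nightly process.** Each night, every at-large animal faces every
active trap within the truncation radius. Per-pair probabilities are
converted to hazards `h = −ln(1−P)`; the animal is captured with
probability `1 − exp(−Σh)` over currently active traps and, conditional
on capture, assigned to a trap with probability ∝ h (competing hazards —
the standard multi-catch formulation in spatial capture–recapture, which
degenerates to a plain Bernoulli trial for a single trap). Animals are
processed in uniformly random order, so a trap that saturates mid-night
no longer contributes hazard to animals processed later. A captured
animal is removed permanently; a trap whose capacity reaches zero stays
out of service for the remainder of the period (traps are only cleared
and reset at the end of the checking interval).

Because within-night competition could plausibly be modelled other ways,
an alternative rule (`assignment: bernoulli`) draws an independent
Bernoulli success per active pair and picks uniformly among successes.
Both rules give an animal the identical nightly capture probability
(`1 − Π(1−P) = 1 − exp(−Σh)`) and differ only in trap assignment; the
sensitivity of headline statistics to the choice is well inside the
replicate spread.

**Immigration (rats).** When enabled, `total_immigrants` animals
(default: equal to the initial resident population, i.e. daily arrivals =
initial density / nights) arrive over the period on a deterministic
schedule: night *k* receives `round(k·T/N) − round((k−1)·T/N)`, so
nightly counts differ by at most one and sum exactly to *T*. A
deterministic schedule (rather than Poisson thinning) matches the
definition of the pressure as "a population equal to the initial one
over the period". Arrivals settle with a perimeter-to-centre gradient:
the buffered rectangle is partitioned into three nested frames of equal
step width (one third of half the smaller dimension), and immigrants are
assigned to outer/middle/inner zones with weights 0.6/0.3/0.1, then
placed uniformly within their zone (by exact rejection sampling).
Immigrants arrive at the start of each night, including night one, and
are exposed to capture from their arrival night onward. The kill
proportion's denominator is residents plus **all** immigrants introduced
during the run, including late arrivals with little exposure — that is
the population a manager would have had to deal with.

## Parameters

| Parameter | Units | Possum | Stoat | Ship rat | Meaning |
|---|---|---|---|---|---|
| g0 | night⁻¹ | 0.05 | 0.045 | 0.03 | capture prob. at home-range centre |
| σ | m | 63 | 641 | 32 | home-range scale (95% radius = 2.45σ) |
| trap spacing | m | 50 | 200 | 25 | along lines |
| line spacing | m | 100 | 800 | 100 | between lines |
| grid | sites | 81×26 = 2106 | 12×7 = 84 | 140×30 = 4200 | factorisation chosen to span ≈ the published block |
| buffer | m | 100 | 300 | 100 | untrapped margin |
| buffered area | ha | 1140 | 1472 | 1148 | nominal; sets population size |
| density range | ha⁻¹ | 0.5–3 | 0.02–0.12 | 1–11 | typical maintenance densities |
| immigration | — | off | off | density/30 per night | rats only |

Scenario-level defaults: 30 nights between checks (a realistic lure/bait
maintenance interval), 100 replicates, capacity ∈ {1, 2, 3, 6, 12}.

**Truncation.** Trap–animal pairs farther than `truncation_sigma·σ`
(default 5σ) are dropped from the encounter table; the discarded
probabilities are below `g0·e^(−12.5) ≈ 4·10⁻⁶·g0`. Moving the radius
from 5σ to 10σ shifts the kill proportion by far less than 0.1
percentage points (tested) while the sparse table keeps the largest
scenario (25k rats × 4200 traps × 30 nights × 100 replicates) under a
minute. The floor `truncation_sigma ≥ 2.45` guarantees the 95% home
range is always covered.

**Randomness.** One base seed per scenario. Replicate *r* runs on the
independent stream `default_rng([seed, r])`; sweep cell (density *di*,
capacity *ci*) uses `default_rng([seed, di, ci, r])`, so adding cells to
a sweep never perturbs existing ones and any replicate is reproducible
in isolation. The within-night thinning (candidate captures drawn
against the start-of-night hazard, re-checked against the current active
set in random processing order) is an exact simulation of sequential
processing because the active trap set can only shrink within a night.

**Cost model.** Per-hectare cost of a strategy =
`price·traps_per_site·n_sites/area` (hardware) +
`(setup + n_checks·check)·traps_per_site·n_sites / minutes_per_day ·
daily_rate · exchange_rate / area` (labour). Published per-hectare
figures rarely state the number of checks, the working day or the
currency conversion, so these are explicit parameters (defaults: 1 check
per period, 480 min/day, exchange rate 1, daily rate NZ$300) and the
model is compared on its internal properties (itemisation additivity,
linearity, monotonicity, the single-vs-multi crossing point) rather than
on any specific published dollar figure.

## What the simulation does and does not represent

The generator *is* the study system: there is no external data. Passing
tests therefore demonstrate the internal consistency of the model —
saturation arithmetic, removal dynamics, immigration bookkeeping — and
its agreement with the published summary statistics for the same
parameterisation, not field accuracy. Real trapping adds processes the
model deliberately omits: individual and trap-type variation in g0,
behavioural responses, lure decay, trap failures, home-range drift,
seasonal immigration, and non-rectangular landscapes.

One published scenario is internally inconsistent and the simulator does
not reproduce it: the stoat layout has 84 single-capture traps but the
reported outcomes at 0.12 stoats/ha (177 animals) imply more captures
than 84 traps can hold (60% of 177 ≈ 106 > 84; and 74% of traps with two
stoats plus ">99% of the population captured with capacity 2" cannot
both hold, since 84×2 = 168 < 0.99×177·2). At full trap saturation —
where this simulator lands — single-capture traps can remove at most
84/177 ≈ 47.5% of the population, and the low-density occupancy is
29/84 ≈ 34.5% when essentially all 29 animals are caught. The published
stoat figures presumably reflect a different (unstated) trap count.

## Numerical and design notes

- Population size rounds to nearest; density 0 is a valid empty scenario.
- A trap is deactivated the moment `remaining` hits 0, mid-night.
- Hazard-proportional trap choice uses inverse-CDF sampling on the
  animal's active hazard row; ties and degenerate rows (all traps
  saturated) are handled by skipping the animal that night.
- `g0 = 1` yields an infinite hazard for a trap at the home-range
  centre; capture is then certain and the assignment goes to the
  highest-hazard trap.
- Aggregation across replicates is the arithmetic mean, with the
  empirical SD and 2.5/97.5 percentiles reported alongside.
- Replicate counts: the shipped default is 100. The test suite uses
  25–30 replicates for full-preset checks and smaller grids for
  Monte-Carlo oracles; the across-replicate SD of the headline means is
  of order 0.1–0.5 percentage points, so these sizes leave Monte-Carlo
  error far inside the ±3-percentage-point comparison bands.
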