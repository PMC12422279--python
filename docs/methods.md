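# Methods

This note documents the model implemented by `camtrapdensity`, the
choices made where the published description of the approach leaves the
design open, and what the synthetic experiments do and do not show.

## Movement model

Animal movement is a discrete-time correlated random walk (CRW). At each
step the heading accumulates a Normal(0, σ_θ) deflection and the step
length is drawn from a Normal(μ, σ) truncated at zero (negative
proposals are redrawn). The initial heading is uniform on [0°, 360°) and
the walk starts at the individual's home centre. Activity is expressed
as a fixed number of steps per calendar month; step timestamps are
evenly spaced within each month at its (i + ½)/S quantiles, so they are
strictly increasing over the survey and a 13-month survey at 5,000
steps/month yields 65,000 positions. Diel and seasonal activity cycles
are not modelled.

Shipped parameter defaults (per species; step lengths in m, deflection
SD in degrees, home range in km²):

| species            | μ     | σ     | σ_θ   | steps/month | home range |
|--------------------|-------|-------|-------|-------------|------------|
| *Lycalopex* spp.   | 13.18 | 17.31 | 26.31 | 5,000       | 5.31       |
| *Leopardus guigna* | 19.03 | 13.07 | 41.04 | 3,000       | 4.85       |
| *Conepatus chinga* | 12.77 | 15.16 | 52.12 | 4,000       | 1.614      |

The home-range areas are means of published telemetry estimates for each
species; for the pooled foxes the mean spans both *L. culpaeus* and
*L. griseus* values and is deliberately exposed as a config knob, since
any single number for a two-species pool is a modelling convenience.

**Home-range confinement.** The home range is modelled as a disc of the
stated area centred on the home centre. A proposed step landing outside
the disc — or outside the simulation arena rectangle — is rejected and
fully redrawn (new turn and length), up to 100 attempts; the heading is
then pointed at the home centre and lengths are resampled until a
proposal lands inside (after 1,000 failures the walker stays put for
that step, a guard that is unreachable for realistic parameters). This
is the simplest mechanism that makes the stated home-range areas binding
and testable; it slightly stiffens turning near the boundary, which is
shared by training and observed simulations and therefore absorbed by
the matching step. Setting the home range to infinity disables
confinement (used by the degenerate-walk tests).

**Home centres** are drawn uniformly over the buffered arena (below), so
simulated abundance refers to exactly the area used for the
abundance-to-density conversion.

**Seeding.** All randomness derives from one user seed through
`numpy.random.SeedSequence(seed, spawn_key=...)`, which is documented
and platform-stable; per-individual walks run in a numba kernel seeded
from the derived stream. Identical seeds give bit-identical populations.

## Detection model

A camera's detection zone is a circular sector: radius 20 m, full
opening 45° (half-width 22.5°) around the facing azimuth. Bearings use
compass convention (0° = north, clockwise); the radius and sector
boundaries are inclusive and a point exactly at the camera counts as
inside. Detection is evaluated at step endpoints, not along segments;
with step lengths of 13–19 m against a 20 m radius this undercounts
mildly, but identically so in training and observed simulations, so the
matching step absorbs it. Within-zone detection is perfect (no miss
probability, no trigger-speed model).

Field deployment tables rarely record facing azimuths (cameras are aimed
at trails). Unknown facings are drawn uniformly at random per camera
per simulation replicate, marginalising orientation out of the training
set; recorded facings are honoured.

## Independence filter

Within each (site, camera, species) group sorted by time, a photo is
kept iff it is the group's first or exceeds the last *kept* photo by
strictly more than 60 minutes (greedy anchor). Photos exactly 60 min
apart therefore collapse into one event. The anchor convention is
configurable (`last_kept` | `last_raw`) because published descriptions
of the rule are ambiguous; the greedy convention is the default as the
common camera-trap practice. A zero-minute window returns every photo
(each is its own event). Simulated records pass through the same filter
as observed ones — the two streams must be commensurable — with a flag
to disable filtering of simulated records.

## Random-forest matching

For each abundance on the gradient (default 1..20) and each replicate
(default 100), a full survey is simulated and reduced to the per-camera
independent-event count vector. A `RandomForestRegressor` with 5,000
trees and `max_features = floor(√p)` (p = number of cameras, the
feature count) regresses abundance on the vectors. The gradient's upper
end caps the estimator's range: observed vectors richer than anything
in training saturate near the maximum, so the gradient must be chosen to
bracket the plausible abundance. Features are whole-survey counts by
default; per-month counts are available behind `monthly_features` (the
default follows the rule that the number of variables equals the number
of cameras).

- **Point estimate** `N̂`: forest-mean prediction (regression, not class
  vote, so fractional abundances are allowed).
- **95% CI**: 2.5th and 97.5th percentiles (linear interpolation) of the
  per-tree predictions. The per-tree spread is the uncertainty object;
  it reflects sampling noise in the training simulations and the
  ambiguity of the observed vector, not a formal posterior.
- **Density** = abundance / effective area.

**Effective sampling area.** The bounding box of the camera positions
buffered on all sides by the home-range disc radius, in km². The same
rectangle is the simulation arena, making abundance and density
self-consistent; for the 2 × 5 grid at 1,000 m spacing and a 2 km² home
range this is (4 + 2·0.798) × (1 + 2·0.798) ≈ 14.53 km². Any other
convention (e.g. the unbuffered grid) rescales densities by a constant
factor; the choice is isolated in `effective_area` and reported in every
output.

**Reliability rules.** An estimate is reliable iff (1) the CI lower
bound is above zero, (2) the per-tree prediction distribution is
bell-shaped, and (3) at least `min_events` (default 100) independent
events back the observed vector. Bell shape is proxied by a 20-bin
histogram, 3-bin moving-average smoothing, equal-neighbour collapsing,
and the requirement of exactly one local maximum. This proxy is
deliberately conservative: per-tree predictions cluster on discrete leaf
means, so sparsely-informed fits (tens of events) are almost always
flagged, consistent with the guidance that such estimates should not be
trusted; the heuristic is exposed as a replaceable function.

## Synthetic-data generator

`generate_study` emulates the field design: three sites (2 × 5 camera
grids, 1,000 m spacing, within ~1,000 ha), cameras active
2021-03-01–2022-03-31 (13 calendar months), species-specific CRW
movement, 20 m / 45° detection. Per site and species it simulates
`n = round(density × effective area)` individuals and writes raw
(pre-filter) records, a deployment table with the realised facings, and
a truth file with the exact n, areas and seeds. Default true densities
are 0.4 (*Lycalopex* spp.), 0.8 (*C. chinga*) and 0.3 (*L. guigna*)
individuals/km², chosen once so the implied true abundances sit
mid-range of the default 1..20 gradient — the regime the estimator is
designed for.

What the generator does *not* emulate: habitat structure and
trail-biased camera placement, imperfect detection, diel activity,
interactions between individuals, misidentification, and multi-photo
trigger bursts finer than the filter window. Passing tests on this
generator therefore demonstrate internal consistency of the estimator
under its own movement model — the estimator recovering truth here does
not certify field accuracy where those un-modelled features matter.

## Experiment sizes

The monotonicity check uses 100 replicate surveys at abundances 2/8/16
and a 3-SE tolerance. The parameter-recovery experiment builds one
training set (1..20 × 50 replicates), shares it across 20 evaluation
runs with true abundances cycling through 4/8/16, fits 500 trees, and
requires |mean relative bias| ≤ 30% and ≥ 80% CI coverage; sharing the
training set mirrors real usage (one simulation library per site and
species). The acceptance script uses 30 replicates per abundance and
5,000 trees for the per-species estimates, and 12 recovery runs. These
sizes were fixed as a precision/cost compromise before freezing the
tests.

## Numerical choices and degenerate inputs

- Truncated-normal step lengths by rejection; σ = 0 degenerates to a
  constant step, and σ_θ = 0 to a straight line, exactly.
- Percentile CIs use numpy's default linear interpolation.
- Tie-breaks in the filter: equal timestamps keep input order (stable
  sort); duplicate timestamps are legal.
- Timestamps are naive local times; no time-zone or DST arithmetic.
- A zero-abundance simulation yields an all-zero feature row; a
  degenerate all-zero observed vector predicts near the gradient
  minimum and is flagged unreliable by the event-count rule.
- Empty record tables flow through every stage (header-only CSVs).

## Known limitations

- The abundance gradient caps the estimable density from above;
  saturation at the top of the gradient is not flagged automatically.
- The CI is a heuristic spread, not a calibrated frequentist interval;
  the recovery experiment measures its empirical coverage under the
  model rather than guaranteeing it.
- Endpoint-only detection and the single shared detection geometry per
  grid are simplifications; cameras with differing radii/sectors are
  supported but grouped internally by geometry.
- The movement parameters were measured on ecological analogues of the
  focal species; density estimates inherit that transfer assumption.
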