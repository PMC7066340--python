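# Methods

## Problem and model

`mddvuln` operationalises a vulnerability-assessment scheme for major
depressive disorder (MDD) in adolescents and the compartmental model built
on top of it.  A cohort is scored on four questionnaire variables —
subjective well-being (SWB, the Satisfaction With Life Scale total) and the
three Trait Meta-Mood Scale subscales Attention (EQ-A), Clarity (EQ-C) and
Mood Repair (EQ-R) — and stratified into three groups: high vulnerability
(V1), low vulnerability (V2) and complete mental health (M).  Group sizes
then parameterise a three-compartment nonlinear ODE system in the
population fractions x = V1/N, y = V2/N, z = M/N:

    dx/dt = aμ − μx + εxy − αx
    dy/dt = bμ − μy − εxy + αx − δyz + βz
    dz/dt = cμ − μz + δyz − βz

where μ is the per-day rate of entering/leaving the 15–23-year system,
(a, b, c) are entry probabilities into V1/V2/M, ε and δ are negative and
positive peer-pressure contact rates (V1→V2 upward pull and M→V2 downward
pull acting on the low-vulnerability class), α is the physical-exercise
rate moving V1→V2, and β the technology-use rate moving M→V2.  All rates
are per day; trajectories are integrated in days.

Summing the equations gives the conservation law
d(x+y+z)/dt = μ((a+b+c) − (x+y+z)): the total fraction relaxes to a+b+c at
rate μ, so the unit simplex is invariant exactly when a+b+c = 1.

## Stratification

Each variable is discretised into low / adequate (SWB: "neutral") / high.
Cut-offs are sex-specific for EQ-A and EQ-C and sex-invariant for SWB and
EQ-R.  Storing only the two cut points (low_max, high_min) makes the three
level intervals a partition of the integer score axis by construction.  The
published female EQ-A low cut-off is internally inconsistent (it overlaps
the high range); the only value preserving a partition against the adequate
range 25–35 is ≤24, which the default scheme uses.

The 3⁴ = 81 level combinations ("superposed states") carry a total score.
The representative points each level contributes are not part of the
published scheme; the default map is built from the cut-offs themselves:
per variable and sex, take the midpoint of each level's score interval
(open intervals capped at the instrument bounds, SWLS 5–35 and TMMS
subscales 8–40), map the low midpoint to 20 and the high midpoint to 35 by
the affine map between them, and average the two sexes' mapped middle
values so the map depends only on (variable, level).  This makes all-low
states total exactly 80 and all-high states exactly 140, matching the
published 80–140 span, and is user-configurable through `ScoringScheme`.
Under this default the 81 states split 15/50/16 across the
high/low/complete bands; the published split (30/50/1) depends on an
unstated level-score map and is deliberately not asserted — only the
partition, distinctness and monotonicity properties are.

Band boundaries are read inclusively: totals > 120 are complete mental
health, totals in [100, 120] low vulnerability, totals < 100 high
vulnerability — the only reading that is exhaustive and exclusive on
integers.  Scores must be integers; non-integers are rejected, not rounded.

## Parameter estimation

The estimation stage reproduces the source cohort arithmetic:

* fractions (x, y, z) from the band counts (88/136/3 of 227);
* entry probabilities a = (x/μ)/365 and likewise b, c;
* peer-pressure rates as contacts/day × conversion probability:
  δ = 5·(1/10) = 0.5 and ε = 5·(1/25) = 0.2 (assumed contact counts, stored
  as config defaults, not estimated from data);
* lifestyle rates from weighted mean daily hours.  Exercise categories
  carry (1, 0.5, 0.15) hours and technology categories (2, 1, 0.3) hours;
  the two relevant group means are averaged, multiplied by a persistence
  window (30 days exercise, 15 days technology) and divided by 24, giving
  α ≈ 0.6796 and β ≈ 0.694.

Two deliberate dualities are carried rather than resolved.  First, μ: one
over the 8-year adolescent span is 1/2920 = 0.000342/day, but the source
analysis carried 0.00342 throughout, and every downstream published value
requires it; `estimate_mu` returns the true arithmetic while `MU_CANONICAL
= 0.00342` feeds the defaults, and the estimation report records both.
Second, rounding: computations run at full precision by default, and an
`EstimationConfig(chained_rounding=True)` mode rounds intermediate
quantities (fractions, weighted means) to 4 decimal places to emulate the
source's chained arithmetic — full precision gives α = 0.67954 where the
chained path gives 0.6796 exactly.  Known last-digit quirks of the source
(a printed as 0.3104 vs 0.31055 computed, c as 0.0105 vs 0.01059, the
complete-band technology mean 0.8666 vs 0.86667) are absorbed by the
tolerances of the tests, not patched over.

## Dynamics

Integration uses SciPy's LSODA (adaptive, stiff-capable) at rtol 1e-8 /
atol 1e-10 with a fixed daily output grid.  "Steady state" means the
vector-field infinity-norm at the final state is below 1e-8; when no
horizon is given, the horizon doubles from 512 days until that check
passes (cap ≈ 2.1e6 days).  With the cohort parameter vector the system
stabilizes by ~4100 days with y rising and x, z falling from the cohort
initial values, consistent with the published qualitative description.
The model is integrated as parameterised by default even though the
estimated a+b+c ≈ 0.8008 ≠ 1; `normalize_entry` rescales (a, b, c) to sum
to 1 for analyses relying on the simplex assumption (the equilibrium
cubic).  Sweeps over δ, ε, α, β re-integrate from a common initial state
and horizon per grid point and report terminal fractions; failures at a
grid point are flagged and the sweep continues.  No direction is
hard-coded for the peer-pressure sweeps — the published ε effect is itself
described as contrary to expectation, so sweeps report whatever the
equations give.

## Equilibrium and stability

Eliminating x = 1 − y − z and z = cμ/(β + μ − δy) at equilibrium yields a
cubic Ay³ + By² + Cy + D = 0 with A = εδ; the coefficients implemented are
the published expressions, which re-derivation confirms are the exact
algebra of the system under x+y+z = 1.  Roots come from the companion
matrix (`numpy.roots`); complex parts below 1e-9 are discarded; roots in
[0, 1] (configurable to [0, a+b+c]) are flagged admissible.  Vieta sums
S1 = −B/A, S2 = C/A, P = −D/A and their strict positivity screen for three
positive roots.  A degenerate leading coefficient falls back to the
quadratic/linear problem; the z back-substitution raises a dedicated error
within 1e-12 of its pole.

The disease-free equilibrium (0, 0, 1) has the block-triangular Jacobian
[[−μ−α, 0, 0], [α, −μ−δ, β], [0, δ, −μ−β]] with closed-form eigenvalues
−(μ+α), −μ, −(μ+β+δ) — the 2×2 block's trace and determinant force the
negative grouping even though the source prints "−μ+α" and "−μ+β+δ"
without parentheses.  All three are negative whenever μ > 0, so the DFE is
asymptotically stable for any strictly positive parameter vector.  Two
reproduction-number quantities are reported side by side because the
source defines them inconsistently: the literal R0 = −μ + β + δ (≈ 1.19
for the cohort vector, i.e. > 1 despite stability — the report flags this)
and the bound δ(μ+α)/ε implied by the S1 > 0 manipulation.  The package
takes no position on which is "the" R0.

## Synthetic cohorts

`reference_cohort()` is a fully deterministic 227-record cohort
reproducing every published marginal: the 88/136/3 band split, exercise
tables 32/13/43 (high band) and 60/20/56 (low band), technology tables
63/52/21 (low band) and 1/0/2 (complete band), and 99 female / 128 male
overall.  Cross-tabulations the study never printed are synthetic
fill-ins: sex-by-band counts by largest-remainder proportional allocation
(39/59/1 females), high-band technology 30/29/29 and complete-band
exercise 1/1/1 by round-robin cycling.  Records carry fixed representative
scores of an all-low / all-adequate / all-high state and the cohort mean
age 18.58.

`generate_cohort()` is the seeded random generator over the same
configuration space (defaults = the study conditions: n = 227, the sex
split, age mean 18.58 / SD 0.29 truncated-normal on [15, 23], the printed
group targets and category tables).  Each record draws a superposed state
uniformly among the states of its target band and samples each score
uniformly over that level's integer range for the record's sex, so
generation and stratification agree by construction.  Bands without a
printed category table sample categories uniformly.  Neither generator
models psychometric correlations between SWB and the EQ subscales beyond
band membership, within-band score distributions, or sex-specific lifestyle
patterns — passing tests therefore certify the pipeline arithmetic and the
printed marginals, not distributional realism of real questionnaire data.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on the 227-record
cohort, steady-state integrations of a few thousand model days, 1000-draw
eigenvalue comparisons and 100–200-example property tests; everything is
desk-scale and deterministic (property tests use fixed seeds or
derandomised Hypothesis profiles).  Tolerances mirror the precision the
source arithmetic supports: 4-decimal agreement where values are printed
exactly (δ, ε, the weighted means), ±0.001 where chained rounding
intervenes (α, β, x/y/z), and the documented ±0.0002 / ±0.0001 last-digit
allowances for a and c.

## Known limitations

* The level-score map underlying the published 1/50/30 state split is
  unknowable from the printed scheme; the default map is principled but
  not guaranteed to match it.
* The model ignores endogenous (internal-field) depression factors by the
  source's own design; the package inherits that scope.
* No uncertainty quantification: the source provides single point
  estimates, and none of the estimation steps propagate sampling error.
* Figure-derived quantities (the δ ≈ 0.6875 threshold, sex-specific
  technology percentages) have no printed computation and are not
  reproduced.
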