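# Methods

## Model overview

`chronoecol` simulates exploitative competition for a shared, temporally
structured resource supply among organisms whose activity is governed by
a heritable circadian rhythm. There is no day/night forcing: the
environment is symmetric in time, and any temporal structure in resource
availability is *created* by the organisms' own consumption. This makes
the model a clean test bed for how competition alone shapes activity
timing.

Time is measured in degrees, 360° per simulated day (1 h = 15°), and
advances in 10 discrete steps of 36°. One trial runs a fixed horizon
(default 2000 days) from a founding population.

### Movement and foraging

An organism's instantaneous movement rate is
`(M_total/360)·(1 + A·cos(t − φ))` with `M_total = 20` moves/day. The
expected moves over a step are the closed-form integral of this rate;
fractional moves are carried between steps in a per-organism credit
accumulator (floor with carry), which realizes exactly 20 moves over any
day started with zero credit, without the variance a Bernoulli rounding
would add. Totals within 1e-9 of an integer are snapped to it so the
analytic telescoping of the sine terms survives floating point.

Each realized jump goes to one of the 59 spaces other than the occupied
one, uniformly. All of a step's jumps are foraged at the step's midpoint
time (the integral fixes how *many* moves a step contains but not their
within-step times; the midpoint is the natural single-point quadrature).
Resource contention is first-come first-served in an organism order
reshuffled every step, each organism taking its jumps consecutively.
Landing on a stocked space consumes exactly one resource, even if the
space holds several.

### Energy, death, and the step schedule

Organisms pay a flat 0.2 energy per step (2/day) regardless of realized
movement, gain `E_orig·(1 + S·cos(t − φ))` per resource (`E_orig = 0.5`;
`S` is the time-of-day specialization, sharing the activity phase), die
immediately at energy ≤ 0, and die of old age when their age reaches 12
days. Event order within a step: resource input → movement/foraging →
metabolism → energy cull → reproduction → (on day wrap) aging and age
cull. Organisms therefore eat before being charged, and newborns cannot
forage or be culled in their birth step. The implied carrying capacity
is 600·0.5/2 = 150 organisms, and healthy populations fluctuate near it.

### Reproduction

Matings accrue at 10%/day of the population into fractional birth
ledgers (floor with carry, like movement). Parents are drawn with
probability proportional to current stored energy; each donates 1/3 of
its energy to the single offspring (energy is conserved exactly across
the event). Offspring amplitude is the parental mean plus
`Normal(0, amp_sd)` clamped to [0, 1]; offspring phase is the parental
circular mean plus `Normal(0, phase_sd_frac·360°)` wrapped. Clamping
(rather than redrawing) at the amplitude boundaries keeps the mutation
kernel explicit; the slight boundary bias is accepted. An exactly
antipodal parental pair has no defined circular mean; one parent's phase
is then chosen uniformly at random, because any deterministic tie-break
would bias phase evolution.

Two allocation regimes decide *which* species a birth belongs to:

* **Stabilization on** (all two-species scenarios not testing
  competitive exclusion, and single-species scenarios with k = 1, where
  it is inert): each species accrues `p·r_adj·dt/360` births with
  `r_adj = r·k·P_total/p`, so a species below its target share k
  reproduces more per capita and one above it less. Mating pairs are
  drawn within the species.
* **Stabilization off** (competitive-exclusion tests): births accrue at
  the community rate `P_total·r·dt/360` and each mating draws an
  energy-proportional pair from the whole community, redrawn until the
  pair is conspecific (up to 20 attempts, then the birth is forfeited).
  A species holding a larger share of the community's energy thereby
  captures a more-than-proportional share of births. This
  frequency-dependent feedback is what makes exclusion of temporally
  identical competitors systematic rather than a pure random walk; per
  species fixed quotas would (and in pilots did) let identical species
  coexist indefinitely, which is not the phenomenon under study.

Under assortative mating, the second parent is drawn with probability
proportional to energy × mating-window overlap with the first; if no
candidate overlaps, a fresh first parent is drawn, up to 10 attempts,
after which the birth is forfeited. Forfeiting (rather than forcing a
mating the window forbids) keeps realized growth ≤ the nominal rate.
Newborns become eligible as parents only from the following step.

### Mating windows and the CGM

Each organism's mating window is a 135° (9 h) arc fixed relative to its
phase. The overlap of two windows falls linearly from 1 at zero phase
difference to 0 at 135°; for widths above 180° the arcs also meet around
the far side of the circle, so a 360° window makes the assortative
filter exactly inert. The cross-group mating statistic (CGM) clusters
the rows of the pairwise overlap matrix with 2-means (Lloyd's algorithm,
Euclidean metric, 10 restarts initialized at random row pairs, 300
iteration cap, tolerance 1e-6, best within-cluster sum of squares kept;
a restart that empties a cluster is re-initialized, up to 5 times) and
reports the mean overlap across the two clusters. CGM is computed once
per day on the full living population in assortative scenarios, is
undefined (missing, never an exception) below two organisms, and for a
population of identical phases equals 1 under any split. Speciation is
declared the first day CGM < 0.1.

## Randomness and determinism

Each trial derives two independent generator streams from its seed: one
drives the dynamics (resource placement, jump destinations, contention
order, mate choice, mutation, tie-breaks), the other the recording layer
(k-means initialization inside the daily CGM). The split guarantees that
observation cadence cannot perturb the trajectory. A trial is bit-
reproducible from (config, seed); batches seed trials as
`base_seed + index` and are therefore independent of worker count.

## Initial conditions

Founders carry their species' exact initial traits (optionally scattered
in phase by `init_phase_sd`), 2.0 energy (one day's cost), ages uniform
on 0–11 days (avoiding a synchronized old-age die-off), zero move
credit, and uniform random positions. Two-species scenarios start at
75 + 75 organisms, single-species at 150 — the carrying capacity. Where
an initial amplitude is needed but not pinned by a scenario (the
evolving-amplitude scenarios), 0.5 — the midpoint of the trait range —
is used; the speciation scenario fixes the initial amplitude at 1.

## Scenario presets and summary statistics

The presets (`exclusion_arrhythmic`, `exclusion_inphase`,
`coexist_antiphase`, `character_displacement`, `single_species(S)`,
`two_species(S, ratio)`, `speciation(phase_sd, amp_sd)`) fully determine
a configuration given a seed; every knob remains overridable. The
`two_species` scenarios default to S = 0.2 for both species — a small
positive specialization, consistent with the worked 20%-bonus example —
since the asymmetric-ratio experiments require some S > 0 to give
amplitude a benefit at all.

Per day and species the record stores population, mean amplitude,
circular mean and circular SD of phase, the CGM, and the total grid
stock at each of the 10 step boundaries (the time-of-day resource
profile). Circular SD is `sqrt(−2 ln R̄)` in degrees, capped at
`sqrt(−2 ln 1e-12)` rad ≈ 426° when the resultant length underflows.
"Equilibrium" summaries average the final 200 recorded days. Records
round-trip bit-exactly through CSV + JSON (floats written as `%.17g`,
parsed with round-trip precision).

## Problem sizes

Default trial counts follow the standard designs (40 trials for the
exclusion/coexistence comparisons, 20 per speciation grid cell, 5 seeds
for the ratio experiments); the test suite runs scaled-down versions
(typically 5–10 trials) with early stopping once a trial's outcome is
decided (a species extinct, CGM below threshold, an amplitude threshold
crossed), and asserts binomial-noise-aware bounds. The engine is
vectorized over the population (struct-of-arrays; contention resolved by
a stable sort over the step's jump sequence), giving roughly 3–8 s per
2000-day trial.

## What the simulations do and do not show

The generator *is* the study system: conclusions are about this model,
not field data. Known limitations, deliberate:

* purely exploitative competition — no interference, no predation;
* a sinusoidal activity profile and a single shared phase for activity
  and specialization (separate phases would converge anyway, since
  specialization pays most when active);
* genetics are a constant-variance phenotypic blend (no allele-level
  model), so heritability cannot evolve;
* no behavioral (non-genetic) adjustment of activity timing;
* no spatial structure beyond uniform jumps;
* one environment size and resource rate; carrying capacity ~150 means
  demographic noise is material, which is why trial counts matter.

Two results are sensitive to choices the model leaves open: the
equilibrium amplitudes in the asymmetric-ratio scenarios scale with the
chosen S = 0.2 (only their ordering — minority above majority, and the
majority falling as its dominance grows — is robust), and times-to-
speciation depend on the assortative partner rule (the energy × overlap
partner draw used here never penalizes edge individuals for their
position, so splitting is faster than under pair-level rejection,
although *whether* a mutation-SD corner speciates at all is unchanged).
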