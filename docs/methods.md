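# Methods

## Model structure

The simulator advances a population of diploid, genderless agents in
yearly steps.  Each year executes, in fixed order: (1) life support,
(2) meme invention, (3) forgetting, (4) teaching, (5) collective
hunting, (6) sharing of the haul, (7) useless actions, (8) learning,
(9) death, (10) reproduction, (11) group splitting, (12) migration.
Ages then increment and a statistics record is emitted.  A single
pseudo-random stream (numpy PCG64) seeded once per run drives every
stochastic decision, so a (configuration, seed) pair reproduces a
bit-identical trajectory; replicate *r* of a batch uses seed
`base_seed + r`.

Within steps that visit individuals, visiting order is freshly shuffled
each year to avoid positional artifacts.  Newborns appear at the
reproduction step and first act the following year; they are counted
for group splitting, which follows reproduction.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `R_env` | 3000 | resources/yr | fixed environmental supply; caps the population near `R_env` / costs |
| `G_max` | 800 / 40 / 15 | individuals | maximum group size; the lever of between-group competition |
| `life_support_cost` | 3 | resources/yr | unavoidable upkeep; two consecutive short years are lethal |
| `hunt_cost` | 2 | resources | price of joining the hunt (skipped if unaffordable) |
| `useless_cost` | 1 | resources | price of one useless action |
| `p_forget` | 0.02 | /meme/yr | spontaneous forgetting |
| invention rate | 0.000133 | /individual/category/yr | spontaneous meme invention |
| `death_coeff` | 0.002 | /yr per year of age | age-proportional hazard; mean lifespan 27.7 yr (analytic) |
| `min_repro_age` | 6 | years | eligibility is strictly age > 6 |
| `child_cost_multiplier` | 2 | — | child costs 2 × its brain volume |
| `transfer_fraction` | 0.4 | — | share of the cost, then of the remaining pool, given to the child |
| `migration_rate` | 0.001 | /yr | chance of moving to a random other group |
| `brain_base`, `k1,k2,k3` | 20; 1, 0, 0 | volume units | brain = 20 + k₁·MC + k₂·LE_g + k₃·TE_g |
| MC locus | init 0, rate 0.04, sd 0.4, bounds [0, ∞) | | memory capacity |
| LE/TE loci | fixed (1 / 0) unless evolvable: rate 0.04, sd 0.1, bounds [0, 1] | | social-learning fidelity |
| TrE/HE memes | mean eff 4, sd 6, C 0.25, R 2 | | additive-trait memes, mean size 1 |
| Useless/LE/TE memes | mean eff 0.2, sd 0.3, C 5, R 2 | | probability-valued memes, clamped ≤ 1 |

Meme size is generated as `C · efficiency · R^z` with `z ~ Uniform(−1, 1)`,
floored at 0.01; efficiency is normal, truncated below at 0.01 by
resampling.  This law yields mean size ≈ C · mean efficiency, a weak
positive size–efficiency correlation, and makes `R = 1` the
deterministic no-noise case.  The TrE and Useless parameter blocks are
set symmetric to the HE and LE/TE blocks respectively, since the
scenarios treat the culture types as mirror images.

## Design choices where the design was open

- **Probability combination.** "Sums of probabilities" (teaching success
  from TE and LE, the LE/TE phenotypes, useless propensity) are
  complementary products `1 − Π(1 − pᵢ)`, the only rule consistent with
  the worked combination 0.2 ⊕ 0.3 = 0.44 and with boundedness in [0, 1].
- **Mutation bounds.** Out-of-bounds mutation draws are cancelled and
  retried (fresh deviate, cap 100) for *all* loci including MC's lower
  bound at 0.  Retrying (rather than clamping or cancelling outright) is
  the strongest upward bias at the boundary; alternatives would lower
  the dormant-phase equilibrium further.
- **Sharing weights** are `1 + TrE`, not raw TrE: naive individuals with
  TrE = 0 must still receive a share (they survive by learning), and the
  all-equal case then reduces to an equal split.
- **Reproduction economics.** The pair pools resources; the child's
  brain volume is computed from its own realized (post-mutation)
  genotype before the affordability test; on failure the drawn genotype
  is discarded and no resources move.  On success the child receives
  40% of the cost plus 40% of the remaining pool, and each parent keeps
  30% of the remainder.
- **Hunger.** Life support takes what an individual has; paying short
  marks the year hungry, and only two *consecutive* hungry years kill —
  so the lean year that typically follows a birth is survivable.
- **Lost inventions.** An invented meme larger than the inventor's free
  memory is discarded permanently; this is what makes the dormant phase
  dormant.
- **Group edge cases.** A group reduced to one member loses it at the
  death step; groups emptied by migration are removed immediately;
  splitting partitions uniformly at random into halves differing by at
  most one.
- **Initialization** (not otherwise specified): 250 founders, ages
  uniform on {0..20}, 10 resources each, founder alleles at the locus
  initial values, dealt round-robin into ⌈N₀/G_max⌉ groups.

## Statistics

Per-year records report demography (population, groups, births, deaths,
mean age at death), mean phenotypes (brain volume, genotypic MC, HE,
TrE, LE, TE), and culture: cultural richness (unique memes among the
living), mean memes per individual, mean stored-meme size, mean
efficiency-to-size ratio, and *memory clogging* — the fraction of an
individual's occupied memory held by each category, averaged over
individuals with non-empty memories.  Ratio statistics over empty sets
are missing values, never zeros.  Replicate batches report per-year
cross-run means and a windowed mean (default years 50,000–70,000,
configurable for shorter runs).

## What the experiments show, and at what scale

Full-scale scenarios (70,000 years, 10 replicates, population ~500)
reproduce the published experimental designs exactly and take hours of
CPU; the package runs them, but its test suite demonstrates the
qualitative phenomena on scaled-down worlds chosen to express the same
mechanisms in minutes:

- a smaller environment (`R_env = 900`, population ~140, 120 founders),
- a faster invention rate (0.002–0.005 per category per year, restoring
  roughly one invention per few years at the smaller population),
- horizons of 3,000–4,000 years and three (paired) seeds.

Under these conditions the suite checks: **ignition asymmetry** —
Machiavellian culture ignites runaway MC growth in an undivided
population while cooperative culture stays dormant (HE memes are
worthless without between-group competition); **purging** — memory
clogging by Useless memes is lower under strong between-group
competition (G = 15) than without it (G = 800), with the Useless
deleterious burden amplified (mean efficiency 0.7) so that group
selection expresses within the shortened horizon — both arms of the
comparison use identical parameters, differing only in G; and **meme
simplification** — smoothed mean stored-meme size ends well below its
trajectory maximum under strong competition.  These scaled checks
demonstrate mechanism, not the published magnitudes; window lengths,
thresholds and seed counts are fixed in `tests/test_acceptance.py`.

The dormant-phase equilibrium check runs at full fidelity (baseline
world, invention disabled, 5 replicates × 2,000 years): genotypic MC
settles near 0.22 in this implementation.  The demographic anchor is
exact: a 10⁵ cohort under the hazard alone matches the analytic
discrete survival sum (27.70 years) within Monte-Carlo error, and the
closed-form lifetime migration probability at the default rate is
≈ 2.7%.

## Numerical choices

Sharing assigns the float remainder to the last member so shares sum to
the haul exactly; memory bookkeeping tolerates 10⁻¹² of float drift;
the death hazard is capped at 1; efficiency and size floors (0.01)
prevent degenerate zero-size memes; the mutation retry cap (100) cannot
trigger under any preset's parameters and aborts the run if it ever
does.  Extinction ends a run early with a flagged final record.

## Known limitations

- Culture is not cumulative: memes cannot be modified or combined, so
  late-stage cultural dynamics decelerate rather than accelerate.
- No spatial structure, free riders, punishment, gendered pairing, or
  evolvable hunting participation; HE and TrE genetic predispositions
  are fixed constants.
- The dormant-phase MC equilibrium is sensitive to micro-details of the
  resource economy (who pairs, when costs bind); different defensible
  readings of the reproduction and hunger rules shift it by ~±0.05
  around 0.22.
- Scaled-down test worlds compress evolutionary time by boosting
  invention and amplifying selective differentials; they preserve the
  direction of effects, not published magnitudes, and say nothing about
  real-world parameter values.
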