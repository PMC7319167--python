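"""World state, groups, and the 12-step yearly scheduler.

Every simulated year runs, in fixed order: life support, meme invention,
forgetting, teaching, collective hunting, sharing of the haul, useless
actions, learning, death, reproduction, group splitting, and migration.
Ages then increment and a per-year statistics record is emitted.

The population is structured into groups that hunt collectively and
compete proportionally for the environment's fixed yearly resource
supply; a group exceeding the maximum size splits in two, and rare
migration moves individuals between groups.  A single pseudo-random
stream (numpy PCG64) drives the whole run, so a given (config, seed)
pair reproduces bit-identical trajectories.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ConfigError, WorldConfig
from .genetics import make_gamete, make_genotype, phenotype, TraitSet
from .memes import Memory, attempt_learn, attempt_teach, draw_meme


class Individual:
    """One agent: age, resources, hunger bookkeeping, genotype, memory."""

    __slots__ = ("id", "age", "resources", "hungry_last_year", "starving",
                 "genotype", "memory", "_traits", "_config")

    def __init__(self, ind_id: int, age: int, resources: float,
                 genotype: np.ndarray, config: WorldConfig) -> None:
        self.id = ind_id
        self.age = age
        self.resources = resources
        self.hungry_last_year = False
        self.starving = False
        self.genotype = genotype
        self._config = config
        self._traits: Optional[TraitSet] = None
        # memory capacity is the phenotypic MC, fixed at birth
        self.memory = Memory(genotype[0].mean())

    @property
    def traits(self) -> TraitSet:
        if self._traits is None:
            self._traits = phenotype(self.genotype, self.memory, self._config)
        return self._traits

    def invalidate_traits(self) -> None:
        self._traits = None


class Group:
    """A set of individuals that hunts and shares resources together."""

    __slots__ = ("id", "members")

    def __init__(self, group_id: int, members: Optional[list[Individual]] = None):
        self.id = group_id
        self.members = members if members is not None else []

    def __len__(self) -> int:
        return len(self.members)


class YearLog:
    """Demographic counters accumulated within one simulated year."""

    __slots__ = ("births", "deaths", "death_ages", "inventions")

    def __init__(self) -> None:
        self.births = 0
        self.deaths = 0
        self.death_ages: list[int] = []
        self.inventions = 0


class WorldState:
    """Mutable state of one run: year, groups, id counters, RNG."""

    __slots__ = ("year", "groups", "next_individual_id", "next_meme_id", "rng")

    def __init__(self, groups: list[Group], rng: np.random.Generator,
                 next_individual_id: int = 0, next_meme_id: int = 0) -> None:
        self.year = 0
        self.groups = groups
        self.next_individual_id = next_individual_id
        self.next_meme_id = next_meme_id
        self.rng = rng

    def individuals(self) -> list[Individual]:
        return [ind for g in self.groups for ind in g.members]

    @property
    def population(self) -> int:
        return sum(len(g) for g in self.groups)


# ----------------------------------------------------------------------
# initialization


def init_population(config: WorldConfig, rng: np.random.Generator) -> WorldState:
    """Found the population: uniform random ages, fixed starting resources,
    founder genotypes at locus initial values, empty memories, individuals
    dealt round-robin into ``ceil(N0 / G_max)`` groups."""
    n0 = config.initial_population
    if n0 < 2:
        raise ConfigError("initial_population: need at least 2 individuals")
    n_groups = -(-n0 // config.G_max)
    groups = [Group(i) for i in range(n_groups)]
    ages = rng.integers(0, config.initial_max_age + 1, size=n0)
    for i in range(n0):
        ind = Individual(i, int(ages[i]), config.initial_resources,
                         make_genotype(config.ordered_locus_specs), config)
        groups[i % n_groups].members.append(ind)
    return WorldState(groups, rng, next_individual_id=n0)


# ----------------------------------------------------------------------
# yearly steps


def life_support_step(state: WorldState, config: WorldConfig) -> None:
    """Each individual pays the life-support cost, or everything it has.

    Paying short marks the year hungry; a second consecutive hungry year
    flags the individual for death at the death step.
    """
    cost = config.life_support_cost
    for group in state.groups:
        for ind in group.members:
            if ind.resources >= cost:
                ind.resources -= cost
                hungry = False
            else:
                ind.resources = 0.0
                hungry = True
            ind.starving = hungry and ind.hungry_last_year
            ind.hungry_last_year = hungry


def invention_step(state: WorldState, config: WorldConfig,
                   log: Optional[YearLog] = None) -> None:
    """Sporadic invention: per enabled category, each individual invents
    with the category's rate; an invented meme survives only if it fits
    the inventor's free memory."""
    enabled = [p for p in config.enabled_meme_params if p.invention_rate > 0.0]
    if not enabled:
        return
    rng = state.rng
    inds = state.individuals()
    n = len(inds)
    if n == 0:
        return
    for params in enabled:
        u = rng.random(n)
        hits = np.flatnonzero(u < params.invention_rate)
        for idx in hits:
            ind = inds[idx]
            meme = draw_meme(params, rng, state.next_meme_id)
            if ind.memory.fits(meme):
                ind.memory.add(meme)
                ind.invalidate_traits()
                state.next_meme_id += 1
                if log is not None:
                    log.inventions += 1
            # a meme that does not fit is lost permanently


def forgetting_step(state: WorldState, config: WorldConfig) -> None:
    """Each stored meme is independently forgotten with probability p_forget."""
    p = config.p_forget
    if p <= 0.0:
        return
    rng = state.rng
    for group in state.groups:
        for ind in group.members:
            mem = ind.memory
            if not len(mem):
                continue
            ids = mem.meme_ids()
            u = rng.random(len(ids))
            changed = False
            for meme_id, ui in zip(ids, u):
                if ui < p:
                    mem.remove(meme_id)
                    changed = True
            if changed:
                ind.invalidate_traits()


def _random_partner(n: int, i: int, rng: np.random.Generator) -> int:
    """Uniform index in [0, n) excluding i."""
    j = int(rng.integers(0, n - 1))
    return j + 1 if j >= i else j


def teaching_step(state: WorldState, config: WorldConfig) -> None:
    """Each individual, in random order, tries to teach one meme to a
    uniformly chosen group mate.  Singleton groups skip."""
    rng = state.rng
    for group in state.groups:
        n = len(group)
        if n < 2:
            continue
        if not any(len(ind.memory) for ind in group.members):
            continue  # nobody has anything to teach
        order = rng.permutation(n)
        members = group.members
        for i in order:
            teacher = members[i]
            if not len(teacher.memory):
                continue  # attempt trivially fails: nothing to transfer
            student = members[_random_partner(n, i, rng)]
            attempt_teach(teacher, student, rng)


def learning_step(state: WorldState, config: WorldConfig) -> None:
    """Each individual, in random order, tries to learn one meme from a
    uniformly chosen group mate."""
    rng = state.rng
    for group in state.groups:
        n = len(group)
        if n < 2:
            continue
        if not any(len(ind.memory) for ind in group.members):
            continue
        order = rng.permutation(n)
        members = group.members
        for i in order:
            student = members[i]
            model = members[_random_partner(n, i, rng)]
            if not len(model.memory):
                continue  # attempt trivially fails
            attempt_learn(student, model, rng)


def allocate_hauls(efforts: Sequence[float], r_env: float) -> list[float]:
    """Divide the environment's yearly resources among group hunting efforts.

    If total effort does not exceed the supply, each group takes exactly
    its effort; otherwise each takes a share of the supply proportional
    to its effort.
    """
    total = float(sum(efforts))
    if total <= r_env or total == 0.0:
        return [float(e) for e in efforts]
    scale = r_env / total
    return [float(e) * scale for e in efforts]


def hunting_step(state: WorldState, config: WorldConfig) -> list[float]:
    """Individuals able to pay the hunting cost hunt; group effort is the
    sum of its hunters' HE; the environment's supply is allocated by
    :func:`allocate_hauls`.  Returns the per-group hauls."""
    cost = config.hunt_cost
    efforts = []
    for group in state.groups:
        effort = 0.0
        for ind in group.members:
            if ind.resources >= cost:
                ind.resources -= cost
                effort += ind.traits.he
        efforts.append(effort)
    return allocate_hauls(efforts, config.R_env)


def sharing_step(group: Group, haul: float) -> None:
    """Distribute the group's haul by Machiavellian weight ``1 + TrE``;
    the last member takes the float remainder so shares sum exactly."""
    if not group.members or haul <= 0.0:
        return
    weights = [1.0 + ind.traits.tre for ind in group.members]
    total_w = sum(weights)
    given = 0.0
    for ind, w in zip(group.members[:-1], weights[:-1]):
        share = haul * w / total_w
        ind.resources += share
        given += share
    group.members[-1].resources += haul - given


def useless_step(state: WorldState, config: WorldConfig) -> None:
    """With its useless-action propensity, an individual pays the useless
    cost; skipped when it cannot afford the action."""
    cost = config.useless_cost
    rng = state.rng
    for group in state.groups:
        for ind in group.members:
            p = ind.traits.useless_propensity
            if p <= 0.0 or ind.resources < cost:
                continue
            if rng.random() < p:
                ind.resources -= cost


def death_step(state: WorldState, config: WorldConfig,
               log: Optional[YearLog] = None) -> None:
    """Age-proportional hazard plus starvation deaths; afterwards any group
    left with a single member loses it and empty groups disappear."""
    coeff = config.death_coeff
    rng = state.rng
    for group in state.groups:
        members = group.members
        if not members:
            continue
        u = rng.random(len(members))
        survivors = []
        for ind, ui in zip(members, u):
            hazard = coeff * ind.age
            if ind.starving or ui < hazard:
                if log is not None:
                    log.deaths += 1
                    log.death_ages.append(ind.age)
            else:
                survivors.append(ind)
        group.members = survivors
    # the last individual of a group cannot survive alone
    for group in state.groups:
        if len(group.members) == 1:
            ind = group.members.pop()
            if log is not None:
                log.deaths += 1
                log.death_ages.append(ind.age)
    state.groups = [g for g in state.groups if g.members]


def reproduction_step(state: WorldState, config: WorldConfig,
                      log: Optional[YearLog] = None) -> None:
    """Random within-group pairing of eligible individuals; a pair produces
    one child if the pooled parental resources cover twice the child's
    brain volume.

    The child's genotype is drawn first (one gamete per parent, with
    mutation); its brain volume sets the cost.  On success the child
    receives 40% of the cost plus 40% of the remaining pool, and each
    parent keeps 30% of the remainder; on failure no resources move and
    the drawn genotype is discarded.
    """
    rng = state.rng
    specs = config.ordered_locus_specs
    mult = config.child_cost_multiplier
    tf = config.transfer_fraction
    for group in state.groups:
        eligible = [ind for ind in group.members if ind.age > config.min_repro_age]
        if len(eligible) < 2:
            continue
        order = rng.permutation(len(eligible))
        newborns: list[Individual] = []
        for k in range(0, len(order) - 1, 2):
            p1 = eligible[order[k]]
            p2 = eligible[order[k + 1]]
            child_geno = np.column_stack(
                (make_gamete(p1.genotype, specs, rng),
                 make_gamete(p2.genotype, specs, rng)))
            mc_g, le_g, te_g = child_geno.mean(axis=1)
            bv = (config.brain_base + config.k1 * mc_g
                  + config.k2 * le_g + config.k3 * te_g)
            cost = mult * bv
            pool = p1.resources + p2.resources
            if pool < cost:
                continue  # cannot afford this child
            remainder = pool - cost
            child_res = tf * cost + tf * remainder
            parent_res = (1.0 - tf) * remainder / 2.0
            p1.resources = parent_res
            p2.resources = parent_res
            child = Individual(state.next_individual_id, 0, child_res,
                               child_geno, config)
            state.next_individual_id += 1
            newborns.append(child)
            if log is not None:
                log.births += 1
        group.members.extend(newborns)


def split_step(state: WorldState, config: WorldConfig) -> None:
    """A group larger than G_max splits uniformly at random into two
    fragments of (near-)equal size."""
    rng = state.rng
    new_groups: list[Group] = []
    for group in state.groups:
        while len(group) > config.G_max:
            members = group.members
            order = rng.permutation(len(members))
            half = len(members) // 2
            group.members = [members[i] for i in order[:len(members) - half]]
            fragment = Group(_next_group_id(state, new_groups),
                             [members[i] for i in order[len(members) - half:]])
            new_groups.append(fragment)
    state.groups.extend(new_groups)


def _next_group_id(state: WorldState, pending: list[Group]) -> int:
    existing = max((g.id for g in state.groups), default=-1)
    if pending:
        existing = max(existing, max(g.id for g in pending))
    return existing + 1


def migration_step(state: WorldState, config: WorldConfig) -> None:
    """Each individual independently moves to a uniformly random other
    group with the migration rate; no-op with a single group."""
    rate = config.migration_rate
    if rate <= 0.0 or len(state.groups) < 2:
        return
    rng = state.rng
    n_groups = len(state.groups)
    moves: list[tuple[Individual, int, int]] = []
    for gi, group in enumerate(state.groups):
        if not group.members:
            continue
        u = rng.random(len(group.members))
        for ind, ui in zip(group.members, u):
            if ui < rate:
                target = int(rng.integers(0, n_groups - 1))
                if target >= gi:
                    target += 1
                moves.append((ind, gi, target))
    for ind, src, dst in moves:
        state.groups[src].members.remove(ind)
        state.groups[dst].members.append(ind)
    state.groups = [g for g in state.groups if g.members]


# ----------------------------------------------------------------------
# year loop


def run_year(state: WorldState, config: WorldConfig) -> "pd.Series":
    """Advance the world by one year and return its statistics record."""
    from .stats import summarize  # local import to avoid a cycle

    log = YearLog()
    life_support_step(state, config)
    invention_step(state, config, log)
    forgetting_step(state, config)
    teaching_step(state, config)
    hauls = hunting_step(state, config)
    for group, haul in zip(state.groups, hauls):
        sharing_step(group, haul)
    useless_step(state, config)
    learning_step(state, config)
    death_step(state, config, log)
    reproduction_step(state, config, log)
    split_step(state, config)
    migration_step(state, config)
    for group in state.groups:
        for ind in group.members:
            ind.age += 1
    state.year += 1
    return summarize(state, log)


def run_simulation(config: WorldConfig,
                   progress: bool = False) -> pd.DataFrame:
    """Run a full simulation and return the per-year statistics table.

    The run is seeded once from ``config.seed``.  Extinction ends the run
    early; the final record carries ``extinct = True``.
    """
    rng = np.random.default_rng(config.seed)
    state = init_population(config, rng)
    records = []
    iterator = range(config.years)
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm
            iterator = tqdm(iterator, desc="years")
        except ImportError:
            pass
    for _ in iterator:
        record = run_year(state, config)
        records.append(record)
        if state.population == 0:
            record["extinct"] = True
            break
    df = pd.DataFrame(records)
    if not df.empty:
        df = df.reset_index(drop=True)
    return df


# ----------------------------------------------------------------------
# demography helpers


def cohort_lifespans(n: int, death_coeff: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Ages at death of a cohort exposed to the age hazard alone.

    Each year an individual of age ``a`` dies with probability
    ``min(1, death_coeff * a)``; survivors age by one year.  Vectorized
    over the cohort; used as the demographic oracle's counterpart.
    """
    alive = np.arange(n)
    out = np.empty(n, dtype=np.int64)
    age = 0
    while alive.size:
        p = min(1.0, death_coeff * age)
        if p > 0.0:
            dead = rng.random(alive.size) < p
            out[alive[dead]] = age
            alive = alive[~dead]
        age += 1
    return out


def expected_lifespan(death_coeff: float) -> float:
    """Analytic mean age at death under the discrete age hazard:
    ``sum_{a>=1} prod_{k=0}^{a-1} (1 - min(1, death_coeff * k))``."""
    total = 0.0
    surv = 1.0
    a = 1
    while surv > 1e-15:
        surv *= 1.0 - min(1.0, death_coeff * (a - 1))
        total += surv
        a += 1
    return total
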