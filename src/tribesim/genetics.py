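"""Diploid genetics and phenotype computation.

Individuals carry three mutable-in-principle loci (memory capacity MC,
learning efficiency LE, teaching efficiency TE) plus two fixed genetic
base values (hunting efficiency and Machiavellian trick efficiency).
Each locus holds an ordered pair of allele values; the genotypic value
of a trait is the arithmetic mean of its two alleles.  Mutation acts on
gametes: with a per-locus probability a normal deviate is added to the
transmitted allele, and draws landing outside the locus bounds are
cancelled and retried.

Probability-valued traits (LE, TE, propensity for useless actions) are
assembled from several independent sources with the complementary-product
rule ``1 - prod(1 - p_i)``, so that stacking sources never pushes a
probability past 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, TYPE_CHECKING

import math

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .config import WorldConfig
    from .memes import Memory

#: Canonical locus order used by every genotype array.
LOCUS_ORDER: tuple[str, ...] = ("MC", "LE", "TE")

#: Mutation draws landing outside locus bounds are retried up to this many
#: times; exhausting the cap indicates a pathological spec and aborts.
MUTATION_RETRY_CAP = 100


@dataclass(frozen=True)
class LocusSpec:
    """Specification of one mutable locus.

    Parameters
    ----------
    name:
        One of ``MC``, ``LE``, ``TE``.
    initial_value:
        Allele value every founder carries (both copies).
    mutation_rate:
        Probability per gamete that the transmitted allele mutates.
    mutation_sd:
        Standard deviation of the normal mutation effect (mean 0).
    lower_bound, upper_bound:
        Hard allele bounds; out-of-bounds mutation draws are cancelled
        and retried.  MC is bounded below at 0 and unbounded above;
        LE and TE live in [0, 1].
    """

    name: str
    initial_value: float
    mutation_rate: float = 0.0
    mutation_sd: float = 0.0
    lower_bound: float = 0.0
    upper_bound: float = math.inf

    def __post_init__(self) -> None:
        if self.name not in LOCUS_ORDER:
            raise ValueError(f"unknown locus {self.name!r}; expected one of {LOCUS_ORDER}")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError(f"locus {self.name}: mutation_rate must be in [0, 1]")
        if self.mutation_sd < 0.0:
            raise ValueError(f"locus {self.name}: mutation_sd must be >= 0")
        if not self.lower_bound <= self.initial_value <= self.upper_bound:
            raise ValueError(f"locus {self.name}: initial_value outside bounds")


@dataclass(frozen=True)
class TraitSet:
    """Phenotype of one individual, derived from genotype plus memory."""

    mc: float
    le: float
    te: float
    he: float
    tre: float
    useless_propensity: float
    brain_volume: float


def genotypic_value(allele_pair: Sequence[float]) -> float:
    """Mean of the two allele values of a diploid locus."""
    a, b = allele_pair
    return (a + b) / 2.0


def combine_probabilities(ps: Iterable[float]) -> float:
    """Combine independent success probabilities: ``1 - prod(1 - p)``.

    The empty sequence combines to 0; any argument equal to 1 is
    absorbing.  Raises ``ValueError`` on inputs outside [0, 1].
    """
    miss = 1.0
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
        miss *= 1.0 - p
    return 1.0 - miss


def make_genotype(locus_specs: Sequence[LocusSpec]) -> np.ndarray:
    """Founder genotype: both alleles at each locus set to the initial value."""
    arr = np.empty((len(locus_specs), 2))
    for i, spec in enumerate(locus_specs):
        arr[i, :] = spec.initial_value
    return arr


def genotypic_values(genotype: np.ndarray) -> np.ndarray:
    """Per-locus genotypic values (allele means), in :data:`LOCUS_ORDER`."""
    return genotype.mean(axis=1)


def make_gamete(
    genotype: np.ndarray,
    locus_specs: Sequence[LocusSpec],
    rng: np.random.Generator,
) -> np.ndarray:
    """Form one gamete: per locus, one parental allele plus possible mutation.

    One of the two alleles is chosen uniformly.  With probability
    ``mutation_rate`` a ``Normal(0, mutation_sd)`` deviate is added; if the
    mutated value leaves the locus bounds, the draw is cancelled and
    repeated (fresh deviate) up to :data:`MUTATION_RETRY_CAP` times.
    """
    n = len(locus_specs)
    gamete = np.empty(n)
    which = rng.integers(0, 2, size=n)
    for i, spec in enumerate(locus_specs):
        allele = genotype[i, which[i]]
        if spec.mutation_rate > 0.0 and rng.random() < spec.mutation_rate:
            for _ in range(MUTATION_RETRY_CAP):
                candidate = allele + rng.normal(0.0, spec.mutation_sd)
                if spec.lower_bound <= candidate <= spec.upper_bound:
                    allele = candidate
                    break
            else:  # pragma: no cover - unreachable with sane specs
                raise RuntimeError(
                    f"locus {spec.name}: mutation retry cap exceeded "
                    f"(sd {spec.mutation_sd} vs bounds "
                    f"[{spec.lower_bound}, {spec.upper_bound}])"
                )
        gamete[i] = allele
    return gamete


def brain_volume_from_genotype(genotype: np.ndarray, config: "WorldConfig") -> float:
    """Brain volume ``base + k1*MC + k2*LE_g + k3*TE_g`` (genotypic values)."""
    mc_g, le_g, te_g = genotypic_values(genotype)
    return config.brain_base + config.k1 * mc_g + config.k2 * le_g + config.k3 * te_g


def phenotype(genotype: np.ndarray, memory: "Memory", config: "WorldConfig") -> TraitSet:
    """Compute the full trait set from a genotype and the memes in memory.

    HE and TrE are additive (genetic base plus meme efficiencies);
    LE, TE and the useless-action propensity are probabilities combined
    with the complementary-product rule; MC and brain volume are purely
    genetic.
    """
    mc_g, le_g, te_g = genotypic_values(genotype)
    he = config.he_base
    tre = config.tre_base
    miss_le = 1.0 - le_g
    miss_te = 1.0 - te_g
    miss_useless = 1.0
    for meme in memory:
        cat = meme.category
        if cat == "HE":
            he += meme.efficiency
        elif cat == "TrE":
            tre += meme.efficiency
        elif cat == "LE":
            miss_le *= 1.0 - meme.efficiency
        elif cat == "TE":
            miss_te *= 1.0 - meme.efficiency
        else:  # Useless
            miss_useless *= 1.0 - meme.efficiency
    return TraitSet(
        mc=mc_g,
        le=1.0 - miss_le,
        te=1.0 - miss_te,
        he=he,
        tre=tre,
        useless_propensity=1.0 - miss_useless,
        brain_volume=config.brain_base + config.k1 * mc_g + config.k2 * le_g + config.k3 * te_g,
    )
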