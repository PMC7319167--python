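"""Memes, capacity-limited memory, and social transmission.

A meme is a unique, indivisible unit of culture with a category (which
trait it boosts), a size (memory it occupies) and an efficiency (its
phenotypic effect).  Memes enter the world only by sporadic invention,
spread by teacher- or learner-initiated transfer between group mates,
and leave a memory by forgetting or by the owner's death.  Transfers
copy references: a meme keeps its identity for its whole existence, and
cultural richness counts unique meme ids among the living.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .genetics import combine_probabilities

#: Meme categories, in the order used for reporting.
CATEGORIES: tuple[str, ...] = ("TrE", "HE", "Useless", "LE", "TE")

#: Categories whose efficiency is a probability and is clamped to <= 1.
PROBABILITY_CATEGORIES = frozenset({"LE", "TE", "Useless"})

#: Efficiency draws are resampled until they exceed this floor.
EFFICIENCY_FLOOR = 0.01
#: Meme sizes never fall below this floor.
SIZE_FLOOR = 0.01


@dataclass(frozen=True)
class Meme:
    """One culturally transmissible unit."""

    id: int
    category: str
    size: float
    efficiency: float


@dataclass(frozen=True)
class MemeCategoryParams:
    """Generative law and invention rate for one meme category.

    Efficiency is drawn from ``Normal(mean_eff, sd_eff)`` truncated below
    at 0.01 (out-of-range draws resampled); probability-valued categories
    additionally clamp efficiency to 1.  Size is
    ``size_coeff * efficiency * size_noise**z`` with ``z ~ Uniform(-1, 1)``,
    floored at 0.01 — so size and efficiency are positively but weakly
    correlated, and ``size_noise = 1`` makes size deterministic given
    efficiency.
    """

    category: str
    mean_eff: float
    sd_eff: float
    size_coeff: float
    size_noise: float
    enabled: bool = True
    invention_rate: float = 0.000133

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown meme category {self.category!r}")
        if self.mean_eff <= 0:
            raise ValueError(f"{self.category} memes: mean_eff must be > 0")
        if self.sd_eff < 0:
            raise ValueError(f"{self.category} memes: sd_eff must be >= 0")
        if self.size_coeff <= 0:
            raise ValueError(f"{self.category} memes: size_coeff must be > 0")
        if self.size_noise < 1:
            raise ValueError(f"{self.category} memes: size_noise must be >= 1")
        if not 0.0 <= self.invention_rate <= 1.0:
            raise ValueError(f"{self.category} memes: invention_rate must be in [0, 1]")


class Memory:
    """Capacity-limited meme store of one individual.

    Capacity is the owner's phenotypic memory capacity (MC) and is fixed
    at birth; the sum of stored meme sizes never exceeds it.
    """

    __slots__ = ("capacity", "_memes", "used")

    def __init__(self, capacity: float) -> None:
        self.capacity = float(capacity)
        self._memes: dict[int, Meme] = {}
        self.used = 0.0

    @property
    def free_capacity(self) -> float:
        return self.capacity - self.used

    def __len__(self) -> int:
        return len(self._memes)

    def __iter__(self) -> Iterator[Meme]:
        return iter(self._memes.values())

    def __contains__(self, meme_id: int) -> bool:
        return meme_id in self._memes

    def fits(self, meme: Meme) -> bool:
        return meme.size <= self.free_capacity + 1e-12

    def add(self, meme: Meme) -> None:
        if meme.id in self._memes:
            raise ValueError(f"meme {meme.id} already in memory")
        if not self.fits(meme):
            raise ValueError(f"meme {meme.id} does not fit in free capacity")
        self._memes[meme.id] = meme
        self.used += meme.size

    def remove(self, meme_id: int) -> None:
        meme = self._memes.pop(meme_id)
        self.used -= meme.size
        if self.used < 0.0:  # guard against float drift
            self.used = 0.0

    def meme_ids(self) -> list[int]:
        return list(self._memes)


def draw_meme(
    params: MemeCategoryParams, rng: np.random.Generator, meme_id: int
) -> Meme:
    """Mint a new meme of one category from its generative law."""
    for _ in range(1000):
        eff = rng.normal(params.mean_eff, params.sd_eff)
        if eff >= EFFICIENCY_FLOOR:
            break
    else:
        eff = EFFICIENCY_FLOOR
    if params.category in PROBABILITY_CATEGORIES:
        eff = min(eff, 1.0)
    z = rng.uniform(-1.0, 1.0)
    size = params.size_coeff * eff * params.size_noise**z
    if size < SIZE_FLOOR:
        size = SIZE_FLOOR
    return Meme(id=meme_id, category=params.category, size=size, efficiency=eff)


def try_invent(
    individual,
    enabled_params: Sequence[MemeCategoryParams],
    rng: np.random.Generator,
    next_meme_id,
) -> list[Meme]:
    """One year of spontaneous invention for one individual.

    Independently for each enabled category, with probability
    ``invention_rate`` a meme is drawn.  A drawn meme is kept only when it
    fits the inventor's free memory; otherwise it is lost permanently and
    never enters the meme pool.  ``next_meme_id`` is a callable minting
    fresh ids; returns the memes actually stored.
    """
    stored: list[Meme] = []
    for params in enabled_params:
        if not params.enabled or params.invention_rate <= 0.0:
            continue
        if rng.random() < params.invention_rate:
            meme = draw_meme(params, rng, next_meme_id())
            if individual.memory.fits(meme):
                individual.memory.add(meme)
                individual.invalidate_traits()
                stored.append(meme)
    return stored


def forget(memory: Memory, p_forget: float, rng: np.random.Generator) -> int:
    """Independently drop each stored meme with probability ``p_forget``.

    Returns the number of memes forgotten.
    """
    if not 0.0 <= p_forget <= 1.0:
        raise ValueError("p_forget must be in [0, 1]")
    if p_forget <= 0.0 or not len(memory):
        return 0
    ids = memory.meme_ids()
    u = rng.random(len(ids))
    dropped = 0
    for meme_id, ui in zip(ids, u):
        if ui < p_forget:
            memory.remove(meme_id)
            dropped += 1
    return dropped


def select_transferable(
    teacher_memory: Memory, student_memory: Memory, rng: np.random.Generator
) -> Optional[Meme]:
    """Uniform draw from memes the teacher knows and the student does not."""
    candidates = [m for m in teacher_memory if m.id not in student_memory]
    if not candidates:
        return None
    return candidates[rng.integers(0, len(candidates))]


def attempt_teach(teacher, student, rng: np.random.Generator) -> bool:
    """Teacher-initiated transfer of one meme to a group mate.

    Fails when the teacher has nothing new for the student or the chosen
    meme exceeds the student's free memory; otherwise succeeds with
    probability ``combine(TE_teacher, LE_student)``.
    """
    meme = select_transferable(teacher.memory, student.memory, rng)
    if meme is None or not student.memory.fits(meme):
        return False
    p = combine_probabilities((teacher.traits.te, student.traits.le))
    if p >= 1.0 or rng.random() < p:
        student.memory.add(meme)
        student.invalidate_traits()
        return True
    return False


def attempt_learn(student, model, rng: np.random.Generator) -> bool:
    """Learner-initiated transfer; succeeds with the student's LE alone."""
    meme = select_transferable(model.memory, student.memory, rng)
    if meme is None or not student.memory.fits(meme):
        return False
    p = student.traits.le
    if p >= 1.0 or rng.random() < p:
        student.memory.add(meme)
        student.invalidate_traits()
        return True
    return False
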