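"""Per-year population summaries.

One :func:`summarize` call per simulated year produces a flat record of
demography, mean phenotypes, and culture-level statistics: cultural
richness (unique memes among the living), mean memes per individual,
mean stored-meme size, efficiency-to-size ratio, and the "memory
clogging" occupancy fractions per meme category.  Ratio statistics over
empty sets are reported as missing values (NaN), never as 0.
"""

from __future__ import annotations

import math
from typing import Optional, TYPE_CHECKING

import pandas as pd

from .memes import CATEGORIES

if TYPE_CHECKING:  # pragma: no cover
    from .population import WorldState, YearLog

#: Column order of the per-year statistics table.
STAT_COLUMNS: tuple[str, ...] = (
    "year", "population", "n_groups",
    "mean_brain_volume", "mean_genotypic_mc",
    "cultural_richness", "mean_memes_per_individual",
    "mean_meme_size", "mean_eff_to_size",
    "mean_he", "mean_tre", "mean_le", "mean_te",
    *(f"occupancy_{cat}" for cat in CATEGORIES),
    "mean_age_at_death", "births", "deaths", "extinct",
)


def summarize(state: "WorldState", log: Optional["YearLog"] = None) -> pd.Series:
    """Compute the statistics record for the state's current year.

    All means run over living individuals; memory-occupancy fractions
    (share of an individual's *used* memory held by each category) are
    averaged over individuals with non-empty memory.
    """
    nan = math.nan
    inds = state.individuals()
    n = len(inds)
    rec: dict[str, float] = dict.fromkeys(STAT_COLUMNS, nan)
    rec["year"] = state.year
    rec["population"] = n
    rec["n_groups"] = len(state.groups)
    rec["extinct"] = False
    if log is not None:
        rec["births"] = log.births
        rec["deaths"] = log.deaths
        rec["mean_age_at_death"] = (
            sum(log.death_ages) / len(log.death_ages) if log.death_ages else nan)
    else:
        rec["births"] = rec["deaths"] = 0

    if n == 0:
        rec["cultural_richness"] = 0
        rec["mean_memes_per_individual"] = nan
        return pd.Series(rec)

    sum_bv = sum_mc = sum_he = sum_tre = sum_le = sum_te = 0.0
    unique_ids: set[int] = set()
    meme_count = 0
    size_sum = 0.0
    ratio_sum = 0.0
    occ_sums = dict.fromkeys(CATEGORIES, 0.0)
    n_occupied = 0

    for ind in inds:
        t = ind.traits
        sum_bv += t.brain_volume
        sum_mc += t.mc
        sum_he += t.he
        sum_tre += t.tre
        sum_le += t.le
        sum_te += t.te
        mem = ind.memory
        if len(mem):
            by_cat = dict.fromkeys(CATEGORIES, 0.0)
            for meme in mem:
                unique_ids.add(meme.id)
                meme_count += 1
                size_sum += meme.size
                ratio_sum += meme.efficiency / meme.size
                by_cat[meme.category] += meme.size
            used = mem.used
            if used > 0.0:
                n_occupied += 1
                for cat in CATEGORIES:
                    occ_sums[cat] += by_cat[cat] / used

    rec["mean_brain_volume"] = sum_bv / n
    rec["mean_genotypic_mc"] = sum_mc / n
    rec["mean_he"] = sum_he / n
    rec["mean_tre"] = sum_tre / n
    rec["mean_le"] = sum_le / n
    rec["mean_te"] = sum_te / n
    rec["cultural_richness"] = len(unique_ids)
    rec["mean_memes_per_individual"] = meme_count / n
    rec["mean_meme_size"] = size_sum / meme_count if meme_count else nan
    rec["mean_eff_to_size"] = ratio_sum / meme_count if meme_count else nan
    for cat in CATEGORIES:
        rec[f"occupancy_{cat}"] = (
            occ_sums[cat] / n_occupied if n_occupied else nan)
    return pd.Series(rec)
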