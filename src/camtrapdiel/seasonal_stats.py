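"""Seasonal comparison of sunrise/sunset offsets.

One-way ANOVA with season as the explanatory variable and the signed
solar offset (decimal hours) as the response, followed by Tukey HSD on
all season pairs.  Group sizes differ wildly between seasons in real
camera-trap data, so the Tukey comparisons use the unequal-n
(Tukey-Kramer) form, as implemented in statsmodels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)

__all__ = ["SeasonalOffsetTest", "anova_offsets"]


@dataclass
class SeasonalOffsetTest:
    """One-way ANOVA of solar offsets across seasons for one species."""

    species: str
    F: float
    df_between: int
    df_within: int
    p: float
    tukey: pd.DataFrame  # columns: group1, group2, meandiff, p_adj, lower, upper, reject
    group_stats: pd.DataFrame  # columns: season, n, mean, sd


def anova_offsets(
    offsets_by_season: dict[str, np.ndarray],
    species: str = "",
    alpha: float = 0.05,
) -> SeasonalOffsetTest:
    """Test whether mean solar offsets differ between seasons.

    Parameters
    ----------
    offsets_by_season
        Mapping season -> signed offsets in decimal hours.  Seasons with
        fewer than 2 observations are dropped with a warning; at least
        two usable seasons are required.
    """
    groups = {}
    for season, values in offsets_by_season.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            logger.warning(
                "%s: season %s has %d observation(s); dropped from ANOVA",
                species or "species", season, arr.size,
            )
            continue
        groups[season] = arr
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two seasons with >= 2 observations")

    arrays = list(groups.values())
    F, p = stats.f_oneway(*arrays)
    n_total = sum(a.size for a in arrays)
    df_between = len(groups) - 1
    df_within = n_total - len(groups)

    values = np.concatenate(arrays)
    labels = np.concatenate([[season] * a.size for season, a in groups.items()])
    hsd = pairwise_tukeyhsd(values, labels, alpha=alpha)
    tukey = pd.DataFrame(
        hsd.summary().data[1:],
        columns=["group1", "group2", "meandiff", "p_adj", "lower", "upper", "reject"],
    )

    group_stats = pd.DataFrame(
        {
            "season": list(groups),
            "n": [a.size for a in arrays],
            "mean": [a.mean() for a in arrays],
            "sd": [a.std(ddof=1) for a in arrays],
        }
    )
    return SeasonalOffsetTest(
        species=species,
        F=float(F),
        df_between=df_between,
        df_within=df_within,
        p=float(p),
        tukey=tukey,
        group_stats=group_stats,
    )
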