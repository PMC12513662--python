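"""Per-female fecundity series, lifetime totals, and effect sizes.

Egg counts are per 3-hour laying window and are never rescaled to daily
totals. k_x counts females alive at the start of the laying window on
census day x: deaths and censors recorded at censuses up to and
including x have already left the cage (an optional midpoint convention
averages the counts entering and leaving the day).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

EFFECT_BANDS = ((0.2, "small"), (0.5, "medium"), (0.8, "large"))


@dataclass
class FecunditySeries:
    group_label: str
    days: np.ndarray
    eggs: np.ndarray
    females_alive: np.ndarray          # k_x
    per_female: np.ndarray             # m_x = b_x / k_x, NaN where k_x = 0
    inconsistencies: list = field(default_factory=list)  # eggs > 0 with k_x = 0


@dataclass
class EffectSize:
    d: float
    band: str
    defined: bool = True


def females_at_risk(deaths: pd.DataFrame, days: np.ndarray,
                    initial_females: int,
                    convention: str = "start-of-window") -> np.ndarray:
    """Females alive at the laying window on each census day.

    Events recorded at a census occurred during the preceding interval,
    so they are excluded from k_x at that census.
    """
    fem = deaths[deaths["sex"] == "female"] if "sex" in deaths else deaths
    removed_by = fem.groupby("day")[["n_dead", "n_censored"]].sum().sum(axis=1)
    removed_by = removed_by.reindex(days, fill_value=0).cumsum().to_numpy()
    k_start = initial_females - removed_by
    if convention == "start-of-window":
        return np.maximum(k_start, 0)
    if convention == "midpoint":
        k_prev = initial_females - np.concatenate([[0], removed_by[:-1]])
        return np.maximum((k_start + k_prev) / 2.0, 0)
    raise ValueError(f"unknown k_x convention {convention!r}")


def per_female_series(eggs: pd.DataFrame, deaths: pd.DataFrame,
                      group_label: str = "",
                      initial_females: Optional[int] = None,
                      convention: str = "start-of-window") -> FecunditySeries:
    """Age-specific per-female fecundity m_x = b_x / k_x for one group.

    If ``initial_females`` is omitted it is taken as the total number of
    female terminal events in the death census (every female eventually
    dies or is censored).
    """
    b = eggs.groupby("day")["eggs"].sum().sort_index()
    days = b.index.to_numpy()
    if initial_females is None:
        fem = deaths[deaths["sex"] == "female"] if "sex" in deaths else deaths
        initial_females = int(fem["n_dead"].sum() + fem["n_censored"].sum())
    k = females_at_risk(deaths, days, initial_females, convention)
    bx = b.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_female = np.where(k > 0, bx / np.where(k > 0, k, 1), np.nan)
    bad = [int(d) for d, e, kk in zip(days, bx, k) if e > 0 and kk == 0]
    return FecunditySeries(group_label=group_label, days=days, eggs=bx,
                           females_alive=np.asarray(k, dtype=float),
                           per_female=per_female, inconsistencies=bad)


def lifetime_fecundity(eggs: pd.DataFrame, n_cages: Optional[int] = None):
    """Lifetime egg total across cages and the per-cage mean.

    Returns (total, mean_per_cage).
    """
    if len(eggs) == 0:
        return 0.0, 0.0
    total = float(eggs["eggs"].sum())
    if n_cages is None:
        n_cages = eggs["cage_id"].nunique()
    return total, total / n_cages


def hedges_d(sample_a: Sequence[float], sample_b: Sequence[float]) -> EffectSize:
    """Hedges' d standardized mean difference with small-sample correction.

    d = J * (mean_a - mean_b) / s_pooled, J = 1 - 3 / (4(n_a + n_b) - 9).
    The magnitude band uses |d| thresholds 0.2 / 0.5 / 0.8; a positive d
    means the first sample has the larger mean.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least two observations")
    s2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if s2 == 0:
        if a.mean() == b.mean():
            return EffectSize(d=0.0, band="small")
        return EffectSize(d=np.nan, band="undefined", defined=False)
    j = 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    d = j * (a.mean() - b.mean()) / np.sqrt(s2)
    return EffectSize(d=float(d), band=effect_band(d))


def effect_band(d: float) -> str:
    """Magnitude interpretation band for a standardized mean difference."""
    mag = abs(d)
    for threshold, name in EFFECT_BANDS:
        if mag < threshold:
            return name
    return "very large"


def percent_change(reference: float, comparison: float) -> float:
    """Percent change from reference to comparison, to one decimal."""
    if reference <= 0:
        raise ValueError("reference must be > 0")
    return round(100.0 * (comparison - reference) / reference, 1)


def fecundity_summary(eggs: pd.DataFrame, deaths: pd.DataFrame,
                      by: str = "regime") -> pd.DataFrame:
    """Long-format per-group fecundity table (group, day, eggs, kx, per_female)."""
    recs = []
    for key in sorted(eggs[by].unique()):
        series = per_female_series(eggs[eggs[by] == key],
                                   deaths[deaths[by] == key],
                                   group_label=str(key))
        for d, e, k, m in zip(series.days, series.eggs,
                              series.females_alive, series.per_female):
            recs.append((series.group_label, int(d), e, k, m))
    return pd.DataFrame(recs, columns=["group", "day", "eggs", "kx", "per_female"])


def effects_table(eggs: pd.DataFrame, by: str = "regime",
                  value: str = "eggs") -> pd.DataFrame:
    """Pairwise Hedges' d between groups on per-cage lifetime totals."""
    totals = eggs.groupby([by, "cage_id"])[value].sum()
    groups = sorted(totals.index.get_level_values(0).unique())
    recs = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            es = hedges_d(totals[groups[i]].to_numpy(),
                          totals[groups[j]].to_numpy())
            recs.append((f"{groups[i]} vs {groups[j]}", es.d, es.band))
    return pd.DataFrame(recs, columns=["pair", "d", "band"])
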