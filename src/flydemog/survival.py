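"""Product-limit survival estimation and log-rank comparisons.

Works directly on grouped cage-census tables (day, n_dead, n_censored):
deaths tallied at a census are treated as events at that census day
(right-endpoint convention; an optional midpoint convention shifts each
event to the middle of its census interval). Censored flies remain at
risk through their census day and are removed after it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

P_FLOOR = 1e-16  # reporting floor for p-values


@dataclass
class SurvivalCurve:
    """Product-limit estimate for one group."""

    times: np.ndarray          # sorted distinct census days with any event
    survival: np.ndarray       # S(t) just after each day
    at_risk: np.ndarray        # n at risk entering each day
    events: np.ndarray         # deaths at each day
    variance: np.ndarray       # Greenwood variance of S(t)
    group_label: str = ""

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t (S(0) = 1)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class PercentileEstimate:
    level: float
    day: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    defined: bool = True


@dataclass
class LogRankResult:
    chi2: float
    df: int
    p: float


def _aggregate(rows: pd.DataFrame, convention: str = "census-day") -> pd.DataFrame:
    """Collapse census rows to one row per event day."""
    df = rows.groupby("day", as_index=False)[["n_dead", "n_censored"]].sum()
    df = df.sort_values("day").reset_index(drop=True)
    if convention == "midpoint":
        days = df["day"].to_numpy(dtype=float)
        prev = np.concatenate([[0.0], days[:-1]])
        df["day"] = (days + prev) / 2.0
    elif convention != "census-day":
        raise ValueError(f"unknown day convention {convention!r}")
    return df


def km_estimate(rows: pd.DataFrame, group_label: str = "",
                convention: str = "census-day") -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate from grouped census rows.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i), with the Greenwood variance
    S(t)^2 * sum d_i / (n_i (n_i - d_i)) attached.
    """
    df = _aggregate(rows, convention)
    if (df["day"] < 0).any():
        raise ValueError("event days must be >= 0")
    if (df[["n_dead", "n_censored"]] < 0).to_numpy().any():
        raise ValueError("event counts must be >= 0")
    total = int(df["n_dead"].sum() + df["n_censored"].sum())
    if total == 0:
        raise ValueError("no events in input")
    if df["n_dead"].sum() == 0:
        warnings.warn("all observations censored: S(t) is identically 1 and "
                      "percentiles are undefined", stacklevel=2)
    removed = (df["n_dead"] + df["n_censored"]).to_numpy()
    at_risk = total - np.concatenate([[0], np.cumsum(removed[:-1])])
    d = df["n_dead"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.cumprod(1.0 - d / at_risk)
        gw_terms = np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.inf)
        var = s**2 * np.cumsum(gw_terms)
    var = np.where(s == 0.0, 0.0, var)
    return SurvivalCurve(
        times=df["day"].to_numpy(),
        survival=s, at_risk=at_risk.astype(int),
        events=df["n_dead"].to_numpy(dtype=int),
        variance=var, group_label=group_label,
    )


def _loglog_bands(curve: SurvivalCurve, alpha: float = 0.05):
    """Pointwise log(-log S) Greenwood confidence bands."""
    z = stats.norm.ppf(1 - alpha / 2)
    s = curve.survival
    lower = np.empty_like(s)
    upper = np.empty_like(s)
    for i, (si, vi) in enumerate(zip(s, curve.variance)):
        if si <= 0.0:
            lower[i] = upper[i] = 0.0
        elif si >= 1.0 or vi == 0.0:
            lower[i] = upper[i] = si
        else:
            se_theta = np.sqrt(vi) / (si * abs(np.log(si)))
            expo = np.exp(np.clip(z * se_theta, -50.0, 50.0))
            lower[i] = si ** expo
            upper[i] = si ** (1.0 / expo)
    return lower, upper


def percentile(curve: SurvivalCurve, level: float,
               alpha: float = 0.05) -> PercentileEstimate:
    """First day at which S(t) <= level, with a Brookmeyer-Crowley-style
    confidence interval from inverting the log(-log) Greenwood bands.

    If the curve never reaches the level the estimate is flagged
    undefined rather than imputed.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")

    def first_crossing(values):
        idx = np.nonzero(values <= level)[0]
        return float(curve.times[idx[0]]) if len(idx) else None

    day = first_crossing(curve.survival)
    if day is None:
        return PercentileEstimate(level, None, None, None, defined=False)
    lower, upper = _loglog_bands(curve, alpha)
    # the CI is {t : lower(t) <= level <= upper(t)}; the lower band dips
    # below the level first, the upper band last
    return PercentileEstimate(level, day,
                              ci_low=first_crossing(lower),
                              ci_high=first_crossing(upper),
                              defined=True)


def logrank(groups: dict, convention: str = "census-day") -> LogRankResult:
    """k-sample log-rank test on grouped census tables.

    Observed-minus-expected deaths per group with the hypergeometric
    variance at each distinct event day; chi2 has k-1 degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("log-rank needs at least two groups")
    labels = list(groups)
    aggs = {g: _aggregate(groups[g], convention) for g in labels}
    totals = {g: int(a["n_dead"].sum() + a["n_censored"].sum())
              for g, a in aggs.items()}
    if sum(int(a["n_dead"].sum()) for a in aggs.values()) == 0:
        raise ValueError("log-rank needs at least one death event")
    event_days = np.array(sorted(set().union(
        *(set(a.loc[a["n_dead"] > 0, "day"]) for a in aggs.values()))))
    k = len(labels)
    T = len(event_days)
    n_it = np.zeros((k, T))
    d_it = np.zeros((k, T))
    for j, g in enumerate(labels):
        a = aggs[g]
        days = a["day"].to_numpy()
        removed = np.concatenate(
            [[0.0], np.cumsum((a["n_dead"] + a["n_censored"]).to_numpy())])
        # removals strictly before t; censors stay at risk through their day
        n_it[j] = totals[g] - removed[np.searchsorted(days, event_days, "left")]
        dead = a["n_dead"].to_numpy()
        pos = np.searchsorted(days, event_days, "left")
        hit = (pos < len(days)) & (days[np.minimum(pos, len(days) - 1)]
                                   == event_days)
        d_it[j, hit] = dead[pos[hit]]
    n_t = n_it.sum(axis=0)
    d_t = d_it.sum(axis=0)
    use = (n_t > 1) & (d_t > 0)
    O = d_it[:, use].sum(axis=1)
    E = (d_t[use] * n_it[:, use] / n_t[use]).sum(axis=1)
    V = np.zeros((k, k))
    hyper = d_t[use] * (n_t[use] - d_t[use]) / (n_t[use] - 1)
    P = n_it[:, use] / n_t[use]
    V = np.einsum("t,it,jt->ij", hyper, P, -P)
    V[np.diag_indices(k)] += (hyper * P).sum(axis=1)
    z = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    chi2 = float(z @ np.linalg.pinv(Vsub) @ z)
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = max(float(stats.chi2.sf(chi2, df)), P_FLOOR)
    return LogRankResult(chi2=chi2, df=df, p=p)


def pairwise_logrank_bh(groups: dict,
                        convention: str = "census-day") -> pd.DataFrame:
    """All pairwise log-rank tests with Benjamini-Hochberg adjustment.

    Returns one row per unordered pair with the raw and BH step-up
    adjusted p-values.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    labels = list(groups)
    pairs, raw = [], []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            res = logrank({labels[i]: groups[labels[i]],
                           labels[j]: groups[labels[j]]}, convention)
            pairs.append((labels[i], labels[j]))
            raw.append(res.p)
    adj = multipletests(raw, method="fdr_bh")[1]
    adj = np.maximum(adj, raw)  # adjusted never below raw
    return pd.DataFrame({
        "group_a": [p[0] for p in pairs],
        "group_b": [p[1] for p in pairs],
        "p_raw": raw,
        "p_adj": adj,
    })


def survival_summary(deaths: pd.DataFrame, by: Sequence[str] = ("regime",),
                     levels: Sequence[float] = (0.9, 0.5, 0.1)) -> pd.DataFrame:
    """Percentile lifespan table (group, level, day, ci_low, ci_high)."""
    recs = []
    for key, rows in deaths.groupby(list(by)):
        label = key if isinstance(key, str) else "_".join(map(str, key))
        curve = km_estimate(rows, group_label=label)
        for level in levels:
            est = percentile(curve, level)
            recs.append((label, level, est.day, est.ci_low, est.ci_high,
                         est.defined))
    return pd.DataFrame(
        recs, columns=["group", "level", "day", "ci_low", "ci_high", "defined"])
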