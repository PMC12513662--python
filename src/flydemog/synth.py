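"""Synthetic cage-census generator.

Simulates individual fly lifespans under regime- and sex-specific Gompertz
mortality, plus cage-level egg output from a piecewise-constant per-female
laying rate, then degrades the individual ground truth to the observation
format of a Mon/Wed/Fri cage census: deaths and censors tallied per census
day, eggs counted in a 3-hour laying window per census day.

Day 0 is eclosion. Census days are integers with consecutive gaps of
2, 2, 3 days (Mon -> Wed -> Fri -> Mon).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

REGIMES = ("HH", "HL", "LH", "LL")
SEXES = ("female", "male")

DEATHS_COLUMNS = ["cage_id", "regime", "sex", "day", "n_dead", "n_censored"]
EGGS_COLUMNS = ["cage_id", "regime", "day", "eggs"]


@dataclass
class RegimeConfig:
    """Generating parameters for one larval x adult diet regime.

    Parameters
    ----------
    regime_label : str
        One of HH, HL, LH, LL (larval then adult protein level).
    gompertz_a : dict
        Baseline hazard per day (> 0), keyed by sex.
    gompertz_b : dict
        Hazard growth rate per day (>= 0), keyed by sex.
    fecundity_segments : list of (start_day, rate)
        Piecewise-constant eggs-per-female-per-3-hour-window rate; start
        days strictly increasing, rates >= 0. Days before the first
        (shifted) start have rate 0.
    peak_delay_days : float
        Shift added to every segment boundary (delayed laying onset under
        adult low protein).
    n_flies : int
        Initial flies per cage (both sexes combined).
    sex_ratio : float
        Fraction female at release.
    censor_prob : float
        Per-census, per-fly probability of censoring (escape/accident).
    """

    regime_label: str
    gompertz_a: dict
    gompertz_b: dict
    fecundity_segments: list
    peak_delay_days: float = 0.0
    n_flies: int = 80
    sex_ratio: float = 0.5
    censor_prob: float = 0.002

    def __post_init__(self):
        if self.regime_label not in REGIMES:
            raise ValueError(f"unknown regime label {self.regime_label!r}")
        for sex in SEXES:
            if self.gompertz_a[sex] <= 0:
                raise ValueError(f"gompertz_a[{sex}] must be > 0")
            if self.gompertz_b[sex] < 0:
                raise ValueError(f"gompertz_b[{sex}] must be >= 0")
        starts = [s for s, _ in self.fecundity_segments]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment start days must be strictly increasing")
        if any(r < 0 for _, r in self.fecundity_segments):
            raise ValueError("segment rates must be >= 0")
        if self.n_flies < 1:
            raise ValueError("n_flies must be >= 1")
        if not 0 <= self.censor_prob < 1:
            raise ValueError("censor_prob must be in [0, 1)")
        if not 0 < self.sex_ratio < 1:
            raise ValueError("sex_ratio must be in (0, 1)")

    def shifted_segments(self) -> list:
        """Segment boundaries after applying the peak delay."""
        return [(s + self.peak_delay_days, r) for s, r in self.fecundity_segments]

    def rate_at(self, day: float) -> float:
        """Per-female per-window laying rate in effect on a given day."""
        rate = 0.0
        for start, r in self.shifted_segments():
            if day >= start:
                rate = r
            else:
                break
        return rate


@dataclass
class Individual:
    id: int
    cage_id: str
    regime_label: str
    sex: str
    death_day: float
    censored_day: Optional[float] = None


@dataclass
class CensusSchedule:
    """Integer census days following the Mon/Wed/Fri cadence."""

    census_days: np.ndarray
    window_hours: float = 3.0

    def __post_init__(self):
        days = np.asarray(self.census_days, dtype=int)
        if len(days) == 0:
            raise ValueError("schedule needs at least one census day")
        gaps = np.diff(days)
        if not np.all(np.isin(gaps, (2, 3))):
            raise ValueError("consecutive census gaps must be 2 or 3 days")
        self.census_days = days

    @classmethod
    def weekly(cls, first_day: int = 2, until_day: int = 120,
               window_hours: float = 3.0) -> "CensusSchedule":
        """Mon/Wed/Fri schedule: repeating +2, +2, +3 day gaps."""
        days = [first_day]
        gaps = (2, 2, 3)
        i = 0
        while days[-1] < until_day:
            days.append(days[-1] + gaps[i % 3])
            i += 1
        return cls(np.array(days), window_hours)

    def extended_to(self, day: float) -> "CensusSchedule":
        """Extend with the repeating +2,+2,+3 pattern until `day` is covered."""
        days = list(self.census_days)
        while days[-1] < day:
            last = days[-1] - days[-2] if len(days) > 1 else 3
            prev = days[-2] - days[-3] if len(days) > 2 else 3
            # Mon->Wed->Fri->Mon: after two +2 gaps comes a +3, else +2
            days.append(days[-1] + (3 if (last, prev) == (2, 2) else 2))
        return CensusSchedule(np.array(days), self.window_hours)


def gompertz_lifespans(a: float, b: float, size: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw lifespans from a Gompertz(a, b) by inverse-CDF.

    T = (1/b) * log(1 - (b/a) * log U); b = 0 degenerates to an
    exponential with rate a.
    """
    if a <= 0:
        raise ValueError("baseline hazard a must be > 0")
    if b < 0:
        raise ValueError("hazard growth rate b must be >= 0")
    u = rng.uniform(size=size)
    if b == 0:
        return -np.log(u) / a
    return (1.0 / b) * np.log(1.0 - (b / a) * np.log(u))


def gompertz_median(a: float, b: float) -> float:
    """Closed-form median lifespan of a Gompertz(a, b)."""
    if b == 0:
        return np.log(2) / a
    return (1.0 / b) * np.log(1.0 + (b / a) * np.log(2.0))


def simulate_cohort(config: RegimeConfig, n_cages: int, seed: int,
                    schedule: Optional[CensusSchedule] = None) -> list:
    """Simulate `n_cages` cages of one regime; independent per-cage substreams.

    Censoring is applied per census day: any fly still alive at a census
    is censored there with probability ``config.censor_prob``.
    """
    ss = np.random.SeedSequence(seed)
    cage_streams = ss.spawn(n_cages)
    cohort: list[Individual] = []
    uid = 0
    for c, stream in enumerate(cage_streams):
        rng = np.random.default_rng(stream)
        cage_id = f"{config.regime_label}_c{c + 1}"
        n_female = int(round(config.n_flies * config.sex_ratio))
        counts = {"female": n_female, "male": config.n_flies - n_female}
        for sex in SEXES:
            n = counts[sex]
            if n == 0:
                continue
            t = gompertz_lifespans(config.gompertz_a[sex],
                                   config.gompertz_b[sex], n, rng)
            censored = np.full(n, np.nan)
            if config.censor_prob > 0 and schedule is not None:
                sched = schedule.extended_to(float(t.max()))
                for day in sched.census_days:
                    alive = (t > day) & np.isnan(censored)
                    hit = alive & (rng.uniform(size=n) < config.censor_prob)
                    censored[hit] = float(day)
            for i in range(n):
                cohort.append(Individual(
                    id=uid, cage_id=cage_id, regime_label=config.regime_label,
                    sex=sex, death_day=float(t[i]),
                    censored_day=None if np.isnan(censored[i]) else float(censored[i]),
                ))
                uid += 1
    return cohort


def observe_deaths(cohort: Sequence[Individual],
                   schedule: CensusSchedule) -> pd.DataFrame:
    """Tally deaths and censors per cage x sex x census day.

    Each terminal event (death, or censoring if it precedes death) is
    assigned to the first census day >= its event time; the schedule is
    extended, never truncated, so totals are conserved.
    """
    if not cohort:
        return pd.DataFrame(columns=DEATHS_COLUMNS)
    max_event = max(
        ind.censored_day if ind.censored_day is not None else ind.death_day
        for ind in cohort)
    sched = schedule.extended_to(max_event)
    days = sched.census_days
    rows = {}
    for ind in cohort:
        if ind.censored_day is not None:
            event_time, kind = ind.censored_day, "n_censored"
        else:
            event_time, kind = ind.death_day, "n_dead"
        day = int(days[np.searchsorted(days, event_time, side="left")])
        key = (ind.cage_id, ind.regime_label, ind.sex, day)
        rec = rows.setdefault(key, {"n_dead": 0, "n_censored": 0})
        rec[kind] += 1
    out = pd.DataFrame(
        [(k[0], k[1], k[2], k[3], v["n_dead"], v["n_censored"])
         for k, v in rows.items()],
        columns=DEATHS_COLUMNS,
    )
    return out.sort_values(["cage_id", "sex", "day"]).reset_index(drop=True)


def females_alive(cohort: Sequence[Individual], cage_id: str,
                  day: float) -> int:
    """Females alive and uncensored at the start of the laying window."""
    return sum(
        1 for ind in cohort
        if ind.cage_id == cage_id and ind.sex == "female"
        and ind.death_day > day
        and (ind.censored_day is None or ind.censored_day > day)
    )


def observe_eggs(cohort: Sequence[Individual], config: RegimeConfig,
                 schedule: CensusSchedule, seed: int,
                 noiseless: bool = False) -> pd.DataFrame:
    """Cage-level egg counts per census day.

    Mean egg count on day d is (per-female rate at d) x (females alive at
    d); counts are Poisson unless ``noiseless`` (then the exact mean is
    emitted, for recovery tests).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cages = sorted({ind.cage_id for ind in cohort})
    recs = []
    for cage in cages:
        for day in schedule.census_days:
            k = females_alive(cohort, cage, day)
            mean = config.rate_at(day) * k
            eggs = float(mean) if noiseless else int(rng.poisson(mean))
            recs.append((cage, config.regime_label, int(day), eggs))
    return pd.DataFrame(recs, columns=EGGS_COLUMNS)


def gompertz_survival(a: float, b: float, t: np.ndarray) -> np.ndarray:
    """Gompertz survivorship S(t) = exp(-(a/b)(e^{bt} - 1)); exponential at b=0."""
    t = np.asarray(t, dtype=float)
    if b == 0:
        return np.exp(-a * t)
    return np.exp(-(a / b) * (np.exp(b * t) - 1.0))


def expected_life_schedule(config: RegimeConfig, sex: str,
                           first_day: int = 2, cutoff: float = 1e-6):
    """Deterministic discrete survivorship for one sex on the census grid.

    Returns (boundaries, l) where boundaries start at day 0 (eclosion)
    and survivorship is truncated to exactly 0 at the first census day
    where it falls below ``cutoff``. This finite schedule is the
    generating model for the noiseless observation path.
    """
    a = config.gompertz_a[sex]
    b = config.gompertz_b[sex]
    horizon = 60
    while gompertz_survival(a, b, np.array([horizon]))[0] >= cutoff:
        horizon *= 2
    days = CensusSchedule.weekly(first_day, until_day=horizon).census_days
    boundaries = np.concatenate([[0], days]).astype(float)
    l = gompertz_survival(a, b, boundaries)
    z = int(np.argmax(l < cutoff))
    l[z] = 0.0
    return boundaries[:z + 1], l[:z + 1]


def noiseless_study(configs: Optional[dict] = None, n_cages: int = 2) -> tuple:
    """Exact expected censuses from the generating model (no sampling).

    Death counts per census equal the expected survivorship drops
    (fractional flies allowed) and egg counts equal rate x females alive
    exactly, so the downstream life table reproduces the generating
    schedule to machine precision. Returns (deaths, eggs, truth).
    """
    if configs is None:
        configs = default_configs()
    deaths_recs, eggs_recs = [], []
    truth = {"regimes": {}, "noiseless": True}
    for reg in sorted(configs):
        cfg = configs[reg]
        n_female = cfg.n_flies * cfg.sex_ratio
        counts = {"female": n_female, "male": cfg.n_flies - n_female}
        bound_f, l_f = expected_life_schedule(cfg, "female")
        for c in range(n_cages):
            cage = f"{reg}_c{c + 1}"
            for sex in SEXES:
                bound, l = ((bound_f, l_f) if sex == "female"
                            else expected_life_schedule(cfg, sex))
                drops = counts[sex] * (l[:-1] - l[1:])
                for day, nd in zip(bound[1:], drops):
                    deaths_recs.append((cage, reg, sex, int(day), nd, 0.0))
            for day, lv in zip(bound_f[1:], l_f[1:]):
                eggs_recs.append((cage, reg, int(day),
                                  cfg.rate_at(day) * n_female * lv))
        truth["regimes"][reg] = {
            "config": _config_dict(cfg),
            "planted_boundaries": [s for s, _ in cfg.shifted_segments()],
        }
    deaths = pd.DataFrame(deaths_recs, columns=DEATHS_COLUMNS)
    eggs = pd.DataFrame(eggs_recs, columns=EGGS_COLUMNS)
    return deaths, eggs, truth


def default_configs(n_flies: int = 80, censor_prob: float = 0.002) -> dict:
    """The four diet-regime configurations used throughout.

    Gompertz hazards share b = 0.1/day; baseline hazards are set so the
    closed-form medians match the observed regime- and sex-specific
    medians (female 26/36/31/36 d, male 38/38/38/43 d for HH/HL/LH/LL).
    Laying-rate segments follow each regime's early/mid/late per-female
    output, with a 14-day onset delay under adult low protein (HL, LL).
    """
    b = 0.1

    def a_for_median(t_med):
        return b * np.log(2.0) / (np.exp(b * t_med) - 1.0)

    medians = {
        "HH": {"female": 26, "male": 38},
        "HL": {"female": 36, "male": 38},
        "LH": {"female": 31, "male": 38},
        "LL": {"female": 36, "male": 43},
    }
    segments = {
        "HH": [(0, 1.0), (8, 6.5), (30, 3.9), (55, 1.7)],
        "HL": [(0, 1.0), (8, 6.8), (30, 8.5), (55, 1.0)],
        "LH": [(0, 1.5), (8, 12.1), (30, 5.1), (55, 1.0)],
        "LL": [(0, 1.0), (8, 6.8), (30, 12.6), (55, 1.2)],
    }
    delays = {"HH": 0.0, "HL": 14.0, "LH": 0.0, "LL": 14.0}
    configs = {}
    for reg in REGIMES:
        configs[reg] = RegimeConfig(
            regime_label=reg,
            gompertz_a={s: a_for_median(medians[reg][s]) for s in SEXES},
            gompertz_b={s: b for s in SEXES},
            fecundity_segments=segments[reg],
            peak_delay_days=delays[reg],
            n_flies=n_flies,
            censor_prob=censor_prob,
        )
    return configs


def simulate_study(configs: Optional[dict] = None, n_cages: int = 2,
                   seed: int = 0,
                   schedule: Optional[CensusSchedule] = None):
    """Simulate the full factorial study (all regimes, replicate cages).

    Returns (deaths, eggs, truth) where truth carries the generating
    configs, per-individual lifespans, and planted segment boundaries.
    """
    if configs is None:
        configs = default_configs()
    if schedule is None:
        schedule = CensusSchedule.weekly()
    state = np.random.SeedSequence(seed).generate_state(2 * len(configs))
    deaths_parts, eggs_parts = [], []
    truth = {"seed": int(seed), "regimes": {}}
    for j, reg in enumerate(sorted(configs)):
        cfg = configs[reg]
        cohort = simulate_cohort(cfg, n_cages, int(state[2 * j]) % (2**31),
                                 schedule=schedule)
        max_ev = max(i.death_day for i in cohort)
        sched = schedule.extended_to(max_ev)
        deaths_parts.append(observe_deaths(cohort, sched))
        eggs_parts.append(
            observe_eggs(cohort, cfg, sched, int(state[2 * j + 1]) % (2**31)))
        truth["regimes"][reg] = {
            "config": _config_dict(cfg),
            "planted_boundaries": [s for s, _ in cfg.shifted_segments()],
            "lifespans": {
                ind.cage_id + "/" + str(ind.id): round(ind.death_day, 4)
                for ind in cohort},
        }
    deaths = pd.concat(deaths_parts, ignore_index=True)
    eggs = pd.concat(eggs_parts, ignore_index=True)
    return deaths, eggs, truth


def _config_dict(cfg: RegimeConfig) -> dict:
    d = asdict(cfg)
    d["fecundity_segments"] = [list(s) for s in cfg.fecundity_segments]
    return d


def write_outputs(deaths: pd.DataFrame, eggs: pd.DataFrame, truth: dict,
                  outdir) -> None:
    """Write deaths.csv, eggs.csv and the truth.json sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    deaths.to_csv(outdir / "deaths.csv", index=False)
    eggs.to_csv(outdir / "eggs.csv", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
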