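"""Pipeline orchestration: simulate -> survival -> fecundity -> demography
-> changepoint, with a manifest for reproducibility.

All outputs are comma-separated UTF-8 text with a header row; days are
integers, missing values empty fields. Rounding happens only at this
report layer (days integer, percents 1 decimal, lambda / V_x 3
decimals).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import changepoint as cpt
from . import demography, fecundity, survival, synth

log = logging.getLogger("flydemog")

REPORT_FILES = ("survival_summary.csv", "logrank.csv", "fecundity_summary.csv",
                "effects.csv", "demography.csv", "changepoints.csv")


@dataclass
class RunConfig:
    """Settings for one end-to-end run."""

    outdir: str = "flydemog_out"
    seed: int = 0
    n_cages: int = 2
    n_flies: int = 80
    censor_prob: float = 0.002
    deaths_path: Optional[str] = None   # read instead of simulating
    eggs_path: Optional[str] = None
    levels: Sequence[float] = (0.9, 0.5, 0.1)
    group_by: Sequence[str] = ("regime",)
    changepoint_method: str = "pelt"
    changepoint_penalty: object = "sic"
    min_seg_len: int = 2
    noiseless: bool = False
    regimes: Optional[dict] = None      # RegimeConfig overrides

    def __post_init__(self):
        if any(not 0 < lv < 1 for lv in self.levels):
            raise ValueError("percentile levels must be in (0, 1)")
        for p in (self.deaths_path, self.eggs_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(
        {k: (list(v) if isinstance(v, tuple) else v)
         for k, v in vars(config).items() if k != "regimes"},
        sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_or_simulate(config: RunConfig):
    if config.deaths_path and config.eggs_path:
        deaths = pd.read_csv(config.deaths_path)
        eggs = pd.read_csv(config.eggs_path)
        return deaths, eggs, None
    configs = config.regimes or synth.default_configs(
        n_flies=config.n_flies, censor_prob=config.censor_prob)
    if config.noiseless:
        deaths, eggs, truth = synth.noiseless_study(configs,
                                                    n_cages=config.n_cages)
    else:
        deaths, eggs, truth = synth.simulate_study(
            configs, n_cages=config.n_cages, seed=config.seed)
    truth["generating_lambda"] = {
        reg: generating_lambda(cfg) for reg, cfg in configs.items()}
    return deaths, eggs, truth


def generating_lambda(cfg: synth.RegimeConfig) -> float:
    """Dominant eigenvalue of the regime's generating Leslie matrix:
    deterministic female survivorship on the census grid and the planted
    per-female laying rates (eggs are only observed at census days, so
    the eclosion interval has zero observable fecundity)."""
    boundaries, l_bound = synth.expected_life_schedule(cfg, "female")
    starts = boundaries[:-1]
    nLx = (l_bound[:-1] + l_bound[1:]) / 2.0
    mx = np.array([cfg.rate_at(d) if d > 0 else 0.0 for d in starts])
    table = demography.LifeTable(
        starts=starts, widths=np.diff(boundaries), lx=l_bound[:-1],
        nLx=nLx, kx=l_bound[:-1], bx=mx * l_bound[:-1], mx=mx)
    return demography.eigen_analysis(demography.build_leslie(table)).lam


def summarize_gaps(summary: pd.DataFrame, pairs: Sequence[dict]) -> pd.DataFrame:
    """Derived contrasts on a percentile-lifespan summary table.

    Each request is either a within-group gap between two survival levels
    ({"group", "level_a", "level_b"}) or a between-group gap at one level
    ({"group_a", "group_b", "level"}); day differences are level_a minus
    level_b (or group_a minus group_b), with percent change of the
    comparison day relative to the reference day where requested.
    """

    def day_of(group, level):
        rows = summary[(summary["group"] == group)
                       & (np.isclose(summary["level"], level))]
        if len(rows) == 0 or pd.isna(rows["day"].iloc[0]):
            return None
        return float(rows["day"].iloc[0])

    recs = []
    for req in pairs:
        if "level_a" in req:
            da = day_of(req["group"], req["level_a"])
            db = day_of(req["group"], req["level_b"])
            label = (f"{req['group']}: day({req['level_a']}) - "
                     f"day({req['level_b']})")
        else:
            da = day_of(req["group_a"], req["level"])
            db = day_of(req["group_b"], req["level"])
            label = (f"{req['group_a']} - {req['group_b']} at "
                     f"{req['level']}")
        if da is None or db is None:
            recs.append((label, np.nan, np.nan))
            continue
        pct = (fecundity.percent_change(db, da)
               if req.get("percent", False) and db > 0 else np.nan)
        recs.append((label, da - db, pct))
    return pd.DataFrame(recs, columns=["contrast", "day_difference",
                                       "percent_change"])


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle to config.outdir.

    Returns a dict of the in-memory tables. Any stage failure removes
    partial outputs and re-raises with the stage named.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    results = {}

    def emit(name: str, df: pd.DataFrame):
        path = outdir / name
        df.to_csv(path, index=False)
        written.append(path)
        results[name[:-4]] = df
        log.info("stage=%s rows=%d", name[:-4], len(df))

    stage = "simulate"
    try:
        deaths, eggs, truth = _load_or_simulate(config)
        emit("deaths.csv", deaths)
        emit("eggs.csv", eggs)
        if truth is not None:
            with open(outdir / "truth.json", "w") as fh:
                json.dump(truth, fh, indent=1, sort_keys=True)
            written.append(outdir / "truth.json")

        stage = "survival"
        summary = survival.survival_summary(
            deaths, by=config.group_by, levels=config.levels)
        emit("survival_summary.csv", summary)
        groups = {str(k) if isinstance(k, str) else "_".join(map(str, k)): g
                  for k, g in deaths.groupby(list(config.group_by))}
        overall = survival.logrank(groups)
        lr = survival.pairwise_logrank_bh(groups)
        lr.insert(0, "overall_chi2", overall.chi2)
        lr.insert(1, "overall_df", overall.df)
        lr.insert(2, "overall_p", overall.p)
        emit("logrank.csv", lr)

        stage = "fecundity"
        emit("fecundity_summary.csv",
             fecundity.fecundity_summary(eggs, deaths, by="regime"))
        effects = fecundity.effects_table(eggs, by="regime")
        effects["d"] = effects["d"].round(3)
        emit("effects.csv", effects)

        stage = "demography"
        dem = demography.demography_table(deaths, eggs, by="regime")
        for col in ("lambda", "rho", "max_vx", "min_vx", "range_vx"):
            dem[col] = dem[col].round(3)
        emit("demography.csv", dem)

        stage = "changepoint"
        recs = []
        for reg in sorted(eggs["regime"].unique()):
            series = eggs[eggs["regime"] == reg].groupby("day")["eggs"].sum()
            res = cpt.segment_mean(series.to_numpy(),
                                   penalty=config.changepoint_penalty,
                                   method=config.changepoint_method,
                                   min_seg_len=config.min_seg_len)
            for start, end, mean in cpt.segment_durations(
                    res, series.index.to_numpy()):
                recs.append((reg, start, end, round(mean, 3)))
        emit("changepoints.csv", pd.DataFrame(recs, columns=[
            "group", "segment_start_day", "segment_end_day", "mean_eggs"]))

        manifest = {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "tables": {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                       for p in written if p.suffix == ".csv"},
            "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        results["manifest"] = manifest
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return results
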