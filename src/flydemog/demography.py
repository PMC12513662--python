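"""Life tables and Leslie-matrix eigen analysis.

A census-interval life table is built from the female death census and
the egg census: survivorship l_x at each interval boundary, mid-interval
survivorship nL_x = (l_x + l_{x+n}) / 2 on the proportion scale (the
census cadence yields a mix of 2- and 3-day intervals), and per-female
fecundity m_x = b_x / k_x. The Leslie projection matrix puts the
fecundities on the top row and the survival ratios nL_{x+n}/nL_x on the
subdiagonal; its dominant eigenvalue is the asymptotic growth rate
lambda per projection step, the right eigenvector the stable age
distribution, the left eigenvector the reproductive values V_x, and
lambda / |lambda_2| the damping ratio rho.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .fecundity import females_at_risk

EIG_TOL = 1e-8


@dataclass
class LifeTable:
    starts: np.ndarray      # interval start days x (first is 0, eclosion)
    widths: np.ndarray      # interval lengths n (days)
    lx: np.ndarray          # survivorship proportion at x, l0 = 1
    nLx: np.ndarray         # mid-interval survivorship (proportion scale)
    kx: np.ndarray          # females alive at the laying window at x
    bx: np.ndarray          # eggs laid in the window at x
    mx: np.ndarray          # per-female fecundity b_x / k_x
    group_label: str = ""
    inconsistencies: list = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "start": self.starts, "width": self.widths, "lx": self.lx,
            "nLx": self.nLx, "kx": self.kx, "bx": self.bx, "mx": self.mx,
        })


@dataclass
class ProjectionResult:
    matrix: np.ndarray
    lam: float                 # dominant eigenvalue (lambda)
    stable_age: np.ndarray     # right eigenvector, sums to 1
    repro_value: np.ndarray    # left eigenvector V_x, V[0] = 1
    rho: Optional[float]       # damping ratio lambda / |lambda_2|


def build_life_table(deaths: pd.DataFrame, eggs: pd.DataFrame,
                     group_label: str = "",
                     initial_females: Optional[int] = None,
                     trim: bool = True) -> LifeTable:
    """Interval life table for one group from its census tables.

    Interval boundaries are eclosion (day 0) plus the census days; eggs
    counted in the window on day x and the females alive at that window
    belong to the interval starting at x. Trailing intervals after
    survivorship reaches zero carry no information and are trimmed.
    """
    fem = deaths[deaths["sex"] == "female"] if "sex" in deaths else deaths
    if initial_females is None:
        initial_females = int(fem["n_dead"].sum() + fem["n_censored"].sum())
    if initial_females <= 0:
        raise ValueError("no female events: cannot anchor survivorship")
    census_days = np.unique(np.concatenate([
        fem["day"].to_numpy(), eggs["day"].to_numpy()])).astype(int)
    boundaries = np.concatenate([[0], census_days])
    removed = fem.groupby("day")[["n_dead", "n_censored"]].sum().sum(axis=1)
    removed = removed.reindex(census_days, fill_value=0).cumsum().to_numpy()
    l_bound = np.concatenate([[1.0], (initial_females - removed) / initial_females])
    l_bound = np.clip(l_bound, 0.0, 1.0)

    starts = boundaries[:-1]
    widths = np.diff(boundaries)
    lx = l_bound[:-1]
    nLx = (l_bound[:-1] + l_bound[1:]) / 2.0

    b = eggs.groupby("day")["eggs"].sum()
    bx = b.reindex(starts, fill_value=0.0).to_numpy(dtype=float)
    k = females_at_risk(fem, starts, initial_females)
    with np.errstate(divide="ignore", invalid="ignore"):
        mx = np.where(k > 0, bx / np.where(k > 0, k, 1), 0.0)
    bad = [int(d) for d, e, kk in zip(starts, bx, k) if e > 0 and kk == 0]

    if trim:
        keep = len(starts)
        while keep > 1 and lx[keep - 1] == 0.0 and bx[keep - 1] == 0.0:
            keep -= 1
        sl = slice(0, keep)
    else:
        sl = slice(None)
    return LifeTable(starts=starts[sl], widths=widths[sl], lx=lx[sl],
                     nLx=nLx[sl], kx=np.asarray(k, dtype=float)[sl],
                     bx=bx[sl], mx=mx[sl], group_label=group_label,
                     inconsistencies=bad)


def build_leslie(table: LifeTable) -> np.ndarray:
    """Leslie projection matrix: fecundities m_x on the top row, survival
    ratios nL_{x+n}/nL_x (capped at 1) on the subdiagonal.

    One projection step corresponds to one census interval.
    """
    m = len(table.starts)
    if m < 2:
        raise ValueError("need at least two intervals to project")
    A = np.zeros((m, m))
    A[0, :] = table.mx
    for i in range(m - 1):
        num, den = table.nLx[i + 1], table.nLx[i]
        if den <= 0:
            if num > 0:
                raise ValueError(
                    f"non-finite survival ratio at interval starting day "
                    f"{int(table.starts[i])}")
            p = 0.0
        else:
            p = min(num / den, 1.0)
        A[i + 1, i] = p
    return A


def eigen_analysis(matrix: np.ndarray) -> ProjectionResult:
    """Dominant-eigenpair analysis of a non-negative projection matrix.

    lambda is the eigenvalue of maximum modulus (ties broken by larger
    real part) and must be real; the right eigenvector (stable age
    distribution) is normalized to sum 1, the left eigenvector
    (reproductive value V_x) to V[0] = 1; rho = lambda / |lambda_2|.
    """
    A = np.asarray(matrix, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("projection matrix must be square")
    if (A < 0).any():
        raise ValueError("projection matrix must be non-negative")
    n = A.shape[0]
    if n == 1:
        lam = float(A[0, 0])
        return ProjectionResult(matrix=A, lam=lam,
                                stable_age=np.array([1.0]),
                                repro_value=np.array([1.0]), rho=None)
    if not np.any(A):
        raise ValueError("zero projection matrix has no dominant eigenpair")
    vals, right = np.linalg.eig(A)
    order = sorted(range(n), key=lambda i: (abs(vals[i]), vals[i].real),
                   reverse=True)
    lead = vals[order[0]]
    scale = max(1.0, abs(lead))
    if abs(lead.imag) > EIG_TOL * scale:
        raise ValueError("dominant eigenvalue is a complex pair "
                         "(non-primitive projection matrix)")
    lam = float(lead.real)
    # second-largest modulus among the remaining eigenvalues
    lam2 = abs(vals[order[1]]) if n > 1 else None
    rho = float(lam / lam2) if lam2 and lam2 > 0 else None

    w = right[:, order[0]].real
    if w.sum() < 0:
        w = -w
    if w.sum() == 0:
        raise ValueError("degenerate stable age distribution")
    w = w / w.sum()

    vals_l, left = np.linalg.eig(A.T)
    il = int(np.argmin(np.abs(vals_l - lam)))
    v = left[:, il].real
    if v[0] == 0:
        nz = np.nonzero(v)[0]
        if len(nz) == 0:
            raise ValueError("degenerate reproductive value vector")
        v = v / v[nz[0]]
    else:
        v = v / v[0]
    return ProjectionResult(matrix=A, lam=lam, stable_age=w,
                            repro_value=v, rho=rho)


def vx_summary(result: ProjectionResult):
    """(max V_x, min V_x, range V_x) over age classes."""
    v = result.repro_value
    return float(v.max()), float(v.min()), float(v.max() - v.min())


def demography_table(deaths: pd.DataFrame, eggs: pd.DataFrame,
                     by: str = "regime") -> pd.DataFrame:
    """Per-group lambda, rho and reproductive-value summary."""
    recs = []
    for key in sorted(eggs[by].unique()):
        table = build_life_table(deaths[deaths[by] == key],
                                 eggs[eggs[by] == key], group_label=str(key))
        res = eigen_analysis(build_leslie(table))
        vmax, vmin, vrange = vx_summary(res)
        recs.append((str(key), res.lam, res.rho, vmax, vmin, vrange))
    return pd.DataFrame(recs, columns=[
        "group", "lambda", "rho", "max_vx", "min_vx", "range_vx"])
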