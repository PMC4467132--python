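"""Statistical comparison of simulated vs measured readouts.

Association between one simulated prediction per condition (X) and the
replicate wet measurements (Y) is summarised two ways, as is conventional
for simulation-validation scatter data:

* Spearman's rank correlation (midrank ties), with a 95% confidence
  interval from the Fisher z-transform (SE = 1/sqrt(n-3)) and a two-tailed
  p-value — exact by permutation enumeration for n <= 9, t-approximation
  otherwise;
* R^2 of the ordinary least-squares regression of log(Y) on log(X)
  (natural log; R^2 is base-invariant), the fraction of experimental
  variation the simulation accounts for.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SpearmanResult",
    "ValidationReport",
    "spearman_with_ci",
    "r_squared_loglinear",
    "validate",
]

EXACT_PERMUTATION_MAX_N = 9


@dataclass
class SpearmanResult:
    rho: float
    ci_low: float
    ci_high: float
    p_two_tailed: float
    n: int
    degenerate: bool = False  # constant X or Y: rho undefined


@dataclass
class ValidationReport:
    per_endpoint: pd.DataFrame  # endpoint, n, rho, ci_low, ci_high, p, r2_loglinear

    def to_text(self) -> str:
        lines = ["endpoint  n  rho [95% CI]  p  R2(log-linear)"]
        for _, r in self.per_endpoint.iterrows():
            lines.append(
                f"{r['endpoint']}: n={int(r['n'])} rho={r['rho']:.3f} "
                f"[{r['ci_low']:.3f}, {r['ci_high']:.3f}] p={r['p']:.2g} "
                f"R2={r['r2_loglinear']:.3f}"
            )
        return "\n".join(lines)


def _exact_perm_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-tailed exact permutation p for Spearman rho (small n)."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = len(rx)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = float(np.mean(rx[list(perm)] * ry))
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_with_ci(
    x: np.ndarray | list[float],
    y: np.ndarray | list[float],
    ci_level: float = 0.95,
) -> SpearmanResult:
    """Spearman rho with Fisher-z confidence interval and two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(math.nan, math.nan, math.nan, math.nan, n, degenerate=True)

    rho, p_t = sps.spearmanr(x, y)
    rho = float(rho)
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_perm_p(x, y, rho)
    else:
        p = float(p_t)

    z_crit = sps.norm.ppf(0.5 + ci_level / 2.0)
    if abs(rho) >= 1.0:
        ci_low, ci_high = rho, rho
    else:
        z = math.atanh(rho)
        se = 1.0 / math.sqrt(n - 3)
        ci_low = math.tanh(z - z_crit * se)
        ci_high = math.tanh(z + z_crit * se)
    return SpearmanResult(rho, float(ci_low), float(ci_high), p, n)


def r_squared_loglinear(x, y) -> float:
    """R^2 of OLS log(y) ~ log(x); all values must be positive."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    bad = np.flatnonzero((x <= 0) | (y <= 0) | ~np.isfinite(x) | ~np.isfinite(y))
    if bad.size:
        raise ValueError(
            f"log-linear regression needs positive finite values; offending rows: {bad.tolist()}"
        )
    if len(x) < 3:
        raise ValueError("need at least 3 pairs for regression")
    res = sps.linregress(np.log(x), np.log(y))
    return float(res.rvalue**2)


def validate(
    readouts_sim: pd.DataFrame,
    readouts_exp: pd.DataFrame,
    join_on: tuple[str, ...] = ("treatment", "endpoint", "time_s"),
) -> ValidationReport:
    """Join simulated (one X per condition) to replicate measurements and score.

    ``readouts_sim`` needs columns (treatment, endpoint, time_s, value);
    ``readouts_exp`` the same plus ``replicate``.  Conditions present in
    one table but not the other raise an error listing the orphan labels.
    Replicates stay as separate pairs sharing one simulated X.
    """
    sim = readouts_sim.copy()
    exp = readouts_exp.copy()
    for df, cols in ((sim, ["value"]), (exp, ["value"])):
        missing = [c for c in (*join_on, *cols) if c not in df.columns]
        if missing:
            raise ValueError(f"readout table missing columns {missing}")

    sim_keys = set(map(tuple, sim[list(join_on)].itertuples(index=False)))
    exp_keys = set(map(tuple, exp[list(join_on)].itertuples(index=False)))
    orphans_sim = sorted(sim_keys - exp_keys)
    orphans_exp = sorted(exp_keys - sim_keys)
    if orphans_sim or orphans_exp:
        raise ValueError(
            "unmatched condition labels; simulated-only: "
            f"{orphans_sim}; experimental-only: {orphans_exp}"
        )

    merged = exp.merge(
        sim[[*join_on, "value"]].rename(columns={"value": "value_sim"}),
        on=list(join_on),
        how="left",
    )
    rows = []
    for endpoint, grp in merged.groupby("endpoint", sort=True):
        grp = grp.dropna(subset=["value", "value_sim"])
        x = grp["value_sim"].to_numpy()
        y = grp["value"].to_numpy()
        sp = spearman_with_ci(x, y)
        try:
            r2 = r_squared_loglinear(x, y)
        except ValueError:
            r2 = math.nan
        rows.append(
            dict(endpoint=endpoint, n=sp.n, rho=sp.rho, ci_low=sp.ci_low,
                 ci_high=sp.ci_high, p=sp.p_two_tailed, r2_loglinear=r2,
                 degenerate=sp.degenerate)
        )
    return ValidationReport(per_endpoint=pd.DataFrame(rows))
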