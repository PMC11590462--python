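"""Residency frequency summaries.

Odds of residency per calendar month are the ratio of resident to
non-resident classified months (unusable months excluded from both sides).
The confidence interval comes from the delta method on the sample
proportion: SE(odds) = SE(p) / (1 - p)^2 mapped to odds +/- z * SE, floored
at zero.  Seasonal contrasts use a two-sample permutation test on the
month-level resident/non-resident labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import season_of


@dataclass(frozen=True)
class MonthCounts:
    month: int
    n_resident: int
    n_nonresident: int

    def __post_init__(self):
        if self.n_resident < 0 or self.n_nonresident < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class OddsEstimate:
    odds: float
    ci_low: float
    ci_high: float
    p_hat: float
    n: int
    finite: bool = True  # False when no non-resident months (odds = +inf)


def monthly_odds(counts: MonthCounts, z: float = 1.96) -> OddsEstimate:
    """Point estimate and delta-method CI of the residency odds."""
    n = counts.n_resident + counts.n_nonresident
    if n < 1:
        raise ValueError("need at least one classified month")
    p_hat = counts.n_resident / n
    if counts.n_nonresident == 0:
        return OddsEstimate(odds=np.inf, ci_low=np.nan, ci_high=np.nan, p_hat=p_hat, n=n, finite=False)
    # the ratio of counts (= p/(1-p) exactly, without float round-off)
    odds = counts.n_resident / counts.n_nonresident
    se_p = np.sqrt(p_hat * (1.0 - p_hat) / n)
    se_odds = se_p / (1.0 - p_hat) ** 2
    return OddsEstimate(
        odds=float(odds),
        ci_low=float(max(0.0, odds - z * se_odds)),
        ci_high=float(odds + z * se_odds),
        p_hat=float(p_hat),
        n=int(n),
    )


def _usable(calls: pd.DataFrame) -> pd.DataFrame:
    return calls[calls["usable"]] if "usable" in calls.columns else calls


def monthly_odds_table(calls: pd.DataFrame, by=(), z: float = 1.96) -> pd.DataFrame:
    """OddsEstimate per calendar month (and optional extra groupers)."""
    df = _usable(calls)
    keys = list(by) + ["month"]
    rows = []
    for key, grp in df.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        est = monthly_odds(
            MonthCounts(int(key[-1]), int(grp["resident"].sum()), int((~grp["resident"]).sum())), z=z
        )
        rows.append(
            dict(zip(keys, key))
            | {
                "n": est.n,
                "p_hat": est.p_hat,
                "odds": est.odds,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "finite": est.finite,
            }
        )
    return pd.DataFrame(rows)


def residency_percentages(calls: pd.DataFrame, by=("species", "age_class")) -> pd.DataFrame:
    """Percent of usable months classed resident, by group; empty groups omitted."""
    df = _usable(calls)
    rows = []
    for key, grp in df.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n = len(grp)
        if n == 0:
            continue
        pct = 100.0 * grp["resident"].sum() / n
        rows.append(dict(zip(by, key)) | {"n_months": n, "percent_resident": pct, "percent_rounded": int(round(pct))})
    return pd.DataFrame(rows)


def seasonal_proportion_test(
    calls: pd.DataFrame, season_a: str, season_b: str, n_perm: int = 1000, seed=None
) -> tuple[float, float]:
    """Two-sample permutation test for a difference of residency proportions.

    Permutes month-level resident labels between the two season pools;
    returns ``(prop_a - prop_b, two-sided p)`` with the +1 correction.
    """
    df = _usable(calls)
    seasons = df["month"].map(season_of)
    a = df.loc[seasons == season_a, "resident"].to_numpy(dtype=float)
    b = df.loc[seasons == season_b, "resident"].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both seasons need at least one usable month")
    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_perm, len(pooled))), axis=1)
    perm = pooled[order]
    diff = np.abs(perm[:, : len(a)].mean(axis=1) - perm[:, len(a):].mean(axis=1))
    exceed = int(np.sum(diff >= abs(observed) - 1e-12))
    return float(observed), (1 + exceed) / (1 + n_perm)


def plot_monthly_odds(odds_table: pd.DataFrame, path=None, ax=None):
    """Odds +/- CI per calendar month (matplotlib; lazy import)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    t = odds_table.sort_values("month")
    ax.plot(t["month"], t["odds"], "k-", label="odds")
    ax.plot(t["month"], t["ci_low"], "k--", lw=0.8)
    ax.plot(t["month"], t["ci_high"], "k--", lw=0.8)
    ax.set_xlabel("calendar month")
    ax.set_ylabel("odds of residency")
    ax.set_xticks(range(1, 13))
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
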