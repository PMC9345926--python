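"""Replication power and discovery/test effect-size comparison.

Replication power is the probability that the test sample's one-sided
correlation test at level alpha rejects the null, taking the discovery
effect size as the true effect.  It uses the Fisher-z normal
approximation::

    power = Phi( sqrt(n - 3) * atanh(|r|) - z_{1-alpha} )

with the test direction taken from the sign of the discovery correlation.
The module also provides a self-contained Mann-Whitney U comparison of
power between replicated and non-replicated ROIs (exact enumeration for
small groups) and per-group OLS lines for the discovery-vs-test
effect-size scatter — the winner's-curse diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats


@dataclass
class PowerRecord:
    roi_id: str
    r_discovery: float
    n_test: int
    power: float
    replicated: bool
    alpha: float = 0.05


def replication_power(r_discovery: float, n_test: int, alpha: float = 0.05) -> float:
    """One-sided power of the test-sample correlation test at the discovery
    effect size.  ``r = 0`` returns exactly ``alpha``."""
    if not -1.0 < r_discovery < 1.0:
        raise ValueError("|r| must be < 1")
    if n_test < 4:
        raise ValueError("need n >= 4")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    z_crit = stats.norm.ppf(1.0 - alpha)
    shift = np.sqrt(n_test - 3.0) * np.arctanh(abs(r_discovery))
    return float(stats.norm.cdf(shift - z_crit))


def mann_whitney_u(
    group_a, group_b, exact_max: int = 8
) -> tuple[float, float]:
    """Two-sample Mann-Whitney U (two-sided), self-contained.

    ``U`` is reported for the first group.  When both groups have at most
    ``exact_max`` observations the p-value is computed by exhaustive
    enumeration of all group assignments of the pooled values (tie-safe);
    otherwise the normal approximation with tie correction is used
    (no continuity correction).
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    if n1 <= exact_max and n2 <= exact_max:
        obs_dev = abs(u1 - mu)
        total = hits = 0
        idx = np.arange(n1 + n2)
        for comb in combinations(idx, n1):
            rsum = ranks[list(comb)].sum()
            u = rsum - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u - mu) >= obs_dev - 1e-12:
                hits += 1
        return u1, hits / total
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u1, 1.0
    z = (u1 - mu) / np.sqrt(var)
    return u1, float(2.0 * stats.norm.sf(abs(z)))


def compare_power_groups(records: list[PowerRecord]) -> tuple[float, float]:
    """Mann-Whitney U comparison of replication power between replicated and
    non-replicated ROIs (U reported for the replicated group)."""
    rep = [r.power for r in records if r.replicated]
    not_rep = [r.power for r in records if not r.replicated]
    if not rep or not not_rep:
        raise ValueError("both replicated and non-replicated groups must be non-empty")
    return mann_whitney_u(rep, not_rep)


def effectsize_regression(
    pairs: list[tuple[float, float]], group: list[bool]
) -> dict[bool, dict[str, float]]:
    """Per-group OLS of the test effect size on the discovery effect size.

    ``group[i]`` flags whether pair ``i`` replicated (by sign); each group
    needs at least 3 pairs.  Returns slope, intercept and Pearson r per
    group — the regression lines of the effect-size scatter.
    """
    arr = np.asarray(pairs, dtype=float).reshape(-1, 2)
    flags = np.asarray(group, dtype=bool).ravel()
    if flags.size != arr.shape[0]:
        raise ValueError("group flags do not match pairs")
    out: dict[bool, dict[str, float]] = {}
    for g in (True, False):
        sel = arr[flags == g]
        if len(sel) == 0:
            continue
        if len(sel) < 3:
            raise ValueError(f"group {g} has fewer than 3 pairs")
        res = stats.linregress(sel[:, 0], sel[:, 1])
        out[g] = {
            "slope": float(res.slope),
            "intercept": float(res.intercept),
            "pearson_r": float(res.rvalue),
            "n": int(len(sel)),
        }
    return out
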