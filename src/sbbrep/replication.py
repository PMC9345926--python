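"""Confirmatory ROI-based replication.

Each significant cluster from a discovery sample becomes a region of
interest (ROI); its mean thickness is correlated with the behavioural
score in the matched test sample using a ranked partial correlation
(Spearman-type, controlling for age, gender and education).  Replication
is judged by three increasingly strict criteria:

* **sign** — discovery and test correlations share a direction;
* **significance** — same direction and the test p-value clears a
  Bonferroni threshold ``alpha / k`` where ``k`` is the number of
  significant clusters from the paired discovery analysis;
* **Bayes factor** — the test-sample evidence, summarized into four
  categories (moderate-to-strong or anecdotal, for H1 or H0) from a
  two-sided correlation Bayes factor under a stretched-beta prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

BF_CATEGORIES = ("strong_H1", "anecdotal_H1", "anecdotal_H0", "strong_H0")


@dataclass
class ReplicationRecord:
    """Per-ROI outcome of one discovery/test comparison."""

    roi_id: str
    score_name: str
    split_id: int
    sample_size_ratio: float
    n_clusters_in_split: int
    cluster_sign: int
    cluster_size: int
    r_discovery: float
    r_test: float
    p_test: float
    bf10: float
    verdict_sign: bool
    verdict_significance: bool
    bf_category: str
    power: float | None = None


def roi_mean_thickness(thickness: np.ndarray, cluster: np.ndarray) -> np.ndarray:
    """Per-subject mean thickness over a cluster's vertices (mm)."""
    cluster = np.asarray(cluster, dtype=np.int64)
    if cluster.size == 0:
        raise ValueError("cluster is empty")
    y = np.asarray(thickness, dtype=float)
    if cluster.max() >= y.shape[1]:
        raise ValueError("cluster vertex outside thickness matrix")
    return y[:, cluster].mean(axis=1)


def rank_partial_correlation(
    x, y, confounders=None
) -> tuple[float, float]:
    """Spearman-type partial correlation with covariate control.

    Both variables are rank-transformed (average ranks for ties),
    residualized on the confounders plus an intercept, and the Pearson
    correlation of the residuals is returned with a two-sided p-value from
    ``t = rho * sqrt((n - 2 - k) / (1 - rho**2))`` on ``n - 2 - k`` df.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("x and y lengths differ")
    z = (
        np.empty((n, 0))
        if confounders is None
        else np.asarray(confounders, dtype=float).reshape(n, -1)
    )
    k = z.shape[1]
    if n <= k + 3:
        raise ValueError("too few observations for the partial correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    zz = np.column_stack([np.ones(n), z])
    coef, *_ = np.linalg.lstsq(zz, np.column_stack([rx, ry]), rcond=None)
    res = np.column_stack([rx, ry]) - zz @ coef
    ex, ey = res[:, 0], res[:, 1]
    denom = np.sqrt((ex @ ex) * (ey @ ey))
    if denom == 0:
        raise ValueError("degenerate residuals; correlation undefined")
    rho = float(np.clip((ex @ ey) / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return rho, float(p)


def verdict_by_sign(r_discovery: float, r_test: float) -> bool:
    """Direction agreement; an exactly-zero test correlation counts as a
    mismatch (conservative)."""
    if not (np.isfinite(r_discovery) and np.isfinite(r_test)):
        raise ValueError("correlations must be finite")
    if r_test == 0.0 or r_discovery == 0.0:
        return False
    return bool(np.sign(r_discovery) == np.sign(r_test))


def verdict_by_significance(
    p_test: float, sign_match: bool, n_clusters_in_split: int, alpha: float = 0.05
) -> bool:
    """Bonferroni-corrected significant replication in the same direction.

    The denominator is the number of significant clusters found in the
    paired discovery sample for this score."""
    if n_clusters_in_split < 1:
        raise ValueError("no clusters: replication verdict undefined")
    return bool(sign_match and p_test < alpha / n_clusters_in_split)


# ---------------------------------------------------------------------------
# Correlation Bayes factor
# ---------------------------------------------------------------------------


def _log_r_density(r: float, rho: np.ndarray, n: int) -> np.ndarray:
    """Log sampling density of a Pearson correlation ``r`` given true ``rho``
    (Hotelling's exact hypergeometric form)."""
    rho = np.asarray(rho, dtype=float)
    log_c = (
        np.log(n - 2)
        + special.gammaln(n - 1)
        - 0.5 * np.log(2 * np.pi)
        - special.gammaln(n - 0.5)
        + (n - 4) / 2.0 * np.log1p(-(r**2))
    )
    return (
        log_c
        + (n - 1) / 2.0 * np.log1p(-(rho**2))
        - (n - 1.5) * np.log1p(-rho * r)
        + np.log(special.hyp2f1(0.5, 0.5, n - 0.5, (1.0 + rho * r) / 2.0))
    )


def correlation_bayes_factor(
    r_test: float, n: int, prior_width: float = 1.0, side: str = "two-sided"
) -> float:
    """BF10 for a Pearson-type correlation under a stretched-beta prior.

    H1 places a stretched beta(1/kappa, 1/kappa) prior on rho over (-1, 1)
    (``prior_width`` = kappa; kappa = 1 is uniform); H0 fixes rho = 0.  The
    Bayes factor is the prior-weighted likelihood ratio, integrated
    numerically.  ``side`` may restrict the prior mass to the sign of
    ``r_test`` (one-sided variant).  BF10 is continuous and increasing in
    |r| at fixed n.
    """
    if n < 4:
        raise ValueError("need n >= 4 for a correlation Bayes factor")
    if not np.isfinite(r_test):
        raise ValueError("r must be finite")
    if abs(r_test) >= 1.0:
        return float("inf")
    a = 1.0 / prior_width
    log_f0 = _log_r_density(r_test, np.array(0.0), n)

    def integrand(rho):
        # stretched beta density on (-1, 1): beta((1+rho)/2; a, a) / 2
        log_prior = (
            (a - 1) * (np.log1p(rho) + np.log1p(-rho))
            - special.betaln(a, a)
            - (2 * a - 1) * np.log(2.0)
        )
        return np.exp(_log_r_density(r_test, rho, n) + log_prior - log_f0)

    if side == "two-sided":
        lo, hi, scale = -1.0, 1.0, 1.0
    elif side == "one-sided":
        lo, hi = (0.0, 1.0) if r_test >= 0 else (-1.0, 0.0)
        scale = 2.0  # renormalize the half prior
    else:
        raise ValueError("side must be 'two-sided' or 'one-sided'")
    val, _ = integrate.quad(integrand, lo, hi, limit=200)
    return float(scale * val)


def classify_bf(bf10: float) -> str:
    """Four evidence categories; boundaries: BF = 3 counts as strong_H1,
    BF = 1 as anecdotal_H1, BF = 1/3 as strong_H0."""
    if not bf10 > 0:
        raise ValueError("Bayes factor must be positive")
    if bf10 >= 3.0:
        return "strong_H1"
    if bf10 >= 1.0:
        return "anecdotal_H1"
    if bf10 > 1.0 / 3.0:
        return "anecdotal_H0"
    return "strong_H0"


# ---------------------------------------------------------------------------
# Record assembly and summaries
# ---------------------------------------------------------------------------


def replicate_rois(
    cluster_set,
    score_name: str,
    discovery_cohort,
    test_cohort,
    ratio: float,
    split_id: int,
    alpha: float = 0.05,
    prior_width: float = 1.0,
) -> list[ReplicationRecord]:
    """Evaluate all three replication criteria for every discovery cluster.

    Both samples use the same confounder set (age, gender, education).
    The Bayes factor is computed on the test sample's rank-residual
    correlation with the test sample size.
    """
    from .effect_power import replication_power

    records = []
    k = len(cluster_set)
    if k == 0:
        return records
    score_d = discovery_cohort.phenotypes[score_name].to_numpy(dtype=float)
    score_t = test_cohort.phenotypes[score_name].to_numpy(dtype=float)
    # never partial the tested variable out of its own correlation (relevant
    # when a demographic such as age is the score of interest)
    conf_cols = [c for c in ("age", "gender", "education") if c != score_name]
    conf_d = discovery_cohort.phenotypes[conf_cols].to_numpy(dtype=float)
    conf_t = test_cohort.phenotypes[conf_cols].to_numpy(dtype=float)
    for i, cl in enumerate(cluster_set):
        roi_d = roi_mean_thickness(discovery_cohort.thickness[cl.hemisphere], cl.vertices)
        roi_t = roi_mean_thickness(test_cohort.thickness[cl.hemisphere], cl.vertices)
        r_d, _ = rank_partial_correlation(roi_d, score_d, conf_d)
        r_t, p_t = rank_partial_correlation(roi_t, score_t, conf_t)
        sign_ok = verdict_by_sign(r_d, r_t) if r_d != 0 and r_t != 0 else False
        sig_ok = verdict_by_significance(p_t, sign_ok, k, alpha=alpha)
        bf = correlation_bayes_factor(r_t, n=test_cohort.n_subjects, prior_width=prior_width)
        records.append(
            ReplicationRecord(
                roi_id=f"{score_name}:r{ratio:.2f}:s{split_id}:c{i + 1}",
                score_name=score_name,
                split_id=split_id,
                sample_size_ratio=ratio,
                n_clusters_in_split=k,
                cluster_sign=cl.sign,
                cluster_size=cl.size,
                r_discovery=r_d,
                r_test=r_t,
                p_test=p_t,
                bf10=bf,
                verdict_sign=sign_ok,
                verdict_significance=sig_ok,
                bf_category=classify_bf(bf),
                power=replication_power(r_d, test_cohort.n_subjects, alpha=alpha)
                if abs(r_d) < 1
                else None,
            )
        )
    return records


def replication_summary(records: list[ReplicationRecord]) -> pd.DataFrame:
    """Percentages of ROIs replicating under each criterion, pooled across
    splits, one row per (score, sample-size ratio)."""
    if not records:
        raise ValueError("no replication records")
    df = records_to_frame(records)
    rows = []
    for (score, ratio), grp in df.groupby(["score_name", "sample_size_ratio"]):
        n = len(grp)
        row = {
            "score_name": score,
            "sample_size_ratio": ratio,
            "n_rois": n,
            "pct_sign": grp.verdict_sign.mean() * 100.0,
            "pct_significance": grp.verdict_significance.mean() * 100.0,
        }
        for cat in BF_CATEGORIES:
            row[f"pct_bf_{cat}"] = (grp.bf_category == cat).mean() * 100.0
        rows.append(row)
    return pd.DataFrame(rows)


def records_to_frame(records: list[ReplicationRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])
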