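"""Matched discovery/test splits of a cohort.

The replicability design draws, at each sample-size ratio, many random
"discovery" subsamples; each is paired with an age- and gender-matched
"test" sample from the remaining participants.  Matching is achieved by
stratified sampling: subjects are binned jointly on gender and age
quintile, and the discovery sample takes each stratum in proportion to its
cohort share (largest-remainder apportionment, so sizes are exact).  The
complement then automatically mirrors the same strata mix and forms the
test sample.

Homogeneity of the behavioural score across splits is reported with a
one-way ANOVA (means) and a Brown-Forsythe/Levene test (variances); these
are diagnostics, never a resampling criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import Cohort


class MatchingError(RuntimeError):
    """Raised when a stratum cannot supply its required count."""


@dataclass
class SplitPlan:
    """One discovery/test partition with its balance audit."""

    split_id: int
    ratio: float
    discovery_ids: list[str]
    test_ids: list[str]
    matching_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.discovery_ids) & set(self.test_ids):
            raise ValueError("discovery and test samples overlap")


@dataclass
class HomogeneityResult:
    anova_f: float
    anova_p: float
    levene_stat: float
    levene_p: float


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _strata(cohort: Cohort, n_age_bins: int = 5) -> pd.Series:
    """Joint gender x age-quantile-bin stratum label per subject."""
    df = cohort.phenotypes
    age_bin = pd.qcut(df["age"], q=n_age_bins, labels=False, duplicates="drop")
    return df["gender"].astype(int).astype(str) + ":" + age_bin.astype(str)


def _apportion(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` over ``weights``."""
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def make_splits(
    cohort: Cohort,
    ratio: float,
    n_splits: int,
    seed: int | None = None,
    n_age_bins: int = 5,
) -> list[SplitPlan]:
    """Draw ``n_splits`` stratified discovery/test partitions.

    Discovery size is ``round(ratio * n)`` (half away from zero); the test
    sample is the full remainder, matched on gender and age bin by
    construction of the stratified draw.  Reproducible given ``seed``.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    n = cohort.n_subjects
    n_disc = _round_half_away(ratio * n)
    if n_disc < 2 or n - n_disc < 2:
        raise ValueError("both discovery and test samples need >= 2 subjects")
    rng = np.random.default_rng(seed)
    labels = _strata(cohort, n_age_bins=n_age_bins)
    ids = cohort.phenotypes["subject_id"].to_numpy()
    gender = cohort.phenotypes["gender"].to_numpy()
    # apportion hierarchically: gender totals first (so gender counts are
    # exact whenever ratio * count is an integer), then age bins within
    # each gender
    gender_levels = sorted(np.unique(gender))
    gender_sizes = np.array([(gender == g).sum() for g in gender_levels], float)
    gender_targets = _apportion(gender_sizes, n_disc)
    strata: dict[str, np.ndarray] = {}
    targets_list: list[int] = []
    for g, g_total in zip(gender_levels, gender_targets):
        g_labels = sorted(labels[(gender == g)].unique())
        sizes = np.array(
            [((labels == lab) & (gender == g)).sum() for lab in g_labels], float
        )
        for lab, want in zip(g_labels, _apportion(sizes, int(g_total))):
            members = ids[((labels == lab) & (gender == g)).to_numpy()]
            if want > len(members):
                raise MatchingError(
                    f"stratum {lab!r} has {len(members)} subjects but needs {want}"
                )
            strata[lab] = members
            targets_list.append(int(want))
    targets = np.array(targets_list)
    plans = []
    for k in range(n_splits):
        disc: list[str] = []
        for members, want in zip(strata.values(), targets):
            take = rng.choice(len(members), size=want, replace=False)
            disc.extend(members[take])
        disc_set = set(disc)
        test = [s for s in ids if s not in disc_set]
        plan = SplitPlan(
            split_id=k + 1,
            ratio=ratio,
            discovery_ids=sorted(disc),
            test_ids=sorted(test),
        )
        plan.matching_report = balance_report(plan, cohort)
        plans.append(plan)
    return plans


def check_homogeneity(
    splits: list[SplitPlan], cohort: Cohort, score: str
) -> HomogeneityResult:
    """ANOVA (means) and Brown-Forsythe (variances) of a score across the
    splits' discovery samples.

    High p-values indicate the subsamples are statistically interchangeable
    on this score.  Groups share subjects across splits, so this is a
    descriptive audit rather than an independent-samples test.
    """
    if len(splits) < 2:
        raise ValueError("need at least two splits")
    pheno = cohort.phenotypes.set_index("subject_id")
    groups = [
        pheno.loc[p.discovery_ids, score].dropna().to_numpy(dtype=float)
        for p in splits
    ]
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        raise ValueError(f"score {score!r} is constant; homogeneity undefined")
    if all(np.array_equal(g, groups[0]) for g in groups[1:]):
        return HomogeneityResult(0.0, 1.0, 0.0, 1.0)
    f, p_anova = stats.f_oneway(*groups)
    w, p_lev = stats.levene(*groups, center="median")
    return HomogeneityResult(float(f), float(p_anova), float(w), float(p_lev))


def balance_report(plan: SplitPlan, cohort: Cohort) -> dict:
    """Audit of the age/gender(/education) match between the two samples."""
    pheno = cohort.phenotypes.set_index("subject_id")
    out: dict = {}
    parts = {"discovery": plan.discovery_ids, "test": plan.test_ids}
    for name, idx in parts.items():
        g = pheno.loc[idx]
        out[name] = {
            "n": len(idx),
            "age_mean": float(g["age"].mean()),
            "age_sd": float(g["age"].std(ddof=1)),
            "n_female": int(g["gender"].sum()),
            "education_mean": float(g["education"].mean()),
        }
    d = pheno.loc[plan.discovery_ids]
    t = pheno.loc[plan.test_ids]
    out["age_diff"] = out["discovery"]["age_mean"] - out["test"]["age_mean"]
    if np.ptp(pheno["age"]) > 0:
        _, out["age_ttest_p"] = stats.ttest_ind(d["age"], t["age"], equal_var=False)
    counts = np.array(
        [
            [out["discovery"]["n_female"], out["discovery"]["n"] - out["discovery"]["n_female"]],
            [out["test"]["n_female"], out["test"]["n"] - out["test"]["n_female"]],
        ]
    )
    if counts.sum(axis=0).min() > 0:
        _, out["gender_chi2_p"], *_ = stats.chi2_contingency(counts, correction=True)
    _, out["education_ttest_p"] = stats.ttest_ind(
        d["education"], t["education"], equal_var=False
    )
    return out


def write_splits_tsv(plans: list[SplitPlan], path) -> None:
    rows = []
    for p in plans:
        rows += [(p.split_id, s, "discovery") for s in p.discovery_ids]
        rows += [(p.split_id, s, "test") for s in p.test_ids]
    pd.DataFrame(rows, columns=["split_id", "subject_id", "role"]).to_csv(
        path, sep="\t", index=False
    )


def read_splits_tsv(path, ratio: float) -> list[SplitPlan]:
    df = pd.read_csv(path, sep="\t")
    plans = []
    for sid, grp in df.groupby("split_id"):
        plans.append(
            SplitPlan(
                split_id=int(sid),
                ratio=ratio,
                discovery_ids=sorted(grp.loc[grp.role == "discovery", "subject_id"]),
                test_ids=sorted(grp.loc[grp.role == "test", "subject_id"]),
            )
        )
    return plans
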