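"""Matched discovery/test splits and homogeneity diagnostics."""

import numpy as np
import pandas as pd
import pytest

from sbbrep.splits import (
    HomogeneityResult,
    MatchingError,
    SplitPlan,
    balance_report,
    check_homogeneity,
    make_splits,
    read_splits_tsv,
    write_splits_tsv,
)
from sbbrep.synthetic import Cohort, ScoreSpec, generate_cohort


@pytest.fixture(scope="module")
def cohort200():
    return generate_cohort(200, score_specs=[ScoreSpec("s")], seed=42)


class TestMakeSplits:
    def test_tiny_balanced_cohort_splits_six_six(self):
        cohort = generate_cohort(12, gender_balance=0.5, seed=1)
        plans = make_splits(cohort, 0.5, 5, seed=2, n_age_bins=1)
        for p in plans:
            assert len(p.discovery_ids) == 6 and len(p.test_ids) == 6
            pheno = cohort.phenotypes.set_index("subject_id")
            assert (
                pheno.loc[p.discovery_ids].gender.sum()
                == pheno.loc[p.test_ids].gender.sum()
            )

    def test_partition_is_disjoint_and_exhaustive(self, cohort200):
        plans = make_splits(cohort200, 0.7, 3, seed=0)
        ids = set(cohort200.phenotypes.subject_id)
        for p in plans:
            d, t = set(p.discovery_ids), set(p.test_ids)
            assert not d & t
            assert d | t == ids

    def test_reproducible_by_seed(self, cohort200):
        a = make_splits(cohort200, 0.5, 4, seed=9)
        b = make_splits(cohort200, 0.5, 4, seed=9)
        assert [p.discovery_ids for p in a] == [p.discovery_ids for p in b]
        c = make_splits(cohort200, 0.5, 4, seed=10)
        assert any(
            p.discovery_ids != q.discovery_ids for p, q in zip(a, c)
        )

    def test_gender_proportions_equal_in_every_half_split(self, cohort200):
        """Exact gender stratification at ratio 0.5: both halves carry the
        same number of each gender in all splits."""
        plans = make_splits(cohort200, 0.5, 100, seed=5)
        pheno = cohort200.phenotypes.set_index("subject_id")
        for p in plans:
            assert (
                pheno.loc[p.discovery_ids].gender.mean()
                == pheno.loc[p.test_ids].gender.mean()
            )

    def test_invalid_ratio_rejected(self, cohort200):
        for ratio in (0.0, 1.0, -0.2, 1.4):
            with pytest.raises(ValueError):
                make_splits(cohort200, ratio, 1)

    def test_overlapping_plan_rejected(self):
        with pytest.raises(ValueError):
            SplitPlan(1, 0.5, ["a", "b"], ["b", "c"])

    def test_row_permutation_preserves_sizes_and_balance(self, cohort200):
        shuffled = Cohort(
            phenotypes=cohort200.phenotypes.sample(frac=1, random_state=3).reset_index(
                drop=True
            ),
            score_names=list(cohort200.score_names),
        )
        a = make_splits(cohort200, 0.7, 5, seed=1)
        b = make_splits(shuffled, 0.7, 5, seed=1)
        for p, q in zip(a, b):
            assert len(p.discovery_ids) == len(q.discovery_ids)
            assert (
                p.matching_report["discovery"]["n_female"]
                == q.matching_report["discovery"]["n_female"]
            )

    def test_exhausted_stratum_raises_matching_error(self):
        # one lone male cannot supply a male stratum at high ratios
        pheno = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(10)],
                "age": np.linspace(22, 37, 10),
                "gender": [1] * 9 + [0],
                "education": 15.0,
            }
        )
        cohort = Cohort(phenotypes=pheno)
        # force an infeasible target by requesting more from the male stratum
        from sbbrep import splits as sp

        strata_targets = sp._apportion(np.array([1.0, 9.0]), 8)
        assert strata_targets.sum() == 8  # sanity of the apportionment helper
        with pytest.raises((MatchingError, ValueError)):
            # ratio so high the remainder is < 2
            make_splits(cohort, 0.95, 1, seed=0)


class TestCheckHomogeneity:
    def _plans_from_groups(self, groups):
        plans, pheno_rows, start = [], [], 0
        for k, g in enumerate(groups):
            ids = [f"S{start + i}" for i in range(len(g))]
            start += len(g)
            pheno_rows += [
                {"subject_id": i, "age": 30.0, "gender": 0, "education": 15.0, "s": v}
                for i, v in zip(ids, g)
            ]
            plans.append(SplitPlan(k + 1, 0.5, ids, [f"T{k}a", f"T{k}b"]))
        extra = [
            {"subject_id": f"T{k}{c}", "age": 30.0, "gender": 0, "education": 15.0,
             "s": 0.0}
            for k in range(len(groups))
            for c in "ab"
        ]
        cohort = Cohort(phenotypes=pd.DataFrame(pheno_rows + extra))
        return plans, cohort

    def test_identical_splits_give_f_zero_p_one(self):
        plans, cohort = self._plans_from_groups([[1.0, 2.0, 3.0]] * 3)
        res = check_homogeneity(plans, cohort, "s")
        assert res == HomogeneityResult(0.0, 1.0, 0.0, 1.0)

    def test_hand_computed_anova_f(self):
        """Groups (1,2,3) vs (4,5,6): between-SS 13.5, within-SS 4,
        df (1, 4) -> F = 13.5."""
        plans, cohort = self._plans_from_groups([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        res = check_homogeneity(plans, cohort, "s")
        assert res.anova_f == pytest.approx(13.5)

    def test_constant_score_rejected(self):
        plans, cohort = self._plans_from_groups([[2.0, 2.0], [2.0, 2.0]])
        cohort.phenotypes["s"] = 2.0
        with pytest.raises(ValueError, match="constant"):
            check_homogeneity(plans, cohort, "s")

    def test_needs_two_splits(self, cohort200):
        plans = make_splits(cohort200, 0.5, 1, seed=0)
        with pytest.raises(ValueError):
            check_homogeneity(plans, cohort200, "s")

    def test_random_splits_yield_valid_high_p(self, cohort200):
        """Matched random subsamples of one cohort should look homogeneous;
        p-values are diagnostics and must be valid probabilities."""
        plans = make_splits(cohort200, 0.5, 50, seed=11)
        res = check_homogeneity(plans, cohort200, "s")
        assert 0.0 <= res.anova_p <= 1.0
        assert 0.0 <= res.levene_p <= 1.0
        assert res.anova_p > 0.5  # heavily overlapping matched subsamples


class TestBalanceReport:
    def test_identical_groups_have_zero_differences(self, cohort200):
        ids = list(cohort200.phenotypes.subject_id[:50])
        plan = SplitPlan.__new__(SplitPlan)  # bypass overlap check deliberately
        plan.split_id, plan.ratio = 1, 0.5
        plan.discovery_ids, plan.test_ids = ids, ids
        rep = balance_report(plan, cohort200)
        assert rep["age_diff"] == 0.0
        assert rep["discovery"]["n_female"] == rep["test"]["n_female"]

    def test_matched_split_reports_balanced_genders(self, cohort200):
        plan = make_splits(cohort200, 0.7, 1, seed=3)[0]
        rep = plan.matching_report
        prop_d = rep["discovery"]["n_female"] / rep["discovery"]["n"]
        prop_t = rep["test"]["n_female"] / rep["test"]["n"]
        assert abs(prop_d - prop_t) < 0.02
        assert abs(rep["age_diff"]) < 1.0

    def test_unmatched_groups_report_nonzero_differences(self, cohort200):
        pheno = cohort200.phenotypes.sort_values("age")
        young = list(pheno.subject_id[:40])
        old = list(pheno.subject_id[-40:])
        plan = SplitPlan(1, 0.5, young, old)
        rep = balance_report(plan, cohort200)
        assert rep["age_diff"] < -5.0
        assert rep["age_ttest_p"] < 1e-6


def test_splits_tsv_roundtrip(tmp_path, cohort200):
    plans = make_splits(cohort200, 0.7, 3, seed=8)
    path = tmp_path / "splits.tsv"
    write_splits_tsv(plans, path)
    back = read_splits_tsv(path, ratio=0.7)
    assert [p.discovery_ids for p in back] == [p.discovery_ids for p in plans]
    assert [p.test_ids for p in back] == [p.test_ids for p in plans]
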