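"""Median stratification, log-rank, Cox HR, and the per-feature screen.

The Cox and log-rank routines are validated against lifelines as an
independent oracle, including datasets with heavily tied event times.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ratiosurv as rs
from ratiosurv.screen import DegenerateStratification, median_stratify
from ratiosurv.screen import (
    _build_risk_sets,
    _cox_binary_efron,
    _group_counts,
    _logrank_vectorized,
)


def _cohort(days, event=None, ids=None):
    n = len(days)
    return pd.DataFrame(
        {
            "subject_id": ids if ids is not None else [f"s{i}" for i in range(n)],
            "days_to_death": days,
            "event": event if event is not None else [True] * n,
            "stage": "IIIC",
        }
    )


class TestMedianStratify:
    def test_odd_n_median_to_low(self):
        g = median_stratify(pd.Series([1, 2, 3, 4, 5],
                                      index=list("abcde"), dtype=float))
        assert set(g.low_ids) == {"a", "b", "c"}
        assert set(g.high_ids) == {"d", "e"}
        assert g.median_value == 3.0

    def test_even_n_between_values(self):
        g = median_stratify(pd.Series([1, 1, 2, 2], index=list("abcd"), dtype=float))
        assert g.median_value == 1.5
        assert set(g.low_ids) == {"a", "b"}

    def test_189_distinct_values_split_95_94(self):
        rng = np.random.default_rng(0)
        vals = pd.Series(rng.permutation(189).astype(float),
                         index=[f"s{i}" for i in range(189)])
        g = median_stratify(vals)
        assert (len(g.low_ids), len(g.high_ids)) == (95, 94)

    def test_degenerate_all_identical(self):
        with pytest.raises(DegenerateStratification):
            median_stratify(pd.Series([2.0] * 10))

    def test_too_few_subjects(self):
        with pytest.raises(DegenerateStratification):
            median_stratify(pd.Series([1.0, 2.0, 3.0]))


class TestKmLogrank:
    def test_identical_groups_p_one(self):
        days = [100, 200, 300, 400, 100, 200, 300, 400]
        groups = rs.median_stratify(
            pd.Series([1, 1, 1, 1, 2, 2, 2, 2], dtype=float,
                      index=[f"s{i}" for i in range(8)])
        )
        p = rs.km_logrank(groups, _cohort(days))
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_lifelines(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(1)
        for _ in range(5):
            n = 60
            days = rng.integers(1, 30, size=n)   # heavy ties
            event = rng.random(n) < 0.8
            vals = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
            g = median_stratify(vals)
            p = rs.km_logrank(g, _cohort(days, event))
            hi = vals.index.isin(g.high_ids)
            ref = logrank_test(days[hi], days[~hi], event[hi], event[~hi])
            assert p == pytest.approx(ref.p_value, abs=1e-10)

    def test_null_p_values_uniform(self):
        # permute group labels under the null; p-values should be ~U(0,1)
        rng = np.random.default_rng(2)
        n = 100
        days = rng.permutation(np.arange(1, n + 1))
        rs_ = _build_risk_sets(days, np.ones(n, bool))
        Z = np.array([rng.permutation(n) < n // 2 for _ in range(1000)])
        n1, d1 = _group_counts(rs_, Z)
        pvals = _logrank_vectorized(rs_, n1, d1)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestCoxHr:
    def test_agrees_with_lifelines(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(3)
        for _ in range(4):
            n = 80
            days = rng.integers(1, 40, size=n)
            event = rng.random(n) < 0.85
            z = rng.random(n) < 0.5
            groups = rs.screen.StratifiedGroups(
                low_ids=[f"s{i}" for i in range(n) if not z[i]],
                high_ids=[f"s{i}" for i in range(n) if z[i]],
                median_value=0.0,
            )
            hr = rs.cox_hr(groups, _cohort(days, event))
            df = pd.DataFrame({"T": days, "E": event, "z": z.astype(int)})
            ref = float(np.exp(CoxPHFitter().fit(df, "T", "E").params_.iloc[0]))
            # lifelines' stopping rule is coarser than ours near flat optima
            assert hr == pytest.approx(ref, rel=1e-4)

    def test_label_swap_reciprocal(self):
        rng = np.random.default_rng(4)
        n = 50
        days = rng.integers(1, 500, size=n)
        vals = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        g = median_stratify(vals)
        swapped = rs.screen.StratifiedGroups(g.high_ids, g.low_ids, g.median_value)
        hr = rs.cox_hr(g, _cohort(days))
        hr_swapped = rs.cox_hr(swapped, _cohort(days))
        assert hr * hr_swapped == pytest.approx(1.0, rel=1e-6)

    def test_identical_groups_hr_one(self):
        days = [10, 20, 30, 40] * 2
        groups = rs.screen.StratifiedGroups(
            [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)], 0.0
        )
        assert rs.cox_hr(groups, _cohort(days)) == pytest.approx(1.0, abs=1e-9)

    def test_separation_raises(self):
        # all high-group subjects die before any low-group subject
        days = [1, 2, 3, 4, 100, 200, 300, 400]
        groups = rs.screen.StratifiedGroups(
            [f"s{i}" for i in range(4, 8)], [f"s{i}" for i in range(4)], 0.0
        )
        with pytest.raises(ValueError):
            rs.cox_hr(groups, _cohort(days))


class TestImprovementFilter:
    @pytest.mark.parametrize(
        "p_ratio,p_single,expected",
        [(0.009, 0.01, True), (0.0095, 0.01, False), (0.5, 0.5, False),
         (1e-6, 1e-6, False), (0.0, 0.5, True)],
    )
    def test_truth_table(self, p_ratio, p_single, expected):
        assert rs.improvement_filter(p_ratio, p_single) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rs.improvement_filter(1.5, 0.5)


class TestScreenAll:
    def test_anchor_absent_and_sorted(self, small_cohort, small_screen):
        cfg, _, _ = small_cohort
        rec = small_screen.records_
        assert cfg.anchor_feature_id not in set(rec["feature_id"])
        assert list(rec["feature_id"]) == sorted(rec["feature_id"])
        assert len(rec) == cfg.n_features - 1

    def test_stored_p_reproducible_from_groups(self, small_cohort, small_screen):
        """Re-deriving a feature's p-value from its stored stratification
        reproduces the stored value exactly (same code path)."""
        _, _, cohort = small_cohort
        rec = small_screen.records_.set_index("feature_id")
        for fid in rec.index[:10]:
            g = median_stratify(small_screen.ratios_.values.loc[fid])
            assert rs.km_logrank(g, cohort) == rec.loc[fid, "km_p_ratio"]
            assert rs.cox_hr(g, cohort) == pytest.approx(
                rec.loc[fid, "cox_hr"], rel=1e-9
            )

    def test_subject_order_invariance(self, small_cohort):
        cfg, expr, cohort = small_cohort
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(cohort))
        expr_p = expr.subset_subjects([expr.subject_ids[i] for i in perm])
        cohort_p = cohort.iloc[perm].reset_index(drop=True)
        a = rs.RatioSurvivalScreen().fit(rs.log2p4_transform(expr), cohort).records_
        b = rs.RatioSurvivalScreen().fit(rs.log2p4_transform(expr_p), cohort_p).records_
        pd.testing.assert_frame_equal(a, b)

    def test_duplicate_of_anchor_is_skipped(self, small_cohort):
        cfg, expr, cohort = small_cohort
        dup = expr.values.copy()
        dup.loc["DUP_ANCHOR"] = dup.loc[cfg.anchor_feature_id]
        est = rs.RatioSurvivalScreen().fit(
            rs.log2p4_transform(rs.ExpressionMatrix(dup)), cohort
        )
        row = est.records_.set_index("feature_id").loc["DUP_ANCHOR"]
        assert row["skipped_reason"] == "degenerate"
        assert np.isnan(row["cox_hr"])

    def test_null_type_one_error_rate(self):
        """Fraction of ratio log-rank p < .05 under the null, averaged over
        independent cohorts (within one cohort the shared anchor numerator
        correlates the per-feature tests)."""
        fracs = []
        for seed in range(5):
            cfg = rs.SimulationConfig(n_subjects=100, n_features=400, seed=seed)
            expr = rs.generate_expression(cfg)
            cohort = rs.generate_survival(cfg, expr)
            rec = rs.RatioSurvivalScreen().fit(
                rs.log2p4_transform(expr), cohort
            ).records_
            fracs.append((rec["km_p_ratio"] < 0.05).mean())
        assert 0.02 < np.mean(fracs) < 0.09

    def test_hrz_standardized_over_screen(self, small_screen):
        hz = small_screen.records_["hr_z"].dropna()
        assert abs(hz.mean()) < 1e-9
        assert hz.std(ddof=1) == pytest.approx(1.0, abs=1e-9)


def test_estimator_clonable():
    from sklearn.base import clone

    est = rs.RatioSurvivalScreen(anchor="OPCML", improvement_factor=0.8)
    cloned = clone(est)
    assert cloned.get_params() == est.get_params()
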