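"""ROC AUC, stratified bootstrap CI and the significance rule."""

import numpy as np
import pytest

from salovlap import (
    AUCResult,
    DetectionPerformance,
    Label,
    ScoredImage,
    ValidationError,
    auc,
    bootstrap_ci,
    significance,
)


def scored(case_scores, control_scores):
    out = [
        ScoredImage(f"c{i}", float(s), Label.CASE, woman_id=f"wc{i}")
        for i, s in enumerate(case_scores)
    ]
    out += [
        ScoredImage(f"n{i}", float(s), Label.CONTROL, woman_id=f"wn{i}")
        for i, s in enumerate(control_scores)
    ]
    return out


class TestAuc:
    def test_perfect_separation(self):
        assert auc(scored([0.9, 0.8], [0.2, 0.1])) == 1.0

    def test_all_ties(self):
        assert auc(scored([0.5, 0.5], [0.5, 0.5])) == 0.5

    def test_pair_enumeration(self):
        # pairs (1, 1, 0, 0.5) / 4 = 0.625
        assert auc(scored([0.8, 0.4], [0.6, 0.4])) == 0.625

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            auc(scored([0.8, 0.4], []))

    def test_label_flip_antisymmetry(self):
        rng = np.random.default_rng(5)
        cases, controls = rng.normal(1, 1, 30), rng.normal(0, 1, 40)
        assert auc(scored(cases, controls)) == pytest.approx(
            1.0 - auc(scored(controls, cases)), abs=1e-15
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        cases, controls = rng.normal(1, 1, 30), rng.normal(0, 1, 40)
        a1 = auc(scored(cases, controls))
        a2 = auc(scored(np.exp(cases), np.exp(controls)))
        assert a1 == a2


class TestBootstrap:
    def test_zero_variance_degenerate(self):
        res = bootstrap_ci(scored([1.0, 1.0, 1.0], [0.0, 0.0]), n_boot=200, seed=3)
        assert res.auc == 1.0
        assert (res.ci_low, res.ci_high) == (1.0, 1.0)

    def test_bit_identical_given_seed(self):
        data = scored(np.random.default_rng(1).normal(1, 1, 50),
                      np.random.default_rng(2).normal(0, 1, 50))
        r1 = bootstrap_ci(data, n_boot=500, seed=99)
        r2 = bootstrap_ci(data, n_boot=500, seed=99)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_ci_width_shrinks_with_n(self):
        # ~1/sqrt(n): CI at 400/400 narrower than at 100/100 in >=95% of reps
        wins = 0
        reps = 30
        for i in range(reps):
            rng = np.random.default_rng(1000 + i)
            small = scored(rng.normal(1, 1, 100), rng.normal(0, 1, 100))
            large = scored(rng.normal(1, 1, 400), rng.normal(0, 1, 400))
            rs = bootstrap_ci(small, n_boot=400, seed=i)
            rl = bootstrap_ci(large, n_boot=400, seed=i)
            wins += (rl.ci_high - rl.ci_low) < (rs.ci_high - rs.ci_low)
        assert wins >= int(np.ceil(0.95 * reps))

    def test_cluster_bootstrap_deterministic(self):
        data = scored(np.random.default_rng(3).normal(1, 1, 20),
                      np.random.default_rng(4).normal(0, 1, 20))
        clusters = [s.woman_id for s in data]
        r1 = bootstrap_ci(data, n_boot=200, seed=5, clusters=clusters)
        r2 = bootstrap_ci(data, n_boot=200, seed=5, clusters=clusters)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert r1.ci_low <= r1.ci_high


def make_result(lo, hi, point=None):
    return AUCResult(
        auc=point if point is not None else (lo + hi) / 2,
        ci_low=lo, ci_high=hi, n_boot=2000, level=0.95, seed=0,
        n_cases=10, n_controls=10,
    )


class TestSignificance:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [
            (0.535, 0.606, True),
            (0.494, 0.561, False),
            (0.5, 0.5, False),  # exclusion must be strict
            (0.3, 0.45, True),  # below-chance CIs are also significant
        ],
    )
    def test_ci_excludes_half_rule(self, lo, hi, expected):
        assert significance(make_result(lo, hi)) is expected


class TestModelObjects:
    def test_fit_returns_summary(self):
        rng = np.random.default_rng(11)
        model = DetectionPerformance(scored(rng.normal(1, 1, 60), rng.normal(0, 1, 60)))
        res = model.fit(n_boot=300, seed=2)
        row = res.table_row()
        assert 0.0 <= row["auc"] <= 1.0
        assert row["ci_low"] <= row["ci_high"]
        assert "AUC" in res.summary_text()
        assert {"fpr", "tpr"} <= set(res.roc.columns)

    def test_per_woman_aggregation_takes_max(self):
        recs = [
            ScoredImage("i1", 0.2, Label.CASE, woman_id="w1"),
            ScoredImage("i2", 0.9, Label.CASE, woman_id="w1"),
            ScoredImage("i3", 0.1, Label.CONTROL, woman_id="w2"),
            ScoredImage("i4", 0.3, Label.CONTROL, woman_id="w2"),
        ]
        model = DetectionPerformance(recs, aggregate_by_woman=True)
        units = model._analysis_units()
        assert len(units) == 2
        assert {u.score for u in units} == {0.9, 0.3}
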