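import numpy as np
import pandas as pd
import pytest

from degsig import (ClinicalTable, classify_signatures, contrast_groups,
                    correlate_predictor_signatures, pearson_r, stage_trend,
                    student_t_test)
from degsig._utils import DegsigError
from degsig.association import CorrelationProfile
from degsig.enrichment import EnrichmentMatrix


def _enr(z: pd.DataFrame) -> EnrichmentMatrix:
    return EnrichmentMatrix(es=z.copy(), z=z, alpha=0.75)


class TestCorrelate:
    def test_self_correlation_is_one(self):
        samples = [f"s{i}" for i in range(6)]
        z = pd.DataFrame([[1.0, 2, 3, 4, 5, 6], [2, 1, 2, 1, 2, 1]],
                         index=["A", "B"], columns=samples)
        pred = z.loc["A"]
        r = correlate_predictor_signatures(pred, _enr(z))
        assert r["A"] == pytest.approx(1.0)

    def test_planted_sign_recovered(self, base_cohort):
        from degsig import ssgsea_matrix

        enr = ssgsea_matrix(base_cohort.expression, base_cohort.true_signatures)
        r = correlate_predictor_signatures(base_cohort.expression.row("JAG1"), enr)
        assert r["POS_SIG"] > 0
        assert r["NEG_SIG"] < 0

    def test_null_correlations_are_small(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(500)]
        z = pd.DataFrame(rng.standard_normal((50, 500)),
                         index=[f"SIG{i}" for i in range(50)], columns=samples)
        pred = pd.Series(rng.standard_normal(500), index=samples)
        r = correlate_predictor_signatures(pred, _enr(z))
        assert r.abs().max() < 0.2

    def test_too_few_shared_samples_errors(self):
        z = pd.DataFrame([[1.0, 2.0]], index=["A"], columns=["s0", "s1"])
        pred = pd.Series([1.0, 2.0], index=["s0", "s1"])
        with pytest.raises(DegsigError, match=">= 3"):
            correlate_predictor_signatures(pred, _enr(z))

    def test_agrees_with_shared_pearson(self, base_cohort):
        """Association r equals the package-wide pearson_r to 1e-12."""
        from degsig import ssgsea_matrix

        enr = ssgsea_matrix(base_cohort.expression, base_cohort.true_signatures)
        pred = base_cohort.expression.row("JAG1")
        r = correlate_predictor_signatures(pred, enr)
        for name in enr.set_names:
            direct = pearson_r(pred.to_numpy(), enr.z.loc[name].to_numpy())
            assert r[name] == pytest.approx(direct, abs=1e-12)


class TestClassify:
    def _profile(self, matrix):
        return CorrelationProfile(matrix=matrix, dataset_tag="t")

    def test_uniform_positive(self):
        m = pd.DataFrame(0.3, index=["A", "B", "C"], columns=["p1", "p2"])
        cls = classify_signatures([self._profile(m)])
        assert set(cls.positive) == {"A", "B", "C"}
        assert cls.negative == []

    def test_negation_flips_classes(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.standard_normal((6, 3)),
                         index=[f"S{i}" for i in range(6)], columns=["a", "b", "c"])
        c1 = classify_signatures([self._profile(m)])
        c2 = classify_signatures([self._profile(-m)])
        assert set(c1.positive) == set(c2.negative)
        assert set(c1.negative) == set(c2.positive)

    def test_profile_order_invariance(self):
        rng = np.random.default_rng(2)
        m1 = pd.DataFrame(rng.standard_normal((5, 2)), index=[f"S{i}" for i in range(5)])
        m2 = pd.DataFrame(rng.standard_normal((5, 2)), index=[f"S{i}" for i in range(5)])
        a = classify_signatures([self._profile(m1), self._profile(m2)])
        b = classify_signatures([self._profile(m2), self._profile(m1)])
        assert a.positive == b.positive
        assert a.negative == b.negative
        pd.testing.assert_series_equal(a.sum_r, b.sum_r)

    def test_empty_profiles_error(self):
        with pytest.raises(DegsigError):
            classify_signatures([])


class TestStudentT:
    def test_identical_groups(self):
        with pytest.raises(DegsigError):  # zero pooled variance
            student_t_test([1.0, 1.0], [1.0, 1.0])
        t, df, p = student_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_unpaired_worked_example(self):
        t, df, p = student_t_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == 4
        assert p == pytest.approx(0.0213, abs=1e-3)

    def test_paired_worked_example(self):
        t, df, p = student_t_test([2, 4, 6], [1, 2, 3], paired=True)
        assert t == pytest.approx(3.464, abs=1e-3)
        assert df == 2


class TestStageTrend:
    def test_monotone_gives_rho_one(self):
        values = pd.Series([1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 4.0])
        stages = pd.Series([1, 1, 2, 2, 3, 3, 4, 4])
        rho, p = stage_trend(values, stages)
        assert rho == pytest.approx(1.0)
        # strictly increasing values across strictly ordered stages
        rho2, _ = stage_trend(pd.Series([1.0, 2.0, 3.0, 4.0, 5.0]),
                              pd.Series([1, 1, 2, 3, 4]))
        assert rho2 > 0.9

    def test_single_stage_errors(self):
        with pytest.raises(DegsigError, match="distinct"):
            stage_trend(pd.Series([1.0, 2, 3, 4, 5]), pd.Series([2] * 5))

    def test_planted_slope_power(self):
        """A stage-linear score yields rho > 0, p < 0.05 in nearly all seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            stages = rng.integers(1, 5, size=400)
            values = 0.5 * (stages - 2.5) + rng.standard_normal(400)
            rho, p = stage_trend(pd.Series(values), pd.Series(stages))
            hits += (rho > 0) and (p < 0.05)
        assert hits >= 9


class TestContrast:
    def _clin(self, n, column, levels, patient_ids=None):
        df = pd.DataFrame({
            "os_time": np.ones(n), "os_event": np.ones(n, dtype=int),
            column: levels,
        }, index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"))
        if patient_ids is not None:
            df["patient_id"] = patient_ids
        return ClinicalTable(df)

    def test_planted_tumor_shift_detected(self):
        rng = np.random.default_rng(3)
        n = 400
        tissue = ["tumor"] * 200 + ["normal"] * 200
        values = pd.Series(rng.standard_normal(n) + np.where(np.arange(n) < 200, 1.0, 0.0),
                           index=[f"s{i}" for i in range(n)])
        res = contrast_groups(values, self._clin(n, "tissue_class", tissue), "tumor_vs_normal")
        assert res.direction > 0
        assert res.p < 0.001
        assert not res.paired

    def test_paired_pre_post_detected(self):
        rng = np.random.default_rng(4)
        n = 100  # 50 pairs
        timepoint = ["pre", "post"] * 50
        patient = [f"P{i // 2}" for i in range(n)]
        base = np.repeat(rng.standard_normal(50), 2)
        effect = np.where(np.array(timepoint) == "post", 0.5, 0.0)
        values = pd.Series(base + effect + 0.3 * rng.standard_normal(n),
                           index=[f"s{i}" for i in range(n)])
        res = contrast_groups(values, self._clin(n, "timepoint", timepoint, patient), "pre_vs_post")
        assert res.paired
        assert res.df == 49
        assert res.p < 0.001
        assert res.direction < 0  # pre minus post is negative

    def test_missing_level_errors(self):
        values = pd.Series(np.arange(4.0), index=[f"s{i}" for i in range(4)])
        clin = self._clin(4, "tissue_class", ["tumor"] * 4)
        with pytest.raises(DegsigError, match="missing level"):
            contrast_groups(values, clin, "tumor_vs_normal")
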