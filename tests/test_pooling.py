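import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dta_meta.errors import InsufficientStudiesError, ValidationError
from dta_meta.pooling import (
    MEASURES,
    dsl_tau_squared,
    heterogeneity,
    leave_one_out,
    pool_inverse_variance,
    pool_measure,
)
from dta_meta.studies import StudyRecord, apply_continuity_correction, per_study_measures

from conftest import make_panel
from oracles import oracle_dl_tau2, oracle_fixed_pool, oracle_random_pool

panels = st.integers(min_value=0, max_value=10_000)


def _random_values(rng, k):
    values = rng.normal(0.0, 2.0, size=k)
    variances = rng.uniform(0.05, 2.0, size=k)
    return values, variances


class TestPoolInverseVariance:
    def test_identical_studies_degenerate(self):
        est, se = pool_inverse_variance([1.7] * 5, [0.3] * 5, model="fixed")
        assert est == pytest.approx(1.7)
        assert dsl_tau_squared([1.7] * 5, [0.3] * 5) == 0.0
        est_r, _ = pool_inverse_variance([1.7] * 5, [0.3] * 5, model="random")
        assert est_r == pytest.approx(1.7)

    def test_single_study_identity(self):
        est, se = pool_inverse_variance([2.5], [0.4], model="random")
        assert est == pytest.approx(2.5)
        assert se == pytest.approx(math.sqrt(0.4))

    def test_three_study_closed_form(self):
        est, se = pool_inverse_variance([1.0, 2.0, 3.0], [1.0, 1.0, 1.0], model="fixed")
        assert est == pytest.approx(2.0)
        assert se == pytest.approx(1.0 / math.sqrt(3.0))

    def test_empty_input(self):
        with pytest.raises(InsufficientStudiesError):
            pool_inverse_variance([], [])

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValidationError):
            pool_inverse_variance([1.0, 2.0], [1.0, 0.0])

    def test_bad_model_rejected(self):
        with pytest.raises(ValidationError):
            pool_inverse_variance([1.0], [1.0], model="mixed")

    @given(seed=panels, k=st.integers(min_value=2, max_value=6))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, seed, k):
        rng = np.random.default_rng(seed)
        values, variances = _random_values(rng, k)
        for model, oracle in (("fixed", oracle_fixed_pool), ("random", oracle_random_pool)):
            est, se = pool_inverse_variance(values, variances, model=model)
            o_est, o_se = oracle(list(values), list(variances))
            assert est == pytest.approx(o_est, abs=1e-10)
            assert se == pytest.approx(o_se, abs=1e-10)

    @given(seed=panels, k=st.integers(min_value=2, max_value=6))
    @settings(max_examples=60, deadline=None)
    def test_convex_combination(self, seed, k):
        rng = np.random.default_rng(seed)
        values, variances = _random_values(rng, k)
        for model in ("fixed", "random"):
            est, _ = pool_inverse_variance(values, variances, model=model)
            assert values.min() - 1e-12 <= est <= values.max() + 1e-12

    @given(seed=panels)
    @settings(max_examples=40, deadline=None)
    def test_random_ci_never_narrower(self, seed):
        rng = np.random.default_rng(seed)
        values, variances = _random_values(rng, 5)
        _, se_f = pool_inverse_variance(values, variances, model="fixed")
        _, se_r = pool_inverse_variance(values, variances, model="random")
        assert se_r >= se_f - 1e-15

    def test_zero_tau_collapses_to_fixed(self):
        values, variances = [1.0, 1.1, 0.9], [0.5, 0.7, 0.6]
        est_f, se_f = pool_inverse_variance(values, variances, model="fixed")
        est_r, se_r = pool_inverse_variance(values, variances, model="random", tau_squared=0.0)
        assert est_r == pytest.approx(est_f, abs=1e-12)
        assert se_r == pytest.approx(se_f, abs=1e-12)


class TestHeterogeneity:
    def test_identical_studies(self):
        h = heterogeneity([2.0] * 4, [0.5] * 4)
        assert h.cochran_q == pytest.approx(0.0)
        assert h.i_squared == 0.0 and h.tau_squared == 0.0
        assert h.df == 3

    def test_needs_two_studies(self):
        with pytest.raises(InsufficientStudiesError):
            heterogeneity([1.0], [1.0])

    @given(seed=panels, k=st.integers(min_value=2, max_value=8))
    @settings(max_examples=60, deadline=None)
    def test_i_squared_truncation_formula(self, seed, k):
        rng = np.random.default_rng(seed)
        values, variances = _random_values(rng, k)
        h = heterogeneity(values, variances)
        expected = max(0.0, (h.cochran_q - h.df) / h.cochran_q) if h.cochran_q > 0 else 0.0
        assert h.i_squared == pytest.approx(expected)
        assert 0.0 <= h.i_squared < 1.0
        assert h.tau_squared >= 0.0
        assert 0.0 < h.p_het <= 1.0

    def test_i_squared_known_values(self):
        # Q = 14 on 7 df halves; Q below df truncates to zero.
        assert max(0.0, (14.0 - 7.0) / 14.0) == pytest.approx(0.5)
        assert max(0.0, (6.15 - 7.0) / 6.15) == 0.0

    @given(seed=panels, k=st.integers(min_value=2, max_value=6))
    @settings(max_examples=60, deadline=None)
    def test_tau2_matches_oracle(self, seed, k):
        rng = np.random.default_rng(seed)
        values, variances = _random_values(rng, k)
        o_tau2, o_q = oracle_dl_tau2(list(values), list(variances))
        h = heterogeneity(values, variances)
        assert h.tau_squared == pytest.approx(o_tau2, abs=1e-10)
        assert h.cochran_q == pytest.approx(o_q, abs=1e-10)


class TestPoolMeasure:
    def test_single_study_identity(self):
        rec = StudyRecord("a", "T", 8, 1, 2, 89)
        for model in ("fixed", "random"):
            res = pool_measure([rec], "sens", model=model)
            assert res.estimate == pytest.approx(0.8)
            assert res.df == 0 and res.cochran_q == 0.0
            assert math.isnan(res.p_het)

    def test_mixed_labels_rejected(self, rng):
        studies = make_panel(rng, k=2, label="A") + make_panel(rng, k=2, label="B")
        with pytest.raises(ValidationError, match="mixed"):
            pool_measure(studies, "dor")

    def test_unknown_measure_rejected(self, panel):
        with pytest.raises(ValidationError):
            pool_measure(panel, "accuracy")

    def test_empty_rejected(self):
        with pytest.raises(InsufficientStudiesError):
            pool_measure([], "sens")

    @pytest.mark.parametrize("measure", MEASURES)
    def test_pooled_value_within_study_range(self, panel, measure):
        res = pool_measure(panel, measure, model="fixed")
        per_study = []
        for s in panel:
            m = per_study_measures(apply_continuity_correction(s))
            per_study.append(getattr(m, measure))
        assert min(per_study) - 1e-9 <= res.estimate <= max(per_study) + 1e-9

    @pytest.mark.parametrize("measure", ["sens", "spec"])
    def test_proportion_ci_clamped(self, measure):
        # tiny studies with extreme rates force a CI beyond [0, 1]
        studies = [
            StudyRecord("a", "T", 4, 1, 0, 4),
            StudyRecord("b", "T", 5, 1, 0, 5),
            StudyRecord("c", "T", 6, 1, 0, 6),
        ]
        res = pool_measure(studies, measure, model="random")
        assert 0.0 <= res.ci_low <= res.estimate <= res.ci_high <= 1.0

    def test_all_perfect_sensitivity_pools_to_one(self):
        # raw-scale pooling keeps the point estimate at 1.0 even though the
        # variance comes from the corrected cells
        studies = [StudyRecord(f"s{i}", "T", 10 + i, 1, 0, 50) for i in range(4)]
        res = pool_measure(studies, "sens", model="random")
        assert res.estimate == pytest.approx(1.0)

    def test_log_scale_pooling_matches_oracle(self, panel):
        values, variances = [], []
        for s in panel:
            c = apply_continuity_correction(s)
            m = per_study_measures(c)
            values.append(math.log(m.dor))
            variances.append(m.var_log_dor)
        o_est, _ = oracle_random_pool(values, variances)
        res = pool_measure(panel, "dor", model="random")
        assert res.estimate == pytest.approx(math.exp(o_est), rel=1e-10)


class TestLeaveOneOut:
    def test_cardinality(self, panel):
        rows = leave_one_out(panel, lambda s: len(s))
        assert len(rows) == 8
        assert all(n == 7 for _, n in rows)
        assert [sid for sid, _ in rows] == [s.study_id for s in panel]

    def test_two_studies_leaves_single(self, rng):
        studies = make_panel(rng, k=2)
        rows = leave_one_out(studies, lambda s: pool_measure(s, "sens").estimate)
        m0 = per_study_measures(apply_continuity_correction(studies[0])).sens
        m1 = per_study_measures(apply_continuity_correction(studies[1])).sens
        assert rows[0][1] == pytest.approx(m1)
        assert rows[1][1] == pytest.approx(m0)

    def test_needs_two(self, rng):
        with pytest.raises(InsufficientStudiesError):
            leave_one_out(make_panel(rng, k=1), lambda s: s)
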