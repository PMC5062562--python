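import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from quadarray.errors import DegenerateArrayError
from quadarray.preprocess import (
    ArrayPreprocessor,
    PipelineConfig,
    apply_floor,
    apply_normalization,
    collapse_replicates,
    compute_scaling_factor,
    exclude_replicates,
    preprocess_sample,
)

from conftest import clean_quad, fence_oracle, make_table, quantile_oracle

CFG = PipelineConfig()


class TestScalingFactor:
    def test_reference_percentile_gives_unity(self):
        # a sample whose 75th percentile already sits at the series
        # reference of 1500 needs no rescaling
        values = [0, 500, 1000, 1500, 1500, 1500, 1500, 2000]
        assert compute_scaling_factor(values, CFG) == pytest.approx(1.0)

    def test_half_reference_doubles(self):
        values = [750.0] * 10
        assert compute_scaling_factor(values, CFG) == pytest.approx(2.0)

    def test_matches_independent_quantile_oracle(self):
        values = np.arange(10.0, 1010.0, 10.0)  # 10, 20, ..., 1000
        factor = compute_scaling_factor(values, CFG)
        assert factor == pytest.approx(1500.0 / quantile_oracle(values, 75))

    def test_degenerate_all_zero(self):
        with pytest.raises(DegenerateArrayError):
            compute_scaling_factor([0.0, 0.0, 0.0], CFG)

    def test_mostly_zero_percentile_degenerate(self):
        with pytest.raises(DegenerateArrayError):
            compute_scaling_factor([0.0] * 99 + [5.0], CFG)

    @given(st.lists(st.floats(1.0, 1e6), min_size=4, max_size=200))
    def test_post_scaling_percentile_is_reference(self, values):
        factor = compute_scaling_factor(values, CFG)
        scaled = np.asarray(values) * factor
        assert np.percentile(scaled, 75) == pytest.approx(1500.0, rel=1e-9)


class TestNormalization:
    def test_identity_factor(self):
        t = make_table(clean_quad("A", [100, 110, 120, 115]))
        out = apply_normalization(t, 1.0)
        pd.testing.assert_frame_equal(out.features, t.features)

    def test_doubling(self):
        t = make_table(clean_quad("A", [100, 200]))
        out = apply_normalization(t, 2.0)
        assert list(out.features["gps"]) == [200.0, 400.0]
        # flags and CVs untouched
        assert (out.features["pixel_cv"] == 0.1).all()

    @given(c=st.floats(0.01, 100.0))
    def test_scale_equivariance(self, c):
        # normalize(c*x) == normalize(x): raw scale cancels
        values = np.array([30.0, 700.0, 1200.0, 5000.0, 90.0, 250.0])
        f1 = compute_scaling_factor(values, CFG)
        f2 = compute_scaling_factor(c * values, CFG)
        np.testing.assert_allclose(values * f1, c * values * f2, rtol=1e-9)


class TestExclusion:
    def test_clean_quadruplicate_all_survive(self):
        rec = exclude_replicates(
            [(100, 0, 0, 0.1), (110, 0, 0, 0.1), (120, 0, 0, 0.1), (115, 0, 0, 0.1)]
        )
        assert rec.excluded == []
        assert sorted(rec.surviving_values) == [100, 110, 115, 120]

    def test_pixel_cv_above_half_excluded(self):
        rec = exclude_replicates(
            [(100, 0, 0, 0.6), (100, 0, 0, 0.1), (100, 0, 0, 0.1), (100, 0, 0, 0.1)]
        )
        assert rec.excluded == [(1, "pixel_cv")]

    def test_pixel_cv_exactly_half_survives(self):
        rec = exclude_replicates([(100, 0, 0, 0.5), (100, 0, 0, 0.1)])
        assert rec.excluded == []

    def test_far_outlier_matches_oracle(self):
        members = [(10, 0, 0, 0.1), (10, 0, 0, 0.1), (10, 0, 0, 0.1), (1000, 0, 0, 0.1)]
        rec = exclude_replicates(members)
        reasons = fence_oracle(members)
        assert reasons[3] == "iqr_fence"
        assert rec.excluded == [(4, "iqr_fence")]

    def test_first_matching_rule_wins(self):
        # manually flagged AND high CV -> recorded once, as manual_flag
        members = [(10, 1, 1, 0.9), (10, 0, 1, 0.1), (10, 0, 0, 0.9), (10, 0, 0, 0.1)]
        rec = exclude_replicates(members)
        assert rec.excluded == [
            (1, "manual_flag"),
            (2, "software_outlier"),
            (3, "pixel_cv"),
        ]

    def test_flagged_members_leave_the_fence_pool(self):
        # with the flagged member in the pool, {10, 10, 10, 40} would fence
        # out the 40; without it, the 3-member fences are wide enough that
        # the 40 survives
        flagged = [(10, 1, 0, 0.1), (10, 0, 0, 0.1), (10, 0, 0, 0.1), (40, 0, 0, 0.1)]
        rec = exclude_replicates(flagged)
        assert rec.excluded == [(1, "manual_flag")]
        assert rec.excluded == [
            (i + 1, r) for i, r in enumerate(fence_oracle(flagged)) if r
        ]
        unflagged = [(10, 0, 0, 0.1), (10, 0, 0, 0.1), (10, 0, 0, 0.1), (40, 0, 0, 0.1)]
        assert exclude_replicates(unflagged).excluded == [(4, "iqr_fence")]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            exclude_replicates([])

    @given(
        values=st.lists(st.floats(1.0, 1e5), min_size=1, max_size=4),
        cvs=st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4),
        flags=st.integers(0, 255),
    )
    def test_oracle_equivalence_randomized(self, values, cvs, flags):
        members = [
            (v, bool((flags >> i) & 1), bool((flags >> (i + 4)) & 1), cvs[i])
            for i, v in enumerate(values)
        ]
        rec = exclude_replicates(members)
        reasons = fence_oracle(members)
        expected = [(i + 1, r) for i, r in enumerate(reasons) if r]
        assert rec.excluded == expected

    def test_monotone_in_cv_threshold(self):
        # raising the CV cutoff never excludes a previously retained member
        members = [(100, 0, 0, 0.45), (101, 0, 0, 0.55), (99, 0, 0, 0.2), (100, 0, 0, 0.7)]
        excl = {}
        for cv_max in (0.3, 0.5, 0.6, 0.8):
            cfg = PipelineConfig(pixel_cv_max=cv_max)
            excl[cv_max] = {i for i, _ in exclude_replicates(members, cfg).excluded}
        assert excl[0.8] <= excl[0.6] <= excl[0.5] <= excl[0.3]

    def test_median_centered_convention_differs(self):
        cfg = PipelineConfig(fence_convention="median_centered")
        members = [(10, 0, 0, 0.1), (11, 0, 0, 0.1), (12, 0, 0, 0.1), (30, 0, 0, 0.1)]
        rec = exclude_replicates(members, cfg)
        reasons = fence_oracle(members, convention="median_centered")
        assert rec.excluded == [(i + 1, r) for i, r in enumerate(reasons) if r]


class TestCollapse:
    def test_constant_input(self):
        assert collapse_replicates([100, 100, 100, 100]) == pytest.approx(100.0)

    def test_two_point_geometric_mean(self):
        assert collapse_replicates([10, 1000]) == pytest.approx(100.0)

    def test_agrees_with_product_root(self):
        vals = [37.0, 210.0, 95.0]
        expected = (37.0 * 210.0 * 95.0) ** (1.0 / 3.0)
        assert collapse_replicates(vals) == pytest.approx(expected, rel=1e-12)

    def test_empty_is_missing(self):
        assert collapse_replicates([]) is None

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            collapse_replicates([10.0, 0.0])

    @given(st.lists(st.floats(0.1, 1e6), min_size=1, max_size=4))
    def test_bounded_by_extremes(self, vals):
        g = collapse_replicates(vals)
        assert min(vals) * (1 - 1e-12) <= g <= max(vals) * (1 + 1e-12)


class TestFloor:
    @pytest.mark.parametrize("value,expected", [(5.0, 20.0), (20.0, 20.0), (1500.0, 1500.0)])
    def test_substitution(self, value, expected):
        assert apply_floor(value, CFG) == expected

    def test_missing_propagates(self):
        assert apply_floor(None, CFG) is None


class TestPreprocessSample:
    def test_clean_array_every_probe_present(self, small_dataset):
        tables, _ = small_dataset
        values, norm, audit = preprocess_sample(tables[0])
        assert norm.scaling_factor == pytest.approx(
            1500.0 / norm.observed_p75, rel=1e-12
        )
        assert values.index.is_unique
        assert np.nanmin(values.to_numpy()) >= 20.0

    def test_all_flagged_probe_missing(self):
        rows = [("A", i + 1, 100.0, True, False, 0.1, False) for i in range(4)]
        rows += clean_quad("B", [1000, 1010, 990, 1050])
        values, _, audit = preprocess_sample(make_table(rows))
        assert np.isnan(values["A"])
        assert not np.isnan(values["B"])
        assert set(audit["reason"]) == {"manual_flag"}

    def test_scale_invariance_of_output(self, small_dataset):
        tables, _ = small_dataset
        t = tables[0]
        scaled = apply_normalization(t, 3.7)
        v1, _, _ = preprocess_sample(t)
        v2, _, _ = preprocess_sample(scaled)
        pd.testing.assert_series_equal(v1, v2, rtol=1e-9)

    def test_exclusions_match_per_quadruplicate_path(self, small_dataset):
        # the vectorised pipeline and the scalar exclude_replicates agree
        tables, _ = small_dataset
        t = tables[1]
        values, norm, audit = preprocess_sample(t)
        nc = t.noncontrol().copy()
        nc["gps"] = nc["gps"] * norm.scaling_factor
        audited = {
            (r.probe_id, int(r.replicate_index)): r.reason
            for r in audit.itertuples(index=False)
        }
        for probe, grp in nc.groupby("probe_id", sort=False):
            members = [
                (r.gps, r.manual_flag, r.outlier_flag, r.pixel_cv)
                for r in grp.itertuples(index=False)
            ]
            rec = exclude_replicates(members)
            expected = {
                (probe, int(grp.iloc[i - 1]["replicate_index"]))
                for i, _ in rec.excluded
            }
            got = {k for k in audited if k[0] == probe}
            assert got == expected

    def test_pre_collapse_floor_stage(self):
        rows = clean_quad("A", [5.0, 5.0, 5.0, 5.0]) + clean_quad(
            "B", [2000.0, 2000.0, 2000.0, 2000.0]
        )
        t = make_table(rows)
        cfg_post = PipelineConfig()
        cfg_pre = PipelineConfig(floor_stage="pre_collapse")
        v_post, _, _ = preprocess_sample(t, cfg_post)
        v_pre, _, _ = preprocess_sample(t, cfg_pre)
        # both floor the low probe to 20, by different routes
        assert v_post["A"] == 20.0 and v_pre["A"] == 20.0


class TestArrayPreprocessor:
    def test_matrix_shape_and_floor(self, small_dataset):
        tables, _ = small_dataset
        pre = ArrayPreprocessor()
        m = pre.fit_transform(tables)
        assert m.shape == (300, len(tables))
        assert np.nanmin(m.to_numpy()) >= 20.0
        assert len(pre.normalization_) == len(tables)

    def test_sklearn_param_contract(self):
        from sklearn.base import clone

        pre = ArrayPreprocessor(iqr_multiplier=2.0)
        assert pre.get_params()["iqr_multiplier"] == 2.0
        pre2 = clone(pre).set_params(pixel_cv_max=0.7)
        assert pre2.get_params()["pixel_cv_max"] == 0.7
        with pytest.raises(ValueError):
            ArrayPreprocessor(surrogate_floor=-1).fit()
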