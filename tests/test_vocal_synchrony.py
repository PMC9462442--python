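import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadsync import (
    ComplexityVector,
    SampEnConfig,
    complexity_vector,
    dtw_distance,
    sample_entropy,
    scdc,
)
from oracles import dtw_all_paths, dtw_recursive, sampen_naive


class TestDtw:
    def test_identical_matrices_zero(self):
        x = np.random.default_rng(0).normal(size=(7, 3))
        assert dtw_distance(x, x, normalize=False).distance == pytest.approx(0, abs=1e-12)

    def test_stretched_ramp_zero_raw_distance(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 2.0, 3.0])
        res = dtw_distance(x, y, normalize=False)
        assert res.distance == pytest.approx(0, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(9, 2)), rng.normal(size=(6, 2))
        a = dtw_distance(x, y, normalize=False).distance
        b = dtw_distance(y, x, normalize=False).distance
        assert a == pytest.approx(b, abs=1e-12)

    def test_path_length_bounds(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(8, 2)), rng.normal(size=(5, 2))
        res = dtw_distance(x, y)
        assert max(8, 5) <= res.path_len <= 8 + 5 - 1

    def test_normalized_is_distance_over_path_length(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(6, 2)), rng.normal(size=(9, 2))
        raw = dtw_distance(x, y, normalize=False)
        norm = dtw_distance(x, y, normalize=True)
        assert norm.distance == pytest.approx(raw.distance / norm.path_len)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension mismatch"):
            dtw_distance(np.zeros((3, 2)), np.zeros((3, 3)))

    def test_matches_recursive_oracle_random_suite(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            tx, ty, d = rng.integers(1, 13), rng.integers(1, 13), rng.integers(1, 4)
            x, y = rng.normal(size=(tx, d)), rng.normal(size=(ty, d))
            got = dtw_distance(x, y, normalize=False).distance
            assert got == pytest.approx(dtw_recursive(x, y), abs=1e-9)

    def test_matches_full_path_enumeration_tiny(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            tx, ty = rng.integers(1, 6), rng.integers(1, 6)
            x, y = rng.normal(size=(tx, 2)), rng.normal(size=(ty, 2))
            got = dtw_distance(x, y, normalize=False).distance
            assert got == pytest.approx(dtw_all_paths(x, y), abs=1e-9)


class TestSampleEntropy:
    def test_constant_series_zero(self):
        assert sample_entropy([5.0] * 6) == 0.0

    def test_alternating_matches_oracle(self):
        x = [1.0, 2.0] * 5
        got, exp = sample_entropy(x), sampen_naive(x)
        assert (math.isnan(got) and math.isnan(exp)) or got == pytest.approx(exp)

    def test_monotone_ramp_matches_oracle_and_nonnegative(self):
        x = np.arange(20.0)
        got, exp = sample_entropy(x), sampen_naive(x)
        if not math.isnan(got):
            assert got >= 0
        assert (math.isnan(got) and math.isnan(exp)) or got == pytest.approx(exp)

    def test_too_short_is_nan(self):
        assert math.isnan(sample_entropy([1.0, 2.0, 3.0]))

    def test_random_suite_matches_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            t = int(rng.integers(8, 51))
            kind = rng.integers(3)
            if kind == 0:
                x = rng.normal(size=t)
            elif kind == 1:
                x = np.sin(np.arange(t) * 0.7) + 0.1 * rng.normal(size=t)
            else:
                x = np.round(rng.normal(size=t), 1)  # ties stress strict <
            got, exp = sample_entropy(x), sampen_naive(x)
            assert (math.isnan(got) and math.isnan(exp)) or got == pytest.approx(
                exp, abs=1e-12
            )

    def test_nonnegative_whenever_defined(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            v = sample_entropy(rng.normal(size=30))
            if not math.isnan(v):
                assert v >= 0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SampEnConfig(m=0)
        with pytest.raises(ValueError):
            SampEnConfig(r_factor=0)


class TestComplexityVector:
    def test_constant_column_convention(self):
        rng = np.random.default_rng(13)
        x = np.column_stack([np.full(20, 3.0), rng.normal(size=20)])
        cv = complexity_vector(x)
        assert cv.valid_mask.all()
        assert cv.values[0] == 0.0
        assert cv.values[1] == pytest.approx(sampen_naive(x[:, 1]))

    def test_precondition_boundary_errors(self):
        with pytest.raises(ValueError, match="no valid complexity"):
            complexity_vector(np.random.default_rng(0).normal(size=(3, 2)))

    def test_identical_columns_identical_entries(self):
        col = np.random.default_rng(14).normal(size=25)
        cv = complexity_vector(np.column_stack([col, col]))
        assert cv.values[0] == cv.values[1]


class TestScdc:
    def test_parallel_vectors(self):
        c = ComplexityVector([0.5, 1.0], [True, True])
        res = scdc(c, c)
        assert res.sigma == pytest.approx(1.0)
        assert res.distance == pytest.approx(0.0)

    def test_orthogonal_vectors(self):
        res = scdc(
            ComplexityVector([1, 0], [True, True]),
            ComplexityVector([0, 1], [True, True]),
        )
        assert res.sigma == pytest.approx(0.0)

    def test_hand_computed_example(self):
        res = scdc(
            ComplexityVector([1, 2], [True, True]),
            ComplexityVector([2, 1], [True, True]),
        )
        assert res.sigma == pytest.approx(0.64)

    def test_joint_mask_restricts_features(self):
        c1 = ComplexityVector([1.0, 9.0], [True, False])
        c2 = ComplexityVector([2.0, 1.0], [True, True])
        assert scdc(c1, c2).sigma == pytest.approx(1.0)  # 1-d vectors are parallel

    def test_zero_norm_excluded(self):
        c1 = ComplexityVector([0.0, 0.0], [True, True])
        c2 = ComplexityVector([1.0, 1.0], [True, True])
        assert scdc(c1, c2) is None

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        v1=st.lists(st.floats(-10, 10), min_size=2, max_size=8),
        v2=st.lists(st.floats(-10, 10), min_size=2, max_size=8),
        a=st.floats(0.001, 1000),
        b=st.floats(0.001, 1000),
    )
    def test_sigma_in_unit_interval_and_scale_invariant(self, v1, v2, a, b):
        n = min(len(v1), len(v2))
        c1 = ComplexityVector(v1[:n], [True] * n)
        c2 = ComplexityVector(v2[:n], [True] * n)
        res = scdc(c1, c2)
        if res is None:
            return
        assert 0.0 <= res.sigma <= 1.0
        scaled = scdc(
            ComplexityVector(a * np.array(v1[:n]), [True] * n),
            ComplexityVector(b * np.array(v2[:n]), [True] * n),
        )
        assert scaled.sigma == pytest.approx(res.sigma, abs=1e-9)
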