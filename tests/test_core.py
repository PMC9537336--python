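import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from wamr.core import (
    UNDEFINED,
    DimensionMismatchError,
    FeatureFunction,
    RecognitionParams,
    WeightedAMR,
    _discretized_normal,
)

from conftest import random_amr, random_cue


def total(levels, m):
    return FeatureFunction.total(levels, m)


class TestFeatureFunction:
    def test_rejects_out_of_range_levels(self):
        with pytest.raises(ValueError):
            FeatureFunction(2, 2, np.array([0, 2]))

    def test_partial_function_flagged(self):
        f = FeatureFunction(3, 4, np.array([1, UNDEFINED, 0]))
        assert not f.is_total
        assert f.defined_mask.tolist() == [True, False, True]

    def test_total_constructor(self):
        f = total([0, 1, 2], 4)
        assert f.is_total and f.n_args == 3


class TestRegister:
    def test_first_registration_marks_exactly_hit_cells(self, empty_4x4):
        empty_4x4.register(total([0, 1, 2, 3], 4))
        expected = np.zeros((4, 4), dtype=int)
        expected[np.arange(4), np.arange(4)] = 1
        assert np.array_equal(empty_4x4.weights, expected)

    def test_repeated_registration_accumulates_and_stays_determinate(self):
        amr = WeightedAMR(4, 4)
        cue = total([3, 2, 1, 0], 4)
        for _ in range(5):
            amr.register(cue)
        assert amr.weights[np.arange(4), [3, 2, 1, 0]].tolist() == [5] * 4
        assert amr.entropy()[0] == 0.0

    def test_two_functions_generalize_to_four(self):
        amr = WeightedAMR(2, 2)
        amr.register(total([0, 0], 2))
        amr.register(total([1, 1], 2))
        assert np.array_equal(amr.weights, np.ones((2, 2), dtype=int))
        assert amr.count_functions(registered=2) == (4, 2)

    def test_partial_cue_skips_undefined_columns(self):
        amr = WeightedAMR(3, 2)
        amr.register(FeatureFunction(3, 2, np.array([0, UNDEFINED, 1])))
        assert amr.weights[1].sum() == 0
        assert amr.weights[0, 0] == 1 and amr.weights[2, 1] == 1

    def test_dimension_mismatch_rejected(self, empty_4x4):
        with pytest.raises(DimensionMismatchError):
            empty_4x4.register(total([0, 0], 2))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_registration_is_monotone(self, seed):
        rng = np.random.default_rng(seed)
        amr = random_amr(rng, 4, 4)
        before = amr.weights.copy()
        amr.register(random_cue(rng, 4, 4))
        assert (amr.weights >= before).all()


class TestEntropy:
    def test_uniform_column_is_log2_m(self):
        amr = WeightedAMR(1, 4, weights=np.array([[1, 1, 1, 1]]))
        assert amr.entropy()[0] == pytest.approx(2.0)

    def test_skewed_column(self):
        amr = WeightedAMR(1, 4, weights=np.array([[3, 1, 0, 0]]))
        expected = -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))
        assert amr.entropy()[0] == pytest.approx(expected)
        assert amr.entropy()[0] == pytest.approx(0.8112781244591)

    def test_single_function_any_multiplicity_has_zero_entropy(self):
        amr = WeightedAMR(3, 5)
        for _ in range(7):
            amr.register(total([4, 0, 2], 5))
        assert amr.entropy()[0] == 0.0

    def test_empty_register_has_zero_entropy(self, empty_4x4):
        e, stats = empty_4x4.entropy()
        assert e == 0.0
        assert all(s.weight_sum == 0 and s.omega == 0.0 for s in stats)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_entropy_bounds_and_column_normalization(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(1, 6)), int(rng.integers(1, 6))
        amr = random_amr(rng, n, m)
        e, stats = amr.entropy()
        assert 0.0 <= e <= math.log2(m) + 1e-12
        for s in stats:
            if s.weight_sum > 0:
                assert s.p.sum() == pytest.approx(1.0)
                assert 0.0 <= s.entropy <= math.log2(m) + 1e-12
            else:
                assert not s.p.any()


class TestBasicEntropy:
    def test_empty_is_zero(self, empty_4x4):
        assert empty_4x4.basic_entropy() == 0.0

    def test_two_on_cells_per_column(self):
        amr = WeightedAMR(2, 4, weights=np.array([[1, 1, 0, 0], [0, 5, 2, 0]]))
        assert amr.basic_entropy() == pytest.approx(1.0)

    def test_ignores_weight_magnitudes(self):
        light = WeightedAMR(1, 4, weights=np.array([[1, 1, 0, 0]]))
        heavy = WeightedAMR(1, 4, weights=np.array([[3, 1, 0, 0]]))
        assert light.basic_entropy() == heavy.basic_entropy() == pytest.approx(1.0)


def enumerate_functions(amr: WeightedAMR) -> int:
    """Oracle: count stored functions by exhaustive enumeration of level
    assignments.  Empty columns are outside the relation's domain (the
    stored functions are undefined there), so they are skipped rather than
    zeroing the count — consistent with an empty column contributing no
    entropy."""
    active = [i for i in range(amr.n_cols) if amr.weights[i].any()]
    count = 0
    for combo in itertools.product(range(amr.n_rows), repeat=len(active)):
        if all(amr.weights[i, j] > 0 for i, j in zip(active, combo)):
            count += 1
    return count


class TestCountFunctions:
    def test_single_function(self):
        amr = WeightedAMR(3, 3)
        amr.register(total([0, 1, 2], 3))
        assert amr.count_functions(registered=1) == (1, 0)

    def test_full_table_is_m_to_the_n(self):
        amr = WeightedAMR(3, 4, weights=np.ones((3, 4), dtype=int))
        assert amr.count_functions()[0] == 4**3

    def test_inconsistent_registered_count_rejected(self):
        amr = WeightedAMR(2, 2)
        amr.register(total([0, 0], 2))
        with pytest.raises(ValueError):
            amr.count_functions(registered=5)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(1, 5)), int(rng.integers(1, 5))
        amr = random_amr(rng, n, m, density=float(rng.uniform(0.2, 1.0)))
        assert amr.count_functions()[0] == enumerate_functions(amr)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_equals_two_to_entropy_times_n_for_equal_weights(self, seed):
        # with equal non-zero weights per column the entropy is log2 of the
        # column support, so 2**(e*n) is exactly the function count
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(1, 5)), int(rng.integers(1, 6))
        w = (rng.random((n, m)) < 0.6).astype(int) * int(rng.integers(1, 9))
        amr = WeightedAMR(n, m, weights=w)
        e, _ = amr.entropy()
        assert 2 ** (e * n) == pytest.approx(amr.count_functions()[0], rel=1e-9)


class TestRecognize:
    def test_own_cue_accepted(self):
        amr = WeightedAMR(3, 4)
        cue = total([1, 2, 3], 4)
        amr.register(cue)
        res = amr.recognize(cue, RecognitionParams(iota=0.3))
        assert res.accepted
        assert res.rho == pytest.approx(1.0)
        assert res.omega_bar == pytest.approx(1.0)

    def test_kappa_rejects_weak_cue(self, two_function_2x2):
        res = two_function_2x2.recognize(
            total([1, 1], 2), RecognitionParams(iota=0.3, kappa=1.5)
        )
        assert res.per_arg_pass.all()  # 1 >= 0.3 * 2 per column
        assert res.rho == pytest.approx(1.0)
        assert res.omega_bar == pytest.approx(2.0)
        assert not res.accepted  # rho < kappa * Omega = 3

    def test_empty_register_rejects_everything(self, empty_4x4):
        res = empty_4x4.recognize(total([0, 1, 2, 3], 4), RecognitionParams())
        assert not res.accepted and res.failed_args == 4

    def test_zero_weight_cell_fails_even_at_iota_zero(self):
        amr = WeightedAMR(2, 2)
        amr.register(total([0, 0], 2))
        res = amr.recognize(total([0, 1], 2), RecognitionParams())
        assert not res.accepted and res.failed_args == 1

    def test_xi_relaxation_admits_failing_argument(self):
        amr = WeightedAMR(2, 2)
        amr.register(total([0, 0], 2))
        params = RecognitionParams(xi=1)
        assert amr.recognize(total([0, 1], 2), params).accepted

    def test_undefined_arguments_pass_vacuously(self):
        amr = WeightedAMR(3, 2)
        amr.register(total([0, 1, 0], 2))
        cue = FeatureFunction(3, 2, np.array([0, UNDEFINED, 0]))
        res = amr.recognize(cue, RecognitionParams())
        assert res.accepted
        assert res.rho == pytest.approx(2 / 3)  # undefined contributes 0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_acceptance_monotone_in_parameters(self, seed):
        rng = np.random.default_rng(seed)
        amr = random_amr(rng, 5, 4)
        cues = [random_cue(rng, 5, 4) for _ in range(12)]

        def accepted(params):
            return {
                k for k, c in enumerate(cues) if amr.recognize(c, params).accepted
            }

        base = RecognitionParams()
        for hi, lo in [
            (RecognitionParams(iota=0.8), RecognitionParams(iota=0.2)),
            (RecognitionParams(kappa=1.5), RecognitionParams(kappa=0.5)),
        ]:
            assert accepted(hi) <= accepted(lo) <= accepted(base)
        assert accepted(base) <= accepted(RecognitionParams(xi=2))


class TestRetrieve:
    def test_rejected_cue_returns_none(self, empty_4x4):
        out = empty_4x4.retrieve(
            total([0, 1, 2, 3], 4), RecognitionParams(), seed=0
        )
        assert out is None

    def test_sigma_zero_is_photographic(self):
        rng = np.random.default_rng(5)
        amr = random_amr(rng, 6, 5, density=1.0)
        cue = random_cue(rng, 6, 5)
        out = amr.retrieve(cue, RecognitionParams(sigma=0.0), seed=1)
        assert out == cue

    def test_single_function_register_echoes_cue_for_any_sigma(self):
        amr = WeightedAMR(4, 6)
        cue = total([0, 5, 2, 3], 6)
        amr.register(cue)
        for sigma in (0.0, 0.5, 3.0, 100.0):
            out = amr.retrieve(cue, RecognitionParams(sigma=sigma), seed=9)
            assert out == cue

    def test_partial_cue_filled_from_column_distribution(self):
        amr = WeightedAMR(2, 3)
        amr.register(total([0, 2], 3))
        cue = FeatureFunction(2, 3, np.array([0, UNDEFINED]))
        out = amr.retrieve(cue, RecognitionParams(), seed=3)
        assert out is not None and out.assignment.tolist() == [0, 2]

    def test_fixed_seed_is_deterministic(self):
        rng = np.random.default_rng(11)
        amr = random_amr(rng, 6, 8, density=1.0)
        cue = random_cue(rng, 6, 8)
        params = RecognitionParams(sigma=2.0)
        a = amr.retrieve(cue, params, seed=42)
        b = amr.retrieve(cue, params, seed=42)
        assert a == b

    def test_large_sigma_sampling_matches_column_distribution(self):
        # Psi = [0.75, 0.25], flat kernel: level-0 frequency ~ 0.75
        amr = WeightedAMR(1, 2, weights=np.array([[3, 1]]))
        cue = total([0], 2)
        params = RecognitionParams(sigma=1e6)
        rng = np.random.default_rng(7)
        n = 10_000
        hits = sum(
            amr.retrieve(cue, params, seed=rng).assignment[0] == 0
            for _ in range(n)
        )
        se = math.sqrt(0.75 * 0.25 / n)
        assert abs(hits / n - 0.75) < 3 * se

    def test_sampling_matches_phi_by_chisquare(self):
        amr = WeightedAMR(1, 4, weights=np.array([[4, 3, 2, 1]]))
        cue = total([1], 4)
        sigma = 1.5
        params = RecognitionParams(sigma=sigma)
        psi = amr.column_stats()[0].p
        zeta = _discretized_normal(4, center=1, sigma=sigma)
        phi = psi * zeta
        phi /= phi.sum()
        rng = np.random.default_rng(123)
        n = 10_000
        counts = np.zeros(4)
        for _ in range(n):
            counts[amr.retrieve(cue, params, seed=rng).assignment[0]] += 1
        stat, p = chisquare(counts, phi * n)
        assert p > 0.001


class TestDiscretizedNormal:
    def test_point_mass_at_sigma_zero(self):
        z = _discretized_normal(5, center=2, sigma=0.0)
        assert z.tolist() == [0, 0, 1, 0, 0]

    def test_integrates_bins_and_peaks_at_center(self):
        z = _discretized_normal(7, center=3, sigma=1.0)
        assert np.argmax(z) == 3
        assert z.sum() <= 1.0  # tails outside the table are dropped
        assert z[2] == pytest.approx(z[4])
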