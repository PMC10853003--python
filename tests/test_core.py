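import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ldabf import (
    ConvergenceError,
    WindowConfig,
    fit_penalized_logistic,
    ld_abf_at_site,
    log_abf,
    logf_log_prior,
    matrix_from_arrays,
)
from ldabf.core import _log_abf_counts

from .oracles import numeric_mode, penalized_objective, table_vectors


class TestLogFPrior:
    def test_reference_values(self):
        assert logf_log_prior(0.0, 1.0) == pytest.approx(-math.log(2), abs=1e-12)
        assert logf_log_prior(0.0, 2.0) == pytest.approx(-2 * math.log(2), abs=1e-12)

    @given(beta=st.floats(-600, 600), m=st.floats(0, 10))
    def test_even_function_and_finite(self, beta, m):
        v = logf_log_prior(beta, m)
        assert math.isfinite(v)
        assert v == pytest.approx(logf_log_prior(-beta, m), rel=1e-12, abs=1e-9)


class TestPenalizedFit:
    def test_intercept_only_closed_form(self):
        fit = fit_penalized_logistic(None, [0, 0, 0, 0], m=1.0)
        assert fit.beta0 == pytest.approx(math.log(1 / 9), abs=1e-12)
        assert fit.objective == pytest.approx(
            penalized_objective([fit.beta0], None, [0, 0, 0, 0], 1.0), abs=1e-12
        )

    def test_symmetric_independent_case_mode_at_zero(self):
        fit = fit_penalized_logistic([0, 0, 1, 1], [0, 1, 0, 1], m=1.0)
        assert fit.beta0 == pytest.approx(0.0, abs=1e-9)
        assert fit.beta1 == pytest.approx(0.0, abs=1e-9)

    def test_perfect_separation_has_finite_positive_slope(self):
        x = np.array([0] * 5 + [1] * 5)
        fit = fit_penalized_logistic(x, x, m=1.0)
        assert math.isfinite(fit.beta1) and fit.beta1 > 0
        mode, obj = numeric_mode(x, x, 1.0)
        assert fit.beta0 == pytest.approx(mode[0], abs=1e-6)
        assert fit.beta1 == pytest.approx(mode[1], abs=1e-6)
        assert fit.objective == pytest.approx(obj, abs=1e-8)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            fit_penalized_logistic([0, 2, 1], [0, 1, 0], m=1.0)

    def test_ml_intercept_infinite_for_constant_outcome(self):
        with pytest.raises(ConvergenceError):
            fit_penalized_logistic(None, [1, 1, 1], m=0.0)

    @pytest.mark.parametrize(
        "s0,n0,s1,n1",
        [(1, 3, 2, 2), (0, 4, 4, 4), (2, 5, 1, 6), (0, 1, 0, 3), (3, 3, 0, 5)],
    )
    @pytest.mark.parametrize("m", [0.5, 1.0, 2.0])
    def test_augmented_newton_matches_direct_optimization(self, s0, n0, s1, n1, m):
        x, y = table_vectors(s0, n0, s1, n1)
        fit = fit_penalized_logistic(x, y, m=m)
        mode, obj = numeric_mode(x, y, m)
        assert fit.beta0 == pytest.approx(mode[0], abs=1e-6)
        assert fit.beta1 == pytest.approx(mode[1], abs=1e-6)
        assert fit.objective == pytest.approx(obj, abs=1e-8)


class TestLogAbf:
    def test_monomorphic_neighbor_is_uninformative(self):
        assert log_abf([0, 1, 0, 1], [0, 0, 0, 0], m=1.0) == 0.0
        assert log_abf([0, 1, 0, 1], [1, 1, 1, 1], m=1.0) == 0.0

    def test_symmetric_independent_pair(self):
        # both modes sit at zero; likelihoods cancel, one prior factor remains
        v = log_abf([0, 0, 1, 1], [0, 1, 0, 1], m=1.0)
        assert v == pytest.approx(-math.log(2), abs=1e-9)

    def test_perfect_ld_positive_and_matches_oracle(self):
        x = np.array([0] * 5 + [1] * 5)
        _, obj1 = numeric_mode(x, x, 1.0)
        _, obj0 = numeric_mode(None, x, 1.0)
        v = log_abf(x, x, m=1.0)
        assert v > 0
        assert v == pytest.approx(obj1 - obj0, abs=1e-8)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            log_abf([0, 1], [0, 1, 1], m=1.0)

    def test_finite_under_all_small_configurations(self):
        """Exhaustive tables up to n = 12: finite, and flipping the neighbor
        coding leaves the value unchanged (label symmetry)."""
        for n0, n1 in product(range(0, 13), repeat=2):
            if not 0 < n1 or n0 + n1 < 2 or n0 + n1 > 12 or n0 < 1:
                continue
            for s0, s1 in product(range(n0 + 1), range(n1 + 1)):
                v = _log_abf_counts(s0, n0, s1, n1, 1.0)
                assert math.isfinite(v)
                flipped = _log_abf_counts(n0 - s0, n0, n1 - s1, n1, 1.0)
                assert v == pytest.approx(flipped, abs=1e-7)

    def test_m_zero_reduces_to_likelihood_ratio(self):
        """With the prior removed the statistic is the log-likelihood ratio
        of the two logistic models (checked against statsmodels)."""
        import statsmodels.api as sm

        x, y = table_vectors(2, 6, 5, 8)
        v = log_abf(x, y, m=0.0)
        X1 = sm.add_constant(np.asarray(x, dtype=float))
        fit1 = sm.Logit(np.asarray(y, dtype=float), X1).fit(disp=0)
        fit0 = sm.Logit(np.asarray(y, dtype=float), np.ones((len(y), 1))).fit(disp=0)
        assert v == pytest.approx(fit1.llf - fit0.llf, abs=1e-6)

    def test_monotone_in_departure_from_independence(self):
        """At n = 20 with fixed marginals, the statistic grows as the
        haplotype count n11 moves away from its independence expectation,
        on each side of independence (positive and negative D; the two
        sides need not be exchangeable when the marginals differ)."""
        n = 20
        for nx, ny in [(10, 10), (8, 6), (4, 12), (5, 5), (2, 10)]:
            lo, hi = max(0, nx + ny - n), min(nx, ny)
            expected = nx * ny / n
            vals = {
                n11: _log_abf_counts(ny - n11, n - nx, n11, nx, 1.0)
                for n11 in range(lo, hi + 1)
            }
            above = sorted(k for k in vals if k >= expected)
            below = sorted((k for k in vals if k <= expected), reverse=True)
            for side in (above, below):
                for k1, k2 in zip(side, side[1:]):
                    assert vals[k2] >= vals[k1] - 1e-9, (nx, ny, k1, k2)


class TestWindowedScore:
    def test_no_neighbors_scores_zero(self):
        H = matrix_from_arrays(np.array([[1], [0], [1], [0]]), [5000])
        r = ld_abf_at_site(H, 0, WindowConfig(1000))
        assert r.score == 0.0 and r.n_neighbors == 0

    def test_score_is_sum_of_pair_values_over_width(self, toy_matrix):
        w = WindowConfig(1000)
        x = toy_matrix.column(1)
        expected = (
            log_abf(x, toy_matrix.column(0), 1.0)
            + log_abf(x, toy_matrix.column(2), 1.0)
        ) / 1000
        r = ld_abf_at_site(toy_matrix, 1, w)
        assert r.score == pytest.approx(expected, abs=1e-12)
        assert r.n_neighbors == 2

    def test_window_membership_closed_at_half_width(self):
        cols = np.array([[1, 1, 1], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        H = matrix_from_arrays(cols, [1000, 1500, 1501])
        r = ld_abf_at_site(H, 0, WindowConfig(1000))
        assert r.n_neighbors == 1  # 1500 included (|d| = 500), 1501 not

    def test_duplicating_positive_neighbor_never_decreases_score(self):
        x = np.array([0] * 5 + [1] * 5)
        y = x.copy()  # perfect LD: positive log-ABF
        H1 = matrix_from_arrays(np.column_stack([x, y]), [500, 600])
        H2 = matrix_from_arrays(np.column_stack([x, y, y]), [500, 600, 700])
        s1 = ld_abf_at_site(H1, 0).score
        s2 = ld_abf_at_site(H2, 0).score
        assert s2 >= s1

    def test_out_of_range_site(self, toy_matrix):
        with pytest.raises(IndexError):
            ld_abf_at_site(toy_matrix, 5)
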