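"""Weinstein tetrad analysis: forward model, inversion, EM MLE, bootstrap."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from flymeio.markers import CrossoverClassCounts
from flymeio.tetrad import (
    TetradDistribution,
    TetradMLE,
    bootstrap_tetrad_ci,
    chromatid_class_probs,
    map_length_from_classes,
    tetrad_mle,
    transmission_matrix,
    weinstein_invert,
)

CONTROL = CrossoverClassCounts({0: 879, 1: 779, 2: 62, 3: 1})
RNAI = CrossoverClassCounts({0: 1131, 1: 569, 2: 80, 3: 2})


def random_simplex(rng, size, floor=0.0):
    x = rng.dirichlet(np.ones(size))
    x = floor + (1 - size * floor) * x
    return x / x.sum()


class TestForwardModel:
    @pytest.mark.parametrize(
        "E, f",
        [
            ([1, 0, 0, 0], [1, 0, 0, 0]),
            ([0, 1, 0, 0], [0.5, 0.5, 0, 0]),
            ([0, 0, 0, 1], [0.125, 0.375, 0.375, 0.125]),
        ],
    )
    def test_single_rank_chromatid_probs(self, E, f):
        np.testing.assert_allclose(chromatid_class_probs(np.array(E)), f)

    def test_columns_of_transmission_matrix_sum_to_one(self):
        A = transmission_matrix(6)
        np.testing.assert_allclose(A.sum(axis=0), np.ones(7))

    def test_negative_E_rejected(self):
        with pytest.raises(ValueError):
            chromatid_class_probs(np.array([1.2, -0.2]))


class TestInversion:
    def test_rank1_inverse(self):
        inv = weinstein_invert(np.array([0.5, 0.5, 0, 0]))
        np.testing.assert_allclose(inv.E, [0, 1, 0, 0], atol=1e-12)
        assert inv.valid

    def test_control_counts_reproduce_published_exchange_ranks(self):
        f = np.array(CONTROL.fractions())
        inv = weinstein_invert(f)
        assert inv.valid
        # hand back-substitution: E3 = 8/1721, E2 = 4(62/1721 - 3E3/8), ...
        np.testing.assert_allclose(
            inv.E, [0.0935503, 0.7646717, 0.1371296, 0.0046485], atol=1e-7
        )
        # and agreement with the published 4-decimal presentation
        np.testing.assert_allclose(
            inv.E, [0.0935, 0.7647, 0.1372, 0.0046], atol=1e-3
        )

    def test_invalid_inversion_flagged(self):
        inv = weinstein_invert(np.array([0.9, 0.05, 0.05, 0.0]))
        np.testing.assert_allclose(inv.E, [0.9, -0.1, 0.2, 0.0], atol=1e-12)
        assert not inv.valid

    @given(st.integers(0, 2**32 - 1), st.integers(1, 6))
    def test_roundtrip_forward_then_invert(self, seed, max_rank):
        rng = np.random.default_rng(seed)
        E = random_simplex(rng, max_rank + 1)
        f = chromatid_class_probs(E)
        np.testing.assert_allclose(weinstein_invert(f).E, E, atol=1e-10)


class TestMLE:
    def test_all_nco_gives_rank_zero(self):
        fit = tetrad_mle(CrossoverClassCounts({0: 1000}))
        np.testing.assert_allclose(fit.E_hat.E, [1.0])

    @pytest.mark.parametrize(
        "counts, expected",
        [
            (CONTROL, [0.0935, 0.7647, 0.1372, 0.0046]),
            (RNAI, [0.3591, 0.4659, 0.1661, 0.0090]),
        ],
    )
    def test_published_exchange_ranks(self, counts, expected):
        fit = tetrad_mle(counts, max_rank=3)
        assert fit.converged
        np.testing.assert_allclose(fit.E_hat.E, expected, atol=1e-3)

    def test_half_sco_recovers_pure_rank_one(self):
        fit = tetrad_mle(CrossoverClassCounts({0: 500, 1: 500}), max_rank=1)
        np.testing.assert_allclose(fit.E_hat.E, [0, 1], atol=1e-8)

    def test_loglik_monotone_nondecreasing(self):
        fit = tetrad_mle(RNAI, max_rank=3)
        diffs = np.diff(fit.loglik_path)
        assert (diffs >= -1e-9).all()

    def test_interior_mle_equals_inversion_on_exact_fractions(self):
        # 50 random interior E: supply exact expected counts, the MLE must
        # coincide with the (non-negative) direct inversion
        rng = np.random.default_rng(2024)
        for _ in range(50):
            E = random_simplex(rng, 4, floor=0.02)
            f = chromatid_class_probs(E)
            fit = tetrad_mle(f * 1_000_000, max_rank=3)
            np.testing.assert_allclose(fit.E_hat.E, E, atol=1e-6)

    def test_mle_nonnegative_and_beats_clipped_inversion_when_invalid(self):
        # class fractions whose inversion leaves the simplex
        f = np.array([0.9, 0.05, 0.05, 0.0])
        counts = (f * 2000).astype(int)
        inv = weinstein_invert(f)
        assert not inv.valid
        fit = tetrad_mle(counts, max_rank=3)
        assert (fit.E_hat.E >= 0).all()
        assert fit.boundary
        clipped = np.clip(inv.E, 0, None)
        clipped /= clipped.sum()
        f_clip = chromatid_class_probs(clipped)
        with np.errstate(divide="ignore"):
            ll_clipped = np.where(counts > 0, counts * np.log(f_clip), 0.0).sum()
        assert fit.log_likelihood >= ll_clipped - 1e-9

    def test_max_rank_below_observed_rejected(self):
        with pytest.raises(ValueError):
            tetrad_mle(CONTROL, max_rank=2)

    def test_sklearn_param_interface(self):
        est = TetradMLE(max_rank=3)
        assert est.get_params()["max_rank"] == 3
        est.set_params(max_iter=10)
        assert est.max_iter == 10

    def test_recovery_bias_at_study_sample_size(self):
        # 200 multinomial datasets of N=1721 chromatids from a control-like
        # exchange distribution: mean estimate within 0.02 of truth per rank
        E = np.array([0.09, 0.77, 0.14, 0.00])
        f = chromatid_class_probs(E)
        rng = np.random.default_rng(1721)
        draws = rng.multinomial(1721, f, size=200)
        ests = np.array(
            [tetrad_mle(d, max_rank=3).E_hat.E for d in draws]
        )
        assert (np.abs(ests.mean(axis=0) - E) < 0.02).all()


class TestMapLength:
    def test_control_total(self):
        assert round(map_length_from_classes(CONTROL), 1) == 52.6

    @pytest.mark.parametrize("counts, cm", [({0: 50}, 0.0), ({3: 7}, 300.0)])
    def test_pure_class_limits(self, counts, cm):
        assert map_length_from_classes(CrossoverClassCounts(counts)) == cm


class TestBootstrap:
    def test_intervals_contain_point_mle(self):
        ci = bootstrap_tetrad_ci(CONTROL, reps=500, seed=11)
        assert (ci.lower <= ci.point + 1e-9).all()
        assert (ci.upper >= ci.point - 1e-9).all()

    def test_degenerate_single_class_collapses(self):
        with pytest.warns(RuntimeWarning, match="collapse"):
            ci = bootstrap_tetrad_ci(CrossoverClassCounts({0: 500}),
                                     reps=200, seed=1)
        assert ci.degenerate
        np.testing.assert_allclose(ci.lower, ci.upper)

    def test_seed_determinism(self):
        a = bootstrap_tetrad_ci(CONTROL, reps=300, seed=3)
        b = bootstrap_tetrad_ci(CONTROL, reps=300, seed=3)
        np.testing.assert_array_equal(a.lower, b.lower)
        np.testing.assert_array_equal(a.upper, b.upper)

    def test_widths_shrink_with_quadrupled_sample(self):
        big = CrossoverClassCounts({k: 4 * v for k, v in CONTROL.counts.items()})
        small_ci = bootstrap_tetrad_ci(CONTROL, reps=600, seed=8)
        big_ci = bootstrap_tetrad_ci(big, reps=600, seed=8)
        w_small = small_ci.upper - small_ci.lower
        w_big = big_ci.upper - big_ci.lower
        # quadrupling N should roughly halve widths; allow slack
        assert (w_big < 0.75 * w_small + 1e-3).all()

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_tetrad_ci(CONTROL, reps=10, seed=0)


class TestTetradDistribution:
    def test_simplex_enforced(self):
        with pytest.raises(ValueError):
            TetradDistribution(E=np.array([0.5, 0.4]))

    def test_validity_flag_reflects_negative_entries(self):
        d = TetradDistribution(E=np.array([1.2, -0.2]), valid=True)
        assert not d.valid
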