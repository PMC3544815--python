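"""Bayesian decoding: posterior matrices, alpha distances, ML decoding, 2AFC."""

import numpy as np
import pytest

import vretina as vr
from vretina.decode import (
    check_disjoint,
    contrast_sensitivity,
    fraction_correct,
    js_alpha,
    kl_alpha,
    mse_alpha,
    posterior_matrix,
    split_half,
)
from vretina.info import BinnedResponse, RateProfiles


def _random_posterior(n, seed):
    rng = np.random.default_rng(seed)
    Q = rng.random((n, n))
    return Q / Q.sum(axis=1, keepdims=True)


class TestPosteriorMatrix:
    def test_perfectly_discriminating_profiles_give_identity(self):
        u = np.diag([40.0, 40.0, 40.0]) + 0.0
        prof = RateProfiles(u=u, dt=0.25, labels=list("abc"))
        counts = np.tile((u * 1).astype(int)[None], (5, 1, 1))
        test = BinnedResponse(counts, 0.25, list("abc"))
        Q = posterior_matrix(prof, test).Q
        np.testing.assert_allclose(Q, np.eye(3), atol=1e-6)

    def test_identical_profiles_give_uniform_rows(self):
        u = np.tile(np.array([1.0, 0.5]), (4, 1))
        prof = RateProfiles(u=u, dt=0.5, labels=list("abcd"))
        rng = np.random.default_rng(0)
        test = BinnedResponse(rng.poisson(u, size=(6, 4, 2)), 0.5, list("abcd"))
        Q = posterior_matrix(prof, test).Q
        np.testing.assert_allclose(Q, 0.25, atol=1e-9)

    def test_two_stimulus_hand_bayes(self):
        # one bin, u = (1, 2), observed count 0:
        # posterior = (e^-1, e^-2) / (e^-1 + e^-2)
        prof = RateProfiles(u=np.array([[1.0], [2.0]]), dt=1.0, labels=["a", "b"])
        test = BinnedResponse(np.zeros((1, 2, 1), dtype=int), 1.0, ["a", "b"])
        Q = posterior_matrix(prof, test).Q
        expected = np.exp(-1) / (np.exp(-1) + np.exp(-2))
        assert Q[0, 0] == pytest.approx(expected, abs=1e-9)
        assert Q[0, 0] == pytest.approx(0.731, abs=1e-3)

    def test_rows_sum_to_one(self, binned_responses):
        train, test = split_half(binned_responses, seed=0)
        Q = posterior_matrix(vr.rate_profiles(train), test).Q
        np.testing.assert_allclose(Q.sum(axis=1), 1.0, atol=1e-9)

    def test_overlapping_train_test_rejected(self, binned_responses):
        train, test = split_half(binned_responses, seed=0)
        with pytest.raises(ValueError, match="overlap"):
            check_disjoint(train, train)
        check_disjoint(train, test)  # disjoint halves pass


class TestMseAlpha:
    def test_identical_matrices_give_zero(self):
        Q = _random_posterior(30, 1)
        assert mse_alpha(Q, Q, seed=0).alpha == 0.0

    def test_shuffled_matrix_scores_about_one(self):
        Q = _random_posterior(30, 2)
        vals = []
        for s in range(40):
            rng = np.random.default_rng(100 + s)
            Qp = np.stack([rng.permutation(row) for row in Q])
            vals.append(mse_alpha(Qp, Q, n_shuffles=60, seed=s).alpha)
        assert np.mean(vals) == pytest.approx(1.0, abs=0.05)

    def test_values_above_one_not_clipped(self):
        # an anti-correlated model row is farther than a typical shuffle
        Q_real = np.array([[0.8, 0.15, 0.05, 0.0]])
        Q_model = np.array([[0.0, 0.05, 0.15, 0.8]])
        a = mse_alpha(Q_model, Q_real, n_shuffles=500, seed=3)
        assert a.alpha > 1.0

    def test_constant_rows_excluded(self):
        Q = np.full((3, 4), 0.25)
        a = mse_alpha(Q, np.full((3, 4), 0.25), seed=0)
        assert a.n_excluded_rows == 3
        assert np.isnan(a.per_row).all()


class TestKlAlpha:
    def test_identical_rows_give_zero(self):
        Q = _random_posterior(10, 5)
        assert kl_alpha(Q, Q).alpha == pytest.approx(0.0, abs=1e-12)

    def test_delta_vs_uniform_reaches_stimulus_entropy_unregularized(self):
        n = 30
        Q_real = np.zeros((n, n))
        Q_real[np.arange(n), np.arange(n)] = 1.0
        Q_model = np.full((n, n), 1.0 / n)
        a = kl_alpha(Q_model, Q_real, regularize=False)
        assert a.alpha == pytest.approx(np.log2(30), abs=1e-9)
        assert a.alpha == pytest.approx(4.9, abs=0.01)

    def test_plain_add_half_arithmetic(self):
        # delta row over 3 options with the counts-equivalent rule at n -> large
        # reduces to (q + 0.5) / (1 + 0.5 * N): (1,0,0) -> (0.6, 0.2, 0.2)
        from vretina.decode import _regularize_row

        row = np.array([1.0, 0.0, 0.0])
        big_n = 10**9
        reg = _regularize_row(row, big_n) * (big_n + 1.5) / big_n
        plain = (row + 0.5) / (1 + 0.5 * 3)
        np.testing.assert_allclose(plain, [0.6, 0.2, 0.2])
        np.testing.assert_allclose(_regularize_row(row, big_n),
                                   [1.0, 0.0, 0.0], atol=1e-6)

    def test_regularization_keeps_divergence_finite_with_zeros(self):
        Q_real = np.array([[1.0, 0.0], [0.0, 1.0]])
        Q_model = np.array([[0.0, 1.0], [1.0, 0.0]])
        a = kl_alpha(Q_model, Q_real, n_trials=25)
        assert np.isfinite(a.alpha)


class TestJsAlpha:
    def test_identical_rows_give_zero(self):
        Q = _random_posterior(8, 6)
        assert js_alpha(Q, Q).alpha == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_delta_rows_reach_one_bit(self):
        Q_real = np.zeros((5, 5))
        Q_real[np.arange(5), np.arange(5)] = 1.0
        Q_model = np.roll(Q_real, 1, axis=1)
        assert js_alpha(Q_model, Q_real).alpha == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self):
        A, B = _random_posterior(6, 7), _random_posterior(6, 8)
        assert js_alpha(A, B).alpha == pytest.approx(js_alpha(B, A).alpha)

    def test_bounded_by_one(self):
        A, B = _random_posterior(12, 9), _random_posterior(12, 10)
        assert np.all(js_alpha(A, B).per_row <= 1.0 + 1e-12)


class TestFractionCorrect:
    def _chance_setup(self, n_opts, n_test, seed):
        rng = np.random.default_rng(seed)
        lam = rng.uniform(0.1, 0.6, 8)
        u = np.stack([rng.poisson(np.tile(lam, (40, 1))).mean(0)
                      for _ in range(n_opts)])
        labels = [f"o{i}" for i in range(n_opts)]
        prof = RateProfiles(u=u, dt=0.125, labels=labels)
        counts = rng.poisson(np.tile(lam, (n_test, n_opts, 1)))
        return prof, BinnedResponse(counts, 0.125, labels)

    def test_stimulus_independent_responses_decode_at_chance(self):
        prof, resp = self._chance_setup(7, 400, seed=0)
        rep = fraction_correct([prof], [resp])
        se = np.sqrt((1 / 7) * (6 / 7) / (400 * 7))
        assert rep.overall == pytest.approx(1 / 7, abs=4 * se)

    def test_noiseless_distinct_profiles_decode_perfectly(self):
        u = np.diag([30.0, 30.0, 30.0])
        prof = RateProfiles(u=u, dt=0.25, labels=list("abc"))
        counts = np.tile(u.astype(int)[None], (4, 1, 1))
        rep = fraction_correct([prof], [BinnedResponse(counts, 0.25, list("abc"))])
        assert rep.overall == 1.0

    def test_uninformative_cell_leaves_decoding_unchanged(self):
        prof, resp = self._chance_setup(4, 50, seed=1)
        u_good = np.diag([25.0, 25.0, 25.0, 25.0])
        prof_good = RateProfiles(u=np.hstack([u_good, u_good]), dt=0.125,
                                 labels=prof.labels)
        rng = np.random.default_rng(2)
        counts_good = rng.poisson(
            np.hstack([u_good, u_good])[None].repeat(50, axis=0))
        resp_good = BinnedResponse(counts_good, 0.125, prof.labels)
        flat = RateProfiles(u=np.tile(prof.u[0], (4, 1)), dt=0.125,
                            labels=prof.labels)
        alone = fraction_correct([prof_good], [resp_good])
        with_flat = fraction_correct([prof_good, flat], [resp_good, resp])
        np.testing.assert_allclose(alone.per_stimulus, with_flat.per_stimulus)

    def test_label_mismatch_rejected(self):
        prof, resp = self._chance_setup(3, 10, seed=3)
        bad = RateProfiles(u=prof.u, dt=0.125, labels=["x", "y", "z"])
        with pytest.raises(ValueError):
            fraction_correct([bad], [resp])


@pytest.fixture(scope="module")
def curves(small_population):
    on_cells = [c for c in small_population if c.polarity == "ON"]
    return contrast_sensitivity(
        on_cells, temporal_freqs=[2.0],
        contrasts=[1.0, 0.5, 0.12, 0.0], n_trials=200, seed=4)


class TestContrastSensitivity:

    def test_zero_contrast_performs_at_chance(self, curves):
        fc0 = curves[0].fraction_correct[-1]  # contrast grid is descending
        assert fc0 == pytest.approx(0.5, abs=0.12)

    def test_full_contrast_near_perfect_for_responsive_population(self, curves):
        assert curves[0].fraction_correct[0] > 0.9

    def test_threshold_uses_75_percent_criterion(self, curves):
        c = curves[0]
        assert c.criterion == 0.75
        if c.threshold is not None:
            i = np.flatnonzero(c.contrasts == c.threshold)[0]
            assert c.fraction_correct[i] >= 0.75
            assert c.sensitivity == pytest.approx(1.0 / c.threshold)
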