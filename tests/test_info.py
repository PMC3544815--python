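"""Information metrics: binning, Poisson likelihoods, MI estimators, debiasing."""

import numpy as np
import pytest

import vretina as vr
from vretina import stimulus as stim
from vretina.info import (
    BinnedResponse,
    RateProfiles,
    _mi_exact,
    bin_counts,
    debias_quadratic,
    mutual_information_poisson,
    mutual_information_quartile,
    rate_profiles,
    response_log_prob,
)


def _mini_stream_labels():
    """Two 1 s segments with 333 ms gray separators at 15 Hz."""
    labels = (["GRAY"] * 5 + ["a"] * 15 + ["GRAY"] * 5 + ["b"] * 15 + ["GRAY"] * 5)
    return np.array(labels, dtype=object)


class TestBinCounts:
    def test_quarter_second_bins_give_four_bins(self):
        labels = _mini_stream_labels()
        raster = vr.SpikeRaster(trials=[np.array([0.5])], duration=labels.size / 15)
        binned = bin_counts(raster, labels, 0.25)
        assert binned.n_bins == 4 and binned.n_stim == 2

    def test_half_open_bin_boundaries(self):
        labels = _mini_stream_labels()
        t0 = 5 / 15.0  # onset of segment 'a'
        spikes = np.sort(np.array([t0 + 0.10, t0 + 0.25]))
        raster = vr.SpikeRaster(trials=[spikes], duration=labels.size / 15)
        binned = bin_counts(raster, labels, 0.25)
        np.testing.assert_array_equal(binned.counts[0, 0], [1, 1, 0, 0])

    def test_empty_raster_gives_zero_counts(self):
        labels = _mini_stream_labels()
        raster = vr.SpikeRaster(trials=[np.array([])], duration=labels.size / 15)
        assert bin_counts(raster, labels, 0.25).counts.sum() == 0

    def test_gray_spikes_excluded_segment_spikes_conserved(self):
        labels = _mini_stream_labels()
        t_a, t_b = 5 / 15.0, 25 / 15.0
        spikes = np.sort(np.array([0.1, t_a + 0.5, t_b + 0.2, t_b + 0.9]))
        raster = vr.SpikeRaster(trials=[spikes], duration=labels.size / 15)
        binned = bin_counts(raster, labels, 0.0625)
        assert binned.counts.sum() == 3  # the 0.1 s spike falls in gray

    def test_non_dividing_dt_rejected(self):
        labels = _mini_stream_labels()
        raster = vr.SpikeRaster(trials=[np.array([])], duration=labels.size / 15)
        with pytest.raises(ValueError):
            bin_counts(raster, labels, 0.3)


class TestRateProfiles:
    def test_mean_of_trials(self):
        counts = np.array([[[2, 0]], [[4, 0]]])  # two trials, one stimulus
        b = BinnedResponse(counts=counts, dt=0.5, labels=["s"])
        np.testing.assert_allclose(rate_profiles(b).u, [[3.0, 0.0]])

    def test_duplicated_trials_leave_mean_unchanged(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(1.0, size=(8, 3, 4))
        b1 = BinnedResponse(counts, 0.25, ["a", "b", "c"])
        b2 = BinnedResponse(np.concatenate([counts, counts]), 0.25, ["a", "b", "c"])
        np.testing.assert_allclose(rate_profiles(b1).u, rate_profiles(b2).u)


class TestResponseLogProb:
    @pytest.mark.parametrize(
        "n, u, expected",
        [
            ([0], [1.0], -1.0),
            ([0, 0], [1.0, 2.0], -3.0),
            ([2], [0.5], 2 * np.log(0.5) - 0.5 - np.log(2.0)),
        ],
    )
    def test_hand_values(self, n, u, expected):
        assert response_log_prob(np.array(n), np.array(u)) == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            response_log_prob(np.array([-1]), np.array([1.0]))


class TestMutualInformationPoisson:
    def test_identical_profiles_carry_no_information(self):
        u = np.tile(np.array([0.5, 1.0, 0.2]), (5, 1))
        prof = RateProfiles(u=u, dt=0.25, labels=list("abcde"))
        res = mutual_information_poisson(prof, seed=0)
        assert abs(res.value) < 1e-9

    def test_bounded_by_stimulus_entropy(self, binned_responses):
        prof = rate_profiles(binned_responses)
        res = mutual_information_poisson(prof, mc_samples=20_000, seed=1)
        assert -0.02 <= res.value <= np.log2(30) + 0.02

    def test_mc_matches_enumeration_on_two_stimulus_problem(self):
        u = np.array([[0.01], [8.0]])
        prof = RateProfiles(u=u, dt=1.0, labels=["lo", "hi"])
        exact = mutual_information_poisson(prof)
        assert exact.exact
        mc = mutual_information_poisson(prof, force_mc=True,
                                        mc_samples=50_000, seed=2)
        assert mc.value == pytest.approx(exact.value, abs=3 * mc.se)

    def test_merging_stimuli_never_increases_information(self):
        # data-processing inequality on an enumerable problem
        rng = np.random.default_rng(3)
        u = rng.uniform(0.05, 3.0, size=(4, 2))
        prof4 = RateProfiles(u=u, dt=0.5, labels=list("abcd"))
        i4 = mutual_information_poisson(prof4).value
        # merge stimuli a and b: mixture response under one label
        prior3 = np.array([0.5, 0.25, 0.25])
        caps = np.array([20, 20])
        u3 = np.stack([u[0], u[2], u[3]])
        # exact MI for the merged ensemble, mixture handled by averaging
        # conditionals of the two merged members
        from scipy.special import gammaln, logsumexp

        grids = np.meshgrid(*[np.arange(c + 1) for c in caps], indexing="ij")
        R = np.stack([g.ravel() for g in grids], axis=1)

        def logpois(r, uu):
            return (r * np.log(uu) - uu - gammaln(r + 1.0)).sum(axis=1)

        cond = [
            np.log(0.5 * np.exp(logpois(R, u[0])) + 0.5 * np.exp(logpois(R, u[1]))),
            logpois(R, u[2]),
            logpois(R, u[3]),
        ]
        cond = np.stack(cond)
        log_pr = logsumexp(cond + np.log(prior3)[:, None], axis=0)
        i3 = sum(
            prior3[s] * np.sum(np.exp(cond[s]) * (cond[s] - log_pr))
            for s in range(3)
        ) / np.log(2)
        assert i3 <= i4 + 1e-9

    def test_unbiased_against_oracle_on_random_small_problems(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            u = rng.uniform(0.02, 5.0, size=(rng.integers(2, 5), rng.integers(1, 3)))
            labels = [str(i) for i in range(u.shape[0])]
            prof = RateProfiles(u=u, dt=0.25, labels=labels)
            exact = mutual_information_poisson(prof)
            mc = mutual_information_poisson(prof, force_mc=True,
                                            mc_samples=20_000,
                                            seed=int(rng.integers(2**31)))
            assert mc.value == pytest.approx(exact.value, abs=3 * mc.se)


class TestMutualInformationQuartile:
    def test_noiseless_distinct_patterns_reach_label_entropy(self):
        # four stimuli coded deterministically by distinct level patterns
        patterns = np.array([[0, 0], [1, 0], [2, 1], [3, 3]])
        counts = np.tile(patterns[None], (10, 1, 1))
        b = BinnedResponse(counts, 0.5, list("abcd"))
        res = mutual_information_quartile(b, debias=False, seed=0)
        assert res.value == pytest.approx(2.0, abs=1e-9)

    def test_all_zero_counts_carry_no_information(self):
        b = BinnedResponse(np.zeros((6, 3, 4), dtype=int), 0.25, list("abc"))
        assert mutual_information_quartile(b, debias=False).value == 0.0

    def test_single_trial_rejected(self):
        b = BinnedResponse(np.zeros((1, 2, 2), dtype=int), 0.5, list("ab"))
        with pytest.raises(ValueError):
            mutual_information_quartile(b)

    def test_agrees_with_poisson_estimator_on_matched_simulation(
            self, binned_responses):
        prof = rate_profiles(binned_responses)
        mi_p = mutual_information_poisson(prof, mc_samples=30_000, seed=4)
        mi_q = mutual_information_quartile(binned_responses, seed=5)
        assert mi_q.value == pytest.approx(mi_p.value, rel=0.15)

    def test_debiased_value_not_above_plugin(self, binned_responses):
        # plug-in MI has positive small-sample bias
        plug = mutual_information_quartile(binned_responses, debias=False, seed=6)
        deb = mutual_information_quartile(binned_responses, seed=6)
        assert deb.value <= plug.value + 0.05


class TestDebiasQuadratic:
    def test_recovers_exact_quadratic(self):
        # values on I(x) = 2 + x + 0.5 x^2 at x in {0.1, 0.2, 0.4}
        fractions = np.array([1.0, 0.5, 0.25])
        x = 1.0 / (fractions * 10)
        values = 2.0 + x + 0.5 * x**2
        assert debias_quadratic(fractions, values, 10) == pytest.approx(2.0)

    def test_constant_values_returned_unchanged(self):
        assert debias_quadratic([1.0, 0.5, 0.25], [1.7, 1.7, 1.7], 20) == (
            pytest.approx(1.7))

    def test_fewer_than_three_fractions_rejected(self):
        with pytest.raises(ValueError):
            debias_quadratic([1.0, 0.5], [1.0, 1.1], 20)
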