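import numpy as np
import pytest

from ssapipe.exceptions import ConfigError
from ssapipe.stimulus import make_train
from ssapipe.synth import (
    LIGHT_OFF,
    LIGHT_ON,
    SynthParams,
    amplitude_sequence,
    generate_experiment,
    indicator_kernel,
    render_trial_movie,
    simulate_cohort_summaries,
)


class TestAmplitudeSequence:
    def test_first_tone_gets_a1_exactly(self, train_1hz):
        amps = amplitude_sequence(train_1hz, 0.08, 0.03, 3.0, 0.9)
        assert amps[0] == pytest.approx(0.08)

    def test_infinite_tau_means_no_adaptation(self, train_1hz):
        amps = amplitude_sequence(train_1hz, 0.08, 0.03, 1e12, 0.9)
        np.testing.assert_allclose(amps[:-1], 0.08)

    def test_tenth_standard_follows_the_decay_law(self, train_1hz):
        # a_inf + (a1 - a_inf) * exp(-9/tau) with a1=1, a_inf=0.4, tau=3
        amps = amplitude_sequence(train_1hz, 1.0, 0.4, 3.0, 0.9)
        assert amps[9] == pytest.approx(0.4 + 0.6 * np.exp(-3.0), abs=1e-12)

    def test_opto_gain_scales_standards_but_not_deviant(self, train_1hz):
        base = amplitude_sequence(train_1hz, 0.08, 0.03, 3.0, 0.9, opto_gain=1.0)
        mod = amplitude_sequence(train_1hz, 0.08, 0.03, 3.0, 0.9, opto_gain=0.7)
        np.testing.assert_allclose(mod[:-1], 0.7 * base[:-1])
        assert mod[-1] == base[-1]

    def test_monotone_adaptation(self, train_1hz):
        amps = amplitude_sequence(train_1hz, 0.08, 0.03, 2.0, 0.9)
        assert np.all(np.diff(amps[:-1]) < 0)

    def test_nonpositive_tau_rejected(self, train_1hz):
        with pytest.raises(ConfigError):
            amplitude_sequence(train_1hz, 0.08, 0.03, 0.0, 0.9)


class TestIndicatorKernel:
    def test_starts_at_zero_peaks_at_one(self):
        k = indicator_kernel(0.04, 0.4, 20.0, 3.0)
        assert k[0] == 0.0
        assert k.max() <= 1.0 + 1e-12
        # sampled peak sits within 1% of the analytic unit peak
        assert k.max() > 0.99

    def test_tail_decays_away(self):
        k = indicator_kernel(0.04, 0.4, 20.0, 4.0)  # 10 decay constants
        assert k[-1] < 0.01

    def test_tau_ordering_enforced(self):
        with pytest.raises(ConfigError):
            indicator_kernel(0.5, 0.4, 20.0, 2.0)


class TestRenderTrialMovie:
    def test_no_response_no_noise_gives_flat_baseline(self, train_1hz):
        params = SynthParams(
            image_shape=(20, 30),
            blob_centers=((10.0, 8.0), (10.0, 22.0)),
            blob_sigma_px=3.0,
            a1=0.0,
            a_inf=0.0,
            noise_sd=0.0,
            anatomy_amp=0.0,
            bleach_tau_s=1e12,
        )
        movie, truth = render_trial_movie(train_1hz, params)
        np.testing.assert_allclose(movie.frames, params.baseline_f0, rtol=1e-9)
        np.testing.assert_allclose(truth.amp_sequence[:-1], 0.0)

    def test_single_tone_peak_dff_matches_injected_amplitude(self):
        train = make_train(1.0, 1, 8000.0, 16000.0)
        params = SynthParams(
            image_shape=(40, 60),
            blob_centers=((20.0, 15.0), (20.0, 45.0)),
            blob_sigma_px=6.0,
            a1=0.1,
            a_inf=0.1,
            dev_gain=1e-9,
            noise_sd=0.0,
            anatomy_amp=0.0,
            bleach_tau_s=1e12,
        )
        movie, truth = render_trial_movie(train, params)
        center = movie.frames[:, 20, 15]
        baseline = center[movie.times_s < 0].mean()
        dff = (center - baseline) / baseline
        # kernel discretization error at 20 fps is below 1%
        assert dff.max() == pytest.approx(0.1, rel=0.01)

    def test_same_seed_is_bit_identical(self, small_params, train_1hz):
        m1, _ = render_trial_movie(train_1hz, small_params, seed=99)
        m2, _ = render_trial_movie(train_1hz, small_params, seed=99)
        assert np.array_equal(m1.frames, m2.frames)

    def test_different_seed_changes_noise(self, small_params, train_1hz):
        m1, _ = render_trial_movie(train_1hz, small_params, seed=1)
        m2, _ = render_trial_movie(train_1hz, small_params, seed=2)
        assert not np.array_equal(m1.frames, m2.frames)

    def test_unknown_condition_rejected(self, small_params, train_1hz):
        with pytest.raises(ConfigError):
            render_trial_movie(train_1hz, small_params, condition="light-maybe")


class TestGenerateExperiment:
    def test_trial_counting_and_interleaving(self, small_params):
        records = generate_experiment(
            small_params, rates=(1.0, 2.0, 4.0), n_trials_per_condition=2
        )
        assert len(records) == 12
        by_cond = [r.condition for r in records[:4]]
        assert by_cond == [LIGHT_OFF, LIGHT_ON, LIGHT_OFF, LIGHT_ON]
        assert all(r.inter_trial_gap_s >= 30.0 for r in records)

    def test_no_light_effect_means_identical_amplitude_laws(self, small_params):
        records = generate_experiment(
            small_params, rates=(1.0,), n_trials_per_condition=1
        )
        off = next(r for r in records if r.condition == LIGHT_OFF)
        on = next(r for r in records if r.condition == LIGHT_ON)
        np.testing.assert_allclose(off.truth.amp_sequence, on.truth.amp_sequence)

    @pytest.mark.parametrize("bad", [dict(rates=()), dict(n_trials_per_condition=0)])
    def test_bad_experiment_requests_rejected(self, small_params, bad):
        kwargs = dict(rates=(1.0,), n_trials_per_condition=1)
        kwargs.update(bad)
        with pytest.raises(ConfigError):
            generate_experiment(small_params, **kwargs)


def test_cohort_summaries_shape_and_reproducibility(small_params):
    c1 = simulate_cohort_summaries(3, rates=(1.0, 4.0), params=small_params, seed=5)
    c2 = simulate_cohort_summaries(3, rates=(1.0, 4.0), params=small_params, seed=5)
    assert set(c1) == {1.0, 4.0}
    assert len(c1[1.0]) == 3
    off, on, labels = c1[1.0][0]
    assert off.amps.size == len(labels) == 11
    np.testing.assert_allclose(off.amps, c2[1.0][0][0].amps)
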