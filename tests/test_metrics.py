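import numpy as np
import pytest

from ssapipe.exceptions import ConfigError, DataError, InsufficientDataError
from ssapipe.metrics import (
    adaptation_difference,
    deviance_difference,
    fit_adaptation_decay,
    opto_modulation_index,
    summarize_recording,
)
from ssapipe.quantify import (
    TO_FIRST_CONTROL,
    TO_MATCHED_CONTROL,
    NormalizedResponses,
    TrialAmplitudes,
)
from ssapipe.synth import LIGHT_OFF, LIGHT_ON

LABELS = ("standard",) * 10 + ("deviant",)


def norm_of(values, scheme=TO_FIRST_CONTROL):
    return NormalizedResponses(values, LABELS, scheme)


class TestAdaptationDifference:
    def test_no_adaptation_gives_zero(self):
        assert adaptation_difference(norm_of([1.0] * 11)) == 0.0

    def test_decayed_train(self):
        values = list(np.linspace(1.0, 0.4, 10)) + [0.9]
        assert adaptation_difference(norm_of(values)) == pytest.approx(-0.6)

    def test_requires_first_control_scheme(self):
        with pytest.raises(ConfigError):
            adaptation_difference(norm_of([1.0] * 11, TO_MATCHED_CONTROL))

    def test_requires_ten_standards(self):
        short = NormalizedResponses([1.0] * 6, ("standard",) * 5 + ("deviant",), TO_FIRST_CONTROL)
        with pytest.raises(InsufficientDataError):
            adaptation_difference(short)


class TestDevianceDifference:
    def test_deviant_equal_to_tenth_standard_gives_zero(self):
        values = [1.0] * 9 + [0.4, 0.4]
        assert deviance_difference(norm_of(values)) == 0.0

    def test_enhanced_deviant(self):
        values = [1.0] * 9 + [0.4, 0.9]
        assert deviance_difference(norm_of(values)) == pytest.approx(0.5)

    def test_missing_deviant_label_is_an_error(self):
        all_std = NormalizedResponses([1.0] * 11, ("standard",) * 11, TO_FIRST_CONTROL)
        with pytest.raises(DataError):
            deviance_difference(all_std)


def test_adaptation_plus_deviance_telescopes(rng):
    values = np.abs(rng.normal(1, 0.3, 11)) + 0.1
    n = norm_of(values)
    total = adaptation_difference(n) + deviance_difference(n)
    assert total == pytest.approx(values[-1] - values[0], abs=1e-12)


class TestOptoModulation:
    def _pair(self, factor):
        off = TrialAmplitudes(np.linspace(1.0, 0.4, 11), LABELS, 1.0, LIGHT_OFF)
        on = TrialAmplitudes(off.amps * factor, LABELS, 1.0, LIGHT_ON)
        return on, off

    def test_identical_conditions_give_unity(self):
        on, off = self._pair(1.0)
        assert opto_modulation_index(on, off) == pytest.approx(1.0)

    def test_uniform_suppression_recovered(self):
        on, off = self._pair(0.8)
        assert opto_modulation_index(on, off) == pytest.approx(0.8)

    def test_scale_invariance(self, rng):
        off = TrialAmplitudes(np.abs(rng.normal(1, 0.2, 11)) + 0.1, LABELS, 1.0, LIGHT_OFF)
        on = TrialAmplitudes(np.abs(rng.normal(0.8, 0.2, 11)) + 0.1, LABELS, 1.0, LIGHT_ON)
        base = opto_modulation_index(on, off)
        scaled = opto_modulation_index(
            TrialAmplitudes(on.amps * 3.7, LABELS, 1.0, LIGHT_ON),
            TrialAmplitudes(off.amps * 3.7, LABELS, 1.0, LIGHT_OFF),
        )
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_deviant_is_excluded_from_the_index(self):
        on, off = self._pair(1.0)
        boosted = TrialAmplitudes(
            np.concatenate([on.amps[:-1], [on.amps[-1] * 5]]), LABELS, 1.0, LIGHT_ON
        )
        assert opto_modulation_index(boosted, off) == pytest.approx(1.0)

    def test_ratio_of_means_variant(self):
        on, off = self._pair(0.8)
        assert opto_modulation_index(on, off, method="ratio_of_means") == pytest.approx(0.8)

    def test_zero_control_is_an_error(self):
        off = TrialAmplitudes(np.zeros(11), LABELS, 1.0, LIGHT_OFF)
        on = TrialAmplitudes(np.ones(11), LABELS, 1.0, LIGHT_ON)
        with pytest.raises(DataError):
            opto_modulation_index(on, off)


class TestDecayFit:
    def test_exact_exponential_recovered_to_machine_precision(self):
        n = np.arange(10)
        values = list(0.4 + 0.6 * np.exp(-n / 3.0)) + [0.9]
        fit = fit_adaptation_decay(norm_of(values))
        assert fit.a1_hat == pytest.approx(1.0, abs=1e-6)
        assert fit.a_inf_hat == pytest.approx(0.4, abs=1e-6)
        assert fit.tau_hat == pytest.approx(3.0, abs=1e-6)
        assert fit.rss < 1e-12

    def test_constant_input_flags_tau_unidentifiable(self):
        fit = fit_adaptation_decay(norm_of([0.7] * 11))
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        assert not fit.tau_identifiable

    def test_noisy_recordings_recover_tau_within_fifteen_percent(self, rng):
        # each replicate is a recording: the 5-trial average of curves with
        # per-trial noise SD 0.05, the quantity the pipeline feeds the fit
        n = np.arange(10)
        clean = 0.4 + 0.6 * np.exp(-n / 3.0)
        errors = []
        for _ in range(20):
            avg = np.clip(
                clean + rng.normal(0, 0.05, (5, 10)).mean(axis=0), 1e-3, None
            )
            fit = fit_adaptation_decay(norm_of(list(avg) + [0.9]))
            errors.append(abs(fit.tau_hat - 3.0) / 3.0)
        assert np.median(errors) < 0.15


def test_summarize_recording_combines_all_indices():
    off = TrialAmplitudes(np.linspace(1.0, 0.4, 10).tolist() + [0.9], LABELS, 1.0, LIGHT_OFF, n_trials=5)
    on = TrialAmplitudes(off.amps * 0.7, LABELS, 1.0, LIGHT_ON, n_trials=5)
    s = summarize_recording(off, on)
    assert s.adaptation_diff == pytest.approx(-0.6)
    assert s.deviance_diff == pytest.approx(0.5)
    assert s.opto_modulation == pytest.approx(0.7)
    assert s.n_trials_used == 10
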