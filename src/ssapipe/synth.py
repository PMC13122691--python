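"""Synthetic widefield GCaMP movie generator with recorded ground truth.

Every stage of the quantification pipeline is validated against movies built
here, because the generator records exactly what it injected: the per-tone
response amplitudes, the light-on modulation factor, the indicator kernel and
the noise model.

Model
-----
A trial movie is

    F(t, x, y) = F0 * bleach(t) * [1 + G(x, y) * sum_n A_n * k(t - onset_n)]
                 + eps(t, x, y)

where ``G`` is a two-blob Gaussian response footprint (the A1 and AAF
low-frequency tonotopic fields), ``k`` is a difference-of-exponentials
indicator kernel normalized to unit peak, ``bleach`` is a slow multiplicative
exponential photobleach, and ``eps`` is i.i.d. Gaussian camera noise on raw
fluorescence.  Negative values after noise are clipped at zero and logged.

The per-tone amplitude law is exponential adaptation in tone index with an
asymptote, an enlarged deviant response, and a multiplicative light-on factor
applied to standard tones only (light-on does not alter the deviant response
by default):

    A_n(standard) = g_opto * (a_inf + (a1 - a_inf) * exp(-(n - 1) / tau))
    A(deviant)    = a1 * dev_gain
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigError, DataError
from .stimulus import DEVIANT, STANDARD, StimulusTrain, make_train

logger = logging.getLogger(__name__)

LIGHT_OFF = "light-off"
LIGHT_ON = "light-on"

#: adaptation decay constant (tones) per repetition rate; faster rates adapt
#: harder, reproducing the ordering of first-minus-tenth differences.
DEFAULT_TAU_TONES = {1.0: 5.0, 2.0: 2.5, 4.0: 1.25}

#: no light effect by default
DEFAULT_OPTO_GAIN = {1.0: 1.0, 2.0: 1.0, 4.0: 1.0}

#: SOM-inactivation-like profile: suppression at slow rates, none at 4 Hz.
SOM_OPTO_GAIN = {1.0: 0.70, 2.0: 0.75, 4.0: 1.0}

#: PV-inactivation-like profile: enhancement at fast rates only.
PV_OPTO_GAIN = {1.0: 1.0, 2.0: 1.10, 4.0: 1.15}


@dataclass(frozen=True)
class SynthParams:
    """Ground-truth parameters for the synthetic experiment.

    Defaults emulate the acquisition described for the real recordings
    (20 Hz frame rate, 200 x 150 px field) with indicator kinetics plausible
    for bulk widefield GCaMP signals; kinetics are deliberately generic, not
    sensor-specific.
    """

    image_shape: tuple = (150, 200)  # (rows, cols)
    fps: float = 20.0
    baseline_f0: float = 1000.0
    blob_centers: tuple = ((75.0, 60.0), (75.0, 140.0))  # (A1, AAF)
    blob_sigma_px: float = 15.0
    a1: float = 0.08  # first-tone dF/F amplitude
    a_inf: float = 0.028  # asymptotic standard amplitude
    tau_tones: dict = field(default_factory=lambda: dict(DEFAULT_TAU_TONES))
    dev_gain: float = 0.9  # deviant amplitude = a1 * dev_gain
    opto_gain: dict = field(default_factory=lambda: dict(DEFAULT_OPTO_GAIN))
    tau_rise_s: float = 0.04
    tau_decay_s: float = 0.4
    noise_sd: float = 10.0  # raw-fluorescence units
    anatomy_amp: float = 0.15  # SD of the static multiplicative anatomy pattern
    anatomy_sigma_px: float = 3.0  # correlation length of that pattern
    bleach_tau_s: float = 300.0
    pre_s: float = 1.2  # quiet time before the first tone (>= 1 s baseline)
    post_s: float = 1.5  # tail after the last onset (window + kernel decay)
    seed: int = 0

    def __post_init__(self):
        if self.a_inf > self.a1:
            raise ConfigError("a_inf must not exceed a1")
        if any(t <= 0 for t in self.tau_tones.values()):
            raise ConfigError("tau_tones must be positive")
        if self.dev_gain <= 0 or any(g <= 0 for g in self.opto_gain.values()):
            raise ConfigError("gains must be positive")
        if not 0 < self.tau_rise_s < self.tau_decay_s:
            raise ConfigError("need 0 < tau_rise_s < tau_decay_s")
        if self.fps <= 0:
            raise ConfigError("fps must be positive")
        if self.pre_s < 1.0:
            raise ConfigError("pre_s must allow a 1 s pre-stimulus baseline")

    def tau_for(self, rate_hz: float) -> float:
        try:
            return self.tau_tones[float(rate_hz)]
        except KeyError:
            raise ConfigError(f"no tau_tones entry for rate {rate_hz} Hz") from None

    def gain_for(self, rate_hz: float) -> float:
        try:
            return self.opto_gain[float(rate_hz)]
        except KeyError:
            raise ConfigError(f"no opto_gain entry for rate {rate_hz} Hz") from None


@dataclass(frozen=True)
class GroundTruth:
    """Hidden parameters of one rendered trial, for recovery tests."""

    amp_sequence: np.ndarray  # intended per-tone dF/F amplitudes
    condition: str
    rate_hz: float
    seed: int

    def __post_init__(self):
        amps = np.asarray(self.amp_sequence, dtype=float)
        object.__setattr__(self, "amp_sequence", amps)
        if np.any(amps < 0):
            raise DataError("ground-truth amplitudes must be non-negative")


@dataclass(frozen=True)
class Movie:
    """Raw fluorescence frame stack with acquisition timing."""

    frames: np.ndarray  # (time, rows, cols), non-negative
    fps: float
    t0_s: float  # trial time of frame 0 (first tone onset defines t = 0)

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", frames)
        if frames.ndim != 3 or frames.shape[0] < 1:
            raise DataError("movie must be a (time, rows, cols) stack")
        if not np.all(np.isfinite(frames)):
            raise DataError("movie contains non-finite values")

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.frames.shape[0]) / self.fps


def amplitude_sequence(
    train: StimulusTrain,
    a1: float,
    a_inf: float,
    tau_tones: float,
    dev_gain: float,
    opto_gain: float = 1.0,
) -> np.ndarray:
    """Intended per-tone dF/F amplitudes under the adaptation law.

    Standard tone n (1-based among standards) receives
    ``opto_gain * (a_inf + (a1 - a_inf) * exp(-(n - 1) / tau_tones))``;
    the deviant receives ``a1 * dev_gain`` with no light-on factor.
    """
    if tau_tones <= 0:
        raise ConfigError("tau_tones must be positive")
    amps = np.empty(train.n_tones)
    n_std = 0
    for i, lab in enumerate(train.labels):
        if lab == STANDARD:
            amps[i] = opto_gain * (a_inf + (a1 - a_inf) * np.exp(-n_std / tau_tones))
            n_std += 1
        else:
            amps[i] = a1 * dev_gain
    return amps


def indicator_kernel(
    tau_rise_s: float, tau_decay_s: float, fps: float, dur_s: float
) -> np.ndarray:
    """Difference-of-exponentials kernel sampled at 1/fps, unit peak.

    ``k(t) = (exp(-t/tau_decay) - exp(-t/tau_rise)) / k_peak`` for t >= 0.
    """
    t = np.arange(0.0, dur_s, 1.0 / fps)
    return _kernel_at(t, tau_rise_s, tau_decay_s)


def _kernel_peak_time(tau_rise_s: float, tau_decay_s: float) -> float:
    return (
        np.log(tau_decay_s / tau_rise_s)
        * tau_rise_s
        * tau_decay_s
        / (tau_decay_s - tau_rise_s)
    )


def _kernel_at(t, tau_rise_s: float, tau_decay_s: float) -> np.ndarray:
    """Analytic kernel evaluated at arbitrary times (0 for t < 0)."""
    if not 0 < tau_rise_s < tau_decay_s:
        raise ConfigError("need 0 < tau_rise_s < tau_decay_s")
    t = np.asarray(t, dtype=float)
    tp = _kernel_peak_time(tau_rise_s, tau_decay_s)
    peak = np.exp(-tp / tau_decay_s) - np.exp(-tp / tau_rise_s)
    out = np.where(
        t >= 0, np.exp(-np.maximum(t, 0) / tau_decay_s) - np.exp(-np.maximum(t, 0) / tau_rise_s), 0.0
    )
    return out / peak


def anatomy_map(params: SynthParams) -> np.ndarray:
    """Static multiplicative fluorescence heterogeneity (vasculature-like).

    A smooth random field shared by every trial of a recording (it derives
    from the recording-level seed, not the trial seed).  It multiplies the
    resting fluorescence, so per-pixel dF/F cancels it exactly, but it gives
    motion estimation a persistent spatial pattern to lock onto, as real
    anatomy does.
    """
    if params.anatomy_amp == 0:
        return np.ones(params.image_shape)
    from scipy import ndimage

    rng = np.random.default_rng([int(params.seed) % (2**31), 0xA7A7])
    field = ndimage.gaussian_filter(
        rng.standard_normal(params.image_shape), params.anatomy_sigma_px
    )
    field /= field.std()
    return np.clip(1.0 + params.anatomy_amp * field, 0.2, None)


def response_footprint(params: SynthParams) -> np.ndarray:
    """Two-blob Gaussian footprint with unit peak at each blob center."""
    rows, cols = params.image_shape
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    g = np.zeros((rows, cols))
    for cr, cc in params.blob_centers:
        g += np.exp(-((r - cr) ** 2 + (c - cc) ** 2) / (2 * params.blob_sigma_px**2))
    return g


def render_trial_movie(
    train: StimulusTrain,
    params: SynthParams,
    condition: str = LIGHT_OFF,
    seed: int | None = None,
):
    """Render one trial and return ``(Movie, GroundTruth)``.

    Frame 0 sits at ``t = -pre_s`` so the movie always contains the 1 s
    pre-stimulus baseline; the stack ends ``post_s`` after the last onset.
    The same seed gives a bit-identical stack.
    """
    if condition not in (LIGHT_OFF, LIGHT_ON):
        raise ConfigError(f"unknown condition {condition!r}")
    if seed is None:
        seed = params.seed
    gain = params.gain_for(train.rate_hz) if condition == LIGHT_ON else 1.0
    amps = amplitude_sequence(
        train,
        params.a1,
        params.a_inf,
        params.tau_for(train.rate_hz),
        params.dev_gain,
        opto_gain=gain,
    )
    dur_s = params.pre_s + train.onsets_s[-1] + params.post_s
    n_frames = int(np.ceil(dur_s * params.fps))
    if n_frames < 2:
        raise DataError("movie too short")
    t = -params.pre_s + np.arange(n_frames) / params.fps

    # temporal response at the blob peak: sum of kernel copies
    resp = np.zeros(n_frames)
    for amp, onset in zip(amps, train.onsets_s):
        resp += amp * _kernel_at(t - onset, params.tau_rise_s, params.tau_decay_s)

    footprint = response_footprint(params)
    anatomy = anatomy_map(params)
    bleach = np.exp(-(t - t[0]) / params.bleach_tau_s)
    signal = params.baseline_f0 * anatomy[None, :, :] * bleach[:, None, None] * (
        1.0 + footprint[None, :, :] * resp[:, None, None]
    )
    rng = np.random.default_rng(seed)
    if params.noise_sd > 0:
        signal = signal + rng.normal(0.0, params.noise_sd, size=signal.shape)
    n_clipped = int(np.sum(signal < 0))
    if n_clipped:
        logger.warning("clipped %d negative pixels at zero", n_clipped)
        signal = np.clip(signal, 0.0, None)
    movie = Movie(signal, params.fps, float(t[0]))
    truth = GroundTruth(amps, condition, train.rate_hz, int(seed))
    return movie, truth


@dataclass(frozen=True)
class TrialRecord:
    """One simulated trial plus its manifest metadata."""

    trial_id: str
    rate_hz: float
    condition: str
    seed: int
    inter_trial_gap_s: float
    movie: Movie
    truth: GroundTruth


def derive_trial_seeds(root_seed: int, n: int) -> np.ndarray:
    """Per-trial seeds derived from the root seed (documented derivation)."""
    rng = np.random.default_rng(root_seed)
    return rng.integers(0, 2**31 - 1, size=n)


def generate_experiment(
    params: SynthParams,
    rates=(1.0, 2.0, 4.0),
    n_trials_per_condition: int = 5,
    n_standards: int = 10,
    std_freq_hz: float = 8000.0,
    dev_freq_hz: float = 16000.0,
    inter_trial_gap_s: float = 30.0,
    tone_dur_s: float = 0.1,
) -> list:
    """Simulate a full interleaved experiment.

    For each rate, light-off and light-on trials alternate (off first), with
    fresh noise per trial but a shared ground-truth amplitude law.  Trials are
    spaced by at least 30 s of simulated recovery time (metadata only).
    Returns a list of :class:`TrialRecord`.
    """
    rates = list(rates)
    if not rates:
        raise ConfigError("rate list must not be empty")
    if not 1 <= n_trials_per_condition <= 50:
        raise ConfigError("n_trials_per_condition must be in [1, 50]")
    if inter_trial_gap_s < 30.0:
        raise ConfigError("inter-trial gap must be at least 30 s for recovery")
    total = len(rates) * 2 * n_trials_per_condition
    seeds = derive_trial_seeds(params.seed, total)
    records = []
    i = 0
    for rate in rates:
        train = make_train(rate, n_standards, std_freq_hz, dev_freq_hz, tone_dur_s)
        for rep in range(n_trials_per_condition):
            for condition in (LIGHT_OFF, LIGHT_ON):
                seed = int(seeds[i])
                movie, truth = render_trial_movie(train, params, condition, seed)
                trial_id = f"r{rate:g}_{condition.replace('light-', '')}_{rep:02d}"
                records.append(
                    TrialRecord(
                        trial_id, rate, condition, seed, inter_trial_gap_s, movie, truth
                    )
                )
                i += 1
    return records


def simulate_cohort_summaries(
    n_recordings: int,
    rates=(1.0, 2.0, 4.0),
    params: SynthParams | None = None,
    n_trials_per_condition: int = 5,
    recording_cv_a1: float = 0.2,
    recording_sd_gain: float = 0.08,
    recording_cv_tau: float = 0.15,
    trial_cv: float = 0.05,
    seed: int = 0,
):
    """Amplitude-level cohort simulator for inference power/null studies.

    Skips the imaging stage (validated separately by the movie-level recovery
    tests) and draws per-recording biological variability directly on the
    amplitude law: lognormal jitter on ``a1`` and ``tau``, additive Gaussian
    jitter on the light-on gain, and multiplicative trial-to-trial noise on
    every tone amplitude (default 5% CV, slightly above what the movie-level
    measurement shows under default imaging noise).  Returns per-recording trial-averaged amplitude
    vectors, ``{rate: [(off_amps, on_amps, labels), ...]}``, ready for the
    quantification and metrics layers.
    """
    from . import quantify  # local import to avoid a cycle

    if params is None:
        params = SynthParams()
    rng = np.random.default_rng(seed)
    out = {}
    for rate in rates:
        per_rec = []
        train = make_train(rate, 10, 8000.0, 16000.0)
        for _ in range(n_recordings):
            a1_r = params.a1 * rng.lognormal(0.0, recording_cv_a1)
            tau_r = params.tau_for(rate) * rng.lognormal(0.0, recording_cv_tau)
            gain_r = max(0.05, params.gain_for(rate) + rng.normal(0.0, recording_sd_gain))
            a_inf_r = a1_r * (params.a_inf / params.a1)
            conds = []
            for condition, g in ((LIGHT_OFF, 1.0), (LIGHT_ON, gain_r)):
                law = amplitude_sequence(train, a1_r, a_inf_r, tau_r, params.dev_gain, g)
                trials = []
                for k in range(n_trials_per_condition):
                    noisy = law * np.clip(rng.normal(1.0, trial_cv, law.size), 0.0, None)
                    trials.append(
                        quantify.TrialAmplitudes(
                            noisy, train.labels, rate, condition, trial_id=f"t{k}"
                        )
                    )
                conds.append(quantify.average_across_trials(trials, condition, rate))
            per_rec.append((conds[0], conds[1], train.labels))
        out[rate] = per_rec
    return out
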