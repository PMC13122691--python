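"""Oddball tone-train construction and per-tone analysis windows.

The repeated-sound paradigm is a train of identical "standard" tones followed
by a single frequency-switched "deviant" tone, presented at a fixed repetition
rate.  The inter-stimulus interval (ISI) is the onset-to-onset period: a 1 Hz
train has a 1 s ISI, 2 Hz a 0.5 s ISI and 4 Hz a 0.25 s ISI, irrespective of
the tone duration.  Cosine on/off ramps are carried as metadata only; no audio
waveform is synthesised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError

#: tolerance on onset spacing (seconds)
ONSET_TOL_S = 1e-9

STANDARD = "standard"
DEVIANT = "deviant"


@dataclass(frozen=True)
class StimulusTrain:
    """A timed sequence of tones with standard/deviant labels.

    Attributes
    ----------
    onsets_s : np.ndarray
        Tone onset times in seconds from trial start, strictly increasing.
    labels : tuple of str
        ``"standard"`` or ``"deviant"`` per tone; exactly one deviant, last.
    freqs_hz : np.ndarray
        Carrier frequency per tone (Hz).
    rate_hz : float
        Repetition rate; consecutive onsets are ``1 / rate_hz`` apart.
    tone_dur_s, ramp_s : float
        Tone duration and cosine ramp duration (metadata only).
    """

    onsets_s: np.ndarray
    labels: tuple
    freqs_hz: np.ndarray
    rate_hz: float
    tone_dur_s: float
    ramp_s: float

    def __post_init__(self):
        onsets = np.asarray(self.onsets_s, dtype=float)
        freqs = np.asarray(self.freqs_hz, dtype=float)
        object.__setattr__(self, "onsets_s", onsets)
        object.__setattr__(self, "freqs_hz", freqs)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = onsets.size
        if not (n == len(self.labels) == freqs.size):
            raise DataError("onsets, labels and freqs must have equal length")
        if n < 2:
            raise DataError("a train needs at least one standard and a deviant")
        if np.any(np.diff(onsets) <= 0):
            raise DataError("onsets must be strictly increasing")
        if self.labels.count(DEVIANT) != 1 or self.labels[-1] != DEVIANT:
            raise DataError("exactly one deviant tone is required and it must be last")
        isi = 1.0 / self.rate_hz
        if np.max(np.abs(np.diff(onsets) - isi)) > ONSET_TOL_S:
            raise DataError(
                f"onset-to-onset intervals must equal 1/rate = {isi:g} s"
            )
        if not self.tone_dur_s < isi:
            raise DataError("tone duration must be shorter than the tone period")
        std_freqs = {f for f, lab in zip(freqs, self.labels) if lab == STANDARD}
        if freqs[-1] in std_freqs:
            raise DataError("deviant frequency must differ from the standard frequency")

    @property
    def n_tones(self) -> int:
        return self.onsets_s.size

    @property
    def n_standards(self) -> int:
        return self.n_tones - 1

    @property
    def standard_indices(self) -> np.ndarray:
        """0-based indices of the standard tones, in train order."""
        return np.flatnonzero(np.asarray(self.labels) == STANDARD)

    @property
    def deviant_index(self) -> int:
        return self.n_tones - 1


@dataclass(frozen=True)
class ToneWindow:
    """Half-open analysis interval ``[start_s, end_s)`` for one tone.

    ``tone_index`` is 1-based (tone 1 is the first standard).
    """

    tone_index: int
    start_s: float
    end_s: float

    def __post_init__(self):
        if not self.end_s > self.start_s:
            raise DataError("tone window must have positive duration")


def make_train(
    rate_hz: float,
    n_standards: int,
    std_freq_hz: float,
    dev_freq_hz: float,
    tone_dur_s: float = 0.1,
    ramp_s: float = 0.005,
) -> StimulusTrain:
    """Build an oddball train of ``n_standards`` standards plus one deviant.

    Tone ``n`` (1-based) starts at ``(n - 1) / rate_hz``; the last tone is the
    deviant at a different carrier frequency.
    """
    if rate_hz <= 0:
        raise ConfigError("rate_hz must be positive")
    if n_standards < 1:
        raise ConfigError("need at least one standard tone")
    if not tone_dur_s < 1.0 / rate_hz:
        raise ConfigError("tone duration must be shorter than 1/rate_hz")
    if std_freq_hz == dev_freq_hz:
        raise ConfigError("standard and deviant frequencies must differ")
    n = n_standards + 1
    onsets = np.arange(n) / rate_hz
    labels = (STANDARD,) * n_standards + (DEVIANT,)
    freqs = np.full(n, float(std_freq_hz))
    freqs[-1] = float(dev_freq_hz)
    return StimulusTrain(onsets, labels, freqs, float(rate_hz), tone_dur_s, ramp_s)


def tone_windows(train: StimulusTrain, last_window_s: float = 1.0) -> list:
    """Per-tone analysis windows: onset-to-next-onset, half-open.

    The final (deviant) tone has no successor, so its window extends
    ``last_window_s`` past its onset.  Windows tile ``[0, last_onset +
    last_window_s)`` without overlap.
    """
    if last_window_s <= 0:
        raise ConfigError("last_window_s must be positive")
    onsets = train.onsets_s
    windows = []
    for i, onset in enumerate(onsets):
        end = onsets[i + 1] if i + 1 < onsets.size else onset + last_window_s
        windows.append(ToneWindow(i + 1, float(onset), float(end)))
    return windows


def train_to_table(train: StimulusTrain) -> pd.DataFrame:
    """Flat-table serialization: tone_index, onset_s, label, freq_hz."""
    return pd.DataFrame(
        {
            "tone_index": np.arange(1, train.n_tones + 1),
            "onset_s": train.onsets_s,
            "label": list(train.labels),
            "freq_hz": train.freqs_hz,
        }
    )


def train_from_table(
    table: pd.DataFrame, rate_hz: float, tone_dur_s: float = 0.1, ramp_s: float = 0.005
) -> StimulusTrain:
    """Rebuild a train from its flat-table form (inverse of train_to_table)."""
    t = table.sort_values("tone_index")
    return StimulusTrain(
        t["onset_s"].to_numpy(float),
        tuple(t["label"]),
        t["freq_hz"].to_numpy(float),
        float(rate_hz),
        tone_dur_s,
        ramp_s,
    )
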