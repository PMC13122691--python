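"""Per-tone peak-trough amplitudes, trial averaging, and normalizations.

The response to tone n is measured from the ROI trace inside that tone's
window as peak minus the preceding trough: the window maximum minus the
window minimum at or before the maximum.  This measures the rise evoked by
the tone itself and stays robust to inter-tone decay at fast repetition
rates; ``mode="minmax"`` (window max minus window min) is available as an
alternative.

Two normalizations mirror the conventions used for reporting:
``Response_n / Control_1`` (everything relative to the first light-off tone
of the trial-averaged train) and ``Response_n / Control_n`` (each tone
relative to its matched light-off counterpart).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError, DataError, InsufficientDataError
from .preprocess import frame_index
from .roi import RoiTrace
from .stimulus import StimulusTrain, ToneWindow

#: denominators smaller than this are treated as zero
ZERO_DENOM = 1e-6

TO_FIRST_CONTROL = "to_first_control"
TO_MATCHED_CONTROL = "to_matched_control"


@dataclass(frozen=True)
class TrialAmplitudes:
    """Per-tone response amplitudes for one trial (or a trial average)."""

    amps: np.ndarray
    labels: tuple
    rate_hz: float
    condition: str | None = None
    trial_id: str | None = None
    excluded: bool = False
    n_trials: int = 1

    def __post_init__(self):
        amps = np.asarray(self.amps, dtype=float)
        object.__setattr__(self, "amps", amps)
        object.__setattr__(self, "labels", tuple(self.labels))
        if amps.size != len(self.labels):
            raise DataError("amplitude vector and labels must have equal length")
        if not np.all(np.isfinite(amps)):
            raise DataError("amplitudes must be finite")
        if np.any(amps < -1e-12):
            raise DataError("amplitudes must be non-negative")


@dataclass(frozen=True)
class NormalizedResponses:
    """Dimensionless per-tone responses under a recorded normalization."""

    values: np.ndarray
    labels: tuple
    scheme: str
    denominator_source: str = ""

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(self.labels))
        if not np.all(np.isfinite(values)):
            raise DataError("normalized values must be finite")
        if self.scheme not in (TO_FIRST_CONTROL, TO_MATCHED_CONTROL):
            raise DataError(f"unknown normalization scheme {self.scheme!r}")


def tone_amplitude(trace: RoiTrace, window: ToneWindow, mode: str = "rise") -> float:
    """Peak-trough amplitude of the trace inside one tone window.

    ``mode="rise"`` (default): peak = window maximum, trough = window minimum
    at or before the peak; amplitude = peak - trough >= 0.
    ``mode="minmax"``: window maximum minus window minimum.
    """
    if mode not in ("rise", "minmax"):
        raise ConfigError(f"unknown amplitude mode {mode!r}")
    lo = max(0, frame_index(window.start_s, trace.t0_s, trace.fps))
    hi = min(trace.values.size, frame_index(window.end_s, trace.t0_s, trace.fps))
    if hi - lo < 2:
        raise InsufficientDataError(
            f"tone window [{window.start_s}, {window.end_s}) maps to "
            f"{max(hi - lo, 0)} frames; need at least 2"
        )
    seg = trace.values[lo:hi]
    if mode == "minmax":
        return float(seg.max() - seg.min())
    p = int(np.argmax(seg))
    return float(seg[p] - seg[: p + 1].min())


def train_amplitudes(
    trace: RoiTrace,
    train: StimulusTrain,
    windows,
    condition: str | None = None,
    trial_id: str | None = None,
    mode: str = "rise",
) -> TrialAmplitudes:
    """Apply :func:`tone_amplitude` to every tone window, in order."""
    if len(windows) < train.n_tones:
        raise DataError(
            f"{len(windows)} windows for a {train.n_tones}-tone train"
        )
    amps = np.array(
        [tone_amplitude(trace, w, mode=mode) for w in windows[: train.n_tones]]
    )
    return TrialAmplitudes(amps, train.labels, train.rate_hz, condition, trial_id)


def average_across_trials(
    trials, condition: str, rate_hz: float
) -> TrialAmplitudes:
    """Element-wise mean across non-excluded trials of one condition & rate."""
    eligible = [
        t
        for t in trials
        if not t.excluded and t.condition == condition and t.rate_hz == rate_hz
    ]
    if not eligible:
        raise InsufficientDataError(
            f"no eligible trials for condition={condition!r}, rate={rate_hz} Hz"
        )
    labels = eligible[0].labels
    if any(t.labels != labels for t in eligible):
        raise DataError("trials to be averaged have mismatched tone labels")
    amps = np.mean([t.amps for t in eligible], axis=0)
    return TrialAmplitudes(
        amps, labels, rate_hz, condition, trial_id=None, n_trials=len(eligible)
    )


def normalize_to_first_control(
    resp: TrialAmplitudes, control: TrialAmplitudes
) -> NormalizedResponses:
    """``Response_n / Control_1``: everything over the first light-off tone.

    ``control`` must be the trial-averaged light-off vector for the same
    rate; its first-tone amplitude is the common denominator.
    """
    c1 = float(control.amps[0])
    if c1 <= ZERO_DENOM:
        raise DataError("first control-tone amplitude is zero; cannot normalize")
    return NormalizedResponses(
        resp.amps / c1,
        resp.labels,
        TO_FIRST_CONTROL,
        denominator_source=f"first tone of {control.condition} average (n={control.n_trials})",
    )


def normalize_to_matched_control(
    resp: TrialAmplitudes, control: TrialAmplitudes
) -> NormalizedResponses:
    """``Response_n / Control_n``: each tone over its light-off counterpart."""
    if resp.amps.size != control.amps.size:
        raise DataError("response and control trains differ in length")
    if np.any(control.amps <= ZERO_DENOM):
        raise DataError("control contains zero amplitudes; cannot normalize")
    return NormalizedResponses(
        resp.amps / control.amps,
        resp.labels,
        TO_MATCHED_CONTROL,
        denominator_source=f"matched tones of {control.condition} average (n={control.n_trials})",
    )
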