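"""Headline indices: adaptation, deviance detection, light-on modulation.

Sign conventions follow the dashed-reference-line presentation of the source
panels: adaptation is reported as (tenth standard - first standard), so a
negative value means adaptation; deviance detection as (deviant - tenth
standard), so a positive value means the deviant broke through the adapted
state.  The light-on modulation index is the mean over standard tones of the
per-tone light-on / light-off ratio (deviants excluded; light effects on
deviants are reported separately).

An exponential decay fit over the standard tones provides the
parameter-recovery oracle for the synthetic adaptation law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .exceptions import ConfigError, DataError, InsufficientDataError
from .quantify import (
    TO_FIRST_CONTROL,
    NormalizedResponses,
    TrialAmplitudes,
)
from .stimulus import DEVIANT, STANDARD

MIN_STANDARDS = 10


@dataclass(frozen=True)
class SsaSummary:
    """Per-recording, per-rate summary of the three indices."""

    rate_hz: float
    adaptation_diff: float  # tone 10 - tone 1, normalized; negative = adaptation
    deviance_diff: float  # deviant - tone 10, normalized; positive = detection
    opto_modulation: float | None  # mean light-on/light-off ratio over standards
    tau_hat: float | None = None
    n_trials_used: int = 0


@dataclass(frozen=True)
class DecayFit:
    """Least-squares exponential adaptation fit over standard tones."""

    a1_hat: float
    a_inf_hat: float
    tau_hat: float
    rss: float
    tau_identifiable: bool = True

    def __post_init__(self):
        if self.tau_hat <= 0:
            raise DataError("fitted tau must be positive")
        if self.rss < 0:
            raise DataError("residual sum of squares must be non-negative")


def _standard_values(norm: NormalizedResponses) -> np.ndarray:
    labels = np.asarray(norm.labels)
    return norm.values[labels == STANDARD]


def adaptation_difference(norm: NormalizedResponses) -> float:
    """Tenth-minus-first standard-tone normalized amplitude."""
    if norm.scheme != TO_FIRST_CONTROL:
        raise ConfigError("adaptation_difference expects Response_n/Control_1 values")
    std = _standard_values(norm)
    if std.size < MIN_STANDARDS:
        raise InsufficientDataError(
            f"need >= {MIN_STANDARDS} standard tones, found {std.size}"
        )
    return float(std[MIN_STANDARDS - 1] - std[0])


def deviance_difference(norm: NormalizedResponses) -> float:
    """Deviant-minus-tenth-standard normalized amplitude."""
    if norm.labels[-1] != DEVIANT:
        raise DataError("last tone is not labeled deviant")
    std = _standard_values(norm)
    if std.size < MIN_STANDARDS:
        raise InsufficientDataError(
            f"need >= {MIN_STANDARDS} standard tones, found {std.size}"
        )
    return float(norm.values[-1] - std[MIN_STANDARDS - 1])


def opto_modulation_index(
    on: TrialAmplitudes, off: TrialAmplitudes, method: str = "mean_of_ratios"
) -> float:
    """Light-on standard-tone amplitudes relative to light-off.

    ``mean_of_ratios`` (default) averages the per-tone matched ratios
    On_n / Off_n over the standard tones; ``ratio_of_means`` divides the two
    standard-tone means.  Deviant tones are excluded either way.
    """
    if method not in ("mean_of_ratios", "ratio_of_means"):
        raise ConfigError(f"unknown modulation method {method!r}")
    if on.labels != off.labels or on.rate_hz != off.rate_hz:
        raise DataError("light-on and light-off trains do not match")
    std = np.asarray(on.labels) == STANDARD
    off_std = off.amps[std]
    on_std = on.amps[std]
    if np.any(off_std <= 0):
        raise DataError("light-off standard amplitudes must be positive")
    if method == "ratio_of_means":
        return float(on_std.mean() / off_std.mean())
    return float(np.mean(on_std / off_std))


#: relative a1-a_inf separation below which tau is flagged unidentifiable
_FLAT_TOL = 1e-6


def fit_adaptation_decay(norm: NormalizedResponses) -> DecayFit:
    """Fit ``v_n = a_inf + (a1 - a_inf) * exp(-(n - 1) / tau)`` to standards.

    Multi-start on tau in {1, 3, 9} tones guards against local minima; the
    best (lowest-RSS) converged fit is returned.  A flat input leaves tau
    unidentifiable; the fit is then flagged via ``tau_identifiable=False``.
    """
    y = _standard_values(norm)
    if y.size < 4:
        raise InsufficientDataError("decay fit needs at least 4 standard tones")
    if np.any(y <= 0):
        raise DataError("decay fit expects positive normalized values")
    n = np.arange(y.size, dtype=float)  # n - 1 in the model

    def resid(p):
        a1, a_inf, log_tau = p
        return a_inf + (a1 - a_inf) * np.exp(-n / np.exp(log_tau)) - y

    best = None
    for tau0 in (1.0, 3.0, 9.0):
        sol = least_squares(
            resid,
            x0=[y[0], y[-1], np.log(tau0)],
            xtol=1e-13,
            ftol=1e-13,
            gtol=1e-13,
            max_nfev=5000,
        )
        if not np.all(np.isfinite(sol.x)):
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise DataError("adaptation decay fit failed to converge from all starts")
    rss, (a1_hat, a_inf_hat, log_tau) = best
    spread = abs(a1_hat - a_inf_hat)
    scale = max(abs(a1_hat), abs(a_inf_hat), 1e-12)
    return DecayFit(
        a1_hat=float(a1_hat),
        a_inf_hat=float(a_inf_hat),
        tau_hat=float(np.exp(log_tau)),
        rss=rss,
        tau_identifiable=bool(spread / scale > _FLAT_TOL),
    )


def summarize_recording(
    off_avg: TrialAmplitudes,
    on_avg: TrialAmplitudes | None = None,
    modulation_method: str = "mean_of_ratios",
) -> SsaSummary:
    """Compute all indices for one recording at one rate.

    Adaptation and deviance come from the light-off average normalized to its
    own first tone; the modulation index (when a light-on average is given)
    uses matched per-tone ratios.
    """
    from .quantify import normalize_to_first_control

    off_norm = normalize_to_first_control(off_avg, off_avg)
    fit = fit_adaptation_decay(off_norm)
    modulation = (
        opto_modulation_index(on_avg, off_avg, method=modulation_method)
        if on_avg is not None
        else None
    )
    n_used = off_avg.n_trials + (on_avg.n_trials if on_avg is not None else 0)
    return SsaSummary(
        rate_hz=off_avg.rate_hz,
        adaptation_diff=adaptation_difference(off_norm),
        deviance_diff=deviance_difference(off_norm),
        opto_modulation=modulation,
        tau_hat=fit.tau_hat if fit.tau_identifiable else None,
        n_trials_used=n_used,
    )
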