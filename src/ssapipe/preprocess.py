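"""Raw movie -> dF/F conversion, spatial low-pass filtering, localization map.

dF/F is computed per pixel against the mean fluorescence of the 1 s preceding
the first tone onset; the same baseline serves every tone in the train, since
within-train baselines would be contaminated by the preceding tone's decay.

The spatial filter is a radially symmetric 2-D Butterworth low-pass applied
per frame in the frequency domain (zero phase, unit DC gain) after symmetric
edge padding.  The localization map is the temporal mean of 10 consecutive
frames (0.5 s at 20 fps) starting at the end of the sound stimulus; on it the
two low-frequency tonotopic fields (A1, AAF) appear as bright blobs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError, DataError, InsufficientDataError
from .synth import Movie


#: slack (in frame-index units) when mapping a time boundary to a frame
#: index, so a frame nominally on the boundary is not lost to accumulated
#: floating-point error in the time grid
_IDX_EPS = 1e-6


def frame_index(boundary_s: float, t0_s: float, fps: float) -> int:
    """First frame index whose time is >= ``boundary_s`` (float-robust)."""
    return int(np.ceil((boundary_s - t0_s) * fps - _IDX_EPS))


@dataclass(frozen=True)
class DffMovie:
    """Fractional fluorescence-change stack (dimensionless)."""

    frames: np.ndarray  # (time, rows, cols)
    fps: float
    t0_s: float
    baseline_window_s: tuple  # (start, end) in trial time

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", frames)
        if not np.all(np.isfinite(frames)):
            raise DataError("dF/F contains non-finite values")

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.frames.shape[0]) / self.fps


@dataclass(frozen=True)
class ResponseMap:
    """Temporal-average dF/F image used for field localization."""

    image: np.ndarray
    frames_used: tuple  # (first_index, count)

    def __post_init__(self):
        image = np.asarray(self.image, dtype=float)
        object.__setattr__(self, "image", image)
        if not np.all(np.isfinite(image)):
            raise DataError("response map contains non-finite values")


def compute_dff(movie: Movie, sound_onset_s: float, baseline_s: float = 1.0) -> DffMovie:
    """Per-pixel dF/F against the mean of ``baseline_s`` before sound onset.

    ``dF/F(t) = (F(t) - Fbar) / Fbar`` with ``Fbar`` the per-pixel mean over
    frames in ``[sound_onset_s - baseline_s, sound_onset_s)``.
    """
    if baseline_s <= 0:
        raise ConfigError("baseline_s must be positive")
    lo = max(0, frame_index(sound_onset_s - baseline_s, movie.t0_s, movie.fps))
    hi = min(
        movie.frames.shape[0], frame_index(sound_onset_s, movie.t0_s, movie.fps)
    )
    n_needed = int(round(baseline_s * movie.fps))
    if hi - lo < n_needed:
        raise InsufficientDataError(
            f"need {n_needed} baseline frames before onset, found {max(hi - lo, 0)}"
        )
    fbar = movie.frames[lo:hi].mean(axis=0)
    n_bad = int(np.sum(fbar <= 0))
    if n_bad:
        raise DataError(f"non-positive baseline fluorescence in {n_bad} pixels")
    dff = (movie.frames - fbar) / fbar
    return DffMovie(
        dff, movie.fps, movie.t0_s, (sound_onset_s - baseline_s, sound_onset_s)
    )


def _butterworth_response(shape, cutoff_cyc_per_px: float, order: int) -> np.ndarray:
    rows, cols = shape
    fr = np.fft.fftfreq(rows)[:, None]
    fc = np.fft.fftfreq(cols)[None, :]
    radius = np.hypot(fr, fc)
    return 1.0 / np.sqrt(1.0 + (radius / cutoff_cyc_per_px) ** (2 * order))


def butterworth_filter_frames(
    frames: np.ndarray,
    cutoff_cyc_per_px: float,
    order: int = 2,
    pad_mode: str = "symmetric",
    chunk: int = 64,
) -> np.ndarray:
    """Filter each frame of a (time, rows, cols) stack; shape is preserved.

    Each frame is padded by half its size on every border (``pad_mode``),
    multiplied in the 2-D frequency domain by the real Butterworth magnitude
    response ``H(f) = 1 / sqrt(1 + (f / f_c)^(2 * order))`` (zero phase, unit
    DC gain) and cropped back.  Frames are processed in chunks to bound
    memory.
    """
    if not 0 < cutoff_cyc_per_px < 0.5:
        raise ConfigError("cutoff must be in (0, 0.5) cycles/px")
    if order < 1:
        raise ConfigError("filter order must be >= 1")
    frames = np.asarray(frames, dtype=float)
    squeeze = frames.ndim == 2
    if squeeze:
        frames = frames[None]
    rows, cols = frames.shape[1:]
    pr, pc = rows // 2, cols // 2
    h = _butterworth_response((rows + 2 * pr, cols + 2 * pc), cutoff_cyc_per_px, order)
    out = np.empty_like(frames)
    for lo in range(0, frames.shape[0], chunk):
        block = frames[lo : lo + chunk]
        padded = np.pad(block, ((0, 0), (pr, pr), (pc, pc)), mode=pad_mode)
        spec = np.fft.fft2(padded, axes=(-2, -1)) * h
        filtered = np.real(np.fft.ifft2(spec, axes=(-2, -1)))
        out[lo : lo + chunk] = filtered[:, pr : pr + rows, pc : pc + cols]
    return out[0] if squeeze else out


def spatial_lowpass(
    dff: DffMovie, cutoff_cyc_per_px: float = 0.05, order: int = 2
) -> DffMovie:
    """Radially symmetric Butterworth low-pass applied to every dF/F frame."""
    filtered = butterworth_filter_frames(dff.frames, cutoff_cyc_per_px, order)
    return DffMovie(filtered, dff.fps, dff.t0_s, dff.baseline_window_s)


def localization_map(dff: DffMovie, sound_end_s: float, n_frames: int = 10) -> ResponseMap:
    """Mean of ``n_frames`` consecutive frames starting at the sound's end.

    The window begins at the first frame whose time is >= ``sound_end_s``.
    """
    if n_frames < 1:
        raise ConfigError("n_frames must be >= 1")
    k = frame_index(sound_end_s, dff.t0_s, dff.fps)
    if k >= dff.frames.shape[0]:
        raise InsufficientDataError("movie ends before the sound does")
    if k + n_frames > dff.frames.shape[0]:
        raise InsufficientDataError(
            f"averaging window [{k}, {k + n_frames}) extends past movie end"
        )
    image = dff.frames[k : k + n_frames].mean(axis=0)
    return ResponseMap(image, (k, n_frames))
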