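"""Sound-responsive field detection, A1/AAF labeling, ROI traces, motion check.

The two sound-responsive blobs on the localization map are segmented by
thresholding at a fraction of the map maximum and keeping the two largest
8-connected components.  The centroid farther along the configured anterior
axis is labeled AAF, the other A1.  The ROI trace is the unweighted per-frame
mean of dF/F over the mask.  Motion screening replaces the by-eye exclusion
used at the bench with a quantitative rule: the maximum consecutive-frame
integer rigid shift (cross-correlation argmax) must not exceed a threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .exceptions import ConfigError, DataError
from .preprocess import DffMovie, ResponseMap
from .synth import Movie

logger = logging.getLogger(__name__)

A1 = "A1"
AAF = "AAF"

_AXES = {
    "+col": np.array([0.0, 1.0]),
    "-col": np.array([0.0, -1.0]),
    "+row": np.array([1.0, 0.0]),
    "-row": np.array([-1.0, 0.0]),
}


@dataclass(frozen=True)
class FieldRegion:
    """One connected sound-responsive region."""

    mask: np.ndarray  # boolean pixel mask
    centroid: tuple  # (row, col), intensity weighted
    area_px: int
    peak_dff: float
    label: str | None = None


@dataclass(frozen=True)
class FieldRegions:
    regions: tuple

    def __post_init__(self):
        object.__setattr__(self, "regions", tuple(self.regions))
        labels = [r.label for r in self.regions if r.label is not None]
        if len(labels) != len(set(labels)):
            raise DataError("region labels must be unique")

    def by_label(self, label: str) -> FieldRegion:
        for r in self.regions:
            if r.label == label:
                return r
        raise KeyError(label)


@dataclass(frozen=True)
class RoiTrace:
    """Mean dF/F over an ROI, per frame."""

    values: np.ndarray
    fps: float
    t0_s: float
    roi_label: str | None = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if not np.all(np.isfinite(values)):
            raise DataError("trace contains non-finite values")

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.values.size) / self.fps


@dataclass(frozen=True)
class MotionReport:
    score: float  # max consecutive-frame rigid displacement (px)
    excluded: bool
    threshold_px: float


def detect_responsive_regions(
    resp_map: ResponseMap, threshold_frac: float = 0.5
) -> FieldRegions:
    """Threshold-and-largest-components segmentation of the response map.

    Binarize at ``threshold_frac * max``, label 8-connected components, keep
    the two largest by area (ties broken by higher peak dF/F), and report
    intensity-weighted centroids.
    """
    if not 0 < threshold_frac < 1:
        raise ConfigError("threshold_frac must be in (0, 1)")
    image = resp_map.image
    peak = image.max()
    if peak <= 0:
        raise DataError("response map has no positive pixels")
    binary = image >= threshold_frac * peak
    labeled, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise DataError("no suprathreshold pixels in response map")
    regions = []
    for idx in range(1, n + 1):
        mask = labeled == idx
        vals = image[mask]
        rr, cc = np.nonzero(mask)
        w = vals / vals.sum()
        regions.append(
            FieldRegion(
                mask=mask,
                centroid=(float(np.sum(rr * w)), float(np.sum(cc * w))),
                area_px=int(mask.sum()),
                peak_dff=float(vals.max()),
            )
        )
    regions.sort(key=lambda r: (r.area_px, r.peak_dff), reverse=True)
    return FieldRegions(regions[:2])


def assign_field_labels(regions: FieldRegions, anterior_axis: str = "+col") -> FieldRegions:
    """Label A1 vs AAF by position along the anterior axis.

    With two regions the centroid farther along ``anterior_axis`` becomes AAF.
    A single region is labeled A1 with a logged warning.
    """
    try:
        axis = _AXES[anterior_axis]
    except KeyError:
        raise ConfigError(
            f"anterior_axis must be one of {sorted(_AXES)}, got {anterior_axis!r}"
        ) from None
    regs = list(regions.regions)
    if len(regs) == 1:
        logger.warning("only one sound-responsive region found; labeling it A1")
        return FieldRegions((replace(regs[0], label=A1),))
    if len(regs) != 2:
        raise DataError("expected at most two regions")
    proj = [float(np.dot(np.asarray(r.centroid), axis)) for r in regs]
    aaf_idx = int(np.argmax(proj))
    labeled = [
        replace(r, label=AAF if i == aaf_idx else A1) for i, r in enumerate(regs)
    ]
    return FieldRegions(labeled)


def extract_trace(dff: DffMovie, mask: np.ndarray, roi_label: str | None = None) -> RoiTrace:
    """Unweighted per-frame mean of dF/F over the mask pixels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dff.frames.shape[1:]:
        raise DataError("mask shape does not match the movie frames")
    if not mask.any():
        raise DataError("ROI mask is empty")
    values = dff.frames[:, mask].mean(axis=1)
    return RoiTrace(values, dff.fps, dff.t0_s, roi_label)


#: minimum normalized correlation for a displacement estimate to count;
#: frame pairs dominated by structured signal correlate near 1, while
#: noise-dominated pairs carry no motion information and fall well below.
MIN_PEAK_CORR = 0.5

#: correlations within this relative tolerance of the peak are ties; the
#: smallest displacement wins, so broad smooth structure plus pixel noise
#: does not masquerade as motion.
PEAK_REL_TOL = 0.01

#: Gaussian pre-smoothing (px) applied before correlating frame pairs
MOTION_SMOOTH_SIGMA_PX = 1.5


def _best_shift(a: np.ndarray, b: np.ndarray, radius: int):
    """Integer rigid shift of ``b`` maximizing cross-correlation with ``a``.

    Searches |dr|, |dc| <= radius.  Ties (within a relative tolerance)
    resolve to the smallest displacement, and a peak whose normalized
    correlation falls below :data:`MIN_PEAK_CORR` is treated as "no
    detectable motion" (shift 0), so featureless frames score zero.
    """
    a0 = a - a.mean()
    b0 = b - b.mean()
    norm = np.sqrt(np.sum(a0**2) * np.sum(b0**2))
    if norm <= 0:
        return 0, 0
    corr = np.real(np.fft.ifft2(np.fft.fft2(a0) * np.conj(np.fft.fft2(b0))))
    offsets = np.arange(-radius, radius + 1)
    window = corr[np.ix_(offsets % a.shape[0], offsets % a.shape[1])]
    best = window.max()
    if best / norm < MIN_PEAK_CORR:
        return 0, 0
    tol = PEAK_REL_TOL * abs(best)
    near = np.argwhere(window >= best - tol)
    shifts = offsets[near]
    dr, dc = min(shifts.tolist(), key=lambda s: (np.hypot(*s), abs(s[0]), abs(s[1])))
    return int(dr), int(dc)


def motion_exclusion(
    movie: Movie, threshold_px: float = 2.0, search_radius: int = 5
) -> MotionReport:
    """Score the movie's worst consecutive-frame rigid displacement.

    ``score`` is the maximum over frame pairs of the displacement magnitude
    of the correlation-maximizing integer shift; the movie is excluded when
    the score exceeds ``threshold_px``.
    """
    frames = movie.frames
    if frames.shape[0] < 2:
        raise DataError("motion scoring needs at least two frames")
    smoothed = ndimage.gaussian_filter(
        frames, sigma=(0.0, MOTION_SMOOTH_SIGMA_PX, MOTION_SMOOTH_SIGMA_PX)
    )
    score = 0.0
    for i in range(frames.shape[0] - 1):
        dr, dc = _best_shift(smoothed[i], smoothed[i + 1], search_radius)
        score = max(score, float(np.hypot(dr, dc)))
    return MotionReport(score, bool(score > threshold_px), float(threshold_px))
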