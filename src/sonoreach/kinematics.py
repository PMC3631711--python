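"""Filtering, differentiation, movement segmentation and hand features.

The processing chain for one trial is the standard one for endpoint
kinematics at 100 Hz:

1. Gaussian low-pass filter the raw position (cut-off 5 Hz, −3 dB);
2. differentiate by central differences and take Euclidean norms to obtain
   the tangential speed ``v3D``, acceleration ``a3D`` and jerk ``j3D``;
3. a coarse *primary* segmentation on horizontal displacement from the start
   marker isolates the outbound gesture and discards the return to the
   marker;
4. the movement bounds are then refined on ``v3D``: onset and offset are the
   crossings of a threshold at 3% of the peak speed, found by walking outward
   from the peak-velocity point (PVP) so that noise bumps far from the
   movement cannot capture the bounds.

Scalar features (duration, peak/mean speed, path length, acceleration-peak
counts split at the PVP, relative PVP position) are computed within those
bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .data_model import TrajectorySeries

__all__ = [
    "NoMovementError",
    "KinematicSeries",
    "MovementBounds",
    "HandFeatures",
    "gaussian_sigma_s",
    "gaussian_lowpass",
    "compute_norms",
    "primary_segment",
    "detect_bounds",
    "count_acceleration_peaks",
    "hand_features",
    "DEFAULT_CUTOFF_HZ",
    "DEFAULT_THRESHOLD_FRACTION",
    "DEFAULT_PROMINENCE_FRACTION",
    "DEFAULT_DISPLACEMENT_THRESHOLD_M",
]

DEFAULT_CUTOFF_HZ = 5.0
#: Onset/offset threshold as a fraction of peak speed.
DEFAULT_THRESHOLD_FRACTION = 0.03
#: Acceleration peaks must have prominence >= this fraction of max a3D in bounds.
DEFAULT_PROMINENCE_FRACTION = 0.05
#: Horizontal displacement from the start marker defining the primary segment.
DEFAULT_DISPLACEMENT_THRESHOLD_M = 0.02

_KERNEL_TRUNCATE = 4.0  # kernel support in units of sigma


class NoMovementError(ValueError):
    """No movement could be segmented from the trajectory."""


@dataclass(frozen=True)
class KinematicSeries:
    """Filtered position plus tangential speed/acceleration/jerk norms."""

    p_filt: np.ndarray  # (n, 3) metres
    v3D: np.ndarray     # m/s, >= 0
    a3D: np.ndarray     # m/s^2, >= 0
    j3D: np.ndarray     # m/s^3, >= 0
    fs: float

    def __len__(self) -> int:
        return self.p_filt.shape[0]


@dataclass(frozen=True)
class MovementBounds:
    """Movement onset/offset samples and the peak-velocity point (PVP).

    ``start_at_edge`` / ``end_at_edge`` flag bounds where the 3% threshold was
    never reached before hitting the series edge; the edge sample is used.
    """

    i_start: int
    i_end: int
    i_pvp: int
    v_peak: float
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
    start_at_edge: bool = False
    end_at_edge: bool = False

    def __post_init__(self):
        if not (self.i_start <= self.i_pvp <= self.i_end):
            raise ValueError("bounds must satisfy i_start <= i_pvp <= i_end")

    @property
    def n_samples(self) -> int:
        return self.i_end - self.i_start + 1


@dataclass(frozen=True)
class HandFeatures:
    duration: float            # s
    v_peak: float              # m/s
    v_mean: float              # m/s
    path_length: float         # m
    n_acc_peaks_total: int
    n_acc_peaks_before_pvp: int
    n_acc_peaks_after_pvp: int
    pvp_relative_position: float  # in [0, 1]

    def as_dict(self) -> dict:
        return {
            "duration": self.duration,
            "v_peak": self.v_peak,
            "v_mean": self.v_mean,
            "path_length": self.path_length,
            "n_acc_peaks_total": self.n_acc_peaks_total,
            "n_acc_peaks_before_pvp": self.n_acc_peaks_before_pvp,
            "n_acc_peaks_after_pvp": self.n_acc_peaks_after_pvp,
            "pvp_relative_position": self.pvp_relative_position,
        }


# ---------------------------------------------------------------------------
# Filtering and differentiation
# ---------------------------------------------------------------------------


def gaussian_sigma_s(fc: float) -> float:
    """Gaussian kernel scale (seconds) whose gain is −3 dB at ``fc``.

    The Gaussian filter's frequency response is ``exp(-(2*pi*f*sigma)^2 / 2)``;
    solving for gain ``1/sqrt(2)`` at ``f = fc`` gives
    ``sigma = sqrt(ln 2) / (2*pi*fc)``.
    """
    return np.sqrt(np.log(2.0)) / (2.0 * np.pi * fc)


def gaussian_lowpass(
    p: np.ndarray | TrajectorySeries,
    fs: float | None = None,
    fc: float = DEFAULT_CUTOFF_HZ,
) -> np.ndarray:
    """Zero-phase Gaussian low-pass filter with −3 dB cut-off ``fc``.

    Accepts an (n,) or (n, d) array (plus ``fs``) or a
    :class:`~sonoreach.data_model.TrajectorySeries`.  The kernel is truncated
    at ±4 sigma and normalised to unit sum (DC gain exactly 1); edges are
    handled by reflection padding.
    """
    if isinstance(p, TrajectorySeries):
        fs = p.fs
        p = p.p
    if fs is None:
        raise TypeError("fs is required when passing a bare array")
    if not fs > 2.0 * fc:
        raise ValueError(f"sampling rate {fs} Hz must exceed twice the cut-off {fc} Hz")
    sigma = gaussian_sigma_s(fc) * fs  # in samples
    min_len = 2 * int(np.ceil(_KERNEL_TRUNCATE * sigma)) + 1
    p = np.asarray(p, dtype=float)
    if p.shape[0] < min_len:
        raise ValueError(
            f"series of length {p.shape[0]} is shorter than the filter kernel; "
            f"at least {min_len} samples are required at fs={fs} Hz, fc={fc} Hz"
        )
    return gaussian_filter1d(
        p, sigma=sigma, axis=0, mode="reflect", truncate=_KERNEL_TRUNCATE
    )


def compute_norms(p_filt: np.ndarray, fs: float) -> KinematicSeries:
    """Tangential speed/acceleration/jerk norms by central differences.

    Derivatives use :func:`numpy.gradient` (central differences in the
    interior, one-sided at the edges) applied successively to the filtered
    position; ``v3D``, ``a3D`` and ``j3D`` are the Euclidean norms of the
    resulting vector series.
    """
    p_filt = np.asarray(p_filt, dtype=float)
    if p_filt.ndim != 2 or p_filt.shape[1] != 3:
        raise ValueError("p_filt must be (n, 3)")
    if p_filt.shape[0] < 7:
        raise ValueError("at least 7 samples are needed for three derivative passes")
    dt = 1.0 / fs
    v = np.gradient(p_filt, dt, axis=0)
    a = np.gradient(v, dt, axis=0)
    j = np.gradient(a, dt, axis=0)
    return KinematicSeries(
        p_filt=p_filt,
        v3D=np.linalg.norm(v, axis=1),
        a3D=np.linalg.norm(a, axis=1),
        j3D=np.linalg.norm(j, axis=1),
        fs=fs,
    )


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def primary_segment(
    series: TrajectorySeries | np.ndarray,
    start_marker: np.ndarray,
    threshold_m: float = DEFAULT_DISPLACEMENT_THRESHOLD_M,
) -> tuple[int, int]:
    """Coarse candidate window for the outbound pointing gesture.

    Finds the first contiguous run of samples whose horizontal (x, y)
    displacement from ``start_marker`` exceeds ``threshold_m`` and truncates
    it at its point of maximum displacement, which discards the return to the
    tactile marker.  Returns ``(i_lo, i_hi)`` sample indices (inclusive).
    """
    p = series.p if isinstance(series, TrajectorySeries) else np.asarray(series, float)
    d = np.hypot(p[:, 0] - start_marker[0], p[:, 1] - start_marker[1])
    above = d > threshold_m
    if not above.any():
        raise NoMovementError(
            f"horizontal displacement never exceeds {threshold_m * 100:.1f} cm "
            "from the start marker"
        )
    i_lo = int(np.argmax(above))  # first crossing
    after = np.flatnonzero(~above[i_lo:])
    i_run_end = i_lo + (int(after[0]) - 1) if after.size else len(d) - 1
    # last sample attaining the maximum displacement: a monotonic or held
    # trajectory keeps its full tail, an out-and-back loses the return
    run = d[i_lo : i_run_end + 1]
    i_hi = i_run_end - int(np.argmax(run[::-1]))
    return i_lo, i_hi


def detect_bounds(
    kin: KinematicSeries,
    window: tuple[int, int] | None = None,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> MovementBounds:
    """Movement bounds at the 3%-of-peak-speed threshold.

    The PVP is the argmax of ``v3D`` within ``window`` (whole series when
    ``None``).  Onset is the last sample at or before the PVP with
    ``v3D <= threshold_fraction * v_peak``; offset the first such sample at or
    after it.  The walk may leave the candidate window (the displacement
    stage only locates the gesture; the speed threshold defines its bounds)
    but stops at the series edges, which are then flagged.
    """
    n = len(kin)
    lo, hi = (0, n - 1) if window is None else window
    if hi < lo:
        raise ValueError("empty window")
    v = kin.v3D
    i_pvp = lo + int(np.argmax(v[lo : hi + 1]))
    v_peak = float(v[i_pvp])
    if v_peak <= 0.0:
        raise NoMovementError("peak speed is zero in the candidate window")
    thr = threshold_fraction * v_peak

    below_before = np.flatnonzero(v[: i_pvp + 1] <= thr)
    if below_before.size:
        i_start, start_edge = int(below_before[-1]), False
    else:
        i_start, start_edge = 0, True
    below_after = np.flatnonzero(v[i_pvp:] <= thr)
    if below_after.size:
        i_end, end_edge = i_pvp + int(below_after[0]), False
    else:
        i_end, end_edge = n - 1, True
    if not (i_start < i_pvp < i_end):
        raise NoMovementError("degenerate bounds: movement too short to segment")
    return MovementBounds(
        i_start=i_start,
        i_end=i_end,
        i_pvp=i_pvp,
        v_peak=v_peak,
        threshold_fraction=threshold_fraction,
        start_at_edge=start_edge,
        end_at_edge=end_edge,
    )


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------


def count_acceleration_peaks(
    accel: np.ndarray,
    i_start: int,
    i_end: int,
    i_split: int,
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
) -> tuple[int, int, int]:
    """Count local maxima of an acceleration magnitude series within bounds.

    Peaks are strict local maxima with prominence at least
    ``prominence_fraction`` of the maximum value within the bounds; a plateau
    is attributed to its first sample.  The count is split at ``i_split``
    (the PVP); a peak exactly at the split counts as *after*.  Returns
    ``(total, before, after)``.
    """
    seg = np.asarray(accel[i_start : i_end + 1], dtype=float)
    amax = seg.max() if seg.size else 0.0
    if amax <= 0.0:
        return 0, 0, 0
    peaks, props = find_peaks(
        seg, prominence=prominence_fraction * amax, plateau_size=(1, None)
    )
    idx = props["left_edges"] + i_start  # plateau rule: first sample
    before = int(np.sum(idx < i_split))
    total = int(idx.size)
    return total, before, total - before


def hand_features(
    kin: KinematicSeries,
    bounds: MovementBounds,
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
) -> HandFeatures:
    """Scalar kinematic features of the hand movement within its bounds."""
    i0, i1, ip = bounds.i_start, bounds.i_end, bounds.i_pvp
    duration = (i1 - i0) / kin.fs
    v_seg = kin.v3D[i0 : i1 + 1]
    steps = np.diff(kin.p_filt[i0 : i1 + 1], axis=0)
    total, before, after = count_acceleration_peaks(
        kin.a3D, i0, i1, ip, prominence_fraction
    )
    return HandFeatures(
        duration=float(duration),
        v_peak=float(bounds.v_peak),
        v_mean=float(v_seg.mean()),
        path_length=float(np.linalg.norm(steps, axis=1).sum()),
        n_acc_peaks_total=total,
        n_acc_peaks_before_pvp=before,
        n_acc_peaks_after_pvp=after,
        pvp_relative_position=float((ip - i0) / (i1 - i0)),
    )
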