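"""Head-orienting (heading) analysis.

The heading angle is the yaw of the head about the vertical axis: the azimuth
of the head's forward axis (body ``+y`` rotated into the world) projected on
the horizontal plane, with 0° forward and positive to the right.  Pitch and
roll are ignored.  The yaw series is unwrapped, low-pass filtered with the
same Gaussian filter as the hand trajectory, and differentiated by central
differences.

Head features mirror the hand features but are referenced to the *hand*
movement bounds: the range of motion (ROM) is taken over the whole trial
window because head orienting typically starts before hand onset, the final
heading is read at hand-movement offset, and the yaw-acceleration peak counts
are split at the hand's peak-velocity point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .data_model import HeadPoseSeries
from .kinematics import (
    DEFAULT_CUTOFF_HZ,
    DEFAULT_PROMINENCE_FRACTION,
    MovementBounds,
    count_acceleration_peaks,
    gaussian_lowpass,
)

__all__ = [
    "DegeneratePoseError",
    "HeadingSeries",
    "HeadFeatures",
    "extract_heading",
    "head_features",
    "early_heading_fraction",
]

_MIN_HORIZONTAL_SIN = np.sin(np.deg2rad(5.0))  # forward axis within 5° of vertical


class DegeneratePoseError(ValueError):
    """Head forward axis too close to vertical for a defined heading."""


@dataclass(frozen=True)
class HeadingSeries:
    """Unwrapped, filtered heading angle with its derivatives.

    ``yaw`` in degrees (0° forward, positive right), ``yaw_rate`` in deg/s,
    ``yaw_accel`` is the magnitude of the angular acceleration in deg/s².
    """

    yaw: np.ndarray
    yaw_rate: np.ndarray
    yaw_accel: np.ndarray
    fs: float

    def __len__(self) -> int:
        return self.yaw.shape[0]


@dataclass(frozen=True)
class HeadFeatures:
    rom: float          # degrees, max - min of yaw over the trial window
    final_yaw: float    # degrees, yaw at hand movement offset
    n_acc_peaks_total: int
    n_acc_peaks_before_hand_pvp: int
    n_acc_peaks_after_hand_pvp: int
    head_pvp_relative_position: float  # in [0, 1] relative to hand bounds

    def as_dict(self) -> dict:
        return {
            "head_rom": self.rom,
            "head_final_yaw": self.final_yaw,
            "head_n_acc_peaks_total": self.n_acc_peaks_total,
            "head_n_acc_peaks_before_hand_pvp": self.n_acc_peaks_before_hand_pvp,
            "head_n_acc_peaks_after_hand_pvp": self.n_acc_peaks_after_hand_pvp,
            "head_pvp_relative_position": self.head_pvp_relative_position,
        }


def extract_heading(
    head: HeadPoseSeries, fc: float | None = DEFAULT_CUTOFF_HZ
) -> HeadingSeries:
    """Yaw angle series from the head pose quaternions.

    ``fc`` is the Gaussian low-pass cut-off shared with the hand analysis;
    pass ``None`` to skip smoothing (raw unwrapped yaw).  Raises
    :class:`DegeneratePoseError` if the forward axis comes within 5° of
    vertical at any sample (the horizontal projection then no longer defines
    an azimuth reliably).
    """
    rot = Rotation.from_quat(head.q, scalar_first=True)
    fwd = rot.apply(np.array([0.0, 1.0, 0.0]))
    horiz = np.hypot(fwd[:, 0], fwd[:, 1])
    bad = np.flatnonzero(horiz < _MIN_HORIZONTAL_SIN)
    if bad.size:
        raise DegeneratePoseError(
            f"head forward axis within 5° of vertical at sample {bad[0]}"
        )
    yaw_raw = np.degrees(np.arctan2(fwd[:, 0], fwd[:, 1]))
    yaw_unwrapped = np.unwrap(yaw_raw, period=360.0)
    if fc is None:
        yaw = yaw_unwrapped
    else:
        yaw = gaussian_lowpass(yaw_unwrapped, fs=head.fs, fc=fc)
    dt = 1.0 / head.fs
    rate = np.gradient(yaw, dt)
    accel = np.abs(np.gradient(rate, dt))
    return HeadingSeries(yaw=yaw, yaw_rate=rate, yaw_accel=accel, fs=head.fs)


def head_features(
    h: HeadingSeries,
    hand_bounds: MovementBounds,
    trial_window: tuple[int, int] | None = None,
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
) -> HeadFeatures:
    """Head-movement features referenced to the hand movement bounds.

    ``trial_window`` (inclusive sample indices) defaults to the whole series;
    ROM and the heading peak-velocity search use this window so that head
    orienting that precedes hand onset is not truncated.
    """
    n = len(h)
    lo, hi = (0, n - 1) if trial_window is None else trial_window
    if not (0 <= lo <= hand_bounds.i_start and hand_bounds.i_end <= hi <= n - 1):
        raise ValueError("hand bounds must lie within the trial window")
    yaw_win = h.yaw[lo : hi + 1]
    rom = float(yaw_win.max() - yaw_win.min())
    final_yaw = float(h.yaw[hand_bounds.i_end])
    total, before, after = count_acceleration_peaks(
        h.yaw_accel,
        hand_bounds.i_start,
        hand_bounds.i_end,
        hand_bounds.i_pvp,
        prominence_fraction,
    )
    i_head_pvp = lo + int(np.argmax(np.abs(h.yaw_rate[lo : hi + 1])))
    rel = (i_head_pvp - hand_bounds.i_start) / (hand_bounds.i_end - hand_bounds.i_start)
    return HeadFeatures(
        rom=rom,
        final_yaw=final_yaw,
        n_acc_peaks_total=total,
        n_acc_peaks_before_hand_pvp=before,
        n_acc_peaks_after_hand_pvp=after,
        head_pvp_relative_position=float(np.clip(rel, 0.0, 1.0)),
    )


def early_heading_fraction(trials, by_condition: bool = True):
    """Fraction of trials whose heading/hand peak velocity falls in the first
    third of the hand movement.

    ``trials`` is a tidy per-trial table (DataFrame or list of dicts) with
    columns ``head_pvp_relative_position``, ``pvp_relative_position`` and,
    when ``by_condition`` is true, ``condition``.  Returns a DataFrame with
    columns ``condition`` (or a single ``all`` row), ``head_fraction``,
    ``hand_fraction`` and ``n``.
    """
    import pandas as pd

    df = pd.DataFrame(trials)
    if df.empty:
        raise ValueError("no trials provided")

    def _frac(g):
        return pd.Series(
            {
                "head_fraction": float((g["head_pvp_relative_position"] <= 1 / 3).mean()),
                "hand_fraction": float((g["pvp_relative_position"] <= 1 / 3).mean()),
                "n": int(len(g)),
            }
        )

    if by_condition and "condition" in df.columns:
        out = (
            df.groupby("condition", sort=True)
            .apply(_frac, include_groups=False)
            .reset_index()
        )
    else:
        out = _frac(df).to_frame().T
        out.insert(0, "condition", "all")
    out["n"] = out["n"].astype(int)
    return out
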