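"""Target geometry, pointed-direction measurement and angular errors.

Azimuths follow the protractor convention of the task: the angle of a point
relative to the start marker is ``atan2(x, y)`` in degrees, 0° straight
ahead, positive to the right.  The signed pointing error is the pointed
azimuth minus the target azimuth, so pointing left of the target gives a
negative error.

The conflicting-avatar transform shifts the *heard* hand direction by a
constant azimuthal offset (−18.5° in condition D) without touching the real
hand position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import TARGET_AZIMUTHS_DEG, TARGET_DISTANCE_M, TrialRecord
from .kinematics import MovementBounds, gaussian_lowpass

__all__ = [
    "UnstableAngleError",
    "PointingResult",
    "TargetSpec",
    "azimuth_deg",
    "pointed_azimuth",
    "pointing_errors",
    "avatar_render_azimuth",
    "head_relative_azimuth",
    "wrap_deg",
    "MIN_ENDPOINT_RADIUS_M",
]

#: Minimum horizontal endpoint distance from the start marker for the pointed
#: angle to be numerically stable (a trial-level guard; distinct from the
#: 10 cm subject-level short-trajectory exclusion).
MIN_ENDPOINT_RADIUS_M = 0.05


class UnstableAngleError(ValueError):
    """Endpoint too close to the protractor origin for a stable angle."""


@dataclass(frozen=True)
class TargetSpec:
    """A virtual auditory target on the table plane."""

    azimuth_deg: float
    distance_m: float = TARGET_DISTANCE_M

    def __post_init__(self):
        if not any(abs(self.azimuth_deg - a) < 1e-9 for a in TARGET_AZIMUTHS_DEG):
            raise ValueError(
                f"target azimuth must be one of {TARGET_AZIMUTHS_DEG}, "
                f"got {self.azimuth_deg}"
            )


@dataclass(frozen=True)
class PointingResult:
    pointed_azimuth_deg: float
    signed_error_deg: float   # pointed - target; negative = left of target
    abs_error_deg: float

    def as_dict(self) -> dict:
        return {
            "pointed_azimuth_deg": self.pointed_azimuth_deg,
            "signed_error_deg": self.signed_error_deg,
            "abs_error_deg": self.abs_error_deg,
        }


def wrap_deg(angle: float) -> float:
    """Wrap an angle in degrees to the interval (−180, 180]."""
    return -((-np.asarray(angle) + 180.0) % 360.0 - 180.0)


def azimuth_deg(p, origin=(0.0, 0.0, 0.0)) -> float:
    """Horizontal-plane azimuth of ``p`` seen from ``origin``: ``atan2(x, y)``."""
    p = np.asarray(p, dtype=float)
    o = np.asarray(origin, dtype=float)
    return float(np.degrees(np.arctan2(p[0] - o[0], p[1] - o[1])))


def pointed_azimuth(
    trial: TrialRecord,
    bounds: MovementBounds,
    p_filt: np.ndarray | None = None,
    min_radius_m: float = MIN_ENDPOINT_RADIUS_M,
) -> float:
    """Pointed direction: azimuth of the movement endpoint from the marker.

    The endpoint is the filtered hand position at the movement offset sample
    (in-silico equivalent of reading the table protractor).  Raises
    :class:`UnstableAngleError` if the endpoint lies within ``min_radius_m``
    of the marker in the horizontal plane.
    """
    if p_filt is None:
        p_filt = gaussian_lowpass(trial.hand)
    end = p_filt[bounds.i_end]
    r = np.hypot(end[0] - trial.start_marker[0], end[1] - trial.start_marker[1])
    if r < min_radius_m:
        raise UnstableAngleError(
            f"endpoint {r * 100:.1f} cm from start marker; "
            f"need >= {min_radius_m * 100:.0f} cm for a stable angle"
        )
    return azimuth_deg(end, trial.start_marker)


def pointing_errors(pointed_deg: float, target: TargetSpec | float) -> PointingResult:
    """Signed and absolute angular pointing error for one trial."""
    target_deg = target.azimuth_deg if isinstance(target, TargetSpec) else float(target)
    if not (np.isfinite(pointed_deg) and np.isfinite(target_deg)):
        raise ValueError("pointed and target azimuths must be finite")
    signed = float(pointed_deg - target_deg)
    return PointingResult(
        pointed_azimuth_deg=float(pointed_deg),
        signed_error_deg=signed,
        abs_error_deg=abs(signed),
    )


def avatar_render_azimuth(
    hand_pos, start_marker, shift_deg: float
) -> float:
    """Azimuth at which the auditory hand avatar is rendered.

    The rendered direction is the actual hand azimuth plus ``shift_deg``
    (0 for the veridical avatar in condition C; −18.5° for the conflicting
    avatar in condition D, i.e. 18.5° to the left of the real hand).
    """
    hand_pos = np.asarray(hand_pos, dtype=float)
    sm = np.asarray(start_marker, dtype=float)
    r = np.hypot(hand_pos[0] - sm[0], hand_pos[1] - sm[1])
    if r < 0.01:
        raise UnstableAngleError(
            "hand within 1 cm of the start marker: avatar azimuth undefined"
        )
    if not np.isfinite(shift_deg):
        raise ValueError("shift_deg must be finite")
    return azimuth_deg(hand_pos, sm) + float(shift_deg)


def head_relative_azimuth(world_azimuth_deg: float, head_yaw_deg: float) -> float:
    """Azimuth of a world direction in head-centred coordinates.

    ``world − yaw``, wrapped to (−180, 180].  Used by the generator's
    head-centred stimulus bookkeeping.
    """
    return float(wrap_deg(world_azimuth_deg - head_yaw_deg))
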