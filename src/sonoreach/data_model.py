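"""Trial and session data model with plain-text on-disk formats.

A *trial* is one pointing gesture toward a virtual auditory target: the hand
endpoint (index fingertip) trajectory, the head rigid-body pose, and the trial
metadata (condition, target azimuth, stimulus duration).  Trials are stored as
UTF-8 CSV files with ``#``-prefixed ``key=value`` header lines; a *session*
directory holds one manifest (JSON) plus one CSV per trial.

Conventions (recorded in every trial header):

* coordinate frame: x to the subject's right, y forward, z up; the azimuth of
  a point is ``atan2(x, y)`` in degrees, so 0° is straight ahead and positive
  angles are to the right (the protractor convention of the task);
* quaternions are scalar-first ``(w, x, y, z)``, right-handed, world-from-body;
* time is stored as a sample index plus the sampling rate ``fs``; the time
  vector ``t = i / fs`` is derived, never stored, so grid-uniformity checks do
  not accumulate float drift;
* units are metres, seconds and degrees at all interfaces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "CONDITIONS",
    "CONDITION_STIMULUS_MS",
    "CONDITION_AVATAR_SHIFT_DEG",
    "TARGET_AZIMUTHS_DEG",
    "TARGET_DISTANCE_M",
    "FormatError",
    "TrajectorySeries",
    "HeadPoseSeries",
    "TrialMeta",
    "TrialRecord",
    "SessionConfig",
    "read_trial",
    "write_trial",
    "load_session",
    "save_session",
]

#: The four experimental conditions: A = short target sound (250 ms),
#: B = long target sound (2000 ms), C = short sound + veridical auditory hand
#: avatar, D = short sound + avatar shifted 18.5° to the left of the hand.
CONDITIONS = ("A", "B", "C", "D")
CONDITION_STIMULUS_MS = {"A": 250, "B": 2000, "C": 250, "D": 250}
CONDITION_AVATAR_SHIFT_DEG = {"A": 0.0, "B": 0.0, "C": 0.0, "D": -18.5}

#: Target loudspeaker azimuths (degrees, positive right) and virtual distance.
TARGET_AZIMUTHS_DEG = (-35.0, -20.0, 0.0, 20.0, 35.0)
TARGET_DISTANCE_M = 0.60

_FLOAT_FMT = "%.10f"
_TRIAL_MAGIC = "sonoreach-trial v1"
_COLUMNS = ("i", "hx", "hy", "hz", "px", "py", "pz", "qw", "qx", "qy", "qz")


class FormatError(ValueError):
    """A trial or manifest file violates the on-disk format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrajectorySeries:
    """Uniformly sampled 3-vector position series.

    Parameters
    ----------
    p : (n, 3) array of float
        Positions in metres; every coordinate must be finite, ``n >= 2``.
    fs : float
        Sampling rate in Hz.
    """

    p: np.ndarray
    fs: float

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if p.ndim != 2 or p.shape[1] != 3:
            raise ValueError(f"position array must be (n, 3), got {p.shape}")
        if p.shape[0] < 2:
            raise ValueError("series must contain at least 2 samples")
        if not np.all(np.isfinite(p)):
            raise ValueError("positions contain non-finite values")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return self.p.shape[0]

    @property
    def t(self) -> np.ndarray:
        """Derived time vector ``i / fs`` in seconds."""
        return np.arange(len(self)) / self.fs


@dataclass(frozen=True)
class HeadPoseSeries:
    """Position plus scalar-first unit-quaternion orientation series.

    The quaternion rotates body-frame vectors into the world frame; the head's
    forward axis is body ``+y``.  ``||q|| = 1`` within 1e-6 at every sample.
    """

    p: np.ndarray
    q: np.ndarray
    fs: float

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "q", q)
        if p.ndim != 2 or p.shape[1] != 3:
            raise ValueError(f"position array must be (n, 3), got {p.shape}")
        if q.ndim != 2 or q.shape[1] != 4:
            raise ValueError(f"quaternion array must be (n, 4), got {q.shape}")
        if p.shape[0] != q.shape[0]:
            raise ValueError("position and quaternion series differ in length")
        if p.shape[0] < 2:
            raise ValueError("series must contain at least 2 samples")
        if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
            raise ValueError("pose series contains non-finite values")
        norms = np.linalg.norm(q, axis=1)
        bad = np.flatnonzero(np.abs(norms - 1.0) > 1e-6)
        if bad.size:
            raise ValueError(
                f"non-unit quaternion at sample {bad[0]} (norm {norms[bad[0]]:.8f})"
            )
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return self.p.shape[0]

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self)) / self.fs


@dataclass(frozen=True)
class TrialMeta:
    """Metadata for one pointing trial."""

    subject_id: str
    condition: str
    target_azimuth_deg: float
    stimulus_duration_ms: int | None = None
    trial_index: int = 0
    avatar_shift_deg: float | None = None

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        expected_ms = CONDITION_STIMULUS_MS[self.condition]
        if self.stimulus_duration_ms is None:
            object.__setattr__(self, "stimulus_duration_ms", expected_ms)
        elif self.stimulus_duration_ms != expected_ms:
            raise ValueError(
                f"condition {self.condition} implies stimulus_duration_ms={expected_ms}, "
                f"got {self.stimulus_duration_ms}"
            )
        expected_shift = CONDITION_AVATAR_SHIFT_DEG[self.condition]
        if self.avatar_shift_deg is None:
            object.__setattr__(self, "avatar_shift_deg", expected_shift)
        elif abs(self.avatar_shift_deg - expected_shift) > 1e-9:
            raise ValueError(
                f"condition {self.condition} implies avatar_shift_deg={expected_shift}, "
                f"got {self.avatar_shift_deg}"
            )
        if self.trial_index < 0:
            raise ValueError("trial_index must be >= 0")

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "condition": self.condition,
            "target_azimuth_deg": self.target_azimuth_deg,
            "stimulus_duration_ms": self.stimulus_duration_ms,
            "trial_index": self.trial_index,
            "avatar_shift_deg": self.avatar_shift_deg,
        }


@dataclass(frozen=True)
class TrialRecord:
    """One trial: hand trajectory, head pose, metadata and start marker.

    ``start_marker`` is the tactile marker on the table where the palm rests
    at trial start; it is the origin of the pointing protractor.
    """

    meta: TrialMeta
    hand: TrajectorySeries
    head: HeadPoseSeries
    start_marker: np.ndarray

    def __post_init__(self):
        sm = np.asarray(self.start_marker, dtype=float)
        object.__setattr__(self, "start_marker", sm)
        if sm.shape != (3,) or not np.all(np.isfinite(sm)):
            raise ValueError("start_marker must be a finite 3-vector")
        if len(self.hand) != len(self.head):
            raise ValueError("hand and head series must cover a common time window")
        if abs(self.hand.fs - self.head.fs) > 1e-9:
            raise ValueError("hand and head series must share the sampling rate")


@dataclass(frozen=True)
class SessionConfig:
    """Configuration of a four-condition recording session.

    ``order_seed`` fixes the pseudo-random target order, which — as in the
    task protocol — is the *same* for every subject; ``seed`` drives all
    stochastic trajectory generation and differs across subjects.
    """

    subject_id: str
    condition_order: tuple = CONDITIONS
    trials_per_session: int = 32
    targets_deg: tuple = TARGET_AZIMUTHS_DEG
    seed: int = 0
    order_seed: int = 20130422
    group: int = 1
    hrtf: str = "selected"
    generator_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if sorted(self.condition_order) != sorted(CONDITIONS):
            raise ValueError("condition_order must be a permutation of A, B, C, D")
        if self.trials_per_session < 1:
            raise ValueError("trials_per_session must be >= 1")

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "condition_order": list(self.condition_order),
            "trials_per_session": self.trials_per_session,
            "targets_deg": list(self.targets_deg),
            "seed": self.seed,
            "order_seed": self.order_seed,
            "group": self.group,
            "hrtf": self.hrtf,
            "generator_params": self.generator_params,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        d["condition_order"] = tuple(d.get("condition_order", CONDITIONS))
        d["targets_deg"] = tuple(d.get("targets_deg", TARGET_AZIMUTHS_DEG))
        return cls(**d)


# ---------------------------------------------------------------------------
# Trial file I/O
# ---------------------------------------------------------------------------


def write_trial(trial: TrialRecord, path: str | Path) -> Path:
    """Write one trial to a CSV file with a ``#`` key=value header.

    The float format is fixed, so two writes of the same trial produce
    identical bytes.
    """
    path = Path(path)
    m = trial.meta
    sm = ",".join(_FLOAT_FMT % v for v in trial.start_marker)
    lines = [
        f"# {_TRIAL_MAGIC}",
        f"# subject_id={m.subject_id}",
        f"# condition={m.condition}",
        f"# target_azimuth_deg={m.target_azimuth_deg!r}",
        f"# stimulus_duration_ms={m.stimulus_duration_ms}",
        f"# trial_index={m.trial_index}",
        f"# avatar_shift_deg={m.avatar_shift_deg!r}",
        f"# fs={trial.hand.fs!r}",
        f"# start_marker={sm}",
        "# quaternion=scalar-first,world-from-body",
        "# frame=x-right,y-forward,z-up",
        ",".join(_COLUMNS),
    ]
    n = len(trial.hand)
    body = np.empty((n, 10))
    body[:, 0:3] = trial.hand.p
    body[:, 3:6] = trial.head.p
    body[:, 6:10] = trial.head.q
    rows = [
        "%d," % i + ",".join(_FLOAT_FMT % v for v in body[i]) for i in range(n)
    ]
    path.write_text("\n".join(lines + rows) + "\n", encoding="utf-8")
    return path


def _parse_header(lines: list[str], path: Path) -> dict:
    header = {}
    for ln in lines:
        body = ln[1:].strip()
        if "=" in body:
            k, v = body.split("=", 1)
            header[k.strip()] = v.strip()
    required = (
        "subject_id", "condition", "target_azimuth_deg", "stimulus_duration_ms",
        "trial_index", "avatar_shift_deg", "fs", "start_marker",
    )
    missing = [k for k in required if k not in header]
    if missing:
        raise FormatError(f"{path}: malformed header, missing keys {missing}")
    return header


def read_trial(path: str | Path) -> TrialRecord:
    """Read a trial CSV written by :func:`write_trial`.

    Raises
    ------
    FormatError
        On a malformed header, a non-contiguous sample index (non-uniform time
        grid), a non-finite coordinate, or a non-unit quaternion; the message
        names the offending row.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    hdr_lines = [ln for ln in lines if ln.startswith("#")]
    if not hdr_lines or _TRIAL_MAGIC not in hdr_lines[0]:
        raise FormatError(f"{path}: malformed header, missing '{_TRIAL_MAGIC}' magic line")
    header = _parse_header(hdr_lines, path)

    data_lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not data_lines or data_lines[0].split(",") != list(_COLUMNS):
        raise FormatError(f"{path}: malformed column header, expected {','.join(_COLUMNS)}")
    try:
        data = np.array(
            [[float(x) for x in ln.split(",")] for ln in data_lines[1:]], dtype=float
        )
    except ValueError as exc:
        raise FormatError(f"{path}: unparseable numeric value ({exc})") from exc
    if data.ndim != 2 or data.shape[1] != len(_COLUMNS):
        raise FormatError(f"{path}: expected {len(_COLUMNS)} columns")

    bad = np.flatnonzero(~np.isfinite(data).all(axis=1))
    if bad.size:
        raise FormatError(f"{path}: non-finite coordinate at row {bad[0]}")
    idx = data[:, 0]
    expect = np.arange(len(idx), dtype=float)
    off = np.flatnonzero(idx != expect)
    if off.size:
        raise FormatError(
            f"{path}: non-uniform time grid at row {off[0]} "
            f"(sample index {idx[off[0]]:g}, expected {expect[off[0]]:g})"
        )
    qnorm = np.linalg.norm(data[:, 7:11], axis=1)
    badq = np.flatnonzero(np.abs(qnorm - 1.0) > 1e-6)
    if badq.size:
        raise FormatError(f"{path}: non-unit quaternion at row {badq[0]}")

    fs = float(header["fs"])
    meta = TrialMeta(
        subject_id=header["subject_id"],
        condition=header["condition"],
        target_azimuth_deg=float(header["target_azimuth_deg"]),
        stimulus_duration_ms=int(header["stimulus_duration_ms"]),
        trial_index=int(header["trial_index"]),
        avatar_shift_deg=float(header["avatar_shift_deg"]),
    )
    try:
        return TrialRecord(
            meta=meta,
            hand=TrajectorySeries(p=data[:, 1:4], fs=fs),
            head=HeadPoseSeries(p=data[:, 4:7], q=data[:, 7:11], fs=fs),
            start_marker=np.array([float(v) for v in header["start_marker"].split(",")]),
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Session I/O
# ---------------------------------------------------------------------------

_MANIFEST_NAME = "manifest.json"


def save_session(
    trials: Sequence[TrialRecord], config: SessionConfig, dir_path: str | Path
) -> Path:
    """Write all trials plus a JSON manifest preserving trial order."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    names = []
    for k, trial in enumerate(trials):
        name = f"trial_{k:04d}_{trial.meta.condition}.csv"
        write_trial(trial, dir_path / name)
        names.append(name)
    manifest = {"config": config.as_dict(), "trials": names}
    (dir_path / _MANIFEST_NAME).write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return dir_path


def load_session(dir_path: str | Path) -> tuple[list[TrialRecord], SessionConfig]:
    """Load a session directory; trials are returned in manifest order."""
    dir_path = Path(dir_path)
    manifest_path = dir_path / _MANIFEST_NAME
    if not manifest_path.exists():
        raise FormatError(f"{dir_path}: missing {_MANIFEST_NAME}")
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    config = SessionConfig.from_dict(manifest["config"])
    trials = []
    for name in manifest["trials"]:
        p = dir_path / name
        if not p.exists():
            raise FileNotFoundError(f"manifest references absent trial file {p}")
        trials.append(read_trial(p))
    return trials, config
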