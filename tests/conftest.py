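"""Shared builders and fixtures for the test suite.

Everything is generated programmatically; session-scoped fixtures hold the
expensive synthetic cohorts so several tests can share one generation pass.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pytest

import sonoreach as sr
from sonoreach.synthetic import minimum_jerk

logging.getLogger("sonoreach").setLevel(logging.ERROR)

FS = 100.0

# Analytic 3%-of-peak crossing of the minimum-jerk speed profile:
# 30 tau^2 (1-tau)^2 = 0.03 * 1.875  =>  tau (1-tau) = sqrt(0.001875)
TAU_ONSET = 0.5 * (1.0 - np.sqrt(1.0 - 4.0 * np.sqrt(0.03 * 1.875 / 30.0)))


def minjerk_positions(
    D: float,
    T: float,
    fs: float = FS,
    pre_s: float = 0.5,
    post_s: float = 0.5,
    azimuth_deg: float = 0.0,
) -> np.ndarray:
    """(n, 3) positions of a straight minimum-jerk reach with stationary pads."""
    n = int(round((pre_s + T + post_s) * fs)) + 1
    t = np.arange(n) / fs
    x = D * minimum_jerk((t - pre_s) / T)
    th = np.deg2rad(azimuth_deg)
    return np.outer(x, np.array([np.sin(th), np.cos(th), 0.0]))


def identity_quats(n: int) -> np.ndarray:
    q = np.zeros((n, 4))
    q[:, 0] = 1.0
    return q


def yaw_quats(yaw_deg: np.ndarray) -> np.ndarray:
    """Scalar-first quaternions for a pure heading rotation (positive right)."""
    half = -np.deg2rad(np.asarray(yaw_deg, float)) / 2.0
    q = np.zeros((half.shape[0], 4))
    q[:, 0] = np.cos(half)
    q[:, 3] = np.sin(half)
    return q


def make_trial(
    hand_p: np.ndarray,
    yaw_deg: np.ndarray | None = None,
    condition: str = "A",
    target_azimuth_deg: float = 0.0,
    fs: float = FS,
    subject_id: str = "T01",
) -> sr.TrialRecord:
    n = hand_p.shape[0]
    yaw = np.zeros(n) if yaw_deg is None else np.asarray(yaw_deg, float)
    head_p = np.tile(np.array([0.0, -0.35, 0.45]), (n, 1))
    return sr.TrialRecord(
        meta=sr.TrialMeta(
            subject_id=subject_id,
            condition=condition,
            target_azimuth_deg=target_azimuth_deg,
        ),
        hand=sr.TrajectorySeries(p=hand_p, fs=fs),
        head=sr.HeadPoseSeries(p=head_p, q=yaw_quats(yaw), fs=fs),
        start_marker=np.zeros(3),
    )


def identity_params(**overrides) -> sr.GeneratorParams:
    """Noise-free, submovement-free generator with unit gain and zero bias."""
    conds = {c: sr.ConditionParams(head_lead_sd_s=0.0) for c in sr.CONDITIONS}
    defaults = dict(
        conditions=conds,
        mocap_noise_sd_m=0.0,
        head_yaw_noise_deg=0.0,
        reach_duration_jitter=0.0,
    )
    defaults.update(overrides)
    return sr.GeneratorParams(**defaults)


@pytest.fixture(scope="session")
def calibrated_cohort():
    """50-subject cohort at the calibrated defaults, analyzed end to end."""
    sessions = sr.generate_cohort(50, seed=20214)
    return sr.analyze_cohort(sessions)


@pytest.fixture(scope="session")
def exclusion_cohort():
    """24-subject cohort with 3 slow, 2 target-independent and 1
    short-trajectory subject planted at known indices."""
    base = sr.default_calibration()
    slow = dataclasses.replace(base, reach_duration_s=3.0)
    indep = dataclasses.replace(base, pointing_override_deg=(-90.0, 90.0))
    short = dataclasses.replace(base, reach_distance_m=0.07)
    subject_params = {2: slow, 9: slow, 17: slow, 5: indep, 12: indep, 20: short}
    sessions = sr.generate_cohort(24, seed=77, subject_params=subject_params)
    results = sr.analyze_cohort(sessions)
    planted = {
        "S03": "slow_indirect", "S10": "slow_indirect", "S18": "slow_indirect",
        "S06": "no_target_dependence", "S13": "no_target_dependence",
        "S21": "short_trajectory",
    }
    return results, planted
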