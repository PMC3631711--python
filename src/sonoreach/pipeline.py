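"""Per-trial analysis orchestration, exclusions, aggregation and statistics.

``analyze_trial`` composes the kinematic, heading and geometric measures into
one tidy feature row; ``analyze_trials`` maps it over a session or cohort.
``apply_exclusions`` implements the three subject-level exclusion rules
(slow/indirect movements, no target dependence, short trajectories);
``build_design_table`` averages features per subject x condition x target for
the repeated-measures design; ``rm_anova`` runs the repeated-measures ANOVA
(two within factors) with Bonferroni-adjusted pairwise post-hoc comparisons;
``report`` writes the tidy CSVs and summary figures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import heading as hd
from . import kinematics as km
from .data_model import TrialRecord
from .geometry import UnstableAngleError, pointed_azimuth, pointing_errors
from .kinematics import NoMovementError

__all__ = [
    "AnalysisSettings",
    "ExclusionThresholds",
    "ExclusionReport",
    "AnovaSummary",
    "analyze_trial",
    "analyze_trials",
    "apply_exclusions",
    "build_design_table",
    "rm_anova",
    "mixed_anova",
    "report",
    "FEATURE_COLUMNS",
]

logger = logging.getLogger("sonoreach")

FEATURE_COLUMNS = (
    "duration", "v_peak", "v_mean", "path_length",
    "n_acc_peaks_total", "n_acc_peaks_before_pvp", "n_acc_peaks_after_pvp",
    "pvp_relative_position",
    "head_rom", "head_final_yaw", "head_n_acc_peaks_total",
    "head_n_acc_peaks_before_hand_pvp", "head_n_acc_peaks_after_hand_pvp",
    "head_pvp_relative_position",
    "pointed_azimuth_deg", "signed_error_deg", "abs_error_deg",
)


@dataclass(frozen=True)
class AnalysisSettings:
    """Tunable thresholds of the per-trial analysis chain."""

    cutoff_hz: float = km.DEFAULT_CUTOFF_HZ
    threshold_fraction: float = km.DEFAULT_THRESHOLD_FRACTION
    prominence_fraction: float = km.DEFAULT_PROMINENCE_FRACTION
    displacement_threshold_m: float = km.DEFAULT_DISPLACEMENT_THRESHOLD_M


@dataclass(frozen=True)
class ExclusionThresholds:
    """Subject-level exclusion rule parameters.

    Rule 1 (slow/indirect): mean movement duration > ``slow_factor`` x cohort
    mean AND > ``slow_abs_s`` (the longer stimulus duration).  Rule 2 (no
    target dependence): pointed-vs-target regression slope below
    ``min_slope`` OR at least ``pm90_fraction`` of endpoints within
    ``pm90_tol_deg`` of +/-90 deg.  Rule 3 (short trajectories): median path
    length below ``min_path_m``.
    """

    slow_factor: float = 2.0
    slow_abs_s: float = 2.0
    min_slope: float = 0.1
    pm90_tol_deg: float = 5.0
    pm90_fraction: float = 0.9
    min_path_m: float = 0.10


@dataclass(frozen=True)
class ExclusionReport:
    excluded_subjects: tuple  # of (subject_id, rule)
    retained_subjects: tuple

    def rule_of(self, subject_id: str) -> str | None:
        for sid, rule in self.excluded_subjects:
            if sid == subject_id:
                return rule
        return None


@dataclass(frozen=True)
class AnovaSummary:
    """Repeated-measures ANOVA table plus Bonferroni post-hoc comparisons."""

    dv: str
    anova: pd.DataFrame     # Source, F, df1, df2, p
    posthoc: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Per-trial analysis
# ---------------------------------------------------------------------------


def analyze_trial(
    trial: TrialRecord, settings: AnalysisSettings = AnalysisSettings()
) -> dict:
    """One tidy feature row for a trial; failures yield a flagged row."""
    row = dict(trial.meta.as_dict())
    row["flag"] = ""
    try:
        p_filt = km.gaussian_lowpass(trial.hand, fc=settings.cutoff_hz)
        kin = km.compute_norms(p_filt, trial.hand.fs)
        window = km.primary_segment(
            trial.hand, trial.start_marker, settings.displacement_threshold_m
        )
        bounds = km.detect_bounds(kin, window, settings.threshold_fraction)
        feats = km.hand_features(kin, bounds, settings.prominence_fraction)
        row.update(feats.as_dict())

        heading = hd.extract_heading(trial.head, fc=settings.cutoff_hz)
        row.update(
            hd.head_features(
                heading, bounds, prominence_fraction=settings.prominence_fraction
            ).as_dict()
        )

        pointed = pointed_azimuth(trial, bounds, p_filt=p_filt)
        row.update(pointing_errors(pointed, trial.meta.target_azimuth_deg).as_dict())
    except NoMovementError as exc:
        row["flag"] = "no_movement"
        logger.warning("trial %s/%s: %s", row["subject_id"], row["trial_index"], exc)
    except (UnstableAngleError, hd.DegeneratePoseError) as exc:
        row["flag"] = type(exc).__name__
        logger.warning("trial %s/%s: %s", row["subject_id"], row["trial_index"], exc)
    for col in FEATURE_COLUMNS:
        row.setdefault(col, np.nan)
    return row


def analyze_trials(
    trials: Iterable[TrialRecord],
    settings: AnalysisSettings = AnalysisSettings(),
    group: int | None = None,
    hrtf: str | None = None,
) -> pd.DataFrame:
    """Tidy per-trial feature table for a sequence of trials."""
    rows = [analyze_trial(t, settings) for t in trials]
    df = pd.DataFrame(rows)
    if group is not None:
        df["group"] = group
    if hrtf is not None:
        df["hrtf"] = hrtf
    return df


def analyze_cohort(sessions, settings: AnalysisSettings = AnalysisSettings()) -> pd.DataFrame:
    """Analyze ``(trials, config)`` pairs as produced by the generator."""
    frames = []
    for trials, config in sessions:
        logger.info("analyzing subject %s (%d trials)", config.subject_id, len(trials))
        frames.append(
            analyze_trials(trials, settings, group=config.group, hrtf=config.hrtf)
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Subject-level exclusions
# ---------------------------------------------------------------------------


def apply_exclusions(
    results: pd.DataFrame, thresholds: ExclusionThresholds = ExclusionThresholds()
) -> tuple[ExclusionReport, pd.DataFrame]:
    """Apply the three subject-level exclusion rules.

    The cohort mean duration for rule 1 is computed once over *all* subjects
    before any removal, so the outcome does not depend on subject order.  A
    subject tripping several rules is attributed to the first in the order
    slow_indirect, no_target_dependence, short_trajectory.
    """
    valid = results[results["flag"] == ""]
    cohort_mean_duration = valid["duration"].mean()
    excluded, retained = [], []
    for sid, g in valid.groupby("subject_id", sort=True):
        rule = None
        if (
            g["duration"].mean() > thresholds.slow_factor * cohort_mean_duration
            and g["duration"].mean() > thresholds.slow_abs_s
        ):
            rule = "slow_indirect"
        if rule is None:
            x = g["target_azimuth_deg"].to_numpy(float)
            y = g["pointed_azimuth_deg"].to_numpy(float)
            slope = (
                np.polyfit(x, y, 1)[0] if np.ptp(x) > 0 and len(g) >= 2 else 0.0
            )
            near_pm90 = np.minimum(np.abs(y - 90.0), np.abs(y + 90.0))
            if (
                abs(slope) < thresholds.min_slope
                or np.mean(near_pm90 <= thresholds.pm90_tol_deg) >= thresholds.pm90_fraction
            ):
                rule = "no_target_dependence"
        if rule is None and g["path_length"].median() < thresholds.min_path_m:
            rule = "short_trajectory"
        if rule is None:
            retained.append(sid)
        else:
            excluded.append((sid, rule))
            logger.info("excluding subject %s (%s)", sid, rule)
    report_ = ExclusionReport(tuple(excluded), tuple(retained))
    filtered = results[results["subject_id"].isin(retained)].reset_index(drop=True)
    return report_, filtered


# ---------------------------------------------------------------------------
# Aggregation and statistics
# ---------------------------------------------------------------------------


def build_design_table(
    results: pd.DataFrame, features: Sequence[str] = FEATURE_COLUMNS
) -> pd.DataFrame:
    """Cell means per subject x condition x target for every feature.

    Flagged trials are dropped before averaging; ``group`` and ``hrtf``
    columns are carried through when present.
    """
    if results.empty:
        raise ValueError("no results to aggregate")
    valid = results[results["flag"] == ""]
    keys = ["subject_id", "condition", "target_azimuth_deg"]
    carry = [c for c in ("group", "hrtf") if c in results.columns]
    agg = {f: "mean" for f in features if f in valid.columns}
    agg.update({c: "first" for c in carry})
    table = valid.groupby(keys, sort=True).agg(agg).reset_index()

    n_cond = valid["condition"].nunique()
    n_targ = valid["target_azimuth_deg"].nunique()
    cells = table.groupby("subject_id").size()
    incomplete = cells[cells < n_cond * n_targ].index.tolist()
    if incomplete:
        logger.warning(
            "dropping %d subject(s) with missing design cells: %s",
            len(incomplete), incomplete,
        )
        table = table[~table["subject_id"].isin(incomplete)].reset_index(drop=True)
    return table


def _guard_degenerate(aov: pd.DataFrame) -> pd.DataFrame:
    # All-equal cells make every sum of squares vanish (0/0); the null-case
    # contract is F = 0, p = 1.
    bad = ~np.isfinite(aov["F"].to_numpy(float))
    if bad.any() and (np.nanmax(np.abs(aov.get("SS", pd.Series([0.0])))) < 1e-12):
        aov.loc[bad, "F"] = 0.0
        aov.loc[bad, "p"] = 1.0
    return aov


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    within: Sequence[str] = ("condition", "target_azimuth_deg"),
    subject: str = "subject_id",
    posthoc_factor: str | None = "condition",
) -> AnovaSummary:
    """Two-way repeated-measures ANOVA with Bonferroni post-hoc tests.

    The table must be balanced and complete (one row per subject x factor
    cell); unbalanced input raises rather than silently imputing.  Reported
    degrees of freedom are uncorrected (no sphericity correction).
    """
    import pingouin as pg

    counts = table.groupby([subject, *within], observed=True).size()
    if counts.empty:
        raise ValueError("empty design table")
    if counts.nunique() != 1 or counts.iloc[0] != 1:
        raise ValueError("unbalanced design table: one row per subject x cell required")
    n_cells = table.groupby(subject).size()
    if n_cells.nunique() != 1:
        raise ValueError("unbalanced design table: subjects differ in cell count")

    import warnings

    with warnings.catch_warnings():
        # sphericity epsilon is estimated but not used: uncorrected df only
        warnings.filterwarnings("ignore", message="Epsilon values might be")
        aov = pg.rm_anova(
            data=table, dv=dv, within=list(within), subject=subject, detailed=True
        )
    out = aov.rename(
        columns={"Source": "source", "ddof1": "df1", "ddof2": "df2", "p_unc": "p"}
    )[["source", "SS", "df1", "df2", "F", "p"]].copy()
    out = _guard_degenerate(out.rename(columns={"F": "F"}))

    posthoc = None
    if posthoc_factor is not None:
        ph = pg.pairwise_tests(
            data=table, dv=dv, within=[posthoc_factor], subject=subject,
            padjust="bonf",
        )
        posthoc = ph
    return AnovaSummary(dv=dv, anova=out, posthoc=posthoc)


def mixed_anova(
    table: pd.DataFrame,
    dv: str,
    within: str = "condition",
    between: str = "group",
    subject: str = "subject_id",
) -> AnovaSummary:
    """Mixed ANOVA: one within factor, one between-subject grouping factor."""
    import pingouin as pg

    cell = table.groupby([subject, within], observed=True)[dv].mean().reset_index()
    grp = table.groupby(subject, observed=True)[between].first().reset_index()
    data = cell.merge(grp, on=subject)
    aov = pg.mixed_anova(
        data=data, dv=dv, within=within, between=between, subject=subject
    )
    out = aov.rename(
        columns={"Source": "source", "DF1": "df1", "DF2": "df2", "p-unc": "p"}
    )
    keep = [c for c in ("source", "SS", "df1", "df2", "F", "p") if c in out.columns]
    return AnovaSummary(dv=dv, anova=out[keep].copy())


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

_CSV_FLOAT_FMT = "%.6g"


def report(results: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """Write tidy CSVs and summary figures for an analyzed cohort.

    Produces ``trials.csv``, ``design_table.csv``, ``condition_means.csv``
    and four figures: pointing error by condition/target, trajectory length,
    head ROM and final heading, and the distribution of hand/head
    peak-velocity relative positions.  Output bytes are deterministic for
    identical input.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if results.empty:
        raise ValueError("no results to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _save_csv(df: pd.DataFrame, name: str):
        path = out_dir / name
        df.to_csv(path, index=False, float_format=_CSV_FLOAT_FMT)
        written.append(path)

    _save_csv(results, "trials.csv")
    design = build_design_table(results)
    _save_csv(design, "design_table.csv")
    cond_means = (
        design.groupby("condition")[list(c for c in FEATURE_COLUMNS if c in design)]
        .mean()
        .reset_index()
    )
    _save_csv(cond_means, "condition_means.csv")

    valid = results[results["flag"] == ""]

    # Figure: pointing error by condition and by target
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    by_cond = valid.groupby("condition")["abs_error_deg"].mean()
    axes[0].bar(by_cond.index, by_cond.values, color="0.6")
    axes[0].set_xlabel("condition")
    axes[0].set_ylabel("absolute pointing error (deg)")
    for cond, g in valid.groupby("condition"):
        m = g.groupby("target_azimuth_deg")["signed_error_deg"].mean()
        axes[1].plot(m.index, m.values, marker="o", label=cond)
    axes[1].axhline(0.0, color="k", lw=0.5)
    axes[1].set_xlabel("target azimuth (deg)")
    axes[1].set_ylabel("signed pointing error (deg)")
    axes[1].legend(title="condition")
    fig.tight_layout()
    fig.savefig(out_dir / "pointing_error.png", dpi=120)
    plt.close(fig)
    written.append(out_dir / "pointing_error.png")

    # Figure: trajectory length by target and condition
    fig, ax = plt.subplots(figsize=(6, 4))
    for cond, g in valid.groupby("condition"):
        m = g.groupby("target_azimuth_deg")["path_length"].mean()
        ax.plot(m.index, m.values, marker="o", label=cond)
    ax.set_xlabel("target azimuth (deg)")
    ax.set_ylabel("trajectory length (m)")
    ax.legend(title="condition")
    fig.tight_layout()
    fig.savefig(out_dir / "trajectory_length.png", dpi=120)
    plt.close(fig)
    written.append(out_dir / "trajectory_length.png")

    # Figure: head ROM and final heading angle
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    rom = valid.groupby("condition")["head_rom"].mean()
    axes[0].bar(rom.index, rom.values, color="0.6")
    axes[0].set_xlabel("condition")
    axes[0].set_ylabel("heading ROM (deg)")
    for cond, g in valid.groupby("condition"):
        m = g.groupby("target_azimuth_deg")["head_final_yaw"].mean()
        axes[1].plot(m.index, m.values, marker="o", label=cond)
    axes[1].set_xlabel("target azimuth (deg)")
    axes[1].set_ylabel("final heading angle (deg)")
    axes[1].legend(title="condition")
    fig.tight_layout()
    fig.savefig(out_dir / "head_movement.png", dpi=120)
    plt.close(fig)
    written.append(out_dir / "head_movement.png")

    # Figure: distribution of peak-velocity relative positions
    fig, ax = plt.subplots(figsize=(6, 4))
    bins = np.linspace(0, 1, 21)
    ax.hist(valid["pvp_relative_position"].dropna(), bins=bins, alpha=0.6,
            label="hand", density=True)
    ax.hist(valid["head_pvp_relative_position"].dropna(), bins=bins, alpha=0.6,
            label="head", density=True)
    ax.axvline(1 / 3, color="k", ls="--", lw=0.8)
    ax.set_xlabel("peak-velocity relative position in hand movement")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "pvp_distribution.png", dpi=120)
    plt.close(fig)
    written.append(out_dir / "pvp_distribution.png")

    return written
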