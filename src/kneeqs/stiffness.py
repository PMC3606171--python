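"""Quasi-stiffness extraction from stance-phase moment-angle loops.

The knee's moment-angle trajectory in the weight-acceptance phase is nearly
linear in each of its two stages: flexion (loop point a, minimum moment after
heel contact, to b, maximum moment) and extension (b to c, minimum moment
before toe-off).  The quasi-stiffness of a stage is the slope of the ordinary
least-squares line fit of moment on angle over that stage, in N*m/rad; the
weight-acceptance quasi-stiffness is defined as the mean of the two stage
slopes (a single fit over a-c would be dominated by the longer extension
stage).  Stage excursions are reported as magnitudes in degrees and averaged
the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gait_data import Dataset, GaitTrial


class SegmentationError(RuntimeError):
    """Stage boundary detection failed (trial should be excluded)."""


class DegenerateFitError(RuntimeError):
    """Stage fit is ill-posed (constant angle or too few samples)."""


@dataclass
class StiffnessSummary:
    """Per-trial stage stiffnesses, excursions, fit quality and boundaries."""

    trial_id: str
    subject_id: str
    speed_mps: float
    K_flex: float          # N*m/rad
    K_ext: float           # N*m/rad
    K_wa: float            # (K_flex + K_ext) / 2, exactly
    dtheta_flex_deg: float
    dtheta_ext_deg: float
    dtheta_wa_deg: float   # (dtheta_flex + dtheta_ext) / 2, exactly
    r2_flex: float
    r2_ext: float
    idx_a: int
    idx_b: int
    idx_c: int
    intercept_flex: float  # N*m
    intercept_ext: float   # N*m


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge shrinkage (output length preserved)."""
    if window <= 1:
        return np.asarray(x, dtype=float)
    kernel = np.ones(window) / window
    padded = np.pad(np.asarray(x, dtype=float), window // 2, mode="edge")
    out = np.convolve(padded, kernel, mode="same")
    lo = window // 2
    return out[lo:lo + len(x)]


def detect_stage_points(trial_or_moment) -> tuple[int, int, int]:
    """Locate the stage boundary samples (a, b, c) on the moment trace.

    b is the global maximum of the moment; a the minimum on [start, b]; c the
    minimum on [b, end].  Ties break to the earliest sample.  Raises
    :class:`SegmentationError` if b sits on a boundary or either stage has
    fewer than 3 samples.
    """
    if isinstance(trial_or_moment, GaitTrial):
        moment = trial_or_moment.knee_moment_nm
    else:
        moment = np.asarray(trial_or_moment, dtype=float)
    n = moment.size
    if n < 5:
        raise SegmentationError("series too short to segment")
    idx_b = int(np.argmax(moment))
    if idx_b == 0 or idx_b == n - 1:
        raise SegmentationError("moment maximum at a series boundary")
    idx_a = int(np.argmin(moment[: idx_b + 1]))
    idx_c = idx_b + int(np.argmin(moment[idx_b:]))
    if idx_b - idx_a + 1 < 3 or idx_c - idx_b + 1 < 3:
        raise SegmentationError("fewer than 3 samples in a stage")
    return idx_a, idx_b, idx_c


def fit_stage(angle_rad, moment_nm, i0: int, i1: int):
    """OLS fit of moment on angle over samples i0..i1 inclusive.

    Returns (slope N*m/rad, intercept N*m, r2).
    """
    angle_rad = np.asarray(angle_rad, dtype=float)
    moment_nm = np.asarray(moment_nm, dtype=float)
    if i1 - i0 < 1:
        raise DegenerateFitError("need at least 2 samples to fit a stage")
    x = angle_rad[i0:i1 + 1]
    y = moment_nm[i0:i1 + 1]
    if np.ptp(x) == 0.0:
        raise DegenerateFitError("constant angle over the stage")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue) ** 2


def summarize_trial(trial: GaitTrial, smooth_window: int = 0) -> StiffnessSummary:
    """Segment one trial and compute stage quasi-stiffnesses and excursions.

    Smoothing (if requested) is applied to the moment trace before boundary
    detection only; fits always use the raw samples.
    """
    moment = trial.knee_moment_nm
    detect_on = moving_average(moment, smooth_window) if smooth_window else moment
    idx_a, idx_b, idx_c = detect_stage_points(detect_on)

    angle_rad = np.deg2rad(trial.knee_angle_deg)
    k_flex, b_flex, r2_flex = fit_stage(angle_rad, moment, idx_a, idx_b)
    k_ext, b_ext, r2_ext = fit_stage(angle_rad, moment, idx_b, idx_c)

    theta = trial.knee_angle_deg
    dth_flex = float(theta[idx_b] - theta[idx_a])
    dth_ext = float(abs(theta[idx_c] - theta[idx_b]))
    return StiffnessSummary(
        trial_id=trial.trial_id,
        subject_id=trial.subject_id,
        speed_mps=trial.speed,
        K_flex=k_flex,
        K_ext=k_ext,
        K_wa=(k_flex + k_ext) / 2.0,
        dtheta_flex_deg=dth_flex,
        dtheta_ext_deg=dth_ext,
        dtheta_wa_deg=(dth_flex + dth_ext) / 2.0,
        r2_flex=r2_flex,
        r2_ext=r2_ext,
        idx_a=idx_a,
        idx_b=idx_b,
        idx_c=idx_c,
        intercept_flex=b_flex,
        intercept_ext=b_ext,
    )


def summarize_dataset(dataset: Dataset, smooth_window: int = 0):
    """Summarize every trial; trials failing segmentation are excluded.

    Returns (summaries, exclusions) where exclusions is a list of
    (trial_id, reason) pairs.
    """
    summaries: list[StiffnessSummary] = []
    exclusions: list[tuple[str, str]] = []
    for trial in dataset.trials:
        try:
            summaries.append(summarize_trial(trial, smooth_window=smooth_window))
        except (SegmentationError, DegenerateFitError) as exc:
            exclusions.append((trial.trial_id, str(exc)))
    return summaries, exclusions
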