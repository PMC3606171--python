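"""Domain containers and plain-text IO for stance-phase gait datasets.

A dataset couples a subject table (anthropometrics) with a trial manifest;
each trial carries the sagittal-plane knee angle and internal knee moment
sampled over the stance phase of one walking condition.

Sign conventions: knee flexion angle positive (degrees in files), internal
knee extension moment positive (N*m), so the weight-acceptance moment-angle
slope is a positive quasi-stiffness.  A manifest may flag individual series
files recorded with the opposite convention; those are negated on load.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

#: Leg length as a fraction of stature (standard anthropometric ratio).
DEFAULT_LEG_RATIO = 0.53

SUBJECT_COLUMNS = ["subject_id", "sex", "weight_kg", "height_m"]
MANIFEST_COLUMNS = ["subject_id", "trial_id", "speed_mps", "series_file"]

SUMMARY_COLUMNS = [
    "trial_id", "subject_id", "speed_mps",
    "K_flex", "K_ext", "K_wa",
    "dtheta_flex_deg", "dtheta_ext_deg", "dtheta_wa_deg",
    "r2_flex", "r2_ext",
    "idx_a", "idx_b", "idx_c",
    "intercept_flex", "intercept_ext",
]


class GaitDataError(ValueError):
    """Validation failure in a gait data file or container."""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: identity plus body weight W (kg) and height H (m)."""

    subject_id: str
    weight: float
    height: float
    sex: Optional[str] = None
    leg_length: Optional[float] = None

    def __post_init__(self):
        if self.weight <= 0:
            raise GaitDataError(f"subject {self.subject_id}: weight must be > 0")
        if self.height <= 0:
            raise GaitDataError(f"subject {self.subject_id}: height must be > 0")
        if self.sex is not None and self.sex not in ("M", "F"):
            raise GaitDataError(f"subject {self.subject_id}: sex must be M or F")
        leg = self.effective_leg_length
        if not (0 < leg < self.height):
            raise GaitDataError(
                f"subject {self.subject_id}: leg length {leg} not in (0, height)"
            )

    @property
    def effective_leg_length(self) -> float:
        """Given leg length, or the anthropometric default 0.53*H."""
        if self.leg_length is not None:
            return self.leg_length
        return DEFAULT_LEG_RATIO * self.height


@dataclass
class GaitTrial:
    """One walking condition: gait speed V plus stance angle/moment series.

    ``grid`` is the abscissa the series was sampled on -- either time in
    seconds or a percent-of-stance grid; segmentation and fitting operate on
    sample indices, so either is accepted.
    """

    trial_id: str
    subject_id: str
    speed: float
    knee_angle_deg: np.ndarray
    knee_moment_nm: np.ndarray
    grid: Optional[np.ndarray] = None
    grid_kind: str = "stance_pct"  # or "time_s"
    source_protocol: str = "synthetic"  # treadmill | overground | synthetic

    def __post_init__(self):
        self.knee_angle_deg = np.asarray(self.knee_angle_deg, dtype=float)
        self.knee_moment_nm = np.asarray(self.knee_moment_nm, dtype=float)
        if self.knee_angle_deg.shape != self.knee_moment_nm.shape:
            raise GaitDataError(
                f"trial {self.trial_id}: angle/moment lengths differ "
                f"({self.knee_angle_deg.size} vs {self.knee_moment_nm.size})"
            )
        if self.knee_angle_deg.size < 10:
            raise GaitDataError(
                f"trial {self.trial_id}: series shorter than 10 samples"
            )
        if self.speed <= 0:
            raise GaitDataError(f"trial {self.trial_id}: speed must be > 0")
        if self.grid is not None:
            self.grid = np.asarray(self.grid, dtype=float)
            if self.grid.shape != self.knee_angle_deg.shape:
                raise GaitDataError(f"trial {self.trial_id}: grid length mismatch")
            if self.grid_kind == "time_s" and not np.all(np.diff(self.grid) > 0):
                raise GaitDataError(
                    f"trial {self.trial_id}: time must be strictly increasing"
                )

    @property
    def n_samples(self) -> int:
        return self.knee_angle_deg.size


@dataclass
class Dataset:
    """Validated collection of subjects and their trials."""

    subjects: dict[str, SubjectRecord] = field(default_factory=dict)
    trials: list[GaitTrial] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for t in self.trials:
            if t.subject_id not in self.subjects:
                raise GaitDataError(
                    f"trial {t.trial_id}: unknown subject_id {t.subject_id!r}"
                )
            key = (t.subject_id, t.trial_id)
            if key in seen:
                raise GaitDataError(f"duplicate (subject_id, trial_id) pair {key}")
            seen.add(key)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_trials(self) -> int:
        return len(self.trials)


# ---------------------------------------------------------------------------
# readers


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise GaitDataError(f"{path}: missing column(s) {missing}")


def read_subjects(path) -> dict[str, SubjectRecord]:
    """Read a subjects CSV (subject_id, sex, weight_kg, height_m[, leg_length_m])."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    _require_columns(df, ["subject_id", "weight_kg", "height_m"], path)
    subjects: dict[str, SubjectRecord] = {}
    for i, row in df.iterrows():
        try:
            weight = float(row["weight_kg"])
            height = float(row["height_m"])
            leg = row.get("leg_length_m")
            leg = None if leg is None or pd.isna(leg) else float(leg)
        except (TypeError, ValueError) as exc:
            raise GaitDataError(f"{path}: row {i}: non-numeric cell ({exc})") from exc
        sex = row.get("sex")
        sex = None if sex is None or pd.isna(sex) else str(sex)
        rec = SubjectRecord(str(row["subject_id"]), weight, height, sex, leg)
        if rec.subject_id in subjects:
            raise GaitDataError(f"{path}: duplicate subject_id {rec.subject_id!r}")
        subjects[rec.subject_id] = rec
    return subjects


def read_series(path, sign_convention: str = "standard"):
    """Read one series CSV -> (grid, grid_kind, angle_deg, moment_nm).

    ``sign_convention='flipped'`` negates angle and moment, for files recorded
    with extension angle / external moment positive.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "time_s" in df.columns:
        grid_col, grid_kind = "time_s", "time_s"
    elif "stance_pct" in df.columns:
        grid_col, grid_kind = "stance_pct", "stance_pct"
    else:
        raise GaitDataError(f"{path}: need a time_s or stance_pct column")
    _require_columns(df, ["knee_angle_deg", "knee_moment_Nm"], path)
    try:
        grid = df[grid_col].to_numpy(dtype=float)
        angle = df["knee_angle_deg"].to_numpy(dtype=float)
        moment = df["knee_moment_Nm"].to_numpy(dtype=float)
    except ValueError as exc:
        raise GaitDataError(f"{path}: non-numeric cell ({exc})") from exc
    if sign_convention == "flipped":
        angle, moment = -angle, -moment
    elif sign_convention != "standard":
        raise GaitDataError(f"{path}: unknown sign_convention {sign_convention!r}")
    return grid, grid_kind, angle, moment


def read_dataset(subjects_path, manifest_path) -> Dataset:
    """Load and validate a full dataset from a subjects CSV and trial manifest.

    Series files named in the manifest are resolved relative to the manifest's
    directory.
    """
    subjects = read_subjects(subjects_path)
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, dtype={"subject_id": str, "trial_id": str})
    if df.empty and not set(MANIFEST_COLUMNS) <= set(df.columns):
        # header-only file written by pandas keeps columns; a truly empty file
        # yields no columns at all -> treat as zero trials
        return Dataset(subjects=subjects, trials=[])
    _require_columns(df, MANIFEST_COLUMNS, manifest_path)
    trials = []
    for i, row in df.iterrows():
        sid = str(row["subject_id"])
        if sid not in subjects:
            raise GaitDataError(
                f"{manifest_path}: row {i}: unknown subject_id {sid!r}"
            )
        sign = row.get("sign_convention")
        sign = "standard" if sign is None or pd.isna(sign) else str(sign)
        series_path = manifest_path.parent / str(row["series_file"])
        grid, grid_kind, angle, moment = read_series(series_path, sign)
        try:
            speed = float(row["speed_mps"])
        except (TypeError, ValueError) as exc:
            raise GaitDataError(
                f"{manifest_path}: row {i}: non-numeric speed ({exc})"
            ) from exc
        protocol = row.get("source_protocol")
        protocol = "synthetic" if protocol is None or pd.isna(protocol) else str(protocol)
        trials.append(
            GaitTrial(
                trial_id=str(row["trial_id"]),
                subject_id=sid,
                speed=speed,
                knee_angle_deg=angle,
                knee_moment_nm=moment,
                grid=grid,
                grid_kind=grid_kind,
                source_protocol=protocol,
            )
        )
    return Dataset(subjects=subjects, trials=trials)


# ---------------------------------------------------------------------------
# writers

_FLOAT_FMT = "%.10g"  # round-trips comfortably beyond 6 significant digits


def write_dataset(dataset: Dataset, out_dir) -> tuple[Path, Path]:
    """Write subjects.csv, manifest.csv and per-trial series under out_dir.

    Returns (subjects_path, manifest_path) suitable for :func:`read_dataset`.
    """
    out_dir = Path(out_dir)
    series_dir = out_dir / "series"
    series_dir.mkdir(parents=True, exist_ok=True)

    subj_rows = [
        {
            "subject_id": s.subject_id,
            "sex": s.sex,
            "weight_kg": s.weight,
            "height_m": s.height,
            "leg_length_m": s.leg_length,
        }
        for s in dataset.subjects.values()
    ]
    subjects_path = out_dir / "subjects.csv"
    pd.DataFrame(subj_rows, columns=["subject_id", "sex", "weight_kg", "height_m",
                                     "leg_length_m"]).to_csv(
        subjects_path, index=False, float_format=_FLOAT_FMT)

    man_rows = []
    for t in dataset.trials:
        fname = f"series/{t.trial_id}.csv"
        grid = t.grid if t.grid is not None else np.linspace(0.0, 100.0, t.n_samples)
        pd.DataFrame(
            {
                t.grid_kind: grid,
                "knee_angle_deg": t.knee_angle_deg,
                "knee_moment_Nm": t.knee_moment_nm,
            }
        ).to_csv(out_dir / fname, index=False, float_format=_FLOAT_FMT)
        man_rows.append(
            {
                "subject_id": t.subject_id,
                "trial_id": t.trial_id,
                "speed_mps": t.speed,
                "series_file": fname,
                "sign_convention": "standard",
                "source_protocol": t.source_protocol,
            }
        )
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(
        man_rows,
        columns=MANIFEST_COLUMNS + ["sign_convention", "source_protocol"],
    ).to_csv(manifest_path, index=False, float_format=_FLOAT_FMT)
    return subjects_path, manifest_path


def write_summary_table(summaries, path) -> None:
    """Write per-trial stiffness summaries as CSV (one row per trial)."""
    rows = [dataclasses.asdict(s) for s in summaries]
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_summary_table(path) -> pd.DataFrame:
    """Read a stiffness summary CSV back into a DataFrame."""
    df = pd.read_csv(path, dtype={"trial_id": str, "subject_id": str})
    if df.empty and not df.columns.size:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    _require_columns(df, [c for c in SUMMARY_COLUMNS if c not in
                          ("intercept_flex", "intercept_ext")], path)
    return df
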