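"""Published summary values of the 14-subject reference cohort.

These are the per-subject summary statistics of the gait dataset the knee
quasi-stiffness models were developed on: nine adults walking four treadmill
speeds each and five adults walking twenty overground speeds each (136
trials).  Stored here are each subject's body weight W (kg), height H (m),
gait-speed range (m/s), per-stage quasi-stiffness ranges (N*m/rad), mean R^2
of the stage line fits (percent) and the Froude number at which the flexion
and extension stiffnesses are closest.  Only cohort-level mean and SD are
available for the weight-acceptance excursion.

The table serves as a plausibility envelope for synthetic data and as the
input to the cohort summary arithmetic.
"""

from __future__ import annotations

import pandas as pd

from .gait_data import DEFAULT_LEG_RATIO

#: Cohort mean / SD of the weight-acceptance excursion (degrees).
REF_EXCURSION_MEAN_DEG = 16.5
REF_EXCURSION_SD_DEG = 4.4

_COLUMNS = ["subject_id", "sex", "n_trials", "protocol",
            "weight_kg", "height_m", "v_min", "v_max",
            "kflex_min", "kflex_max", "kext_min", "kext_max",
            "kwa_min", "kwa_max", "r2_flex_pct", "r2_ext_pct",
            "crossing_froude"]

_ROWS = [
    ("S01", "M", 4, "treadmill", 92.3, 1.86, 0.75, 2.00, 284, 376, 283, 297, 330, 390, 90, 96, 0.174),
    ("S02", "M", 4, "treadmill", 68.4, 1.70, 0.75, 2.00, 141, 225, 223, 255, 186, 233, 89, 95, 0.191),
    ("S03", "M", 4, "treadmill", 65.6, 1.65, 0.75, 2.00, 155, 266, 221, 261, 198, 244, 90, 94, 0.197),
    ("S04", "M", 4, "treadmill", 94.0, 1.86, 0.75, 2.00, 326, 478, 361, 556, 344, 517, 92, 95, 0.174),
    ("S05", "M", 4, "treadmill", 68.1, 1.72, 0.75, 2.00, 182, 255, 291, 582, 273, 382, 91, 84, 0.189),
    ("S06", "F", 4, "treadmill", 57.7, 1.43, 0.75, 2.00, 145, 255, 197, 291, 187, 255, 91, 97, 0.227),
    ("S07", "F", 4, "treadmill", 63.1, 1.45, 0.75, 2.00, 114, 185, 81, 308, 98, 231, 87, 95, 0.224),
    ("S08", "F", 4, "treadmill", 65.7, 1.75, 0.75, 2.00, 161, 456, 237, 739, 278, 450, 93, 94, 0.185),
    ("S09", "F", 4, "treadmill", 75.9, 1.80, 0.75, 2.00, 237, 393, 292, 378, 291, 343, 93, 94, 0.180),
    ("S10", "M", 20, "overground", 85.7, 1.74, 1.26, 2.43, 236, 569, 244, 342, 279, 422, 99, 96, 0.254),
    ("S11", "M", 20, "overground", 79.2, 1.82, 1.38, 2.25, 227, 414, 258, 331, 256, 343, 98, 98, 0.246),
    ("S12", "M", 20, "overground", 62.1, 1.64, 1.04, 2.29, 119, 379, 144, 278, 155, 269, 98, 96, 0.234),
    ("S13", "M", 20, "overground", 62.0, 1.62, 1.01, 2.44, 163, 351, 143, 188, 158, 263, 99, 95, 0.262),
    ("S14", "M", 20, "overground", 75.1, 1.77, 1.30, 2.63, 248, 745, 210, 384, 260, 565, 99, 96, 0.247),
]


def reference_subjects() -> pd.DataFrame:
    """Per-subject reference cohort summary table."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def cohort_summary() -> dict[str, float]:
    """Cohort-level arithmetic over the per-subject reference values.

    Means are unweighted across the 14 subjects; stiffness extremes are the
    global min/max over all per-subject stage ranges.
    """
    df = reference_subjects()
    k_cols_min = df[["kflex_min", "kext_min", "kwa_min"]].to_numpy()
    k_cols_max = df[["kflex_max", "kext_max", "kwa_max"]].to_numpy()
    return {
        "n_subjects": int(len(df)),
        "n_trials": int(df["n_trials"].sum()),
        "mean_weight_kg": float(df["weight_kg"].mean()),
        "sd_weight_kg": float(df["weight_kg"].std(ddof=1)),
        "mean_height_m": float(df["height_m"].mean()),
        "sd_height_m": float(df["height_m"].std(ddof=1)),
        "mean_crossing_froude": float(df["crossing_froude"].mean()),
        "sd_crossing_froude": float(df["crossing_froude"].std(ddof=1)),
        "mean_r2_flex_pct": float(df["r2_flex_pct"].mean()),
        "mean_r2_ext_pct": float(df["r2_ext_pct"].mean()),
        "stiffness_min_nm_rad": float(k_cols_min.min()),
        "stiffness_max_nm_rad": float(k_cols_max.max()),
        "mean_excursion_wa_deg": REF_EXCURSION_MEAN_DEG,
        "sd_excursion_wa_deg": REF_EXCURSION_SD_DEG,
        "leg_length_ratio": DEFAULT_LEG_RATIO,
    }
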