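"""Synthetic stance-phase gait datasets with known quasi-stiffness truth.

The generator emulates the study design behind the regression models: 14
adults (nine walking four treadmill speeds on 0.75-2.00 m/s, five walking
twenty overground speeds on 1.01-2.63 m/s, 136 trials in all), with
anthropometrics drawn around a 72.5 kg / 1.70 m cohort mean and
weight-acceptance excursions around 16.5 deg (SD 4.4 deg).

Each trial's moment-angle loop is piecewise linear by construction (the
near-linear stage behaviour the quasi-stiffness concept assumes): the moment
rises from the post-contact minimum (a) with slope K_flex* to the peak (b)
and returns with slope K_ext* to the pre-toe-off minimum (c), with short
lead-in/lead-out segments so a, b and c are interior extrema.  Gaussian
noise is added to the moment only (the angle is treated as the precise
measurement).

True stiffnesses follow a global linear model in three basis terms,

    K_stage = a_stage * WH/dtheta + b_stage * WH*V/dtheta + c_wh * WH,

with b_flex > 0 (flexion stiffness grows with speed) and b_ext < 0 (mild
decrease).  The shared WH term makes the flexion and extension stiffnesses
cross at a single speed, placed at the preferred speed for the Froude number
``fr_cross`` at the reference height, so per-subject crossing Froude numbers
spread around fr_cross the way the cohort's do.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .gait_data import Dataset, GaitTrial, SubjectRecord, DEFAULT_LEG_RATIO
from .predictors import G_DEFAULT, compute_froude, preferred_speed

DEFAULT_SEED = 20130322


class SyntheticConfigError(ValueError):
    """Infeasible generator configuration."""


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic cohort (defaults = the
    conditions the pipeline is validated under)."""

    # protocol mix
    n_treadmill_subjects: int = 9
    treadmill_speed_range: tuple[float, float] = (0.75, 2.00)
    n_treadmill_speeds: int = 4
    n_overground_subjects: int = 5
    overground_lo_range: tuple[float, float] = (1.01, 1.40)
    overground_hi_range: tuple[float, float] = (2.20, 2.63)
    n_overground_speeds: int = 20
    # anthropometrics
    weight_mean: float = 72.5   # kg
    weight_sd: float = 11.5
    weight_bounds: tuple[float, float] = (50.0, 100.0)
    height_mean: float = 1.70   # m
    height_sd: float = 0.13
    height_bounds: tuple[float, float] = (1.40, 1.90)
    # excursion model (weight-acceptance, degrees; truncated positive)
    dtheta_mean_deg: float = 16.5
    dtheta_sd_deg: float = 4.4
    # stiffness truth: K = a*WH/dth + b*WH*V/dth + c_wh*WH  (dth in rad)
    a_flex: float = 0.10
    b_flex: float = 0.12
    b_ext: float = -0.04
    c_wh: float = 1.30
    fr_cross: float = 0.22      # Froude number of the K_flex = K_ext crossing
    leg_coeff: float = DEFAULT_LEG_RATIO
    g: float = G_DEFAULT
    # series synthesis
    n_samples: int = 101
    noise_frac: float = 0.03    # moment noise SD as fraction of peak moment
    curvature: float = 0.0      # optional within-stage bend (0 = exactly linear)
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        for name in ("weight_mean", "weight_sd", "height_mean", "height_sd",
                     "dtheta_mean_deg", "dtheta_sd_deg"):
            if getattr(self, name) <= 0:
                raise SyntheticConfigError(f"{name} must be positive")
        for lo, hi in (self.treadmill_speed_range, self.overground_lo_range,
                       self.overground_hi_range):
            if not (0.5 <= lo <= hi <= 3.0):
                raise SyntheticConfigError("speed ranges must lie within [0.5, 3.0]")
        if self.noise_frac < 0:
            raise SyntheticConfigError("noise_frac must be non-negative")
        if self.n_samples < 20:
            raise SyntheticConfigError("n_samples too small for segmentation")

    @property
    def crossing_speed(self) -> float:
        """Speed at which the true flexion and extension stiffnesses cross."""
        return preferred_speed(self.height_mean, self.fr_cross,
                               self.leg_coeff, self.g)

    @property
    def a_ext(self) -> float:
        """Extension WH/dtheta coefficient implied by the crossing speed."""
        return self.a_flex + (self.b_flex - self.b_ext) * self.crossing_speed

    def true_coefficients(self) -> dict[str, dict[str, float]]:
        """Generating coefficients on the basis terms, per response."""
        flex = {"WH/dtheta": self.a_flex, "WHV/dtheta": self.b_flex,
                "WH": self.c_wh}
        ext = {"WH/dtheta": self.a_ext, "WHV/dtheta": self.b_ext,
               "WH": self.c_wh}
        wa = {k: (flex[k] + ext[k]) / 2.0 for k in flex}
        return {"K_flex": flex, "K_ext": ext, "K_wa": wa}


@dataclass
class GroundTruth:
    """Per-trial generating values plus the global model coefficients."""

    trials: pd.DataFrame
    coefficients: dict[str, dict[str, float]] = field(default_factory=dict)


def _trunc_normal(rng, mean, sd, lo, hi, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _true_stiffness(cfg: SyntheticConfig, W, H, V, dtheta_rad):
    wh = W * H
    k_flex = wh * ((cfg.a_flex + cfg.b_flex * V) / dtheta_rad + cfg.c_wh)
    k_ext = wh * ((cfg.a_ext + cfg.b_ext * V) / dtheta_rad + cfg.c_wh)
    return k_flex, k_ext


def _synth_loop(cfg: SyntheticConfig, rng, k_flex, k_ext, dtheta_deg):
    """Build one stance angle/moment series; returns arrays + truth indices."""
    n = cfg.n_samples
    idx_a = int(round(rng.uniform(0.05, 0.11) * (n - 1)))
    idx_b = int(round(rng.uniform(0.30, 0.40) * (n - 1)))
    idx_c = int(round(rng.uniform(0.55, 0.65) * (n - 1)))

    theta_a = rng.uniform(2.0, 6.0)
    theta_b = theta_a + dtheta_deg
    dtheta_rad = math.radians(dtheta_deg)
    m_b = k_flex * dtheta_rad / 0.95   # so the pre-flexion minimum is 5% of peak
    m_a = 0.05 * m_b
    m_c = m_b - k_ext * dtheta_rad
    if m_c >= m_b or theta_b <= theta_a:
        raise SyntheticConfigError("infeasible loop geometry (negative excursion)")

    angle = np.empty(n)
    moment = np.empty(n)
    # lead-in: moment falls to its post-contact minimum at a
    angle[:idx_a + 1] = np.linspace(theta_a - 2.0, theta_a, idx_a + 1)
    moment[:idx_a + 1] = np.linspace(m_a + 0.15 * m_b, m_a, idx_a + 1)
    # flexion stage: linear in angle with slope k_flex
    seg = np.linspace(theta_a, theta_b, idx_b - idx_a + 1)
    angle[idx_a:idx_b + 1] = seg
    moment[idx_a:idx_b + 1] = m_a + k_flex * np.deg2rad(seg - theta_a)
    # extension stage: back down with slope k_ext
    seg = np.linspace(theta_b, theta_a, idx_c - idx_b + 1)
    angle[idx_b:idx_c + 1] = seg
    moment[idx_b:idx_c + 1] = m_b - k_ext * np.deg2rad(theta_b - seg)
    # lead-out: pre-swing flexion, moment rising off its minimum at c
    angle[idx_c:] = np.linspace(theta_a, theta_a + 5.0, n - idx_c)
    moment[idx_c:] = np.linspace(m_c, m_c + 0.25 * m_b, n - idx_c)

    if cfg.curvature != 0.0:
        for lo, hi in ((idx_a, idx_b), (idx_b, idx_c)):
            s = np.linspace(0.0, 1.0, hi - lo + 1)
            moment[lo:hi + 1] += cfg.curvature * m_b * 4.0 * s * (1.0 - s)
    if cfg.noise_frac > 0.0:
        moment = moment + cfg.noise_frac * m_b * rng.standard_normal(n)
    return angle, moment, idx_a, idx_b, idx_c, m_b


def generate_dataset(config: SyntheticConfig | None = None,
                     ) -> tuple[Dataset, GroundTruth]:
    """Draw a full synthetic cohort; reproducible given config.seed."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)

    n_subj = cfg.n_treadmill_subjects + cfg.n_overground_subjects
    weights = _trunc_normal(rng, cfg.weight_mean, cfg.weight_sd,
                            *cfg.weight_bounds, size=n_subj)
    heights = _trunc_normal(rng, cfg.height_mean, cfg.height_sd,
                            *cfg.height_bounds, size=n_subj)
    sexes = rng.choice(["M", "F"], size=n_subj)

    subjects: dict[str, SubjectRecord] = {}
    trials: list[GaitTrial] = []
    truth_rows = []
    for i in range(n_subj):
        sid = f"S{i + 1:02d}"
        subjects[sid] = SubjectRecord(sid, float(weights[i]), float(heights[i]),
                                      sex=str(sexes[i]))
        if i < cfg.n_treadmill_subjects:
            speeds = np.linspace(*cfg.treadmill_speed_range, cfg.n_treadmill_speeds)
            protocol = "treadmill"
        else:
            lo = rng.uniform(*cfg.overground_lo_range)
            hi = rng.uniform(*cfg.overground_hi_range)
            speeds = np.linspace(lo, hi, cfg.n_overground_speeds)
            protocol = "overground"
        for j, v in enumerate(speeds):
            tid = f"{sid}_T{j + 1:02d}"
            dtheta_deg = float(_trunc_normal(rng, cfg.dtheta_mean_deg,
                                             cfg.dtheta_sd_deg, 1e-6, np.inf))
            k_flex, k_ext = _true_stiffness(cfg, weights[i], heights[i], v,
                                            math.radians(dtheta_deg))
            angle, moment, ia, ib, ic, m_b = _synth_loop(
                cfg, rng, k_flex, k_ext, dtheta_deg)
            trials.append(GaitTrial(
                trial_id=tid, subject_id=sid, speed=float(v),
                knee_angle_deg=angle, knee_moment_nm=moment,
                grid=np.linspace(0.0, 100.0, cfg.n_samples),
                grid_kind="stance_pct", source_protocol=protocol,
            ))
            truth_rows.append({
                "trial_id": tid, "subject_id": sid, "speed_mps": float(v),
                "K_flex": float(k_flex), "K_ext": float(k_ext),
                "K_wa": float((k_flex + k_ext) / 2.0),
                "dtheta_wa_deg": dtheta_deg, "peak_moment_nm": float(m_b),
                "idx_a": ia, "idx_b": ib, "idx_c": ic,
            })
    dataset = Dataset(subjects=subjects, trials=trials)
    truth = GroundTruth(trials=pd.DataFrame(truth_rows),
                        coefficients=cfg.true_coefficients())
    return dataset, truth


def crossing_froude(stiffness_table, subjects: dict[str, SubjectRecord],
                    leg_coeff: float = DEFAULT_LEG_RATIO,
                    g: float = G_DEFAULT) -> pd.DataFrame:
    """Per-subject Froude number at which K_flex and K_ext cross.

    ``stiffness_table`` is a DataFrame (or iterable of summaries) with
    subject_id, speed_mps, K_flex and K_ext.  The crossing speed is found by
    linear interpolation of K_flex - K_ext between the adjacent trial speeds
    bracketing its sign change; subjects whose difference never changes sign
    are skipped with a warning, and a subject with K_flex identical to K_ext
    everywhere is reported at the lowest speed and flagged degenerate.
    """
    if not isinstance(stiffness_table, pd.DataFrame):
        stiffness_table = pd.DataFrame([vars(s) for s in stiffness_table])
    rows = []
    for sid, grp in stiffness_table.groupby("subject_id", sort=True):
        grp = grp.sort_values("speed_mps", kind="stable")
        v = grp["speed_mps"].to_numpy(dtype=float)
        d = (grp["K_flex"] - grp["K_ext"]).to_numpy(dtype=float)
        height = subjects[sid].height
        if np.all(d == 0.0):
            rows.append({"subject_id": sid, "crossing_speed_mps": float(v[0]),
                         "crossing_froude": compute_froude(v[0], height,
                                                           leg_coeff, g),
                         "status": "degenerate"})
            continue
        v_star = None
        for i in range(len(d) - 1):
            if d[i] == 0.0:
                v_star = v[i]
                break
            if d[i] * d[i + 1] < 0.0:
                v_star = v[i] + d[i] * (v[i + 1] - v[i]) / (d[i] - d[i + 1])
                break
        else:
            if d[-1] == 0.0:
                v_star = v[-1]
        if v_star is None:
            warnings.warn(f"subject {sid}: no K_flex/K_ext sign change; skipped")
            continue
        rows.append({"subject_id": sid, "crossing_speed_mps": float(v_star),
                     "crossing_froude": compute_froude(float(v_star), height,
                                                       leg_coeff, g),
                     "status": "ok"})
    return pd.DataFrame(rows,
                        columns=["subject_id", "crossing_speed_mps",
                                 "crossing_froude", "status"])
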