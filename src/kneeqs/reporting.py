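"""Cohort-style summary reports and the end-to-end pipeline driver."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gait_data import (Dataset, SubjectRecord, write_dataset,
                        write_summary_table, DEFAULT_LEG_RATIO)
from .predictors import BasisSpec, G_DEFAULT, FR_OPT_DEFAULT, design_matrix
from .regression import (stepwise_backward, pls_loso_cv, mean_pct_error,
                         flag_outliers)
from .simulate import SyntheticConfig, generate_dataset, crossing_froude
from .stature import average_value_baseline, compare_models, reduce_to_stature
from .stiffness import summarize_dataset

RESPONSES = ("K_flex", "K_ext", "K_wa")


def dataset_report(subjects: dict[str, SubjectRecord], summaries,
                   leg_coeff: float = DEFAULT_LEG_RATIO,
                   g: float = G_DEFAULT) -> pd.DataFrame:
    """Per-subject dataset summary with cohort mean/SD footer rows.

    Rows: one per subject with trial count, W, H, speed range, per-stage
    stiffness ranges, mean fit R^2 and the crossing Froude number; then a
    ``mean`` and ``sd`` footer (anthropometrics and Froude aggregated across
    subjects; stiffness, excursion and speed across trials).
    """
    if isinstance(summaries, pd.DataFrame):
        df = summaries.copy()
    else:
        df = pd.DataFrame([vars(s) for s in summaries])
    cols = ["subject_id", "n_trials", "weight_kg", "height_m",
            "v_min", "v_max", "kflex_min", "kflex_max", "kext_min", "kext_max",
            "kwa_min", "kwa_max", "dtheta_wa_mean_deg",
            "r2_flex_pct", "r2_ext_pct", "crossing_froude"]
    if df.empty:
        return pd.DataFrame(columns=cols)
    cross = crossing_froude(df, subjects, leg_coeff, g)
    cross_by_sid = dict(zip(cross["subject_id"], cross["crossing_froude"]))
    rows = []
    for sid, grp in df.groupby("subject_id", sort=True):
        s = subjects[sid]
        rows.append({
            "subject_id": sid,
            "n_trials": len(grp),
            "weight_kg": s.weight,
            "height_m": s.height,
            "v_min": grp["speed_mps"].min(),
            "v_max": grp["speed_mps"].max(),
            "kflex_min": grp["K_flex"].min(), "kflex_max": grp["K_flex"].max(),
            "kext_min": grp["K_ext"].min(), "kext_max": grp["K_ext"].max(),
            "kwa_min": grp["K_wa"].min(), "kwa_max": grp["K_wa"].max(),
            "dtheta_wa_mean_deg": grp["dtheta_wa_deg"].mean(),
            "r2_flex_pct": 100.0 * grp["r2_flex"].mean(),
            "r2_ext_pct": 100.0 * grp["r2_ext"].mean(),
            "crossing_froude": cross_by_sid.get(sid, np.nan),
        })
    body = pd.DataFrame(rows, columns=cols)
    # footer aggregates: subject-level for anthropometrics/Froude,
    # trial-level for speed, stiffness, excursion and fit quality
    sub_w = body["weight_kg"]
    sub_h = body["height_m"]
    sub_fr = body["crossing_froude"].dropna()
    footer = []
    for label, agg in (("mean", np.mean), ("sd", lambda x: np.std(x, ddof=1))):
        footer.append({
            "subject_id": label,
            "n_trials": len(df) if label == "mean" else np.nan,
            "weight_kg": agg(sub_w), "height_m": agg(sub_h),
            "v_min": agg(df["speed_mps"]), "v_max": np.nan,
            "kflex_min": agg(df["K_flex"]), "kflex_max": np.nan,
            "kext_min": agg(df["K_ext"]), "kext_max": np.nan,
            "kwa_min": agg(df["K_wa"]), "kwa_max": np.nan,
            "dtheta_wa_mean_deg": agg(df["dtheta_wa_deg"]),
            "r2_flex_pct": 100.0 * agg(df["r2_flex"]),
            "r2_ext_pct": 100.0 * agg(df["r2_ext"]),
            "crossing_froude": agg(sub_fr) if len(sub_fr) > 1 else np.nan,
        })
    return pd.concat([body, pd.DataFrame(footer, columns=cols)],
                     ignore_index=True)


@dataclass
class RunConfig:
    """Configuration of one end-to-end synthetic pipeline run."""

    out_dir: str = "kneeqs_run"
    seed: int = 20130322
    alpha: float = 0.05
    fr_opt: float = FR_OPT_DEFAULT
    leg_coeff: float = DEFAULT_LEG_RATIO
    g: float = G_DEFAULT
    smooth_window: int = 0
    basis: BasisSpec = field(default_factory=BasisSpec.default)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["basis"] = self.basis.to_dict()
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_csv_with_hash(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_sha256={config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> extract -> fit (3 responses) -> stature -> compare -> report.

    Writes every artifact under config.out_dir with the config echo and hash,
    and returns the in-memory results keyed by artifact name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash
    echo = {"config": config.to_dict(), "config_sha256": chash}

    syn = dataclasses.replace(config.synthetic, seed=config.seed)
    dataset, truth = generate_dataset(syn)
    write_dataset(dataset, out / "data")
    _write_csv_with_hash(truth.trials, out / "ground_truth.csv", chash)

    summaries, exclusions = summarize_dataset(dataset, config.smooth_window)
    write_summary_table(summaries, out / "summary.csv")
    sdf = pd.DataFrame([vars(s) for s in summaries])
    if len(sdf) != dataset.n_trials - len(exclusions):
        raise RuntimeError("extract stage: summary count mismatch")

    models, statures = {}, {}
    stage_dth = {"K_flex": "dtheta_flex_deg", "K_ext": "dtheta_ext_deg",
                 "K_wa": "dtheta_wa_deg"}
    for response in RESPONSES:
        X, y, groups = design_matrix(dataset.subjects, sdf, response,
                                     config.basis)
        model = stepwise_backward(X, y, alpha=config.alpha, response=response,
                                  basis=config.basis)
        model.pls = pls_loso_cv(X, y, groups)
        model.mean_pct_error = mean_pct_error(y, model.predict(X))
        model.outlier_trial_ids = flag_outliers(model, X, y)
        models[response] = model
        mean_dth = math.radians(float(sdf[stage_dth[response]].mean()))
        statures[response] = reduce_to_stature(
            model, fr_opt=config.fr_opt, leg_coeff=config.leg_coeff,
            mean_dtheta_rad=mean_dth, g=config.g)
        with open(out / f"model_{response}.json", "w") as fh:
            json.dump({**echo, "model": model.to_dict()}, fh, indent=2)
        with open(out / f"stature_{response}.json", "w") as fh:
            json.dump({**echo, "stature_model": statures[response].to_dict()},
                      fh, indent=2)

    baseline = average_value_baseline(sdf)
    comparison = compare_models(models, statures, baseline, dataset.subjects,
                                sdf, config.fr_opt, config.leg_coeff, config.g)
    _write_csv_with_hash(comparison, out / "comparison.csv", chash)

    report = dataset_report(dataset.subjects, sdf, config.leg_coeff, config.g)
    _write_csv_with_hash(report, out / "dataset_report.csv", chash)
    with open(out / "run_config.json", "w") as fh:
        json.dump(echo, fh, indent=2)

    return {
        "dataset": dataset,
        "truth": truth,
        "summaries": summaries,
        "exclusions": exclusions,
        "models": models,
        "stature_models": statures,
        "baseline": baseline,
        "comparison": comparison,
        "report": report,
    }
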