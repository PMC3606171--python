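"""Stature-based reduction of general-form models and baseline comparisons.

Substituting the Froude-predicted preferred speed V_opt(H) =
sqrt(fr_opt * g * leg_coeff * H) and the cohort-mean excursion into a
general-form model collapses it to a closed form in body weight and height
only.  Each basis term c * (WH)^e * V^p * dtheta^d becomes

    c * (fr_opt * g * leg_coeff)^(p/2) * mean_dtheta^d * (WH)^e * H^(p/2),

so for the default basis the reduced models live on {1, WH, WH^1.5, WH^2}.
The module also provides the average-value baseline (predicting every trial
by the dataset-mean stiffness) and the near-optimal-speed model comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gait_data import SubjectRecord, DEFAULT_LEG_RATIO
from .predictors import (BasisSpec, G_DEFAULT, FR_OPT_DEFAULT, design_matrix,
                         preferred_speed)
from .regression import FittedModel, mean_pct_error

MEAN_DTHETA_WA_DEG = 16.5  # cohort-mean weight-acceptance excursion, degrees


class UnsupportedTermError(ValueError):
    """A retained term is not a (WH, V, dtheta) power product."""


@dataclass(frozen=True)
class StatureTerm:
    """One reduced term: coeff * (W*H)^wh_exp * H^h_exp."""

    name: str
    wh_exp: float
    h_exp: float
    coeff: float


@dataclass
class StatureModel:
    """Closed-form quasi-stiffness K(W, H) at the preferred gait speed."""

    response: str
    intercept: float
    terms: tuple[StatureTerm, ...]
    fr_opt: float
    leg_coeff: float
    g: float
    mean_dtheta_rad: float

    def evaluate(self, weight: float, height: float) -> float:
        wh = weight * height
        val = self.intercept
        for t in self.terms:
            val += t.coeff * wh ** t.wh_exp * height ** t.h_exp
        return val

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "intercept": float(self.intercept),
            "terms": [
                {"name": t.name, "wh_exp": t.wh_exp, "h_exp": t.h_exp,
                 "coeff": float(t.coeff)}
                for t in self.terms
            ],
            "conditions": {
                "fr_opt": self.fr_opt,
                "leg_coeff": self.leg_coeff,
                "g": self.g,
                "mean_dtheta_deg": math.degrees(self.mean_dtheta_rad),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StatureModel":
        cond = d["conditions"]
        return cls(
            response=d["response"],
            intercept=d["intercept"],
            terms=tuple(StatureTerm(t["name"], t["wh_exp"], t["h_exp"], t["coeff"])
                        for t in d["terms"]),
            fr_opt=cond["fr_opt"],
            leg_coeff=cond["leg_coeff"],
            g=cond["g"],
            mean_dtheta_rad=math.radians(cond["mean_dtheta_deg"]),
        )


def reduce_to_stature(model: FittedModel,
                      fr_opt: float = FR_OPT_DEFAULT,
                      leg_coeff: float = DEFAULT_LEG_RATIO,
                      mean_dtheta_rad: float = math.radians(MEAN_DTHETA_WA_DEG),
                      g: float = G_DEFAULT) -> StatureModel:
    """Symbolically substitute V -> V_opt(H) and dtheta -> mean_dtheta.

    The model must carry its BasisSpec so every retained term's exponents on
    (WH, V, dtheta) are known.  The result depends only on (W, H) and agrees
    with the parent model evaluated at (W, H, V_opt(H), mean_dtheta).
    """
    if model.basis is None:
        raise UnsupportedTermError("model carries no basis specification")
    speed_const = fr_opt * g * leg_coeff  # V_opt^2 / H
    terms = []
    for name in model.retained_terms:
        try:
            bt = model.basis.term(name)
        except KeyError as exc:
            raise UnsupportedTermError(f"term {name!r} not in basis") from exc
        coeff = (model.coefficients[name]
                 * speed_const ** (bt.v / 2.0)
                 * mean_dtheta_rad ** bt.dtheta)
        terms.append(StatureTerm(name=name, wh_exp=float(bt.wh),
                                 h_exp=bt.v / 2.0, coeff=coeff))
    return StatureModel(
        response=model.response,
        intercept=model.coefficients.get("intercept", 0.0),
        terms=tuple(terms),
        fr_opt=fr_opt,
        leg_coeff=leg_coeff,
        g=g,
        mean_dtheta_rad=mean_dtheta_rad,
    )


def average_value_baseline(summaries) -> dict[str, float]:
    """Dataset-mean K_flex, K_ext, K_wa: the constant-prediction baseline."""
    if isinstance(summaries, pd.DataFrame):
        df = summaries
    else:
        df = pd.DataFrame([vars(s) for s in summaries])
    if df.empty:
        raise ValueError("need at least one summary")
    return {r: float(df[r].mean()) for r in ("K_flex", "K_ext", "K_wa")}


def select_near_optimal_trials(subjects: dict[str, SubjectRecord], summaries,
                               fr_opt: float = FR_OPT_DEFAULT,
                               leg_coeff: float = DEFAULT_LEG_RATIO,
                               g: float = G_DEFAULT) -> pd.DataFrame:
    """Per subject, the trial whose speed is closest to the preferred speed.

    Ties in |V - V_opt| break to the slower trial.
    """
    if isinstance(summaries, pd.DataFrame):
        df = summaries.copy()
    else:
        df = pd.DataFrame([vars(s) for s in summaries])
    rows = []
    for sid, grp in df.groupby("subject_id", sort=True):
        subject = subjects[sid]
        v_opt = preferred_speed(subject.height, fr_opt, leg_coeff, g)
        grp = grp.sort_values("speed_mps", kind="stable")
        gap = (grp["speed_mps"] - v_opt).abs()
        best = grp.loc[gap.idxmin()]  # idxmin takes the first (slower) tie
        row = best.to_dict()
        row["v_opt"] = v_opt
        rows.append(row)
    return pd.DataFrame(rows).reset_index(drop=True)


def compare_models(general: dict[str, FittedModel],
                   stature: dict[str, StatureModel],
                   baseline: dict[str, float],
                   subjects: dict[str, SubjectRecord], summaries,
                   fr_opt: float = FR_OPT_DEFAULT,
                   leg_coeff: float = DEFAULT_LEG_RATIO,
                   g: float = G_DEFAULT) -> pd.DataFrame:
    """Mean % error of the three model families at near-optimal speeds.

    For each subject the trial closest to the preferred speed is selected;
    errors are tabulated per response (rows) for the general-form model
    (actual V and excursion), the stature model (W, H only) and the
    average-value baseline.
    """
    selected = select_near_optimal_trials(subjects, summaries, fr_opt, leg_coeff, g)
    rows = []
    for response in ("K_flex", "K_ext", "K_wa"):
        gm = general[response]
        X, y, _ = design_matrix(subjects, selected, response,
                                gm.basis or BasisSpec.default())
        y_obs = y.to_numpy()
        pred_general = gm.predict(X)
        pred_stature = np.array([
            stature[response].evaluate(subjects[sid].weight,
                                       subjects[sid].height)
            for sid in selected["subject_id"]
        ])
        pred_baseline = np.full(len(selected), baseline[response])
        rows.append({
            "response": response,
            "general_pct_error": mean_pct_error(y_obs, pred_general),
            "stature_pct_error": mean_pct_error(y_obs, pred_stature),
            "baseline_pct_error": mean_pct_error(y_obs, pred_baseline),
            "n_subjects": len(selected),
        })
    return pd.DataFrame(rows)
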