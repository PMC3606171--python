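"""Candidate regressors for knee quasi-stiffness and Froude-number utilities.

A pseudo-static reduction of stance-phase inverse dynamics puts the peak knee
moment proportional to body weight times height, W*H, modulated by a low-order
polynomial in gait speed V (joint moment arms scale with stature; the peak
ground reaction force scales with weight and grows with speed).  Dividing the
moment by the angular excursion dtheta of a near-linear stage gives the
quasi-stiffness, so the natural candidate terms are products of W*H, powers
of V, and dtheta or its reciprocal.  The default basis is

    WH/dtheta, WHV/dtheta, WHV^2/dtheta, WH, WHV, WHV^2, dtheta

plus an intercept; any other first-order-polynomial basis of the same four
quantities can be supplied via :class:`BasisSpec`.

Dynamic similarity enters through the Froude number Fr = V^2 / (g*l) with
leg length l = leg_coeff * H; walking is dynamically similar at equal Fr and
the preferred speed corresponds to a characteristic Fr (default 0.25).
"""

from __future__ import annotations

import math
from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .gait_data import SubjectRecord, DEFAULT_LEG_RATIO

G_DEFAULT = 9.81       # m/s^2
FR_OPT_DEFAULT = 0.25  # Froude number of the preferred walking speed


class PredictorError(ValueError):
    """Ill-posed basis or degenerate predictor evaluation."""


def compute_froude(speed: float, height: float,
                   leg_coeff: float = DEFAULT_LEG_RATIO,
                   g: float = G_DEFAULT) -> float:
    """Froude number Fr = V^2 / (g * leg_coeff * H)."""
    if height <= 0:
        raise PredictorError("height must be positive")
    if speed < 0:
        raise PredictorError("speed must be non-negative")
    return speed ** 2 / (g * leg_coeff * height)


def preferred_speed(height: float, fr_opt: float = FR_OPT_DEFAULT,
                    leg_coeff: float = DEFAULT_LEG_RATIO,
                    g: float = G_DEFAULT) -> float:
    """Froude-predicted preferred walking speed, sqrt(fr_opt * g * leg_coeff * H).

    Exact inverse of :func:`compute_froude`: the returned speed has Froude
    number fr_opt for the same height.
    """
    if height <= 0:
        raise PredictorError("height must be positive")
    return math.sqrt(fr_opt * g * leg_coeff * height)


@dataclass(frozen=True)
class BasisTerm:
    """One polynomial term (W*H)^wh * V^v * dtheta^dth."""

    name: str
    wh: int
    v: int
    dtheta: int

    def __post_init__(self):
        if self.dtheta not in (-1, 0, 1):
            raise PredictorError(f"term {self.name}: dtheta exponent must be -1, 0 or 1")

    def value(self, W: float, H: float, V: float, dtheta: float) -> float:
        if self.dtheta == -1 and dtheta == 0:
            raise PredictorError(f"term {self.name}: dtheta = 0 with reciprocal term")
        return (W * H) ** self.wh * V ** self.v * dtheta ** self.dtheta


@dataclass(frozen=True)
class BasisSpec:
    """Ordered list of basis terms plus an intercept flag."""

    terms: tuple[BasisTerm, ...]
    intercept: bool = True

    def __post_init__(self):
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise PredictorError("duplicate term names in basis")

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.terms]

    def term(self, name: str) -> BasisTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    @classmethod
    def default(cls) -> "BasisSpec":
        return cls(terms=(
            BasisTerm("WH/dtheta", 1, 0, -1),
            BasisTerm("WHV/dtheta", 1, 1, -1),
            BasisTerm("WHV^2/dtheta", 1, 2, -1),
            BasisTerm("WH", 1, 0, 0),
            BasisTerm("WHV", 1, 1, 0),
            BasisTerm("WHV^2", 1, 2, 0),
            BasisTerm("dtheta", 0, 0, 1),
        ))

    @classmethod
    def from_yaml(cls, path) -> "BasisSpec":
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        terms = tuple(
            BasisTerm(t["name"], int(t["wh"]), int(t["v"]), int(t["dtheta"]))
            for t in spec["terms"]
        )
        return cls(terms=terms, intercept=bool(spec.get("intercept", True)))

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "terms": [
                {"name": t.name, "wh": t.wh, "v": t.v, "dtheta": t.dtheta}
                for t in self.terms
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSpec":
        terms = tuple(
            BasisTerm(t["name"], int(t["wh"]), int(t["v"]), int(t["dtheta"]))
            for t in d["terms"]
        )
        return cls(terms=terms, intercept=bool(d.get("intercept", True)))


@dataclass
class PredictorVector:
    """Evaluated basis terms for one trial, plus its Froude quantities."""

    terms: "OrderedDict[str, float]"
    froude: float
    leg_length: float


def build_predictors(subject: SubjectRecord, speed: float, dtheta_rad: float,
                     basis: BasisSpec | None = None,
                     leg_coeff: float = DEFAULT_LEG_RATIO,
                     g: float = G_DEFAULT) -> PredictorVector:
    """Evaluate every basis term for one (subject, speed, excursion) triple.

    ``dtheta_rad`` is the stage excursion in radians, keeping K = M/dtheta
    dimensionally consistent in N*m/rad.
    """
    basis = basis or BasisSpec.default()
    values = OrderedDict(
        (t.name, t.value(subject.weight, subject.height, speed, dtheta_rad))
        for t in basis.terms
    )
    return PredictorVector(
        terms=values,
        froude=compute_froude(speed, subject.height, leg_coeff, g),
        leg_length=leg_coeff * subject.height,
    )


RESPONSE_STAGE_EXCURSION = {
    "K_flex": "dtheta_flex_deg",
    "K_ext": "dtheta_ext_deg",
    "K_wa": "dtheta_wa_deg",
}


def design_matrix(subjects: dict[str, SubjectRecord], summaries,
                  response: str, basis: BasisSpec | None = None):
    """Assemble (X, y, groups) for a stiffness regression.

    ``summaries`` is an iterable of StiffnessSummary (or a DataFrame with the
    summary columns).  The excursion entering the predictors is the one of the
    stage being modeled.  Returns X as a DataFrame indexed by trial_id with
    one column per basis term, y as the response Series, and groups as the
    subject_id Series (for subject-stratified cross-validation).
    """
    basis = basis or BasisSpec.default()
    if response not in RESPONSE_STAGE_EXCURSION:
        raise PredictorError(f"unknown response {response!r}")
    dth_field = RESPONSE_STAGE_EXCURSION[response]

    if isinstance(summaries, pd.DataFrame):
        records = summaries.to_dict("records")
    else:
        records = [vars(s) for s in summaries]

    rows, yvals, groups, index = [], [], [], []
    for rec in records:
        subject = subjects[rec["subject_id"]]
        dtheta = math.radians(float(rec[dth_field]))
        pv = build_predictors(subject, float(rec["speed_mps"]), dtheta, basis)
        rows.append(pv.terms)
        yvals.append(float(rec[response]))
        groups.append(rec["subject_id"])
        index.append(rec["trial_id"])
    X = pd.DataFrame(rows, index=index, columns=basis.names, dtype=float)
    y = pd.Series(yvals, index=index, name=response, dtype=float)
    g = pd.Series(groups, index=index, name="subject_id")
    return X, y, g
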