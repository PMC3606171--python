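"""General-form quasi-stiffness models: stepwise OLS and subject-wise PLS CV.

Model fitting follows the pipeline used to build the published design
formulas: ordinary least squares of a stiffness response on the candidate
basis, backward elimination of non-significant terms (p > alpha, largest p
first), and a stratified leave-one-subject-out PLS cross-validation whose
PRESS statistic chooses the optimal number of latent components.  The
intercept is never eliminated but its p-value is reported.

OLS is fit on raw predictor scales so coefficients drop directly into design
formulas; predictors are z-scored only inside PLS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.cross_decomposition import PLSRegression

from .predictors import BasisSpec


class SingularDesignError(ValueError):
    """Design matrix is rank deficient."""


@dataclass
class PLSReport:
    """Leave-one-subject-out PLS cross-validation diagnostics."""

    n_components_optimal: int
    press_by_components: np.ndarray  # PRESS(k), k = 1..max_components
    cv_r2: float                     # mean training R^2 at optimal k, percent
    cv_predicted_r2: float           # 1 - PRESS(k_opt)/SS_tot, percent

    def to_dict(self) -> dict:
        return {
            "n_components_optimal": int(self.n_components_optimal),
            "press_by_components": [float(v) for v in self.press_by_components],
            "cv_r2_pct": float(self.cv_r2),
            "cv_predicted_r2_pct": float(self.cv_predicted_r2),
        }


@dataclass
class FittedModel:
    """A fitted (possibly stepwise-reduced) stiffness regression."""

    response: str
    retained_terms: list[str]
    coefficients: dict[str, float]        # includes "intercept"
    std_errors: dict[str, float]
    p_values: dict[str, float]
    r2: float
    adj_r2: float
    n_obs: int
    basis: Optional[BasisSpec] = None
    mean_pct_error: Optional[float] = None
    outlier_trial_ids: list[str] = field(default_factory=list)
    pls: Optional[PLSReport] = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Evaluate the model on a predictor table containing the retained terms."""
        yhat = np.full(len(X), self.coefficients.get("intercept", 0.0))
        for name in self.retained_terms:
            yhat = yhat + self.coefficients[name] * X[name].to_numpy(dtype=float)
        return yhat

    def to_dict(self) -> dict:
        d = {
            "response": self.response,
            "retained_terms": list(self.retained_terms),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "std_errors": {k: float(v) for k, v in self.std_errors.items()},
            "p_values": {k: float(v) for k, v in self.p_values.items()},
            "r2": float(self.r2),
            "adj_r2": float(self.adj_r2),
            "n_obs": int(self.n_obs),
            "mean_pct_error": None if self.mean_pct_error is None
            else float(self.mean_pct_error),
            "outlier_trial_ids": list(self.outlier_trial_ids),
        }
        if self.basis is not None:
            d["basis"] = self.basis.to_dict()
        if self.pls is not None:
            d["pls"] = self.pls.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        pls = None
        if d.get("pls"):
            p = d["pls"]
            pls = PLSReport(
                n_components_optimal=p["n_components_optimal"],
                press_by_components=np.asarray(p["press_by_components"]),
                cv_r2=p["cv_r2_pct"],
                cv_predicted_r2=p["cv_predicted_r2_pct"],
            )
        basis = BasisSpec.from_dict(d["basis"]) if d.get("basis") else None
        return cls(
            response=d["response"],
            retained_terms=list(d["retained_terms"]),
            coefficients=dict(d["coefficients"]),
            std_errors=dict(d["std_errors"]),
            p_values=dict(d["p_values"]),
            r2=d["r2"],
            adj_r2=d["adj_r2"],
            n_obs=d["n_obs"],
            basis=basis,
            mean_pct_error=d.get("mean_pct_error"),
            outlier_trial_ids=list(d.get("outlier_trial_ids", [])),
            pls=pls,
        )


def _check_rank(X: pd.DataFrame) -> None:
    A = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(A) == A.shape[1]:
        return
    # identify the columns that fail to increase rank when added in order
    culprits = []
    cols = [np.ones(len(X))]
    for name in X.columns:
        trial = np.column_stack(cols + [X[name].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            cols.append(X[name].to_numpy(dtype=float))
        else:
            culprits.append(name)
    raise SingularDesignError(f"collinear predictor term(s): {culprits}")


def _sm_fit(X: pd.DataFrame, y) -> sm.regression.linear_model.RegressionResultsWrapper:
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    return sm.OLS(np.asarray(y, dtype=float), design).fit()


def _wrap(res, response: str, term_names: list[str], basis) -> FittedModel:
    names = ["intercept"] + list(term_names)
    return FittedModel(
        response=response,
        retained_terms=list(term_names),
        coefficients=dict(zip(names, res.params)),
        std_errors=dict(zip(names, res.bse)),
        p_values=dict(zip(names, res.pvalues)),
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        n_obs=int(res.nobs),
        basis=basis,
    )


def fit_ols(X: pd.DataFrame, y, response: str = "K",
            basis: BasisSpec | None = None) -> FittedModel:
    """OLS of y on X with intercept; classical SEs and two-sided t p-values."""
    if len(X) < X.shape[1] + 1:
        raise SingularDesignError("fewer rows than parameters")
    _check_rank(X)
    res = _sm_fit(X, y)
    return _wrap(res, response, list(X.columns), basis)


def stepwise_backward(X: pd.DataFrame, y, alpha: float = 0.05,
                      response: str = "K",
                      basis: BasisSpec | None = None) -> FittedModel:
    """Backward elimination: drop the worst non-significant term until all
    retained terms have p <= alpha.

    One term is removed per refit (the largest p among non-intercept terms
    with p > alpha).  The intercept is always retained; its p-value is
    reported.  If every term is eliminated an intercept-only model is
    returned with a warning.
    """
    _check_rank(X)
    terms = list(X.columns)
    while terms:
        res = _sm_fit(X[terms], y)
        pvals = dict(zip(terms, res.pvalues[1:]))
        worst = max(pvals, key=pvals.get)
        if pvals[worst] <= alpha:
            return _wrap(res, response, terms, basis)
        terms.remove(worst)
    warnings.warn("all terms eliminated; returning intercept-only model")
    res = sm.OLS(np.asarray(y, dtype=float), np.ones((len(X), 1))).fit()
    model = FittedModel(
        response=response,
        retained_terms=[],
        coefficients={"intercept": float(res.params[0])},
        std_errors={"intercept": float(res.bse[0])},
        p_values={"intercept": float(res.pvalues[0])},
        r2=0.0,
        adj_r2=0.0,
        n_obs=int(res.nobs),
        basis=basis,
    )
    return model


def pls_loso_cv(X: pd.DataFrame, y, groups, max_components: int | None = None,
                ) -> PLSReport:
    """Leave-one-subject-out PLS cross-validation with PRESS.

    For every held-out subject and component count k, a PLS model (NIPALS,
    z-scored predictors) is fit on the remaining subjects and the held-out
    trials are predicted; PRESS(k) sums the squared held-out residuals over
    all folds.  The optimal k minimizes PRESS (ties -> fewest components).
    cv_predicted_r2 = 1 - PRESS(k_opt)/SS_tot about the grand mean; cv_r2 is
    the mean in-sample training R^2 across folds at k_opt.  Both in percent.
    """
    Xa = X.to_numpy(dtype=float)
    ya = np.asarray(y, dtype=float)
    garr = np.asarray(groups)
    unique_groups = pd.unique(garr)
    if len(unique_groups) < 3:
        raise ValueError("need at least 3 groups for leave-one-subject-out CV")
    kmax = max_components or X.shape[1]
    if kmax > X.shape[1]:
        raise ValueError("max_components exceeds the number of basis terms")

    press = np.zeros(kmax)
    train_r2 = np.zeros((kmax, len(unique_groups)))
    fold_used = np.ones(len(unique_groups), dtype=bool)
    for gi, g in enumerate(unique_groups):
        test = garr == g
        train = ~test
        y_tr = ya[train]
        if np.ptp(y_tr) == 0.0:
            warnings.warn(f"fold {g!r}: constant response in training set; skipped")
            fold_used[gi] = False
            continue
        for k in range(1, kmax + 1):
            pls = PLSRegression(n_components=k, scale=True)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pls.fit(Xa[train], y_tr)
                yhat = pls.predict(Xa[test]).ravel()
                press[k - 1] += float(np.sum((ya[test] - yhat) ** 2))
                train_r2[k - 1, gi] = pls.score(Xa[train], y_tr)
    k_opt = int(np.argmin(press)) + 1
    ss_tot = float(np.sum((ya - ya.mean()) ** 2))
    return PLSReport(
        n_components_optimal=k_opt,
        press_by_components=press,
        cv_r2=100.0 * float(np.mean(train_r2[k_opt - 1, fold_used])),
        cv_predicted_r2=100.0 * (1.0 - press[k_opt - 1] / ss_tot),
    )


def mean_pct_error(y_obs, y_pred) -> float:
    """Mean over trials of |predicted - observed| / observed * 100.

    Trials with observed == 0 are excluded with a warning.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    nonzero = y_obs != 0.0
    if not np.all(nonzero):
        warnings.warn(f"excluding {np.sum(~nonzero)} trial(s) with observed == 0")
    if not np.any(nonzero):
        raise ValueError("no trials with non-zero observed response")
    return float(np.mean(np.abs(y_pred[nonzero] - y_obs[nonzero])
                         / np.abs(y_obs[nonzero])) * 100.0)


def flag_outliers(model: FittedModel, X: pd.DataFrame, y,
                  threshold: float = 3.0) -> list[str]:
    """Trial ids with |externally studentized residual| > threshold.

    Flagged trials are reported, never auto-removed.
    """
    if not model.retained_terms:
        return []
    res = _sm_fit(X[model.retained_terms], y)
    # an (effectively) exact fit has only rounding-level residuals; the
    # studentization would divide noise by noise
    if res.mse_resid <= 1e-16 * float(np.mean(np.asarray(y, dtype=float) ** 2)):
        return []
    student = res.get_influence().resid_studentized_external
    mask = np.abs(student) > threshold
    return [str(idx) for idx, m in zip(X.index, mask) if m]
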