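import math

import numpy as np
import pandas as pd
import pytest

from kneeqs.gait_data import SubjectRecord
from kneeqs.predictors import (BasisSpec, build_predictors, design_matrix,
                               preferred_speed)
from kneeqs.regression import FittedModel, stepwise_backward
from kneeqs.stature import (UnsupportedTermError, average_value_baseline,
                            compare_models, reduce_to_stature,
                            select_near_optimal_trials)

G = 9.81


def _single_term_model(coeff=2.0):
    basis = BasisSpec.default()
    return FittedModel(
        response="K_wa", retained_terms=["WHV/dtheta"],
        coefficients={"intercept": 0.0, "WHV/dtheta": coeff},
        std_errors={}, p_values={}, r2=1.0, adj_r2=1.0, n_obs=10, basis=basis)


class TestReduceToStature:
    def test_symbolic_form_of_whv_over_dtheta(self):
        """c*WHV/dtheta at the preferred speed becomes a WH^1.5 term."""
        fr_opt, lc, dth = 0.25, 0.53, math.radians(16.5)
        sm = reduce_to_stature(_single_term_model(2.0), fr_opt, lc, dth)
        (term,) = sm.terms
        assert term.wh_exp == 1.0
        assert term.h_exp == 0.5
        assert term.coeff == pytest.approx(
            2.0 * math.sqrt(fr_opt * G * lc) / dth, rel=1e-12)
        # evaluates to c * W * H^1.5 * sqrt(fr*g*lc) / dtheta
        W, H = 70.0, 1.75
        assert sm.evaluate(W, H) == pytest.approx(
            2.0 * W * H * math.sqrt(fr_opt * G * lc * H) / dth, rel=1e-12)

    def test_substitution_identity_against_parent_model(
            self, default_run, default_summary_frame):
        """Stature model at (W, H) equals the parent general model at
        (W, H, V_opt(H), mean_dtheta) for 100 random bodies."""
        _, dataset, _, _ = default_run
        basis = BasisSpec.default()
        X, y, _ = design_matrix(dataset.subjects, default_summary_frame,
                                "K_wa", basis)
        model = stepwise_backward(X, y, basis=basis)
        dth = math.radians(float(default_summary_frame["dtheta_wa_deg"].mean()))
        sm = reduce_to_stature(model, mean_dtheta_rad=dth)
        rng = np.random.default_rng(12)
        for _ in range(100):
            W = rng.uniform(50, 100)
            H = rng.uniform(1.4, 1.9)
            v_opt = preferred_speed(H, sm.fr_opt, sm.leg_coeff, sm.g)
            pv = build_predictors(SubjectRecord("x", W, H), v_opt, dth, basis)
            parent = model.predict(pd.DataFrame([pv.terms]))[0]
            assert sm.evaluate(W, H) == pytest.approx(parent, rel=1e-12)

    def test_monotone_in_weight_with_positive_coefficients(self):
        sm = reduce_to_stature(_single_term_model(3.0))
        vals = [sm.evaluate(w, 1.7) for w in (55, 65, 75, 85, 95)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_model_without_basis_rejected(self):
        m = _single_term_model()
        m.basis = None
        with pytest.raises(UnsupportedTermError):
            reduce_to_stature(m)

    def test_round_trip_through_dict(self):
        from kneeqs.stature import StatureModel
        sm = reduce_to_stature(_single_term_model(2.5))
        back = StatureModel.from_dict(sm.to_dict())
        assert back.evaluate(70, 1.7) == pytest.approx(sm.evaluate(70, 1.7),
                                                       rel=1e-12)


class TestBaseline:
    def test_mean_of_two_trials(self):
        df = pd.DataFrame({"K_flex": [210.0, 290.0], "K_ext": [150.0, 250.0],
                           "K_wa": [200.0, 300.0]})
        base = average_value_baseline(df)
        assert base["K_wa"] == 250.0

    def test_single_trial_has_zero_error(self):
        df = pd.DataFrame({"K_flex": [210.0], "K_ext": [150.0],
                           "K_wa": [200.0]})
        base = average_value_baseline(df)
        assert abs(base["K_wa"] - 200.0) == 0.0


class TestTrialSelection:
    def _frame(self, speeds):
        return pd.DataFrame({
            "subject_id": ["S1"] * len(speeds),
            "trial_id": [f"T{i}" for i in range(len(speeds))],
            "speed_mps": speeds,
        })

    def test_nearest_speed_selected(self):
        subjects = {"S1": SubjectRecord("S1", 70.0, 1.70)}
        # V_opt(1.70) = 1.486; 1.5 is nearest among 1.2 / 1.5 / 1.8
        sel = select_near_optimal_trials(subjects, self._frame([1.2, 1.5, 1.8]))
        assert sel.loc[0, "speed_mps"] == 1.5

    def test_tie_breaks_to_slower_trial(self):
        subjects = {"S1": SubjectRecord("S1", 70.0, 1.70, leg_length=None)}
        v_opt = preferred_speed(1.70)
        sel = select_near_optimal_trials(
            subjects, self._frame([v_opt - 0.1, v_opt + 0.1]))
        assert sel.loc[0, "speed_mps"] == pytest.approx(v_opt - 0.1)


class TestCompareModels:
    def test_identical_models_give_identical_error_columns(
            self, default_run, default_summary_frame):
        _, dataset, _, _ = default_run
        basis = BasisSpec.default()
        general = {}
        for response in ("K_flex", "K_ext", "K_wa"):
            X, y, _ = design_matrix(dataset.subjects, default_summary_frame,
                                    response, basis)
            general[response] = stepwise_backward(X, y, response=response,
                                                  basis=basis)
        # stature family built to agree exactly with the general one would
        # need V and dtheta; instead check the degenerate identity: a baseline
        # equal to the general model's own predictions is not available, so
        # compare a family against itself via two calls
        dth = math.radians(float(default_summary_frame["dtheta_wa_deg"].mean()))
        stature = {r: reduce_to_stature(general[r], mean_dtheta_rad=dth)
                   for r in general}
        baseline = average_value_baseline(default_summary_frame)
        t1 = compare_models(general, stature, baseline, dataset.subjects,
                            default_summary_frame)
        t2 = compare_models(general, stature, baseline, dataset.subjects,
                            default_summary_frame)
        pd.testing.assert_frame_equal(t1, t2)
        assert set(t1["response"]) == {"K_flex", "K_ext", "K_wa"}
        assert (t1["n_subjects"] == 14).all()
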