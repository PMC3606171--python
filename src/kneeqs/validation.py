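"""Monte-Carlo validation of the extraction + regression pipeline.

The published regression coefficients cannot be refit without the original
laboratory trials, so the pipeline is validated by parameter recovery on
synthetic cohorts whose generating truth is known: exact recovery of stage
slopes on noiseless loops, retention of the true active basis terms by
backward stepwise elimination, type-I behaviour of a planted pure-noise
predictor, recovery of the flexion/extension crossing Froude number, and
the error ordering of the three model families at near-optimal speeds.

All experiments take an explicit seed (default 20130322) and derive
per-replicate seeds from it.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .predictors import BasisSpec, design_matrix
from .regression import stepwise_backward, mean_pct_error
from .simulate import (SyntheticConfig, generate_dataset, crossing_froude,
                       DEFAULT_SEED)
from .stature import (average_value_baseline, compare_models, reduce_to_stature)
from .stiffness import summarize_dataset

_SEED_CAP = 2 ** 31 - 1


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, _SEED_CAP, size=n)


def noiseless_recovery(seed: int = DEFAULT_SEED) -> dict[str, float]:
    """Extraction exactness on one noiseless piecewise-linear cohort.

    Returns the maximum relative stage-slope error against generator truth,
    the minimum stage-fit R^2, the maximum K_wa identity defect and the
    number of boundary-index mismatches.
    """
    cfg = SyntheticConfig(noise_frac=0.0, seed=int(seed))
    dataset, truth = generate_dataset(cfg)
    summaries, exclusions = summarize_dataset(dataset)
    est = pd.DataFrame([vars(s) for s in summaries]).set_index("trial_id")
    tru = truth.trials.set_index("trial_id")
    rel_flex = np.abs(est["K_flex"] / tru["K_flex"] - 1.0)
    rel_ext = np.abs(est["K_ext"] / tru["K_ext"] - 1.0)
    kwa_defect = np.abs(est["K_wa"] - (est["K_flex"] + est["K_ext"]) / 2.0)
    idx_mismatch = int(
        (est[["idx_a", "idx_b", "idx_c"]] != tru[["idx_a", "idx_b", "idx_c"]])
        .to_numpy().sum())
    return {
        "n_trials": int(len(est)),
        "n_excluded": len(exclusions),
        "max_rel_error": float(np.maximum(rel_flex, rel_ext).max()),
        "min_r2": float(est[["r2_flex", "r2_ext"]].to_numpy().min()),
        "max_kwa_defect": float(kwa_defect.max()),
        "index_mismatches": idx_mismatch,
    }


def stepwise_recovery(n_replicates: int = 200, seed: int = DEFAULT_SEED,
                      response: str = "K_flex",
                      config: SyntheticConfig | None = None) -> dict:
    """Active-set recovery of backward stepwise regression on full pipelines.

    Each replicate draws a fresh synthetic cohort (generator defaults unless
    ``config`` overrides them), extracts stiffness summaries, and runs
    backward elimination on the default basis.  Reports the fraction of
    replicates retaining exactly the generating active set, the fraction in
    which every active estimate lies within 3 classical SEs of its true
    value, and the retention rate of each inactive term.
    """
    basis = BasisSpec.default()
    seeds = _child_seeds(seed, n_replicates)
    exact = 0
    within = 0
    inactive_hits: dict[str, int] = {}
    for s in seeds:
        cfg_kwargs = {} if config is None else {
            f.name: getattr(config, f.name)
            for f in config.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        cfg_kwargs["seed"] = int(s)
        cfg = SyntheticConfig(**cfg_kwargs)
        dataset, truth = generate_dataset(cfg)
        summaries, _ = summarize_dataset(dataset)
        X, y, _ = design_matrix(dataset.subjects, summaries, response, basis)
        model = stepwise_backward(X, y, alpha=0.05, response=response,
                                  basis=basis)
        active = truth.coefficients[response]
        retained = set(model.retained_terms)
        if retained == set(active):
            exact += 1
        for name in basis.names:
            if name not in active and name in retained:
                inactive_hits[name] = inactive_hits.get(name, 0) + 1
        if set(active) <= retained and all(
            abs(model.coefficients[t] - active[t]) <= 3.0 * model.std_errors[t]
            for t in active
        ):
            within += 1
    return {
        "n_replicates": n_replicates,
        "exact_recovery_rate": exact / n_replicates,
        "within_3se_rate": within / n_replicates,
        "inactive_retention_rates": {
            name: inactive_hits.get(name, 0) / n_replicates
            for name in basis.names
            if name not in SyntheticConfig().true_coefficients()[response]
        },
    }


def planted_noise_type1(n_replicates: int = 200, seed: int = DEFAULT_SEED,
                        n_obs: int = 136, alpha: float = 0.05) -> dict:
    """Retention rate of a pure-noise predictor alongside a real one.

    y depends linearly on x1 only; x2 is independent noise.  With backward
    elimination at the given alpha, x2 should be retained in about alpha of
    replicates.
    """
    seeds = _child_seeds(seed, n_replicates)
    retained = 0
    for s in seeds:
        rng = np.random.default_rng(int(s))
        x1 = rng.normal(size=n_obs)
        x2 = rng.normal(size=n_obs)
        y = 3.0 + 2.0 * x1 + rng.normal(size=n_obs)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        model = stepwise_backward(X, y, alpha=alpha)
        if "x2" in model.retained_terms:
            retained += 1
    return {
        "n_replicates": n_replicates,
        "retention_rate": retained / n_replicates,
    }


def crossing_recovery(n_seeds: int = 20, seed: int = DEFAULT_SEED,
                      fr_cross: float = 0.22) -> dict:
    """Recover the flexion/extension crossing Froude number from synthetic data.

    For each seed a default cohort (crossing configured at ``fr_cross``) is
    generated and extracted; the per-subject crossing Froude numbers are
    estimated from the stiffness summaries and averaged.
    """
    seeds = _child_seeds(seed, n_seeds)
    means = []
    for s in seeds:
        cfg = SyntheticConfig(fr_cross=fr_cross, seed=int(s))
        dataset, _ = generate_dataset(cfg)
        summaries, _ = summarize_dataset(dataset)
        table = crossing_froude(pd.DataFrame([vars(x) for x in summaries]),
                                dataset.subjects, cfg.leg_coeff, cfg.g)
        ok = table[table["status"] == "ok"]
        if len(ok):
            means.append(float(ok["crossing_froude"].mean()))
    return {
        "n_seeds": n_seeds,
        "mean_crossing_froude": float(np.mean(means)),
        "sd_across_seeds": float(np.std(means, ddof=1)) if len(means) > 1 else 0.0,
        "true_crossing_froude": fr_cross,
    }


def model_comparison(n_seeds: int = 50, seed: int = DEFAULT_SEED) -> dict:
    """Mean % error of general / stature / baseline models over fresh cohorts.

    Each seed: generate, extract, fit the three stepwise general-form models,
    reduce them to stature form (dataset-mean stage excursions), build the
    average-value baseline, and evaluate all three families on the trial
    closest to each subject's preferred speed.  Errors are averaged over
    responses and seeds.
    """
    basis = BasisSpec.default()
    seeds = _child_seeds(seed, n_seeds)
    per_family = {"general": [], "stature": [], "baseline": []}
    for s in seeds:
        cfg = SyntheticConfig(seed=int(s))
        dataset, _ = generate_dataset(cfg)
        summaries, _ = summarize_dataset(dataset)
        sdf = pd.DataFrame([vars(x) for x in summaries])
        general, stature = {}, {}
        for response, dth_col in (("K_flex", "dtheta_flex_deg"),
                                  ("K_ext", "dtheta_ext_deg"),
                                  ("K_wa", "dtheta_wa_deg")):
            X, y, _ = design_matrix(dataset.subjects, sdf, response, basis)
            model = stepwise_backward(X, y, response=response, basis=basis)
            general[response] = model
            stature[response] = reduce_to_stature(
                model, mean_dtheta_rad=math.radians(float(sdf[dth_col].mean())))
        baseline = average_value_baseline(sdf)
        table = compare_models(general, stature, baseline, dataset.subjects, sdf)
        per_family["general"].append(float(table["general_pct_error"].mean()))
        per_family["stature"].append(float(table["stature_pct_error"].mean()))
        per_family["baseline"].append(float(table["baseline_pct_error"].mean()))
    return {
        "n_seeds": n_seeds,
        "general_pct_error": float(np.mean(per_family["general"])),
        "stature_pct_error": float(np.mean(per_family["stature"])),
        "baseline_pct_error": float(np.mean(per_family["baseline"])),
    }
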