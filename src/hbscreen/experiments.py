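"""Reproducible study-condition experiments over the synthetic cohorts.

These functions bundle the analyses the package exists to run — screening a
default synthetic cohort end to end, recovering the shipped model coefficients
from data simulated under them, and turning the shipped clinical-validation
counts into performance percentages — so that the analysis drivers, the test
suite and the reproduction script all execute the same code path.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Optional

import numpy as np

from .performance import (
    ConfusionMatrix,
    confusion,
    detection_rate,
    sensitivity_specificity,
    youden_index,
)
from .quantify import load_is_config, load_transition_registry, quantify_sample
from .risk_models import (
    FitResult,
    auc,
    default_p_alpha,
    default_p_beta,
    fit_logistic,
    predict_profile,
    roc_curve,
)
from .screening import Category, default_cutoffs, screen_cohort
from .synthetic_cohort import (
    TRUTH_CATEGORIES,
    CohortSpec,
    default_cohort_spec,
    generate_cohort,
    preset_effects,
)

__all__ = [
    "load_validation_counts",
    "validation_performance",
    "end_to_end_screen",
    "recovery_experiment",
]


def load_validation_counts() -> dict:
    """The shipped clinical-validation reference counts (confusion + per-genotype)."""
    text = resources.files("hbscreen.data").joinpath("validation_counts.json").read_text()
    return json.loads(text)


def validation_performance() -> dict:
    """Sensitivity/specificity pairs and detection rates from the shipped counts."""
    counts = load_validation_counts()
    out: dict[str, dict] = {"confusion": {}, "detection": {}}
    for disease, methods in counts["confusion"].items():
        out["confusion"][disease] = {}
        for method, c in methods.items():
            cm = ConfusionMatrix(**c)
            sens, spec = sensitivity_specificity(cm)
            out["confusion"][disease][method] = {
                "sensitivity_pct": sens,
                "specificity_pct": spec,
                "youden": None if sens is None or spec is None
                else round(youden_index(sens, spec), 4),
            }
    for genotype, row in counts["per_genotype_detection"].items():
        out["detection"][genotype] = {
            m: detection_rate(row[m], row["total"]) for m in ("hplc_hrms", "sebia_ce")
        }
    return out


def end_to_end_screen(seed: int, spec: Optional[CohortSpec] = None) -> dict:
    """Simulate the default cohort, run the full pipeline, score it against truth.

    Default cohort: 200 normals, 50 --SEA-like, 50 β0-like carriers at 10%
    measurement CV.  Sensitivity/specificity are computed per screening axis
    (α call vs α truth, β call vs β truth) and for the --SEA-like stratum.
    """
    if spec is None:
        spec = default_cohort_spec(seed)
    samples = generate_cohort(spec)
    is_config = load_is_config()
    registry = load_transition_registry()
    profiles = [quantify_sample(s, is_config, registry) for s in samples]
    model_a, model_b = default_p_alpha(), default_p_beta()
    calls, counts = screen_cohort(profiles, model_a, model_b, default_cutoffs())

    truth = {s.sample_id: s.truth_genotype for s in samples}
    truth_cat = {sid: TRUTH_CATEGORIES.get(g, g) for sid, g in truth.items()}
    alpha_call = {Category.ALPHA, Category.ALPHA_AND_BETA}
    beta_call = {Category.BETA, Category.ALPHA_AND_BETA}

    def axis(call_set, truth_set):
        pred = [1 if c.category in call_set else 0 for c in calls]
        tru = [1 if truth_cat[c.sample_id] in truth_set else 0 for c in calls]
        cm = confusion(pred, tru)
        sens, spec_ = sensitivity_specificity(cm)
        return cm, sens, spec_

    cm_a, sens_a, spec_a = axis(alpha_call, alpha_call)
    cm_b, sens_b, spec_b = axis(beta_call, beta_call)

    # --SEA-like stratum specifically: carriers flagged on the alpha axis
    sea_pred, sea_truth = [], []
    for c in calls:
        sea_pred.append(1 if c.category in alpha_call else 0)
        sea_truth.append(1 if truth[c.sample_id] == "aa/--SEA" else 0)
    cm_sea = confusion(sea_pred, sea_truth)
    sens_sea, spec_sea = sensitivity_specificity(cm_sea)

    # development-style ROC of the model scores against the truth axes
    pa_scores = [c.p_alpha for c in calls if c.p_alpha is not None]
    pb_scores = [c.p_beta for c in calls if c.p_beta is not None]
    ya = [1 if truth_cat[c.sample_id] in alpha_call else 0
          for c in calls if c.p_alpha is not None]
    yb = [1 if truth_cat[c.sample_id] in beta_call else 0
          for c in calls if c.p_beta is not None]
    return {
        "n": len(calls),
        "counts": counts,
        "alpha_axis": {"confusion": cm_a, "sensitivity_pct": sens_a,
                       "specificity_pct": spec_a},
        "beta_axis": {"confusion": cm_b, "sensitivity_pct": sens_b,
                      "specificity_pct": spec_b},
        "sea_stratum": {"confusion": cm_sea, "sensitivity_pct": sens_sea,
                        "specificity_pct": spec_sea},
        "auc_p_alpha": round(auc(roc_curve(pa_scores, ya)), 4),
        "auc_p_beta": round(auc(roc_curve(pb_scores, yb)), 4),
    }


def recovery_experiment(seed: int, n: int = 5000) -> dict:
    """Refit P(α) on data simulated from its own shipped coefficients.

    Features are chain ratios from a synthetic half-normal / half---SEA-like
    cohort; labels are Bernoulli draws at the shipped model's probabilities,
    so the generating coefficients are known exactly.  Reports the refit and
    each coefficient's distance from truth in reported standard errors.
    """
    presets = preset_effects()
    spec = CohortSpec(
        strata=[(presets["normal"], n // 2), (presets["aa/--SEA"], n - n // 2)],
        seed=seed,
    )
    samples = generate_cohort(spec)
    is_config = load_is_config()
    registry = load_transition_registry()
    model = default_p_alpha()
    feature_names = ["zT8_bT2", "aT1_bT1"]

    X, probs = [], []
    for s in samples:
        profile = quantify_sample(s, is_config, registry)
        X.append([profile.ratios[f] for f in feature_names])
        probs.append(predict_profile(model, profile))
    rng = np.random.default_rng(seed + 1)
    y = (rng.random(len(probs)) < np.asarray(probs)).astype(int)

    fit: FitResult = fit_logistic(X, y, feature_names=feature_names, name="P_alpha_refit")
    truth = {"intercept": model.intercept, **model.coefficients}
    deltas_se = {}
    for key, true_value in truth.items():
        est = fit.model.intercept if key == "intercept" else fit.model.coefficients[key]
        deltas_se[key] = abs(est - true_value) / fit.standard_errors[key]
    return {"n": len(y), "fit": fit, "true": truth, "deltas_in_se": deltas_se}
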