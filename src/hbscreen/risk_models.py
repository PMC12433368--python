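"""Binary logistic risk models and cutoff optimization for the screen.

Two shipped models turn chain ratios into disease probabilities:

* ``P(α)`` — probability of α-thalassemia from ζT8/βT2 (embryonic ζ chain
  persists when α genes are deleted, positive coefficient) and αT1/βT1
  (α output falls, negative coefficient).
* ``P(β)`` — probability of β-thalassemia from δT2/βT2 (relative δ excess,
  positive) and αT3/βT1 (α-like/β-like imbalance, positive).

Model fitting is maximum likelihood via iteratively reweighted least squares
(IRLS), written out in this module.  Screening cutoffs come from ROC analysis:
the ROC curve is built over the distinct observed scores with the positive
call made at score >= threshold, and the operating point maximizes the Youden
index J = sensitivity + specificity - 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np

from .quantify import RatioProfile

__all__ = [
    "PredictionModel",
    "ROCCurve",
    "FitResult",
    "DegenerateInputError",
    "MissingRatioError",
    "load_model",
    "default_p_alpha",
    "default_p_beta",
    "sigmoid",
    "predict",
    "predict_profile",
    "fit_logistic",
    "roc_curve",
    "auc",
    "select_candidates",
    "youden_cutoff",
]

AUC_SELECTION_THRESHOLD = 0.850

# IRLS controls: convergence on max parameter change, a tiny ridge on the
# normal equations for stability, and a divergence guard that flags complete
# separation instead of iterating to infinity.
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100
IRLS_RIDGE = 1e-8
SEPARATION_GUARD = 1e4


class DegenerateInputError(ValueError):
    """Labels contain a single class, or too few samples to fit."""


class MissingRatioError(KeyError):
    """A profile lacks a ratio the model requires; the prediction is non-evaluable."""


@dataclass(frozen=True)
class PredictionModel:
    """Logistic risk model: P = logistic(intercept + sum coef_r * ratio_r)."""

    name: str
    intercept: float
    coefficients: dict[str, float]

    def linear_predictor(self, ratios: Mapping[str, float]) -> float:
        eta = self.intercept
        for ratio_name, coef in self.coefficients.items():
            if ratio_name not in ratios:
                raise MissingRatioError(
                    f"model {self.name} requires ratio {ratio_name!r}"
                )
            eta += coef * ratios[ratio_name]
        return eta

    def to_json(self) -> str:
        return json.dumps(
            {"name": self.name, "intercept": self.intercept, "coefficients": self.coefficients},
            indent=2,
        )


@dataclass
class ROCCurve:
    """ROC curve over the distinct observed scores (positive call: score >= threshold).

    Includes the degenerate +inf endpoint (nothing called positive) so the
    curve spans sensitivity 1 → 0 as the threshold rises.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_positive: int
    n_negative: int


@dataclass
class FitResult:
    model: PredictionModel
    log_likelihood: float
    converged: bool
    iterations: int
    standard_errors: dict[str, float] = field(default_factory=dict)
    separation_flag: bool = False


def load_model(path: Optional[str] = None, *, shipped: Optional[str] = None) -> PredictionModel:
    """Load a model from a JSON file, or a shipped default ('p_alpha' / 'p_beta')."""
    if path is None:
        if shipped not in ("p_alpha", "p_beta"):
            raise ValueError("provide a path or shipped='p_alpha'/'p_beta'")
        text = resources.files("hbscreen.data").joinpath(f"{shipped}.json").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    obj = json.loads(text)
    return PredictionModel(
        name=obj["name"],
        intercept=float(obj["intercept"]),
        coefficients={str(k): float(v) for k, v in obj["coefficients"].items()},
    )


def default_p_alpha() -> PredictionModel:
    return load_model(shipped="p_alpha")


def default_p_beta() -> PredictionModel:
    return load_model(shipped="p_beta")


def sigmoid(eta: float | np.ndarray) -> float | np.ndarray:
    """Overflow-safe logistic function, branching on the sign of eta."""
    eta = np.asarray(eta, dtype=float)
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return float(out) if out.ndim == 0 else out


def predict(model: PredictionModel, ratios: Mapping[str, float]) -> float:
    """Predicted disease probability for one sample's ratios."""
    return float(sigmoid(model.linear_predictor(ratios)))


def predict_profile(model: PredictionModel, profile: RatioProfile) -> Optional[float]:
    """Predict from a RatioProfile; None when the profile is non-evaluable or incomplete."""
    if not profile.evaluable:
        return None
    try:
        return predict(model, profile.ratios)
    except MissingRatioError:
        return None


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), with the stable log1p form
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    features: np.ndarray | Sequence[Sequence[float]],
    labels: np.ndarray | Sequence[int],
    feature_names: Optional[Sequence[str]] = None,
    name: str = "fitted",
) -> FitResult:
    """Maximum-likelihood logistic regression by IRLS (implemented here).

    ``features`` is (n, p) without an intercept column; the intercept is added
    internally.  Deterministic for a fixed input order.  Complete separation is
    reported via ``separation_flag`` (divergence guard on coefficient size)
    rather than raised.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree in length")
    if np.any(~np.isin(y, (0.0, 1.0))):
        raise ValueError("labels must be binary 0/1")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos < 2 or n_neg < 2:
        raise DegenerateInputError(
            f"need at least 2 samples per class, got {n_pos} positive / {n_neg} negative"
        )
    if np.any(~np.isfinite(X)):
        raise ValueError("features contain missing or non-finite values")

    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    if len(feature_names) != p:
        raise ValueError("feature_names length mismatch")

    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    ll_prev = _log_likelihood(Xd @ beta, y)
    converged = False
    separation = False
    it = 0
    for it in range(1, IRLS_MAX_ITER + 1):
        eta = Xd @ beta
        mu = sigmoid(eta)
        w = mu * (1.0 - mu)
        # working response z = eta + (y - mu)/w, solved by weighted least squares
        XtW = Xd.T * w
        H = XtW @ Xd + IRLS_RIDGE * np.eye(p + 1)
        g = Xd.T @ (y - mu)
        step = np.linalg.solve(H, g)
        beta = beta + step
        ll = _log_likelihood(Xd @ beta, y)
        # step-halve if the likelihood decreased (keeps the ascent monotone)
        halvings = 0
        while ll < ll_prev and halvings < 30:
            step *= 0.5
            beta = beta - step
            ll = _log_likelihood(Xd @ beta, y)
            halvings += 1
        ll_prev = ll
        if np.max(np.abs(beta)) > SEPARATION_GUARD:
            separation = True
            break
        if np.max(np.abs(step)) < IRLS_TOL:
            converged = True
            break

    eta = Xd @ beta
    if not separation and not converged:
        # slow divergence under complete separation: the data are perfectly
        # classified with wide margins yet the step never settles
        margin_ok = np.all(eta[y == 1] > 0) and np.all(eta[y == 0] < 0)
        if margin_ok and np.min(np.abs(eta)) > 5.0:
            separation = True
    mu = sigmoid(eta)
    w = mu * (1.0 - mu)
    H = (Xd.T * w) @ Xd + IRLS_RIDGE * np.eye(p + 1)
    cov = np.linalg.inv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    model = PredictionModel(
        name=name,
        intercept=float(beta[0]),
        coefficients={feature_names[j]: float(beta[j + 1]) for j in range(p)},
    )
    ses = {"intercept": float(se[0])}
    ses.update({feature_names[j]: float(se[j + 1]) for j in range(p)})
    return FitResult(
        model=model,
        log_likelihood=float(ll_prev),
        converged=converged,
        iterations=it,
        standard_errors=ses,
        separation_flag=separation,
    )


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """ROC curve with thresholds at the distinct observed scores.

    Positive call at score >= threshold; sensitivity and specificity are exact
    fractions.  A +inf threshold (no positives called) closes the curve.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int).ravel()
    if s.shape[0] != y.shape[0]:
        raise ValueError("scores and labels disagree in length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("both classes must be present for a ROC curve")

    thresholds = np.concatenate([np.unique(s), [np.inf]])
    sens = np.empty(thresholds.shape)
    spec = np.empty(thresholds.shape)
    for i, t in enumerate(thresholds):
        called = s >= t
        sens[i] = np.sum(called & (y == 1)) / n_pos
        spec[i] = np.sum(~called & (y == 0)) / n_neg
    return ROCCurve(thresholds, sens, spec, n_pos, n_neg)


def auc(curve: ROCCurve) -> float:
    """Area under the ROC curve by the trapezoid rule.

    Equals the Mann–Whitney concordance: the proportion of (positive,
    negative) score pairs with the positive scored higher, ties counting half.
    """
    fpr = 1.0 - curve.specificity
    # traverse from (0,0) to (1,1): ascending fpr, sensitivity breaking ties
    order = np.lexsort((curve.sensitivity, fpr))
    x = np.concatenate([[0.0], fpr[order], [1.0]])
    ysens = np.concatenate([[0.0], curve.sensitivity[order], [1.0]])
    return float(np.trapezoid(ysens, x))


def select_candidates(
    ratio_table: Mapping[str, Sequence[float]],
    labels: Sequence[int],
    threshold: float = AUC_SELECTION_THRESHOLD,
) -> dict[str, float]:
    """Screen candidate biomarkers: ratios whose (orientation-corrected) AUC exceeds ``threshold``.

    Each ratio is oriented so its AUC is at least 0.5 before comparison, since
    a marker that falls with disease is as usable as one that rises.  Returns
    ratio_name -> AUC for the selected candidates (possibly empty).
    """
    selected: dict[str, float] = {}
    for ratio_name, values in ratio_table.items():
        a = auc(roc_curve(values, labels))
        a = max(a, 1.0 - a)
        if a > threshold:
            selected[ratio_name] = a
    return selected


def youden_cutoff(curve: ROCCurve) -> tuple[float, float, float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties break toward higher sensitivity, then toward the lower threshold
    (a screening context penalizes false negatives).
    Returns (cutoff, J, sensitivity, specificity).
    """
    j = curve.sensitivity + curve.specificity - 1.0
    best = 0
    for i in range(1, len(j)):
        if j[i] > j[best] + 1e-15:
            best = i
        elif abs(j[i] - j[best]) <= 1e-15:
            if curve.sensitivity[i] > curve.sensitivity[best] + 1e-15:
                best = i
            elif (
                abs(curve.sensitivity[i] - curve.sensitivity[best]) <= 1e-15
                and curve.thresholds[i] < curve.thresholds[best]
            ):
                best = i
    return (
        float(curve.thresholds[best]),
        float(j[best]),
        float(curve.sensitivity[best]),
        float(curve.specificity[best]),
    )
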