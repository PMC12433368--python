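"""Screening decision rules: cutoff table and per-sample classification.

The primary screen is a pair of probability thresholds applied to the two risk
models — P(α) >= 0.33 flags α-thalassemia, P(β) >= 0.13 flags β-thalassemia —
plus per-variant thresholds on the mutant-to-wild-type ratio G_M/β (any
detected mutant peptide for most variants; >= 2.19 for Hb G-Coushatta, whose
peptide responds strongly even in trace amounts).

Higher P(α) thresholds (0.66 / 0.87 / 0.88) published per genotype class are
layered on top as descriptive *severity bands* rather than alternative calls:
genotype is unknown at screening time, so genotype-specific thresholds cannot
drive the primary decision, but the band reached is informative about likely
severity (two-gene deletions and HbH sit at the top of the P(α) scale).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

from .quantify import RatioProfile
from .risk_models import PredictionModel, predict_profile

__all__ = [
    "Category",
    "CutoffTable",
    "ScreeningCall",
    "default_cutoffs",
    "discussion_cutoffs",
    "load_cutoffs",
    "classify",
    "screen_cohort",
]


class Category:
    """Closed set of screening call categories."""

    NORMAL = "normal"
    ALPHA = "alpha_thalassemia"
    BETA = "beta_thalassemia"
    ALPHA_AND_BETA = "alpha_and_beta_thalassemia"
    ABNORMAL_HB = "abnormal_hb"
    NON_EVALUABLE = "non_evaluable"

    ALL = (NORMAL, ALPHA, BETA, ALPHA_AND_BETA, ABNORMAL_HB, NON_EVALUABLE)


#: severity bands on the P(α) scale, low to high
SEVERITY_BANDS = ("alpha_plus_range", "alpha0_range", "sea_range", "hbh_range")


@dataclass(frozen=True)
class CutoffTable:
    """Decision thresholds for the screen (shipped defaults from the published table)."""

    p_alpha_screen: float = 0.33
    p_beta_screen: float = 0.13
    p_alpha_alpha0: float = 0.66
    p_alpha_sea: float = 0.87
    p_alpha_hbh: float = 0.88
    variant_thresholds: Mapping[str, float] = field(
        default_factory=lambda: {
            "Hb S": 0.0,
            "Hb E": 0.0,
            "Hb D-Los Angeles": 0.0,
            "Hb G-Coushatta": 2.19,
            "Hb Watford": 0.0,
            "Hb Nanchang": 0.0,
            "Hb Hekinan II": 0.0,
        }
    )

    def __post_init__(self) -> None:
        for t in (self.p_alpha_screen, self.p_beta_screen, self.p_alpha_alpha0,
                  self.p_alpha_sea, self.p_alpha_hbh):
            if not (0.0 < t < 1.0):
                raise ValueError(f"probability threshold {t} outside (0, 1)")
        if not (self.p_alpha_screen <= self.p_alpha_alpha0
                <= self.p_alpha_sea <= self.p_alpha_hbh):
            raise ValueError("severity bands must be non-decreasing")

    def severity_band(self, p_alpha: float) -> Optional[str]:
        if p_alpha >= self.p_alpha_hbh:
            return "hbh_range"
        if p_alpha >= self.p_alpha_sea:
            return "sea_range"
        if p_alpha >= self.p_alpha_alpha0:
            return "alpha0_range"
        if p_alpha >= self.p_alpha_screen:
            return "alpha_plus_range"
        return None


@dataclass
class ScreeningCall:
    sample_id: str
    p_alpha: Optional[float]
    p_beta: Optional[float]
    category: str
    severity_band: Optional[str] = None
    variants_detected: list[str] = field(default_factory=list)
    reasons: list[str] = field(default_factory=list)


def default_cutoffs() -> CutoffTable:
    """The shipped cutoff table (screen thresholds 0.33 / 0.13)."""
    return CutoffTable()


def discussion_cutoffs() -> CutoffTable:
    """Alternative preset with the unrounded ROC decision points 0.329 / 0.126."""
    return CutoffTable(p_alpha_screen=0.329, p_beta_screen=0.126)


def load_cutoffs(path: Optional[str] = None) -> CutoffTable:
    if path is None:
        text = resources.files("hbscreen.data").joinpath("cutoffs.json").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    obj = json.loads(text)
    return CutoffTable(
        p_alpha_screen=float(obj["p_alpha_screen"]),
        p_beta_screen=float(obj["p_beta_screen"]),
        p_alpha_alpha0=float(obj["p_alpha_alpha0"]),
        p_alpha_sea=float(obj["p_alpha_sea"]),
        p_alpha_hbh=float(obj["p_alpha_hbh"]),
        variant_thresholds={str(k): float(v) for k, v in obj["variant_thresholds"].items()},
    )


def classify(
    p_alpha: Optional[float],
    p_beta: Optional[float],
    variant_ratios: Mapping[str, float],
    cutoffs: Optional[CutoffTable] = None,
    sample_id: str = "",
    reason: Optional[str] = None,
) -> ScreeningCall:
    """Apply the cutoff table to one sample's predictions and variant ratios.

    Abnormal-Hb flags fire independently of the thalassemia flags (compound
    carriers are reported with both); both thalassemia flags firing yields the
    combined category.  Non-evaluable predictions propagate.
    """
    if cutoffs is None:
        cutoffs = default_cutoffs()
    if p_alpha is None or p_beta is None:
        return ScreeningCall(
            sample_id=sample_id, p_alpha=p_alpha, p_beta=p_beta,
            category=Category.NON_EVALUABLE,
            reasons=[reason or "prediction not evaluable"],
        )
    if not (0.0 <= p_alpha <= 1.0 and 0.0 <= p_beta <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")

    reasons: list[str] = []
    variants: list[str] = []
    for variant_name, ratio in variant_ratios.items():
        if ratio < 0:
            raise ValueError(f"variant ratio for {variant_name} is negative")
        threshold = cutoffs.variant_thresholds.get(variant_name, 0.0)
        fired = ratio >= threshold if threshold > 0 else ratio > 0.0
        if fired:
            variants.append(variant_name)
            reasons.append(f"G_M/beta for {variant_name} = {ratio:.4g} met cutoff")

    alpha_flag = p_alpha >= cutoffs.p_alpha_screen
    beta_flag = p_beta >= cutoffs.p_beta_screen
    if alpha_flag:
        reasons.append(f"P(alpha) = {p_alpha:.4g} >= {cutoffs.p_alpha_screen}")
    if beta_flag:
        reasons.append(f"P(beta) = {p_beta:.4g} >= {cutoffs.p_beta_screen}")

    if alpha_flag and beta_flag:
        category = Category.ALPHA_AND_BETA
    elif alpha_flag:
        category = Category.ALPHA
    elif beta_flag:
        category = Category.BETA
    elif variants:
        category = Category.ABNORMAL_HB
    else:
        category = Category.NORMAL
        reasons.append("below all screen cutoffs, no variant detected")

    return ScreeningCall(
        sample_id=sample_id,
        p_alpha=p_alpha,
        p_beta=p_beta,
        category=category,
        severity_band=cutoffs.severity_band(p_alpha) if alpha_flag else None,
        variants_detected=sorted(variants),
        reasons=reasons,
    )


def screen_cohort(
    profiles: Sequence[RatioProfile],
    p_alpha_model: PredictionModel,
    p_beta_model: PredictionModel,
    cutoffs: Optional[CutoffTable] = None,
) -> tuple[list[ScreeningCall], dict[str, int]]:
    """Screen a cohort of ratio profiles: one call per sample plus category counts.

    Output ordering is stable by sample_id; non-evaluable samples are kept,
    never dropped.
    """
    calls: list[ScreeningCall] = []
    for profile in sorted(profiles, key=lambda p: p.sample_id):
        pa = predict_profile(p_alpha_model, profile)
        pb = predict_profile(p_beta_model, profile)
        calls.append(
            classify(pa, pb, profile.variant_ratios, cutoffs,
                     sample_id=profile.sample_id, reason=profile.reason)
        )
    counts = {cat: 0 for cat in Category.ALL}
    for call in calls:
        counts[call.category] += 1
    return calls, counts
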