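"""Clinical screening performance and assay-validation statistics.

Clinical side: confusion matrices against a confirmed-genotype truth labeling,
sensitivity/specificity (reported to two decimals, half-up, matching clinical
reporting convention), and the Youden index.

Assay side: the conventional clinical-MS validation statistics — coefficient
of variation over replicates, carryover of a high sample into the following
blank, matrix effect of a biological matrix versus a neat solution, spike
recovery, and a storage-stability flag (ratio CV across timepoints < 20%).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "STABILITY_CV_LIMIT",
    "round_pct",
    "confusion",
    "sensitivity_specificity",
    "detection_rate",
    "youden_index",
    "coefficient_of_variation",
    "carryover_rate",
    "matrix_effect",
    "recovery",
    "stability_flag",
]

#: a storage condition is stable when the ratio CV across timepoints is below this (%)
STABILITY_CV_LIMIT = 20.0


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def round_pct(value: float, ndigits: int = 2) -> float:
    """Round a percentage half-up (25.005 -> 25.01), not banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def confusion(calls: Sequence[int], truth: Sequence[int]) -> ConfusionMatrix:
    """Count TP/FP/FN/TN for aligned binary call and truth sequences."""
    c = np.asarray(calls, dtype=int).ravel()
    t = np.asarray(truth, dtype=int).ravel()
    if c.shape != t.shape:
        raise ValueError(f"calls ({c.shape[0]}) and truth ({t.shape[0]}) differ in length")
    return ConfusionMatrix(
        tp=int(np.sum((c == 1) & (t == 1))),
        fp=int(np.sum((c == 1) & (t == 0))),
        fn=int(np.sum((c == 0) & (t == 1))),
        tn=int(np.sum((c == 0) & (t == 0))),
    )


def sensitivity_specificity(cm: ConfusionMatrix) -> tuple[Optional[float], Optional[float]]:
    """(sensitivity %, specificity %), two decimals; None where the denominator is zero."""
    sens = round_pct(100.0 * cm.tp / (cm.tp + cm.fn)) if cm.tp + cm.fn > 0 else None
    spec = round_pct(100.0 * cm.tn / (cm.tn + cm.fp)) if cm.tn + cm.fp > 0 else None
    return sens, spec


def detection_rate(detected: int, total: int) -> float:
    """Per-genotype detection rate in %, two decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= detected <= total:
        raise ValueError("detected must lie in [0, total]")
    return round_pct(100.0 * detected / total)


def youden_index(sensitivity_pct: float, specificity_pct: float) -> float:
    """J = sensitivity + specificity - 1, from percentage inputs."""
    for v in (sensitivity_pct, specificity_pct):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"percentage {v} outside [0, 100]")
    return sensitivity_pct / 100.0 + specificity_pct / 100.0 - 1.0


def coefficient_of_variation(replicates: Sequence[float]) -> Optional[float]:
    """CV % = 100 * sample SD (n-1) / mean; None for < 2 values or zero mean."""
    x = np.asarray(replicates, dtype=float)
    if x.size < 2:
        return None
    mean = float(np.mean(x))
    if mean == 0.0:
        return None
    return 100.0 * float(np.std(x, ddof=1)) / mean


def carryover_rate(high_signal: float, following_blank: float, baseline_blank: float) -> float:
    """Carryover % = 100 * max(blank-after-high - baseline-blank, 0) / high signal."""
    if high_signal <= 0:
        raise ValueError("high_signal must be positive")
    return 100.0 * max(following_blank - baseline_blank, 0.0) / high_signal


def matrix_effect(matrix_spiked_response: float, neat_response: float) -> float:
    """Matrix effect % = 100 * |matrix-spiked / neat - 1|."""
    if neat_response <= 0:
        raise ValueError("neat_response must be positive")
    return 100.0 * abs(matrix_spiked_response / neat_response - 1.0)


def recovery(measured_total: float, endogenous: float, added: float) -> float:
    """Spike recovery % = 100 * (measured - endogenous) / added."""
    if added <= 0:
        raise ValueError("added must be positive")
    return 100.0 * (measured_total - endogenous) / added


def stability_flag(ratio_series: Sequence[float]) -> bool:
    """True when the ratio series over storage timepoints has CV below 20%."""
    cv = coefficient_of_variation(ratio_series)
    if cv is None:
        raise ValueError("stability requires >= 2 timepoints with nonzero mean")
    return cv < STABILITY_CV_LIMIT
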