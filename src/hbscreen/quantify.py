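"""Peptide quantification and globin-chain ratio computation.

The screening assay monitors one tryptic "proteo-specific" peptide per globin
chain (αT1, αT3, βT1, βT2, γT10, δT2, ζT8) plus mutation-bearing peptides for
structural Hb variants, each with a stable-isotope-labeled internal standard
(IS) spiked at a known concentration.  Quantification is isotope-dilution
style, with no calibration curve:

    concentration = analyte_area * C_IS / IS_area

Screening biomarkers are dimensionless chain ratios — the ratio of two such
concentrations — which capture the α-like/β-like chain imbalance that defines
thalassemia.  For structural variants the mutant-to-wild-type peptide area
ratio G_M/β is used; by convention it carries no IS concentration terms (the
mutant and wild-type peptides share a backbone and the ratio of areas per IS
area is already comparable).

A peptide counts as detected when its signal-to-noise ratio is at least 10;
ratios whose denominator chain is undetected are never emitted as infinities —
the sample is flagged non-evaluable instead.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

__all__ = [
    "SN_THRESHOLD",
    "RATIO_DEFINITIONS",
    "CORE_PANEL",
    "TransitionDefinition",
    "PeakMeasurement",
    "SampleRecord",
    "RatioProfile",
    "InvalidMeasurementError",
    "ConfigError",
    "InputError",
    "load_transition_registry",
    "load_is_config",
    "compute_concentration",
    "compute_chain_ratio",
    "compute_variant_ratio",
    "is_detected",
    "quantify_sample",
]

#: signal-to-noise ratio required to call a peptide detected
SN_THRESHOLD = 10.0

#: length of the chromatographic run, minutes (retention-time sanity window)
RUN_WINDOW_MIN = 2.6

#: closed set of named chain ratios: ratio_name -> (numerator, denominator)
RATIO_DEFINITIONS: dict[str, tuple[str, str]] = {
    "aT1_bT1": ("alphaT1", "betaT1"),
    "zT8_bT2": ("zetaT8", "betaT2"),
    "aT3_bT1": ("alphaT3", "betaT1"),
    "dT2_bT2": ("deltaT2", "betaT2"),
    "gT10_aT3": ("gammaT10", "alphaT3"),
    "gT10_bT1": ("gammaT10", "betaT1"),
}

#: peptides expected for a fully evaluable sample
CORE_PANEL = ("alphaT1", "alphaT3", "betaT1", "betaT2", "gammaT10", "deltaT2", "zetaT8")

#: wild-type denominator peptide for all variant ratios (the published cutoff
#: table expresses the mutant ratio as G_M/βT1)
VARIANT_WILDTYPE_PEPTIDE = "betaT1"

VALID_CHAINS = frozenset({"alpha", "beta", "gamma", "delta", "zeta", "variant"})


class InvalidMeasurementError(ValueError):
    """A peak measurement cannot be quantified (non-positive IS area / IS concentration)."""


class ConfigError(ValueError):
    """A required configuration entry (IS concentration, registry entry) is missing or invalid."""


class InputError(ValueError):
    """Malformed input data (duplicate peptides, mismatched tables, ...)."""


@dataclass(frozen=True)
class TransitionDefinition:
    """One monitored precursor→product transition from the assay registry."""

    peptide_id: str
    sequence: str
    precursor_mz: float
    product_mz: float
    retention_time: float
    collision_energy: float
    is_internal_standard: bool = False
    chain: str = "beta"
    variant_name: Optional[str] = None
    wildtype_partner: Optional[str] = None
    note: Optional[str] = None

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0 or self.product_mz <= 0:
            raise ConfigError(f"{self.peptide_id}: m/z values must be positive")
        if not (0 < self.retention_time <= RUN_WINDOW_MIN):
            raise ConfigError(
                f"{self.peptide_id}: retention time {self.retention_time} min outside "
                f"the {RUN_WINDOW_MIN}-min run window"
            )
        if not self.sequence or not self.sequence.isupper() or not self.sequence.isalpha():
            raise ConfigError(f"{self.peptide_id}: sequence must be uppercase one-letter codes")
        if self.chain not in VALID_CHAINS:
            raise ConfigError(f"{self.peptide_id}: unknown chain {self.chain!r}")


@dataclass(frozen=True)
class PeakMeasurement:
    """Analyte and internal-standard peak areas for one peptide in one sample.

    Areas are integrated mass-spectra peak areas (MSPA) in arbitrary units;
    ``noise`` is the baseline noise level in the same units, used for the
    S/N >= 10 detection rule when present.
    """

    sample_id: str
    peptide_id: str
    area: float
    is_area: float
    noise: Optional[float] = None

    def __post_init__(self) -> None:
        if self.area < 0:
            raise InvalidMeasurementError(
                f"sample {self.sample_id}, peptide {self.peptide_id}: negative analyte area"
            )
        if self.noise is not None and self.noise < 0:
            raise InvalidMeasurementError(
                f"sample {self.sample_id}, peptide {self.peptide_id}: negative noise"
            )

    @property
    def evaluable(self) -> bool:
        return self.is_area > 0


@dataclass
class SampleRecord:
    """All peak measurements for one newborn DBS sample plus metadata."""

    sample_id: str
    age_days: int = 0
    measurements: list[PeakMeasurement] = field(default_factory=list)
    truth_genotype: Optional[str] = None

    def __post_init__(self) -> None:
        if self.age_days < 0:
            raise InputError(f"sample {self.sample_id}: negative age")
        seen: set[str] = set()
        for m in self.measurements:
            if m.peptide_id in seen:
                raise InputError(
                    f"sample {self.sample_id}: duplicate peptide {m.peptide_id}"
                )
            seen.add(m.peptide_id)

    def measurement(self, peptide_id: str) -> Optional[PeakMeasurement]:
        for m in self.measurements:
            if m.peptide_id == peptide_id:
                return m
        return None


@dataclass
class RatioProfile:
    """Per-sample dimensionless globin-chain ratios and variant ratios."""

    sample_id: str
    ratios: dict[str, float] = field(default_factory=dict)
    variant_ratios: dict[str, float] = field(default_factory=dict)
    detection: dict[str, bool] = field(default_factory=dict)
    evaluable: bool = True
    reason: Optional[str] = None


def load_transition_registry(path: Optional[str] = None) -> list[TransitionDefinition]:
    """Load the transition registry (shipped assay panel by default)."""
    if path is None:
        text = resources.files("hbscreen.data").joinpath("transitions.json").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    entries = [TransitionDefinition(**obj) for obj in json.loads(text)]
    # every IS entry must pair with exactly one analyte entry of the same id
    analytes = [e.peptide_id for e in entries if not e.is_internal_standard]
    for e in entries:
        if e.is_internal_standard and analytes.count(e.peptide_id) != 1:
            raise ConfigError(f"IS entry {e.peptide_id} lacks a unique analyte partner")
    return entries


def load_is_config(path: Optional[str] = None) -> dict[str, float]:
    """Load peptide_id -> IS concentration (mg/L); shipped defaults otherwise."""
    if path is None:
        text = resources.files("hbscreen.data").joinpath("is_concentrations.json").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    config = {str(k): float(v) for k, v in json.loads(text).items()}
    for pid, c in config.items():
        if c <= 0:
            raise ConfigError(f"IS concentration for {pid} must be positive, got {c}")
    return config


def compute_concentration(area: float, is_area: float, c_is: float) -> float:
    """Peptide concentration (mg/L) by isotope dilution: area * C_IS / IS_area."""
    if is_area <= 0 or c_is <= 0:
        raise InvalidMeasurementError(
            f"non-positive IS area ({is_area}) or IS concentration ({c_is})"
        )
    if area < 0:
        raise InvalidMeasurementError(f"negative analyte area {area}")
    return area * c_is / is_area


def compute_chain_ratio(
    num: PeakMeasurement,
    den: PeakMeasurement,
    is_config: Mapping[str, float],
) -> Optional[float]:
    """Dimensionless chain ratio: the ratio of two isotope-dilution concentrations.

    Equals (num.area * den.is_area * C_num_IS) / (num.is_area * den.area * C_den_IS).
    Returns None (non-evaluable flag) when the denominator peptide has zero area.
    """
    for m in (num, den):
        if m.peptide_id not in is_config:
            raise ConfigError(f"no IS concentration configured for {m.peptide_id}")
        if not m.evaluable:
            raise InvalidMeasurementError(
                f"sample {m.sample_id}, peptide {m.peptide_id}: IS area must be positive"
            )
    if den.area <= 0:
        return None
    c_num = compute_concentration(num.area, num.is_area, is_config[num.peptide_id])
    c_den = compute_concentration(den.area, den.is_area, is_config[den.peptide_id])
    return c_num / c_den


def compute_variant_ratio(mutant: PeakMeasurement, wildtype_beta: PeakMeasurement) -> Optional[float]:
    """Mutant-to-wild-type peptide ratio G_M/β.

    By convention this ratio carries no IS concentration terms:
    (mutant.area * wt.is_area) / (mutant.is_area * wt.area).
    Returns None when the wild-type β area is zero (non-evaluable sample).
    """
    if mutant.is_area <= 0 or wildtype_beta.is_area <= 0:
        raise InvalidMeasurementError("IS areas must be positive for the variant ratio")
    if wildtype_beta.area <= 0:
        return None
    return (mutant.area * wildtype_beta.is_area) / (mutant.is_area * wildtype_beta.area)


def is_detected(area: float, noise: Optional[float], floor: float = 0.0) -> bool:
    """Detection call: S/N >= 10 when a noise level is available.

    Without a noise channel the peptide is detected when its area exceeds the
    configured detection floor (default 0, i.e. any signal).
    """
    if area < 0 or (noise is not None and noise < 0) or floor < 0:
        raise InvalidMeasurementError("areas, noise and floor must be non-negative")
    if noise is not None and noise > 0:
        return area / noise >= SN_THRESHOLD
    if noise == 0:
        # an explicit zero-noise channel with zero area is an empty channel
        return area > floor and area > 0
    return area > floor


def quantify_sample(
    sample: SampleRecord,
    is_config: Optional[Mapping[str, float]] = None,
    registry: Optional[list[TransitionDefinition]] = None,
    detection_floor: float = 0.0,
) -> RatioProfile:
    """Turn a sample's peak areas into a full ratio profile.

    Emits every named chain ratio whose numerator and denominator peptides are
    present and evaluable (undetected numerators contribute 0), plus one
    variant ratio per registry variant peptide present in the sample.  The
    sample is flagged non-evaluable when βT1 or βT2 — the denominators of the
    screening ratios — is missing or undetected.  Pure function of its inputs.
    """
    if is_config is None:
        is_config = load_is_config()
    if registry is None:
        registry = load_transition_registry()

    known = {t.peptide_id for t in registry}
    variant_defs = {
        t.peptide_id: t for t in registry if t.chain == "variant" and not t.is_internal_standard
    }

    profile = RatioProfile(sample_id=sample.sample_id)
    usable: dict[str, PeakMeasurement] = {}
    for m in sample.measurements:
        if m.peptide_id not in known:
            warnings.warn(
                f"sample {sample.sample_id}: unknown peptide {m.peptide_id} skipped",
                stacklevel=2,
            )
            continue
        usable[m.peptide_id] = m
        profile.detection[m.peptide_id] = m.evaluable and is_detected(
            m.area, m.noise, detection_floor
        )

    for beta_pid in ("betaT1", "betaT2"):
        if not profile.detection.get(beta_pid, False):
            profile.evaluable = False
            profile.reason = f"{beta_pid} missing or undetected"
            return profile

    for name, (num_pid, den_pid) in RATIO_DEFINITIONS.items():
        num, den = usable.get(num_pid), usable.get(den_pid)
        if num is None or den is None or not den.evaluable or not num.evaluable:
            continue
        if not profile.detection[den_pid]:
            continue
        if not profile.detection[num_pid]:
            profile.ratios[name] = 0.0
            continue
        value = compute_chain_ratio(num, den, is_config)
        if value is not None:
            profile.ratios[name] = value

    wt = usable.get(VARIANT_WILDTYPE_PEPTIDE)
    for pid, tdef in variant_defs.items():
        assert tdef.variant_name is not None
        m = usable.get(pid)
        if m is None:
            continue
        if not profile.detection[pid]:
            profile.variant_ratios[tdef.variant_name] = 0.0
            continue
        if wt is None:
            continue
        value = compute_variant_ratio(m, wt)
        profile.variant_ratios[tdef.variant_name] = 0.0 if value is None else value

    return profile
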