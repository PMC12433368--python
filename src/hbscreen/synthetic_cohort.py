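"""Genotype-stratified synthetic DBS cohort generator.

Emulates the structure the screen relies on — genotype-dependent globin-chain
imbalance measured through noisy peptide peak areas — so that every pipeline
stage can be exercised without patient data:

* each genotype preset scales the five chain abundances multiplicatively
  relative to a normal-newborn baseline (α-gene deletions lower α and raise
  the persistent embryonic ζ and fetal γ signals; β-thalassemia alleles lower
  β and raise the relative δ excess);
* structural variants divert a fraction of β-chain output into a mutant
  peptide, reducing the wild-type peptide that carries the mutated residue;
* peak areas get independent multiplicative lognormal measurement noise
  (lognormal keeps areas positive and is parameterized directly by CV), and
  internal-standard areas are drawn independently of the analytes, as
  separately spiked standards are.

All effect sizes here are synthetic calibration values, chosen once so the
qualitative severity ordering (normal < one-gene deletion < two-gene deletion
< HbH on the P(α) scale) holds; they are not measured biology and must not be
quoted as chain-concentration estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .quantify import (
    CORE_PANEL,
    PeakMeasurement,
    SampleRecord,
    TransitionDefinition,
    load_is_config,
    load_transition_registry,
)

__all__ = [
    "GenotypeEffect",
    "CohortSpec",
    "TRUTH_CATEGORIES",
    "preset_effects",
    "default_cohort_spec",
    "generate_cohort",
]

#: generator genotype label -> truth screening category
TRUTH_CATEGORIES: dict[str, str] = {
    "normal": "normal",
    "aa/-a3.7": "alpha_thalassemia",
    "-a3.7/-a3.7": "alpha_thalassemia",
    "aa/--SEA": "alpha_thalassemia",
    "HbH": "alpha_thalassemia",
    "beta_plus_het": "beta_thalassemia",
    "beta0_het": "beta_thalassemia",
    "alpha_beta_het": "alpha_and_beta_thalassemia",
    "HbS_het": "abnormal_hb",
    "HbE_het": "abnormal_hb",
    "HbD_het": "abnormal_hb",
    "HbG_het": "abnormal_hb",
}

CHAINS = ("alpha", "beta", "gamma", "delta", "zeta")

#: normal-newborn baseline chain abundances, mg/L scale (synthetic; most Hb at
#: birth is HbF so α-like output exceeds β; δ is barely expressed and the
#: embryonic ζ chain is near-absent)
DEFAULT_BASELINE: dict[str, float] = {
    "alpha": 8.0,
    "beta": 2.0,
    "gamma": 4.0,
    "delta": 0.04,
    "zeta": 0.004,
}

#: nominal analyte/IS peak-area scale (arbitrary MSPA units)
NOMINAL_IS_AREA = 4.0e5

#: synthetic ionization response factors relative to βT1; the Hb G-Coushatta
#: peptide is given a strong response so its ratio scale matches its high
#: published cutoff (>= 2.19)
RESPONSE_FACTORS: dict[str, float] = {"betaHbG_T3": 8.0}


@dataclass(frozen=True)
class GenotypeEffect:
    """Multiplicative chain effects of one genotype, plus variant fractions.

    ``chain_multipliers`` scale the baseline chain abundances; ``variant_
    fractions`` give the fraction of β-chain output carried by each mutant
    peptide.  All values are synthetic calibration knobs.
    """

    label: str
    chain_multipliers: Mapping[str, float] = field(default_factory=dict)
    variant_fractions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chain, m in self.chain_multipliers.items():
            if chain not in CHAINS:
                raise ValueError(f"{self.label}: unknown chain {chain!r}")
            if m <= 0:
                raise ValueError(f"{self.label}: chain multiplier must be positive")
        for variant, f in self.variant_fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{self.label}: variant fraction for {variant} outside [0, 1]")

    def multiplier(self, chain: str) -> float:
        return float(self.chain_multipliers.get(chain, 1.0))


@dataclass
class CohortSpec:
    """Recipe for one synthetic cohort; the seed is mandatory for reproducibility."""

    strata: list[tuple[GenotypeEffect, int]]
    seed: int
    baseline: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINE))
    measurement_cv_pct: float = 10.0
    is_area_mean: float = NOMINAL_IS_AREA
    is_area_cv_pct: float = 5.0
    noise_level: float = 300.0
    detection_floor: float = 0.0

    def __post_init__(self) -> None:
        for _, n in self.strata:
            if n < 0:
                raise ValueError("stratum size must be non-negative")
        for cv in (self.measurement_cv_pct, self.is_area_cv_pct):
            if cv < 0:
                raise ValueError("CVs must be non-negative")
        if self.is_area_mean <= 0:
            raise ValueError("IS area mean must be positive")


def preset_effects() -> dict[str, GenotypeEffect]:
    """Library of genotype presets (synthetic effect sizes, see module docstring)."""
    presets = [
        GenotypeEffect("normal"),
        # one α gene deleted: mild α deficit, modest embryonic-chain persistence
        GenotypeEffect("aa/-a3.7", {"alpha": 0.75, "zeta": 10.0, "gamma": 1.1}),
        # two α genes deleted in trans
        GenotypeEffect("-a3.7/-a3.7", {"alpha": 0.55, "zeta": 20.0, "gamma": 1.2}),
        # two α genes deleted in cis (Southeast-Asian deletion carrier); the
        # deletion spares the ζ gene, so ζ persists strongly
        GenotypeEffect("aa/--SEA", {"alpha": 0.5, "zeta": 100.0, "gamma": 1.3}),
        # three α genes lost
        GenotypeEffect("HbH", {"alpha": 0.3, "zeta": 200.0, "gamma": 1.5}),
        # heterozygous β-thalassemia, reduced vs absent allele output
        GenotypeEffect("beta_plus_het", {"beta": 0.65, "delta": 3.2}),
        GenotypeEffect("beta0_het", {"beta": 0.5, "delta": 3.5, "gamma": 1.2}),
        # compound α + β carrier
        GenotypeEffect(
            "alpha_beta_het",
            {"alpha": 0.5, "zeta": 100.0, "beta": 0.65, "delta": 3.5},
        ),
        # structural variant heterozygotes: a fraction of β output is mutant
        GenotypeEffect("HbS_het", {"beta": 0.95}, {"Hb S": 0.45}),
        GenotypeEffect("HbE_het", {"beta": 0.85}, {"Hb E": 0.30}),
        GenotypeEffect("HbD_het", {"beta": 0.95}, {"Hb D-Los Angeles": 0.45}),
        GenotypeEffect("HbG_het", {"beta": 0.95}, {"Hb G-Coushatta": 0.40}),
    ]
    return {p.label: p for p in presets}


def default_cohort_spec(seed: int) -> CohortSpec:
    """The default study cohort: 200 normals, 50 --SEA-like, 50 β0-like, CV 10%."""
    presets = preset_effects()
    return CohortSpec(
        strata=[
            (presets["normal"], 200),
            (presets["aa/--SEA"], 50),
            (presets["beta0_het"], 50),
        ],
        seed=seed,
    )


def _lognormal_factor(rng: np.random.Generator, cv_pct: float, size: int = 1) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV (%)."""
    if cv_pct == 0:
        return np.ones(size)
    sigma = float(np.sqrt(np.log1p((cv_pct / 100.0) ** 2)))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def generate_cohort(
    spec: CohortSpec,
    registry: Optional[Sequence[TransitionDefinition]] = None,
) -> list[SampleRecord]:
    """Draw a cohort of labeled SampleRecords from the spec; reproducible from its seed."""
    if registry is None:
        registry = load_transition_registry()
    is_config = load_is_config()
    chain_of = {
        t.peptide_id: t.chain for t in registry if not t.is_internal_standard
    }
    variant_defs = {
        t.variant_name: t
        for t in registry
        if t.chain == "variant" and not t.is_internal_standard and t.variant_name
    }

    rng = np.random.default_rng(spec.seed)
    samples: list[SampleRecord] = []
    idx = 0
    for effect, n in spec.strata:
        for variant in effect.variant_fractions:
            if variant not in variant_defs:
                raise ValueError(f"{effect.label}: no registry peptide for variant {variant!r}")
        for _ in range(n):
            idx += 1
            sid = f"S{idx:04d}"
            age = int(rng.integers(2, 31))
            measurements: list[PeakMeasurement] = []

            chain_abund = {
                c: spec.baseline[c] * effect.multiplier(c) for c in CHAINS
            }
            # fraction of β output diverted per wild-type partner peptide
            wt_loss: dict[str, float] = {}
            for variant, f in effect.variant_fractions.items():
                partner = variant_defs[variant].wildtype_partner
                if partner is not None and f > 0:
                    wt_loss[partner] = wt_loss.get(partner, 0.0) + f

            for pid in CORE_PANEL:
                conc = chain_abund[chain_of[pid]] * (1.0 - wt_loss.get(pid, 0.0))
                area = (
                    conc / is_config[pid] * spec.is_area_mean
                    * float(_lognormal_factor(rng, spec.measurement_cv_pct)[0])
                )
                is_area = spec.is_area_mean * float(
                    _lognormal_factor(rng, spec.is_area_cv_pct)[0]
                )
                noise = spec.noise_level
                if area < spec.detection_floor:
                    noise = max(noise, area)  # force S/N < 10 below the floor
                measurements.append(
                    PeakMeasurement(sid, pid, float(area), float(is_area), float(noise))
                )

            for variant, f in effect.variant_fractions.items():
                if f <= 0:
                    continue
                vdef = variant_defs[variant]
                resp = RESPONSE_FACTORS.get(vdef.peptide_id, 1.0)
                conc = chain_abund["beta"] * f
                area = (
                    conc / is_config["betaT1"] * spec.is_area_mean * resp
                    * float(_lognormal_factor(rng, spec.measurement_cv_pct)[0])
                )
                is_area = spec.is_area_mean * float(
                    _lognormal_factor(rng, spec.is_area_cv_pct)[0]
                )
                measurements.append(
                    PeakMeasurement(sid, vdef.peptide_id, float(area), float(is_area),
                                    float(spec.noise_level))
                )

            samples.append(
                SampleRecord(
                    sample_id=sid,
                    age_days=age,
                    measurements=measurements,
                    truth_genotype=effect.label,
                )
            )
    return samples
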