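# Methods

## Quantification model

Each monitored peptide is quantified by isotope dilution against a
stable-isotope-labeled internal standard (IS) spiked at a known
concentration: `C = Area · C_IS / Area_IS` (mg/L). No calibration curves are
involved; the IS concentration anchors the scale. The shipped IS
concentrations are 2 (αT1), 10 (αT3), 5 (βT1), 5 (βT2), 0.5 (γT10), 0.2
(δT2) and 0.1 (ζT8) mg/L, and the transition registry carries the peptide
sequences, precursor/product m/z, retention times (all within the 2.6-minute
run) and collision energies. One registry oddity is preserved deliberately:
the βT2 IS product ion is stored as 68.3927 Th, as published, with a note
field marking it as an almost-certain typo — the registry is configuration
data, not a place to silently "fix" the record.

Screening biomarkers are chain ratios — ratios of two such concentrations —
so all area and IS-area terms appear explicitly and the result is
dimensionless and invariant under common rescaling of a sample's areas. The
variant ratio G_M/β is, by convention, a pure area ratio without the IS
concentration terms: the mutant and wild-type peptides share a backbone, so
their per-IS-area responses are directly comparable. The asymmetry with the
chain-ratio formula is intentional and implemented exactly as defined. The
cutoff table expresses variant ratios against βT1, so βT1 is the wild-type
denominator for every variant, including those whose mutated tryptic peptide
(T3, T13, …) is not itself monitored.

Detection uses signal-to-noise ≥ 10 when a noise channel is present,
otherwise a configurable per-run detection floor (default 0). A sample whose
βT1 or βT2 — the denominators of every screening ratio — is missing or
undetected is flagged non-evaluable rather than producing an infinite ratio;
an undetected mutant peptide contributes G_M/β = 0, which makes the "> 0.00"
variant cutoffs read as "mutant peptide detected".

## Risk models and cutoff optimization

P(α) and P(β) are binary logistic models over ratio pairs; the shipped
coefficient files carry the published values (see README). The logistic is
evaluated overflow-safely by branching on the sign of the linear predictor —
the δ coefficient of 105.132 would overflow a naïve exponential at modest
ratios.

Refitting is maximum likelihood via iteratively reweighted least squares,
implemented in `risk_models` rather than delegated: convergence when the
largest parameter change falls below 1e-8, at most 100 iterations, a 1e-8
ridge on the normal equations for numerical stability, and step-halving to
keep the likelihood ascent monotone. Complete separation is reported through
`separation_flag` (a runaway guard at |β| > 1e4, plus a post-hoc check for a
perfectly classified fit with wide margins that failed to settle) instead of
an exception, since separated data still answer the scientific question.
Tests cross-check the fitter against statsmodels on random problems and
against the closed-form 2×2 log odds ratio.

ROC curves enumerate the distinct observed scores as thresholds with the
positive call at score ≥ threshold (matching the "≥" convention of the
cutoff table), closed by a +∞ threshold. AUC is the trapezoid area, which
for this construction equals the tie-aware Mann–Whitney concordance — the
test suite verifies that equivalence against an all-pairs scan. The Youden
maximizer breaks ties toward higher sensitivity, then the lower threshold:
in a screening context a false negative is the costlier error. Candidate
biomarkers are ratios whose orientation-corrected AUC (max of AUC and
1−AUC) exceeds 0.850.

## Screening decision rules

The primary screen applies P(α) ≥ 0.33 and P(β) ≥ 0.13; both firing yields
the combined α+β category, and variant flags fire independently so compound
carriers are reported with both. The per-genotype thresholds published
alongside (0.66 for two-gene α deletions, 0.87 for the --SEA carrier row,
0.88 for HbH) are layered on as descriptive severity bands: genotype is
unknown at screening time, so genotype-specific thresholds cannot drive the
primary call. The band reported is the highest whose threshold is met.
A preset with the unrounded decision points (0.329 / 0.126) is exposed as
`discussion_cutoffs()`; which variant was used prospectively is not
determinable, so both are available and neither is guessed at.

## Performance statistics

Sensitivity = 100·TP/(TP+FN), specificity = 100·TN/(TN+FP), reported to two
decimals rounded half-up to match clinical reporting; zero denominators
yield an undefined-metric `None`, never a crash. The shipped
clinical-validation reference counts reproduce the published percentage
pairs exactly, with one exception: the abnormal-Hb comparator row prints
99.10% against counts of 296/299, which computes to 99.00% — the package
reports the value computed from the counts.

The assay-validation statistics use the conventional clinical-MS forms,
since the validation protocol names the assessments but not formulas:
CV% = 100·SD(n−1)/mean; carryover = 100·max(blank-after-high − baseline
blank, 0)/high signal; matrix effect = 100·|matrix-spiked/neat − 1|;
recovery = 100·(measured − endogenous)/added; storage stability = ratio CV
across timepoints < 20%.

## Synthetic cohort generator

The generator emulates the data-generating structure the screen assumes. Per
sample, chain abundances are a normal-newborn baseline (α 8, β 2, γ 4,
δ 0.04, ζ 0.004 on the mg/L scale — fetal-dominant hemoglobin, barely
expressed δ, near-absent embryonic ζ) times a genotype-specific multiplier.
Peptide analyte areas are derived from their chain's abundance at a nominal
IS-area scale of 4·10⁵ with independent multiplicative lognormal measurement
noise (default CV 10%, within the assay's validated ≤ 14.67% range);
lognormal noise keeps areas strictly positive and is parameterized directly
by CV. IS areas are drawn independently (default CV 5%) because the
standards are spiked separately from the biological extract. Variant
heterozygotes divert a fraction of β-chain output into the mutant peptide;
where the mutated residue lies in a monitored wild-type peptide (Hb S and
Hb Watford in βT1), that peptide is reduced by the same fraction, while
variants mutated in unmonitored peptides leave βT1/βT2 untouched — exactly
the behavior of shared tryptic peptides. The Hb G-Coushatta peptide carries
a synthetic ionization response factor of 8 so that its ratio scale is
commensurate with its high published cutoff (2.19).

Every preset effect size is an invented calibration value — the study
reports no per-genotype chain concentrations — chosen once so the severity
ordering on the P(α) scale (normal < one-gene deletion < two-gene deletion <
HbH) holds, and must not be cited as a biological estimate. Consequently the
default cohort (200 normals, 50 --SEA-like, 50 β0-like, seed-controlled)
demonstrates that the pipeline's machinery is correct and well-calibrated
under its assumed data model; passing tests on it say nothing quantitative
about performance on real newborn cohorts, whose effect-size distributions,
genotype mix and pre-analytical variation the generator does not model (no
retention drift, co-elution, age-dependent hemoglobin switching, or
between-batch effects).

## Problem sizes and numerics

The shipped experiments use a 300-sample default cohort for end-to-end
screening and 5,000 samples for the coefficient-recovery refit, sizes at
which the recovery standard errors are small enough for a meaningful 3-SE
check while everything runs in seconds. Floating-point conventions: peak
tables are written at %.17g and parsed with round-trip float precision, so
write/read is bit-exact; ratio identities are tested to 1e-12 relative;
Youden tie detection treats J values within 1e-15 as equal (distinct
empirical J values on n samples differ by at least 1/n², far above that).

## Known limitations

- Severity bands are suggestive, not diagnostic; no genotype prediction is
  attempted (confirmation is a sequencing task, outside this artifact).
- No rule is implemented for hereditary persistence of fetal hemoglobin;
  how it should be called is unspecified upstream.
- The LLOQ is represented only as a configurable detection floor; no
  dilution-series estimation is performed.
- Raw spectra, chromatogram peak picking and instrument settings are out of
  scope; the pipeline starts at integrated peak areas.
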