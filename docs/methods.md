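# Methods

## Scope and data model

`pfasquant` implements the computational chain of a targeted multi-residue
PFAS wastewater method: from integrated MRM peak tables (quantifier and
qualifier areas, ISTD areas, signal-to-noise, retention times) through
internal-standard calibration, limit determination, validation metrics,
wastewater-based-epidemiology (WBE) loads and environmental risk
quotients. Chromatographic processing (peak detection/integration) and all
wet-lab protocol are out of scope; the pipeline's inputs begin where the
vendor quantification software ends.

Canonical units: in-vial (instrument) concentrations in µg L⁻¹
(numerically equal to ng mL⁻¹), in-sample concentrations in ng L⁻¹, flow
in L day⁻¹, daily load (DL) in mg day⁻¹ and population-normalised daily
load (PNDL) in µg day⁻¹ 1000 inh⁻¹ — chosen to match the units each
report table uses. All conversions pass through `convert_units`, which
scales by exact powers of ten in rational arithmetic. Exact round-trip
identity is guaranteed for `Decimal`/`Fraction` inputs; float inputs
receive the correctly rounded result (a float round-trip can be off by one
ulp in rare cases — an inherent property of binary floating point, which
is why exactness-critical code should pass `Decimal`).

Analyte names are the short names used in the PFAS literature (e.g.
"8:2 diPAP") and match exactly and case-sensitively: PFAS naming
collisions across studies are common enough that silent aliasing would be
worse than a hard mismatch. No CAS-number or structure handling is
attempted.

## Calibration and quantification

The response ratio y = quantifier area / ISTD area is regressed on nominal
in-vial concentration by least squares. Defaults and the reasoning behind
them:

- **Weighting**: unweighted by default, `1/x` available. Published
  method-validation reports rarely state the weighting; the choice mainly
  shifts low-end accuracy, so it is an explicit config knob rather than a
  hidden default.
- **Replicates**: individual injections enter the fit as individual points
  (not level means), preserving the triplicate design's variance
  structure. For exactly collinear data the two choices coincide (tested).
- **r²** is computed on the fitted (possibly weighted) model; it is
  exactly 1.0 for collinear input.
- **Back-calculation** inverts the line. Negative concentrations are
  returned as computed and flagged, because spike recovery is defined on
  differences and can legitimately be negative. Values outside the fitted
  level range are flagged as extrapolated; out-of-range-high values are
  treated as reporting errors downstream.

The ion ratio is quantifier/qualifier area (the direction is a convention;
only consistency matters). Ratios are summarised in two bands — from the
IQL to 100 µg L⁻¹ and from 100 to 1000 µg L⁻¹ — because variability rises
near the quantification limit. The identification window (default ±40 %,
configurable to ±50 % to match EPA method 1633A practice) is applied on
the linear ratio around the band mean.

## Limits

The IQL is the lowest calibration level at which a strict majority of
replicate injections shows quantifier S/N ≥ 10 and qualifier S/N ≥ 3.3
(waived for single-transition compounds). "Most injections" is read as a
strict majority; a tie at exactly half fails. No model-based
(calibration-residual) limit estimator is offered — only the S/N rule.

**IDL = IQL × 0.33.** The source method's formula as printed (IQL/(10 ×
3.3) = IQL/33) contradicts every one of its own tabulated IDL/IQL pairs,
all of which equal IQL × 3.3/10 = IQL × 0.33 — the ratio of the detection
to the quantification S/N threshold. The tables win; this is pinned by a
regression test across all 35 compounds.

Method limits bridge instrument (in-vial, µg L⁻¹) to in-sample (ng L⁻¹)
concentrations: the µg→ng conversion (×1000) is an explicit unit
conversion followed by `limit × 100 / (recovery% × Cf)` with Cf = 100 for
influent wastewater — never a fused constant. A compound with missing or
non-positive recovery has undefined method limits (reported as absent, as
for 8:2 monoPAP, which could not be recovered from the matrix).
Recomputing the published MDL/MQL table from the published IQLs and
recoveries reproduces nearly every value to its printed rounding; the
regression tolerance is one unit in the last printed digit plus the
propagated rounding of the recovery (printed to 0.1 %), which also covers
the two cells of the published table that are internally off by one final
digit (the PFOA MDL and PFDA MQL).

## Validation

Accuracy is C_exp/C_theo × 100. Precision is implemented as the percent
relative standard deviation (sd/mean × 100): the source formula as printed
is an absolute standard deviation, but it is labelled RSD and reported as
percent throughout, so the label wins. Recovery subtracts the unspiked
(native) concentration before normalising by the nominal spike; method
recovery is reported as mean ± sd across all spike levels inside the
calibration range, with per-level values retained. QC-level exclusions
near the IQL are an explicit config list of (analyte, level) pairs, never
automatic.

Classification bands (boundary conventions pinned by tests): quantitative
iff 50 ≤ accuracy ≤ 120 and precision < 30; semi-quantitative iff
30 ≤ accuracy < 50 or 30 ≤ precision ≤ 50; else qualitative. The
one-transition cap (single-transition compounds at most semi-quantitative)
is **per-analyte and opt-in**: published usage applies it to some
single-transition compounds (PFOPA, PFDPA, 8:8 PFPiA) but not others
(PFBA), so a global rule would misclassify validated labels. Five
compounds in the published table carry semi-quantitative labels that the
stated bands alone cannot produce (their accuracy exceeds 120 %, which
the bands map to qualitative); they are flagged in the fixture and
excluded from the label-reproduction test.

Treatment comparisons (dry-down, HDPE adsorbance, elution variants) use
the sd-overlap rule: a difference is significant only when it falls
outside the standard deviations of both preparations — no distributional
test, by design. Suitability bands on the absolute accuracy delta:
< 15 suitable, 15–30 medium, ≥ 30 unsuitable, assessed only when
significant.

## WBE loads

Censored days substitute zero in all sums: this is the only convention
that reconciles with the published cumulative concentrations, and no
LOD/2-style alternative is offered so that outputs stay reconcilable. A
< LOQ day counts toward the detection frequency; a < LOD day does not.
Loads use each day's own flow, not a campaign mean. The ± on cumulative
quantities is the sample standard deviation of the detected per-day
values (this reproduces the published ± column). PNDL is reported in
µg day⁻¹ 1000 inh⁻¹ following the table convention of the source method
(its equation text says mg; the published table values are in µg and are
not self-consistent with a plausible catchment population — the pipeline
follows the algebra with table units and does not attempt to reconcile).
One published campaign row (PFNA) is internally inconsistent (its day-3
value does not match its printed cumulative) and is excluded from
regression fixtures rather than repaired.

Population-normalised daily intake (PNDI) and tolerable-weekly-intake
conversions are deliberately absent: PFAS lack a characteristic human
metabolite, and the body-weight assumptions behind published TWI
conversions are not stated.

## Risk

RQ = MEC/(PNEC × dilution) per analyte per day, with bands low (< 0.1),
medium (0.1 ≤ RQ < 1, lower edge inclusive), high (≥ 1). The headline RQ
per analyte uses the maximum single-day concentration — cumulative
concentrations are sums across days and are not environmental
concentrations; per-day results are always emitted so any other
convention can be read off. The default dilution is 1 (raw influent, the
combined-sewer-overflow worst case); a tenfold dilution scenario is one
flag away and can only lower a band (property-tested). Report rounding is
2 significant figures; internals keep full precision. Only compounds
present in the PNEC registry (7 of 35) are assessable. No
chronic-exposure or mixture-toxicity modelling is included.

## Synthetic campaign generator

The generator emulates what the instrument software exports, with known
ground truth:

- **Noise**: multiplicative lognormal on areas, normalised to unit mean,
  parameterised by a CV (default 0.05 — mid-range for stable-isotope
  -corrected peak-area ratios). Areas stay positive and variability is
  heteroscedastic, matching the observed rise in ion-ratio scatter near
  the IQL.
- **ISTD coupling**: the quantifier area is proportional to the same
  injection's ISTD area, so the response ratio cancels ISTD-level
  fluctuation exactly as a co-injected internal standard does.
- **Design defaults**: 19 calibration points from 0.01 to 1000 µg L⁻¹
  (geometric), triplicate injections, QC/spike levels 5/20/200/500
  ng mL⁻¹, triplicate matrix replicates — the validation design of the
  source method.
- **Recovery and background**: matrix samples see
  `recovery × (native + spike)`; native background defaults to 0 but is
  configurable to exercise the unspiked-subtraction in the recovery
  formula. Recovery may exceed 1 (matrix enhancement).
- **Influent truth**: per-day concentrations are lognormal
  (median/shape per analyte) or an explicit per-day list; the ledger
  retains uncensored truth.
- **Determinism**: one campaign seed, with substreams derived per
  (analyte or ISTD, sample, replicate) via hashed spawn keys, so adding
  an analyte never perturbs existing draws. Fixed seed ⇒ byte-identical
  outputs.

What the generator does **not** model: chromatographic peak shapes,
co-elution, carry-over, drift, matrix-dependent ionisation suppression
beyond a scalar recovery, or inter-day batch effects. Passing tests
therefore demonstrate the correctness of the downstream arithmetic and
estimator behaviour under well-behaved noise, not robustness to real
matrix pathology.

With noise off, the full pipeline is an exact identity (calibration slope
= response factor, recovery = truth, influent concentrations recovered
bit-accurately). At noise CV 0.05 and 1000 replicates, estimated
recovery, accuracy and ion ratio converge to truth within 2 % relative
(seeded tests). An unweighted 19-level fit at CV 0.05 carries r² ≈
1 − O(cv²) ≈ 0.994–0.999; the test floors are 0.99 at CV 0.05 and 0.999
at CV 0.01.

The synthetic influent site records (`site_days_synthetic.csv`) are a
stand-in for unpublished flow/population data: flow 2.289 × 10⁸ L day⁻¹
(a large works), population 9 × 10⁵. Published DL/PNDL columns are
consequently not regression targets.

## Numerical and degenerate-input choices

- Zero-ISTD-area injections are excluded from fits with a warning; a zero
  fitted slope raises on back-calculation.
- `precision` is undefined (None) at zero mean; it requires ≥ 2
  replicates.
- The influent censoring path also applies the S/N rule (mean quantifier
  S/N < 3.3 ⇒ < LOD, < 10 ⇒ < LOQ) before comparing against MDL/MQL, so a
  slightly negative calibration intercept cannot manufacture detections
  from blank signal.
- Ties and boundaries are fixed and tested: strict majority for the IQL
  rule; 50/120/30 edges for classification; 0.1/1 edges for risk bands
  (lower edges inclusive).

## Known limitations

- The label-reproduction test covers only compounds whose published
  status follows from the stated bands (30 of 35); the remaining five
  reflect judgement calls (poor linearity, interday behaviour) the bands
  do not encode.
- Method limits inherit any bias in the estimated recovery; no
  uncertainty is propagated onto MDL/MQL.
- Censoring by substitution at zero biases cumulative loads downward when
  many days sit just below the LOQ; this is intentional for
  reconcilability, not a statistical recommendation (use proper
  left-censored estimators for inference).
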