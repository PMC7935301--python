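# Methods

## Isotope patterns

Isotopologue distributions are computed per element by the multinomial
expansion over its stable isotopes (terms evaluated with log-factorials, so
formulas with dozens of atoms stay numerically stable) and convolved across
elements.  Isotopologues are binned by their integer nominal-mass offset
from the all-lightest-isotope species — the resolution at which a unit-mass
triple-quadrupole instrument separates them — and each bin carries the
abundance-weighted centroid mass of its members.  No truncation is applied
during convolution; the full distribution sums to 1 within float round-off,
and pruning affects only reported entries beyond `max_offset`.

Isotopic masses and abundances are pinned in code from the CIAAW/NIST
representative values (C, H, N, O, Cl, S, P, F), so results are identical
on every machine.  Published unit-mass tables computed with other abundance
compilations can differ in the third decimal of a satellite percentage;
comparisons in the test suite therefore allow ±0.010 absolute on +4 bins
and ±0.005 on +5/+6 bins.

Normalization is to the most abundant bin.  For every supported analyte
this is the monoisotopic bin; if a formula's base peak shifts upward (e.g.
four or more chlorines) the code raises rather than silently renormalizing,
because the cross-talk planner's offsets are anchored at the monoisotopic
peak.  Deuterium is a distinct pseudo-element `D` (mass 2.014102, abundance
1): a d4/d5 label shifts the whole pattern without broadening it, which the
tests assert.

## Internal-standard windows

The planner evaluates `C_IS,min = m% × ULOQ / t%` with the analyte-to-IS
tolerance `t` defaulting to 5%, and `C_IS,max = u% × LLOQ / n%` with the
IS-to-analyte tolerance `u` defaulting to 20%.  `n` defaults to 0 for fully
deuterated labels (cross-talk from the label into the analyte channel is
typically negligible), which reports an unbounded window as `inf` rather
than a sentinel number.  Candidate channels below a configurable
IS-signal floor (default 1% of the IS base peak) are flagged, never
dropped: sensitivity trade-offs belong to the analyst.

A reference convention worth noting: published planning tables for this
assay family evaluate C_IS,min with ULOQ = 1000 ng/mL for *all* analytes,
including those whose own validated ULOQ is 500 or 250 ng/mL (the values
120 and 81.6 ng/mL for the two metabolites are only consistent with 1000).
The operations here take ULOQ as an explicit argument so either convention
is expressible.

## Calibration

Fits minimize `Σ w_i (y_i − f(x_i))²` over response ratios with weights
1, 1/x or 1/x², solved by `numpy.linalg.lstsq` on the weighted design
(a brute-force normal-equation solver serves as an independent oracle in
the tests).  Goodness of fit lives on the concentration scale: SSR in the
AIC is the sum of squared *relative back-calculation errors*, not
response-space residuals, matching the %RE-sum practice of weighting-factor
selection.  `M` counts regression coefficients only (2 linear, 3
quadratic); the weighting choice adds no parameter.  A numerically perfect
fit (SSR = 0) maps to an AIC of −∞ so it dominates any comparison; ties
break toward fewer coefficients, then simpler weighting.  The reported
correlation coefficient is the weighted Pearson correlation between
observed and fitted ratios (plain vs weighted is rarely distinguishable at
r > 0.995; the weighted form is consistent with the loss being minimized).

Quadratic back-calculation solves the two roots and accepts the one inside
[0, 2 × top calibrator] — wide enough for the validated 10-fold-dilution
workflow — preferring the root nearer the linear-term estimate when both
qualify.  A response with no admissible root (e.g. beyond a saturating
parabola's apex) returns NaN, a flagged non-quantifiable result rather
than an exception, so batch processing survives pathological samples.
Calibrator exclusion is only ever explicit, via a boolean mask.

## Validation statistics

Precision is 100 × sample SD (n−1) / mean; accuracy is 100 × (mean −
nominal) / nominal.  Inter-day statistics pool every replicate of every run
(4 runs × 6 replicates → n = 24), which makes the pooled %dev exactly the
replicate-weighted mean of per-run deviations (asserted as a conservation
check).  Acceptance flags are pure thresholds: ±15% (±20% at the LLOQ) on
the inter-day statistics, blank/carryover ≤ 20% of the LLOQ response in
the analyte channel and ≤ 5% in the IS channel, stability within 100 ± 15%
remaining or ±15% difference from fresh controls, IS-normalized matrix
effect within 100 ± 10%.  Run-level gating (flagging each run's intra-day
statistics) is a stricter rule some laboratories layer on top; it is
available via `pa_table(..., flag_intra_runs=True)` but is off by default —
the battery's defined criteria are per-statistic thresholds, and the
per-run ranges are always tabulated for inspection.

Validation operations consume measured concentrations; the pipeline
back-calculates each sample through the calibration fit of its own run
(falling back to the first run's fit), keeping the statistics layer
independent of the regression layer.

## Matrix effect

ME, RE and PE are ratios of arithmetic mean peak areas across replicates
(no trimming), computed separately for analyte and IS; PE = ME × RE / 100
is an algebraic identity when all three come from the same means and is
asserted to 1e-12.  IS normalization defaults to the ratio of the two ME
percentages (100 × ME_analyte / ME_IS); computing ME on the mean
analyte/IS response ratio instead is available via
`is_normalization="ratio"` — the two agree when replicates pair up and the
phrase "IS-normalized matrix effect" does not by itself pick one.

## Synthetic data

The generator emulates the statistical structure the battery assumes, not
chromatography.  A replicate's effective concentration is
`nominal × (1 + bias) × (1 + run shift) × (1 + ε)`, ε ~ N(0, γ) truncated
at zero, pushed through the analyte's true response curve and an
independently drawn IS area.  Multiplicative (proportional) error is the
standard rationale for 1/x²-type weighting and reproduces the near-constant
%CV across levels that real QC tables show; the between-run term is a
single relative shift per run, the simplest structure separating intra-
from inter-day precision.  In the three-set ME experiment the analyte and
IS channels of one injection share a common signal factor with only small
(2%) channel-specific residuals — co-eluting deuterated standards track
their analytes' ionization, which is the entire point of IS normalization,
and independent channel noise would contradict it.

Default campaign: four analytes with the calibration ranges 2–1000 /
2–1000 / 1–500 / 0.5–250 ng/mL over nine levels, QC at LLOQ / 3× / 30× /
400× LLOQ, 4 runs × 6 replicates, triplicate ME design, n = 3 stability
arms, n = 5 ten-fold dilutions of a 4 × ULOQ sample.  One analyte (AZM)
carries mild saturation curvature (−3·10⁻⁷ quadratic term against a
3·10⁻³ slope, a 10% deflection at the top calibrator) so that AIC model
selection has something real to find; the others are linear.  Replicate CV
is 5%, run-shift SD 2%, per-level biases ≤ 4%, degradation factors
0.95–0.97, blank and carryover fractions a few to ~17% of the LLOQ signal.
These truths describe a well-behaved assay that passes its own validation:
analyte ME/RE truths follow the published low/med/high magnitudes, while
IS ME truths track the analyte within a few percent.  Determinism is
guaranteed by seeding each (stage, analyte) pair from the config seed, so
generating one stage alone reproduces its slice of the full campaign
byte-for-byte.

What the generator does not emulate — chromatographic peak shapes,
integration error, drift and batch-order effects, carryover accumulating
over a sequence, matrix lot-to-lot heterogeneity — bounds what passing
tests show: they validate the statistics and their wiring, not robustness
of any real assay.

## Problem sizes in tests

Monte-Carlo checks use 100–200 seeded replicates for model-selection and
ME-recovery rates, and n = 1000 replicates for parameter-recovery checks
at 3×SE tolerance; the full default campaign is ~800 records and runs the
entire pipeline in well under a second.

## Known limitations

* Element coverage is the small-molecule organic set (C, H, N, O, Cl, S,
  P, F plus D); adding elements means adding pinned isotope rows.
* The AIC uses the raw `n ln(SSR) + 2M` form (no small-sample correction),
  as is conventional for calibration weighting comparisons at n = 9.
* S/N-based LLOQ determination, product-ion (fragment) isotope patterns,
  and adduct/charge arithmetic are out of scope: patterns are computed for
  neutral precursor compositions.
* Published run-level tables (%RE sums, P&A ranges) from any specific
  campaign are not reproducible without that campaign's raw data; the
  package reproduces the procedures and their orderings, and its own
  simulated campaigns, exactly.
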