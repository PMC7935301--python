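# mrmvalid

Design and validation statistics for quantitative LC-MS/MS bioanalysis with
stable-isotope-labelled internal standards, built around a four-analyte
human-plasma assay for hydroxychloroquine (HCQ), its metabolites
desethylhydroxychloroquine (DHCQ) and bisdesethylchloroquine (BDCQ), and
azithromycin (AZM).

It is written for bioanalytical chemists and pharmacology-lab data
scientists who need to (1) plan deuterated internal-standard (IS)
concentrations and MRM channels from first principles, (2) fit and compare
weighted calibration models, and (3) compute the regulatory validation
battery — precision/accuracy, dilution integrity, blanks and carryover,
stability, matrix effect/recovery — with explicit acceptance flags, all
reproducibly from plain CSV peak-area records.

## What it computes

**Isotope cross-talk planning.** An analyte's natural isotopologues leak
signal into its deuterated IS's MRM channel.  From a molecular formula the
package computes the nominal-mass isotope pattern by exact per-element
multinomial convolution (percent of the monoisotopic base peak), and bounds
the usable IS concentration:

```
C_IS,min = m% × ULOQ / 5%        C_IS,max = 20% × LLOQ / n%
```

where `m` is the analyte's cross-signal into the IS channel and `n` the IS's
cross-signal into the analyte channel.  For chlorinated analytes the ³⁷Cl
satellite of the IS (label shift + 2) offers a channel where `m` is orders
of magnitude smaller: for HCQ (C18H26ClN3O, monoisotopic 335.18 Da) the +4
abundance is 0.740%, forcing C_IS,min = 148 ng/mL, while the +6 channel at
0.003% needs only 0.6 ng/mL.

**Weighted calibration with AIC model selection.**  Response ratios
(analyte area / IS area) versus nominal concentration are fitted by least
squares weighted 1, 1/x or 1/x², linear or quadratic.  Calibrators are
back-calculated, and models compared by the sum of absolute percent
relative errors (%RE sum) and

```
AIC = n ln(SSR) + 2M,    SSR = Σ (%RE_i / 100)²
```

with `n` calibrators and `M` coefficients; the smallest AIC wins.

**Validation battery.** %CV (n−1 sample SD / mean), %dev versus nominal,
intra-/inter-day precision-and-accuracy tables, 10-fold dilution integrity,
blank interference and post-ULOQ carryover as percent of the LLOQ signal,
stability as % remaining versus nominal or % difference versus fresh
controls, and treated-versus-control matrix comparisons.  Limits: ±15%
(±20% at the LLOQ), 20% of LLOQ signal for blanks/carryover in the analyte
channel, 5% in the IS channel.

**Matrix effect / recovery / process efficiency.** The three-set
post-extraction-spike design: ME = 100 × set2/set1, RE = 100 × set3/set2,
PE = 100 × set3/set1 (so PE = ME × RE / 100 identically), for analyte and
IS areas, plus the IS-normalized ME (100 × ME_analyte / ME_IS, acceptance
window 100 ± 10%).

**Synthetic campaigns.** A seeded generator emulates a full validation:
nine-level calibration series (2–1000, 1–500, 0.5–250 ng/mL) over 4 runs,
4 QC levels × 6 replicates/run, triplicate three-set ME design, blanks,
double blanks after the ULOQ, stability arms and 10× dilution samples, with
multiplicative proportional noise — so the entire pipeline runs and can be
tested with no instrument data.

## Worked example

Isotope pattern and channel planning for HCQ:

```
$ mrmvalid isotopes --formula C18H26ClN3O --max-offset 6
monoisotopic mass: 335.1764 Da
 offset  mass_da abundance_pct
      0 335.1764      100.0000
      1 336.1795       20.9014
      2 337.1741       34.2783
      3 338.1768        6.8610
      4 339.1796        0.7404
      5 340.1823        0.0559
      6 341.1849        0.0032
```

The +2 bin (34.3%) is the ³⁷Cl satellite; +4 (0.7404%) is where an HCQ-d4
IS sits, +6 is its ³⁷Cl twin.  Planning the d4 channels for a 2–1000 ng/mL
range:

```
$ mrmvalid plan-is --analyte C18H26ClN3O --label-shift 4 --lloq 2 --uloq 1000
 channel_offset    m_pct  c_is_min_ng_ml  c_is_max_ng_ml  is_channel_signal_pct  low_is_signal
              6 0.003239        0.647886             inf              34.268713          False
              4 0.740388      148.077504             inf             100.000000          False
```

Monitoring the IS on its +6 (³⁷Cl) channel drops the minimum IS
concentration from ~148 ng/mL to ~0.6 ng/mL at the cost of a channel
carrying 34% of the IS base-peak signal — exactly the trade the assay makes
(40 ng/mL HCQ-d4 comfortably inside the window).

A full simulated validation campaign:

```
$ mrmvalid full --seed 0 --out campaign/
acceptance: 112/112 criteria passed; overall PASS
```

which writes `peak_records.csv` plus five report tables
(`calibration_comparison.csv`, `precision_accuracy.csv`, `stability.csv`,
`matrix_effect.csv`, `acceptance_summary.csv`).  The calibration comparison
shows the curved-response analyte (AZM) selecting quadratic/1/x² by AIC
while the linear-response chloroquines select linear/1/x²; every acceptance
row carries the observed percentage, its limit, and the pass flag.

The same operations are importable (`mrmvalid.isotope_pattern`,
`mrmvalid.fit_curve`, `mrmvalid.run_full_validation`, ...) for notebook use.

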