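# Methods

## Problem setting

Urban snow acts as a passive sampler for road and atmospheric
contaminants: tire-wear compounds, road-salt additives, pesticides and
biocides washed from facades and roofs, and pharmaceuticals. When the
snowpack melts over a few days, the accumulated chemical burden is
released as a pulse into storm drains and the municipal wastewater
treatment plant (WWTP). `meltrisk` implements the desk-side analysis of
such a campaign: mixture toxic-risk screening of per-site concentration
tables, attribution of WWTP influent compounds to runoff versus steady
wastewater sources, and load-based removal-rate estimation — plus a
synthetic-scenario generator so every estimator can be validated against
known ground truth.

## Mixture risk model

For compound *i*, organism group (biological quality element, BQE)
*b* ∈ {algae, crustacean, fish}, and measured environmental
concentration MEC_i:

    TU_{b,i} = MEC_i / EC50_{b,i}          (both in mg/L)
    TUsum_b  = Σ_i TU_{b,i}                 (detected compounds only)

TUsum assumes concentration addition: components act as dilutions of one
another, so their scaled concentrations add. Concentrations are stored in
ng/L and effect values in mg/L; the factor 10⁻⁶ is applied exactly once,
inside `toxic_unit`. Summation uses exact compensated summation
(`math.fsum`), so TUsum is bitwise invariant to input order.

Samples are prioritised by strict exceedance of per-BQE chronic TUsum
thresholds: algae 0.02, crustaceans 0.001, fish 0.01. The acute threshold
defaults to TUsum = 1 for every BQE (TU = 1 means exposure equals the
median acute effect level); it is configurable because screening
frameworks differ. Equality with a threshold is never exceedance.

Risk drivers per sample and BQE are the compounds with the largest
individual TUs; contributors with TU ≥ `min_tu` (default 0.01) are named
individually and the remainder is aggregated as a single "further
compounds" term chosen so that named + further equals TUsum exactly.

## EC50 selection hierarchy

Effect values are selected deterministically per compound × BQE:

1. **Experimental records**, aggregated as the 5th percentile of all
   EC50 values supplied for that compound and BQE. The percentile uses
   linear interpolation between order statistics (the common "type 7"
   convention); the convention is an explicit choice, exposed for
   sensitivity analysis, since different registries disagree here. The
   percentile is taken across all supplied records, including multiple
   records per species.
2. **Baseline-toxicity prediction** otherwise:
   log₁₀ EC50 [mg/L] = a·logKow + b with per-BQE coefficients. This is
   the narcosis (minimal, nonspecific toxicity) model class; coefficients
   ship as data in `data/baseline_model.yaml` (generic mass-basis values
   folding a representative molar mass of ~250 g/mol into the intercept)
   and are meant to be replaced per assessment. Tests use synthetic
   coefficients, so package correctness never depends on these numbers.
3. **Solubility cap**: a predicted EC50 cannot exceed the water
   solubility, because no higher dissolved exposure is attainable. The
   cap fires when log₁₀(EC50_pred) − log₁₀ S > 0.5; the half-log
   tolerance absorbs uncertainty in the solubility estimate. Capping is
   contractive (never raises the EC50), so it can only increase a toxic
   unit — the conservative direction, countering the tendency of linear
   logKow models to underestimate toxicity of very hydrophobic compounds.

A compound with neither experimental data nor a logKow is excluded from
that BQE and written to an exclusion report; nothing is imputed.
"daphnia" and "crustacean" are accepted as the same BQE label. Toxic
units are mass-based (mg/L); a molar option is deliberately out of scope.

## Censoring and detection limits

The method detection limit (MDL) per compound follows the US-EPA
replicate procedure: MDL = t(n−1, one-sided, 0.99) × s over ≥ 2 replicate
low-level injections. Entries strictly below their MDL are flagged
censored; a value exactly at the MDL counts as detected. Censored values
are retained for audit but contribute zero to every aggregate and toxic
unit (the data represent detections; an MDL/2 substitution is available
as a sensitivity option through `default_mdl` handling but is off by
default). A compound without an MDL is a hard configuration error —
silent defaults hide data problems. A single MDL cutoff is used; values
between MDL and a quantification limit are not treated specially.

Category aggregation sums non-censored concentrations per probable-source
category (traffic, human consumption, pesticide/biocide, other). A
compound with several use tags resolves by precedence
traffic > pesticide_biocide > human_consumption > other: any
traffic-related use makes a compound traffic.

## WWTP source attribution and removal

Each influent compound's daily concentrations are correlated with the
daily inlet flow using the Spearman rank correlation (average ranks on
ties, detected days only, ≥ 3 pairs required; a zero-variance series has
no rank association and gets ρ = 0). Classification uses only the
coefficient, both boundaries strict:

    ρ >  0.5  → runoff_dominated
    ρ < −0.5  → diluted_other_source
    otherwise → mixed

No p-values are computed: with n = 6 daily composites the permutation
distribution of ρ is too coarse for meaningful significance testing, and
the classification is deliberately descriptive.

Removal is estimated from cumulative loads over the whole melt period,
load = Σ_days conc_d × flow_d (reported in mg; censored days contribute
zero), which damps day-to-day flow fluctuation and residence-time
effects:

    removal = 1 − effluent_load / influent_load

binned as: effluent entirely below MDL; high (> 80%); medium (50–80%,
both boundaries inclusive — the verbal bin definitions are
inclusive-ambiguous, so the boundary convention is fixed here); low
(0 to < 50%); negative (apparent in-plant formation, e.g. deconjugation,
or matrix effects). The compound set is the explicit intersection of
snow detections with influent detections, reported alongside the
results; mismatched influent/effluent date spans are truncated to their
overlap with a warning, and the analysis window is configuration, not
code.

## Synthetic scenarios and ground truth

The generator emulates the statistical structure the analysis assumes,
not any particular dataset:

- **Snow campaign** (default 20 road + 3 background sites): road sites
  share per-traffic-compound log-normal fingerprints scaled by a shared
  log-normal site factor (σ_site = 0.35, σ_compound = 0.2), calibrated so
  road-site traffic sums average ≈ 118 µg/L with ≈ 40% between-site
  spread; background sites carry the fingerprint attenuated by 0.02. A
  configurable fraction of compounds (default 0.6) is placed at exactly
  one site, reflecting how many analytes in screening campaigns are
  single-site detections. Concentrations are log-normal, spanning the
  ng/L-to-µg/L range such campaigns report. A stated fraction of entries
  is planted below the MDL for censoring round-trips.
- **Planted risk driver**: an optional high-potency traffic compound
  (experimental fish EC50 9.5·10⁻⁵ mg/L, the scale of tire-wear quinone
  toxicity to juvenile salmonids) whose road-site concentration is raised
  until its fish TU exceeds 3× the largest other fish TU at that site
  (and at least TU = 2), making it the dominant fish-risk compound — and
  the road sites acutely exceeded — by construction.
- **WWTP week** (default 6 daily composites, flow rising to a melt peak
  then receding): flow-driven compounds follow c ∝ flow, diluted
  compounds c ∝ 1/flow, each with Gaussian noise of sd equal to 5% of
  the signal range by default. "Mixed" compounds are planted by
  rejection-sampling a rank pattern whose Spearman correlation with the
  flow series is ≤ 0.35 in absolute value: with n = 6, a *random*
  pattern lands above the 0.5 cutoff about one time in eight, so pure
  noise would not constitute a recoverable mixed class — the planted
  pattern makes "mixed" a genuine ground truth. Effluent concentrations
  are constant over days and scaled so the cumulative effluent load
  equals influent load × (1 − true removal); true removal rates cycle
  through all bins, including a negative rate and full removal (effluent
  below MDL).
- Synthetic experimental EC50s are drawn log-uniformly over
  10⁻² – 10³ mg/L, the span of common acute algae/daphnia/fish EC50s, so
  ordinary compounds contribute small TUs at ng/L–µg/L concentrations.
  High-logKow compounds with only predicted (often solubility-capped)
  EC50s can still dominate algae risk — the same behaviour, and the same
  uncertainty, seen with real hydrophobic plasticizers.

All generators are deterministic functions of (scenario, seed); ground
truth is returned separately and written to sidecar files
(`ground_truth_*.{json,csv}`), never embedded in the data files, so
pipelines cannot accidentally read it.

What the generator does **not** emulate: spatial correlation between
sites beyond the shared fingerprint, real compound identities and
physico-chemistry, analytical matrix effects, between-day MDL variation,
or hydraulic residence time inside the plant. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
statistical assumptions, not performance on any real campaign.

## Numerical and design choices

- Compensated summation for TUsum; exact permutation invariance is a
  tested property, not a tolerance.
- Strict inequalities at every classification boundary (MDL detection is
  the one ≥ boundary: a value at the MDL is detected).
- Percentile type 7 (linear interpolation); configurable in principle by
  supplying pre-aggregated records.
- Spearman via `scipy.stats.spearmanr`; tests verify equivalence with an
  independently written average-rank + Pearson oracle to 10⁻¹².
- Degenerate inputs: empty concentration tables produce empty outputs
  with a warning and exit code 0; zero influent load leaves removal
  undefined and excluded from binning; < 3 detected days leaves a
  compound unclassifiable rather than classified.
- Problem sizes in the tests and acceptance script — 80-compound
  libraries, 23 snow sites, 6-day WWTP series, tens of seeds for
  recovery rates — are chosen as the smallest sizes at which the
  recovery properties are meaningful for this design.

## Known limitations

- Chronic risk is approximated by acute EC50s against chronic threshold
  factors; no NOEC/EC10 quotients and no species sensitivity
  distributions.
- The baseline model is a single linear narcosis QSAR per BQE; class-
  specific QSARs (e.g. for reactive or specifically acting compounds)
  are out of scope, and mass-basis coefficients fold molar mass into the
  intercept.
- Removal rates from 6–7 day cumulative loads conflate biodegradation,
  sorption and in-plant transformation; negative rates are reported, not
  explained.
- Spearman classification at n = 6 has coarse granularity (ρ takes few
  distinct values); cutoff 0.5 is a convention, not an inference.
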