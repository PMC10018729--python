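# Default baseline-toxicity (narcosis-type) coefficients.
#
# log10 EC50 [mg/L] = slope * logKow + intercept, per biological quality
# element.  These are generic nonspecific-toxicity coefficients on a mass
# basis (folding a representative molar mass of ~250 g/mol into the
# intercept of classical molar narcosis QSARs); they are shipped as data
# and meant to be replaced by a user-supplied model for any real
# assessment.  Tests never rely on these numbers.
baseline_model:
  fish:
    slope: -0.87
    intercept: 3.5
  crustacean:
    slope: -0.95
    intercept: 3.2
  algae:
    slope: -1.00
    intercept: 3.3
cap_tolerance_log10: 0.5
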