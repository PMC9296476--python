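# HDAC-mediation path model over the simulated cohort's column names.
# Edges are [source, target]; a third element would fix the coefficient.
# Covariances are omitted, so the default applies: free variances
# everywhere, free covariances among exogenous variables, endogenous
# residual covariances fixed at zero.
variables: [amyloid, tau, hdac, atrophy, cognition, age, sex, education]
edges:
  - [amyloid, tau]
  - [amyloid, hdac]
  - [tau, hdac]
  - [amyloid, atrophy]
  - [tau, atrophy]
  - [hdac, atrophy]
  - [amyloid, cognition]
  - [tau, cognition]
  - [hdac, cognition]
  - [atrophy, cognition]
  - [age, atrophy]
  - [sex, atrophy]
  - [education, atrophy]
  - [age, cognition]
  - [sex, cognition]
  - [education, cognition]
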