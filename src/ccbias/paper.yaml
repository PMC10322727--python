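# Default study configuration.
#
# The factor grids reproduce the published factorial design; n, the factor
# levels, and the population targets are the study's values.  n_sim and m
# default to the desk scale (200 replicates, 20 imputations); the CLI flag
# --paper-scale restores the full 1,000 / 100.
n: 10000
n_sim: 200
m: 20
seed: 2023
burn_in: 20
strict_paper: true

# Factor 1: fraction of missing outcome data
factor1: [0.2, 0.4, 0.6, 0.8]
# Factor 2: proxy sensitivity
factor2: [0.25, 0.75]
# Factor 3: exposure-outcome interaction in the selection model
factor3: [false, true]
# Factor 4: fraction of missing proxy values (nonzero levels run only at the
# interaction / sensitivity-75% corner, per the published design)
factor4: [0.0, 0.25]
factor4_sensitivity: 0.75
factor4_interaction: true

specificity: 0.975
gy_or: 0.75      # observation OR per 1 SD of the continuous outcome
link: logit

population:
  prev: 0.15     # marginal binary-outcome prevalence
  log_or: 0.405  # full-population exposure log OR (OR 1.50)
  pi_x: 0.25     # exposure prevalence
  dicho: threshold
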