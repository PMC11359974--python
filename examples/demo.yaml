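# Demo pipeline config: simulate a 13-subject two-session MVC study and
# produce the reliability report. Run from the repository root:
#   dynoreli run --config examples/demo.yaml
seed: 2024
out_dir: dynoreli_out
simulate:
  n_subjects: 13
  mu: 142.0            # N, population mean peak force
  sigma_between: 64.7  # N, between-subject SD
  sigma_session: 6.0   # N, subject-by-session SD
  sigma_trial: 14.0    # N, trial-to-trial SD
  trials_per_session: 3
  trace:
    rise_tau: 0.35     # s; time to 90% of peak = 2*tau*atanh(0.9)
    onset_time: 1.5    # s of quiet baseline before the pull
stats:
  alpha_normality: 0.05
  log_transform: true
  sem_formula: mse
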