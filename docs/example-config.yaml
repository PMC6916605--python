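# Example run configuration for the duotherapy CLI.
# Any omitted field keeps its documented default.

generator:
  n_patients: 20000
  seed: 1
  duo_target_fraction: 0.06          # marginal share of two-drug initiators
  confounding_strength: 1.0          # scales shared covariate effects
  true_log_hr_bp_control: 0.157      # ln(1.17), conditional two-drug effect
  true_log_hr_mace: 0.0
  visit_rate: 8.0                    # BP visits per year after the index

eligibility:
  washout_days: 183
  min_history_days: 365
  elevated_bp_lookback_days: 92
  repeated_bp_lookback_days: 365
  mi_stroke_exclusion_days: 365
  tia_exclusion: false

episode:
  discontinuation_gap_days: 60
  min_concomitant_overlap_days: 30

match:
  ratio: 2
  caliper_multiplier: 0.2            # x SD of logit(PS), pooled cohort

mode: as_treated                     # or itt
subgroups: [all, grade1, grade23, acei_ccb]
variants: [gap90, overlap60, washout365]
seed: 1
outdir: output
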