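# Synthetic-cohort generating distributions (median/IQR/range summaries of
# the development cohort; families are moment-matched to median and IQR).
ga_weeks: {median: 30.1, iqr: 6.9, lo: 24.1, hi: 41.3, family: normal}
pna_days: {median: 17.0, iqr: 14.0, lo: 7.0, hi: 114.0, family: lognormal}
birth_weight_kg: {median: 1.32, iqr: 0.89, lo: 0.44, hi: 4.14, family: lognormal}
scr_umol_l: {median: 42.0, iqr: 34.0, lo: 8.0, hi: 252.0, family: lognormal}
dose_mg_per_kg: {median: 14.0, iqr: 3.0, lo: 5.0, hi: 31.0, family: normal}
ga_weight_corr: 0.6
growth_rate_per_day: 0.015
growth_rate_sd: 0.005
scr_drift_per_day: -0.01
male_fraction: 0.541
n_doses_range: [6, 10]
infusion_duration_h: 1.0
sampling:
  troughs_before: [4]
  peaks_after: [4]
  trough_offset_h: 0.1
seed: 0
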