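# Dosing-optimization policy: exposure target and search grid.
target:
  auc_mic_low: 400.0    # h; lower bound of the AUC24/MIC window
  auc_mic_high: 600.0   # h; upper bound
  mic: 1.0              # mg/L
dosing:
  dose_min_mg_per_kg: 5.0
  dose_max_mg_per_kg: 30.0
  dose_step_mg_per_kg: 0.5
  intervals_h: [6, 8, 12, 18, 24, 36, 48]
  infusion_duration_h: 1.0
  round_mg: 0.1
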