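# Proprioception-cued Reaction Time task: a small 0.5 N.m shoulder
# perturbation is the go cue for an elbow extension; 27 epochs of 2
# rewarded + 2 non-rewarded trials = 108 trials.  MT-form return with
# g = 10 cents and the Reaction Time calibration row (scaler 1, shifter 0,
# tau 2.447, MTmax 728 ms).
task_id: proprio_rt
factors:
  reward: [non_rewarded, rewarded]
epoch_size: 4
copies_per_combo: 2
n_epochs: 27
epochs_per_block: 27
baseline_rule: {event: perturbation, start_ms: -350, end_ms: -300}
mt_definition: perturbation_to_target_entry
design_constants:
  background_load_nm: 2.0
  perturbation_nm: 0.5
  fs_hz: 1000
  onset_correction_ms: 4
contrasts: []
return_params:
  - select: {}
    form: movement_time
    g_max: 10
    scaler: 1.0
    shifter: 0.0
    tau: 2.447
    mt_max: 728
geometry: {target_distance_cm: 15.0, target_radius_cm: 2.0, start_radius_cm: 0.3}
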