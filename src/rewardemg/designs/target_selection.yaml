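# Target Selection task: one- vs two-target trials with inward/outward
# perturbations; on two-target trials the goal is the target opposite the
# push.  224 trials in 2 blocks of 112, epochs of 16.  MT-form return with
# g = 15 cents and per-condition Table parameters.
task_id: target_selection
factors:
  targets: [one, two]
  perturbation: [inward, outward]
  reward: [non_rewarded, rewarded]
epoch_size: 16
copies_per_combo: 2
n_epochs: 14
epochs_per_block: 7
baseline_rule: {event: perturbation, start_ms: -350, end_ms: -300}
mt_definition: perturbation_to_target_entry
design_constants:
  background_load_nm: 2.0
  perturbation_nm: 2.0
  fs_hz: 1000
  onset_correction_ms: 4
contrasts:
  - name: selection
    a: {targets: two, perturbation: inward}
    b: {targets: one, perturbation: inward}
    window_ms: 50
    align_event: perturbation
return_params:
  - select: {targets: one, perturbation: inward}
    form: movement_time
    g_max: 15
    scaler: 0.676
    shifter: -0.034
    tau: 6.236
    mt_max: 1673
  - select: {targets: one, perturbation: outward}
    form: movement_time
    g_max: 15
    scaler: 0.690
    shifter: 0.004
    tau: 5.534
    mt_max: 2241
  - select: {targets: two, perturbation: inward}
    form: movement_time
    g_max: 15
    scaler: 0.749
    shifter: -0.021
    tau: 4.904
    mt_max: 2373
  - select: {targets: two, perturbation: outward}
    form: movement_time
    g_max: 15
    scaler: 0.749
    shifter: 0.009
    tau: 5.350
    mt_max: 2208
geometry: {target_distance_cm: 18.0, target_radius_cm: 7.0, start_radius_cm: 0.3}
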