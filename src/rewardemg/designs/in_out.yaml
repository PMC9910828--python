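# In-Out Target task: elbow perturbations toward/away from an inward or
# outward target; 336 trials in 3 blocks of 112, epochs of 16 with two of
# each of the 8 condition combinations.  Return is a function of time in
# target; g = 15 cents, x0 = 500 ms, xf = 800 ms, tau per condition.
task_id: in_out
factors:
  perturbation: [inward, outward]
  target: [inward, outward]
  reward: [non_rewarded, rewarded]
epoch_size: 16
copies_per_combo: 2
n_epochs: 21
epochs_per_block: 7
baseline_rule: {event: perturbation, start_ms: -350, end_ms: -300}
mt_definition: perturbation_to_target_entry
design_constants:
  background_load_nm: 2.0
  perturbation_nm: 2.0
  fs_hz: 1000
  onset_correction_ms: 4
  trial_end_after_perturbation_ms: 800
contrasts:
  - name: slr
    a: {perturbation: inward}
    b: {perturbation: outward}
    window_ms: 25
    align_event: perturbation
  - name: llr
    a: {perturbation: inward, target: outward}
    b: {perturbation: inward, target: inward}
    window_ms: 50
    align_event: perturbation
return_params:
  - select: {perturbation: inward, target: outward}
    form: time_in_target
    g_max: 15
    tau: 1.428
    x0: 500
    xf: 800
  - select: {perturbation: outward, target: outward}
    form: time_in_target
    g_max: 15
    tau: 2.600
    x0: 500
    xf: 800
  - select: {perturbation: inward, target: inward}
    form: time_in_target
    g_max: 15
    tau: 2.766
    x0: 500
    xf: 800
  - select: {perturbation: outward, target: inward}
    form: time_in_target
    g_max: 15
    tau: 1.351
    x0: 500
    xf: 800
geometry: {target_distance_cm: 12.0, target_radius_cm: 10.0, start_radius_cm: 0.3}
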