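# Cursor Jump task: mid-reach the hand cursor jumps +/-10 deg or stays;
# 312 trials in one block, epochs of 12 (2 x 3 design, two copies each).
# MT-form return with g = 10 cents.  EMG analysis is aligned to the
# photodiode-recorded jump; the trial baseline precedes target appearance.
task_id: cursor_jump
factors:
  jump: [inward, none, outward]
  reward: [non_rewarded, rewarded]
epoch_size: 12
copies_per_combo: 2
n_epochs: 26
epochs_per_block: 26
baseline_rule: {event: target_onset, start_ms: -350, end_ms: -300}
mt_definition: exit_to_target_below_velocity
design_constants:
  background_load_nm: 2.0
  fs_hz: 1000
  onset_correction_ms: 0
contrasts:
  - name: jump
    a: {jump: inward}
    b: {jump: outward}
    window_ms: 50
    align_event: jump
return_params:
  - select: {jump: inward}
    form: movement_time
    g_max: 10
    scaler: 0.996
    shifter: -0.029
    tau: 4.273
    mt_max: 2781
  - select: {jump: none}
    form: movement_time
    g_max: 10
    scaler: 0.667
    shifter: 0.079
    tau: 5.433
    mt_max: 2335
  - select: {jump: outward}
    form: movement_time
    g_max: 10
    scaler: 0.996
    shifter: -0.041
    tau: 3.958
    mt_max: 2864
geometry: {target_distance_cm: 15.0, target_radius_cm: 2.0, start_radius_cm: 0.8}
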