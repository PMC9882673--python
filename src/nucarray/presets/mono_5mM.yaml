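# Mononucleosome, 5 mM Na+ (low salt).
# Alpha mixture: major 39 +/- 5 deg (54%), minor 14 +/- 16 deg (46%).
# Beta: -9 +/- 11 deg. Unwrapping: entry -5 +/- 5 bp, exit -11 +/- 13 bp.
name: mono_5mM
description: mononucleosome at low ionic strength
template: {n_ncp: 1, entry_arm_bp: 200, exit_arm_bp: 100, linker_bp: 40}
alpha:
  weights: [0.54, 0.46]
  means_deg: [39.0, 14.0]
  stds_deg: [5.0, 16.0]
beta:
  weights: [1.0]
  means_deg: [-9.0]
  stds_deg: [11.0]
delta_entry: {mean_bp: -5.0, std_bp: 5.0}
delta_exit: {mean_bp: -11.0, std_bp: 13.0}
noise_sigma_A: 2.0
ii2_distance_A: {mean: 265.0, std: 30.0}
defaults_filled: [ii2_distance_A]
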