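# Trinucleosome, 5 mM Na+. Alpha populations 36% vs 64%; minor-peak position
# and widths filled as in di_5mM.
name: tri_5mM
description: trinucleosome at low ionic strength (partially specified)
template: {n_ncp: 3, entry_arm_bp: 200, exit_arm_bp: 100, linker_bp: 40}
alpha:
  weights: [0.36, 0.64]
  means_deg: [32.0, -8.0]
  stds_deg: [5.0, 16.0]
beta:
  weights: [1.0]
  means_deg: [-9.0]
  stds_deg: [11.0]
delta_entry: {mean_bp: -7.0, std_bp: 7.0}
delta_exit: {mean_bp: -10.0, std_bp: 11.0}
noise_sigma_A: 2.0
ii2_distance_A: {mean: 265.0, std: 30.0}
defaults_filled: ["alpha.means_deg[1]", "alpha.stds_deg", "beta.stds_deg", "ii2_distance_A"]
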