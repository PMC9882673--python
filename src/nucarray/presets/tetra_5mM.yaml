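# Tetranucleosome, 5 mM Na+. Alpha peaks 32 deg (39%) and -8 deg (61%);
# beta -9 deg; unwrapping entry -4 +/- 8 bp, exit -14 +/- 12 bp;
# i,i+2 center distance peak 265 A. Component widths follow the
# mononucleosome values (5 / 16 deg alpha, 11 deg beta).
name: tetra_5mM
description: tetranucleosome at low ionic strength
template: {n_ncp: 4, entry_arm_bp: 200, exit_arm_bp: 100, linker_bp: 40}
alpha:
  weights: [0.39, 0.61]
  means_deg: [32.0, -8.0]
  stds_deg: [5.0, 16.0]
beta:
  weights: [1.0]
  means_deg: [-9.0]
  stds_deg: [11.0]
delta_entry: {mean_bp: -4.0, std_bp: 8.0}
delta_exit: {mean_bp: -14.0, std_bp: 12.0}
noise_sigma_A: 2.0
ii2_distance_A: {mean: 265.0, std: 30.0}
defaults_filled: [alpha.stds_deg, beta.stds_deg, ii2_distance_A.std]
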