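# Tetranucleosome, 50 mM Na+ (high salt). Alpha peaks 32 deg (38%) and
# -14 deg (62%); beta -4 deg; unwrapping entry -4 +/- 9 bp, exit -9 +/- 8 bp;
# i,i+2 center distance peak 114 A.
name: tetra_50mM
description: tetranucleosome at elevated ionic strength
template: {n_ncp: 4, entry_arm_bp: 200, exit_arm_bp: 100, linker_bp: 40}
alpha:
  weights: [0.38, 0.62]
  means_deg: [32.0, -14.0]
  stds_deg: [5.0, 16.0]
beta:
  weights: [1.0]
  means_deg: [-4.0]
  stds_deg: [11.0]
delta_entry: {mean_bp: -4.0, std_bp: 9.0}
delta_exit: {mean_bp: -9.0, std_bp: 8.0}
noise_sigma_A: 2.0
ii2_distance_A: {mean: 114.0, std: 30.0}
defaults_filled: [alpha.stds_deg, beta.stds_deg, ii2_distance_A.std]
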