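# Tetranucleosome, 5 mM Na+ with linker histone H1 (1:4 molar ratio).
# Alpha peaks 27 deg (33%) and -16 deg (67%); beta -1 deg; unwrapping
# entry -6 +/- 8 bp, exit -17 +/- 19 bp; i,i+2 center distance peak 213 A.
name: tetra_H1
description: tetranucleosome at low ionic strength with linker histone H1
template: {n_ncp: 4, entry_arm_bp: 200, exit_arm_bp: 100, linker_bp: 40}
alpha:
  weights: [0.33, 0.67]
  means_deg: [27.0, -16.0]
  stds_deg: [5.0, 16.0]
beta:
  weights: [1.0]
  means_deg: [-1.0]
  stds_deg: [11.0]
delta_entry: {mean_bp: -6.0, std_bp: 8.0}
delta_exit: {mean_bp: -17.0, std_bp: 19.0}
noise_sigma_A: 2.0
ii2_distance_A: {mean: 213.0, std: 30.0}
defaults_filled: [alpha.stds_deg, beta.stds_deg, ii2_distance_A.std]
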