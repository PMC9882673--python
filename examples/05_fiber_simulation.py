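"""Hecta-nucleosome fiber simulation at two ionic strengths.

Assembles 100-NCP coarse-grained fibers by sequentially connecting units
sampled from the measured low-salt (5 mM Na+) and elevated-salt (50 mM Na+)
tetranucleosome angle/unwrapping statistics, then reports contour length,
width, persistence length and worm-like-chain radius of gyration /
hydrodynamic radius / NCP density.  The high-salt statistics produce
shorter, narrower, denser fibers — the compaction direction seen
experimentally.
"""

import numpy as np

from nucarray.fiber import (build_fiber, fiber_dimensions, persistence_length,
                            wlc_metrics, _smoothed_centerline)
from nucarray.synthetic import load_preset

for preset in ("tetra_5mM", "tetra_50mM"):
    params = load_preset(preset)
    metrics = []
    for seed in range(10):
        f = build_fiber(params, n_ncp=100, rng_seed=1000 + seed)
        L, W = fiber_dimensions(f)
        P = persistence_length(_smoothed_centerline(f.centers / 10.0))
        metrics.append(wlc_metrics(P, L, f.n_ncp, W))
    L = np.mean([m.contour_length_nm for m in metrics])
    W = np.mean([m.width_nm for m in metrics])
    Rg = np.mean([m.gyration_radius_nm for m in metrics])
    Rh = np.mean([m.hydrodynamic_radius_nm for m in metrics])
    dens = np.mean([m.density_uM for m in metrics])
    print(f"{preset}: L = {L:5.0f} nm, width = {W:4.1f} nm, "
          f"R_g = {Rg:5.0f} nm, R_h = {Rh:5.0f} nm, density = {dens:5.1f} uM")
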