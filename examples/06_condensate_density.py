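"""Bracket the condensate density: seamless assembling vs random docking.

Builds 24-NCP fibers per salt condition, estimates the upper density bound
as the mean per-fiber worm-like-chain density ("seamless assembling": no
space between fibers) and the lower bound by docking rigid fibers into a
200-nm sphere without envelope overlap, with inter-fiber spacing drawn from
the measured i,i+2 NCP distance.  The high-salt fibers pack to a higher
concentration — the direction behind salt-driven condensate densification.
"""

from nucarray.condensate import (condensate_concentration, random_dock,
                                 seamless_density)
from nucarray.fiber import (build_fiber, fiber_dimensions, persistence_length,
                            wlc_metrics, _smoothed_centerline)
from nucarray.synthetic import load_preset

for preset in ("tetra_5mM", "tetra_50mM"):
    params = load_preset(preset)
    fibers, metrics = [], []
    for seed in range(30):
        f = build_fiber(params, n_ncp=24, rng_seed=600 + seed)
        L, W = fiber_dimensions(f)
        P = persistence_length(_smoothed_centerline(f.centers / 10.0))
        metrics.append(wlc_metrics(P, L, f.n_ncp, W))
        fibers.append(f)
    upper = seamless_density(metrics)
    spacing = (params.ii2_distance_A[0] / 10.0, params.ii2_distance_A[1] / 10.0)
    cond = random_dock(fibers * 4, spacing_nm=spacing, rng_seed=1)
    lower = condensate_concentration(cond)
    print(f"{preset}: docking {lower:6.1f} uM (lower bound, "
          f"{len(cond.placements)} fibers placed)  <=  "
          f"seamless {upper.value_uM:6.1f} uM (upper bound)")
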