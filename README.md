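# nucarray

Per-particle geometry, statistics and coarse-grained simulation of
nucleosome array conformations.

Nucleosome arrays — "beads on a string" of nucleosome core particles (NCPs,
~147 bp of DNA wrapped ~1.7 left-handed turns around a histone octamer)
joined by linker DNA — change shape with ionic strength and linker histone
H1, and those changes regulate how chromatin condenses.  Individual-particle
cryo-ET can trace the DNA of every single array, but turning flexible 3D
traces into numbers requires a careful measurement framework.  `nucarray`
implements that framework for structural biologists working with per-bp DNA
traces of mono- to tetranucleosomes (and for anyone who wants to explore how
measured linker statistics propagate to chromatin-fiber morphology):

* **Geometry** — detection of each NCP's wrapped DNA interval (8 Å overlap
  with an ideal superhelical path), entry/exit unwrapping in bp, the NCP
  frame (superhelical Z, dyad Y), the 20-bp arm vectors and their angles
  θ, θ∥, θ⊥ (arm–arm) and α, β (wrapping/bending per arm), open/closed
  classification (θ∥ < 0), unwrapping footprints, inter-NCP center
  distances and disc-plane dihedrals, and a linker-length self-consistency
  regression.
* **Statistics** — 1-/2-component Gaussian mixtures (BIC-selected), KDE,
  the sin(φ) random-plane null for dihedrals (KS test), and two-state
  Boltzmann energetics ΔU_ij = −ln(p_i/p_j) k_BT.
* **Classification** — all-pairs superposition RMSD (proper rotations only)
  with single-linkage conformational ordering.
* **Simulation** — hecta-nucleosome fibers assembled from sampled coarse
  NCP units (70° left-handed linker twist, hard-sphere clash rejection),
  worm-like-chain analysis (persistence length from tangent autocorrelation
  of 15-nm segments, R_g² = ⅓PL[1 − (P/L)(1 − e^(−L/P))], R_h = 0.662 R_g),
  and condensate density bounds by seamless assembling vs random docking
  into a 200-nm sphere.
* **Synthetic data** — a generator with presets for the six study
  conditions (mono/di/tri/tetra at 5 mM Na⁺, tetra at 50 mM Na⁺, tetra
  + H1) that drives the whole pipeline with prescribed ground truth.

See `docs/methods.md` for the models, conventions and numerical choices.

## Worked example

Generate 200 synthetic mononucleosomes from the low-salt preset (wrapping
angle α drawn from 39° ± 5° with probability 0.54 and 14° ± 16° with 0.46),
measure them back through the full detection pipeline, and fit the
two-state mixture:

```python
import numpy as np
from nucarray import boltzmann_gap, fit_mixture, measure_population
from nucarray.synthetic import generate_population, load_preset

params = load_preset("mono_5mM")
models = generate_population(params, 200, seed=7)
angles, pairs = measure_population(models)

alpha = np.concatenate([angles.alpha_entry_deg, angles.alpha_exit_deg])
fit = fit_mixture(alpha, k=2)
for w, m, s in zip(fit.weights, fit.means, fit.stds):
    print(f"component: weight {w:.2f}, mean {m:6.1f} deg, sd {s:5.1f} deg")
print(f"gap: {boltzmann_gap(fit.weights[0], fit.weights[1]).delta_u_kbt:+.2f} kT")
```

prints

```
component: weight 0.54, mean   38.6 deg, sd   5.1 deg
component: weight 0.46, mean   12.2 deg, sd  16.8 deg
gap: -0.18 kT
```

The measured mixture recovers the generating populations (0.54/0.46) and
peak positions; the Boltzmann gap −ln(0.54/0.46) = −0.16 k_BT says the
39°-state is slightly favored, and its small magnitude means switching
between the two arm states costs far less than one k_BT — the arms are
essentially free to toggle.  `examples/` contains one short script per
capability (single-array measurement, population statistics, linker
self-consistency, clustering, fiber simulation, condensate density); the
`nucarray` CLI (`synth`, `measure`, `stats`, `cluster`, `fiber`,
`condense`, `report`) runs the same stages on directories of model JSONs.

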