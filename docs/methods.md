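# Methods

`nucarray` quantifies the conformation of nucleosome arrays from per-base-pair
DNA traces and extrapolates the measured statistics into coarse-grained
chromatin fibers and condensates.  This note records the models, the numerical
choices, and what the synthetic benchmark does and does not establish.

## The array model

An array is a 3D polyline of DNA helical centers, one point per base pair
(Å), attached to a designed template: a 200-bp entry arm, `n` 147-bp
nucleosome-positioning repeats separated by 40-bp linkers, and a 100-bp exit
arm (447/634/821/1008 bp total for n = 1..4; the asymmetric arms identify the
array's orientation).  Each repeat carries an NCP placement: the half-open bp
interval in contact with the histone surface, signed entry/exit offsets
against the designed repeat (negative = unwrapped, "breathing"), and an
orthonormal frame — Z along the superhelical axis oriented with the
entry→exit advance, Y toward the dyad, X = Y × Z.

The wrapped DNA path is idealized as a left-handed superhelix of radius
41.8 Å and pitch 25.0 Å making 1.7 turns over 147 bp.  This reproduces the
nucleosome core geometry to well within the 8 Å overlap criterion used for
detection, so the crystal structure itself is not required.  Free DNA
(arms/linkers) rises 3.4 Å per bp.

## Measurement framework

**Wrapped-interval detection.**  The ideal 147-bp path is aligned to each
designed repeat by annealed trimmed least-squares superposition (thresholds
40 → 20 → 12 → 8 Å), bp are scored by their distance to the aligned path at
their sequence register, and the maximal contiguous run within 8 Å (gaps
≤ 2 bp bridged) is taken.  Because a straight arm leaving the wrap
near-tangentially stays within 8 Å of the path for several bp, the raw run
systematically overshoots; each boundary is therefore refined by a
changepoint that competes two *fixed* templates — the aligned helix at
register vs a rigid straight rod (3.4 Å/bp spacing) fitted on clear arm bp
and extrapolated inward.  Fixed templates leave no free parameters to absorb
contested points, so the changepoint is exact for noise-free geometry and
unbiased under isotropic noise.  Alignment and boundaries are iterated to a
fixed point.  Runs shorter than 40 bp are reported as absent placements
(the frame would be unreliable); absent placements keep their template slot
so repeat indices stay stable.

**Sub-bp junction and angle measurement.**  Boundary integers carry ~1–2 bp
of noise at σ = 2 Å, which would enter the wrapping angle at the superhelical
phase rate of 4.163°/bp (360°×1.7/147).  The junction is therefore
re-estimated at sub-bp resolution: for each candidate path parameter k the
arm bp must lie on a straight rod anchored at path(k) at their fixed 3.4 Å
arc offsets; the closed-form residual is scanned over k ∈ [boundary − 3,
boundary + 3] (a ±3 bp capture range balances boundary jitter against
shallow minima when the arm leaves near-tangentially).  The arm direction is
the unanchored least-squares rod over the 20-bp arm segment, extended bp by
bp (to at most 30 bp, ~10 nm, still well below the ~50 nm DNA persistence
length) while the next bp stays within a noise-scaled distance of the rod's
extrapolation.  Using the rod rather than the two-point chord keeps the
direction noise near 1° and — because it is independent of the wrap model —
preserves the mirror symmetry of the bending angle exactly.

**Frame fitting.**  The frame of a wrapped run comes from superposing the
ideal helix segment of the same length (register known: the points are
consecutive bp).  The origin is the fitted axis point nearest the centroid.
Y is the aligned template's radial direction at the run midpoint — the
least-squares version of "unit vector from the origin to the dyad bp", which
it equals exactly for noise-free data while carrying ~10× less phase noise
than the single midpoint coordinate (azimuthal noise of one bp at radius
41.8 Å is ~2.7° of phase, which would otherwise leak straight into the
wrapping angle).

**Angles.**  With entry/exit arm unit vectors e, x (pointing away from the
particle):

| quantity | definition | convention |
|---|---|---|
| θ | unsigned 3D angle(e, x) | [0°, 180°] |
| θ∥ | signed angle between XY projections, about +Z, entry→exit | (−180°, 180°] |
| θ⊥ | signed angle between YZ projections, about +X | (−180°, 180°] |
| α | in-plane angle from the local wrap tangent at the junction to the arm's XY projection | positive = rotating radially outward |
| β | arcsin(arm · Z) | [−90°, 90°], positive toward +Z |
| deltas | wrap boundary − designed boundary | negative = unwrapped |

For a left-handed wrap the in-plane tangent at a point p is ±(Z × r̂) with
r̂ the in-plane radial direction — a closed form requiring only the frame,
robust to noise.  An NCP is *closed-arm* iff θ∥ < 0 (θ∥ = 0 classifies as
open); an arm parallel to Z leaves θ∥/θ⊥ undefined (NaN, classified open).
Measurement error at σ = 2 Å noise: α ≈ 3° s.d. (≈0.1° bias), β ≈ 0.7°,
deltas ≈ 2 bp s.d. (≤0.5 bp bias); all quantities are exact for noise-free
models.

**Pairwise geometry.**  D(n, n+m) is the distance between frame origins;
the plane–plane dihedral is arccos(|z_i · z_j|) ∈ [0°, 90°].  For two
independently uniformly oriented planes the dihedral density is sin φ
(CDF 1 − cos φ), the null used by the KS comparison.

**Unwrapping footprint.**  `path8A` mode scores a bp as histone-contacting
iff it belongs to a detected wrapped run.  (Scoring raw distance to the path
would mark the first ~2 arm bp as contacts, since the 3.4 Å rise is below
the 8 Å criterion.)  `atomic4A` mode applies the any-atom < 4 Å criterion to
supplied all-atom structures with a chain-role assignment.

**Linker self-consistency.**  For each junction, L(n) = bp contour length
between the exit origin of NCP n and the entry origin of NCP n+1 (× 3.4 Å)
and θ(n) = (Δexit(n) + Δentry(n+1)) × 4.163°/bp.  Contour (not Euclidean)
length is used: with template DNA conserved, L = 3.4·(40 − Δex − Δen)
identically, so on self-consistent models the regression is exactly linear
with r = −1 even under coordinate noise — coordinate noise moves both
variables together.  An experimental pipeline that measures L from a density
map and θ from a fitted model decorrelates the two and yields |r| < 1.

## Distribution statistics

Angle samples are summarized by 1- or 2-component Gaussian mixtures (k = 1
closed form — the exact ML solution; k = 2 by EM with 10 restarts, 1e-6
log-likelihood tolerance; k selected by BIC under `auto`).  Angles are
treated as linear variables, as the observed ranges are far from wrap-around.
KDE uses a Gaussian kernel with Silverman's bandwidth by default.  Two-state
populations convert to energy gaps via ΔU_ij = −ln(p_i/p_j) k_BT, computed
as ln p_j − ln p_i so the antisymmetry is exact in floating point.  Note the
published gap values differ by 2–6% from −ln of the published (rounded)
populations; the package always computes from the supplied populations.

## Conformational classification

Pairwise superposition RMSD over all trace bp, equally weighted, with proper
rotations only (reflections would invert DNA chirality), followed by
single-linkage agglomeration; merge heights equal the sorted minimum
spanning tree edge weights, and leaf order is the standard recursive
dendrogram order with lower-index-first ties.

## Coarse-grained fiber simulator

A fiber unit is a 50 Å hard sphere with entry/exit arm vectors sampled from
the per-side (α, β) distributions at arm origins varied on the superhelical
track by the unwrapping distributions — the same primitives the measurement
framework defines, so measuring a sampled unit returns its own parameters.
Units are chained by joining unit i's exit arm collinearly to unit i+1's
entry arm across a straight linker (3.4 Å/bp; the bp count follows the
sampled unwrapping) and rotating unit i+1 by 70° left-handed about the
linker axis.  A variant that scales the twist with the actual linker length
(−70°·bp/40) is available behind `twist_scales_with_linker`; it is off by
default.  Placements with any center pair closer than 100 Å (below the
closest observed inter-NCP stacking distance) are resampled, with
backtracking after 100 failures and a total budget of 500 attempts per unit.

Fiber dimensions: the centerline is a window-5 moving average of NCP centers
(edge windows shrink symmetrically so the endpoints are kept); contour
length is its arc length, width is 2 × (RMS transverse center distance +
unit radius).  Persistence length comes from resampling the centerline at
fixed 15-nm arc steps and fitting ⟨cos θ(s)⟩ = exp(−s/P) by least squares on
the log over the first decade of decay (correlations ≤ 0.1 or ≤ 0 excluded);
near-straight chains report the 10⁵ nm cap.  The worm-like-chain summary
uses R_g² = (1/3)PL[1 − (P/L)(1 − e^(−L/P))], R_h = 0.662 R_g, and density
n/((4/3)πR_g³), also expressed in µM.

**A direction the simulator does not reproduce.**  Freezing the unwrapping
at the distribution means (the "no breathing" control) *shortens* this
simulator's fibers by ~3–7% — sampled breathing adds linker-length variance
whose extended tail preferentially survives clash rejection, and freezing at
zero (full wrap, 40-bp linkers) shortens them much further.  The study
reports the opposite direction (fibers 11–13% longer without breathing); its
fiber-pool construction is not described in enough detail to reproduce that
behavior, and per-bp twist scaling does not change the sign here.  Tests
assert only what this model guarantees (the breathing flag materially
changes the ensemble), not the literature direction.

## Condensates

*Seamless assembling* takes the condensate density as the mean per-fiber
WLC density (an upper bound: no inter-fiber space).  *Random docking*
places fibers as rigid bodies (uniform rotations and centers) into a 200-nm
sphere, rejecting on envelope overlap; the envelope is a union of spheres at
NCP centers with radii drawn as half the i,i+2 center-distance distribution
(clamped to at least the 5-nm unit radius), so inter-fiber spacing reflects
the observed equilibrium NCP approach distance.  Docking stops at the first
unplaceable fiber; the concentration (NCPs over the full sphere volume) is
the lower bound.  A 25-nm slab crop is provided for visualization.

## Synthetic data and presets

The generator builds each NCP as the ideal superhelix trimmed/extended by
sampled integer deltas (clamped to [−100, +20] bp; wraps below 45 bp or
junction gaps below 20 bp are resampled so every arm remains measurable),
emits arms/linkers as straight 3.4 Å/bp segments in directions drawn from
the per-side (α, β) distributions, chains consecutive NCPs with the 70°
left-handed linker twist, rejects models with NCP centers closer than
100 Å, and finally adds isotropic Gaussian noise (default σ = 2 Å) to every
bp — a stand-in for map-fitting error.  Sampled ground truth is stored in a
separate block that measurement code never reads.

Presets encode the measured statistics of the six study conditions
(mono/di/tri/tetra at 5 mM Na⁺, tetra at 50 mM Na⁺, tetra with linker
histone H1).  Dispersions not reported numerically (array α component
widths, β widths, i,i+2 spread, the di/tri minor α position) default to the
mononucleosome values or to the tetranucleosome position and are flagged in
`defaults_filled`.  Consequences: passing recovery tests show the
*pipeline* is unbiased under these conditions — they cannot validate the
unprinted dispersions, and the generator idealizes arms as straight and
noise as isotropic Gaussian, neither exactly true of cryo-ET model fitting.

## Problem sizes

Benchmarks use populations of 200 arrays per condition for parameter
recovery, 30 tetranucleosome arrays for the linker self-consistency
regression, 20 fibers × 100 NCPs per salt condition for fiber statistics,
and 100 fibers × 24 NCPs for docking (24-NCP fibers built from these stiff
presets fit the 200-nm sphere as rigid bodies; hecta-nucleosome fibers do
not, because this simulator's fibers are straighter than the study's).

## Known limitations

- Real (experimentally fitted) traces have curved arms and anisotropic
  error; the junction estimator assumes locally straight free DNA over
  ≤ 30 bp.
- Angles are fitted as linear, not circular, variables.
- H1 enters only through its measured effect on the distributions; invaded
  ("foreign DNA") topologies are not generated.
- The published fiber dimensions and condensate concentrations depend on
  dispersion values shown only graphically in the source material; only
  directional salt responses are asserted here.
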