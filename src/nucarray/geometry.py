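"""Per-particle geometric measurement of nucleosome arrays.

Implements the full measurement framework: detection of the wrapped DNA
interval of each designed positioning repeat (8 A overlap with the ideal
superhelical path), least-squares fitting of the NCP frame, the 20-bp arm
vectors and every angle defined on them (theta, theta_par, theta_perp, the
wrapping angle alpha and the bending angle beta), open/closed classification,
unwrapping footprints, pairwise center distances / discoidal-plane dihedrals,
and the linker-length self-consistency regression.

Sign conventions (fixed; the study reports magnitudes without stating them):

===========  ==============================================================
quantity     convention
===========  ==============================================================
+Z           along the entry->exit superhelical advance of the wrap
theta        unsigned 3D angle between entry and exit arm vectors, [0, 180]
theta_par    signed about +Z from the entry to the exit XY-projection
theta_perp   signed about +X from the entry to the exit YZ-projection
alpha        signed in the XY plane from the local wrap tangent to the
             arm projection; positive = rotating radially outward
beta         arcsin(arm . Z), positive = toward +Z; [-90, 90]
deltas       negative = unwrapped relative to the designed 147-bp repeat
closed arm   theta_par < 0 (strict; theta_par = 0 classifies as open)
===========  ==============================================================
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    ArmTooShortError,
    FitError,
    InvalidArgumentError,
    PlacementNotFoundError,
    UndefinedCorrelationError,
)
from .model import ArrayModel, NcpFrame, NcpPlacement, TemplateSpec
from . import superhelix as sh

__all__ = [
    "ArmVector",
    "AngleMeasurements",
    "PairGeometry",
    "FootprintCurve",
    "LinkerConsistency",
    "detect_wrapped_interval",
    "detect_placements",
    "fit_ncp_frame",
    "arm_vector",
    "measure_angles",
    "pair_geometry",
    "unwrap_footprint",
    "linker_consistency",
    "measure_population",
]

#: overlap criterion between trace and ideal wrapped path, A
OVERLAP_CUTOFF_A = 8.0
#: runs may bridge gaps of at most this many non-overlapping bp
GAP_TOLERANCE_BP = 2
#: length of the stiff DNA segment defining an arm vector, bp
ARM_BP = 20
#: boundary changepoint search range around the raw 8 A run, bp
REFINE_RANGE_BP = 12

ARM_LENGTH_A = ARM_BP * sh.LINKER_RISE_A  # ~68 A, ~6.8 nm


@dataclass(frozen=True)
class ArmVector:
    """A 20-bp arm vector anchored at a wrap boundary, pointing away from the NCP."""

    side: str
    origin_bp: int
    direction: np.ndarray
    length_bp: int = ARM_BP


@dataclass(frozen=True)
class AngleMeasurements:
    theta_deg: float
    theta_par_deg: float
    theta_perp_deg: float
    alpha_entry_deg: float
    alpha_exit_deg: float
    beta_entry_deg: float
    beta_exit_deg: float
    arm_state: str  # "open" | "closed"


@dataclass(frozen=True)
class PairGeometry:
    i: int
    j: int
    distance_A: float
    dihedral_deg: float


@dataclass(frozen=True)
class FootprintCurve:
    """Per-bp histone-contact probability along the template."""

    values: np.ndarray
    n_models: int
    mode: str


@dataclass(frozen=True)
class LinkerConsistency:
    r: float
    p_value: float
    slope: float
    intercept: float
    n: int


# ---------------------------------------------------------------------------
# rigid superposition helper (correspondence known)

def _kabsch(moving: np.ndarray, fixed: np.ndarray):
    """Least-squares proper rotation R, translation t with R@moving + t ~ fixed."""
    import warnings

    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    with warnings.catch_warnings():
        # degenerate (e.g. collinear) candidate regions are rejected later
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(fixed - fc, moving - mc)
    R = rot.as_matrix()
    return R, fc - R @ mc


# ---------------------------------------------------------------------------
# wrapped interval detection

def _registered_residuals(trace, template, repeat_index, R, t, k_lo, k_hi):
    """Distance of each trace bp to the aligned ideal path at its register.

    Register k of global bp j is j - designed_start; the ideal path is
    evaluated beyond [0, 147) to cover unwrapping/over-wrapping.
    Returns (global bp indices, residuals).
    """
    ds, _ = template.nps_intervals[repeat_index]
    j_lo = max(0, ds + k_lo)
    j_hi = min(template.total_bp, ds + k_hi)
    ks = np.arange(j_lo - ds, j_hi - ds)
    ideal = sh.path_points(ks) @ R.T + t
    res = np.linalg.norm(trace[j_lo:j_hi] - ideal, axis=1)
    return np.arange(j_lo, j_hi), res


def _robust_align(trace, template, repeat_index, hint: Optional[NcpFrame]):
    """Anneal a registered rigid alignment of the ideal 147-bp path to the repeat."""
    ds, de = template.nps_intervals[repeat_index]
    ks = np.arange(0, 147)
    ideal = sh.path_points(ks)
    pts = trace[ds:de]
    if hint is not None:
        R, t = hint.rotation, hint.origin
    else:
        R, t = _kabsch(ideal, pts)
    for cutoff in (40.0, 20.0, 12.0, OVERLAP_CUTOFF_A, OVERLAP_CUTOFF_A, OVERLAP_CUTOFF_A):
        res = np.linalg.norm(pts - (ideal @ R.T + t), axis=1)
        keep = res < cutoff
        if keep.sum() < 3:
            return None
        R, t = _kabsch(ideal[keep], pts[keep])
    return R, t


def _longest_run(indices: np.ndarray, gap_tol: int) -> tuple[int, int]:
    """Longest contiguous stretch of sorted indices bridging gaps <= gap_tol."""
    splits = np.where(np.diff(indices) > gap_tol + 1)[0]
    starts = np.concatenate([[0], splits + 1])
    ends = np.concatenate([splits, [len(indices) - 1]])
    lengths = indices[ends] - indices[starts]
    best = int(np.argmax(lengths))
    return int(indices[starts[best]]), int(indices[ends[best]]) + 1


class _Rod:
    """Straight free-DNA model: consecutive bp at 3.4 A steps along a line.

    Fitted by least squares with the arc positions fixed (closed form:
    direction = normalized first moment of the centered points against the
    centered arc coordinate), then used as a *fixed* template to predict any
    bp position by extrapolation.
    """

    def __init__(self, points: np.ndarray, indices: np.ndarray,
                 spacing: float = sh.LINKER_RISE_A):
        points = np.asarray(points, dtype=float)
        self.indices = np.asarray(indices)
        u = spacing * (self.indices - self.indices.mean())
        v = u @ (points - points.mean(axis=0))
        nv = np.linalg.norm(v)
        self.direction = v / nv if nv > 0 else np.array([1.0, 0.0, 0.0])
        self.anchor = points.mean(axis=0)
        self.ref = float(self.indices.mean())
        self.spacing = spacing

    def predict(self, j) -> np.ndarray:
        return self.anchor + (np.asarray(j, dtype=float) - self.ref)[..., None] * (
            self.spacing * self.direction
        )


#: bp used to fit the fixed straight-arm rod template outside the contested window
ROD_FIT_BP = 12


def _refine_boundary(trace, res_by_bp: dict[int, float], raw_edge: int, side: str,
                     lo_lim: int, hi_lim: int) -> int:
    """Changepoint refinement of one wrap boundary.

    A straight arm leaving the wrap near-tangentially stays within 8 A of the
    ideal path for a few bp, so the raw 8 A run systematically overshoots.
    The boundary is re-estimated by competing two *fixed* templates over the
    contested window around the raw edge: the aligned superhelical path at
    register (fitted on the run interior) versus a rigid straight 3.4 A/bp
    rod fitted on clear arm bp outside the window and extrapolated inward.
    Fixed templates leave no free parameters to absorb contested points, so
    the changepoint is exact for noise-free geometry and unbiased under
    isotropic noise; exact cost ties resolve toward the maximal wrapped run
    (the boundary bp lies on both templates).
    """
    if side == "entry":
        c_lo = max(lo_lim + 1, raw_edge - 3)
        c_hi = min(raw_edge + REFINE_RANGE_BP, hi_lim - 1)
        cands = np.arange(c_lo, c_hi + 1)  # ascending: ties -> smaller start
        rod_idx = np.arange(max(lo_lim, c_lo - ROD_FIT_BP), c_lo)
    else:  # raw_edge is one past the last wrapped bp
        c_lo = max(lo_lim + 1, raw_edge - REFINE_RANGE_BP)
        c_hi = min(raw_edge + 3, hi_lim - 1)
        cands = np.arange(c_hi, c_lo - 1, -1)  # descending: ties -> larger end
        rod_idx = np.arange(c_hi, min(hi_lim, c_hi + ROD_FIT_BP))
    if len(rod_idx) < 4:
        return raw_edge
    rod = _Rod(trace[rod_idx], rod_idx)
    window = np.arange(c_lo, c_hi + 1)
    rod_res2 = ((trace[window] - rod.predict(window)) ** 2).sum(axis=1)
    rod_by_bp = dict(zip(window.tolist(), rod_res2.tolist()))

    best_c, best_cost = raw_edge, np.inf
    for c in cands:
        if side == "entry":
            arm_idx = window[window < c]
            helix_idx = window[window >= c]
        else:
            arm_idx = window[window >= c]
            helix_idx = window[window < c]
        cost = sum(res_by_bp.get(j, 10.0) ** 2 for j in helix_idx)
        cost += sum(rod_by_bp[j] for j in arm_idx)
        # 1e-6 A^2 tie tolerance: above numerical noise, far below any
        # physical residual
        if cost < best_cost - 1e-6:
            best_cost, best_c = cost, int(c)
    return best_c


def detect_wrapped_interval(
    trace: np.ndarray,
    repeat_index: int,
    template: TemplateSpec,
    reference_frame_hint: Optional[NcpFrame] = None,
) -> NcpPlacement:
    """Detect the wrapped DNA interval of one designed repeat.

    Aligns the ideal 147-bp superhelical path to the repeat region (robustly,
    by annealed trimmed superposition), marks trace bp within 8 A of the
    aligned path at their register, takes the maximal contiguous run (gaps of
    up to 2 bp bridged), refines both boundaries by a straight-arm vs helix
    changepoint, and fits the NCP frame on the wrapped points.

    Raises ``PlacementNotFoundError`` when no bp overlaps the path within
    8 A (the repeat's placement is then flagged absent by callers).
    """
    trace = np.asarray(trace, dtype=float)
    if not (0 <= repeat_index < template.n_ncp):
        raise InvalidArgumentError(f"repeat_index {repeat_index} out of range")
    ds, de = template.nps_intervals[repeat_index]

    aligned = _robust_align(trace, template, repeat_index, reference_frame_hint)
    if aligned is None:
        raise PlacementNotFoundError(
            f"repeat {repeat_index}: no trace bp within {OVERLAP_CUTOFF_A} A of the wrapped path"
        )
    R, t = aligned
    bps, res = _registered_residuals(trace, template, repeat_index, R, t, -53, 200)
    inside = bps[res < OVERLAP_CUTOFF_A]
    if len(inside) < ARM_BP:
        raise PlacementNotFoundError(
            f"repeat {repeat_index}: only {len(inside)} bp overlap the wrapped path"
        )
    start, end = _longest_run(inside, GAP_TOLERANCE_BP)

    # iterate: refit the alignment on the current run interior (boundary
    # pollution biases the registered residuals) and re-refine both
    # boundaries against fixed templates until stable
    lo_lim, hi_lim = int(bps[0]), int(bps[-1]) + 1
    ds = template.nps_intervals[repeat_index][0]
    for _ in range(4):
        pad = 5 if end - start >= 50 else 0
        ks = np.arange(start + pad, end - pad) - ds
        R, t = _kabsch(sh.path_points(ks), trace[start + pad:end - pad])
        bps, res = _registered_residuals(trace, template, repeat_index, R, t, -53, 200)
        res_by_bp = dict(zip(bps.tolist(), res.tolist()))
        new_start = _refine_boundary(trace, res_by_bp, start, "entry", lo_lim, hi_lim)
        new_end = _refine_boundary(trace, res_by_bp, end, "exit", lo_lim, hi_lim)
        if new_end - new_start < ARM_BP:
            raise PlacementNotFoundError(f"repeat {repeat_index}: wrapped run too short")
        if (new_start, new_end) == (start, end):
            break
        start, end = new_start, new_end

    if end - start < 40:  # too short for a reliable frame: treat as not found
        raise PlacementNotFoundError(
            f"repeat {repeat_index}: wrapped run of {end - start} bp too short to fit a frame"
        )
    frame = fit_ncp_frame(trace[start:end])
    placement = NcpPlacement(
        frame=frame,
        wrap_interval=(start, end),
        delta_entry_bp=ds - start,
        delta_exit_bp=end - de,
    )

    # sub-bp junction refinement of both boundaries (rod / path closest
    # approach); rounding back to integers keeps deltas bp-valued
    j_d = (start + end - 1) / 2.0
    new_start, new_end = start, end
    jr = _junction(trace, placement, "entry")
    if jr is not None:
        j_star = jr[0] - sh.DYAD_K + j_d
        cand = int(np.rint(j_star))
        if abs(cand - start) <= 3 and cand >= lo_lim:
            new_start = cand
    jr = _junction(trace, placement, "exit")
    if jr is not None:
        j_star = jr[0] - sh.DYAD_K + j_d
        cand = int(np.rint(j_star)) + 1
        if abs(cand - end) <= 3 and cand <= hi_lim:
            new_end = cand
    if (new_start, new_end) != (start, end) and new_end - new_start >= ARM_BP:
        start, end = new_start, new_end
        placement = NcpPlacement(
            frame=fit_ncp_frame(trace[start:end]),
            wrap_interval=(start, end),
            delta_entry_bp=ds - start,
            delta_exit_bp=end - de,
        )
    return placement


def detect_placements(model: ArrayModel) -> ArrayModel:
    """Re-detect every placement of a model from its trace alone.

    Stored placements and ground truth are ignored; repeats where detection
    fails are flagged absent.
    """
    placements = []
    for i in range(model.template.n_ncp):
        try:
            placements.append(detect_wrapped_interval(model.trace, i, model.template))
        except PlacementNotFoundError:
            placements.append(NcpPlacement.absent())
    return ArrayModel(
        template=model.template,
        trace=model.trace,
        placements=placements,
        label=model.label,
        provenance=model.provenance,
    )


# ---------------------------------------------------------------------------
# sub-bp junction estimation
#
# The integer changepoint locates the boundary to ~1-2 bp under coordinate
# noise, which propagates into the wrapping angle at ~4.2 deg/bp (the wrap
# tangent rotates by one bp of superhelical phase).  The junction is
# therefore re-estimated at sub-bp precision as the closest approach between
# the straight-arm rod (fitted on clear arm bp, a robust estimate of the arm
# direction) and the ideal wrapped path reconstructed in the NCP frame; the
# true arm passes exactly through the true origin, so this is exact for
# noise-free geometry.


def _local_path_k(placement: NcpPlacement, j) -> np.ndarray:
    """Ideal-path parameter of global bp j in the placement's frame register.

    The frame's Y axis points to the run midpoint (the geometric dyad), so
    that bp maps to the canonical dyad parameter.
    """
    start, end = placement.wrap_interval
    j_d = (start + end - 1) / 2.0
    return np.asarray(j, dtype=float) - j_d + sh.DYAD_K


#: maximum bp of free DNA recruited for the junction rod (10 nm, still well
#: below the ~50 nm DNA persistence length)
JUNCTION_ROD_MAX_BP = 30


def _extend_arm(trace: np.ndarray, idx: np.ndarray, side: str) -> np.ndarray:
    """Greedily extend the arm-rod window outward while the DNA stays straight.

    Each candidate bp is accepted if its distance to the current rod's
    extrapolation stays within a noise-scaled threshold; extension stops at
    the first rejection (the linker bends into the next particle's wrap, or
    the free DNA genuinely curves) or at JUNCTION_ROD_MAX_BP.
    """
    step = -1 if side == "entry" else 1
    while len(idx) < JUNCTION_ROD_MAX_BP - 3:
        j = int(idx[0] if side == "entry" else idx[-1]) + step
        if j < 0 or j >= len(trace):
            break
        rod = _Rod(trace[idx], idx)
        rms = np.sqrt(((trace[idx] - rod.predict(idx)) ** 2).sum(axis=1).mean())
        if np.linalg.norm(trace[j] - rod.predict(np.asarray([j]))[0]) > max(2.0, 3.0 * rms):
            break
        idx = np.concatenate([[j], idx]) if side == "entry" else np.concatenate([idx, [j]])
    return idx


def _junction(trace: np.ndarray, placement: NcpPlacement, side: str):
    """(junction parameter k*, unit arm direction pointing away, both local).

    Returns None when the arm is too short to fit the rod.
    """
    start, end = placement.wrap_interval
    f = placement.frame
    if side == "entry":
        origin = start
        idx = np.arange(origin - ARM_BP, origin - 2)
    else:
        origin = end - 1
        idx = np.arange(origin + 3, origin + ARM_BP + 1)
    if idx[0] < 0 or idx[-1] >= len(trace):
        return None
    idx = _extend_arm(trace, idx, side)
    local = f.to_local(trace[idx])

    # anchored-rod scan: for each candidate junction parameter k the arm bp
    # must lie on a straight rod through path(k) at their 3.4 A arc offsets;
    # the residual is closed-form in the free direction
    # +-3 bp capture range: wide enough for integer-boundary jitter, narrow
    # enough to bound excursions when the arm leaves near-tangentially and
    # the closest-approach minimum is shallow
    k0 = _local_path_k(placement, origin)
    ks = k0 + np.linspace(-3.0, 3.0, 121)
    j_of_k = idx - (origin - k0)  # arm bp as path-parameter offsets
    best = (np.inf, float(k0))
    for k in ks:
        s = sh.LINKER_RISE_A * (j_of_k - k)
        q = local - sh.path_points(k)
        cost = float((q**2).sum() + (s**2).sum() - 2.0 * np.linalg.norm(s @ q))
        if cost < best[0]:
            best = (cost, float(k))
    k_star = best[1]
    # arm direction from the unanchored rod: independent of the wrap model,
    # so mirror/handedness properties of beta and theta hold exactly
    rod = _Rod(local, idx)
    away = rod.direction if side == "exit" else -rod.direction
    return k_star, away, origin


# ---------------------------------------------------------------------------
# NCP frame fitting

def fit_ncp_frame(wrapped_points: np.ndarray) -> NcpFrame:
    """Fit the NCP frame to a sequential run of wrapped bp coordinates.

    The superhelical (Z) axis comes from a least-squares superposition of the
    ideal helix segment of the same length onto the points (register known:
    the points are consecutive bp).  The origin is the axis point nearest the
    centroid; Y points from the origin to the dyad bp (midpoint of the run),
    orthogonalized against Z; X = Y x Z.
    """
    pts = np.asarray(wrapped_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidArgumentError("wrapped_points must be (n, 3)")
    n = len(pts)
    if n < 40:
        raise FitError(f"need >= 40 wrapped points, got {n}")
    sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-6 * sv[0]:
        raise FitError("wrapped points are collinear; helix axis undefined")

    ideal = sh.path_points(np.arange(n))
    R, t = _kabsch(ideal, pts)
    z = R @ np.array([0.0, 0.0, 1.0])
    axis_point = t  # image of the local helix axis origin
    centroid = pts.mean(axis=0)
    origin = axis_point + np.dot(centroid - axis_point, z) * z

    # Y points from the axis to the dyad bp (midpoint of the run).  Using
    # the aligned template's radial direction at the midpoint rather than
    # the single noisy midpoint coordinate estimates the same direction by
    # least squares over all points (identical for noise-free data, ~10x
    # less phase noise otherwise).
    mid = (n - 1) / 2.0
    phi_mid = 0.5 * np.pi - sh.PHI_PER_BP * (mid - sh.DYAD_K)
    y = R @ np.array([np.cos(phi_mid), np.sin(phi_mid), 0.0])
    y = y - np.dot(y, z) * z
    y = y / np.linalg.norm(y)
    x = np.cross(y, z)
    return NcpFrame(origin, x, y, z)


# ---------------------------------------------------------------------------
# angles

def _signed_angle(u: np.ndarray, v: np.ndarray, axis: np.ndarray) -> float:
    """Signed angle (deg) from u to v about ``axis``, using their projections
    onto the plane perpendicular to ``axis``; in (-180, 180]."""
    u_p = u - np.dot(u, axis) * axis
    v_p = v - np.dot(v, axis) * axis
    if np.linalg.norm(u_p) < 1e-12 or np.linalg.norm(v_p) < 1e-12:
        raise FitError("vector parallel to the projection axis; angle undefined")
    ang = np.degrees(np.arctan2(np.dot(np.cross(u_p, v_p), axis), np.dot(u_p, v_p)))
    return float(ang if ang > -180.0 else 180.0)


def arm_vector(trace: np.ndarray, placement: NcpPlacement, side: str) -> ArmVector:
    """The 20-bp arm vector on one side of a placement, pointing away from it."""
    if side not in ("entry", "exit"):
        raise InvalidArgumentError(f"side must be 'entry' or 'exit', got {side!r}")
    start, end = placement.wrap_interval
    n_bp = len(trace)
    if side == "entry":
        origin = start
        if origin - ARM_BP < 0:
            raise ArmTooShortError(f"entry arm shorter than {ARM_BP} bp")
        d = trace[origin - ARM_BP] - trace[origin]
    else:
        origin = end - 1
        if origin + ARM_BP >= n_bp:
            raise ArmTooShortError(f"exit arm shorter than {ARM_BP} bp")
        d = trace[origin + ARM_BP] - trace[origin]
    return ArmVector(side=side, origin_bp=origin, direction=d / np.linalg.norm(d))


def _side_angles(trace: np.ndarray, placement: NcpPlacement, side: str):
    """(global arm direction, alpha_deg, beta_deg) for one side.

    The arm direction is the least-squares rod over the 20-bp arm segment
    (robust version of the segment chord; identical for straight noise-free
    arms) and alpha is measured against the in-plane wrap tangent at the
    sub-bp junction, which decouples it from integer boundary jitter.
    """
    f = placement.frame
    z = np.array([0.0, 0.0, 1.0])
    jr = _junction(trace, placement, side)
    if jr is not None:
        k_star, away_local, _origin = jr
        t_xy = sh.inplane_tangent(sh.path_points(k_star), z, np.zeros(3),
                                  outgoing=(side == "exit"))
    else:  # arm clipped by the trace end: fall back to the chord
        av = arm_vector(trace, placement, side)
        away_local = f.to_local(trace[av.origin_bp] + av.direction) - f.to_local(
            trace[av.origin_bp]
        )
        k_star = _local_path_k(placement, av.origin_bp)
        t_xy = sh.inplane_tangent(sh.path_points(k_star), z, np.zeros(3),
                                  outgoing=(side == "exit"))
    sgn = 1.0 if side == "exit" else -1.0
    try:
        alpha = sgn * _signed_angle(t_xy, away_local, z)
    except FitError:  # arm along the superhelical axis: no in-plane projection
        alpha = float("nan")
    beta = float(np.degrees(np.arcsin(np.clip(away_local[2], -1.0, 1.0))))
    return f.rotation @ away_local, alpha, beta


def measure_angles(placement: NcpPlacement, trace: np.ndarray) -> AngleMeasurements:
    """All arm angles of one NCP; requires >= 20 bp of DNA beyond each boundary."""
    if not placement.present:
        raise InvalidArgumentError("cannot measure an absent placement")
    trace = np.asarray(trace, dtype=float)
    # raises ArmTooShortError when < 20 bp of free DNA remain on a side
    arm_vector(trace, placement, "entry")
    arm_vector(trace, placement, "exit")
    f = placement.frame

    e, alpha_en, beta_en = _side_angles(trace, placement, "entry")
    x, alpha_ex, beta_ex = _side_angles(trace, placement, "exit")
    theta = float(np.degrees(np.arccos(np.clip(np.dot(e, x), -1.0, 1.0))))
    try:
        theta_par = _signed_angle(e, x, f.z_axis)
    except FitError:  # an arm parallel to Z has no disc-plane projection
        theta_par = float("nan")
    try:
        theta_perp = _signed_angle(e, x, f.x_axis)
    except FitError:
        theta_perp = float("nan")
    return AngleMeasurements(
        theta_deg=theta,
        theta_par_deg=theta_par,
        theta_perp_deg=theta_perp,
        alpha_entry_deg=alpha_en,
        alpha_exit_deg=alpha_ex,
        beta_entry_deg=beta_en,
        beta_exit_deg=beta_ex,
        arm_state="closed" if theta_par < 0.0 else "open",  # NaN -> open
    )


# ---------------------------------------------------------------------------
# pairwise geometry

def pair_geometry(placements: Sequence[NcpPlacement], m: int) -> list[PairGeometry]:
    """Center-center distance and discoidal-plane dihedral for every (n, n+m) pair."""
    if m < 1:
        raise InvalidArgumentError(f"m must be >= 1, got {m}")
    out = []
    for n in range(len(placements) - m):
        a, b = placements[n], placements[n + m]
        if not (a.present and b.present):
            continue
        d = float(np.linalg.norm(a.frame.origin - b.frame.origin))
        cosang = abs(float(np.dot(a.frame.z_axis, b.frame.z_axis)))
        phi = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        out.append(PairGeometry(i=n, j=n + m, distance_A=d, dihedral_deg=phi))
    return out


# ---------------------------------------------------------------------------
# unwrapping footprint

def unwrap_footprint(
    models: Sequence[ArrayModel],
    mode: str = "path8A",
    atomic_structures=None,
    dna_chains: Sequence[str] = ("I", "J"),
    histone_chains: Sequence[str] = ("A", "B", "C", "D", "E", "F", "G", "H"),
) -> FootprintCurve:
    """Mean per-bp histone-contact score across a model population.

    ``path8A`` (default, coarse surrogate): a bp scores 1 iff it belongs to a
    placement's detected wrapped run (the contiguous stretch within 8 A of
    the aligned ideal superhelical path).  ``atomic4A``: a bp scores 1 iff
    any of its atoms lies within 4 A of any histone atom; requires one
    all-atom structure (biotite AtomArray) per model with the given
    chain-role assignment.
    """
    models = list(models)
    if not models:
        raise InvalidArgumentError("empty model list")
    template = models[0].template
    if any(m.template != template for m in models):
        raise InvalidArgumentError("models mix different templates")

    if mode == "path8A":
        scores = np.zeros((len(models), template.total_bp))
        for r, model in enumerate(models):
            placements = model.placements
            if not placements:
                placements = detect_placements(model).placements
            for p in placements:
                if p.present:
                    s, e = p.wrap_interval
                    scores[r, s:e] = 1.0
        return FootprintCurve(scores.mean(axis=0), n_models=len(models), mode=mode)

    if mode == "atomic4A":
        if atomic_structures is None or len(atomic_structures) != len(models):
            raise InvalidArgumentError("atomic4A mode needs one atomic structure per model")
        from scipy.spatial import cKDTree

        scores = np.zeros((len(models), template.total_bp))
        for r, atoms in enumerate(atomic_structures):
            hist = atoms[np.isin(atoms.chain_id, list(histone_chains))]
            if hist.array_length() == 0:
                raise InvalidArgumentError("atomic4A: no histone atoms under the given chains")
            tree = cKDTree(hist.coord)
            dna = atoms[np.isin(atoms.chain_id, list(dna_chains))]
            dmin = tree.query(dna.coord)[0]
            for res_id in np.unique(dna.res_id):
                bp = int(res_id) - 1  # residue numbers are bp index + 1
                if 0 <= bp < template.total_bp:
                    if (dmin[dna.res_id == res_id] < 4.0).any():
                        scores[r, bp] = 1.0
        return FootprintCurve(scores.mean(axis=0), n_models=len(models), mode=mode)

    raise InvalidArgumentError(f"unknown footprint mode {mode!r}")


# ---------------------------------------------------------------------------
# linker-length self-consistency

def linker_consistency(models: Sequence[ArrayModel]) -> LinkerConsistency:
    """Regression of inter-NCP linker contour length against summed unwrap angle.

    For every junction n -> n+1, L(n) is the bp contour length between the
    exit origin of NCP n and the entry origin of NCP n+1 (bp count x 3.4 A)
    and theta(n) = (delta_exit(n) + delta_entry(n+1)) x 4.163 deg/bp (negative
    when unwrapped).  Unwrapping lengthens the linker, so r is negative.
    """
    from scipy.stats import pearsonr

    L, TH = [], []
    for model in models:
        ps = model.placements or detect_placements(model).placements
        for n in range(len(ps) - 1):
            a, b = ps[n], ps[n + 1]
            if not (a.present and b.present):
                continue
            L.append((b.wrap_interval[0] - a.wrap_interval[1]) * sh.LINKER_RISE_A)
            TH.append((a.delta_exit_bp + b.delta_entry_bp) * sh.DEG_PER_BP)
    if len(L) < 3:
        raise UndefinedCorrelationError(f"need >= 3 junctions, got {len(L)}")
    L = np.asarray(L)
    TH = np.asarray(TH)
    if np.ptp(L) == 0 or np.ptp(TH) == 0:
        raise UndefinedCorrelationError("zero variance in linker length or unwrap angle")
    r, p = pearsonr(TH, L)
    slope, intercept = np.polyfit(TH, L, 1)
    return LinkerConsistency(
        r=float(r), p_value=float(p), slope=float(slope), intercept=float(intercept), n=len(L)
    )


# ---------------------------------------------------------------------------
# population measurement (tidy output)

def measure_population(models: Sequence[ArrayModel], redetect: bool = True,
                       max_pair_order: Optional[int] = None):
    """Measure a model population into tidy angle and pair tables.

    Returns (angles_df, pairs_df) pandas DataFrames: one row per (model, ncp)
    with all angles/deltas/state, one row per (model, pair, m) with center
    distance and dihedral.  With ``redetect`` (default) placements are
    re-detected from each trace; otherwise stored placements are used.
    """
    import pandas as pd

    angle_rows, pair_rows = [], []
    for model in models:
        mm = detect_placements(model) if redetect else model
        for i, p in enumerate(mm.placements):
            if not p.present:
                continue
            try:
                am = measure_angles(p, mm.trace)
            except ArmTooShortError:
                continue
            angle_rows.append(
                {
                    "model": model.label,
                    "ncp": i,
                    "wrap_length_bp": p.wrap_length_bp,
                    "delta_entry_bp": p.delta_entry_bp,
                    "delta_exit_bp": p.delta_exit_bp,
                    "theta_deg": am.theta_deg,
                    "theta_par_deg": am.theta_par_deg,
                    "theta_perp_deg": am.theta_perp_deg,
                    "alpha_entry_deg": am.alpha_entry_deg,
                    "alpha_exit_deg": am.alpha_exit_deg,
                    "beta_entry_deg": am.beta_entry_deg,
                    "beta_exit_deg": am.beta_exit_deg,
                    "arm_state": am.arm_state,
                }
            )
        n_present = sum(p.present for p in mm.placements)
        upper = max_pair_order if max_pair_order is not None else len(mm.placements) - 1
        for m in range(1, upper + 1):
            if n_present < m + 1:
                break
            for pg in pair_geometry(mm.placements, m):
                pair_rows.append(
                    {
                        "model": model.label,
                        "i": pg.i,
                        "j": pg.j,
                        "m": m,
                        "distance_A": pg.distance_A,
                        "dihedral_deg": pg.dihedral_deg,
                    }
                )
    return pd.DataFrame(angle_rows), pd.DataFrame(pair_rows)
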