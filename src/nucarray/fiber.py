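"""Coarse-grained chromatin fiber simulator and worm-like-chain analysis.

Hecta-nucleosome fibers are assembled by sequentially connecting coarse NCP
units (a 50 A hard sphere with two 20-bp arm vectors sampled from the
measured per-side wrapping/bending angle distributions, and arm origins
varied on the superhelical track by the measured unwrapping distributions).
The exit arm of unit i is joined collinearly to the entry arm of unit i+1
across a straight 40-bp linker carrying a 70 degree left-handed DNA twist;
clashing placements (< 100 A center distance) are resampled with
backtracking.

Fiber dimensions (smoothed-centerline contour length and width), persistence
length from the tangent autocorrelation of fixed 15-nm segments, and the
worm-like-chain radius of gyration

    R_g^2 = (1/3) P L [1 - (P/L)(1 - exp(-L/P))],   R_h = 0.662 R_g

summarize each fiber; NCP density is n / ((4/3) pi R_g^3), also reported in
micromolar.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import AssemblyError, InvalidArgumentError, TooShortError
from .model import NcpFrame
from .synthetic import (
    CLASH_DISTANCE_A,
    LINKER_TWIST_DEG,
    SyntheticParams,
    _align_rotation,
    _rotation_about,
    arm_direction_local,
)
from . import superhelix as sh

__all__ = [
    "CoarseNcpUnit",
    "FiberModel",
    "FiberMetrics",
    "sample_unit",
    "build_fiber",
    "fiber_dimensions",
    "persistence_length",
    "wlc_metrics",
    "fiber_gyration_radius_nm",
]

#: hard-sphere radius of a coarse NCP unit, A
UNIT_RADIUS_A = 50.0
#: fixed segment length for the persistence-length resampling, nm
SEGMENT_NM = 15.0
#: reported persistence cap for effectively straight chains, nm
PERSISTENCE_CAP_NM = 1e5
#: R_h / R_g for a worm-like chain
RH_OVER_RG = 0.662

AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class CoarseNcpUnit:
    """One NCP of the coarse model, in its own local frame.

    Arm vectors are unit vectors pointing away from the particle; the arm
    origins are positions on the ideal superhelical track (entry: first
    wrapped bp; exit: last), varied by the sampled unwrapping deltas.
    """

    entry_k: float
    exit_k: float
    entry_vec: np.ndarray
    exit_vec: np.ndarray
    alpha_entry: float
    alpha_exit: float
    beta_entry: float
    beta_exit: float
    delta_entry: int
    delta_exit: int
    radius_A: float = UNIT_RADIUS_A

    @property
    def entry_origin(self) -> np.ndarray:
        return sh.path_points(self.entry_k)

    @property
    def exit_origin(self) -> np.ndarray:
        return sh.path_points(self.exit_k)


@dataclass
class FiberModel:
    """A chain of coarse NCP units with global frames."""

    units: list[CoarseNcpUnit]
    frames: list[NcpFrame]
    linker_bp: int
    rng_seed: int
    preset: str = ""

    @property
    def centers(self) -> np.ndarray:
        return np.array([f.origin for f in self.frames])

    @property
    def n_ncp(self) -> int:
        return len(self.units)


@dataclass(frozen=True)
class FiberMetrics:
    contour_length_nm: float
    width_nm: float
    persistence_nm: float
    gyration_radius_nm: float
    hydrodynamic_radius_nm: float
    density_per_nm3: float
    density_uM: float
    segment_length_nm: float
    n_ncp: int


def sample_unit(
    params: SyntheticParams,
    rng: np.random.Generator,
    sample_unwrap: bool = True,
) -> CoarseNcpUnit:
    """Draw one coarse NCP unit from the preset's angle/unwrap distributions.

    With ``sample_unwrap=False`` the arm origins are fixed at the rounded
    means of the unwrapping distributions (the "no breathing" variant);
    the angle distributions are sampled either way.
    """
    if sample_unwrap:
        d_en = params.delta_entry.sample(rng) if params.delta_entry else 0
        d_ex = params.delta_exit.sample(rng) if params.delta_exit else 0
    else:
        d_en = int(np.rint(params.delta_entry.mean_bp)) if params.delta_entry else 0
        d_ex = int(np.rint(params.delta_exit.mean_bp)) if params.delta_exit else 0
    a_en = float(params.alpha_entry.sample(rng))
    a_ex = float(params.alpha_exit.sample(rng))
    b_en = float(params.beta_entry.sample(rng))
    b_ex = float(params.beta_exit.sample(rng))
    entry_k = -d_en
    exit_k = 146 + d_ex
    return CoarseNcpUnit(
        entry_k=entry_k,
        exit_k=exit_k,
        entry_vec=arm_direction_local(entry_k, a_en, b_en, "entry"),
        exit_vec=arm_direction_local(exit_k, a_ex, b_ex, "exit"),
        alpha_entry=a_en,
        alpha_exit=a_ex,
        beta_entry=b_en,
        beta_exit=b_ex,
        delta_entry=int(d_en),
        delta_exit=int(d_ex),
    )


def _place_next(prev_frame: NcpFrame, prev_unit: CoarseNcpUnit, unit: CoarseNcpUnit,
                linker_bp: int, twist_scales_with_linker: bool) -> NcpFrame:
    """Rigid frame of the next unit: collinear arm join + left-handed twist."""
    R_prev = prev_frame.rotation
    exit_dir = R_prev @ prev_unit.exit_vec
    exit_point = R_prev @ prev_unit.exit_origin + prev_frame.origin
    gap_bp = linker_bp - prev_unit.delta_exit - unit.delta_entry
    q_target = exit_point + (gap_bp + 1) * sh.LINKER_RISE_A * exit_dir
    twist = LINKER_TWIST_DEG * (gap_bp / linker_bp if twist_scales_with_linker else 1.0)
    R_align = _align_rotation(unit.entry_vec, -exit_dir)
    R = _rotation_about(exit_dir, np.deg2rad(twist)) @ R_align
    t = q_target - R @ unit.entry_origin
    return NcpFrame(t, R[:, 0], R[:, 1], R[:, 2])


def build_fiber(
    params: SyntheticParams,
    n_ncp: int = 100,
    rng_seed: int = 0,
    sample_unwrap: bool = True,
    twist_scales_with_linker: bool = False,
    unit_source: Optional[Callable[[np.random.Generator], CoarseNcpUnit]] = None,
    retry_per_position: int = 100,
) -> FiberModel:
    """Sequentially assemble a clash-free fiber of ``n_ncp`` coarse units.

    Each placement failing the 100 A center-distance criterion is resampled
    (up to ``retry_per_position`` times), after which the previous unit is
    backtracked; the total attempt budget is 500 n.  Deterministic under
    ``rng_seed``.  ``unit_source`` overrides the unit sampler (used for
    controlled chain constructions).
    """
    if n_ncp < 2:
        raise InvalidArgumentError(f"n_ncp must be >= 2, got {n_ncp}")
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    draw = unit_source if unit_source is not None else (
        lambda r: sample_unit(params, r, sample_unwrap=sample_unwrap)
    )
    linker_bp = params.template.linker_bp if params is not None else 40

    units: list[CoarseNcpUnit] = [draw(rng)]
    frames: list[NcpFrame] = [NcpFrame.identity()]
    total_budget = 500 * n_ncp
    attempts = 0
    fails_here = 0
    while len(units) < n_ncp:
        if attempts >= total_budget:
            raise AssemblyError(
                f"fiber assembly exhausted its budget at {len(units)} units",
                reached=len(units),
            )
        attempts += 1
        unit = draw(rng)
        frame = _place_next(frames[-1], units[-1], unit, linker_bp, twist_scales_with_linker)
        centers = np.array([f.origin for f in frames])
        if len(centers) and (np.linalg.norm(centers - frame.origin, axis=1) < CLASH_DISTANCE_A).any():
            fails_here += 1
            if fails_here > retry_per_position and len(units) > 1:
                units.pop()
                frames.pop()
                fails_here = 0
            continue
        units.append(unit)
        frames.append(frame)
        fails_here = 0

    fiber = FiberModel(
        units=units,
        frames=frames,
        linker_bp=linker_bp,
        rng_seed=int(rng_seed),
        preset=params.name if params is not None else "",
    )
    d = fiber.centers
    dists = np.linalg.norm(d[:, None] - d[None, :], axis=-1)
    assert (dists[np.triu_indices(len(d), 1)] >= CLASH_DISTANCE_A).all()
    return fiber


# ---------------------------------------------------------------------------
# fiber geometry

def _smoothed_centerline(centers_nm: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average; windows shrink symmetrically at the ends so
    the smoothed line keeps the fiber's full span (endpoints unshifted)."""
    n = len(centers_nm)
    half = window // 2
    out = np.empty_like(centers_nm)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = centers_nm[i - h:i + h + 1].mean(axis=0)
    return out


def _point_polyline_distance(p: np.ndarray, line: np.ndarray) -> float:
    a = line[:-1]
    b = line[1:]
    ab = b - a
    tt = np.clip(np.einsum("ij,ij->i", p - a, ab) / np.einsum("ij,ij->i", ab, ab), 0, 1)
    proj = a + tt[:, None] * ab
    return float(np.linalg.norm(p - proj, axis=1).min())


def fiber_dimensions(fiber: FiberModel) -> tuple[float, float]:
    """(contour_length_nm, width_nm) of a fiber.

    Contour length is the arc length of the smoothed centerline (window-5
    moving average of NCP centers); width is twice the RMS transverse
    distance of the centers from that centerline plus the unit diameter.
    """
    if fiber.n_ncp < 5:
        raise TooShortError(f"need >= 5 units, got {fiber.n_ncp}")
    centers = fiber.centers / 10.0  # A -> nm
    line = _smoothed_centerline(centers)
    contour = float(np.linalg.norm(np.diff(line, axis=0), axis=1).sum())
    trans = np.array([_point_polyline_distance(c, line) for c in centers])
    radius_nm = fiber.units[0].radius_A / 10.0
    width = 2.0 * (float(np.sqrt((trans**2).mean())) + radius_nm)
    return contour, width


def _resample_polyline(line: np.ndarray, step: float) -> np.ndarray:
    """Points at fixed arc-length steps along a polyline."""
    seg = np.linalg.norm(np.diff(line, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(0.0, s[-1] + 1e-9, step)
    out = np.empty((len(targets), line.shape[1]))
    for d in range(line.shape[1]):
        out[:, d] = np.interp(targets, s, line[:, d])
    return out


def persistence_length(
    centerlines_nm, d_nm: float = SEGMENT_NM, cap_nm: float = PERSISTENCE_CAP_NM
) -> float:
    """Persistence length from the tangent autocorrelation of d-segments.

    The centerline (or an ensemble of centerlines, whose correlations are
    averaged) is resampled at fixed arc step d; <cos theta(s)> is fitted as
    exp(-s/P) by least squares on the log over the first decade of decay
    (lags with mean correlation above 0.1; non-positive correlations are
    excluded).  Effectively straight chains report the cap value.
    """
    if isinstance(centerlines_nm, np.ndarray) and centerlines_nm.ndim == 2:
        centerlines_nm = [centerlines_nm]
    corr_sums: dict[int, list[float]] = {}
    max_lag = 0
    for line in centerlines_nm:
        line = np.asarray(line, dtype=float)
        pts = _resample_polyline(line, d_nm)
        if len(pts) < 4:
            raise TooShortError("centerline shorter than 3 segments at the given step")
        tang = np.diff(pts, axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        n = len(tang)
        for lag in range(1, n):
            c = float(np.einsum("ij,ij->", tang[:-lag], tang[lag:]) / (n - lag))
            corr_sums.setdefault(lag, []).append(c)
        max_lag = max(max_lag, n - 1)

    lags, corrs = [], []
    for lag in range(1, max_lag + 1):
        if lag not in corr_sums:
            break
        c = float(np.mean(corr_sums[lag]))
        if c <= 0.1:  # first decade of decay only
            break
        lags.append(lag * d_nm)
        corrs.append(c)
    if not lags:
        raise TooShortError("no usable correlation lags")
    s = np.asarray(lags)
    ln_c = np.log(np.asarray(corrs))
    denom = float(np.dot(s, ln_c))
    if denom >= 0.0:
        return cap_nm
    p = float(-np.dot(s, s) / denom)
    return min(p, cap_nm)


def fiber_gyration_radius_nm(fiber: FiberModel) -> float:
    """Geometric radius of gyration of the NCP centers (nm)."""
    c = fiber.centers / 10.0
    return float(np.sqrt(((c - c.mean(axis=0)) ** 2).sum(axis=1).mean()))


def wlc_metrics(
    P_nm: float, contour_L_nm: float, n_ncp: int,
    width_nm: float = float("nan"), segment_length_nm: float = SEGMENT_NM,
) -> FiberMetrics:
    """Worm-like-chain summary of a fiber from its persistence and contour.

    R_g from the Benoit-Doty expression, R_h = 0.662 R_g, and NCP density
    n / ((4/3) pi R_g^3) in nm^-3 and micromolar.
    """
    if P_nm <= 0 or contour_L_nm <= 0 or n_ncp < 1:
        raise InvalidArgumentError("P, L must be positive and n_ncp >= 1")
    x = P_nm / contour_L_nm
    rg2 = (P_nm * contour_L_nm / 3.0) * (1.0 - x * (1.0 - np.exp(-1.0 / x)))
    rg = float(np.sqrt(rg2))
    vol_nm3 = (4.0 / 3.0) * np.pi * rg**3
    per_nm3 = n_ncp / vol_nm3
    uM = per_nm3 / AVOGADRO * 1e24 * 1e6  # nm^-3 -> mol/L -> uM
    return FiberMetrics(
        contour_length_nm=float(contour_L_nm),
        width_nm=float(width_nm),
        persistence_nm=float(P_nm),
        gyration_radius_nm=rg,
        hydrodynamic_radius_nm=RH_OVER_RG * rg,
        density_per_nm3=float(per_nm3),
        density_uM=float(uM),
        segment_length_nm=float(segment_length_nm),
        n_ncp=int(n_ncp),
    )
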