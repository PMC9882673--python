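"""Synthetic nucleosome-array generator.

Builds array models with prescribed angle/unwrapping statistics so that the
whole measurement pipeline can be exercised (and validated by parameter
recovery) without experimental data.  Each NCP is an ideal left-handed
superhelix (41.8 A radius, 25.0 A pitch, 1.7 turns per 147 bp) trimmed or
extended by sampled unwrapping deltas; arms and linkers are straight 3.4 A/bp
segments leaving the wrap in directions sampled from per-side wrapping (alpha)
and bending (beta) distributions; consecutive NCPs are connected across the
linker with a fixed 70 degree left-handed DNA twist; isotropic Gaussian noise
emulates model-fitting error.

The generating parameters (``SyntheticParams``) mirror the measured
statistics of the cryo-ET study conditions and are shipped as YAML presets:
``mono_5mM``, ``di_5mM``, ``tri_5mM``, ``tetra_5mM``, ``tetra_50mM``,
``tetra_H1``.  Every generated model carries a ``ground_truth`` block holding
the sampled angles, deltas and frames; measurement code never reads it.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import AssemblyError, InvalidArgumentError
from .model import ArrayModel, NcpFrame, NcpPlacement, TemplateSpec, build_template
from . import superhelix as sh

__all__ = [
    "MixtureSpec",
    "NormalSpec",
    "SyntheticParams",
    "generate_array",
    "generate_population",
    "preset_table",
    "load_preset",
]

#: hard-sphere clash threshold between NCP centers, A
CLASH_DISTANCE_A = 100.0
#: left-handed DNA twist across one 40-bp linker, degrees (negative = left-handed)
LINKER_TWIST_DEG = -70.0
#: sampled deltas are clamped to this range, bp
DELTA_RANGE_BP = (-100, 20)
#: minimum wrapped length kept when sampling deltas, bp
MIN_WRAP_BP = 45
#: minimum free-DNA gap between consecutive wraps, bp (one 20-bp arm per side
#: must fit on the linker for the arm vectors to be measurable)
MIN_GAP_BP = 20


@dataclass(frozen=True)
class MixtureSpec:
    """1- or 2-component Gaussian mixture over an angle (degrees)."""

    weights: tuple[float, ...]
    means: tuple[float, ...]
    stds: tuple[float, ...]

    def __post_init__(self):
        if not (len(self.weights) == len(self.means) == len(self.stds)):
            raise InvalidArgumentError("mixture: weights/means/stds length mismatch")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise InvalidArgumentError("mixture: weights must sum to 1")
        if any(s <= 0 for s in self.stds):
            raise InvalidArgumentError("mixture: stds must be positive")

    def sample(self, rng: np.random.Generator, size=None):
        comp = rng.choice(len(self.weights), p=self.weights, size=size)
        return rng.normal(np.asarray(self.means)[comp], np.asarray(self.stds)[comp])

    @property
    def mean(self) -> float:
        return float(np.dot(self.weights, self.means))

    def cdf(self, x):
        from scipy.stats import norm

        x = np.asarray(x, dtype=float)
        return sum(
            w * norm.cdf(x, m, s) for w, m, s in zip(self.weights, self.means, self.stds)
        )


@dataclass(frozen=True)
class NormalSpec:
    """Gaussian over an unwrapping delta (bp; negative = unwrapped)."""

    mean_bp: float
    std_bp: float

    def sample(self, rng: np.random.Generator) -> int:
        lo, hi = DELTA_RANGE_BP
        return int(np.clip(np.rint(rng.normal(self.mean_bp, self.std_bp)), lo, hi))


@dataclass(frozen=True)
class SyntheticParams:
    """Distributional ground truth for the generator.

    Alpha/beta distributions are per arm side; the study pools entry and exit
    samples, so presets use the same mixture for both sides.
    """

    template: TemplateSpec
    alpha_entry: MixtureSpec
    alpha_exit: MixtureSpec
    beta_entry: MixtureSpec
    beta_exit: MixtureSpec
    delta_entry: Optional[NormalSpec] = None
    delta_exit: Optional[NormalSpec] = None
    noise_sigma_A: float = 2.0
    ii2_distance_A: tuple[float, float] = (265.0, 30.0)
    name: str = ""
    defaults_filled: tuple[str, ...] = ()

    def __post_init__(self):
        if self.noise_sigma_A < 0:
            raise InvalidArgumentError("noise_sigma_A must be >= 0")


def _rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def _align_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a onto unit vector b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.cross(a, b)
    d = float(np.dot(a, b))
    if np.linalg.norm(c) < 1e-12:
        if d > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any axis perpendicular to a
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return _rotation_about(perp, np.pi)
    angle = np.arctan2(np.linalg.norm(c), d)
    return _rotation_about(c, angle)


def arm_direction_local(k: float, alpha_deg: float, beta_deg: float, side: str) -> np.ndarray:
    """Unit arm direction (pointing away from the NCP) in the local frame.

    The direction is built from the in-plane tangent of the wrap at track
    position ``k``: rotate it by the signed wrapping angle alpha about +Z
    (positive = radially outward), then tilt by the bending angle beta out of
    the discoidal plane (positive = toward +Z).
    """
    if side not in ("entry", "exit"):
        raise InvalidArgumentError(f"side must be 'entry' or 'exit', got {side!r}")
    p = sh.path_points(k)
    z = np.array([0.0, 0.0, 1.0])
    t_xy = sh.inplane_tangent(p, z, np.zeros(3), outgoing=(side == "exit"))
    sgn = 1.0 if side == "exit" else -1.0
    a = np.deg2rad(alpha_deg) * sgn
    b = np.deg2rad(beta_deg)
    u = _rotation_about(z, a) @ t_xy
    return np.cos(b) * u + np.sin(b) * z


def _sample_ncp_params(params: SyntheticParams, rng: np.random.Generator, n_ncp: int):
    """Sample per-NCP angles and deltas honoring the joint geometric bounds."""
    out = []
    for _ in range(n_ncp):
        for _attempt in range(1000):
            d_en = params.delta_entry.sample(rng) if params.delta_entry else 0
            d_ex = params.delta_exit.sample(rng) if params.delta_exit else 0
            if 147 + d_en + d_ex >= MIN_WRAP_BP:
                break
        else:
            raise AssemblyError("could not sample a viable wrap length")
        out.append(
            {
                "alpha_entry": float(params.alpha_entry.sample(rng)),
                "alpha_exit": float(params.alpha_exit.sample(rng)),
                "beta_entry": float(params.beta_entry.sample(rng)),
                "beta_exit": float(params.beta_exit.sample(rng)),
                "delta_entry": int(d_en),
                "delta_exit": int(d_ex),
            }
        )
    # enforce a measurable free-DNA gap at every junction
    linker = params.template.linker_bp
    for i in range(n_ncp - 1):
        for _attempt in range(1000):
            gap = linker - out[i]["delta_exit"] - out[i + 1]["delta_entry"]
            if gap >= MIN_GAP_BP:
                break
            out[i]["delta_exit"] = params.delta_exit.sample(rng) if params.delta_exit else 0
            out[i + 1]["delta_entry"] = (
                params.delta_entry.sample(rng) if params.delta_entry else 0
            )
        else:
            raise AssemblyError(f"could not sample a viable linker at junction {i}")
    return out


def _build_trace(params: SyntheticParams, samples: list[dict]):
    """Deterministically assemble the noise-free trace from sampled parameters.

    Returns (trace, frames) with one global rigid frame per NCP.
    """
    template = params.template
    trace = np.full((template.total_bp, 3), np.nan)
    frames: list[NcpFrame] = []
    intervals = template.nps_intervals
    n_ncp = template.n_ncp

    R = np.eye(3)
    T = np.zeros(3)
    prev_exit_point = None
    prev_exit_dir = None
    prev_actual_end = None

    for i in range(n_ncp):
        s = samples[i]
        ds, de = intervals[i]
        a_k = -s["delta_entry"]          # local track index of the first wrapped bp
        b_k = 147 + s["delta_exit"]      # one past the last wrapped bp
        actual_start = ds + a_k
        actual_end = ds + b_k

        e_loc = arm_direction_local(a_k, s["alpha_entry"], s["beta_entry"], "entry")
        x_loc = arm_direction_local(b_k - 1, s["alpha_exit"], s["beta_exit"], "exit")
        q_en_loc = sh.path_points(a_k)
        q_ex_loc = sh.path_points(b_k - 1)

        if i > 0:
            gap = actual_start - prev_actual_end
            q_target = prev_exit_point + (gap + 1) * sh.LINKER_RISE_A * prev_exit_dir
            R_align = _align_rotation(e_loc, -prev_exit_dir)
            R = _rotation_about(prev_exit_dir, np.deg2rad(LINKER_TWIST_DEG)) @ R_align
            T = q_target - R @ q_en_loc
            # linker bp between the two wraps, straight along the exit direction
            for j in range(prev_actual_end, actual_start):
                trace[j] = prev_exit_point + (
                    (j - (prev_actual_end - 1)) * sh.LINKER_RISE_A
                ) * prev_exit_dir

        ks = np.arange(a_k, b_k)
        trace[actual_start:actual_end] = sh.path_points(ks) @ R.T + T
        frames.append(NcpFrame(T.copy(), R[:, 0].copy(), R[:, 1].copy(), R[:, 2].copy()))

        entry_dir = R @ e_loc
        exit_dir = R @ x_loc
        entry_point = R @ q_en_loc + T
        exit_point = R @ q_ex_loc + T

        if i == 0:
            for j in range(0, actual_start):
                trace[j] = entry_point + (actual_start - j) * sh.LINKER_RISE_A * entry_dir
        if i == n_ncp - 1:
            for j in range(actual_end, template.total_bp):
                trace[j] = exit_point + (
                    (j - (actual_end - 1)) * sh.LINKER_RISE_A
                ) * exit_dir

        prev_exit_point = exit_point
        prev_exit_dir = exit_dir
        prev_actual_end = actual_end

    assert not np.isnan(trace).any()
    return trace, frames


def generate_array(
    params: SyntheticParams,
    rng_seed: int,
    label: str = "",
    max_retries: int = 50,
) -> ArrayModel:
    """Generate one array model (with ground truth) from ``params``.

    Models whose NCP centers clash (< 100 A apart) are resampled, as in the
    study's rejection scheme; persistent failure raises ``AssemblyError``.
    """
    root = np.random.SeedSequence(rng_seed)
    for child in root.spawn(max_retries):
        rng = np.random.default_rng(child)
        samples = _sample_ncp_params(params, rng, params.template.n_ncp)
        trace, frames = _build_trace(params, samples)
        centers = np.array([f.origin for f in frames])
        if len(centers) > 1:
            d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
            if (d[np.triu_indices(len(centers), 1)] < CLASH_DISTANCE_A).any():
                continue
        if params.noise_sigma_A > 0:
            trace = trace + rng.normal(0.0, params.noise_sigma_A, trace.shape)
        placements = []
        gt_ncps = []
        for i, (s, f) in enumerate(zip(samples, frames)):
            ds, de = params.template.nps_intervals[i]
            placements.append(
                NcpPlacement(
                    frame=f,
                    wrap_interval=(ds - s["delta_entry"], de + s["delta_exit"]),
                    delta_entry_bp=s["delta_entry"],
                    delta_exit_bp=s["delta_exit"],
                )
            )
            gt_ncps.append(
                dict(
                    s,
                    frame={
                        "origin": f.origin.tolist(),
                        "x": f.x_axis.tolist(),
                        "y": f.y_axis.tolist(),
                        "z": f.z_axis.tolist(),
                    },
                )
            )
        ground_truth = {
            "preset": params.name,
            "rng_seed": int(rng_seed),
            "noise_sigma_A": params.noise_sigma_A,
            "ncps": gt_ncps,
        }
        return ArrayModel(
            template=params.template,
            trace=trace,
            placements=placements,
            label=label or f"{params.name or 'synthetic'}-{rng_seed}",
            provenance="synthetic",
            ground_truth=ground_truth,
        )
    raise AssemblyError(f"generation failed after {max_retries} clash retries")


def generate_population(
    params: SyntheticParams, n: int, seed: int
) -> list[ArrayModel]:
    """Generate ``n`` independent models with seeds derived from ``seed``."""
    if n < 1:
        raise InvalidArgumentError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    return [
        generate_array(params, int(s), label=f"{params.name or 'synthetic'}-{i}")
        for i, s in enumerate(child_seeds)
    ]


# ---------------------------------------------------------------------------
# presets

def _mixture_from_dict(d: dict) -> MixtureSpec:
    return MixtureSpec(
        weights=tuple(d["weights"]),
        means=tuple(d["means_deg"]),
        stds=tuple(d["stds_deg"]),
    )


def params_from_dict(d: dict) -> SyntheticParams:
    t = d["template"]
    template = build_template(
        t["n_ncp"],
        t.get("entry_arm_bp", 200),
        t.get("exit_arm_bp", 100),
        t.get("linker_bp", 40),
    )
    alpha = _mixture_from_dict(d["alpha"])
    beta = _mixture_from_dict(d["beta"])
    ii2 = d.get("ii2_distance_A", {"mean": 265.0, "std": 30.0})
    return SyntheticParams(
        template=template,
        alpha_entry=alpha,
        alpha_exit=alpha,
        beta_entry=beta,
        beta_exit=beta,
        delta_entry=NormalSpec(d["delta_entry"]["mean_bp"], d["delta_entry"]["std_bp"]),
        delta_exit=NormalSpec(d["delta_exit"]["mean_bp"], d["delta_exit"]["std_bp"]),
        noise_sigma_A=d.get("noise_sigma_A", 2.0),
        ii2_distance_A=(ii2["mean"], ii2["std"]),
        name=d.get("name", ""),
        defaults_filled=tuple(d.get("defaults_filled", ())),
    )


def load_preset(name: str) -> SyntheticParams:
    """Load a named study-condition preset shipped with the package."""
    res = importlib.resources.files("nucarray").joinpath(f"presets/{name}.yaml")
    if not res.is_file():
        available = sorted(
            p.name[:-5]
            for p in importlib.resources.files("nucarray").joinpath("presets").iterdir()
            if p.name.endswith(".yaml")
        )
        raise InvalidArgumentError(f"unknown preset {name!r}; available: {available}")
    d = yaml.safe_load(res.read_text())
    d.setdefault("name", name)
    return params_from_dict(d)


def preset_table() -> dict[str, SyntheticParams]:
    """All shipped presets, keyed by name."""
    out = {}
    for p in sorted(
        importlib.resources.files("nucarray").joinpath("presets").iterdir(),
        key=lambda p: p.name,
    ):
        if p.name.endswith(".yaml"):
            out[p.name[:-5]] = load_preset(p.name[:-5])
    return out
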