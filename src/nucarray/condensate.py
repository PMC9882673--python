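"""Condensate density estimation and explicit fiber docking.

Two bracketing estimates of chromatin condensate density: "seamless
assembling" (fibers packed with no inter-fiber space, so the condensate
density equals the mean per-fiber density — an upper bound) and "random
docking" (fibers placed as rigid bodies at uniform random orientations and
positions inside a 200-nm sphere, rejected on envelope overlap — a lower
bound).  Fiber envelopes are unions of spheres at the NCP centers whose
radii are drawn as half the experimentally motivated i,i+2 center-distance
distribution, reflecting the equilibrium approach distance of NCPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import AssemblyError, InvalidArgumentError
from .fiber import AVOGADRO, FiberMetrics, FiberModel, UNIT_RADIUS_A

__all__ = [
    "CondensateModel",
    "DensityEstimate",
    "seamless_density",
    "random_dock",
    "condensate_concentration",
    "slab_crop",
]

DEFAULT_SPHERE_DIAMETER_NM = 200.0


@dataclass(frozen=True)
class DensityEstimate:
    mode: str  # "seamless" | "random_docking"
    value_uM: float
    bound: str  # "upper" | "lower"


@dataclass
class CondensateModel:
    """Rigid fiber placements inside a spherical volume."""

    placements: list[dict]  # {"fiber": index, "rotation": 3x3, "translation": 3}
    ncp_centers_nm: np.ndarray  # all placed NCP centers, nm
    envelope_radii_nm: np.ndarray
    sphere_diameter_nm: float = DEFAULT_SPHERE_DIAMETER_NM

    @property
    def total_ncp(self) -> int:
        return len(self.ncp_centers_nm)

    @property
    def concentration_uM(self) -> float:
        return condensate_concentration(self)


def _uM(n: int, volume_nm3: float) -> float:
    return n / volume_nm3 / AVOGADRO * 1e30


def seamless_density(fibers: Sequence[FiberMetrics]) -> DensityEstimate:
    """Upper-bound condensate density: the mean per-fiber NCP density."""
    fibers = list(fibers)
    if not fibers:
        raise InvalidArgumentError("empty fiber list")
    return DensityEstimate(
        mode="seamless",
        value_uM=float(np.mean([f.density_uM for f in fibers])),
        bound="upper",
    )


def random_dock(
    fibers: Sequence[FiberModel],
    sphere_diameter_nm: float = DEFAULT_SPHERE_DIAMETER_NM,
    spacing_nm: tuple[float, float] = (26.5, 3.0),
    rng_seed: int = 0,
    attempts_per_fiber: int = 1000,
) -> CondensateModel:
    """Sequentially dock rigid fibers into a sphere without envelope overlap.

    ``spacing_nm`` is the (mean, std) of the inter-NCP approach distance;
    each NCP's envelope radius is half a draw from it, clamped to at least
    the unit hard-sphere radius.  Docking stops at the first fiber that
    cannot be placed within the attempt budget; at least one fiber must fit.
    Deterministic under ``rng_seed``.
    """
    fibers = list(fibers)
    if not fibers:
        raise InvalidArgumentError("empty fiber list")
    if sphere_diameter_nm <= 0:
        raise InvalidArgumentError("sphere diameter must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    R_sph = sphere_diameter_nm / 2.0
    unit_radius_nm = UNIT_RADIUS_A / 10.0

    placed_centers: list[np.ndarray] = []
    placed_radii: list[np.ndarray] = []
    placements: list[dict] = []
    tree = None
    max_placed_radius = 0.0

    for idx, fiber in enumerate(fibers):
        centers = fiber.centers / 10.0  # nm, in the fiber frame
        centers = centers - centers.mean(axis=0)
        radii = np.maximum(
            0.5 * rng.normal(spacing_nm[0], spacing_nm[1], len(centers)), unit_radius_nm
        )
        placed = False
        for _ in range(attempts_per_fiber):
            rot = Rotation.random(rng=rng).as_matrix()
            pos = rng.uniform(-R_sph, R_sph, 3)
            if np.linalg.norm(pos) > R_sph:
                continue
            cand = centers @ rot.T + pos
            if (np.linalg.norm(cand, axis=1) > R_sph).any():
                continue
            if tree is not None:
                pairs = tree.query_ball_point(cand, r=radii.max() + max_placed_radius)
                all_centers = np.vstack(placed_centers)
                all_radii = np.concatenate(placed_radii)
                ok = True
                for ci, neigh in enumerate(pairs):
                    if not neigh:
                        continue
                    d = np.linalg.norm(all_centers[neigh] - cand[ci], axis=1)
                    if (d < all_radii[neigh] + radii[ci]).any():
                        ok = False
                        break
                if not ok:
                    continue
            placed_centers.append(cand)
            placed_radii.append(radii)
            placements.append({"fiber": idx, "rotation": rot, "translation": pos})
            tree = cKDTree(np.vstack(placed_centers))
            max_placed_radius = max(max_placed_radius, float(radii.max()))
            placed = True
            break
        if not placed:
            break

    if not placements:
        raise AssemblyError("no fiber could be docked into the sphere")
    return CondensateModel(
        placements=placements,
        ncp_centers_nm=np.vstack(placed_centers),
        envelope_radii_nm=np.concatenate(placed_radii),
        sphere_diameter_nm=sphere_diameter_nm,
    )


def condensate_concentration(model: CondensateModel) -> float:
    """NCP concentration of a condensate in micromolar (full sphere volume)."""
    vol = (4.0 / 3.0) * np.pi * (model.sphere_diameter_nm / 2.0) ** 3
    return _uM(model.total_ncp, vol)


def slab_crop(model: CondensateModel, z0_nm: float, thickness_nm: float = 25.0) -> CondensateModel:
    """Sub-model keeping only NCP centers with z in [z0, z0 + thickness)."""
    if thickness_nm <= 0:
        raise InvalidArgumentError("thickness must be positive")
    z = model.ncp_centers_nm[:, 2]
    keep = (z >= z0_nm) & (z < z0_nm + thickness_nm)
    return CondensateModel(
        placements=model.placements,
        ncp_centers_nm=model.ncp_centers_nm[keep],
        envelope_radii_nm=model.envelope_radii_nm[keep],
        sphere_diameter_nm=model.sphere_diameter_nm,
    )
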