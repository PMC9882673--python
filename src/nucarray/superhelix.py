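"""Idealized nucleosomal DNA superhelix.

The 147 bp of core DNA wrap ~1.7 left-handed turns around the histone
octamer.  The package idealizes that path as a left-handed circular helix of
radius 41.8 A and pitch 25.0 A, expressed in the canonical NCP frame:

* Z is the superhelical axis, oriented along the entry -> exit advance of the
  wrap (bp index increases 5' -> 3');
* Y points from the NCP center to the dyad base pair (the middle of the wrap);
* X = Y x Z completes a right-handed frame.

Base-pair ``k`` of a fully wrapped particle runs from 0 (entry) to 146 (exit)
with the dyad at k = 73.  The parametrization accepts any real ``k`` so the
same path describes partially unwrapped (k trimmed inwards) and over-wrapped
(k extended outwards) particles.
"""

from __future__ import annotations

import numpy as np

#: superhelix radius, A
RADIUS_A = 41.8
#: rise of the superhelix per full turn, A
PITCH_A = 25.0
#: number of left-handed turns over the canonical 147-bp wrap
TURNS = 1.7
#: canonical wrapped length, bp
WRAP_BP = 147
#: index of the dyad base pair within the canonical wrap
DYAD_K = 73
#: helical phase advance per wrapped bp (magnitude), radians
PHI_PER_BP = 2.0 * np.pi * TURNS / WRAP_BP
#: rise along the superhelical axis per wrapped bp, A
RISE_PER_BP = PITCH_A * TURNS / WRAP_BP
#: unwrapping angle equivalent of one bp, degrees (360 deg x 1.7 turns / 147 bp)
DEG_PER_BP = 360.0 * TURNS / WRAP_BP
#: contour rise per bp of free (linker/arm) DNA, A
LINKER_RISE_A = 3.4


def _phase(k):
    # left-handed: phase decreases as k (and z) increase
    return 0.5 * np.pi - PHI_PER_BP * (np.asarray(k, dtype=float) - DYAD_K)


def path_points(k) -> np.ndarray:
    """Coordinates of superhelix bp ``k`` (scalar or array) in the NCP frame."""
    k = np.asarray(k, dtype=float)
    phi = _phase(k)
    pts = np.stack(
        [
            RADIUS_A * np.cos(phi),
            RADIUS_A * np.sin(phi),
            RISE_PER_BP * (k - DYAD_K),
        ],
        axis=-1,
    )
    return pts


def path_tangents(k) -> np.ndarray:
    """Unit tangent d(path)/dk at bp ``k``, pointing along increasing k."""
    k = np.asarray(k, dtype=float)
    phi = _phase(k)
    t = np.stack(
        [
            RADIUS_A * PHI_PER_BP * np.sin(phi),
            -RADIUS_A * PHI_PER_BP * np.cos(phi),
            np.broadcast_to(RISE_PER_BP, phi.shape).copy(),
        ],
        axis=-1,
    )
    return t / np.linalg.norm(t, axis=-1, keepdims=True)


def inplane_tangent(point: np.ndarray, z_axis: np.ndarray, center: np.ndarray,
                    outgoing: bool) -> np.ndarray:
    """In-plane (XY) unit tangent of the left-handed wrap at ``point``.

    Derived from the frame alone: for a left-handed wrap viewed along +Z the
    path advances clockwise, so the in-plane tangent along increasing bp is
    ``-(z x r_hat)`` with ``r_hat`` the in-plane radial direction.  With
    ``outgoing=True`` the tangent points away from the particle along the exit
    arm continuation; with ``outgoing=False`` it points away along the entry
    arm continuation (i.e. along decreasing bp).
    """
    z = np.asarray(z_axis, dtype=float)
    r = np.asarray(point, dtype=float) - np.asarray(center, dtype=float)
    r_in = r - np.dot(r, z) * z
    nrm = np.linalg.norm(r_in)
    if nrm < 1e-9:
        raise ValueError("arm origin is on the superhelical axis")
    r_hat = r_in / nrm
    t = -np.cross(z, r_hat)
    return t if outgoing else -t
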