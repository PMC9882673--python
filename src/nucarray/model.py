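"""Nucleosome-array data model, template arithmetic and I/O.

An :class:`ArrayModel` is the central measurable object: a per-base-pair
trace of DNA helical centers (one 3D point per bp, A) attached to a declared
:class:`TemplateSpec`, plus one :class:`NcpPlacement` per designed 147-bp
positioning repeat.  Templates follow the study design: a 200-bp entry arm,
``n`` 147-bp positioning repeats separated by 40-bp linkers, and a 100-bp
exit arm.  bp indices are 0-based and increase 5'->3' from the entry arm;
intervals are half-open.

Models serialize to a JSON schema (``nucarray-model-1``) that round-trips
coordinates at full precision, and export to pseudo-atom PDB (one phosphorus
pseudo-atom per bp, one HETATM per NCP center) for visualization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidArgumentError, SchemaError

__all__ = [
    "TemplateSpec",
    "NcpFrame",
    "NcpPlacement",
    "ArrayModel",
    "build_template",
    "read_array_model",
    "write_array_model",
    "export_pseudo_pdb",
]

NPS_BP = 147  # length of one positioning repeat

#: sanity bounds on consecutive bp spacing in a trace, A
MIN_BP_STEP_A = 2.0
MAX_BP_STEP_A = 7.0


@dataclass(frozen=True)
class TemplateSpec:
    """Designed layout of an array: arms, positioning repeats and linkers."""

    n_ncp: int
    entry_arm_bp: int = 200
    exit_arm_bp: int = 100
    linker_bp: int = 40

    @property
    def nps_intervals(self) -> tuple[tuple[int, int], ...]:
        """Half-open (start, end) bp intervals of the designed 147-bp repeats."""
        out = []
        pos = self.entry_arm_bp
        for _ in range(self.n_ncp):
            out.append((pos, pos + NPS_BP))
            pos += NPS_BP + self.linker_bp
        return tuple(out)

    @property
    def total_bp(self) -> int:
        return (
            self.entry_arm_bp
            + self.n_ncp * NPS_BP
            + (self.n_ncp - 1) * self.linker_bp
            + self.exit_arm_bp
        )

    def to_dict(self) -> dict:
        return {
            "n_ncp": self.n_ncp,
            "entry_arm_bp": self.entry_arm_bp,
            "exit_arm_bp": self.exit_arm_bp,
            "linker_bp": self.linker_bp,
        }


def build_template(
    n_ncp: int,
    entry_arm_bp: int = 200,
    exit_arm_bp: int = 100,
    linker_bp: int = 40,
) -> TemplateSpec:
    """Build a :class:`TemplateSpec` with computed repeat intervals.

    ``build_template(1)`` gives the 447-bp mononucleosome template and
    ``build_template(4)`` the 1008-bp tetranucleosome template.
    """
    if not isinstance(n_ncp, (int, np.integer)) or n_ncp < 1:
        raise InvalidArgumentError(f"n_ncp must be a positive integer, got {n_ncp!r}")
    for name, v in (
        ("entry_arm_bp", entry_arm_bp),
        ("exit_arm_bp", exit_arm_bp),
        ("linker_bp", linker_bp),
    ):
        if not isinstance(v, (int, np.integer)) or v < 0:
            raise InvalidArgumentError(f"{name} must be a non-negative integer, got {v!r}")
    return TemplateSpec(int(n_ncp), int(entry_arm_bp), int(exit_arm_bp), int(linker_bp))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


@dataclass
class NcpFrame:
    """Orthonormal, right-handed NCP coordinate system.

    Z lies along the superhelical axis of the wrapped DNA (entry->exit
    advance), Y along the dyad axis, and X = Y x Z.  ``origin`` is the NCP
    center in A.
    """

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.x_axis = np.asarray(self.x_axis, dtype=float).reshape(3)
        self.y_axis = np.asarray(self.y_axis, dtype=float).reshape(3)
        self.z_axis = np.asarray(self.z_axis, dtype=float).reshape(3)
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise InvalidArgumentError("NcpFrame axes are not orthonormal")
        if not np.allclose(np.cross(self.y_axis, self.z_axis), self.x_axis, atol=1e-6):
            raise InvalidArgumentError("NcpFrame axes are not right-handed (x != y cross z)")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix with the frame axes as columns (local -> global)."""
        return np.stack([self.x_axis, self.y_axis, self.z_axis], axis=1)

    @classmethod
    def identity(cls) -> "NcpFrame":
        return cls(np.zeros(3), np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0]))

    def to_global(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float) @ self.rotation.T + self.origin

    def to_local(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=float) - self.origin) @ self.rotation

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "NcpFrame":
        """Frame after the rigid motion p -> R p + t."""
        R = np.asarray(R, dtype=float)
        t = np.asarray(t, dtype=float)
        return NcpFrame(R @ self.origin + t, R @ self.x_axis, R @ self.y_axis, R @ self.z_axis)


@dataclass
class NcpPlacement:
    """A detected (or generated) NCP on the trace.

    ``wrap_interval`` is the half-open bp interval of DNA in contact with the
    histone surface.  Deltas are signed offsets of the wrap boundaries against
    the designed repeat: negative = unwrapped ("breathing"), positive =
    over-wrapped.  ``present=False`` marks a repeat with no detectable NCP;
    such placements keep their template slot so repeat indices stay stable.
    """

    frame: Optional[NcpFrame]
    wrap_interval: Optional[tuple[int, int]]
    delta_entry_bp: int = 0
    delta_exit_bp: int = 0
    present: bool = True

    def __post_init__(self):
        if self.present:
            s, e = self.wrap_interval
            if e - s != NPS_BP + self.delta_entry_bp + self.delta_exit_bp:
                raise InvalidArgumentError(
                    "wrap_length_bp inconsistent with deltas: "
                    f"{e - s} != 147 + {self.delta_entry_bp} + {self.delta_exit_bp}"
                )
            for d in (self.delta_entry_bp, self.delta_exit_bp):
                if not (-NPS_BP <= d <= 53):
                    raise InvalidArgumentError(f"delta {d} outside [-147, 53]")

    @property
    def wrap_length_bp(self) -> int:
        if not self.present:
            return 0
        s, e = self.wrap_interval
        return e - s

    @classmethod
    def absent(cls) -> "NcpPlacement":
        return cls(frame=None, wrap_interval=None, present=False)


@dataclass
class ArrayModel:
    """A bp trace plus ordered NCP placements on a declared template."""

    template: TemplateSpec
    trace: np.ndarray
    placements: list[NcpPlacement] = field(default_factory=list)
    label: str = ""
    provenance: str = "synthetic"
    ground_truth: Optional[dict] = None

    def __post_init__(self):
        self.trace = np.asarray(self.trace, dtype=float)
        if self.trace.ndim != 2 or self.trace.shape[1] != 3:
            raise SchemaError("trace: expected an (n, 3) coordinate array")
        if self.trace.shape[0] != self.template.total_bp:
            raise SchemaError(
                f"trace: length {self.trace.shape[0]} != template total_bp "
                f"{self.template.total_bp}"
            )
        if self.provenance not in ("synthetic", "fitted"):
            raise SchemaError(f"provenance: must be 'synthetic' or 'fitted', got {self.provenance!r}")
        prev_end = None
        for p in self.placements:
            if not p.present:
                continue
            s, e = p.wrap_interval
            if prev_end is not None and s < prev_end:
                raise SchemaError("placements: wrap intervals overlap or are unordered")
            prev_end = e

    @property
    def n_present(self) -> int:
        return sum(p.present for p in self.placements)

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "ArrayModel":
        """A copy moved by the rigid motion p -> R p + t (ground truth dropped)."""
        R = np.asarray(R, dtype=float)
        t = np.asarray(t, dtype=float)
        placements = [
            replace(p, frame=p.frame.transformed(R, t)) if p.present else NcpPlacement.absent()
            for p in self.placements
        ]
        return ArrayModel(
            template=self.template,
            trace=self.trace @ R.T + t,
            placements=placements,
            label=self.label,
            provenance=self.provenance,
        )


# ---------------------------------------------------------------------------
# JSON schema I/O

SCHEMA_NAME = "nucarray-model-1"


def _frame_to_dict(f: NcpFrame) -> dict:
    return {
        "origin": f.origin.tolist(),
        "x": f.x_axis.tolist(),
        "y": f.y_axis.tolist(),
        "z": f.z_axis.tolist(),
    }


def _frame_from_dict(d: dict) -> NcpFrame:
    for key in ("origin", "x", "y", "z"):
        if key not in d:
            raise SchemaError(f"placements[].frame.{key}: missing")
    return NcpFrame(d["origin"], d["x"], d["y"], d["z"])


def model_to_dict(model: ArrayModel) -> dict:
    placements = []
    for p in model.placements:
        if not p.present:
            placements.append({"present": False})
        else:
            placements.append(
                {
                    "present": True,
                    "wrap_start_bp": p.wrap_interval[0],
                    "wrap_end_bp": p.wrap_interval[1],
                    "delta_entry_bp": p.delta_entry_bp,
                    "delta_exit_bp": p.delta_exit_bp,
                    "frame": _frame_to_dict(p.frame),
                }
            )
    d = {
        "schema": SCHEMA_NAME,
        "label": model.label,
        "provenance": model.provenance,
        "template": model.template.to_dict(),
        "trace": {"coords": model.trace.tolist()},
        "placements": placements,
    }
    if model.ground_truth is not None:
        d["ground_truth"] = model.ground_truth
    return d


def model_from_dict(d: dict) -> ArrayModel:
    if not isinstance(d, dict):
        raise SchemaError("document: expected a JSON object")
    for key in ("template", "trace", "placements", "provenance"):
        if key not in d:
            raise SchemaError(f"{key}: missing")
    t = d["template"]
    for key in ("n_ncp", "entry_arm_bp", "exit_arm_bp", "linker_bp"):
        if key not in t:
            raise SchemaError(f"template.{key}: missing")
    template = build_template(
        t["n_ncp"], t["entry_arm_bp"], t["exit_arm_bp"], t["linker_bp"]
    )
    if "coords" not in d["trace"]:
        raise SchemaError("trace.coords: missing")
    placements = []
    for i, p in enumerate(d["placements"]):
        if not p.get("present", True):
            placements.append(NcpPlacement.absent())
            continue
        for key in ("wrap_start_bp", "wrap_end_bp", "delta_entry_bp", "delta_exit_bp", "frame"):
            if key not in p:
                raise SchemaError(f"placements[{i}].{key}: missing")
        placements.append(
            NcpPlacement(
                frame=_frame_from_dict(p["frame"]),
                wrap_interval=(p["wrap_start_bp"], p["wrap_end_bp"]),
                delta_entry_bp=p["delta_entry_bp"],
                delta_exit_bp=p["delta_exit_bp"],
            )
        )
    try:
        return ArrayModel(
            template=template,
            trace=np.asarray(d["trace"]["coords"], dtype=float),
            placements=placements,
            label=d.get("label", ""),
            provenance=d["provenance"],
            ground_truth=d.get("ground_truth"),
        )
    except ValueError as exc:  # ragged coords etc.
        raise SchemaError(f"trace.coords: {exc}") from exc


def write_array_model(model: ArrayModel, path) -> Path:
    """Serialize ``model`` to JSON; ``read_array_model`` inverts it exactly."""
    path = Path(path)
    path.write_text(json.dumps(model_to_dict(model)))
    return path


def read_array_model(path) -> ArrayModel:
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise SchemaError(f"{path}: empty file")
    try:
        d = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    return model_from_dict(d)


# ---------------------------------------------------------------------------
# pseudo-atom PDB export

PDB_MAX_ATOMS = 99_999


def export_pseudo_pdb(model: ArrayModel, path) -> Path:
    """Export a model as a pseudo-atom PDB for visualization.

    One phosphorus pseudo-atom per bp on chain D (residue number = bp index
    + 1) and one HETATM per present NCP center on chain N.  Coordinates keep
    PDB precision (1e-3 A).
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_bp = model.trace.shape[0]
    centers = [p.frame.origin for p in model.placements if p.present]
    n_atoms = n_bp + len(centers)
    if n_atoms > PDB_MAX_ATOMS:
        raise InvalidArgumentError(
            f"{n_atoms} atoms exceed the PDB fixed-width limit of {PDB_MAX_ATOMS}"
        )

    atoms = struc.AtomArray(n_atoms)
    coords = np.vstack([model.trace] + ([np.asarray(centers)] if centers else []))
    atoms.coord = coords.astype(np.float32)
    atoms.chain_id = np.array(["D"] * n_bp + ["N"] * len(centers))
    atoms.res_id = np.array(
        list(range(1, n_bp + 1)) + list(range(1, len(centers) + 1))
    )
    atoms.res_name = np.array(["DBP"] * n_bp + ["NCP"] * len(centers))
    atoms.atom_name = np.array(["P"] * n_atoms)
    atoms.element = np.array(["P"] * n_atoms)
    atoms.hetero = np.array([False] * n_bp + [True] * len(centers))

    pdb = PDBFile()
    pdb.set_structure(atoms)
    path = Path(path)
    pdb.write(str(path))
    return path
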