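"""Gating-residue (dynamic paddle) dihedrals and pre-reactive state detection.

The paddle residues — Phe432 (φF) and Trp531 (φW) — rotate about their
Cα–Cβ axes to open and close the membrane-access channel.  φ is reported in
[0, 360); the gate is CLOSED around the crystallographic φF ≈ 65° (bin
[45°, 85°]) and OPEN around the φF ≈ 150–180° mode (bin [140°, 200°]),
INTERMEDIATE otherwise.  Bin edges are configurable.

A frame is "pre-reactive" (catalytically significant) when a configurable
set of geometric criteria is satisfied — by default a nucleophilic-attack
distance Ser241:Oγ–carbonyl C ≤ 4.0 Å, a Bürgi–Dunitz-like attack angle
Oγ···C=O in [75°, 115°], and two oxyanion-hole H-bond distances ≤ 3.5 Å.
These numeric defaults are this package's own choices and are expected to
be overridden per system.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .geometry import FrameCoordinates, Trajectory, dihedral_angles, select
from .occupancy import DistanceTriplet, RegionLabel

__all__ = [
    "GateState",
    "GateBins",
    "PaddleAngles",
    "AtomRef",
    "GeometricCriterion",
    "PrereactiveCriteria",
    "PolarPlotRecord",
    "default_prereactive_criteria",
    "compute_paddle_angles",
    "evaluate_prereactive",
    "evaluate_prereactive_series",
    "build_polar_records",
    "count_gate_transitions",
]


class GateState(str, Enum):
    OPEN = "OPEN"
    CLOSED = "CLOSED"
    INTERMEDIATE = "INTERMEDIATE"


@dataclass
class GateBins:
    closed: tuple[float, float] = (45.0, 85.0)
    open: tuple[float, float] = (140.0, 200.0)

    def classify(self, phi_deg: float) -> GateState:
        phi = float(phi_deg) % 360.0
        if self.closed[0] <= phi <= self.closed[1]:
            return GateState.CLOSED
        if self.open[0] <= phi <= self.open[1]:
            return GateState.OPEN
        return GateState.INTERMEDIATE


@dataclass(frozen=True)
class PaddleAngles:
    time: float
    phiF: float  # degrees, [0, 360)
    phiW: float
    gate: GateState


@dataclass(frozen=True)
class AtomRef:
    """'chain:resid:atomname' reference into the topology."""

    chain_id: str
    residue_id: int
    name: str

    @classmethod
    def parse(cls, text: str) -> "AtomRef":
        parts = text.split(":")
        if len(parts) != 3:
            raise ValueError(f"atom reference must be chain:resid:name, got {text!r}")
        return cls(parts[0], int(parts[1]), parts[2])

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.residue_id}:{self.name}"

    def resolve(self, topology) -> int:
        for i, a in enumerate(topology):
            if (
                a.chain_id == self.chain_id
                and a.residue_id == self.residue_id
                and a.name == self.name
            ):
                return i
        raise ValueError(f"atom {self} not found in topology")


@dataclass
class GeometricCriterion:
    """One distance/angle/dihedral bound contributing to the flag."""

    name: str
    kind: str  # distance | angle | dihedral
    atoms: tuple[AtomRef, ...]
    min: float | None = None
    max: float | None = None

    _NEEDED = {"distance": 2, "angle": 3, "dihedral": 4}

    def __post_init__(self) -> None:
        if self.kind not in self._NEEDED:
            raise ValueError(f"unknown criterion kind {self.kind!r}")
        if len(self.atoms) != self._NEEDED[self.kind]:
            raise ValueError(
                f"{self.kind} criterion needs {self._NEEDED[self.kind]} atoms"
            )
        if self.min is not None and self.max is not None and self.min >= self.max:
            raise ValueError("criterion min must be < max")

    def measure(self, positions: np.ndarray, indices: Sequence[int]) -> float:
        p = positions[list(indices)]
        if self.kind == "distance":
            return float(np.linalg.norm(p[1] - p[0]))
        if self.kind == "angle":
            v1 = p[0] - p[1]
            v2 = p[2] - p[1]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        return float(dihedral_angles(p[0], p[1], p[2], p[3], on_collinear="raise"))

    def passes(self, value: float) -> bool:
        if self.min is not None and value < self.min:
            return False
        if self.max is not None and value > self.max:
            return False
        return True


@dataclass
class PrereactiveCriteria:
    criteria: list[GeometricCriterion]
    combine: str = "all"  # all | any

    def __post_init__(self) -> None:
        if self.combine not in {"all", "any"}:
            raise ValueError("combine must be 'all' or 'any'")

    def resolve(self, topology) -> list[list[int]]:
        return [[ref.resolve(topology) for ref in c.atoms] for c in self.criteria]


def default_prereactive_criteria(
    chain_id: str = "A",
    substrate_resid: int = 701,
) -> PrereactiveCriteria:
    """Package-default near-attack geometry criteria (combine = all)."""
    c = chain_id
    sub = substrate_resid
    return PrereactiveCriteria(
        criteria=[
            GeometricCriterion(
                "attack_distance", "distance",
                (AtomRef(c, 241, "OG"), AtomRef(c, sub, "C")), max=4.0,
            ),
            GeometricCriterion(
                "attack_angle", "angle",
                (AtomRef(c, 241, "OG"), AtomRef(c, sub, "C"),
                 AtomRef(c, sub, "O")), min=75.0, max=115.0,
            ),
            GeometricCriterion(
                "oxyanion_hbond_239", "distance",
                (AtomRef(c, 239, "N"), AtomRef(c, sub, "O")), max=3.5,
            ),
            GeometricCriterion(
                "oxyanion_hbond_240", "distance",
                (AtomRef(c, 240, "N"), AtomRef(c, sub, "O")), max=3.5,
            ),
        ],
        combine="all",
    )


def compute_paddle_angles(
    trajectory: Trajectory,
    resF: tuple[str, int] = ("A", 432),
    resW: tuple[str, int] = ("A", 531),
    quadruple: tuple[str, str, str, str] = ("N", "CA", "CB", "CG"),
    bins: GateBins | None = None,
) -> list[PaddleAngles]:
    """φF/φW time series with the per-frame MA-gate state.

    The default quadruple N–Cα–Cβ–Cγ is the side-chain χ1 torsion about the
    Cα–Cβ axis; a C–Cα–Cβ–Cγ policy may be passed instead.
    """
    bins = bins or GateBins()

    def indices_for(res: tuple[str, int]) -> list[int]:
        chain, resid = res
        out = []
        for nm in quadruple:
            sel = select(trajectory.topology, chain_id=chain,
                         residue_id=resid, names=[nm])
            if len(sel) != 1:
                raise ValueError(
                    f"residue {chain}:{resid} missing atom {nm!r} "
                    f"(needed for the paddle torsion)"
                )
            out.append(int(sel.resolved_indices[0]))
        return out

    iF = indices_for(resF)
    iW = indices_for(resW)
    if trajectory.n_frames == 0:
        return []
    coords = trajectory.coordinates()
    phiF = dihedral_angles(coords[:, iF[0]], coords[:, iF[1]],
                           coords[:, iF[2]], coords[:, iF[3]]) % 360.0
    phiW = dihedral_angles(coords[:, iW[0]], coords[:, iW[1]],
                           coords[:, iW[2]], coords[:, iW[3]]) % 360.0
    times = trajectory.times
    return [
        PaddleAngles(float(times[i]), float(phiF[i]), float(phiW[i]),
                     bins.classify(phiF[i]))
        for i in range(trajectory.n_frames)
    ]


def evaluate_prereactive(
    frame: FrameCoordinates,
    criteria: PrereactiveCriteria,
    topology=None,
    resolved: list[list[int]] | None = None,
) -> tuple[bool, list[dict]]:
    """Evaluate the criteria on one frame.

    Returns the combined flag plus a per-criterion report of measured value
    and pass/fail.  ``resolved`` (from :meth:`PrereactiveCriteria.resolve`)
    avoids re-resolving atoms per frame.
    """
    if resolved is None:
        if topology is None:
            raise ValueError("either topology or resolved indices required")
        resolved = criteria.resolve(topology)
    report = []
    passes = []
    for crit, idx in zip(criteria.criteria, resolved):
        value = crit.measure(frame.positions, idx)
        ok = crit.passes(value)
        passes.append(ok)
        report.append(
            {"name": crit.name, "kind": crit.kind, "value": value,
             "min": crit.min, "max": crit.max, "passed": ok}
        )
    if not passes:
        flag = True
    elif criteria.combine == "all":
        flag = all(passes)
    else:
        flag = any(passes)
    return flag, report


def evaluate_prereactive_series(
    trajectory: Trajectory, criteria: PrereactiveCriteria
) -> np.ndarray:
    """Boolean pre-reactive flag per frame."""
    resolved = criteria.resolve(trajectory.topology)
    flags = np.zeros(trajectory.n_frames, dtype=bool)
    for i, frame in enumerate(trajectory.frames):
        flags[i], _ = evaluate_prereactive(frame, criteria, resolved=resolved)
    return flags


@dataclass(frozen=True)
class PolarPlotRecord:
    """(region, pocket distance, φF, φW) for one pre-reactive frame."""

    region: str  # MA | T | AB
    radius: float  # the matching pocket distance, Å
    phiF: float
    phiW: float


def build_polar_records(
    labels: Sequence[RegionLabel],
    triplets: Sequence[DistanceTriplet],
    paddle: Sequence[PaddleAngles],
    flags: Sequence[bool],
) -> list[PolarPlotRecord]:
    """One record per pre-reactive frame located in MA, T, or AB.

    The radius is the distance matching the frame's label (d-MA, d-T or
    d-AB), pairing the paddle angles with the substrate position as in the
    polar φ-versus-distance analysis.
    """
    n = len(labels)
    if not (len(triplets) == len(paddle) == len(flags) == n):
        raise ValueError("labels, triplets, paddle and flags must be frame-aligned")
    radius_of = {
        RegionLabel.MA: lambda t: t.dMA,
        RegionLabel.T: lambda t: t.dT,
        RegionLabel.AB: lambda t: t.dAB,
    }
    records = []
    for lab, trip, pad, fl in zip(labels, triplets, paddle, flags):
        if fl and lab in radius_of:
            records.append(
                PolarPlotRecord(lab.value, radius_of[lab](trip), pad.phiF, pad.phiW)
            )
    return records


def count_gate_transitions(
    paddle: Sequence[PaddleAngles | GateState],
    min_dwell: int = 1,
) -> dict[str, int]:
    """Count CLOSED→OPEN and OPEN→CLOSED gate flips.

    A flip is committed once the destination bin has been occupied for
    *min_dwell* consecutive (non-INTERMEDIATE) frames; INTERMEDIATE frames
    neither advance nor reset the pending transition.
    """
    if min_dwell < 1:
        raise ValueError("min_dwell must be >= 1")
    gates = [p.gate if isinstance(p, PaddleAngles) else p for p in paddle]
    events = {"CLOSED_to_OPEN": 0, "OPEN_to_CLOSED": 0}
    qualified: GateState | None = None
    cand: GateState | None = None
    cand_count = 0
    for g in gates:
        if g == GateState.INTERMEDIATE:
            continue
        if g == cand:
            cand_count += 1
        else:
            cand = g
            cand_count = 1
        if cand_count >= min_dwell:
            if qualified is not None and cand != qualified:
                key = (
                    "CLOSED_to_OPEN"
                    if qualified == GateState.CLOSED
                    else "OPEN_to_CLOSED"
                )
                events[key] += 1
            qualified = cand
    return events
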