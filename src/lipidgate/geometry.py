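"""Atom/coordinate data model and elementary geometric primitives.

Distances are in Å, times in ns, angles in degrees throughout the package.
Coordinates are used as stored — no periodic-boundary re-imaging is done, so
trajectories must be unwrapped (ligand whole, protein whole) before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ATOMIC_MASSES",
    "AtomRecord",
    "FrameCoordinates",
    "Trajectory",
    "AtomSelection",
    "select",
    "center_of_mass",
    "group_min_distance",
    "dihedral_angle",
    "dihedral_angles",
    "end_to_end_distance",
    "contour_length",
    "mass_for_element",
]

#: Standard atomic weights (amu) for the elements that occur in protein/lipid
#: heavy-atom work plus hydrogen; config may override per atom.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "F": 18.998,
    "CL": 35.45,
    "NA": 22.990,
    "K": 39.098,
    "MG": 24.305,
    "CA": 40.078,
    "ZN": 65.38,
    "FE": 55.845,
    "SE": 78.971,
}


def mass_for_element(element: str) -> float:
    """Standard atomic weight for *element* (case-insensitive symbol)."""
    try:
        return ATOMIC_MASSES[element.strip().upper()]
    except KeyError:
        raise KeyError(f"no default mass for element {element!r}") from None


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology.

    ``residue_id`` is 1-based, as written in the source PDB.
    """

    serial: int
    name: str
    residue_name: str
    residue_id: int
    chain_id: str
    element: str
    mass: float

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(
                f"atom {self.chain_id}:{self.residue_id}:{self.name} has "
                f"non-positive mass {self.mass}"
            )


@dataclass
class FrameCoordinates:
    """Coordinates of every topology atom at one stored time point."""

    time: float  # ns
    positions: np.ndarray  # (n_atoms, 3) Å

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n_atoms, 3) array")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinate in frame")


@dataclass
class Trajectory:
    """A topology plus a time-ordered sequence of coordinate frames."""

    topology: list[AtomRecord]
    frames: list[FrameCoordinates]
    frame_interval: float = 0.01  # ns between stored frames

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        n = len(self.topology)
        for i, fr in enumerate(self.frames):
            if fr.positions.shape[0] != n:
                raise ValueError(
                    f"frame {i} has {fr.positions.shape[0]} atoms, "
                    f"topology has {n}"
                )
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames], dtype=float)

    def coordinates(self) -> np.ndarray:
        """All coordinates stacked as an (n_frames, n_atoms, 3) array."""
        if not self.frames:
            return np.empty((0, self.n_atoms, 3))
        return np.stack([fr.positions for fr in self.frames])


@dataclass
class AtomSelection:
    """An ordered, duplicate-free set of topology indices with their masses."""

    resolved_indices: np.ndarray
    masses: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.resolved_indices = np.asarray(self.resolved_indices, dtype=int)
        self.masses = np.asarray(self.masses, dtype=float)
        if len(set(self.resolved_indices.tolist())) != len(self.resolved_indices):
            raise ValueError(f"duplicate indices in selection {self.label!r}")
        if self.resolved_indices.size != self.masses.size:
            raise ValueError("indices and masses length mismatch")

    def __len__(self) -> int:
        return int(self.resolved_indices.size)


def select(
    topology: Sequence[AtomRecord],
    chain_id: str | None = None,
    residue_id: int | Iterable[int] | None = None,
    residue_name: str | None = None,
    names: Iterable[str] | None = None,
    label: str = "",
) -> AtomSelection:
    """Resolve predicate filters into an :class:`AtomSelection`.

    When ``names`` is given the selection is ordered by the name list (the
    declared chain order); otherwise topology order is kept.
    """
    resids = None
    if residue_id is not None:
        resids = {residue_id} if isinstance(residue_id, int) else set(residue_id)
    name_list = list(names) if names is not None else None

    def matches(a: AtomRecord) -> bool:
        if chain_id is not None and a.chain_id != chain_id:
            return False
        if resids is not None and a.residue_id not in resids:
            return False
        if residue_name is not None and a.residue_name != residue_name:
            return False
        if name_list is not None and a.name not in name_list:
            return False
        return True

    hits = [(i, a) for i, a in enumerate(topology) if matches(a)]
    if name_list is not None:
        order = {n: k for k, n in enumerate(name_list)}
        hits.sort(key=lambda ia: (order[ia[1].name], ia[0]))
    idx = np.array([i for i, _ in hits], dtype=int)
    masses = np.array([a.mass for _, a in hits], dtype=float)
    return AtomSelection(idx, masses, label=label)


def center_of_mass(selection: AtomSelection, frame: FrameCoordinates) -> np.ndarray:
    """Mass-weighted mean position of the selected atoms, in Å."""
    if len(selection) == 0:
        raise ValueError("empty selection")
    pos = frame.positions[selection.resolved_indices]
    m = selection.masses
    return (pos * m[:, None]).sum(axis=0) / m.sum()


def group_min_distance(
    probe: AtomSelection,
    residues: Sequence[AtomSelection],
    frame: FrameCoordinates,
    mode: str = "com_per_residue",
) -> float:
    """Minimum distance between *probe* and a group of residue selections.

    ``com_per_residue`` (default): min over residues of the distance between
    the probe COM and each residue COM — the prose definition of the pocket
    distances.  ``atom_pair``: minimum interatomic distance over all
    probe-atom × residue-atom pairs (the g_mindist convention).
    """
    if len(residues) == 0:
        raise ValueError("empty residue list")
    if len(probe) == 0:
        raise ValueError("empty selection")
    if mode == "com_per_residue":
        pc = center_of_mass(probe, frame)
        best = np.inf
        for res in residues:
            d = float(np.linalg.norm(center_of_mass(res, frame) - pc))
            best = min(best, d)
        return best
    if mode == "atom_pair":
        ppos = frame.positions[probe.resolved_indices]
        best = np.inf
        for res in residues:
            if len(res) == 0:
                raise ValueError("empty selection")
            rpos = frame.positions[res.resolved_indices]
            d = np.linalg.norm(ppos[:, None, :] - rpos[None, :, :], axis=-1)
            best = min(best, float(d.min()))
        return best
    raise ValueError(f"unknown mode {mode!r}")


_COLLINEAR_TOL = 1e-10


def dihedral_angles(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    p4: np.ndarray,
    on_collinear: str = "nan",
) -> np.ndarray:
    """Vectorised torsion angle over stacked point arrays of shape (..., 3).

    Returns degrees in (−180, 180] with the IUPAC sign convention (looking
    from p2 to p3, clockwise rotation of the far bond is positive; cis = 0°,
    trans = 180°).  Windows with a collinear triple yield NaN
    (``on_collinear="nan"``) or raise (``"raise"``).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    bad = (np.linalg.norm(n1, axis=-1) < _COLLINEAR_TOL) | (
        np.linalg.norm(n2, axis=-1) < _COLLINEAR_TOL
    )
    if np.any(bad):
        if on_collinear == "raise":
            raise ValueError("undefined torsion: collinear triple")
    y = np.einsum("...i,...i->...", n1, b3) * np.linalg.norm(b2, axis=-1)
    x = np.einsum("...i,...i->...", n1, n2)
    ang = np.degrees(np.arctan2(y, x))
    # atan2 maps the anti case to ±180; fold onto (−180, 180]
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    ang = np.where(bad, np.nan, ang)
    return ang


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Torsion angle of four points, degrees in (−180, 180] (IUPAC sign)."""
    return float(dihedral_angles(p1, p2, p3, p4, on_collinear="raise"))


def end_to_end_distance(chain: AtomSelection, frame: FrameCoordinates) -> float:
    """Distance between the first and last atoms of the declared chain, Å."""
    if len(chain) < 2:
        raise ValueError("chain needs at least 2 atoms")
    pos = frame.positions[chain.resolved_indices]
    return float(np.linalg.norm(pos[-1] - pos[0]))


def contour_length(chain: AtomSelection, frame: FrameCoordinates) -> float:
    """Sum of consecutive bond-vector norms along the chain, Å."""
    if len(chain) < 2:
        raise ValueError("chain needs at least 2 atoms")
    pos = frame.positions[chain.resolved_indices]
    return float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())


def place_fourth_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float,
    torsion_deg: float,
) -> np.ndarray:
    """Position d such that |c−d| = bond, ∠(b,c,d) = angle and the torsion
    a–b–c–d equals *torsion_deg* (natural extension reference frame).

    Used by the synthetic generator to realise prescribed internal coordinates.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
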