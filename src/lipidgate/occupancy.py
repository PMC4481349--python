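"""Pocket occupancy: per-frame d-MA/d-AB/d-T distances and region labels.

The substrate's acyl-chain terminus (by default the COM of the last three
heavy atoms) is tracked against three residue groups lining the
membrane-access (MA) channel, the acyl-chain-binding (AB) channel, and the
MA/AB interface (transition, T) region.  Labels follow strict-inequality
cutoff rules: MA if d-MA < 6 Å and d-AB > 6 Å; AB if d-MA > 6 Å and
d-AB < 6 Å; else T if d-T < 5 Å; frames far from all three groups are
not-bound (NB); anything left is UNASSIGNED.  The 6/6/5 Å defaults reflect
the ~16/17 Å MA–AB center separation: ~6 Å of channel on either side and a
~4–5 Å interface between them.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .geometry import AtomSelection, Trajectory, select

__all__ = [
    "RegionDefinition",
    "DistanceTriplet",
    "RegionLabel",
    "default_regions",
    "compute_distance_series",
    "classify_region",
    "label_trajectory",
    "detect_unbinding",
    "DEFAULT_NB_THRESHOLD",
    "DEFAULT_MIN_DWELL",
]

#: NB is declared when the tail is farther than this from all three groups.
#: Not pinned by the channel geometry itself; ~the channel length scale.
DEFAULT_NB_THRESHOLD = 12.0
#: Frames an NB run must last to count as an unbinding episode (flicker guard).
DEFAULT_MIN_DWELL = 10


class RegionLabel(str, Enum):
    MA = "MA"
    AB = "AB"
    T = "T"
    NB = "NB"
    UNASSIGNED = "UNASSIGNED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class RegionDefinition:
    """A named pocket: lining residues plus the distance cutoff in Å."""

    name: str
    residues: list[tuple[int, str]]  # (residue_id, residue_name)
    cutoff: float

    def __post_init__(self) -> None:
        if self.name not in {"MA", "AB", "T"}:
            raise ValueError(f"region name must be MA/AB/T, got {self.name!r}")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")


def default_regions() -> dict[str, RegionDefinition]:
    """The default pocket definitions for the FAAH binding site."""
    return {
        "MA": RegionDefinition(
            "MA",
            [(403, "ASP"), (407, "ILE"), (486, "ARG"), (530, "ILE")],
            cutoff=6.0,
        ),
        "AB": RegionDefinition(
            "AB",
            [(335, "TYR"), (373, "GLU"), (428, "ARG"), (527, "PHE")],
            cutoff=6.0,
        ),
        "T": RegionDefinition(
            "T",
            [(381, "PHE"), (432, "PHE"), (531, "TRP")],
            cutoff=5.0,
        ),
    }


@dataclass(frozen=True)
class DistanceTriplet:
    """Per-frame minimum distances to the MA, AB and T residue groups (Å)."""

    time: float
    dMA: float
    dAB: float
    dT: float

    def __post_init__(self) -> None:
        for nm in ("dMA", "dAB", "dT"):
            v = getattr(self, nm)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{nm} must be finite and >= 0, got {v}")


def _resolve_region(
    topology,
    region: RegionDefinition,
    chain_id: str,
) -> list[AtomSelection]:
    sels = []
    for resid, resname in region.residues:
        sel = select(topology, chain_id=chain_id, residue_id=resid,
                     label=f"{chain_id}:{resid}")
        if len(sel) == 0:
            raise ValueError(
                f"region {region.name}: residue {chain_id}:{resid} "
                f"({resname}) not found in topology"
            )
        sels.append(sel)
    return sels


def compute_distance_series(
    trajectory: Trajectory,
    tail: AtomSelection,
    regions: dict[str, RegionDefinition],
    chain_id: str = "A",
    mode: str = "com_per_residue",
) -> list[DistanceTriplet]:
    """One :class:`DistanceTriplet` per frame for the given tail selection.

    ``mode`` selects COM-per-residue distances (default, the prose
    definition) or all-atom-pair minima (the g_mindist convention).
    """
    if len(tail) == 0:
        raise ValueError("empty selection")
    region_sels = {
        name: _resolve_region(trajectory.topology, regions[name], chain_id)
        for name in ("MA", "AB", "T")
    }
    if trajectory.n_frames == 0:
        return []

    coords = trajectory.coordinates()  # (F, N, 3)
    times = trajectory.times
    tail_m = tail.masses
    tail_pos = coords[:, tail.resolved_indices, :]
    tail_com = (tail_pos * tail_m[None, :, None]).sum(axis=1) / tail_m.sum()

    dmin: dict[str, np.ndarray] = {}
    for name, sels in region_sels.items():
        per_res = []
        for res in sels:
            rpos = coords[:, res.resolved_indices, :]
            if mode == "com_per_residue":
                m = res.masses
                rcom = (rpos * m[None, :, None]).sum(axis=1) / m.sum()
                per_res.append(np.linalg.norm(rcom - tail_com, axis=1))
            elif mode == "atom_pair":
                d = np.linalg.norm(
                    tail_pos[:, :, None, :] - rpos[:, None, :, :], axis=-1
                )
                per_res.append(d.min(axis=(1, 2)))
            else:
                raise ValueError(f"unknown mode {mode!r}")
        dmin[name] = np.min(per_res, axis=0)

    return [
        DistanceTriplet(float(times[i]), float(dmin["MA"][i]),
                        float(dmin["AB"][i]), float(dmin["T"][i]))
        for i in range(trajectory.n_frames)
    ]


def classify_region(
    t: DistanceTriplet,
    regions: dict[str, RegionDefinition],
    nb_threshold: float = DEFAULT_NB_THRESHOLD,
) -> RegionLabel:
    """Assign one region label to a distance triplet.

    Rule order: NB first (all three distances beyond *nb_threshold*), then
    the MA and AB cutoff rules, then T, else UNASSIGNED.  All inequalities
    are strict; equality with a cutoff fails that condition.
    """
    c_ma = regions["MA"].cutoff
    c_ab = regions["AB"].cutoff
    c_t = regions["T"].cutoff
    if nb_threshold <= max(c_ma, c_ab, c_t):
        raise ValueError("nb_threshold must exceed every region cutoff")
    if min(t.dMA, t.dAB, t.dT) > nb_threshold:
        return RegionLabel.NB
    if t.dMA < c_ma and t.dAB > c_ab:
        return RegionLabel.MA
    if t.dMA > c_ma and t.dAB < c_ab:
        return RegionLabel.AB
    if t.dT < c_t:
        return RegionLabel.T
    return RegionLabel.UNASSIGNED


def label_trajectory(
    series: Sequence[DistanceTriplet],
    regions: dict[str, RegionDefinition],
    nb_threshold: float = DEFAULT_NB_THRESHOLD,
) -> list[RegionLabel]:
    """Element-wise :func:`classify_region` over a distance series."""
    return [classify_region(t, regions, nb_threshold) for t in series]


def detect_unbinding(
    labels: Sequence[RegionLabel],
    min_dwell: int = DEFAULT_MIN_DWELL,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Maximal NB runs, split into unbinding episodes and transient excursions.

    Returns ``(episodes, excursions)``: inclusive 0-based ``(start, end)``
    frame spans of NB runs with length >= *min_dwell*, and the shorter runs.
    """
    if min_dwell < 1:
        raise ValueError("min_dwell must be >= 1")
    episodes: list[tuple[int, int]] = []
    excursions: list[tuple[int, int]] = []
    start = None
    for i, lab in enumerate(labels):
        if lab == RegionLabel.NB:
            if start is None:
                start = i
        else:
            if start is not None:
                run = (start, i - 1)
                (episodes if i - start >= min_dwell else excursions).append(run)
                start = None
    if start is not None:
        run = (start, len(labels) - 1)
        (episodes if len(labels) - start >= min_dwell else excursions).append(run)
    return episodes, excursions
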