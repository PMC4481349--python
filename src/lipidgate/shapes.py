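"""Acyl-chain conformational taxonomy (Applegate–Glomset style).

Per-frame torsion profiles along the declared chain path are mapped onto the
coarse shapes *elongated* / *hooked* / *curved* and, for unsaturated chains,
onto the fine classes Ex, Uex (elongated), J, J' (hooked), U, Hx, Hx-A,
Hx-B (curved).  Saturated chains carry no torsion signature that separates
the fine classes, so an end-to-end-length policy is provided as a fallback:
it uses only the ratio of end-to-end to contour length and the location of
the largest bend.

The torsion-state thresholds (trans |ω| ≥ 150°, gauche 30° ≤ |ω| < 90°,
cis |ω| < 30°) and the block-position rules are this package's own
configurable defaults, chosen so the fine classes are mutually exclusive
and exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .geometry import (
    AtomSelection,
    FrameCoordinates,
    Trajectory,
    contour_length,
    dihedral_angles,
    end_to_end_distance,
)

__all__ = [
    "TorsionProfile",
    "ShapeDescriptors",
    "FineShape",
    "CoarseShape",
    "ShapeClass",
    "ShapeThresholds",
    "ShapeClassificationError",
    "FINE_TO_COARSE",
    "compute_torsion_profile",
    "compute_shape_descriptors",
    "classify_shape",
    "shape_time_series",
]


class CoarseShape(str, Enum):
    ELONGATED = "elongated"
    HOOKED = "hooked"
    CURVED = "curved"


class FineShape(str, Enum):
    EX = "Ex"
    UEX = "Uex"
    J = "J"
    JP = "Jp"
    U = "U"
    HX = "Hx"
    HXA = "HxA"
    HXB = "HxB"
    NA = "NA"  # fine classification disabled (end-to-end fallback)


#: Fixed, total fine→coarse map.  NA is handled by the fallback policy.
FINE_TO_COARSE: dict[FineShape, CoarseShape] = {
    FineShape.EX: CoarseShape.ELONGATED,
    FineShape.UEX: CoarseShape.ELONGATED,
    FineShape.J: CoarseShape.HOOKED,
    FineShape.JP: CoarseShape.HOOKED,
    FineShape.U: CoarseShape.CURVED,
    FineShape.HX: CoarseShape.CURVED,
    FineShape.HXA: CoarseShape.CURVED,
    FineShape.HXB: CoarseShape.CURVED,
}


@dataclass(frozen=True)
class ShapeClass:
    coarse: CoarseShape
    fine: FineShape

    def __post_init__(self) -> None:
        if self.fine is not FineShape.NA and FINE_TO_COARSE[self.fine] != self.coarse:
            raise ValueError(f"fine {self.fine} does not map to coarse {self.coarse}")


@dataclass
class TorsionProfile:
    """Ordered torsions ω (degrees, (−180, 180]) along the chain path.

    ``omegas`` holds NaN where a window was geometrically degenerate
    (collinear triple); those entries are counted as missing.
    """

    time: float
    omegas: np.ndarray

    def __post_init__(self) -> None:
        self.omegas = np.asarray(self.omegas, dtype=float)
        valid = self.omegas[np.isfinite(self.omegas)]
        if np.any(valid <= -180) or np.any(valid > 180):
            raise ValueError("torsions must lie in (-180, 180]")

    @property
    def missing_fraction(self) -> float:
        if self.omegas.size == 0:
            return 0.0
        return float(np.mean(~np.isfinite(self.omegas)))


@dataclass
class ShapeDescriptors:
    """Coordinate-level descriptors used by the end-to-end fallback policy."""

    r: float  # end-to-end / contour length, in [0, 1]
    max_bend_deg: float
    bend_position: float  # fractional position of the largest bend, [0, 1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 1.0 + 1e-9:
            raise ValueError(f"r out of [0,1]: {self.r}")
        if not 0.0 <= self.bend_position <= 1.0:
            raise ValueError("bend_position out of [0,1]")


@dataclass
class ShapeThresholds:
    """Configurable boundaries of the taxonomy."""

    trans_min_deg: float = 150.0
    gauche_max_deg: float = 90.0
    cis_max_deg: float = 30.0
    r_elongated: float = 0.75
    terminal_bend_frac: float = 0.35  # hooked if bend within this of either end
    terminal_third: float = 1.0 / 3.0
    max_missing_fraction: float = 0.20


class ShapeClassificationError(ValueError):
    """Raised when a profile is too degenerate to classify."""


def compute_torsion_profile(
    chain: AtomSelection, frame: FrameCoordinates
) -> TorsionProfile:
    """ω_i over every sliding 4-atom window (i, i+1, i+2, i+3) of the chain."""
    if len(chain) < 4:
        raise ValueError("chain needs at least 4 atoms for torsions")
    pos = frame.positions[chain.resolved_indices]
    om = dihedral_angles(pos[:-3], pos[1:-2], pos[2:-1], pos[3:], on_collinear="nan")
    return TorsionProfile(frame.time, np.atleast_1d(om))


def compute_shape_descriptors(
    chain: AtomSelection,
    frame: FrameCoordinates,
    segment_len: int = 4,
) -> ShapeDescriptors:
    """Length ratio and largest inter-segment bend of the chain.

    The chain is cut into non-overlapping windows of *segment_len* atoms;
    each window's direction is the vector from its first to its last atom,
    and bends are angles between successive directions.
    """
    n = len(chain)
    if n < 2 * segment_len:
        raise ValueError("chain too short for the requested segment length")
    pos = frame.positions[chain.resolved_indices]
    e2e = end_to_end_distance(chain, frame)
    contour = contour_length(chain, frame)
    r = min(e2e / contour, 1.0) if contour > 0 else 0.0

    n_seg = n // segment_len
    starts = np.arange(n_seg) * segment_len
    ends = starts + segment_len - 1
    dirs = pos[ends] - pos[starts]
    norms = np.linalg.norm(dirs, axis=1)
    dirs = dirs / np.where(norms > 0, norms, 1.0)[:, None]
    cosb = np.clip(np.einsum("ij,ij->i", dirs[:-1], dirs[1:]), -1.0, 1.0)
    bends = np.degrees(np.arccos(cosb))
    k = int(np.argmax(bends))
    max_bend = float(bends[k])
    # the bend sits at the boundary between segments k and k+1
    boundary_atom = ends[k] + (starts[k + 1] - ends[k]) / 2.0
    bend_position = float(boundary_atom / (n - 1))
    return ShapeDescriptors(r=r, max_bend_deg=max_bend,
                            bend_position=min(max(bend_position, 0.0), 1.0))


def _nontrans_blocks(states: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of non-trans windows as inclusive (start, end) spans."""
    blocks = []
    start = None
    for i, s in enumerate(states):
        if s:
            if start is None:
                start = i
        elif start is not None:
            blocks.append((start, i - 1))
            start = None
    if start is not None:
        blocks.append((start, len(states) - 1))
    return blocks


def classify_shape(
    profile: TorsionProfile | None,
    descriptors: ShapeDescriptors | None,
    policy: str = "torsion_pattern",
    thresholds: ShapeThresholds | None = None,
) -> ShapeClass:
    """Map one frame's torsion profile / descriptors onto a shape class.

    ``torsion_pattern`` reads the pattern of non-trans windows: all-trans is
    Ex; a single isolated non-trans window is Uex; one contiguous block in a
    terminal third is J (positive block sum) or J' (negative); one central
    block is U; two or more blocks are helical Hx (Hx-A / Hx-B when all
    blocks fall in the first / second half).  ``end_to_end`` uses only the
    descriptors and returns fine = NA.
    """
    th = thresholds or ShapeThresholds()

    if policy == "end_to_end":
        if descriptors is None:
            raise ValueError("end_to_end policy requires descriptors")
        if descriptors.r >= th.r_elongated:
            return ShapeClass(CoarseShape.ELONGATED, FineShape.NA)
        bp = descriptors.bend_position
        if bp <= th.terminal_bend_frac or bp >= 1.0 - th.terminal_bend_frac:
            return ShapeClass(CoarseShape.HOOKED, FineShape.NA)
        return ShapeClass(CoarseShape.CURVED, FineShape.NA)

    if policy != "torsion_pattern":
        raise ValueError(f"unknown policy {policy!r}")
    if profile is None:
        raise ValueError("torsion_pattern policy requires a torsion profile")
    if profile.missing_fraction > th.max_missing_fraction:
        raise ShapeClassificationError(
            f"{profile.missing_fraction:.0%} of torsions undefined "
            f"(limit {th.max_missing_fraction:.0%}); classification refused"
        )

    om = profile.omegas
    n = om.size
    finite = np.isfinite(om)
    # missing windows are treated as trans for pattern purposes
    nontrans = finite & (np.abs(om) < th.trans_min_deg)
    blocks = _nontrans_blocks(nontrans)

    if not blocks:
        return ShapeClass(CoarseShape.ELONGATED, FineShape.EX)
    if len(blocks) == 1:
        s, e = blocks[0]
        if s == e:
            return ShapeClass(CoarseShape.ELONGATED, FineShape.UEX)
        third = n * th.terminal_third
        in_terminal = e < third or s >= n - third
        if in_terminal:
            block_sum = float(np.nansum(om[s : e + 1]))
            fine = FineShape.J if block_sum >= 0 else FineShape.JP
            return ShapeClass(CoarseShape.HOOKED, fine)
        return ShapeClass(CoarseShape.CURVED, FineShape.U)
    mids = np.array([(s + e) / 2.0 for s, e in blocks])
    half = (n - 1) / 2.0
    if np.all(mids < half):
        return ShapeClass(CoarseShape.CURVED, FineShape.HXA)
    if np.all(mids > half):
        return ShapeClass(CoarseShape.CURVED, FineShape.HXB)
    return ShapeClass(CoarseShape.CURVED, FineShape.HX)


def shape_time_series(
    trajectory: Trajectory,
    chain: AtomSelection,
    policy: str = "torsion_pattern",
    thresholds: ShapeThresholds | None = None,
    segment_len: int = 4,
) -> tuple[list[ShapeClass | None], dict[str, float]]:
    """Per-frame shape classes plus per-coarse-class fractions.

    Frames whose classification is refused are returned as ``None`` and
    counted in the ``"unclassified"`` bin; fractions are over all frames
    and sum to 1 when the trajectory is non-empty.
    """
    classes: list[ShapeClass | None] = []
    counts = {c.value: 0 for c in CoarseShape}
    counts["unclassified"] = 0
    for frame in trajectory.frames:
        profile = None
        descriptors = None
        if policy == "torsion_pattern":
            profile = compute_torsion_profile(chain, frame)
        else:
            descriptors = compute_shape_descriptors(chain, frame, segment_len)
        try:
            sc = classify_shape(profile, descriptors, policy, thresholds)
        except ShapeClassificationError:
            classes.append(None)
            counts["unclassified"] += 1
            continue
        classes.append(sc)
        counts[sc.coarse.value] += 1
    total = len(classes)
    fractions = {k: (v / total if total else 0.0) for k, v in counts.items()}
    return classes, fractions
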