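"""Equilibration-aware aggregation of per-frame labels and flags.

Statistics are collected over frames after a configurable equilibration
cutoff (default 150 ns for real trajectories; synthetic fixtures use 0) and
can be pooled over the two monomers of the homodimer, weighting by frame
count so that pooling equals statistics over the concatenated streams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .occupancy import RegionLabel

__all__ = [
    "OccupancySummary",
    "PrereactiveCrossTab",
    "TransitionSummary",
    "MonomerComparison",
    "summarize_occupancy",
    "crosstab_prereactive",
    "count_region_transitions",
    "compare_monomers",
    "DEFAULT_EQUILIBRATION_NS",
]

DEFAULT_EQUILIBRATION_NS = 150.0

_LABELS = [l.value for l in RegionLabel]
_ASSIGNED = ["MA", "AB", "T", "NB"]


@dataclass
class OccupancySummary:
    """Per-region occupancy percentages over equilibrated frames.

    With ``renormalize`` on (the default), percentages are over the assigned
    labels (MA/AB/T/NB) so they sum to 100 even when some frames are
    UNASSIGNED — matching how bar-graph style occupancy reports are usually
    normalized; the raw counts are kept for exact pooling.
    """

    counts: dict[str, int]
    n_frames_total: int
    n_frames_equilibrated: int
    equilibration_cutoff: float  # ns
    renormalize: bool = True

    @property
    def percentages(self) -> dict[str, float]:
        if self.renormalize:
            denom = sum(self.counts[l] for l in _ASSIGNED)
            labels = _ASSIGNED
        else:
            denom = self.n_frames_equilibrated
            labels = _LABELS
        if denom == 0:
            return {l: 0.0 for l in labels}
        out = {l: 100.0 * self.counts[l] / denom for l in labels}
        if self.renormalize:
            out["UNASSIGNED"] = 0.0 if self.n_frames_equilibrated == 0 else (
                100.0 * self.counts["UNASSIGNED"] / self.n_frames_equilibrated
            )
        return out


@dataclass
class PrereactiveCrossTab:
    """Overall pre-reactive % and its conditional split over MA/T/AB."""

    overall_percent: float
    conditional_percent: dict[str, float] | None  # None when no flagged frame
    n_flagged: int
    n_equilibrated: int


@dataclass
class TransitionSummary:
    """MA↔AB transfer counts and mean per-region dwell times."""

    n_MA_to_AB: int
    n_AB_to_MA: int
    mean_dwell_ns: dict[str, float]


@dataclass
class MonomerComparison:
    monomers: list[OccupancySummary]
    pooled: OccupancySummary
    max_abs_difference: float  # percentage points, over regions


def summarize_occupancy(
    labels: Sequence[RegionLabel],
    times: Sequence[float],
    equilibration_cutoff: float = DEFAULT_EQUILIBRATION_NS,
    renormalize: bool = True,
) -> OccupancySummary:
    """Count labels over frames with time > *equilibration_cutoff*."""
    if len(labels) != len(times):
        raise ValueError("labels and times must be aligned")
    if equilibration_cutoff < 0:
        raise ValueError("equilibration_cutoff must be >= 0")
    times = np.asarray(times, dtype=float)
    keep = times > equilibration_cutoff
    n_eq = int(keep.sum())
    if n_eq == 0:
        raise ValueError("no equilibrated frames")
    counts = {l: 0 for l in _LABELS}
    for lab, k in zip(labels, keep):
        if k:
            counts[RegionLabel(lab).value] += 1
    return OccupancySummary(
        counts=counts,
        n_frames_total=len(labels),
        n_frames_equilibrated=n_eq,
        equilibration_cutoff=equilibration_cutoff,
        renormalize=renormalize,
    )


def crosstab_prereactive(
    labels: Sequence[RegionLabel],
    flags: Sequence[bool],
    times: Sequence[float],
    equilibration_cutoff: float = DEFAULT_EQUILIBRATION_NS,
) -> PrereactiveCrossTab:
    """Overall pre-reactive percentage and conditional region distribution.

    Overall % is flagged / equilibrated frames; the conditional split is
    over flagged frames whose label is MA, T, or AB (normalised to 100).
    """
    if not (len(labels) == len(flags) == len(times)):
        raise ValueError("labels, flags and times must be aligned")
    times = np.asarray(times, dtype=float)
    keep = times > equilibration_cutoff
    n_eq = int(keep.sum())
    flagged = [
        RegionLabel(lab).value
        for lab, fl, k in zip(labels, flags, keep)
        if k and fl
    ]
    n_flagged = len(flagged)
    overall = 100.0 * n_flagged / n_eq if n_eq else 0.0
    conditional = None
    in_region = [l for l in flagged if l in ("MA", "T", "AB")]
    if in_region:
        conditional = {
            r: 100.0 * in_region.count(r) / len(in_region) for r in ("MA", "T", "AB")
        }
    return PrereactiveCrossTab(overall, conditional, n_flagged, n_eq)


def count_region_transitions(
    labels: Sequence[RegionLabel],
    min_dwell: int = 1,
    frame_interval: float = 0.01,
) -> TransitionSummary:
    """Count MA→AB and AB→MA transfer events and mean dwell times.

    An event is a dwell-qualified run (>= *min_dwell* consecutive frames,
    T/UNASSIGNED frames transparent) in one channel followed by a qualified
    run in the other with no intervening qualified run of the origin.
    T frames are "in transit" and never break a chain; NB episodes do.
    """
    if min_dwell < 1:
        raise ValueError("min_dwell must be >= 1")
    labs = [RegionLabel(l) for l in labels]
    n_ma_ab = 0
    n_ab_ma = 0
    qualified: RegionLabel | None = None
    cand: RegionLabel | None = None
    cand_count = 0
    for lab in labs:
        if lab == RegionLabel.NB:
            qualified = None
            cand = None
            cand_count = 0
            continue
        if lab in (RegionLabel.T, RegionLabel.UNASSIGNED):
            continue
        if lab == cand:
            cand_count += 1
        else:
            cand = lab
            cand_count = 1
        if cand_count >= min_dwell:
            if qualified is not None and cand != qualified:
                if qualified == RegionLabel.MA and cand == RegionLabel.AB:
                    n_ma_ab += 1
                elif qualified == RegionLabel.AB and cand == RegionLabel.MA:
                    n_ab_ma += 1
            qualified = cand

    # mean dwell per region over maximal same-label runs
    dwell_frames: dict[str, list[int]] = {l: [] for l in _LABELS}
    i = 0
    while i < len(labs):
        j = i
        while j < len(labs) and labs[j] == labs[i]:
            j += 1
        dwell_frames[labs[i].value].append(j - i)
        i = j
    mean_dwell = {
        l: (float(np.mean(runs)) * frame_interval if runs else 0.0)
        for l, runs in dwell_frames.items()
    }
    return TransitionSummary(n_ma_ab, n_ab_ma, mean_dwell)


def compare_monomers(
    summaries: Sequence[OccupancySummary],
    agreement_threshold: float = 5.0,
) -> MonomerComparison:
    """Frame-weighted pooling of per-monomer occupancy with an agreement check.

    Pooling adds raw counts, so the pooled summary equals the summary of the
    concatenated label streams.  A max per-region difference beyond
    *agreement_threshold* percentage points raises a warning (possible
    insufficient equilibration), never an error.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two monomer summaries")
    first = summaries[0]
    for s in summaries[1:]:
        if s.renormalize != first.renormalize or not np.isclose(
            s.equilibration_cutoff, first.equilibration_cutoff
        ):
            raise ValueError("monomer summaries use mismatched configurations")
    pooled_counts = {l: sum(s.counts[l] for s in summaries) for l in _LABELS}
    pooled = OccupancySummary(
        counts=pooled_counts,
        n_frames_total=sum(s.n_frames_total for s in summaries),
        n_frames_equilibrated=sum(s.n_frames_equilibrated for s in summaries),
        equilibration_cutoff=first.equilibration_cutoff,
        renormalize=first.renormalize,
    )
    percs = [s.percentages for s in summaries]
    regions = set(percs[0])
    max_diff = max(
        abs(pa[r] - pb[r])
        for r in regions
        for pa in percs
        for pb in percs
    )
    if max_diff > agreement_threshold:
        warnings.warn(
            f"monomer occupancy differs by up to {max_diff:.1f} percentage "
            f"points (threshold {agreement_threshold}); the system may not "
            f"be equilibrated",
            stacklevel=2,
        )
    return MonomerComparison(list(summaries), pooled, max_diff)
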