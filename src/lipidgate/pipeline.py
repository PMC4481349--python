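"""Pipeline configuration and the full per-monomer → pooled analysis run.

A :class:`PipelineConfig` (YAML or JSON on disk) declares the input paths,
the substrate chain path and tail selection, the pocket definitions and
cutoffs, the paddle residues, the pre-reactive criteria and the shape
policy.  :func:`run_pipeline` executes every stage per monomer, pools the
occupancy statistics over monomers, and returns one JSON-serialisable
report bundle with all effective thresholds echoed for provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import occupancy as occ
from . import paddle as pad
from . import shapes as shp
from . import stats as st
from .geometry import Trajectory, select
from .io import read_structure_and_trajectory

logger = logging.getLogger("lipidgate")

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "save_config"]


def _default_chain_atoms() -> list[str]:
    return [f"C{i}" for i in range(1, 17)]


def _default_regions_dict() -> dict:
    return {
        name: {
            "residues": [list(r) for r in rd.residues],
            "cutoff": rd.cutoff,
        }
        for name, rd in occ.default_regions().items()
    }


def _default_criteria() -> list[dict]:
    crit = pad.default_prereactive_criteria()
    return [
        {
            "name": c.name,
            "kind": c.kind,
            # chain-relative refs ("resid:atom"); the monomer chain id is
            # prepended at run time so one config drives both monomers
            "atoms": [f"{a.residue_id}:{a.name}" for a in c.atoms],
            "min": c.min,
            "max": c.max,
        }
        for c in crit.criteria
    ]


@dataclass
class PipelineConfig:
    """Everything a full analysis run needs, with provenance-ready defaults."""

    trajectory_path: str = "trajectory.pdb"
    topology_path: str | None = None
    output_dir: str | None = None
    frame_interval: float = 0.01  # ns
    monomers: list[str] = field(default_factory=lambda: ["A"])

    substrate_residue_id: int = 700
    chain_atom_names: list[str] = field(default_factory=_default_chain_atoms)
    tail_n_atoms: int = 3

    regions: dict = field(default_factory=_default_regions_dict)
    distance_mode: str = "com_per_residue"
    nb_threshold: float = occ.DEFAULT_NB_THRESHOLD
    min_dwell: int = occ.DEFAULT_MIN_DWELL
    equilibration_cutoff_ns: float = st.DEFAULT_EQUILIBRATION_NS
    renormalize: bool = True

    paddle_resF: int = 432
    paddle_resW: int = 531
    paddle_quadruple: list[str] = field(
        default_factory=lambda: ["N", "CA", "CB", "CG"]
    )
    gate_closed: list[float] = field(default_factory=lambda: [45.0, 85.0])
    gate_open: list[float] = field(default_factory=lambda: [140.0, 200.0])

    prereactive_criteria: list[dict] = field(default_factory=_default_criteria)
    prereactive_combine: str = "all"

    shape_policy: str = "torsion_pattern"
    shape_thresholds: dict = field(default_factory=dict)
    segment_len: int = 4

    seed: int = 0

    def region_definitions(self) -> dict[str, occ.RegionDefinition]:
        return {
            name: occ.RegionDefinition(
                name,
                [tuple(r) for r in spec["residues"]],
                float(spec["cutoff"]),
            )
            for name, spec in self.regions.items()
        }

    def criteria_for_monomer(self, chain_id: str) -> pad.PrereactiveCriteria:
        crits = []
        for c in self.prereactive_criteria:
            refs = []
            for ref in c["atoms"]:
                parts = ref.split(":")
                if len(parts) == 2:  # chain-relative
                    refs.append(pad.AtomRef(chain_id, int(parts[0]), parts[1]))
                else:
                    refs.append(pad.AtomRef.parse(ref))
            crits.append(
                pad.GeometricCriterion(
                    c["name"], c["kind"], tuple(refs),
                    c.get("min"), c.get("max"),
                )
            )
        return pad.PrereactiveCriteria(crits, combine=self.prereactive_combine)

    def gate_bins(self) -> pad.GateBins:
        return pad.GateBins(tuple(self.gate_closed), tuple(self.gate_open))

    def shape_threshold_obj(self) -> shp.ShapeThresholds:
        return shp.ShapeThresholds(**self.shape_thresholds)


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML (or JSON — YAML is a superset) configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    return path


def _occupancy_dict(s: st.OccupancySummary) -> dict:
    return {
        "percent": {k: float(v) for k, v in s.percentages.items()},
        "counts": dict(s.counts),
        "n_frames_total": s.n_frames_total,
        "n_frames_equilibrated": s.n_frames_equilibrated,
        "equilibration_cutoff_ns": s.equilibration_cutoff,
        "renormalized_over_assigned": s.renormalize,
    }


def analyze_monomer(
    trajectory: Trajectory, config: PipelineConfig, chain_id: str
) -> dict:
    """Run every analysis stage for one monomer chain; returns raw results."""
    regions = config.region_definitions()
    tail_names = config.chain_atom_names[-config.tail_n_atoms:]
    tail = select(
        trajectory.topology, chain_id=chain_id,
        residue_id=config.substrate_residue_id, names=tail_names,
        label=f"{chain_id}:tail",
    )
    if len(tail) != config.tail_n_atoms:
        raise ValueError(
            f"tail selection resolved {len(tail)} atoms, expected "
            f"{config.tail_n_atoms} ({chain_id}:{config.substrate_residue_id} "
            f"{tail_names})"
        )
    chain = select(
        trajectory.topology, chain_id=chain_id,
        residue_id=config.substrate_residue_id, names=config.chain_atom_names,
    )

    triplets = occ.compute_distance_series(
        trajectory, tail, regions, chain_id=chain_id, mode=config.distance_mode
    )
    labels = occ.label_trajectory(triplets, regions, config.nb_threshold)
    episodes, excursions = occ.detect_unbinding(labels, config.min_dwell)

    shape_classes, shape_fractions = shp.shape_time_series(
        trajectory, chain, policy=config.shape_policy,
        thresholds=config.shape_threshold_obj(), segment_len=config.segment_len,
    )

    paddle_series = pad.compute_paddle_angles(
        trajectory,
        resF=(chain_id, config.paddle_resF),
        resW=(chain_id, config.paddle_resW),
        quadruple=tuple(config.paddle_quadruple),
        bins=config.gate_bins(),
    )
    gate_events = pad.count_gate_transitions(paddle_series, config.min_dwell)

    criteria = config.criteria_for_monomer(chain_id)
    flags = pad.evaluate_prereactive_series(trajectory, criteria)
    polar = pad.build_polar_records(labels, triplets, paddle_series, flags)

    times = trajectory.times
    summary = st.summarize_occupancy(
        labels, times, config.equilibration_cutoff_ns, config.renormalize
    )
    crosstab = st.crosstab_prereactive(
        labels, flags, times, config.equilibration_cutoff_ns
    )
    transitions = st.count_region_transitions(
        labels, config.min_dwell, trajectory.frame_interval
    )
    return {
        "chain_id": chain_id,
        "triplets": triplets,
        "labels": labels,
        "flags": flags,
        "paddle": paddle_series,
        "shape_classes": shape_classes,
        "shape_fractions": shape_fractions,
        "polar": polar,
        "summary": summary,
        "crosstab": crosstab,
        "transitions": transitions,
        "gate_events": gate_events,
        "unbinding_episodes": episodes,
        "transient_excursions": excursions,
    }


def run_pipeline(
    config: PipelineConfig, trajectory: Trajectory | None = None
) -> dict:
    """Full per-monomer + pooled analysis; returns the report bundle.

    When *config.output_dir* is set, report.json plus per-frame and polar
    CSVs are written there; re-running on identical inputs produces
    byte-identical files.
    """
    logger.info(
        "pipeline thresholds: cutoffs %s, nb_threshold %.2f A, min_dwell %d, "
        "equilibration %.1f ns, gate closed %s / open %s",
        {n: s["cutoff"] for n, s in config.regions.items()},
        config.nb_threshold, config.min_dwell, config.equilibration_cutoff_ns,
        config.gate_closed, config.gate_open,
    )
    if trajectory is None:
        trajectory = read_structure_and_trajectory(
            config.trajectory_path, config.topology_path, config.frame_interval
        )
        logger.info(
            "read %d frames x %d atoms (interval %.3f ns)",
            trajectory.n_frames, trajectory.n_atoms, trajectory.frame_interval,
        )

    monomer_results = {}
    for chain_id in config.monomers:
        try:
            monomer_results[chain_id] = analyze_monomer(
                trajectory, config, chain_id
            )
        except Exception as exc:
            raise RuntimeError(
                f"analysis failed for monomer {chain_id!r}: {exc}"
            ) from exc

    report: dict = {"config": asdict(config), "monomers": {}, "pooled": {}}
    for chain_id, res in monomer_results.items():
        report["monomers"][chain_id] = {
            "occupancy": _occupancy_dict(res["summary"]),
            "prereactive": {
                "overall_pct": res["crosstab"].overall_percent,
                "conditional_pct": res["crosstab"].conditional_percent,
                "n_flagged": res["crosstab"].n_flagged,
            },
            "transitions": {
                "n_MA_to_AB": res["transitions"].n_MA_to_AB,
                "n_AB_to_MA": res["transitions"].n_AB_to_MA,
                "mean_dwell_ns": res["transitions"].mean_dwell_ns,
            },
            "gate_events": res["gate_events"],
            "shape_fractions": res["shape_fractions"],
            "unbinding_episodes": [list(e) for e in res["unbinding_episodes"]],
            "n_polar_records": len(res["polar"]),
        }

    summaries = [res["summary"] for res in monomer_results.values()]
    if len(summaries) >= 2:
        comparison = st.compare_monomers(summaries)
        pooled = comparison.pooled
        report["pooled"]["max_abs_monomer_difference_pct"] = (
            comparison.max_abs_difference
        )
    else:
        pooled = summaries[0]
    report["pooled"]["occupancy"] = _occupancy_dict(pooled)

    # pooled pre-reactive statistics over concatenated monomer streams
    all_labels = [l for res in monomer_results.values() for l in res["labels"]]
    all_flags = np.concatenate(
        [res["flags"] for res in monomer_results.values()]
    )
    all_times = np.concatenate(
        [trajectory.times for _ in monomer_results]
    )
    pooled_ct = st.crosstab_prereactive(
        all_labels, all_flags, all_times, config.equilibration_cutoff_ns
    )
    report["pooled"]["prereactive"] = {
        "overall_pct": pooled_ct.overall_percent,
        "conditional_pct": pooled_ct.conditional_percent,
        "n_flagged": pooled_ct.n_flagged,
    }

    if config.output_dir:
        _write_outputs(config, trajectory, monomer_results, report)
    return report


def _write_outputs(config, trajectory, monomer_results, report) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for chain_id, res in monomer_results.items():
        rows = []
        for trip, lab, fl, padl, sc in zip(
            res["triplets"], res["labels"], res["flags"], res["paddle"],
            res["shape_classes"],
        ):
            rows.append(
                {
                    "time_ns": trip.time,
                    "dMA": trip.dMA,
                    "dAB": trip.dAB,
                    "dT": trip.dT,
                    "label": lab.value,
                    "prereactive": int(fl),
                    "phiF_deg": padl.phiF,
                    "phiW_deg": padl.phiW,
                    "gate": padl.gate.value,
                    "shape_coarse": sc.coarse.value if sc else "unclassified",
                    "shape_fine": sc.fine.value if sc else "unclassified",
                }
            )
        pd.DataFrame(rows).to_csv(
            out / f"frames_{chain_id}.csv", index=False
        )
        pd.DataFrame(
            [
                {
                    "region": r.region,
                    "radius_A": r.radius,
                    "phiF_deg": r.phiF,
                    "phiW_deg": r.phiW,
                }
                for r in res["polar"]
            ],
            columns=["region", "radius_A", "phiF_deg", "phiW_deg"],
        ).to_csv(out / f"polar_{chain_id}.csv", index=False)
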