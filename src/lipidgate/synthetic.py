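"""Desk-scale synthetic trajectories with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes — a substrate tail hopping among the MA/T/AB pockets (plus a
not-bound NB state) with Markov dwell structure, an acyl chain whose
torsions realise a per-state shape emission, bimodal gating dihedrals
coupled to the pocket state, and sparse pre-reactive geometry events —
without any physical forces.  Pocket residue groups are emitted as static
pseudo-residues at configurable anchor points; the same residue numbering
as the real enzyme (403/407/486/530, 335/373/428/527, 381/432/531) is used
so one pipeline configuration drives real and synthetic runs.

Everything is driven by a single :class:`numpy.random.Generator`; the same
seed reproduces the trajectory bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import (
    AtomRecord,
    FrameCoordinates,
    Trajectory,
    mass_for_element,
    place_fourth_atom,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "STATES",
    "generate_trajectory",
    "analytic_expectations",
    "stationary_distribution",
    "write_fixture",
    "read_fixture",
]

STATES = ("MA", "T", "AB", "NB")

#: Anchor geometry: the MA and AB group centers are ~16.5 Å apart with the
#: transition region midway; the NB anchor sits 20 Å off in the membrane.
_DEFAULT_ANCHORS = {
    "MA": (0.0, 0.0, 0.0),
    "T": (8.25, 0.0, 0.0),
    "AB": (16.5, 0.0, 0.0),
    "NB": (8.25, 20.0, 0.0),
}


def _default_transition_matrix() -> np.ndarray:
    # Rank-one mixing kernel P = (1-a) I + a 1·pi^T: stationary distribution
    # is exactly pi, rows sum to 1, chain irreducible.  a = 0.4 keeps the
    # second eigenvalue at 0.6 (autocorrelation time ~4 frames) so a 2x10^4
    # frame run resolves each occupancy to well under one percentage point;
    # dwell times are deliberately scaled down relative to real pocket
    # kinetics to make desk-scale statistics meaningful.
    pi = np.array([0.24, 0.68, 0.07, 0.01])
    a = 0.4
    return (1 - a) * np.eye(4) + a * np.outer(np.ones(4), pi)


def _default_shape_emission() -> dict[str, dict[str, float]]:
    return {
        "MA": {"elongated": 0.50, "hooked": 0.30, "curved": 0.20},
        "T": {"elongated": 0.10, "hooked": 0.20, "curved": 0.70},
        "AB": {"elongated": 0.30, "hooked": 0.20, "curved": 0.50},
        "NB": {"elongated": 0.20, "hooked": 0.60, "curved": 0.20},
    }


def _default_phi_mixtures() -> dict[str, dict[str, list[tuple[float, float, float]]]]:
    # (mean deg, von Mises concentration, weight); kappa 50 is ~8 deg spread,
    # mimicking the tight open (~160 deg) and closed (~65 deg) gate modes.
    return {
        "phiF": {
            "MA": [(160.0, 50.0, 1.0)],
            "T": [(150.0, 50.0, 0.5), (65.0, 50.0, 0.5)],
            "AB": [(65.0, 50.0, 1.0)],
            "NB": [(160.0, 50.0, 1.0)],
        },
        "phiW": {
            "MA": [(180.0, 50.0, 1.0)],
            "T": [(180.0, 50.0, 0.6), (145.0, 50.0, 0.4)],
            "AB": [(180.0, 50.0, 0.5), (145.0, 50.0, 0.5)],
            "NB": [(180.0, 50.0, 1.0)],
        },
    }


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic trajectory generator."""

    seed: int = 0
    n_frames: int = 5000
    frame_interval: float = 0.01  # ns
    transition_matrix: np.ndarray = field(
        default_factory=_default_transition_matrix
    )  # row-stochastic over STATES
    pocket_anchors: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_ANCHORS)
    )
    positional_noise_sigma: float = 0.8  # Å, isotropic tail placement noise
    chain_length: int = 16
    shape_emission: dict[str, dict[str, float]] = field(
        default_factory=_default_shape_emission
    )
    prereactive_p: dict[str, float] = field(
        default_factory=lambda: {"MA": 0.10, "T": 0.40, "AB": 0.05, "NB": 0.0}
    )
    phi_mixtures: dict[str, dict[str, list[tuple[float, float, float]]]] = field(
        default_factory=_default_phi_mixtures
    )
    chain_id: str = "A"

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.transition_matrix.shape != (4, 4):
            raise ValueError("transition_matrix must be 4x4 over (MA, T, AB, NB)")
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition_matrix rows must sum to 1")
        if np.any(self.transition_matrix < 0):
            raise ValueError("transition_matrix entries must be >= 0")
        if self.n_frames < 0:
            raise ValueError("n_frames must be >= 0")
        for s, p in self.prereactive_p.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prereactive_p[{s}] out of [0,1]")
        for s, dist in self.shape_emission.items():
            if not np.isclose(sum(dist.values()), 1.0):
                raise ValueError(f"shape_emission[{s}] must sum to 1")


@dataclass
class GroundTruth:
    """Per-frame generating labels and the state-change event log."""

    states: list[str]
    shapes: list[str]
    prereactive: np.ndarray  # bool per frame
    events: list[tuple[int, str, str]]  # (frame, from_state, to_state)


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Stationary vector of an irreducible row-stochastic matrix."""
    P = np.asarray(transition_matrix, dtype=float)
    n = P.shape[0]
    reach = np.eye(n, dtype=bool)
    adj = P > 0
    for _ in range(n):
        reach = reach | (reach @ adj)
    if not reach.all():
        raise ValueError("transition matrix is reducible")
    w, v = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def analytic_expectations(config: GeneratorConfig) -> dict:
    """Closed-form targets implied by the generator parameters (percent).

    Occupancy is the stationary vector of the transition matrix; the
    overall pre-reactive percentage is sum(pi_s * p_s) over the assigned
    (non-NB) states, and the conditional cross-tab is pi_s * p_s normalised
    over MA/T/AB.
    """
    pi = stationary_distribution(config.transition_matrix)
    occ = {s: 100.0 * pi[i] for i, s in enumerate(STATES)}
    joint = {
        s: pi[i] * config.prereactive_p.get(s, 0.0)
        for i, s in enumerate(STATES)
        if s != "NB"
    }
    overall = 100.0 * sum(joint.values())
    total = sum(joint.values())
    conditional = (
        {s: 100.0 * joint[s] / total for s in ("MA", "T", "AB")} if total > 0 else None
    )
    return {
        "occupancy": occ,
        "prereactive_overall": overall,
        "prereactive_conditional": conditional,
    }


# --- topology -----------------------------------------------------------

_BOND = 1.53  # Å, C-C
_ANGLE = 111.0  # deg, C-C-C

_POCKET_RESIDUES = {
    "MA": [(403, "ASP"), (407, "ILE"), (486, "ARG"), (530, "ILE")],
    "AB": [(335, "TYR"), (373, "GLU"), (428, "ARG"), (527, "PHE")],
}
SUBSTRATE_RESID = 700
HEAD_RESID = 701


def _make_atom(serial, name, resname, resid, chain, element):
    return AtomRecord(serial, name, resname, resid, chain, element,
                      mass_for_element(element))


def _build_topology(config: GeneratorConfig) -> tuple[list[AtomRecord], dict]:
    """Pseudo-topology plus an index map for coordinate assembly."""
    atoms: list[AtomRecord] = []
    index: dict = {"pocket_static": []}  # (atom_index, xyz)
    ch = config.chain_id
    serial = 1

    def add(name, resname, resid, element):
        nonlocal serial
        atoms.append(_make_atom(serial, name, resname, resid, ch, element))
        serial += 1
        return len(atoms) - 1

    for region in ("MA", "AB"):
        anchor = np.array(config.pocket_anchors[region])
        for resid, resname in _POCKET_RESIDUES[region]:
            i = add("CA", resname, resid, "C")
            index["pocket_static"].append((i, anchor))

    t_anchor = np.array(config.pocket_anchors["T"])
    i = add("CA", "PHE", 381, "C")
    index["pocket_static"].append((i, t_anchor))

    # paddle residues flank the T anchor; N/CA/CB static, CG set per frame
    for key, resid, resname, off in (
        ("F", 432, "PHE", np.array([0.0, 1.8, 1.0])),
        ("W", 531, "TRP", np.array([0.0, -1.8, 1.0])),
    ):
        base = t_anchor + off
        n_i = add("N", resname, resid, "N")
        ca_i = add("CA", resname, resid, "C")
        cb_i = add("CB", resname, resid, "C")
        cg_i = add("CG", resname, resid, "C")
        n_pos = base + np.array([-1.46, 0.0, 0.0])
        ca_pos = base
        cb_pos = base + _BOND * np.array(
            [np.cos(np.radians(180 - _ANGLE)), np.sin(np.radians(180 - _ANGLE)), 0.0]
        )
        index[f"paddle_{key}"] = {
            "N": (n_i, n_pos),
            "CA": (ca_i, ca_pos),
            "CB": (cb_i, cb_pos),
            "CG": cg_i,
        }

    chain_idx = [add(f"C{k + 1}", "LIP", SUBSTRATE_RESID, "C")
                 for k in range(config.chain_length)]
    index["chain"] = chain_idx

    index["marker"] = {
        "C": add("C", "SUB", HEAD_RESID, "C"),
        "O": add("O", "SUB", HEAD_RESID, "O"),
        "OG": add("OG", "SER", 241, "O"),
        "N239": add("N", "GLY", 239, "N"),
        "N240": add("N", "GLY", 240, "N"),
    }
    return atoms, index


def _build_chain_template(torsions_deg: np.ndarray, n_atoms: int) -> np.ndarray:
    """Kinematic chain with fixed bond length/angle and given torsions."""
    pos = np.zeros((n_atoms, 3))
    pos[1] = [_BOND, 0.0, 0.0]
    ang = np.radians(180 - _ANGLE)
    pos[2] = pos[1] + _BOND * np.array([np.cos(ang), np.sin(ang), 0.0])
    for k in range(3, n_atoms):
        pos[k] = place_fourth_atom(
            pos[k - 3], pos[k - 2], pos[k - 1], _BOND, _ANGLE, torsions_deg[k - 3]
        )
    return pos


def _shape_torsions(shape: str, n_windows: int) -> np.ndarray:
    om = np.full(n_windows, 180.0)
    if shape == "hooked":
        # one contiguous gauche block in the head-side terminal third
        end = max(min(n_windows // 3, n_windows) - 1, 1)
        om[1 : end + 1] = 60.0
    elif shape == "curved":
        mid = n_windows // 2
        om[mid - 1 : mid + 2] = 60.0
    elif shape != "elongated":
        raise ValueError(f"unknown shape {shape!r}")
    return om


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _sample_mixture_angles(
    rng: np.random.Generator,
    components: list[tuple[float, float, float]],
    n: int,
) -> np.ndarray:
    """n draws (degrees, [0, 360)) from a von Mises mixture."""
    means = np.array([c[0] for c in components])
    kappas = np.array([c[1] for c in components])
    weights = np.array([c[2] for c in components], dtype=float)
    weights = weights / weights.sum()
    comp = rng.choice(len(components), size=n, p=weights)
    draws = rng.vonmises(np.radians(means[comp]), kappas[comp])
    return np.degrees(draws) % 360.0


def generate_trajectory(config: GeneratorConfig) -> tuple[Trajectory, GroundTruth]:
    """Generate a synthetic trajectory plus its generating ground truth."""
    anchors = {s: np.array(config.pocket_anchors[s], dtype=float) for s in STATES}
    sep = min(
        np.linalg.norm(anchors[a] - anchors[b])
        for i, a in enumerate(STATES)
        for b in STATES[i + 1 :]
    )
    if sep < 2.0 * config.positional_noise_sigma:
        raise ValueError("states not separable: anchors closer than 2x noise sigma")

    topology, index = _build_topology(config)
    rng = np.random.default_rng(config.seed)
    n = config.n_frames

    # -- latent sequences (fixed draw order for determinism) --
    pi = stationary_distribution(config.transition_matrix)
    states_i = np.zeros(n, dtype=int)
    if n > 0:
        states_i[0] = rng.choice(4, p=pi)
        for t in range(1, n):
            states_i[t] = rng.choice(4, p=config.transition_matrix[states_i[t - 1]])
    states = [STATES[i] for i in states_i]

    shape_names = ("elongated", "hooked", "curved")
    shapes: list[str] = []
    for s in states:
        dist = config.shape_emission[s]
        p = np.array([dist.get(k, 0.0) for k in shape_names])
        shapes.append(shape_names[rng.choice(3, p=p / p.sum())])

    p_state = np.array([config.prereactive_p.get(s, 0.0) for s in states])
    flags = rng.random(n) < p_state

    phiF = np.empty(n)
    phiW = np.empty(n)
    for which, out in (("phiF", phiF), ("phiW", phiW)):
        for s in STATES:
            mask = np.array([st == s for st in states])
            if mask.any():
                out[mask] = _sample_mixture_angles(
                    rng, config.phi_mixtures[which][s], int(mask.sum())
                )

    offsets = rng.normal(scale=config.positional_noise_sigma, size=(n, 3))
    jitter = rng.normal(scale=0.05, size=(n, 5, 3))  # marker atoms

    # -- chain templates, tail-centred --
    n_windows = config.chain_length - 3
    templates = {}
    for shape in shape_names:
        tpl = _build_chain_template(_shape_torsions(shape, n_windows),
                                    config.chain_length)
        templates[shape] = tpl - tpl[-3:].mean(axis=0)  # tail COM at origin

    # -- frame assembly --
    n_atoms = len(topology)
    coords = np.zeros((n, n_atoms, 3))
    for i, xyz in index["pocket_static"]:
        coords[:, i, :] = xyz
    for key in ("F", "W"):
        info = index[f"paddle_{key}"]
        for nm in ("N", "CA", "CB"):
            ai, xyz = info[nm]
            coords[:, ai, :] = xyz

    chain_idx = np.array(index["chain"])
    mk = index["marker"]
    c_base = np.array([8.25, -15.0, 0.0])
    o_base = c_base + np.array([1.23, 0.0, 0.0])
    th = np.radians(95.0)
    og_dir = np.array([np.cos(th), np.sin(th), 0.0])

    for t in range(n):
        R = _random_rotation(rng)
        tpl = templates[shapes[t]]
        coords[t, chain_idx, :] = tpl @ R.T + anchors[states[t]] + offsets[t]

        for key, phi in (("F", phiF[t]), ("W", phiW[t])):
            info = index[f"paddle_{key}"]
            cg = place_fourth_atom(
                info["N"][1], info["CA"][1], info["CB"][1], 1.5, 114.0,
                phi if phi <= 180.0 else phi - 360.0,
            )
            coords[t, info["CG"], :] = cg

        # carbonyl C/O fixed so the attack angle stays well inside its band;
        # jitter (sd 0.05 Å) never crosses the 0.3-0.8 Å criterion margins
        d_og = 3.2 if flags[t] else 6.0
        coords[t, mk["C"], :] = c_base
        coords[t, mk["O"], :] = o_base
        coords[t, mk["OG"], :] = c_base + d_og * og_dir + jitter[t, 2]
        coords[t, mk["N239"], :] = o_base + np.array([0.0, 3.0, 0.0]) + jitter[t, 3]
        coords[t, mk["N240"], :] = o_base + np.array([0.0, -3.0, 0.0]) + jitter[t, 4]

    frames = [
        FrameCoordinates(time=(t + 1) * config.frame_interval, positions=coords[t])
        for t in range(n)
    ]
    trajectory = Trajectory(topology, frames, config.frame_interval)

    events = [
        (t, states[t - 1], states[t])
        for t in range(1, n)
        if states[t] != states[t - 1]
    ]
    truth = GroundTruth(states, shapes, flags, events)
    return trajectory, truth


# --- fixtures -----------------------------------------------------------

def config_to_dict(config: GeneratorConfig) -> dict:
    return {
        "seed": config.seed,
        "n_frames": config.n_frames,
        "frame_interval": config.frame_interval,
        "transition_matrix": config.transition_matrix.tolist(),
        "pocket_anchors": {k: list(v) for k, v in config.pocket_anchors.items()},
        "positional_noise_sigma": config.positional_noise_sigma,
        "chain_length": config.chain_length,
        "shape_emission": config.shape_emission,
        "prereactive_p": config.prereactive_p,
        "phi_mixtures": {
            w: {s: [list(c) for c in comps] for s, comps in per.items()}
            for w, per in config.phi_mixtures.items()
        },
        "chain_id": config.chain_id,
    }


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    if "phi_mixtures" in d:
        d["phi_mixtures"] = {
            w: {s: [tuple(c) for c in comps] for s, comps in per.items()}
            for w, per in d["phi_mixtures"].items()
        }
    if "pocket_anchors" in d:
        d["pocket_anchors"] = {k: tuple(v) for k, v in d["pocket_anchors"].items()}
    return GeneratorConfig(**d)


def write_fixture(
    trajectory: Trajectory,
    truth: GroundTruth,
    directory: str | Path,
    config: GeneratorConfig | None = None,
) -> dict[str, Path]:
    """Write trajectory.pdb + truth.csv (+ generator.yaml) into *directory*."""
    import pandas as pd
    import yaml

    from .io import write_trajectory_pdb

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {"trajectory": directory / "trajectory.pdb",
             "truth": directory / "truth.csv"}
    write_trajectory_pdb(trajectory, paths["trajectory"])
    pd.DataFrame(
        {
            "frame": np.arange(len(truth.states)),
            "time_ns": trajectory.times,
            "state": truth.states,
            "shape": truth.shapes,
            "prereactive": truth.prereactive.astype(int),
        }
    ).to_csv(paths["truth"], index=False)
    if config is not None:
        paths["config"] = directory / "generator.yaml"
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)
    return paths


def read_fixture(directory: str | Path):
    """Read back a fixture directory -> (Trajectory, truth DataFrame, config)."""
    import pandas as pd
    import yaml

    from .io import read_structure_and_trajectory

    directory = Path(directory)
    cfg = None
    cfg_path = directory / "generator.yaml"
    if cfg_path.exists():
        with open(cfg_path) as fh:
            cfg = config_from_dict(yaml.safe_load(fh))
    interval = cfg.frame_interval if cfg is not None else 0.01
    traj = read_structure_and_trajectory(
        directory / "trajectory.pdb", frame_interval=interval
    )
    truth = pd.read_csv(directory / "truth.csv")
    return traj, truth, cfg
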