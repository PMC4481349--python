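"""Trajectory I/O: multi-model PDB natively, XTC/DCD/TRR via MDAnalysis.

Multi-model PDB is the native text format (topology + coordinates in one
file); binary trajectory formats are accepted through the same MDAnalysis
adapter when a separate PDB topology is supplied.  PDB files store no time
axis, so frame times are assigned as (i+1)·frame_interval — the time of
the i-th stored frame after production start.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .geometry import ATOMIC_MASSES, AtomRecord, FrameCoordinates, Trajectory

__all__ = [
    "read_structure_and_trajectory",
    "write_trajectory_pdb",
    "SUPPORTED_TRAJECTORY_SUFFIXES",
]

SUPPORTED_TRAJECTORY_SUFFIXES = (".pdb", ".xtc", ".dcd", ".trr")


def _element_from_name(name: str) -> str:
    """Fallback element guess from the atom name (first alphabetic char)."""
    for ch in name:
        if ch.isalpha():
            # two-letter symbols only when the name matches one exactly
            if name.strip().upper() in ATOMIC_MASSES and len(name.strip()) > 1 \
                    and name.strip().upper() not in {"CA", "CB", "CG", "CD"}:
                return name.strip().upper()
            return ch.upper()
    raise ValueError(f"cannot infer element for atom name {name!r}")


def _validate_multimodel_pdb(path: Path) -> None:
    """Check every MODEL block has the same atom count.

    Raises naming the first offending model, so a truncated trailing model
    is reported precisely.  (Validation only — parsing is done by
    MDAnalysis.)
    """
    counts: list[tuple[int, int]] = []  # (model number, atom count)
    model_no = None
    n = 0
    seen_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                seen_model = True
                model_no = int(line.split()[1]) if len(line.split()) > 1 else (
                    (counts[-1][0] + 1) if counts else 1
                )
                n = 0
            elif rec in ("ATOM  ", "HETATM"):
                n += 1
            elif rec == "ENDMDL":
                counts.append((model_no if model_no is not None else 1, n))
                model_no = None
                n = 0
    if seen_model and (model_no is not None or n > 0):
        # file ended inside a MODEL block
        last = model_no if model_no is not None else (
            counts[-1][0] + 1 if counts else 1
        )
        raise ValueError(f"trajectory PDB truncated inside model {last}")
    if counts:
        n0 = counts[0][1]
        for mno, cnt in counts:
            if cnt != n0:
                raise ValueError(
                    f"model {mno} has {cnt} atoms, expected {n0} "
                    f"(topology/trajectory atom-count mismatch)"
                )


def read_structure_and_trajectory(
    trajectory_path: str | Path,
    topology_path: str | Path | None = None,
    frame_interval: float = 0.01,
) -> Trajectory:
    """Read a trajectory into the package's :class:`Trajectory` model.

    *trajectory_path* may be a multi-model PDB (self-contained) or a binary
    format (XTC/DCD/TRR), in which case *topology_path* must be a PDB.
    Atoms are identified by (chain, resid, atom name); masses are assigned
    from the element.
    """
    import MDAnalysis as mda

    trajectory_path = Path(trajectory_path)
    if not trajectory_path.exists():
        raise FileNotFoundError(f"trajectory not found: {trajectory_path}")
    suffix = trajectory_path.suffix.lower()
    if suffix not in SUPPORTED_TRAJECTORY_SUFFIXES:
        raise ValueError(
            f"unsupported trajectory format {suffix!r}; supported: "
            + ", ".join(SUPPORTED_TRAJECTORY_SUFFIXES)
        )
    if suffix == ".pdb":
        _validate_multimodel_pdb(trajectory_path)
        args = (str(trajectory_path),)
    else:
        if topology_path is None:
            raise ValueError(f"{suffix} trajectories require a PDB topology")
        args = (str(topology_path), str(trajectory_path))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(*args)

    atoms = u.atoms
    try:
        chain_ids = atoms.chainIDs
    except (AttributeError, mda.exceptions.NoDataError):
        chain_ids = [s[:1] or "A" for s in atoms.segids]
    try:
        elements = list(atoms.elements)
    except (AttributeError, mda.exceptions.NoDataError):
        elements = [""] * len(atoms)

    topology: list[AtomRecord] = []
    for i, a in enumerate(atoms):
        elem = (elements[i] or "").strip().upper()
        if not elem:
            elem = _element_from_name(a.name)
        mass = ATOMIC_MASSES.get(elem)
        if mass is None:
            raise ValueError(
                f"no mass for element {elem!r} (atom {a.name} in residue "
                f"{a.resid})"
            )
        topology.append(
            AtomRecord(
                serial=int(getattr(a, "id", i + 1)),
                name=str(a.name),
                residue_name=str(a.resname),
                residue_id=int(a.resid),
                chain_id=str(chain_ids[i]) or "A",
                element=elem,
                mass=mass,
            )
        )

    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, ts in enumerate(u.trajectory):
            frames.append(
                FrameCoordinates(
                    time=(k + 1) * frame_interval,
                    positions=np.array(ts.positions, dtype=float),
                )
            )
    return Trajectory(topology, frames, frame_interval)


def write_trajectory_pdb(trajectory: Trajectory, path: str | Path) -> Path:
    """Write the trajectory as a multi-model PDB (one MODEL per frame)."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    top = trajectory.topology
    n_atoms = len(top)
    residue_keys: list[tuple[str, int]] = []
    atom_resindex = []
    for a in top:
        key = (a.chain_id, a.residue_id)
        if not residue_keys or residue_keys[-1] != key:
            residue_keys.append(key)
        atom_resindex.append(len(residue_keys) - 1)

    u = mda.Universe.empty(
        n_atoms,
        n_residues=len(residue_keys),
        atom_resindex=np.array(atom_resindex),
        residue_segindex=np.zeros(len(residue_keys), dtype=int),
        trajectory=False,
    )
    u.add_TopologyAttr("names", [a.name for a in top])
    u.add_TopologyAttr("elements", [a.element for a in top])
    u.add_TopologyAttr("masses", [a.mass for a in top])
    u.add_TopologyAttr("chainIDs", [a.chain_id for a in top])
    resnames = []
    resids = []
    seen = set()
    for a in top:
        key = (a.chain_id, a.residue_id)
        if key not in seen:
            seen.add(key)
            resnames.append(a.residue_name)
            resids.append(a.residue_id)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", resids)
    u.add_TopologyAttr("segids", ["SYS"])

    coords = trajectory.coordinates()
    if coords.shape[0] == 0:
        raise ValueError("cannot write a trajectory with no frames")
    u.load_new(coords.astype(np.float32), format=MemoryReader)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
    return path
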