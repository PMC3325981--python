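"""Coordinate I/O and atom bookkeeping for trajectory analysis.

Structures and trajectories are thin wrappers around biotite AtomArrays:
a `Structure` is a fixed atom topology with coordinates, a `Trajectory`
adds a (n_frames, n_atoms, 3) coordinate block and per-frame timestamps
in ps. Multi-model PDB is the on-disk trajectory format; timestamps come
from a sidecar dt (default 1 ps/model) since PDB has no time records.

The `CatalyticAtomSet` resolves the seven heavy atoms that drive all
active-site geometry statistics for a Ser-His-Asp hydrolase: the serine
hydroxyl oxygen (OG), both histidine imidazole nitrogens (ND1/NE2), both
aspartate carboxylate oxygens (OD1/OD2), and the two oxyanion-hole
backbone nitrogens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "ROLES",
    "DEFAULT_RESIDUE_MAP",
    "Structure",
    "Trajectory",
    "CatalyticAtomSet",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "select_atoms",
    "catalytic_atom_set",
    "window_frames",
]

ROLES = ("SER_OG", "HIS_ND1", "HIS_NE2", "ASP_OD1", "ASP_OD2",
         "OXY_N1", "OXY_N2")

# residue numbering of the B. subtilis lipase catalytic machinery:
# Ser77, His156, Asp133, oxyanion-hole backbone N of Ile12 and Met78
DEFAULT_RESIDUE_MAP = {"SER": 77, "HIS": 156, "ASP": 133,
                       "OXY1": 12, "OXY2": 78}

# (role, residue-map key, atom name) for resolution
_ROLE_ATOMS = (
    ("SER_OG", "SER", "OG"),
    ("HIS_ND1", "HIS", "ND1"),
    ("HIS_NE2", "HIS", "NE2"),
    ("ASP_OD1", "ASP", "OD1"),
    ("ASP_OD2", "ASP", "OD2"),
    ("OXY_N1", "OXY1", "N"),
    ("OXY_N2", "OXY2", "N"),
)


@dataclass
class Structure:
    """A fixed atom topology with one coordinate set (Angstrom)."""

    atoms: struc.AtomArray
    role_tags: dict = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return self.atoms.array_length()

    @property
    def coords(self) -> np.ndarray:
        return self.atoms.coord

    @property
    def atom_names(self) -> np.ndarray:
        return self.atoms.atom_name

    @property
    def res_ids(self) -> np.ndarray:
        return self.atoms.res_id

    @property
    def res_names(self) -> np.ndarray:
        return self.atoms.res_name

    @property
    def chains(self) -> np.ndarray:
        return self.atoms.chain_id

    def with_coords(self, coords: np.ndarray) -> "Structure":
        new = self.atoms.copy()
        new.coord = np.asarray(coords, dtype=np.float32)
        return Structure(new, dict(self.role_tags))


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology.

    coords: (n_frames, n_atoms, 3) in Angstrom; times_ps strictly
    increasing, one per frame.
    """

    topology: Structure
    coords: np.ndarray
    times_ps: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("frame atom count must match topology")
        if self.times_ps.shape != (self.coords.shape[0],):
            raise ValueError("one timestamp per frame required")
        if self.n_frames > 1 and np.any(np.diff(self.times_ps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, k: int) -> Structure:
        return self.topology.with_coords(self.coords[k])


@dataclass(frozen=True)
class CatalyticAtomSet:
    """Role -> atom index map for the 7 catalytic heavy atoms."""

    indices: dict

    def __post_init__(self) -> None:
        missing = [r for r in ROLES if r not in self.indices]
        if missing:
            raise ValueError(f"unresolved catalytic roles: {missing}")
        vals = [self.indices[r] for r in ROLES]
        if len(set(vals)) != len(vals):
            raise ValueError("catalytic roles must map to distinct atoms")

    def __getitem__(self, role: str) -> int:
        return self.indices[role]

    def as_array(self) -> np.ndarray:
        return np.array([self.indices[r] for r in ROLES], dtype=int)


# --------------------------------------------------------------------------
# PDB I/O


def _atom_keys(atoms: struc.AtomArray):
    return list(zip(atoms.chain_id, atoms.res_id, atoms.atom_name))


def read_multimodel_pdb(path, chain_filter: str | None = None,
                        dt_ps: float = 1.0, t0_ps: float = 0.0) -> Trajectory:
    """Read a (multi-)model PDB into a Trajectory.

    One frame per MODEL; atoms are matched across models by
    (chain, residue number, atom name) and any mismatch is an error, not a
    silent drop. Alternate locations: altloc 'A'/blank kept, others
    dropped with a warning. Timestamps default to t0 + k*dt (ps).
    """
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    try:
        first = pdb.get_structure(model=1, altloc="first")
    except Exception as exc:  # biotite reports the offending line
        raise ValueError(f"unparseable coordinate records in {path}: {exc}")
    keys0 = _atom_keys(first)
    if len(set(keys0)) != len(keys0):
        warnings.warn("duplicate (chain, residue, atom) keys in model 1")
    frames = [first.coord]
    for m in range(2, n_models + 1):
        model = pdb.get_structure(model=m, altloc="first")
        keys = _atom_keys(model)
        if keys != keys0:
            diff = next(
                (i for i, (a, b) in enumerate(zip(keys, keys0)) if a != b),
                min(len(keys), len(keys0)),
            )
            got = keys[diff] if diff < len(keys) else "<missing>"
            want = keys0[diff] if diff < len(keys0) else "<extra>"
            raise ValueError(
                f"atom set of MODEL {m} differs from MODEL 1 at atom "
                f"{diff}: got {got}, expected {want}"
            )
        frames.append(model.coord)
    topo = Structure(first)
    coords = np.stack(frames).astype(float)
    if chain_filter is not None:
        mask = first.chain_id == chain_filter
        if not mask.any():
            raise ValueError(f"chain {chain_filter!r} not present in {path}")
        topo = Structure(first[mask])
        coords = coords[:, mask, :]
    times = t0_ps + dt_ps * np.arange(len(frames))
    return Trajectory(topo, coords, times)


def write_multimodel_pdb(traj: Trajectory, path) -> None:
    """Write MODEL/ENDMDL records, coordinates to 3 decimals, 80-column
    padded lines."""
    if traj.n_frames == 0:
        raise ValueError("cannot write an empty trajectory")
    stack = struc.from_template(
        traj.topology.atoms, traj.coords.astype(np.float32)
    )
    pdb = PDBFile()
    pdb.set_structure(stack)
    lines = [line.ljust(80) for line in pdb.lines]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def structure_from_arrays(coords, atom_names, res_names, res_ids,
                          chain="A", elements=None,
                          role_tags=None) -> Structure:
    """Assemble a Structure from plain arrays (generator plumbing)."""
    coords = np.asarray(coords, dtype=np.float32)
    n = coords.shape[0]
    atoms = struc.AtomArray(n)
    atoms.coord = coords
    atoms.atom_name = np.asarray(atom_names, dtype="U6")
    atoms.res_name = np.asarray(res_names, dtype="U5")
    atoms.res_id = np.asarray(res_ids, dtype=int)
    atoms.chain_id = np.full(n, chain, dtype="U4")
    atoms.element = (np.asarray(elements, dtype="U2") if elements is not None
                     else np.array([n_[0] for n_ in atom_names], dtype="U2"))
    atoms.hetero = np.zeros(n, dtype=bool)
    return Structure(atoms, dict(role_tags or {}))


# --------------------------------------------------------------------------
# selection & catalytic set


def _topology_of(obj) -> Structure:
    return obj.topology if isinstance(obj, Trajectory) else obj


def select_atoms(obj, chain: str | None = None,
                 residue_numbers=None, atom_names=None) -> np.ndarray:
    """Ordered topology indices matching the criteria.

    Criteria combine with AND. An empty selection is allowed but flagged
    with a warning; an unknown chain is an error.
    """
    topo = _topology_of(obj)
    mask = np.ones(topo.n_atoms, dtype=bool)
    if chain is not None:
        if chain not in set(topo.chains.tolist()):
            raise ValueError(f"unknown chain {chain!r}")
        mask &= topo.chains == chain
    if residue_numbers is not None:
        residue_numbers = np.atleast_1d(residue_numbers)
        mask &= np.isin(topo.res_ids, residue_numbers)
    if atom_names is not None:
        atom_names = np.atleast_1d(atom_names)
        mask &= np.isin(topo.atom_names, atom_names)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        warnings.warn("selection matched no atoms")
    return idx


def catalytic_atom_set(obj, residue_map: dict | None = None,
                       chain: str | None = None,
                       ser_og_name: str = "OG") -> CatalyticAtomSet:
    """Resolve the 7 catalytic heavy atoms by residue number + atom name.

    `residue_map` assigns residue numbers to the keys SER/HIS/ASP/OXY1/OXY2
    (default: the B. subtilis lipase numbering 77/156/133/12/78).
    `ser_og_name` allows an override for structures in which the catalytic
    serine is covalently modified and its O-gamma carries a nonstandard
    atom name.
    """
    topo = _topology_of(obj)
    residue_map = dict(residue_map or DEFAULT_RESIDUE_MAP)
    indices, missing = {}, []
    for role, key, atom_name in _ROLE_ATOMS:
        if role == "SER_OG":
            atom_name = ser_og_name
        res_id = residue_map[key]
        mask = (topo.res_ids == res_id) & (topo.atom_names == atom_name)
        if chain is not None:
            mask &= topo.chains == chain
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            missing.append(role)
        else:
            indices[role] = int(idx[0])
    if missing:
        raise ValueError(f"unresolved catalytic roles: {missing}")
    return CatalyticAtomSet(indices)


# --------------------------------------------------------------------------
# frame windowing


def window_frames(runs, t_start_ps: float, t_end_ps: float,
                  stride_ps: float = 1.0,
                  tol: float = 1e-6):
    """Window each run to [t_start, t_end] (closed at both ends) at exact
    stride multiples from t_start; return (sub-trajectories, total count).

    The closed-interval convention makes a 0-20,000 ps run at 1 ps
    contribute 20,001 frames, so three runs give 60,003 snapshots and the
    2-20 ns window gives 54,003.
    """
    if t_start_ps > t_end_ps:
        raise ValueError("t_start must not exceed t_end")
    if stride_ps <= 0:
        raise ValueError("stride must be positive")
    subs, total = [], 0
    for run in runs:
        t = run.times_ps
        offsets = (t - t_start_ps) / stride_ps
        keep = (
            (t >= t_start_ps - tol)
            & (t <= t_end_ps + tol)
            & (np.abs(offsets - np.round(offsets)) < tol)
        )
        idx = np.nonzero(keep)[0]
        subs.append(Trajectory(run.topology, run.coords[idx], t[idx]))
        total += idx.size
    if total == 0:
        warnings.warn("window selected no frames in any run")
    return subs, total
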