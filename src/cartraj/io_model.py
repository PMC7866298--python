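"""Core data model and structure/trajectory I/O.

Coordinates are in Å throughout and times in ns.  Residue numbering is the
1-based numbering printed in the PDB records; residues are identified by
``(chain id, residue number)`` pairs and role labels are resolved through the
run configuration, never hard-coded.

PDB parsing/writing is delegated to :mod:`biotite`; DCD files are read and
written through :mod:`mdtraj`'s raw DCD reader (both used for format I/O
only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chemdata


class PDBParseError(ValueError):
    """A structure file could not be parsed into the data model."""


@dataclass(frozen=True)
class Residue:
    """One residue: ``(chain, number, name)`` plus the atom rows it owns."""

    chain: str
    number: int
    name: str
    atom_indices: np.ndarray  # positional indices into the topology arrays

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain, self.number)


@dataclass
class Topology:
    """Atoms grouped into residues and chains.

    All per-atom annotations are parallel numpy arrays in file order.  Atom
    ``serial`` numbers must be unique; every atom belongs to exactly one
    residue (consecutive rows sharing ``(chain, res_number)``).
    """

    serial: np.ndarray
    name: np.ndarray
    element: np.ndarray
    mass: np.ndarray
    vdw_radius: np.ndarray
    chain: np.ndarray
    res_number: np.ndarray
    res_name: np.ndarray
    _residues: list[Residue] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        n = len(self.serial)
        for arr_name in ("name", "element", "mass", "vdw_radius", "chain",
                         "res_number", "res_name"):
            if len(getattr(self, arr_name)) != n:
                raise ValueError(f"topology field {arr_name!r} has wrong length")
        uniq, counts = np.unique(self.serial, return_counts=True)
        if uniq.size != n:
            raise PDBParseError(
                f"duplicate atom serial number(s), e.g. {uniq[counts > 1][0]}")
        if np.any(self.mass <= 0):
            bad = self.name[self.mass <= 0][0]
            raise ValueError(f"non-positive mass for atom {bad!r}")
        heavy = self.element != "H"
        if np.any(self.vdw_radius[heavy] <= 0):
            bad = self.name[heavy][self.vdw_radius[heavy] <= 0][0]
            raise ValueError(f"non-positive vdW radius for heavy atom {bad!r}")
        self._rebuild_residues()

    def _rebuild_residues(self) -> None:
        residues: list[Residue] = []
        seen: dict[tuple[str, int], int] = {}
        n = len(self.serial)
        i = 0
        while i < n:
            chain = str(self.chain[i])
            num = int(self.res_number[i])
            j = i
            while (j < n and str(self.chain[j]) == chain
                   and int(self.res_number[j]) == num):
                j += 1
            key = (chain, num)
            if key in seen:
                raise PDBParseError(
                    f"residue {chain}/{num} appears in two separate blocks; "
                    "atoms of one residue must be contiguous")
            seen[key] = len(residues)
            residues.append(Residue(chain, num, str(self.res_name[i]),
                                    np.arange(i, j)))
            i = j
        self._residues = residues
        self._residue_index = seen

    # -- residue/chain views -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    @property
    def residues(self) -> list[Residue]:
        return self._residues

    @property
    def chain_order(self) -> list[str]:
        order: list[str] = []
        for r in self._residues:
            if not order or order[-1] != r.chain:
                if r.chain in order:  # chain re-appears later in the file
                    continue
                order.append(r.chain)
        return order

    def residue(self, chain: str, number: int) -> Residue:
        try:
            return self._residues[self._residue_index[(chain, int(number))]]
        except KeyError:
            raise KeyError(f"no residue {chain}/{number} in topology") from None

    def has_residue(self, chain: str, number: int) -> bool:
        return (chain, int(number)) in self._residue_index

    def atom_index(self, chain: str, res_number: int, atom_name: str) -> int:
        """Positional index of a named atom (prime/asterisk tolerant)."""
        res = self.residue(chain, res_number)
        want = chemdata.normalize_atom_name(atom_name)
        for i in res.atom_indices:
            if chemdata.normalize_atom_name(str(self.name[i])) == want:
                return int(i)
        raise KeyError(f"no atom {atom_name!r} in residue {chain}/{res_number}")

    def subset(self, indices: np.ndarray) -> "Topology":
        """New topology restricted to the given positional indices (ordered)."""
        idx = np.asarray(indices, dtype=int)
        if idx.size == 0:
            raise ValueError("cannot build an empty topology subset")
        return Topology(
            serial=self.serial[idx].copy(),
            name=self.name[idx].copy(),
            element=self.element[idx].copy(),
            mass=self.mass[idx].copy(),
            vdw_radius=self.vdw_radius[idx].copy(),
            chain=self.chain[idx].copy(),
            res_number=self.res_number[idx].copy(),
            res_name=self.res_name[idx].copy(),
        )


def make_topology(rows: list[tuple], vdw_overrides: dict[str, float] | None = None,
                  ) -> Topology:
    """Build a Topology from ``(serial, name, element, chain, resnum, resname)``
    rows, assigning masses and vdW radii from the packaged tables."""
    radii_table = dict(chemdata.VDW_RADIUS)
    if vdw_overrides:
        radii_table.update({k.upper(): v for k, v in vdw_overrides.items()})
    serial, name, element, chain, resnum, resname = ([] for _ in range(6))
    mass, radius = [], []
    for row in rows:
        s, nm, el, ch, rn, rname = row
        el = (el or "").strip().upper()
        if not el:
            el = chemdata.infer_element(nm, rname)
        if el not in chemdata.ATOMIC_MASS:
            raise PDBParseError(
                f"unknown element {el!r} for atom {nm!r} (serial {s})")
        serial.append(int(s))
        name.append(chemdata.normalize_atom_name(nm))
        element.append(el)
        chain.append(str(ch))
        resnum.append(int(rn))
        resname.append(str(rname).strip().upper())
        mass.append(chemdata.ATOMIC_MASS[el])
        radius.append(radii_table.get(el, 0.0 if el == "H" else -1.0))
    return Topology(
        serial=np.asarray(serial, dtype=int),
        name=np.asarray(name, dtype=object),
        element=np.asarray(element, dtype=object),
        mass=np.asarray(mass, dtype=float),
        vdw_radius=np.asarray(radius, dtype=float),
        chain=np.asarray(chain, dtype=object),
        res_number=np.asarray(resnum, dtype=int),
        res_name=np.asarray(resname, dtype=object),
    )


@dataclass
class Trajectory:
    """Ordered frames of coordinates (Å) on a topology, with times in ns."""

    topology: Topology
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray   # (n_frames,), strictly increasing

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] != self.times.shape[0]:
            raise ValueError("times length does not match frame count")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"trajectory has {self.coords.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in trajectory")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass
class ReplicateSet:
    """Replicate trajectories of one condition with an equilibration cutoff."""

    condition: str
    trajectories: list[Trajectory]
    equilibration_ns: float = 20.0

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise ValueError("a replicate set needs at least one trajectory")
        if self.equilibration_ns < 0:
            raise ValueError("equilibration cutoff must be >= 0")
        shortest = min(t.times[-1] for t in self.trajectories)
        if self.equilibration_ns >= shortest:
            raise ValueError(
                f"equilibration cutoff {self.equilibration_ns} ns is not below "
                f"the shortest replicate duration {shortest} ns")
        ref = self.trajectories[0].topology
        for t in self.trajectories[1:]:
            if t.topology.n_atoms != ref.n_atoms or \
                    not np.array_equal(t.topology.name, ref.name):
                raise ValueError("replicates do not share a topology schema")


# -- readers / writers -------------------------------------------------------

def _check_pdb_lines(path) -> None:
    """Pre-validate fixed-column ATOM/HETATM records, naming the bad line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")) and len(line.rstrip("\n")) < 54:
                raise PDBParseError(
                    f"{path}: malformed ATOM/HETATM record at line {lineno}: "
                    f"{line.rstrip()!r}")


def _atoms_from_biotite(array, vdw_overrides=None) -> Topology:
    serials = (array.atom_id if "atom_id" in array.get_annotation_categories()
               else np.arange(1, array.array_length() + 1))
    rows = [
        (int(serials[i]), str(array.atom_name[i]), str(array.element[i]),
         str(array.chain_id[i]), int(array.res_id[i]), str(array.res_name[i]))
        for i in range(array.array_length())
    ]
    return make_topology(rows, vdw_overrides)


def read_pdb(path, vdw_overrides: dict[str, float] | None = None,
             ) -> tuple[Topology, np.ndarray]:
    """Read a PDB file; return the topology and first-model coordinates (Å)."""
    import biotite.structure.io.pdb as pdb

    _check_pdb_lines(path)
    try:
        pfile = pdb.PDBFile.read(str(path))
        array = pfile.get_structure(model=1, extra_fields=["atom_id"])
    except PDBParseError:
        raise
    except Exception as exc:  # biotite's own parse failures
        raise PDBParseError(f"{path}: {exc}") from exc
    if array.array_length() == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records")
    topology = _atoms_from_biotite(array, vdw_overrides)
    return topology, np.asarray(array.coord, dtype=float)


def read_trajectory(path, topology: Topology, fmt: str | None = None,
                    frame_interval_ns: float = 1.0) -> Trajectory:
    """Read a multi-model PDB or DCD trajectory onto an existing topology.

    Times are assigned as ``frame_index * frame_interval_ns`` (no trajectory
    format in use here embeds physical times).
    """
    path = str(path)
    if fmt is None:
        fmt = "dcd" if path.lower().endswith(".dcd") else "pdb"
    if fmt == "pdb":
        import biotite.structure.io.pdb as pdb

        _check_pdb_lines(path)
        try:
            stack = pdb.PDBFile.read(path).get_structure()
        except Exception as exc:
            raise PDBParseError(f"{path}: {exc}") from exc
        coords = np.asarray(stack.coord, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
    elif fmt == "dcd":
        from mdtraj.formats import DCDTrajectoryFile

        with DCDTrajectoryFile(path) as fh:
            xyz, _, _ = fh.read()  # raw reader returns Å
        coords = np.asarray(xyz, dtype=float)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")
    if coords.size == 0:
        raise PDBParseError(f"{path}: trajectory contains no frames")
    if coords.shape[1] != topology.n_atoms:
        raise ValueError(
            f"{path}: trajectory frames have {coords.shape[1]} atoms but the "
            f"topology has {topology.n_atoms}")
    times = np.arange(coords.shape[0], dtype=float) * float(frame_interval_ns)
    return Trajectory(topology, coords, times)


def write_trajectory(traj: Trajectory, path, fmt: str | None = None) -> None:
    """Write a trajectory as multi-model PDB or DCD."""
    path = str(path)
    if fmt is None:
        fmt = "dcd" if path.lower().endswith(".dcd") else "pdb"
    if fmt == "pdb":
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        top = traj.topology
        n = top.n_atoms
        array = struc.AtomArray(n)
        array.chain_id = np.asarray([str(c) for c in top.chain])
        array.res_id = np.asarray(top.res_number, dtype=int)
        array.res_name = np.asarray([str(r)[:5] for r in top.res_name])
        array.atom_name = np.asarray([str(a) for a in top.name])
        array.element = np.asarray([str(e) for e in top.element])
        array.hetero = np.zeros(n, dtype=bool)
        stack = struc.from_template(array, traj.coords.astype(np.float32))
        pfile = pdb.PDBFile()
        pfile.set_structure(stack)
        pfile.write(path)
    elif fmt == "dcd":
        from mdtraj.formats import DCDTrajectoryFile

        with DCDTrajectoryFile(path, "w") as fh:
            fh.write(traj.coords.astype(np.float32))
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")


# -- frame/atom subsetting ---------------------------------------------------

def strip(traj: Trajectory, selection) -> Trajectory:
    """Restrict a trajectory to the atoms of a selection; times preserved."""
    indices = np.asarray(getattr(selection, "indices", selection), dtype=int)
    if indices.size == 0:
        raise ValueError("cannot strip to an empty selection")
    if indices.min() < 0 or indices.max() >= traj.n_atoms:
        raise IndexError("selection indices outside topology")
    return Trajectory(traj.topology.subset(indices),
                      traj.coords[:, indices].copy(),
                      traj.times.copy())


def sample_frames(traj: Trajectory, start_ns: float, end_ns: float,
                  step_ns: float = 1.0, atol: float = 1e-9) -> Trajectory:
    """Frames at times ``start, start+step, ..., end`` (both ends inclusive).

    The endpoint-inclusive convention makes a 20-60 ns window at 1 frame/ns
    yield 41 frames.
    """
    if step_ns <= 0:
        raise ValueError("step must be positive")
    if start_ns > end_ns:
        raise ValueError("start must not exceed end")
    if start_ns < traj.times[0] - atol or end_ns > traj.times[-1] + atol:
        raise ValueError(
            f"sampling window [{start_ns}, {end_ns}] ns outside trajectory "
            f"time range [{traj.times[0]}, {traj.times[-1]}] ns")
    n_points = int(np.floor((end_ns - start_ns) / step_ns + atol)) + 1
    wanted = start_ns + step_ns * np.arange(n_points)
    idx = np.searchsorted(traj.times, wanted - atol)
    if np.any(idx >= traj.n_frames) or \
            np.any(np.abs(traj.times[idx] - wanted) > atol):
        missing = wanted[np.abs(traj.times[np.minimum(idx, traj.n_frames - 1)]
                                - wanted) > atol][0]
        raise ValueError(f"no frame at requested time {missing} ns")
    return Trajectory(traj.topology, traj.coords[idx].copy(),
                      traj.times[idx].copy())


def production_window(traj: Trajectory, equilibration_ns: float,
                      step_ns: float = 1.0) -> Trajectory:
    """Post-equilibration frames sampled at ``step_ns`` up to the final time."""
    end = traj.times[-1]
    n_steps = int(np.floor((end - equilibration_ns) / step_ns + 1e-9))
    return sample_frames(traj, equilibration_ns,
                         equilibration_ns + n_steps * step_ns, step_ns)
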