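"""Synthetic CAR-interface trajectories with known ground truth.

The generator emulates the statistical structure of the simulated
neighborhood around the CAR surface — twelve residues: the CAR triple
(C1054, A1196, (m)R146), the +1 codon (G1, C2, U3), the A-site codon and
the tRNA anticodon (nt34-36) — so that every analysis stage can be exercised
and scored against known parameters without any third-party trajectory data.

Dynamics are kinematic, not physical: geometry is sampled directly from the
target statistics.

* Guanidinium stacking follows a two-state (stacked/unstacked) Markov chain;
  the guanidinium-core center of mass is placed at exactly the drawn
  distance d(t) ~ Normal(mu_state, sigma_state) from the A1196 core center
  of mass, along a jittered direction, so the analysis-side COM distance
  recovers the mixture parameters exactly at the frame level.
* Configured hydrogen-bond pairs toggle between a bond-satisfying geometry
  (2.8 Å, collinear) and a broken one (3.6 Å) by rigid translation of the
  donor residue along the donor-acceptor axis, in exactly the frames drawn
  Bernoulli(f_target); optional Markov smoothing is off by default so the
  frame process is exactly Bernoulli.  The three atoms defining each
  configured bond are exempt from thermal noise so detection is
  deterministic per frame.
* All other atoms receive isotropic Gaussian thermal noise, and every frame
  receives a random global rigid motion which the analysis' superposition
  must absorb.

Two presets encode the study's two conditions: ``R146`` (predominantly
stacked, stronger +1-codon H-bonding) and ``mR146`` (destacked half the
time, elevated guanidinium fluctuation, reduced H-bonding).  Preset values
are chosen to reproduce the directions of the condition differences, not
any absolute published magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_model import Topology, Trajectory, ReplicateSet, make_topology

GUANIDINIUM_ATOMS = ("CZ", "NE", "NH1", "NH2")

#: role -> (chain, residue number, residue name); the mRNA chain M carries
#: the A-site codon (8-10) and the +1 codon (11-13).
_LAYOUT_RESIDUES = {
    "C1054": ("A", 1054, "C"),
    "A1196": ("A", 1196, "A"),
    "R146": ("S", 146, "ARG"),
    "Asite_C1": ("M", 8, "C"),
    "Asite_C2": ("M", 9, "C"),
    "Asite_U3": ("M", 10, "U"),
    "plus1_G1": ("M", 11, "G"),
    "plus1_C2": ("M", 12, "C"),
    "plus1_U3": ("M", 13, "U"),
    "nt34": ("T", 34, "A"),
    "nt35": ("T", 35, "G"),
    "nt36": ("T", 36, "C"),
}

#: role -> rigid translation of the residue's local frame (Å).  Base planes
#: stay parallel to xy so the anticodon/C1054/A1196 stack runs along z; the
#: guanidinium sits above A1196 and the codon strands flank the stack.
_PLACEMENTS = {
    "A1196": (0.0, 0.0, 0.0),
    "C1054": (0.8, 0.5, -3.4),
    "nt34": (0.5, 1.2, -6.8),
    "nt35": (1.2, 0.4, -10.2),
    "nt36": (0.6, 1.0, -13.6),
    "Asite_C1": (-11.0, 0.5, -2.0),
    "Asite_C2": (-11.0, 0.0, -5.5),
    "Asite_U3": (-11.0, 0.6, -9.0),
    "plus1_G1": (9.0, 0.0, -4.0),
    "plus1_C2": (9.0, 0.5, 0.5),
    "plus1_U3": (9.0, 0.0, 5.0),
    "R146": (0.0, 0.0, 3.8),
}

#: donor-residue distance used in the built template; generation translates
#: the donor residue along the bond axis to 2.8 Å (bond on, collinear) or
#: 3.6 Å (bond off) against the default 3.0 Å detection cutoff.
_TEMPLATE_HBOND_DIST = 3.2
HBOND_ON_DIST = 2.8
HBOND_OFF_DIST = 3.6


@dataclass(frozen=True)
class HBondSpec:
    """A generator-controlled donor-acceptor contact with target occupancy."""

    donor_role: str
    donor_heavy: str
    donor_hydrogen: str
    acceptor_role: str
    acceptor_atom: str
    occupancy: float

    def key(self) -> tuple[str, str, str, str]:
        return (self.donor_role, self.donor_heavy,
                self.acceptor_role, self.acceptor_atom)


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic condition.

    The default replicate schedule is the study schedule: 20 replicates of
    60 ns plus 10 of 100 ns, sampled at 1 frame/ns.  Distances in Å.
    """

    preset: str = "R146"
    replicate_lengths_ns: tuple = tuple([60.0] * 20 + [100.0] * 10)
    frame_interval_ns: float = 1.0
    mu_stacked: float = 3.8
    mu_unstacked: float = 5.5
    sigma_stacked: float = 0.25
    sigma_unstacked: float = 0.8
    stacked_fraction: float = 0.9
    # per-replicate stacked fraction ~ Beta(kappa*f, kappa*(1-f)); models the
    # slow between-run modes that make independently-initiated replicates
    # genuinely differ (what the pooled 2D-RMSD reads out)
    stacked_fraction_concentration: float = 40.0
    stacking_switch_rate_per_ns: float = 1.0
    thermal_sigma: float = 0.15
    hbonds: tuple[HBondSpec, ...] = ()
    hbond_smoothing: float = 0.0  # 0 = exactly Bernoulli per frame
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_unstacked <= self.mu_stacked:
            raise ValueError("mu_unstacked must exceed mu_stacked")
        if min(self.sigma_stacked, self.sigma_unstacked,
               self.thermal_sigma) <= 0:
            raise ValueError("all sigmas must be positive")
        if not 0.0 <= self.stacked_fraction <= 1.0:
            raise ValueError("stacked_fraction must be in [0, 1]")
        for hb in self.hbonds:
            if not 0.0 <= hb.occupancy <= 1.0:
                raise ValueError(f"occupancy {hb.occupancy} outside [0, 1]")
        if not 0.0 <= self.hbond_smoothing < 1.0:
            raise ValueError("hbond_smoothing must be in [0, 1)")

    @property
    def methylated(self) -> bool:
        return self.preset == "mR146"


def preset_spec(preset: str, **overrides) -> GeneratorSpec:
    """The two study presets.

    ``R146``: 90% stacked, +1 G1/C2 bound 30%/25% of frames.
    ``mR146``: 50% stacked, elevated unstacked fluctuation, 20%/10%.
    """
    common_pairs = [
        ("plus1_G1", "N2", "H21", "C1054", "O2"),
        ("plus1_C2", "N4", "H41", "A1196", "N1"),
    ]
    if preset == "R146":
        occ = {"plus1_G1": 0.30, "plus1_C2": 0.25}
        params: dict = dict(stacked_fraction=0.9)
    elif preset == "mR146":
        occ = {"plus1_G1": 0.20, "plus1_C2": 0.10}
        params = dict(stacked_fraction=0.5)
    else:
        raise ValueError(f"unknown preset {preset!r} (R146 | mR146)")
    hbonds = tuple(HBondSpec(r, d, h, ar, aa, occ[r])
                   for r, d, h, ar, aa in common_pairs)
    params.update(preset=preset, hbonds=hbonds)
    params.update(overrides)
    return GeneratorSpec(**params)


def default_role_map_config() -> dict:
    """Role-map config matching the synthetic topology."""
    cfg: dict = {role: [chain, num]
                 for role, (chain, num, _) in _LAYOUT_RESIDUES.items()}
    cfg["methylarginine_aliases"] = ["2MR"]
    return cfg


# -- idealized residue geometry ----------------------------------------------

def _ring_polygon(n: int, bond: float = 1.39) -> np.ndarray:
    radius = bond / (2.0 * np.sin(np.pi / n))
    ang = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.stack([radius * np.cos(ang), radius * np.sin(ang),
                     np.zeros(n)], axis=1)


def _outward(pos: np.ndarray, dist: float) -> np.ndarray:
    u = pos[:2] / np.linalg.norm(pos[:2])
    return pos + dist * np.array([u[0], u[1], 0.0])


def _pyrimidine(kind: str) -> dict[str, np.ndarray]:
    ring = _ring_polygon(6)
    atoms = dict(zip(["N1", "C2", "N3", "C4", "C5", "C6"], ring))
    atoms["O2"] = _outward(atoms["C2"], 1.23)
    if kind == "C":
        atoms["N4"] = _outward(atoms["C4"], 1.34)
        base = (atoms["N4"] - atoms["C4"]) / np.linalg.norm(
            atoms["N4"] - atoms["C4"])
        for h, dphi in (("H41", 0.6), ("H42", -0.6)):
            c, s = np.cos(dphi), np.sin(dphi)
            rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
            atoms[h] = atoms["N4"] + rot @ base
    else:  # uracil
        atoms["O4"] = _outward(atoms["C4"], 1.23)
        atoms["H3"] = _outward(atoms["N3"], 1.03)
    return atoms


def _purine(kind: str) -> dict[str, np.ndarray]:
    ring = _ring_polygon(6)
    atoms = dict(zip(["N1", "C2", "N3", "C4", "C5", "C6"], ring))
    # fuse a regular pentagon C4-C5-N7-C8-N9 on the far side of the C4-C5 edge
    c4, c5 = atoms["C4"], atoms["C5"]
    mid = (c4 + c5) / 2.0
    out = mid / np.linalg.norm(mid)
    side = np.linalg.norm(c5 - c4)
    r5 = side / (2.0 * np.sin(np.pi / 5.0))
    center5 = mid + out * r5 * np.cos(np.pi / 5.0)
    ang4 = np.arctan2(c4[1] - center5[1], c4[0] - center5[0])
    ang5 = np.arctan2(c5[1] - center5[1], c5[0] - center5[0])
    step = 2.0 * np.pi / 5.0
    direction = 1.0 if np.sin(ang4 - ang5) > 0 else -1.0
    for k, name in enumerate(("N9", "C8", "N7"), start=1):
        a = ang4 + direction * step * k
        atoms[name] = center5 + r5 * np.array([np.cos(a), np.sin(a), 0.0])
    if kind == "A":
        atoms["N6"] = _outward(atoms["C6"], 1.34)
        atoms["H61"] = _outward(atoms["N6"], 1.01)
        atoms["H62"] = atoms["N6"] + np.array([0.0, 0.0, 0.95])
    else:  # guanine
        atoms["O6"] = _outward(atoms["C6"], 1.23)
        atoms["N2"] = _outward(atoms["C2"], 1.34)
        atoms["H21"] = _outward(atoms["N2"], 1.01)
        atoms["H22"] = atoms["N2"] + np.array([0.0, 0.0, 0.95])
        atoms["H1"] = _outward(atoms["N1"], 1.03)
    return atoms


_SUGAR_OFFSETS = {
    # offsets from the glycosidic nitrogen, out of the base plane
    "C1'": (0.0, 0.0, 1.47),
    "C2'": (1.2, 0.4, 2.2), "O2'": (2.3, 0.9, 1.7), "HO2'": (2.9, 1.2, 2.4),
    "C3'": (1.0, -0.6, 3.3), "O3'": (1.8, -1.6, 3.8),
    "C4'": (-0.4, -0.8, 3.7), "O4'": (-1.1, 0.3, 3.2),
    "C5'": (-1.1, -2.0, 3.5), "O5'": (-2.4, -1.9, 4.0),
    "P": (-3.5, -2.9, 3.8), "OP1": (-4.7, -2.3, 4.4), "OP2": (-3.2, -4.2, 4.4),
}


def _nucleotide(kind: str) -> dict[str, np.ndarray]:
    atoms = _purine(kind) if kind in ("A", "G") else _pyrimidine(kind)
    glyco = atoms["N9"] if kind in ("A", "G") else atoms["N1"]
    for name, off in _SUGAR_OFFSETS.items():
        atoms[name] = glyco + np.asarray(off, dtype=float)
    return atoms


def _arginine(methylated: bool) -> dict[str, np.ndarray]:
    """Guanidinium group centered at the origin in the xy plane, aliphatic
    tail and backbone extending along +x."""
    atoms: dict[str, np.ndarray] = {"CZ": np.zeros(3)}
    for name, ang in (("NE", 0.0), ("NH1", 2.0 * np.pi / 3.0),
                      ("NH2", -2.0 * np.pi / 3.0)):
        atoms[name] = 1.33 * np.array([np.cos(ang), np.sin(ang), 0.0])
    atoms["HE"] = atoms["NE"] + np.array([0.0, 0.0, 1.01])
    atoms["HH11"] = _outward(atoms["NH1"], 1.01)
    atoms["HH12"] = atoms["NH1"] + np.array([0.0, 0.0, 1.01])
    atoms["HH21"] = _outward(atoms["NH2"], 1.01)
    if methylated:
        # omega-N(G)-monomethyl: methyl carbon replaces one NH2 hydrogen
        atoms["CM"] = atoms["NH2"] + np.array([0.0, 0.0, 1.46])
    else:
        atoms["HH22"] = atoms["NH2"] + np.array([0.0, 0.0, 1.01])
    tail = {"CD": (1.4, 0.6, 0.8), "CG": (2.6, 0.1, 1.5),
            "CB": (3.9, 0.8, 1.3), "CA": (5.1, 0.1, 1.9),
            "N": (5.4, -1.2, 1.4), "H": (5.0, -1.9, 2.0),
            "C": (6.4, 0.9, 1.7), "O": (6.5, 2.0, 2.2)}
    for name, off in tail.items():
        atoms[name] = atoms["NE"] + np.asarray(off, dtype=float)
    return atoms


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation mapping unit vector a onto unit vector b (Rodrigues)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, perp)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]],
                   [-v[1], v[0], 0.0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


@dataclass
class _Template:
    topology: Topology
    coords: np.ndarray                      # (n_atoms, 3) template positions
    atom_of: dict[tuple[str, str], int]     # (role, atom name) -> index
    residue_atoms: dict[str, np.ndarray]    # role -> atom indices
    base_atoms: dict[str, np.ndarray]       # role -> non-sugar-phosphate idx
    hbond_axes: dict[tuple, np.ndarray]     # pair key -> unit donor->acceptor
    noise_exempt: np.ndarray                # bool mask over atoms


def build_topology(spec: GeneratorSpec) -> Topology:
    """Topology of the twelve role residues with full atom-name inventories
    (hydrogens on donors included)."""
    return _build_template(spec).topology


def _build_template(spec: GeneratorSpec) -> _Template:
    rows = []
    coords = []
    atom_of: dict[tuple[str, str], int] = {}
    residue_atoms: dict[str, list[int]] = {}
    serial = 1
    for role, (chain, num, res_name) in _LAYOUT_RESIDUES.items():
        if role == "R146":
            atoms = _arginine(spec.methylated)
            res_name = "2MR" if spec.methylated else "ARG"
        else:
            atoms = _nucleotide(res_name)
        shift = np.asarray(_PLACEMENTS[role], dtype=float)
        for atom_name, pos in atoms.items():
            element = "H" if atom_name.startswith("H") else atom_name[0]
            rows.append((serial, atom_name, element, chain, num, res_name))
            coords.append(pos + shift)
            atom_of[(role, atom_name)] = serial - 1
            residue_atoms.setdefault(role, []).append(serial - 1)
            serial += 1
    topology = make_topology(rows)
    x = np.asarray(coords, dtype=float)

    # orient each configured H-bond donor residue so that its D-H vector
    # points at the acceptor, with D at the template distance from A
    hbond_axes: dict[tuple, np.ndarray] = {}
    exempt = np.zeros(len(rows), dtype=bool)
    for hb in spec.hbonds:
        d_idx = atom_of[(hb.donor_role, hb.donor_heavy)]
        h_idx = atom_of[(hb.donor_role, hb.donor_hydrogen)]
        a_idx = atom_of[(hb.acceptor_role, hb.acceptor_atom)]
        res_idx = np.asarray(residue_atoms[hb.donor_role], dtype=int)
        a_pos = x[a_idx]
        u = x[d_idx] - a_pos
        u /= np.linalg.norm(u)
        d_new = a_pos + _TEMPLATE_HBOND_DIST * u
        rot = _rotation_between(x[h_idx] - x[d_idx], -u)
        x[res_idx] = (x[res_idx] - x[d_idx]) @ rot.T + d_new
        hbond_axes[hb.key()] = -u  # unit vector donor -> acceptor
        exempt[[d_idx, h_idx, a_idx]] = True

    sugar_names = set(_SUGAR_OFFSETS)
    base_idx = {
        role: np.asarray([i for i in idx
                          if str(topology.name[i]) not in sugar_names],
                         dtype=int)
        for role, idx in residue_atoms.items()
    }
    return _Template(topology, x, atom_of,
                     {r: np.asarray(i, dtype=int)
                      for r, i in residue_atoms.items()},
                     base_idx, hbond_axes, exempt)


# -- stochastic processes ----------------------------------------------------

def _markov_states(rng: np.random.Generator, n: int, p_on: float,
                   total_rate: float) -> np.ndarray:
    """Two-state chain with stationary P(on) = p_on.

    ``total_rate`` is the sum of the per-step switching probabilities; at
    ``total_rate = 1`` successive states are independent Bernoulli(p_on).
    """
    p_on = min(max(p_on, 0.0), 1.0)
    a = min(total_rate * (1.0 - p_on), 1.0)  # P(on -> off)
    b = min(total_rate * p_on, 1.0)          # P(off -> on)
    states = np.empty(n, dtype=bool)
    states[0] = rng.random() < p_on
    u = rng.random(n)
    for t in range(1, n):
        if states[t - 1]:
            states[t] = u[t] >= a
        else:
            states[t] = u[t] < b
    return states


def _random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform random rotation matrices via normalized quaternions."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack([
        np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z),
                  2 * (x * z + w * y)], -1),
        np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z),
                  2 * (y * z - w * x)], -1),
        np.stack([2 * (x * z - w * y), 2 * (y * z + w * x),
                  1 - 2 * (x * x + y * y)], -1),
    ], axis=1)


@dataclass
class GroundTruth:
    """Per-replicate generating processes, sufficient to score recovery."""

    stacked_state: list[np.ndarray] = field(default_factory=list)
    stacked_fraction: list[float] = field(default_factory=list)
    com_distance: list[np.ndarray] = field(default_factory=list)
    hbond_state: dict[tuple, list[np.ndarray]] = field(default_factory=dict)
    spec: GeneratorSpec | None = None
    changepoint_frame: int | None = None


@dataclass
class SyntheticBundle:
    topology: Topology
    replicates: ReplicateSet
    truth: GroundTruth

    @property
    def spec(self) -> GeneratorSpec:
        return self.truth.spec


def generate_replicates(spec: GeneratorSpec, seed: int | None = None,
                        equilibration_ns: float = 20.0) -> SyntheticBundle:
    """Generate the full replicate set for one condition.

    Reproducible: the same spec and seed give bit-identical trajectories.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    template = _build_template(spec)
    truth = GroundTruth(spec=replace(spec, seed=seed))
    trajectories = []
    for length_ns in spec.replicate_lengths_ns:
        n_frames = int(round(length_ns / spec.frame_interval_ns)) + 1
        coords, rep_truth = _generate_frames(spec, template, rng, n_frames)
        times = np.arange(n_frames) * spec.frame_interval_ns
        trajectories.append(Trajectory(template.topology, coords, times))
        truth.stacked_state.append(rep_truth["stacked"])
        truth.stacked_fraction.append(rep_truth["stacked_fraction"])
        truth.com_distance.append(rep_truth["distance"])
        for key, states in rep_truth["hbonds"].items():
            truth.hbond_state.setdefault(key, []).append(states)
    condition = "mR146" if spec.methylated else "R146"
    reps = ReplicateSet(condition, trajectories, equilibration_ns)
    return SyntheticBundle(template.topology, reps, truth)


def _generate_frames(spec: GeneratorSpec, template: _Template,
                     rng: np.random.Generator, n_frames: int,
                     ) -> tuple[np.ndarray, dict]:
    top = template.topology
    masses = top.mass
    x0 = template.coords
    n_atoms = x0.shape[0]

    # per-replicate stacked fraction: slow between-run heterogeneity
    f = spec.stacked_fraction
    kappa = spec.stacked_fraction_concentration
    if 0.0 < f < 1.0 and kappa > 0:
        f_rep = float(rng.beta(kappa * f, kappa * (1.0 - f)))
    else:
        f_rep = f
    # per-frame switching probability from the per-ns rate
    p_switch = spec.stacking_switch_rate_per_ns * spec.frame_interval_ns
    stacked = _markov_states(rng, n_frames, f_rep, p_switch)
    sigma = np.where(stacked, spec.sigma_stacked, spec.sigma_unstacked)
    mu = np.where(stacked, spec.mu_stacked, spec.mu_unstacked)
    dist = mu + sigma * rng.standard_normal(n_frames)
    dist = np.maximum(dist, 2.5)  # keep groups from interpenetrating

    hbond_rate = 1.0 - spec.hbond_smoothing
    hbond_states = {
        hb.key(): _markov_states(rng, n_frames, hb.occupancy, hbond_rate)
        for hb in spec.hbonds
    }

    # the stacking motion moves the arginine side chain only: the backbone
    # stays anchored, as it would be in the folded protein
    backbone_names = {"N", "CA", "C", "O", "H"}
    arg_idx = np.array([
        i for i in template.residue_atoms["R146"]
        if str(top.name[i]) not in backbone_names], dtype=int)
    guan_idx = np.array([template.atom_of[("R146", a)]
                         for a in GUANIDINIUM_ATOMS])
    a1196_core = np.array([
        template.atom_of[("A1196", a)]
        for a in ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")])
    m_guan = masses[guan_idx]
    m_a = masses[a1196_core]

    noise = rng.standard_normal((n_frames, n_atoms, 3)) * spec.thermal_sigma
    noise[:, template.noise_exempt] = 0.0
    jitter = rng.standard_normal((n_frames, 2)) * sigma[:, None]
    rotations = _random_rotations(rng, n_frames)
    shifts = rng.normal(scale=5.0, size=(n_frames, 3))

    coords = np.empty((n_frames, n_atoms, 3))
    for t in range(n_frames):
        x = x0 + noise[t]
        # toggle configured H-bonds by translating the donor base along the
        # donor->acceptor axis (base motion about the glycosidic bond; the
        # sugar-phosphate backbone stays anchored so the backbone panels
        # remain condition-blind)
        for hb in spec.hbonds:
            key = hb.key()
            target = (HBOND_ON_DIST if hbond_states[key][t]
                      else HBOND_OFF_DIST)
            u = template.hbond_axes[key]
            shift = (_TEMPLATE_HBOND_DIST - target) * u
            x[template.base_atoms[hb.donor_role]] += shift
        # place the guanidinium core COM at exactly dist[t] from the A1196
        # core COM, along a jittered direction
        com_a = (m_a[:, None] * x[a1196_core]).sum(0) / m_a.sum()
        v = np.array([jitter[t, 0], jitter[t, 1], dist[t]])
        target_com = com_a + dist[t] * v / np.linalg.norm(v)
        com_g = (m_guan[:, None] * x[guan_idx]).sum(0) / m_guan.sum()
        x[arg_idx] += target_com - com_g
        # global rigid motion, absorbed by the analysis' superposition
        coords[t] = x @ rotations[t].T + shifts[t]
    return coords, {"stacked": stacked, "stacked_fraction": f_rep,
                    "distance": dist, "hbonds": hbond_states}


def demethylation_restart(bundle: SyntheticBundle, at_frame: int,
                          seed: int, continuation_frames: int | None = None,
                          ) -> SyntheticBundle:
    """Continue mR146 replicates with the methyl group removed.

    Mirrors the restart protocol: from ``at_frame`` onward the generating
    parameters switch to the unmethylated (R146) preset, so +1-codon
    H-bonding recovers toward the R146 targets.  The continuation runs for
    ``continuation_frames`` frames (default: the frames remaining after
    ``at_frame`` in the shortest source replicate, or a full replicate
    length if restarting at the final frame is requested).
    """
    spec = bundle.spec
    if spec.preset != "mR146":
        raise ValueError("demethylation restart requires an mR146 bundle")
    n_source = min(t.n_frames for t in bundle.replicates.trajectories)
    if not 0 <= at_frame < n_source:
        raise ValueError(
            f"at_frame {at_frame} outside source replicate length {n_source}")
    if continuation_frames is None:
        continuation_frames = n_source - 1 - at_frame
        if continuation_frames == 0:
            continuation_frames = n_source - 1
    if continuation_frames <= 0:
        raise ValueError("continuation must be at least 1 frame long")
    restart_spec = preset_spec(
        "R146",
        replicate_lengths_ns=tuple(
            continuation_frames * spec.frame_interval_ns
            for _ in spec.replicate_lengths_ns),
        frame_interval_ns=spec.frame_interval_ns,
        mu_stacked=spec.mu_stacked, mu_unstacked=spec.mu_unstacked,
        sigma_stacked=spec.sigma_stacked, sigma_unstacked=spec.sigma_unstacked,
        thermal_sigma=spec.thermal_sigma,
        stacking_switch_rate_per_ns=spec.stacking_switch_rate_per_ns,
        hbond_smoothing=spec.hbond_smoothing,
        seed=seed,
    )
    equil = min(bundle.replicates.equilibration_ns,
                0.5 * continuation_frames * spec.frame_interval_ns)
    out = generate_replicates(restart_spec, seed, equilibration_ns=equil)
    out.truth.changepoint_frame = at_frame
    return out
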