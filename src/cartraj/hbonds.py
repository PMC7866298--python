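"""Geometric hydrogen-bond detection, occupancy and per-residue counts.

A hydrogen bond is recorded when the donor heavy-atom-to-acceptor distance is
at most ``dist_cutoff`` (default 3.0 Å) and the D-H...A angle is at least
``angle_cutoff`` (default 135 degrees) — the cpptraj default criteria; both
are configurable.  One event is recorded per (hydrogen, acceptor) pair per
frame.

Occupancy f of a donor-acceptor atom pair is the fraction of frames in which
the bond is present, classified as strong (f > 0.095), weak
(0.025 < f <= 0.095) or below-threshold.  Per-residue counts are the mean
number of simultaneous bonds per frame between a focus residue and a partner
set; by linearity this equals the sum of the pair occupancies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import chemdata
from .io_model import Topology, Trajectory
from .selections import RoleMap

logger = logging.getLogger(__name__)

DEFAULT_DIST_CUTOFF = 3.0    # Å, donor heavy atom to acceptor
DEFAULT_ANGLE_CUTOFF = 135.0  # degrees, D-H...A
WEAK_THRESHOLD = 0.025
STRONG_THRESHOLD = 0.095


@dataclass(frozen=True)
class DonorTriple:
    role: str
    heavy_index: int
    hydrogen_index: int
    heavy_name: str
    hydrogen_name: str


@dataclass(frozen=True)
class AcceptorAtom:
    role: str
    index: int
    name: str


def classify_occupancy(f: float,
                       weak: float = WEAK_THRESHOLD,
                       strong: float = STRONG_THRESHOLD) -> str:
    if f > strong:
        return "strong"
    if f > weak:
        return "weak"
    return "below-threshold"


def donors_for_roles(topology: Topology, role_map: RoleMap, roles,
                     ) -> list[DonorTriple]:
    """Donor (heavy, hydrogen) atom pairs for the given roles.

    Donor heavy atoms whose hydrogens are absent from the topology are
    reported in the log and skipped.
    """
    donors: list[DonorTriple] = []
    for role in roles:
        chain, num = role_map[role]
        res = topology.residue(chain, num)
        key = chemdata.hbond_chemistry_key(res.name)
        if key is None:
            continue
        table = chemdata.HBOND_DONORS.get(key, {})
        for heavy_name, hydrogens in table.items():
            try:
                heavy_idx = topology.atom_index(chain, num, heavy_name)
            except KeyError:
                continue
            found_h = False
            for h_name in hydrogens:
                try:
                    h_idx = topology.atom_index(chain, num, h_name)
                except KeyError:
                    continue
                found_h = True
                donors.append(DonorTriple(role, heavy_idx, h_idx,
                                          heavy_name, h_name))
            if not found_h:
                logger.warning(
                    "donor %s of %s (%s/%s) has no hydrogen in the topology; "
                    "skipped", heavy_name, role, chain, num)
    return donors


def acceptors_for_roles(topology: Topology, role_map: RoleMap, roles,
                        ) -> list[AcceptorAtom]:
    acceptors: list[AcceptorAtom] = []
    for role in roles:
        chain, num = role_map[role]
        res = topology.residue(chain, num)
        key = chemdata.hbond_chemistry_key(res.name)
        if key is None:
            continue
        for name in chemdata.HBOND_ACCEPTORS.get(key, ()):
            try:
                idx = topology.atom_index(chain, num, name)
            except KeyError:
                continue
            acceptors.append(AcceptorAtom(role, idx, name))
    return acceptors


def detect_hbonds(coords: np.ndarray, donors: list[DonorTriple],
                  acceptors: list[AcceptorAtom],
                  dist_cutoff: float = DEFAULT_DIST_CUTOFF,
                  angle_cutoff: float = DEFAULT_ANGLE_CUTOFF) -> np.ndarray:
    """Boolean event matrix (n_donors, n_acceptors) for one frame.

    Donor and acceptor atoms in the same residue are never paired.
    """
    x = np.asarray(coords, dtype=float)
    if not donors or not acceptors:
        return np.zeros((len(donors), len(acceptors)), dtype=bool)
    d_heavy = x[[d.heavy_index for d in donors]]
    d_hyd = x[[d.hydrogen_index for d in donors]]
    a_pos = x[[a.index for a in acceptors]]
    diff = a_pos[None, :, :] - d_heavy[:, None, :]
    dist = np.linalg.norm(diff, axis=-1)
    hd = d_heavy - d_hyd                       # H -> D vectors
    ha = a_pos[None, :, :] - d_hyd[:, None, :]  # H -> A vectors
    cos = (hd[:, None, :] * ha).sum(-1) / (
        np.linalg.norm(hd, axis=-1)[:, None] * np.linalg.norm(ha, axis=-1)
        + 1e-300)
    angle = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    events = (dist <= dist_cutoff) & (angle >= angle_cutoff)
    same_res = np.array([[d.role == a.role for a in acceptors]
                         for d in donors])
    events &= ~same_res
    return events


def _pair_events(traj: Trajectory, role_map: RoleMap, group_a, group_b,
                 dist_cutoff: float, angle_cutoff: float):
    """Per-frame event matrices for donors/acceptors between two role groups
    (both directions)."""
    top = traj.topology
    donors = (donors_for_roles(top, role_map, group_a)
              + donors_for_roles(top, role_map, group_b))
    acceptors = (acceptors_for_roles(top, role_map, group_b)
                 + acceptors_for_roles(top, role_map, group_a))
    set_a, set_b = set(group_a), set(group_b)
    # keep only cross-group donor/acceptor combinations
    valid = np.array([[
        (d.role in set_a and a.role in set_b)
        or (d.role in set_b and a.role in set_a)
        for a in acceptors] for d in donors], dtype=bool)
    events = np.zeros((traj.n_frames, len(donors), len(acceptors)), dtype=bool)
    for f in range(traj.n_frames):
        events[f] = detect_hbonds(traj.coords[f], donors, acceptors,
                                  dist_cutoff, angle_cutoff) & valid
    return donors, acceptors, events


def _collapsed_presence(traj: Trajectory, role_map: RoleMap, group_a, group_b,
                        dist_cutoff: float, angle_cutoff: float):
    """Per-frame presence of each (donor heavy atom, acceptor atom) pair,
    with hydrogens collapsed by OR.

    Returns ``(pair_meta, presence)`` where ``pair_meta`` is a list of
    ``(donor_role, donor_atom, acceptor_role, acceptor_atom)`` and
    ``presence`` is a boolean (n_frames, n_pairs) array.  Counting and
    occupancy both work at this granularity, which makes the identity
    mean count per frame == sum of pair occupancies exact.
    """
    donors, acceptors, events = _pair_events(
        traj, role_map, group_a, group_b, dist_cutoff, angle_cutoff)
    pair_cells: dict[tuple, list[tuple[int, int]]] = {}
    for di, d in enumerate(donors):
        for ai, a in enumerate(acceptors):
            key = (d.role, d.heavy_name, a.role, a.name)
            pair_cells.setdefault(key, []).append((di, ai))
    meta = list(pair_cells)
    presence = np.zeros((traj.n_frames, len(meta)), dtype=bool)
    for p, key in enumerate(meta):
        for di, ai in pair_cells[key]:
            presence[:, p] |= events[:, di, ai]
    return meta, presence


def occupancy(traj: Trajectory, role_map: RoleMap, group_a, group_b,
              dist_cutoff: float = DEFAULT_DIST_CUTOFF,
              angle_cutoff: float = DEFAULT_ANGLE_CUTOFF,
              weak: float = WEAK_THRESHOLD,
              strong: float = STRONG_THRESHOLD) -> pd.DataFrame:
    """Donor-acceptor pair occupancies between two role groups.

    Returns one row per (donor heavy atom, acceptor atom) pair that forms at
    least once, with occupancy f and its frequency class.
    """
    if traj.n_frames == 0:
        raise ValueError("occupancy needs at least one frame")
    meta, presence = _collapsed_presence(
        traj, role_map, group_a, group_b, dist_cutoff, angle_cutoff)
    rows = []
    for p, (d_role, d_name, a_role, a_name) in enumerate(meta):
        f = float(presence[:, p].mean())
        if f == 0.0:
            continue
        rows.append({
            "donor_role": d_role, "donor_atom": d_name,
            "acceptor_role": a_role, "acceptor_atom": a_name,
            "occupancy": f, "n_frames": traj.n_frames,
            "class": classify_occupancy(f, weak, strong),
        })
    return pd.DataFrame(rows, columns=[
        "donor_role", "donor_atom", "acceptor_role", "acceptor_atom",
        "occupancy", "n_frames", "class"])


def per_residue_counts(traj: Trajectory, role_map: RoleMap,
                       focus_roles, partner_roles,
                       dist_cutoff: float = DEFAULT_DIST_CUTOFF,
                       angle_cutoff: float = DEFAULT_ANGLE_CUTOFF,
                       ) -> pd.DataFrame:
    """Mean simultaneous H-bonds per frame between each focus residue and the
    partner set (either bonding direction)."""
    if traj.n_frames == 0:
        raise ValueError("per_residue_counts needs at least one frame")
    meta, presence = _collapsed_presence(
        traj, role_map, list(focus_roles), list(partner_roles),
        dist_cutoff, angle_cutoff)
    rows = []
    for focus in focus_roles:
        cols = [p for p, (d_role, _, a_role, _) in enumerate(meta)
                if d_role == focus or a_role == focus]
        per_frame = presence[:, cols].sum(1)
        rows.append({"role": focus,
                     "mean_hbonds_per_frame": float(per_frame.mean()),
                     "max_hbonds": int(per_frame.max()) if cols else 0,
                     "n_frames": traj.n_frames})
    return pd.DataFrame(rows)
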