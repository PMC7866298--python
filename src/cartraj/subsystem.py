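"""Onion-shell neighborhood construction and MD-preparation planning.

A neighborhood is the residue set of a sphere (default radius 35 Å) around a
center residue, split into an inner unrestrained region and an outer "onion
shell" (default ~8 Å thick) whose atoms an MD engine would positionally
restrain to hold the embedding ribosome conformation.  Membership is
all-or-none per residue: a residue is included if any atom lies within the
sphere radius of the center-residue center of mass, and unrestrained if any
atom lies within (radius - shell thickness).

Also provided: single-gap contiguity repair with chain-break/hole
diagnostics, an Amber-style restraint-mask writer (with parser, so masks
round-trip), the mRNA sequence-edit planner and 5'-phosphate stripping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chemdata
from .io_model import Topology

DEFAULT_RADIUS = 35.0  # Å
DEFAULT_SHELL = 8.0    # Å
DEFAULT_RESTRAINT_WEIGHT = 20.0  # kcal/mol Å²


@dataclass
class Neighborhood:
    center: tuple[str, int]
    radius: float
    shell_thickness: float
    unrestrained: set[tuple[str, int]]
    shell: set[tuple[str, int]]
    chain_breaks: list[tuple[str, int, int]] = field(default_factory=list)
    holes: list[tuple[str, int]] = field(default_factory=list)
    added: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.unrestrained & self.shell:
            raise ValueError("unrestrained and shell residue sets overlap")

    @property
    def selected(self) -> set[tuple[str, int]]:
        return self.unrestrained | self.shell

    @property
    def n_residues(self) -> int:
        return len(self.unrestrained) + len(self.shell)


def _residue_min_distances(topology: Topology, coords: np.ndarray,
                           center_point: np.ndarray) -> dict[tuple[str, int], float]:
    d = np.linalg.norm(coords - center_point, axis=1)
    return {res.key: float(d[res.atom_indices].min())
            for res in topology.residues}


def build_neighborhood(topology: Topology, coords: np.ndarray,
                       center: tuple[str, int],
                       radius: float = DEFAULT_RADIUS,
                       shell_thickness: float = DEFAULT_SHELL,
                       center_atom: str | None = None,
                       include: list | None = None,
                       exclude: list | None = None) -> Neighborhood:
    """Sphere + onion-shell residue selection around a center residue.

    The sphere is measured from the center residue's center of mass, or from
    a named atom via ``center_atom``.  ``include``/``exclude`` apply the kind
    of manual curation a modeller would do by hand: forced-in residues are
    added to the shell, forced-out residues are dropped.
    """
    if not radius > shell_thickness > 0:
        raise ValueError("need radius > shell thickness > 0")
    chain, num = str(center[0]), int(center[1])
    res = topology.residue(chain, num)
    x = np.asarray(coords, dtype=float)
    if center_atom is not None:
        point = x[topology.atom_index(chain, num, center_atom)]
    else:
        m = topology.mass[res.atom_indices]
        point = (m[:, None] * x[res.atom_indices]).sum(0) / m.sum()
    extent = np.linalg.norm(x[res.atom_indices] - point, axis=1).max()
    if radius < extent:
        raise ValueError(
            f"radius {radius} Å is smaller than the center residue's extent "
            f"({extent:.1f} Å)")
    min_dist = _residue_min_distances(topology, x, point)
    inner_radius = radius - shell_thickness
    unrestrained = {k for k, d in min_dist.items() if d <= inner_radius}
    shell = {k for k, d in min_dist.items()
             if d <= radius and k not in unrestrained}
    added: list[tuple[str, int]] = []
    for key in include or []:
        key = (str(key[0]), int(key[1]))
        if key not in unrestrained and key not in shell:
            shell.add(key)
            added.append(key)
    for key in exclude or []:
        key = (str(key[0]), int(key[1]))
        unrestrained.discard(key)
        shell.discard(key)
    nb = Neighborhood((chain, num), radius, shell_thickness,
                      unrestrained, shell, added=added)
    nb.chain_breaks = _find_chain_breaks(nb, topology)
    nb.holes = _find_shell_holes(nb, topology, x)
    return nb


def _chain_runs(nb: Neighborhood, topology: Topology) -> dict[str, list[int]]:
    runs: dict[str, list[int]] = {}
    for chain, num in sorted(nb.selected):
        runs.setdefault(chain, []).append(num)
    return {c: sorted(nums) for c, nums in runs.items()}


def _find_chain_breaks(nb: Neighborhood, topology: Topology,
                       ) -> list[tuple[str, int, int]]:
    """Gaps of >= 1 missing residue inside a chain's selected run (only
    counting residues that exist in the topology)."""
    breaks = []
    for chain, nums in _chain_runs(nb, topology).items():
        for a, b in zip(nums, nums[1:]):
            if b - a > 1 and any(topology.has_residue(chain, m)
                                 for m in range(a + 1, b)):
                breaks.append((chain, a, b))
    return breaks


def _find_shell_holes(nb: Neighborhood, topology: Topology,
                      coords: np.ndarray, cutoff: float = 5.0,
                      ) -> list[tuple[str, int]]:
    """Shell residues with < 2 selected neighbors within ``cutoff`` Å
    (minimum atom-atom distance).  Reported only, never auto-acted on."""
    selected = sorted(nb.selected)
    centers = {}
    for key in selected:
        res = topology.residue(*key)
        centers[key] = coords[res.atom_indices]
    holes = []
    for key in sorted(nb.shell):
        n_neigh = 0
        for other in selected:
            if other == key:
                continue
            d = np.linalg.norm(
                centers[key][:, None, :] - centers[other][None, :, :],
                axis=-1).min()
            if d < cutoff:
                n_neigh += 1
                if n_neigh >= 2:
                    break
        if n_neigh < 2:
            holes.append(key)
    return holes


def repair_contiguity(nb: Neighborhood, topology: Topology) -> Neighborhood:
    """Fill single-residue gaps in each chain's selected run (added to the
    shell); larger gaps are reported as chain breaks, not auto-filled.
    Idempotent."""
    shell = set(nb.shell)
    added = list(nb.added)
    for chain, nums in _chain_runs(nb, topology).items():
        for a, b in zip(nums, nums[1:]):
            if b - a == 2 and topology.has_residue(chain, a + 1):
                key = (chain, a + 1)
                shell.add(key)
                added.append(key)
    repaired = Neighborhood(nb.center, nb.radius, nb.shell_thickness,
                            set(nb.unrestrained), shell,
                            holes=list(nb.holes), added=added)
    repaired.chain_breaks = _find_chain_breaks(repaired, topology)
    return repaired


# -- Amber-style restraint mask ---------------------------------------------

def _ordinals(topology: Topology, keys) -> list[int]:
    """1-based global residue ordinals (Amber mask numbering) for keys."""
    index = {res.key: i + 1 for i, res in enumerate(topology.residues)}
    return sorted(index[k] for k in keys)


def _compress_ranges(ordinals: list[int]) -> str:
    parts = []
    i = 0
    while i < len(ordinals):
        j = i
        while j + 1 < len(ordinals) and ordinals[j + 1] == ordinals[j] + 1:
            j += 1
        parts.append(str(ordinals[i]) if i == j
                     else f"{ordinals[i]}-{ordinals[j]}")
        i = j + 1
    return ",".join(parts)


def restraint_mask(nb: Neighborhood, topology: Topology,
                   weight: float = DEFAULT_RESTRAINT_WEIGHT) -> str:
    """Amber-style residue mask covering exactly the shell residues, with the
    positional restraint weight (kcal/mol Å²)."""
    if not nb.shell:
        raise ValueError("cannot write a restraint mask for an empty shell")
    mask = ":" + _compress_ranges(_ordinals(topology, nb.shell))
    return (f"restraintmask = \"{mask}\"\n"
            f"restraint_wt = {weight:g}\n")


def parse_restraint_mask(text: str, topology: Topology,
                         ) -> tuple[set[tuple[str, int]], float]:
    """Parse a mask written by :func:`restraint_mask` back into a residue-key
    set and weight (round-trip oracle for the writer)."""
    mask_str = None
    weight = None
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip()
        value = value.strip().strip('"')
        if key == "restraintmask":
            mask_str = value
        elif key == "restraint_wt":
            weight = float(value)
    if mask_str is None or weight is None:
        raise ValueError("not a restraint-mask text")
    if not mask_str.startswith(":"):
        raise ValueError(f"unsupported mask syntax {mask_str!r}")
    ordinals: set[int] = set()
    for part in mask_str[1:].split(","):
        if "-" in part:
            lo, hi = part.split("-")
            ordinals.update(range(int(lo), int(hi) + 1))
        else:
            ordinals.add(int(part))
    residues = topology.residues
    keys = set()
    for o in ordinals:
        if not 1 <= o <= len(residues):
            raise ValueError(f"mask ordinal {o} outside topology")
        keys.add(residues[o - 1].key)
    return keys, weight


# -- mRNA sequence-edit planning --------------------------------------------

@dataclass(frozen=True)
class SequenceEdit:
    position: int          # 1-based along the sequence
    source: str
    target: str
    retained: tuple[str, ...]
    grown: tuple[str, ...]


def plan_sequence_edit(source: str, target: str) -> list[SequenceEdit]:
    """Plan nucleotide replacements that keep the maximum number of resolved
    atomic positions, leaving the rest for an MD-prep tool to grow.

    Backbone and sugar atoms are always retained.  Base atoms are retained by
    shared name only within a class (purine->purine or
    pyrimidine->pyrimidine); cross-class replacements retain backbone/sugar
    only.
    """
    src = source.strip().upper().replace("T", "U")
    tgt = target.strip().upper().replace("T", "U")
    if len(src) != len(tgt):
        raise ValueError(
            f"sequence lengths differ ({len(src)} vs {len(tgt)})")
    for seq in (src, tgt):
        bad = set(seq) - set("ACGU")
        if bad:
            raise ValueError(f"non-RNA letters in sequence: {sorted(bad)}")
    purine = {"A", "G"}
    plan = []
    for pos, (s, t) in enumerate(zip(src, tgt), start=1):
        if s == t:
            continue
        retained = list(chemdata.SUGAR_PHOSPHATE)
        if (s in purine) == (t in purine):
            shared = [a for a in chemdata.BASE_ATOMS[t]
                      if a in chemdata.BASE_ATOMS[s]]
            retained.extend(shared)
        grown = tuple(a for a in chemdata.BASE_ATOMS[t] if a not in retained)
        plan.append(SequenceEdit(pos, s, t, tuple(retained), grown))
    return plan


# -- 5'-phosphate stripping --------------------------------------------------

_5P_ATOMS = {"P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P"}


def strip_5prime_phosphates(topology: Topology, coords: np.ndarray | None = None,
                            ):
    """Remove the 5'-terminal phosphate group (P, OP1/OP2/OP3) from the first
    nucleotide of every nucleotide chain.  Protein chains are untouched.

    Returns the new topology, or ``(topology, coords)`` if coordinates are
    given.
    """
    drop: set[int] = set()
    first_of_chain: dict[str, object] = {}
    for res in topology.residues:
        if res.chain not in first_of_chain:
            first_of_chain[res.chain] = res
    for res in first_of_chain.values():
        if not chemdata.is_nucleotide(res.name):
            continue
        for i in res.atom_indices:
            if chemdata.normalize_atom_name(str(topology.name[i])) in _5P_ATOMS:
                drop.add(int(i))
    keep = np.array([i for i in range(topology.n_atoms) if i not in drop],
                    dtype=int)
    new_top = topology.subset(keep)
    if coords is None:
        return new_top
    return new_top, np.asarray(coords, dtype=float)[keep]
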