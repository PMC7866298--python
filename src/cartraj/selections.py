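"""Atom-selection rules and role resolution.

Two named rules encode the analysis conventions:

* ``core`` — the heavy atoms of the base rings (6 for pyrimidines, 9 for
  purines) and the four guanidinium heavy atoms CZ, NE, NH1, NH2 of
  (methyl)arginine.  Hydrogens and the methylarginine methyl carbon are never
  included.
* ``backbone`` — N, CA, C, carbonyl O for amino acids; sugar-phosphate P,
  O5', C5', O3' for nucleotides (a 5'-terminal residue lacking P is allowed
  and noted).

Role labels (C1054, A1196, R146, the +1-codon, A-site-codon and anticodon
nucleotides) are free-form strings resolved to ``(chain, residue number)``
through the run configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import chemdata
from .io_model import Topology

logger = logging.getLogger(__name__)

#: The twelve role labels of the CAR / +1-codon / A-site / anticodon system.
ROLE_LABELS = (
    "C1054", "A1196", "R146",
    "plus1_G1", "plus1_C2", "plus1_U3",
    "Asite_C1", "Asite_C2", "Asite_U3",
    "nt34", "nt35", "nt36",
)

CAR_ROLES = ("C1054", "A1196", "R146")
PLUS1_ROLES = ("plus1_G1", "plus1_C2", "plus1_U3")
ASITE_ROLES = ("Asite_C1", "Asite_C2", "Asite_U3")
ANTICODON_ROLES = ("nt34", "nt35", "nt36")


@dataclass(frozen=True)
class AtomSelection:
    """Ordered atom indices with the rule that produced them."""

    indices: np.ndarray
    rule: str  # core | backbone | custom
    residues: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        if idx.size and len(np.unique(idx)) != idx.size:
            raise ValueError("selection contains duplicate atom indices")

    def __len__(self) -> int:
        return int(self.indices.size)

    def union(self, other: "AtomSelection") -> "AtomSelection":
        idx = np.unique(np.concatenate([self.indices, other.indices]))
        rule = self.rule if self.rule == other.rule else "custom"
        return AtomSelection(idx, rule, tuple(dict.fromkeys(
            self.residues + other.residues)))


@dataclass
class RoleMap:
    """Validated mapping from role label to ``(chain, residue number)``."""

    roles: dict[str, tuple[str, int]]
    residue_names: dict[str, str] = field(default_factory=dict)
    methylarginine_aliases: set[str] = field(default_factory=set)

    def __getitem__(self, role: str) -> tuple[str, int]:
        return self.roles[role]

    def __contains__(self, role: str) -> bool:
        return role in self.roles

    def residues(self, roles) -> list[tuple[str, int]]:
        return [self.roles[r] for r in roles]

    @property
    def labels(self) -> list[str]:
        return list(self.roles)


def _residue_keys(residues) -> list[tuple[str, int]]:
    keys = []
    for r in residues:
        if hasattr(r, "key"):
            keys.append(r.key)
        else:
            chain, num = r
            keys.append((str(chain), int(num)))
    return keys


def _select_named(topology: Topology, res, wanted: tuple[str, ...],
                  require_all: bool) -> list[int]:
    names = {chemdata.normalize_atom_name(str(topology.name[i])): int(i)
             for i in res.atom_indices}
    found, missing = [], []
    for w in wanted:
        key = chemdata.normalize_atom_name(w)
        if key in names:
            found.append(names[key])
        else:
            missing.append(w)
    if missing and require_all:
        raise ValueError(
            f"residue {res.chain}/{res.number} ({res.name}) lacks required "
            f"atoms {missing}")
    if missing:
        logger.info("residue %s/%s (%s): skipped missing backbone atom(s) %s",
                    res.chain, res.number, res.name, missing)
    return found


def core_atoms(topology: Topology, residues,
               methylarginine_aliases: set[str] | None = None) -> AtomSelection:
    """Base-ring / guanidinium heavy-atom selection for the given residues.

    Pyrimidines contribute N1, C2, N3, C4, C5, C6; purines additionally N7,
    C8, N9; (methyl)arginine contributes CZ, NE, NH1, NH2 only — the methyl
    carbon of monomethylarginine is excluded.
    """
    keys = _residue_keys(residues)
    if not keys:
        raise ValueError("core_atoms requires at least one residue")
    indices: list[int] = []
    res_keys: list[tuple[str, int]] = []
    for chain, num in keys:
        res = topology.residue(chain, num)
        letter = chemdata.base_letter(res.name)
        if letter in ("A", "G"):
            wanted = chemdata.CORE_PURINE
        elif letter in ("C", "U"):
            wanted = chemdata.CORE_PYRIMIDINE
        elif chemdata.is_arginine(res.name, methylarginine_aliases):
            wanted = chemdata.CORE_GUANIDINIUM
        else:
            raise ValueError(
                f"no core-atom rule for residue {chain}/{num} ({res.name}); "
                "core selections cover nucleotides and (methyl)arginine")
        indices.extend(_select_named(topology, res, wanted, require_all=True))
        res_keys.append((chain, num))
    return AtomSelection(np.asarray(sorted(indices), dtype=int), "core",
                         tuple(res_keys))


def backbone_atoms(topology: Topology, residues) -> AtomSelection:
    """Backbone selection: N/CA/C/O for amino acids, P/O5'/C5'/O3' for
    nucleotides.  Missing atoms (e.g. a 5'-terminal P) are skipped with a
    logged note."""
    keys = _residue_keys(residues)
    if not keys:
        raise ValueError("backbone_atoms requires at least one residue")
    indices: list[int] = []
    res_keys: list[tuple[str, int]] = []
    for chain, num in keys:
        res = topology.residue(chain, num)
        if chemdata.is_nucleotide(res.name):
            wanted = chemdata.BACKBONE_NUCLEOTIDE
        elif chemdata.is_amino_acid(res.name):
            wanted = chemdata.BACKBONE_PROTEIN
        else:
            raise ValueError(
                f"no backbone rule for residue {chain}/{num} ({res.name})")
        indices.extend(_select_named(topology, res, wanted, require_all=False))
        res_keys.append((chain, num))
    if not indices:
        raise ValueError("backbone selection is empty")
    return AtomSelection(np.asarray(sorted(indices), dtype=int), "backbone",
                         tuple(res_keys))


def selection_for_rule(topology: Topology, residues, rule: str,
                       methylarginine_aliases: set[str] | None = None,
                       ) -> AtomSelection:
    if rule == "core":
        return core_atoms(topology, residues, methylarginine_aliases)
    if rule == "backbone":
        return backbone_atoms(topology, residues)
    raise ValueError(f"unknown selection rule {rule!r}")


def resolve_roles(config: dict, topology: Topology) -> RoleMap:
    """Validate a role-map config against a topology.

    ``config`` maps role labels to ``[chain, residue number]``; the optional
    key ``methylarginine_aliases`` extends the recognised modified-residue
    names.  All twelve roles must resolve to distinct residues and the R146
    role must be arginine or monomethylarginine.
    """
    aliases = {a.upper() for a in config.get("methylarginine_aliases", [])}
    roles: dict[str, tuple[str, int]] = {}
    residue_names: dict[str, str] = {}
    for role in ROLE_LABELS:
        if role not in config:
            raise ValueError(f"role map is missing role {role!r}")
        chain, num = config[role]
        chain, num = str(chain), int(num)
        if not topology.has_residue(chain, num):
            raise ValueError(
                f"role {role!r} names residue {chain}/{num}, which is not in "
                "the topology")
        res = topology.residue(chain, num)
        roles[role] = (chain, num)
        residue_names[role] = res.name
    if len(set(roles.values())) != len(roles):
        seen: dict[tuple[str, int], str] = {}
        for role, key in roles.items():
            if key in seen:
                raise ValueError(
                    f"roles {seen[key]!r} and {role!r} map to the same residue "
                    f"{key[0]}/{key[1]}")
            seen[key] = role
    r146_name = residue_names["R146"]
    if not chemdata.is_arginine(r146_name, aliases):
        raise ValueError(
            f"role 'R146' must be arginine or monomethylarginine, got "
            f"{r146_name!r}")
    nucleotide_roles = [r for r in ROLE_LABELS if r != "R146"]
    for role in nucleotide_roles:
        if not chemdata.is_nucleotide(residue_names[role]):
            raise ValueError(
                f"role {role!r} must be a nucleotide, got "
                f"{residue_names[role]!r}")
    return RoleMap(roles, residue_names, aliases)
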