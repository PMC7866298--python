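"""Packaged chemistry tables: elements, masses, vdW radii, residue classes,
core/backbone atom rules, nucleotide atom-name templates and H-bond chemistry.

Atom names are normalised so that prime (``'``), typographic prime (``′``) and
asterisk (``*``) sugar-atom dialects compare equal (all mapped to ``'``).
"""

from __future__ import annotations

# Atomic masses (amu) and Bondi-style van der Waals radii (Å) for the elements
# that occur in nucleic acids and proteins.  Radii are overridable via config.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "K": 39.098,
    "MG": 24.305,
    "ZN": 65.38,
}

VDW_RADIUS: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
    "H": 1.20,
    "K": 2.75,
    "MG": 1.73,
    "ZN": 1.39,
}

# Residue-name vocabularies.  RNA single-letter names are the PDB v3 standard;
# the longer aliases cover common force-field and legacy dialects.
PURINE_A = {"A", "ADE", "RA", "DA", "A3", "A5", "AN"}
PURINE_G = {"G", "GUA", "RG", "DG", "G3", "G5", "GN"}
PYRIMIDINE_C = {"C", "CYT", "RC", "DC", "C3", "C5", "CN"}
PYRIMIDINE_U = {"U", "URA", "RU", "DT", "U3", "U5", "UN", "T", "THY"}

PURINES = PURINE_A | PURINE_G
PYRIMIDINES = PYRIMIDINE_C | PYRIMIDINE_U
NUCLEOTIDES = PURINES | PYRIMIDINES

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HID", "HIE", "HIP", "CYX", "DDE",
}

# Monomethyl-arginine residue names.  The set is extended at run time from the
# role-map config (``methylarginine_aliases``) because modified-residue naming
# varies between preparation tools.
METHYLARGININE_NAMES = {"MR1", "2MR", "MRG", "ARM"}
ARGININE_NAMES = {"ARG"} | METHYLARGININE_NAMES

# Core (base-ring / guanidinium) heavy-atom rules.
CORE_PYRIMIDINE = ("N1", "C2", "N3", "C4", "C5", "C6")
CORE_PURINE = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")
CORE_GUANIDINIUM = ("NE", "CZ", "NH1", "NH2")

# Backbone rules: amide backbone for amino acids, sugar-phosphate trace for
# nucleotides.  5'-terminal nucleotides may legitimately lack P.
BACKBONE_PROTEIN = ("N", "CA", "C", "O")
BACKBONE_NUCLEOTIDE = ("P", "O5'", "C5'", "O3'")

# Full heavy-atom name templates for ribonucleotides, used by the mRNA
# sequence-edit planner.  Backbone + sugar atoms are shared by all four.
SUGAR_PHOSPHATE = (
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'",
    "O2'", "C1'",
)
BASE_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"),
    "C": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"),
    "U": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"),
}

# Geometric H-bond chemistry: donors as (heavy atom -> hydrogen names),
# acceptors as lone-pair-bearing N/O atom names.  The 2'-OH and the
# phosphate/sugar oxygens are included for RNA.
_SUGAR_ACCEPTORS = ("O2'", "O4'", "O3'", "O5'", "OP1", "OP2")

HBOND_DONORS: dict[str, dict[str, tuple[str, ...]]] = {
    "A": {"N6": ("H61", "H62"), "O2'": ("HO2'",)},
    "G": {"N1": ("H1",), "N2": ("H21", "H22"), "O2'": ("HO2'",)},
    "C": {"N4": ("H41", "H42"), "O2'": ("HO2'",)},
    "U": {"N3": ("H3",), "O2'": ("HO2'",)},
    "ARG": {
        "NE": ("HE",),
        "NH1": ("HH11", "HH12"),
        "NH2": ("HH21", "HH22"),
        "N": ("H",),
    },
    # omega-N(G)-monomethylarginine: the methylated NH2 keeps one hydrogen.
    "MRG": {
        "NE": ("HE",),
        "NH1": ("HH11", "HH12"),
        "NH2": ("HH21",),
        "N": ("H",),
    },
}

HBOND_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "A": ("N1", "N3", "N7") + _SUGAR_ACCEPTORS,
    "G": ("N3", "N7", "O6") + _SUGAR_ACCEPTORS,
    "C": ("N3", "O2") + _SUGAR_ACCEPTORS,
    "U": ("O2", "O4") + _SUGAR_ACCEPTORS,
    "ARG": ("O",),
    "MRG": ("O",),
}


def normalize_atom_name(name: str) -> str:
    """Map prime/asterisk sugar-name dialects onto a single convention."""
    return name.strip().replace("*", "'").replace("′", "'").upper()


def base_letter(res_name: str) -> str | None:
    """Canonical one-letter base for a nucleotide residue name, else None."""
    r = res_name.strip().upper()
    if r in PURINE_A:
        return "A"
    if r in PURINE_G:
        return "G"
    if r in PYRIMIDINE_C:
        return "C"
    if r in PYRIMIDINE_U:
        return "U"
    return None


def is_nucleotide(res_name: str) -> bool:
    return base_letter(res_name) is not None


def is_amino_acid(res_name: str) -> bool:
    return res_name.strip().upper() in AMINO_ACIDS or is_arginine(res_name)


def is_arginine(res_name: str, extra_aliases: set[str] | None = None) -> bool:
    r = res_name.strip().upper()
    return r in ARGININE_NAMES or bool(extra_aliases and r in extra_aliases)


def is_methylarginine(res_name: str, extra_aliases: set[str] | None = None) -> bool:
    r = res_name.strip().upper()
    return r in METHYLARGININE_NAMES or bool(extra_aliases and r in extra_aliases)


def hbond_chemistry_key(res_name: str) -> str | None:
    """Key into the donor/acceptor tables for a residue name."""
    b = base_letter(res_name)
    if b is not None:
        return b
    if is_methylarginine(res_name):
        return "MRG"
    if is_arginine(res_name):
        return "ARG"
    return None


def infer_element(atom_name: str, res_name: str = "") -> str:
    """Infer the element from a PDB atom name when the element column is absent.

    Follows the usual PDB convention: digits and primes are decoration; a
    leading digit (e.g. ``1HB``) or a name starting with H after stripping
    digits is hydrogen.
    """
    name = normalize_atom_name(atom_name)
    stripped = name.lstrip("0123456789'")
    if not stripped:
        raise ValueError(f"cannot infer element for atom name {atom_name!r}")
    first = stripped[0]
    if first == "H":
        return "H"
    if first in ("C", "N", "O", "P", "S"):
        # Disambiguate two-letter metals that also start with these letters.
        if stripped[:2] in ("CL", "NA"):
            return stripped[:2]
        return first
    if stripped[:2] in ATOMIC_MASS:
        return stripped[:2]
    if first in ATOMIC_MASS:
        return first
    raise ValueError(
        f"cannot infer element for atom {atom_name!r} in residue {res_name!r}"
    )
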