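"""Shared fixtures: tiny hand-built PDB structures and small synthetic
replicate bundles (session-scoped, so the generator runs once)."""

from __future__ import annotations

import numpy as np
import pytest

import cartraj as ct
from cartraj import synthetic


def pdb_line(serial, name, resname, chain, resseq, x, y, z,
             element="", record="ATOM"):
    name_field = name if len(name) == 4 else f" {name:<3}"
    return (f"{record:<6}{serial:>5} {name_field}{'':1}{resname:<3} {chain}"
            f"{resseq:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2}")


def write_pdb(path, atoms, models=None):
    """atoms: list of (serial, name, resname, chain, resseq, xyz, element).

    With ``models`` (list of coordinate arrays) writes a multi-model file.
    """
    lines = []
    if models is None:
        for (serial, name, resname, chain, resseq, xyz, el) in atoms:
            lines.append(pdb_line(serial, name, resname, chain, resseq,
                                  *xyz, element=el))
    else:
        for m, coords in enumerate(models, start=1):
            lines.append(f"MODEL     {m:>4}")
            for (serial, name, resname, chain, resseq, _, el), xyz in zip(
                    atoms, coords):
                lines.append(pdb_line(serial, name, resname, chain, resseq,
                                      *xyz, element=el))
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def ala_atoms():
    return [
        (1, "N", "ALA", "A", 1, (0.0, 0.0, 0.0), "N"),
        (2, "CA", "ALA", "A", 1, (1.46, 0.0, 0.0), "C"),
        (3, "C", "ALA", "A", 1, (2.0, 1.4, 0.0), "C"),
    ]


@pytest.fixture
def ala_pdb(tmp_path, ala_atoms):
    return write_pdb(tmp_path / "ala.pdb", ala_atoms)


def linear_chain_atoms(n_residues=10, spacing=10.0, resname="ALA",
                       chain="A"):
    """One CA-plus-backbone residue every ``spacing`` Å along x."""
    atoms = []
    serial = 1
    for i in range(1, n_residues + 1):
        x0 = spacing * i
        for name, off in (("N", -0.7), ("CA", 0.0), ("C", 0.7), ("O", 1.2)):
            atoms.append((serial, name, resname, chain, i,
                          (x0 + off * 0.1, 0.0, 0.0), name[0]))
            serial += 1
    return atoms


@pytest.fixture(scope="session")
def r146_bundle():
    spec = synthetic.preset_spec("R146", replicate_lengths_ns=(60.0,) * 6)
    return synthetic.generate_replicates(spec, seed=101)


@pytest.fixture(scope="session")
def mr146_bundle():
    spec = synthetic.preset_spec("mR146", replicate_lengths_ns=(60.0,) * 6)
    return synthetic.generate_replicates(spec, seed=102)


@pytest.fixture(scope="session")
def role_map_r146(r146_bundle):
    return ct.resolve_roles(synthetic.default_role_map_config(),
                            r146_bundle.topology)


@pytest.fixture(scope="session")
def role_map_mr146(mr146_bundle):
    return ct.resolve_roles(synthetic.default_role_map_config(),
                            mr146_bundle.topology)


@pytest.fixture(scope="session")
def long_bundles():
    """Single long replicates of both presets for recovery checks."""
    out = {}
    for seed, preset in ((201, "R146"), (202, "mR146")):
        spec = synthetic.preset_spec(preset,
                                     replicate_lengths_ns=(2000.0,))
        out[preset] = synthetic.generate_replicates(spec, seed=seed)
    return out
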