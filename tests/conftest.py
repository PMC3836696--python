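"""Shared fixtures: hand-built structures and PDB text snippets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bindprop.structure import AtomRecord, LigandInstance, ResidueId, Structure


def make_atom(name, element, xyz, serial=1, occupancy=1.0, altloc="", het=False):
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        coords=np.asarray(xyz, dtype=float),
        occupancy=occupancy,
        altloc=altloc,
        is_hetatm=het,
    )


def make_structure(residues, ligands=(), structure_id="test"):
    """Build a Structure directly.

    residues: [(chain, seqnum, resname, [(atom_name, element, xyz), ...]), ...]
    ligands:  [(het_code, chain, seqnum, validity, [(name, element, xyz), ...]), ...]
    """
    polymer = {}
    serial = 1
    for chain, seqnum, resname, atoms in residues:
        rid = ResidueId(chain, seqnum, "", resname)
        recs = []
        for name, element, xyz in atoms:
            recs.append(make_atom(name, element, xyz, serial=serial))
            serial += 1
        polymer[rid] = recs
    het_groups = []
    for het_code, chain, seqnum, validity, atoms in ligands:
        recs = []
        for name, element, xyz in atoms:
            recs.append(make_atom(name, element, xyz, serial=serial, het=True))
            serial += 1
        het_groups.append(
            LigandInstance(het_code, (chain, seqnum, ""), recs, validity)
        )
    chains = {r.chain for r in polymer}
    return Structure(
        structure_id=structure_id,
        polymer_residues=polymer,
        het_groups=het_groups,
        waters=[],
        chain_count=len(chains),
        normalized=True,
    )


def pdb_line(record, serial, name, resname, chain, seqnum, xyz,
             element, occupancy=1.00, altloc=" ", icode=" "):
    atom_field = name if len(name) == 4 else f" {name:<3s}"
    x, y, z = xyz
    return (
        f"{record:<6s}{serial:>5d} {atom_field:<4s}{altloc}{resname:>3s} "
        f"{chain}{seqnum:>4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{occupancy:6.2f}{0.0:6.2f}          {element:>2s}"
    )


@pytest.fixture
def toy_pdb_text():
    """3 polymer residues + 1 glycerol HETATM group + 2 waters."""
    lines = [
        pdb_line("ATOM", 1, "N", "ALA", "A", 1, (0, 0, 0), "N"),
        pdb_line("ATOM", 2, "CA", "ALA", "A", 1, (1.4, 0, 0), "C"),
        pdb_line("ATOM", 3, "C", "ALA", "A", 1, (2.2, 1.1, 0), "C"),
        pdb_line("ATOM", 4, "O", "ALA", "A", 1, (3.4, 1.1, 0), "O"),
        pdb_line("ATOM", 5, "CB", "ALA", "A", 1, (1.9, -1.3, 0), "C"),
        pdb_line("ATOM", 6, "N", "GLY", "A", 2, (1.7, 2.2, 0), "N"),
        pdb_line("ATOM", 7, "CA", "GLY", "A", 2, (2.4, 3.4, 0), "C"),
        pdb_line("ATOM", 8, "C", "GLY", "A", 2, (3.9, 3.3, 0), "C"),
        pdb_line("ATOM", 9, "O", "GLY", "A", 2, (4.5, 2.2, 0), "O"),
        pdb_line("ATOM", 10, "N", "SER", "A", 3, (4.5, 4.5, 0), "N"),
        pdb_line("ATOM", 11, "CA", "SER", "A", 3, (5.9, 4.5, 0), "C"),
        pdb_line("ATOM", 12, "C", "SER", "A", 3, (6.6, 5.8, 0), "C"),
        pdb_line("ATOM", 13, "O", "SER", "A", 3, (7.8, 5.8, 0), "O"),
        pdb_line("ATOM", 14, "CB", "SER", "A", 3, (6.6, 3.2, 0), "C"),
        pdb_line("ATOM", 15, "OG", "SER", "A", 3, (6.0, 2.0, 0), "O"),
        pdb_line("HETATM", 16, "C1", "GOL", "A", 101, (0.0, 5.0, 3.0), "C"),
        pdb_line("HETATM", 17, "O1", "GOL", "A", 101, (0.0, 6.3, 3.3), "O"),
        pdb_line("HETATM", 18, "C2", "GOL", "A", 101, (1.2, 4.3, 3.5), "C"),
        pdb_line("HETATM", 19, "O2", "GOL", "A", 101, (1.2, 3.0, 3.1), "O"),
        pdb_line("HETATM", 20, "C3", "GOL", "A", 101, (2.4, 5.0, 3.1), "C"),
        pdb_line("HETATM", 21, "O3", "GOL", "A", 101, (3.6, 4.4, 3.4), "O"),
        pdb_line("HETATM", 22, "O", "HOH", "A", 201, (9.0, 9.0, 9.0), "O"),
        pdb_line("HETATM", 23, "O", "HOH", "A", 202, (10.0, 10.0, 10.0), "O"),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def gol_annotations():
    return pd.DataFrame(
        {
            "structure_id": ["test"],
            "het_code": ["GOL"],
            "chain": [""],
            "seqnum": [""],
            "icode": [""],
            "validity": ["invalid"],
        }
    )
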