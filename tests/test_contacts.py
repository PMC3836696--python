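"""Contact detection, hbond/vdW typing and SC/BB-only classification."""

import numpy as np
import pytest

from bindprop.contacts import (
    classify_contact_type,
    classify_residue_interaction,
    find_contacts,
    group_contacts,
    summarize_contacts,
)
from bindprop.sites import build_binding_site
from bindprop.structure import normalize_structure, parse_structure
from bindprop.synthetic import ToyComplexSpec, generate_toy_complex

from conftest import make_structure


@pytest.mark.parametrize(
    "pe,le,d,expected",
    [
        ("N", "O", 3.2, "hbond"),
        ("C", "O", 3.2, "vdw"),   # carbon on either side is never an hbond
        ("N", "C", 3.2, "vdw"),
        ("N", "O", 3.8, "vdw"),   # beyond 3.5 everything is vdw
        ("N", "O", 3.5, "hbond"), # boundary inclusive
        ("S", "P", 3.5, "hbond"),
        ("C", "C", 4.0, "vdw"),
    ],
)
def test_contact_type_rules(pe, le, d, expected):
    assert classify_contact_type(pe, le, d) == expected


def _one_atom_structure(x, element="N", resname="ALA", name="N"):
    s = make_structure(
        [("A", 1, resname, [(name, element, (x, 0.0, 0.0))])],
        ligands=[("LIG", "X", 901, "valid", [("O1", "O", (0.0, 0.0, 0.0))])],
    )
    return s, s.het_groups[0]


def test_contact_within_cutoff():
    s, lig = _one_atom_structure(3.9)
    contacts = find_contacts(s, lig)
    assert len(contacts) == 1
    assert contacts[0].distance == pytest.approx(3.9)
    assert contacts[0].interaction == "vdw"


def test_no_contact_beyond_cutoff():
    s, lig = _one_atom_structure(4.05)
    assert find_contacts(s, lig) == []


def test_cutoff_boundary_inclusive_exact():
    s, lig = _one_atom_structure(4.0)
    assert len(find_contacts(s, lig)) == 1
    s, lig = _one_atom_structure(3.5)
    (c,) = find_contacts(s, lig)
    assert c.interaction == "hbond"


def test_residue_contacting_two_ligands_counted_per_ligand():
    s = make_structure(
        [("A", 1, "SER", [("OG", "O", (0.0, 0.0, 0.0))])],
        ligands=[
            ("AAA", "X", 901, "valid", [("O1", "O", (3.0, 0.0, 0.0))]),
            ("BBB", "X", 902, "valid", [("O1", "O", (-3.0, 0.0, 0.0))]),
        ],
    )
    for lig in s.het_groups:
        contacts = find_contacts(s, lig)
        assert len(contacts) == 1
        assert contacts[0].residue.seqnum == 1


def test_empty_ligand_rejected():
    s, lig = _one_atom_structure(3.0)
    lig.atoms = []
    with pytest.raises(ValueError, match="no heavy atoms"):
        find_contacts(s, lig)


def test_residue_category_sidechain_only():
    s = make_structure(
        [("A", 1, "ALA", [("CB", "C", (3.0, 0, 0))])],
        ligands=[("LIG", "X", 901, "valid", [("O1", "O", (0, 0, 0))])],
    )
    contacts = find_contacts(s, s.het_groups[0])
    ri = classify_residue_interaction(contacts)
    assert ri.category == "SC"
    assert ri.n_contacts == ri.n_hbond + ri.n_vdw == 1


def test_residue_category_backbone_only():
    s = make_structure(
        [("A", 1, "ALA", [("N", "N", (3.0, 0, 0)), ("O", "O", (0, 3.2, 0))])],
        ligands=[("LIG", "X", 901, "valid", [("O1", "O", (0, 0, 0))])],
    )
    ri = classify_residue_interaction(find_contacts(s, s.het_groups[0]))
    assert ri.category == "BB_only"
    assert ri.n_hbond == 2


def test_gly_ca_contact_is_sidechain():
    s = make_structure(
        [("A", 1, "GLY", [("CA", "C", (3.0, 0, 0))])],
        ligands=[("LIG", "X", 901, "valid", [("O1", "O", (0, 0, 0))])],
    )
    ri = classify_residue_interaction(find_contacts(s, s.het_groups[0]))
    assert ri.category == "SC"


def test_empty_contact_group_rejected():
    with pytest.raises(ValueError, match="empty"):
        classify_residue_interaction([])


def test_cutoff_monotonicity_on_toy_complex():
    text, _ = generate_toy_complex(ToyComplexSpec(n_shell_residues=40, seed=2))
    s = normalize_structure(parse_structure(text))
    lig = s.het_groups[0]
    small = {
        (c.residue.key(), c.protein_atom, c.ligand_atom)
        for c in find_contacts(s, lig, cutoff=3.5)
    }
    large = {
        (c.residue.key(), c.protein_atom, c.ligand_atom)
        for c in find_contacts(s, lig, cutoff=4.0)
    }
    assert small <= large
    assert small != large  # the generator straddles the boundary


def test_kdtree_matches_all_pairs_scan():
    """Independent O(n^2) oracle for the neighbor search."""
    text, _ = generate_toy_complex(
        ToyComplexSpec(n_shell_residues=60, jitter=0.15, seed=9)
    )
    s = normalize_structure(parse_structure(text))
    lig = s.het_groups[0]
    found = {
        (c.residue.key(), c.protein_atom, c.ligand_atom): round(c.distance, 6)
        for c in find_contacts(s, lig)
    }
    naive = {}
    rids, atoms, coords = s.polymer_atom_table()
    for rid, pa in zip(rids, atoms):
        for la in lig.atoms:
            d = float(np.linalg.norm(pa.coords - la.coords))
            if d <= 4.0:
                naive[(rid.key(), pa.name, la.name)] = round(d, 6)
    assert found == naive


def _site_from(residues, lig_atoms, validity="valid"):
    s = make_structure(residues, ligands=[("LIG", "X", 901, validity, lig_atoms)])
    lig = s.het_groups[0]
    contacts = find_contacts(s, lig)
    return build_binding_site(s, lig, contacts, surface=None)


def test_summary_single_ala_site():
    # Ala with 4 ligand atoms in range of CB: 4 contacts over 5 heavy atoms
    site = _site_from(
        [("A", 1, "ALA", [("CB", "C", (3.0, 0, 0))])],
        [("C1", "C", (0, 0, 0)), ("C2", "C", (0.5, 0, 0)),
         ("C3", "C", (0, 0.5, 0)), ("C4", "C", (0.5, 0.5, 0))],
    )
    table = summarize_contacts([site])
    ala = table[table.resname == "ALA"].iloc[0]
    assert ala["contacts_per_residue"] == pytest.approx(4.0)
    assert ala["contacts_per_heavy_atom"] == pytest.approx(0.8)
    assert ala["pct_site"] == pytest.approx(100.0)


def test_summary_mean_over_residues():
    lig5 = [("C1", "C", (0, 0, 0))] * 5
    lig7 = [("C1", "C", (0, 0, 0))] * 7
    s1 = _site_from([("A", 1, "SER", [("OG", "O", (3.0, 0, 0))])], lig5)
    s2 = _site_from([("A", 2, "SER", [("OG", "O", (3.0, 0, 0))])], lig7)
    table = summarize_contacts([s1, s2])
    ser = table[table.resname == "SER"].iloc[0]
    assert ser["contacts_per_residue"] == pytest.approx(6.0)


def test_summary_matches_naive_tally_on_generated_sites():
    sites = []
    expected_counts = {}
    expected_hb = {}
    for i in range(10):
        text, truth = generate_toy_complex(
            ToyComplexSpec(n_shell_residues=12, seed=100 + i)
        )
        s = normalize_structure(parse_structure(text, structure_id=f"t{i}"))
        lig = s.het_groups[0]
        contacts = find_contacts(s, lig)
        sites.append(build_binding_site(s, lig, contacts, surface=None))
        # naive recount from the generator's independent ground truth
        per_res = {}
        for (ch, seq, ic, resname, *_rest) in truth.contacts:
            per_res.setdefault((i, ch, seq), resname)
        for (ch, seq, ic, resname, _a, _l, _d, inter, _r) in truth.contacts:
            expected_counts[resname] = expected_counts.get(resname, 0) + 1
            if inter == "hbond":
                expected_hb[resname] = expected_hb.get(resname, 0) + 1
    table = summarize_contacts(sites).set_index("resname")
    for resname, total in expected_counts.items():
        row = table.loc[resname]
        assert row["n_residues"] > 0
        assert row["contacts_per_residue"] * row["n_residues"] == pytest.approx(total)
    # exhaustiveness: hbond + vdw = total
    for site in sites:
        n_hb = sum(c.interaction == "hbond" for c in site.contacts)
        n_vdw = sum(c.interaction == "vdw" for c in site.contacts)
        assert n_hb + n_vdw == len(site.contacts)


def test_summary_rejects_empty():
    with pytest.raises(ValueError):
        summarize_contacts([])
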