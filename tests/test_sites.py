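"""Binding-site assembly, surface filtering, dedup and accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bindprop.contacts import find_contacts
from bindprop.residues import AMINO_ACIDS
from bindprop.sasa import SurfaceTable
from bindprop.sites import (
    BindingSite,
    build_binding_site,
    dataset_summary,
    deduplicate_sites,
)

from conftest import make_structure


def _surface(rows):
    return SurfaceTable(
        residues=pd.DataFrame(
            rows, columns=["chain", "seqnum", "icode", "resname", "abs_side", "abs_main"]
        ).assign(abs_total=lambda d: d.abs_side + d.abs_main),
        atom_areas=np.array([]),
    )


def _three_residue_site(areas, resnames=("SER", "THR", "ASN"), cutoff=5.0):
    residues = [
        ("A", i + 1, rn, [("OG" if rn == "SER" else "CB", "O" if rn == "SER" else "C",
                           (3.0, 0.6 * i, 0))])
        for i, rn in enumerate(resnames)
    ]
    s = make_structure(residues, ligands=[("LIG", "X", 901, "valid",
                                           [("O1", "O", (0, 0, 0))])])
    lig = s.het_groups[0]
    table = _surface(
        [("A", i + 1, "", rn, a, 1.0) for i, (rn, a) in enumerate(zip(resnames, areas))]
    )
    contacts = find_contacts(s, lig)
    return build_binding_site(s, lig, contacts, table, cutoff=cutoff)


def test_surface_subset_by_threshold():
    site = _three_residue_site([10.0, 6.0, 1.0])
    assert site.n_residues == 3
    assert len(site.surface_sc_residues) == 2


def test_all_buried_site_has_empty_surface_subset():
    site = _three_residue_site([1.0, 0.5, 0.0])
    assert not site.has_exposed_residues
    assert site.surface_resnames("SC") == []


def test_gly_max_rule_in_sc_surface_subset():
    s = make_structure(
        [("A", 1, "GLY", [("CA", "C", (3.0, 0, 0))])],
        ligands=[("LIG", "X", 901, "valid", [("O1", "O", (0, 0, 0))])],
    )
    lig = s.het_groups[0]
    table = _surface([("A", 1, "", "GLY", 1.0, 7.0)])  # abs_side 1, abs_main 7
    site = build_binding_site(s, lig, find_contacts(s, lig), table, cutoff=5.0)
    assert site.surface_sc_residues == {("A", 1, "")}


def test_site_sasa_sums_contacting_residue_areas():
    site = _three_residue_site([10.0, 6.0, 1.0])
    # each residue row has abs_main 1.0 -> totals 11, 7, 2
    assert site.site_sasa == pytest.approx(11.0 + 7.0 + 2.0)


def _stub_site(het, resnames, validity="valid", instance=0, sasa=0.0,
               structure_id="s1", surface_resnames=None):
    keys = {("A", i + 1, ""): rn for i, rn in enumerate(resnames)}
    surf = set(keys) if surface_resnames is None else {
        k for k, rn in keys.items() if rn in surface_resnames
    }
    return BindingSite(
        structure_id=structure_id,
        het_code=het,
        ligand_instance=("X", 900 + instance, ""),
        validity=validity,
        contacts=[],
        interactions=[],
        sc_residues=set(keys),
        bb_only_residues=set(),
        surface_sc_residues=surf,
        surface_bb_residues=set(),
        site_sasa=sasa,
        resname_by_key=keys,
    )


def test_dedup_identical_composition_collapses():
    a = _stub_site("GOL", ["SER", "SER", "ASP"], instance=0)
    b = _stub_site("GOL", ["SER", "SER", "ASP"], instance=1)
    kept = deduplicate_sites([a, b])
    assert kept == [a]


def test_dedup_keeps_differing_compositions():
    a = _stub_site("GOL", ["SER", "SER", "ASP"], instance=0)
    b = _stub_site("GOL", ["SER", "SER", "ASP", "ASP"], instance=1)
    assert len(deduplicate_sites([a, b])) == 2


def test_dedup_is_per_ligand_code():
    a = _stub_site("GOL", ["SER", "ASP"], instance=0)
    b = _stub_site("EDO", ["SER", "ASP"], instance=1)
    assert len(deduplicate_sites([a, b])) == 2


@settings(max_examples=30, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.sampled_from(["AAA", "BBB"]),
            st.lists(st.sampled_from(list(AMINO_ACIDS[:6])), min_size=1, max_size=4),
        ),
        min_size=1,
        max_size=12,
    )
)
def test_dedup_idempotent_and_preserves_classes(specs):
    sites = [
        _stub_site(het, resnames, instance=i)
        for i, (het, resnames) in enumerate(specs)
    ]
    once = deduplicate_sites(sites)
    assert deduplicate_sites(once) == once
    # every (het, count-vector) class keeps exactly one representative
    assert {s.site_key() for s in sites} == {s.site_key() for s in once}
    assert len(once) == len({s.site_key() for s in sites})


def test_dataset_summary_means_and_medians():
    sites = {
        "s1": [
            _stub_site("AAA", ["SER"] * 4, structure_id="s1", instance=0),
            _stub_site("BBB", ["ASP"] * 4, structure_id="s1", instance=1),
        ],
        "s2": [_stub_site("AAA", ["THR"] * 6, structure_id="s2", instance=0)],
    }
    table = dataset_summary(sites)
    row = table[(table.validity == "valid") & (table.category == "SC")].iloc[0]
    assert row["n_sites_nonredundant"] == 3
    assert row["mean_residues_per_site"] == pytest.approx(14 / 3, rel=1e-6)
    assert row["median_residues_per_site"] == pytest.approx(4)


def test_dataset_summary_dedup_accounting():
    dup = [
        _stub_site("AAA", ["SER", "ASP"], structure_id="s1", instance=0),
        _stub_site("AAA", ["SER", "ASP"], structure_id="s1", instance=1),
        _stub_site("AAA", ["SER", "THR"], structure_id="s1", instance=2),
    ]
    table = dataset_summary({"s1": dup})
    row = table[(table.validity == "valid") & (table.category == "SC")].iloc[0]
    assert row["n_sites_total"] == 3
    assert row["n_sites_nonredundant"] == 2  # one duplicate removed


def test_dataset_summary_matches_naive_recount():
    rng = np.random.default_rng(4)
    sites_by_structure = {}
    naive_sizes = {"valid": [], "invalid": []}
    for sid in ("s1", "s2", "s3"):
        sites = []
        for i in range(int(rng.integers(1, 5))):
            validity = "valid" if rng.random() < 0.6 else "invalid"
            resnames = list(
                rng.choice(AMINO_ACIDS[:8], size=int(rng.integers(1, 6)))
            )
            sites.append(
                _stub_site("AAA", resnames, validity=validity,
                           structure_id=sid, instance=i)
            )
        sites_by_structure[sid] = sites
        seen = {"valid": set(), "invalid": set()}
        for s in sites:
            key = s.site_key()
            if key not in seen[s.validity]:
                seen[s.validity].add(key)
                naive_sizes[s.validity].append(s.n_residues)
    table = dataset_summary(sites_by_structure)
    for validity, sizes in naive_sizes.items():
        if not sizes:
            continue
        row = table[(table.validity == validity) & (table.category == "SC")].iloc[0]
        assert row["n_sites_nonredundant"] == len(sizes)
        assert row["mean_residues_per_site"] == pytest.approx(np.mean(sizes))
        assert row["median_residues_per_site"] == pytest.approx(np.median(sizes))
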