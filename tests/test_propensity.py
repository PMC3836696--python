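"""Pooled frequencies, propensities and ratio statistics."""

import numpy as np
import pytest

from bindprop.propensity import (
    CompositionDataset,
    FrequencyTable,
    accumulate_frequencies,
    compute_propensity,
    exclude_top_ligands,
    pooled_propensity,
    propensity_ratio,
)
from bindprop.residues import AA_INDEX, AMINO_ACIDS, N_AA
from bindprop.synthetic import (
    CompositionSpec,
    enrichment_from_dict,
    generate_composition_dataset,
)


def vec(**counts):
    v = np.zeros(N_AA, dtype=np.int64)
    for name, c in counts.items():
        v[AA_INDEX[name.upper()]] = c
    return v


def test_pooling_sums_counts_before_division():
    t = accumulate_frequencies([vec(ALA=1), vec(ARG=1)])
    assert t.frequencies[AA_INDEX["ALA"]] == pytest.approx(0.5)
    assert t.frequencies.sum() == pytest.approx(1.0)


def test_single_site_frequencies():
    t = accumulate_frequencies([vec(TRP=2, ALA=2)])
    assert t.frequencies[AA_INDEX["TRP"]] == pytest.approx(0.5)


def test_resname_lists_accepted():
    t = accumulate_frequencies([["ALA", "ALA", "TRP"], ["TRP"]])
    assert t.counts[AA_INDEX["ALA"]] == 2
    assert t.counts[AA_INDEX["TRP"]] == 2


def test_zero_total_is_an_error():
    with pytest.raises(ValueError, match="zero total"):
        accumulate_frequencies([vec()], interaction_class="SC", validity="valid")


def test_pooled_table_matches_naive_recount():
    rng = np.random.default_rng(0)
    sites = [rng.multinomial(10, np.full(N_AA, 1 / N_AA)) for _ in range(100)]
    t = accumulate_frequencies(np.array(sites))
    naive = np.zeros(N_AA, dtype=int)
    for s in sites:
        for i in range(N_AA):
            naive[i] += s[i]
    np.testing.assert_array_equal(t.counts, naive)
    np.testing.assert_allclose(t.frequencies, naive / naive.sum())


def _ft(counts, region="binding_site", cls="SC"):
    return FrequencyTable(region, cls, "all", np.asarray(counts))


def test_identical_frequencies_give_unit_propensity():
    counts = np.arange(1, N_AA + 1)
    res = compute_propensity(_ft(counts), _ft(counts, region="protein_surface"))
    np.testing.assert_allclose(res.values, 1.0)


def test_direct_ratio():
    bs = np.ones(N_AA)
    ps = np.ones(N_AA)
    bs[AA_INDEX["TRP"]] = 4.0   # F_bs(Trp) doubles relative to F_ps(Trp)
    ps[AA_INDEX["TRP"]] = 2.0
    bs_f = bs / bs.sum()
    ps_f = ps / ps.sum()
    expected = bs_f[AA_INDEX["TRP"]] / ps_f[AA_INDEX["TRP"]]
    res = compute_propensity(_ft(bs), _ft(ps, region="protein_surface"))
    assert res.values[AA_INDEX["TRP"]] == pytest.approx(expected)


def test_zero_surface_frequency_flagged_not_infinite():
    bs = np.ones(N_AA)
    ps = np.ones(N_AA)
    ps[AA_INDEX["CYS"]] = 0
    res = compute_propensity(_ft(bs), _ft(ps, region="protein_surface"))
    assert res.undefined[AA_INDEX["CYS"]]
    assert np.isnan(res.values[AA_INDEX["CYS"]])
    assert np.isfinite(res.values[~res.undefined]).all()


def test_class_mismatch_rejected():
    with pytest.raises(ValueError, match="mismatch"):
        compute_propensity(_ft(np.ones(N_AA), cls="SC"),
                           _ft(np.ones(N_AA), cls="BB_only"))


def test_ratio_identity_and_arithmetic():
    a = compute_propensity(_ft(np.ones(N_AA)), _ft(np.ones(N_AA)))
    np.testing.assert_allclose(propensity_ratio(a, a), 1.0)
    v = compute_propensity(_ft(np.ones(N_AA)), _ft(np.ones(N_AA)))
    i = compute_propensity(_ft(np.ones(N_AA)), _ft(np.ones(N_AA)))
    v.values = np.full(N_AA, 1.2)
    i.values = np.full(N_AA, 0.8)
    np.testing.assert_allclose(propensity_ratio(v, i), 1.5)


def test_ratio_propagates_undefined():
    v = compute_propensity(_ft(np.ones(N_AA)), _ft(np.ones(N_AA)))
    i = compute_propensity(_ft(np.ones(N_AA)), _ft(np.ones(N_AA)))
    i.values[0] = np.nan
    assert np.isnan(propensity_ratio(v, i)[0])


def _tiny_dataset():
    surface = np.tile(vec(ALA=5, ARG=5, ASN=5, TRP=1), (4, 1))
    site_counts = np.array([
        vec(ALA=2, TRP=1), vec(ARG=2), vec(ALA=1, ASN=1), vec(TRP=2),
    ])
    return CompositionDataset(
        surface_counts=surface,
        site_counts=site_counts,
        site_protein=np.array([0, 1, 2, 3]),
        site_validity=np.array(["valid", "valid", "invalid", "invalid"]),
        site_het=np.array(["AAA", "AAA", "BBB", "CCC"], dtype=object),
    )


def test_pooled_propensity_counts_only_contributing_proteins():
    ds = _tiny_dataset()
    res = pooled_propensity(ds, "valid")
    # valid sites live on proteins 0 and 1 only -> surface pools 2 proteins
    assert res.n_structures == 2
    f_bs = np.array([2, 2, 0, 1]) / 5  # ALA, ARG, ASN, TRP among 5 residues
    f_ps = np.array([10, 10, 10, 2]) / 32
    for aa, b, p in zip(["ALA", "ARG", "ASN", "TRP"], f_bs, f_ps):
        assert res.values[AA_INDEX[aa]] == pytest.approx(b / p)


def test_scale_invariance_under_duplication():
    ds = _tiny_dataset()
    doubled = CompositionDataset(
        surface_counts=np.vstack([ds.surface_counts] * 2),
        site_counts=np.vstack([ds.site_counts] * 2),
        site_protein=np.concatenate([ds.site_protein, ds.site_protein + 4]),
        site_validity=np.concatenate([ds.site_validity] * 2),
        site_het=np.concatenate([ds.site_het] * 2),
    )
    a = pooled_propensity(ds, "valid").values
    b = pooled_propensity(doubled, "valid").values
    np.testing.assert_allclose(a[~np.isnan(a)], b[~np.isnan(b)])


def test_pooling_differs_from_mean_of_per_site_propensities():
    ds = _tiny_dataset()
    pooled = pooled_propensity(ds, "valid").values[AA_INDEX["ALA"]]
    per_site = []
    for j in [0, 1]:
        bs = ds.site_counts[j] / ds.site_counts[j].sum()
        ps = ds.surface_counts[j] / ds.surface_counts[j].sum()
        per_site.append(bs[AA_INDEX["ALA"]] / ps[AA_INDEX["ALA"]])
    assert pooled != pytest.approx(np.mean(per_site))
    # but pooling equals the per-site value when all sites are identical
    same = CompositionDataset(
        surface_counts=ds.surface_counts[:2],
        site_counts=np.array([vec(ALA=2), vec(ALA=2)]),
        site_protein=np.array([0, 1]),
        site_validity=np.array(["valid", "valid"]),
    )
    pooled_same = pooled_propensity(same, "valid").values[AA_INDEX["ALA"]]
    one_site = (2 / 2) / (5 / 16)
    assert pooled_same == pytest.approx(one_site)


def test_exclude_top_ligands_identity_and_boundary():
    ds = _tiny_dataset()
    assert exclude_top_ligands(ds, 0) is ds
    none_left = exclude_top_ligands(ds, 3)
    assert none_left.n_sites == 0


def test_exclude_top_ligands_drops_dominant_code():
    ds = _tiny_dataset()
    filtered = exclude_top_ligands(ds, 1)
    # AAA dominates valids; BBB and CCC tie at 1 among invalids -> BBB dropped
    assert "AAA" not in set(filtered.site_het)
    assert "CCC" in set(filtered.site_het)
    assert "BBB" not in set(filtered.site_het)


def test_enrichment_recovery_moderate_size():
    k = enrichment_from_dict({"PHE": 1.5, "TRP": 2.0, "GLU": 0.6})
    ds, truth = generate_composition_dataset(
        CompositionSpec(n_proteins=600, enrichment_valid=k, seed=21)
    )
    est = pooled_propensity(ds, "valid").values
    expected = truth.expected_propensity_valid
    common = truth.background >= 0.02
    assert np.all(np.abs(est[common] / expected[common] - 1) < 0.10)
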