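"""Pooled residue frequencies and binding-site propensities.

The propensity of amino acid *i* is the ratio of its pooled frequency
over binding-site surfaces to its pooled frequency over whole protein
surfaces:

    P_i = F_i^BS / F_i^PS,
    F_i^BS = (Σ_j n_ij) / (Σ_j Σ_k n_kj),   j over binding sites,
    F_i^PS = (Σ_p m_ip) / (Σ_p Σ_k m_kp),   p over proteins.

Counts are summed across the whole set *before* division — never a mean
of per-protein ratios — because rare residues are absent from many
individual surfaces and per-protein ratios would divide by zero or blow
up.  P_i > 1 marks over-representation in binding sites; P_i < 1
under-representation.  When computing a binding-site class (SC or
BB-only, valid or invalid), only proteins contributing at least one site
of that class enter the surface denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .residues import AMINO_ACIDS, N_AA

VALID = "valid"
INVALID = "invalid"


@dataclass
class CompositionDataset:
    """Count-matrix view of a structure set, the unit of all statistics.

    surface_counts
        (P, 20) pooled surface residue-type counts per protein.
    site_counts
        (J, 20) residue-type counts of each (surface-filtered) site.
    site_protein
        (J,) index of the owning protein.
    site_validity
        (J,) array of "valid" / "invalid".
    site_het
        (J,) HET codes ("" when synthetic sites carry none).
    enzyme
        optional (P,) boolean subgroup labels.
    """

    surface_counts: np.ndarray
    site_counts: np.ndarray
    site_protein: np.ndarray
    site_validity: np.ndarray
    site_het: np.ndarray | None = None
    enzyme: np.ndarray | None = None
    protein_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.surface_counts = np.asarray(self.surface_counts)
        self.site_counts = np.asarray(self.site_counts)
        self.site_protein = np.asarray(self.site_protein)
        self.site_validity = np.asarray(self.site_validity)
        if self.surface_counts.shape[1] != N_AA:
            raise ValueError("surface_counts must have 20 columns")
        if self.site_counts.shape[0] != len(self.site_protein):
            raise ValueError("site_counts and site_protein disagree")
        if self.site_het is not None:
            self.site_het = np.asarray(self.site_het, dtype=object)

    @property
    def n_proteins(self) -> int:
        return self.surface_counts.shape[0]

    @property
    def n_sites(self) -> int:
        return self.site_counts.shape[0]

    def subset_proteins(self, idx: np.ndarray) -> "CompositionDataset":
        """Restrict to the given protein indices (sites follow)."""
        idx = np.asarray(idx)
        keep_protein = np.zeros(self.n_proteins, dtype=bool)
        keep_protein[idx] = True
        remap = -np.ones(self.n_proteins, dtype=np.int64)
        remap[idx] = np.arange(len(idx))
        site_mask = keep_protein[self.site_protein]
        return CompositionDataset(
            surface_counts=self.surface_counts[idx],
            site_counts=self.site_counts[site_mask],
            site_protein=remap[self.site_protein[site_mask]],
            site_validity=self.site_validity[site_mask],
            site_het=None if self.site_het is None else self.site_het[site_mask],
            enzyme=None if self.enzyme is None else self.enzyme[idx],
        )


@dataclass
class FrequencyTable:
    region: str  # "binding_site" | "protein_surface"
    interaction_class: str  # "SC" | "BB_only" | "any"
    validity: str  # "valid" | "invalid" | "all"
    counts: np.ndarray
    n_structures: int = 0
    n_sites: int = 0

    @property
    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError(
                f"zero total count for ({self.region}, {self.interaction_class}, "
                f"{self.validity})"
            )
        return self.counts / total


@dataclass
class PropensityResult:
    values: np.ndarray  # (20,), NaN where undefined
    undefined: np.ndarray  # (20,) bool: surface frequency was zero
    interaction_class: str = "SC"
    validity: str = "all"
    n_structures: int = 0
    n_sites: int = 0

    def as_dict(self) -> dict[str, float]:
        return {aa: float(v) for aa, v in zip(AMINO_ACIDS, self.values)}


def accumulate_frequencies(
    items,
    region: str = "binding_site",
    interaction_class: str = "SC",
    validity: str = "all",
    n_structures: int = 0,
) -> FrequencyTable:
    """Pool residue counts across sites or protein surfaces.

    ``items`` is either an (n, 20) count matrix or an iterable of
    per-item count vectors / resname lists.  Counts are summed before
    any division.
    """
    from .residues import count_vector

    if isinstance(items, np.ndarray) and items.ndim == 2:
        arr = items
    else:
        vectors = []
        for item in items:
            v = np.asarray(item)
            if v.dtype.kind in "iuf" and v.shape == (N_AA,):
                vectors.append(v)
            else:
                vectors.append(count_vector(item))
        arr = np.array(vectors)
    if arr.ndim != 2 or arr.shape[1] != N_AA:
        raise ValueError("items must reduce to an (n, 20) count matrix")
    counts = arr.sum(axis=0).astype(np.int64)
    table = FrequencyTable(
        region=region,
        interaction_class=interaction_class,
        validity=validity,
        counts=counts,
        n_structures=n_structures,
        n_sites=arr.shape[0] if region == "binding_site" else 0,
    )
    table.frequencies  # trigger zero-total error eagerly
    return table


def compute_propensity(bs: FrequencyTable, ps: FrequencyTable) -> PropensityResult:
    """P_i = F_i^BS / F_i^PS with explicit undefined handling.

    A zero surface frequency never produces infinity: the residue is
    flagged undefined (NaN) instead, whether or not it was seen in
    sites.
    """
    if bs.interaction_class != ps.interaction_class:
        raise ValueError(
            f"class mismatch: {bs.interaction_class} vs {ps.interaction_class}"
        )
    f_bs = bs.frequencies
    f_ps = ps.frequencies
    undefined = f_ps == 0
    values = np.full(N_AA, np.nan)
    ok = ~undefined
    values[ok] = f_bs[ok] / f_ps[ok]
    return PropensityResult(
        values=values,
        undefined=undefined,
        interaction_class=bs.interaction_class,
        validity=bs.validity,
        n_structures=ps.n_structures,
        n_sites=bs.n_sites,
    )


def propensity_ratio(
    valid: PropensityResult, invalid: PropensityResult
) -> np.ndarray:
    """Per-residue valid/invalid propensity ratio; NaN propagates."""
    if valid.interaction_class != invalid.interaction_class:
        raise ValueError("class mismatch between valid and invalid results")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = valid.values / invalid.values
    ratio[~np.isfinite(ratio)] = np.nan
    return ratio


def pooled_propensity(
    dataset: CompositionDataset,
    validity: str | None = None,
    protein_idx: np.ndarray | None = None,
) -> PropensityResult:
    """Pooled propensity of one validity class over a protein subset.

    The surface denominator pools only proteins that contribute at least
    one site of the class within the subset.
    """
    site_mask = np.ones(dataset.n_sites, dtype=bool)
    if validity is not None:
        site_mask &= dataset.site_validity == validity
    if protein_idx is not None:
        keep = np.zeros(dataset.n_proteins, dtype=bool)
        keep[np.asarray(protein_idx)] = True
        site_mask &= keep[dataset.site_protein]
    bs_counts = dataset.site_counts[site_mask].sum(axis=0)
    contributing = np.unique(dataset.site_protein[site_mask])
    ps_counts = dataset.surface_counts[contributing].sum(axis=0)
    bs = FrequencyTable(
        "binding_site", "SC", validity or "all", bs_counts,
        n_structures=len(contributing), n_sites=int(site_mask.sum()),
    )
    ps = FrequencyTable(
        "protein_surface", "SC", validity or "all", ps_counts,
        n_structures=len(contributing),
    )
    return compute_propensity(bs, ps)


def exclude_top_ligands(dataset: CompositionDataset, k: int) -> CompositionDataset:
    """Drop every site whose ligand is among the k most frequent HET codes
    of its validity class (site-count ranking, ties broken lexicographically).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return dataset
    if dataset.site_het is None:
        raise ValueError("dataset carries no HET codes")
    drop = np.zeros(dataset.n_sites, dtype=bool)
    for validity in np.unique(dataset.site_validity):
        mask = dataset.site_validity == validity
        hets, counts = np.unique(dataset.site_het[mask], return_counts=True)
        order = sorted(zip(-counts, hets))  # count desc, het asc
        top = {het for _, het in order[:k]}
        drop |= mask & np.isin(dataset.site_het, list(top))
    keep = ~drop
    return replace(
        dataset,
        site_counts=dataset.site_counts[keep],
        site_protein=dataset.site_protein[keep],
        site_validity=dataset.site_validity[keep],
        site_het=dataset.site_het[keep],
    )


def dataset_from_sites(
    sites_by_structure: dict[str, list],
    surface_resnames_by_structure: dict[str, list[str]],
    category: str = "SC",
) -> CompositionDataset:
    """Build the count-matrix dataset from built, deduplicated sites.

    ``surface_resnames_by_structure`` lists the resnames of every surface
    residue of each structure (class-appropriate surface definition).
    Sites with no exposed residue in the category are excluded from the
    pools, as sites too buried to admit a probe carry no surface signal.
    """
    from .residues import count_vector

    protein_ids = sorted(sites_by_structure)
    surface = np.array(
        [count_vector(surface_resnames_by_structure[p]) for p in protein_ids]
    )
    site_rows, site_protein, site_validity, site_het = [], [], [], []
    for pi, pid in enumerate(protein_ids):
        for site in sites_by_structure[pid]:
            resnames = site.surface_resnames(category)
            if not resnames:
                continue
            site_rows.append(count_vector(resnames))
            site_protein.append(pi)
            site_validity.append(site.validity)
            site_het.append(site.het_code)
    return CompositionDataset(
        surface_counts=surface,
        site_counts=np.array(site_rows).reshape(-1, N_AA),
        site_protein=np.array(site_protein, dtype=np.int64),
        site_validity=np.array(site_validity),
        site_het=np.array(site_het, dtype=object),
        protein_ids=protein_ids,
    )
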