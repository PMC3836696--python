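"""Binding-site assembly, surface filtering and deduplication.

A binding site is the set of protein residues with at least one heavy
atom within 4.0 Å of a ligand heavy atom.  Within one biounit, multiple
copies of the same ligand with identical residue-type composition are
symmetry duplicates and collapse to one representative; copies with
differing composition are all retained, as each documents real
variability of the binding event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import ContactRecord, ResidueInteraction, classify_residue_interaction, group_contacts
from .residues import AMINO_ACIDS, count_vector
from .sasa import SurfaceTable, surface_residues
from .structure import LigandInstance, ResidueId, Structure


@dataclass
class BindingSite:
    structure_id: str
    het_code: str
    ligand_instance: tuple[str, int, str]
    validity: str
    contacts: list[ContactRecord]
    interactions: list[ResidueInteraction]
    sc_residues: set[tuple[str, int, str]]
    bb_only_residues: set[tuple[str, int, str]]
    surface_sc_residues: set[tuple[str, int, str]]
    surface_bb_residues: set[tuple[str, int, str]]
    site_sasa: float
    resname_by_key: dict[tuple[str, int, str], str] = field(default_factory=dict)

    @property
    def n_residues(self) -> int:
        return len(self.sc_residues) + len(self.bb_only_residues)

    @property
    def is_empty(self) -> bool:
        return self.n_residues == 0

    @property
    def has_exposed_residues(self) -> bool:
        """False for sites too buried to expose any residue at the cutoff."""
        return bool(self.surface_sc_residues or self.surface_bb_residues)

    def site_key(self) -> tuple[str, tuple[int, ...]]:
        """(het_code, residue-type count vector) identity used for dedup."""
        resnames = [self.resname_by_key[k] for k in self.sc_residues | self.bb_only_residues]
        return (self.het_code, tuple(count_vector(resnames)))

    def surface_resnames(self, category: str) -> list[str]:
        keys = (
            self.surface_sc_residues if category == "SC" else self.surface_bb_residues
        )
        return [self.resname_by_key[k] for k in keys]


def build_binding_site(
    s: Structure,
    lig: LigandInstance,
    contacts: list[ContactRecord],
    surface: SurfaceTable | None = None,
    cutoff: float = 5.0,
) -> BindingSite:
    """Assemble one ligand's binding site from its contact records.

    SC residues are filtered on side-chain area (abs_side), BB-only
    residues on main-chain area (abs_main); glycine uses the larger of
    the two in either case.  Site SASA is the summed total residue SASA
    of all contacting residues — only residues in contact with the
    ligand enter a site's surface area.
    """
    groups = group_contacts(contacts)
    interactions = [classify_residue_interaction(recs) for recs in groups.values()]
    sc = {i.residue.key() for i in interactions if i.category == "SC"}
    bb = {i.residue.key() for i in interactions if i.category == "BB_only"}
    resname_by_key = {i.residue.key(): i.residue.resname for i in interactions}

    surface_sc: set = set()
    surface_bb: set = set()
    site_sasa = 0.0
    if surface is not None and interactions:
        sc_surface = surface_residues(surface, cutoff, atom_class="sidechain")
        bb_surface = surface_residues(surface, cutoff, atom_class="mainchain")
        surface_sc = sc & sc_surface
        surface_bb = bb & bb_surface
        for key in sc | bb:
            try:
                site_sasa += surface.residue_area(key)
            except KeyError:
                pass
    return BindingSite(
        structure_id=s.structure_id,
        het_code=lig.het_code,
        ligand_instance=lig.instance_id,
        validity=lig.validity,
        contacts=contacts,
        interactions=interactions,
        sc_residues=sc,
        bb_only_residues=bb,
        surface_sc_residues=surface_sc,
        surface_bb_residues=surface_bb,
        site_sasa=site_sasa,
        resname_by_key=resname_by_key,
    )


def deduplicate_sites(sites: list[BindingSite]) -> list[BindingSite]:
    """Collapse symmetry-duplicate sites within one biounit.

    Two sites are duplicates when they share the HET code and an
    identical residue-type count vector; the first (by ligand instance
    order) is retained.  Dedup never crosses structures and never
    compares different HET codes.  Idempotent.
    """
    seen: set[tuple[str, tuple[int, ...]]] = set()
    kept: list[BindingSite] = []
    for site in sites:
        key = site.site_key()
        if key in seen:
            continue
        seen.add(key)
        kept.append(site)
    return kept


def dataset_summary(
    sites_by_structure: dict[str, list[BindingSite]],
    surface_residue_totals: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per validity class and SC / BB-only class site accounting.

    Reports total and non-redundant site counts, mean and median
    residues per site and SASA per site, and — when per-structure
    surface-residue totals are supplied — the ratio of pooled protein
    surface residues to pooled site residues.
    """
    rows = []
    all_sites = [s for sites in sites_by_structure.values() for s in sites]
    validities = sorted({s.validity for s in all_sites})
    for validity in validities:
        n_total = sum(
            1 for s in all_sites if s.validity == validity and not s.is_empty
        )
        nr_by_structure = {
            sid: deduplicate_sites(
                [s for s in sites if s.validity == validity and not s.is_empty]
            )
            for sid, sites in sites_by_structure.items()
        }
        for category in ("SC", "BB_only"):
            sizes, sasas, pooled_res = [], [], 0
            n_nr = 0
            structures_with = set()
            for sid, sites in nr_by_structure.items():
                for s in sites:
                    res = (
                        s.surface_sc_residues
                        if category == "SC"
                        else s.surface_bb_residues
                    )
                    if not res:
                        continue
                    n_nr += 1
                    sizes.append(len(res))
                    sasas.append(s.site_sasa)
                    pooled_res += len(res)
                    structures_with.add(sid)
            row = {
                "validity": validity,
                "category": category,
                "n_sites_total": n_total,
                "n_sites_nonredundant": n_nr,
                "mean_residues_per_site": float(np.mean(sizes)) if sizes else np.nan,
                "median_residues_per_site": float(np.median(sizes)) if sizes else np.nan,
                "mean_sasa_per_site": float(np.mean(sasas)) if sasas else np.nan,
                "median_sasa_per_site": float(np.median(sasas)) if sasas else np.nan,
            }
            if surface_residue_totals is not None and pooled_res > 0:
                pooled_surface = sum(
                    surface_residue_totals.get(sid, 0) for sid in structures_with
                )
                row["protein_site_residue_ratio"] = pooled_surface / pooled_res
            else:
                row["protein_site_residue_ratio"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def sites_to_frame(sites: list[BindingSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "structure_id": s.structure_id,
                "het_code": s.het_code,
                "lig_chain": s.ligand_instance[0],
                "lig_seqnum": s.ligand_instance[1],
                "validity": s.validity,
                "n_residues": s.n_residues,
                "n_sc": len(s.sc_residues),
                "n_bb_only": len(s.bb_only_residues),
                "n_surface_sc": len(s.surface_sc_residues),
                "site_sasa": round(s.site_sasa, 2),
                "residues": ";".join(
                    f"{k[0]}{k[1]}{k[2]}:{s.resname_by_key[k]}"
                    for k in sorted(s.sc_residues | s.bb_only_residues)
                ),
            }
            for s in sites
        ]
    )
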