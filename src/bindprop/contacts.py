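"""Ligand-protein heavy-atom contact detection and typing.

A contact is any (protein heavy atom, ligand heavy atom) pair at 4.0 Å
or less.  Typing is purely geometric: pairs of non-carbon atoms within
3.5 Å are hydrogen bonds; everything else (carbon involvement, or
3.5 < d ≤ 4.0 Å) is a van der Waals contact.  No angle criterion or
donor/acceptor typing is applied.

A residue-ligand pair is categorised SC if any of its contacts runs
through a side-chain atom (glycine's Cα counts as side chain), and
BB-only if every contact runs through the backbone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .residues import AMINO_ACIDS, HEAVY_ATOMS
from .structure import LigandInstance, ResidueId, Structure, classify_atom_role

CONTACT_CUTOFF = 4.0
HBOND_CUTOFF = 3.5


@dataclass
class ContactRecord:
    residue: ResidueId
    het_code: str
    ligand_instance: tuple[str, int, str]
    protein_atom: str
    protein_role: str
    protein_element: str
    ligand_atom: str
    ligand_element: str
    distance: float
    interaction: str  # "hbond" | "vdw"


@dataclass
class ResidueInteraction:
    residue: ResidueId
    het_code: str
    ligand_instance: tuple[str, int, str]
    category: str  # "SC" | "BB_only"
    n_contacts: int
    n_hbond: int
    n_vdw: int


def classify_contact_type(
    protein_element: str,
    ligand_element: str,
    distance: float,
    hbond_cutoff: float = HBOND_CUTOFF,
) -> str:
    """Hydrogen bond vs van der Waals, by element and distance only."""
    if distance > hbond_cutoff:
        return "vdw"
    if protein_element.upper() == "C" or ligand_element.upper() == "C":
        return "vdw"
    return "hbond"


def find_contacts(
    s: Structure,
    lig: LigandInstance,
    cutoff: float = CONTACT_CUTOFF,
    hbond_cutoff: float = HBOND_CUTOFF,
) -> list[ContactRecord]:
    """All protein-ligand heavy-atom pairs within the cutoff (inclusive).

    Contacts to residues of any chain in the biounit are allowed; the
    assembly is one protein.  Waters never mediate contacts.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if not lig.atoms:
        raise ValueError(f"ligand {lig.het_code} has no heavy atoms")
    rids, atoms, coords = s.polymer_atom_table()
    if len(atoms) == 0:
        return []
    lig_coords = np.array([a.coords for a in lig.atoms])
    tree = cKDTree(coords)
    pairs = tree.query_ball_point(lig_coords, r=cutoff)
    records: list[ContactRecord] = []
    for li, prot_idx in enumerate(pairs):
        la = lig.atoms[li]
        for pi in sorted(prot_idx):
            pa = atoms[pi]
            rid = rids[pi]
            d = float(np.linalg.norm(pa.coords - la.coords))
            if d > cutoff:  # KD-tree returns <= r; guard for fp noise
                continue
            records.append(
                ContactRecord(
                    residue=rid,
                    het_code=lig.het_code,
                    ligand_instance=lig.instance_id,
                    protein_atom=pa.name,
                    protein_role=classify_atom_role(pa.name, rid.resname),
                    protein_element=pa.element,
                    ligand_atom=la.name,
                    ligand_element=la.element,
                    distance=d,
                    interaction=classify_contact_type(
                        pa.element, la.element, d, hbond_cutoff
                    ),
                )
            )
    return records


def classify_residue_interaction(
    contacts: list[ContactRecord],
) -> ResidueInteraction:
    """Collapse one residue-ligand contact group into SC / BB-only."""
    if not contacts:
        raise ValueError("empty contact collection")
    first = contacts[0]
    for c in contacts:
        if c.residue != first.residue or c.ligand_instance != first.ligand_instance:
            raise ValueError("contacts span multiple residue-ligand pairs")
    any_sidechain = any(c.protein_role == "sidechain" for c in contacts)
    n_hbond = sum(c.interaction == "hbond" for c in contacts)
    return ResidueInteraction(
        residue=first.residue,
        het_code=first.het_code,
        ligand_instance=first.ligand_instance,
        category="SC" if any_sidechain else "BB_only",
        n_contacts=len(contacts),
        n_hbond=n_hbond,
        n_vdw=len(contacts) - n_hbond,
    )


def group_contacts(
    contacts: list[ContactRecord],
) -> dict[tuple, list[ContactRecord]]:
    """Group contact records by (residue, ligand instance)."""
    groups: dict[tuple, list[ContactRecord]] = {}
    for c in contacts:
        key = (c.residue, c.het_code, c.ligand_instance)
        groups.setdefault(key, []).append(c)
    return groups


def contacts_to_frame(contacts: list[ContactRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chain": c.residue.chain,
                "seqnum": c.residue.seqnum,
                "icode": c.residue.icode,
                "resname": c.residue.resname,
                "het_code": c.het_code,
                "lig_chain": c.ligand_instance[0],
                "lig_seqnum": c.ligand_instance[1],
                "protein_atom": c.protein_atom,
                "protein_role": c.protein_role,
                "ligand_atom": c.ligand_atom,
                "distance": round(c.distance, 3),
                "interaction": c.interaction,
            }
            for c in contacts
        ]
    )


def summarize_contacts(sites, surface_filter=None) -> pd.DataFrame:
    """Per-amino-acid contact summary across binding sites.

    For each residue type: share of site residues (``pct_site``), mean
    contacts per residue, mean contacts per heavy atom, and mean hydrogen
    bonds per residue split into backbone N / backbone O / named
    side-chain atoms.  ``surface_filter`` is an optional
    ``(SurfaceTable, cutoff)`` pair restricting the tally to residues
    passing the side-chain surface definition (Gly by its larger area).

    ``sites`` is an iterable of :class:`bindprop.sites.BindingSite`.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("empty site collection")

    from .sasa import surface_residues  # local import to avoid cycle

    allowed = None
    if surface_filter is not None:
        table, cutoff = surface_filter
        allowed = surface_residues(table, cutoff, atom_class="sidechain")

    per_res_contacts: dict[str, list[int]] = {aa: [] for aa in AMINO_ACIDS}
    hb_backbone_n: dict[str, int] = {aa: 0 for aa in AMINO_ACIDS}
    hb_backbone_o: dict[str, int] = {aa: 0 for aa in AMINO_ACIDS}
    hb_sidechain: dict[str, dict[str, int]] = {aa: {} for aa in AMINO_ACIDS}

    for site in sites:
        groups = group_contacts(site.contacts)
        for (rid, _het, _inst), recs in groups.items():
            if rid.resname not in per_res_contacts:
                continue
            if allowed is not None and rid.key() not in allowed:
                continue
            per_res_contacts[rid.resname].append(len(recs))
            for c in recs:
                if c.interaction != "hbond":
                    continue
                if c.protein_role == "backbone":
                    if c.protein_atom == "N":
                        hb_backbone_n[rid.resname] += 1
                    else:
                        hb_backbone_o[rid.resname] += 1
                else:
                    sc = hb_sidechain[rid.resname]
                    sc[c.protein_atom] = sc.get(c.protein_atom, 0) + 1

    total_residues = sum(len(v) for v in per_res_contacts.values())
    if total_residues == 0:
        raise ValueError("no residue-ligand interactions to summarize")
    rows = []
    for aa in AMINO_ACIDS:
        counts = per_res_contacts[aa]
        n_res = len(counts)
        mean_contacts = float(np.mean(counts)) if n_res else np.nan
        sc_hb = sum(hb_sidechain[aa].values())
        rows.append(
            {
                "resname": aa,
                "n_residues": n_res,
                "pct_site": 100.0 * n_res / total_residues,
                "contacts_per_residue": mean_contacts,
                "contacts_per_heavy_atom": (
                    mean_contacts / HEAVY_ATOMS[aa] if n_res else np.nan
                ),
                "hbond_backbone_N_per_res": hb_backbone_n[aa] / n_res if n_res else np.nan,
                "hbond_backbone_O_per_res": hb_backbone_o[aa] / n_res if n_res else np.nan,
                "hbond_sidechain_per_res": sc_hb / n_res if n_res else np.nan,
                "hbond_sidechain_atoms": ";".join(
                    f"{k}:{v}" for k, v in sorted(hb_sidechain[aa].items())
                ),
                "hbond_total_per_res": (
                    (hb_backbone_n[aa] + hb_backbone_o[aa] + sc_hb) / n_res
                    if n_res
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
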