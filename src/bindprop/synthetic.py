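"""Synthetic inputs with known ground truth.

Two generators back the test strategy of this package:

* **Composition datasets** — abstract per-protein surface counts and
  per-site residue counts drawn from multinomials over a configurable
  background profile, with per-residue multiplicative enrichment factors
  applied (and renormalised) inside binding sites.  Because the
  generating distribution is known exactly, every downstream statistic
  (frequencies, propensities, ratios, resampling dispersion) has a
  brute-force-computable expectation.  Defaults echo the scale of a
  large curated complex set: a few hundred surface residues per protein,
  roughly two valid sites per structure averaging ~11 exposed residues,
  and sparser, much smaller invalid (additive) sites on about a third of
  the structures.
* **Toy complexes** — small PDB-format protein-ligand assemblies whose
  residues straddle the 3.5/4.0 Å contact boundaries with known atom
  roles and elements, so the exact contact list, hydrogen-bond/vdW types
  and SC/BB-only categories are enumerable by an independent all-pairs
  scan; optional fully caged decoy residues provide known zero-SASA
  burial states.  The geometry is deliberately non-physical: these
  structures exercise the geometric code paths, nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .propensity import CompositionDataset, INVALID, VALID
from .residues import AA_INDEX, AMINO_ACIDS, N_AA

#: Default surface-like background profile (charged/polar-heavy, rare
#: Cys/Trp/Met).  A package choice for realistic-looking simulations,
#: configurable per spec.
SURFACE_BACKGROUND: np.ndarray = np.array(
    [
        6.5,  # ALA
        6.0,  # ARG
        5.0,  # ASN
        7.0,  # ASP
        0.9,  # CYS
        4.5,  # GLN
        8.5,  # GLU
        5.5,  # GLY
        2.5,  # HIS
        3.5,  # ILE
        7.0,  # LEU
        8.0,  # LYS
        1.5,  # MET
        3.0,  # PHE
        5.5,  # PRO
        6.5,  # SER
        6.0,  # THR
        1.3,  # TRP
        3.3,  # TYR
        4.5,  # VAL
    ]
)
SURFACE_BACKGROUND = SURFACE_BACKGROUND / SURFACE_BACKGROUND.sum()


@dataclass
class CompositionSpec:
    """Parameters of the abstract composition generator.

    Site sizes are shifted Poisson (always ≥ 1 residue); surface sizes
    are truncated normal.  Defaults: ~270 surface residues per protein,
    1 + Poisson(1.34) valid sites of mean size 11.4, and invalid sites
    on a third of proteins with mean size 3.6 — valid sites several
    times larger than invalid ones.
    """

    n_proteins: int = 500
    surface_mean: float = 270.0
    surface_sd: float = 60.0
    background: np.ndarray = field(
        default_factory=lambda: SURFACE_BACKGROUND.copy()
    )
    valid_sites_extra_mean: float = 1.34   # sites/protein = 1 + Poisson(this)
    invalid_site_prob: float = 1 / 3
    invalid_sites_mean: float = 4.5        # count when present: 1 + Poisson(mean-1)
    valid_site_size_mean: float = 11.4
    invalid_site_size_mean: float = 3.6
    enrichment_valid: np.ndarray = field(default_factory=lambda: np.ones(N_AA))
    enrichment_invalid: np.ndarray = field(default_factory=lambda: np.ones(N_AA))
    normalize_enrichment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        self.enrichment_valid = np.asarray(self.enrichment_valid, dtype=float)
        self.enrichment_invalid = np.asarray(self.enrichment_invalid, dtype=float)
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        if np.any(self.enrichment_valid <= 0) or np.any(self.enrichment_invalid <= 0):
            raise ValueError("enrichment factors must be > 0")
        if self.valid_site_size_mean < 1 or self.invalid_site_size_mean < 1:
            raise ValueError("site size means must be >= 1")


def enrichment_from_dict(factors: dict[str, float]) -> np.ndarray:
    """Build an enrichment vector from residue-name overrides (rest 1.0)."""
    k = np.ones(N_AA)
    for name, f in factors.items():
        k[AA_INDEX[name]] = f
    return k


@dataclass
class CompositionGroundTruth:
    background: np.ndarray
    enrichment_valid: np.ndarray
    enrichment_invalid: np.ndarray
    expected_propensity_valid: np.ndarray
    expected_propensity_invalid: np.ndarray

    @property
    def expected_ratio(self) -> np.ndarray:
        return self.expected_propensity_valid / self.expected_propensity_invalid


def _site_probs(background: np.ndarray, enrichment: np.ndarray) -> np.ndarray:
    q = background * enrichment
    return q / q.sum()


def generate_composition_dataset(
    spec: CompositionSpec,
) -> tuple[CompositionDataset, CompositionGroundTruth]:
    """Draw a composition dataset and its exact generating truth.

    The expected pooled propensity of residue *i* in class *c* is
    ``k_i / Σ_j b_j k_j`` for enrichment vector ``k`` over background
    ``b``; with ``normalize_enrichment`` the supplied vector is divided
    by that normaliser up front so the recorded truth equals the
    effective enrichment.
    """
    rng = np.random.default_rng(spec.seed)
    b = spec.background
    k_valid = spec.enrichment_valid.copy()
    k_invalid = spec.enrichment_invalid.copy()
    if spec.normalize_enrichment:
        k_valid = k_valid / (b * k_valid).sum()
        k_invalid = k_invalid / (b * k_invalid).sum()
    q_valid = _site_probs(b, k_valid)
    q_invalid = _site_probs(b, k_invalid)

    surface_sizes = np.maximum(
        np.round(rng.normal(spec.surface_mean, spec.surface_sd, spec.n_proteins)),
        20,
    ).astype(int)
    surface_counts = rng.multinomial(surface_sizes[:, None], b).reshape(
        spec.n_proteins, N_AA
    )

    site_rows, site_protein, site_validity = [], [], []
    n_valid_sites = 1 + rng.poisson(spec.valid_sites_extra_mean, spec.n_proteins)
    has_invalid = rng.random(spec.n_proteins) < spec.invalid_site_prob
    n_invalid_sites = np.where(
        has_invalid, 1 + rng.poisson(max(spec.invalid_sites_mean - 1, 0), spec.n_proteins), 0
    )
    for p in range(spec.n_proteins):
        for _ in range(n_valid_sites[p]):
            size = 1 + rng.poisson(spec.valid_site_size_mean - 1)
            site_rows.append(rng.multinomial(size, q_valid))
            site_protein.append(p)
            site_validity.append(VALID)
        for _ in range(n_invalid_sites[p]):
            size = 1 + rng.poisson(spec.invalid_site_size_mean - 1)
            site_rows.append(rng.multinomial(size, q_invalid))
            site_protein.append(p)
            site_validity.append(INVALID)

    dataset = CompositionDataset(
        surface_counts=surface_counts,
        site_counts=np.array(site_rows),
        site_protein=np.array(site_protein, dtype=np.int64),
        site_validity=np.array(site_validity),
        site_het=np.array([""] * len(site_rows), dtype=object),
    )
    truth = CompositionGroundTruth(
        background=b,
        enrichment_valid=k_valid,
        enrichment_invalid=k_invalid,
        expected_propensity_valid=k_valid / (b * k_valid).sum(),
        expected_propensity_invalid=k_invalid / (b * k_invalid).sum(),
    )
    return dataset, truth


def generate_enzyme_split(
    dataset: CompositionDataset,
    truth: CompositionGroundTruth,
    fraction_enzyme: float = 0.7,
    subgroup_enrichment: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[CompositionDataset, np.ndarray, np.ndarray]:
    """Label proteins enzyme/non-enzyme and enrich the non-enzyme sites.

    Valid sites of non-enzyme proteins are redrawn with the extra
    enrichment applied on top of the valid-class enrichment.  Returns
    the relabelled dataset, the enzyme boolean array, and the subgroup
    (non-enzyme) protein indices.
    """
    rng = np.random.default_rng(seed)
    if subgroup_enrichment is None:
        subgroup_enrichment = np.ones(N_AA)
    subgroup_enrichment = np.asarray(subgroup_enrichment, dtype=float)
    enzyme = rng.random(dataset.n_proteins) < fraction_enzyme
    subgroup_idx = np.flatnonzero(~enzyme)

    q_sub = _site_probs(truth.background, truth.enrichment_valid * subgroup_enrichment)
    site_counts = dataset.site_counts.copy()
    in_subgroup = ~enzyme[dataset.site_protein]
    redraw = in_subgroup & (dataset.site_validity == VALID)
    sizes = site_counts[redraw].sum(axis=1)
    site_counts[redraw] = rng.multinomial(sizes[:, None], q_sub).reshape(-1, N_AA)

    out = CompositionDataset(
        surface_counts=dataset.surface_counts,
        site_counts=site_counts,
        site_protein=dataset.site_protein,
        site_validity=dataset.site_validity,
        site_het=dataset.site_het,
        enzyme=enzyme,
    )
    return out, enzyme, subgroup_idx


# --------------------------------------------------------------------------
# Toy PDB complexes
# --------------------------------------------------------------------------

#: Simplified residue templates: (atom name, element) in order — the four
#: backbone atoms first, then side-chain atoms.
RESIDUE_TEMPLATES: dict[str, list[tuple[str, str]]] = {
    "GLY": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")],
    "ALA": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C")],
    "SER": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("OG", "O")],
    "CYS": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("SG", "S")],
    "THR": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("OG1", "O"), ("CG2", "C")],
    "VAL": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("CG1", "C"), ("CG2", "C")],
    "ASP": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("CG", "C"), ("OD1", "O"), ("OD2", "O")],
    "ASN": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("CG", "C"), ("OD1", "O"), ("ND2", "N")],
    "LYS": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("CG", "C"), ("CD", "C"), ("CE", "C"), ("NZ", "N")],
    "MET": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("CG", "C"), ("SD", "S"), ("CE", "C")],
}

DEFAULT_SHELL_TYPES = tuple(RESIDUE_TEMPLATES)

#: Minimum ligand-to-contact-atom distances cycled over shell residues;
#: chosen to straddle the 3.5 Å hydrogen-bond and 4.0 Å contact cutoffs.
CONTACT_DISTANCES = (3.2, 3.45, 3.5, 3.55, 3.8, 4.0, 4.05, 4.3, 4.6)


@dataclass
class ToyComplexSpec:
    n_shell_residues: int = 50
    residue_types: tuple[str, ...] = DEFAULT_SHELL_TYPES
    ligand_elements: tuple[str, ...] = ("C", "O", "N", "O", "C", "P")
    ligand_het_code: str = "LIG"
    buried_decoy_count: int = 0
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        unknown = set(self.residue_types) - set(RESIDUE_TEMPLATES)
        if unknown:
            raise ValueError(f"no template for residue types: {sorted(unknown)}")
        if not self.ligand_elements:
            raise ValueError("ligand needs at least one atom")


@dataclass
class ToyGroundTruth:
    """Brute-force-derived expectations for one toy complex.

    ``contacts`` rows: (chain, seqnum, icode, resname, protein_atom,
    ligand_atom, distance, interaction, protein_role), computed on the
    exact coordinates written to the PDB text (3-decimal precision).
    """

    contacts: list[tuple]
    residue_categories: dict[tuple[str, int, str], str]
    buried_residues: list[tuple[str, int, str]]
    n_shell_in_contact: int


def _unit_directions(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def _pdb_line(
    record: str, serial: int, name: str, resname: str, chain: str,
    seqnum: int, coords: np.ndarray, element: str, occupancy: float = 1.0,
) -> str:
    atom_field = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial:>5d} {atom_field:<4s} {resname:>3s} {chain:1s}"
        f"{seqnum:>4d}    {coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}"
        f"{occupancy:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def _brute_force_truth(
    protein_atoms: list[tuple],
    ligand_atoms: list[tuple],
    cutoff: float = 4.0,
    hbond_cutoff: float = 3.5,
) -> tuple[list[tuple], dict]:
    """Independent O(n²) contact enumeration on the written coordinates."""
    contacts = []
    categories: dict[tuple[str, int, str], str] = {}
    for (chain, seqnum, icode, resname, aname, elem, pcoord) in protein_atoms:
        role = (
            "sidechain"
            if (resname == "GLY" and aname == "CA")
            or aname not in ("N", "CA", "C", "O", "OXT")
            else "backbone"
        )
        for (lname, lelem, lcoord) in ligand_atoms:
            d = float(np.sqrt(np.sum((pcoord - lcoord) ** 2)))
            if d > cutoff:
                continue
            if d <= hbond_cutoff and elem != "C" and lelem != "C":
                interaction = "hbond"
            else:
                interaction = "vdw"
            contacts.append(
                (chain, seqnum, icode, resname, aname, lname, d, interaction, role)
            )
            key = (chain, seqnum, icode)
            if role == "sidechain":
                categories[key] = "SC"
            else:
                categories.setdefault(key, "BB_only")
    return contacts, categories


def generate_toy_complex(spec: ToyComplexSpec) -> tuple[str, ToyGroundTruth]:
    """Emit a toy complex as PDB text plus its brute-force ground truth.

    Shell residues are placed on outward rays around the ligand with
    their designated contact atom at a controlled minimum distance
    straddling the 3.5/4.0 Å boundaries; the contact atom alternates
    between a side-chain atom and the backbone nitrogen (for Gly, its
    Cα) so both SC and BB-only categories occur.  Decoy residues are
    fully caged by wall residues and have zero solvent accessibility.
    """
    rng = np.random.default_rng(spec.seed)

    ligand_atoms: list[tuple] = []
    lig_dirs = _unit_directions(len(spec.ligand_elements))
    for i, elem in enumerate(spec.ligand_elements):
        pos = np.round(0.8 * lig_dirs[i], 3)
        name = f"{elem}{i + 1}"
        ligand_atoms.append((name, elem, pos))

    protein_atoms: list[tuple] = []
    dirs = _unit_directions(max(spec.n_shell_residues, 1))
    lig_coords = np.array([a[2] for a in ligand_atoms])
    for i in range(spec.n_shell_residues):
        resname = spec.residue_types[i % len(spec.residue_types)]
        template = RESIDUE_TEMPLATES[resname]
        u = dirs[i]
        d_min = CONTACT_DISTANCES[i % len(CONTACT_DISTANCES)]
        if spec.jitter > 0:
            d_min = max(2.5, d_min + rng.normal(0, spec.jitter))
        # anchor on the ligand atom most aligned with this ray
        anchor = lig_coords[np.argmax(lig_coords @ u)]
        via_sidechain = i % 2 == 0
        if resname == "GLY":
            contact_name = "CA" if via_sidechain else "N"
        else:
            contact_name = template[-1][0] if via_sidechain else "N"
        # orthonormal frame for lateral offsets
        ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        v = np.cross(u, ref)
        v /= np.linalg.norm(v)
        w = np.cross(u, v)
        contact_pos = anchor + d_min * u
        seqnum = i + 1
        offset = 0
        for j, (aname, elem) in enumerate(template):
            if aname == contact_name:
                pos = contact_pos
            else:
                offset += 1
                lateral = 0.9 * (v if offset % 2 else w) * (1 if offset % 4 < 2 else -1)
                pos = contact_pos + (1.3 * offset) * u + lateral
            pos = np.round(pos, 3)
            protein_atoms.append(("A", seqnum, "", resname, aname, elem, pos))

    buried: list[tuple[str, int, str]] = []
    cage_dirs = _unit_directions(12)
    for k in range(spec.buried_decoy_count):
        center = np.array([60.0 + 20.0 * k, 0.0, 0.0])
        seq_decoy = 500 + 10 * k
        # compact decoy GLY at the cage center
        for j, (aname, elem) in enumerate(RESIDUE_TEMPLATES["GLY"]):
            pos = np.round(center + 0.45 * _unit_directions(4)[j], 3)
            protein_atoms.append(("B", seq_decoy, "", "GLY", aname, elem, pos))
        buried.append(("B", seq_decoy, ""))
        # cage: 12 carbon atoms at 3.0 Å grouped into 3 wall "GLY" residues
        for j in range(12):
            pos = np.round(center + 3.0 * cage_dirs[j], 3)
            wall_seq = seq_decoy + 1 + j // 4
            aname = ["N", "CA", "C", "O"][j % 4]
            elem = {"N": "N", "CA": "C", "C": "C", "O": "O"}[aname]
            protein_atoms.append(("B", wall_seq, "", "GLY", aname, elem, pos))

    contacts, categories = _brute_force_truth(protein_atoms, ligand_atoms)
    shell_keys = {(c, s, i) for (c, s, i, *_rest) in protein_atoms if c == "A"}
    truth = ToyGroundTruth(
        contacts=contacts,
        residue_categories=categories,
        buried_residues=buried,
        n_shell_in_contact=len({k for k in categories if k in shell_keys}),
    )

    lines = []
    serial = 1
    for (chain, seqnum, _icode, resname, aname, elem, pos) in protein_atoms:
        lines.append(_pdb_line("ATOM", serial, aname, resname, chain, seqnum, pos, elem))
        serial += 1
    lig_seq = 901
    for (name, elem, pos) in ligand_atoms:
        lines.append(
            _pdb_line("HETATM", serial, name, spec.ligand_het_code, "X", lig_seq, pos, elem)
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n", truth


def annotation_table_for(
    structure_ids: list[str], het_code: str = "LIG", validity: str = VALID
):
    """Annotation frame marking every toy ligand with one validity."""
    import pandas as pd

    return pd.DataFrame(
        {
            "structure_id": structure_ids,
            "het_code": het_code,
            "chain": "",
            "seqnum": "",
            "icode": "",
            "validity": validity,
        }
    )
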