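"""Typed structure model for protein-ligand complexes.

Parses PDB biounit files (via biotite) into a small, explicit model that
partitions every heavy atom into exactly one of three pools: polymer
residues, HET (ligand candidate) groups, and waters.  Multimeric biounits
are kept as a single structure — the whole assembly is "one protein" for
surface and contact purposes.

Ligand validity (biologically relevant "valid" vs crystallographic
additive "invalid") is never inferred from the structure; it is supplied
through an annotation table emulating database curation.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .residues import (
    AMINO_ACIDS,
    BACKBONE_ATOMS,
    DEFAULT_MODIFIED_RESIDUES,
    WATER_NAMES,
)

STANDARD_AA = frozenset(AMINO_ACIDS)

VALIDITY_VALID = "valid"
VALIDITY_INVALID = "invalid"
VALIDITY_UNANNOTATED = "unannotated"


class PDBParseError(ValueError):
    """Raised for malformed ATOM/HETATM records; message names the line."""


@dataclass(frozen=True)
class ResidueId:
    """Author-numbering identity of a residue: (chain, seqnum, icode)."""

    chain: str
    seqnum: int
    icode: str
    resname: str

    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seqnum, self.icode)


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float
    altloc: str
    is_hetatm: bool

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.serial}")


@dataclass
class LigandInstance:
    """One HET group: a ligand candidate with its heavy atoms."""

    het_code: str
    instance_id: tuple[str, int, str]
    atoms: list[AtomRecord]
    validity: str = VALIDITY_UNANNOTATED


@dataclass
class Structure:
    structure_id: str
    polymer_residues: dict[ResidueId, list[AtomRecord]]
    het_groups: list[LigandInstance]
    waters: list[AtomRecord]
    chain_count: int
    normalized: bool = field(default=False)

    @property
    def n_polymer_atoms(self) -> int:
        return sum(len(a) for a in self.polymer_residues.values())

    def polymer_atom_table(self):
        """Flat view of polymer atoms: (residue_ids, atoms, coords array)."""
        rids: list[ResidueId] = []
        atoms: list[AtomRecord] = []
        for rid, recs in self.polymer_residues.items():
            for rec in recs:
                rids.append(rid)
                atoms.append(rec)
        coords = (
            np.array([a.coords for a in atoms])
            if atoms
            else np.empty((0, 3))
        )
        return rids, atoms, coords


def _infer_element(atom_name: str) -> str:
    """Guess the element from a PDB atom name (older files omit column 77-78)."""
    name = atom_name.strip()
    stripped = name.lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[:2].upper() in {"SE", "CL", "BR", "FE", "ZN", "MG", "MN", "NA"} and len(name) >= 2:
        # two-letter elements only when the name starts in column 13
        if len(atom_name) == 4 and not atom_name[0].isspace() and not atom_name[0].isdigit():
            return stripped[:2].upper()
    return stripped[0].upper()


def _prevalidate_pdb(pdb_text: str) -> list[np.ndarray]:
    """Validate ATOM/HETATM records (naming the line on failure) and harvest
    full-precision float64 coordinates per model.

    The harvested coordinates replace the parser's float32 values so that
    distances written with three decimals are reproduced exactly — contact
    cutoffs are inclusive boundaries and must not drift with storage
    precision.
    """
    serials: set[int] = set()
    dup_warned = False
    models: list[list[list[float]]] = [[]]
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if models[-1]:
                models.append([])
            continue
        if rec not in ("ATOM", "HETATM"):
            continue
        if len(line) < 54:
            raise PDBParseError(f"malformed {rec} record at line {lineno}: too short")
        try:
            serial = int(line[6:11])
            xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        except ValueError as exc:
            raise PDBParseError(
                f"malformed {rec} record at line {lineno}: {exc}"
            ) from None
        models[-1].append(xyz)
        if serial in serials and not dup_warned:
            warnings.warn(
                f"duplicate atom serial {serial} at line {lineno}; keeping both",
                stacklevel=3,
            )
            dup_warned = True
        serials.add(serial)
    return [np.asarray(m, dtype=float).reshape(-1, 3) for m in models]


def read_annotations(path_or_buf) -> pd.DataFrame:
    """Read a ligand-annotation TSV.

    Columns: structure_id, het_code, chain, seqnum, icode, validity.
    chain/seqnum/icode may be empty, in which case the row annotates every
    instance of the HET code in the structure.
    """
    df = pd.read_csv(
        path_or_buf,
        sep="\t",
        dtype={"structure_id": str, "het_code": str, "chain": str, "icode": str},
        keep_default_na=False,
    )
    required = {"structure_id", "het_code", "validity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return df


def _lookup_validity(
    annotations: pd.DataFrame | None,
    structure_id: str,
    het_code: str,
    instance: tuple[str, int, str],
) -> str:
    if annotations is None or len(annotations) == 0:
        return VALIDITY_UNANNOTATED
    rows = annotations[
        (annotations["structure_id"].astype(str) == structure_id)
        & (annotations["het_code"].astype(str) == het_code)
    ]
    if len(rows) == 0:
        return VALIDITY_UNANNOTATED
    chain, seqnum, icode = instance
    if "chain" in rows.columns:
        specific = rows[
            (rows["chain"].astype(str) == chain)
            & (pd.to_numeric(rows.get("seqnum"), errors="coerce") == seqnum)
        ]
        if len(specific):
            return str(specific.iloc[0]["validity"])
        generic = rows[rows["chain"].astype(str).str.strip() == ""]
        if len(generic):
            return str(generic.iloc[0]["validity"])
        return VALIDITY_UNANNOTATED
    return str(rows.iloc[0]["validity"])


def parse_structure(
    pdb_text: str,
    annotations: pd.DataFrame | None = None,
    structure_id: str = "structure",
    modified_residues: dict[str, str] | None = None,
    model: int = 1,
) -> Structure:
    """Parse PDB text into a partitioned :class:`Structure`.

    Every heavy or hydrogen atom of the file lands in exactly one of the
    polymer / HET / water pools.  Multi-MODEL files yield the requested
    model only (default: first).  HETATM groups that are not water are
    ligand candidates; modified residues with a configured parent mapping
    (default: MSE→MET and selenocysteine codes) are folded into the
    polymer under the parent name, other non-standard polymer residues
    are excluded with a warning.
    """
    if modified_residues is None:
        modified_residues = DEFAULT_MODIFIED_RESIDUES
    model_coords = _prevalidate_pdb(pdb_text)
    pdb_file = pdbio.PDBFile.read(io.StringIO(pdb_text))
    atoms = pdb_file.get_structure(
        model=model, altloc="all", extra_fields=["occupancy", "atom_id"]
    )
    # substitute full-precision coordinates (the parser stores float32)
    coords64 = model_coords[model - 1] if len(model_coords) >= model else None
    if coords64 is None or len(coords64) != atoms.array_length():
        coords64 = atoms.coord.astype(float)

    polymer: dict[ResidueId, list[AtomRecord]] = {}
    het_atoms: dict[tuple[str, str, int, str], list[AtomRecord]] = {}
    waters: list[AtomRecord] = []
    skipped: set[str] = set()

    altloc_ids = (
        atoms.get_annotation("altloc_id")
        if "altloc_id" in atoms.get_annotation_categories()
        else [""] * atoms.array_length()
    )
    for i in range(atoms.array_length()):
        resname = str(atoms.res_name[i]).strip()
        element = str(atoms.element[i]).strip().upper()
        name = str(atoms.atom_name[i]).strip()
        if not element:
            element = _infer_element(name)
        altloc = str(altloc_ids[i]).strip().replace(".", "")
        rec = AtomRecord(
            serial=int(atoms.atom_id[i]),
            name=name,
            element=element,
            coords=coords64[i],
            occupancy=float(atoms.occupancy[i]),
            altloc=altloc,
            is_hetatm=bool(atoms.hetero[i]),
        )
        chain = str(atoms.chain_id[i]).strip()
        seqnum = int(atoms.res_id[i])
        icode = str(atoms.ins_code[i]).strip()

        if resname in WATER_NAMES:
            waters.append(rec)
            continue
        target_resname = modified_residues.get(resname, resname)
        if target_resname in STANDARD_AA:
            rid = ResidueId(chain, seqnum, icode, target_resname)
            polymer.setdefault(rid, []).append(rec)
        elif rec.is_hetatm:
            het_atoms.setdefault((resname, chain, seqnum, icode), []).append(rec)
        else:
            if resname not in skipped:
                warnings.warn(
                    f"{structure_id}: non-standard polymer residue {resname} "
                    "without a parent mapping; excluded",
                    stacklevel=2,
                )
                skipped.add(resname)

    het_groups = []
    for (het_code, chain, seqnum, icode), recs in het_atoms.items():
        heavy = [a for a in recs if a.element not in ("H", "D")]
        if not heavy:
            continue
        instance = (chain, seqnum, icode)
        het_groups.append(
            LigandInstance(
                het_code=het_code,
                instance_id=instance,
                atoms=heavy,
                validity=_lookup_validity(annotations, structure_id, het_code, instance),
            )
        )

    chains = {rid.chain for rid in polymer}
    return Structure(
        structure_id=structure_id,
        polymer_residues=polymer,
        het_groups=het_groups,
        waters=waters,
        chain_count=len(chains),
    )


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, tie → first."""
    best: dict[str, AtomRecord] = {}
    order: list[str] = []
    for rec in atoms:
        if rec.name not in best:
            best[rec.name] = rec
            order.append(rec.name)
        elif rec.occupancy > best[rec.name].occupancy:
            best[rec.name] = rec
    return [best[n] for n in order]


def normalize_structure(s: Structure, altloc_policy: str = "occupancy") -> Structure:
    """Strip hydrogens everywhere and resolve alternate locations.

    ``altloc_policy`` "occupancy" keeps the highest-occupancy conformer
    per (residue, atom name), ties broken by file order; "first" keeps the
    first conformer encountered.  Waters stay in their pool but are
    excluded from all downstream geometry by construction.  Idempotent.
    """
    if altloc_policy not in ("occupancy", "first"):
        raise ValueError(f"unknown altloc policy: {altloc_policy}")

    def dedup(atoms: list[AtomRecord]) -> list[AtomRecord]:
        heavy = [a for a in atoms if a.element not in ("H", "D")]
        if altloc_policy == "occupancy":
            return _resolve_altlocs(heavy)
        seen: set[str] = set()
        out = []
        for a in heavy:
            if a.name not in seen:
                seen.add(a.name)
                out.append(a)
        return out

    polymer = {rid: dedup(recs) for rid, recs in s.polymer_residues.items()}
    polymer = {rid: recs for rid, recs in polymer.items() if recs}
    het_groups = []
    for lig in s.het_groups:
        atoms = dedup(lig.atoms)
        if atoms:
            het_groups.append(replace(lig, atoms=atoms))
    waters = [a for a in s.waters if a.element not in ("H", "D")]
    return Structure(
        structure_id=s.structure_id,
        polymer_residues=polymer,
        het_groups=het_groups,
        waters=waters,
        chain_count=s.chain_count,
        normalized=True,
    )


def classify_atom_role(atom_name: str, resname: str) -> str:
    """Classify a protein heavy atom as ``backbone`` or ``sidechain``.

    N, CA, C, O and terminal OXT are backbone — except glycine's CA,
    which always counts as side chain (Gly has no other side-chain atom,
    and its Cα takes that role in contact classification and in the
    side-chain surface area).
    """
    name = atom_name.strip().upper()
    res = resname.strip().upper()
    if res not in STANDARD_AA:
        warnings.warn(
            f"atom-role classification by name convention for non-standard "
            f"residue {res}",
            stacklevel=2,
        )
    if res == "GLY" and name == "CA":
        return "sidechain"
    return "backbone" if name in BACKBONE_ATOMS else "sidechain"
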