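"""Solvent-accessible surface area by Shrake-Rupley quadrature.

A water-sized probe (radius 1.4 Å) is rolled over the van der Waals
surface of the ligand-free, water-free protein; the area traced by the
probe *center* is the SASA.  Per-residue areas are split into side-chain
(``abs_side``) and main-chain (``abs_main``) absolute areas following the
atom-role convention of :func:`bindprop.structure.classify_atom_role`:
glycine's Cα counts toward the side-chain area.

Quadrature points are laid out on a deterministic golden-spiral lattice,
so areas are reproducible bit-for-bit without any random seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import Structure, classify_atom_role

#: NACCESS-style van der Waals radii (Å) keyed by element.
DEFAULT_RADII: dict[str, float] = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
    "SE": 1.90,
}


@dataclass
class SasaParams:
    """Quadrature parameters.

    probe_radius
        Probe radius in Å; 1.4 Å approximates a water molecule.
    n_sphere_points
        Points per atom sphere.  960 gives < 2% error on an isolated
        sphere; cost is linear in this number.
    radii
        Element → vdW radius (Å).  Unknown elements raise.
    """

    probe_radius: float = 1.4
    n_sphere_points: int = 960
    radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be > 0")
        if self.n_sphere_points < 60:
            raise ValueError("n_sphere_points must be >= 60")
        if any(r <= 0 for r in self.radii.values()):
            raise ValueError("all radii must be > 0")


@dataclass
class SurfaceTable:
    """Per-residue SASA split into side-chain and main-chain areas.

    ``residues`` has one row per polymer residue with columns
    chain/seqnum/icode/resname/abs_side/abs_main/abs_total.  ``atom_areas``
    aligns with the flat polymer atom order of the source structure.
    """

    residues: pd.DataFrame
    atom_areas: np.ndarray

    def _areas(self, atom_class: str) -> pd.Series:
        """Class-appropriate area with the Gly max rule applied."""
        if atom_class == "sidechain":
            base = self.residues["abs_side"].copy()
        elif atom_class == "mainchain":
            base = self.residues["abs_main"].copy()
        else:
            raise ValueError(f"unknown atom class: {atom_class}")
        gly = self.residues["resname"] == "GLY"
        base[gly] = self.residues.loc[gly, ["abs_side", "abs_main"]].max(axis=1)
        return base

    def residue_area(self, key: tuple[str, int, str]) -> float:
        row = self.residues[
            (self.residues["chain"] == key[0])
            & (self.residues["seqnum"] == key[1])
            & (self.residues["icode"] == key[2])
        ]
        if len(row) == 0:
            raise KeyError(key)
        return float(row.iloc[0]["abs_total"])

    def to_tsv(self, path, structure_id: str = "") -> None:
        df = self.residues.copy()
        df.insert(0, "structure_id", structure_id)
        df["effective_side"] = self._areas("sidechain").values
        df["effective_main"] = self._areas("mainchain").values
        df.to_csv(path, sep="\t", index=False, float_format="%.3f")


def sphere_points(n: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere lattice (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def atom_sasa(
    coords: np.ndarray, radii: np.ndarray, params: SasaParams
) -> np.ndarray:
    """Per-atom Shrake-Rupley areas (Å²) for an arbitrary atom set."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    areas = np.zeros(n)
    if n == 0:
        return areas
    unit = sphere_points(params.n_sphere_points)
    ext = radii + params.probe_radius
    max_reach = 2.0 * ext.max()
    tree = cKDTree(coords)
    neighbor_lists = tree.query_ball_point(coords, r=max_reach)
    for i in range(n):
        pts = coords[i] + ext[i] * unit
        exposed = np.ones(params.n_sphere_points, dtype=bool)
        for j in neighbor_lists[i]:
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > ext[j] ** 2
            if not exposed.any():
                break
        areas[i] = (
            exposed.sum() / params.n_sphere_points * 4.0 * np.pi * ext[i] ** 2
        )
    return areas


def compute_sasa(s: Structure, params: SasaParams | None = None) -> SurfaceTable:
    """SASA of the polymer alone: ligands and waters are removed first.

    Known ligands are excluded from the atom set before the calculation
    (a bound ligand would otherwise shield its own binding site), as are
    waters and hydrogens.
    """
    if params is None:
        params = SasaParams()
    rids, atoms, coords = s.polymer_atom_table()
    radii = np.empty(len(atoms))
    for k, a in enumerate(atoms):
        try:
            radii[k] = params.radii[a.element]
        except KeyError:
            raise KeyError(
                f"no vdW radius configured for element {a.element!r} "
                f"(atom {a.serial} {a.name})"
            ) from None
    areas = atom_sasa(coords, radii, params)

    rows: dict[tuple[str, int, str, str], dict[str, float]] = {}
    for rid, atom, area in zip(rids, atoms, areas):
        key = (rid.chain, rid.seqnum, rid.icode, rid.resname)
        acc = rows.setdefault(key, {"abs_side": 0.0, "abs_main": 0.0})
        role = classify_atom_role(atom.name, rid.resname)
        acc["abs_side" if role == "sidechain" else "abs_main"] += area
    df = pd.DataFrame(
        [
            {
                "chain": k[0],
                "seqnum": k[1],
                "icode": k[2],
                "resname": k[3],
                "abs_side": v["abs_side"],
                "abs_main": v["abs_main"],
                "abs_total": v["abs_side"] + v["abs_main"],
            }
            for k, v in rows.items()
        ]
    )
    return SurfaceTable(residues=df, atom_areas=areas)


def surface_residues(
    table: SurfaceTable, cutoff: float, atom_class: str = "sidechain"
) -> set[tuple[str, int, str]]:
    """Residues with class-appropriate SASA ≥ cutoff (inclusive).

    ``atom_class`` "sidechain" keys on abs_side, "mainchain" on abs_main.
    For glycine the larger of the two areas is used in both cases, since
    its Cα plays the side-chain role but contributes backbone-like area.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    areas = table._areas(atom_class)
    keep = table.residues[areas >= cutoff]
    return {
        (r["chain"], r["seqnum"], r["icode"]) for _, r in keep.iterrows()
    }
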