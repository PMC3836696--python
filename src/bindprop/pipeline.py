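"""End-to-end orchestration: structures in, report tables out.

Stages run in fixed order — parse → normalize → SASA → contacts → sites
→ dedup → pooled frequencies → propensities → ratios → resampling — and
every report row is traceable to structure ids recorded in the manifest.
Reruns with the same configuration and seed produce byte-identical
reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import sites as sites_mod
from .contacts import contacts_to_frame, find_contacts, summarize_contacts
from .propensity import (
    CompositionDataset,
    INVALID,
    VALID,
    dataset_from_sites,
    pooled_propensity,
    propensity_ratio,
)
from .residues import AMINO_ACIDS
from .resampling import (
    ResampleConfig,
    leave_k_out,
    shuffle_validity_null,
)
from .sasa import SasaParams, compute_sasa, surface_residues
from .structure import normalize_structure, parse_structure, read_annotations

logger = logging.getLogger("bindprop")


@dataclass
class RunConfig:
    structures_dir: str = "."
    annotations: str | None = None
    output_dir: str = "bindprop_out"
    contact_cutoff: float = 4.0
    hbond_cutoff: float = 3.5
    sasa_cutoff: float = 5.0
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    n_resample_reps: int = 1000
    leave_out_fraction: float = 0.10
    n_shuffles: int = 1000
    top_k_exclude: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0 or self.hbond_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.hbond_cutoff > self.contact_cutoff:
            raise ValueError("hbond cutoff must not exceed contact cutoff")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class StructureResult:
    structure_id: str
    structure: object
    surface: object
    sites: list
    n_sites_built: int
    n_sites_deduped: int
    n_sites_empty_surface: int


def analyze_structure(
    pdb_text: str,
    structure_id: str,
    annotations: pd.DataFrame | None,
    cfg: RunConfig,
) -> StructureResult:
    """Run the geometric stages for one biounit."""
    s = parse_structure(pdb_text, annotations, structure_id=structure_id)
    s = normalize_structure(s)
    params = SasaParams(
        probe_radius=cfg.probe_radius, n_sphere_points=cfg.n_sphere_points
    )
    surface = compute_sasa(s, params)
    built = []
    for lig in s.het_groups:
        contacts = find_contacts(
            s, lig, cutoff=cfg.contact_cutoff, hbond_cutoff=cfg.hbond_cutoff
        )
        site = sites_mod.build_binding_site(
            s, lig, contacts, surface, cutoff=cfg.sasa_cutoff
        )
        if not site.is_empty:
            built.append(site)
    deduped = sites_mod.deduplicate_sites(built)
    n_empty_surface = sum(1 for x in deduped if not x.has_exposed_residues)
    logger.info(
        "%s: %d ligands, %d sites built, %d after dedup, %d empty-surface",
        structure_id, len(s.het_groups), len(built), len(deduped), n_empty_surface,
    )
    return StructureResult(
        structure_id=structure_id,
        structure=s,
        surface=surface,
        sites=deduped,
        n_sites_built=len(built),
        n_sites_deduped=len(built) - len(deduped),
        n_sites_empty_surface=n_empty_surface,
    )


def run_full_analysis(cfg: RunConfig) -> dict:
    """Execute the complete analysis and write the report bundle.

    Returns a manifest dict (also written to ``manifest.json``).
    Any stage error aborts with the stage name and structure id.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotations = (
        read_annotations(cfg.annotations) if cfg.annotations else None
    )
    pdb_paths = sorted(Path(cfg.structures_dir).glob("*.pdb"))
    if not pdb_paths:
        raise FileNotFoundError(f"no .pdb files in {cfg.structures_dir}")

    results: list[StructureResult] = []
    for path in pdb_paths:
        sid = path.stem
        try:
            results.append(
                analyze_structure(path.read_text(), sid, annotations, cfg)
            )
        except Exception as exc:
            raise RuntimeError(f"stage analyze_structure failed for {sid}: {exc}") from exc

    sites_by_structure = {r.structure_id: r.sites for r in results}
    all_sites = [s for r in results for s in r.sites]

    # per-structure reports
    pd.concat(
        [contacts_to_frame([c for s in r.sites for c in s.contacts]).assign(
            structure_id=r.structure_id
        ) for r in results],
        ignore_index=True,
    ).to_csv(out / "contacts.tsv", sep="\t", index=False)
    sites_mod.sites_to_frame(all_sites).to_csv(
        out / "sites.tsv", sep="\t", index=False
    )
    for r in results:
        r.surface.to_tsv(out / f"sasa_{r.structure_id}.tsv", r.structure_id)

    surface_totals = {}
    surface_resnames: dict[str, list[str]] = {}
    for r in results:
        keys = surface_residues(r.surface, cfg.sasa_cutoff, "sidechain")
        df = r.surface.residues
        names = [
            row["resname"]
            for _, row in df.iterrows()
            if (row["chain"], row["seqnum"], row["icode"]) in keys
        ]
        surface_resnames[r.structure_id] = names
        surface_totals[r.structure_id] = len(names)

    sites_mod.dataset_summary(sites_by_structure, surface_totals).to_csv(
        out / "dataset_summary.tsv", sep="\t", index=False
    )
    try:
        summarize_contacts(all_sites).to_csv(
            out / "contact_summary_raw.tsv", sep="\t", index=False
        )
    except ValueError:
        logger.warning("no interactions: contact summary skipped")

    dataset = dataset_from_sites(sites_by_structure, surface_resnames, "SC")
    manifest = {
        "config": asdict(cfg),
        "config_digest": cfg.digest(),
        "structures": [r.structure_id for r in results],
        "n_sites": int(dataset.n_sites),
        "per_structure": {
            r.structure_id: {
                "sites_built": r.n_sites_built,
                "sites_deduped": r.n_sites_deduped,
                "sites_empty_surface": r.n_sites_empty_surface,
            }
            for r in results
        },
    }

    if dataset.n_sites > 0:
        rows = []
        for validity in np.unique(dataset.site_validity):
            try:
                prop = pooled_propensity(dataset, validity=str(validity))
            except ValueError:
                continue
            for aa, v in zip(AMINO_ACIDS, prop.values):
                rows.append({"validity": validity, "resname": aa, "propensity": v})
        pd.DataFrame(rows).to_csv(out / "propensities.tsv", sep="\t", index=False)

        labels = set(dataset.site_validity)
        if VALID in labels and INVALID in labels:
            pv = pooled_propensity(dataset, VALID)
            pi = pooled_propensity(dataset, INVALID)
            pd.DataFrame(
                {"resname": AMINO_ACIDS, "ratio": propensity_ratio(pv, pi)}
            ).to_csv(out / "propensity_ratios.tsv", sep="\t", index=False)
            shuffle = shuffle_validity_null(
                dataset, n_shuffles=cfg.n_shuffles, seed=cfg.seed
            )
            shuffle.to_frame().to_csv(out / "shuffle_null.tsv", sep="\t", index=False)
        if dataset.n_proteins >= 2:
            rcfg = ResampleConfig(
                n_reps=cfg.n_resample_reps,
                leave_out_fraction=cfg.leave_out_fraction,
                seed=cfg.seed,
            )
            leave_k_out(dataset, rcfg).to_frame().to_csv(
                out / "leave_out_bounds.tsv", sep="\t", index=False
            )

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
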