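# Methods

## Model and procedure

`bindprop` quantifies which amino acids are over- or under-represented
on the surfaces of ligand binding sites relative to whole protein
surfaces, and whether that bias differs between biologically relevant
("valid") ligands and crystallisation additives ("invalid").  The
pipeline runs in fixed stages:

1. **Parse & normalise.**  PDB biounit files are read (via biotite)
   into a model that partitions every atom into polymer / HET group /
   water.  A multimeric biounit is one protein: contacts and surfaces
   never distinguish chains.  Hydrogens are removed; for alternate
   locations the highest-occupancy conformer is kept (tie → first in
   file order).  Coordinates are re-read from the fixed text columns in
   full double precision, because contact cutoffs are inclusive
   boundaries and must not drift with single-precision storage.
   Ligand validity is supplied by an annotation table, emulating
   database curation; it is never inferred from geometry.
2. **Surface.**  Solvent-accessible surface area is computed on the
   ligand-free, water-free polymer by Shrake–Rupley quadrature and
   split per residue into side-chain (`abs_side`) and main-chain
   (`abs_main`) absolute areas; glycine's Cα counts to the side-chain
   area.  A residue is "surface" for the SC analysis when
   `abs_side ≥ cutoff` (main-chain analogue for BB-only); glycine uses
   the larger of its two areas in both tests.
3. **Contacts & sites.**  All protein–ligand heavy-atom pairs within
   4.0 Å (inclusive) are contacts.  Pairs of non-carbon atoms within
   3.5 Å are hydrogen bonds; everything else is van der Waals — by
   design no angle criterion or donor/acceptor typing, so the typing is
   purely geometric and scale-robust.  A residue–ligand pair is SC if
   any contact runs through a side-chain atom (Gly Cα included), else
   BB-only.  A residue near two ligands belongs to both sites
   independently.  Within one biounit, sites of the same HET code with
   identical residue-type count vectors are symmetry duplicates and
   collapse to the first instance; differing vectors are all kept.
   Sites whose residues all fail the surface cutoff carry no surface
   signal and are excluded from the frequency pools (they remain in the
   raw-contact summaries).
4. **Propensities.**  Counts are pooled across all sites of a class and
   across all contributing protein surfaces *before* division
   (`P_i = F_i^BS / F_i^PS`).  Only proteins contributing at least one
   site of the class enter the surface denominator.  A zero surface
   frequency flags the residue as undefined rather than producing
   infinity.
5. **Significance.**  Three resampling schemes, all protein-level and
   all reproducible under one master seed with deterministic
   per-operation streams:
   leave-10%-out (median + empirical 2.5/97.5 percentile bounds, linear
   interpolation); label shuffling over the site multiset preserving
   class proportions (per-residue mean sits at 1 under exchangeability;
   the min/max envelope is the dataset-specific significance band,
   reported alongside the conventional fixed 1.2/0.8 ratio thresholds);
   and set-size scans / fixed-size tables exposing how dispersion
   shrinks with the number of structures.  A subgroup (e.g. non-enzyme
   structures) is called different only when its leave-10%-out interval
   is disjoint from the interval of random same-size subsets — the
   strictest version of the comparison.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| contact cutoff | 4.0 | Å | heavy-atom interaction distance; inclusive |
| hydrogen-bond cutoff | 3.5 | Å | non-carbon pairs only; inclusive |
| probe radius | 1.4 | Å | water-sized probe |
| quadrature points | 960 | – | <2% error on an isolated sphere |
| vdW radii | C 1.87, N 1.65, O 1.40, S 1.85, P 1.90, Se 1.90 | Å | protein-atom radii in the NACCESS tradition; configurable |
| surface cutoff | 5.0 (variant 0.5) | Å² | standard exposed-residue definition; ≥ is inclusive |
| leave-out fraction | 0.10 | – | resampling unit is the protein |
| percentile bounds | 2.5 / 97.5 | % | 95% empirical interval |

## Synthetic data

The composition generator draws per-protein surface counts
(multinomial over a configurable surface-like background profile —
charged/polar-heavy, Cys/Trp/Met rare — itself a package choice, not a
measured fact) and per-site counts from the background multiplied by a
per-residue enrichment vector and renormalised.  Defaults reproduce the
scale of a large curated complex set: ~270 surface residues per
protein, 1 + Poisson(1.34) valid sites of mean size 11.4 residues, and
invalid sites on a third of proteins (mean count 4.5 when present) of
mean size 3.6 — valid sites several times larger than invalid ones.

For enrichment vector `k` over background `b`, the expected pooled
propensity is `k_i / Σ_j b_j k_j`; the generator records this as ground
truth and can pre-normalise `k` by that sum so the recorded truth
equals the effective enrichment.  An enrichment vector constructed with
`Σ b_j k_j = 1` makes the expected propensity equal the nominal `k`
exactly, which is how parameter-recovery tests are set up.

The toy-complex generator writes small PDB files whose shell residues
straddle the 3.5/4.0 Å boundaries with known atom roles, so the exact
contact list is enumerable by an independent all-pairs scan computed on
the same 3-decimal coordinates that are written to the file.  Decoy
residues caged by 12 wall atoms at 3.0 Å have provably zero solvent
accessibility (the cage blocks every probe-center direction).

What the generators do **not** emulate: real fold geometry, chemistry
of specific ligand classes, correlations between site size and
composition, redundancy between related proteins, or curation noise in
validity labels.  Passing tests therefore demonstrate the correctness
of the statistical and geometric machinery under the stated sampling
model, not the field values of any propensity.

## Numerical choices

- Quadrature points are a deterministic golden-spiral lattice: results
  are bit-for-bit reproducible without a seed.  The lattice is not
  mirror-symmetric, so geometrically symmetric atoms agree only to
  quadrature resolution (~0.5%), not exactly.
- Boundary equality at 3.5/4.0 Å and at the SASA cutoffs is inclusive
  and exercised with exact decimal coordinates.
- Tie-breaks: altloc ties keep the first conformer in file order;
  ligand-frequency ties in top-k exclusion break lexicographically by
  HET code; duplicate sites keep the first ligand instance.
- Undefined propensities (zero surface frequency) are flagged NaN and
  propagate through ratios; they are never clamped or dropped silently.
- Resampling replicates with no counts at all are discarded with a
  warning and the discarded count is reported.

## Design choices on genuinely open points

- Terminal OXT is classified as backbone.
- Covalently attached HET groups and coordinated metal ions are treated
  as ligand candidates like any other non-water HET group.
- Site identity for deduplication compares total residue-type counts
  only, not chain/position and not the SC/BB split.
- The label shuffle preserves the global valid/invalid proportion, not
  per-protein label counts.
- The Gly max rule is applied uniformly, in site surface filtering and
  in the protein-surface denominator alike.
- Site SASA is the summed total (side + main) area of the contacting
  residues; per-site areas of a few hundred Å² for ~10-residue sites
  are only meaningful on that convention.
- Each atom-pair within range counts as one contact in per-residue
  contact statistics (one residue atom touching three ligand atoms
  contributes three contacts).

## Problem sizes

Tests and the acceptance script run on synthetic sets of 300–2,500
proteins (thousands of sites), 200–1,000 resampling replicates and
1,000 label shuffles; toy complexes use 8–60 residues.  These sizes
give sampling errors comfortably inside the asserted tolerances (e.g.
~2–3% relative error on pooled propensities of non-rare residues at
2,000 proteins) while keeping the full suite under a minute of compute
for the statistical parts.

## Known limitations

- No mmCIF input; biounits must be pre-expanded (no symmetry-operator
  assembly generation).
- Non-redundancy across proteins (sequence-identity clustering) is an
  input property, not recomputed here; deduplication acts only within
  one biounit.
- Relative (percent) accessibilities and molecular surface area are out
  of scope; only absolute SASA is computed.
- Hydrogen-bond detection is distance-only by design; it will count
  some non-bonding polar pairs and miss geometry-dependent effects.
- The SASA engine targets correctness and testability over speed; very
  large assemblies (>50k atoms) will be slow at 960 points.
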