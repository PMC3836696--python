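"""Resampling significance for pooled propensities.

Three complementary schemes quantify how stable a propensity estimate
is and whether an observed contrast is meaningful:

* leave-10%-out — recompute the propensity on random 90% subsets of the
  *proteins* (never the sites); the median of the replicates is reported
  with 95th-percentile bounds (2.5th / 97.5th empirical percentiles).
* label shuffling — permute the valid/invalid labels over sites,
  keeping their overall proportion, and recompute the valid/invalid
  propensity ratio each time; the per-residue mean of the shuffled
  ratios sits at 1 under exchangeability, and the min/max envelope gives
  a dataset-specific significance band.
* set-size scans — recompute propensities on random subsets of growing
  size to expose how many structures are needed before the estimates
  converge, and how much wider the spread is for rare residues.

All operations derive their randomness from a single seed through
deterministic child streams, so any stage can be rerun independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .propensity import (
    INVALID,
    VALID,
    CompositionDataset,
)
from .residues import AMINO_ACIDS, N_AA


@dataclass
class ResampleConfig:
    n_reps: int = 1000
    leave_out_fraction: float = 0.10
    seed: int = 0
    percentile_bounds: tuple[float, float] = (2.5, 97.5)

    def __post_init__(self) -> None:
        if not (0 <= self.leave_out_fraction < 1):
            raise ValueError("leave_out_fraction must be in [0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class ResampleResult:
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    std: np.ndarray
    n_reps: int
    n_discarded: int = 0
    replicates: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "resname": AMINO_ACIDS,
                "median": self.median,
                "lower": self.lower,
                "upper": self.upper,
                "std": self.std,
            }
        )


def _rng_stream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-operation stream derived from a master seed."""
    digest = np.frombuffer(label.encode(), dtype=np.uint8)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=tuple(int(b) for b in digest))
    )


def _propensity_vector(
    dataset: CompositionDataset,
    validity: str | None,
    keep_mask: np.ndarray,
    site_validity: np.ndarray | None = None,
) -> np.ndarray:
    """Fast pooled propensity; NaN where the replicate has no counts or a
    zero surface frequency."""
    labels = dataset.site_validity if site_validity is None else site_validity
    site_mask = keep_mask[dataset.site_protein]
    if validity is not None:
        site_mask = site_mask & (labels == validity)
    if not site_mask.any():
        return np.full(N_AA, np.nan)
    bs = dataset.site_counts[site_mask].sum(axis=0).astype(float)
    has_site = (
        np.bincount(
            dataset.site_protein[site_mask], minlength=dataset.n_proteins
        )
        > 0
    )
    ps = dataset.surface_counts[has_site].sum(axis=0).astype(float)
    bs_total = bs.sum()
    ps_total = ps.sum()
    if bs_total == 0 or ps_total == 0:
        return np.full(N_AA, np.nan)
    out = np.full(N_AA, np.nan)
    ok = ps > 0
    out[ok] = (bs[ok] / bs_total) / (ps[ok] / ps_total)
    return out


def _summarize(replicates: np.ndarray, cfg: ResampleConfig, keep_replicates: bool) -> ResampleResult:
    ok_rows = ~np.isnan(replicates).all(axis=1)
    n_discarded = int((~ok_rows).sum())
    if n_discarded:
        warnings.warn(f"{n_discarded} replicate(s) discarded (no counts)")
    reps = replicates[ok_rows]
    lo, hi = cfg.percentile_bounds
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return ResampleResult(
            median=np.nanmedian(reps, axis=0),
            lower=np.nanpercentile(reps, lo, axis=0),
            upper=np.nanpercentile(reps, hi, axis=0),
            std=np.nanstd(reps, axis=0),
            n_reps=len(reps),
            n_discarded=n_discarded,
            replicates=reps if keep_replicates else None,
        )


def leave_k_out(
    dataset: CompositionDataset,
    cfg: ResampleConfig,
    validity: str | None = None,
    keep_replicates: bool = False,
) -> ResampleResult:
    """Leave-``f``-out percentile bounds for one propensity configuration.

    Each replicate drops a random fraction ``f`` of the *proteins* (their
    sites go with them) and recomputes the pooled propensity.
    """
    rng = _rng_stream(cfg.seed, f"leave_k_out:{validity}")
    n = dataset.n_proteins
    n_keep = n - int(round(cfg.leave_out_fraction * n))
    reps = np.empty((cfg.n_reps, N_AA))
    keep_mask = np.zeros(n, dtype=bool)
    for r in range(cfg.n_reps):
        keep_mask[:] = False
        if n_keep == n:
            keep_mask[:] = True
        else:
            keep_mask[rng.permutation(n)[:n_keep]] = True
        reps[r] = _propensity_vector(dataset, validity, keep_mask)
    return _summarize(reps, cfg, keep_replicates)


@dataclass
class ShuffleNullResult:
    observed_ratio: np.ndarray
    mean: np.ndarray
    min: np.ndarray
    max: np.ndarray
    significant: np.ndarray  # observed outside the shuffle envelope
    n_shuffles: int
    fixed_thresholds: tuple[float, float] = (1.2, 0.8)

    @property
    def significant_fixed(self) -> np.ndarray:
        """Flags under the conventional >1.2 / <0.8 ratio thresholds."""
        hi, lo = self.fixed_thresholds
        with np.errstate(invalid="ignore"):
            return (self.observed_ratio > hi) | (self.observed_ratio < lo)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "resname": AMINO_ACIDS,
                "observed_ratio": self.observed_ratio,
                "null_mean": self.mean,
                "null_min": self.min,
                "null_max": self.max,
                "significant_envelope": self.significant,
                "significant_fixed": self.significant_fixed,
            }
        )


def shuffle_validity_null(
    dataset: CompositionDataset,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> ShuffleNullResult:
    """Label-shuffle null for the valid/invalid propensity ratio.

    Validity labels are permuted over the site multiset (their relative
    proportion is preserved exactly); protein membership of each site is
    untouched.  Residues whose observed ratio falls outside the
    [min, max] envelope of the shuffled ratios are flagged.
    """
    labels = dataset.site_validity
    n_valid = int((labels == VALID).sum())
    n_invalid = int((labels == INVALID).sum())
    if n_valid == 0 or n_invalid == 0:
        raise ValueError("both validity classes must be present")
    rng = _rng_stream(seed, "shuffle_validity_null")
    all_keep = np.ones(dataset.n_proteins, dtype=bool)

    def ratio_for(lbls: np.ndarray) -> np.ndarray:
        pv = _propensity_vector(dataset, VALID, all_keep, site_validity=lbls)
        pi = _propensity_vector(dataset, INVALID, all_keep, site_validity=lbls)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = pv / pi
        r[~np.isfinite(r)] = np.nan
        return r

    observed = ratio_for(labels)
    ratios = np.empty((n_shuffles, N_AA))
    for k in range(n_shuffles):
        ratios[k] = ratio_for(rng.permutation(labels))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        null_mean = np.nanmean(ratios, axis=0)
        null_min = np.nanmin(ratios, axis=0)
        null_max = np.nanmax(ratios, axis=0)
    with np.errstate(invalid="ignore"):
        significant = (observed > null_max) | (observed < null_min)
    return ShuffleNullResult(
        observed_ratio=observed,
        mean=null_mean,
        min=null_min,
        max=null_max,
        significant=significant,
        n_shuffles=n_shuffles,
    )


@dataclass
class ConvergenceCurve:
    sizes: np.ndarray
    propensity_std: np.ndarray  # (S, 20)
    propensity_median: np.ndarray
    frequency_std: np.ndarray
    reps_per_point: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for si, size in enumerate(self.sizes):
            for ai, aa in enumerate(AMINO_ACIDS):
                rows.append(
                    {
                        "size": int(size),
                        "resname": aa,
                        "propensity_median": self.propensity_median[si, ai],
                        "propensity_std": self.propensity_std[si, ai],
                        "frequency_std": self.frequency_std[si, ai],
                    }
                )
        return pd.DataFrame(rows)


def _subset_samples(
    dataset: CompositionDataset,
    validity: str | None,
    sizes: np.ndarray,
    reps: int,
    rng: np.random.Generator,
):
    """Propensity and site-frequency replicate stacks for random subsets."""
    n = dataset.n_proteins
    prop = np.empty((len(sizes), reps, N_AA))
    freq = np.empty((len(sizes), reps, N_AA))
    keep_mask = np.zeros(n, dtype=bool)
    for si, size in enumerate(sizes):
        for r in range(reps):
            keep_mask[:] = False
            keep_mask[rng.permutation(n)[:size]] = True
            prop[si, r] = _propensity_vector(dataset, validity, keep_mask)
            site_mask = keep_mask[dataset.site_protein]
            if validity is not None:
                site_mask &= dataset.site_validity == validity
            counts = dataset.site_counts[site_mask].sum(axis=0).astype(float)
            total = counts.sum()
            freq[si, r] = counts / total if total > 0 else np.nan
    return prop, freq


def convergence_scan(
    dataset: CompositionDataset,
    validity: str | None = VALID,
    step_fraction: float = 0.01,
    reps_per_point: int = 100,
    seed: int = 0,
    sizes: np.ndarray | None = None,
) -> ConvergenceCurve:
    """Dispersion of propensities vs structure-set size.

    Sizes default to every ``step_fraction`` of the full set from the
    first step up to (but excluding) the full size; each size is sampled
    ``reps_per_point`` times without replacement within a subset.
    """
    n = dataset.n_proteins
    if sizes is None:
        step = int(round(step_fraction * n))
        if step < 1:
            warnings.warn("step smaller than 1 structure; coerced to 1")
            step = 1
        sizes = np.arange(step, n, step)
    sizes = np.asarray(sizes, dtype=int)
    if not np.all(np.diff(sizes) > 0):
        raise ValueError("sizes must be strictly increasing")
    rng = _rng_stream(seed, f"convergence_scan:{validity}")
    prop, freq = _subset_samples(dataset, validity, sizes, reps_per_point, rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return ConvergenceCurve(
            sizes=sizes,
            propensity_std=np.nanstd(prop, axis=1),
            propensity_median=np.nanmedian(prop, axis=1),
            frequency_std=np.nanstd(freq, axis=1),
            reps_per_point=reps_per_point,
        )


def fixed_size_table(
    dataset: CompositionDataset,
    sizes=(100, 500, 1000, 2000),
    n_reps: int = 10000,
    seed: int = 0,
    validities=(VALID, INVALID),
    percentile_bounds: tuple[float, float] = (2.5, 97.5),
) -> pd.DataFrame:
    """Median, std dev and percentile interval of propensities at fixed
    structure-set sizes, per validity class and residue."""
    if n_reps == 1:
        warnings.warn("n_reps = 1: standard deviations are degenerate (0)")
    sizes = np.asarray(sizes, dtype=int)
    if sizes.max() > dataset.n_proteins:
        raise ValueError("requested size exceeds dataset size")
    lo, hi = percentile_bounds
    rows = []
    for validity in validities:
        rng = _rng_stream(seed, f"fixed_size_table:{validity}")
        prop, _ = _subset_samples(dataset, validity, sizes, n_reps, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(prop, axis=1)
            std = np.nanstd(prop, axis=1)
            p_lo = np.nanpercentile(prop, lo, axis=1)
            p_hi = np.nanpercentile(prop, hi, axis=1)
        for si, size in enumerate(sizes):
            for ai, aa in enumerate(AMINO_ACIDS):
                rows.append(
                    {
                        "validity": validity,
                        "size": int(size),
                        "resname": aa,
                        "median": med[si, ai],
                        "std": std[si, ai],
                        "lower": p_lo[si, ai],
                        "upper": p_hi[si, ai],
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class SubgroupResult:
    subgroup_lower: np.ndarray
    subgroup_upper: np.ndarray
    random_lower: np.ndarray
    random_upper: np.ndarray
    flagged: np.ndarray  # intervals disjoint
    higher: np.ndarray  # subgroup interval entirely above random

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "resname": AMINO_ACIDS,
                "subgroup_lower": self.subgroup_lower,
                "subgroup_upper": self.subgroup_upper,
                "random_lower": self.random_lower,
                "random_upper": self.random_upper,
                "flagged": self.flagged,
                "higher": self.higher,
            }
        )


def subgroup_vs_random(
    dataset: CompositionDataset,
    subgroup_idx: np.ndarray,
    matched_size: int | None = None,
    n_reps: int = 1000,
    seed: int = 0,
    validity: str | None = VALID,
    leave_out_fraction: float = 0.10,
) -> SubgroupResult:
    """Flag residues whose subgroup propensity differs beyond chance.

    The subgroup's leave-10%-out 95th-percentile interval is compared
    against the 95th-percentile interval of propensities from random
    structure subsets of matched size drawn from the full set; a residue
    is flagged only when the two intervals are disjoint — the strictest
    version of the comparison.
    """
    subgroup_idx = np.asarray(subgroup_idx)
    if matched_size is None:
        matched_size = len(subgroup_idx)
    if matched_size > dataset.n_proteins:
        raise ValueError("matched_size exceeds dataset size")
    sub = dataset.subset_proteins(subgroup_idx)
    cfg = ResampleConfig(
        n_reps=n_reps, leave_out_fraction=leave_out_fraction, seed=seed
    )
    sub_res = leave_k_out(sub, cfg, validity=validity)

    rng = _rng_stream(seed, f"subgroup_vs_random:{validity}")
    prop, _ = _subset_samples(
        dataset, validity, np.array([matched_size]), n_reps, rng
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rand_lo = np.nanpercentile(prop[0], 2.5, axis=0)
        rand_hi = np.nanpercentile(prop[0], 97.5, axis=0)
    with np.errstate(invalid="ignore"):
        higher = sub_res.lower > rand_hi
        lower = sub_res.upper < rand_lo
    return SubgroupResult(
        subgroup_lower=sub_res.lower,
        subgroup_upper=sub_res.upper,
        random_lower=rand_lo,
        random_upper=rand_hi,
        flagged=higher | lower,
        higher=higher,
    )
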