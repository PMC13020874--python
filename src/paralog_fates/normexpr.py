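"""Cross-species RNA-seq normalization.

Turns raw gene-level counts from multiple species into comparable
log2(RPKM + 1) values through a three-step pipeline:

1. a multimap concordance filter removes genes whose counts from
   unique-read counting and fractional multimap counting disagree by
   more than a threshold (default 20%) in any sample;
2. TMM (trimmed mean of M values) factors are computed on the counts of
   single-copy orthologs — genes present exactly once per species, whose
   expression is not perturbed by duplication — and applied to effective
   library sizes before RPKM;
3. after conversion to log2(RPKM + 1), a set of stably expressed
   single-copy orthologs is selected by percent-rank stability and each
   sample is rescaled so that the median stable-gene expression matches
   a reference sample.

A pass-through hook (``corrected``) lets an externally batch-corrected
matrix (e.g. from surrogate-variable analysis) replace the log2 matrix
between steps 2 and 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset

logger = logging.getLogger(__name__)


@dataclass
class NormalizationReport:
    """Record of every decision the normalization pipeline made."""

    reference_sample: str
    tmm_factors: dict[str, float] = field(default_factory=dict)
    effective_lib_sizes: dict[str, float] = field(default_factory=dict)
    stable_genes: list[str] = field(default_factory=list)
    cross_species_factors: dict[str, float] = field(default_factory=dict)
    removed_multimap: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "reference_sample": self.reference_sample,
            "tmm_factors": self.tmm_factors,
            "effective_lib_sizes": self.effective_lib_sizes,
            "stable_genes": self.stable_genes,
            "cross_species_factors": self.cross_species_factors,
            "removed_multimap": self.removed_multimap,
            "warnings": self.warnings,
        }


def multimap_concordance_filter(
    counts_unique: pd.DataFrame,
    counts_fractional: pd.DataFrame,
    threshold: float = 0.2,
    per_sample: bool = True,
) -> tuple[list[str], list[str]]:
    """Split genes into kept/removed by unique-vs-multimap count concordance.

    A gene is removed when |fractional - unique| / max(unique, 1)
    exceeds ``threshold`` in any sample (default, strictest reading) or,
    with ``per_sample=False``, on counts summed over samples. The
    max(unique, 1) denominator makes the zero-unique-count case
    deterministic: any fractional signal above the threshold at a gene
    that unique counting misses entirely is discordant.
    """
    if not counts_unique.index.equals(counts_fractional.index) or not (
        counts_unique.columns.equals(counts_fractional.columns)
    ):
        raise ValueError("unique and fractional count matrices must share gene x sample index")
    u = counts_unique.to_numpy(dtype=float)
    f = counts_fractional.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if per_sample:
            ratio = np.abs(f - u) / np.maximum(u, 1.0)
            bad = np.nanmax(ratio, axis=1) > threshold
        else:
            us, fs = np.nansum(u, axis=1), np.nansum(f, axis=1)
            bad = np.abs(fs - us) / np.maximum(us, 1.0) > threshold
    genes = counts_unique.index
    kept = list(genes[~bad])
    removed = list(genes[bad])
    return kept, removed


def _tmm_factor_vs_ref(
    obs: np.ndarray,
    ref: np.ndarray,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one sample against the reference (edgeR-style).

    M (log2 ratio of count proportions) and A (mean log2 proportion)
    values are computed on genes with positive counts in both samples;
    the most extreme ``trim_m`` fraction of M (each tail) and ``trim_a``
    of A are removed, and the factor is 2 to the precision-weighted mean
    of the remaining M values (weights: inverse binomial variance).
    """
    lib_o, lib_r = obs.sum(), ref.sum()
    ok = (obs > 0) & (ref > 0)
    if ok.sum() < 2:
        logger.warning("fewer than 2 genes shared with the reference; TMM factor = 1")
        return 1.0
    o, r = obs[ok], ref[ok]
    p_o, p_r = o / lib_o, r / lib_r
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    w = (lib_o - o) / (lib_o * o) + (lib_r - r) / (lib_r * r)
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m), np.ceil(n * (1 - trim_m))
    lo_a, hi_a = np.floor(n * trim_a), np.ceil(n * (1 - trim_a))
    rank_m = pd.Series(m).rank(method="first").to_numpy()
    rank_a = pd.Series(a).rank(method="first").to_numpy()
    keep = (rank_m > lo_m) & (rank_m <= hi_m) & (rank_a > lo_a) & (rank_a <= hi_a)
    if keep.sum() < 2:
        logger.warning("fewer than 2 genes left after TMM trimming; factor = 1")
        return 1.0
    if np.max(np.abs(m[keep])) < 1e-6:
        return 1.0
    wm = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0**wm)


def tmm_factors(
    counts: pd.DataFrame,
    reference_sample: str,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Per-sample TMM factors against a reference sample.

    ``counts`` should be restricted to single-copy orthologs (rows are
    ortholog groups, one value per sample from the sample species'
    member gene). NaN rows (group absent in a species) are ignored
    pairwise. The reference sample's factor is 1 by construction.
    """
    if reference_sample not in counts.columns:
        raise ValueError(f"reference sample {reference_sample!r} not in matrix")
    ref = counts[reference_sample].to_numpy(dtype=float)
    factors = {}
    for sample in counts.columns:
        obs = counts[sample].to_numpy(dtype=float)
        ok = ~(np.isnan(obs) | np.isnan(ref))
        factors[sample] = _tmm_factor_vs_ref(obs[ok], ref[ok], trim_m, trim_a)
    factors[reference_sample] = 1.0
    return pd.Series(factors, name="tmm_factor")


def compute_rpkm_log2(
    counts: pd.DataFrame,
    lengths: pd.Series,
    effective_lib_sizes: pd.Series,
) -> pd.DataFrame:
    """log2(RPKM + 1) from counts, gene lengths (bp) and library sizes.

    RPKM = count / (length_kb * lib_size_millions); jointly doubling all
    counts and library sizes leaves the result unchanged.
    """
    lengths = lengths.loc[counts.index]
    libs = effective_lib_sizes.loc[counts.columns]
    if (libs <= 0).any():
        raise ValueError("effective library sizes must be positive")
    if (lengths[counts.notna().any(axis=1)] <= 0).any():
        raise ValueError("gene lengths must be positive")
    rpkm = counts.div(lengths / 1000.0, axis=0).div(libs / 1e6, axis=1)
    return np.log2(rpkm + 1.0)


def select_stable_genes(expr: pd.DataFrame, n_select: int = 375) -> list[str]:
    """Single-copy orthologs with the most stable expression percent rank.

    Per sample, each gene's percent rank of expression is computed;
    genes whose median percent rank across samples falls within the top
    or bottom 25% of all genes are removed, and of the remainder the
    ``n_select`` genes with the smallest standard deviation of percent
    ranks are returned. If fewer are eligible, all are returned with a
    warning.
    """
    expr = expr.dropna(how="all")
    pct = expr.rank(axis=0, pct=True)
    med = pct.median(axis=1)
    order = med.sort_values(kind="mergesort")
    n = len(order)
    cut = int(np.floor(0.25 * n))
    eligible = order.iloc[cut : n - cut].index if cut > 0 else order.index
    sds = pct.loc[eligible].std(axis=1, ddof=1).sort_values(kind="mergesort")
    if n_select > len(sds):
        logger.warning(
            "requested %d stable genes but only %d eligible; returning all",
            n_select, len(sds),
        )
        n_select = len(sds)
    return list(sds.index[:n_select])


def cross_species_factor(
    expr: pd.DataFrame,
    stable_genes: list[str],
    reference_sample: str,
) -> tuple[pd.Series, pd.DataFrame]:
    """Rescale each sample so stable-gene medians match the reference.

    factor_s = median(expr[stable, ref]) / median(expr[stable, s]);
    the normalized matrix is expr * factor_s columnwise, making the
    stable-gene median identical across samples (the reference factor is
    1). Rejects samples whose stable-gene median is not positive.
    """
    missing = [g for g in stable_genes if g not in expr.index]
    if missing:
        raise ValueError(f"stable genes missing from matrix: {missing[:5]}...")
    med = expr.loc[stable_genes].median(axis=0)
    if (med <= 0).any():
        bad = list(med.index[med <= 0])
        raise ValueError(f"non-positive stable-gene median in samples {bad}")
    factors = med[reference_sample] / med
    factors[reference_sample] = 1.0
    return factors.rename("cross_species_factor"), expr.mul(factors, axis=1)


def normalize_pipeline(
    counts_unique: ExpressionDataset,
    counts_fractional: pd.DataFrame | None = None,
    reference_sample: str | None = None,
    multimap_threshold: float = 0.2,
    n_stable: int = 375,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    corrected: pd.DataFrame | None = None,
) -> tuple[ExpressionDataset, NormalizationReport]:
    """Full normalization: filter -> TMM -> log2 RPKM -> stable-gene rescale.

    ``counts_unique`` must be a raw-counts dataset with single-copy
    ortholog annotations; ``counts_fractional`` (same shape) enables the
    multimap filter. ``corrected`` optionally replaces the log2(RPKM+1)
    matrix before the cross-species step (hook for external
    batch-effect correction). The reference defaults to the
    lexicographically first sample.
    """
    counts_unique.require_stage("raw_counts")
    if reference_sample is None:
        reference_sample = sorted(counts_unique.samples)[0]
    report = NormalizationReport(reference_sample=reference_sample)

    values = counts_unique.values
    if counts_fractional is not None:
        kept, removed = multimap_concordance_filter(
            values, counts_fractional, threshold=multimap_threshold
        )
        report.removed_multimap = removed
        values = values.loc[kept]
    filtered = counts_unique.with_values(values, "raw_counts")

    og_counts = filtered.ortholog_matrix()
    tmm = tmm_factors(og_counts, reference_sample, trim_m=trim_m, trim_a=trim_a)
    report.tmm_factors = tmm.to_dict()

    lib_sizes = filtered.values.sum(axis=0, skipna=True)
    eff_lib = lib_sizes * tmm
    report.effective_lib_sizes = eff_lib.to_dict()

    log2_expr = compute_rpkm_log2(
        filtered.values, filtered.gene_meta["length_bp"], eff_lib
    )
    if corrected is not None:
        if not corrected.index.equals(log2_expr.index) or not corrected.columns.equals(
            log2_expr.columns
        ):
            raise ValueError("corrected matrix must match the filtered gene x sample index")
        log2_expr = corrected
        report.warnings.append("externally corrected matrix substituted before rescaling")

    log2_ds = filtered.with_values(log2_expr, "rpkm_log2")
    og_expr = log2_ds.ortholog_matrix()
    stable = select_stable_genes(og_expr, n_select=n_stable)
    report.stable_genes = stable

    factors, _ = cross_species_factor(og_expr, stable, reference_sample)
    report.cross_species_factors = factors.to_dict()
    normalized = log2_expr.mul(factors, axis=1)
    out = filtered.with_values(normalized, "normalized")
    return out, report
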