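"""Tissue-specificity and expression-distance metrics.

Implements the tissue-specificity index tau, per-gene median expression,
aggregation of secondary duplicates (elementwise max), total-expression
profiles of a paralog pair, relative (composition) profiles, and the
absolute/relative Euclidean distance table comparing each paralog (and
the paralog total) with the pre-duplication species' profile.

Scale conventions: absolute distances are computed on log2(RPKM + 1);
the total profile of a pair is formed by summing RPKM before re-logging
(expression adds on the linear scale). Relative profiles divide each
tissue's value by the summed value across tissues; by default the ratio
is taken on the linear RPKM scale, under which a pure dosage change
(both paralogs scaled down proportionally) leaves the relative profile
exactly invariant — the defining property of dosage sharing. A log2
variant is available via ``rel_scale="log2"``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset

logger = logging.getLogger(__name__)


@dataclass
class TissueProfile:
    """Per-tissue expression values of one gene in one species."""

    gene_id: str
    species: str
    values: np.ndarray
    tissues: tuple[str, ...]
    scale: str = "log2"  # "log2" (log2(RPKM+1)) or "rpkm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.tissues = tuple(self.tissues)
        if len(self.tissues) != len(self.values):
            raise ValueError("tissue labels and values must align")
        if len(set(self.tissues)) != len(self.tissues):
            raise ValueError("tissue labels must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")

    @property
    def n_tissues(self) -> int:
        return len(self.tissues)

    def restrict(self, tissues: tuple[str, ...]) -> "TissueProfile":
        idx = [self.tissues.index(t) for t in tissues]
        return TissueProfile(self.gene_id, self.species, self.values[idx], tissues, self.scale)


@dataclass
class SpecificitySummary:
    """Tau tissue-specificity (None when undefined) and median expression."""

    tau: float | None
    median_expression: float
    flags: list[str]


def tau(profile: TissueProfile) -> SpecificitySummary:
    """Tissue-specificity index tau in [0, 1].

    Values are clamped at zero (normalization can push log2 values of
    very low-expression genes below zero, which would otherwise yield
    tau > 1). With x_i the clamped value in tissue i relative to the
    maximum across tissues, tau = sum(1 - x_i) / (N - 1): 0 for uniform
    expression, 1 for single-tissue expression. Undefined (flagged) for
    an all-zero profile.
    """
    if profile.n_tissues < 2:
        raise ValueError("tau needs at least 2 tissues")
    v = np.clip(profile.values, 0.0, None)
    median = float(np.median(v))
    vmax = v.max()
    if vmax <= 0:
        return SpecificitySummary(tau=None, median_expression=median,
                                  flags=["all_zero_profile"])
    x = v / vmax
    t = float((1.0 - x).sum() / (profile.n_tissues - 1))
    return SpecificitySummary(tau=t, median_expression=median, flags=[])


def aggregate_secondary_duplicates(profiles: list[TissueProfile]) -> TissueProfile:
    """Elementwise-max profile over secondary duplicates of one paralog.

    When a paralog is represented by more than one sequence in a species
    (secondary duplications or assembly artifacts), the per-tissue
    maximum is used so that odd low-expression copies do not dilute the
    paralog's signal.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    first = profiles[0]
    for p in profiles[1:]:
        if p.tissues != first.tissues:
            raise ValueError("profiles must share the same tissue set and order")
        if p.scale != first.scale:
            raise ValueError("profiles must share the same scale")
    values = np.max([p.values for p in profiles], axis=0)
    return TissueProfile(first.gene_id, first.species, values, first.tissues, first.scale)


def total_profile(a: TissueProfile, b: TissueProfile) -> TissueProfile:
    """Per-tissue total RPKM of a paralog pair (RPKM scale in, RPKM out)."""
    if a.scale != "rpkm" or b.scale != "rpkm":
        raise ValueError("total_profile requires RPKM-scale inputs")
    if a.tissues != b.tissues:
        raise ValueError("profiles must share the same tissue set and order")
    if a.species != b.species:
        raise ValueError("paralogs must come from the same species")
    return TissueProfile(
        f"{a.gene_id}+{b.gene_id}", a.species, a.values + b.values, a.tissues, "rpkm"
    )


def log2_profile(p: TissueProfile) -> TissueProfile:
    if p.scale != "rpkm":
        raise ValueError("log2_profile requires an RPKM-scale input")
    return TissueProfile(p.gene_id, p.species, np.log2(p.values + 1.0), p.tissues, "log2")


def relative_profile(profile: TissueProfile) -> TissueProfile:
    """Composition profile: each tissue's value over the summed value.

    Negative inputs (possible on the normalized log2 scale) clamp to
    zero first. Output sums to 1; rejects an all-zero profile.
    """
    v = np.clip(profile.values, 0.0, None)
    total = v.sum()
    if total <= 0:
        raise ValueError(f"all-zero profile for {profile.gene_id}; relative profile undefined")
    return TissueProfile(
        profile.gene_id, profile.species, v / total, profile.tissues, "relative"
    )


def euclidean_distance(x: TissueProfile, y: TissueProfile) -> float:
    """Euclidean distance between two profiles over the same tissues."""
    if x.tissues != y.tissues:
        raise ValueError("profiles must share the same tissue set and order")
    return float(np.sqrt(((x.values - y.values) ** 2).sum()))


# ---------------------------------------------------------------------------
# distance table
# ---------------------------------------------------------------------------

def _gene_profiles(
    dataset: ExpressionDataset, gene_ids: list[str], scale: str
) -> TissueProfile | None:
    """Aggregate (max) RPKM profile over the given genes of one species."""
    profs = []
    for gid in gene_ids:
        series = dataset.tissue_profile(gid)
        series = series.dropna()
        profs.append(
            TissueProfile(
                gid,
                dataset.gene_meta.at[gid, "species"],
                series.to_numpy(),
                tuple(series.index),
                scale,
            )
        )
    if not profs:
        return None
    return aggregate_secondary_duplicates(profs)


def build_distance_table(
    dataset: ExpressionDataset,
    pre_species: list[str],
    rel_scale: str = "linear",
) -> pd.DataFrame:
    """Absolute and relative Euclidean distances to the pre-duplication profile.

    For every family, every (pre-duplication species, post-duplication
    species) combination yields six rows: entities A, B and T (the
    paralog total, always derived, never supplied) x the absolute
    distance (log2(RPKM+1) scale) and the relative distance
    (composition profiles, see module docstring). Distances use the
    intersection of tissues available in the two species. A missing
    paralog is treated as all-zero (and logged). Pre-duplication species
    that carry duplicates of a family are excluded from that family
    (mirroring the removal of lineages whose "pre-duplication" copy is
    itself duplicated). Families without any usable pre-duplication
    profile are skipped with a warning.

    Input must be RPKM-scale (use ``.to_rpkm()`` on normalized data).
    """
    dataset.require_stage("rpkm")
    if rel_scale not in ("linear", "log2"):
        raise ValueError("rel_scale must be 'linear' or 'log2'")
    meta = dataset.gene_meta
    rows = []
    post_species_all = [
        sp for sp in dataset.sample_meta["species"].unique() if sp not in pre_species
    ]
    for family, fam_meta in meta.groupby("family", sort=True):
        if not {"A", "B"} & set(fam_meta["paralog_label"]):
            continue  # not a paralog-pair family (e.g. single-copy anchors)
        pre_profiles: dict[str, TissueProfile] = {}
        for sp in pre_species:
            fam_pre = fam_meta[
                (fam_meta["species"] == sp) & (fam_meta["paralog_label"] == "pre")
            ]
            n_copies = len(fam_meta[fam_meta["species"] == sp])
            if n_copies > 1:
                logger.info(
                    "family %s: pre-duplication species %s carries %d copies; excluded",
                    family, sp, n_copies,
                )
                continue
            if fam_pre.empty:
                continue
            prof = _gene_profiles(dataset, list(fam_pre.index), "rpkm")
            if prof is not None:
                pre_profiles[sp] = prof
        if not pre_profiles:
            logger.warning("family %s: no pre-duplication profile; skipped", family)
            continue
        for post_sp in post_species_all:
            fam_post = fam_meta[fam_meta["species"] == post_sp]
            if fam_post.empty:
                continue
            entity_profiles: dict[str, TissueProfile | None] = {}
            for label in ("A", "B"):
                gids = list(fam_post.index[fam_post["paralog_label"] == label])
                entity_profiles[label] = _gene_profiles(dataset, gids, "rpkm")
            if entity_profiles["A"] is None and entity_profiles["B"] is None:
                continue
            # a missing paralog counts as zero expression
            present = next(p for p in entity_profiles.values() if p is not None)
            for label in ("A", "B"):
                if entity_profiles[label] is None:
                    logger.info(
                        "family %s: paralog %s absent in %s; treated as all-zero",
                        family, label, post_sp,
                    )
                    entity_profiles[label] = TissueProfile(
                        f"{family}.{post_sp}.{label}(absent)", post_sp,
                        np.zeros(present.n_tissues), present.tissues, "rpkm",
                    )
            a, b = entity_profiles["A"], entity_profiles["B"]
            t = total_profile(a, b)
            for pre_sp, pre_prof in pre_profiles.items():
                shared = tuple(ti for ti in pre_prof.tissues if ti in a.tissues)
                if len(shared) < 2:
                    logger.warning(
                        "family %s: <2 shared tissues between %s and %s; skipped",
                        family, pre_sp, post_sp,
                    )
                    continue
                pre_r = pre_prof.restrict(shared)
                for entity, prof in (("A", a), ("B", b), ("T", t)):
                    prof_r = prof.restrict(shared)
                    d_abs = euclidean_distance(log2_profile(prof_r), log2_profile(pre_r))
                    if rel_scale == "linear":
                        rel_post = _safe_relative(prof_r)
                        rel_pre = _safe_relative(pre_r)
                    else:
                        rel_post = _safe_relative(log2_profile(prof_r))
                        rel_pre = _safe_relative(log2_profile(pre_r))
                    d_rel = (
                        euclidean_distance(rel_post, rel_pre)
                        if rel_post is not None and rel_pre is not None
                        else math.nan
                    )
                    rows.append(
                        {
                            "family": family,
                            "pre_species": pre_sp,
                            "post_species": post_sp,
                            "entity": entity,
                            "d_abs": d_abs,
                            "d_rel": d_rel,
                        }
                    )
    return pd.DataFrame(
        rows, columns=["family", "pre_species", "post_species", "entity", "d_abs", "d_rel"]
    )


def _safe_relative(p: TissueProfile) -> TissueProfile | None:
    try:
        return relative_profile(p)
    except ValueError:
        return None


def specificity_table(dataset: ExpressionDataset) -> pd.DataFrame:
    """Per-gene tau and median expression on the log2(RPKM+1) scale."""
    if dataset.stage == "rpkm":
        dataset = dataset.to_log2()
    dataset.require_stage("rpkm_log2", "normalized")
    rows = []
    for gid in dataset.genes:
        series = dataset.tissue_profile(gid).dropna()
        prof = TissueProfile(
            gid, dataset.gene_meta.at[gid, "species"],
            series.to_numpy(), tuple(series.index), "log2",
        )
        summary = tau(prof)
        rows.append(
            {
                "gene_id": gid,
                "species": prof.species,
                "family": dataset.gene_meta.at[gid, "family"],
                "paralog_label": dataset.gene_meta.at[gid, "paralog_label"],
                "tau": summary.tau,
                "median_expression": summary.median_expression,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
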