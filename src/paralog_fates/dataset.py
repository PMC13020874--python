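"""Gene-by-sample expression container shared across pipeline stages.

An :class:`ExpressionDataset` holds a gene x sample value matrix together
with gene metadata (species, gene family, paralog label, length, optional
single-copy ortholog group) and sample metadata (species, tissue). Because
genes belong to one species, a gene's value is defined only in samples of
its own species; other cells are NaN.

Each dataset carries a ``stage`` tag so that pipeline stages can refuse
out-of-order input:

``raw_counts``
    unnormalized read counts;
``rpkm``
    linear reads-per-kilobase-per-million values;
``rpkm_log2``
    log2(RPKM + 1);
``normalized``
    log2(RPKM + 1) after cross-species rescaling (values may drop below
    zero downstream consumers clamp where needed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

STAGES = ("raw_counts", "rpkm", "rpkm_log2", "normalized")

GENE_META_COLUMNS = ["species", "family", "paralog_label", "length_bp", "single_copy_og"]
SAMPLE_META_COLUMNS = ["species", "tissue"]


@dataclass
class ExpressionDataset:
    """Gene x sample matrix with species/tissue/orthology annotations."""

    values: pd.DataFrame  # genes x samples
    gene_meta: pd.DataFrame  # indexed by gene_id
    sample_meta: pd.DataFrame  # indexed by sample_id
    stage: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if not self.values.index.equals(self.gene_meta.index):
            self.gene_meta = self.gene_meta.loc[self.values.index]
        if not self.values.columns.equals(self.sample_meta.index):
            self.sample_meta = self.sample_meta.loc[self.values.columns]
        missing = [c for c in SAMPLE_META_COLUMNS if c not in self.sample_meta.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns {missing}")
        missing = [c for c in GENE_META_COLUMNS if c not in self.gene_meta.columns]
        if missing:
            raise ValueError(f"gene metadata missing columns {missing}")
        if self.stage == "raw_counts":
            with np.errstate(invalid="ignore"):
                if (self.values.to_numpy() < 0).any():
                    raise ValueError("negative counts")
        lengths = self.gene_meta["length_bp"]
        has_values = self.values.notna().any(axis=1)
        if (lengths[has_values] <= 0).any():
            raise ValueError("length_bp must be positive for genes with values")

    # -- basic accessors ----------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def samples_of_species(self, species: str) -> list[str]:
        return list(self.sample_meta.index[self.sample_meta["species"] == species])

    def require_stage(self, *stages: str) -> None:
        if self.stage not in stages:
            raise ValueError(
                f"operation requires stage in {stages}, got {self.stage!r}"
            )

    def with_values(self, values: pd.DataFrame, stage: str) -> "ExpressionDataset":
        return ExpressionDataset(
            values=values,
            gene_meta=self.gene_meta.loc[values.index].copy(),
            sample_meta=self.sample_meta.loc[values.columns].copy(),
            stage=stage,
        )

    # -- scale conversions --------------------------------------------

    def to_log2(self) -> "ExpressionDataset":
        """log2(RPKM + 1) view of an RPKM-scale dataset."""
        self.require_stage("rpkm")
        return self.with_values(np.log2(self.values + 1.0), "rpkm_log2")

    def to_rpkm(self) -> "ExpressionDataset":
        """Linear-RPKM view of a log2 dataset (negatives clamp to zero RPKM)."""
        self.require_stage("rpkm_log2", "normalized")
        rpkm = np.exp2(self.values) - 1.0
        return self.with_values(rpkm.clip(lower=0.0), "rpkm")

    # -- orthology helpers --------------------------------------------

    def ortholog_matrix(self) -> pd.DataFrame:
        """Single-copy-ortholog-group x sample matrix.

        For each ortholog group and sample, picks the value of the group
        member gene belonging to the sample's species. Groups missing a
        member in some sample's species get NaN there.
        """
        sco = self.gene_meta.dropna(subset=["single_copy_og"])
        if sco.empty:
            raise ValueError("dataset has no single-copy ortholog annotations")
        dup = sco.groupby(["single_copy_og", "species"]).size()
        if (dup > 1).any():
            bad = dup[dup > 1].index[0]
            raise ValueError(f"ortholog group {bad[0]} has >1 gene in species {bad[1]}")
        gene_by_group = {
            (row["single_copy_og"], row["species"]): gid for gid, row in sco.iterrows()
        }
        groups = sorted(sco["single_copy_og"].unique())
        out = pd.DataFrame(np.nan, index=pd.Index(groups, name="og"), columns=self.samples)
        for sid in self.samples:
            sp = self.sample_meta.at[sid, "species"]
            for og in groups:
                gid = gene_by_group.get((og, sp))
                if gid is not None:
                    out.at[og, sid] = self.values.at[gid, sid]
        return out

    # -- tissue profiles ----------------------------------------------

    def tissue_profile(self, gene_id: str) -> pd.Series:
        """Per-tissue values of one gene in its own species' samples.

        Replicate samples of the same tissue average; returns a Series
        indexed by tissue.
        """
        sp = self.gene_meta.at[gene_id, "species"]
        cols = self.samples_of_species(sp)
        vals = self.values.loc[gene_id, cols]
        tissues = self.sample_meta.loc[cols, "tissue"]
        return vals.groupby(tissues).mean()

    # -- I/O -----------------------------------------------------------

    def write_tsv(self, outdir: str | Path, prefix: str = "expression") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "values": outdir / f"{prefix}_{self.stage}.tsv",
            "genes": outdir / f"{prefix}_genes.tsv",
            "samples": outdir / f"{prefix}_samples.tsv",
        }
        self.values.to_csv(paths["values"], sep="\t", index_label="gene_id")
        self.gene_meta.to_csv(paths["genes"], sep="\t", index_label="gene_id")
        self.sample_meta.to_csv(paths["samples"], sep="\t", index_label="sample_id")
        return paths

    @classmethod
    def read_tsv(
        cls,
        values_path: str | Path,
        genes_path: str | Path,
        samples_path: str | Path,
        stage: str,
    ) -> "ExpressionDataset":
        values = pd.read_csv(values_path, sep="\t", index_col="gene_id")
        gene_meta = pd.read_csv(genes_path, sep="\t", index_col="gene_id")
        sample_meta = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
        return cls(values=values, gene_meta=gene_meta, sample_meta=sample_meta, stage=stage)


def subset_species(dataset: ExpressionDataset, species: list[str]) -> ExpressionDataset:
    """Restrict a dataset to samples (and genes) of the given species."""
    keep_samples = dataset.sample_meta.index[dataset.sample_meta["species"].isin(species)]
    keep_genes = dataset.gene_meta.index[dataset.gene_meta["species"].isin(species)]
    return ExpressionDataset(
        values=dataset.values.loc[keep_genes, keep_samples].copy(),
        gene_meta=dataset.gene_meta.loc[keep_genes].copy(),
        sample_meta=dataset.sample_meta.loc[keep_samples].copy(),
        stage=dataset.stage,
    )
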