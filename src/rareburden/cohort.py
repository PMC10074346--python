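"""The Cohort container shared by every pipeline stage.

A cohort bundles the sample sheet, the variant annotation table, the dosage
matrix (samples x variants), per-gene features (pLI, CoNeS) and per-gene MSC
thresholds.  Dosages are 0/1/2 on autosomes, 0/1 for male X (hemizygous,
ploidy 1); negative entries denote missing genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ["status", "sex", "age", "ancestry", "pipeline", "auto_ab"]
VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "vclass",
                   "gnomad_af", "cadd", "blof", "bp_flag"]

__all__ = ["Cohort", "SAMPLE_COLUMNS", "VARIANT_COLUMNS"]


@dataclass
class Cohort:
    samples: pd.DataFrame        # index: sample_id
    variants: pd.DataFrame       # index: variant_id
    genotypes: np.ndarray        # samples x variants, int dosage
    gene_features: pd.DataFrame  # index: gene; columns pli, cones
    msc: pd.Series               # gene -> CADD threshold

    def validate(self) -> "Cohort":
        if self.samples.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.genotypes.shape != (len(self.samples), len(self.variants)):
            raise ValueError("genotype matrix does not match samples x variants")
        genes = set(self.variants["gene"])
        missing_feat = genes - set(self.gene_features.index)
        if missing_feat:
            raise ValueError(f"genes missing from gene_features: {sorted(missing_feat)[:5]}")
        missing_msc = genes - set(self.msc.index)
        if missing_msc:
            raise ValueError(f"genes missing from msc: {sorted(missing_msc)[:5]}")
        pl = self.ploidy()
        obs = self.genotypes >= 0
        if np.any(self.genotypes[obs] > pl[obs]):
            raise ValueError("dosage exceeds ploidy")
        return self

    # -- convenience accessors -------------------------------------------
    @property
    def status(self) -> np.ndarray:
        """Case indicator (1 = case, 0 = control)."""
        return (self.samples["status"].to_numpy() == "case").astype(int)

    @property
    def male(self) -> np.ndarray:
        return (self.samples["sex"].to_numpy() == "M").astype(int)

    def ploidy(self) -> np.ndarray:
        """Samples x variants ploidy (1 for male X, 2 otherwise)."""
        is_x = (self.variants["chrom"].astype(str) == "X").to_numpy()
        male = self.male.astype(bool)
        pl = np.full(self.genotypes.shape, 2, dtype=np.int8)
        pl[np.ix_(male, is_x)] = 1
        return pl

    def dosages_for(self, variant_ids) -> tuple[np.ndarray, np.ndarray]:
        """(dosages, ploidy) sub-matrices for a list of variant ids."""
        idx = self.variants.index.get_indexer(list(variant_ids))
        if np.any(idx < 0):
            raise KeyError("unknown variant id requested")
        return self.genotypes[:, idx], self.ploidy()[:, idx]

    def covariates(self, pcs: np.ndarray | None = None) -> np.ndarray:
        """Standard adjustment set: male indicator, age, then optional PCs."""
        cols = [self.male.astype(float), self.samples["age"].to_numpy(float)]
        mat = np.column_stack(cols)
        if pcs is not None:
            mat = np.column_stack([mat, pcs])
        return mat
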