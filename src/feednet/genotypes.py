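"""Genotype container shared across QC, simulation, I/O and association.

Genotypes use the additive substitution coding {-1, 0, +1} (alt-allele
homozygote = +1, heterozygote = 0) with NaN marking missing calls, stored as a
samples x SNPs float matrix alongside a SNP map of chromosome / 1-based
position / alleles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SNP_MAP_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    sample_ids: pd.Index
    snp_ids: pd.Index
    codes: np.ndarray  # shape (n_samples, n_snps), values {-1,0,1,nan}
    snp_map: pd.DataFrame  # indexed by snp_id: chrom, pos, ref, alt

    def __post_init__(self):
        self.sample_ids = pd.Index(self.sample_ids).rename(None)
        self.snp_ids = pd.Index(self.snp_ids).rename(None)
        self.snp_map = self.snp_map.rename_axis(None)
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        missing_map = self.snp_ids.difference(self.snp_map.index)
        if len(missing_map):
            raise ValueError(
                f"{len(missing_map)} SNPs lack a map entry, e.g. {missing_map[0]!r}"
            )
        obs = self.codes[np.isfinite(self.codes)]
        if obs.size and not np.isin(obs, (-1.0, 0.0, 1.0)).all():
            raise ValueError("genotype codes must be in {-1, 0, +1} or NaN")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_call_frequency(self) -> pd.Series:
        """Fraction of non-missing calls per SNP."""
        called = np.isfinite(self.codes).mean(axis=0)
        return pd.Series(called, index=self.snp_ids, name="call_frequency")

    def sample_call_rate(self) -> pd.Series:
        """Fraction of non-missing calls per sample."""
        called = np.isfinite(self.codes).mean(axis=1)
        return pd.Series(called, index=self.sample_ids, name="call_rate")

    def minor_allele_frequency(self) -> pd.Series:
        """MAF per SNP, computed over non-missing calls only."""
        with np.errstate(invalid="ignore"):
            # mean of codes over called genotypes maps to 2*p_alt - 1
            mean_code = np.nanmean(np.where(np.isfinite(self.codes), self.codes, np.nan), axis=0)
        p_alt = (mean_code + 1.0) / 2.0
        maf = np.minimum(p_alt, 1.0 - p_alt)
        return pd.Series(maf, index=self.snp_ids, name="maf")

    def subset(self, samples=None, snps=None) -> "GenotypeMatrix":
        rows = (
            slice(None)
            if samples is None
            else self.sample_ids.get_indexer(pd.Index(samples))
        )
        cols = (
            slice(None) if snps is None else self.snp_ids.get_indexer(pd.Index(snps))
        )
        new_samples = self.sample_ids if samples is None else pd.Index(samples)
        new_snps = self.snp_ids if snps is None else pd.Index(snps)
        return GenotypeMatrix(
            sample_ids=new_samples,
            snp_ids=new_snps,
            codes=self.codes[rows][:, cols],
            snp_map=self.snp_map.loc[new_snps],
        )

    def snp_vector(self, snp_id) -> np.ndarray:
        j = self.snp_ids.get_loc(snp_id)
        return self.codes[:, j]
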