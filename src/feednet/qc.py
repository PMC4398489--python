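"""Marker and sample quality control.

Filters mirror the 50k-chip QC of the source study: keep autosomal SNPs with
call frequency strictly above 0.85 and minor allele frequency strictly above
0.01, and samples with call rate strictly above 0.98.  Hardy-Weinberg
disequilibrium is a report-only diagnostic (in the original workflow it
triggered manual cluster review, never automatic removal).

MAF is computed on non-missing calls only.  The pipeline applies the filters
in the order SNP filters -> sample call rate; SNP call frequencies are
computed over whichever samples are present in the matrix handed in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

DEFAULT_MIN_CALL_FREQ = 0.85
DEFAULT_MIN_MAF = 0.01
DEFAULT_MIN_SAMPLE_CALL_RATE = 0.98

#: Chromosome labels treated as non-autosomal (case-insensitive, with or
#: without a "chr" prefix).
NON_AUTOSOMES = {"x", "y", "mt", "m", "w", "z"}


class EmptyPanelError(ValueError):
    """All SNPs (or all samples) were removed by filtering."""


@dataclass
class QcReport:
    """Per-rule bookkeeping of a filtering pass."""

    snp_call_frequency: pd.Series | None = None
    snp_maf: pd.Series | None = None
    sample_call_rate: pd.Series | None = None
    removed: dict = field(default_factory=dict)
    n_retained: int = 0

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())


def is_autosomal(chrom) -> np.ndarray:
    labels = pd.Index(chrom).astype(str).str.lower().str.removeprefix("chr")
    return ~labels.isin(NON_AUTOSOMES)


def filter_snps(
    g: GenotypeMatrix,
    min_call_freq: float = DEFAULT_MIN_CALL_FREQ,
    min_maf: float = DEFAULT_MIN_MAF,
    autosomes_only: bool = True,
) -> tuple[GenotypeMatrix, QcReport]:
    """Retain autosomal SNPs with call frequency and MAF above threshold.

    Both inequalities are strict.  Removal counts are itemised per rule; a
    SNP failing several rules is charged to the first violated rule in the
    order non-autosomal -> call frequency -> MAF.
    """
    for name, value in [("min_call_freq", min_call_freq), ("min_maf", min_maf)]:
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {value}")
    call_freq = g.snp_call_frequency()
    maf = g.minor_allele_frequency()
    autosomal = (
        pd.Series(is_autosomal(g.snp_map.loc[g.snp_ids, "chrom"]), index=g.snp_ids)
        if autosomes_only
        else pd.Series(True, index=g.snp_ids)
    )
    pass_call = call_freq > min_call_freq
    pass_maf = maf.fillna(0.0) > min_maf
    keep = autosomal & pass_call & pass_maf
    removed = {
        "non_autosomal": int((~autosomal).sum()),
        "call_frequency": int((autosomal & ~pass_call).sum()),
        "maf": int((autosomal & pass_call & ~pass_maf).sum()),
    }
    if not keep.any():
        raise EmptyPanelError("no SNPs survive filtering")
    filtered = g.subset(snps=g.snp_ids[keep])
    report = QcReport(
        snp_call_frequency=call_freq,
        snp_maf=maf,
        removed=removed,
        n_retained=int(keep.sum()),
    )
    return filtered, report


def filter_samples(
    g: GenotypeMatrix, min_call_rate: float = DEFAULT_MIN_SAMPLE_CALL_RATE
) -> tuple[GenotypeMatrix, QcReport]:
    """Retain samples with call rate strictly above ``min_call_rate``."""
    if not 0.0 <= min_call_rate <= 1.0:
        raise ValueError(f"min_call_rate must lie in [0, 1], got {min_call_rate}")
    rate = g.sample_call_rate()
    keep = rate > min_call_rate
    if not keep.any():
        raise EmptyPanelError("no samples survive filtering")
    filtered = g.subset(samples=g.sample_ids[keep])
    report = QcReport(
        sample_call_rate=rate,
        removed={"call_rate": int((~keep).sum())},
        n_retained=int(keep.sum()),
    )
    return filtered, report


def hwe_test(snp_genotypes) -> float:
    """Chi-square (1 df) goodness-of-fit p-value against Hardy-Weinberg.

    Takes one SNP's {-1, 0, +1} code vector (NaN = missing).  Monomorphic
    SNPs return p = 1 by convention.  This is a flagging diagnostic only.
    """
    codes = np.asarray(snp_genotypes, dtype=float)
    codes = codes[np.isfinite(codes)]
    n = codes.size
    if n < 2:
        raise ValueError("need at least 2 non-missing genotypes")
    n_ref = int((codes == -1).sum())
    n_het = int((codes == 0).sum())
    n_alt = int((codes == 1).sum())
    p = (2 * n_alt + n_het) / (2 * n)
    if p == 0.0 or p == 1.0:
        return 1.0
    expected = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2]) * n
    observed = np.array([n_ref, n_het, n_alt], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def run_qc(
    g: GenotypeMatrix,
    min_call_freq: float = DEFAULT_MIN_CALL_FREQ,
    min_maf: float = DEFAULT_MIN_MAF,
    min_sample_call_rate: float = DEFAULT_MIN_SAMPLE_CALL_RATE,
    autosomes_only: bool = True,
) -> tuple[GenotypeMatrix, QcReport, QcReport]:
    """SNP filters then sample call-rate filter, in the documented order."""
    g_snp, snp_report = filter_snps(
        g, min_call_freq=min_call_freq, min_maf=min_maf, autosomes_only=autosomes_only
    )
    g_final, sample_report = filter_samples(g_snp, min_call_rate=min_sample_call_rate)
    return g_final, snp_report, sample_report
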