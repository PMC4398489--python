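"""Association weight matrix (AWM) construction.

The AWM condenses single-trait GWAS results into a genes x traits matrix of
standardized additive SNP effects, built around one key trait (RFI here) and
a panel of supportive traits:

1. normalize effects: per SNP-trait the signed t-value (effect / SE), then
   each trait column is z-scaled (mean 0, SD 1) across SNPs;
2. select SNPs associated with the key trait at p <= 0.05 (inclusive);
3. compute A_P, the average number of supportive traits (also at p <= 0.05)
   those SNPs associate with, kept fractional;
4. rescue SNPs that missed the key trait but associate with strictly more
   than A_P supportive traits;
5. keep only SNPs inside a gene or strictly closer than 2,500 bp to one,
   each SNP assigned to its nearest gene;
6. per gene keep the single SNP associated with the highest number of key +
   supportive traits (ties: smaller key-trait p, then lower position);
7. assemble the matrix and hierarchically cluster its trait columns
   (average linkage on 1 - Pearson correlation).

Internal coordinates are 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

DEFAULT_SIGNIFICANCE = 0.05
DEFAULT_GENE_DISTANCE_BP = 2500


@dataclass
class TraitConfig:
    """Key/supportive trait layout and AWM thresholds."""

    key_trait: str
    supportive_traits: list[str]
    significance_threshold: float = DEFAULT_SIGNIFICANCE
    gene_distance_bp: int = DEFAULT_GENE_DISTANCE_BP

    def __post_init__(self):
        if self.key_trait in self.supportive_traits:
            raise ValueError("key trait must not appear among supportive traits")
        if not 0.0 < self.significance_threshold < 1.0:
            raise ValueError("significance threshold must lie in (0, 1)")

    @property
    def traits(self) -> list[str]:
        return [self.key_trait] + list(self.supportive_traits)


@dataclass
class AwmSelectionSummary:
    n_key_selected: int = 0
    a_p: float = np.nan
    n_rescued: int = 0
    n_gene_mapped: int = 0
    n_genes_final: int = 0


@dataclass
class AwmMatrix:
    """Genes x traits matrix of standardized additive effects."""

    values: pd.DataFrame  # index: gene, columns: key + supportive traits
    gene_info: pd.DataFrame  # per gene: chosen snp, chrom, pos, n_assoc
    summary: AwmSelectionSummary = field(default_factory=AwmSelectionSummary)

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise ValueError("duplicated gene rows in AWM")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("AWM cells must all be finite")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def traits(self) -> pd.Index:
        return self.values.columns


def standardize_effects(gwas: pd.DataFrame, scale_columns: bool = True) -> pd.DataFrame:
    """Signed t-values (effect/SE) pivoted to a SNP x trait table.

    With ``scale_columns`` each trait column is additionally centred and
    scaled to unit SD across SNPs (the default normalisation); raw t-values
    are available with ``scale_columns=False``.  Rows with SE = 0 or missing
    are excluded with a warning.
    """
    df = gwas.copy()
    bad = ~np.isfinite(df["se"]) | (df["se"] == 0) | ~np.isfinite(df["effect"])
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} GWAS rows with zero/undefined SE excluded "
            "from effect standardization"
        )
        df = df[~bad]
    df = df.assign(t=df["effect"] / df["se"])
    table = df.pivot(index="snp", columns="trait", values="t")
    if scale_columns:
        sd = table.std(ddof=0)
        zero = sd[sd == 0].index.tolist()
        if zero:
            warnings.warn(f"trait columns with zero variance left unscaled: {zero}")
            sd = sd.replace(0.0, 1.0)
        table = (table - table.mean()) / sd
    return table


def pvalue_table(gwas: pd.DataFrame) -> pd.DataFrame:
    """SNP x trait p-value table (untestable rows carry p = 1)."""
    return gwas.pivot(index="snp", columns="trait", values="p")


def select_key_snps(pvals: pd.DataFrame, config: TraitConfig) -> pd.Index:
    """SNPs associated with the key trait at p <= threshold (inclusive)."""
    p = pvals[config.key_trait]
    selected = p.index[p <= config.significance_threshold]
    if len(selected) == 0:
        warnings.warn("no SNPs pass the key-trait threshold")
    return selected


def supportive_counts(pvals: pd.DataFrame, config: TraitConfig) -> pd.Series:
    """Per SNP: number of supportive traits at p <= threshold."""
    sub = pvals[list(config.supportive_traits)]
    return (sub <= config.significance_threshold).sum(axis=1)


def compute_ap(selected: pd.Index, pvals: pd.DataFrame, config: TraitConfig) -> float:
    """Average supportive-trait association count of key-selected SNPs.

    Kept fractional; the rescue rule compares strictly against this value.
    """
    if len(selected) == 0:
        raise ValueError("cannot compute A_P from an empty key selection")
    return float(supportive_counts(pvals.loc[selected], config).mean())


def rescue_snps(
    selected: pd.Index, pvals: pd.DataFrame, a_p: float, config: TraitConfig
) -> pd.Index:
    """SNPs not key-selected but with strictly more than A_P supportive hits."""
    counts = supportive_counts(pvals, config)
    candidates = counts.index.difference(selected)
    return candidates[counts.loc[candidates] > a_p]


def map_snps_to_genes(
    snps: pd.Index,
    snp_map: pd.DataFrame,
    annotation: pd.DataFrame,
    max_distance: int = DEFAULT_GENE_DISTANCE_BP,
) -> pd.DataFrame:
    """Assign each SNP to its nearest gene within the distance rule.

    A SNP qualifies for a gene when its position lies inside the gene span
    (distance 0) or strictly closer than ``max_distance`` bp to either end.
    A SNP reachable by several genes goes to the nearest one (ties: lower
    gene start).  SNPs with no qualifying gene are dropped.

    ``annotation`` columns: gene_id, chrom, start, end (1-based inclusive).

    Returns a frame (snp, gene, chrom, pos, distance).
    """
    snp_chroms = set(snp_map.loc[snps, "chrom"].astype(str))
    ann_chroms = set(annotation["chrom"].astype(str))
    orphan = snp_chroms - ann_chroms
    if orphan and not snp_chroms & ann_chroms:
        raise ValueError(
            f"chromosome names do not match between SNP map and annotation: "
            f"{sorted(orphan)}"
        )
    rows = []
    ann_by_chrom = {c: g for c, g in annotation.groupby(annotation["chrom"].astype(str))}
    for snp in snps:
        chrom = str(snp_map.at[snp, "chrom"])
        pos = int(snp_map.at[snp, "pos"])
        genes = ann_by_chrom.get(chrom)
        if genes is None:
            continue
        start = genes["start"].to_numpy()
        end = genes["end"].to_numpy()
        dist = np.maximum.reduce([start - pos, pos - end, np.zeros(len(genes))])
        ok = dist < max_distance
        if not ok.any():
            continue
        cand = genes[ok].assign(distance=dist[ok])
        cand = cand.sort_values(["distance", "start"], kind="mergesort")
        best = cand.iloc[0]
        rows.append((snp, best["gene_id"], chrom, pos, float(best["distance"])))
    return pd.DataFrame(rows, columns=["snp", "gene", "chrom", "pos", "distance"])


def dedupe_genes(
    assignments: pd.DataFrame, pvals: pd.DataFrame, config: TraitConfig
) -> pd.DataFrame:
    """One SNP per gene: the one associated with most key+supportive traits.

    Ties break by smaller key-trait p-value, then lower genomic position.
    Returns one row per gene (gene, snp, chrom, pos, n_assoc).
    """
    if assignments.empty:
        raise ValueError("no SNP-gene assignments to deduplicate")
    traits = config.traits
    counts = (pvals[traits] <= config.significance_threshold).sum(axis=1)
    df = assignments.assign(
        n_assoc=counts.loc[assignments["snp"]].to_numpy(),
        key_p=pvals.loc[assignments["snp"], config.key_trait].to_numpy(),
    )
    df = df.sort_values(
        ["gene", "n_assoc", "key_p", "pos"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    chosen = df.groupby("gene", sort=True).head(1)
    return chosen[["gene", "snp", "chrom", "pos", "n_assoc"]].reset_index(drop=True)


def build_awm(
    chosen: pd.DataFrame,
    std_effects: pd.DataFrame,
    config: TraitConfig,
    summary: AwmSelectionSummary | None = None,
) -> AwmMatrix:
    """Assemble the genes x traits matrix from the per-gene chosen SNPs."""
    if chosen.empty:
        raise ValueError("empty gene set; cannot build an AWM")
    traits = config.traits
    missing_cols = [t for t in traits if t not in std_effects.columns]
    if missing_cols:
        raise KeyError(f"standardized effects missing traits: {missing_cols}")
    block = std_effects.loc[chosen["snp"], traits]
    if block.isna().any().any():
        bad = block.index[block.isna().any(axis=1)][0]
        raise ValueError(f"missing standardized effect for SNP {bad!r}")
    values = block.set_axis(chosen["gene"], axis=0)
    values.index.name = "gene"
    info = chosen.set_index("gene")
    summary = summary or AwmSelectionSummary()
    summary.n_genes_final = len(values)
    return AwmMatrix(values=values, gene_info=info, summary=summary)


def build_awm_from_gwas(
    gwas: pd.DataFrame,
    snp_map: pd.DataFrame,
    annotation: pd.DataFrame,
    config: TraitConfig,
) -> AwmMatrix:
    """Full AWM pipeline: standardize, select, rescue, map, dedupe, build."""
    pvals = pvalue_table(gwas)
    std = standardize_effects(gwas)
    pvals = pvals.loc[std.index]
    selected = select_key_snps(pvals, config)
    a_p = compute_ap(selected, pvals, config)
    rescued = rescue_snps(selected, pvals, a_p, config)
    all_snps = selected.union(rescued, sort=False)
    assignments = map_snps_to_genes(
        all_snps, snp_map, annotation, max_distance=config.gene_distance_bp
    )
    chosen = dedupe_genes(assignments, pvals, config)
    summary = AwmSelectionSummary(
        n_key_selected=len(selected),
        a_p=a_p,
        n_rescued=len(rescued),
        n_gene_mapped=len(assignments),
    )
    return build_awm(chosen, std, config, summary=summary)


def cluster_traits(awm: AwmMatrix | pd.DataFrame):
    """Hierarchical clustering of AWM trait columns.

    Average linkage on 1 - Pearson correlation between trait columns; the
    leaf order is deterministic.  Returns (ordered trait labels, linkage
    matrix).  Constant columns have undefined correlation and are rejected.
    """
    values = awm.values if isinstance(awm, AwmMatrix) else awm
    if values.shape[1] < 2:
        raise ValueError("need at least 2 trait columns to cluster")
    sd = values.std(ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant trait columns cannot be clustered: {constant}")
    corr = np.corrcoef(values.to_numpy().T)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(hierarchy.optimal_leaf_ordering(
        Z, squareform(dist, checks=False)))
    labels = [values.columns[i] for i in order]
    return labels, Z
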