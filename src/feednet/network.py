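"""Co-association network topology and the randomized-AWM null comparison.

The co-association network is an undirected simple graph whose nodes are AWM
genes and whose edges are PCIT-significant gene-pair correlations passing the
|PC| filter.  Topology here means the degree distribution, its low/high
connectivity summaries, hub genes (degree >= 80 by default) and the edge
density relative to the n(n-1)/2 possible pairs.

The null comparison destroys the SNP-trait association structure by
independently permuting the AWM cell values within each trait column (the
marginal effect distribution per trait is preserved), re-runs the identical
PCIT -> |PC| filter -> network pipeline on each of 10 randomized matrices,
and contrasts node/edge counts and degree histograms with the observed
network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .awm import AwmMatrix
from .pcit import DEFAULT_MIN_ABS_PC, extract_edges, gene_correlations, run_pcit

DEFAULT_HUB_DEGREE = 80
DEFAULT_LOW_DEGREE = 10
DEFAULT_N_REPLICATES = 10


def build_network(edges: pd.DataFrame) -> nx.Graph:
    """Undirected simple graph from an edge frame (gene1, gene2, correlation).

    Self-loops are rejected; duplicate pairs are collapsed with a warning.
    Genes without edges are not nodes.
    """
    if (edges["gene1"] == edges["gene2"]).any():
        bad = edges.loc[edges["gene1"] == edges["gene2"], "gene1"].iloc[0]
        raise ValueError(f"self-loop on gene {bad!r} rejected")
    key = edges[["gene1", "gene2"]].apply(frozenset, axis=1) if len(edges) else None
    if key is not None and key.duplicated().any():
        warnings.warn(
            f"{int(key.duplicated().sum())} duplicate edges collapsed"
        )
        edges = edges[~key.duplicated()]
    g = nx.Graph()
    for g1, g2, w in edges[["gene1", "gene2", "correlation"]].itertuples(index=False):
        g.add_edge(g1, g2, weight=float(w))
    return g


def degree_distribution(
    net: nx.Graph,
    low_degree: int = DEFAULT_LOW_DEGREE,
    hub_degree: int = DEFAULT_HUB_DEGREE,
) -> dict:
    """Histogram degree -> gene count plus low/high connectivity summaries."""
    degrees = [d for _, d in net.degree()]
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    return {
        "histogram": dict(sorted(hist.items())),
        "n_low": sum(1 for d in degrees if d <= low_degree),
        "n_high": sum(1 for d in degrees if d >= hub_degree),
        "max_degree": max(degrees, default=0),
    }


def find_hubs(net: nx.Graph, min_degree: int = DEFAULT_HUB_DEGREE) -> pd.DataFrame:
    """Genes with degree >= min_degree, sorted by degree desc then label."""
    rows = [(g, d) for g, d in net.degree() if d >= min_degree]
    rows.sort(key=lambda t: (-t[1], str(t[0])))
    return pd.DataFrame(rows, columns=["gene", "degree"])


def count_possible_pairs(n_genes: int) -> int:
    """Number of unordered gene pairs, n(n-1)/2."""
    if n_genes < 0:
        raise ValueError("gene count must be non-negative")
    return n_genes * (n_genes - 1) // 2


def network_density(n_edges: int, n_genes: int) -> float:
    """Realized edges as a percentage of all possible pairs."""
    if n_genes < 2:
        raise ValueError("density needs at least 2 genes")
    return 100.0 * n_edges / count_possible_pairs(n_genes)


def randomize_awm(awm: AwmMatrix | pd.DataFrame, seed: int) -> pd.DataFrame:
    """Independently permute AWM values within each trait column.

    Preserves every trait's marginal effect distribution while making the
    SNP-trait associations independent of the GWAS that produced them.
    Deterministic per seed.
    """
    values = awm.values if isinstance(awm, AwmMatrix) else awm
    rng = np.random.default_rng(seed)
    out = values.copy()
    for col in out.columns:
        out[col] = rng.permutation(out[col].to_numpy())
    return out


def shuffle_awm(awm: AwmMatrix | pd.DataFrame, seed: int) -> pd.DataFrame:
    """Whole-matrix shuffle (alternative null behind a flag)."""
    values = awm.values if isinstance(awm, AwmMatrix) else awm
    rng = np.random.default_rng(seed)
    flat = rng.permutation(values.to_numpy().ravel())
    return pd.DataFrame(
        flat.reshape(values.shape), index=values.index, columns=values.columns
    )


def network_from_awm(
    values: pd.DataFrame, min_abs_pc: float = DEFAULT_MIN_ABS_PC
) -> nx.Graph:
    """AWM values -> row correlations -> PCIT -> |PC| filter -> graph."""
    corr = gene_correlations(values)
    result = run_pcit(corr)
    edges = extract_edges(result, min_abs_pc=min_abs_pc)
    return build_network(edges)


@dataclass
class NullComparisonSummary:
    observed_nodes: int
    observed_edges: int
    observed_histogram: dict
    replicate_nodes: list = field(default_factory=list)
    replicate_edges: list = field(default_factory=list)
    pooled_random_histogram: dict = field(default_factory=dict)
    n_replicates: int = DEFAULT_N_REPLICATES
    seed: int = 0

    @property
    def mean_random_nodes(self) -> float:
        return float(np.mean(self.replicate_nodes)) if self.replicate_nodes else 0.0

    @property
    def mean_random_edges(self) -> float:
        return float(np.mean(self.replicate_edges)) if self.replicate_edges else 0.0


def null_comparison(
    awm: AwmMatrix | pd.DataFrame,
    n_replicates: int = DEFAULT_N_REPLICATES,
    min_abs_pc: float = DEFAULT_MIN_ABS_PC,
    seed: int = 0,
    randomizer=randomize_awm,
) -> NullComparisonSummary:
    """Observed network versus networks from randomized AWM replicates.

    Each replicate permutes the AWM, then applies the identical
    PCIT -> |PC| -> network pipeline used for the observed matrix.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    values = awm.values if isinstance(awm, AwmMatrix) else awm
    observed = network_from_awm(values, min_abs_pc=min_abs_pc)
    obs_dist = degree_distribution(observed)
    summary = NullComparisonSummary(
        observed_nodes=observed.number_of_nodes(),
        observed_edges=observed.number_of_edges(),
        observed_histogram=obs_dist["histogram"],
        n_replicates=n_replicates,
        seed=seed,
    )
    pooled: dict[int, int] = {}
    child_seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    for child in child_seeds:
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        permuted = randomizer(values, seed=rep_seed)
        net = network_from_awm(permuted, min_abs_pc=min_abs_pc)
        summary.replicate_nodes.append(net.number_of_nodes())
        summary.replicate_edges.append(net.number_of_edges())
        for d, c in degree_distribution(net)["histogram"].items():
            pooled[d] = pooled.get(d, 0) + c
    summary.pooled_random_histogram = dict(sorted(pooled.items()))
    return summary
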