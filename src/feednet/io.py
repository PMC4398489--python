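"""Readers/writers for the external formats and the pipeline orchestrator.

Formats: VCF v4.2 or genotype TSV for genotypes (biallelic sites coded
{-1,0,+1}, alt-homozygote = +1), TSV pedigree (animal/sire/dam, 0 = unknown),
TSV phenotype tables (missing = empty field), BED (0-based half-open) or GFF3
gene annotation, TSV AWM/edge lists, GraphML networks, a YAML pipeline
configuration and a JSON run manifest.

Internal coordinates are 1-based inclusive everywhere; conversion happens
only at the I/O boundary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from . import __version__
from .genotypes import GenotypeMatrix

logger = logging.getLogger("feednet")

_CODE_BY_GT_TYPE = {0: -1.0, 1: 0.0, 2: np.nan, 3: 1.0}  # cyvcf2 gt_types


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read a VCF; biallelic sites only, multiallelic sites skipped."""
    vcf = VCF(str(path))
    samples = pd.Index(vcf.samples)
    codes_cols = []
    map_rows = []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        col = np.array(
            [_CODE_BY_GT_TYPE[t] for t in variant.gt_types], dtype=float
        )
        codes_cols.append(col)
        snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        map_rows.append(
            (snp_id, str(variant.CHROM), int(variant.POS), variant.REF,
             variant.ALT[0])
        )
    if n_multi:
        warnings.warn(f"{n_multi} multiallelic sites skipped")
    if not map_rows:
        raise FormatError(f"no biallelic variants in {path}")
    snp_map = pd.DataFrame(
        map_rows, columns=["snp_id", "chrom", "pos", "ref", "alt"]
    )
    return GenotypeMatrix(
        sample_ids=samples,
        snp_ids=pd.Index(snp_map["snp_id"]),
        codes=np.column_stack(codes_cols),
        snp_map=snp_map.set_index("snp_id", drop=False).rename_axis(None),
    )


_GT_BY_CODE = {-1.0: "0/0", 0.0: "0/1", 1.0: "1/1"}


def write_genotypes_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with GT fields only."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=feednet\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = pd.unique(g.snp_map.loc[g.snp_ids, "chrom"].astype(str))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, g.sample_ids))
            + "\n"
        )
        for j, snp in enumerate(g.snp_ids):
            row = g.snp_map.loc[snp]
            gts = [
                _GT_BY_CODE.get(c, "./.") if np.isfinite(c) else "./."
                for c in g.codes[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{snp}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_genotypes_tsv(path) -> GenotypeMatrix:
    """Genotype TSV: columns snp_id, chrom, pos, ref, alt, then one column
    per sample holding codes in {-1, 0, 1} (empty = missing)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    fixed = ["snp_id", "chrom", "pos", "ref", "alt"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise FormatError(f"genotype TSV missing columns {missing}")
    sample_cols = [c for c in df.columns if c not in fixed]
    codes = df[sample_cols].to_numpy(dtype=float).T
    snp_map = df[fixed].copy()
    return GenotypeMatrix(
        sample_ids=pd.Index(sample_cols),
        snp_ids=pd.Index(df["snp_id"]),
        codes=codes,
        snp_map=snp_map.set_index("snp_id", drop=False).rename_axis(None),
    )


def write_genotypes_tsv(g: GenotypeMatrix, path) -> None:
    df = g.snp_map.loc[g.snp_ids, ["snp_id", "chrom", "pos", "ref", "alt"]].copy()
    codes = pd.DataFrame(
        g.codes.T, index=df.index, columns=list(map(str, g.sample_ids))
    )
    out = pd.concat([df, codes], axis=1)
    out.to_csv(path, sep="\t", index=False, float_format="%g")


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if format == "vcf":
        return read_genotypes_vcf(path)
    if format == "tsv":
        return read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# pedigree / phenotypes


def read_pedigree_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("0")
    needed = {"animal", "sire", "dam"}
    if not needed <= set(df.columns):
        raise FormatError(f"pedigree TSV must have columns {sorted(needed)}")
    return df


def write_pedigree_tsv(pedigree, path) -> None:
    df = pedigree.df if hasattr(pedigree, "df") else pedigree
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="animal")
    df.index = df.index.astype(str)
    return df


def write_phenotypes_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=True, index_label="animal")


# ---------------------------------------------------------------------------
# gene annotation


def read_gene_annotation(path, format: str | None = None) -> pd.DataFrame:
    """Gene annotation as a frame (gene_id, chrom, start, end), 1-based
    inclusive internally.  BED input (0-based half-open) is converted."""
    path = Path(path)
    if format is None:
        format = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "bed"
    if format == "bed":
        return _read_bed(path)
    if format == "gff3":
        return _read_gff3(path)
    raise ValueError(f"unknown annotation format {format!r}")


def _read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: BED line with <3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end < start:
                raise FormatError(f"{path}:{ln}: end < start")
            name = parts[3] if len(parts) > 3 else f"feature{ln}"
            rows.append((name, chrom, start + 1, end))  # to 1-based inclusive
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def _read_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{ln}: GFF3 line with {len(parts)} fields")
            if parts[2] != "gene":
                continue
            start, end = int(parts[3]), int(parts[4])
            if end < start:
                raise FormatError(f"{path}:{ln}: end < start")
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("Name") or f"gene{ln}"
            rows.append((gene_id, parts[0], start, end))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def write_gene_annotation_bed(annotation: pd.DataFrame, path) -> None:
    """Internal 1-based inclusive intervals -> BED 0-based half-open."""
    with open(path, "w") as fh:
        for row in annotation.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.gene_id}\n")


# ---------------------------------------------------------------------------
# results


def write_gwas_tsv(gwas: pd.DataFrame, path) -> None:
    gwas.to_csv(path, sep="\t", index=False)


def read_gwas_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_awm_tsv(awm, path) -> None:
    """Tab-delimited matrix, gene rows x trait columns (PermutMatrix layout)."""
    values = awm.values if hasattr(awm, "gene_info") else awm
    values.to_csv(path, sep="\t", index_label="gene")


def read_awm_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_edges_tsv(edges: pd.DataFrame, path) -> None:
    """Cytoscape-loadable 3-column edge list (gene1, gene2, pc)."""
    edges.rename(columns={"correlation": "pc"}).to_csv(path, sep="\t", index=False)


def read_edges_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").rename(columns={"pc": "correlation"})


def write_graphml(net, path) -> None:
    import networkx as nx

    nx.write_graphml(net, str(path))


# ---------------------------------------------------------------------------
# pipeline configuration and orchestration


@dataclass
class PipelineConfig:
    genotypes: str
    phenotypes: str
    pedigree: str
    annotation: str
    out_dir: str
    key_trait: str = "RFI"
    supportive_traits: list = field(default_factory=list)
    min_call_freq: float = 0.85
    min_maf: float = 0.01
    min_sample_call_rate: float = 0.98
    significance_threshold: float = 0.05
    gene_distance_bp: int = 2500
    min_abs_pc: float = 0.80
    n_null_replicates: int = 10
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for attr in ("genotypes", "phenotypes", "pedigree", "annotation"):
            p = Path(getattr(self, attr))
            if not p.exists():
                raise FileNotFoundError(f"{attr} input not found: {p}")
        if not 0 < self.significance_threshold < 1:
            raise ValueError("significance_threshold must lie in (0,1)")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute qc -> phenotypes -> gwas -> awm -> pcit -> network -> nullcheck.

    Writes every stage artifact plus a JSON manifest (input hashes,
    parameters, seed, version).  Identical configuration yields identical
    artifacts.  Returns the manifest dict.
    """
    from . import awm as awm_mod
    from . import network as net_mod
    from . import pcit as pcit_mod
    from . import qc as qc_mod
    from .gwas import Pedigree, default_trait_fixed_effects, run_gwas
    from .phenotypes import derive_phenotypes
    from .traits import ANALYSIS_TRAITS, SUPPORTIVE_TRAITS

    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "inputs": {
            k: _sha256(getattr(config, k))
            for k in ("genotypes", "phenotypes", "pedigree", "annotation")
        },
        "stages": {},
    }

    def stage(name):
        t0 = time.time()
        logger.info("stage %s started", name)
        return t0

    def done(name, t0, **counts):
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3), **counts}
        logger.info("stage %s done (%s)", name, counts)

    # QC
    t0 = stage("qc")
    g = read_genotypes(config.genotypes)
    g, snp_report, sample_report = qc_mod.run_qc(
        g,
        min_call_freq=config.min_call_freq,
        min_maf=config.min_maf,
        min_sample_call_rate=config.min_sample_call_rate,
    )
    write_genotypes_vcf(g, out / "genotypes.qc.vcf")
    pd.DataFrame(
        [
            {"rule": k, "removed": v}
            for k, v in {**snp_report.removed, **sample_report.removed}.items()
        ]
    ).to_csv(out / "qc_report.tsv", sep="\t", index=False)
    done("qc", t0, snps=g.n_snps, samples=g.n_samples)

    # phenotypes
    t0 = stage("phenotypes")
    raw = read_phenotypes_tsv(config.phenotypes)
    pheno, rfi_fit = derive_phenotypes(raw)
    write_phenotypes_tsv(pheno, out / "phenotypes.derived.tsv")
    done("phenotypes", t0, animals=len(pheno), rfi_excluded=len(rfi_fit.excluded))

    # GWAS
    t0 = stage("gwas")
    ped = Pedigree(read_pedigree_tsv(config.pedigree))
    relationship = ped.relationship_matrix()
    traits = [t for t in ANALYSIS_TRAITS if t in pheno.columns]
    trait_config = default_trait_fixed_effects(traits)
    gwas = run_gwas(pheno, g, trait_config, relationship, traits=traits)
    write_gwas_tsv(gwas, out / "gwas.tsv")
    done("gwas", t0, tests=len(gwas))

    # AWM
    t0 = stage("awm")
    annotation = read_gene_annotation(config.annotation)
    supportive = config.supportive_traits or [
        t for t in SUPPORTIVE_TRAITS if t in traits
    ]
    tconf = awm_mod.TraitConfig(
        key_trait=config.key_trait,
        supportive_traits=supportive,
        significance_threshold=config.significance_threshold,
        gene_distance_bp=config.gene_distance_bp,
    )
    awm = awm_mod.build_awm_from_gwas(gwas, g.snp_map, annotation, tconf)
    write_awm_tsv(awm, out / "awm.tsv")
    pd.DataFrame([dataclasses.asdict(awm.summary)]).to_csv(
        out / "awm_summary.tsv", sep="\t", index=False
    )
    done("awm", t0, genes=len(awm.genes), a_p=round(awm.summary.a_p, 3))

    # PCIT
    t0 = stage("pcit")
    corr = pcit_mod.gene_correlations(awm.values)
    result = pcit_mod.run_pcit(corr)
    edges = pcit_mod.extract_edges(result, min_abs_pc=config.min_abs_pc)
    write_edges_tsv(edges, out / "edges.tsv")
    done("pcit", t0, significant=result.n_significant, edges=len(edges))

    # network
    t0 = stage("network")
    net = net_mod.build_network(edges)
    write_graphml(net, out / "network.graphml")
    dist = net_mod.degree_distribution(net)
    hubs = net_mod.find_hubs(net)
    hubs.to_csv(out / "hubs.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(dist["histogram"].items()), columns=["degree", "n_genes"]
    ).to_csv(out / "degree_distribution.tsv", sep="\t", index=False)
    done(
        "network", t0, nodes=net.number_of_nodes(), edges=net.number_of_edges(),
        hubs=len(hubs),
    )

    # null comparison
    t0 = stage("nullcheck")
    summary = net_mod.null_comparison(
        awm,
        n_replicates=config.n_null_replicates,
        min_abs_pc=config.min_abs_pc,
        seed=config.seed,
    )
    null_json = {
        "observed_nodes": summary.observed_nodes,
        "observed_edges": summary.observed_edges,
        "replicate_nodes": summary.replicate_nodes,
        "replicate_edges": summary.replicate_edges,
        "mean_random_nodes": summary.mean_random_nodes,
        "mean_random_edges": summary.mean_random_edges,
    }
    (out / "null_comparison.json").write_text(json.dumps(null_json, indent=2))
    pd.DataFrame(
        sorted(summary.pooled_random_histogram.items()),
        columns=["degree", "n_genes"],
    ).to_csv(out / "null_degree_distribution.tsv", sep="\t", index=False)
    done("nullcheck", t0, replicates=config.n_null_replicates)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
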