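# feednet

Feed-efficiency genetics in cattle, end to end: residual-feed-intake
phenotypes, pedigree mixed-model GWAS, association weight matrices (AWM),
PCIT co-association networks, and randomized-network null controls — with a
synthetic-data generator that emulates an F2 resource population so the whole
pipeline runs and is tested entirely offline.

The package is aimed at quantitative geneticists and systems biologists who
want to combine single-trait GWAS across a key trait and a panel of
supportive traits (here: metabolite concentrations) into a gene network, and
at anyone who needs a tested, scriptable re-implementation of the AWM/PCIT
workflow.

## The models

**Residual feed intake (RFI).** Daily energy intake is regressed on growth
and maintenance by ordinary least squares,

```
dEI_i = β₀ + β₁·ADG_i + β₂·MMWT_i + e_i ,
```

where dEI is daily metabolizable energy intake (MJ ME/day), ADG the average
daily gain (kg/day), MMWT the metabolic mid-weight ((mid-test body weight in
kg)^0.75), and the residual e_i is the RFI of animal *i*: negative RFI marks
an efficient animal. FCR (MJ ME per kg gain) and an efficient/inefficient
classification complete the phenotype set.

**Single-SNP mixed model.** Each SNP k is tested per trait with the animal
model

```
y_i = X_i φ + Z_k g + u_i + e_i ,   u ~ N(0, A σ²_u),  e ~ N(0, I σ²_e),
```

with Z ∈ {−1, 0, +1} additive coding, trait-specific fixed effects φ (birth
year and season for RFI/FCR, birth year for dEI/ADG, sampling year and
measurement day for metabolites), and a polygenic effect u whose covariance
is the pedigree numerator relationship matrix **A**. Significance is a
1-df likelihood-ratio test (ML); computation uses the standard
eigendecomposition of **A** so that thousands of SNP tests reduce to
weighted least squares in a rotated basis. Targeted 2-SNP and
2-SNP-interaction models are available for candidate-locus pairs.

**AWM.** SNP effects are normalized (signed t-values, then per-trait
z-scaling), SNPs associated with the key trait at p ≤ 0.05 are selected,
the mean supportive-trait association count A_P of those SNPs is computed,
SNPs exceeding A_P supportive associations are rescued, SNPs within (or
strictly closer than 2,500 bp to) a gene are mapped to their nearest gene,
and one SNP per gene is kept — the one associated with the most traits. The
result is a genes × traits matrix of standardized additive effects.

**PCIT.** For every gene trio (x, y, z) the three first-order partial
correlations are compared with the direct correlations through the trio
tolerance ε = mean(r·.·/r··); an edge is discarded when some third gene
explains it (|r_xy| ≤ |ε·r_xz| and |r_xy| ≤ |ε·r_yz|). Significant edges
with |PC| ≥ 0.80 form the co-association network, whose topology (degree
distribution, hubs, density) is compared against networks rebuilt from ten
AWMs with independently permuted columns.

## Worked example

```python
from feednet import SimulationConfig, simulate_study
from feednet.phenotypes import derive_phenotypes
from feednet.gwas import default_trait_fixed_effects, run_gwas
from feednet.awm import TraitConfig, build_awm_from_gwas
from feednet.pcit import gene_correlations, run_pcit, extract_edges
from feednet.network import build_network, null_comparison
from feednet.traits import ANALYSIS_TRAITS, SUPPORTIVE_TRAITS

study = simulate_study(SimulationConfig(seed=1, n_f2=200, n_snps=1500, n_genes=750))
pheno, rfi_fit = derive_phenotypes(study.phenotypes)
gwas = run_gwas(pheno, study.f2_genotypes(),
                default_trait_fixed_effects(ANALYSIS_TRAITS),
                study.relationship, traits=ANALYSIS_TRAITS)
awm = build_awm_from_gwas(gwas, study.genotypes.snp_map, study.annotation,
                          TraitConfig("RFI", SUPPORTIVE_TRAITS))
edges = extract_edges(run_pcit(gene_correlations(awm.values)), min_abs_pc=0.80)
net = build_network(edges)
```

This prints (via the corresponding summaries):

```
RFI model: dEI = 12.93 + 23.29*ADG + 0.42*MMWT + e   (R^2 = 0.435)
efficient animals: 99 of 200
top RFI SNP: SNP00002  effect -3.44 (SE 0.72), p = 2.30e-06
AWM: 70 key SNPs, A_P = 1.46, 224 rescued, 153 genes x 14 traits
PCIT: 2311 significant pairs; network: 108 genes, 182 edges (density 3.1%)
randomized AWMs: mean 13 genes / 7 edges across 10 replicates
```

Reading this: the RFI regression explains 43.5% of intake variance and splits
the cohort into 99 efficient / 101 inefficient animals; the top RFI SNP is
one of the two embedded major loci, recovered with the simulated effect
direction; 70 SNPs enter the AWM through the key trait and 224 more through
the A_P rescue rule (each supported by more than 1.46 supportive traits);
PCIT plus the |PC| ≥ 0.80 filter leaves a 108-gene network that dwarfs its
permuted controls (13 genes / 7 edges on average) — the signature of real
cross-trait structure.

The same stages are exposed as a CLI:

```
feednet simulate --config sim.yaml --out-dir data/
feednet run --config pipeline.yaml        # qc → phenotypes → gwas → awm → pcit → network → nullcheck
```

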