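"""AWM construction: effect standardization, key-trait selection, the A_P
rescue rule, SNP-to-gene mapping, per-gene deduplication, the end-to-end
hand-enumerable toy fixture, and trait-column clustering."""

import numpy as np
import pandas as pd
import pytest

from feednet.awm import (
    AwmMatrix,
    TraitConfig,
    build_awm,
    build_awm_from_gwas,
    cluster_traits,
    compute_ap,
    dedupe_genes,
    map_snps_to_genes,
    pvalue_table,
    rescue_snps,
    select_key_snps,
    standardize_effects,
    supportive_counts,
)


def gwas_frame(records):
    """records: (snp, trait, effect, se, p)."""
    return pd.DataFrame(
        records, columns=["snp", "trait", "effect", "se", "p"]
    ).assign(lrt=1.0, testable=True, flag="")


class TestStandardize:
    def test_t_values_before_scaling(self):
        gwas = gwas_frame([("s1", "T", 2.0, 1.0, 0.05), ("s2", "T", 1.0, 0.5, 0.05)])
        t = standardize_effects(gwas, scale_columns=False)
        assert t.loc["s1", "T"] == pytest.approx(2.0)
        assert t.loc["s2", "T"] == pytest.approx(2.0)

    def test_column_scaling(self):
        gwas = gwas_frame(
            [(f"s{i}", "T", float(i), 1.0, 0.5) for i in range(10)]
        )
        z = standardize_effects(gwas)
        assert z["T"].mean() == pytest.approx(0.0, abs=1e-12)
        assert z["T"].std(ddof=0) == pytest.approx(1.0)

    def test_sign_preserved_under_negation(self):
        recs = [(f"s{i}", "T", v, 1.0, 0.5) for i, v in enumerate([1.0, -2.0, 0.5])]
        z1 = standardize_effects(gwas_frame(recs))
        z2 = standardize_effects(
            gwas_frame([(s, t, -e, se, p) for s, t, e, se, p in recs])
        )
        assert np.allclose(z1["T"], -z2["T"])

    def test_zero_se_excluded_with_warning(self):
        gwas = gwas_frame(
            [("s1", "T", 1.0, 0.0, 0.5), ("s2", "T", 1.0, 1.0, 0.5),
             ("s3", "T", 2.0, 1.0, 0.5)]
        )
        with pytest.warns(UserWarning, match="zero/undefined SE"):
            z = standardize_effects(gwas)
        assert "s1" not in z.index


class TestSelectionRules:
    config = TraitConfig("RFI", ["T1", "T2", "T3", "T4"])

    def pvals(self, rows):
        return pd.DataFrame(rows, columns=["RFI", "T1", "T2", "T3", "T4"])

    def test_inclusive_threshold(self):
        pvals = self.pvals(
            {"a": [0.05, 1, 1, 1, 1], "b": [0.051, 1, 1, 1, 1]}.values()
        ).set_axis(["a", "b"])
        selected = select_key_snps(pvals, self.config)
        assert list(selected) == ["a"]

    def test_toy_selection_count(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.06, 1.0, (10, 5))
        p[:4, 0] = [0.01, 0.02, 0.05, 0.04]
        pvals = self.pvals(p).set_axis([f"s{i}" for i in range(10)])
        assert len(select_key_snps(pvals, self.config)) == 4

    def test_ap_fractional_mean(self):
        pvals = self.pvals(
            [
                [0.01, 0.01, 0.01, 0.2, 0.2],  # 2 supportive
                [0.02, 0.01, 0.01, 0.01, 0.2],  # 3
                [0.03, 0.01, 0.01, 0.01, 0.01],  # 4
            ]
        ).set_axis(["a", "b", "c"])
        assert compute_ap(pd.Index(["a", "b", "c"]), pvals, self.config) == 3.0
        pvals2 = self.pvals(
            [[0.01, 0.01, 0.2, 0.2, 0.2], [0.02, 0.01, 0.01, 0.2, 0.2]]
        ).set_axis(["a", "b"])
        assert compute_ap(pd.Index(["a", "b"]), pvals2, self.config) == 1.5

    def test_ap_empty_selection_rejected(self):
        pvals = self.pvals([[0.5, 1, 1, 1, 1]]).set_axis(["a"])
        with pytest.raises(ValueError):
            compute_ap(pd.Index([]), pvals, self.config)

    def test_rescue_strictly_greater(self):
        pvals = self.pvals(
            [
                [0.01, 0.01, 0.01, 0.01, 0.2],  # selected, 3 supportive
                [0.2, 0.01, 0.01, 0.01, 0.01],  # 4 > 3 -> rescued
                [0.2, 0.01, 0.01, 0.01, 0.2],  # 3, not > 3
            ]
        ).set_axis(["a", "b", "c"])
        selected = select_key_snps(pvals, self.config)
        a_p = compute_ap(selected, pvals, self.config)
        assert a_p == 3.0
        rescued = rescue_snps(selected, pvals, a_p, self.config)
        assert list(rescued) == ["b"]

    def test_selected_snp_never_rescued(self):
        pvals = self.pvals(
            [[0.01, 0.01, 0.01, 0.01, 0.01], [0.2, 1, 1, 1, 1]]
        ).set_axis(["a", "b"])
        selected = select_key_snps(pvals, self.config)
        rescued = rescue_snps(selected, pvals, 0.0, self.config)
        assert "a" not in rescued

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        pvals = self.pvals(rng.uniform(size=(50, 5))).set_axis(
            [f"s{i}" for i in range(50)]
        )
        loose = select_key_snps(pvals, TraitConfig("RFI", ["T1", "T2", "T3", "T4"]))
        tight = select_key_snps(
            pvals,
            TraitConfig("RFI", ["T1", "T2", "T3", "T4"],
                        significance_threshold=0.01),
        )
        assert set(tight) <= set(loose)


def snp_map_frame(positions, chrom="1"):
    ids = list(positions)
    return pd.DataFrame(
        {
            "snp_id": ids,
            "chrom": chrom,
            "pos": [positions[s] for s in ids],
            "ref": "A",
            "alt": "B",
        }
    ).set_index("snp_id", drop=False).rename_axis(None)


class TestGeneMapping:
    annotation = pd.DataFrame(
        {
            "gene_id": ["G1", "G2"],
            "chrom": ["1", "1"],
            "start": [12400, 50000],
            "end": [20000, 60000],
        }
    )

    def test_distance_rule_strict(self):
        smap = snp_map_frame({"near": 10000, "far": 9900, "inside": 15000})
        # near: 12400-10000 = 2400 < 2500 assigned; far: 2500 exactly -> out
        out = map_snps_to_genes(pd.Index(["near", "far", "inside"]), smap,
                                self.annotation)
        assert set(out["snp"]) == {"near", "inside"}
        assert out.set_index("snp").loc["inside", "distance"] == 0.0
        assert out.set_index("snp").loc["near", "distance"] == 2400.0

    def test_nearest_gene_wins(self):
        ann = pd.DataFrame(
            {
                "gene_id": ["A", "B"],
                "chrom": ["1", "1"],
                "start": [1000, 3000],
                "end": [1500, 3500],
            }
        )
        smap = snp_map_frame({"s": 2400})  # 900 from A end, 600 from B start
        out = map_snps_to_genes(pd.Index(["s"]), smap, ann)
        assert out.iloc[0]["gene"] == "B"

    def test_chromosome_mismatch_detected(self):
        smap = snp_map_frame({"s": 100}, chrom="99")
        with pytest.raises(ValueError, match="99"):
            map_snps_to_genes(pd.Index(["s"]), smap, self.annotation)


class TestDedup:
    config = TraitConfig("RFI", ["T1", "T2", "T3", "T4"])

    def test_highest_count_kept_and_tiebreaks(self):
        pvals = pd.DataFrame(
            {
                "RFI": [0.01, 0.03, 0.01, 0.03],
                "T1": [0.01, 0.2, 0.01, 0.01],
                "T2": [0.01, 0.2, 0.01, 0.01],
                "T3": [0.01, 0.01, 0.01, 0.01],
                "T4": [0.01, 0.01, 0.2, 0.2],
            },
            index=["s1", "s2", "s3", "s4"],
        )
        # gene X: s1 (5 traits) vs s2 (3) -> s1; gene Y: s3 vs s4 tie at 4,
        # key p 0.01 < 0.03 -> s3
        assignments = pd.DataFrame(
            {
                "snp": ["s1", "s2", "s3", "s4"],
                "gene": ["X", "X", "Y", "Y"],
                "chrom": "1",
                "pos": [100, 200, 300, 400],
                "distance": 0.0,
            }
        )
        chosen = dedupe_genes(assignments, pvals, self.config)
        assert dict(zip(chosen["gene"], chosen["snp"])) == {"X": "s1", "Y": "s3"}
        assert chosen.set_index("gene").loc["X", "n_assoc"] == 5


class TestToyOracle:
    """20-SNP fixture small enough to walk by hand; the AWM that the full
    pipeline assembles is checked cell-for-cell against an independently
    computed expectation."""

    def build(self):
        traits = ["RFI", "T1", "T2"]
        config = TraitConfig("RFI", ["T1", "T2"])
        rng = np.random.default_rng(99)
        snps = [f"s{i:02d}" for i in range(1, 21)]
        p = pd.DataFrame(1.0, index=snps, columns=traits)
        # key-selected: s01..s04
        p.loc["s01", "RFI"] = 0.01
        p.loc["s02", "RFI"] = 0.02
        p.loc["s03", "RFI"] = 0.05
        p.loc["s04", "RFI"] = 0.04
        # supportive hits: s01 both, s02 one, s03 none, s04 one -> A_P = 1.0
        p.loc["s01", ["T1", "T2"]] = 0.01
        p.loc["s02", "T1"] = 0.03
        p.loc["s04", "T2"] = 0.02
        # s05 misses the key trait but hits both supportive -> rescued (2 > 1)
        p.loc["s05", ["T1", "T2"]] = 0.04
        # s06 hits exactly one supportive -> not rescued
        p.loc["s06", "T1"] = 0.01
        effects = pd.DataFrame(
            rng.normal(0, 2, (20, 3)), index=snps, columns=traits
        )
        ses = pd.DataFrame(
            rng.uniform(0.5, 1.5, (20, 3)), index=snps, columns=traits
        )
        records = [
            (s, t, effects.loc[s, t], ses.loc[s, t], p.loc[s, t])
            for s in snps
            for t in traits
        ]
        gwas = gwas_frame(records)
        positions = {s: 100_000 + 10_000 * i for i, s in enumerate(snps)}
        # place the surviving SNPs against genes:
        positions["s01"] = 5_000  # inside G1
        positions["s02"] = 12_400  # 2,400 bp from G1 -> G1, loses dedup to s01
        positions["s03"] = 32_499  # 2,501 bp from G2 start -> dropped
        positions["s04"] = 51_000  # inside G3
        positions["s05"] = 72_000  # inside G4
        annotation = pd.DataFrame(
            {
                "gene_id": ["G1", "G2", "G3", "G4"],
                "chrom": "1",
                "start": [1_000, 35_000, 50_000, 70_000],
                "end": [10_000, 40_000, 60_000, 80_000],
            }
        )
        return gwas, snp_map_frame(positions), annotation, config, effects, ses

    def test_selection_summary(self):
        gwas, smap, annotation, config, _, _ = self.build()
        awm = build_awm_from_gwas(gwas, smap, annotation, config)
        assert awm.summary.n_key_selected == 4
        assert awm.summary.a_p == 1.0
        assert awm.summary.n_rescued == 1
        assert awm.summary.n_genes_final == 3

    def test_cells_match_hand_computation(self):
        gwas, smap, annotation, config, effects, ses = self.build()
        awm = build_awm_from_gwas(gwas, smap, annotation, config)
        assert list(awm.genes) == ["G1", "G3", "G4"]
        assert list(awm.gene_info["snp"]) == ["s01", "s04", "s05"]
        # independent expectation: z-scored t-values over all 20 SNPs
        t = (effects / ses).to_numpy()
        z = (t - t.mean(axis=0)) / t.std(axis=0)
        zf = pd.DataFrame(z, index=effects.index, columns=effects.columns)
        expected = zf.loc[["s01", "s04", "s05"]].to_numpy()
        assert np.allclose(awm.values.to_numpy(), expected, atol=1e-12)

    def test_rescue_consistency_invariant(self):
        gwas, smap, annotation, config, _, _ = self.build()
        awm = build_awm_from_gwas(gwas, smap, annotation, config)
        pvals = pvalue_table(gwas)
        for snp in awm.gene_info["snp"]:
            key_ok = pvals.loc[snp, "RFI"] <= 0.05
            support_ok = supportive_counts(pvals, config).loc[snp] > awm.summary.a_p
            assert key_ok or support_ok


class TestBuildErrors:
    def test_empty_gene_set_rejected(self):
        config = TraitConfig("RFI", ["T1"])
        std = pd.DataFrame({"RFI": [1.0], "T1": [1.0]}, index=["s"])
        with pytest.raises(ValueError, match="empty"):
            build_awm(pd.DataFrame(columns=["gene", "snp"]), std, config)

    def test_duplicate_gene_rows_rejected(self):
        values = pd.DataFrame(
            np.ones((2, 3)), index=["G", "G"], columns=["RFI", "T1", "T2"]
        )
        with pytest.raises(ValueError, match="duplicated"):
            AwmMatrix(values=values, gene_info=pd.DataFrame())

    def test_key_trait_in_supportive_rejected(self):
        with pytest.raises(ValueError):
            TraitConfig("RFI", ["RFI", "T1"])


class TestClustering:
    def test_identical_columns_merge_first(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=30)
        values = pd.DataFrame(
            {"A": base, "B": base, "C": rng.normal(size=30)}
        )
        labels, Z = cluster_traits(values)
        # first merge is at distance ~0 joining the two identical columns
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-10)
        pos = {l: i for i, l in enumerate(labels)}
        assert abs(pos["A"] - pos["B"]) == 1

    def test_block_structure_recovered(self):
        rng = np.random.default_rng(2)
        n = 200
        f1, f2 = rng.normal(size=n), rng.normal(size=n)
        values = pd.DataFrame(
            {
                "a1": f1 + 0.1 * rng.normal(size=n),
                "a2": f1 + 0.1 * rng.normal(size=n),
                "b1": f2 + 0.1 * rng.normal(size=n),
                "b2": f2 + 0.1 * rng.normal(size=n),
            }
        )
        labels, _ = cluster_traits(values)
        pos = {l: i for i, l in enumerate(labels)}
        assert abs(pos["a1"] - pos["a2"]) == 1
        assert abs(pos["b1"] - pos["b2"]) == 1

    def test_constant_column_rejected(self):
        values = pd.DataFrame({"A": [1.0, 1.0, 1.0], "B": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            cluster_traits(values)

    def test_metabolite_blocks_separate_on_synthetic_gwas(self, study_gwas,
                                                          small_study):
        """Trait columns of the AWM built from the synthetic study cluster
        the phosphocholine/sphingomyelin block apart from the feed traits."""
        from feednet.traits import SUPPORTIVE_TRAITS

        config = TraitConfig("RFI", SUPPORTIVE_TRAITS)
        awm = build_awm_from_gwas(
            study_gwas, small_study.genotypes.snp_map, small_study.annotation,
            config,
        )
        labels, _ = cluster_traits(awm)
        pos = {l: i for i, l in enumerate(labels)}
        pc_block = ["PC_aa_C32:0", "PC_ae_C36:1", "SM_C20:2"]
        block_pos = sorted(pos[t] for t in pc_block)
        # contiguous block, and RFI/FCR/dEI outside it
        assert block_pos[-1] - block_pos[0] == 2
        for t in ("RFI", "FCR", "dEI"):
            assert not block_pos[0] <= pos[t] <= block_pos[-1]
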