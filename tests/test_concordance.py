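import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster import hierarchy

from protscape import (
    GeneratorConfig,
    PairedOmics,
    across_sample_rna_protein,
    cv_by_group,
    generate_multistudy,
    generate_paired_rna,
    hierarchical_cluster,
    lineage_anova,
    pairwise_correlation,
    within_between_summary,
    within_sample_rna_protein,
)

from .conftest import make_annotation
from .oracles import bh_adjust_oracle, pairwise_complete_corr_oracle


def frame(arr, prefix="a"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


class TestPairwiseCorrelation:
    def test_perfect_linear_relationships(self):
        x = np.arange(20.0)
        df = frame(np.column_stack([x, 2 * x + 1, -x]))
        out = pairwise_correlation(df, method="pearson", min_overlap=5)
        assert out.iloc[0, 1] == pytest.approx(1.0)
        assert out.iloc[0, 2] == pytest.approx(-1.0)
        assert (np.diag(out) == 1.0).all()

    @pytest.mark.parametrize("method", ["pearson", "spearman"])
    def test_matches_brute_force_oracle(self, method):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 5))
        X[rng.random(X.shape) < 0.2] = np.nan
        out = pairwise_correlation(frame(X), method=method, min_overlap=3)
        oracle = pairwise_complete_corr_oracle(X, method)
        np.testing.assert_allclose(out.to_numpy(), oracle, atol=1e-12)

    def test_min_overlap_and_constant_vectors_undefined(self):
        X = np.column_stack([np.arange(6.0), np.ones(6)])
        out = pairwise_correlation(frame(X), min_overlap=3)
        assert np.isnan(out.iloc[0, 1])  # constant vector
        X2 = np.full((6, 2), np.nan)
        X2[:2, :] = [[1.0, 2.0], [3.0, 1.0]]
        out2 = pairwise_correlation(frame(X2), min_overlap=3)
        assert np.isnan(out2.iloc[0, 1])  # overlap 2 < 3


class TestHierarchicalCluster:
    def test_identical_assays_merge_at_zero(self):
        corr = pd.DataFrame(
            [[1.0, 1.0, 0.1], [1.0, 1.0, 0.1], [0.1, 0.1, 1.0]],
            index=list("abc"), columns=list("abc"),
        )
        Z, order = hierarchical_cluster(corr)
        assert Z[0, 2] == 0.0 and set(Z[0, :2]) == {0.0, 1.0}

    def test_block_structure_recovered(self):
        block = np.full((4, 4), 0.2)
        block[:2, :2] = 0.9
        block[2:, 2:] = 0.9
        np.fill_diagonal(block, 1.0)
        corr = pd.DataFrame(block, index=list("abcd"), columns=list("abcd"))
        Z, _ = hierarchical_cluster(corr)
        labels = hierarchy.fcluster(Z, t=2, criterion="maxclust")
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_single_assay_trivial(self):
        corr = pd.DataFrame([[1.0]], index=["a"], columns=["a"])
        Z, order = hierarchical_cluster(corr)
        assert order == ["a"] and Z.shape == (0, 4)

    def test_undefined_entries_rejected(self):
        corr = pd.DataFrame([[1.0, np.nan], [np.nan, 1.0]])
        with pytest.raises(ValueError, match="undefined"):
            hierarchical_cluster(corr)


class TestWithinBetweenSummary:
    def test_pair_counting(self):
        ann = make_annotation(
            [
                ("c1", "s1", "c1", "cell_line", "breast", "trypsin"),
                ("c2", "s1", "c2", "cell_line", "breast", "trypsin"),
                ("t1", "s2", "t1", "tumour", "breast", "trypsin"),
                ("t2", "s2", "t2", "tumour", "breast", "trypsin"),
            ]
        )
        corr = pd.DataFrame(
            np.ones((4, 4)), index=["c1", "c2", "t1", "t2"],
            columns=["c1", "c2", "t1", "t2"],
        )
        out = within_between_summary(corr, ann)
        assert len(out["within_cell_line"]) == 1
        assert len(out["within_tumour"]) == 1
        assert len(out["between"]) == 4
        assert all(s.median() == 1.0 for s in out.values() if len(s))


class TestCvByGroup:
    @pytest.fixture
    def annotation(self):
        return make_annotation(
            [
                (f"a{i}", "s1", f"smp{i}", "cell_line", "breast", "trypsin")
                for i in range(3)
            ]
        )

    def test_forced_arithmetic(self, annotation):
        vals = frame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        out = cv_by_group(vals, annotation, group_by="lineage", linear_scale=True)
        row = out.set_index("protein_id")
        assert row.loc["g0", "cv_percent"] == pytest.approx(50.0)
        assert row.loc["g1", "cv_percent"] == 0.0

    def test_lognormal_matches_analytic_cv(self, annotation_large=None):
        rng = np.random.default_rng(6)
        sigma_log2 = 0.5
        n = 200
        ann = make_annotation(
            [
                (f"a{i}", "s1", f"smp{i}", "cell_line", "breast", "trypsin")
                for i in range(n)
            ]
        )
        log2_vals = rng.normal(10.0, sigma_log2, size=(300, n))
        from protscape import IntensityMatrix

        m = IntensityMatrix(values=frame(log2_vals, prefix="a"), stage="batch_corrected")
        out = cv_by_group(m, ann, group_by="lineage")
        sigma_ln = sigma_log2 * np.log(2.0)
        analytic = 100.0 * np.sqrt(np.exp(sigma_ln**2) - 1.0)
        assert out["cv_percent"].median() == pytest.approx(analytic, rel=0.10)

    def test_small_groups_excluded(self):
        ann = make_annotation(
            [("a0", "s1", "smp0", "cell_line", "breast", "trypsin"),
             ("a1", "s1", "smp1", "cell_line", "colorectal", "trypsin")]
        )
        out = cv_by_group(frame([[1.0, 2.0]]), ann, group_by="lineage", linear_scale=True)
        assert out.empty


class TestRnaProteinCorrelation:
    def test_monotone_and_reversed_extremes(self):
        prot = frame(np.arange(40.0).reshape(10, 4))
        rna_up = np.exp2(prot / 7.0)
        paired = PairedOmics(protein=prot, rna=rna_up)
        w = within_sample_rna_protein(paired, min_overlap=5)
        assert np.allclose(w["rs"], 1.0)
        rna_down = np.exp2(-prot)
        w2 = within_sample_rna_protein(PairedOmics(protein=prot, rna=rna_down),
                                       min_overlap=5)
        assert np.allclose(w2["rs"], -1.0)

    def test_across_sample_perfect_coupling(self):
        rng = np.random.default_rng(2)
        prot = frame(rng.normal(size=(30, 12)))
        paired = PairedOmics(protein=prot, rna=np.exp2(prot))
        out = across_sample_rna_protein(paired, min_overlap=5)
        assert np.allclose(out["rs"], 1.0)
        assert (out["adjusted_p"] < 1e-6).all()
        assert out["significant"].all()

    def test_bh_hand_example_and_properties(self):
        # independent check of the adjustment machinery on a known case
        from statsmodels.stats.multitest import multipletests

        pvals = [0.01, 0.02, 0.03, 0.04]
        adj = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(adj, bh_adjust_oracle(pvals))
        rng = np.random.default_rng(1)
        p = rng.random(50)
        a1 = multipletests(p, method="fdr_bh")[1]
        # monotone (order preserving), and a fixed point of the step-up
        # monotonicity enforcement: min over the upper tail changes nothing
        assert (np.diff(a1[np.argsort(p, kind="stable")]) >= -1e-15).all()
        sorted_a1 = a1[np.argsort(p, kind="stable")]
        stabilized = np.minimum.accumulate(sorted_a1[::-1])[::-1]
        np.testing.assert_allclose(sorted_a1, stabilized, atol=1e-15)

    def test_constant_gene_excluded_from_adjustment(self):
        prot = frame(np.vstack([np.arange(12.0), np.ones(12)]))
        paired = PairedOmics(protein=prot, rna=np.exp2(prot))
        out = across_sample_rna_protein(paired, min_overlap=5)
        assert np.isnan(out.loc["g1", "rs"]) and np.isnan(out.loc["g1", "adjusted_p"])


class TestLineageAnova:
    @staticmethod
    def annotated_rs(groups, studies, values):
        ann = make_annotation(
            [
                (f"a{i}", st, f"smp{i}", "cell_line", g, "trypsin")
                for i, (g, st) in enumerate(zip(groups, studies))
            ]
        )
        rs = pd.Series(values, index=[f"a{i}" for i in range(len(values))])
        return rs, ann

    def test_balanced_two_lineage_single_study_reduces_to_one_way(self):
        rng = np.random.default_rng(3)
        values = np.concatenate([rng.normal(0.5, 0.05, 10), rng.normal(0.6, 0.05, 10)])
        groups = ["breast"] * 10 + ["colorectal"] * 10
        rs, ann = self.annotated_rs(groups, ["s1"] * 20, values)
        table, tukey = lineage_anova(rs, ann)
        f_direct = stats.f_oneway(values[:10], values[10:]).statistic
        assert table.loc["C(lineage)", "F"] == pytest.approx(f_direct, rel=1e-9)

    def test_shifted_lineage_detected_by_tukey(self):
        rng = np.random.default_rng(9)
        lineages = ["breast", "colorectal", "ovarian"]
        groups, studies, values = [], [], []
        for i, lin in enumerate(lineages):
            for j in range(8):
                groups.append(lin)
                studies.append(f"s{j % 2}")
                shift = 0.2 if lin == "ovarian" else 0.0
                values.append(rng.normal(0.5 + shift, 0.02))
        rs, ann = self.annotated_rs(groups, studies, values)
        table, tukey = lineage_anova(rs, ann)
        assert table.loc["C(lineage)", "PR(>F)"] < 1e-6
        ov = tukey[(tukey["group1"] == "ovarian") | (tukey["group2"] == "ovarian")]
        assert ov["reject"].astype(bool).all()

    def test_equal_group_means_rarely_flag_tukey_pairs(self):
        # Tukey controls FWER at 5%: across 20 null replicates the
        # family-wise rejection rate must stay near that level (a real
        # lineage shift drives it to ~100%, see the power test below)
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(200 + seed)
            groups = ["breast"] * 10 + ["colorectal"] * 10 + ["ovarian"] * 10
            studies = [f"s{i % 2}" for i in range(30)]
            values = rng.normal(0.55, 0.05, size=30)
            rs, ann = self.annotated_rs(groups, studies, values)
            _, tukey = lineage_anova(rs, ann)
            if tukey["reject"].astype(bool).any():
                hits += 1
        assert hits / n_seeds <= 0.25

    def test_small_lineages_excluded_and_single_level_rejected(self):
        rs, ann = self.annotated_rs(
            ["breast"] * 5 + ["colorectal"] * 2, ["s1"] * 7, np.linspace(0.4, 0.6, 7)
        )
        with pytest.raises(ValueError, match="two lineages"):
            lineage_anova(rs, ann)


class TestGeneratorRecovery:
    def test_within_type_similarity_ordering(self):
        cfg = GeneratorConfig(n_proteins=150, seed=23, lineage_sd=1.0)
        raw, ann, truth = generate_multistudy(cfg)
        # correlations on true abundances: same-lineage pairs more similar
        corr = pairwise_correlation(
            truth.true_log2_abundance, method="pearson", min_overlap=5
        )
        lin = ann.table.set_index("sample_id")["lineage"]
        within, between = [], []
        samples = list(corr.index)
        for i, a in enumerate(samples):
            for b in samples[i + 1:]:
                (within if lin[a] == lin[b] else between).append(corr.loc[a, b])
        assert np.median(within) > np.median(between)
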