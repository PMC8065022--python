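import numpy as np
import pandas as pd
import pytest

from protscape import (
    GeneratorConfig,
    IntensityMatrix,
    NormalizationConfig,
    generate_multistudy,
    impute_lls,
    impute_lod,
    impute_svd,
    log2_transform,
    ppb_normalize,
    presence_filter,
    remove_batch_effects,
    run_normalization,
)
from protscape.normalization import PPB_TOTAL, batch_offset_estimates

from .conftest import make_annotation
from .oracles import batch_removal_oracle, svd_impute_oracle


def matrix_of(data, stage, proteins=None, assays=None):
    arr = np.asarray(data, dtype=float)
    proteins = proteins or [f"P{i}" for i in range(arr.shape[0])]
    assays = assays or [f"a{j}" for j in range(arr.shape[1])]
    return IntensityMatrix(
        values=pd.DataFrame(arr, index=proteins, columns=assays), stage=stage
    )


class TestPpbNormalize:
    def test_single_observed_protein_gets_full_total(self):
        out = ppb_normalize(matrix_of([[5.0]], "raw_ibaq"))
        assert out.values.iloc[0, 0] == PPB_TOTAL
        assert out.stage == "ppb"

    def test_proportional_scaling(self):
        out = ppb_normalize(matrix_of([[1.0], [1.0], [2.0]], "raw_ibaq"))
        np.testing.assert_allclose(
            out.values.iloc[:, 0], [25_000_000.0, 25_000_000.0, 50_000_000.0]
        )

    def test_missing_excluded_from_denominator(self):
        out = ppb_normalize(matrix_of([[4.0], [np.nan]], "raw_ibaq"))
        assert out.values.iloc[0, 0] == PPB_TOTAL
        assert np.isnan(out.values.iloc[1, 0])

    def test_observed_sums_conserved(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(10, 2, size=(60, 5))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        out = ppb_normalize(matrix_of(vals, "raw_ibaq"))
        sums = out.values.sum(axis=0, skipna=True)
        np.testing.assert_allclose(sums, PPB_TOTAL, atol=1e-3)

    def test_dead_assay_named_in_error(self):
        with pytest.raises(ValueError, match="a1"):
            ppb_normalize(matrix_of([[1.0, np.nan]], "raw_ibaq"))

    def test_wrong_stage_rejected(self):
        m = ppb_normalize(matrix_of([[1.0]], "raw_ibaq"))
        with pytest.raises(ValueError, match="stage"):
            ppb_normalize(m)


class TestLog2Transform:
    def test_values(self):
        out = log2_transform(matrix_of([[PPB_TOTAL], [1.0], [np.nan]], "ppb"))
        assert out.values.iloc[0, 0] == pytest.approx(26.5754247590989, abs=1e-10)
        assert out.values.iloc[1, 0] == 0.0
        assert np.isnan(out.values.iloc[2, 0])

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            log2_transform(matrix_of([[0.0]], "ppb"))


class TestPresenceFilter:
    def test_inclusive_boundary(self):
        m = matrix_of(
            [[1, 2, np.nan, np.nan], [1, np.nan, np.nan, np.nan], [1, 2, 3, 4]],
            "log2_ppb",
        )
        out = presence_filter(m, 0.5)
        assert out.protein_ids == ["P0", "P2"]  # 2/4 kept, 1/4 dropped

    def test_fully_observed_identity(self):
        m = matrix_of([[1, 2], [3, 4]], "log2_ppb")
        pd.testing.assert_frame_equal(presence_filter(m, 0.5).values, m.values)

    def test_empty_result_warns(self):
        m = matrix_of([[1, np.nan, np.nan, np.nan]], "log2_ppb")
        with pytest.warns(UserWarning):
            out = presence_filter(m, 0.5)
        assert out.n_proteins == 0


class TestImputeSvd:
    def test_no_missing_is_identity(self):
        m = matrix_of([[1, 2], [3, 4]], "log2_ppb")
        out = impute_svd(m, rank=1)
        pd.testing.assert_frame_equal(out.values, m.values)
        assert out.stage == "imputed"

    def test_rank1_closed_form_completion(self):
        vals = np.outer([1.0, 2.0, 3.0], [1.0, 2.0])
        vals[2, 1] = np.nan
        out = impute_svd(matrix_of(vals, "log2_ppb"), rank=1, tol=1e-10)
        assert out.values.iloc[2, 1] == pytest.approx(6.0, abs=1e-6)

    def test_exact_rank2_recovery(self):
        rng = np.random.default_rng(1)
        truth = rng.normal(size=(12, 2)) @ rng.normal(size=(2, 8))
        masked = truth.copy()
        holes = rng.random(truth.shape) < 0.15
        masked[holes] = np.nan
        out = impute_svd(matrix_of(masked, "log2_ppb"), rank=2, tol=1e-10)
        assert np.abs(out.values.to_numpy()[holes] - truth[holes]).max() < 1e-6

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            X = rng.normal(size=(10, 8))
            mask = rng.random(X.shape) < 0.2
            mask[:, mask.all(axis=0)] = False
            mask[mask.all(axis=1), :] = False
            Xm = X.copy()
            Xm[mask] = np.nan
            ours = impute_svd(matrix_of(Xm, "log2_ppb"), rank=3, tol=1e-9).values.to_numpy()
            oracle = svd_impute_oracle(Xm, rank=3, tol=1e-9)
            np.testing.assert_allclose(ours, oracle, atol=1e-8)

    def test_observed_entries_untouched(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 6))
        mask = rng.random(X.shape) < 0.2
        Xm = X.copy()
        Xm[mask] = np.nan
        for f in (lambda m: impute_svd(m, rank=2), impute_lod, lambda m: impute_lls(m, k=2)):
            out = f(matrix_of(Xm, "log2_ppb")).values.to_numpy()
            np.testing.assert_array_equal(out[~mask], X[~mask])

    def test_excessive_rank_rejected(self):
        m = matrix_of([[1, 2], [3, np.nan]], "log2_ppb")
        with pytest.raises(ValueError, match="rank"):
            impute_svd(m, rank=2)


class TestImputeLod:
    def test_per_assay_minimum(self):
        out = impute_lod(matrix_of([[10.0], [12.0], [np.nan]], "log2_ppb"))
        assert out.values.iloc[2, 0] == 10.0

    def test_all_equal_observed(self):
        out = impute_lod(matrix_of([[7.0], [7.0], [np.nan]], "log2_ppb"))
        assert out.values.iloc[2, 0] == 7.0

    def test_empty_assay_rejected(self):
        with pytest.raises(ValueError):
            impute_lod(matrix_of([[np.nan], [np.nan]], "log2_ppb"))


class TestImputeLls:
    def test_perfect_single_neighbor(self):
        neighbor = np.array([1.0, 5.0, 2.0, 8.0])
        target = neighbor.copy()
        target[3] = np.nan
        vals = np.vstack([neighbor, target, [0.3, 0.1, 0.9, 0.2]])
        out = impute_lls(matrix_of(vals, "log2_ppb"), k=1)
        assert out.values.iloc[1, 3] == pytest.approx(8.0, abs=1e-9)

    def test_rank1_structure_recovered(self):
        truth = np.outer([1.0, 2.0, 3.0, 4.0, 5.0], [1.0, 0.5, 2.0, 1.5])
        masked = truth.copy()
        masked[4, 3] = np.nan
        out = impute_lls(matrix_of(masked, "log2_ppb"), k=2)
        assert abs(out.values.iloc[4, 3] - truth[4, 3]) < 1e-6

    def test_too_few_complete_neighbors_rejected(self):
        vals = np.array([[1.0, np.nan], [np.nan, 1.0], [1.0, 2.0]])
        with pytest.raises(ValueError, match="complete"):
            impute_lls(matrix_of(vals, "log2_ppb"), k=2)


class TestRemoveBatchEffects:
    @staticmethod
    def annotation_for(assays, studies, lineages=None):
        lineages = lineages or ["breast"] * len(assays)
        return make_annotation(
            [
                (a, s, f"smp_{a}", "cell_line", l, "trypsin")
                for a, s, l in zip(assays, studies, lineages)
            ]
        )

    def test_exact_additive_offset_removed(self):
        shared = np.array([[5.0, 6.0], [1.0, 3.0]])
        vals = np.hstack([shared + 1.0, shared - 1.0])
        m = matrix_of(vals, "imputed", assays=["a1", "a2", "a3", "a4"])
        ann = self.annotation_for(
            ["a1", "a2", "a3", "a4"], ["s1", "s1", "s2", "s2"],
            ["breast", "colorectal", "breast", "colorectal"],
        )
        out = remove_batch_effects(m, ann).values.to_numpy()
        for i in range(2):
            assert out[i, :2].mean() == pytest.approx(out[i, 2:].mean(), abs=1e-12)
        # within-batch deviations preserved exactly
        np.testing.assert_allclose(out[:, :2] - out[:, :2].mean(axis=1, keepdims=True),
                                   shared - shared.mean(axis=1, keepdims=True))

    def test_recovers_planted_offsets(self):
        cfg = GeneratorConfig(
            n_proteins=40, noise_sd=0.0, lineage_sd=0.0, sample_sd=0.0,
            mcar_rate=0.0, mnar_enabled=False, batch_offset_sd=1.5, seed=13,
        )
        raw, ann, truth = generate_multistudy(cfg)
        m = IntensityMatrix(values=np.log2(raw.values), stage="log2_ppb")
        m = IntensityMatrix(values=m.values, stage="imputed")
        est = batch_offset_estimates(m, ann)
        diff_est = est["study0"] - est["study1"]
        diff_true = truth.batch_offsets["study0"] - truth.batch_offsets["study1"]
        # estimated offset differences are exact up to per-protein structure
        # induced by unbalanced lineage composition; noise-free gives equality
        np.testing.assert_allclose(diff_est, diff_true, atol=1e-6)

    def test_single_batch_is_identity_with_warning(self):
        m = matrix_of([[1.0, 2.0]], "imputed")
        ann = self.annotation_for(["a0", "a1"], ["s1", "s1"])
        with pytest.warns(UserWarning):
            out = remove_batch_effects(m, ann)
        pd.testing.assert_frame_equal(out.values, m.values)
        assert out.stage == "batch_corrected"

    def test_matches_ols_oracle_and_preserves_grand_mean(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 9))
        studies = ["s1"] * 3 + ["s2"] * 4 + ["s3"] * 2
        assays = [f"a{i}" for i in range(9)]
        m = matrix_of(X, "imputed", assays=assays)
        ann = self.annotation_for(assays, studies)
        out = remove_batch_effects(m, ann).values.to_numpy()
        np.testing.assert_allclose(out, batch_removal_oracle(X, studies), atol=1e-9)
        np.testing.assert_allclose(out.mean(axis=1), X.mean(axis=1), atol=1e-9)

    def test_confounded_design_rejected(self):
        m = matrix_of([[1.0, 2.0, 3.0, 4.0]], "imputed", assays=["a1", "a2", "a3", "a4"])
        ann = self.annotation_for(
            ["a1", "a2", "a3", "a4"], ["s1", "s1", "s2", "s2"],
            ["breast", "breast", "colorectal", "colorectal"],
        )
        with pytest.raises(ValueError, match="confounded"):
            remove_batch_effects(m, ann)

    def test_requires_complete_matrix(self):
        m = matrix_of([[1.0, np.nan]], "imputed")
        ann = self.annotation_for(["a0", "a1"], ["s1", "s2"])
        with pytest.raises(ValueError, match="complete"):
            remove_batch_effects(m, ann)


class TestRunNormalization:
    def test_noise_free_pipeline_reduces_to_log2_ppb(self):
        cfg = GeneratorConfig(
            n_proteins=30, batch_offset_sd=0.0, noise_sd=0.0, lineage_sd=0.0,
            sample_sd=0.0, mcar_rate=0.0, mnar_enabled=False, seed=21,
        )
        raw, ann, _ = generate_multistudy(cfg)
        out = run_normalization(raw, ann)
        expected = log2_transform(ppb_normalize(raw)).values
        np.testing.assert_allclose(out.values.to_numpy(), expected.to_numpy(), atol=1e-9)
        assert out.stage == "batch_corrected"

    def test_deterministic_and_logged(self):
        cfg = GeneratorConfig(n_proteins=60, seed=2)
        raw, ann, _ = generate_multistudy(cfg)
        log1, log2_ = [], []
        out1 = run_normalization(raw, ann, log=log1)
        out2 = run_normalization(raw, ann, log=log2_)
        pd.testing.assert_frame_equal(out1.values, out2.values)
        assert log1 == log2_ and len(log1) == 5

    def test_stage_order_enforced(self):
        m = matrix_of([[1.0, 2.0]], "raw_ibaq")
        with pytest.raises(ValueError, match="stage"):
            log2_transform(m)
        with pytest.raises(ValueError, match="stage"):
            impute_svd(m, rank=1)
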