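"""Pseudo-bulk, TMM normalisation and PCA staging of samples."""
import numpy as np
import pandas as pd
import pytest

from scstage import staging
from scstage.synthdata import SimConfig, simulate_experiment
from scstage.validation import tmm_brute_force


class TestPseudobulk:
    def test_conservation_and_additivity(self, small_experiment):
        _, adata, _ = small_experiment
        pb = staging.pseudobulk(adata)
        assert np.allclose(pb.sum(axis=0),
                           np.asarray(adata.X.sum(axis=0)).ravel())
        # splitting a sample in two and re-merging reproduces its row
        s0 = adata[(adata.obs["sample"] == "s00").to_numpy()]
        half = s0.n_obs // 2
        row = (np.asarray(s0.X[:half].sum(axis=0)).ravel()
               + np.asarray(s0.X[half:].sum(axis=0)).ravel())
        assert np.allclose(pb.loc["s00"].to_numpy(), row)

    def test_one_cell_per_sample_identity(self, small_experiment):
        _, adata, _ = small_experiment
        single = adata[:3].copy()
        single.obs["sample"] = ["x", "y", "z"]
        pb = staging.pseudobulk(single)
        assert np.allclose(pb.to_numpy(), single.X.toarray())


class TestTmm:
    def test_identical_libraries_unit_factors(self):
        pb = pd.DataFrame([[10, 20, 30]] * 4, index=list("abcd"))
        fac, _ = staging.tmm_factors(pb)
        assert np.allclose(fac, 1.0)

    def test_pure_depth_difference_unit_factors(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(50, size=40) + 1
        pb = pd.DataFrame([base, 2 * base], index=["a", "b"])
        fac, _ = staging.tmm_factors(pb)
        assert np.allclose(fac, 1.0, atol=1e-12)

    def test_matches_brute_force_oracle(self):
        pb = pd.DataFrame(
            [[100, 50, 20, 500, 10, 400],
             [200, 100, 45, 950, 25, 820],
             [90, 300, 20, 480, 12, 390]],
            index=["s1", "s2", "s3"], dtype=float)
        fac, ref = staging.tmm_factors(pb)
        oracle = tmm_brute_force(pb, ref)
        assert np.abs(fac - oracle).max() < 1e-10

    def test_depth_change_invariance_of_scaled_axis(self, small_experiment):
        _, adata, _ = small_experiment
        pb = staging.pseudobulk(adata)
        res1 = staging.staging_pca(pb, anchor_samples=["s00"])
        res2 = staging.staging_pca(pb * 5, anchor_samples=["s00"])
        assert np.allclose(res1.pc1_scaled, res2.pc1_scaled, atol=1e-8)


class TestStagingPca:
    def test_recovers_true_order(self):
        cfg = SimConfig(n_samples=8, cells_per_sample=500, n_genes=300,
                        seed=55)
        adata, truth = simulate_experiment(cfg)
        pb = staging.pseudobulk(adata)
        res = staging.staging_pca(pb, anchor_samples=["s00"])
        from scstage.statcore import spearman_rho
        assert spearman_rho(res.pc1.to_numpy(),
                            truth.samples["stage"].to_numpy()) == 1.0

    def test_scaled_axis_extremes(self, small_experiment):
        _, adata, _ = small_experiment
        pb = staging.pseudobulk(adata)
        res = staging.staging_pca(pb, anchor_samples=["s00"])
        assert res.pc1_scaled.min() == 0.0
        assert res.pc1_scaled.max() == 1.0

    def test_sign_convention_anchors_low(self, small_experiment):
        _, adata, truth = small_experiment
        pb = staging.pseudobulk(adata)
        early = truth.samples["stage"].idxmin()
        res = staging.staging_pca(pb, anchor_samples=[early])
        assert res.pc1[early] <= res.pc1.mean()

    def test_permuting_samples_permutes_outputs(self, small_experiment):
        _, adata, _ = small_experiment
        pb = staging.pseudobulk(adata)
        res1 = staging.staging_pca(pb, anchor_samples=["s00"])
        perm = pb.iloc[::-1]
        res2 = staging.staging_pca(perm, anchor_samples=["s00"])
        assert np.allclose(res1.pc1_scaled.sort_index(),
                           res2.pc1_scaled.sort_index(), atol=1e-10)

    def test_identical_samples_rejected(self):
        pb = pd.DataFrame([[10, 20, 30, 5]] * 5, index=list("abcde"))
        with pytest.raises(ValueError):
            staging.staging_pca(pb, anchor_samples=["a"])


class TestBinStages:
    def _result_with_scaled(self, values):
        pc1 = pd.Series(values, index=[f"s{i}" for i in range(len(values))])
        return staging.StagingResult(
            pseudobulk=pd.DataFrame(), tmm=pd.Series(dtype=float),
            genes=pd.Index([]), gene_means=np.array([]),
            loadings=np.empty((0, 0)), pc1=pc1, pc1_scaled=pc1,
            pc1_min=0.0, pc1_max=1.0, explained_variance=np.array([]),
            ref_sample="s0")

    def test_equal_width_binning(self):
        res = self._result_with_scaled([0, .2, .4, .6, .9, 1])
        stages = staging.bin_stages(res, n_bins=4)
        assert stages.tolist() == ["1", "1", "2", "3", "4", "4"]

    def test_single_bin(self):
        res = self._result_with_scaled([0, 0.5, 1])
        assert staging.bin_stages(res, n_bins=1).eq("1").all()

    def test_explicit_boundaries_and_tumour_passthrough(self):
        res = self._result_with_scaled([0, .2, .4, .6, .9, 1])
        stages = staging.bin_stages(res, boundaries=[0.3, 0.95],
                                    tumour_samples=["s5"])
        assert stages.tolist() == ["1", "1", "2", "2", "2", "tumour"]
        with pytest.raises(ValueError):
            staging.bin_stages(res, boundaries=[0.5, 0.4])


class TestProjection:
    def test_training_sample_projects_to_itself(self, small_experiment):
        _, adata, _ = small_experiment
        pb = staging.pseudobulk(adata)
        res = staging.staging_pca(pb, anchor_samples=["s00"])
        proj = staging.project_samples(pb.iloc[[2]], res)
        assert proj["pc1"].iloc[0] == pytest.approx(res.pc1.iloc[2],
                                                    abs=1e-9)

    def test_heldout_early_sample_lands_low(self):
        cfg = SimConfig(n_samples=10, cells_per_sample=500, n_genes=300,
                        latent_stages=[0.1, 0, 0.22, 0.33, 0.44, 0.55,
                                       0.66, 0.77, 0.88, 1.0], seed=21)
        adata, truth = simulate_experiment(cfg)
        pb = staging.pseudobulk(adata)
        train = pb.drop(index="s00")  # hold out the s=0.1 sample
        res = staging.staging_pca(train, anchor_samples=["s01"])
        proj = staging.project_samples(pb.loc[["s00"]], res)
        assert proj["pc1_scaled"].iloc[0] < res.pc1_scaled.median()

    def test_all_zero_sample_is_finite_with_warning(self, small_experiment):
        _, adata, _ = small_experiment
        pb = staging.pseudobulk(adata)
        res = staging.staging_pca(pb, anchor_samples=["s00"])
        zero = pd.DataFrame(0, index=["z"], columns=pb.columns)
        proj = staging.project_samples(zero, res)
        assert np.isfinite(proj["pc1"].iloc[0])

    def test_low_gene_overlap_rejected(self, small_experiment):
        _, adata, _ = small_experiment
        pb = staging.pseudobulk(adata)
        res = staging.staging_pca(pb, anchor_samples=["s00"])
        few = pb[list(res.genes[: len(res.genes) // 3])]
        with pytest.raises(ValueError):
            staging.project_samples(few.iloc[[0]], res)
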