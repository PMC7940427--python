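"""Tests of the synthetic-data generator and its ground truth."""
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scstage import statcore
from scstage.synthdata import (ConfigurationError, CorrModule, SimConfig,
                               inject_artifacts, read_fixtures,
                               simulate_composition, simulate_experiment,
                               write_fixtures)


class TestConfig:
    def test_invalid_configs_raise(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_celltypes=1).validate()
        with pytest.raises(ConfigurationError):
            SimConfig(latent_stages=[0.5, 1.2], n_samples=2).validate()
        with pytest.raises(ConfigurationError):
            SimConfig(doublet_rate=0.3, rbc_rate=0.2, nuclei_rate=0.1
                      ).validate()
        with pytest.raises(ConfigurationError):
            SimConfig(base_proportions=(0.5, 0.6), n_celltypes=2).validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimConfig(n_samples=3, seed=5,
                        corr_modules=(CorrModule("A", 0.5, 10),))
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = SimConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back.n_samples == 3 and back.seed == 5
        assert back.corr_modules[0].rho == 0.5


class TestComposition:
    def test_zero_trend_means_match_base(self):
        """With no trend, realised proportions scatter around the base."""
        cfg = SimConfig(n_samples=20, cells_per_sample=1000, n_genes=20,
                        n_celltypes=4, base_proportions=(0.1, 0.2, 0.3, 0.4),
                        composition_trends=(0.0,) * 4, seed=3)
        counts, props, _ = simulate_composition(cfg)
        base = np.array([0.1, 0.2, 0.3, 0.4])
        mean_prop = counts.mean(axis=0) / 1000
        # 3 binomial SEs plus the Dirichlet overdispersion allowance
        se = 3 * np.sqrt(base * (1 - base) / (1000 * 20)) + 3 * np.sqrt(
            base * (1 - base) / (cfg.dirichlet_concentration * 20))
        assert np.all(np.abs(mean_prop - base) < se)

    def test_expansion_slope_recovered_from_realised_proportions(self):
        """Logit-linear fit on realised proportions recovers the true slope."""
        cfg = SimConfig(n_samples=40, cells_per_sample=2000, n_genes=20,
                        seed=9)
        counts, props, s = simulate_composition(cfg)
        p = counts[:, 0] / 2000
        # logit of the expanding type against the remaining mixture is not
        # exactly linear in s (softmax renormalisation); fit on the model's
        # own expected values to compare like with like
        logit = np.log(p / (1 - p))
        slope = np.polyfit(s, logit, 1)[0]
        from scstage.synthdata import composition_proportions
        exp_p = composition_proportions(cfg, s)[:, 0]
        exp_slope = np.polyfit(s, np.log(exp_p / (1 - exp_p)), 1)[0]
        assert abs(slope - exp_slope) / exp_slope < 0.2

    def test_counts_sum_to_cells_per_sample(self):
        cfg = SimConfig(n_samples=5, cells_per_sample=700, n_genes=20, seed=1)
        counts, _, _ = simulate_composition(cfg)
        assert (counts.sum(axis=1) == 700).all()


class TestSimulateExperiment:
    def test_determinism_bit_identical(self):
        cfg = SimConfig(n_samples=2, cells_per_sample=150, n_genes=250,
                        seed=77)
        a1, t1 = simulate_experiment(cfg)
        a2, t2 = simulate_experiment(cfg)
        assert (a1.X != a2.X).nnz == 0
        pd.testing.assert_frame_equal(t1.cells, t2.cells)

    def test_gene_flags_disjoint(self, small_experiment):
        _, adata, _ = small_experiment
        flags = adata.var[["is_mito", "is_ribo", "is_hb"]].to_numpy()
        assert flags.sum(axis=1).max() <= 1

    def test_library_size_tracks_true_size_factor(self, flat_experiment):
        # homogeneous setting: type totals match, no stage program
        _, adata, truth = flat_experiment
        lib = np.asarray(adata.X.sum(axis=1)).ravel()
        r = np.corrcoef(lib, truth.cells["size_factor"])[0, 1]
        assert r > 0.95

    def test_program_pseudobulk_monotone_in_stage(self, small_experiment):
        _, adata, truth = small_experiment
        prog = truth.genes.index[truth.genes["is_program"]]
        pb = []
        for s in truth.samples.index:
            cells = adata.obs["sample"] == s
            sub = adata[cells.to_numpy(), adata.var_names.isin(prog)]
            pb.append(float(sub.X.sum()) / cells.sum())
        rho = statcore.spearman_rho(pb, truth.samples["stage"].to_numpy())
        assert rho == pytest.approx(1.0)

    def test_truth_labels_cover_all_cells(self, small_experiment):
        _, adata, truth = small_experiment
        assert set(truth.cells.index) == set(adata.obs_names)
        assert (truth.cells["artifact"] == "singlet").all()


class TestInjectArtifacts:
    def test_zero_rates_identity(self, flat_experiment):
        cfg, adata, truth = flat_experiment
        import dataclasses
        cfg0 = dataclasses.replace(cfg, doublet_rate=0.0, rbc_rate=0.0,
                                   nuclei_rate=0.0)
        out, t_out = inject_artifacts(adata, truth, cfg0)
        assert out.n_obs == adata.n_obs
        assert (out.X != adata.X).nnz == 0

    def test_doublet_is_exact_sum_of_parents(self, flat_experiment):
        cfg, adata, truth = flat_experiment
        out, t_out = inject_artifacts(adata, truth, cfg)
        doubs = t_out.cells[t_out.cells["artifact"] == "doublet"]
        X = sp.csr_matrix(out.X)
        for bc, row in doubs.head(5).iterrows():
            pa, pb = row["parents"].split("|")
            i = out.obs_names.get_loc(bc)
            ia = out.obs_names.get_loc(pa)
            ib = out.obs_names.get_loc(pb)
            assert (X[i] - X[ia] - X[ib]).nnz == 0

    def test_rbc_count_and_expression(self, flat_experiment):
        cfg, adata, truth = flat_experiment
        out, t_out = inject_artifacts(adata, truth, cfg)
        rbc = t_out.cells[t_out.cells["artifact"] == "rbc"]
        assert len(rbc) == round(cfg.rbc_rate * adata.n_obs)
        hb = out.var["is_hb"].to_numpy()
        X = sp.csr_matrix(out.X)
        for bc in rbc.index:
            i = out.obs_names.get_loc(bc)
            assert np.median(X[i, hb].toarray()) > 0

    def test_nuclei_have_low_mito_fraction(self, flat_experiment):
        cfg, adata, truth = flat_experiment
        out, t_out = inject_artifacts(adata, truth, cfg)
        nuc = t_out.cells[t_out.cells["artifact"] == "nucleus"]
        mito = out.var["is_mito"].to_numpy()
        X = sp.csr_matrix(out.X)
        for bc in nuc.index:
            i = out.obs_names.get_loc(bc)
            tot = X[i].sum()
            assert X[i, mito].sum() / max(tot, 1) < 0.005

    def test_rates_exceeding_cells_raise(self, flat_experiment):
        cfg, adata, truth = flat_experiment
        import dataclasses
        big = dataclasses.replace(cfg, doublet_rate=0.45, rbc_rate=0.01,
                                  nuclei_rate=0.12)
        with pytest.raises(ConfigurationError):
            inject_artifacts(adata, truth, big)

    def test_artifacts_refused_on_non_singlet_input(self, flat_experiment):
        cfg, adata, truth = flat_experiment
        out, t_out = inject_artifacts(adata, truth, cfg)
        with pytest.raises(ConfigurationError):
            inject_artifacts(out, t_out, cfg)


class TestFixtures:
    def test_mtx_round_trip(self, tmp_path, flat_experiment):
        _, adata, truth = flat_experiment
        write_fixtures(adata, truth, tmp_path / "fx")
        back, t_back = read_fixtures(tmp_path / "fx")
        assert (sp.csr_matrix(back.X) != sp.csr_matrix(adata.X)).nnz == 0
        assert list(back.obs_names) == list(adata.obs_names)
        assert (back.var["is_mito"] == adata.var["is_mito"]).all()
        assert np.allclose(t_back.samples["stage"],
                           truth.samples["stage"])

    def test_refuses_nonempty_dir_without_overwrite(self, tmp_path,
                                                    flat_experiment):
        _, adata, truth = flat_experiment
        write_fixtures(adata, truth, tmp_path / "fx")
        with pytest.raises(IOError):
            write_fixtures(adata, truth, tmp_path / "fx")
        write_fixtures(adata, truth, tmp_path / "fx", overwrite=True)

    def test_empty_matrix_round_trip(self, tmp_path):
        import anndata as ad
        from scstage import io as scio
        empty = ad.AnnData(
            X=sp.csr_matrix((0, 5)),
            obs=pd.DataFrame(index=pd.Index([], dtype=str)),
            var=pd.DataFrame({"gene_symbol": [f"g{i}" for i in range(5)],
                              "is_mito": False, "is_ribo": False,
                              "is_hb": False},
                             index=[f"g{i}" for i in range(5)]))
        scio.write_sample_mtx(empty, tmp_path / "empty")
        back = scio.read_sample_mtx(tmp_path / "empty")
        assert back.shape == (0, 5)
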