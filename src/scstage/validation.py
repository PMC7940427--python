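"""End-to-end validation benchmarks on synthetic data with known truth.

Each function builds a synthetic experiment with the generator's study-like
conditions, runs the relevant pipeline stage(s) from scratch and returns
summary metrics. They power both the acceptance test suite and the
``scripts/acceptance.py`` reporting script, so problem sizes are chosen to
finish in minutes on a single core; the methods note records them.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from . import abundance as _abundance
from . import diffcor as _diffcor
from . import doublets as _doublets
from . import interactions as _interactions
from . import normalize as _normalize
from . import qc as _qc
from . import staging as _staging
from .synthdata import (CorrModule, LRAxis, SimConfig, inject_artifacts,
                        simulate_composition, simulate_experiment)

__all__ = [
    "staging_recovery",
    "da_null_calibration",
    "da_power",
    "tmm_brute_force",
    "tmm_oracle_check",
    "doublet_pipeline_metrics",
    "diffcor_power_run",
    "diffcor_null_ks",
    "diffcor_exhaustive_check",
    "interaction_planted_run",
    "interaction_null_calibration",
    "size_factor_recovery",
]


# ---------------------------------------------------------------------------
# staging
# ---------------------------------------------------------------------------

def staging_recovery(n_runs: int = 20, n_samples: int = 12,
                     cells_per_sample: int = 2000, n_genes: int = 300,
                     seed: int = 0) -> dict:
    """Rank agreement between recovered PC1 and the true latent stage.

    Each run simulates a cohort with a monotone stage program, pseudo-bulks
    it, and checks Spearman correlation between the staging axis and the
    true stage ranks.
    """
    rhos = []
    for r in range(n_runs):
        cfg = SimConfig(n_samples=n_samples, cells_per_sample=cells_per_sample,
                        n_genes=n_genes, seed=seed + 1000 * r)
        adata, truth = simulate_experiment(cfg)
        pb = _staging.pseudobulk(adata)
        res = _staging.staging_pca(pb, anchor_samples=[pb.index[0]])
        rho = stats.spearmanr(res.pc1.to_numpy(),
                              truth.samples["stage"].to_numpy()).statistic
        rhos.append(float(rho))
    rhos = np.asarray(rhos)
    return {
        "success_rate": float(np.mean(rhos >= 0.9)),
        "min_spearman": float(rhos.min()),
        "median_spearman": float(np.median(rhos)),
        "n_runs": n_runs,
    }


# ---------------------------------------------------------------------------
# differential abundance
# ---------------------------------------------------------------------------

def _da_from_composition(counts: np.ndarray, s: np.ndarray,
                         min_mean_cells: float = 10.0) -> pd.DataFrame:
    tab = pd.DataFrame(counts.T,
                       index=[f"c{i}" for i in range(counts.shape[1])],
                       columns=[f"s{j:02d}" for j in range(counts.shape[0])])
    totals = tab.sum(axis=0).to_numpy(dtype=float)
    prior = 2.0 * totals / totals.mean()
    logcpm = np.log2((tab.to_numpy() + prior[None, :])
                     / (totals + 2 * prior)[None, :] * 1e6)
    abund = pd.DataFrame(logcpm, index=tab.index, columns=tab.columns)
    pc1 = pd.Series((s - s.min()) / (s.max() - s.min()), index=tab.columns)
    return _abundance.differential_abundance(abund, pc1, counts=tab,
                                             min_mean_cells=min_mean_cells)


def da_null_calibration(n_reps: int = 1000, n_samples: int = 12,
                        cells_per_sample: int = 1000, n_clusters: int = 8,
                        seed: int = 0) -> dict:
    """Raw p < 0.05 rate under zero composition trend (should be ~0.05)."""
    rng = np.random.default_rng(seed)
    base = tuple([1.0 / n_clusters] * n_clusters)
    trends = tuple([0.0] * n_clusters)
    n_p, n_tests = 0, 0
    for _ in range(n_reps):
        cfg = SimConfig(n_samples=n_samples,
                        cells_per_sample=cells_per_sample, n_genes=10,
                        n_celltypes=n_clusters, base_proportions=base,
                        composition_trends=trends,
                        seed=int(rng.integers(2 ** 31)))
        counts, _, s = simulate_composition(cfg)
        res = _da_from_composition(counts, s)
        tested = res[res["tested"]]
        n_p += int((tested["p"] < 0.05).sum())
        n_tests += len(tested)
    return {"rejection_rate": n_p / n_tests, "n_tests": n_tests}


def da_power(n_runs: int = 50, n_samples: int = 12,
             cells_per_sample: int = 2000, seed: int = 0) -> dict:
    """Detection rate of the expanding type (2% -> ~40%) at FDR < 0.1.

    The scaled true stage stands in for the scaled PC1 predictor here; the
    staging benchmark separately establishes their rank agreement.
    """
    detected = 0
    for r in range(n_runs):
        cfg = SimConfig(n_samples=n_samples,
                        cells_per_sample=cells_per_sample, n_genes=10,
                        seed=seed + 7919 * r)
        counts, _, s = simulate_composition(cfg)
        res = _da_from_composition(counts, s)
        avd = res.loc["c0"]  # the expanding type is always the first
        if avd["tested"] and avd["fdr"] < 0.1 and avd["logFC"] > 0:
            detected += 1
    return {"detection_rate": detected / n_runs, "n_runs": n_runs}


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def tmm_brute_force(pb: pd.DataFrame, ref: str, trim_m: float = 0.30,
                    trim_a: float = 0.05) -> pd.Series:
    """Independent enumeration of the trimmed-mean-of-M-values formula.

    Deliberately written as plain per-gene loops so it shares no code with
    the vectorised implementation it cross-checks.
    """
    lib = {s: float(pb.loc[s].sum()) for s in pb.index}
    ref_vals = pb.loc[ref]
    out = {}
    for s in pb.index:
        if s == ref:
            out[s] = 1.0
            continue
        M, A, w = [], [], []
        for g in pb.columns:
            y, rv = float(pb.loc[s, g]), float(ref_vals[g])
            if y > 0 and rv > 0:
                po, pr = y / lib[s], rv / lib[ref]
                M.append(np.log2(po / pr))
                A.append(0.5 * np.log2(po * pr))
                w.append((lib[s] - y) / (lib[s] * y)
                         + (lib[ref] - rv) / (lib[ref] * rv))
        n = len(M)
        rM = stats.rankdata(M)
        rA = stats.rankdata(A)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rM[i] <= hi_m and lo_a <= rA[i] <= hi_a:
                num += M[i] / w[i]
                den += 1.0 / w[i]
        out[s] = 2.0 ** (num / den) if den > 0 else 1.0
    fac = pd.Series(out).reindex(pb.index)
    return fac / np.exp(np.mean(np.log(fac)))


def tmm_oracle_check() -> dict:
    """Compare the TMM implementation with the brute-force oracle on a toy."""
    pb = pd.DataFrame(
        [[100, 50, 20, 500, 10, 400],
         [200, 100, 45, 950, 25, 820],
         [90, 300, 20, 480, 12, 390]],
        index=["s1", "s2", "s3"],
        columns=[f"g{i}" for i in range(6)], dtype=float)
    fac, ref = _staging.tmm_factors(pb)
    oracle = tmm_brute_force(pb, ref)
    identical = pd.DataFrame(
        [[100, 50, 20, 500, 10, 400]] * 3, index=["a", "b", "c"],
        columns=pb.columns, dtype=float)
    fac_id, _ = _staging.tmm_factors(identical)
    return {
        "max_abs_diff": float((fac - oracle).abs().max()),
        "identical_max_dev": float((fac_id - 1.0).abs().max()),
    }


# ---------------------------------------------------------------------------
# doublets / artifacts
# ---------------------------------------------------------------------------

def doublet_pipeline_metrics(n_seeds: int = 10, n_samples: int = 3,
                             cells_per_sample: int = 800,
                             n_genes: int = 250, seed: int = 0) -> dict:
    """Sensitivity/specificity of the full artifact-removal pipeline.

    Two well separated types A and B with 5% A+B doublets, 2% RBC-like
    contaminants and 2% stripped nuclei; metrics are aggregated over seeds.
    """
    sens, false_rm, rbc_ok, nuc_ok = [], [], [], []
    for r in range(n_seeds):
        cfg = SimConfig(n_samples=n_samples,
                        cells_per_sample=cells_per_sample, n_genes=n_genes,
                        n_celltypes=2, celltype_names=("A", "B"),
                        base_proportions=(0.5, 0.5),
                        composition_trends=(0.0, 0.0),
                        doublet_pairing="cross_type", doublet_rate=0.05,
                        rbc_rate=0.02, nuclei_rate=0.02,
                        seed=seed + 104729 * r)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            adata, truth = simulate_experiment(cfg)
            adata, truth = inject_artifacts(adata, truth, cfg)
            model = _normalize.fit_normalization(adata)
            L = _normalize.log_normalize(adata.X, model,
                                         batches=adata.obs["batch"].to_numpy())
            hvgs, _ = _normalize.select_hvgs(L, adata.var_names, adata.var,
                                             adata.obs["batch"].to_numpy())
            hvg_mask = adata.var_names.isin(hvgs)
            qt = _qc.compute_cell_metrics(adata)
            flags = _doublets.detect_artifacts(
                adata, L, hvg_mask, qt["pct_mito"].to_numpy(), seed=seed)
        art = truth.cells.loc[adata.obs_names, "artifact"].to_numpy()
        reason = flags["removal_reason"].to_numpy()
        dbl = art == "doublet"
        sens.append(float((reason[dbl] == "doublet").mean()))
        false_rm.append(float((reason[art == "singlet"] != "").mean()))
        # cluster-level removal of contaminants: every coarse cluster whose
        # majority is rbc (nuclei) must be flagged entirely
        coarse = flags["coarse_cluster"].to_numpy()
        for kind, store in (("rbc", rbc_ok), ("nucleus", nuc_ok)):
            ok = True
            for c in pd.unique(coarse):
                m = coarse == c
                if (art[m] == kind).mean() > 0.5:
                    ok &= bool((reason[m] != "").all())
            store.append(ok)
    return {
        "doublet_sensitivity_min": float(np.min(sens)),
        "doublet_sensitivity_mean": float(np.mean(sens)),
        "singlet_false_removal_max": float(np.max(false_rm)),
        "rbc_clusters_removed_all_seeds": bool(all(rbc_ok)),
        "nuclei_clusters_removed_all_seeds": bool(all(nuc_ok)),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# differential correlation
# ---------------------------------------------------------------------------

def _diffcor_experiment(n_cells_per_group: int, n_genes: int,
                        n_planted: int, rho: float, seed: int):
    cfg = SimConfig(n_samples=2, cells_per_sample=n_cells_per_group,
                    n_genes=n_genes, n_celltypes=2,
                    celltype_names=("Lp", "Avd"),
                    base_proportions=(0.5, 0.5),
                    composition_trends=(0.0, 0.0), program_genes=0,
                    markers_per_type=10, batch_assignment=["b0", "b0"],
                    sample_conditions=["tumourigenesis", "gestation"],
                    corr_modules=(CorrModule("tumourigenesis", rho,
                                             n_planted),),
                    seed=seed)
    adata, truth = simulate_experiment(cfg)
    model = _normalize.fit_normalization(adata)
    L = _normalize.log_normalize(adata.X, model,
                                 batches=adata.obs["batch"].to_numpy())
    cond = truth.samples.loc[adata.obs["sample"], "condition"].to_numpy()
    anchor = adata.uns["anchor_gene"]
    planted = truth.genes.index[truth.genes["module_condition"] != ""]
    return adata, L, cond, anchor, planted


def diffcor_power_run(n_cells_per_group: int = 600, n_genes: int = 200,
                      n_planted: int = 20, rho: float = 0.6,
                      n_perm: int = 9999, seed: int = 0) -> dict:
    """Recovery of planted correlation modules at the study thresholds.

    20 genes correlate with the anchor (rho 0.6) only in one condition; a
    hit requires BH FDR strictly below 0.001, and with the add-one p-value
    convention the smallest attainable q is ``m / (rank * (n_perm + 1))``,
    so the permutation count must be large enough for that floor to clear
    the threshold — hence 9999.
    """
    adata, L, cond, anchor, planted = _diffcor_experiment(
        n_cells_per_group, n_genes, n_planted, rho, seed)
    res = _diffcor.differential_correlation(
        L, adata.var_names, anchor, cond, n_perm=n_perm, seed=seed + 1)
    hit_planted = res.loc[res.index.isin(planted), "hit"]
    hit_null = res.loc[~res.index.isin(planted), "hit"]
    return {
        "power": float(hit_planted.mean()),
        "n_planted_tested": int(len(hit_planted)),
        "null_hits": int(hit_null.sum()),
        "mean_abs_delta_planted": float(
            res.loc[res.index.isin(planted), "delta_rho"].abs().mean()),
    }


def diffcor_null_ks(n_cells_per_group: int = 200, n_genes: int = 520,
                    n_perm: int = 1000, seed: int = 0) -> dict:
    """KS distance of null p-values from uniform (random split of one pool)."""
    cfg = SimConfig(n_samples=2, cells_per_sample=n_cells_per_group,
                    n_genes=n_genes, n_celltypes=2,
                    celltype_names=("Lp", "Avd"),
                    base_proportions=(0.5, 0.5),
                    composition_trends=(0.0, 0.0), program_genes=0,
                    markers_per_type=5, batch_assignment=["b0", "b0"],
                    corr_modules=(CorrModule("none", 0.6, 2),),
                    seed=seed)
    adata, truth = simulate_experiment(cfg)
    model = _normalize.fit_normalization(adata)
    L = _normalize.log_normalize(adata.X, model,
                                 batches=adata.obs["batch"].to_numpy())
    rng = np.random.default_rng(seed + 5)
    groups = np.where(rng.random(adata.n_obs) < 0.5, "A", "B")
    anchor = adata.uns["anchor_gene"]
    res = _diffcor.differential_correlation(
        L, adata.var_names, anchor, groups, n_perm=n_perm, seed=seed + 9)
    ks = stats.kstest(res["p"].to_numpy(), "uniform").statistic
    return {"ks_statistic": float(ks), "n_genes_tested": int(len(res))}


def diffcor_exhaustive_check(seed: int = 0) -> dict:
    """Exact agreement of the permutation p with brute-force enumeration.

    A 5+5-cell instance with one gene: the implementation's exhaustive mode
    must equal an independent oracle that loops over label assignments with
    scipy's Spearman directly.
    """
    from itertools import combinations
    rng = np.random.default_rng(seed)
    n = 10
    X = np.column_stack([rng.normal(size=n), rng.normal(size=n)])
    X = np.abs(X) + 0.5  # keep everything "non-zero expressed"
    groups = np.array(["A"] * 5 + ["B"] * 5)

    res = _diffcor.differential_correlation(
        X, ["anchor", "gene"], "anchor", groups, min_nonzero=3,
        exhaustive=True)
    p_impl = float(res.loc["gene", "p"])

    def sp(a, b):
        return stats.spearmanr(a, b).statistic

    obs = sp(X[:5, 0], X[:5, 1]) - sp(X[5:, 0], X[5:, 1])
    count = total = 0
    for combo in combinations(range(n), 5):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        d = sp(X[mask, 0], X[mask, 1]) - sp(X[~mask, 0], X[~mask, 1])
        count += abs(d) >= abs(obs) - 1e-12
        total += 1
    p_oracle = count / total
    return {"p_impl": p_impl, "p_oracle": p_oracle,
            "abs_diff": abs(p_impl - p_oracle)}


# ---------------------------------------------------------------------------
# interactions
# ---------------------------------------------------------------------------

def interaction_planted_run(n_cells_per_type: int = 300, n_genes: int = 200,
                            n_perm: int = 1000, seed: int = 0) -> dict:
    """Significance of a planted Hs -> Avd ligand-receptor axis."""
    cfg = SimConfig(n_samples=3, cells_per_sample=n_cells_per_type * 3,
                    n_genes=n_genes, n_celltypes=3,
                    celltype_names=("Hs", "Avd", "Lp"),
                    base_proportions=(1 / 3, 1 / 3, 1 / 3),
                    composition_trends=(0.0, 0.0, 0.0), program_genes=0,
                    lr_pairs=1, seed=seed)
    adata, truth = simulate_experiment(cfg)
    axis = truth.lr_axes.iloc[0]
    model = _normalize.fit_normalization(adata)
    L = _normalize.log_normalize(adata.X, model,
                                 batches=adata.obs["batch"].to_numpy())
    labels = truth.cells.loc[adata.obs_names, "celltype"].to_numpy()
    pairs = pd.DataFrame({"pair_id": ["planted"], "ligand": [axis["ligand"]],
                          "receptor": [axis["receptor"]]})
    res = _interactions.score_interactions_named(
        L, adata.var_names, labels, pairs, n_perm=n_perm, seed=seed + 3)
    row = res[(res["sender"] == axis["sender"])
              & (res["receiver"] == axis["receiver"])].iloc[0]
    return {"p": float(row["p"]), "fdr": float(row["fdr"]),
            "significant": bool(row["significant"]),
            "sender": axis["sender"], "receiver": axis["receiver"]}


def interaction_null_calibration(n_cells: int = 1200, n_genes: int = 320,
                                 n_pairs: int = 120, n_perm: int = 999,
                                 seed: int = 0) -> dict:
    """p < 0.05 rate over gated tests when cluster labels carry no signal."""
    cfg = SimConfig(n_samples=3, cells_per_sample=n_cells // 3,
                    n_genes=n_genes, n_celltypes=5, program_genes=0,
                    markers_per_type=0,
                    base_proportions=(0.2,) * 5,
                    composition_trends=(0.0,) * 5, seed=seed)
    adata, truth = simulate_experiment(cfg)
    model = _normalize.fit_normalization(adata)
    L = _normalize.log_normalize(adata.X, model,
                                 batches=adata.obs["batch"].to_numpy())
    rng = np.random.default_rng(seed + 11)
    labels = truth.cells.loc[adata.obs_names, "celltype"].to_numpy()
    labels = labels[rng.permutation(labels.size)]  # break any structure
    free = [g for g in adata.var_names
            if not (adata.var.loc[g, ["is_mito", "is_ribo", "is_hb"]].any())]
    lig = free[: n_pairs]
    rec = free[n_pairs: 2 * n_pairs]
    pairs = pd.DataFrame({"pair_id": [f"p{i}" for i in range(n_pairs)],
                          "ligand": lig, "receptor": rec})
    res = _interactions.score_interactions_named(
        L, adata.var_names, labels, pairs, n_perm=n_perm, seed=seed + 13)
    gated = res[res["gated"]]
    return {"rejection_rate": float((gated["p"] < 0.05).mean()),
            "n_gated_tests": int(len(gated))}


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def size_factor_recovery(n_cells: int = 500, n_genes: int = 400,
                         seed: int = 0) -> dict:
    """Correlation of deconvolved size factors with the simulated truth.

    DE-free setting: one sample, identical type profiles, only the log-
    normal cell size factors differ.
    """
    cfg = SimConfig(n_samples=1, cells_per_sample=n_cells, n_genes=n_genes,
                    n_celltypes=2, base_proportions=(0.5, 0.5),
                    composition_trends=(0.0, 0.0), markers_per_type=0,
                    program_genes=0, batch_effect_sd=0.0, seed=seed)
    adata, truth = simulate_experiment(cfg)
    sf = _normalize.pooled_size_factors(adata.X)
    true = truth.cells.loc[adata.obs_names, "size_factor"].to_numpy()
    lib = np.asarray(adata.X.sum(axis=1)).ravel()
    r_pooled = float(np.corrcoef(sf, true)[0, 1])
    r_lib = float(np.corrcoef(lib / lib.mean(), true)[0, 1])
    return {"pearson_r": r_pooled, "library_size_r": r_lib,
            "n_cells": n_cells}
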