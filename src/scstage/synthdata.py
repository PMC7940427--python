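"""Synthetic multi-sample scRNA-seq experiments with known ground truth.

The generator emulates the statistical structure a stage-resolved mammary
tumourigenesis study assumes: each sample carries a latent disease stage
``s`` in [0, 1]; cell-type composition drifts with ``s`` on the logit scale
(one secretory-alveolar-like type expanding from ~2% to ~40% of the tissue,
fibroblast-like types contracting); expression is negative-binomial with
per-cell size factors, multiplicative log-normal per-batch gene effects and
type-specific marker programs; a designated gene program scales its mean
with ``s`` so the pseudo-bulk signal is monotone in stage.  Optional layers
plant condition-specific gene-gene correlation modules around an anchor
gene (via a Gaussian copula), ligand-receptor signalling axes, and the three
artifact classes the QC/doublet stages must remove: cell-pair doublets,
haemoglobin-high contaminant cells and low-mitochondria stripped nuclei.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from scipy import stats

from . import io as scio

__all__ = [
    "ConfigurationError",
    "SimConfig",
    "CorrModule",
    "LRAxis",
    "SyntheticTruth",
    "simulate_experiment",
    "simulate_composition",
    "inject_artifacts",
    "write_fixtures",
    "read_fixtures",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class CorrModule:
    """A set of genes correlated with the anchor gene in one condition."""

    condition: str
    rho: float
    genes: tuple[str, ...] | int = 20  # explicit ids or a count to auto-pick


@dataclass(frozen=True)
class LRAxis:
    """A planted ligand-receptor signalling axis between two cell types."""

    ligand: str
    receptor: str
    sender: str
    receiver: str


_DEFAULT_TYPES = ("Avd", "Fibro 1", "Fibro 2", "Lp", "Hs")


@dataclass
class SimConfig:
    """Parameters of a synthetic experiment.

    Composition defaults mirror the study design being emulated: the first
    type ("Avd") expands from ~2% at s=0 to ~40% at s=1 (logit-linear slope
    3.2), two fibroblast-like types contract, the rest stay flat.
    """

    n_samples: int = 12
    cells_per_sample: int = 2000
    n_genes: int = 1000
    n_celltypes: int = 5
    latent_stages: list[float] | str = "grid"
    stage_jitter: float = 0.0
    celltype_names: tuple[str, ...] | None = None
    base_proportions: tuple[float, ...] | None = None
    composition_trends: tuple[float, ...] | None = None
    dirichlet_concentration: float = 300.0
    n_batches: int = 3
    batch_assignment: list[str] | None = None  # per sample; default round-robin
    batch_effect_sd: float = 0.1
    nb_dispersion: float = 0.1
    size_factor_sd: float = 0.3
    mean_umi: float = 5000.0
    markers_per_type: int = 30
    marker_log2fc: float = 3.0
    program_genes: tuple[str, ...] | int = 50
    program_types: tuple[str, ...] = ("Avd",)
    program_log2fc: float = 2.0
    n_mito: int = 10
    n_ribo: int = 20
    n_hb: int = 5
    mito_fraction: float = 0.08
    hb_baseline_share: float = 2e-5
    doublet_rate: float = 0.05
    doublet_pairing: str = "random"  # or "cross_type"
    rbc_rate: float = 0.02
    nuclei_rate: float = 0.02
    anchor_gene: str | None = None
    corr_gene_mean: float = 8.0
    corr_modules: tuple[CorrModule, ...] = ()
    corr_celltypes: tuple[str, ...] | None = None
    sample_conditions: list[str] | None = None
    lr_pairs: tuple[LRAxis, ...] | int = 0
    lr_log2fc: float = 3.0
    seed: int = 0

    # ---- derived helpers -------------------------------------------------
    def type_names(self) -> tuple[str, ...]:
        if self.celltype_names is not None:
            if len(self.celltype_names) != self.n_celltypes:
                raise ConfigurationError("celltype_names length mismatch")
            return tuple(self.celltype_names)
        names = list(_DEFAULT_TYPES[: self.n_celltypes])
        names += [f"Type {i}" for i in range(len(names), self.n_celltypes)]
        return tuple(names)

    def stages(self) -> np.ndarray:
        if isinstance(self.latent_stages, str):
            if self.latent_stages != "grid":
                raise ConfigurationError(
                    f"unknown latent_stages mode {self.latent_stages!r}")
            if self.n_samples == 1:
                s = np.array([0.5])
            else:
                s = np.linspace(0.0, 1.0, self.n_samples)
            if self.stage_jitter > 0:
                rng = np.random.default_rng([self.seed, 7])
                s = np.clip(s + rng.normal(0, self.stage_jitter, s.size), 0, 1)
            return s
        s = np.asarray(self.latent_stages, dtype=float)
        if s.size != self.n_samples:
            raise ConfigurationError("latent_stages length != n_samples")
        if np.any((s < 0) | (s > 1)):
            raise ConfigurationError("latent stages must lie in [0, 1]")
        return s

    def batches(self) -> list[str]:
        if self.batch_assignment is not None:
            if len(self.batch_assignment) != self.n_samples:
                raise ConfigurationError("batch_assignment length != n_samples")
            return [str(b) for b in self.batch_assignment]
        return [f"b{i % self.n_batches}" for i in range(self.n_samples)]

    def conditions(self) -> list[str]:
        if self.sample_conditions is None:
            return ["A"] * self.n_samples
        if len(self.sample_conditions) != self.n_samples:
            raise ConfigurationError("sample_conditions length != n_samples")
        return [str(c) for c in self.sample_conditions]

    def proportions_trends(self) -> tuple[np.ndarray, np.ndarray]:
        k = self.n_celltypes
        if self.base_proportions is None:
            base = np.full(k, 0.98 / (k - 1))
            base[0] = 0.02
        else:
            base = np.asarray(self.base_proportions, dtype=float)
        if self.composition_trends is None:
            trend = np.zeros(k)
            trend[0] = 3.2
            if k >= 2:
                trend[1] = -1.0
            if k >= 3:
                trend[2] = -0.8
        else:
            trend = np.asarray(self.composition_trends, dtype=float)
        if base.size != k or trend.size != k:
            raise ConfigurationError("proportions/trends length != n_celltypes")
        if np.any(base <= 0) or not np.isclose(base.sum(), 1.0):
            raise ConfigurationError("base proportions must be positive and sum to 1")
        return base, trend

    def validate(self) -> None:
        if self.n_celltypes < 2:
            raise ConfigurationError("need at least 2 cell types")
        if self.n_samples < 1 or self.cells_per_sample < 1 or self.n_genes < 10:
            raise ConfigurationError("degenerate experiment size")
        if self.doublet_rate + self.rbc_rate + self.nuclei_rate >= 0.5:
            raise ConfigurationError("artifact rates must sum to < 0.5")
        if self.doublet_pairing not in ("random", "cross_type"):
            raise ConfigurationError("doublet_pairing must be random|cross_type")
        self.stages()
        self.batches()
        self.conditions()
        self.proportions_trends()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "corr_modules" in raw:
            raw["corr_modules"] = tuple(
                CorrModule(**m) if isinstance(m, dict) else m
                for m in raw["corr_modules"])
        if "lr_pairs" in raw and isinstance(raw["lr_pairs"], list):
            raw["lr_pairs"] = tuple(
                LRAxis(**m) if isinstance(m, dict) else m
                for m in raw["lr_pairs"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, default_flow_style=False)


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated experiment.

    ``cells`` has one row per generated cell (type, artifact label, true
    size factor); ``samples`` carries the latent stage and condition;
    ``genes`` records program/module membership and target correlations;
    ``celltypes`` the true logit-linear abundance slopes; ``lr_axes`` the
    planted signalling axes.
    """

    cells: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.DataFrame
    celltypes: pd.DataFrame
    lr_axes: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(outdir / "truth_cells.csv")
        self.samples.to_csv(outdir / "truth_samples.csv")
        self.genes.to_csv(outdir / "truth_genes.csv")
        self.celltypes.to_csv(outdir / "truth_celltypes.csv")
        self.lr_axes.to_csv(outdir / "truth_lr_axes.csv", index=False)

    @classmethod
    def read(cls, indir: str | Path) -> "SyntheticTruth":
        indir = Path(indir)
        return cls(
            cells=pd.read_csv(indir / "truth_cells.csv", index_col=0),
            samples=pd.read_csv(indir / "truth_samples.csv", index_col=0),
            genes=pd.read_csv(indir / "truth_genes.csv", index_col=0),
            celltypes=pd.read_csv(indir / "truth_celltypes.csv", index_col=0),
            lr_axes=pd.read_csv(indir / "truth_lr_axes.csv"),
        )


# ---------------------------------------------------------------------------
# gene layout
# ---------------------------------------------------------------------------

def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def _resolve_gene_layout(config: SimConfig):
    """Assign marker/program/module/LR/flag genes to disjoint index blocks."""
    n = config.n_genes
    ids = _gene_ids(n)
    n_flag = config.n_mito + config.n_ribo + config.n_hb
    hb_idx = list(range(n - config.n_hb, n))
    mito_idx = list(range(n - config.n_hb - config.n_mito, n - config.n_hb))
    ribo_idx = list(range(n - n_flag, n - config.n_hb - config.n_mito))

    cursor = 0

    def take(count):
        nonlocal cursor
        if cursor + count > n - n_flag:
            raise ConfigurationError("n_genes too small for requested gene sets")
        block = list(range(cursor, cursor + count))
        cursor += count
        return block

    types = config.type_names()
    marker_idx = {t: take(config.markers_per_type) for t in types}

    if isinstance(config.program_genes, int):
        program_idx = take(config.program_genes)
    else:
        program_idx = [ids.index(g) for g in config.program_genes]

    id_of = lambda idx: [ids[i] for i in idx]

    modules = []
    for m in config.corr_modules:
        if isinstance(m.genes, int):
            genes = tuple(id_of(take(m.genes)))
            modules.append(CorrModule(m.condition, m.rho, genes))
        else:
            modules.append(m)

    anchor = config.anchor_gene
    if anchor is None and modules:
        anchor = ids[take(1)[0]]

    if isinstance(config.lr_pairs, int):
        types_cycle = list(types)
        axes = []
        for i in range(config.lr_pairs):
            lig, rec = id_of(take(2))
            sender = types_cycle[i % len(types_cycle)]
            receiver = types_cycle[(i + 1) % len(types_cycle)]
            axes.append(LRAxis(lig, rec, sender, receiver))
        axes = tuple(axes)
    else:
        axes = tuple(config.lr_pairs)

    return dict(ids=ids, mito=mito_idx, ribo=ribo_idx, hb=hb_idx,
                markers=marker_idx, program=program_idx,
                modules=modules, anchor=anchor, lr_axes=axes)


def _baseline_means(config: SimConfig, layout, rng) -> np.ndarray:
    """Per-gene baseline mean counts, normalised to the target cell depth."""
    n = config.n_genes
    mu = rng.lognormal(mean=0.0, sigma=1.2, size=n)
    mu[layout["hb"]] = 0.0
    mu[layout["mito"]] = 0.0
    body = 1.0 - config.mito_fraction - config.hb_baseline_share
    mu *= body * config.mean_umi / mu.sum()
    mu[layout["mito"]] = config.mito_fraction * config.mean_umi / config.n_mito
    mu[layout["hb"]] = config.hb_baseline_share * config.mean_umi / config.n_hb
    return mu


def _type_mean_matrix(config: SimConfig, layout, baseline) -> np.ndarray:
    """(n_types, n_genes) mean matrix at stage s=0, before stage scaling."""
    types = config.type_names()
    M = np.tile(baseline, (len(types), 1))
    for ti, t in enumerate(types):
        M[ti, layout["markers"][t]] *= 2.0 ** config.marker_log2fc
    for axis in layout["lr_axes"]:
        gi = layout["ids"].index(axis.ligand)
        ri = layout["ids"].index(axis.receptor)
        M[types.index(axis.sender), gi] *= 2.0 ** config.lr_log2fc
        M[types.index(axis.receiver), ri] *= 2.0 ** config.lr_log2fc
    # anchor/module genes get a fixed moderate mean so rank correlations are
    # not destroyed by ties at zero
    module_gene_idx = set()
    for m in layout["modules"]:
        module_gene_idx.update(layout["ids"].index(g) for g in m.genes)
    if layout["anchor"] is not None:
        module_gene_idx.add(layout["ids"].index(layout["anchor"]))
    if module_gene_idx:
        M[:, sorted(module_gene_idx)] = config.corr_gene_mean
    return M


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def composition_proportions(config: SimConfig, s: np.ndarray) -> np.ndarray:
    """Expected type proportions per sample: softmax(log base + trend * s)."""
    base, trend = config.proportions_trends()
    logits = np.log(base)[None, :] + trend[None, :] * np.asarray(s)[:, None]
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def simulate_composition(config: SimConfig, rng=None):
    """Draw per-sample type counts from the Dirichlet-multinomial composition model.

    Returns ``(counts, proportions, stages)`` with ``counts`` of shape
    (n_samples, n_celltypes) summing to ``cells_per_sample`` per row.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    s = config.stages()
    expected = composition_proportions(config, s)
    alpha = config.dirichlet_concentration * expected
    props = np.vstack([rng.dirichlet(a) for a in alpha])
    counts = np.vstack([
        rng.multinomial(config.cells_per_sample, p) for p in props])
    return counts, props, s


# ---------------------------------------------------------------------------
# main simulation
# ---------------------------------------------------------------------------

def _nb_draw(rng, mu, dispersion):
    """Negative-binomial draw, mean mu, variance mu + dispersion*mu^2."""
    r = 1.0 / dispersion
    mu = np.maximum(mu, 1e-12)
    return rng.negative_binomial(r, r / (r + mu))


def simulate_experiment(config: SimConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Generate a multi-sample experiment of singlet cells plus its truth.

    Counts are negative-binomial with cell size factors and batch factors;
    composition follows the logit-linear trend with Dirichlet noise; program
    genes scale log-linearly with the sample's latent stage in the program
    types. Same config (including seed) gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    layout = _resolve_gene_layout(config)
    baseline = _baseline_means(config, layout, rng)
    type_mean = _type_mean_matrix(config, layout, baseline)
    types = config.type_names()
    type_counts, props, s = simulate_composition(config, rng)
    batches = config.batches()
    conditions = config.conditions()
    batch_names = sorted(set(batches))
    batch_factor = {
        b: np.exp(rng.normal(0.0, config.batch_effect_sd, config.n_genes))
        for b in batch_names
    }
    disp = config.nb_dispersion

    module_cols: dict[int, list[tuple[int, float]]] = {}  # condition use
    anchor_idx = (layout["ids"].index(layout["anchor"])
                  if layout["anchor"] is not None else None)

    X_blocks, obs_rows, truth_rows = [], [], []
    sf_mean_correction = np.exp(-0.5 * config.size_factor_sd ** 2)
    for si in range(config.n_samples):
        sample = f"s{si:02d}"
        n_cells = config.cells_per_sample
        cell_types = np.repeat(np.arange(config.n_celltypes), type_counts[si])
        rng.shuffle(cell_types)
        sf = rng.lognormal(np.log(sf_mean_correction), config.size_factor_sd,
                           n_cells)
        stage_scale = np.ones(config.n_genes)
        stage_scale[layout["program"]] = 2.0 ** (config.program_log2fc * s[si])
        bf = batch_factor[batches[si]]
        mu = type_mean[cell_types] * stage_scale[None, :] * bf[None, :]
        mu *= sf[:, None]
        counts = _nb_draw(rng, mu, disp)

        # copula overrides for anchor/module genes in this sample's condition
        active = [m for m in layout["modules"]
                  if m.condition == conditions[si]]
        if active and anchor_idx is not None:
            if config.corr_celltypes is None:
                cell_mask = np.ones(n_cells, dtype=bool)
            else:
                keep_t = [types.index(t) for t in config.corr_celltypes]
                cell_mask = np.isin(cell_types, keep_t)
            nm = int(cell_mask.sum())
            if nm > 0:
                f_lat = rng.normal(size=nm)
                gene_idx = [anchor_idx]
                rho_lat = [1.0]
                for m in active:
                    for g in m.genes:
                        gene_idx.append(layout["ids"].index(g))
                        rho_lat.append(2 * np.sin(np.pi * m.rho / 6))
                gene_idx = np.asarray(gene_idx)
                rho_lat = np.asarray(rho_lat)
                eps = rng.normal(size=(nm, gene_idx.size))
                z = rho_lat[None, :] * f_lat[:, None] \
                    + np.sqrt(1 - rho_lat ** 2)[None, :] * eps
                u = stats.norm.cdf(z)
                mu_mod = mu[np.ix_(cell_mask, gene_idx)]
                r = 1.0 / disp
                counts[np.ix_(cell_mask, gene_idx)] = stats.nbinom.ppf(
                    u, r, r / (r + np.maximum(mu_mod, 1e-12))).astype(counts.dtype)

        X_blocks.append(sp.csr_matrix(counts))
        for ci in range(n_cells):
            bc = f"{sample}_c{ci:05d}"
            obs_rows.append((bc, sample, batches[si]))
            truth_rows.append((bc, sample, batches[si], types[cell_types[ci]],
                               "singlet", sf[ci], ""))

    X = sp.vstack(X_blocks, format="csr")
    obs = pd.DataFrame(obs_rows, columns=["barcode", "sample", "batch"]) \
        .set_index("barcode")
    obs.index.name = None

    var = pd.DataFrame(index=layout["ids"])
    var["gene_symbol"] = layout["ids"]
    var["is_mito"] = False
    var["is_ribo"] = False
    var["is_hb"] = False
    var.iloc[layout["mito"], var.columns.get_loc("is_mito")] = True
    var.iloc[layout["ribo"], var.columns.get_loc("is_ribo")] = True
    var.iloc[layout["hb"], var.columns.get_loc("is_hb")] = True
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["anchor_gene"] = layout["anchor"] or ""

    truth = _build_truth(config, layout, truth_rows, s, conditions, batches,
                         props)
    return adata, truth


def _build_truth(config, layout, truth_rows, s, conditions, batches, props):
    types = config.type_names()
    cells = pd.DataFrame(
        truth_rows,
        columns=["barcode", "sample", "batch", "celltype", "artifact",
                 "size_factor", "parents"]).set_index("barcode")
    cells.index.name = None
    samples = pd.DataFrame({
        "sample": [f"s{i:02d}" for i in range(config.n_samples)],
        "stage": s,
        "condition": conditions,
        "batch": batches,
    }).set_index("sample")
    for ti, t in enumerate(types):
        samples[f"prop_{t}"] = props[:, ti]

    genes = pd.DataFrame(index=layout["ids"])
    genes["is_program"] = False
    genes.iloc[layout["program"], genes.columns.get_loc("is_program")] = True
    genes["module_condition"] = ""
    genes["rho_target"] = 0.0
    for m in layout["modules"]:
        for g in m.genes:
            genes.loc[g, "module_condition"] = m.condition
            genes.loc[g, "rho_target"] = m.rho
    conds = sorted({m.condition for m in layout["modules"]})
    if len(conds) == 2:
        rho_by = {c: np.zeros(len(genes)) for c in conds}
        for m in layout["modules"]:
            for g in m.genes:
                rho_by[m.condition][genes.index.get_loc(g)] = m.rho
        genes["true_delta_rho"] = rho_by[conds[0]] - rho_by[conds[1]]
    else:
        genes["true_delta_rho"] = 0.0
    genes["is_anchor"] = genes.index == (layout["anchor"] or "")
    marker_of = np.array([""] * config.n_genes, dtype=object)
    for t, idx in layout["markers"].items():
        marker_of[idx] = t
    genes["marker_of"] = marker_of

    base, trend = config.proportions_trends()
    celltypes = pd.DataFrame({
        "celltype": types,
        "base_proportion": base,
        "true_da_slope": trend,
    }).set_index("celltype")

    lr_axes = pd.DataFrame(
        [(a.ligand, a.receptor, a.sender, a.receiver)
         for a in layout["lr_axes"]],
        columns=["ligand", "receptor", "sender", "receiver"])
    return SyntheticTruth(cells=cells, samples=samples, genes=genes,
                          celltypes=celltypes, lr_axes=lr_axes)


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------

def inject_artifacts(adata: ad.AnnData, truth: SyntheticTruth,
                     config: SimConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Append doublets, RBC-like contaminants and stripped nuclei.

    Doublets are element-wise sums of two random same-sample cells (total
    UMI adds exactly); RBC cells express haemoglobin genes at high mean and
    little else; stripped nuclei lose nearly all mitochondrial transcripts
    (fraction < 0.005) while retaining a distinct nuclear-enriched profile,
    emulating the loss of cytoplasmic RNA.
    """
    if not (truth.cells["artifact"] == "singlet").all():
        raise ConfigurationError("input must contain only singlets")
    rng = np.random.default_rng([config.seed, 2])
    n = adata.n_obs
    n_doub = int(round(config.doublet_rate * n))
    n_rbc = int(round(config.rbc_rate * n))
    n_nuc = int(round(config.nuclei_rate * n))
    if 2 * n_doub + n_nuc > n:
        raise ConfigurationError("artifact rates exceed available cells")
    if n_doub == n_rbc == n_nuc == 0:
        return adata, truth

    X = sp.csr_matrix(adata.X)
    samples = adata.obs["sample"].to_numpy()
    batches = adata.obs["batch"].to_numpy()
    celltype = truth.cells.loc[adata.obs_names, "celltype"].to_numpy()
    hb_idx = np.where(adata.var["is_hb"].to_numpy())[0]
    mito_idx = np.where(adata.var["is_mito"].to_numpy())[0]
    disp = config.nb_dispersion

    new_rows, new_obs, new_truth = [], [], []

    # --- doublets: allocated per sample in proportion to its cells --------
    sample_names = pd.unique(samples)
    sample_sizes = np.array([(samples == s).sum() for s in sample_names])
    per_sample = np.array([int(round(config.doublet_rate * ns))
                           for ns in sample_sizes])
    di = 0
    for sname, k in zip(sample_names, per_sample):
        idx = np.where(samples == sname)[0]
        for _ in range(k):
            if config.doublet_pairing == "cross_type" and \
                    len(np.unique(celltype[idx])) > 1:
                while True:
                    a, b = rng.choice(idx, size=2, replace=False)
                    if celltype[a] != celltype[b]:
                        break
            else:
                a, b = rng.choice(idx, size=2, replace=False)
            row = X[a] + X[b]
            bc = f"{sname}_dbl{di:05d}"
            di += 1
            new_rows.append(row)
            new_obs.append((bc, sname, batches[idx[0]]))
            new_truth.append((bc, sname, batches[idx[0]],
                              f"{celltype[a]}+{celltype[b]}", "doublet",
                              np.nan,
                              f"{adata.obs_names[a]}|{adata.obs_names[b]}"))

    # --- RBC contaminants -------------------------------------------------
    base_profile = np.asarray(X.mean(axis=0)).ravel()
    rbc_mu = 0.02 * base_profile
    rbc_mu[hb_idx] = 0.6 * config.mean_umi / max(len(hb_idx), 1)
    which = rng.integers(0, len(sample_names), n_rbc)
    for ri in range(n_rbc):
        sname = sample_names[which[ri]]
        bidx = batches[np.where(samples == sname)[0][0]]
        counts = _nb_draw(rng, rbc_mu, disp)
        bc = f"{sname}_rbc{ri:05d}"
        new_rows.append(sp.csr_matrix(counts))
        new_obs.append((bc, sname, bidx))
        new_truth.append((bc, sname, bidx, "RBC", "rbc", np.nan, ""))

    # --- stripped nuclei --------------------------------------------------
    # nuclear-retained gene set: a deterministic 10% slice of non-flag genes
    flagged = adata.var[["is_mito", "is_ribo", "is_hb"]].any(axis=1).to_numpy()
    free = np.where(~flagged)[0]
    nuclear_set = free[:: max(len(free) // max(config.n_genes // 10, 1), 1)]
    # stripped nuclei largely lose cytoplasmic identity: profile is the
    # sample-mean profile, depleted of mitochondrial reads, strongly
    # enriched for the nuclear-retained set
    parents = rng.choice(n, size=n_nuc, replace=False)
    sample_profile: dict[str, np.ndarray] = {}
    for ni, pi in enumerate(parents):
        key = samples[pi]
        if key not in sample_profile:
            sample_profile[key] = np.asarray(
                X[samples == key].mean(axis=0)).ravel()
        mu = np.maximum(sample_profile[key].copy(), 0.02)
        mu[mito_idx] *= 0.001
        mu *= 0.15
        mu[nuclear_set] *= 20.0
        counts = _nb_draw(rng, mu, disp)
        sname, bidx = samples[pi], batches[pi]
        bc = f"{sname}_nuc{ni:05d}"
        new_rows.append(sp.csr_matrix(counts))
        new_obs.append((bc, sname, bidx))
        new_truth.append((bc, sname, bidx, "nucleus", "nucleus", np.nan,
                          str(adata.obs_names[pi])))

    X_new = sp.vstack([X] + new_rows, format="csr")
    obs_new = pd.concat([
        adata.obs,
        pd.DataFrame(new_obs, columns=["barcode", "sample", "batch"])
        .set_index("barcode")])
    obs_new.index.name = None
    out = ad.AnnData(X=X_new, obs=obs_new, var=adata.var.copy(),
                     uns=dict(adata.uns))
    cells_new = pd.concat([
        truth.cells,
        pd.DataFrame(new_truth, columns=["barcode", "sample", "batch",
                                         "celltype", "artifact",
                                         "size_factor", "parents"])
        .set_index("barcode")])
    cells_new.index.name = None
    truth_new = SyntheticTruth(cells=cells_new, samples=truth.samples,
                               genes=truth.genes, celltypes=truth.celltypes,
                               lr_axes=truth.lr_axes)
    return out, truth_new


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def write_fixtures(adata: ad.AnnData, truth: SyntheticTruth,
                   outdir: str | Path, overwrite: bool = False) -> None:
    """Emit per-sample MTX triplets, cells.csv and the truth tables."""
    scio.write_experiment(adata, outdir, overwrite=overwrite)
    truth.write(Path(outdir) / "truth")


def read_fixtures(indir: str | Path) -> tuple[ad.AnnData, SyntheticTruth]:
    adata = scio.read_experiment(indir)
    truth = SyntheticTruth.read(Path(indir) / "truth")
    return adata, truth
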