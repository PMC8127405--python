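"""Synthetic data with the statistical structure the scoring method assumes.

The generator emulates the three input legs of the pipeline:

* **Genotypes** — diploid hard calls from paired haplotypes whose alleles are
  thresholded from a latent Gaussian AR(1) process, giving LD that decays
  with base-pair distance; allele frequencies Uniform(0.05, 0.5).
* **SNP-weight sets** — per-gene cis predictors with 1-5 causal variants,
  effect vectors correlated across panels (tissues) at ``cross_tissue_r``,
  and weight files carrying noisy estimates whose error shrinks with the
  panel's training-sample size.
* **Phenotype and GWAS summary statistics** — the phenotype decomposes into
  a component mediated by cis-genetic expression (variance
  ``h2_total * mediated_frac``), direct variant effects
  (``h2_total * (1 - mediated_frac)``) and Gaussian noise; GWAS Z-scores are
  computed by per-variant regression in an independently simulated cohort so
  that sumstats-target independence holds by construction.

One chromosome is labelled "6" and carries a pseudo-MHC block of 10
overlapping genes over a dense high-LD variant block at 28-34 Mb, to
exercise the MHC single-gene / single-variant rules.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .formats import GenotypePanel, GwasSumstats, SnpWeightSet

_GENE_WIDTH = 100_000
_GENE_SPACING = 1_200_000
_MHC_VARIANTS = 40
_MHC_SPAN = (28_000_000, 28_390_000)   # dense block, 10 kb spacing


@dataclass
class SimConfig:
    """Study conditions for the synthetic pipeline.

    Defaults mirror a desk-scale version of the real design: a ~500-sample
    reference (1KG-EUR-sized), a 5000-sample target cohort, a 20 000-sample
    GWAS cohort, two SNP-weight panels with moderately correlated
    (r = 0.6) cis effects, a trait with h2 = 0.5 of which 40% acts through
    cis expression, and half of the genes phenotypically null.
    """
    n_ref: int = 500
    n_target: int = 5000
    n_gwas: int = 20000
    n_chrom: int = 4
    n_genes: int = 40            # non-MHC genes, spread across chromosomes
    n_mhc_genes: int = 10
    variants_per_gene: int = 6
    n_panels: int = 2
    ld_decay: float = 1e-5       # latent AR(1) decay per bp
    h2_total: float = 0.5
    mediated_frac: float = 0.4
    cross_tissue_r: float = 0.6
    prop_null_genes: float = 0.5
    hsq_range: tuple = (0.05, 0.4)
    n_train: int = 300           # weight-panel training sample size
    seed: int = 0

    def __post_init__(self):
        for name in ("h2_total", "mediated_frac", "cross_tissue_r",
                     "prop_null_genes"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class SimData:
    """Everything one simulation run produces."""
    cfg: SimConfig
    ref: GenotypePanel
    target: GenotypePanel
    weight_sets: list
    sumstats: GwasSumstats
    phenotype: pd.DataFrame          # FID, IID, PHENO (target cohort)
    truth: dict
    genes: pd.DataFrame
    variants: pd.DataFrame


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def _chrom_labels(n_chrom: int) -> list[str]:
    # one chromosome is always "6" so the MHC region exists
    labels = [str(c) for c in range(1, n_chrom + 1)]
    if "6" not in labels:
        labels[-1] = "6"
    return labels


def build_layout(cfg: SimConfig, rng: np.random.Generator
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Variant and gene tables. Non-MHC genes are spaced far enough apart
    that their cis windows are effectively LD-independent; the pseudo-MHC
    genes overlap one dense variant block."""
    chroms = _chrom_labels(cfg.n_chrom)
    genes, variants = [], []
    vid = 0
    for g in range(cfg.n_genes):
        chrom = chroms[g % len(chroms)]
        k = g // len(chroms)
        start = 1_000_000 + k * _GENE_SPACING
        if chrom == "6":
            start += 40_000_000   # keep ordinary chr6 genes clear of the MHC
        end = start + _GENE_WIDTH
        gid = f"GENE{g:03d}"
        genes.append({"gene_id": gid, "chrom": chrom, "start": start,
                      "end": end, "is_mhc": False})
        step = _GENE_WIDTH // (cfg.variants_per_gene - 1) \
            if cfg.variants_per_gene > 1 else 0
        for j in range(cfg.variants_per_gene):
            vid += 1
            variants.append({"id": f"rs{vid}", "chrom": chrom,
                             "pos": start + j * step, "gene_id": gid})
    # pseudo-MHC block: overlapping genes over one dense variant run
    lo, hi = _MHC_SPAN
    step = (hi - lo) // (_MHC_VARIANTS - 1)
    mhc_vids = []
    for j in range(_MHC_VARIANTS):
        vid += 1
        variants.append({"id": f"rs{vid}", "chrom": "6", "pos": lo + j * step,
                         "gene_id": "MHC_BLOCK"})
        mhc_vids.append(f"rs{vid}")
    for g in range(cfg.n_mhc_genes):
        start = lo + g * 50_000
        genes.append({"gene_id": f"MHC{g:02d}", "chrom": "6", "start": start,
                      "end": start + 400_000, "is_mhc": True})
    var = pd.DataFrame(variants).sort_values(
        ["chrom", "pos"], kind="stable").reset_index(drop=True)
    var["maf"] = rng.uniform(0.05, 0.5, size=len(var))
    var["a1"], var["a2"] = "A", "G"
    return var, pd.DataFrame(genes)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _draw_calls(var: pd.DataFrame, n: int, ld_decay: float,
                rng: np.random.Generator) -> np.ndarray:
    """Diploid A1 counts from 2n haplotypes under a latent Gaussian AR(1)
    per chromosome (correlation exp(-ld_decay * gap) between neighbours)."""
    calls = np.empty((n, len(var)), dtype=float)
    thresh = stats.norm.ppf(var["maf"].to_numpy())
    for chrom, grp in var.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        m = idx.size
        z = np.empty((2 * n, m))
        z[:, 0] = rng.standard_normal(2 * n)
        gaps = np.diff(pos)
        rho = np.exp(-ld_decay * gaps)
        for j in range(1, m):
            z[:, j] = rho[j - 1] * z[:, j - 1] + \
                np.sqrt(1 - rho[j - 1] ** 2) * rng.standard_normal(2 * n)
        hap = (z < thresh[idx][None, :]).astype(float)
        calls[:, idx] = hap[0::2] + hap[1::2]
    return calls


def _panel(var: pd.DataFrame, calls: np.ndarray, prefix: str
           ) -> GenotypePanel:
    n = calls.shape[0]
    samples = pd.DataFrame({"FID": [f"{prefix}{i}" for i in range(n)],
                            "IID": [f"{prefix}{i}" for i in range(n)]})
    return GenotypePanel(samples,
                         var[["chrom", "id", "pos", "a1", "a2"]].copy(),
                         calls)


# ---------------------------------------------------------------------------
# the simulation
# ---------------------------------------------------------------------------

class Simulation:
    """Deterministic simulation of all pipeline inputs from a SimConfig."""

    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        root = np.random.SeedSequence(cfg.seed)
        keys = ("layout", "ref", "target", "gwas", "effects", "weights",
                "pheno")
        self._rng = {k: np.random.default_rng(s)
                     for k, s in zip(keys, root.spawn(len(keys)))}
        self.variants, self.genes = build_layout(cfg, self._rng["layout"])
        self._draw_effects()
        self._cohorts: dict[str, GenotypePanel] = {}

    # -- genotypes ---------------------------------------------------------
    def cohort(self, name: str) -> GenotypePanel:
        if name not in self._cohorts:
            n = {"ref": self.cfg.n_ref, "target": self.cfg.n_target,
                 "gwas": self.cfg.n_gwas}[name]
            calls = _draw_calls(self.variants, n, self.cfg.ld_decay,
                                self._rng[name])
            self._cohorts[name] = _panel(self.variants, calls,
                                         prefix=name[0].upper())
        return self._cohorts[name]

    def simulate_genotypes(self) -> tuple[GenotypePanel, GenotypePanel]:
        return self.cohort("ref"), self.cohort("target")

    # -- cis effects -------------------------------------------------------
    def _draw_effects(self) -> None:
        cfg, rng = self.cfg, self._rng["effects"]
        var_by_gene = {g: grp.index.to_numpy()
                       for g, grp in self.variants.groupby("gene_id")}
        mhc_pool = var_by_gene.get("MHC_BLOCK", np.array([], dtype=int))
        self.cis: dict[str, dict] = {}
        r = cfg.cross_tissue_r
        for _, gene in self.genes.iterrows():
            gid = gene["gene_id"]
            if gene["is_mhc"]:
                pool = mhc_pool
            else:
                pool = var_by_gene[gid]
            k = int(rng.integers(1, min(5, pool.size) + 1))
            causal = np.sort(rng.choice(pool, size=k, replace=False))
            shared = rng.standard_normal(k)
            betas = []
            for _ in range(cfg.n_panels):
                own = rng.standard_normal(k)
                betas.append(np.sqrt(r) * shared + np.sqrt(1 - r) * own)
            h2 = rng.uniform(*cfg.hsq_range)
            self.cis[gid] = {"causal": causal, "betas": betas, "h2": h2}
        # phenotype-level gene effects (panel 0 is the causal tissue)
        n_gene = len(self.genes)
        null = self._rng["effects"].random(n_gene) < cfg.prop_null_genes
        gamma = np.where(null, 0.0, self._rng["effects"].standard_normal(n_gene))
        self.gene_gamma = pd.Series(gamma, index=self.genes["gene_id"].to_numpy())
        # direct (non-mediated) variant effects on a random half of variants
        m = len(self.variants)
        direct_mask = self._rng["effects"].random(m) < 0.5
        delta = np.where(direct_mask,
                         self._rng["effects"].standard_normal(m), 0.0)
        self.direct_delta = delta

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        return (X - mu) / sd

    def genetic_expression(self, panel: GenotypePanel, tissue: int
                           ) -> pd.DataFrame:
        """Cis-genetic component of expression (no environmental noise),
        scaled so its variance is the gene's cis-h2."""
        Xs = self._standardize(panel.calls)
        out = {}
        for gid, info in self.cis.items():
            g = Xs[:, info["causal"]] @ info["betas"][tissue]
            sd = g.std()
            if sd > 0:
                g = g * (np.sqrt(info["h2"]) / sd)
            out[gid] = g
        return pd.DataFrame(out)

    # -- weight sets -------------------------------------------------------
    def simulate_weight_sets(self) -> tuple[list[SnpWeightSet],
                                            dict[str, pd.DataFrame]]:
        """Per-panel weight sets with training-noise-corrupted betas, plus
        the true (noise-free) genetic expression of the target cohort."""
        cfg = self.cfg
        rng = self._rng["weights"]
        target = self.cohort("target")
        Xsd = np.nanstd(self.cohort("ref").calls, axis=0)
        Xsd[Xsd == 0] = 1.0
        sets = []
        for p in range(cfg.n_panels):
            feats, weights = [], {}
            for gi, (_, gene) in enumerate(self.genes.iterrows()):
                gid = gene["gene_id"]
                info = self.cis[gid]
                h2 = info["h2"]
                beta_std = info["betas"][p]
                scale = np.sqrt(h2) / max(np.linalg.norm(beta_std), 1e-12)
                beta_std = beta_std * scale
                noise = rng.standard_normal(beta_std.size) * \
                    np.sqrt((1 - h2) / cfg.n_train)
                beta_hat_std = beta_std + noise
                causal = info["causal"]
                w = self.variants.iloc[causal][
                    ["id", "a1", "a2", "chrom", "pos"]].copy()
                # convert standardized-scale effects to allele-count scale
                w["beta"] = beta_hat_std / Xsd[causal]
                fid = f"P{p}_{gid}"
                h2_hat = max(h2 + rng.standard_normal() *
                             np.sqrt(2 / cfg.n_train), 1e-4)
                # plumbing-grade significance of the cis-h2 estimate
                h2_p = float(np.clip(stats.chi2.sf(cfg.n_train * h2_hat, 1),
                                     1e-300, 1.0))
                feats.append({"feature_id": fid, "gene_id": gid,
                              "chrom": gene["chrom"], "start": gene["start"],
                              "end": gene["end"], "hsq": h2_hat,
                              "hsq_p": h2_p})
                weights[fid] = w.reset_index(drop=True)
            sets.append(SnpWeightSet(f"panel{p}", pd.DataFrame(feats),
                                     weights, n_train=cfg.n_train))
        true_expr = {f"panel{p}": self.genetic_expression(target, p)
                     for p in range(cfg.n_panels)}
        return sets, true_expr

    # -- phenotype + GWAS --------------------------------------------------
    def _phenotype(self, panel: GenotypePanel, rng: np.random.Generator
                   ) -> np.ndarray:
        cfg = self.cfg
        G = self.genetic_expression(panel, tissue=0)
        mediated = G.to_numpy() @ self.gene_gamma.to_numpy()
        Xs = self._standardize(panel.calls)
        direct = Xs @ self.direct_delta

        def _scaled(v, target_var):
            sd = v.std()
            if sd == 0 or target_var == 0:
                return np.zeros_like(v)
            return v * np.sqrt(target_var) / sd

        mediated = _scaled(mediated, cfg.h2_total * cfg.mediated_frac)
        direct = _scaled(direct, cfg.h2_total * (1 - cfg.mediated_frac))
        noise = rng.standard_normal(panel.n_samples) * \
            np.sqrt(max(1 - cfg.h2_total, 0))
        return mediated + direct + noise

    def simulate_phenotype_and_gwas(self) -> tuple[pd.DataFrame, GwasSumstats]:
        cfg = self.cfg
        target = self.cohort("target")
        y_t = self._phenotype(target, self._rng["pheno"])
        pheno = target.samples.copy()
        pheno["PHENO"] = y_t

        gwas_panel = self.cohort("gwas")
        y_g = self._phenotype(gwas_panel, self._rng["pheno"])
        Xs = self._standardize(gwas_panel.calls)
        ys = (y_g - y_g.mean()) / y_g.std()
        z = (Xs.T @ ys) / np.sqrt(cfg.n_gwas)
        tab = pd.DataFrame({"SNP": self.variants["id"],
                            "A1": self.variants["a1"],
                            "A2": self.variants["a2"],
                            "N": cfg.n_gwas, "Z": z})
        # free the largest cohort once the sumstats exist
        del self._cohorts["gwas"]
        return pheno, GwasSumstats(tab.reset_index(drop=True))

    def truth(self) -> dict:
        return {
            "config": asdict(self.cfg),
            "mediating_genes": [g for g in self.gene_gamma.index
                                if self.gene_gamma[g] != 0],
            "null_genes": [g for g in self.gene_gamma.index
                           if self.gene_gamma[g] == 0],
            "gene_effects": {g: float(v) for g, v in self.gene_gamma.items()},
            "cis_h2": {g: float(info["h2"]) for g, info in self.cis.items()},
            "causal_variants": {g: [self.variants["id"].iloc[i]
                                    for i in info["causal"]]
                                for g, info in self.cis.items()},
        }


def simulate_all(cfg: SimConfig) -> SimData:
    sim = Simulation(cfg)
    ref, target = sim.simulate_genotypes()
    weight_sets, _ = sim.simulate_weight_sets()
    pheno, sumstats = sim.simulate_phenotype_and_gwas()
    return SimData(cfg, ref, target, weight_sets, sumstats, pheno,
                   sim.truth(), sim.genes, sim.variants)


def synthetic_pp4(sim: SimData, assocs: pd.DataFrame,
                  seed: int = 0) -> pd.DataFrame:
    """Synthetic colocalization posterior: genes simulated as truly
    mediating receive high PP4, null genes low PP4. A stand-in for coloc
    output, used to exercise the coloc-restricted score path."""
    rng = np.random.default_rng(seed)
    mediating = set(sim.truth["mediating_genes"])
    pp4 = np.where(assocs["gene_id"].isin(mediating),
                   rng.uniform(0.85, 1.0, len(assocs)),
                   rng.uniform(0.0, 0.5, len(assocs)))
    return pd.DataFrame({"panel_id": assocs["panel_id"],
                         "feature_id": assocs["feature_id"], "pp4": pp4})


def write_fixture(data: SimData, outdir: str) -> dict:
    """Write the simulation as on-disk pipeline inputs (PLINK genotypes,
    weight-set directories, munged sumstats, phenotype table, HapMap3-style
    id list and truth.json). Returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {"ref": os.path.join(outdir, "ref"),
             "target": os.path.join(outdir, "target"),
             "sumstats": os.path.join(outdir, "sumstats.tsv"),
             "pheno": os.path.join(outdir, "pheno.tsv"),
             "hm3": os.path.join(outdir, "hm3.txt"),
             "weights": os.path.join(outdir, "weights"),
             "truth": os.path.join(outdir, "truth.json")}
    data.ref.to_plink(paths["ref"])
    data.target.to_plink(paths["target"])
    data.sumstats.table.to_csv(paths["sumstats"], sep="\t", index=False)
    data.phenotype.to_csv(paths["pheno"], sep="\t", index=False)
    pd.Series(data.variants["id"]).to_csv(paths["hm3"], index=False,
                                          header=False)
    for ws in data.weight_sets:
        ws.to_directory(os.path.join(paths["weights"], ws.panel_id))
    with open(paths["truth"], "w") as fh:
        json.dump(data.truth, fh, indent=1)
    return paths
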