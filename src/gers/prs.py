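"""Baseline polygenic risk scores: P-value thresholding with LD-based
clumping (pT+clump), the MHC single-variant rule, gene-region-restricted
scores, and ingestion of externally computed score files.

Scores are computed on the GWAS Z scale (beta := Z); the correlation-based
evaluation downstream is invariant to any per-variant rescaling that is
constant across individuals, so the effect-size scale is immaterial and this
convention avoids carrying per-variant sample sizes around.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .formats import GenotypePanel, GwasSumstats
from .scoring import MHC_REGION, ScoreMatrix

#: default GWAS P-value thresholds
PRS_THRESHOLDS = (1e-8, 1e-6, 1e-4, 1e-2, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0)


@dataclass
class PrsSpec:
    """pT+clump parameters: clumping R^2 0.1 within 250 kb, MHC
    single-variant rule on by default."""
    r2_max: float = 0.1
    window_bp: int = 250_000
    thresholds: tuple = PRS_THRESHOLDS
    mhc_rule: str = "single_variant"          # or "none"
    region_restrict: pd.DataFrame | None = None  # chrom, start, end
    flank_bp: int = 500_000

    def __post_init__(self):
        if not (0 < self.r2_max < 1):
            raise ValueError("r2_max must lie in (0, 1)")
        if any(not (0 < t <= 1) for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1]")


def _gwas_p(z: np.ndarray) -> np.ndarray:
    return 2 * stats.norm.sf(np.abs(z))


def clump_variants(sumstats: GwasSumstats, ref: GenotypePanel,
                   spec: PrsSpec) -> list[str]:
    """Greedy LD clumping by ascending GWAS P.

    A variant is removed when its reference-genotype R^2 with a retained
    variant exceeds ``spec.r2_max`` and it lies within ``spec.window_bp``
    (point-to-point) of it. With the single-variant MHC rule, only the most
    significant variant in chr6:28-34 Mb is retained.
    """
    tab = sumstats.table.merge(
        ref.variants[["id", "chrom", "pos"]], left_on="SNP", right_on="id")
    tab["p"] = _gwas_p(tab["Z"].to_numpy())
    ids = pd.Index(ref.variants["id"])

    if spec.mhc_rule == "single_variant":
        chrom, lo, hi = MHC_REGION
        in_mhc = ((tab["chrom"].astype(str) == str(chrom))
                  & (tab["pos"] >= lo) & (tab["pos"] <= hi))
        if in_mhc.sum() > 1:
            mhc_best = tab[in_mhc].sort_values(["p", "SNP"]).index[0]
            keep = ~in_mhc
            keep.loc[mhc_best] = True
            tab = tab[keep]

    tab = tab.sort_values(["p", "SNP"])
    X = ref.calls.astype(float)
    mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mean, X)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    n = X.shape[0]

    kept: list[str] = []
    kept_pos: list[tuple[str, int, int]] = []   # (chrom, pos, column)
    for _, row in tab.iterrows():
        j = ids.get_loc(row["SNP"])
        drop = False
        for chrom_k, pos_k, k in kept_pos:
            if chrom_k != str(row["chrom"]):
                continue
            if abs(pos_k - row["pos"]) > spec.window_bp:
                continue
            r = float(Xs[:, j] @ Xs[:, k]) / n
            if r * r > spec.r2_max:
                drop = True
                break
        if not drop:
            kept.append(row["SNP"])
            kept_pos.append((str(row["chrom"]), int(row["pos"]), j))
    return kept


def restrict_to_gene_regions(retained: list[str], ref: GenotypePanel,
                             gene_intervals: pd.DataFrame,
                             flank_bp: int = 500_000) -> list[str]:
    """Keep retained variants lying within ``flank_bp`` of any gene interval
    (columns chrom, start, end; 1-based inclusive)."""
    if len(gene_intervals) == 0:
        return []
    var = ref.variants.set_index("id")
    out = []
    by_chrom = {str(c): g for c, g in gene_intervals.groupby(
        gene_intervals["chrom"].astype(str))}
    for vid in retained:
        chrom = str(var.at[vid, "chrom"])
        pos = int(var.at[vid, "pos"])
        genes = by_chrom.get(chrom)
        if genes is None:
            continue
        near = ((genes["start"] - flank_bp <= pos)
                & (pos <= genes["end"] + flank_bp))
        if near.any():
            out.append(vid)
    return out


def compute_prs(panel: GenotypePanel, sumstats: GwasSumstats,
                retained: list[str], thresholds=PRS_THRESHOLDS,
                ref: GenotypePanel | None = None,
                column_prefix: str = "prs") -> ScoreMatrix:
    """PRS columns per threshold: sum over retained variants with p <= t of
    allele count times Z, reference-standardized when ``ref`` is given.

    Missing genotypes are mean-imputed from the reference allele frequency.
    """
    tab = sumstats.table.set_index("SNP").loc[retained]
    p = _gwas_p(tab["Z"].to_numpy())
    z = tab["Z"].to_numpy()

    def _dosages(pnl: GenotypePanel) -> np.ndarray:
        sub = pnl.subset_variants(retained)
        X = sub.calls.astype(float)
        if ref is not None:
            freq = pd.Series(ref.allele_freq(),
                             index=pd.Index(ref.variants["id"]))
            fill = 2.0 * freq.reindex(retained).to_numpy()
        else:
            fill = np.nanmean(X, axis=0)  # 2 x own allele frequency
        return np.where(np.isnan(X), fill[None, :], X)

    Xt = _dosages(panel)
    Xr = _dosages(ref) if ref is not None else None
    cols, meta = {}, {}
    for t in sorted(thresholds, reverse=True):
        sel = p <= t
        if not sel.any():
            continue
        raw = Xt[:, sel] @ z[sel]
        name = f"{column_prefix}.p{t:g}"
        if Xr is not None:
            raw_ref = Xr[:, sel] @ z[sel]
            mu, sd = raw_ref.mean(), raw_ref.std(ddof=1)
            if sd <= 1e-12:
                continue
            raw = (raw - mu) / sd
            meta[name] = {"threshold": t, "n_variants": int(sel.sum()),
                          "ref_mean": float(mu), "ref_sd": float(sd)}
        else:
            meta[name] = {"threshold": t, "n_variants": int(sel.sum()),
                          "ref_standardized": False}
        cols[name] = raw
    if not cols:
        raise ValueError("no variant passes the loosest threshold")
    return ScoreMatrix(panel.samples.copy(), pd.DataFrame(cols), meta)


def ingest_external_scores(path: str, ref_ids: pd.DataFrame | None = None
                           ) -> ScoreMatrix:
    """Read an FID/IID-keyed score table (e.g. PRScs output).

    When reference-sample rows (``ref_ids``: FID, IID) are present in the
    table, columns are re-standardized against those rows and the reference
    rows are dropped; otherwise values are kept as-is and flagged
    unstandardized.
    """
    tab = pd.read_csv(path, sep=r"\s+", dtype={"FID": str, "IID": str})
    for col in ("FID", "IID"):
        if col not in tab:
            raise KeyError(f"external score file lacks {col} column")
    score_cols = [c for c in tab.columns if c not in ("FID", "IID")]
    meta = {}
    if ref_ids is not None:
        key = tab["FID"] + "\t" + tab["IID"]
        ref_key = set(ref_ids["FID"].astype(str) + "\t" + ref_ids["IID"].astype(str))
        is_ref = key.isin(ref_key)
        if is_ref.any():
            mu = tab.loc[is_ref, score_cols].mean()
            sd = tab.loc[is_ref, score_cols].std(ddof=1)
            tab[score_cols] = (tab[score_cols] - mu) / sd
            tab = tab[~is_ref]
            meta = {c: {"ref_standardized": True} for c in score_cols}
    if not meta:
        meta = {c: {"ref_standardized": False} for c in score_cols}
    tab = tab.sort_values(["FID", "IID"]).reset_index(drop=True)
    return ScoreMatrix(tab[["FID", "IID"]], tab[score_cols], meta)
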