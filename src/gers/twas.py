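"""TWAS association statistics from GWAS Z-scores, SNP-weights and
reference-panel LD.

For a feature with weight vector :math:`w` over its cis variants, GWAS
Z-scores :math:`z` and reference LD matrix :math:`V`, the weighted-burden
TWAS statistic is

.. math:: z_{TWAS} = \\frac{w^\\top z}{\\sqrt{w^\\top V w}}

which is standard normal under the null of no association between the
cis-genetic component of expression and the trait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formats import GenotypePanel, GwasSumstats, SnpWeightSet

LD_RIDGE = 1e-3  # diagonal ridge stabilising near-singular cis blocks


@dataclass
class LdBlock:
    variant_ids: list[str]
    corr: np.ndarray


class NonImputableFeature(ValueError):
    """The quadratic form w'Vw is numerically zero — expression for this
    feature cannot be imputed from the harmonized variants."""


def ld_matrix(ref: GenotypePanel, variant_ids, ridge: float = LD_RIDGE) -> LdBlock:
    """Pearson LD among ``variant_ids`` in the reference panel.

    Missing genotypes are mean-imputed before correlation; zero-variance
    variants are excluded with a warning. A small ridge is added to the
    diagonal to keep near-singular blocks positive definite.
    """
    if ref.n_samples < 2:
        raise ValueError("LD estimation needs at least 2 reference samples")
    sub = ref.subset_variants(list(variant_ids))
    X = sub.calls.astype(float)
    mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mean, X)
    sd = X.std(axis=0)
    nonzero = sd > 0
    if not nonzero.all():
        import warnings
        warnings.warn(f"{(~nonzero).sum()} zero-variance variants excluded "
                      "from LD block", stacklevel=2)
    X = X[:, nonzero]
    ids = [v for v, keep in zip(variant_ids, nonzero) if keep]
    corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(corr)
    corr = corr + ridge * np.eye(corr.shape[0])
    return LdBlock(ids, corr)


def twas_z(w: np.ndarray, z: np.ndarray, ld: LdBlock,
           tol: float = 1e-12) -> tuple[float, float]:
    """Weighted-burden TWAS Z and its two-sided normal P.

    ``w``, ``z`` and ``ld.corr`` must be aligned on the same ordered variants.
    """
    w = np.asarray(w, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (w.shape == z.shape and ld.corr.shape == (w.size, w.size)):
        raise ValueError("w, z and LD block are not aligned")
    denom = float(w @ ld.corr @ w)
    if denom <= tol:
        raise NonImputableFeature("w'Vw <= 0: feature not imputable")
    zt = float(w @ z) / np.sqrt(denom)
    return zt, float(2 * stats.norm.sf(abs(zt)))


def run_twas(harm_sumstats: GwasSumstats, weight_set: SnpWeightSet,
             ref: GenotypePanel) -> pd.DataFrame:
    """TWAS over every feature of one SNP-weight set.

    Returns a table (panel_id, feature_id, gene_id, chrom, start, end,
    z_twas, p_twas, n_weight_variants); features whose LD quadratic form is
    degenerate are skipped and recorded with NaN statistics.
    """
    ztab = harm_sumstats.table.set_index("SNP")["Z"]
    rows = []
    for _, feat in weight_set.features.iterrows():
        w = weight_set.weights[feat["feature_id"]]
        ids = list(w["id"])
        rec = {"panel_id": weight_set.panel_id,
               "feature_id": feat["feature_id"], "gene_id": feat["gene_id"],
               "chrom": feat["chrom"], "start": feat["start"],
               "end": feat["end"], "hsq": feat.get("hsq", np.nan),
               "hsq_p": feat.get("hsq_p", np.nan),
               "n_weight_variants": len(ids)}
        try:
            ld = ld_matrix(ref, ids)
            keep = w["id"].isin(ld.variant_ids).to_numpy()
            zt, pt = twas_z(w["beta"].to_numpy()[keep],
                            ztab.loc[ld.variant_ids].to_numpy(), ld)
            rec.update(z_twas=zt, p_twas=pt)
        except (NonImputableFeature, KeyError):
            rec.update(z_twas=np.nan, p_twas=np.nan)
        rows.append(rec)
    return pd.DataFrame(rows)


def attach_pp4(assocs: pd.DataFrame, pp4: pd.DataFrame) -> pd.DataFrame:
    """Join a per-feature colocalization posterior (PP4) column.

    ``pp4``: DataFrame with panel_id, feature_id, pp4 in [0, 1].
    """
    out = assocs.merge(pp4[["panel_id", "feature_id", "pp4"]],
                       on=["panel_id", "feature_id"], how="left")
    bad = out["pp4"].dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise ValueError("PP4 must lie in [0, 1]")
    return out


def filter_coloc(assocs: pd.DataFrame, pp4_min: float = 0.8,
                 coloc_p: float = 0.05) -> pd.DataFrame:
    """Features with colocalization evidence: PP4 strictly above ``pp4_min``.

    Colocalization is only run for features with TWAS P below ``coloc_p``, so
    features without a PP4 (including those with p_twas >= coloc_p) are
    excluded from coloc-restricted scores.
    """
    if "pp4" not in assocs:
        raise ValueError("assocs lack a pp4 column; attach_pp4 first")
    missing_needed = assocs["pp4"].isna() & (assocs["p_twas"] < coloc_p)
    if missing_needed.any():
        raise ValueError("PP4 missing for features with TWAS P < "
                         f"{coloc_p}; colocalization input incomplete")
    keep = assocs["pp4"].notna() & (assocs["pp4"] > pp4_min)
    return assocs[keep].reset_index(drop=True)


def flag_tissue_specific(assocs: pd.DataFrame, blood_panel_ids,
                         ref_expression: dict[str, pd.DataFrame],
                         hsq_p_max: float = 0.01,
                         r2_max: float = 0.01) -> pd.DataFrame:
    """Flag features whose expression signal is specific to their own tissue
    class (blood vs non-blood).

    A non-blood feature is tissue-specific iff its gene has no feature with
    significant cis-heritability (hsq_p < ``hsq_p_max``) in any blood panel,
    OR its reference predicted expression has squared correlation below
    ``r2_max`` with every blood-panel feature of the same gene. Blood-panel
    features are flagged by the symmetric criterion against non-blood panels.

    ``ref_expression``: panel_id -> reference predicted-expression DataFrame
    (columns = feature ids, standardized).
    """
    blood = set(blood_panel_ids)
    out = assocs.copy()
    is_blood = out["panel_id"].isin(blood)

    def heritable_genes(panel_ids) -> set:
        sel = out["panel_id"].isin(panel_ids) & (out["hsq_p"] < hsq_p_max)
        return set(out.loc[sel, "gene_id"])

    def gene_features(panel_ids):
        sel = out["panel_id"].isin(panel_ids)
        return out.loc[sel, ["panel_id", "feature_id", "gene_id"]]

    blood_herit = heritable_genes(blood)
    nonblood_panels = set(out["panel_id"]) - blood
    nonblood_herit = heritable_genes(nonblood_panels)
    blood_feats = gene_features(blood)
    nonblood_feats = gene_features(nonblood_panels)

    flags, max_r2s = [], []
    for _, row in out.iterrows():
        other_herit = blood_herit if row["panel_id"] not in blood else nonblood_herit
        other_feats = blood_feats if row["panel_id"] not in blood else nonblood_feats
        max_r2 = 0.0
        same_gene = other_feats[other_feats["gene_id"] == row["gene_id"]]
        expr = ref_expression.get(row["panel_id"])
        if expr is not None and row["feature_id"] in expr:
            x = expr[row["feature_id"]].to_numpy()
            for _, o in same_gene.iterrows():
                oexpr = ref_expression.get(o["panel_id"])
                if oexpr is None or o["feature_id"] not in oexpr:
                    continue
                y = oexpr[o["feature_id"]].to_numpy()
                if x.std() > 0 and y.std() > 0:
                    max_r2 = max(max_r2, float(np.corrcoef(x, y)[0, 1] ** 2))
        specific = (row["gene_id"] not in other_herit) or (max_r2 < r2_max)
        flags.append(bool(specific))
        max_r2s.append(max_r2)
    out["tissue_specific"] = flags
    out["max_r2_vs_other_class"] = max_r2s
    return out
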