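"""Imputation of the cis-heritable component of gene expression.

Predicted expression for individual *i* at feature *g* is the weight-file
linear predictor over the feature's retained variants,

.. math:: \\mathrm{GeneExp}_{ig} = \\sum_j X_{ij} \\beta_{gj},

with missing allele counts mean-imputed from the reference allele frequency
(2f). Predicted expression is then centred and scaled per feature by its
mean and standard deviation in the reference panel, so target-sample
properties never enter the scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import GenotypePanel, SnpWeightSet


@dataclass
class ExpressionMatrix:
    """Samples x features predicted expression for one SNP-weight set."""
    samples: pd.DataFrame          # FID, IID
    panel_id: str
    values: pd.DataFrame           # columns = feature ids
    ref_mean: pd.Series | None = None
    ref_sd: pd.Series | None = None
    standardized: bool = False

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def to_table(self) -> pd.DataFrame:
        return pd.concat([self.samples.reset_index(drop=True),
                          self.values.reset_index(drop=True)], axis=1)


def impute_expression(panel: GenotypePanel, weights: SnpWeightSet,
                      ref_freq: pd.Series | None = None) -> ExpressionMatrix:
    """Raw predicted expression ``X @ beta`` per feature.

    ``ref_freq``: per-variant A1 allele frequency from the *reference* panel,
    used to mean-impute missing calls as 2f (falls back to the scored panel's
    own frequency when absent — only appropriate for the reference itself).
    Features with no retained weight variants are dropped.
    """
    ids = pd.Index(panel.variants["id"])
    if ref_freq is None:
        ref_freq = pd.Series(panel.allele_freq(), index=ids)
    fill = (2.0 * ref_freq.reindex(ids)).to_numpy()
    X = panel.calls.astype(float)
    X = np.where(np.isnan(X), fill[None, :], X)

    cols, names = [], []
    for fid in weights.features["feature_id"]:
        w = weights.weights[fid]
        idx = ids.get_indexer(w["id"])
        keep = idx >= 0
        if not keep.any():
            continue
        cols.append(X[:, idx[keep]] @ w["beta"].to_numpy()[keep])
        names.append(fid)
    values = pd.DataFrame(np.column_stack(cols) if cols else
                          np.empty((panel.n_samples, 0)), columns=names)
    return ExpressionMatrix(panel.samples.copy(), weights.panel_id, values)


def standardize_by_reference(raw: ExpressionMatrix, raw_ref: ExpressionMatrix,
                             sd_tol: float = 1e-8
                             ) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Centre/scale target and reference expression by the reference panel's
    per-feature mean and SD (ddof=1); degenerate features (ref SD below
    ``sd_tol``) are dropped from both."""
    common = [f for f in raw.values.columns if f in raw_ref.values.columns]
    if len(common) != len(raw.values.columns) or \
            len(common) != len(raw_ref.values.columns):
        raise ValueError("target and reference expression feature mismatch")
    mean = raw_ref.values[common].mean(axis=0)
    sd = raw_ref.values[common].std(axis=0, ddof=1)
    keep = sd > sd_tol
    common = [f for f in common if keep[f]]
    mean, sd = mean[common], sd[common]

    def _std(m: ExpressionMatrix) -> ExpressionMatrix:
        vals = (m.values[common] - mean) / sd
        return ExpressionMatrix(m.samples.copy(), m.panel_id, vals,
                                ref_mean=mean.copy(), ref_sd=sd.copy(),
                                standardized=True)

    return _std(raw), _std(raw_ref)


def impute_and_standardize(target: GenotypePanel, ref: GenotypePanel,
                           weights: SnpWeightSet
                           ) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Convenience: impute expression on target and reference, then
    reference-standardize both."""
    freq = pd.Series(ref.allele_freq(), index=pd.Index(ref.variants["id"]))
    raw_t = impute_expression(target, weights, ref_freq=freq)
    raw_r = impute_expression(ref, weights, ref_freq=freq)
    return standardize_by_reference(raw_t, raw_r)


def write_expression(expr: ExpressionMatrix, path: str) -> None:
    expr.to_table().to_csv(path, sep="\t", index=False)


def write_score_file(weights: SnpWeightSet, path: str) -> None:
    """PLINK-style score file: variant id, effect allele, one beta column per
    feature (zeros where a variant does not enter a feature)."""
    all_vars: dict[str, str] = {}
    for fid in weights.features["feature_id"]:
        for _, r in weights.weights[fid].iterrows():
            all_vars.setdefault(r["id"], r["a1"])
    out = pd.DataFrame({"id": list(all_vars), "a1": list(all_vars.values())})
    for fid in weights.features["feature_id"]:
        w = weights.weights[fid].set_index("id")["beta"]
        out[fid] = w.reindex(out["id"]).fillna(0.0).to_numpy()
    out.to_csv(path, sep="\t", index=False)
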