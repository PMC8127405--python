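"""Gene expression risk scores (GeRS).

A GeRS is the TWAS-Z-weighted sum of an individual's reference-standardized
predicted expression over the features passing a TWAS P-value threshold,

.. math:: \\mathrm{GeRS}_i = \\sum_g \\mathrm{GeneExp}_{ig} \\, Z_g,

built per SNP-weight set after (i) reducing the MHC region to its single most
significant feature and (ii) greedily clumping features whose reference
predicted expression is nearly collinear (R^2 > 0.9 within 500 kb of the lead
gene's boundaries). Final score columns are centred and scaled by their mean
and SD in the reference sample.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .impute import ExpressionMatrix
from .twas import filter_coloc

#: nested TWAS P-value thresholds used to select features
GERS_THRESHOLDS = (1.0, 5e-1, 1e-1, 5e-2, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6)

#: MHC region: chromosome 6, 28-34 Mb
MHC_REGION = ("6", 28_000_000, 34_000_000)


class EmptyScoreError(ValueError):
    """No feature passes even the loosest threshold."""


@dataclass
class ClumpResult:
    kept: list[str]                 # ordered, lead-first
    removed: dict[str, str]         # removed feature -> lead feature


@dataclass
class ScoreMatrix:
    """Individuals x named score columns, reference-standardized."""
    samples: pd.DataFrame           # FID, IID
    values: pd.DataFrame            # columns = score names
    meta: dict[str, dict] = field(default_factory=dict)

    def to_table(self) -> pd.DataFrame:
        return pd.concat([self.samples.reset_index(drop=True),
                          self.values.reset_index(drop=True)], axis=1)

    def write(self, prefix: str) -> None:
        self.to_table().to_csv(prefix + ".score.tsv", sep="\t", index=False)
        with open(prefix + ".score.json", "w") as fh:
            json.dump(self.meta, fh, indent=1, default=str)

    @classmethod
    def read(cls, prefix: str) -> "ScoreMatrix":
        tab = pd.read_csv(prefix + ".score.tsv", sep="\t",
                          dtype={"FID": str, "IID": str})
        try:
            with open(prefix + ".score.json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            meta = {}
        return cls(tab[["FID", "IID"]], tab.drop(columns=["FID", "IID"]), meta)

    def hstack(self, other: "ScoreMatrix") -> "ScoreMatrix":
        if not self.samples[["FID", "IID"]].equals(other.samples[["FID", "IID"]]):
            raise ValueError("sample lists differ; keyed join required")
        vals = pd.concat([self.values, other.values], axis=1)
        if vals.columns.duplicated().any():
            raise ValueError("duplicate score column names")
        return ScoreMatrix(self.samples, vals, {**self.meta, **other.meta})


def _interval_distance(s1, e1, s2, e2) -> int:
    """Closest-edge distance between two gene boundary intervals (0 if they
    overlap)."""
    if e1 < s2:
        return s2 - e1
    if e2 < s1:
        return s1 - e2
    return 0


def mhc_reduce(assocs: pd.DataFrame,
               mhc: tuple[str, int, int] = MHC_REGION) -> pd.DataFrame:
    """Within the MHC region keep only the single most significant feature.

    Ties on p_twas are broken by larger |z_twas|, then by feature id.
    """
    chrom, lo, hi = mhc
    in_mhc = ((assocs["chrom"].astype(str) == str(chrom))
              & (assocs["start"] <= hi) & (assocs["end"] >= lo))
    if in_mhc.sum() <= 1:
        return assocs.reset_index(drop=True)
    sub = assocs[in_mhc].copy()
    sub["_absz"] = -sub["z_twas"].abs()
    best = sub.sort_values(["p_twas", "_absz", "feature_id"]).index[0]
    keep = ~in_mhc
    keep.loc[best] = True
    return assocs[keep].reset_index(drop=True)


def clump_features(assocs: pd.DataFrame, ref_expr: ExpressionMatrix,
                   r2_max: float = 0.9,
                   window_bp: int = 500_000) -> ClumpResult:
    """Greedy clumping of features by ascending TWAS P-value.

    A candidate is removed when its reference predicted-expression squared
    correlation with an already-retained feature exceeds ``r2_max`` and its
    gene boundaries lie within ``window_bp`` of that feature's boundaries.
    """
    order = assocs.dropna(subset=["p_twas"]).sort_values(
        ["p_twas", "feature_id"])
    kept: list[str] = []
    removed: dict[str, str] = {}
    rows = {r["feature_id"]: r for _, r in order.iterrows()}
    E = ref_expr.values
    for fid, row in rows.items():
        lead = None
        for kid in kept:
            krow = rows[kid]
            if str(krow["chrom"]) != str(row["chrom"]):
                continue
            if _interval_distance(row["start"], row["end"],
                                  krow["start"], krow["end"]) > window_bp:
                continue
            if fid not in E or kid not in E:
                continue
            r = np.corrcoef(E[fid], E[kid])[0, 1]
            if r * r > r2_max:
                lead = kid
                break
        if lead is None:
            kept.append(fid)
        else:
            removed[fid] = lead
    return ClumpResult(kept, removed)


def compute_gers(expr: ExpressionMatrix, ref_expr: ExpressionMatrix,
                 assocs: pd.DataFrame,
                 thresholds=GERS_THRESHOLDS,
                 column_prefix: str | None = None) -> ScoreMatrix:
    """Aggregate standardized expression into GeRS columns, one per TWAS
    P-value threshold, then centre/scale each column by its reference-sample
    mean and SD. ``assocs`` must already be MHC-reduced and clumped.

    Thresholds whose feature set is empty are omitted; thresholds are nested,
    so feature sets shrink as the threshold tightens.
    """
    if not expr.standardized or not ref_expr.standardized:
        raise ValueError("expression must be reference-standardized")
    prefix = column_prefix or f"{expr.panel_id}.gers"
    avail = assocs[assocs["feature_id"].isin(expr.values.columns)
                   & assocs["p_twas"].notna()]
    thresholds = sorted(thresholds, reverse=True)
    cols, ref_cols, meta = {}, {}, {}
    for t in thresholds:
        sel = avail[avail["p_twas"] <= t]
        if len(sel) == 0:
            continue
        fids = list(sel["feature_id"])
        z = sel["z_twas"].to_numpy()
        raw = expr.values[fids].to_numpy() @ z
        raw_ref = ref_expr.values[fids].to_numpy() @ z
        mu, sd = raw_ref.mean(), raw_ref.std(ddof=1)
        if sd <= 1e-12:
            continue
        name = f"{prefix}.p{t:g}"
        cols[name] = (raw - mu) / sd
        ref_cols[name] = (raw_ref - mu) / sd
        meta[name] = {"threshold": t, "panel": expr.panel_id,
                      "n_features": len(fids), "ref_mean": float(mu),
                      "ref_sd": float(sd), "features": fids}
    if not cols:
        raise EmptyScoreError("no feature passes the loosest TWAS threshold")
    sm = ScoreMatrix(expr.samples.copy(), pd.DataFrame(cols), meta)
    sm.ref_values = pd.DataFrame(ref_cols)  # kept for duality/QC checks
    return sm


def stratified_gers(expr: ExpressionMatrix, ref_expr: ExpressionMatrix,
                    assocs: pd.DataFrame, thresholds=GERS_THRESHOLDS,
                    mode: str = "all", pp4_min: float = 0.8,
                    r2_max: float = 0.9, window_bp: int = 500_000,
                    mhc=MHC_REGION) -> ScoreMatrix:
    """Full GeRS construction for one panel and one stratification.

    mode 'all' uses every feature; 'coloc' keeps PP4 > ``pp4_min``;
    'tissue_specific' keeps features flagged tissue-specific. The MHC rule
    and expression clumping are applied after stratification.
    """
    if mode == "all":
        sub = assocs
        tag = ""
    elif mode == "coloc":
        sub = filter_coloc(assocs, pp4_min=pp4_min)
        tag = ".coloc"
    elif mode == "tissue_specific":
        if "tissue_specific" not in assocs:
            raise ValueError("tissue_specific mode requires "
                             "flag_tissue_specific output")
        sub = assocs[assocs["tissue_specific"]]
        tag = ".tissue"
    else:
        raise ValueError(f"unknown stratification mode {mode!r}")
    if len(sub) == 0:
        warnings.warn(f"stratification {mode!r} leaves zero features; "
                      "no columns emitted", stacklevel=2)
        return ScoreMatrix(expr.samples.copy(), pd.DataFrame(index=range(len(expr.samples))), {})
    sub = mhc_reduce(sub.reset_index(drop=True), mhc)
    clump = clump_features(sub, ref_expr, r2_max=r2_max, window_bp=window_bp)
    sub = sub[sub["feature_id"].isin(clump.kept)]
    prefix = f"{expr.panel_id}.gers{tag}"
    try:
        return compute_gers(expr, ref_expr, sub, thresholds, prefix)
    except EmptyScoreError:
        warnings.warn(f"stratification {mode!r}: no imputable feature passes "
                      "the loosest threshold", stacklevel=2)
        return ScoreMatrix(expr.samples.copy(),
                           pd.DataFrame(index=range(len(expr.samples))), {})


def collapse_to_variant_weights(assocs: pd.DataFrame, weight_set,
                                ref_expr: ExpressionMatrix,
                                threshold: float) -> pd.DataFrame:
    """Equivalent per-variant weights for one GeRS column:
    w_j = sum_g z_g * beta_gj / ref_sd_g. Applying these to raw allele counts
    reproduces the unstandardized GeRS up to the reference-mean constant —
    used as an internal consistency check and for score-file export."""
    sel = assocs[(assocs["p_twas"] <= threshold) & assocs["p_twas"].notna()]
    acc: dict[str, float] = {}
    alleles: dict[str, str] = {}
    for _, row in sel.iterrows():
        fid = row["feature_id"]
        if fid not in ref_expr.values.columns:
            continue
        sd_g = float(ref_expr.ref_sd[fid])
        for _, w in weight_set.weights[fid].iterrows():
            acc[w["id"]] = acc.get(w["id"], 0.0) + \
                row["z_twas"] * w["beta"] / sd_g
            alleles[w["id"]] = w["a1"]
    return pd.DataFrame({"id": list(acc), "a1": [alleles[i] for i in acc],
                         "weight": list(acc.values())})
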