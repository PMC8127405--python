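"""Input legs of the scoring pipeline: GWAS summary statistics, eQTL
SNP-weight sets and PLINK genotypes, plus QC and allele harmonization.

All downstream scoring is *reference-standardized*: a fixed reference genotype
panel supplies allele frequencies, LD and score scaling, so the variant
universe is intersected across sources once, here, and every source is
re-oriented to the reference panel's effect allele.
"""

from __future__ import annotations

import glob
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import plink

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
VALID_ALLELES = {"A", "C", "G", "T"}


class FormatError(ValueError):
    """A required column or structural element is missing."""


class EmptyInputError(ValueError):
    """No rows survive parsing/QC."""


class MismatchError(ValueError):
    """Variant universes barely overlap — inputs are probably on different
    builds or id conventions."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GwasSumstats:
    """Munged GWAS summary statistics: one row per variant.

    ``table`` columns: SNP, A1 (effect allele), A2, Z (signed toward A1), N,
    and optionally INFO / FRQ.
    """
    table: pd.DataFrame
    trait_type: str = "continuous"

    @property
    def variant_ids(self) -> pd.Index:
        return pd.Index(self.table["SNP"])


@dataclass
class GenotypePanel:
    """Diploid hard-call genotypes for a set of samples.

    ``calls``: samples x variants array of A1-allele counts in {0, 1, 2},
    ``nan`` for missing. ``variants`` carries chrom/id/pos/a1/a2.
    """
    samples: pd.DataFrame    # FID, IID
    variants: pd.DataFrame   # chrom, id, pos, a1, a2
    calls: np.ndarray

    def __post_init__(self):
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError("calls shape does not match sample/variant lists")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def allele_freq(self) -> np.ndarray:
        """Per-variant A1 allele frequency, missing genotypes excluded."""
        return np.nanmean(self.calls, axis=0) / 2.0

    def subset_variants(self, mask_or_ids) -> "GenotypePanel":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            pos = pd.Index(self.variants["id"])
            idx = pos.get_indexer(list(mask_or_ids))
            if (idx < 0).any():
                raise KeyError("variant ids not present in panel")
        return GenotypePanel(self.samples,
                             self.variants.iloc[idx].reset_index(drop=True),
                             self.calls[:, idx])

    @classmethod
    def from_plink(cls, prefix: str) -> "GenotypePanel":
        fam, bim, calls = plink.read_plink(prefix)
        variants = bim[["chrom", "id", "pos", "a1", "a2"]].copy()
        return cls(fam[["FID", "IID"]].copy(), variants, calls)

    def to_plink(self, prefix: str) -> None:
        bim = self.variants.copy()
        bim["cm"] = 0
        plink.write_plink(prefix, self.samples, bim, self.calls)


@dataclass
class SnpWeightSet:
    """One tissue/panel of per-feature expression predictors.

    ``features``: feature_id, gene_id, chrom, start, end, hsq, hsq_p.
    ``weights``: feature_id -> DataFrame(id, a1, a2, chrom, pos, beta).
    """
    panel_id: str
    features: pd.DataFrame
    weights: dict[str, pd.DataFrame]
    n_train: int = 0

    def __post_init__(self):
        for fid in self.features["feature_id"]:
            w = self.weights.get(fid)
            if w is None or len(w) == 0 or not (w["beta"] != 0).any():
                raise ValueError(f"feature {fid} has no nonzero weights")

    @classmethod
    def from_directory(cls, path: str) -> "SnpWeightSet":
        idx = pd.read_csv(os.path.join(path, "features.tsv"), sep="\t",
                          dtype={"feature_id": str, "gene_id": str, "chrom": str})
        weights = {}
        for fid in idx["feature_id"]:
            weights[fid] = pd.read_csv(
                os.path.join(path, "weights", f"{fid}.wgt.tsv"), sep="\t",
                dtype={"id": str, "a1": str, "a2": str, "chrom": str})
        meta_path = os.path.join(path, "panel.tsv")
        n_train = 0
        panel_id = os.path.basename(os.path.normpath(path))
        if os.path.exists(meta_path):
            meta = pd.read_csv(meta_path, sep="\t")
            panel_id = str(meta["panel_id"].iloc[0])
            n_train = int(meta["n_train"].iloc[0])
        return cls(panel_id, idx, weights, n_train)

    def to_directory(self, path: str) -> None:
        os.makedirs(os.path.join(path, "weights"), exist_ok=True)
        self.features.to_csv(os.path.join(path, "features.tsv"), sep="\t",
                             index=False)
        pd.DataFrame({"panel_id": [self.panel_id],
                      "n_train": [self.n_train]}).to_csv(
            os.path.join(path, "panel.tsv"), sep="\t", index=False)
        for fid, w in self.weights.items():
            w.to_csv(os.path.join(path, "weights", f"{fid}.wgt.tsv"),
                     sep="\t", index=False)


def find_weight_dirs(root: str) -> list[str]:
    """Panel directories under ``root`` (any directory with a features.tsv)."""
    return sorted(d for d in glob.glob(os.path.join(root, "*"))
                  if os.path.exists(os.path.join(d, "features.tsv")))


# ---------------------------------------------------------------------------
# sumstats
# ---------------------------------------------------------------------------

_COL_ALIASES = {
    "SNP": {"SNP", "RSID", "ID", "MARKERNAME"},
    "A1": {"A1", "EFFECT_ALLELE", "EA"},
    "A2": {"A2", "OTHER_ALLELE", "OA", "NEA"},
    "Z": {"Z", "ZSCORE"},
    "BETA": {"BETA", "B"},
    "OR": {"OR"},
    "SE": {"SE", "STDERR"},
    "N": {"N", "NTOT"},
    "P": {"P", "PVAL", "P_VALUE"},
    "INFO": {"INFO"},
    "FRQ": {"FRQ", "FREQ", "MAF", "EAF"},
}


def _canonical_columns(df: pd.DataFrame) -> pd.DataFrame:
    rename = {}
    for canon, aliases in _COL_ALIASES.items():
        for col in df.columns:
            if col.upper() in aliases and canon not in rename.values():
                rename[col] = canon
                break
    return df.rename(columns=rename)


def read_sumstats(path: str, min_info: float = 0.6,
                  trait_type: str = "continuous") -> GwasSumstats:
    """Read munged, whitespace-delimited GWAS summary statistics.

    Applies munge-style QC: rows with INFO below ``min_info`` (default 0.6)
    are dropped when an INFO column is present, BETA/SE or OR/SE pairs are
    converted to Z-scores, duplicate variant ids are removed, and
    strand-ambiguous (A/T, C/G) variants are removed.
    """
    df = _canonical_columns(pd.read_csv(path, sep=r"\s+", dtype={"SNP": str}))
    for col in ("SNP", "A1", "A2"):
        if col not in df:
            raise FormatError(f"sumstats file lacks mandatory column {col}")
    if "Z" not in df:
        if "BETA" in df and "SE" in df:
            df["Z"] = df["BETA"] / df["SE"]
        elif "OR" in df and "SE" in df:
            df["Z"] = np.log(df["OR"]) / df["SE"]
        else:
            raise FormatError(
                "sumstats file lacks mandatory column Z (or BETA/SE, OR/SE)")
    if "N" not in df:
        raise FormatError("sumstats file lacks mandatory column N")
    df["A1"] = df["A1"].str.upper()
    df["A2"] = df["A2"].str.upper()
    if "INFO" in df:
        df = df[df["INFO"].isna() | (df["INFO"] >= min_info)]
    df = df[df["A1"].isin(VALID_ALLELES) & df["A2"].isin(VALID_ALLELES)]
    ambiguous = [a + b in {"AT", "TA", "CG", "GC"}
                 for a, b in zip(df["A1"], df["A2"])]
    df = df[~np.asarray(ambiguous, dtype=bool)]
    df = df[df["A1"] != df["A2"]]
    df = df[np.isfinite(df["Z"])]
    df = df.drop_duplicates(subset="SNP", keep=False)
    if len(df) == 0:
        raise EmptyInputError("no sumstats rows survive QC")
    keep = [c for c in ("SNP", "A1", "A2", "Z", "N", "INFO", "FRQ") if c in df]
    return GwasSumstats(df[keep].reset_index(drop=True), trait_type)


def write_sumstats(ss: GwasSumstats, path: str) -> None:
    ss.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotype QC
# ---------------------------------------------------------------------------

def hardcall(probs: np.ndarray, threshold: float = 0.9) -> np.ndarray:
    """Convert genotype probabilities to hard calls.

    ``probs``: (samples, variants, 3) with P(count=0), P(count=1), P(count=2)
    of the A1 allele. The call is the genotype whose probability exceeds
    ``threshold``; missing (nan) when none does.
    """
    if not (1 / 3 < threshold <= 1):
        raise ValueError("hard-call threshold must lie in (1/3, 1]")
    probs = np.asarray(probs, dtype=float)
    best = np.argmax(probs, axis=-1).astype(float)
    pmax = np.max(probs, axis=-1)
    # ">0.9" in the source procedure: strictly greater, except threshold 1.0
    # where certainty (==1) must still call
    ok = pmax > threshold if threshold < 1 else pmax >= 1
    return np.where(ok, best, np.nan)


def hwe_chisq_p(calls: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg chi-square P per variant from hard-call counts."""
    valid = ~np.isnan(calls)
    n = valid.sum(axis=0).astype(float)
    n_a1a1 = np.nansum(calls == 2, axis=0)
    n_het = np.nansum(calls == 1, axis=0)
    n_a2a2 = n - n_a1a1 - n_het
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n_a1a1 + n_het) / (2 * n)
        q = 1 - p
        exp = np.stack([n * p ** 2, 2 * n * p * q, n * q ** 2])
        obs = np.stack([n_a1a1, n_het, n_a2a2])
        chisq = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1),
                         0.0).sum(axis=0)
    pval = stats.chi2.sf(chisq, df=1)
    pval[n == 0] = 0.0
    # monomorphic: HWE trivially holds
    pval[(p == 0) | (p == 1)] = 1.0
    return pval


def variant_qc(panel: GenotypePanel, maf_min: float = 0.001,
               miss_max: float = 0.05,
               hwe_p_min: float = 1e-6) -> GenotypePanel:
    """Remove variants failing MAF, missingness or Hardy-Weinberg filters.

    A variant is removed when MAF < ``maf_min``, missingness > ``miss_max``
    or the HWE chi-square P-value < ``hwe_p_min``.
    """
    if panel.calls.shape[1] == 0:
        raise EmptyInputError("variant_qc called on empty panel")
    freq = panel.allele_freq()
    maf = np.minimum(freq, 1 - freq)
    miss = np.isnan(panel.calls).mean(axis=0)
    hwe = hwe_chisq_p(panel.calls)
    keep = (maf >= maf_min) & (miss <= miss_max) & (hwe >= hwe_p_min)
    out = panel.subset_variants(keep)
    if out.calls.shape[1] == 0:
        import warnings
        warnings.warn("variant_qc removed every variant", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

@dataclass
class Harmonized:
    """Sumstats, weight sets and panels on a shared, allele-aligned
    variant universe (orientation: the reference panel's A1)."""
    sumstats: GwasSumstats
    weight_sets: list[SnpWeightSet]
    ref: GenotypePanel
    target: GenotypePanel
    report: dict = field(default_factory=dict)


def _orient(a1, a2, ref_a1, ref_a2) -> int:
    """+1 if (a1,a2) matches the reference orientation, -1 if swapped,
    0 if irreconcilable."""
    if a1 == ref_a1 and a2 == ref_a2:
        return 1
    if a1 == ref_a2 and a2 == ref_a1:
        return -1
    return 0


def harmonize(sumstats: GwasSumstats, weight_sets: list[SnpWeightSet],
              ref: GenotypePanel, target: GenotypePanel,
              hapmap3_ids=None, min_overlap: float = 0.01,
              min_weight_mass: float = 0.5) -> Harmonized:
    """Intersect the variant universes and align every source to the
    reference panel's effect allele.

    Z-scores and weight betas at swapped-allele variants are negated; target
    genotype counts are recoded (2 - count). Unresolvable allele pairs are
    dropped. Features losing more than ``1 - min_weight_mass`` of their
    absolute weight mass are dropped and reported as non-imputable.
    """
    ref_idx = ref.variants.set_index("id")
    univ = pd.Index(ref.variants["id"])
    pairs = {"sumstats": pd.Index(sumstats.table["SNP"]),
             "target": pd.Index(target.variants["id"])}
    for name, ids in pairs.items():
        inter = univ.intersection(ids)
        if len(inter) < min_overlap * max(1, min(len(univ), len(ids))):
            raise MismatchError(
                f"<1% variant overlap between reference and {name}; "
                "likely an id or build mismatch")
        univ = inter
    if hapmap3_ids is not None:
        univ = univ.intersection(pd.Index(list(hapmap3_ids)))
        if len(univ) == 0:
            raise MismatchError("no variants left after HapMap3 restriction")

    report = {"universe": len(univ)}

    # --- sumstats: orient to reference
    ss = sumstats.table[sumstats.table["SNP"].isin(univ)].copy()
    ra1 = ref_idx.loc[ss["SNP"], "a1"].to_numpy()
    ra2 = ref_idx.loc[ss["SNP"], "a2"].to_numpy()
    sign = np.array([_orient(a1, a2, r1, r2) for a1, a2, r1, r2
                     in zip(ss["A1"], ss["A2"], ra1, ra2)])
    ss = ss[sign != 0].copy()
    flip = sign[sign != 0] == -1
    ss.loc[flip, "Z"] = -ss.loc[flip, "Z"]
    ss.loc[flip, ["A1", "A2"]] = ss.loc[flip, ["A2", "A1"]].to_numpy()
    if "FRQ" in ss:
        ss.loc[flip, "FRQ"] = 1 - ss.loc[flip, "FRQ"]
    univ = univ.intersection(ss["SNP"])
    report["sumstats"] = len(ss)

    # --- target panel: orient to reference
    tgt = target.subset_variants(target.variants["id"].isin(univ).to_numpy())
    ra1 = ref_idx.loc[tgt.variants["id"], "a1"].to_numpy()
    ra2 = ref_idx.loc[tgt.variants["id"], "a2"].to_numpy()
    sign = np.array([_orient(a1, a2, r1, r2) for a1, a2, r1, r2
                     in zip(tgt.variants["a1"], tgt.variants["a2"], ra1, ra2)])
    tgt = tgt.subset_variants(sign != 0)
    flip = sign[sign != 0] == -1
    calls = tgt.calls.copy()
    calls[:, flip] = 2 - calls[:, flip]
    var = tgt.variants.copy()
    var.loc[flip, ["a1", "a2"]] = var.loc[flip, ["a2", "a1"]].to_numpy()
    tgt = GenotypePanel(tgt.samples, var, calls)
    univ = univ.intersection(tgt.variants["id"])
    report["target"] = len(univ)

    ss = ss[ss["SNP"].isin(univ)].reset_index(drop=True)
    ref_out = ref.subset_variants(ref.variants["id"].isin(univ).to_numpy())
    tgt = tgt.subset_variants(tgt.variants["id"].isin(univ).to_numpy())

    # --- weight sets: drop out-of-universe variants, orient betas
    out_sets = []
    for ws in weight_sets:
        new_weights = {}
        kept_feats = []
        dropped = 0
        for _, feat in ws.features.iterrows():
            w = ws.weights[feat["feature_id"]]
            mass0 = np.abs(w["beta"]).sum()
            w = w[w["id"].isin(univ)].copy()
            if len(w) == 0:
                dropped += 1
                continue
            ra1 = ref_idx.loc[w["id"], "a1"].to_numpy()
            ra2 = ref_idx.loc[w["id"], "a2"].to_numpy()
            sign = np.array([_orient(a1, a2, r1, r2) for a1, a2, r1, r2
                             in zip(w["a1"], w["a2"], ra1, ra2)])
            w = w[sign != 0].copy()
            flip = sign[sign != 0] == -1
            w.loc[flip, "beta"] = -w.loc[flip, "beta"]
            w.loc[flip, ["a1", "a2"]] = w.loc[flip, ["a2", "a1"]].to_numpy()
            if len(w) == 0 or np.abs(w["beta"]).sum() < min_weight_mass * mass0:
                dropped += 1  # non-imputable: lost most of its weight mass
                continue
            new_weights[feat["feature_id"]] = w.reset_index(drop=True)
            kept_feats.append(feat)
        feats = pd.DataFrame(kept_feats).reset_index(drop=True)
        report[f"weights:{ws.panel_id}"] = {"kept": len(kept_feats),
                                            "non_imputable": dropped}
        if len(kept_feats) > 0:
            out_sets.append(SnpWeightSet(ws.panel_id, feats, new_weights,
                                         ws.n_train))
    return Harmonized(GwasSumstats(ss, sumstats.trait_type), out_sets,
                      ref_out, tgt, report)
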