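"""Predictive-utility estimation and model comparison.

Single scores are evaluated with a generalized linear model (linear for
continuous traits, logistic for binary); multiple scores are combined with an
elastic net whose hyperparameters are tuned by nested cross-validation:
an outer 5-fold split yields out-of-sample predictions for every individual,
and an inner 10-fold CV on each outer-training portion selects the mixing and
penalty parameters, so hyperparameter selection never sees a test fold.

Prediction accuracy is the Pearson correlation r between observed and
predicted values, with SE sqrt((1-r^2)/(n-2)). Dependent correlations from
two models predicting the same phenotype are compared with the
Hotelling-Williams test, which accounts for the correlation between the two
models' predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNetCV, LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold

DEFAULT_L1_RATIOS = (0.1, 0.55, 1.0)
DEFAULT_N_ALPHAS = 25


class DegeneratePredictorError(ValueError):
    pass


@dataclass
class CvScheme:
    outer_k: int = 5
    inner_k: int = 10
    seed: int = 0
    stratify_binary: bool = True

    def __post_init__(self):
        if self.outer_k < 2 or self.inner_k < 2:
            raise ValueError("outer_k and inner_k must be >= 2")

    def outer_splitter(self, trait_type: str):
        if trait_type == "binary" and self.stratify_binary:
            return StratifiedKFold(self.outer_k, shuffle=True,
                                   random_state=self.seed)
        return KFold(self.outer_k, shuffle=True, random_state=self.seed)


def corr_with_se(predictions: np.ndarray, phenotype: np.ndarray
                 ) -> tuple[float, float, int]:
    """Pearson r between predicted and observed, with SE sqrt((1-r^2)/(n-2))."""
    x = np.asarray(predictions, float)
    y = np.asarray(phenotype, float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if x.std() == 0 or y.std() == 0:
        raise DegeneratePredictorError("zero variance in predictions or "
                                       "phenotype")
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    se = float(np.sqrt(max(1 - r ** 2, 0.0) / (n - 2)))
    return r, se, n


def williams_test(r_ay: float, r_by: float, r_ab: float, n: int
                  ) -> tuple[float, float]:
    """Hotelling-Williams t (df = n-3) for the difference between two
    dependent correlations r_ay and r_by sharing the variable y, given the
    correlation r_ab between the two predictors. Two-sided P."""
    if n <= 3:
        raise ValueError("Williams test needs n > 3")
    if r_ay == r_by:
        # includes model-vs-itself, where r_ab = 1 and the test is vacuous
        return 0.0, 1.0
    for r in (r_ay, r_by, r_ab):
        if not -1 < r < 1:
            raise ValueError("correlations must lie strictly in (-1, 1)")
    det = 1 - r_ay ** 2 - r_by ** 2 - r_ab ** 2 + 2 * r_ay * r_by * r_ab
    if det <= 0:
        raise FloatingPointError("correlation matrix is not positive "
                                 "definite")
    rbar = (r_ay + r_by) / 2
    denom = 2 * (n - 1) / (n - 3) * det + rbar ** 2 * (1 - r_ab) ** 3
    t = (r_ay - r_by) * np.sqrt((n - 1) * (1 + r_ab) / denom)
    p = float(2 * stats.t.sf(abs(t), df=n - 3))
    return float(t), p


# ---------------------------------------------------------------------------
# cross-validated fitting
# ---------------------------------------------------------------------------

def fit_single(score: np.ndarray, phenotype: np.ndarray, trait_type: str,
               scheme: CvScheme | None = None) -> np.ndarray:
    """Out-of-sample linear predictors for a one-predictor GLM under outer
    k-fold CV. Linear regression for continuous traits, logistic for binary;
    predictions are on the linear-predictor scale."""
    scheme = scheme or CvScheme()
    x = np.asarray(score, float)
    y = np.asarray(phenotype, float)
    if x.std() == 0:
        raise DegeneratePredictorError("constant score column")
    preds = np.full(y.shape, np.nan)
    for train, test in scheme.outer_splitter(trait_type).split(x[:, None], y):
        if trait_type == "binary":
            m = LogisticRegression(C=np.inf, max_iter=1000)  # unpenalized
            m.fit(x[train, None], y[train])
            preds[test] = m.decision_function(x[test, None])
        else:
            X1 = np.column_stack([np.ones(train.size), x[train]])
            coef, *_ = np.linalg.lstsq(X1, y[train], rcond=None)
            preds[test] = coef[0] + coef[1] * x[test]
    return preds


def fit_elastic_net(scores: pd.DataFrame, phenotype: np.ndarray,
                    trait_type: str, scheme: CvScheme | None = None,
                    l1_ratios=DEFAULT_L1_RATIOS,
                    n_alphas: int = DEFAULT_N_ALPHAS) -> np.ndarray:
    """Out-of-sample predictions from a nested-CV elastic net.

    For each outer fold the inner ``inner_k``-fold CV (on the outer-training
    portion only) selects the l1 ratio and penalty from a log-spaced path
    anchored at the data-derived maximum; the selected model is refit on the
    full outer-training portion and applied to the held-out fold. Binary
    traits are fit on the 0/1 indicator (linear working model) and compared
    on the linear-predictor scale.
    """
    scheme = scheme or CvScheme()
    X = scores.to_numpy(dtype=float)
    y = np.asarray(phenotype, float)
    preds = np.full(y.shape, np.nan)
    for i, (train, test) in enumerate(
            scheme.outer_splitter(trait_type).split(X, y)):
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (X[train] - mu) / sd
        Xte = (X[test] - mu) / sd
        inner = KFold(scheme.inner_k, shuffle=True,
                      random_state=scheme.seed + 1000 + i)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # alphas=int requests a log-spaced path of that length anchored
            # at the data-derived maximum (sklearn >= 1.5 spelling)
            m = ElasticNetCV(l1_ratio=list(l1_ratios), alphas=n_alphas,
                             cv=inner, max_iter=5000, n_jobs=None)
            m.fit(Xtr, y[train])
        if np.all(m.coef_ == 0):
            warnings.warn("elastic net selected the empty model; falling "
                          "back to intercept-only", stacklevel=2)
            preds[test] = y[train].mean()
        else:
            preds[test] = m.predict(Xte)
    return preds


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

@dataclass
class PredictionResults:
    """Out-of-sample predictive performance of one score model."""
    name: str
    predictions: np.ndarray
    phenotype: np.ndarray
    r: float
    se: float
    n: int
    scheme: CvScheme
    n_predictors: int

    def summary(self) -> str:
        lines = [
            f"Score prediction results: {self.name}",
            f"  predictors:         {self.n_predictors}",
            f"  n:                  {self.n}",
            f"  CV: outer {self.scheme.outer_k}-fold / inner "
            f"{self.scheme.inner_k}-fold (seed {self.scheme.seed})",
            f"  predicted-observed r: {self.r:.4f} (SE {self.se:.4f})",
        ]
        return "\n".join(lines)

    def compare(self, other: "PredictionResults") -> dict:
        """Williams test and relative improvement of self over other."""
        if self.n != other.n:
            raise ValueError("results cover different samples")
        if not np.array_equal(self.phenotype, other.phenotype):
            raise ValueError("results evaluated on different phenotypes")
        r_ab = float(np.corrcoef(self.predictions, other.predictions)[0, 1])
        t, p = williams_test(self.r, other.r, r_ab, self.n)
        return {"model_a": self.name, "model_b": other.name,
                "r_a": self.r, "r_b": other.r, "r_ab": r_ab,
                "t_williams": t, "p_two_sided": p,
                "abs_difference": self.r - other.r,
                "rel_improvement": (self.r - other.r) / other.r
                if other.r != 0 else np.inf,
                "ratio": self.r / other.r if other.r != 0 else np.inf}


class ScorePredictor:
    """Cross-validated phenotype prediction from one or more genetic scores.

    A single score column is fit with a GLM; two or more columns with a
    nested-CV elastic net. ``fit`` returns a :class:`PredictionResults`.
    """

    def __init__(self, scores: pd.DataFrame, phenotype: np.ndarray,
                 trait_type: str = "continuous", name: str | None = None):
        if trait_type not in ("continuous", "binary"):
            raise ValueError("trait_type must be continuous or binary")
        self.scores = scores.reset_index(drop=True)
        self.phenotype = np.asarray(phenotype, float)
        if len(self.scores) != self.phenotype.size:
            raise ValueError("scores and phenotype lengths differ")
        self.trait_type = trait_type
        self.name = name or ("+".join(scores.columns[:3]) +
                             ("..." if scores.shape[1] > 3 else ""))

    @classmethod
    def from_score_matrix(cls, sm, phenotype: pd.DataFrame,
                          trait_type: str = "continuous",
                          columns=None, name: str | None = None
                          ) -> "ScorePredictor":
        """Keyed join of a ScoreMatrix with a phenotype table
        (FID, IID, value in the third column)."""
        cols = list(columns) if columns is not None else list(sm.values.columns)
        tab = sm.to_table().merge(phenotype, on=["FID", "IID"], how="inner")
        if len(tab) == 0:
            raise KeyError("no overlapping FID/IID between scores and "
                           "phenotype")
        value_col = [c for c in phenotype.columns if c not in ("FID", "IID")][0]
        return cls(tab[cols], tab[value_col].to_numpy(), trait_type, name)

    def fit(self, scheme: CvScheme | None = None) -> PredictionResults:
        scheme = scheme or CvScheme()
        if self.scores.shape[1] == 1:
            preds = fit_single(self.scores.iloc[:, 0].to_numpy(),
                               self.phenotype, self.trait_type, scheme)
        else:
            preds = fit_elastic_net(self.scores, self.phenotype,
                                    self.trait_type, scheme)
        assert not np.isnan(preds).any(), "outer folds failed to cover sample"
        try:
            r, se, n = corr_with_se(preds, self.phenotype)
        except DegeneratePredictorError:
            r, se, n = 0.0, np.nan, self.phenotype.size
        return PredictionResults(self.name, preds, self.phenotype, r, se, n,
                                 scheme, self.scores.shape[1])


def best_single_column(scores: pd.DataFrame, phenotype: np.ndarray,
                       trait_type: str = "continuous",
                       scheme: CvScheme | None = None
                       ) -> tuple[str, PredictionResults]:
    """Evaluate every column as a single-score model; return the best by
    predicted-observed r."""
    best = None
    for col in scores.columns:
        if scores[col].std() == 0:
            continue
        res = ScorePredictor(scores[[col]], phenotype, trait_type,
                             name=col).fit(scheme)
        if best is None or res.r > best[1].r:
            best = (col, res)
    if best is None:
        raise DegeneratePredictorError("all score columns are constant")
    return best


def evaluation_report(results: list[PredictionResults],
                      comparisons: list[tuple[str, str]] | None = None
                      ) -> dict:
    """JSON-ready report: per-model r/se/n plus pairwise Williams tests."""
    by_name = {r.name: r for r in results}
    models = [{"name": r.name, "r": r.r, "se": r.se, "n": r.n,
               "n_predictors": r.n_predictors} for r in results]
    pairs = []
    if comparisons is None:
        names = list(by_name)
        comparisons = [(a, b) for i, a in enumerate(names)
                       for b in names[i + 1:]]
    for a, b in comparisons:
        pairs.append(by_name[a].compare(by_name[b]))
    return {"models": models, "comparisons": pairs}
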