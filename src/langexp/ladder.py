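"""Covariate-adjusted linear-model ladders compared by BIC-derived Bayes factors.

The central inferential device: a *ladder* of nested-in-spirit linear models
for a vocabulary outcome, all sharing the covariates of no interest (age,
gender, SES, nonverbal reasoning), each adding one language-exposure index
(or, in the bilingual ladder, exposure, L2 distance, and their interaction).
Models are compared with the Bayesian information criterion, converted to a
Bayes factor by

    BF10 = exp(dBIC01 / 2),

where dBIC01 = BIC(model 0) - BIC(model 1), so BF10 > 1 favors model 1.
Alongside the Bayes factors, each comparison carries the frequentist
statistics of the added term (beta, t, residual df, p) and the change in R²,
mirroring the standard multiple-regression report.

The module follows the statsmodels idiom: a :class:`VocabularyLadder` model
object is built from a case table and ``fit()`` returns a
:class:`LadderResults` carrying every fitted model, the comparison table and
a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "FitResult",
    "LadderComparison",
    "LadderResults",
    "VocabularyLadder",
    "fit_ols",
    "bic",
    "bf_from_bic",
    "evidence_label",
    "cohens_f2",
    "run_h2_ladder",
    "run_h3_ladder",
    "ks_residual_normality",
    "outlier_filter",
    "standardize_for_report",
]

#: Bayes-factor interpretation bands, anchored to the LBF thresholds
#: 0 / 1 / 3 / 5 (BF ~ 1 / 3 / 20 / 150).
EVIDENCE_BANDS = (
    (1.0, "anecdotal"),
    (3.0, "positive"),
    (20.0, "strong"),
    (150.0, "very strong"),
)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one rung of the ladder.

    ``index_terms`` are the language-exposure regressors added on top of the
    covariates (empty for the baseline rung); ``interaction_pairs`` multiply
    two already-included main effects.
    """

    name: str
    outcome: str
    covariates: tuple[str, ...]
    index_terms: tuple[str, ...] = ()
    interaction_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        terms = list(self.covariates) + list(self.index_terms)
        if len(set(terms)) != len(terms):
            raise ValueError(f"{self.name}: duplicate terms in spec")
        mains = set(terms)
        for a, b in self.interaction_pairs:
            if a not in mains or b not in mains:
                raise ValueError(
                    f"{self.name}: interaction ({a}, {b}) not drawn from "
                    "included main effects"
                )

    @property
    def terms(self) -> list[str]:
        return list(self.covariates) + list(self.index_terms)


@dataclass
class FitResult:
    """One fitted ladder rung (OLS with intercept)."""

    spec: ModelSpec
    params: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: int
    rsquared: float
    resid: np.ndarray
    n: int
    k: int  # intercept + slopes + error variance
    rss: float
    bic: float
    fvalue: float
    f_pvalue: float
    case_ids: pd.Index

    def term_stats(self, term: str) -> dict:
        """beta / t / df / p for the design column matching ``term``."""
        cols = [c for c in self.params.index if c == term or c.startswith(term + "[")]
        if not cols:
            raise KeyError(f"term {term!r} not in model {self.spec.name}")
        col = cols[0]
        return {
            "beta": float(self.params[col]),
            "t": float(self.tvalues[col]),
            "df_resid": self.df_resid,
            "p": float(self.pvalues[col]),
        }


@dataclass
class LadderComparison:
    """One row of the comparison table: model_a against model_b (reference)."""

    model_a: str
    model_b: str
    delta_r2: float
    bf10: float
    evidence_label: str


def _encode_design(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Design matrix with intercept, treatment-coded categoricals, interactions.

    Categorical levels are sorted lexicographically and the first is the
    reference, so the coding is deterministic.
    """
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(data))}
    encoded: dict[str, list[str]] = {}
    for term in spec.terms:
        if term not in data.columns:
            raise KeyError(f"term {term!r} not in data")
        col = data[term]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(map(str, col.dropna().unique()))
            encoded[term] = []
            for level in levels[1:]:
                name = f"{term}[T.{level}]"
                cols[name] = (col.astype(str) == level).astype(float).to_numpy()
                encoded[term].append(name)
        else:
            cols[term] = col.astype(float).to_numpy()
            encoded[term] = [term]
    for a, b in spec.interaction_pairs:
        for ca in encoded[a]:
            for cb in encoded[b]:
                cols[f"{ca}:{cb}"] = cols[ca] * cols[cb]
    return pd.DataFrame(cols, index=data.index)


def fit_ols(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Ordinary least squares for one rung, with the ladder's BIC convention.

    Raises on missing values (listing the offending case ids) and on
    rank-deficient designs (naming the collinear columns).
    """
    needed = [spec.outcome] + spec.terms
    sub = data[needed]
    missing = sub.index[sub.isna().any(axis=1)]
    if len(missing):
        raise ValueError(
            f"{spec.name}: missing values for cases {list(map(str, missing))}"
        )
    X = _encode_design(data, spec)
    y = data[spec.outcome].astype(float).to_numpy()
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = []
        for c in X.columns:
            reduced = X.drop(columns=[c]).to_numpy()
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(c)
        raise ValueError(f"{spec.name}: rank-deficient design; collinear "
                         f"columns {collinear}")
    if X.shape[0] <= X.shape[1] + 2:
        raise ValueError(f"{spec.name}: too few cases (n={X.shape[0]}) for "
                         f"{X.shape[1]} parameters")
    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    n = int(res.nobs)
    k = X.shape[1] + 1  # + error variance
    tss = float(((y - y.mean()) ** 2).sum())
    degenerate = rss <= 1e-12 * max(tss, 1.0)
    return FitResult(
        spec=spec,
        params=res.params,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        df_resid=int(res.df_resid),
        rsquared=float(res.rsquared),
        resid=np.asarray(res.resid),
        n=n,
        k=k,
        rss=0.0 if degenerate else rss,
        bic=np.nan if degenerate else bic_from_rss(rss, n, k),
        fvalue=float(res.fvalue) if res.df_model > 0 else np.nan,
        f_pvalue=float(res.f_pvalue) if res.df_model > 0 else np.nan,
        case_ids=data.index,
    )


def bic_from_rss(rss: float, n: int, k: int) -> float:
    if rss <= 0:
        raise ValueError("zero residual sum of squares: BIC undefined "
                         "(infinite likelihood)")
    return n * np.log(rss / n) + k * np.log(n)


def bic(fit: FitResult) -> float:
    """Gaussian-likelihood BIC: n ln(RSS/n) + k ln n.

    ``k`` counts intercept + slopes + the error variance.  Only differences
    of BIC matter downstream; the convention is fixed so they are
    well defined.  A (numerically) perfect fit has no finite Gaussian
    likelihood and raises.
    """
    return bic_from_rss(fit.rss, fit.n, fit.k)


def bf_from_bic(bic_0: float, bic_1: float) -> float:
    """BF10 = exp((BIC0 - BIC1)/2); values > 1 favor model 1."""
    return float(np.exp((bic_0 - bic_1) / 2.0))


def evidence_label(bf10: float) -> str:
    """Interpretation band for a Bayes factor >= 1 scale.

    BF10 in 1–3 'anecdotal', 3–20 'positive', 20–150 'strong', > 150
    'very strong'; BF10 < 1 is labelled for the *other* model with a
    'for null: ' prefix.
    """
    if bf10 <= 0:
        raise ValueError("Bayes factor must be positive")
    if bf10 < 1:
        return "for null: " + evidence_label(1.0 / bf10)
    label = "anecdotal"
    for bound, name in EVIDENCE_BANDS:
        if bf10 > bound:
            label = name
    return label


def cohens_f2(full: FitResult, reduced: FitResult) -> float:
    """Cohen's f² for the terms added in ``full`` over nested ``reduced``."""
    if full.n != reduced.n:
        raise ValueError("f² requires the same cases in both fits")
    if full.rsquared >= 1.0:
        raise ValueError("f² undefined when the full model is saturated")
    return (full.rsquared - reduced.rsquared) / (1.0 - full.rsquared)


class LadderResults:
    """Fits and pairwise comparisons for one outcome's model ladder."""

    def __init__(
        self,
        fits: dict[str, FitResult],
        comparisons: list[tuple[str, str]],
        index_term_of: dict[str, str | None],
    ):
        self.fits = fits
        self.index_term_of = index_term_of
        self.comparisons = [
            LadderComparison(
                model_a=a,
                model_b=b,
                delta_r2=fits[a].rsquared - fits[b].rsquared,
                bf10=bf_from_bic(fits[b].bic, fits[a].bic),
                evidence_label=evidence_label(
                    bf_from_bic(fits[b].bic, fits[a].bic)
                ),
            )
            for a, b in comparisons
        ]

    def comparison(self, model_a: str, model_b: str) -> LadderComparison:
        for c in self.comparisons:
            if c.model_a == model_a and c.model_b == model_b:
                return c
        raise KeyError(f"no comparison {model_a} vs {model_b}")

    def bf10(self, model_a: str, model_b: str) -> float:
        return self.comparison(model_a, model_b).bf10

    def to_frame(self) -> pd.DataFrame:
        """Comparison table in the multiple-regression report layout.

        One block row per non-baseline model (beta, t, DF, p of its index
        term) followed by its comparisons (dR², BF10).
        """
        rows = []
        for name, fit in self.fits.items():
            term = self.index_term_of.get(name)
            stats = fit.term_stats(term) if term else {}
            rows.append(
                {
                    "model": name,
                    "term": term or "",
                    "beta": stats.get("beta", np.nan),
                    "t": stats.get("t", np.nan),
                    "DF": f"{fit.n - fit.df_resid - 1},{fit.df_resid}",
                    "p": stats.get("p", np.nan),
                    "R2": fit.rsquared,
                    "delta_R2": np.nan,
                    "BF10": np.nan,
                    "versus": "",
                }
            )
            for c in self.comparisons:
                if c.model_a == name:
                    rows.append(
                        {
                            "model": name,
                            "term": "",
                            "beta": np.nan,
                            "t": np.nan,
                            "DF": "",
                            "p": np.nan,
                            "R2": np.nan,
                            "delta_R2": c.delta_r2,
                            "BF10": c.bf10,
                            "versus": c.model_b,
                        }
                    )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        with pd.option_context("display.float_format", "{:0.4g}".format):
            return (
                f"Model ladder for outcome "
                f"'{next(iter(self.fits.values())).spec.outcome}' "
                f"(n={next(iter(self.fits.values())).n})\n"
                + df.to_string(index=False)
            )


class VocabularyLadder:
    """Model object for a ladder of exposure-index regressions.

    Parameters
    ----------
    data : DataFrame
        Complete-case table with the outcome, covariates and index columns.
    outcome : str
        Outcome column (e.g. ``receptive_score``).
    covariates : sequence of str
        Covariates of no interest shared by every rung.
    rungs : dict[str, dict]
        Mapping rung name -> kwargs (``index_terms``, ``interaction_pairs``)
        added on top of the covariates.  ``m0`` (baseline) is implicit.
    comparisons : list[tuple[str, str]]
        Ordered pairs (model_a, model_b) to report.
    """

    #: comparison schedule shared by both published ladder layouts
    DEFAULT_COMPARISONS = [
        ("m1", "m0"),
        ("m2", "m0"),
        ("m2", "m1"),
        ("m3", "m0"),
        ("m3", "m1"),
        ("m3", "m2"),
    ]

    def __init__(self, data, outcome, covariates, rungs, comparisons=None):
        self.data = data
        self.outcome = outcome
        self.covariates = tuple(covariates)
        self.rungs = rungs
        self.comparisons = comparisons or list(self.DEFAULT_COMPARISONS)

    @classmethod
    def exposure_indices(
        cls,
        data: pd.DataFrame,
        outcome: str,
        covariates=("age_years", "gender", "ses_years", "nonverbal_score"),
        index_columns=(
            "exposure_english",
            "diversity_h",
            "typological_diversity_qe",
        ),
    ) -> "VocabularyLadder":
        """The three-index ladder: baseline, + exposure, + diversity, + QE."""
        rungs = {
            f"m{i + 1}": {"index_terms": (col,)}
            for i, col in enumerate(index_columns)
        }
        return cls(data, outcome, covariates, rungs)

    @classmethod
    def bilingual_distance(
        cls,
        data: pd.DataFrame,
        outcome: str,
        covariates=("age_years", "gender", "ses_years", "nonverbal_score"),
        exposure_col="exposure_english",
        distance_col="l2_distance",
    ) -> "VocabularyLadder":
        """The bilingual ladder: exposure, + L2 distance, + interaction."""
        rungs = {
            "m1": {"index_terms": (exposure_col,)},
            "m2": {"index_terms": (exposure_col, distance_col)},
            "m3": {
                "index_terms": (exposure_col, distance_col),
                "interaction_pairs": ((exposure_col, distance_col),),
            },
        }
        return cls(data, outcome, covariates, rungs)

    def fit(self) -> LadderResults:
        fits: dict[str, FitResult] = {}
        index_term_of: dict[str, str | None] = {"m0": None}
        fits["m0"] = fit_ols(
            self.data,
            ModelSpec(
                name="m0", outcome=self.outcome, covariates=self.covariates
            ),
        )
        for name, kwargs in self.rungs.items():
            spec = ModelSpec(
                name=name,
                outcome=self.outcome,
                covariates=self.covariates,
                index_terms=tuple(kwargs.get("index_terms", ())),
                interaction_pairs=tuple(kwargs.get("interaction_pairs", ())),
            )
            fits[name] = fit_ols(self.data, spec)
            if spec.interaction_pairs:
                a, b = spec.interaction_pairs[0]
                index_term_of[name] = f"{a}:{b}"
            elif spec.index_terms:
                index_term_of[name] = spec.index_terms[-1]
            else:
                index_term_of[name] = None
        return LadderResults(fits, self.comparisons, index_term_of)


def run_h2_ladder(
    data: pd.DataFrame,
    outcome: str,
    covariates=("age_years", "gender", "ses_years", "nonverbal_score"),
) -> LadderResults:
    """Fit and compare the three-index ladder for one outcome."""
    return VocabularyLadder.exposure_indices(
        data, outcome, covariates=covariates
    ).fit()


def run_h3_ladder(
    data: pd.DataFrame,
    outcome: str,
    covariates=("age_years", "gender", "ses_years", "nonverbal_score"),
) -> LadderResults:
    """Fit and compare the bilingual exposure x L2-distance ladder."""
    return VocabularyLadder.bilingual_distance(
        data, outcome, covariates=covariates
    ).fit()


def ks_residual_normality(fit: FitResult) -> float:
    """Kolmogorov–Smirnov p-value for normality of standardized residuals.

    Residuals are standardized by their own mean and SD, then compared
    against N(0,1) with the classic (not Lilliefors-corrected) KS test;
    p-values are therefore conservative for this use.
    """
    resid = np.asarray(fit.resid, dtype=float)
    if fit.n < 8:
        raise ValueError("need n >= 8 residuals for the KS check")
    sd = resid.std(ddof=1)
    if sd == 0 or np.allclose(resid, 0.0, atol=1e-8):
        raise ValueError("degenerate residuals (zero or numerically zero "
                         "variance)")
    z = (resid - resid.mean()) / sd
    return float(scipy.stats.kstest(z, "norm").pvalue)


def outlier_filter(scores, k_sd: float = 3.0) -> np.ndarray:
    """Boolean keep-mask for scores within ``k_sd`` SDs of the mean.

    Mean and SD are computed once on the full vector (no iteration); the
    boundary is closed (exactly ±k SD is retained).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 3:
        raise ValueError("need at least 3 scores")
    sd = scores.std(ddof=1)
    if sd == 0:
        warnings.warn("zero SD: no outliers can be defined, all retained",
                      stacklevel=2)
        return np.ones(scores.size, dtype=bool)
    z = (scores - scores.mean()) / sd
    return np.abs(z) <= k_sd


def standardize_for_report(adjusted_scores) -> np.ndarray:
    """Rescale scores to mean 100, SD 15 for plots and report tables.

    Display convention only — never used for fitting.
    """
    x = np.asarray(adjusted_scores, dtype=float)
    sd = x.std(ddof=1)
    if x.size < 2 or sd == 0:
        raise ValueError("need >= 2 distinct values to standardize")
    return 100.0 + 15.0 * (x - x.mean()) / sd
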