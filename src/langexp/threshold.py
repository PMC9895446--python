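"""Is there a minimal-exposure threshold for vocabulary growth?

A recurring claim in the bilingualism literature is a cut-off (around 60%
L1 exposure) above which bilingual children's L1 vocabulary falls in the
monolingual range.  This module probes for such a threshold in three
complementary ways, each pitted against the plain linear model through the
same BIC -> Bayes-factor machinery used elsewhere in the package:

* :class:`SegmentedRegression` — continuous piecewise-linear (hinge) fits
  with the breakpoint found by grid search over interior observed x values;
* :class:`SmoothVsLinear` — a natural cubic regression spline (4 df)
  against the straight line;
* :class:`ExposureClusterer` — a two-stage cluster analysis (Ward
  hierarchical, then k-means refinement) of (exposure, adjusted score)
  pairs, reporting the exposure boundary between clusters when any
  structure exists.

A linear verdict across all three mirrors the absence of a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from patsy import dmatrix
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import silhouette_score

from .ladder import bf_from_bic, bic_from_rss

__all__ = [
    "BreakpointFit",
    "SmoothFit",
    "ClusterReport",
    "SegmentedRegression",
    "SmoothVsLinear",
    "ExposureClusterer",
    "segmented_fit",
    "smooth_vs_linear",
    "two_stage_cluster",
]


def _lstsq_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def _linear_bic(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    X = np.column_stack([np.ones_like(x), x])
    coef, rss = _lstsq_rss(X, y)
    # k = intercept + slope + error variance
    return coef, rss, bic_from_rss(rss, len(y), 3)


@dataclass
class BreakpointFit:
    """Best continuous piecewise-linear fit and its evidence vs the line."""

    breakpoint: float
    left_slope: float
    right_slope: float
    intercept: float
    bic: float
    bic_linear: float
    bf_vs_linear: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (
            self.intercept
            + self.left_slope * x
            + (self.right_slope - self.left_slope)
            * np.maximum(x - self.breakpoint, 0.0)
        )


class SegmentedRegression:
    """Hinge-regression model for scores as a function of exposure.

    The candidate breakpoints are the distinct observed x values with the
    outer ``trim`` fraction of cases excluded on each side, so the
    breakpoint always has interior support.  At each candidate a continuous
    two-slope model  y = b0 + b1 x + b2 max(x - c, 0)  is fitted by least
    squares; the BIC-best candidate wins.  The searched breakpoint is
    counted as one extra estimated parameter in the segmented model's BIC
    (k = 5 with the error variance).
    """

    def __init__(self, x, y, trim: float = 0.10):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same length")
        if np.unique(self.x).size < 20:
            raise ValueError("need >= 20 distinct x values")
        self.trim = float(trim)

    def _candidates(self) -> np.ndarray:
        order = np.sort(self.x)
        lo = order[int(np.floor(self.trim * len(order)))]
        hi = order[int(np.ceil((1 - self.trim) * len(order))) - 1]
        cand = np.unique(self.x)
        cand = cand[(cand >= lo) & (cand <= hi)]
        # a hinge at the extremes is degenerate with the line
        cand = cand[(cand > order[0]) & (cand < order[-1])]
        if cand.size == 0:
            raise ValueError("no interior breakpoint candidates after trim")
        return cand

    def fit(self) -> BreakpointFit:
        x, y = self.x, self.y
        n = len(y)
        _, _, bic_lin = _linear_bic(x, y)
        best = None
        for c in self._candidates():
            X = np.column_stack(
                [np.ones(n), x, np.maximum(x - c, 0.0)]
            )
            coef, rss = _lstsq_rss(X, y)
            if rss <= 0:
                rss = np.finfo(float).tiny
            b = bic_from_rss(rss, n, 5)
            if best is None or b < best[0]:
                best = (b, c, coef)
        bic_seg, c, coef = best
        return BreakpointFit(
            breakpoint=float(c),
            left_slope=float(coef[1]),
            right_slope=float(coef[1] + coef[2]),
            intercept=float(coef[0]),
            bic=bic_seg,
            bic_linear=bic_lin,
            bf_vs_linear=bf_from_bic(bic_lin, bic_seg),
        )


def segmented_fit(x, y, trim: float = 0.10) -> BreakpointFit:
    """Grid-search hinge regression; see :class:`SegmentedRegression`."""
    return SegmentedRegression(x, y, trim=trim).fit()


@dataclass
class SmoothFit:
    """Spline-vs-line comparison with both fitted curves for plotting."""

    bf_smooth_vs_linear: float
    grid: np.ndarray
    linear_curve: np.ndarray
    smooth_curve: np.ndarray
    bic_linear: float
    bic_smooth: float

    @property
    def prefers_linear(self) -> bool:
        return self.bf_smooth_vs_linear < 1.0


class SmoothVsLinear:
    """Natural cubic regression spline (4 df) against the straight line."""

    def __init__(self, x, y, df: int = 4, n_grid: int = 101):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if len(self.x) < 20:
            raise ValueError("need n >= 20")
        self.df = int(df)
        self.n_grid = int(n_grid)

    def fit(self) -> SmoothFit:
        x, y = self.x, self.y
        n = len(y)
        coef_lin, rss_lin = _lstsq_rss(
            np.column_stack([np.ones(n), x]), y
        )
        bic_lin = bic_from_rss(max(rss_lin, np.finfo(float).tiny), n, 3)
        basis = dmatrix(
            "cr(x, df=df)", {"x": x, "df": self.df}, return_type="dataframe"
        )
        X_s = np.column_stack([np.ones(n), basis.to_numpy()[:, 1:]])
        coef_s, rss_s = _lstsq_rss(X_s, y)
        bic_s = bic_from_rss(
            max(rss_s, np.finfo(float).tiny), n, X_s.shape[1] + 1
        )
        grid = np.linspace(x.min(), x.max(), self.n_grid)
        basis_g = dmatrix(
            "cr(x, df=df)", {"x": grid, "df": self.df}, return_type="dataframe"
        )
        # patsy cr() bases are data-dependent; rebuild on the grid with the
        # training design info so the same basis functions are evaluated
        from patsy import build_design_matrices

        basis_g = build_design_matrices(
            [basis.design_info], {"x": grid, "df": self.df}
        )[0]
        Xg = np.column_stack(
            [np.ones(len(grid)), np.asarray(basis_g)[:, 1:]]
        )
        return SmoothFit(
            bf_smooth_vs_linear=bf_from_bic(bic_lin, bic_s),
            grid=grid,
            linear_curve=coef_lin[0] + coef_lin[1] * grid,
            smooth_curve=Xg @ coef_s,
            bic_linear=bic_lin,
            bic_smooth=bic_s,
        )


def smooth_vs_linear(x, y, df: int = 4) -> SmoothFit:
    """Spline-vs-line Bayes factor; see :class:`SmoothVsLinear`."""
    return SmoothVsLinear(x, y, df=df).fit()


@dataclass
class ClusterReport:
    """Outcome of the two-stage cluster analysis."""

    labels: np.ndarray
    k: int
    silhouette: float
    has_structure: bool
    boundaries: list[float] = field(default_factory=list)

    @property
    def threshold(self) -> float | None:
        """The exposure boundary between clusters (None without structure)."""
        return self.boundaries[0] if self.has_structure and self.boundaries else None


class ExposureClusterer:
    """Two-stage clustering of (exposure, adjusted score) pairs.

    Stage 1: Ward hierarchical clustering on the standardized pairs, with k
    chosen by mean silhouette over k in 2..5.  Stage 2: k-means seeded from
    the stage-1 cluster centroids.  If the best silhouette falls below
    ``min_silhouette`` the data are flagged as having no cluster structure
    (homogeneous clouds sit well below 0.5; separated groups well above).
    The reported threshold is the midpoint between adjacent clusters'
    exposure ranges.
    """

    def __init__(self, exposure, scores, k_range=(2, 3, 4, 5),
                 min_silhouette: float = 0.5, force_k: int | None = None):
        self.exposure = np.asarray(exposure, dtype=float)
        self.scores = np.asarray(scores, dtype=float)
        if len(self.exposure) < 30:
            raise ValueError("need n >= 30")
        sds = np.array([self.exposure.std(), self.scores.std()])
        if np.any(sds == 0):
            raise ValueError("degenerate input: a coordinate has zero spread")
        self.k_range = tuple(k_range)
        self.min_silhouette = float(min_silhouette)
        self.force_k = force_k

    def _features(self) -> np.ndarray:
        Z = np.column_stack([self.exposure, self.scores])
        return (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)

    def fit(self) -> ClusterReport:
        Z = self._features()
        if self.force_k == 1:
            return ClusterReport(
                labels=np.zeros(len(Z), dtype=int), k=1,
                silhouette=np.nan, has_structure=False,
            )
        best = None
        ks = (self.force_k,) if self.force_k else self.k_range
        for k in ks:
            labels = AgglomerativeClustering(
                n_clusters=k, linkage="ward"
            ).fit_predict(Z)
            sil = silhouette_score(Z, labels)
            if best is None or sil > best[0]:
                best = (sil, k, labels)
        sil, k, labels = best
        centroids = np.vstack(
            [Z[labels == c].mean(axis=0) for c in range(k)]
        )
        labels = KMeans(
            n_clusters=k, init=centroids, n_init=1, random_state=0
        ).fit_predict(Z)
        has_structure = bool(sil >= self.min_silhouette) if not self.force_k \
            else True
        boundaries = []
        if has_structure:
            order = np.argsort(
                [self.exposure[labels == c].mean() for c in range(k)]
            )
            for lo_c, hi_c in zip(order[:-1], order[1:]):
                lo = self.exposure[labels == lo_c].max()
                hi = self.exposure[labels == hi_c].min()
                boundaries.append(float((lo + hi) / 2.0))
        return ClusterReport(
            labels=labels, k=k, silhouette=float(sil),
            has_structure=has_structure, boundaries=boundaries,
        )


def two_stage_cluster(exposure, scores, force_k: int | None = None) -> ClusterReport:
    """Two-stage cluster analysis; see :class:`ExposureClusterer`."""
    return ExposureClusterer(exposure, scores, force_k=force_k).fit()
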