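"""Voxel-wise Bayesian model comparison for group-level GLMs.

Given per-subject contrast volumes (one value per voxel summarizing task vs
rest BOLD signal) and a subjects x regressors design table, each candidate
GLM is scored per voxel by its **cross-validated log model evidence**
(cvLME): the design is split in half once (seeded, shared across models),
each half is fitted with a Bayesian linear model under a non-informative
conjugate normal–gamma prior, the resulting posterior is carried over as
the prior for the held-out half, and the closed-form log marginal
likelihood of the held-out data is accumulated over both folds.  Because
the evidence integrates over the parameters, extra regressors only help if
they genuinely predict out-of-sample — complexity is penalized
automatically.

Two models' maps are compared by subtraction, giving **log Bayes factor
(LBF) maps**; voxels above an LBF threshold "prefer" the first model
(LBF > 3 is strong evidence, ~BF 20).  Supra-threshold voxels are grouped
into connected clusters (26-neighborhood by default) and reported as a
cluster table; follow-ups extract ROI percent signal change and partial
correlations with residualized indices.

Closed form: with training data (X1, y1), n1 rows, the non-informative
normal–gamma limit gives the posterior
``beta | tau ~ N(b1, (tau X1'X1)^-1)``, ``tau ~ Gamma(n1/2, RSS1/2)`` with
b1 the OLS estimate.  The held-out y2 then follows a multivariate t with
n1 degrees of freedom, location X2 b1 and scale
``(RSS1/n1) (I + X2 (X1'X1)^-1 X2')``, whose log density is the per-fold
evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.ndimage
from scipy.special import gammaln

__all__ = [
    "VolumeGrid",
    "GroupDataset",
    "EvidenceMap",
    "LBFMap",
    "ClusterTable",
    "VoxelEvidenceModel",
    "EvidenceResults",
    "split_half",
    "cvlme_voxel",
    "cvlme_map",
    "lbf_map",
    "count_preferring_voxels",
    "threshold_clusters",
    "roi_percent_signal_change",
    "residualize",
    "partial_correlation",
    "build_design",
]


@dataclass
class VolumeGrid:
    """A 3D voxel grid with an analysis mask (0-based voxel coordinates)."""

    dims: tuple[int, int, int]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.dims = tuple(int(d) for d in self.dims)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.dims:
            raise ValueError("mask shape must equal dims")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def embed(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a masked-voxel vector back into the 3D volume."""
        vol = np.full(self.dims, fill, dtype=float)
        vol[self.mask] = values
        return vol

    def compatible(self, other: "VolumeGrid") -> bool:
        return self.dims == other.dims and np.array_equal(self.mask, other.mask)


@dataclass
class GroupDataset:
    """Per-subject contrast values on a shared grid plus the design table.

    ``contrast`` has one row per subject and one column per masked voxel;
    ``design`` is a subjects x regressors DataFrame (numeric after
    encoding).  ``baseline`` optionally carries per-subject mean baseline
    volumes for percent-signal-change follow-ups.
    """

    subjects: list[str]
    grid: VolumeGrid
    contrast: np.ndarray
    design: pd.DataFrame
    baseline: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.contrast = np.asarray(self.contrast, dtype=float)
        n = len(self.subjects)
        if self.contrast.shape != (n, self.grid.n_voxels):
            raise ValueError("contrast must be subjects x masked voxels")
        if len(self.design) != n:
            raise ValueError("design rows must align with subjects")
        if n <= self.design.shape[1] + 2:
            raise ValueError("need n_subjects > n_regressors + 2")


@dataclass
class EvidenceMap:
    """Per-voxel cvLME values for one model."""

    model: str
    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_voxels,):
            raise ValueError("values must be one per masked voxel")


@dataclass
class LBFMap:
    """Voxel-wise log Bayes factor: cvLME(model_a) - cvLME(model_b)."""

    model_a: str
    model_b: str
    grid: VolumeGrid
    values: np.ndarray

    def volume(self, fill: float = 0.0) -> np.ndarray:
        return self.grid.embed(self.values, fill=fill)


@dataclass
class ClusterTable:
    """Supra-threshold clusters, largest first."""

    rows: pd.DataFrame  # cluster_id, size, peak_lbf, peak_x, peak_y, peak_z
    threshold: float
    min_size: int

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def empty(self) -> bool:
        return len(self.rows) == 0


def split_half(n_subjects: int, seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Random half-split of subject indices, deterministic given the seed.

    The default seed is the number of datasets, so every model of the same
    data gets the same partition without coordination.  For odd n the first
    part receives the extra subject.
    """
    if n_subjects < 4:
        raise ValueError("need at least 4 subjects to split")
    if seed is None:
        seed = n_subjects
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_subjects)
    half = (n_subjects + 1) // 2
    return np.sort(perm[:half]), np.sort(perm[half:])


def _heldout_logpred_many(
    X1: np.ndarray, Y1: np.ndarray, X2: np.ndarray, Y2: np.ndarray
) -> np.ndarray:
    """Log marginal likelihood of held-out Y2 columns given training Y1.

    Vectorized over voxels (columns of Y1/Y2).  Non-informative conjugate
    normal–gamma training posterior; multivariate-t held-out density.
    """
    n1, k = X1.shape
    n2 = X2.shape[0]
    if n1 <= k or n2 == 0:
        raise ValueError("each split part needs more rows than regressors")
    G1 = X1.T @ X1
    if np.linalg.matrix_rank(G1) < k:
        raise ValueError("rank-deficient design within a split part")
    cho = scipy.linalg.cho_factor(G1)
    B1 = scipy.linalg.cho_solve(cho, X1.T @ Y1)           # k x V
    R1 = Y1 - X1 @ B1
    rss1 = np.einsum("ij,ij->j", R1, R1)                  # V
    if np.any(rss1 <= 0):
        raise ValueError("zero training residual variance at some voxel")
    nu = float(n1)
    scale0 = np.eye(n2) + X2 @ scipy.linalg.cho_solve(cho, X2.T)
    sign, logdet0 = np.linalg.slogdet(scale0)
    L0 = scipy.linalg.cho_factor(scale0)
    delta = Y2 - X2 @ B1                                  # n2 x V
    quad = np.einsum("ij,ij->j", delta, scipy.linalg.cho_solve(L0, delta))
    s2 = rss1 / nu                                        # per-voxel scale
    return (
        gammaln((nu + n2) / 2.0)
        - gammaln(nu / 2.0)
        - (n2 / 2.0) * np.log(nu * np.pi)
        - 0.5 * (logdet0 + n2 * np.log(s2))
        - ((nu + n2) / 2.0) * np.log1p(quad / (s2 * nu))
    )


def cvlme_voxel(
    y: np.ndarray, X: np.ndarray, splits: tuple[np.ndarray, np.ndarray]
) -> float:
    """Cross-validated log model evidence for a single voxel.

    Sum over the two folds of the held-out log marginal likelihood, each
    fold trained on the complementary half.
    """
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    X = np.asarray(X, dtype=float)
    i1, i2 = splits
    out = _heldout_logpred_many(X[i1], y[i1], X[i2], y[i2])
    out = out + _heldout_logpred_many(X[i2], y[i2], X[i1], y[i1])
    return float(out[0])


def build_design(table: pd.DataFrame, regressors: list[str]) -> np.ndarray:
    """Numeric design matrix with intercept from a covariate table.

    Categorical (object) columns are treatment-coded with lexicographically
    sorted levels, first level as reference.
    """
    cols = [np.ones(len(table))]
    for term in regressors:
        col = table[term]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(map(str, col.dropna().unique()))
            for level in levels[1:]:
                cols.append((col.astype(str) == level).astype(float).to_numpy())
        else:
            cols.append(col.astype(float).to_numpy())
    return np.column_stack(cols)


def cvlme_map(
    dataset: GroupDataset,
    regressors: list[str],
    splits: tuple[np.ndarray, np.ndarray] | None = None,
    model_name: str | None = None,
) -> EvidenceMap:
    """cvLME at every masked voxel for one GLM (vectorized over voxels).

    The same split must be used for every model describing the same data;
    when ``splits`` is omitted it is derived deterministically from the
    number of subjects.
    """
    missing = [r for r in regressors if r not in dataset.design.columns]
    if missing:
        raise KeyError(f"regressors not in design table: {missing}")
    X = build_design(dataset.design, regressors)
    if splits is None:
        splits = split_half(len(dataset.subjects))
    i1, i2 = splits
    Y = dataset.contrast  # subjects x voxels
    try:
        vals = _heldout_logpred_many(X[i1], Y[i1], X[i2], Y[i2])
        vals = vals + _heldout_logpred_many(X[i2], Y[i2], X[i1], Y[i1])
    except ValueError as err:
        raise ValueError(f"cvLME failed for model {model_name or regressors}: {err}")
    return EvidenceMap(
        model=model_name or "+".join(regressors),
        grid=dataset.grid,
        values=vals,
    )


def lbf_map(a: EvidenceMap, b: EvidenceMap) -> LBFMap:
    """Voxel-wise log Bayes factor map: a - b (antisymmetric in its inputs)."""
    if not a.grid.compatible(b.grid):
        raise ValueError("evidence maps live on different grids")
    return LBFMap(
        model_a=a.model, model_b=b.model, grid=a.grid, values=a.values - b.values
    )


def count_preferring_voxels(lbf: LBFMap, thr: float) -> int:
    """Number of masked voxels with LBF strictly above the threshold."""
    if thr < 0:
        raise ValueError("threshold must be >= 0")
    return int(np.sum(lbf.values > thr))


_STRUCTURES = {
    26: np.ones((3, 3, 3), dtype=bool),
    6: scipy.ndimage.generate_binary_structure(3, 1),
}


def threshold_clusters(
    lbf: LBFMap, thr: float, min_size: int = 10, connectivity: int = 26
) -> ClusterTable:
    """Connected supra-threshold clusters of at least ``min_size`` voxels.

    Components are found at the given 3D connectivity (26-neighborhood by
    default, 6 selectable) and reported largest-first with the peak LBF and
    its 0-based voxel coordinates.
    """
    if thr < 0 or min_size < 1:
        raise ValueError("thr must be >= 0 and min_size >= 1")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6 or 26")
    vol = lbf.grid.embed(lbf.values, fill=-np.inf)
    supra = vol > thr
    labels, n_found = scipy.ndimage.label(supra, structure=_STRUCTURES[connectivity])
    rows = []
    for lab in range(1, n_found + 1):
        where = labels == lab
        size = int(where.sum())
        if size < min_size:
            continue
        vals = np.where(where, vol, -np.inf)
        peak = np.unravel_index(np.argmax(vals), vol.shape)
        rows.append(
            {
                "size": size,
                "peak_lbf": float(vol[peak]),
                "peak_x": int(peak[0]),
                "peak_y": int(peak[1]),
                "peak_z": int(peak[2]),
            }
        )
    rows.sort(key=lambda r: (-r["size"], -r["peak_lbf"]))
    df = pd.DataFrame(
        rows, columns=["size", "peak_lbf", "peak_x", "peak_y", "peak_z"]
    )
    df.insert(0, "cluster_id", np.arange(1, len(df) + 1))
    return ClusterTable(rows=df, threshold=thr, min_size=min_size)


def roi_percent_signal_change(
    contrast: np.ndarray,
    baseline: np.ndarray,
    grid: VolumeGrid,
    roi_mask: np.ndarray,
) -> np.ndarray:
    """Per-subject percent signal change within an ROI.

    ``100 * mean-over-ROI(contrast) / mean-over-ROI(baseline)`` per subject
    — a simplification of the featquery convention (no peristimulus
    scaling).  ``roi_mask`` is a boolean volume; only its voxels inside the
    analysis mask contribute.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != grid.dims:
        raise ValueError("ROI mask shape must match the grid")
    inside = roi_mask[grid.mask]
    if not inside.any():
        raise ValueError("ROI has no voxels inside the analysis mask")
    base = baseline[:, inside].mean(axis=1)
    if np.any(base == 0):
        raise ValueError("zero baseline mean within the ROI")
    return 100.0 * contrast[:, inside].mean(axis=1) / base


def residualize(target: np.ndarray, nuisance: pd.DataFrame | np.ndarray) -> np.ndarray:
    """OLS residuals of ``target`` on the nuisance columns (with intercept)."""
    y = np.asarray(target, dtype=float)
    Z = np.asarray(nuisance, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    X = np.column_stack([np.ones(len(y)), Z])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient nuisance design")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: pd.DataFrame | np.ndarray | None = None
) -> float:
    """Pearson correlation of covariate-residualized x and y.

    With no covariates this is the plain Pearson r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is not None and np.size(covariates) > 0:
        x = residualize(x, covariates)
        y = residualize(y, covariates)
    else:
        x = x - x.mean()
        y = y - y.mean()
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance residuals: correlation undefined")
    return float((x @ y) / (len(x) * sx * sy))


class EvidenceResults:
    """Evidence maps for a family of GLMs and their pairwise comparisons."""

    def __init__(self, dataset: GroupDataset, maps: dict[str, EvidenceMap],
                 splits: tuple[np.ndarray, np.ndarray]):
        self.dataset = dataset
        self.maps = maps
        self.splits = splits

    def lbf(self, model_a: str, model_b: str) -> LBFMap:
        return lbf_map(self.maps[model_a], self.maps[model_b])

    def preference_counts(
        self, thresholds=(3.0, 1.5)
    ) -> pd.DataFrame:
        """Voxel counts preferring each model over each other at each LBF thr."""
        names = list(self.maps)
        rows = []
        for a in names:
            for b in names:
                if a == b:
                    continue
                m = self.lbf(a, b)
                row = {"preferred": a, "over": b}
                for thr in thresholds:
                    row[f"lbf>{thr:g}"] = count_preferring_voxels(m, thr)
                rows.append(row)
        return pd.DataFrame(rows)

    def cluster_table(
        self,
        model_a: str,
        model_b: str,
        thr: float = 3.0,
        fallback_thr: float | None = 1.5,
        min_size: int = 10,
        connectivity: int = 26,
    ) -> ClusterTable:
        """Cluster table at ``thr``; falls back to ``fallback_thr`` if empty.

        The indices are strongly correlated, so comparisons between them
        often leave nothing at LBF > 3; the published pipeline then lowers
        the threshold to 1.5 rather than reporting an empty table.
        """
        m = self.lbf(model_a, model_b)
        table = threshold_clusters(m, thr, min_size=min_size,
                                   connectivity=connectivity)
        if table.empty and fallback_thr is not None:
            table = threshold_clusters(m, fallback_thr, min_size=min_size,
                                       connectivity=connectivity)
        return table

    def summary(self) -> str:
        counts = self.preference_counts()
        return (
            f"cvLME model comparison over {self.dataset.grid.n_voxels} voxels, "
            f"{len(self.dataset.subjects)} subjects, models "
            f"{list(self.maps)}\n" + counts.to_string(index=False)
        )


class VoxelEvidenceModel:
    """Model object: a family of group-level GLMs scored by cvLME per voxel.

    Parameters
    ----------
    dataset : GroupDataset
    model_specs : dict[str, list[str]]
        Mapping model name -> regressor columns of the design table (the
        intercept is implicit).  All models share one seeded half-split.
    seed : int, optional
        Split seed; defaults to the number of subjects.
    """

    def __init__(self, dataset: GroupDataset,
                 model_specs: dict[str, list[str]], seed: int | None = None):
        self.dataset = dataset
        self.model_specs = dict(model_specs)
        self.seed = seed

    @classmethod
    def index_ladder(
        cls,
        dataset: GroupDataset,
        covariates: list[str],
        index_columns=(
            "exposure_english",
            "diversity_h",
            "typological_diversity_qe",
        ),
        seed: int | None = None,
    ) -> "VoxelEvidenceModel":
        """GLM family mirroring the behavioral ladder: m0 + one index each."""
        specs = {"m0": list(covariates)}
        for i, col in enumerate(index_columns):
            specs[f"m{i + 1}"] = list(covariates) + [col]
        return cls(dataset, specs, seed=seed)

    def fit(self) -> EvidenceResults:
        splits = split_half(len(self.dataset.subjects), seed=self.seed)
        maps = {
            name: cvlme_map(self.dataset, regs, splits=splits, model_name=name)
            for name, regs in self.model_specs.items()
        }
        return EvidenceResults(self.dataset, maps, splits)
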