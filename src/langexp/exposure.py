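"""Language-exposure indices for multilingual children.

Each child's language experience is summarized by cumulative years of
exposure to each language (BiLEC-style questionnaire output).  Three indices
describe that experience:

* **Exposure to English** — cumulative years of English exposure divided by
  age at testing (a proportion of life).
* **Diversity** — Shannon entropy (bits) of the exposure proportions
  ``H = -sum p_i log2 p_i``: variability of the input irrespective of which
  languages are involved.
* **Typological Diversity** — Rao's quadratic entropy
  ``QE = sum_ij d_ij p_i p_j`` with d_ij the pairwise lexical distance
  (LDND): the expected distance between two random draws from the exposure
  distribution.

The module also applies the sample filters the analyses rely on: the
majority-English rule (>= 50% of life exposed to English) and the bilingual
rule (two languages covering >= 95% of exposure, one of them English).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lexdist import DistanceMatrix

__all__ = [
    "ChildExposureProfile",
    "IndexSet",
    "english_exposure_proportion",
    "exposure_proportions",
    "shannon_diversity",
    "rao_typological_diversity",
    "compute_indices",
    "index_table",
    "english_majority_filter",
    "bilingual_subsample_filter",
    "read_exposure_csv",
]

ENGLISH = "English"
PROPORTION_TOL = 1e-9


@dataclass
class ChildExposureProfile:
    """One child's exposure history, covariates and outcomes."""

    child_id: str
    age_years: float
    exposure_years: dict[str, float]
    gender: str = "f"
    ses_years: float = np.nan
    nonverbal_score: float = np.nan
    english_from_birth: bool = True
    receptive_score: float | None = None
    expressive_score: float | None = None
    handedness: str | None = None
    dprime: float | None = None
    headphone_model: str | None = None
    l2_language: str | None = field(default=None, compare=False)
    l2_distance: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.age_years <= 0:
            raise ValueError(f"{self.child_id}: age must be positive")
        self.exposure_years = {
            str(k): float(v) for k, v in self.exposure_years.items()
        }
        if any(v < 0 for v in self.exposure_years.values()):
            raise ValueError(f"{self.child_id}: negative exposure years")
        if not any(v > 0 for v in self.exposure_years.values()):
            raise ValueError(f"{self.child_id}: no language with exposure > 0")
        for lang, years in self.exposure_years.items():
            if years > self.age_years + 1e-9:
                raise ValueError(
                    f"{self.child_id}: exposure to {lang} ({years}) exceeds "
                    f"age ({self.age_years})"
                )

    @property
    def languages(self) -> list[str]:
        return [l for l, y in self.exposure_years.items() if y > 0]


@dataclass
class IndexSet:
    """The three exposure indices for one child."""

    exposure_english: float
    diversity_h: float
    typological_diversity_qe: float


def english_exposure_proportion(profile: ChildExposureProfile) -> float:
    """Cumulative English exposure divided by age at testing, capped at 1."""
    years = profile.exposure_years.get(ENGLISH)
    if years is None:
        warnings.warn(
            f"{profile.child_id}: no English exposure entry, treated as 0",
            stacklevel=2,
        )
        years = 0.0
    return min(years / profile.age_years, 1.0)


def exposure_proportions(profile: ChildExposureProfile) -> dict[str, float]:
    """Proportion of total exposure time per language (sums to 1).

    Cumulative exposures need not sum to the child's age (languages can be
    heard concurrently), so proportions are taken over the summed exposure,
    not over age.
    """
    total = sum(profile.exposure_years.values())
    if total <= 0:
        raise ValueError(f"{profile.child_id}: all-zero exposure")
    return {l: y / total for l, y in profile.exposure_years.items() if y > 0}


def _check_proportions(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > PROPORTION_TOL:
        raise ValueError(f"proportions sum to {p.sum()}, not 1")
    return p


def shannon_diversity(p) -> float:
    """Shannon entropy H = -sum p_i log2 p_i in bits, with 0 log 0 := 0."""
    if isinstance(p, dict):
        p = list(p.values())
    p = _check_proportions(np.asarray(p))
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def rao_typological_diversity(p: dict[str, float], D: DistanceMatrix) -> float:
    """Rao's quadratic entropy QE = sum_i sum_j d_ij p_i p_j.

    ``p`` maps language -> exposure proportion; ``D`` supplies the clipped
    pairwise distances.  Zero for monolinguals (single positive p_i) and
    invariant to languages with p_i = 0.
    """
    langs = sorted(p)
    missing = [l for l in langs if l not in D.language_ids]
    if missing:
        raise ValueError(f"language(s) missing from distance matrix: {missing}")
    weights = _check_proportions(np.array([p[l] for l in langs]))
    sub = D.submatrix(langs)
    return float(weights @ sub @ weights)


def compute_indices(
    profile: ChildExposureProfile, D: DistanceMatrix
) -> IndexSet:
    p = exposure_proportions(profile)
    return IndexSet(
        exposure_english=english_exposure_proportion(profile),
        diversity_h=shannon_diversity(p),
        typological_diversity_qe=rao_typological_diversity(p, D),
    )


def index_table(
    profiles: list[ChildExposureProfile], D: DistanceMatrix
) -> pd.DataFrame:
    """Per-child indices + covariates + outcomes as one analysis DataFrame."""
    rows = []
    for pr in profiles:
        idx = compute_indices(pr, D)
        rows.append(
            {
                "child_id": pr.child_id,
                "age_years": pr.age_years,
                "gender": pr.gender,
                "ses_years": pr.ses_years,
                "nonverbal_score": pr.nonverbal_score,
                "exposure_english": idx.exposure_english,
                "diversity_h": idx.diversity_h,
                "typological_diversity_qe": idx.typological_diversity_qe,
                "receptive_score": pr.receptive_score,
                "expressive_score": pr.expressive_score,
                "l2_language": pr.l2_language,
                "l2_distance": pr.l2_distance,
                "handedness": pr.handedness,
                "dprime": pr.dprime,
                "headphone_model": pr.headphone_model,
            }
        )
    return pd.DataFrame(rows).set_index("child_id")


def english_majority_filter(
    profiles: list[ChildExposureProfile],
) -> tuple[list[ChildExposureProfile], int]:
    """Keep children exposed to English for at least 50% of their lives.

    Children below the majority rule would make the proportion-based
    diversity indices ambiguous (a 0.4/0.6 and a 0.6/0.4 bilingual get the
    same H and QE).  The boundary is closed: exactly 0.5 is retained.
    Returns (retained, n_removed).
    """
    kept = [p for p in profiles if english_exposure_proportion(p) >= 0.5]
    return kept, len(profiles) - len(kept)


def bilingual_subsample_filter(
    profiles: list[ChildExposureProfile],
    D: DistanceMatrix | None = None,
) -> tuple[list[ChildExposureProfile], int]:
    """Keep functional bilinguals: top-two languages cover >= 95% of exposure.

    One of the top two must be English.  The second language's identity and
    (when a distance matrix is given) its clipped LDND to English are
    attached to each retained profile as ``l2_language`` / ``l2_distance``.
    Monolingual-English children pass trivially with an L2 distance of 0.
    Returns (retained, n_removed).
    """
    kept = []
    for pr in profiles:
        p = exposure_proportions(pr)
        ranked = sorted(p.items(), key=lambda kv: (-kv[1], kv[0]))
        top_two = ranked[:2]
        if sum(v for _, v in top_two) < 0.95:
            continue
        if ENGLISH not in {l for l, _ in top_two}:
            continue
        others = [l for l, _ in top_two if l != ENGLISH]
        pr.l2_language = others[0] if others else None
        if D is not None:
            pr.l2_distance = (
                D.get(ENGLISH, pr.l2_language) if pr.l2_language else 0.0
            )
        kept.append(pr)
    return kept, len(profiles) - len(kept)


def read_exposure_csv(exposure_path, covariate_path=None) -> list[ChildExposureProfile]:
    """Build profiles from long-format exposure CSV (+ optional covariates).

    Exposure CSV columns: ``child_id, age_years, language_id, exposure_years``
    (one row per language).  Covariate CSV is keyed by ``child_id`` and may
    carry gender, ses_years, nonverbal_score, outcome scores and the
    fMRI-session covariates.
    """
    exp = pd.read_csv(exposure_path)
    cov = (
        pd.read_csv(covariate_path).set_index("child_id")
        if covariate_path is not None
        else None
    )
    profiles = []
    for child, grp in exp.groupby("child_id", sort=True):
        kwargs: dict = {}
        if cov is not None and child in cov.index:
            row = cov.loc[child]
            for key in (
                "gender",
                "ses_years",
                "nonverbal_score",
                "receptive_score",
                "expressive_score",
                "handedness",
                "dprime",
                "headphone_model",
            ):
                if key in row.index and pd.notna(row[key]):
                    kwargs[key] = row[key]
            if "english_from_birth" in row.index:
                kwargs["english_from_birth"] = bool(row["english_from_birth"])
        profiles.append(
            ChildExposureProfile(
                child_id=str(child),
                age_years=float(grp["age_years"].iloc[0]),
                exposure_years=dict(
                    zip(grp["language_id"].astype(str), grp["exposure_years"])
                ),
                **kwargs,
            )
        )
    return profiles
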