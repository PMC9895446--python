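"""Synthetic study inputs with the statistical structure the analyses assume.

The cohort the pipeline was designed around — ~160 kindergartners (ages
5.05–6.41) exposed to one to five languages from a pool of up to 37, with
English heard from birth — is not publicly available, so this module
generates stand-ins for every input: word lists with controlled pairwise
divergence, exposure histories spanning the monolingual-to-quintilingual
continuum, vocabulary outcomes driven linearly by a chosen exposure index at
a requested effect size, and per-subject contrast volumes whose ROI signal
is coupled to an index.

All randomness flows from a single seed through spawned generator streams,
so a fixed seed reproduces every artifact byte-for-byte.

The lexicon mutation model (per-character substitution / insertion /
deletion at a language-specific rate) is deliberately non-linguistic: it is
sufficient to *order* pairwise LDND values, which is all the downstream
indices consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .evidence import GroupDataset, VolumeGrid, residualize
from .exposure import ENGLISH, ChildExposureProfile, index_table
from .lexdist import N_CONCEPTS, DistanceMatrix, WordList, distance_matrix

__all__ = [
    "CohortConfig",
    "synth_lexicons",
    "synth_cohort",
    "synth_outcomes",
    "synth_contrast_maps",
    "LANGUAGE_POOL",
]

#: simplified segment inventory (one character per segment)
ALPHABET = "ptkbdgmnszlrwjhfv" + "aeiou"

#: label pool for generated languages (English always first)
LANGUAGE_POOL = [ENGLISH] + [f"L{i:02d}" for i in range(1, 37)]

#: breakdown of children by number of languages (1..5), matching the
#: published cohort's 11/79/47/18/7 of 162
N_LANGUAGES_PROBS = np.array([11, 79, 47, 18, 7], dtype=float) / 162.0


@dataclass
class CohortConfig:
    """Study-condition defaults for the synthetic cohort."""

    n_children: int = 160
    language_pool_size: int = 37
    max_languages_per_child: int = 5
    age_range: tuple[float, float] = (5.05, 6.41)
    english_proportion_range: tuple[float, float] = (0.2, 1.0)
    dirichlet_concentration: float = 1.0
    ses_mean: float = 17.0
    ses_sd: float = 1.99
    nonverbal_mean: float = 100.0
    nonverbal_sd: float = 15.0
    seed: int = 0
    n_languages_probs: np.ndarray = field(
        default_factory=lambda: N_LANGUAGES_PROBS.copy()
    )

    def __post_init__(self) -> None:
        if self.n_children <= 0 or not (2 <= self.language_pool_size <= 37):
            raise ValueError("invalid cohort sizes")
        if self.max_languages_per_child < 1:
            raise ValueError("max_languages_per_child must be >= 1")


def _mutate(form: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for ch in form:
        r = rng.random()
        if r < rate:  # substitution
            out.append(ALPHABET[rng.integers(len(ALPHABET))])
        elif r < rate * 1.25:  # deletion
            continue
        else:
            out.append(ch)
        if rng.random() < rate * 0.25:  # insertion after this segment
            out.append(ALPHABET[rng.integers(len(ALPHABET))])
    if not out:
        out.append(ALPHABET[rng.integers(len(ALPHABET))])
    return "".join(out)


def synth_lexicons(
    config: CohortConfig | None = None,
    n_concepts: int = N_CONCEPTS,
    rates: np.ndarray | None = None,
    min_spearman: float = 0.8,
) -> tuple[list[WordList], DistanceMatrix, np.ndarray]:
    """Word lists with controlled pairwise divergence, plus realized LDND.

    One ancestral form per concept is generated, then each language copies
    it with per-character mutations at a language-specific divergence rate
    (English: rate 0, i.e. the ancestral forms themselves).  The *target*
    distance for a pair is ``1 - (1 - r_i)(1 - r_j)``; realized clipped
    LDND must correlate with the target ordering at Spearman rho >=
    ``min_spearman`` (asserted), which the mutation model comfortably
    achieves.

    Returns ``(wordlists, realized_distance_matrix, target_matrix)``.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n_lang = config.language_pool_size
    if rates is None:
        # English 0; the rest spread over (0.15, 0.95) for a wide LDND range
        rates = np.concatenate(
            [[0.0], np.linspace(0.15, 0.95, n_lang - 1)]
        )
        rng.shuffle(rates[1:])
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (n_lang,):
        raise ValueError("need one divergence rate per language")
    if np.ptp(rates) == 0 and n_lang > 2:
        raise ValueError("all-equal rates cannot realize distinct targets")
    ancestral = [
        "".join(
            ALPHABET[rng.integers(len(ALPHABET))]
            for _ in range(rng.integers(3, 8))
        )
        for _ in range(n_concepts)
    ]
    labels = LANGUAGE_POOL[:n_lang]
    wordlists = []
    for lang, rate in zip(labels, rates):
        entries = {
            c + 1: [_mutate(ancestral[c], rate, rng)] for c in range(n_concepts)
        }
        wordlists.append(WordList(language_id=lang, entries=entries))
    realized = distance_matrix(wordlists)
    target = 1.0 - np.outer(1.0 - rates, 1.0 - rates)
    np.fill_diagonal(target, 0.0)
    iu = np.triu_indices(n_lang, k=1)
    if len(iu[0]) >= 3:  # rank correlation needs a few pairs to mean anything
        rho = scipy.stats.spearmanr(target[iu], realized.values[iu]).statistic
        if np.isfinite(rho) and not rho >= min_spearman:
            raise AssertionError(
                f"realized LDND ordering too far from target (rho={rho:.3f})"
            )
    return wordlists, realized, target


def synth_cohort(
    config: CohortConfig | None = None,
    languages: list[str] | None = None,
) -> list[ChildExposureProfile]:
    """Exposure cohort spanning the monolingual-to-quintilingual continuum.

    Every child hears English from birth; the number of languages follows
    the published 1..5 breakdown; each multilingual child's English share
    of total exposure is drawn uniformly over the configured range (default
    0.2–1.0, so the majority-English filter is genuinely exercised) with
    the remainder split by a symmetric Dirichlet over the other languages.
    Covariates: SES ~ N(17, 1.99) years of parental education, gender
    balanced, nonverbal standard score ~ N(100, 15).
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    pool = languages or LANGUAGE_POOL[: config.language_pool_size]
    if ENGLISH not in pool:
        raise ValueError("language pool must include English")
    others = [l for l in pool if l != ENGLISH]
    probs = np.asarray(config.n_languages_probs[: config.max_languages_per_child])
    probs = probs / probs.sum()
    lo, hi = config.english_proportion_range
    profiles = []
    for i in range(config.n_children):
        age = rng.uniform(*config.age_range)
        n_lang = 1 + rng.choice(len(probs), p=probs)
        n_lang = min(n_lang, len(others) + 1)
        if n_lang == 1:
            shares = {ENGLISH: 1.0}
        else:
            p_en = rng.uniform(lo, hi)
            rest = rng.dirichlet(
                np.full(n_lang - 1, config.dirichlet_concentration)
            ) * (1.0 - p_en)
            chosen = rng.choice(len(others), size=n_lang - 1, replace=False)
            shares = {ENGLISH: p_en}
            shares.update(
                {others[j]: float(r) for j, r in zip(chosen, rest) if r > 0}
            )
        profiles.append(
            ChildExposureProfile(
                child_id=f"c{i:03d}",
                age_years=float(age),
                exposure_years={l: s * age for l, s in shares.items()},
                gender="f" if i % 2 == 0 else "m",
                ses_years=float(rng.normal(config.ses_mean, config.ses_sd)),
                nonverbal_score=float(
                    rng.normal(config.nonverbal_mean, config.nonverbal_sd)
                ),
                english_from_birth=True,
                handedness=None,
                dprime=None,
                headphone_model=None,
            )
        )
    # shuffle gender assignment deterministically to decouple it from id order
    genders = [p.gender for p in profiles]
    rng.shuffle(genders)
    for p, g in zip(profiles, genders):
        p.gender = g
    ee = [min(p.exposure_years[ENGLISH] / p.age_years, 1.0) for p in profiles]
    if config.n_children >= 40 and config.max_languages_per_child > 1:
        assert min(ee) < 0.5 < max(ee), (
            "cohort does not straddle the 50% English filter"
        )
    return profiles


#: default covariate effects on the vocabulary scale (standard-score units)
DEFAULT_COVARIATE_BETAS = {
    "age_years": 4.0,
    "ses_years": 1.0,
    "nonverbal_score": 0.3,
    "gender_f": 1.0,
}

_NUMERIC_COVARIATES = ["age_years", "ses_years", "nonverbal_score"]


def _covariate_design(table: pd.DataFrame) -> np.ndarray:
    cols = [table[c].to_numpy(float) for c in _NUMERIC_COVARIATES]
    cols.append((table["gender"] == "f").to_numpy(float))
    return np.column_stack(cols)


def synth_outcomes(
    profiles: list[ChildExposureProfile],
    D: DistanceMatrix,
    index: str = "typological_diversity_qe",
    f2: float = 0.06,
    sigma: float = 15.0,
    sign: int | None = None,
    outcome: str = "receptive_score",
    covariate_betas: dict | None = None,
    seed: int = 0,
) -> float:
    """Attach linearly generated vocabulary scores; returns the realized f².

    The index slope is calibrated on the realized cohort: with v the
    variance of the index after residualizing on the covariates,
    ``beta = sign * sqrt(f2 * sigma**2 / v)`` yields (in expectation) the
    requested Cohen's f² for the index term over the baseline model.
    ``f2 = 0`` gives the null regime.  Sign defaults to the published
    direction (positive for English exposure, negative for the diversity
    indices).  Scores land on a standard-score-like scale (noise SD 15).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    table = index_table(profiles, D)
    if sign is None:
        sign = 1 if index == "exposure_english" else -1
    betas = DEFAULT_COVARIATE_BETAS | (covariate_betas or {})
    Z = _covariate_design(table)
    x = table[index].to_numpy(float)
    resid = residualize(x, Z)
    v = float(resid.var(ddof=1))
    if f2 > 0 and v == 0:
        raise ValueError(f"index {index} has no variance beyond covariates")
    beta_index = sign * np.sqrt(f2 * sigma**2 / v) if f2 > 0 else 0.0
    mean = (
        100.0
        + betas["age_years"] * (table["age_years"].to_numpy(float) - 5.7)
        + betas["ses_years"] * (table["ses_years"].to_numpy(float) - 17.0)
        + betas["nonverbal_score"]
        * (table["nonverbal_score"].to_numpy(float) - 100.0)
        + betas["gender_f"] * (table["gender"] == "f").to_numpy(float)
        + beta_index * x
    )
    noise = rng.normal(0.0, sigma, size=len(profiles)) if sigma > 0 else 0.0
    scores = mean + noise
    for p, s in zip(profiles, scores):
        setattr(p, outcome, float(s))
    # realized f2 from the generating fit itself
    y = scores
    X_full = np.column_stack([np.ones(len(y)), Z, x])
    X_red = np.column_stack([np.ones(len(y)), Z])
    def _r2(X):
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        tss = ((y - y.mean()) ** 2).sum()
        return 1.0 - (r @ r) / tss
    r2f, r2r = _r2(X_full), _r2(X_red)
    return (r2f - r2r) / (1.0 - r2f) if r2f < 1.0 else np.inf


def synth_interaction_outcomes(
    profiles: list[ChildExposureProfile],
    beta_exposure: float = 30.0,
    beta_distance: float = -10.0,
    beta_interaction: float = 0.0,
    sigma: float = 15.0,
    outcome: str = "receptive_score",
    seed: int = 0,
) -> None:
    """Scores for the bilingual ladder: main effects ± a true interaction.

    Requires ``l2_distance`` to be attached (run the bilingual filter
    first).  ``beta_interaction = 0`` generates the main-effects-only
    regime the interaction rung should reject.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[3])
    for p in profiles:
        if p.l2_distance is None:
            raise ValueError(f"{p.child_id}: l2_distance not attached")
        ee = min(p.exposure_years.get(ENGLISH, 0.0) / p.age_years, 1.0)
        mean = (
            100.0
            + beta_exposure * ee
            + beta_distance * p.l2_distance
            + beta_interaction * ee * p.l2_distance
            + 1.0 * (p.gender == "f")
            + 0.3 * (p.nonverbal_score - 100.0)
            + 1.0 * (p.ses_years - 17.0)
            + 4.0 * (p.age_years - 5.7)
        )
        setattr(p, outcome, float(mean + rng.normal(0.0, sigma)))


def synth_contrast_maps(
    profiles: list[ChildExposureProfile],
    D: DistanceMatrix,
    dims: tuple[int, int, int] = (16, 16, 8),
    roi_corner: tuple[int, int, int] = (4, 4, 2),
    roi_shape: tuple[int, int, int] = (5, 3, 2),
    coupling_beta: float = 2.5,
    noise_sd: float = 1.0,
    index: str = "typological_diversity_qe",
    orthogonalize_on: tuple[str, ...] = (),
    baseline_level: float = 1000.0,
    seed: int = 0,
) -> tuple[GroupDataset, np.ndarray]:
    """Per-subject contrast volumes with index-coupled activation in an ROI.

    ROI voxels carry ``coupling_beta * component + noise`` per subject,
    where the component is the chosen index residualized on the covariates
    (and on any extra columns in ``orthogonalize_on``) and standardized;
    everywhere else is pure noise.  Residualizing on the covariates keeps
    the signal inside the span of the GLM that carries the index, so that
    model can fully explain its own ROI activation while competitors
    cannot — extend ``orthogonalize_on`` only if the competitor set should
    lose additional shared variance.  The design table includes the three
    indices and the full neuroimaging covariate set (age, gender, SES,
    nonverbal score, handedness laterality quotient, d-prime, headphone
    model).  Baseline volumes are flat at ``baseline_level`` for percent-
    signal-change follow-ups.

    Returns ``(dataset, roi_mask)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(5)[4])
    n = len(profiles)
    table = index_table(profiles, D)
    # fMRI-session covariates: continuous laterality and d', balanced headphones
    lat = np.clip(rng.normal(70.0, 30.0, size=n), -100.0, 100.0)
    dprime = rng.normal(2.5, 0.6, size=n)
    headphones = np.array(["hpA", "hpB"] * ((n + 1) // 2))[:n]
    rng.shuffle(headphones)
    for p, l, d, h in zip(profiles, lat, dprime, headphones):
        p.handedness, p.dprime, p.headphone_model = float(l), float(d), str(h)
    design = pd.DataFrame(
        {
            "exposure_english": table["exposure_english"].to_numpy(float),
            "diversity_h": table["diversity_h"].to_numpy(float),
            "typological_diversity_qe": table[
                "typological_diversity_qe"
            ].to_numpy(float),
            "age_years": table["age_years"].to_numpy(float),
            "gender": table["gender"].to_numpy(),
            "ses_years": table["ses_years"].to_numpy(float),
            "nonverbal_score": table["nonverbal_score"].to_numpy(float),
            "handedness": lat,
            "dprime": dprime,
            "headphone_model": headphones,
        },
        index=table.index,
    )
    nuisance = np.column_stack(
        [_covariate_design(table)]
        + [table[c].to_numpy(float)[:, None] for c in orthogonalize_on]
    )
    component = residualize(table[index].to_numpy(float), nuisance)
    sd = component.std(ddof=1)
    if sd == 0 and coupling_beta != 0:
        raise ValueError(f"index {index} has no unique variance to couple")
    if sd > 0:
        component = component / sd
    mask = np.ones(dims, dtype=bool)
    grid = VolumeGrid(dims=dims, mask=mask)
    roi_mask = np.zeros(dims, dtype=bool)
    sx, sy, sz = roi_corner
    ex, ey, ez = (c + s for c, s in zip(roi_corner, roi_shape))
    roi_mask[sx:ex, sy:ey, sz:ez] = True
    if not roi_mask.any() or roi_mask.sum() != np.prod(roi_shape):
        raise ValueError("ROI must lie within the grid")
    contrast = rng.normal(0.0, noise_sd, size=(n, grid.n_voxels))
    roi_flat = roi_mask[mask]
    contrast[:, roi_flat] += coupling_beta * component[:, None]
    baseline = np.full((n, grid.n_voxels), baseline_level)
    dataset = GroupDataset(
        subjects=list(table.index),
        grid=grid,
        contrast=contrast,
        design=design,
        baseline=baseline,
        affine=np.eye(4),
    )
    return dataset, roi_mask
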