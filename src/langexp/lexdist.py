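"""Normalized lexical distances between languages from 40-concept word lists.

Languages are compared through standardized word lists in the ASJP tradition:
40 core concepts, each with one or more forms in a simplified one-character-
per-segment orthography.  The distance between two word forms is the
Levenshtein (edit) distance; normalizing by the longer word's length gives
LDN, and dividing the mean same-concept LDN by the mean cross-concept LDN
gives LDND, which corrects for chance resemblance between phoneme
inventories.  LDND is the pairwise dissimilarity d_ij that feeds Rao's
quadratic entropy downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WordList",
    "DistanceMatrix",
    "levenshtein",
    "ldn",
    "ldnd",
    "distance_matrix",
    "read_wordlists",
    "write_wordlists",
]

N_CONCEPTS = 40


def _clean(form: str) -> str:
    return form.strip().lower()


@dataclass
class WordList:
    """One language's concept -> word-forms table.

    Parameters
    ----------
    language_id : str
        Short language label (e.g. ``"English"``).
    entries : dict[int, list[str]]
        Mapping from concept id to the non-empty list of word forms
        (synonyms) attested for that concept.  Forms are lower-cased and
        stripped of surrounding whitespace on construction.
    """

    language_id: str
    entries: dict[int, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[int, list[str]] = {}
        for concept, forms in self.entries.items():
            forms = [_clean(f) for f in forms]
            if not forms or any(len(f) == 0 for f in forms):
                raise ValueError(
                    f"{self.language_id}: concept {concept} has an empty form"
                )
            cleaned[int(concept)] = forms
        self.entries = cleaned

    @property
    def concepts(self) -> set[int]:
        return set(self.entries)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise LDND table over a set of languages.

    ``values`` holds distances clipped to [0, 1] (raw LDND can exceed 1 by
    chance); ``raw_values`` keeps the unclipped ratios.  ``n_shared_concepts``
    records how many concepts each pair was compared on, so callers can
    enforce a floor.
    """

    language_ids: list[str]
    values: np.ndarray
    raw_values: np.ndarray
    n_shared_concepts: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.raw_values = np.asarray(self.raw_values, dtype=float)
        self.n_shared_concepts = np.asarray(self.n_shared_concepts, dtype=int)
        n = len(self.language_ids)
        if self.values.shape != (n, n):
            raise ValueError("values must be square over language_ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("clipped distances must lie in [0, 1]")

    def get(self, a: str, b: str) -> float:
        ia, ib = self.language_ids.index(a), self.language_ids.index(b)
        return float(self.values[ia, ib])

    def submatrix(self, languages: list[str]) -> np.ndarray:
        idx = [self.language_ids.index(l) for l in languages]
        return self.values[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.language_ids, columns=self.language_ids
        )

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, j in itertools.combinations(range(len(self.language_ids)), 2):
            rows.append(
                {
                    "lang_a": self.language_ids[i],
                    "lang_b": self.language_ids[j],
                    "ldnd_raw": self.raw_values[i, j],
                    "ldnd_clipped": self.values[i, j],
                    "n_shared_concepts": self.n_shared_concepts[i, j],
                }
            )
        return pd.DataFrame(rows)


def levenshtein(a: str, b: str) -> int:
    """Edit distance between two strings under unit costs.

    Minimum number of single-character insertions, deletions or
    substitutions converting ``a`` into ``b``.  Total function; symmetric;
    satisfies the triangle inequality.
    """
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    # single-row dynamic programme
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def ldn(a: str, b: str) -> float:
    """Length-normalized Levenshtein distance: LD / max(len(a), len(b))."""
    if not a and not b:
        raise ValueError("LDN undefined for two empty strings")
    return levenshtein(a, b) / max(len(a), len(b))


def _concept_ldn(forms_a: list[str], forms_b: list[str]) -> float:
    # synonym convention: mean LDN over all cross-language form pairs
    return float(
        np.mean([ldn(fa, fb) for fa in forms_a for fb in forms_b])
    )


def ldnd(wla: WordList, wlb: WordList) -> tuple[float, int]:
    """Divided normalized Levenshtein distance between two word lists.

    The mean same-concept LDN is divided by the mean LDN over all ordered
    cross-concept pairs (concept i in A vs concept j in B, i != j, both
    shared), correcting for chance resemblance.  Returns the raw (unclipped)
    ratio and the number of shared concepts.

    Raises
    ------
    ValueError
        If fewer than 2 concepts are shared, or the cross-concept mean is
        zero (degenerate identical-everything lists).
    """
    shared = sorted(wla.concepts & wlb.concepts)
    if len(shared) < 2:
        raise ValueError(
            f"{wla.language_id} vs {wlb.language_id}: need >= 2 shared "
            f"concepts, got {len(shared)}"
        )
    numerator = float(
        np.mean([_concept_ldn(wla.entries[c], wlb.entries[c]) for c in shared])
    )
    cross = [
        _concept_ldn(wla.entries[ci], wlb.entries[cj])
        for ci in shared
        for cj in shared
        if ci != cj
    ]
    denominator = float(np.mean(cross))
    if denominator == 0.0:
        raise ValueError(
            f"{wla.language_id} vs {wlb.language_id}: zero cross-concept "
            "LDN, pair is not normalizable"
        )
    return numerator / denominator, len(shared)


def distance_matrix(wordlists: list[WordList]) -> DistanceMatrix:
    """All pairwise LDND values, clipped to [0, 1], as a DistanceMatrix."""
    if len(wordlists) < 2:
        raise ValueError("need at least 2 word lists")
    ids = [wl.language_id for wl in wordlists]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate language_id in word lists")
    n = len(wordlists)
    raw = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=int)
    for wl in wordlists:
        shared[ids.index(wl.language_id), ids.index(wl.language_id)] = len(
            wl.concepts
        )
    for i, j in itertools.combinations(range(n), 2):
        try:
            value, n_shared = ldnd(wordlists[i], wordlists[j])
        except ValueError as err:
            raise ValueError(f"pair ({ids[i]}, {ids[j]}): {err}") from err
        raw[i, j] = raw[j, i] = value
        shared[i, j] = shared[j, i] = n_shared
    return DistanceMatrix(
        language_ids=ids,
        values=np.clip(raw, 0.0, 1.0),
        raw_values=raw,
        n_shared_concepts=shared,
    )


def read_wordlists(path) -> list[WordList]:
    """Read word lists from TSV (columns language_id, concept_id, form).

    One row per form; ``#`` comment lines ignored; UTF-8.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"form": str})
    required = {"language_id", "concept_id", "form"}
    if not required.issubset(df.columns):
        raise ValueError(f"word-list TSV must have columns {sorted(required)}")
    lists = []
    for lang, grp in df.groupby("language_id", sort=True):
        entries: dict[int, list[str]] = {}
        for _, row in grp.iterrows():
            entries.setdefault(int(row["concept_id"]), []).append(str(row["form"]))
        lists.append(WordList(language_id=str(lang), entries=entries))
    return lists


def write_wordlists(wordlists: list[WordList], path) -> None:
    rows = [
        {"language_id": wl.language_id, "concept_id": c, "form": f}
        for wl in wordlists
        for c in sorted(wl.entries)
        for f in wl.entries[c]
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
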