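import numpy as np
import pytest

from langexp.lexdist import WordList, distance_matrix
from langexp.synth import CohortConfig, synth_cohort, synth_lexicons


@pytest.fixture(scope="session")
def small_pool():
    """8-language synthetic lexicons + realized distance matrix."""
    wordlists, D, target = synth_lexicons(
        CohortConfig(language_pool_size=8, seed=3)
    )
    return wordlists, D, target


@pytest.fixture(scope="session")
def full_pool_distance():
    """The 37-language distance matrix (expensive; built once)."""
    _, D, _ = synth_lexicons(CohortConfig(language_pool_size=37, seed=11))
    return D


@pytest.fixture(scope="session")
def cohort_small(small_pool):
    _, D, _ = small_pool
    profiles = synth_cohort(
        CohortConfig(language_pool_size=8, n_children=160, seed=3),
        languages=D.language_ids,
    )
    return profiles, D


@pytest.fixture
def toy_wordlists():
    wla = WordList("A", {1: ["ab"], 2: ["cd"]})
    wlb = WordList("B", {1: ["ab"], 2: ["ce"]})
    return wla, wlb


def brute_force_ldnd(wla: WordList, wlb: WordList) -> float:
    """Independent LDND oracle: full-table Levenshtein + explicit loops."""

    def lev_table(a: str, b: str) -> int:
        m, n = len(a), len(b)
        T = np.zeros((m + 1, n + 1), dtype=int)
        T[:, 0] = np.arange(m + 1)
        T[0, :] = np.arange(n + 1)
        for i in range(1, m + 1):
            for j in range(1, n + 1):
                T[i, j] = min(
                    T[i - 1, j] + 1,
                    T[i, j - 1] + 1,
                    T[i - 1, j - 1] + (a[i - 1] != b[j - 1]),
                )
        return int(T[m, n])

    def mean_ldn(fa, fb):
        vals = []
        for x in fa:
            for y in fb:
                vals.append(lev_table(x, y) / max(len(x), len(y)))
        return sum(vals) / len(vals)

    shared = sorted(set(wla.entries) & set(wlb.entries))
    num = sum(mean_ldn(wla.entries[c], wlb.entries[c]) for c in shared) / len(shared)
    cross = [
        mean_ldn(wla.entries[ci], wlb.entries[cj])
        for ci in shared
        for cj in shared
        if ci != cj
    ]
    return num / (sum(cross) / len(cross))


@pytest.fixture
def brute_ldnd():
    return brute_force_ldnd
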