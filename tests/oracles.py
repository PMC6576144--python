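"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the Fisher oracle
enumerates hypergeometric tables directly, the Viterbi oracle scores every
state path, and the Tajima oracle re-derives the textbook constants from
scratch.
"""

import itertools
import math

import numpy as np
from scipy.stats import hypergeom


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration of tables with fixed margins:
    sum of hypergeometric probabilities <= that of the observed table."""
    row1, row2 = a + b, c + d
    col1 = a + c
    N = row1 + row2
    kmin, kmax = max(0, col1 - row2), min(col1, row1)
    ks = np.arange(kmin, kmax + 1)
    pm = hypergeom.pmf(ks, N, col1, row1)
    p_obs = hypergeom.pmf(a, N, col1, row1)
    return float(pm[pm <= p_obs * (1 + 1e-9)].sum())


_PATH_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _all_paths(T: int, K: int) -> np.ndarray:
    key = (T, K)
    if key not in _PATH_CACHE:
        _PATH_CACHE[key] = np.array(
            list(itertools.product(range(K), repeat=T)), dtype=np.int8
        )
    return _PATH_CACHE[key]


def viterbi_enum(log_emissions: np.ndarray, k_transition: float) -> np.ndarray:
    """Best state path by scoring all K^T paths (K = 3 states)."""
    T, K = log_emissions.shape
    stay = math.log1p(-2.0 * k_transition)
    switch = math.log(k_transition)
    paths = _all_paths(T, K)
    em = log_emissions[np.arange(T)[None, :], paths].sum(axis=1)
    n_stay = (paths[:, 1:] == paths[:, :-1]).sum(axis=1)
    scores = -math.log(K) + em + n_stay * stay + (T - 1 - n_stay) * switch
    return paths[int(np.argmax(scores))]


def path_score(path, log_emissions: np.ndarray, k_transition: float) -> float:
    stay = math.log1p(-2.0 * k_transition)
    switch = math.log(k_transition)
    s = -math.log(log_emissions.shape[1]) + log_emissions[0, path[0]]
    for t in range(1, len(path)):
        s += stay if path[t] == path[t - 1] else switch
        s += log_emissions[t, path[t]]
    return float(s)


def tajima_d_textbook(freqs, n: int) -> float:
    """Tajima's D re-derived from the classical formulas, independent of the
    package's implementation."""
    p = [q for q in freqs if 0.0 < q < 1.0]
    S = len(p)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    pi = sum(2.0 * q * (1.0 - q) for q in p) * n / (n - 1.0)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
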