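"""Independent naive reference implementations used as test oracles.

Every function here recomputes a quantity by explicit O(N^2) template
loops, explicit sorting, or explicit pair enumeration — deliberately
different code paths from the package's vectorised implementations.
"""

import math
from collections import Counter

import numpy as np


def _cheb_row(templates: np.ndarray, i: int) -> np.ndarray:
    """Chebyshev distances from template i to every template (loop over i)."""
    return np.max(np.abs(templates - templates[i]), axis=1)


def _templates(x: np.ndarray, k: int) -> np.ndarray:
    return np.array([x[i:i + k] for i in range(len(x) - k + 1)])


def apen_naive(x, m: int, r: float) -> float:
    """ApEn by per-template counting, self-matches included."""
    x = np.asarray(x, dtype=float)

    def phi(k: int) -> float:
        tpl = _templates(x, k)
        n = len(tpl)
        total = 0.0
        for i in range(n):
            count = int(np.sum(_cheb_row(tpl, i) <= r))
            total += math.log(count / n)
        return total / n

    return phi(m) - phi(m + 1)


def sampen_naive(x, m: int, r: float) -> float:
    """SampEn by explicit ordered-pair counting, self-matches excluded."""
    x = np.asarray(x, dtype=float)
    n_t = len(x) - m

    def count_pairs(k: int) -> int:
        tpl = _templates(x, k)[:n_t]
        total = 0
        for i in range(n_t):
            within = _cheb_row(tpl, i) <= r
            within[i] = False
            total += int(np.sum(within))
        return total

    b = count_pairs(m)
    a = count_pairs(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def fuzzyen_naive(x, m: int, r: float, n: float = 2.0) -> float:
    """FuzzyEn by per-template averaging of exp(-(d/r)^n) memberships."""
    x = np.asarray(x, dtype=float)
    n_t = len(x) - m

    def phi(k: int) -> float:
        tpl = _templates(x, k)[:n_t]
        tpl = tpl - tpl.mean(axis=1, keepdims=True)
        total = 0.0
        for i in range(n_t):
            d = _cheb_row(tpl, i)
            sims = np.exp(-((d / r) ** n))
            total += (np.sum(sims) - 1.0) / (n_t - 1)  # exclude self (sim 1)
        return total / n_t

    return math.log(phi(m)) - math.log(phi(m + 1))


def pe_naive(x, order: int, delay: int, normalized: bool = True) -> float:
    """PE by explicit ordinal-pattern census with (value, index) sorting."""
    x = np.asarray(x, dtype=float)
    n_pat = len(x) - (order - 1) * delay
    census: Counter = Counter()
    for i in range(n_pat):
        points = [(x[i + j * delay], j) for j in range(order)]
        pattern = tuple(j for _, j in sorted(points))  # ties: earlier index first
        census[pattern] += 1
    h = 0.0
    for count in census.values():
        p = count / n_pat
        h -= p * math.log(p)
    return h / math.log(math.factorial(order)) if normalized else h


def auc_pair_counting(scores, labels) -> float:
    """AUC as the fraction of positive-negative pairs ordered correctly (ties 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == labels.max()]
    neg = scores[labels == labels.min()]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def welch_naive(a, b) -> tuple[float, float]:
    """Welch t statistic and two-sided p from the closed-form expressions."""
    from scipy.stats import t as t_dist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * t_dist.sf(abs(t), df)
    return t, p
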