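"""Independent brute-force oracles used by the test suite.

Everything here is deliberately slow, enumeration-based, and written
without reference to the package's own implementations.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb, inf, log

import numpy as np


# ----------------------------------------------------------------- 2x2 exact

def hypergeom_weights(a: int, b: int, c: int, d: int):
    """All tables with the observed margins as (a', weight) with exact
    rational hypergeometric weights."""
    r1, r2 = a + b, c + d
    c1 = a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = comb(r1 + r2, c1)
    return [(k, Fraction(comb(r1, k) * comb(r2, c1 - k), total))
            for k in range(lo, hi + 1)]


def fisher_p_enum(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by summing outcomes no more likely than observed."""
    weights = hypergeom_weights(a, b, c, d)
    p_obs = dict(weights)[a]
    return sum(w for _, w in weights if w <= p_obs)


def _cond_expectation(a, b, c, d, psi: float) -> float:
    """E[A] under the noncentral hypergeometric at odds ratio psi."""
    terms = [(k, comb(a + b, k) * comb(c + d, a + c - k)) for k, _ in
             hypergeom_weights(a, b, c, d)]
    logs = np.array([log(w) + k * log(psi) for k, w in terms])
    w = np.exp(logs - logs.max())
    ks = np.array([k for k, _ in terms])
    return float((ks * w).sum() / w.sum())


def cmle_or_enum(a: int, b: int, c: int, d: int) -> float:
    """Conditional MLE of the 2x2 odds ratio by bisection on E[A] = a."""
    ks = [k for k, _ in hypergeom_weights(a, b, c, d)]
    if a == min(ks):
        return 0.0
    if a == max(ks):
        return inf
    lo, hi = 1e-12, 1e12
    for _ in range(200):
        mid = (lo * hi) ** 0.5
        if _cond_expectation(a, b, c, d, mid) < a:
            lo = mid
        else:
            hi = mid
    return (lo * hi) ** 0.5


# ---------------------------------------------------------------- binomials

def binom_two_sided_doubling(t: int, n: int) -> Fraction:
    """Tail-doubled exact binomial p against 1/2, capped at 1."""
    denom = Fraction(2) ** n
    lower = sum(Fraction(comb(n, k)) for k in range(0, t + 1)) / denom
    upper = sum(Fraction(comb(n, k)) for k in range(t, n + 1)) / denom
    return min(Fraction(1), 2 * min(lower, upper))


def hwe_p_enum(n_aa: int, n_ab: int, n_bb: int) -> Fraction:
    """Exact conditional HWE p by full enumeration of genotype tables."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    outcomes = []
    for ab in range(n_ab % 2, min(n_a, 2 * n - n_a) + 1, 2):
        aa, bb = (n_a - ab) // 2, (2 * n - n_a - ab) // 2
        from math import factorial
        w = Fraction(factorial(n) * 2 ** ab,
                     factorial(aa) * factorial(ab) * factorial(bb))
        outcomes.append((ab, w))
    total = sum(w for _, w in outcomes)
    probs = {ab: w / total for ab, w in outcomes}
    p_obs = probs[n_ab]
    return sum(p for p in probs.values() if p <= p_obs)


# -------------------------------------------------------------- HMM by paths

def enumerate_hmm(logE: np.ndarray, logA: np.ndarray, logpi: np.ndarray):
    """Posteriors and best path by exhaustive enumeration of all state paths.

    logE: (n, S); logA: (n-1, S, S); returns (posteriors (n, S), best_path,
    best_logprob).
    """
    n, S = logE.shape
    best_lp, best_path = -np.inf, None
    post = np.zeros((n, S))
    lps, paths = [], []
    for path in itertools.product(range(S), repeat=n):
        lp = logpi[path[0]] + logE[0, path[0]]
        for t in range(1, n):
            lp += logA[t - 1, path[t - 1], path[t]] + logE[t, path[t]]
        lps.append(lp)
        paths.append(path)
        if lp > best_lp - 1e-15:
            # ties resolve to the lexicographically smallest (lowest states)
            if lp > best_lp + 1e-15 or (best_path is not None and path < best_path):
                best_path = path
            best_lp = max(best_lp, lp)
    lps = np.array(lps)
    w = np.exp(lps - lps.max())
    w /= w.sum()
    for wi, path in zip(w, paths):
        for t, s in enumerate(path):
            post[t, s] += wi
    return post, np.array(best_path), best_lp


# ------------------------------------------------------------ interval cover

def maximal_cover_sets(intervals):
    """All maximal sets of mutually overlapping 1-based inclusive intervals.

    By Helly's theorem in 1-D, pairwise overlap implies a common point, so
    the maximal groups are the inclusion-maximal point-cover sets.
    ``intervals`` is a list of (start, end); returns a set of frozensets of
    indices.
    """
    points = sorted({p for s, e in intervals for p in (s, e)})
    covers = set()
    for p in points:
        cov = frozenset(i for i, (s, e) in enumerate(intervals) if s <= p <= e)
        if cov:
            covers.add(cov)
    return {c for c in covers if not any(c < d for d in covers)}
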