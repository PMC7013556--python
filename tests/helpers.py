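"""Independent oracles used by the test suite.

Everything here is deliberately naive — brute-force enumeration, closed
forms, direct recomputation — and shares no code with the implementation
paths it checks.
"""

from fractions import Fraction
from itertools import product
from math import factorial

import numpy as np


def fisher_p_bruteforce(a: int, b: int, c: int, d: int, sided: str = "two") -> float:
    """Exact Fisher p by enumerating every table with the observed margins.

    Probabilities are computed as exact Fractions from factorials, so tie
    comparisons in the two-sided point-probability rule are exact.
    """
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2

    def prob(aa, bb, cc, dd):
        num = (factorial(r1) * factorial(r2) * factorial(c1) * factorial(c2))
        den = (factorial(n) * factorial(aa) * factorial(bb) * factorial(cc)
               * factorial(dd))
        return Fraction(num, den)

    p_obs = prob(a, b, c, d)
    total = Fraction(0)
    for aa in range(0, min(r1, c1) + 1):
        bb, cc = r1 - aa, c1 - aa
        dd = r2 - cc
        if bb < 0 or cc < 0 or dd < 0:
            continue
        p = prob(aa, bb, cc, dd)
        if sided == "two" and p <= p_obs:
            total += p
        elif sided == "greater" and aa >= a:
            total += p
        elif sided == "less" and aa <= a:
            total += p
    return float(min(total, Fraction(1)))


def pooled_t_closed_form(x: np.ndarray, y: np.ndarray) -> float:
    """Ordinary pooled two-sample t statistic (textbook formula)."""
    nx, ny = len(x), len(y)
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / (nx + ny - 2)
    return (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))


def bh_stepup_naive(p):
    """Direct transcription of the BH step-up definition."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = min(running, 1.0)
    return q


def propagate_iteratively(b: np.ndarray, delta_e: np.ndarray,
                          n_iter: int = 50_000, tol: float = 1e-14) -> np.ndarray:
    """Fixed-point iteration PF_{k+1} = deltaE + B PF_k."""
    pf = delta_e.copy()
    for _ in range(n_iter):
        nxt = delta_e + b @ pf
        if np.max(np.abs(nxt - pf)) < tol:
            return nxt
        pf = nxt
    return pf


def all_pairs_edges(profiles, tr_genes, r_min):
    """Brute-force |r| >= r_min TR edge list via per-pair np.corrcoef."""
    edges = set()
    genes = list(profiles.index)
    for t in tr_genes:
        for g in genes:
            if g == t:
                continue
            r = np.corrcoef(profiles.loc[t], profiles.loc[g])[0, 1]
            if abs(r) >= r_min:
                edges.add(frozenset((t, g)))
    return edges


def enumerate_pacc_null(weights: np.ndarray, pool, k: int):
    """Exhaustive null of tA: every ordered placement of k pool draws."""
    from itertools import permutations
    tas = []
    for positions in permutations(range(len(weights)), k):
        for assign in product(pool, repeat=k):
            tas.append(sum(weights[p] * v for p, v in zip(positions, assign)))
    return np.asarray(tas)
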