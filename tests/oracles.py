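"""Independent brute-force oracles used to check the implementation.

These deliberately use different algorithmic formulations from the package:
the palindrome oracle enumerates intervals along anti-diagonals rather than
extending arms from loop centers; the Wilson oracle solves the score
quadratic directly; the binomial tail is a term-by-term summation.
"""

import math

import numpy as np

COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def wilson_by_quadratic(k: int, n: int, confidence: float = 0.95):
    """Wilson bounds as the roots of the score-test quadratic in p."""
    from scipy.stats import norm

    z = norm.ppf(1 - (1 - confidence) / 2)
    phat = k / n
    # (phat - p)^2 = z^2 p (1-p) / n  ->  quadratic a p^2 + b p + c = 0
    a = 1 + z * z / n
    b = -(2 * phat + z * z / n)
    c = phat * phat
    disc = math.sqrt(b * b - 4 * a * c)
    return ((-b - disc) / (2 * a), (-b + disc) / (2 * a))


def binom_tail_by_summation(k: int, n: int, p: float) -> float:
    """P(X >= k) by explicit summation of binomial pmf terms."""
    if k <= 0:
        return 1.0
    total = 0.0
    for j in range(k, n + 1):
        total += math.comb(n, j) * p**j * (1 - p) ** (n - j)
    return min(1.0, total)


def bh_stepup(pvals):
    """Benjamini-Hochberg adjusted values straight from the step-up definition."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def _runs_right(mask: np.ndarray) -> np.ndarray:
    """Length of the run of True starting at each index."""
    n = mask.size
    false_idx = np.flatnonzero(~mask)
    if false_idx.size == 0:
        return n - np.arange(n)
    nxt = np.searchsorted(false_idx, np.arange(n))
    next_false = np.where(nxt < false_idx.size, false_idx[np.minimum(nxt, false_idx.size - 1)], n)
    return next_false - np.arange(n)


def palindromes_by_diagonal(seq: str, min_length: int, min_arm: int, max_loop: int):
    """All outward-maximal inverted repeats, by anti-diagonal enumeration.

    For an interval [a, b] the candidate arm pairs (a+i, b-i) all lie on the
    anti-diagonal a+b; the maximal arm is the run of complementary pairs
    from the outside in. Returns a set of (start, end, arm, loop) 1-based
    tuples (before nested removal).
    """
    n = len(seq)
    # integer codes such that two bases are complementary iff codes sum to 3
    code_map = {"A": 0, "C": 1, "G": 2, "T": 3}
    codes = np.array([code_map.get(b, -10) for b in seq])
    found = set()
    for s in range(2 * n - 1):
        i_lo = max(0, s - n + 1)
        i_hi = (s - 1) // 2  # require i < s - i
        if i_hi < i_lo:
            continue
        i = np.arange(i_lo, i_hi + 1)
        m = (codes[i] + codes[s - i]) == 3
        runs = _runs_right(m)
        a = i
        b = s - i
        L = b - a + 1
        arm = np.minimum(runs, L // 2)
        loop = L - 2 * arm
        ok = (L >= min_length) & (arm >= min_arm) & (loop <= max_loop)
        # outward maximality: pair (a-1, b+1) absent or non-complementary
        inner = (a - 1 >= 0) & (b + 1 <= n - 1)
        can_extend = inner & (
            (codes[np.maximum(a - 1, 0)] + codes[np.minimum(b + 1, n - 1)]) == 3
        )
        ok &= ~can_extend
        for j in np.flatnonzero(ok):
            found.add((int(a[j]) + 1, int(b[j]) + 1, int(arm[j]), int(loop[j])))
    return found


def remove_nested_bruteforce(intervals):
    """All-pairs strict-containment filter over (start, end, ...) tuples."""
    items = sorted(set(intervals))
    kept = []
    for x in items:
        contained = any(
            (y[0] <= x[0] and x[1] <= y[1] and (y[0], y[1]) != (x[0], x[1]))
            for y in items
        )
        if not contained:
            kept.append(x)
    return kept
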