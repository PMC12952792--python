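"""Independent brute-force oracles used by unit and acceptance tests.

Everything here deliberately avoids the package's own dynamic programs:
hidden-path likelihoods are summed by explicit path enumeration, and
alignments are scored by exhaustive enumeration of admissible paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

_LOG_2PI = math.log(2.0 * math.pi)


def norm_logpdf(x: float, mu: float, sigma: float) -> float:
    return -0.5 * _LOG_2PI - math.log(sigma) - (x - mu) ** 2 / (2.0 * sigma * sigma)


def inner_loglik_bruteforce(
    samples,
    mu_prev,
    mu_curr,
    mu_next,
    transition,
    initial,
    sigma,
    noise_bounds,
) -> float:
    """Sum the joint density over all 4^n hidden-state paths."""
    y = list(samples)
    lo, hi = noise_bounds
    mus = [mu_prev, mu_curr, mu_next]

    def emit(state: int, v: float) -> float:
        if state == 3:
            return 1.0 / (hi - lo) if lo <= v <= hi else 0.0
        mu = mus[state]
        if mu is None:
            return 0.0
        return math.exp(norm_logpdf(v, mu, sigma))

    total = 0.0
    for path in itertools.product(range(4), repeat=len(y)):
        p = initial[path[0]] * emit(path[0], y[0])
        for t in range(1, len(y)):
            p *= transition[path[t - 1], path[t]] * emit(path[t], y[t])
        total += p
    return math.log(total) if total > 0 else -math.inf


def align_full_bruteforce(means, mus_un, sigmas_un, indel) -> float:
    """Best score over all admissible full-alignment paths, by enumeration.

    Moves mirror the four-case recursion: diagonal match, k-mer skip,
    mean skip and vertical stay; the path runs from (0,0) to (m,n).
    """
    m, n = len(means), len(mus_un)

    def f(i, j):  # match score of mean i (1-based) against k-mer j (1-based)
        return norm_logpdf(means[i - 1], mus_un[j - 1], sigmas_un[j - 1])

    best = [-math.inf]

    def walk(i, j, score):
        if i == m and j == n:
            if score > best[0]:
                best[0] = score
            return
        if i < m and j < n:
            walk(i + 1, j + 1, score + f(i + 1, j + 1))  # match
        if j < n:
            walk(i, j + 1, score + indel)  # deletion of k-mer j+1
        if i < m:
            walk(i + 1, j, score + indel)  # insertion of mean i+1
            if j >= 1:
                walk(i + 1, j, score + f(i + 1, j))  # stay on k-mer j

    walk(0, 0, 0.0)
    return best[0]


def align_partial_bruteforce(means, mus_un, sigmas_un) -> float:
    """Best score over all prefix alignments without indels.

    All m means are split into p contiguous non-empty groups, group g
    aligned to k-mer g, for every prefix length p <= min(m, n).
    """
    m, n = len(means), len(mus_un)

    def f(i, j):
        return norm_logpdf(means[i], mus_un[j], sigmas_un[j])

    best = -math.inf
    for p in range(1, min(m, n) + 1):
        # compositions of m into p positive parts via cut positions
        for cuts in itertools.combinations(range(1, m), p - 1):
            edges = (0,) + cuts + (m,)
            score = 0.0
            for g in range(p):
                for i in range(edges[g], edges[g + 1]):
                    score += f(i, g)
            if score > best:
                best = score
    return best


def drach_expansion() -> set[str]:
    """All DRACH 5-mers by direct IUPAC expansion (DNA alphabet)."""
    return {
        "".join(t)
        for t in itertools.product("AGT", "AG", "A", "C", "ACT")
    }


def count_modification_state_combinations(k: int = 5) -> int:
    """Number of binary modification-state combinations over a k-mer."""
    return len(set(itertools.product((0, 1), repeat=k)))
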