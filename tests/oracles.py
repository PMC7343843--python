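"""Independent reference implementations used only to cross-check the
package.  Each oracle is deliberately written by a different route than the
code it checks (explicit enumeration, closed forms, a re-derived state
machine) and shares no code with the package."""

from __future__ import annotations

import itertools
import math

import numpy as np

MATCH, MISMATCH = 5.0, -4.0
GAP_OPEN, GAP_EXTEND = 10.0, 1.0


def enumerate_global_alignments(a: str, b: str):
    """Yield every global alignment of a and b as a string of column moves
    ('M' aligned, 'D' gap in b, 'I' gap in a)."""

    def rec(i: int, j: int, prefix: str):
        if i == len(a) and j == len(b):
            yield prefix
            return
        if i < len(a) and j < len(b):
            yield from rec(i + 1, j + 1, prefix + "M")
        if i < len(a):
            yield from rec(i + 1, j, prefix + "D")
        if j < len(b):
            yield from rec(i, j + 1, prefix + "I")

    yield from rec(0, 0, "")


def score_alignment(a: str, b: str, moves: str) -> float:
    """Score one alignment: +5/-4 per aligned column; each maximal run of L
    same-type gap columns costs GAP_OPEN + L * GAP_EXTEND."""
    score = 0.0
    i = j = 0
    prev = ""
    for move in moves:
        if move == "M":
            score += MATCH if a[i] == b[j] else MISMATCH
            i += 1
            j += 1
        else:
            score -= GAP_EXTEND + (GAP_OPEN if move != prev else 0.0)
            if move == "D":
                i += 1
            else:
                j += 1
        prev = move
    return score


def best_global_alignment_bruteforce(a: str, b: str) -> tuple[float, set[int]]:
    """Optimal global score by exhaustive path enumeration, plus the set of
    alignment lengths (column counts) achieving it."""
    best = -math.inf
    lengths: set[int] = set()
    for moves in enumerate_global_alignments(a, b):
        s = score_alignment(a, b, moves)
        if s > best + 1e-9:
            best = s
            lengths = {len(moves)}
        elif abs(s - best) <= 1e-9:
            lengths.add(len(moves))
    return best, lengths


def occupancy_harmonic_factor(r: int, n: int) -> float:
    """E[a(K)] where K is the number of distinct pool haploids among r reads
    drawn with replacement from n, via the occupancy-distribution recurrence
    P_{r+1}(k) = P_r(k) k/n + P_r(k-1) (n-k+1)/n."""
    p = np.zeros(min(r, n) + 1)
    p[1] = 1.0  # after one read, exactly one distinct lineage
    for _ in range(r - 1):
        q = np.zeros_like(p)
        for k in range(1, len(p)):
            q[k] = p[k] * k / n
            if k >= 1:
                q[k] += p[k - 1] * (n - k + 1) / n
        p = q
    a = lambda k: sum(1.0 / j for j in range(1, k))
    return float(sum(p[k] * a(k) for k in range(1, len(p))))


def occupancy_distribution(r: int, n: int) -> np.ndarray:
    """P(K = k) for k = 0..min(r, n) (same recurrence as above)."""
    p = np.zeros(min(r, n) + 1)
    p[1] = 1.0
    for _ in range(r - 1):
        q = np.zeros_like(p)
        for k in range(1, len(p)):
            q[k] = p[k] * k / n + p[k - 1] * (n - k + 1) / n
        p = q
    return p


def brute_hysteresis(rates, open_thresh, close_thresh, run):
    """Re-derived hysteresis scanner: precompute all qualifying run starts,
    then walk the track once.  Returns (start_window, end_window) half-open
    pairs."""
    x = list(rates)
    n = len(x)
    opens = [i + run <= n and all(v > open_thresh for v in x[i : i + run]) for i in range(n)]
    closes = [i + run <= n and all(v < close_thresh for v in x[i : i + run]) for i in range(n)]
    regions = []
    inside = False
    start = 0
    for i in range(n):
        if not inside and opens[i]:
            inside = True
            start = i
        elif inside and closes[i]:
            regions.append((start, i))
            inside = False
    if inside:
        regions.append((start, n))
    return regions


def enumerate_hmm_posteriors(e: np.ndarray, pi_C: float, tau: float):
    """Exact two-state HMM marginals by summing over all 2^L paths.

    e has shape (L, 2): emission probability of the observation under
    state C (column 0) and H (column 1).  Returns (posterior P(C) per
    position, log-likelihood, most probable path as 1=C/0=H).
    """
    L = len(e)
    total = 0.0
    marg = np.zeros(L)
    best_w, best_path = -1.0, None
    for path in itertools.product((0, 1), repeat=L):  # 0 = C, 1 = H
        w = pi_C if path[0] == 0 else (1.0 - pi_C)
        w *= e[0][path[0]]
        for t in range(1, L):
            w *= (1.0 - tau) if path[t] == path[t - 1] else tau
            w *= e[t][path[t]]
        total += w
        for t in range(L):
            if path[t] == 0:
                marg[t] += w
        if w > best_w:
            best_w, best_path = w, path
    return marg / total, math.log(total), np.array([1 - s for s in best_path], dtype=int)


def gmm_grid_loglik(x: np.ndarray, n_mu: int = 100, n_sigma: int = 20) -> float:
    """Best equal-variance, equal-weight two-Gaussian mixture log-likelihood
    over a (mu1, mu2, sigma) grid."""
    x = np.asarray(x, dtype=float)
    mus = np.linspace(x.min(), x.max(), n_mu)
    sigmas = np.linspace(np.std(x) / 10, np.std(x) * 2, n_sigma)
    best = -np.inf
    for sigma in sigmas:
        # (n_mu, n_obs) component log-densities
        logp = (
            -0.5 * ((x[None, :] - mus[:, None]) / sigma) ** 2
            - math.log(sigma)
            - 0.5 * math.log(2 * math.pi)
        )
        for i in range(n_mu):
            two = np.logaddexp(logp[i][None, :], logp) - math.log(2.0)
            ll = two.sum(axis=1).max()
            best = max(best, float(ll))
    return best
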