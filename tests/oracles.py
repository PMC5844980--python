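"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package implementation: alignment
scoring enumerates every monotone alignment path; linkage clustering is the
naive O(n^3) agglomeration; the studentized-range tail is computed by direct
numerical integration.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy import integrate, stats


def enumerate_alignments(m: int, n: int):
    """Yield every alignment of lengths m, n as a move string over D/U/L.

    D consumes one base of each, U consumes a (gap in b), L consumes b
    (gap in a).
    """

    def rec(i, j, path):
        if i == m and j == n:
            yield "".join(path)
            return
        if i < m and j < n:
            path.append("D")
            yield from rec(i + 1, j + 1, path)
            path.pop()
        if i < m:
            path.append("U")
            yield from rec(i + 1, j, path)
            path.pop()
        if j < n:
            path.append("L")
            yield from rec(i, j + 1, path)
            path.pop()

    yield from rec(0, 0, [])


def score_alignment_path(a, b, path, match, mismatch, gopen, gext, h):
    """Score one alignment path under the homopolymer-discount contract.

    The leading maximal run of identical gap moves and the trailing one are
    free end gaps.  Within charged gap runs the first column costs
    ``gopen``, later columns ``gext``; a column in homopolymer context is
    multiplied by ``h``.  Returns (score, matches, mismatches, gap_cols)
    with end-gap columns excluded from the counts.
    """
    L = len(path)
    lead = 0
    if path and path[0] in "UL":
        c = path[0]
        while lead < L and path[lead] == c:
            lead += 1
    trail = L
    if path and path[-1] in "UL":
        c = path[-1]
        while trail > 0 and path[trail - 1] == c:
            trail -= 1
    trail = max(trail, lead)

    score = 0.0
    n_match = n_mismatch = n_gap = 0
    i = j = 0
    for p, mv in enumerate(path):
        free = p < lead or p >= trail
        if mv == "D":
            if a[i] == b[j]:
                score += match
                n_match += 1
            else:
                score -= mismatch
                n_mismatch += 1
            i += 1
            j += 1
        elif mv == "U":  # gap in b deleting a[i]
            if not free:
                hp = (j > 0 and b[j - 1] == a[i]) or (j < len(b) and b[j] == a[i])
                f = h if hp else 1.0
                opens = p == 0 or path[p - 1] != "U"
                score -= (gopen if opens else gext) * f
                n_gap += 1
            i += 1
        else:  # L: gap in a inserting b[j]
            if not free:
                hp = (i > 0 and a[i - 1] == b[j]) or (i < len(a) and a[i] == b[j])
                f = h if hp else 1.0
                opens = p == 0 or path[p - 1] != "L"
                score -= (gopen if opens else gext) * f
                n_gap += 1
            j += 1
    return score, n_match, n_mismatch, n_gap


def brute_force_align(a, b, match=1.0, mismatch=1.0, gopen=2.0, gext=1.0, h=0.5):
    """Optimal score and the set of distances among optimal alignments."""
    best = -math.inf
    dists = set()
    for path in enumerate_alignments(len(a), len(b)):
        s, nm, nx, ng = score_alignment_path(a, b, path, match, mismatch, gopen, gext, h)
        if s > best + 1e-9:
            best = s
            dists = set()
        if abs(s - best) <= 1e-9:
            denom = nm + nx + ng
            dists.add(1.0 if denom == 0 else (nx + ng) / denom)
    return best, dists


def naive_average_linkage(d: np.ndarray):
    """O(n^3) average-linkage agglomeration; returns merge heights sorted."""
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    heights = []
    d = d.astype(float).copy()
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = (math.inf, None, None)
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                x, y = keys[ai], keys[bi]
                dist = np.mean([d[p, q] for p in clusters[x] for q in clusters[y]])
                if dist < best[0] - 1e-12:
                    best = (dist, x, y)
        dist, x, y = best
        heights.append(dist)
        clusters[x] = clusters[x] + clusters[y]
        del clusters[y]
    return sorted(heights)


@lru_cache(maxsize=None)
def studentized_range_sf(q: float, k: int, df: int) -> float:
    """P(Q > q) for the studentized range by direct double quadrature."""

    def inner(u):
        # P(range of k std normals <= q*u)
        def f(z):
            return k * stats.norm.pdf(z) * (
                stats.norm.cdf(z) - stats.norm.cdf(z - q * u)
            ) ** (k - 1)

        val, _ = integrate.quad(f, -8.5, 8.5, limit=200)
        return val

    # chi distribution of s/sigma with df degrees of freedom
    def outer(u):
        return stats.chi.pdf(u, df, scale=1.0 / math.sqrt(df)) * inner(u)

    cdf, _ = integrate.quad(outer, 1e-6, 8.0, limit=200)
    return 1.0 - cdf
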