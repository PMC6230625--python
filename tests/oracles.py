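"""Independent brute-force oracles used only by the test suite.

These reimplement, by the most direct method available, quantities the
package computes by faster or more structured algorithms.  They share
no code with the package internals.
"""

from __future__ import annotations

import itertools


def oracle_cpg_sites(seq: str) -> list[int]:
    """Dinucleotide scan for CG."""
    return [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]


def oracle_align_score(
    ref: str,
    read: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = -5,
    gap_extend: int = -2,
) -> float:
    """Plain quadratic-time three-state affine-gap global alignment score.

    A gap of length L costs gap_open + (L-1)*gap_extend.  Reference C
    against read T counts as a match (bisulfite asymmetry).
    """
    n, m = len(ref), len(read)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        ri = ref[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            qj = read[j - 1]
            s = match if (ri == qj or (ri == "C" and qj == "T")) else mismatch
            Mi[j] = max(Mp[j - 1], Xp[j - 1], Yp[j - 1]) + s
            Xi[j] = max(Mp[j] + gap_open, Xp[j] + gap_extend, Yp[j] + gap_open)
            Yi[j] = max(Mi[j - 1] + gap_open, Xi[j - 1] + gap_open, Yi[j - 1] + gap_extend)
    return max(M[n][m], X[n][m], Y[n][m])


def oracle_sign_flip_p(donor_means: list[float]) -> float:
    """Exhaustive donor-level sign-flip two-sided p for the mean."""
    obs = abs(sum(donor_means) / len(donor_means))
    count = 0
    total = 0
    for signs in itertools.product((1, -1), repeat=len(donor_means)):
        t = abs(sum(s * d for s, d in zip(signs, donor_means)) / len(donor_means))
        count += t >= obs - 1e-9 * (1 + obs)
        total += 1
    return count / total


def oracle_complete_linkage(points: list[list[float]]):
    """Brute-force complete-linkage agglomeration.

    Returns the merge history as a list of (frozenset_a, frozenset_b,
    height) with clusters given as frozensets of leaf indices.
    """

    def dist(a, b):
        return sum((x - y) ** 2 for x, y in zip(a, b)) ** 0.5

    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = max(dist(points[i], points[j]) for i in a for j in b)
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
        merges.append((a, b, d))
    return merges
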