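"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the code paths they check: plain dynamic
programming for local alignment, explicit k-mer dictionaries for the
spectrum kernel, and exhaustive enumeration for the greedy amino-acid
clustering.
"""

from __future__ import annotations

import itertools
from collections import Counter


def smith_waterman(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0):
    """Optimal local alignment by DP with traceback.

    Returns (score, identities, columns, span_a, span_b) of one optimal
    alignment (ties broken diagonal-first).
    """
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    best, best_pos = 0.0, (0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = H[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            up = H[i - 1][j] + gap
            left = H[i][j - 1] + gap
            H[i][j] = max(0.0, diag, up, left)
            if H[i][j] > best:
                best, best_pos = H[i][j], (i, j)
    if best == 0.0:
        return 0.0, 0, 0, 0, 0
    i, j = best_pos
    identities = columns = 0
    end_i, end_j = i, j
    while i > 0 and j > 0 and H[i][j] > 0:
        diag = H[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
        if H[i][j] == diag:
            identities += a[i - 1] == b[j - 1]
            columns += 1
            i, j = i - 1, j - 1
        elif H[i][j] == H[i - 1][j] + gap:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    return best, identities, columns, end_i - i, end_j - j


def brute_force_spectrum(seqs, k):
    """Gram matrix via explicit dense k-mer vectors over the union alphabet."""
    counters = [Counter(s[i : i + k] for i in range(len(s) - k + 1)) for s in seqs]
    kmers = sorted(set().union(*counters))
    vecs = [[c[km] for km in kmers] for c in counters]
    n = len(seqs)
    return [
        [sum(vecs[i][t] * vecs[j][t] for t in range(len(kmers))) for j in range(n)]
        for i in range(n)
    ]


def partial_partitions(letters):
    """All partitions of all non-empty subsets of ``letters``.

    Yields tuples of frozensets; each letter appears in at most one set.
    """
    letters = list(letters)

    def rec(i, clusters):
        if i == len(letters):
            if clusters:
                yield tuple(frozenset(c) for c in clusters)
            return
        a = letters[i]
        yield from rec(i + 1, clusters)  # omit the letter
        clusters.append([a])  # start a new cluster
        yield from rec(i + 1, clusters)
        clusters.pop()
        for j in range(len(clusters)):  # join an existing cluster
            clusters[j].append(a)
            yield from rec(i + 1, clusters)
            clusters[j].pop()

    yield from rec(0, [])


def comembership_evaluator(target):
    """Deterministic clustering score maximized uniquely at ``target``.

    +1 per covered letter, +2 per correctly co-clustered pair, -3 per pair
    co-clustered that the target keeps apart. The greedy path reaches the
    global optimum for small targets, making exhaustive comparison exact.
    """
    target = [frozenset(t) for t in target]
    together = {
        frozenset((x, y))
        for t in target
        for x, y in itertools.combinations(sorted(t), 2)
    }

    def score(cluster_set):
        s = 0.0
        for cl in cluster_set.clusters:
            s += len(cl)
            for x, y in itertools.combinations(sorted(cl), 2):
                s += 2.0 if frozenset((x, y)) in together else -3.0
        return s

    return score
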