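"""Independent brute-force reference implementations used only by the tests.

These deliberately use plain Python loops and the defining formulas, staying
independent of the package's vectorized code paths.
"""

import math

import numpy as np


def dist(u, v):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(u, v)))


def silhouette_brute(x, labels):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != len(labels):
        x = x.T
    labels = list(labels)
    n = len(labels)
    clusters = sorted(set(labels))
    s = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            s.append(0.0)
            continue
        a = sum(dist(x[i], x[j]) for j in own) / len(own)
        b = min(
            sum(dist(x[i], x[j]) for j in range(n) if labels[j] == c)
            / sum(1 for j in range(n) if labels[j] == c)
            for c in clusters
            if c != labels[i]
        )
        s.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return sum(s) / n, s


def calinski_harabasz_brute(x, labels):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    labels = list(labels)
    n = len(labels)
    clusters = sorted(set(labels))
    k = len(clusters)
    grand = x.mean(axis=0)
    tr_b = 0.0
    tr_w = 0.0
    for c in clusters:
        idx = [j for j in range(n) if labels[j] == c]
        centroid = x[idx].mean(axis=0)
        tr_b += len(idx) * float(sum((centroid - grand) ** 2))
        for j in idx:
            tr_w += float(sum((x[j] - centroid) ** 2))
    return (tr_b / tr_w) * (n - k) / (k - 1)


def davies_bouldin_brute(x, labels):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    labels = list(labels)
    n = len(labels)
    clusters = sorted(set(labels))
    k = len(clusters)
    centroids = []
    spreads = []
    for c in clusters:
        idx = [j for j in range(n) if labels[j] == c]
        centroid = x[idx].mean(axis=0)
        centroids.append(centroid)
        spreads.append(sum(dist(x[j], centroid) for j in idx) / len(idx))
    total = 0.0
    for i in range(k):
        total += max(
            (spreads[i] + spreads[j]) / dist(centroids[i], centroids[j])
            for j in range(k)
            if j != i
        )
    return total / k


def kmer_row_total_brute(sequence, k):
    """Number of valid k-length windows (all characters in ACGT)."""
    total = 0
    for i in range(len(sequence) - k + 1):
        if all(ch in "ACGT" for ch in sequence[i : i + k]):
            total += 1
    return total


def densities_brute(x, sigma):
    """Naive double-loop kernel densities: rho_i = sum_{j != i} w_ij."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[0]
    rho = []
    for i in range(n):
        total = 0.0
        for j in range(n):
            if j != i:
                total += math.exp(-dist(x[i], x[j]) ** 2 / (2 * sigma**2))
        rho.append(total)
    return np.array(rho)


def connectivity_brute(w, a, b):
    """Mean cross-pair weight between index sets a and b."""
    vals = [w[i, j] for i in a for j in b]
    return sum(vals) / len(vals)
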