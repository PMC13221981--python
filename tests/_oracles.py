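"""Independent brute-force reference implementations of the distance-based
metrics, written with explicit loops and no shared code with the package.
Only meaningful at tiny sample counts; used to pin down the fast paths."""

from __future__ import annotations

import math

import numpy as np


def pearson_distance_oracle(values: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between sample columns, via the raw formula."""
    n = values.shape[1]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            x, y = values[:, i], values[:, j]
            xm, ym = x - x.mean(), y - y.mean()
            r = float(np.sum(xm * ym)) / math.sqrt(
                float(np.sum(xm ** 2)) * float(np.sum(ym ** 2)))
            D[i, j] = 1.0 - r
    return D


def f_score_oracle(D: np.ndarray, labels) -> float:
    labels = list(labels)
    n = len(labels)
    between = within = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] == labels[j]:
                within += D[i, j]
            else:
                between += D[i, j]
    return between / within


def f_score_scaled_oracle(D: np.ndarray, labels, p: float) -> float:
    labels = list(labels)
    n = len(labels)
    Q = []
    for i in range(n):
        row = [D[i, j] for j in range(n) if j != i]
        Q.append(float(np.quantile(row, p)))
    between = within = 0.0
    for i in range(n):
        for j in range(n):
            if j == i:
                continue
            term = D[i, j] / Q[i]          # ordered-pair sum
            if labels[i] == labels[j]:
                within += term
            else:
                between += term
    return between / within


def _pearson_dist_pair(a: np.ndarray, b: np.ndarray) -> float:
    am, bm = a - a.mean(), b - b.mean()
    return 1.0 - float(np.sum(am * bm)) / math.sqrt(
        float(np.sum(am ** 2)) * float(np.sum(bm ** 2)))


def davies_bouldin_oracle(values: np.ndarray, labels) -> float:
    labels = list(labels)
    names = sorted(set(labels))
    members = {c: [i for i, l in enumerate(labels) if l == c] for c in names}
    S = {}
    for c in names:
        centroid = values[:, members[c]].mean(axis=1)
        S[c] = float(np.mean([_pearson_dist_pair(values[:, i], centroid)
                              for i in members[c]]))
    total = 0.0
    for a in names:
        best = -np.inf
        for b in names:
            if a == b:
                continue
            cross = [_pearson_dist_pair(values[:, i], values[:, j])
                     for i in members[a] for j in members[b]]
            best = max(best, (S[a] + S[b]) / float(np.mean(cross)))
        total += best
    return total / len(names)


def knn_proportion_oracle(D: np.ndarray, labels, k: int) -> float:
    labels = list(labels)
    n = len(labels)
    frac = []
    for i in range(n):
        order = sorted((D[i, j], j) for j in range(n) if j != i)
        neigh = [j for _, j in order[:k]]
        frac.append(sum(labels[j] == labels[i] for j in neigh) / k)
    names = sorted(set(labels))
    per_cluster = []
    for c in names:
        idx = [i for i, l in enumerate(labels) if l == c]
        per_cluster.append(float(np.mean([frac[i] for i in idx])))
    return float(np.mean(per_cluster))


def min_distance_oracle(D: np.ndarray, labels) -> float:
    labels = list(labels)
    names = sorted(set(labels))
    minima = []
    for ai, a in enumerate(names):
        for b in names[ai + 1:]:
            ia = [i for i, l in enumerate(labels) if l == a]
            ib = [i for i, l in enumerate(labels) if l == b]
            minima.append(min(D[i, j] for i in ia for j in ib))
    return float(np.mean(minima))
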