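"""Independent brute-force reference implementations used as oracles.

Deliberately naive (explicit loops, textbook formulas) and kept free of
any oabnet internals so they can disagree with the implementation.
"""

import math

import numpy as np


def euclidean_distance_matrix(X):
    n = len(X)
    D = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            D[i][j] = math.sqrt(sum((X[i][k] - X[j][k]) ** 2 for k in range(len(X[i]))))
    return np.array(D)


def pearson(a, b):
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    va = sum((x - ma) ** 2 for x in a)
    vb = sum((y - mb) ** 2 for y in b)
    return cov / math.sqrt(va * vb)


def avg_degree_centrality(edges, members, n_nodes):
    """edges: set of frozensets of node ids."""
    total = 0.0
    for v in members:
        deg = sum(1 for e in edges if v in e)
        total += deg / (n_nodes - 1)
    return total / len(members)


def edge_density(edges, members):
    members = set(members)
    possible = len(members) * (len(members) - 1) / 2
    if possible == 0:
        return 0.0
    inside = sum(1 for e in edges if e <= members)
    return inside / possible


def adjacency_degree_laplacian(edges, nodes):
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for e in edges:
        u, v = tuple(e)
        A[index[u], index[v]] = A[index[v], index[u]] = 1.0
    D = np.diag(A.sum(axis=1))
    return A, D, D - A


def eigenvector_centrality_dense(A):
    """Principal eigenvector of A by dense symmetric eigendecomposition,
    nonnegative and L2-normalised."""
    w, V = np.linalg.eigh(A)
    x = V[:, np.argmax(w)]
    x = np.abs(x)
    return x / np.linalg.norm(x), float(np.max(w))


def kmeans_best_sse(X, k):
    """Exhaustive minimum of the K-means objective over all k-partitions
    (centroid of each part as its centre).  Exponential; tiny n only."""
    n = len(X)
    X = np.asarray(X, dtype=float)
    best = np.inf
    # enumerate assignments via base-k counting; fix point 0 in part 0 to
    # break label symmetry
    total = k ** (n - 1)
    for code in range(total):
        labels = [0]
        c = code
        for _ in range(n - 1):
            labels.append(c % k)
            c //= k
        if len(set(labels)) != k:
            continue
        sse = 0.0
        for part in range(k):
            pts = X[[i for i, l in enumerate(labels) if l == part]]
            mu = pts.mean(axis=0)
            sse += float(((pts - mu) ** 2).sum())
        best = min(best, sse)
    return best


def random_graph_edges(rng, n, p):
    """Erdős–Rényi edge set over nodes 0..n−1 as frozensets."""
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.add(frozenset((i, j)))
    return edges
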