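"""Independent brute-force oracles for small graphs and small-sample tests.

Deliberately naive: Floyd-Warshall distances, exhaustive triple loops for
triangles, shortest-path counting by adjacency-matrix powers, exhaustive
set-partition search for modularity, and full labeling enumeration for the
Mann-Whitney null — slow but transparently correct, used only at N <= 8.
"""

import itertools

import numpy as np


def floyd_warshall(adj):
    a = (np.asarray(adj) != 0)
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[a] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def global_efficiency_bf(adj):
    d = floyd_warshall(adj)
    n = d.shape[0]
    if n < 2:
        return 0.0
    acc = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(d[i, j]) and d[i, j] > 0:
                acc += 1.0 / d[i, j]
    return acc / (n * (n - 1) / 2)


def path_length_bf(adj):
    d = floyd_warshall(adj)
    n = d.shape[0]
    vals, excluded = [], 0
    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(d[i, j]):
                vals.append(d[i, j])
            else:
                excluded += 1
    return (float(np.mean(vals)) if vals else float("nan")), excluded


def clustering_bf(adj):
    a = (np.asarray(adj) != 0).astype(int)
    n = a.shape[0]
    ci = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(a[u, v] for u, v in itertools.combinations(nbrs, 2))
        ci[i] = 2.0 * links / (k * (k - 1))
    return float(ci.mean()), ci


def density_bf(adj):
    a = (np.asarray(adj) != 0).astype(int)
    n = a.shape[0]
    e = sum(a[i, j] for i in range(n) for j in range(i + 1, n))
    return e / (n * (n - 1) / 2)


def betweenness_bf(adj):
    """Normalized betweenness via shortest-path counting with adjacency
    powers: the number of geodesics s->t equals (A^d(s,t))[s,t]."""
    a = (np.asarray(adj) != 0).astype(np.int64)
    n = a.shape[0]
    d = floyd_warshall(a)
    powers = [np.eye(n, dtype=np.int64)]
    for _ in range(n):
        powers.append(powers[-1] @ a)

    def nsp(i, j):
        if i == j:
            return 1
        if not np.isfinite(d[i, j]):
            return 0
        return int(powers[int(d[i, j])][i, j])

    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            total = nsp(s, t)
            if total == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if d[s, v] + d[v, t] == d[s, t]:
                    bc[v] += nsp(s, v) * nsp(v, t) / total
    norm = (n - 1) * (n - 2) / 2
    return bc / norm if norm > 0 else bc


def assortativity_bf(adj):
    a = (np.asarray(adj) != 0).astype(int)
    deg = a.sum(axis=1)
    xs, ys = [], []
    n = a.shape[0]
    for i in range(n):
        for j in range(n):
            if a[i, j]:
                xs.append(deg[i])
                ys.append(deg[j])
    if len(xs) < 2:
        return None
    xs, ys = np.array(xs, float), np.array(ys, float)
    if xs.std() == 0 or ys.std() == 0:
        return None
    return float(np.corrcoef(xs, ys)[0, 1])


def rich_club_curve_bf(adj):
    a = (np.asarray(adj) != 0).astype(int)
    deg = a.sum(axis=1)
    out = {}
    for k in range(0, int(deg.max())):
        survivors = [i for i in range(a.shape[0]) if deg[i] > k]
        if len(survivors) < 2:
            break
        e = sum(a[i, j] for i, j in itertools.combinations(survivors, 2))
        out[k] = 2.0 * e / (len(survivors) * (len(survivors) - 1))
    return out


def modularity_q_bf(adj, partition):
    """Newman Q of a given partition, straight from the definition."""
    a = (np.asarray(adj) != 0).astype(float)
    m = a.sum() / 2.0
    deg = a.sum(axis=1)
    q = 0.0
    for comm in partition:
        comm = list(comm)
        e_c = a[np.ix_(comm, comm)].sum() / 2.0
        d_c = deg[comm].sum()
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


def best_modularity_bf(adj):
    """Exhaustive search over all set partitions (use only for n <= 7)."""
    n = adj.shape[0]

    def partitions(collection):
        if len(collection) == 1:
            yield [collection]
            return
        first = collection[0]
        for smaller in partitions(collection[1:]):
            for i, subset in enumerate(smaller):
                yield smaller[:i] + [[first] + subset] + smaller[i + 1:]
            yield [[first]] + smaller

    best = -np.inf
    for part in partitions(list(range(n))):
        q = modularity_q_bf(adj, part)
        best = max(best, q)
    return best


def mann_whitney_p_bf(a, b):
    """Exact two-tailed Mann-Whitney p by enumerating every group labeling;
    U computed through the rank-sum identity (a second route)."""
    from scipy.stats import rankdata

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    mu = n1 * n2 / 2.0

    def u_of(idx_a):
        r1 = ranks[list(idx_a)].sum()
        return r1 - n1 * (n1 + 1) / 2.0

    u_obs = u_of(range(n1))
    count = total = 0
    for comb in itertools.combinations(range(n1 + n2), n1):
        if abs(u_of(comb) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total
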