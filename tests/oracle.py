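"""Independent brute-force graph-metric oracle for small graphs.

Shortest paths are found by exhaustive simple-path enumeration (no BFS,
no library call), so these routines share nothing with the package
implementation they check. Exponential in n: use only for n <= ~7.
"""

import math


def oracle_distances(adj):
    n = len(adj)
    inf = math.inf
    dist = [[inf] * n for _ in range(n)]
    for start in range(n):
        dist[start][start] = 0
        stack = [(start, (start,))]
        while stack:
            node, path = stack.pop()
            for nb in range(n):
                if adj[node][nb] and nb not in path:
                    if len(path) < dist[start][nb]:
                        dist[start][nb] = len(path)
                    stack.append((nb, path + (nb,)))
    return dist


def oracle_degree(adj):
    return [sum(row) for row in adj]


def oracle_clustering(adj):
    n = len(adj)
    cc = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        k = len(nbrs)
        if k < 2:
            cc.append(0.0)
            continue
        e = sum(adj[a][b] for ai, a in enumerate(nbrs) for b in nbrs[ai + 1:])
        cc.append(2 * e / (k * (k - 1)))
    return cc, sum(cc) / n


def oracle_global_efficiency(adj):
    n = len(adj)
    if n < 2:
        return 0.0
    d = oracle_distances(adj)
    total = sum(
        1 / d[i][j]
        for i in range(n) for j in range(n)
        if i != j and math.isfinite(d[i][j])
    )
    return total / (n * (n - 1))


def oracle_local_efficiency(adj):
    n = len(adj)
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        if len(nbrs) < 2:
            continue
        sub = [[adj[a][b] for b in nbrs] for a in nbrs]
        total += oracle_global_efficiency(sub)
    return total / n


def oracle_path_length(adj):
    n = len(adj)
    d = oracle_distances(adj)
    finite = [d[i][j] for i in range(n) for j in range(i + 1, n)
              if math.isfinite(d[i][j])]
    if not finite:
        return math.inf
    return sum(finite) / len(finite)
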