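"""Independent brute-force oracle for graph metrics on tiny graphs.

Deliberately naive: Floyd-Warshall with explicit triple loops, triangle
counting by triple loops, neighbour-subgraph efficiency by direct recursion.
Kept free of any wmnet import so the oracle cannot share code with the
implementation it checks.
"""
import math

INF = math.inf


def floyd_warshall(lengths):
    """All-pairs shortest paths from an edge-length matrix (0 = no edge)."""
    n = len(lengths)
    d = [[INF] * n for _ in range(n)]
    for i in range(n):
        d[i][i] = 0.0
        for j in range(n):
            if i != j and lengths[i][j] > 0:
                d[i][j] = lengths[i][j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def to_lengths(weights, mode):
    n = len(weights)
    out = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            w = weights[i][j]
            if i != j and w > 0:
                out[i][j] = 1.0 if mode == "binary" else 1.0 / w
    return out


def distances(weights, mode):
    return floyd_warshall(to_lengths(weights, mode))


def global_efficiency(weights, mode):
    d = distances(weights, mode)
    n = len(d)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and d[i][j] < INF:
                total += 1.0 / d[i][j]
    return total / (n * (n - 1))


def nodal_efficiency(weights, mode):
    d = distances(weights, mode)
    n = len(d)
    out = []
    for i in range(n):
        s = sum(1.0 / d[i][j] for j in range(n) if j != i and d[i][j] < INF)
        out.append(s / (n - 1))
    return out


def characteristic_path_length(weights, mode):
    d = distances(weights, mode)
    n = len(d)
    vals = [d[i][j] for i in range(n) for j in range(n) if i != j and d[i][j] < INF]
    return sum(vals) / len(vals) if vals else float("nan")


def degrees(weights):
    n = len(weights)
    return [sum(1 for j in range(n) if j != i and weights[i][j] != 0)
            for i in range(n)]


def clustering_binary(weights):
    """Per-node 2 t_i / (k_i (k_i - 1)) by explicit triangle counting."""
    n = len(weights)
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if j != i and weights[i][j] != 0]
        k = len(nbrs)
        if k < 2:
            out.append(0.0)
            continue
        t = 0
        for a in range(k):
            for b in range(a + 1, k):
                if weights[nbrs[a]][nbrs[b]] != 0:
                    t += 1
        out.append(2.0 * t / (k * (k - 1)))
    return out


def clustering_onnela(weights):
    """Onnela weighted clustering with weights normalised by the graph max."""
    n = len(weights)
    wmax = max((weights[i][j] for i in range(n) for j in range(n)), default=0.0)
    if wmax <= 0:
        return [0.0] * n
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if j != i and weights[i][j] != 0]
        k = len(nbrs)
        if k < 2:
            out.append(0.0)
            continue
        s = 0.0
        for a in nbrs:
            for b in nbrs:
                if a != b and weights[a][b] != 0:
                    s += ((weights[i][a] / wmax) * (weights[i][b] / wmax)
                          * (weights[a][b] / wmax)) ** (1.0 / 3.0)
        out.append(s / (k * (k - 1)))
    return out


def local_efficiency(weights, mode):
    """Mean over nodes of the efficiency of the neighbour-induced subgraph."""
    n = len(weights)
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if j != i and weights[i][j] != 0]
        m = len(nbrs)
        if m < 2:
            continue
        sub = [[weights[a][b] for b in nbrs] for a in nbrs]
        total += global_efficiency(sub, mode)
    return total / n


def step_up_fdr(pvals):
    """Benjamini-Hochberg adjusted p-values by the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj
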