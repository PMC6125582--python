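"""Independent literal oracle implementations shared by the test suite.

Each function transcribes a definition as directly as possible (loops,
no vectorization) so it stays independent of the library code paths it
is used to check.
"""

import numpy as np


def abof_brute_force(X):
    """Angle-based outlier factor by explicit double loop over pairs."""
    n = X.shape[0]
    out = np.empty(n)
    for p in range(n):
        vals = []
        others = [i for i in range(n) if i != p]
        for a in range(len(others)):
            for b in range(a + 1, len(others)):
                dx = X[others[a]] - X[p]
                dy = X[others[b]] - X[p]
                nx, ny = dx @ dx, dy @ dy
                if nx == 0 or ny == 0:
                    continue
                vals.append((dx @ dy) / (nx * ny))
        out[p] = np.var(vals)
    return out


def tom_brute_force(A):
    """Triple-loop TOM dissimilarity (u != i, j excluded explicitly)."""
    n = A.shape[0]
    k = A.sum(axis=1)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            denom = min(k[i], k[j]) + 1 - A[i, j]
            out[i, j] = (l_ij + A[i, j]) / denom if denom > 0 else 0.0
    return 1.0 - out


def bh_oracle(p):
    """Literal sort-scan-cummin transcription of the BH definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, min(1.0, p[order[rank - 1]] * m / rank))
        out[order[rank - 1]] = running
    return out


def literal_ssgsea(values, gene_ids, gene_set, alpha):
    """Straightforward ECDF-sum transcription of the ssGSEA score."""
    order = sorted(range(len(values)), key=lambda i: (-values[i], gene_ids[i]))
    n = len(values)
    in_set = [gene_ids[i] in gene_set for i in order]
    s = sum(in_set)
    weights = [(n - pos) ** alpha for pos in range(n)]  # rank from bottom
    denom_in = sum(w for w, flag in zip(weights, in_set) if flag)
    es = 0.0
    cum_in = cum_out = 0.0
    for pos in range(n):
        if in_set[pos]:
            cum_in += weights[pos] / denom_in
        else:
            cum_out += 1.0 / (n - s)
        es += cum_in - cum_out
    return es
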