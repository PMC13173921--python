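"""Independent brute-force oracles used by the test suite.

Each function implements a definition directly — plain loops, no shared
code with the package — so the tests compare two independent routes to
the same quantity.
"""

from __future__ import annotations

from itertools import combinations
from math import erf, sqrt

import numpy as np


def phi(t: float) -> float:
    return 0.5 * (1.0 + erf(t / sqrt(2.0)))


def gsva_bruteforce(values, gene_ids, member_lists, tau=1.0, es_mode="signed_diff"):
    """Direct loop over the kcdf / rank / walk definitions, no reuse."""
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    z = np.zeros((p, n))
    for i in range(p):
        h = np.std(values[i], ddof=1) / 4.0
        for j in range(n):
            if h <= 0:
                z[i, j] = 0.5
            else:
                z[i, j] = sum(
                    phi((values[i, j] - values[i, k]) / h) for k in range(n)
                ) / n
    es = np.zeros((len(member_lists), n))
    member_sets = []
    for members in member_lists:
        ms = set(members)
        member_sets.append({i for i, g in enumerate(gene_ids) if g in ms})
    for j in range(n):
        order = sorted(range(p), key=lambda i: (-z[i, j], gene_ids[i]))
        rank = {gene: k + 1 for k, gene in enumerate(order)}
        r = {i: abs(p / 2.0 - rank[i]) for i in range(p)}
        for s, memidx in enumerate(member_sets):
            denom = sum(r[i] ** tau for i in memidx)
            out_step = 1.0 / (p - len(memidx))
            nu, cin, cout = [], 0.0, 0.0
            for i in order:
                if i in memidx:
                    cin += r[i] ** tau
                else:
                    cout += out_step
                nu.append((cin / denom if denom > 0 else 0.0) - cout)
            if es_mode == "signed_diff":
                es[s, j] = max(0.0, max(nu)) + min(0.0, min(nu))
            else:
                k = int(np.argmax(np.abs(nu)))
                es[s, j] = nu[k]
    return es


def bh_bruteforce(pvalues):
    """BH step-up by the sorted-minimum definition."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    vals = [min(1.0, sorted_p[j] * m / (j + 1)) for j in range(m)]
    # q_(i) = min over j >= i
    run = np.minimum.accumulate(np.array(vals)[::-1])[::-1]
    q = np.empty(m)
    q[order] = run
    return q


def wilcoxon_exact_bruteforce(x, y):
    """Two-sided exact rank-sum p by enumerating all rank assignments.

    Assumes no ties. p = min(1, 2 * min(P(U <= u), P(U >= u))).
    """
    x, y = list(x), list(y)
    nx, ny = len(x), len(y)
    pooled = sorted(x + y)
    rank_of = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank_of[v] for v in x) - nx * (nx + 1) / 2.0
    dist = [
        sum(c) - nx * (nx + 1) / 2.0
        for c in combinations(range(1, nx + ny + 1), nx)
    ]
    dist = np.array(dist, dtype=float)
    p_le = np.mean(dist <= u_obs)
    p_ge = np.mean(dist >= u_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


def auc_bruteforce(scores, truth01):
    """All-pairs concordance with half credit for score ties."""
    scores = np.asarray(scores, dtype=float)
    truth01 = np.asarray(truth01)
    pos = scores[truth01 == 1]
    neg = scores[truth01 == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (pos.size * neg.size)
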