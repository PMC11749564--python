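"""Independent brute-force oracles used to check the package's results.

Each oracle is deliberately written along a different computational route
than the implementation it checks (enumeration instead of library calls,
explicit matrix inverses instead of QR/SVD, per-read loops instead of
vectorized groupbys).
"""

from __future__ import annotations

import math

import numpy as np


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Fix margins (a+b, c+d, a+c, b+d); sum the probabilities of all
    tables whose point probability is <= the observed one (with a tiny
    relative slack for float ties, the convention of standard
    implementations).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_prob(x: int) -> float:
        # P(A = x) for the 2x2 with these margins
        return (
            math.lgamma(r1 + 1)
            - math.lgamma(x + 1)
            - math.lgamma(r1 - x + 1)
            + math.lgamma(r2 + 1)
            - math.lgamma(c1 - x + 1)
            - math.lgamma(r2 - (c1 - x) + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    lp_obs = log_prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_prob(x)
        if lp <= lp_obs + 1e-7:  # point probability <= observed (relative slack)
            total += math.exp(lp)
    return min(total, 1.0)


def bh_step_up(pvalues) -> np.ndarray:
    """Benjamini-Hochberg q-values by direct step-up arithmetic."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


def assign_reads_enumeration(hit_rows, subject_taxon: dict, evalue_max: float) -> dict:
    """Per-read consensus assignment by explicit enumeration.

    ``hit_rows`` is an iterable of (read_id, subject_id, evalue).
    Returns read_id -> taxon or 'unassigned'.
    """
    by_read: dict = {}
    for rid, sid, ev in hit_rows:
        by_read.setdefault(rid, []).append((sid, float(ev)))
    out = {}
    for rid, rows in by_read.items():
        min_e = min(ev for _, ev in rows)
        taxa = {subject_taxon[sid] for sid, ev in rows if ev == min_e}
        if len(taxa) == 1 and min_e <= evalue_max:
            out[rid] = taxa.pop()
        else:
            out[rid] = "unassigned"
    return out


def transitive_closure_components(ids, gene_sets: dict, threshold: float) -> set:
    """Connected components of the overlap graph via union-find."""
    ids = list(ids)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for i, gi in enumerate(ids):
        for gj in ids[i + 1 :]:
            a, b = gene_sets.get(gi, set()), gene_sets.get(gj, set())
            if a and b and len(a & b) / min(len(a), len(b)) > threshold:
                union(gi, gj)
    comps: dict = {}
    for i in ids:
        comps.setdefault(find(i), set()).add(i)
    return {frozenset(v) for v in comps.values()}


def cca_eigenvalues_dense(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Constrained CA eigenvalues via explicit hat matrix + dense eigh.

    A from-first-principles route: chi-square residual matrix, weighted
    hat matrix built with an explicit pseudo-inverse, eigen-decomposition
    of the fitted cross-product.
    """
    Y = np.asarray(Y, float)
    X = np.asarray(X, float)
    total = Y.sum()
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    E = np.outer(r, c)
    Q = (P - E) / np.sqrt(E)
    Xc = X - (r[:, None] * X).sum(axis=0)
    Xw = np.sqrt(r)[:, None] * Xc
    H = Xw @ np.linalg.pinv(Xw.T @ Xw) @ Xw.T
    F = H @ Q
    vals = np.linalg.eigvalsh(F.T @ F)[::-1]
    return vals[vals > 1e-12]
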