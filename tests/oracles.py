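"""Independent test oracles: deliberately simple, slow reference implementations."""

from __future__ import annotations

import itertools
from typing import Dict, List, Sequence, Tuple

import numpy as np

NEG = float("-inf")


def affine_nw_score(
    ref: str,
    read: str,
    strand: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = -6,
    gap_extend: int = -1,
) -> int:
    """Full-matrix Gotoh global alignment score, pure python.

    Conversion-aware: OT treats ref C / read T as a match, OB treats ref G /
    read A as a match. Opening a gap costs gap_open + gap_extend, extending
    gap_extend, matching the package's convention.
    """

    def s(a: str, b: str) -> int:
        if a == b:
            return match
        if strand == "OT" and a == "C" and b == "T":
            return match
        if strand == "OB" and a == "G" and b == "A":
            return match
        return mismatch

    n, m = len(ref), len(read)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * i
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sc = s(ref[i - 1], read[j - 1])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + sc
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j]) + gap_extend
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1]) + gap_extend
    return int(max(M[n][m], X[n][m], Y[n][m]))


def logistic_ml_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Maximum-likelihood logistic coefficients by direct Newton iteration."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.zeros(X.shape[1])
    for _ in range(100):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        grad = X.T @ (y - p)
        hess = X.T @ (X * w[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return beta


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS coefficients straight from the normal equations."""
    X = np.asarray(X, float)
    return np.linalg.solve(X.T @ X, X.T @ np.asarray(y, float))


def bh_direct(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values by the textbook step-up formula."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        val = min(prev, p[idx] * m / rank_from_top)
        q[idx] = val
        prev = val
    return q


def best_matching(
    cases: Dict[str, Tuple[tuple, float]],
    controls: Dict[str, Tuple[tuple, float]],
) -> Tuple[int, float]:
    """Exhaustive minimum-total-|coverage difference| genotype matching.

    Returns (max pair count, minimum total coverage difference among maximum
    matchings). Feasible for toy problems only.
    """
    case_ids = list(cases)
    control_ids = list(controls)
    best_n, best_cost = 0, float("inf")
    for perm in itertools.permutations(control_ids):
        used = set()
        n, cost = 0, 0.0
        for case_id, control_id in zip(case_ids, perm):
            if control_id in used:
                continue
            g_case, cov_case = cases[case_id]
            g_ctrl, cov_ctrl = controls[control_id]
            if g_case == g_ctrl:
                n += 1
                cost += abs(cov_case - cov_ctrl)
                used.add(control_id)
        if n > best_n or (n == best_n and cost < best_cost):
            best_n, best_cost = n, cost
    return best_n, best_cost


def kruskal_h(groups: Sequence[Sequence[float]]) -> float:
    """Closed-form rank computation of the Kruskal-Wallis H (no ties)."""
    pooled = sorted((v, gi) for gi, g in enumerate(groups) for v in g)
    n = len(pooled)
    ranks: Dict[int, List[float]] = {}
    for rank, (v, gi) in enumerate(pooled, start=1):
        ranks.setdefault(gi, []).append(rank)
    h = 0.0
    for gi, rs in ranks.items():
        h += len(rs) * (np.mean(rs) - (n + 1) / 2.0) ** 2
    return 12.0 / (n * (n + 1)) * h
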