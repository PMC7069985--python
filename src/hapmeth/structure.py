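"""Factor and network structure of site-methylation profiles.

Two complementary views of inter-cytosine correlation: exploratory factor
analysis (parallel analysis for the number of factors, maximum-likelihood
extraction, varimax then oblique promax rotation) and a sparse Gaussian
graphical model estimated with the graphical lasso along a regularization
path, selected by the extended BIC (EBICglasso). Variables are first mapped
to normal scores with the rank-based nonparanormal transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import graphical_lasso
from sklearn.decomposition import FactorAnalysis

MIN_PAIRWISE_OVERLAP = 20


@dataclass
class FactorSolution:
    n_factors: int
    loadings: pd.DataFrame  # site x factor pattern matrix
    factor_correlations: np.ndarray
    communalities: pd.Series

    def __post_init__(self):
        phi = self.factor_correlations
        if not np.allclose(phi, phi.T, atol=1e-8):
            raise ValueError("factor correlation matrix not symmetric")
        if not np.allclose(np.diag(phi), 1.0, atol=1e-6):
            raise ValueError("factor correlation diagonal must be 1")


@dataclass
class NetworkModel:
    nodes: List[str]
    weights: np.ndarray  # standardized partial correlations, zero diagonal
    regularization: float
    ebic: float
    dropped_columns: List[str] = field(default_factory=list)

    def edges(self, tol: float = 1e-6) -> pd.DataFrame:
        rows = []
        p = len(self.nodes)
        for i in range(p):
            for j in range(i + 1, p):
                w = self.weights[i, j]
                if abs(w) > tol:
                    rows.append({"node1": self.nodes[i], "node2": self.nodes[j], "weight": w})
        return pd.DataFrame(rows, columns=["node1", "node2", "weight"])


def nonparanormal_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Map each column to normal scores: Phi^-1(rank / (n + 1)), average ties.

    Constant columns are dropped with a warning; missing cells stay missing.
    Rank order (hence Spearman correlation with the input) is preserved.
    """
    out = {}
    for col in matrix.columns:
        v = matrix[col]
        ok = v.notna()
        x = v[ok].to_numpy(dtype=float)
        if len(x) < 3:
            warnings.warn(f"column {col!r}: fewer than 3 values, dropped")
            continue
        if np.ptp(x) == 0:
            warnings.warn(f"column {col!r} is constant, dropped")
            continue
        ranks = stats.rankdata(x, method="average")
        z = stats.norm.ppf(ranks / (len(x) + 1))
        s = pd.Series(np.nan, index=matrix.index)
        s[ok] = z
        out[col] = s
    return pd.DataFrame(out, index=matrix.index)


def _correlation(matrix: pd.DataFrame, min_overlap: int) -> Tuple[pd.DataFrame, List[str]]:
    """Pairwise-complete correlations; columns below the overlap floor drop."""
    kept = matrix.copy()
    bad: List[str] = []
    while kept.shape[1] >= 2:
        counts = kept.notna().astype(int)
        overlap = counts.T @ counts
        violations = (overlap < min_overlap).sum(axis=1) - (
            np.diag(overlap) < min_overlap
        ).astype(int)
        worst = violations.idxmax()
        if violations[worst] == 0:
            break
        bad.append(worst)
        kept = kept.drop(columns=[worst])
    corr = kept.corr(min_periods=min_overlap)
    return corr, bad


def parallel_analysis(
    matrix: pd.DataFrame,
    n_sims: int = 1000,
    quantile: float = 0.95,
    seed: int = 0,
) -> int:
    """Horn's parallel analysis: retain factors whose correlation eigenvalues
    exceed the chosen quantile of eigenvalues from random normal data of the
    same shape, counting consecutively from the largest."""
    if matrix.shape[1] < 2:
        raise ValueError("parallel analysis needs at least two columns")
    data = matrix.dropna(axis=0)
    n, p = data.shape
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(data.to_numpy(), rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sims, p))
    for k in range(n_sims):
        x = rng.standard_normal((n, p))
        sims[k] = np.sort(np.linalg.eigvalsh(np.corrcoef(x, rowvar=False)))[::-1]
    thresh = np.quantile(sims, quantile, axis=0)
    n_factors = 0
    for o, t in zip(obs, thresh):
        if o > t:
            n_factors += 1
        else:
            break
    return n_factors


def _varimax(loadings: np.ndarray, max_iter: int = 200, tol: float = 1e-8) -> Tuple[np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation (SVD algorithm); returns (rotated, rotation)."""
    n, k = loadings.shape
    rot = np.eye(k)
    if k < 2:
        return loadings.copy(), rot
    d = 0.0
    for _ in range(max_iter):
        lam = loadings @ rot
        u, s, vt = np.linalg.svd(
            loadings.T @ (lam**3 - (1.0 / n) * lam @ np.diag(np.sum(lam**2, axis=0)))
        )
        rot = u @ vt
        d_new = np.sum(s)
        if d_new < d * (1 + tol):
            break
        d = d_new
    return loadings @ rot, rot


def _promax(varimax_loadings: np.ndarray, kappa: int = 4) -> Tuple[np.ndarray, np.ndarray]:
    """Oblique promax rotation of varimax loadings.

    Returns (pattern matrix, factor correlation matrix). Follows the classic
    procedure: regress the varimax loadings onto their kappa-power target,
    rescale so the implied factor correlation matrix has unit diagonal.
    """
    x = varimax_loadings
    if x.shape[1] < 2:
        return x.copy(), np.eye(x.shape[1])
    target = np.sign(x) * np.abs(x) ** kappa
    u, *_ = np.linalg.lstsq(x, target, rcond=None)
    d = np.diag(np.linalg.inv(u.T @ u))
    u = u @ np.diag(np.sqrt(d))
    pattern = x @ u
    phi = np.linalg.inv(u.T @ u)
    # clean tiny asymmetries from the inversions
    phi = (phi + phi.T) / 2.0
    np.fill_diagonal(phi, 1.0)
    return pattern, phi


def efa_promax(
    matrix: pd.DataFrame,
    n_factors: int,
    kappa: int = 4,
    max_iter: int = 2000,
) -> FactorSolution:
    """Maximum-likelihood exploratory factor analysis with promax rotation.

    Columns are standardized (so the analysis runs on the correlation
    structure), factors extracted by ML, rotated varimax then promax
    (power ``kappa``); each factor's sign is aligned so its largest-|loading|
    entry is positive.
    """
    if not (1 <= n_factors < matrix.shape[1]):
        raise ValueError("n_factors must be in [1, n_columns)")
    data = matrix.dropna(axis=0)
    x = data.to_numpy(dtype=float)
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    fa = FactorAnalysis(n_components=n_factors, max_iter=max_iter, svd_method="lapack")
    fa.fit(x)
    if fa.n_iter_ >= max_iter:
        raise RuntimeError(
            f"factor extraction did not converge in {fa.n_iter_} iterations"
        )
    unrotated = fa.components_.T  # p x k
    communalities = pd.Series(
        np.clip(np.sum(unrotated**2, axis=1), 0.0, 1.0), index=matrix.columns
    )
    vmax, _ = _varimax(unrotated)
    pattern, phi = _promax(vmax, kappa=kappa)
    # sign alignment: the largest-|loading| entry of each factor positive
    for j in range(pattern.shape[1]):
        i = int(np.argmax(np.abs(pattern[:, j])))
        if pattern[i, j] < 0:
            pattern[:, j] *= -1
            phi[j, :] *= -1
            phi[:, j] *= -1
    np.fill_diagonal(phi, 1.0)
    loadings = pd.DataFrame(
        pattern,
        index=matrix.columns,
        columns=[f"F{j + 1}" for j in range(n_factors)],
    )
    return FactorSolution(n_factors, loadings, phi, communalities)


def ebicglasso(
    matrix: pd.DataFrame,
    gamma: float = 0.5,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 0.01,
    min_overlap: int = MIN_PAIRWISE_OVERLAP,
) -> NetworkModel:
    """Sparse partial-correlation network via graphical lasso + EBIC selection.

    The lasso path is log-spaced from the largest absolute off-diagonal
    correlation down to ``lambda_min_ratio`` times it; the model minimizing
    EBIC = -2 loglik + E log(n) + 4 E gamma log(p) (E = edge count) is
    selected. Edge weights are standardized partial correlations
    -omega_ij / sqrt(omega_ii * omega_jj).
    """
    corr, dropped = _correlation(matrix, min_overlap)
    nodes = list(corr.columns)
    p = len(nodes)
    if p < 2:
        raise ValueError("need at least two usable columns")
    n = int(matrix[nodes].notna().all(axis=1).sum()) or int(
        matrix[nodes].notna().sum().min()
    )
    if n < 3:
        raise ValueError("need at least three rows")
    s = corr.to_numpy()
    # ridge-stabilize a non-positive-definite pairwise-complete matrix
    w, v = np.linalg.eigvalsh(s), None
    if w.min() < 1e-8:
        warnings.warn("correlation matrix not positive definite; ridge added")
        s = s + (1e-6 - w.min()) * np.eye(p)
        d = np.sqrt(np.diag(s))
        s = s / np.outer(d, d)
    off = np.abs(s - np.eye(p))
    lam_max = max(off.max(), 1e-3)
    lambdas = np.logspace(
        np.log10(lam_max), np.log10(lam_max * lambda_min_ratio), n_lambdas
    )
    best = None
    for lam in lambdas:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, precision = graphical_lasso(s, alpha=float(lam), max_iter=200)
        except FloatingPointError:
            continue
        pcor = -precision / np.sqrt(
            np.outer(np.diag(precision), np.diag(precision))
        )
        np.fill_diagonal(pcor, 0.0)
        pcor[np.abs(pcor) < 1e-4] = 0.0
        n_edges = int(np.count_nonzero(np.triu(pcor, 1)))
        sign, logdet = np.linalg.slogdet(precision)
        if sign <= 0:
            continue
        loglik = (n / 2.0) * (logdet - np.trace(s @ precision))
        ebic = -2.0 * loglik + n_edges * np.log(n) + 4.0 * n_edges * gamma * np.log(p)
        if best is None or ebic < best[0]:
            best = (ebic, float(lam), pcor)
    if best is None:
        raise RuntimeError("graphical lasso failed along the whole path")
    ebic, lam, pcor = best
    pcor = (pcor + pcor.T) / 2.0
    return NetworkModel(
        nodes=nodes,
        weights=pcor,
        regularization=lam,
        ebic=float(ebic),
        dropped_columns=dropped,
    )
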