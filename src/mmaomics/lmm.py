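"""Kinship mixed-model association for expression-phenotype screens.

The differential-expression engine used throughout this package models a
continuous severity surrogate (the propionate-incorporation assay, PI+) as

    y = mu + x * beta + u + eps,    u ~ N(0, sigma_g^2 K),  eps ~ N(0, sigma_e^2 I)

where ``x`` is one gene's (standardized) expression vector and ``K`` is a
sample-sample covariance ("kinship") derived from the doubly standardized
expression matrix itself, ``K = M^T M / p``.  The variance ratio
``delta = sigma_e^2 / sigma_g^2`` is profiled on the eigenbasis of K
(EMMA-style: one eigendecomposition, then every per-gene fit is a cheap 1-D
optimization), by default under REML.

Also here: the iterative row/column standardization that produces the
doubly-standardized matrix, the rank-based inverse-normal transform applied to
the response, and BLUP-based sample prediction/ranking used to select cell
lines by predicted severity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "Kinship",
    "LmmFit",
    "iterative_standardize",
    "rank_inverse_normal",
    "sample_kinship",
    "lmm_fit_one",
    "lmm_scan",
    "mito_filter",
    "predict_blup",
    "genomic_inflation",
]


class DegenerateInputError(ValueError):
    """Raised for constant rows/columns or other inputs with no information."""


class ConvergenceError(RuntimeError):
    """Raised when iterative standardization fails to reach its tolerance."""


# ---------------------------------------------------------------------------
# normalization


def iterative_standardize(
    M: np.ndarray | pd.DataFrame, tol: float = 1e-6, max_iter: int = 100
) -> np.ndarray | pd.DataFrame:
    """Alternately z-score columns then rows until both margins are standard.

    Convergence requires every row/column mean to satisfy ``|m| < tol`` and
    every row/column variance ``|v - 1| < 10 * tol`` (population variance).

    Raises ``DegenerateInputError`` for constant rows/columns and
    ``ConvergenceError`` (naming the worst offending margin) if ``max_iter``
    alternations do not suffice.
    """
    is_df = isinstance(M, pd.DataFrame)
    A = np.asarray(M, dtype=float).copy()
    if A.ndim != 2 or A.shape[0] < 2 or A.shape[1] < 2:
        raise ValueError("need a matrix with at least 2 rows and 2 columns")
    if not np.all(np.isfinite(A)):
        raise ValueError("matrix contains non-finite entries")
    if np.any(A.std(axis=0) == 0):
        raise DegenerateInputError("constant column in input matrix")
    if np.any(A.std(axis=1) == 0):
        raise DegenerateInputError("constant row in input matrix")

    def _margins(X: np.ndarray) -> dict[str, float]:
        return {
            "row mean": np.abs(X.mean(axis=1)).max(),
            "column mean": np.abs(X.mean(axis=0)).max(),
            "row variance": np.abs(X.var(axis=1) - 1.0).max(),
            "column variance": np.abs(X.var(axis=0) - 1.0).max(),
        }

    def _ok(m: dict[str, float]) -> bool:
        return (
            m["row mean"] < tol
            and m["column mean"] < tol
            and m["row variance"] < 10 * tol
            and m["column variance"] < 10 * tol
        )

    m = _margins(A)
    for _ in range(max_iter):
        if _ok(m):
            break
        A = (A - A.mean(axis=0)) / A.std(axis=0)
        A = (A - A.mean(axis=1, keepdims=True)) / A.std(axis=1, keepdims=True)
        m = _margins(A)
    else:
        worst = max(m, key=lambda k: m[k] if "mean" in k else m[k] / 10)
        raise ConvergenceError(
            f"double standardization did not converge in {max_iter} iterations; "
            f"worst margin: {worst} = {m[worst]:.3g}"
        )
    if is_df:
        return pd.DataFrame(A, index=M.index, columns=M.columns)
    return A


def rank_inverse_normal(y: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Rank-based inverse-normal (quantile) transform.

    Maps value with (average, for ties) rank r among n finite values to
    ``Phi^{-1}((r - 0.5) / n)`` so the response follows a standard normal.
    """
    arr = np.asarray(y, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D vector")
    finite = np.isfinite(arr)
    vals = arr[finite]
    if vals.size < 3:
        raise ValueError("need at least 3 finite values")
    if np.all(vals == vals[0]):
        raise DegenerateInputError("all values identical; transform undefined")
    ranks = stats.rankdata(vals, method="average")
    z = special.ndtri((ranks - 0.5) / vals.size)
    out = np.full_like(arr, np.nan)
    out[finite] = z
    if isinstance(y, pd.Series):
        return pd.Series(out, index=y.index, name=y.name)
    return out


# ---------------------------------------------------------------------------
# kinship


@dataclass
class Kinship:
    """Sample-sample covariance with a cached eigendecomposition."""

    K: np.ndarray
    eigenvalues: np.ndarray = field(repr=False)
    eigenvectors: np.ndarray = field(repr=False)
    samples: list[str] | None = None

    @classmethod
    def from_matrix(cls, K: np.ndarray, samples: list[str] | None = None) -> "Kinship":
        K = np.asarray(K, dtype=float)
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        lam, U = np.linalg.eigh(K)
        if lam.min() < -1e-8:
            raise ValueError(f"kinship matrix is not PSD (min eigenvalue {lam.min():.3g})")
        return cls(K=K, eigenvalues=np.clip(lam, 0.0, None), eigenvectors=U, samples=samples)

    @property
    def n(self) -> int:
        return self.K.shape[0]


def sample_kinship(M: np.ndarray | pd.DataFrame) -> Kinship:
    """K = M^T M / p over p genes from a doubly-standardized genes x samples matrix."""
    samples = list(M.columns) if isinstance(M, pd.DataFrame) else None
    A = np.asarray(M, dtype=float)
    p = A.shape[0]
    if p < 2:
        raise ValueError("need at least 2 genes to form a kinship matrix")
    K = A.T @ A / p
    return Kinship.from_matrix(K, samples=samples)


# ---------------------------------------------------------------------------
# per-gene mixed-model fit


@dataclass
class LmmFit:
    gene: str
    beta: float
    se: float
    p: float
    delta: float
    sigma_g2: float
    sigma_e2: float
    loglik: float
    on_boundary: bool = False


_LOGDELTA_LO, _LOGDELTA_HI = -10.0, 10.0
_GRID_POINTS = 41


def _reml_pieces(yr: np.ndarray, Xr: np.ndarray, lam: np.ndarray, delta: float):
    """GLS quantities on the rotated (eigen) basis for V = sigma_g^2 (K + delta I)."""
    w = lam + delta
    Xw = Xr / w[:, None]
    XtWX = Xr.T @ Xw
    XtWy = Xw.T @ yr
    beta = np.linalg.solve(XtWX, XtWy)
    resid = yr - Xr @ beta
    rss = float(resid @ (resid / w))
    return w, XtWX, beta, rss


def _neg_restricted_ll(logdelta: float, yr, Xr, lam, XtX_logdet: float) -> float:
    n, p = Xr.shape
    w, XtWX, _, rss = _reml_pieces(yr, Xr, lam, np.exp(logdelta))
    sigma_g2 = rss / (n - p)
    if sigma_g2 <= 0:
        return np.inf
    ll = -0.5 * (
        (n - p) * np.log(2 * np.pi * sigma_g2)
        + np.sum(np.log(w))
        + np.linalg.slogdet(XtWX)[1]
        - XtX_logdet
        + (n - p)
    )
    return -ll


def _neg_ml_ll(logdelta: float, yr, Xr, lam) -> float:
    n = Xr.shape[0]
    w, _, _, rss = _reml_pieces(yr, Xr, lam, np.exp(logdelta))
    sigma_g2 = rss / n
    if sigma_g2 <= 0:
        return np.inf
    ll = -0.5 * (n * np.log(2 * np.pi * sigma_g2) + np.sum(np.log(w)) + n)
    return -ll


def _profile_delta(yr, Xr, lam, reml: bool):
    """Grid-then-Brent 1-D optimization of the (restricted) likelihood in log delta."""
    XtX_logdet = np.linalg.slogdet(Xr.T @ Xr)[1]
    if reml:
        obj = lambda ld: _neg_restricted_ll(ld, yr, Xr, lam, XtX_logdet)  # noqa: E731
    else:
        obj = lambda ld: _neg_ml_ll(ld, yr, Xr, lam)  # noqa: E731
    grid = np.linspace(_LOGDELTA_LO, _LOGDELTA_HI, _GRID_POINTS)
    vals = np.array([obj(g) for g in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, _GRID_POINTS - 1)]
    res = optimize.minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    logdelta = float(res.x) if res.fun <= vals[i] else float(grid[i])
    on_boundary = logdelta <= _LOGDELTA_LO + 1e-3 or logdelta >= _LOGDELTA_HI - 1e-3
    return logdelta, -obj(logdelta), on_boundary


def lmm_fit_one(
    y: np.ndarray,
    x: np.ndarray,
    kinship: Kinship,
    reml: bool = True,
    gene: str = "",
) -> LmmFit:
    """Fit y = mu + x*beta + u + eps with u ~ N(0, sigma_g^2 K).

    The variance ratio delta = sigma_e^2/sigma_g^2 is profiled on the
    eigenbasis of K; beta, its standard error and a two-sided Wald p-value
    (t reference with n - p degrees of freedom, so the K = I case reduces
    exactly to ordinary least squares) are returned.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = kinship.n
    if y.shape != (n,) or x.shape != (n,):
        raise ValueError("y, x and K are not conformable")
    if n < 5:
        raise ValueError("need at least 5 samples")
    U, lam = kinship.eigenvectors, kinship.eigenvalues
    yr = U.T @ y
    Xr = U.T @ np.column_stack([np.ones(n), x])
    return _fit_rotated(yr, Xr, lam, reml=reml, gene=gene)


def _fit_rotated(yr, Xr, lam, reml: bool, gene: str = "") -> LmmFit:
    n, p = Xr.shape
    logdelta, loglik, on_boundary = _profile_delta(yr, Xr, lam, reml)
    delta = float(np.exp(logdelta))
    w, XtWX, beta, rss = _reml_pieces(yr, Xr, lam, delta)
    dof = n - p
    sigma_g2 = rss / dof if reml else rss / n
    sigma_e2 = delta * sigma_g2
    cov = (rss / dof) * np.linalg.inv(XtWX)
    se = float(np.sqrt(cov[-1, -1]))
    tstat = beta[-1] / se
    pval = float(2.0 * stats.t.sf(abs(tstat), dof))
    return LmmFit(
        gene=gene,
        beta=float(beta[-1]),
        se=se,
        p=pval,
        delta=delta,
        sigma_g2=float(sigma_g2),
        sigma_e2=float(sigma_e2),
        loglik=float(loglik),
        on_boundary=on_boundary,
    )


def lmm_scan(
    y: pd.Series,
    X: pd.DataFrame,
    kinship: Kinship,
    reml: bool = True,
    standardize_genes: bool = True,
) -> pd.DataFrame:
    """Per-gene mixed-model association scan.

    ``y`` is a response indexed by sample; ``X`` a genes x samples expression
    matrix.  Sample identity is verified by identifier, not position.  The
    eigendecomposition of K is computed once and every gene vector is rotated
    with a single matrix product.  Genes are standardized before use as fixed
    effects so beta is on a comparable effect-size scale.

    Returns a DataFrame sorted by p with a Q-Q-ready ``neglog10_p`` column.
    """
    if kinship.samples is None:
        raise ValueError("kinship must carry sample identifiers for a scan")
    missing = [s for s in kinship.samples if s not in y.index]
    missing += [s for s in kinship.samples if s not in X.columns]
    if missing:
        raise ValueError(f"sample identifiers missing from response or matrix: {sorted(set(missing))}")
    order = list(kinship.samples)
    yv = y.loc[order].to_numpy(dtype=float)
    G = X.loc[:, order].to_numpy(dtype=float)
    if standardize_genes:
        sd = G.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise DegenerateInputError("constant gene row in expression matrix")
        G = (G - G.mean(axis=1, keepdims=True)) / sd

    U, lam = kinship.eigenvectors, kinship.eigenvalues
    n = len(order)
    yr = U.T @ yv
    ones_r = U.T @ np.ones(n)
    G_rot = G @ U  # row g is the rotated gene vector

    rows = []
    for g, gene in enumerate(X.index):
        Xr = np.column_stack([ones_r, G_rot[g]])
        fit = _fit_rotated(yr, Xr, lam, reml=reml, gene=str(gene))
        rows.append(fit)
    out = pd.DataFrame(
        {
            "gene": [f.gene for f in rows],
            "beta": [f.beta for f in rows],
            "se": [f.se for f in rows],
            "p": [f.p for f in rows],
            "delta": [f.delta for f in rows],
            "sigma_g2": [f.sigma_g2 for f in rows],
            "sigma_e2": [f.sigma_e2 for f in rows],
            "on_boundary": [f.on_boundary for f in rows],
        }
    )
    out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    out["neglog10_p"] = -np.log10(np.clip(out["p"], 1e-300, None))
    return out


def mito_filter(fits: pd.DataFrame, gene_set: list[str] | set[str]) -> pd.DataFrame:
    """Restrict scan results to a gene set (e.g. mitochondrially localized enzymes)."""
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    sub = fits[fits["gene"].isin(gene_set)]
    if sub.empty:
        warnings.warn("gene set has empty intersection with scan results", stacklevel=2)
    return sub.copy()


def genomic_inflation(pvalues: np.ndarray) -> float:
    """Genomic inflation factor: median chi2(1) of the p-values over 0.4549."""
    p = np.asarray(pvalues, dtype=float)
    chi2 = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


# ---------------------------------------------------------------------------
# BLUP prediction


def predict_blup(
    y: pd.Series | np.ndarray,
    fixed: pd.DataFrame | np.ndarray | None,
    kinship: Kinship,
    variance_components: tuple[float, float] | None = None,
    reml: bool = True,
) -> pd.DataFrame:
    """Predict the response per sample as fixed effects + BLUP of the random effect.

    ``fixed`` holds covariate columns (e.g. GLUD1 and OGDH expression); an
    intercept is always included.  With sigma_g^2 = 0 the prediction reduces to
    the fixed-effect (OLS) regression prediction.  ``variance_components``
    may supply (sigma_g2, sigma_e2) directly, bypassing REML estimation.

    Returns a DataFrame with columns ``predicted`` and ``rank`` (1 = lowest
    predicted response).
    """
    index = y.index if isinstance(y, pd.Series) else (
        pd.Index(kinship.samples) if kinship.samples else pd.RangeIndex(kinship.n)
    )
    yv = np.asarray(y, dtype=float)
    n = kinship.n
    if fixed is None:
        X = np.ones((n, 1))
    else:
        F = np.asarray(fixed, dtype=float)
        if F.ndim == 1:
            F = F[:, None]
        X = np.column_stack([np.ones(n), F])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effect design")

    U, lam = kinship.eigenvectors, kinship.eigenvalues
    yr = U.T @ yv
    Xr = U.T @ X

    if variance_components is None:
        logdelta, _, _ = _profile_delta(yr, Xr, lam, reml)
        delta = float(np.exp(logdelta))
        _, _, beta, rss = _reml_pieces(yr, Xr, lam, delta)
        dof = n - X.shape[1]
        sigma_g2 = rss / dof if reml else rss / n
        sigma_e2 = delta * sigma_g2
    else:
        sigma_g2, sigma_e2 = (float(v) for v in variance_components)
        if sigma_g2 < 0 or sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")
        if sigma_g2 == 0:
            beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
            pred = X @ beta
            return _blup_frame(pred, index)
        delta = sigma_e2 / sigma_g2
        _, _, beta, _ = _reml_pieces(yr, Xr, lam, delta)

    # u_hat = sigma_g2 K V^{-1} (y - X beta) on the eigenbasis:
    # V = sigma_g2 (K + delta I) => K V^{-1} = U diag(lam/(sigma_g2 (lam+delta))) U^T * sigma_g2
    resid_r = yr - Xr @ beta
    shrink = lam / (lam + delta)
    u_hat = U @ (shrink * resid_r)
    pred = X @ beta + u_hat
    return _blup_frame(pred, index)


def _blup_frame(pred: np.ndarray, index) -> pd.DataFrame:
    out = pd.DataFrame({"predicted": pred}, index=index)
    out["rank"] = out["predicted"].rank(method="first").astype(int)
    return out
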