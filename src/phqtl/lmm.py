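"""Spectral linear mixed models with a single genomic random effect.

The model is ``y = X beta + g + e`` with ``g ~ N(0, G tau2)`` and
``e ~ N(0, I sigma2)``.  After rotating by the eigenvectors of ``G`` the
covariance is diagonal, ``Var(y*) = s2_tot * diag(h s_k + 1 - h)`` with
``h = tau2 / (tau2 + sigma2)``, so the fit reduces to a one-dimensional
profile (RE)ML optimization over ``h`` plus weighted least squares.  This is
the standard machinery behind genome scans in multiparent populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

_LOG2PI = math.log(2.0 * math.pi)
H_MAX = 1.0 - 1e-6


@dataclass
class LmmFit:
    h: float          # variance fraction of the random effect, tau2/(tau2+sigma2)
    tau2: float
    sigma2: float
    loglik: float
    beta: np.ndarray
    reml: bool


def eigendecompose(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (clipped at 0) and eigenvectors of a symmetric PSD matrix."""
    s, U = np.linalg.eigh(G)
    if s.min() < -1e-6 * max(1.0, abs(s.max())):
        raise ValueError("kinship matrix is not positive semidefinite")
    return np.clip(s, 0.0, None), U


def gls_rss(yw: np.ndarray, Xw: np.ndarray) -> tuple[float, np.ndarray]:
    """Residual sum of squares of pre-whitened least squares."""
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    return float(resid @ resid), beta


def _neg_profile(h, yr, Xr, s, reml):
    ll = profile_loglik(h, yr, Xr, s, reml)[0]
    return -ll if math.isfinite(ll) else 1e12


def profile_loglik(h: float, yr: np.ndarray, Xr: np.ndarray, s: np.ndarray,
                   reml: bool) -> tuple[float, float, np.ndarray]:
    """Profile (RE)ML log-likelihood at variance fraction ``h``.

    ``yr``/``Xr`` are the eigenvector-rotated response and design; ``s`` the
    kinship eigenvalues.  Returns (loglik, rss_weighted, beta).
    """
    n, p = Xr.shape
    w = h * s + (1.0 - h)
    ws = 1.0 / np.sqrt(w)
    yw = yr * ws
    Xw = Xr * ws[:, None]
    rss, beta = gls_rss(yw, Xw)
    rss = max(rss, 1e-300)
    logdet_w = float(np.sum(np.log(w)))
    if reml:
        df = n - p
        _, ld = np.linalg.slogdet(Xw.T @ Xw)
        ll = -0.5 * (df * (_LOG2PI + math.log(rss / df)) + logdet_w + ld + df)
    else:
        ll = -0.5 * (n * (_LOG2PI + math.log(rss / n)) + logdet_w + n)
    return float(ll), rss, beta


def fit_lmm(y: np.ndarray, X: np.ndarray, *, eig: tuple[np.ndarray, np.ndarray],
            reml: bool = True) -> LmmFit:
    """Fit the one-random-effect LMM by 1-D profile optimization.

    ``eig`` is the precomputed ``(eigenvalues, eigenvectors)`` of the kinship
    matrix restricted to the observations in ``y``.
    """
    s, U = eig
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    if np.ptp(y) == 0:
        raise ValueError("response is constant")
    yr = U.T @ y
    Xr = U.T @ X
    # coarse grid then local refinement: the profile can be multimodal near 0
    grid = np.linspace(0.0, H_MAX, 21)
    lls = np.array([profile_loglik(h, yr, Xr, s, reml)[0] for h in grid])
    k = int(np.argmax(lls))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    if hi > lo:
        res = minimize_scalar(_neg_profile, bounds=(lo, hi), args=(yr, Xr, s, reml),
                              method="bounded", options={"xatol": 1e-7})
        h_hat = float(res.x)
        if -res.fun < lls[k]:
            h_hat = float(grid[k])
    else:
        h_hat = float(grid[k])
    ll, rss, beta = profile_loglik(h_hat, yr, Xr, s, reml)
    n, p = Xr.shape
    s2_tot = rss / (n - p) if reml else rss / n
    return LmmFit(h=h_hat, tau2=h_hat * s2_tot, sigma2=(1.0 - h_hat) * s2_tot,
                  loglik=ll, beta=beta, reml=reml)


@dataclass
class WhitenedProblem:
    """Null-model variance profile frozen for fast per-marker GLS.

    Holds the whitening implied by the null fit: ``yw = W^{-1/2} U^T y`` etc.
    ``Minv`` is the full inverse correlation matrix ``U W^{-1} U^T`` used by
    the indicator-aggregation permutation kernel.
    """

    h: float
    n: int
    U: np.ndarray
    w: np.ndarray
    yw: np.ndarray
    Xw: np.ndarray          # whitened null design (intercept [+ covariates])
    rss0: float
    Minv: np.ndarray
    y: np.ndarray
    X0: np.ndarray

    def whiten(self, columns: np.ndarray) -> np.ndarray:
        """Whiten extra design columns given in observation order."""
        ws = 1.0 / np.sqrt(self.w)
        return (self.U.T @ columns) * ws[:, None]


def whiten_null(y: np.ndarray, X0: np.ndarray, eig, *, reml: bool = True,
                h: float | None = None) -> WhitenedProblem:
    """Estimate the null variance profile and freeze it for GLS scanning."""
    s, U = eig
    y = np.asarray(y, dtype=float)
    X0 = np.atleast_2d(np.asarray(X0, dtype=float))
    if X0.shape[0] != len(y):
        X0 = X0.T
    if h is None:
        h = fit_lmm(y, X0, eig=eig, reml=reml).h
    w = h * s + (1.0 - h)
    ws = 1.0 / np.sqrt(w)
    yw = (U.T @ y) * ws
    Xw = (U.T @ X0) * ws[:, None]
    rss0, _ = gls_rss(yw, Xw)
    Minv = (U / w) @ U.T
    return WhitenedProblem(h=h, n=len(y), U=U, w=w, yw=yw, Xw=Xw, rss0=rss0,
                           Minv=Minv, y=y, X0=X0)


def lod_from_rss(rss0: float, rss1: np.ndarray, n: int) -> np.ndarray:
    """LOD = (n/2) log10(RSS0 / RSS1) under a shared variance profile."""
    lod = 0.5 * n * (np.log10(rss0) - np.log10(rss1))
    return np.maximum(lod, 0.0)
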