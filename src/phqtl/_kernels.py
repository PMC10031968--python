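"""Numerical kernels for genome scans and permutation nulls.

Two interchangeable GLS-scan backends:

* a dense numpy path that handles arbitrary (soft) founder probabilities and
  extra covariates, batched over markers with small batched solves;
* a compiled (numba) path for hard 0/1 haplotype calls, which exploits the
  fact that for indicator dosages ``D^T M D`` is a founder-group aggregation
  of a fixed n x n matrix — this is what makes 10k-permutation nulls cheap.

Both fit, at each marker, ``y = mu (+ covariates) + QTL`` by generalized
least squares under a frozen null variance profile and return the residual
sum of squares; the LOD follows as ``(n/2) log10(RSS0/RSS1)``.  A relative
ridge of 1e-10 on the normal equations guards markers where a founder is
absent from the panel (its column is all zero); the RSS is computed through
the exact quadratic form so the perturbation is negligible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_RIDGE = 1e-10


def dense_marker_rss(yw: np.ndarray, Xw0: np.ndarray, Dw: np.ndarray) -> np.ndarray:
    """RSS at each marker for whitened data.

    Parameters
    ----------
    yw : (n,) whitened response.
    Xw0 : (n, p0) whitened null design (intercept, optional covariates).
    Dw : (M, n, 8) whitened founder-dosage columns per marker.

    Returns (M,) residual sums of squares of the model [Xw0 | Dw[..., :7]].
    """
    M, n, _ = Dw.shape
    p0 = Xw0.shape[1]
    k = p0 + 7
    X = np.empty((M, n, k))
    X[:, :, :p0] = Xw0[None, :, :]
    X[:, :, p0:] = Dw[:, :, :7]
    Xt = X.transpose(0, 2, 1)
    XtX = np.matmul(Xt, X)
    Xty = np.matmul(Xt, yw[None, :, None])[..., 0]
    tr = np.trace(XtX, axis1=1, axis2=2)
    A = XtX + (_RIDGE * tr / k)[:, None, None] * np.eye(k)[None, :, :]
    beta = np.linalg.solve(A, Xty[..., None])[..., 0]
    yy = float(yw @ yw)
    rss = (yy - 2.0 * np.einsum("mk,mk->m", beta, Xty)
           + np.einsum("mk,mkl,ml->m", beta, XtX, beta))
    return np.maximum(rss, 0.0)


def dense_perm_rss(perms: np.ndarray, D: np.ndarray, U: np.ndarray,
                   w: np.ndarray, yw: np.ndarray, Xw0: np.ndarray,
                   chunk: int = 200) -> np.ndarray:
    """Permutation RSS via the dense path (soft probabilities).

    ``D`` is the raw (n, M, 8) dosage array; each permutation re-indexes its
    strain rows, after which the whitened per-marker GLS of
    :func:`dense_marker_rss` is applied.  Returns (P, M).
    """
    P, n = perms.shape
    M = D.shape[1]
    ws = 1.0 / np.sqrt(w)
    out = np.empty((P, M))
    flat = D.reshape(n, M * 8)
    for start in range(0, P, chunk):
        idx = perms[start:start + chunk]
        Dp = flat[idx]                                # (c, n, M*8)
        R = np.matmul(U.T, Dp) * ws[None, :, None]    # whiten
        R = R.reshape(len(idx), n, M, 8)
        for j in range(len(idx)):
            out[start + j] = dense_marker_rss(yw, Xw0, R[j].transpose(1, 0, 2))
    return out


@njit(cache=True)
def _hard_perm_rss(Minv, My, r1, yMy, founders, perms):  # pragma: no cover - compiled
    P, n = perms.shape
    M = founders.shape[0]
    out = np.empty((P, M))
    T = np.empty((8, n))
    fp = np.empty(n, np.int8)
    sum_My = 0.0
    for i in range(n):
        sum_My += My[i]
    one_M_one = 0.0
    for i in range(n):
        one_M_one += r1[i]
    for pi in range(P):
        for mk in range(M):
            for i in range(n):
                fp[i] = founders[mk, perms[pi, i]]
            for a in range(8):
                for j in range(n):
                    T[a, j] = 0.0
            for i in range(n):
                a = fp[i]
                for j in range(n):
                    T[a, j] += Minv[i, j]
            gs1 = np.zeros(8)
            gsy = np.zeros(8)
            for i in range(n):
                gs1[fp[i]] += r1[i]
                gsy[fp[i]] += My[i]
            G8 = np.zeros((8, 8))
            for j in range(n):
                bj = fp[j]
                for a in range(8):
                    G8[a, bj] += T[a, j]
            A = np.zeros((8, 8))
            b = np.zeros(8)
            A[0, 0] = one_M_one
            b[0] = sum_My
            for a in range(7):
                A[0, a + 1] = gs1[a]
                A[a + 1, 0] = gs1[a]
                b[a + 1] = gsy[a]
                for c in range(7):
                    A[a + 1, c + 1] = G8[a, c]
            tr = 0.0
            for a in range(8):
                tr += A[a, a]
            lam = _RIDGE * tr / 8.0
            for a in range(8):
                A[a, a] += lam
            beta = np.linalg.solve(A, b)
            q = 0.0
            for a in range(8):
                for c in range(8):
                    q += beta[a] * (A[a, c] - (lam if a == c else 0.0)) * beta[c]
            lin = 0.0
            for a in range(8):
                lin += beta[a] * b[a]
            rss = yMy - 2.0 * lin + q
            out[pi, mk] = rss if rss > 0.0 else 0.0
    return out


def hard_perm_rss(Minv: np.ndarray, y: np.ndarray, founders: np.ndarray,
                  perms: np.ndarray) -> np.ndarray:
    """Permutation RSS for hard haplotype calls (compiled path).

    Parameters
    ----------
    Minv : (n, n) inverse correlation matrix of the null variance profile.
    y : (n,) response in observation order.
    founders : (M, n) int8 founder label per marker and strain.
    perms : (P, n) permutations; row ``i`` of the design takes the genome of
        strain ``perms[pi, i]`` (phenotype and kinship stay in place).
    """
    My = Minv @ y
    r1 = Minv @ np.ones(len(y))
    yMy = float(y @ My)
    return _hard_perm_rss(
        np.ascontiguousarray(Minv), My, r1, yMy,
        np.ascontiguousarray(founders, dtype=np.int8),
        np.ascontiguousarray(perms, dtype=np.int64),
    )
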