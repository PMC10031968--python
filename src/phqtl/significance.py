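"""Permutation-calibrated genome-wide significance with GEV tail modeling.

For each feature, strain labels on the founder-haplotype rows are permuted
(phenotype and kinship stay paired, breaking the QTL signal but not the
kinship), the genome is rescanned, and the genome-wide maximum LOD recorded.
A generalized extreme value (GEV) distribution fit to the permutation maxima
converts an observed maximum into a genome-wide p-value; Benjamini-Hochberg
across features then yields q-values and interpolated per-feature LOD
thresholds at the target FDR.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import genextreme
from statsmodels.stats.multitest import multipletests

from . import lmm
from ._kernels import dense_perm_rss, hard_perm_rss
from .datatypes import (
    GevFit,
    HaplotypeDosageMatrix,
    PermutationNull,
    ThresholdTable,
)
from .qtl import _null_profile, _observed

N_PERM_DEFAULT = 1_000      # test-scale default
N_PERM_FULL = 10_000        # full-fidelity mode


def permutation_null(y: pd.Series, haplo: HaplotypeDosageMatrix, loco: dict,
                     n_perm: int = N_PERM_DEFAULT, seed: int = 0,
                     reml: bool = True, feature_id: str = "") -> PermutationNull:
    """Genome-wide maximum LOD under strain-label permutation of the genomes.

    Each permutation applies one genome-wide rearrangement of strain labels on
    the haplotype probability rows and rescans every chromosome with the
    feature's frozen null variance profile.  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    obs = _observed(y, haplo, None)
    yv = y.loc[obs].to_numpy(dtype=float)
    idx = haplo.strain_index(obs)
    n = len(obs)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    hard = haplo.is_hard()
    labels = haplo.founder_labels() if hard else None
    max_lod = np.full(n_perm, -np.inf)
    for chrom in haplo.markers.chromosomes:
        cidx = haplo.markers.chrom_indices(chrom)
        wp = _null_profile(yv, None, loco[chrom], idx, reml)
        if hard:
            rss = hard_perm_rss(wp.Minv, yv, labels[np.ix_(cidx, idx)], perms)
        else:
            D = haplo.probs[np.ix_(idx, cidx)]
            rss = dense_perm_rss(perms, D, wp.U, wp.w, wp.yw, wp.Xw)
        lod = lmm.lod_from_rss(wp.rss0, rss, n)   # (P, Mc)
        max_lod = np.maximum(max_lod, lod.max(axis=1))
    return PermutationNull(feature_id=feature_id, n_perm=n_perm,
                           max_lods=max_lod, seed=seed)


def fit_gev(null: PermutationNull) -> GevFit:
    """Maximum-likelihood GEV fit to the permutation maxima."""
    x = null.max_lods
    if null.n_perm < 100:
        warnings.warn(f"{null.n_perm} permutations; GEV fit may be unstable")
    if np.ptp(x) == 0:
        raise ValueError("degenerate permutation sample (constant maxima)")
    c, loc, scale = genextreme.fit(x)
    return GevFit(feature_id=null.feature_id, location=float(loc),
                  scale=float(scale), shape=float(-c), n_perm=null.n_perm)


def permutation_pvalue(fit: GevFit, observed_max_lod: float,
                       clamp: bool = True) -> float:
    """Genome-wide permutation p-value ``p = 1 - F(max LOD)``.

    With ``clamp`` the p-value is kept in ``[1/(n_perm+1), 1 - 1/(n_perm+1)]``
    so downstream BH never sees exact zeros.
    """
    p = float(1.0 - fit.cdf(observed_max_lod))
    if clamp and fit.n_perm > 0:
        eps = 1.0 / (fit.n_perm + 1)
        p = min(max(p, eps), 1.0 - eps)
    else:
        p = min(max(p, np.finfo(float).tiny), 1.0)
    return p


def fdr_thresholds(pvalues: pd.Series, fits: dict, max_lods: pd.Series,
                   q_target: float = 0.1, lenient_q: float = 0.5) -> ThresholdTable:
    """BH q-values and FDR-interpolated per-feature LOD thresholds.

    The p-value at which the (linearly interpolated) q-value equals
    ``q_target`` is mapped through each feature's inverse GEV CDF:
    ``lambda_j = F_j^{-1}(1 - p_interp)``.  Features whose maximum LOD
    reaches ``lambda_j`` form the stringent set; ``lenient_q`` (default 0.5)
    gives a second, lenient set used as input to parent-mediation analysis.
    """
    if len(pvalues) == 0:
        raise ValueError("no features")
    p = pvalues.to_numpy(dtype=float)
    q = multipletests(p, method="fdr_bh")[1]
    qs = pd.Series(q, index=pvalues.index)
    p_interp, attained = _interp_pvalue(p, q, q_target)
    p_len, _ = _interp_pvalue(p, q, lenient_q)
    rows = []
    for fid in pvalues.index:
        fit = fits[fid]
        lam = float(fit.ppf(1.0 - p_interp))
        lam_len = float(fit.ppf(1.0 - p_len))
        ml = float(max_lods.loc[fid])
        rows.append(dict(feature_id=fid, max_lod=ml, pvalue=float(pvalues.loc[fid]),
                         qvalue=float(qs.loc[fid]), lambda_fdr=lam,
                         lambda_lenient=lam_len, significant=ml >= lam,
                         lenient=ml >= lam_len))
    table = pd.DataFrame(rows).set_index("feature_id", drop=False)
    return ThresholdTable(table=table, q_target=q_target, lenient_q=lenient_q,
                          p_interp=p_interp, p_interp_lenient=p_len, attained=attained)


def _interp_pvalue(p: np.ndarray, q: np.ndarray, q_target: float) -> tuple[float, bool]:
    """p-value where interpolated q crosses ``q_target`` (sorted p vs q)."""
    order = np.argsort(p, kind="stable")
    ps, qs = p[order], q[order]
    qs = np.maximum.accumulate(qs)  # BH q already monotone; guard numerics
    if q_target < qs[0]:
        # no feature attains the target FDR: fall back to the smallest
        # achievable q and flag the table
        return float(ps[0]), False
    p_interp = float(np.interp(q_target, qs, ps))
    return p_interp, True
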