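"""Genetic mediation: parent-protein conditioning and mediator scans.

Two questions, two tools:

* Is a phosphopeptide's QTL transmitted through its parent protein's
  abundance (mechanism 1) or independent of it (mechanism 2)?  Refit the QTL
  model at the peak marker with the parent as a fixed covariate (kinship
  retained) and compare LOD before and after: a drop of more than 50%
  (Delta LOD percentage < -50) flags parent mediation.

* Which gene's product drives a distant QTL?  Scan candidate mediators
  (transcripts and proteins): condition the QTL term on each candidate
  (no kinship, for speed) and standardize the conditional LODs across the
  candidate set, which serves as an empirical null centered near the
  original LOD.  Strong candidates sit far in the left tail (z < -8) and are
  expected to co-map a local QTL at the distant locus.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from . import lmm
from .datatypes import (
    AbundanceMatrix,
    GenomicRelationshipMatrix,
    HaplotypeDosageMatrix,
    MediationScanResult,
    ParentMediationResult,
    PveResult,
)

MECH1_DELTA_PCT = -50.0   # parent-mediated when Delta LOD % falls below this
MECH2_DELTA_PCT = -20.0   # convention: "independent" band; between is mixed
STRONG_Z = -8.0


def _ols_rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _lod(rss0: float, rss1: float, n: int) -> float:
    return max(0.0, 0.5 * n * (np.log10(max(rss0, 1e-300)) - np.log10(max(rss1, 1e-300))))


def _marker_design(haplo: HaplotypeDosageMatrix, marker_index: int,
                   strains) -> np.ndarray:
    D = haplo.probs[haplo.strain_index(strains), marker_index, :]
    return D[:, :7]   # one founder dropped against the intercept


def mediate_through_parent(phospho: pd.Series, parent: pd.Series,
                           marker_index: int, haplo: HaplotypeDosageMatrix,
                           loco_grm: GenomicRelationshipMatrix,
                           original_lod: Optional[float] = None,
                           feature_id: str = "", parent_id: str = "",
                           marker_id: str = "") -> ParentMediationResult:
    """Mediation of a phQTL through parent-protein abundance.

    Fits, at the peak marker, ``y = mu + QTL + parent + kinship + e`` against
    the same model without the QTL term; the LOD of that comparison is the
    mediation LOD.  If ``original_lod`` is not given, the unconditioned LOD at
    the marker is computed the same way without the parent covariate.
    """
    both = phospho.dropna().index.intersection(parent.dropna().index)
    both = pd.Index([s for s in haplo.strains if s in set(both)])
    unreliable = parent.reindex(phospho.dropna().index).isna().mean() > 0.5
    n = len(both)
    if n < 5:
        raise ValueError("too few strains with phospho and parent observed")
    y = phospho.loc[both].to_numpy(dtype=float)
    par = parent.loc[both].to_numpy(dtype=float)
    idx = haplo.strain_index(both)
    eig = lmm.eigendecompose(loco_grm.subset(idx))
    D7 = _marker_design(haplo, marker_index, both)

    # mediation model: null covariates = intercept + parent
    X0 = np.column_stack([np.ones(n), par])
    wp = lmm.whiten_null(y, X0, eig, reml=True)
    X1w = np.column_stack([wp.Xw, wp.whiten(D7)])
    rss1, _ = lmm.gls_rss(wp.yw, X1w)
    lod_med = _lod(wp.rss0, rss1, n)

    if original_lod is None:
        wp0 = lmm.whiten_null(y, np.ones((n, 1)), eig, reml=True)
        X1w0 = np.column_stack([wp0.Xw, wp0.whiten(D7)])
        rss10, _ = lmm.gls_rss(wp0.yw, X1w0)
        original_lod = _lod(wp0.rss0, rss10, n)

    if original_lod <= 0:
        raise ValueError("original LOD must be positive for mediation")
    delta_pct = 100.0 * (lod_med - original_lod) / original_lod
    if delta_pct < MECH1_DELTA_PCT:
        mech = "mech1"
    elif delta_pct > MECH2_DELTA_PCT:
        mech = "mech2"
    else:
        mech = "mixed"
    return ParentMediationResult(phospho_id=feature_id, parent_id=parent_id,
                                 marker_id=marker_id, original_lod=float(original_lod),
                                 mediation_lod=float(lod_med), mechanism=mech,
                                 unreliable=bool(unreliable))


def mediation_scan(target: pd.Series, marker_index: int,
                   candidates: AbundanceMatrix, haplo: HaplotypeDosageMatrix,
                   exclude: tuple = (), window_bp: float = 10e6,
                   candidate_peaks: Optional[pd.DataFrame] = None,
                   target_position: Optional[tuple] = None,
                   robust: bool = False, min_overlap: int = 10,
                   target_id: str = "", marker_id: str = "") -> MediationScanResult:
    """Scan candidate mediators of a distant QTL.

    For each candidate ``q``: ``y = mu + QTL + mediator_q + e`` versus the
    same without the QTL term (no kinship), giving a conditional LOD.
    z-scores standardize the conditional LODs over the whole candidate set
    (mean/sd, or median/MAD with ``robust``); the target itself and its
    parent protein must be passed in ``exclude``.  ``candidate_peaks``
    (feature_id -> chromosome, position_bp of the candidate's own local QTL)
    and ``target_position`` (chromosome, position_bp of the distant QTL)
    enable the co-mapping flag.
    """
    cand_ids = [c for c in candidates.values.columns if c not in set(exclude)]
    if len(cand_ids) < 20:
        warnings.warn(f"only {len(cand_ids)} candidates; z-scores unstable")
    obs_t = target.dropna()
    rows = []
    for cid in cand_ids:
        med = candidates.values[cid]
        both = obs_t.index.intersection(med.dropna().index)
        both = pd.Index([s for s in haplo.strains if s in set(both)])
        if len(both) < min_overlap:
            continue
        y = obs_t.loc[both].to_numpy(dtype=float)
        m = med.loc[both].to_numpy(dtype=float)
        D7 = _marker_design(haplo, marker_index, both)
        n = len(both)
        X0 = np.column_stack([np.ones(n), m])
        X1 = np.column_stack([X0, D7])
        lod_med = _lod(_ols_rss(y, X0), _ols_rss(y, X1), n)
        kind = ""
        if len(candidates.feature_meta) and cid in candidates.feature_meta.index:
            kind = str(candidates.feature_meta.loc[cid].get("kind", ""))
        rows.append(dict(mediator_id=cid, mediator_kind=kind, lod_med=lod_med))
    if not rows:
        raise ValueError("no candidate with sufficient overlap")
    tab = pd.DataFrame(rows)
    x = tab["lod_med"].to_numpy()
    if robust:
        center = np.median(x)
        scale = 1.4826 * np.median(np.abs(x - center))
    else:
        center, scale = x.mean(), x.std()
    if scale == 0:
        raise ValueError("degenerate candidate set: constant conditional LODs")
    tab["zscore"] = (x - center) / scale
    tab["strong"] = tab["zscore"] < STRONG_Z
    if candidate_peaks is not None and target_position is not None:
        t_chrom, t_pos = target_position
        co = []
        for cid in tab["mediator_id"]:
            if cid in candidate_peaks.index:
                row = candidate_peaks.loc[cid]
                co.append(bool(row["chromosome"] == t_chrom
                               and abs(row["position_bp"] - t_pos) <= window_bp))
            else:
                co.append(False)
        tab["co_mapping"] = co
    else:
        tab["co_mapping"] = pd.NA
    return MediationScanResult(target_id=target_id, marker_id=marker_id, table=tab)


def compute_pve(response: pd.Series, predictor, covariates=None,
                response_id: str = "", predictor_id: str = "") -> PveResult:
    """Proportion variance explained, ``PVE = 1 - RSS1/RSS0``, with ANOVA p.

    ``predictor`` may be a vector (mediator abundance) or a matrix (founder
    dosages at a marker); both models include the intercept and any
    covariates.
    """
    pred = pd.DataFrame(predictor)
    pred.index = response.index if len(pred) == len(response) else pred.index
    both = response.dropna().index.intersection(pred.dropna().index)
    y = response.loc[both].to_numpy(dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 complete observations")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance response")
    P = pred.loc[both].to_numpy(dtype=float)
    X0 = np.ones((len(y), 1))
    if covariates is not None:
        cov = pd.DataFrame(covariates).loc[both].to_numpy(dtype=float)
        X0 = np.column_stack([X0, cov])
    X1 = np.column_stack([X0, P])
    rss0 = _ols_rss(y, X0)
    rss1 = _ols_rss(y, X1)
    pve = 1.0 - rss1 / rss0
    df1 = np.linalg.matrix_rank(X1) - np.linalg.matrix_rank(X0)
    df2 = len(y) - np.linalg.matrix_rank(X1)
    if df1 <= 0 or df2 <= 0:
        pval = np.nan
    elif rss1 <= 0:
        pval = 0.0
    else:
        F = ((rss0 - rss1) / df1) / (rss1 / df2)
        pval = float(f_dist.sf(F, df1, df2))
    return PveResult(response_id=response_id, predictor_id=predictor_id,
                     pve=float(pve), pvalue=pval)
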