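"""Kinship, heritability, sex-effect tests, genome scans and allele effects.

The QTL model at marker ``p`` regresses the strain-level trait on the
eight founder-haplotype dosages with a polygenic kinship random effect whose
relationship matrix excludes the scanned chromosome (leave-one-chromosome-out,
LOCO), so the kinship term does not absorb the tested QTL.  Significance at a
marker is summarized as a LOD score against the no-QTL null.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from . import lmm
from ._kernels import dense_marker_rss
from .datatypes import (
    GenomicRelationshipMatrix,
    HaplotypeDosageMatrix,
    HeritabilityFit,
    QtlPeak,
    SampleMetadata,
    ScanResult,
)

LOCAL_WINDOW_BP = 10_000_000  # "local" = within 10 Mbp of the gene midpoint


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


def compute_grm(haplo: HaplotypeDosageMatrix, loco_chromosome=None,
                scale: bool = True) -> GenomicRelationshipMatrix:
    """Realized genomic relationship matrix from founder dosages.

    ``G = (1/M) sum_p d_p d_p^T`` over included markers, with each founder
    dosage column mean-centered across strains; PSD by construction.  With
    ``scale`` the matrix is rescaled to unit average diagonal so that the
    kinship variance fraction is interpretable as heritability.
    """
    mask = np.ones(len(haplo.markers), dtype=bool)
    if loco_chromosome is not None:
        mask[haplo.markers.chrom_indices(loco_chromosome)] = False
    if mask.sum() == 0:
        raise ValueError("all markers excluded from the GRM")
    D = haplo.probs[:, mask, :].reshape(haplo.n_strains, -1)
    Dc = D - D.mean(axis=0, keepdims=True)
    G = (Dc @ Dc.T) / mask.sum()
    if scale:
        tr = np.trace(G)
        if tr <= 0:
            raise ValueError("degenerate GRM: no genetic variation among strains")
        G = G * (haplo.n_strains / tr)
    return GenomicRelationshipMatrix(list(haplo.strains), G,
                                     excluded_chromosome=loco_chromosome)


def loco_grms(haplo: HaplotypeDosageMatrix, scale: bool = True) -> dict:
    """One LOCO GRM per chromosome (plus ``None`` -> whole-genome GRM)."""
    out = {None: compute_grm(haplo, None, scale=scale)}
    for chrom in haplo.markers.chromosomes:
        out[chrom] = compute_grm(haplo, chrom, scale=scale)
    return out


# ---------------------------------------------------------------------------
# heritability and sex effects
# ---------------------------------------------------------------------------


def estimate_heritability(y: pd.Series, grm: GenomicRelationshipMatrix,
                          sex_covariate: Optional[pd.Series] = None,
                          reml: bool = True) -> HeritabilityFit:
    """REML heritability ``h2 = tau2 / (tau2 + sigma2)`` for one trait.

    ``y`` is indexed by strain (or sample when a sample-level kinship is
    supplied); missing values are dropped.
    """
    y = y.dropna()
    if y.nunique() <= 1:
        raise ValueError("response is constant; heritability undefined")
    if len(y) < 10:
        warnings.warn(f"only {len(y)} observations; heritability estimate unstable")
    lookup = {s: i for i, s in enumerate(grm.strains)}
    idx = np.array([lookup[s] for s in y.index])
    G = grm.subset(idx)
    X = np.ones((len(y), 1))
    if sex_covariate is not None:
        sx = sex_covariate.loc[y.index]
        X = np.column_stack([X, (sx == "M").astype(float).to_numpy()])
    fit = lmm.fit_lmm(y.to_numpy(), X, eig=lmm.eigendecompose(G), reml=reml)
    return HeritabilityFit(tau2=fit.tau2, sigma2=fit.sigma2, h2=fit.h, loglik=fit.loglik)


def expand_grm_to_samples(grm: GenomicRelationshipMatrix,
                          metadata: SampleMetadata) -> GenomicRelationshipMatrix:
    """Sample-level kinship: entries copied from the strains of each sample."""
    samples = metadata.samples
    lookup = {s: i for i, s in enumerate(grm.strains)}
    idx = np.array([lookup[s] for s in samples["strain"]])
    return GenomicRelationshipMatrix(list(samples["sample_id"]),
                                     grm.matrix[np.ix_(idx, idx)])


def test_sex_effect(y: pd.Series, grm: GenomicRelationshipMatrix,
                    metadata: SampleMetadata) -> tuple[float, float]:
    """Likelihood-ratio test of a fixed sex effect under the kinship LMM.

    Both models are fit by maximum likelihood (not REML), as appropriate for
    testing a fixed-effect term; the p-value is from chi-square with 1 df.
    Returns ``(lr_statistic, pvalue)``.
    """
    meta = metadata.samples.set_index("sample_id")
    y = y.dropna()
    sex = meta.loc[y.index, "sex"]
    if sex.nunique() < 2:
        raise ValueError("both sexes must be represented")
    sample_grm = expand_grm_to_samples(grm, metadata)
    lookup = {s: i for i, s in enumerate(sample_grm.strains)}
    idx = np.array([lookup[s] for s in y.index])
    eig = lmm.eigendecompose(sample_grm.subset(idx))
    X0 = np.ones((len(y), 1))
    X1 = np.column_stack([X0, (sex == "M").astype(float).to_numpy()])
    ll0 = lmm.fit_lmm(y.to_numpy(), X0, eig=eig, reml=False).loglik
    ll1 = lmm.fit_lmm(y.to_numpy(), X1, eig=eig, reml=False).loglik
    lr = max(0.0, 2.0 * (ll1 - ll0))
    return lr, float(chi2.sf(lr, df=1))


# ---------------------------------------------------------------------------
# genome scans
# ---------------------------------------------------------------------------


def _observed(y: pd.Series, haplo: HaplotypeDosageMatrix,
              covariate: Optional[pd.Series]) -> pd.Index:
    obs = y.dropna().index
    if covariate is not None:
        obs = obs.intersection(covariate.dropna().index)
    order = [s for s in haplo.strains if s in set(obs)]
    if len(order) < 3:
        raise ValueError("fewer than 3 strains with observed data")
    return pd.Index(order)


def scan_genome(y: pd.Series, haplo: HaplotypeDosageMatrix, loco: dict,
                covariate: Optional[pd.Series] = None, level: str = "avg",
                reml: bool = True, feature_id: str = "") -> ScanResult:
    """Genome-wide LOD scan of a strain-level trait on founder haplotypes.

    Variance components are estimated once per chromosome under the no-QTL
    null (with any covariate included) and frozen across that chromosome's
    markers; each marker is then a GLS fit of intercept (+ covariate) + eight
    founder effects, one founder column dropped to resolve the intercept
    collinearity (the fit, and hence the LOD, is invariant to which).
    """
    obs = _observed(y, haplo, covariate)
    yv = y.loc[obs].to_numpy(dtype=float)
    if np.ptp(yv) == 0:
        raise ValueError("response is constant")
    idx = haplo.strain_index(obs)
    n = len(obs)
    cov = None if covariate is None else covariate.loc[obs].to_numpy(dtype=float)
    lod = np.empty(len(haplo.markers))
    for chrom in haplo.markers.chromosomes:
        cidx = haplo.markers.chrom_indices(chrom)
        wp = _null_profile(yv, cov, loco[chrom], idx, reml)
        D = haplo.probs[np.ix_(idx, cidx)]                       # (n, mc, 8)
        Dw = wp.whiten(D.reshape(n, -1)).reshape(n, len(cidx), 8)
        # exact per-marker least squares (rank-deficient markers handled by
        # lstsq); the batched ridge path is reserved for permutations
        rss1 = np.empty(len(cidx))
        for k in range(len(cidx)):
            X1 = np.column_stack([wp.Xw, Dw[:, k, :7]])
            rss1[k], _ = lmm.gls_rss(wp.yw, X1)
        lod[cidx] = lmm.lod_from_rss(wp.rss0, rss1, n)
    return ScanResult(feature_id=feature_id, markers=haplo.markers, lod=lod,
                      level=level,
                      covariate=None if covariate is None else str(covariate.name))


def _null_profile(yv: np.ndarray, cov: Optional[np.ndarray],
                  grm: GenomicRelationshipMatrix, idx: np.ndarray,
                  reml: bool) -> lmm.WhitenedProblem:
    X0 = np.ones((len(yv), 1))
    if cov is not None:
        X0 = np.column_stack([X0, cov])
    eig = lmm.eigendecompose(grm.subset(idx))
    return lmm.whiten_null(yv, X0, eig, reml=reml)


def scan_sex_interactive(strain_diff: pd.Series, haplo: HaplotypeDosageMatrix,
                         loco: dict, feature_id: str = "") -> ScanResult:
    """Scan male - female strain differences: QTL here are sex-by-genotype
    interactions (the QTL effect differs between sexes)."""
    return scan_genome(strain_diff, haplo, loco, level="diff", feature_id=feature_id)


# ---------------------------------------------------------------------------
# peak calling
# ---------------------------------------------------------------------------


def call_qtl(scan: ScanResult, threshold: float,
             gene_chromosome=None, gene_midpoint_bp: Optional[float] = None,
             local_window_bp: float = LOCAL_WINDOW_BP,
             pvalue: Optional[float] = None, qvalue: Optional[float] = None) -> list[QtlPeak]:
    """Call the genome-wide peak when it clears the feature's LOD threshold.

    One peak per feature (the genome-wide maximum; ties broken by lowest
    genomic coordinate).  ``local`` means within ``local_window_bp`` of the
    gene midpoint on the same chromosome, boundary inclusive.
    """
    if scan.max_lod() < threshold:
        return []
    k = scan.peak_index()
    row = scan.markers.df.iloc[k]
    if gene_midpoint_bp is None or gene_chromosome is None:
        qtl_class = "unknown"
        warnings.warn(f"gene midpoint unknown for {scan.feature_id}; QTL class unset")
    elif (row["chromosome"] == gene_chromosome
          and abs(row["position_bp"] - gene_midpoint_bp) <= local_window_bp):
        qtl_class = "local"
    else:
        qtl_class = "distant"
    return [QtlPeak(feature_id=scan.feature_id, marker_id=row["marker_id"],
                    chromosome=row["chromosome"], position_bp=int(row["position_bp"]),
                    lod=scan.max_lod(), pvalue=pvalue, qvalue=qvalue,
                    qtl_class=qtl_class, sex_interactive=scan.level == "diff")]


# ---------------------------------------------------------------------------
# allele effects
# ---------------------------------------------------------------------------


def allele_effects_blup(y: pd.Series, haplo: HaplotypeDosageMatrix,
                        marker_index: int, grm: GenomicRelationshipMatrix) -> np.ndarray:
    """Shrinkage (BLUP) estimates of the eight founder allele effects.

    The founder effects at the peak marker are modeled as a random effect,
    ``beta ~ N(0, I tau2_qtl)``, on top of the kinship LMM; the reported
    vector is the centered BLUP, finite even for founders that are absent or
    rare in the panel.  The variance ratio is fit by 1-D maximum likelihood
    in the whitened space (Woodbury identities keep everything 8 x 8).
    """
    obs = _observed(y, haplo, None)
    yv = y.loc[obs].to_numpy(dtype=float)
    idx = haplo.strain_index(obs)
    wp = _null_profile(yv, None, grm, idx, reml=True)
    D = haplo.probs[idx, marker_index, :]                    # (n, 8)
    Dw = wp.whiten(D)
    u0 = wp.Xw[:, 0]
    yw = wp.yw
    DtD = Dw.T @ Dw

    def negll(log_r: float) -> float:
        r = np.exp(log_r)
        K = np.eye(8) / r + DtD
        Kinv = np.linalg.inv(K)
        # V^-1 = I - Dw Kinv Dw^T  (Woodbury); logdet V = logdet(I8 + r DtD)
        def vinv(v):
            return v - Dw @ (Kinv @ (Dw.T @ v))
        mu = float((u0 @ vinv(yw)) / (u0 @ vinv(u0)))
        e = yw - mu * u0
        quad = float(e @ vinv(e))
        sign, logdet = np.linalg.slogdet(np.eye(8) + r * DtD)
        n = len(yw)
        return 0.5 * (n * np.log(max(quad, 1e-300) / n) + logdet)

    res = minimize_scalar(negll, bounds=(-12.0, 8.0), method="bounded")
    r = float(np.exp(res.x))
    if negll(-30.0) < res.fun:  # boundary: no QTL variance
        r = 1e-13
    K = np.eye(8) / r + DtD
    Kinv = np.linalg.inv(K)

    def vinv(v):
        return v - Dw @ (Kinv @ (Dw.T @ v))

    mu = float((u0 @ vinv(yw)) / (u0 @ vinv(u0)))
    e = yw - mu * u0
    beta = r * (Dw.T @ vinv(e))
    return beta - beta.mean()


def fixed_allele_effects(y: pd.Series, haplo: HaplotypeDosageMatrix,
                         marker_index: int) -> np.ndarray:
    """Unshrunk per-founder mean effects (centered); NaN for absent founders."""
    obs = y.dropna().index.intersection(haplo.strains)
    yv = y.loc[obs].to_numpy(dtype=float)
    D = haplo.probs[haplo.strain_index(obs), marker_index, :]
    counts = D.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = (D.T @ yv) / counts
    means = means - np.nanmean(means)
    means[counts == 0] = np.nan
    return means
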