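"""Self-evaluation studies: oracle equivalence, calibration, power, mediation
recovery.

Each function simulates its own data at the study conditions, runs the
package's machinery, and returns the measured quantities.  The genome-scan
oracles here are written independently of the scan path (explicit covariance
matrices, Cholesky whitening, their own REML optimizer) so they can serve as
a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import lmm, mediation, qtl, significance, simulate
from .datatypes import HaplotypeDosageMatrix


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# brute-force genome-scan oracles
# ---------------------------------------------------------------------------


def _oracle_reml_h(y: np.ndarray, X: np.ndarray, G: np.ndarray) -> float:
    """Independent 1-D REML for the variance fraction, via explicit V."""
    n, p = X.shape

    def negll(h):
        V = h * G + (1.0 - h) * np.eye(n)
        try:
            L = np.linalg.cholesky(V + 1e-12 * np.eye(n))
        except np.linalg.LinAlgError:
            return 1e12
        yw = np.linalg.solve(L, y)
        Xw = np.linalg.solve(L, X)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        r = yw - Xw @ beta
        rss = float(r @ r)
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(L))))
        _, ld_x = np.linalg.slogdet(Xw.T @ Xw)
        df = n - p
        ll = -0.5 * (df * (math.log(2 * math.pi) + math.log(max(rss, 1e-300) / df))
                     + logdet_v + ld_x + df)
        return -ll if math.isfinite(ll) else 1e12

    grid = np.linspace(0.0, 1.0 - 1e-6, 21)
    vals = [negll(h) for h in grid]
    k = int(np.argmin(vals))
    lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-7})
    return float(res.x) if res.fun <= vals[k] else float(grid[k])


def _oracle_gls_lod(y, X0, X1, G, h) -> float:
    n = len(y)
    V = h * G + (1.0 - h) * np.eye(n)
    L = np.linalg.cholesky(V + 1e-12 * np.eye(n))
    yw = np.linalg.solve(L, y)

    def rss(X):
        Xw = np.linalg.solve(L, X)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        r = yw - Xw @ beta
        return float(r @ r)

    return max(0.0, 0.5 * n * math.log10(rss(X0) / rss(X1)))


def oracle_scan(y: pd.Series, haplo: HaplotypeDosageMatrix, loco: dict,
                per_marker_refit: bool) -> np.ndarray:
    """Brute-force GLS scan via explicit covariance matrices.

    ``per_marker_refit=False`` freezes the per-chromosome null REML variance
    profile (the approximation the fast scan makes); ``True`` re-estimates the
    variance fraction at every marker under the alternative model.
    """
    yv = y.loc[list(haplo.strains)].to_numpy(dtype=float)
    n = len(yv)
    X0 = np.ones((n, 1))
    lod = np.zeros(len(haplo.markers))
    for chrom in haplo.markers.chromosomes:
        cidx = haplo.markers.chrom_indices(chrom)
        G = loco[chrom].matrix
        h_null = _oracle_reml_h(yv, X0, G)
        for p in cidx:
            X1 = np.column_stack([X0, haplo.probs[:, p, :7]])
            h = _oracle_reml_h(yv, X1, G) if per_marker_refit else h_null
            lod[p] = _oracle_gls_lod(yv, X0, X1, G, h)
    return lod


def scan_oracle_comparison(n_strains: int = 20, n_chromosomes: int = 2,
                           markers_per_chromosome: int = 50,
                           pve: float = 0.4, h2_polygenic: float = 0.15,
                           seed: int = 0) -> dict:
    """Max |LOD difference| between the fast scan and the two oracle modes."""
    s1, s2 = _spawn_seeds(seed, 2)
    _, haplo = simulate.simulate_genomes(n_strains, n_chromosomes,
                                         markers_per_chromosome, seed=s1)
    loco = qtl.loco_grms(haplo)
    causal = len(haplo.markers) // 2
    y = simulate.simulate_strain_trait(haplo, causal_marker=causal, pve=pve,
                                       h2_polygenic=h2_polygenic, seed=s2)
    scan = qtl.scan_genome(y, haplo, loco)
    shared = oracle_scan(y, haplo, loco, per_marker_refit=False)
    refit = oracle_scan(y, haplo, loco, per_marker_refit=True)
    return {
        "max_abs_diff_shared_profile": float(np.abs(scan.lod - shared).max()),
        "max_abs_diff_per_marker_refit": float(np.abs(scan.lod - refit).max()),
        "max_lod": float(scan.max_lod()),
        "n": len(haplo.markers),
    }


# ---------------------------------------------------------------------------
# permutation / GEV / BH calibration and power
# ---------------------------------------------------------------------------


def _feature_pvalue(y, haplo, loco, n_perm, seed):
    scan = qtl.scan_genome(y, haplo, loco)
    null = significance.permutation_null(y, haplo, loco, n_perm=n_perm, seed=seed)
    fit = significance.fit_gev(null)
    return scan.max_lod(), fit, significance.permutation_pvalue(fit, scan.max_lod())


def threshold_calibration(n_null: int = 200, n_true: int = 50, pve: float = 0.6,
                          n_strains: int = 58, n_perm: int = 1000,
                          q_target: float = 0.1, n_panels: int = 3,
                          null_h2: float = 0.0, seed: int = 0) -> dict:
    """Empirical FDP of the permutation->GEV->BH chain on spiked panels.

    Each panel mixes ``n_null`` genome-independent features (``null_h2``
    polygenic variance, zero by default: the exchangeable null of the
    genome-shuffling permutation scheme) and ``n_true`` features with a
    planted QTL; the reported FDP and
    power are averaged over ``n_panels`` independent panels, a
    variance-reduced estimate of the replicate-average false-discovery
    proportion.  A BH pass restricted to the null features gives the
    pure-null discovery count.
    """
    panel_seeds = _spawn_seeds(seed, n_panels)
    fdps, powers, n_disc_tot, n_false_tot, n_null_disc_tot = [], [], 0, 0, 0
    for pseed in panel_seeds:
        seeds = _spawn_seeds(pseed, 2 * (n_null + n_true) + 1)
        _, haplo = simulate.simulate_genomes(n_strains, seed=seeds[0])
        loco = qtl.loco_grms(haplo)
        grm = loco[None].matrix
        rng = np.random.default_rng(seeds[0])
        pvals, fits, maxlods, truth_positive = {}, {}, {}, {}
        k = 1
        for i in range(n_null + n_true):
            is_tp = i >= n_null
            causal = int(rng.integers(len(haplo.markers))) if is_tp else None
            y = simulate.simulate_strain_trait(
                haplo, causal_marker=causal, pve=pve if is_tp else 0.0,
                h2_polygenic=0.15 if is_tp else null_h2,
                grm_matrix=grm, seed=seeds[k]); k += 1
            fid = f"f{i:04d}"
            ml, fit, p = _feature_pvalue(y, haplo, loco, n_perm, seeds[k]); k += 1
            pvals[fid], fits[fid], maxlods[fid] = p, fit, ml
            truth_positive[fid] = is_tp

        tt = significance.fdr_thresholds(pd.Series(pvals), fits,
                                         pd.Series(maxlods), q_target=q_target)
        disc = tt.table[tt.table["significant"]].index
        n_false = sum(not truth_positive[f] for f in disc)
        fdps.append(n_false / max(1, len(disc)))
        powers.append(sum(truth_positive[f] for f in disc) / n_true)
        n_disc_tot += len(disc)
        n_false_tot += n_false

        ids_null = [f for f in pvals if not truth_positive[f]]
        tt0 = significance.fdr_thresholds(
            pd.Series({f: pvals[f] for f in ids_null}),
            {f: fits[f] for f in ids_null},
            pd.Series({f: maxlods[f] for f in ids_null}), q_target=q_target)
        if tt0.attained:
            n_null_disc_tot += int(tt0.table["significant"].sum())
    return {"fdp": float(np.mean(fdps)), "n_discoveries": int(n_disc_tot),
            "n_false": int(n_false_tot),
            "power_at_fdr10": float(np.mean(powers)),
            "n_discoveries_pure_null": int(n_null_disc_tot),
            "n": n_panels * (n_null + n_true)}


def detection_power(pves=(0.2, 0.4, 0.6), n_rep: int = 100, n_strains: int = 58,
                    n_perm: int = 1000, alpha: float = 0.1, seed: int = 0) -> dict:
    """Detection rate (permutation p <= alpha) per planted PVE."""
    seeds = _spawn_seeds(seed, 1 + 2 * n_rep * len(pves))
    _, haplo = simulate.simulate_genomes(n_strains, seed=seeds[0])
    loco = qtl.loco_grms(haplo)
    grm = loco[None].matrix
    rng = np.random.default_rng(seeds[0])
    out = {}
    k = 1
    for pve in pves:
        hits = 0
        for _ in range(n_rep):
            causal = int(rng.integers(len(haplo.markers)))
            y = simulate.simulate_strain_trait(haplo, causal_marker=causal,
                                               pve=pve, h2_polygenic=0.15,
                                               grm_matrix=grm, seed=seeds[k]); k += 1
            _, _, p = _feature_pvalue(y, haplo, loco, n_perm, seeds[k]); k += 1
            if p <= alpha:
                hits += 1
        out[pve] = hits / n_rep
    return {"power": out, "n": n_rep}


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------


def mechanism_discrimination(n_each: int = 50, n_strains: int = 58,
                             pqtl_pve: float = 0.4, mediator_pve: float = 0.7,
                             site_noise_sd: float = 0.2,
                             parent_coupling: float = 0.2, seed: int = 0) -> dict:
    """Balanced accuracy of the Delta-LOD-percentage < -50% rule."""
    seeds = _spawn_seeds(seed, 1 + 6 * n_each)
    _, haplo = simulate.simulate_genomes(n_strains, seed=seeds[0])
    loco = qtl.loco_grms(haplo)
    grm = loco[None].matrix
    rng = np.random.default_rng(seeds[0])
    strains = list(haplo.strains)
    k = 1
    correct1 = correct2 = 0
    deltas = {"mech1": [], "mech2": []}
    for mech in ("mech1", "mech2"):
        for _ in range(n_each):
            marker = int(rng.integers(len(haplo.markers)))
            chrom = haplo.markers.df["chromosome"].iloc[marker]
            noise = np.random.default_rng(seeds[k]).normal(
                0, site_noise_sd, len(strains)); k += 1
            if mech == "mech1":
                parent = simulate.simulate_strain_trait(
                    haplo, causal_marker=marker, pve=pqtl_pve,
                    h2_polygenic=0.15, grm_matrix=grm, seed=seeds[k]); k += 1
                ph = parent + noise
            else:
                mediator = simulate.simulate_strain_trait(
                    haplo, causal_marker=marker, pve=mediator_pve,
                    h2_polygenic=0.15, grm_matrix=grm, seed=seeds[k]); k += 1
                parent = simulate.simulate_strain_trait(
                    haplo, pve=0.0, h2_polygenic=0.15, grm_matrix=grm,
                    seed=seeds[k]); k += 1
                ph = mediator + parent_coupling * parent + noise
            res = mediation.mediate_through_parent(
                ph, parent, marker, haplo, loco[chrom])
            deltas[mech].append(res.delta_lod_pct)
            called_mech1 = res.delta_lod_pct < mediation.MECH1_DELTA_PCT
            if mech == "mech1" and called_mech1:
                correct1 += 1
            if mech == "mech2" and not called_mech1:
                correct2 += 1
    bal_acc = 0.5 * (correct1 / n_each + correct2 / n_each)
    return {"balanced_accuracy": float(bal_acc),
            "mech1_sensitivity": correct1 / n_each,
            "mech2_specificity": correct2 / n_each,
            "median_delta_pct_mech1": float(np.median(deltas["mech1"])),
            "median_delta_pct_mech2": float(np.median(deltas["mech2"])),
            "n": 2 * n_each}


def mediator_recovery(n_decoys: int = 200, n_rep: int = 20, n_strains: int = 58,
                      mediator_pve: float = 0.7, site_noise_sd: float = 0.2,
                      seed: int = 0) -> dict:
    """Planted mediator of a distant QTL among decoys: minimum z and z < -8."""
    seeds = _spawn_seeds(seed, 1 + n_rep * (n_decoys + 4))
    _, haplo = simulate.simulate_genomes(n_strains, seed=seeds[0])
    rng = np.random.default_rng(seeds[0])
    grm = qtl.compute_grm(haplo).matrix
    strains = list(haplo.strains)
    k = 1
    hit_min = hit_strong = 0
    null_strong_total = 0
    from .datatypes import AbundanceMatrix
    for _ in range(n_rep):
        marker = int(rng.integers(len(haplo.markers)))
        mediator = simulate.simulate_strain_trait(
            haplo, causal_marker=marker, pve=mediator_pve, h2_polygenic=0.15,
            grm_matrix=grm, seed=seeds[k]); k += 1
        noise = np.random.default_rng(seeds[k]).normal(
            0, site_noise_sd, len(strains)); k += 1
        target = mediator + noise
        decoys = {}
        for d in range(n_decoys):
            decoys[f"decoy{d:03d}"] = simulate.simulate_strain_trait(
                haplo, pve=0.0, h2_polygenic=0.15, grm_matrix=grm,
                seed=seeds[k]); k += 1
        cands = pd.DataFrame({**decoys, "planted": mediator})
        res = mediation.mediation_scan(
            target, marker, AbundanceMatrix(cands, level="strain_avg",
                                            kind="protein"), haplo)
        tab = res.table.set_index("mediator_id")
        z_planted = float(tab.loc["planted", "zscore"])
        if z_planted == tab["zscore"].min():
            hit_min += 1
        if z_planted < mediation.STRONG_Z:
            hit_strong += 1

        # pure null: target has a direct QTL; all candidates are decoys
        target0 = simulate.simulate_strain_trait(
            haplo, causal_marker=marker, pve=0.6, h2_polygenic=0.15,
            grm_matrix=grm, seed=seeds[k]); k += 1
        res0 = mediation.mediation_scan(
            target0, marker, AbundanceMatrix(pd.DataFrame(decoys),
                                             level="strain_avg", kind="protein"),
            haplo)
        null_strong_total += int(res0.table["strong"].sum())
    return {"frac_planted_minimum_z": hit_min / n_rep,
            "frac_planted_strong": hit_strong / n_rep,
            "n_null_decoys_strong": int(null_strong_total),
            "n": n_rep}


# ---------------------------------------------------------------------------
# heritability
# ---------------------------------------------------------------------------


def heritability_recovery(h2: float = 0.5, n_rep: int = 200,
                          n_strains: int = 58, seed: int = 0) -> dict:
    """Mean heritability estimate for planted-h2 and pure-noise traits.

    Estimation follows the study design at the individual level: two mice
    (one per sex) per strain, kinship expanded across individuals, so the
    within-strain replication identifies the genetic variance component.
    """
    from .datatypes import GenomicRelationshipMatrix

    seeds = _spawn_seeds(seed, 1 + 2 * n_rep)
    _, haplo = simulate.simulate_genomes(n_strains, seed=seeds[0])
    grm = qtl.compute_grm(haplo)
    idx = np.repeat(np.arange(n_strains), 2)
    sample_ids = [f"{s}_{x}" for s in grm.strains for x in "FM"]
    sample_grm = GenomicRelationshipMatrix(sample_ids, grm.matrix[np.ix_(idx, idx)])
    est, est_null = [], []
    for r in range(n_rep):
        rng = np.random.default_rng(seeds[1 + 2 * r])
        g = simulate.polygenic_values(grm.matrix, rng)
        y = pd.Series(np.sqrt(h2) * g[idx]
                      + np.sqrt(1.0 - h2) * rng.normal(size=2 * n_strains),
                      index=sample_ids)
        est.append(qtl.estimate_heritability(y, sample_grm).h2)
        rng0 = np.random.default_rng(seeds[2 + 2 * r])
        y0 = pd.Series(rng0.normal(size=2 * n_strains), index=sample_ids)
        est_null.append(qtl.estimate_heritability(y0, sample_grm).h2)
    return {"mean_h2": float(np.mean(est)), "mean_h2_null": float(np.mean(est_null)),
            "n": n_rep}


# ---------------------------------------------------------------------------
# analytic identities
# ---------------------------------------------------------------------------


def analytic_identities(seed: int = 0) -> dict:
    """Closed-form identities of the quantification and significance layers."""
    import pandas as pd

    from . import quantify
    from .datatypes import (GevFit, PeptideIntensityTable, SampleMetadata)

    rng = np.random.default_rng(seed)
    # parent-adjustment orthogonality
    n = 40
    parent = pd.Series(rng.normal(size=n))
    ph = 0.8 * parent + rng.normal(size=n) * 0.3
    X = np.column_stack([np.ones(n), parent])
    beta, *_ = np.linalg.lstsq(X, ph.to_numpy(), rcond=None)
    resid = ph.to_numpy() - X @ beta
    ortho = float(abs(np.corrcoef(resid, parent)[0, 1]))

    # phi normalization equalizes totals within batch
    meta = SampleMetadata(pd.DataFrame(dict(
        sample_id=["s1", "s2", "b"], strain=["c1", "c2", "bridge"],
        sex=["F", "M", "B"], batch=["b1"] * 3, is_bridge=[False, False, True])))
    pep = pd.DataFrame(dict(peptide_id=["p1", "p2"], protein_id=["P1", "P1"],
                            is_phospho=[False, False], site_label=["", ""],
                            sequence_with_flanks=["AAA.CCC.DDD", "AAA.EEE.DDD"]))
    inten = pd.DataFrame([[10.0, 90.0], [70.0, 130.0], [40.0, 60.0]],
                         index=["s1", "s2", "b"], columns=["p1", "p2"])
    table = PeptideIntensityTable(pep, inten)
    scaled, _ = quantify.normalize_within_batch(table, meta)
    totals = scaled.intensities.sum(axis=1)
    phi_spread = float(totals.max() - totals.min())

    # bridge log-ratio worked case: peptides (3, 4) vs bridge (1, 2) -> 1
    inten2 = pd.DataFrame([[3.0, 4.0], [1.0, 2.0]], index=["s1", "b"],
                          columns=["p1", "p2"])
    meta2 = SampleMetadata(pd.DataFrame(dict(
        sample_id=["s1", "b"], strain=["c1", "bridge"], sex=["F", "B"],
        batch=["b1"] * 2, is_bridge=[False, True])))
    mat, _ = quantify.compute_relative_abundance(
        PeptideIntensityTable(pep, inten2), meta2, kind="protein")
    bridge_ratio = float(mat.values.loc["s1", "P1"])

    # PVE degenerate cases: response == predictor -> 1; exactly orthogonal
    # predictor (residual of a random vector on [1, y]) -> 0
    y = pd.Series(rng.normal(size=20))
    pve_self = mediation.compute_pve(y, y).pve
    x = rng.normal(size=20)
    X = np.column_stack([np.ones(20), y.to_numpy()])
    b, *_ = np.linalg.lstsq(X, x, rcond=None)
    x_perp = pd.Series(x - X @ b, index=y.index)
    pve_orth = mediation.compute_pve(y, x_perp).pve

    # BH with one feature: q = p
    fitg = GevFit(feature_id="f", location=3.0, scale=0.5, shape=0.0, n_perm=1000)
    p = significance.permutation_pvalue(fitg, 4.0)
    tt = significance.fdr_thresholds(pd.Series({"f": p}), {"f": fitg},
                                     pd.Series({"f": 4.0}))
    q_eq_p = float(abs(tt.table.loc["f", "qvalue"] - p))
    lam = float(tt.table.loc["f", "lambda_fdr"])
    f_lam = float(abs(fitg.cdf(lam) - (1.0 - tt.p_interp)))

    return {"parent_residual_corr": ortho, "phi_total_spread": phi_spread,
            "bridge_logratio_case": bridge_ratio, "pve_identical": float(pve_self),
            "pve_orthogonal": float(abs(pve_orth)), "bh_single_q_minus_p": q_eq_p,
            "gev_threshold_identity": f_lam, "n": 1}
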