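"""Kinship, heritability, sex tests, genome scans, peak calling, BLUPs."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import phqtl
from phqtl import evaluation, lmm, qtl
from phqtl.datatypes import (FOUNDERS, GenomicRelationshipMatrix,
                             HaplotypeDosageMatrix, MarkerMap, SampleMetadata)


def _tiny_haplo(founder_assign):
    """Strains x markers founder labels -> hard dosage matrix."""
    founder_assign = np.asarray(founder_assign)
    n, m = founder_assign.shape
    rows = [dict(marker_id=f"m{j}", chromosome="chr1", position_bp=(j + 1) * 10**6)
            for j in range(m)]
    probs = np.zeros((n, m, 8))
    for i in range(n):
        for j in range(m):
            probs[i, j, founder_assign[i, j]] = 1.0
    return HaplotypeDosageMatrix([f"c{i}" for i in range(n)],
                                 MarkerMap(pd.DataFrame(rows)), probs)


class TestGrm:
    def test_hand_computed_three_strain_case(self):
        haplo = _tiny_haplo([[0, 1], [0, 2], [3, 1]])
        got = qtl.compute_grm(haplo, scale=False).matrix
        D = haplo.probs.reshape(3, -1)
        Dc = D - D.mean(0)
        expected = Dc @ Dc.T / 2
        assert np.allclose(got, expected)
        assert np.all(np.linalg.eigvalsh(got) > -1e-12)

    def test_identical_strains_off_diagonal_equals_diagonal(self):
        haplo = _tiny_haplo([[0, 1, 2], [0, 1, 2], [3, 4, 5]])
        G = qtl.compute_grm(haplo, scale=False).matrix
        assert G[0, 1] == pytest.approx(G[0, 0])

    def test_loco_excludes_chromosome(self, haplo20):
        g1 = qtl.compute_grm(haplo20, loco_chromosome="chr1")
        shuffled = HaplotypeDosageMatrix(
            list(haplo20.strains), haplo20.markers, haplo20.probs.copy())
        cidx = haplo20.markers.chrom_indices("chr1")
        rng = np.random.default_rng(0)
        shuffled.probs[:, cidx, :] = shuffled.probs[:, cidx, :][:, rng.permutation(len(cidx)), :]
        g2 = qtl.compute_grm(shuffled, loco_chromosome="chr1")
        assert np.allclose(g1.matrix, g2.matrix)

    def test_all_markers_excluded_errors(self):
        haplo = _tiny_haplo([[0, 1], [2, 3]])
        with pytest.raises(ValueError):
            qtl.compute_grm(haplo, loco_chromosome="chr1")


class TestHeritability:
    def test_constant_response_errors(self, haplo20, loco20):
        y = pd.Series(1.0, index=list(haplo20.strains))
        with pytest.raises(ValueError):
            qtl.estimate_heritability(y, loco20[None])

    def test_recovery_and_null(self, haplo58, loco58):
        grm = loco58[None]
        est, null = [], []
        for rep in range(30):
            y = phqtl.simulate_strain_trait(haplo58, pve=0.0, h2_polygenic=0.5,
                                            grm_matrix=grm.matrix, seed=400 + rep)
            est.append(qtl.estimate_heritability(y, grm).h2)
            y0 = pd.Series(np.random.default_rng(500 + rep).normal(size=58),
                           index=list(haplo58.strains))
            null.append(qtl.estimate_heritability(y0, grm).h2)
        assert 0.35 < np.mean(est) < 0.65
        assert np.mean(null) < np.mean(est) - 0.2


def _paired_metadata(strains):
    rows = []
    for i, s in enumerate(strains):
        for sx in "FM":
            rows.append(dict(sample_id=f"{s}_{sx}", strain=s, sex=sx,
                             batch=f"b{i % 3 + 1}", is_bridge=False))
    for b in ("b1", "b2", "b3"):
        rows.append(dict(sample_id=f"br_{b}", strain="pool", sex="B", batch=b,
                         is_bridge=True))
    return SampleMetadata(pd.DataFrame(rows))


class TestSexEffect:
    def test_zero_difference_gives_zero_statistic(self, haplo20, loco20):
        meta = _paired_metadata(list(haplo20.strains))
        vals = {f"{s}_{sx}": float(i) for i, s in enumerate(haplo20.strains)
                for sx in "FM"}
        lr, p = qtl.test_sex_effect(pd.Series(vals), loco20[None], meta)
        assert lr == pytest.approx(0.0, abs=1e-6)

    def test_power_with_planted_difference(self, haplo58, loco58):
        meta = _paired_metadata(list(haplo58.strains))
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(700 + rep)
            vals = {}
            for s in haplo58.strains:
                base = rng.normal()
                vals[f"{s}_F"] = base + rng.normal() * 0.5
                vals[f"{s}_M"] = base + 2.0 + rng.normal() * 0.5
            _, p = qtl.test_sex_effect(pd.Series(vals), loco58[None], meta)
            hits += p < 1e-4
        assert hits >= 9

    def test_null_pvalues_uniform(self, haplo58, loco58):
        meta = _paired_metadata(list(haplo58.strains))
        from phqtl.simulate import polygenic_values
        G = loco58[None].matrix
        pvals = []
        for rep in range(200):
            rng = np.random.default_rng(900 + rep)
            g = polygenic_values(G, rng)
            strain_eff = dict(zip(haplo58.strains, 0.7 * g))
            vals = {f"{s}_{sx}": strain_eff[s] + rng.normal() * 0.7
                    for s in haplo58.strains for sx in "FM"}
            _, p = qtl.test_sex_effect(pd.Series(vals), loco58[None], meta)
            pvals.append(p)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestScan:
    def test_lod_nonnegative_for_random_traits(self, haplo20, loco20, rng):
        y = pd.Series(rng.normal(size=20), index=list(haplo20.strains))
        scan = phqtl.scan_genome(y, haplo20, loco20)
        assert (scan.lod >= 0).all()
        assert len(scan.lod) == len(haplo20.markers)

    def test_planted_founder_dosage_peaks_at_marker(self, haplo58, loco58):
        cast = FOUNDERS.index("CAST")
        p = 17
        dose = haplo58.probs[:, p, cast]
        rng = np.random.default_rng(3)
        y = pd.Series(dose + rng.normal(size=58) * 0.05,
                      index=list(haplo58.strains))
        scan = phqtl.scan_genome(y, haplo58, loco58)
        assert scan.peak_index() == p

    def test_constant_trait_errors(self, haplo20, loco20):
        y = pd.Series(2.0, index=list(haplo20.strains))
        with pytest.raises(ValueError):
            phqtl.scan_genome(y, haplo20, loco20)

    def test_parent_covariate_absorbs_inherited_signal(self, haplo58, loco58):
        parent = phqtl.simulate_strain_trait(haplo58, causal_marker=10, pve=0.6,
                                             seed=31)
        rng = np.random.default_rng(32)
        ph = parent + rng.normal(size=58) * 0.2
        ph.index = parent.index
        plain = phqtl.scan_genome(ph, haplo58, loco58)
        adjusted = phqtl.scan_genome(ph, haplo58, loco58, covariate=parent)
        assert plain.lod[10] > 5
        assert adjusted.lod[10] < plain.lod[10] * 0.3

    def test_oracle_equivalence_shared_profile(self, haplo20, loco20):
        y = phqtl.simulate_strain_trait(haplo20, causal_marker=12, pve=0.4,
                                        h2_polygenic=0.15, seed=77)
        scan = phqtl.scan_genome(y, haplo20, loco20)
        oracle = evaluation.oracle_scan(y, haplo20, loco20, per_marker_refit=False)
        assert np.abs(scan.lod - oracle).max() < 1e-6

    def test_loco_beats_whole_genome_kinship_on_average(self, haplo58):
        loco = phqtl.loco_grms(haplo58)
        whole = {c: loco[None] for c in haplo58.markers.chromosomes}
        whole[None] = loco[None]
        diffs = []
        for rep in range(15):
            rng = np.random.default_rng(1100 + rep)
            p = int(rng.integers(len(haplo58.markers)))
            y = phqtl.simulate_strain_trait(haplo58, causal_marker=p, pve=0.4,
                                            h2_polygenic=0.3, seed=1200 + rep)
            with_loco = phqtl.scan_genome(y, haplo58, loco).lod[p]
            without = phqtl.scan_genome(y, haplo58, whole).lod[p]
            diffs.append(with_loco - without)
        assert np.mean(diffs) >= 0


class TestSexInteractiveScan:
    def test_planted_interaction_peaks_at_marker(self, haplo58, loco58):
        cast = FOUNDERS.index("CAST")
        p = 40
        dose = haplo58.probs[:, p, cast]
        rng = np.random.default_rng(8)
        diff = pd.Series(1.5 * dose + rng.normal(size=58) * 0.3,
                         index=list(haplo58.strains))
        scan = phqtl.scan_sex_interactive(diff, haplo58, loco58)
        assert scan.level == "diff"
        assert abs(scan.peak_index() - p) <= 1

    def test_zero_variance_differences_error(self, haplo20, loco20):
        diff = pd.Series(0.0, index=list(haplo20.strains))
        with pytest.raises(ValueError):
            phqtl.scan_sex_interactive(diff, haplo20, loco20)


class TestCallQtl:
    def _scan(self, haplo, lod_at, value=8.0):
        lod = np.zeros(len(haplo.markers))
        lod[lod_at] = value
        return qtl.ScanResult(feature_id="f", markers=haplo.markers, lod=lod)

    @pytest.mark.parametrize("gene_mid_offset,expected", [
        (9.0e6, "local"), (10.0e6, "local"), (11.0e6, "distant")])
    def test_local_window_boundaries(self, haplo20, gene_mid_offset, expected):
        scan = self._scan(haplo20, lod_at=5)
        pos = haplo20.markers.df["position_bp"].iloc[5]
        peaks = qtl.call_qtl(scan, 4.0, gene_chromosome="chr1",
                             gene_midpoint_bp=pos + gene_mid_offset)
        assert peaks[0].qtl_class == expected

    def test_other_chromosome_is_distant(self, haplo20):
        scan = self._scan(haplo20, lod_at=3)
        peaks = qtl.call_qtl(scan, 4.0, gene_chromosome="chr2",
                             gene_midpoint_bp=haplo20.markers.df["position_bp"].iloc[3])
        assert peaks[0].qtl_class == "distant"

    def test_below_threshold_no_peak(self, haplo20):
        scan = self._scan(haplo20, lod_at=5, value=3.0)
        assert qtl.call_qtl(scan, 4.0, "chr1", 1e6) == []

    def test_unknown_midpoint_warns(self, haplo20):
        scan = self._scan(haplo20, lod_at=5)
        with pytest.warns(UserWarning):
            peaks = qtl.call_qtl(scan, 4.0)
        assert peaks[0].qtl_class == "unknown"


class TestAlleleEffects:
    def test_planted_founder_effect_is_largest(self, haplo58, loco58):
        cast = FOUNDERS.index("CAST")
        p = 17
        rng = np.random.default_rng(5)
        y = pd.Series(haplo58.probs[:, p, cast] + rng.normal(size=58) * 0.1,
                      index=list(haplo58.strains))
        beta = phqtl.allele_effects_blup(y, haplo58, p, loco58["chr1"])
        assert np.argmax(beta) == cast
        assert abs(beta.mean()) < 1e-9

    def test_identical_traits_have_correlation_one(self, haplo58, loco58):
        rng = np.random.default_rng(6)
        y = pd.Series(rng.normal(size=58), index=list(haplo58.strains))
        b1 = phqtl.allele_effects_blup(y, haplo58, 8, loco58["chr1"])
        b2 = phqtl.allele_effects_blup(y.copy(), haplo58, 8, loco58["chr1"])
        assert np.corrcoef(b1, b2)[0, 1] == pytest.approx(1.0)

    def test_blup_shrinks_null_effects(self, haplo58, loco58):
        shrunk = 0
        for rep in range(20):
            rng = np.random.default_rng(1300 + rep)
            y = pd.Series(rng.normal(size=58), index=list(haplo58.strains))
            blup = phqtl.allele_effects_blup(y, haplo58, 12, loco58["chr1"])
            fixed = qtl.fixed_allele_effects(y, haplo58, 12)
            if np.linalg.norm(blup) < np.linalg.norm(fixed[np.isfinite(fixed)]):
                shrunk += 1
        assert shrunk >= 18


class TestMonotonePower:
    def test_detection_rate_nondecreasing_in_pve(self, haplo58, loco58):
        """Genome-wide max LOD grows with planted PVE (fixed-threshold proxy,
        30 replicates per level)."""
        rates = []
        for pve in (0.2, 0.4, 0.6):
            hits = 0
            for rep in range(30):
                rng = np.random.default_rng(int(2000 + 1000 * pve) + rep)
                p = int(rng.integers(len(haplo58.markers)))
                y = phqtl.simulate_strain_trait(haplo58, causal_marker=p,
                                                pve=pve, h2_polygenic=0.15,
                                                seed=3000 + rep)
                hits += phqtl.scan_genome(y, haplo58, loco58).max_lod() >= 6.0
            rates.append(hits / 30)
        assert rates[0] <= rates[1] <= rates[2]
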