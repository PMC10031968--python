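"""Parent-protein mediation, mediator scans and PVE."""

import numpy as np
import pandas as pd
import pytest

import phqtl
from phqtl import mediation
from phqtl.datatypes import AbundanceMatrix


def _strains(haplo):
    return list(haplo.strains)


class TestComputePve:
    def test_identical_response_predictor(self, rng):
        y = pd.Series(rng.normal(size=15))
        assert phqtl.compute_pve(y, y).pve == pytest.approx(1.0)

    def test_orthogonal_predictor_zero(self, rng):
        y = pd.Series(rng.normal(size=25))
        x = rng.normal(size=25)
        X = np.column_stack([np.ones(25), y.to_numpy()])
        b, *_ = np.linalg.lstsq(X, x, rcond=None)
        res = phqtl.compute_pve(y, pd.Series(x - X @ b, index=y.index))
        assert res.pve == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_five_point_case(self):
        # y = b*x + e with b^2 * sum(x^2) = 4 and ||e||^2 = 1, e orthogonal to
        # [1, x]  ->  RSS0 = 5, RSS1 = 1, PVE = 0.8
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        e = np.array([1.0, -2.0, 0.0, 2.0, -1.0]) / np.sqrt(10)
        b = np.sqrt(0.4)
        y = pd.Series(b * x + e)
        res = phqtl.compute_pve(y, pd.Series(x, index=y.index))
        assert res.pve == pytest.approx(0.8, abs=1e-12)
        assert 0 < res.pvalue < 1

    def test_zero_variance_response_errors(self):
        y = pd.Series(np.ones(10))
        with pytest.raises(ValueError):
            phqtl.compute_pve(y, pd.Series(np.arange(10.0)))


class TestParentMediation:
    def test_mech1_large_negative_delta(self, haplo58, loco58):
        marker = 12
        chrom = haplo58.markers.df["chromosome"].iloc[marker]
        parent = phqtl.simulate_strain_trait(haplo58, causal_marker=marker,
                                             pve=0.5, h2_polygenic=0.15, seed=1)
        rng = np.random.default_rng(2)
        ph = parent + rng.normal(size=58) * 0.2
        res = phqtl.mediate_through_parent(ph, parent, marker, haplo58,
                                           loco58[chrom])
        assert res.delta_lod_pct < -50
        assert res.mechanism == "mech1"

    def test_mech2_delta_near_zero(self, haplo58, loco58):
        marker = 30
        chrom = haplo58.markers.df["chromosome"].iloc[marker]
        mediator = phqtl.simulate_strain_trait(haplo58, causal_marker=marker,
                                               pve=0.7, h2_polygenic=0.15, seed=3)
        parent = phqtl.simulate_strain_trait(haplo58, pve=0.0,
                                             h2_polygenic=0.15, seed=4)
        rng = np.random.default_rng(5)
        ph = mediator + 0.2 * parent + rng.normal(size=58) * 0.2
        res = phqtl.mediate_through_parent(ph, parent, marker, haplo58,
                                           loco58[chrom])
        assert res.delta_lod_pct > -20
        assert res.mechanism == "mech2"

    def test_unrelated_parent_leaves_lod_unchanged(self, haplo58, loco58):
        diffs = []
        for rep in range(10):
            marker = 5 + rep
            chrom = haplo58.markers.df["chromosome"].iloc[marker]
            ph = phqtl.simulate_strain_trait(haplo58, causal_marker=marker,
                                             pve=0.5, seed=600 + rep)
            parent = pd.Series(np.random.default_rng(650 + rep).normal(size=58),
                               index=_strains(haplo58))
            res = phqtl.mediate_through_parent(ph, parent, marker, haplo58,
                                               loco58[chrom])
            diffs.append(abs(res.mediation_lod - res.original_lod))
        assert np.mean(diffs) < 0.5

    def test_complete_mediation_drives_lod_to_floor(self, haplo58, loco58):
        marker = 20
        chrom = haplo58.markers.df["chromosome"].iloc[marker]
        parent = phqtl.simulate_strain_trait(haplo58, causal_marker=marker,
                                             pve=0.6, seed=7)
        ph = parent.copy()  # parent is the QTL's sole channel
        res = phqtl.mediate_through_parent(ph, parent, marker, haplo58,
                                           loco58[chrom])
        assert 0.0 <= res.mediation_lod < 0.5
        assert res.delta_lod_pct < -90


class TestMediationScan:
    def _candidates(self, haplo, n, seed, extra=None):
        rng = np.random.default_rng(seed)
        cols = {f"decoy{i:03d}": pd.Series(rng.normal(size=58),
                                           index=_strains(haplo))
                for i in range(n)}
        if extra:
            cols.update(extra)
        return AbundanceMatrix(pd.DataFrame(cols), level="strain_avg",
                               kind="protein")

    def test_zscores_standardized(self, haplo58):
        target = phqtl.simulate_strain_trait(haplo58, causal_marker=9, pve=0.5,
                                             seed=8)
        res = phqtl.mediation_scan(target, 9, self._candidates(haplo58, 40, 9),
                                   haplo58)
        z = res.table["zscore"]
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_candidate_absorbs_qtl(self, haplo58):
        cast_dose = pd.Series(haplo58.probs[:, 9, 5], index=_strains(haplo58))
        rng = np.random.default_rng(10)
        target = cast_dose * 2 + rng.normal(size=58) * 0.1
        cands = self._candidates(haplo58, 40, 11, extra={"collinear": cast_dose})
        res = phqtl.mediation_scan(target, 9, cands, haplo58)
        tab = res.table.set_index("mediator_id")
        assert tab.loc["collinear", "zscore"] == res.table["zscore"].min()
        assert tab.loc["collinear", "zscore"] < -3

    def test_planted_mediator_attains_minimum_z(self, haplo58):
        mediator = phqtl.simulate_strain_trait(haplo58, causal_marker=22,
                                               pve=0.7, h2_polygenic=0.15,
                                               seed=12)
        rng = np.random.default_rng(13)
        target = mediator + rng.normal(size=58) * 0.2
        cands = self._candidates(haplo58, 100, 14, extra={"planted": mediator})
        res = phqtl.mediation_scan(target, 22, cands, haplo58)
        tab = res.table.set_index("mediator_id")
        assert tab.loc["planted", "zscore"] == res.table["zscore"].min()
        assert tab.loc["planted", "zscore"] < -8

    def test_independent_candidates_none_strong(self, haplo58):
        target = phqtl.simulate_strain_trait(haplo58, causal_marker=3, pve=0.6,
                                             seed=15)
        res = phqtl.mediation_scan(target, 3, self._candidates(haplo58, 100, 16),
                                   haplo58)
        assert int(res.table["strong"].sum()) == 0

    def test_excluded_features_absent(self, haplo58):
        target = phqtl.simulate_strain_trait(haplo58, causal_marker=3, pve=0.6,
                                             seed=17)
        cands = self._candidates(haplo58, 30, 18)
        res = phqtl.mediation_scan(target, 3, cands, haplo58,
                                   exclude=("decoy000",))
        assert "decoy000" not in set(res.table["mediator_id"])

    def test_few_candidates_warns(self, haplo58):
        target = phqtl.simulate_strain_trait(haplo58, causal_marker=3, pve=0.6,
                                             seed=19)
        with pytest.warns(UserWarning, match="candidates"):
            phqtl.mediation_scan(target, 3, self._candidates(haplo58, 5, 20),
                                 haplo58)

    def test_co_mapping_flag(self, haplo58):
        target = phqtl.simulate_strain_trait(haplo58, causal_marker=9, pve=0.6,
                                             seed=21)
        cands = self._candidates(haplo58, 25, 22)
        mdf = haplo58.markers.df
        peaks = pd.DataFrame({
            "chromosome": [mdf["chromosome"].iloc[9], "chr2"],
            "position_bp": [mdf["position_bp"].iloc[9] + 5e6, 1e6]},
            index=["decoy000", "decoy001"])
        res = phqtl.mediation_scan(
            target, 9, cands, haplo58, candidate_peaks=peaks,
            target_position=(mdf["chromosome"].iloc[9], mdf["position_bp"].iloc[9]))
        tab = res.table.set_index("mediator_id")
        assert bool(tab.loc["decoy000", "co_mapping"])
        assert not bool(tab.loc["decoy001", "co_mapping"])
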