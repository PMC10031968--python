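"""Quantification layer: filters, normalization, batch and parent adjustment."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phqtl
from phqtl.datatypes import FOUNDERS, PeptideIntensityTable, SampleMetadata


def _meta(samples):
    return SampleMetadata(pd.DataFrame(samples))


def _table(pep_rows, intensities, sample_ids):
    pep = pd.DataFrame(pep_rows)
    inten = pd.DataFrame(intensities, index=sample_ids,
                         columns=list(pep["peptide_id"]))
    return PeptideIntensityTable(pep, inten)


def _pep(pid, prot, seq, phospho=False, site=""):
    return dict(peptide_id=pid, protein_id=prot, is_phospho=phospho,
                site_label=site, sequence_with_flanks=seq)


class TestPolymorphicFilter:
    def _proteomes(self, seq_by_prot, variants=()):
        """Identical proteomes with (founder, protein, pos, aa) substitutions."""
        out = {f: dict(seq_by_prot) for f in FOUNDERS}
        for founder, prot, pos, aa in variants:
            s = out[founder][prot]
            out[founder][prot] = s[:pos] + aa + s[pos + 1:]
        return out

    def test_conserved_peptide_retained_variant_removed(self):
        seq = "MKLVAAPEPTIDESEQRGHW"
        #          body PEPTIDESEQ at 6..16, flanks AAP / RGH
        table = _table(
            [_pep("p1", "P1", "AAP.PEPTIDESEQ.RGH"),
             _pep("p2", "P1", "AAP.PEPTIDESEQ.RGH")],
            [[1.0, 2.0]], ["s1"])
        proteomes = self._proteomes({"P1": seq})
        kept, report = phqtl.filter_polymorphic_peptides(table, proteomes)
        assert report["n_removed_polymorphic"] == 0
        # one substitution inside the body in a single founder removes it
        proteomes = self._proteomes({"P1": seq}, [("CAST", "P1", 8, "W")])
        kept, report = phqtl.filter_polymorphic_peptides(table, proteomes)
        assert len(kept.peptides) == 0
        assert report["n_removed_polymorphic"] == 2

    def test_phospho_flank_variant_removed_but_body_variant_rule_differs(self):
        seq = "MKLVAAPEPTIDESEQRGHW"
        table = _table(
            [_pep("ph1", "P1", "AAP.PEPTIDESEQ.RGH", phospho=True, site="pS8")],
            [[1.0]], ["s1"])
        # variant at flank position -2 ('A' at index 4): body conserved, but
        # the flanked sequence is not -> phosphopeptide removed
        proteomes = self._proteomes({"P1": seq}, [("NZO", "P1", 4, "W")])
        kept, report = phqtl.filter_polymorphic_peptides(table, proteomes)
        assert len(kept.peptides) == 0
        # the same variant does not remove the non-phospho version
        table2 = _table([_pep("p1", "P1", "AAP.PEPTIDESEQ.RGH")], [[1.0]], ["s1"])
        kept2, _ = phqtl.filter_polymorphic_peptides(table2, proteomes)
        assert len(kept2.peptides) == 1

    def test_protein_absent_from_founder_removed_with_warning(self):
        table = _table([_pep("p1", "P9", "AAA.CCCC.DDD")], [[1.0]], ["s1"])
        proteomes = self._proteomes({"P1": "XXAAACCCCDDDXX"})
        with pytest.warns(UserWarning, match="absent"):
            kept, report = phqtl.filter_polymorphic_peptides(table, proteomes)
        assert len(kept.peptides) == 0
        assert report["n_removed_missing_protein"] == 1


class TestPhiNormalization:
    META = [dict(sample_id="s1", strain="c1", sex="F", batch="b1", is_bridge=False),
            dict(sample_id="s2", strain="c2", sex="M", batch="b1", is_bridge=False),
            dict(sample_id="br", strain="pool", sex="B", batch="b1", is_bridge=True)]

    def test_two_sample_batch_phi_values(self):
        table = _table([_pep("p1", "P1", "AAA.CCC.DDD"),
                        _pep("p2", "P1", "AAA.EEE.DDD")],
                       [[10.0, 90.0], [70.0, 130.0], [100.0, 100.0]],
                       ["s1", "s2", "br"])
        scaled, factors = phqtl.normalize_within_batch(table, _meta(self.META))
        assert factors.phi.loc["s1"] == pytest.approx(2.0)
        assert factors.phi.loc["s2"] == pytest.approx(1.0)
        assert scaled.intensities.loc["s1", "p1"] == pytest.approx(20.0)

    def test_equal_totals_unchanged(self):
        table = _table([_pep("p1", "P1", "AAA.CCC.DDD")],
                       [[5.0], [5.0], [5.0]], ["s1", "s2", "br"])
        scaled, factors = phqtl.normalize_within_batch(table, _meta(self.META))
        assert (factors.phi == 1.0).all()
        pd.testing.assert_frame_equal(scaled.intensities, table.intensities)

    def test_zero_total_sample_errors(self):
        table = _table([_pep("p1", "P1", "AAA.CCC.DDD")],
                       [[0.0], [5.0], [5.0]], ["s1", "s2", "br"])
        with pytest.raises(ValueError, match="s1"):
            phqtl.normalize_within_batch(table, _meta(self.META))

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(min_value=0.5, max_value=1e5), min_size=2,
                    max_size=6))
    def test_phi_equalizes_batch_totals(self, base):
        n = len(base)
        meta = _meta([dict(sample_id=f"s{i}", strain=f"c{i}", sex="F",
                           batch="b1", is_bridge=i == 0) for i in range(n)])
        rng = np.random.default_rng(1)
        inten = np.outer(base, rng.uniform(0.5, 2.0, 3))
        table = _table([_pep(f"p{j}", "P1", "AAA.CCC.DDD") for j in range(3)],
                       inten, [f"s{i}" for i in range(n)])
        scaled, _ = phqtl.normalize_within_batch(table, meta)
        totals = scaled.intensities.sum(axis=1)
        assert np.allclose(totals, totals.max())


class TestRelativeAbundance:
    META = [dict(sample_id="s1", strain="c1", sex="F", batch="b1", is_bridge=False),
            dict(sample_id="br", strain="pool", sex="B", batch="b1", is_bridge=True)]

    def test_worked_bridge_logratio(self):
        table = _table([_pep("p1", "P1", "AAA.CCC.DDD"),
                        _pep("p2", "P1", "AAA.EEE.DDD")],
                       [[3.0, 4.0], [1.0, 2.0]], ["s1", "br"])
        mat, _ = phqtl.compute_relative_abundance(table, _meta(self.META))
        assert mat.values.loc["s1", "P1"] == pytest.approx(1.0)

    def test_equal_sums_give_zero(self):
        table = _table([_pep("p1", "P1", "AAA.CCC.DDD")],
                       [[7.0], [7.0]], ["s1", "br"])
        mat, _ = phqtl.compute_relative_abundance(table, _meta(self.META))
        assert mat.values.loc["s1", "P1"] == pytest.approx(0.0)

    def test_all_phospho_parent_dropped_under_exclusion(self):
        # the protein's only peptide body matches a detected phosphopeptide
        table = _table([_pep("p1", "P1", "AAA.CCC.DDD"),
                        _pep("ph1", "P1", "AAA.CCC.DDD", phospho=True, site="pS3")],
                       [[3.0, 5.0], [1.0, 2.0]], ["s1", "br"])
        mat, report = phqtl.compute_relative_abundance(
            table, _meta(self.META), kind="protein",
            exclude_phospho_from_parents=True)
        assert "P1" in report["dropped_proteins"]
        assert "P1" not in mat.values.columns
        # without exclusion the protein is quantified from its peptide
        mat2, _ = phqtl.compute_relative_abundance(table, _meta(self.META))
        assert mat2.values.loc["s1", "P1"] == pytest.approx(1.0)

    def test_phospho_features_are_single_peptides(self):
        table = _table([_pep("ph1", "P1", "AAA.CCC.DDD", phospho=True, site="pS3")],
                       [[7.0], [3.0]], ["s1", "br"])
        mat, _ = phqtl.compute_relative_abundance(table, _meta(self.META),
                                                  kind="phospho")
        assert mat.values.loc["s1", "ph1"] == pytest.approx(np.log2(8 / 4))
        assert mat.feature_meta.loc["ph1", "protein_id"] == "P1"


class TestMissingFilter:
    def _matrix(self, frac_observed, n=100):
        vals = np.ones((n, 1))
        vals[int(round(frac_observed * n)):, 0] = np.nan
        from phqtl.datatypes import AbundanceMatrix
        return AbundanceMatrix(pd.DataFrame(vals, columns=["f"]),
                               level="sample", kind="protein")

    @pytest.mark.parametrize("frac,kept", [(0.49, False), (0.50, False),
                                           (0.51, True), (1.0, True)])
    def test_fifty_percent_rule(self, frac, kept):
        out, removed = phqtl.filter_missing(self._matrix(frac))
        assert ("f" in out.values.columns) is kept


class TestBatchAdjust:
    def _simulated(self, n_strains=24, n_feat=40, offset=1.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_strains):
            for sx in "FM":
                rows.append(dict(sample_id=f"c{i:02d}_{sx}", strain=f"c{i:02d}",
                                 sex=sx, batch=f"b{(i + (sx == 'M')) % 2 + 1}",
                                 is_bridge=False))
        for b in ("b1", "b2"):
            rows.append(dict(sample_id=f"br_{b}", strain="pool", sex="B",
                             batch=b, is_bridge=True))
        meta = SampleMetadata(pd.DataFrame(rows))
        samples = meta.samples
        strain_eff = rng.normal(0, 1, (n_strains, n_feat))
        s_idx = samples["strain"].str[1:].astype(int).to_numpy()
        batch_shift = np.where(samples["batch"].to_numpy() == "b1", offset, -offset)
        vals = (strain_eff[s_idx]
                + batch_shift[:, None]
                + rng.normal(0, 0.3, (len(samples), n_feat)))
        from phqtl.datatypes import AbundanceMatrix
        mat = AbundanceMatrix(
            pd.DataFrame(vals, index=list(samples["sample_id"]),
                         columns=[f"f{j}" for j in range(n_feat)]),
            level="sample", kind="protein")
        return mat, meta, samples

    def test_recovers_planted_offsets_and_centers_batches(self):
        mat, meta, samples = self._simulated()
        adj, fits = phqtl.batch_adjust(mat, meta)
        rec = np.array([f.batch_effects["b1"] - f.batch_effects["b2"]
                        for f in fits.values()])
        # planted between-batch difference is 2.0; BLUPs shrink a little
        assert abs(rec.mean() - 2.0) < 0.3
        b1 = samples[samples["batch"] == "b1"]["sample_id"]
        b2 = samples[samples["batch"] == "b2"]["sample_id"]
        gap = (adj.values.loc[b1].mean() - adj.values.loc[b2].mean()).abs().mean()
        assert gap < 0.25

    def test_strain_means_preserved(self):
        mat, meta, samples = self._simulated(seed=1)
        adj, _ = phqtl.batch_adjust(mat, meta)
        strain = meta.samples.set_index("sample_id")["strain"]
        before = mat.values.groupby(strain).mean()
        after = adj.values.groupby(strain).mean()
        r = np.array([np.corrcoef(before[c], after[c])[0, 1]
                      for c in before.columns])
        assert (r > 0.99).all()

    def test_idempotent(self):
        mat, meta, _ = self._simulated(n_feat=10, seed=2)
        adj, _ = phqtl.batch_adjust(mat, meta)
        adj2, fits2 = phqtl.batch_adjust(adj, meta)
        resid = np.array([list(f.batch_effects.values()) for f in fits2.values()])
        assert np.abs(resid).max() < 0.1

    def test_single_batch_identity(self):
        rows = [dict(sample_id=f"s{i}", strain=f"c{i}", sex="F", batch="b1",
                     is_bridge=False) for i in range(4)]
        rows.append(dict(sample_id="br", strain="pool", sex="B", batch="b1",
                         is_bridge=True))
        meta = SampleMetadata(pd.DataFrame(rows))
        from phqtl.datatypes import AbundanceMatrix
        mat = AbundanceMatrix(pd.DataFrame(np.arange(4.0)[:, None],
                                           index=[f"s{i}" for i in range(4)],
                                           columns=["f"]),
                              level="sample", kind="protein")
        adj, fits = phqtl.batch_adjust(mat, meta)
        pd.testing.assert_frame_equal(adj.values, mat.values)


class TestParentAdjustment:
    def _matrices(self, ph_vals, parent_vals, index=None):
        from phqtl.datatypes import AbundanceMatrix
        idx = index or [f"s{i}" for i in range(len(ph_vals))]
        ph = AbundanceMatrix(pd.DataFrame({"ph1": ph_vals}, index=idx),
                             level="sample", kind="phospho",
                             feature_meta=pd.DataFrame(
                                 {"protein_id": ["P1"]}, index=["ph1"]))
        par = AbundanceMatrix(pd.DataFrame({"P1": parent_vals}, index=idx),
                              level="sample", kind="protein")
        return ph, par

    def test_residual_orthogonal_to_parent(self, rng):
        parent = rng.normal(size=50)
        ph, par = self._matrices(0.7 * parent + rng.normal(size=50) * 0.4, parent)
        adj, _ = phqtl.adjust_for_parent(ph, par)
        r = np.corrcoef(adj.values["ph1"], parent)[0, 1]
        assert abs(r) < 1e-12

    def test_identical_gives_zero_residuals(self, rng):
        x = rng.normal(size=30)
        ph, par = self._matrices(x, x)
        adj, _ = phqtl.adjust_for_parent(ph, par)
        assert np.allclose(adj.values["ph1"], 0.0)

    def test_slope_recovery(self, rng):
        parent = rng.normal(size=200)
        noise = rng.normal(size=200) * 0.3
        ph, par = self._matrices(0.8 * parent + noise, parent)
        y, x = ph.values["ph1"].to_numpy(), parent
        X = np.column_stack([np.ones(200), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        se = 0.3 / np.sqrt(((x - x.mean()) ** 2).sum())
        assert abs(beta[1] - 0.8) < 2 * se * 1.5

    def test_zero_variance_parent_centers(self):
        ph, par = self._matrices([1.0, 2.0, 3.0, 4.0], [5.0] * 4)
        with pytest.warns(UserWarning, match="zero variance"):
            adj, _ = phqtl.adjust_for_parent(ph, par)
        assert np.allclose(adj.values["ph1"], [-1.5, -0.5, 0.5, 1.5])

    def test_missing_parent_dropped(self, rng):
        from phqtl.datatypes import AbundanceMatrix
        idx = [f"s{i}" for i in range(5)]
        ph = AbundanceMatrix(pd.DataFrame({"ph1": rng.normal(size=5)}, index=idx),
                             level="sample", kind="phospho",
                             feature_meta=pd.DataFrame({"protein_id": ["P9"]},
                                                       index=["ph1"]))
        par = AbundanceMatrix(pd.DataFrame({"P1": rng.normal(size=5)}, index=idx),
                              level="sample", kind="protein")
        adj, dropped = phqtl.adjust_for_parent(ph, par)
        assert dropped == ["ph1"]
        assert "ph1" not in adj.values.columns


class TestStrainSummaries:
    def _mat(self, rows, vals):
        from phqtl.datatypes import AbundanceMatrix
        meta = SampleMetadata(pd.DataFrame(
            rows + [dict(sample_id="br", strain="pool", sex="B", batch="b1",
                         is_bridge=True)]))
        mat = AbundanceMatrix(pd.DataFrame({"f": vals},
                                           index=[r["sample_id"] for r in rows]),
                              level="sample", kind="protein")
        return mat, meta

    def test_average_and_male_minus_female(self):
        rows = [dict(sample_id="c1_M", strain="c1", sex="M", batch="b1", is_bridge=False),
                dict(sample_id="c1_F", strain="c1", sex="F", batch="b1", is_bridge=False)]
        mat, meta = self._mat(rows, [2.0, 4.0])
        avg, diff = phqtl.summarize_strains(mat, meta)
        assert avg.values.loc["c1", "f"] == pytest.approx(3.0)
        assert diff.values.loc["c1", "f"] == pytest.approx(-2.0)

    def test_single_sex_average_kept_difference_missing(self):
        rows = [dict(sample_id="c1_M", strain="c1", sex="M", batch="b1", is_bridge=False),
                dict(sample_id="c1_F", strain="c1", sex="F", batch="b1", is_bridge=False)]
        mat, meta = self._mat(rows, [2.0, np.nan])
        avg, diff = phqtl.summarize_strains(mat, meta)
        assert avg.values.loc["c1", "f"] == pytest.approx(2.0)
        assert np.isnan(diff.values.loc["c1", "f"])

    def test_duplicate_strain_sex_errors(self):
        rows = [dict(sample_id="a", strain="c1", sex="M", batch="b1", is_bridge=False),
                dict(sample_id="b", strain="c1", sex="M", batch="b1", is_bridge=False)]
        with pytest.raises(ValueError):
            self._mat(rows, [1.0, 2.0])
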