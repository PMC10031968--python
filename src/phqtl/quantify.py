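"""Peptide-to-abundance quantification for TMT multi-batch designs.

Stages, in the order the pipeline applies them:

1. remove peptides whose sequence is polymorphic among the eight founder
   proteomes (phosphopeptides additionally require the three flanking
   residues on both sides to be conserved);
2. scale each sample's peptide intensities so cumulative intensity is
   equalized within TMT batch (``phi`` factors);
3. roll peptides up to protein abundance (or keep phosphopeptides as single
   features), expressed as a log2 ratio to the batch's bridge channel with a
   +1 pseudo-count;
4. drop features unobserved in half or more of the samples;
5. remove the TMT batch effect with a mixed model (sex fixed; strain and
   batch random) and subtract the batch BLUPs;
6. optionally regress phosphopeptides on their parent protein and keep the
   residuals (the "adjusted" phosphopeptides);
7. summarize strains as the average and the male - female difference.
"""

from __future__ import annotations

import re
import warnings
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import (
    AbundanceMatrix,
    BatchModelFit,
    NormalizationFactors,
    PeptideIntensityTable,
    SampleMetadata,
)


# ---------------------------------------------------------------------------
# polymorphic-peptide filter
# ---------------------------------------------------------------------------


def filter_polymorphic_peptides(table: PeptideIntensityTable,
                                founder_proteomes: dict) -> tuple[PeptideIntensityTable, dict]:
    """Keep only peptides whose sequence is identical in all eight founders.

    Non-phospho peptides are checked on the peptide body; phosphopeptides on
    the body plus three flanking residues on both sides (a variant near the
    site would otherwise masquerade as a phosphorylation signal).  Peptides
    whose protein is absent from any founder proteome are removed with a
    warning (conservative).
    """
    keep, removed_poly, removed_missing = [], 0, 0
    for _, row in table.peptides.iterrows():
        left, body, right = PeptideIntensityTable.split_sequence(row["sequence_with_flanks"])
        query = (left[-3:] + body + right[:3]) if row["is_phospho"] else body
        ok = True
        for founder, proteome in founder_proteomes.items():
            seq = proteome.get(row["protein_id"])
            if seq is None:
                warnings.warn(f"protein {row['protein_id']} absent from founder "
                              f"{founder}; removing peptide {row['peptide_id']}")
                removed_missing += 1
                ok = False
                break
            if query not in seq:
                removed_poly += 1
                ok = False
                break
        if ok:
            keep.append(row["peptide_id"])
    report = dict(n_input=len(table.peptides), n_retained=len(keep),
                  n_removed_polymorphic=removed_poly,
                  n_removed_missing_protein=removed_missing)
    return table.subset(keep), report


# ---------------------------------------------------------------------------
# within-batch loading normalization
# ---------------------------------------------------------------------------


def normalize_within_batch(table: PeptideIntensityTable,
                           metadata: SampleMetadata) -> tuple[PeptideIntensityTable, NormalizationFactors]:
    """Scale samples so each matches the batch's maximum cumulative intensity.

    ``phi_i = max_{i' in batch} (sum_j y_{i'j}) / sum_j y_{ij}`` computed over
    observed cells; the scaled table has equal per-sample totals within batch.
    """
    inten = table.intensities
    meta = metadata.df.set_index("sample_id")
    totals = inten.sum(axis=1, skipna=True)
    bad = totals[totals <= 0]
    if len(bad):
        raise ValueError(f"non-positive cumulative intensity for samples: "
                         f"{list(bad.index)}")
    batch = meta.loc[inten.index, "batch"]
    batch_max = totals.groupby(batch).max()
    phi = batch_max.loc[batch].to_numpy() / totals.to_numpy()
    scaled = inten.mul(phi, axis=0)
    factors = NormalizationFactors(phi=pd.Series(phi, index=inten.index),
                                   batch_max_total=batch_max)
    return PeptideIntensityTable(table.peptides.copy(), scaled), factors


# ---------------------------------------------------------------------------
# bridge-relative abundance
# ---------------------------------------------------------------------------


def detected_phospho_sequences(table: PeptideIntensityTable) -> set:
    """Peptide bodies carrying a detected phosphosite (for parent exclusion)."""
    ph = table.peptides[table.peptides["is_phospho"].astype(bool)]
    return {PeptideIntensityTable.split_sequence(s)[1]
            for s in ph["sequence_with_flanks"]}


def compute_relative_abundance(table: PeptideIntensityTable, metadata: SampleMetadata,
                               kind: str = "protein",
                               exclude_phospho_from_parents: bool = False
                               ) -> tuple[AbundanceMatrix, dict]:
    """Bridge-relative log2 abundance per sample.

    Proteins: ``log2((sum_m y'_im + 1) / (sum_m y'_b[i]m + 1))`` summing each
    protein's retained (non-phospho) peptides; with
    ``exclude_phospho_from_parents`` peptides whose body sequence matches any
    detected phosphopeptide are also excluded, which is how parent proteins
    are quantified for phosphopeptide adjustment.  Phosphopeptides: the same
    log-ratio on the single peptide.  Sums skip missing cells; a sample with
    no observed peptide for a feature is missing.  Bridge samples are
    consumed here and do not appear in the output.
    """
    if kind not in {"protein", "phospho"}:
        raise ValueError("kind must be 'protein' or 'phospho'")
    meta = metadata.df.set_index("sample_id")
    inten = table.intensities
    samples = [s for s in inten.index if not meta.loc[s, "is_bridge"]]
    bridge_of = {b: metadata.bridge_of(b) for b in meta["batch"].unique()}
    missing_bridge = [b for b, s in bridge_of.items() if s not in inten.index]
    if missing_bridge:
        raise ValueError(f"no bridge intensities for batches {missing_bridge}")
    peptides = table.peptides
    dropped = []
    cols, meta_rows = {}, []
    if kind == "protein":
        pep = peptides[~peptides["is_phospho"].astype(bool)]
        if exclude_phospho_from_parents:
            ph_seqs = detected_phospho_sequences(table)
            bodies = pep["sequence_with_flanks"].map(
                lambda s: PeptideIntensityTable.split_sequence(s)[1])
            pep = pep[~bodies.isin(ph_seqs)]
        for prot, sub in peptides.groupby("protein_id", sort=True):
            ids = list(pep[pep["protein_id"] == prot]["peptide_id"])
            if not ids:
                dropped.append(prot)
                continue
            block = inten[ids]
            num = block.loc[samples].sum(axis=1, skipna=True)
            n_obs = block.loc[samples].notna().sum(axis=1)
            bridge_rows = block.loc[[bridge_of[meta.loc[s, "batch"]] for s in samples]]
            den = bridge_rows.sum(axis=1, skipna=True).to_numpy()
            vals = np.log2((num.to_numpy() + 1.0) / (den + 1.0))
            vals[n_obs.to_numpy() == 0] = np.nan
            cols[prot] = vals
            meta_rows.append(dict(feature_id=prot, protein_id=prot, site_label=""))
    else:
        ph = peptides[peptides["is_phospho"].astype(bool)]
        for _, row in ph.iterrows():
            pid = row["peptide_id"]
            y = inten[pid]
            den = y.loc[[bridge_of[meta.loc[s, "batch"]] for s in samples]].to_numpy()
            vals = np.log2((y.loc[samples].to_numpy() + 1.0) / (den + 1.0))
            vals[y.loc[samples].isna().to_numpy()] = np.nan
            cols[pid] = vals
            meta_rows.append(dict(feature_id=pid, protein_id=row["protein_id"],
                                  site_label=row["site_label"]))
    values = pd.DataFrame(cols, index=samples)
    fmeta = pd.DataFrame(meta_rows).set_index("feature_id") if meta_rows else pd.DataFrame()
    report = dict(n_features=values.shape[1], dropped_proteins=dropped)
    return AbundanceMatrix(values, level="sample", kind=kind, feature_meta=fmeta), report


# ---------------------------------------------------------------------------
# missingness filter
# ---------------------------------------------------------------------------


def filter_missing(matrix: AbundanceMatrix,
                   max_missing_fraction: float = 0.5) -> tuple[AbundanceMatrix, list]:
    """Drop features unobserved for ``max_missing_fraction`` or more of samples."""
    frac_missing = matrix.values.isna().mean(axis=0)
    keep = frac_missing[frac_missing < max_missing_fraction].index
    removed = [f for f in matrix.values.columns if f not in set(keep)]
    fmeta = matrix.feature_meta
    if len(fmeta):
        fmeta = fmeta.loc[fmeta.index.intersection(keep)]
    return matrix.copy_with(matrix.values[list(keep)], feature_meta=fmeta), removed


# ---------------------------------------------------------------------------
# TMT batch adjustment (mixed model)
# ---------------------------------------------------------------------------

_BATCH_KEY = re.compile(r"batch\[C\(batch\)\[(.+)\]\]")


def batch_adjust(matrix: AbundanceMatrix, metadata: SampleMetadata,
                 reml: bool = True) -> tuple[AbundanceMatrix, dict]:
    """Remove the TMT batch effect per feature with a crossed-random LMM.

    For each feature: ``y = mu + sex (fixed) + strain (random) + batch
    (random) + e``; the output subtracts the predicted (BLUP) batch effect of
    each sample's batch.  Missing cells stay missing.  With a single batch the
    data are returned unchanged; features with fewer than 3 observations are
    skipped with a warning.
    """
    meta = metadata.samples.set_index("sample_id")
    vals = matrix.values
    meta = meta.loc[vals.index]
    if meta["batch"].nunique() < 2:
        return matrix.copy_with(vals.copy(), batch_adjusted=True), {}
    adjusted = vals.copy()
    fits = {}
    for feat in vals.columns:
        y = vals[feat]
        obs = y.dropna().index
        if len(obs) < 3:
            warnings.warn(f"feature {feat}: <3 observed samples, not batch-adjusted")
            continue
        df = pd.DataFrame({"y": y.loc[obs],
                           "sex": meta.loc[obs, "sex"],
                           "strain": meta.loc[obs, "strain"],
                           "batch": meta.loc[obs, "batch"]})
        if df["batch"].nunique() < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM.from_formula(
                "y ~ sex", groups=np.ones(len(df)), re_formula="0",
                vc_formula={"strain": "0 + C(strain)", "batch": "0 + C(batch)"},
                data=df)
            try:
                res = model.fit(reml=reml)
            except Exception as exc:  # singular fits on degenerate features
                warnings.warn(f"feature {feat}: batch model failed ({exc})")
                continue
        re_effects = res.random_effects[1.0]
        batch_blup = {}
        for key, val in re_effects.items():
            m = _BATCH_KEY.fullmatch(key)
            if m:
                batch_blup[m.group(1)] = float(val)
        shift = meta.loc[obs, "batch"].map(lambda b: batch_blup.get(b, 0.0))
        adjusted.loc[obs, feat] = y.loc[obs] - shift
        params = res.params
        sex_eff = float(params.get("sex[T.M]", 0.0))
        vc = res.vcomp
        fits[feat] = BatchModelFit(
            feature_id=feat, intercept=float(params.get("Intercept", np.nan)),
            sex_effect=sex_eff,
            strain_var=float(vc[1]) if len(vc) == 2 else np.nan,
            batch_var=float(vc[0]) if len(vc) == 2 else np.nan,
            resid_var=float(res.scale), batch_effects=batch_blup)
    return matrix.copy_with(adjusted, batch_adjusted=True), fits


# ---------------------------------------------------------------------------
# parent-protein adjustment
# ---------------------------------------------------------------------------


def adjust_for_parent(phospho: AbundanceMatrix, proteins: AbundanceMatrix
                      ) -> tuple[AbundanceMatrix, list]:
    """Residuals of each phosphopeptide on its parent protein abundance.

    Ordinary least squares of phospho on intercept + parent over the rows
    where both are observed; the residual is exactly orthogonal to the parent
    on those rows.  Phosphopeptides whose parent protein is not quantified
    are dropped and reported.  Works at sample or strain level alike.
    """
    if len(phospho.feature_meta) == 0:
        raise ValueError("phospho matrix lacks feature_meta with protein_id")
    out = {}
    dropped = []
    prot_vals = proteins.values
    for feat in phospho.values.columns:
        parent = phospho.feature_meta.loc[feat, "protein_id"]
        if parent not in prot_vals.columns:
            dropped.append(feat)
            continue
        y = phospho.values[feat]
        x = prot_vals[parent].reindex(y.index)
        both = y.notna() & x.notna()
        resid = pd.Series(np.nan, index=y.index)
        if both.sum() >= 3:
            ys, xs = y[both].to_numpy(), x[both].to_numpy()
            if np.ptp(xs) == 0:
                warnings.warn(f"{feat}: parent {parent} has zero variance; centering only")
                resid[both] = ys - ys.mean()
            else:
                X = np.column_stack([np.ones(both.sum()), xs])
                beta, *_ = np.linalg.lstsq(X, ys, rcond=None)
                resid[both] = ys - X @ beta
        out[feat] = resid
    values = pd.DataFrame(out, index=phospho.values.index)
    fmeta = phospho.feature_meta.loc[phospho.feature_meta.index.intersection(values.columns)]
    adj = AbundanceMatrix(values, level=phospho.level, kind="adj_phospho",
                          feature_meta=fmeta, batch_adjusted=phospho.batch_adjusted,
                          parent_adjusted=True)
    return adj, dropped


# ---------------------------------------------------------------------------
# strain summaries
# ---------------------------------------------------------------------------


def summarize_strains(matrix: AbundanceMatrix, metadata: SampleMetadata
                      ) -> tuple[AbundanceMatrix, AbundanceMatrix]:
    """Strain averages and male - female differences.

    The average is the mean of the observed sexes (a single observed sex
    stands for the strain); the difference is male minus female and is
    missing unless both sexes are observed.
    """
    if matrix.level != "sample":
        raise ValueError("summarize_strains expects a sample-level matrix")
    meta = metadata.samples.set_index("sample_id")
    meta = meta.loc[matrix.values.index]
    if meta.duplicated(subset=["strain", "sex"]).any():
        raise ValueError("duplicate strain x sex samples")
    strains = list(dict.fromkeys(meta["strain"]))
    vals = matrix.values
    by_sex = {}
    for sx in ("F", "M"):
        rows = meta[meta["sex"] == sx]
        sub = vals.loc[rows.index]
        sub.index = rows["strain"]
        by_sex[sx] = sub.reindex(strains)
    avg = pd.concat([by_sex["F"], by_sex["M"]]).groupby(level=0).mean()
    avg = avg.reindex(strains)
    diff = by_sex["M"] - by_sex["F"]
    avg_m = matrix.copy_with(avg, level="strain_avg")
    diff_m = matrix.copy_with(diff, level="strain_diff")
    return avg_m, diff_m
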