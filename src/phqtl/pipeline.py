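"""Config-driven orchestration: simulate -> quantify -> scan -> thresholds ->
call -> mediate -> report.

Every stage reads its inputs from, and writes its outputs to, a run
directory of plain-text artifacts (TSV + JSON sidecars), so stages are
resumable and runs are diff-able.  A run manifest records the configuration
hash and a checksum of every artifact; identical configurations reproduce
identical artifacts bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, mediation, qtl, quantify, significance, simulate
from .datatypes import AbundanceMatrix

log = logging.getLogger("phqtl")

STAGES = ("simulate", "quantify", "heritability", "sex_effects", "scan",
          "thresholds", "call", "mediate", "report")


@dataclass
class RunConfig:
    """All knobs of a pipeline run; unknown keys are rejected on load."""

    outdir: str = "phqtl_run"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGES))
    # genomes
    n_strains: int = 58
    n_chromosomes: int = 2
    markers_per_chromosome: int = 50
    spacing_bp: int = 2_000_000
    recomb_rate: float = 0.1
    # observation layer (None -> MultiomicsDesign defaults)
    design: dict = field(default_factory=dict)
    # quantification
    max_missing_fraction: float = 0.5
    # mapping / significance
    n_perm: int = 1_000
    q_target: float = 0.1
    lenient_q: float = 0.5
    local_window_bp: float = 10e6
    scan_diffs: bool = True
    # mediation
    mech1_delta_pct: float = mediation.MECH1_DELTA_PCT
    mech2_delta_pct: float = mediation.MECH2_DELTA_PCT
    strong_z: float = mediation.STRONG_Z

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        order = {s: i for i, s in enumerate(STAGES)}
        deps = {"quantify": ["simulate"], "heritability": ["quantify"],
                "sex_effects": ["quantify"], "scan": ["quantify"],
                "thresholds": ["scan"], "call": ["thresholds"],
                "mediate": ["call"], "report": []}
        enabled = set(self.stages)
        for s in sorted(enabled, key=order.get):
            for d in deps.get(s, []):
                if d not in enabled and not self._artifact_exists(d):
                    raise ValueError(f"stage '{s}' requires '{d}' (enabled or "
                                     f"already materialized in {self.outdir})")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    def _artifact_exists(self, stage: str) -> bool:
        probe = {"simulate": "markers.tsv", "quantify": "abundance_protein_avg.tsv",
                 "scan": "lods_protein_avg.tsv", "thresholds": "thresholds_protein_avg.tsv",
                 "call": "qtl_catalogue.tsv"}
        f = probe.get(stage)
        return f is not None and (Path(self.outdir) / f).exists()

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    ctx: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        log.info("stage %s", stage)
        _STAGE_FN[stage](config, out, ctx)
    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "artifacts": {p.name: io.file_checksum(p)
                      for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.json"))
                      if p.name != "manifest.json"},
        "wall_clock_s": round(time.time() - t0, 2),
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: RunConfig, out: Path, ctx: dict):
    markers, haplo = simulate.simulate_genomes(
        cfg.n_strains, cfg.n_chromosomes, cfg.markers_per_chromosome,
        cfg.spacing_bp, cfg.recomb_rate, seed=cfg.seed)
    design = simulate.MultiomicsDesign(**cfg.design)
    study = simulate.simulate_multiomics(haplo, design, seed=cfg.seed + 1)
    io.write_marker_map(markers, out / "markers.tsv")
    io.write_haplotypes(haplo, out / "haplotypes.tsv")
    io.write_metadata(study.metadata, out / "metadata.tsv")
    io.write_peptides(study.peptides, out / "peptides.tsv", out / "intensities.tsv")
    io.write_abundance(study.transcripts, out / "transcripts.tsv")
    io.write_proteomes(study.founder_proteomes, out / "founder_proteomes.fasta")
    study.transcripts.feature_meta.to_csv(out / "features_transcript.tsv", sep="\t",
                                          index_label="feature_id")
    io.write_truth(study.truth, out / "truth.tsv")
    study.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    io.write_json({"seed": cfg.seed, "simulate_seed": cfg.seed,
                   "multiomics_seed": cfg.seed + 1}, out / "seeds.json")


def _load_genomes(cfg, out):
    markers = io.read_marker_map(out / "markers.tsv")
    haplo = io.read_haplotypes(out / "haplotypes.tsv", markers)
    return markers, haplo


def _stage_quantify(cfg: RunConfig, out: Path, ctx: dict):
    table = io.read_peptides(out / "peptides.tsv", out / "intensities.tsv")
    metadata = io.read_metadata(out / "metadata.tsv")
    proteomes = io.read_proteomes(out / "founder_proteomes.fasta")
    genes = pd.read_csv(out / "genes.tsv", sep="\t")

    table, poly_report = quantify.filter_polymorphic_peptides(table, proteomes)
    table, factors = quantify.normalize_within_batch(table, metadata)
    counts = {"polymorphic_filter": poly_report}
    matrices = {}
    for kind, excl, tag in (("protein", False, "protein"),
                            ("phospho", False, "phospho"),
                            ("protein", True, "parent")):
        mat, rep = quantify.compute_relative_abundance(
            table, metadata, kind=kind, exclude_phospho_from_parents=excl)
        mat, removed = quantify.filter_missing(mat, cfg.max_missing_fraction)
        mat, _fits = quantify.batch_adjust(mat, metadata)
        counts[tag] = {"report": rep, "n_removed_missing": len(removed)}
        matrices[tag] = mat
    adj, dropped = quantify.adjust_for_parent(matrices["phospho"], matrices["parent"])
    counts["adj_phospho"] = {"n_features": adj.values.shape[1],
                             "dropped_no_parent": dropped}
    matrices["adj_phospho"] = adj
    gene_map = genes.set_index("protein_id")
    for tag, mat in matrices.items():
        avg, diff = quantify.summarize_strains(mat, metadata)
        io.write_abundance(mat, out / f"abundance_{tag}_samples.tsv")
        io.write_abundance(avg, out / f"abundance_{tag}_avg.tsv")
        io.write_abundance(diff, out / f"abundance_{tag}_diff.tsv")
        if len(mat.feature_meta):
            mat.feature_meta.to_csv(out / f"features_{tag}.tsv", sep="\t",
                                    index_label="feature_id")
    io.write_json(counts, out / "quantify_counts.json")
    io.write_json({"phi": factors.phi.to_dict()}, out / "normalization.json")


_KINDS = ("protein", "phospho", "adj_phospho")


def _load_abundance(cfg, out, tag, level):
    kind = "adj_phospho" if tag == "adj_phospho" else ("protein" if tag in ("protein", "parent") else "phospho")
    meta_path = out / f"features_{tag}.tsv"
    fmeta = pd.read_csv(meta_path, sep="\t", index_col="feature_id") if meta_path.exists() else None
    lvl = {"samples": "sample", "avg": "strain_avg", "diff": "strain_diff"}[level]
    return io.read_abundance(out / f"abundance_{tag}_{level}.tsv", lvl, kind, fmeta)


def _stage_heritability(cfg: RunConfig, out: Path, ctx: dict):
    # fit at the individual level (two mice per strain) with a sex covariate:
    # within-strain replication is what identifies the kinship variance
    markers, haplo = _load_genomes(cfg, out)
    metadata = io.read_metadata(out / "metadata.tsv")
    grm = qtl.expand_grm_to_samples(qtl.compute_grm(haplo), metadata)
    sex = metadata.samples.set_index("sample_id")["sex"]
    rows = []
    for tag in _KINDS:
        mat = _load_abundance(cfg, out, tag, "samples")
        for feat in mat.values.columns:
            y = mat.values[feat].dropna()
            if y.nunique() < 3 or len(y) < 10:
                continue
            fit = qtl.estimate_heritability(y, grm, sex_covariate=sex)
            rows.append(dict(kind=tag, feature_id=feat, h2=fit.h2,
                             tau2=fit.tau2, sigma2=fit.sigma2))
    pd.DataFrame(rows).to_csv(out / "heritability.tsv", sep="\t", index=False)


def _stage_sex_effects(cfg: RunConfig, out: Path, ctx: dict):
    markers, haplo = _load_genomes(cfg, out)
    metadata = io.read_metadata(out / "metadata.tsv")
    grm = qtl.compute_grm(haplo)
    from statsmodels.stats.multitest import multipletests
    rows = []
    for tag in _KINDS:
        mat = _load_abundance(cfg, out, tag, "samples")
        stats = {}
        for feat in mat.values.columns:
            y = mat.values[feat].dropna()
            if y.nunique() < 3:
                continue
            lr, p = qtl.test_sex_effect(mat.values[feat], grm, metadata)
            stats[feat] = (lr, p)
        if not stats:
            continue
        feats = list(stats)
        pvals = np.array([stats[f][1] for f in feats])
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for f, p, q in zip(feats, pvals, qvals):
            rows.append(dict(kind=tag, feature_id=f, lr=stats[f][0],
                             pvalue=p, qvalue=q))
    pd.DataFrame(rows).to_csv(out / "sex_effects.tsv", sep="\t", index=False)


def _scan_levels(cfg):
    return ("avg", "diff") if cfg.scan_diffs else ("avg",)


def _stage_scan(cfg: RunConfig, out: Path, ctx: dict):
    markers, haplo = _load_genomes(cfg, out)
    loco = qtl.loco_grms(haplo)
    ctx["loco"] = loco
    for tag in _KINDS:
        for level in _scan_levels(cfg):
            mat = _load_abundance(cfg, out, tag, level)
            lods = {}
            for feat in mat.values.columns:
                y = mat.values[feat]
                if y.dropna().nunique() < 3 or y.dropna().size < 10:
                    continue
                scan = qtl.scan_genome(y, haplo, loco, level=level, feature_id=feat)
                lods[feat] = scan.lod
            df = pd.DataFrame(lods, index=markers.marker_ids)
            df.to_csv(out / f"lods_{tag}_{level}.tsv", sep="\t",
                      index_label="marker_id")


def _stage_thresholds(cfg: RunConfig, out: Path, ctx: dict):
    markers, haplo = _load_genomes(cfg, out)
    loco = ctx.get("loco") or qtl.loco_grms(haplo)
    rng = np.random.default_rng(cfg.seed + 1000)
    for tag in _KINDS:
        for level in _scan_levels(cfg):
            lods = pd.read_csv(out / f"lods_{tag}_{level}.tsv", sep="\t",
                               index_col="marker_id")
            mat = _load_abundance(cfg, out, tag, level)
            pvals, fits, maxlods = {}, {}, {}
            for feat in lods.columns:
                y = mat.values[feat]
                seed = int(rng.integers(2**31 - 1))
                null = significance.permutation_null(
                    y, haplo, loco, n_perm=cfg.n_perm, seed=seed, feature_id=feat)
                fit = significance.fit_gev(null)
                fits[feat] = fit
                maxlods[feat] = float(lods[feat].max())
                pvals[feat] = significance.permutation_pvalue(fit, maxlods[feat])
            if not pvals:
                continue
            tt = significance.fdr_thresholds(pd.Series(pvals), fits,
                                             pd.Series(maxlods),
                                             q_target=cfg.q_target,
                                             lenient_q=cfg.lenient_q)
            tt.table.to_csv(out / f"thresholds_{tag}_{level}.tsv", sep="\t",
                            index=False)
            io.write_json({f: dataclasses.asdict(fits[f]) for f in fits},
                          out / f"gev_{tag}_{level}.json")


def _stage_call(cfg: RunConfig, out: Path, ctx: dict):
    markers, haplo = _load_genomes(cfg, out)
    loco = ctx.get("loco") or qtl.loco_grms(haplo)
    genes = pd.read_csv(out / "genes.tsv", sep="\t").set_index("protein_id")
    peaks = []
    for tag in _KINDS:
        for level in _scan_levels(cfg):
            path = out / f"thresholds_{tag}_{level}.tsv"
            if not path.exists():
                continue
            thr = pd.read_csv(path, sep="\t").set_index("feature_id")
            lods = pd.read_csv(out / f"lods_{tag}_{level}.tsv", sep="\t",
                               index_col="marker_id")
            mat = _load_abundance(cfg, out, tag, level)
            for feat in thr.index:
                row = thr.loc[feat]
                # call at the lenient threshold; label as stringent when the
                # FDR < q_target threshold is also cleared
                prot = (mat.feature_meta.loc[feat, "protein_id"]
                        if len(mat.feature_meta) and feat in mat.feature_meta.index
                        else feat)
                gene = genes.loc[prot] if prot in genes.index else None
                scan = qtl.ScanResult(feature_id=feat, markers=markers,
                                      lod=lods[feat].to_numpy(), level=level)
                called = qtl.call_qtl(
                    scan, row["lambda_lenient"],
                    None if gene is None else gene["gene_chromosome"],
                    None if gene is None else gene["gene_midpoint_bp"],
                    local_window_bp=cfg.local_window_bp,
                    pvalue=row["pvalue"], qvalue=row["qvalue"])
                if not called:
                    continue
                pk = called[0]
                stringency = "stringent" if row["significant"] else "lenient"
                mk = markers.index_of(pk.marker_id)
                effects = qtl.allele_effects_blup(
                    mat.values[feat], haplo, mk, loco[pk.chromosome])
                peaks.append(dict(
                    kind=tag, level=level, stringency=stringency,
                    feature_id=feat, marker_id=pk.marker_id,
                    chromosome=pk.chromosome, position_bp=pk.position_bp,
                    lod=pk.lod, pvalue=pk.pvalue, qvalue=pk.qvalue,
                    qtl_class=pk.qtl_class,
                    **{f"beta_{f}": e for f, e in
                       zip(simulate.FOUNDERS, effects)}))
    pd.DataFrame(peaks).to_csv(out / "qtl_catalogue.tsv", sep="\t", index=False)


def _stage_mediate(cfg: RunConfig, out: Path, ctx: dict):
    markers, haplo = _load_genomes(cfg, out)
    loco = ctx.get("loco") or qtl.loco_grms(haplo)
    catalogue = pd.read_csv(out / "qtl_catalogue.tsv", sep="\t")
    parent_mat = _load_abundance(cfg, out, "parent", "avg")
    phospho_mat = _load_abundance(cfg, out, "phospho", "avg")
    protein_mat = _load_abundance(cfg, out, "protein", "avg")
    tx_meta = pd.read_csv(out / "features_transcript.tsv", sep="\t",
                          index_col="feature_id")
    tx = io.read_abundance(out / "transcripts.tsv", "sample", "transcript", tx_meta)
    metadata = io.read_metadata(out / "metadata.tsv")
    tx_avg, _ = quantify.summarize_strains(tx, metadata)

    ph_peaks = catalogue[(catalogue["kind"] == "phospho")
                         & (catalogue["level"] == "avg")]
    med_rows = []
    for _, pk in ph_peaks.iterrows():
        feat = pk["feature_id"]
        parent = (phospho_mat.feature_meta.loc[feat, "protein_id"]
                  if feat in phospho_mat.feature_meta.index else None)
        if parent is None or parent not in parent_mat.values.columns:
            continue
        mk = markers.index_of(pk["marker_id"])
        res = mediation.mediate_through_parent(
            phospho_mat.values[feat], parent_mat.values[parent], mk, haplo,
            loco[pk["chromosome"]], original_lod=pk["lod"], feature_id=feat,
            parent_id=parent, marker_id=pk["marker_id"])
        med_rows.append(dict(feature_id=feat, parent_id=parent,
                             marker_id=pk["marker_id"],
                             original_lod=res.original_lod,
                             mediation_lod=res.mediation_lod,
                             delta_lod=res.delta_lod,
                             delta_lod_pct=res.delta_lod_pct,
                             mechanism=res.mechanism,
                             unreliable=res.unreliable))
    pd.DataFrame(med_rows).to_csv(out / "mediation_parent.tsv", sep="\t",
                                  index=False)

    # mediator scans for distant phQTL (stringent calls only)
    cand_vals = pd.concat([protein_mat.values, tx_avg.values], axis=1)
    kinds = (["protein"] * protein_mat.values.shape[1]
             + ["transcript"] * tx_avg.values.shape[1])
    cand_meta = pd.DataFrame({"feature_id": cand_vals.columns, "kind": kinds}
                             ).set_index("feature_id", drop=False)
    candidates = AbundanceMatrix(cand_vals, level="strain_avg", kind="protein",
                                 feature_meta=cand_meta)
    tx_parent = (tx.feature_meta["protein_id"].to_dict()
                 if len(tx.feature_meta) else {})
    distant = ph_peaks[(ph_peaks["qtl_class"] == "distant")
                       & (ph_peaks["stringency"] == "stringent")]
    scan_rows = []
    for _, pk in distant.iterrows():
        feat = pk["feature_id"]
        parent = (phospho_mat.feature_meta.loc[feat, "protein_id"]
                  if feat in phospho_mat.feature_meta.index else "")
        excl = {feat, parent}
        excl |= {t for t, p in tx_parent.items() if p == parent}
        mk = markers.index_of(pk["marker_id"])
        res = mediation.mediation_scan(
            phospho_mat.values[feat], mk, candidates, haplo,
            exclude=tuple(excl), window_bp=cfg.local_window_bp,
            target_id=feat, marker_id=pk["marker_id"])
        t = res.table.copy()
        t.insert(0, "target_id", feat)
        t.insert(1, "marker_id", pk["marker_id"])
        scan_rows.append(t)
    if scan_rows:
        pd.concat(scan_rows).to_csv(out / "mediation_scans.tsv", sep="\t",
                                    index=False)
    else:
        pd.DataFrame(columns=["target_id", "marker_id", "mediator_id",
                              "mediator_kind", "lod_med", "zscore", "strong",
                              "co_mapping"]).to_csv(out / "mediation_scans.tsv",
                                                    sep="\t", index=False)


def _stage_report(cfg: RunConfig, out: Path, ctx: dict):
    from . import report
    report.write_report(out)


_STAGE_FN = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "heritability": _stage_heritability,
    "sex_effects": _stage_sex_effects,
    "scan": _stage_scan,
    "thresholds": _stage_thresholds,
    "call": _stage_call,
    "mediate": _stage_mediate,
    "report": _stage_report,
}
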