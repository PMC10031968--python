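"""Run summary: tables, figures and (when ground truth exists) confusion
tables of detection and mechanism calls."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def write_report(outdir) -> Path:
    out = Path(outdir)
    rep = out / "report"
    rep.mkdir(exist_ok=True)
    lines = ["# phqtl run report", ""]

    cat_path = out / "qtl_catalogue.tsv"
    catalogue = pd.read_csv(cat_path, sep="\t") if cat_path.exists() else pd.DataFrame()
    if len(catalogue) == 0:
        lines += ["No QTL were called in this run.", ""]
    else:
        lines += [f"QTL called: {len(catalogue)}", "",
                  catalogue.groupby(["kind", "level", "qtl_class"]).size()
                  .rename("n").reset_index().to_string(index=False), ""]
        _qtl_map(catalogue, out, rep)
        lines.append("![QTL map](report/qtl_map.png)")

    med_path = out / "mediation_parent.tsv"
    if med_path.exists():
        med = pd.read_csv(med_path, sep="\t")
        if len(med):
            lines += ["", f"Parent-mediation results: {len(med)} phQTL",
                      med["mechanism"].value_counts().to_string(), ""]
            fig, ax = plt.subplots(figsize=(5, 4))
            ax.scatter(med["original_lod"], med["delta_lod_pct"], s=12)
            ax.axhline(-50, color="red", ls="--", lw=1)
            ax.set_xlabel("original phQTL LOD")
            ax.set_ylabel("Delta LOD (%) after parent conditioning")
            fig.tight_layout()
            fig.savefig(rep / "delta_lod.png", dpi=110)
            plt.close(fig)
            lines.append("![Delta LOD](report/delta_lod.png)")

    scans_path = out / "mediation_scans.tsv"
    if scans_path.exists():
        scans = pd.read_csv(scans_path, sep="\t")
        if len(scans):
            fig, ax = plt.subplots(figsize=(5, 4))
            for t, sub in scans.groupby("target_id"):
                ax.plot(sorted(sub["zscore"]), label=str(t), lw=1)
            ax.axhline(-8, color="red", ls="--", lw=1)
            ax.set_xlabel("candidate rank")
            ax.set_ylabel("mediation z-score")
            fig.tight_layout()
            fig.savefig(rep / "mediation_z.png", dpi=110)
            plt.close(fig)
            lines.append("![mediation z](report/mediation_z.png)")

    truth_path = out / "truth.tsv"
    if truth_path.exists() and len(catalogue):
        lines += ["", "## Comparison with planted truth", ""]
        lines += _confusion(catalogue, med_path, truth_path)

    text = "\n".join(lines) + "\n"
    (out / "report.md").write_text(text)
    return out / "report.md"


def _qtl_map(catalogue: pd.DataFrame, out: Path, rep: Path):
    genes = pd.read_csv(out / "genes.tsv", sep="\t").set_index("protein_id")
    feats_ph = out / "features_phospho.tsv"
    parent_of = {}
    if feats_ph.exists():
        parent_of = pd.read_csv(feats_ph, sep="\t", index_col="feature_id")[
            "protein_id"].to_dict()
    fig, ax = plt.subplots(figsize=(5, 5))
    colors = {"protein": "tab:blue", "phospho": "tab:orange",
              "adj_phospho": "tab:green"}
    for _, row in catalogue.iterrows():
        prot = parent_of.get(row["feature_id"], row["feature_id"])
        if prot not in genes.index:
            continue
        g = genes.loc[prot]
        if g["gene_chromosome"] != row["chromosome"]:
            continue  # simple one-chromosome projection
        ax.scatter(row["position_bp"] / 1e6, g["gene_midpoint_bp"] / 1e6,
                   c=colors.get(row["kind"], "gray"), s=14)
    ax.set_xlabel("QTL position (Mbp)")
    ax.set_ylabel("gene midpoint (Mbp)")
    fig.tight_layout()
    fig.savefig(rep / "qtl_map.png", dpi=110)
    plt.close(fig)


def _confusion(catalogue: pd.DataFrame, med_path: Path, truth_path: Path) -> list:
    truth = pd.read_csv(truth_path, sep="\t", keep_default_na=False)
    lines = []
    planted = truth[truth["effect_type"].isin(["local_pQTL", "mech1_phQTL",
                                               "mech2_phQTL"])]
    detected = set(catalogue["feature_id"])
    det = planted["feature_id"].isin(detected)
    tab = pd.crosstab(planted["effect_type"], det.rename("detected"))
    lines += ["Detection of planted QTL:", "", tab.to_string(), ""]
    if med_path.exists():
        med = pd.read_csv(med_path, sep="\t")
        merged = med.merge(truth[["feature_id", "effect_type"]], on="feature_id")
        merged = merged[merged["effect_type"].isin(["mech1_phQTL", "mech2_phQTL"])]
        if len(merged):
            tab2 = pd.crosstab(merged["effect_type"], merged["mechanism"])
            lines += ["Mechanism calls vs planted mechanism:", "",
                      tab2.to_string(), ""]
    return lines
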