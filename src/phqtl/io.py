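"""Plain-text interchange: TSV matrices, long-format haplotypes, FASTA, JSON."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import (
    FOUNDERS,
    AbundanceMatrix,
    GroundTruth,
    HaplotypeDosageMatrix,
    MarkerMap,
    PeptideIntensityTable,
    SampleMetadata,
)


def write_marker_map(markers: MarkerMap, path) -> None:
    markers.df.to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> MarkerMap:
    return MarkerMap(pd.read_csv(path, sep="\t"))


def write_haplotypes(haplo: HaplotypeDosageMatrix, path) -> None:
    """Long format: strain, marker, founder, prob (zero rows omitted)."""
    s_idx, m_idx, f_idx = np.nonzero(haplo.probs)
    df = pd.DataFrame({
        "strain": np.asarray(haplo.strains)[s_idx],
        "marker": haplo.markers.marker_ids[m_idx],
        "founder": np.asarray(FOUNDERS)[f_idx],
        "prob": haplo.probs[s_idx, m_idx, f_idx],
    })
    df.to_csv(path, sep="\t", index=False)


def read_haplotypes(path, markers: MarkerMap) -> HaplotypeDosageMatrix:
    df = pd.read_csv(path, sep="\t")
    strains = list(dict.fromkeys(df["strain"]))
    s_pos = {s: i for i, s in enumerate(strains)}
    m_pos = {m: i for i, m in enumerate(markers.marker_ids)}
    f_pos = {f: i for i, f in enumerate(FOUNDERS)}
    probs = np.zeros((len(strains), len(markers), len(FOUNDERS)))
    probs[df["strain"].map(s_pos), df["marker"].map(m_pos),
          df["founder"].map(f_pos)] = df["prob"]
    return HaplotypeDosageMatrix(strains, markers, probs)


def write_metadata(metadata: SampleMetadata, path) -> None:
    metadata.df.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t"))


def write_peptides(table: PeptideIntensityTable, info_path, intensity_path) -> None:
    table.peptides.to_csv(info_path, sep="\t", index=False)
    table.intensities.to_csv(intensity_path, sep="\t", index_label="sample_id")


def read_peptides(info_path, intensity_path) -> PeptideIntensityTable:
    pep = pd.read_csv(info_path, sep="\t")
    pep["site_label"] = pep["site_label"].fillna("")
    inten = pd.read_csv(intensity_path, sep="\t", index_col="sample_id")
    return PeptideIntensityTable(pep, inten)


def write_abundance(matrix: AbundanceMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="row_id")


def read_abundance(path, level: str, kind: str,
                   feature_meta: pd.DataFrame | None = None) -> AbundanceMatrix:
    vals = pd.read_csv(path, sep="\t", index_col="row_id")
    return AbundanceMatrix(vals, level=level, kind=kind,
                           feature_meta=feature_meta if feature_meta is not None
                           else pd.DataFrame())


def write_proteomes(proteomes: dict, path) -> None:
    """One FASTA with ids ``<founder>|<protein_id>``."""
    records = [SeqRecord(Seq(seq), id=f"{founder}|{pid}", description="")
               for founder, prots in proteomes.items()
               for pid, seq in sorted(prots.items())]
    SeqIO.write(records, str(path), "fasta")


def read_proteomes(path) -> dict:
    proteomes: dict = {f: {} for f in FOUNDERS}
    for rec in SeqIO.parse(str(path), "fasta"):
        founder, pid = rec.id.split("|", 1)
        proteomes.setdefault(founder, {})[pid] = str(rec.seq)
    return proteomes


def write_truth(truth: GroundTruth, path) -> None:
    truth.table.to_csv(path, sep="\t", index=False)


def read_truth(path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"causal_marker": str, "mediator_id": str, "parent_id": str})
    df["pve"] = pd.to_numeric(df["pve"])
    df["h2"] = pd.to_numeric(df["h2"])
    df["sex_effect"] = pd.to_numeric(df["sex_effect"])
    df["gene_midpoint_bp"] = pd.to_numeric(df["gene_midpoint_bp"])
    return GroundTruth(df)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default))


def _default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
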