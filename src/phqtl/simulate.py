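"""Synthetic Collaborative-Cross-like study generator.

Generates founder-mosaic homozygous genomes and a multi-omics observation
layer (peptide-level TMT intensities, transcripts, sample metadata, founder
proteomes) with planted, recoverable effects:

* local pQTL: founder allele effects at a marker near the protein's gene;
* mechanism-1 phQTL: a phosphopeptide that tracks its parent protein's
  abundance, so the genetic signal is inherited from the parent;
* mechanism-2 phQTL: a phosphopeptide driven by the abundance of a distant
  mediator protein (e.g. a kinase) rather than its own parent;
* sex effects either on the parent protein (the phospho signal disappears
  after parent adjustment) or directly on the phosphosite (it survives);
* peptide-level multiplicative noise, TMT batch structure with a bridge
  channel, missing-at-random cells, and polymorphic peptides whose sequence
  differs in at least one founder proteome.

Latent strain traits are built on a unit-variance log2 scale with explicit
variance shares, so planted PVE and heritability are directly recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import (
    FOUNDERS,
    GroundTruth,
    HaplotypeDosageMatrix,
    MarkerMap,
    PeptideIntensityTable,
    AbundanceMatrix,
    SampleMetadata,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------


def simulate_genomes(n_strains: int, n_chromosomes: int = 2,
                     markers_per_chromosome: int = 50,
                     spacing_bp: int = 2_000_000, recomb_rate: float = 0.1,
                     seed: int = 0) -> tuple[MarkerMap, HaplotypeDosageMatrix]:
    """Homozygous founder-mosaic genomes via marker-level Markov switching.

    Along each chromosome every strain follows a first-order Markov chain over
    the eight founders: uniform start, switching with probability
    ``recomb_rate`` per marker step to a uniformly chosen *other* founder.
    Probabilities are hard 0/1 (inbred strains are homozygous); see
    :func:`blur_probabilities` for a soft variant.
    """
    if n_strains < 2:
        raise ValueError("need at least 2 strains")
    if n_chromosomes < 1 or markers_per_chromosome < 1:
        raise ValueError("empty marker map")
    if not 0 <= recomb_rate < 1:
        raise ValueError("recomb_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_chromosomes):
        chrom = f"chr{c + 1}"
        for m in range(markers_per_chromosome):
            rows.append(dict(marker_id=f"{chrom}_m{m + 1:04d}", chromosome=chrom,
                             position_bp=(m + 1) * spacing_bp))
    markers = MarkerMap(pd.DataFrame(rows))
    n_markers = len(markers)
    probs = np.zeros((n_strains, n_markers, len(FOUNDERS)))
    strains = [f"CC{i + 1:03d}" for i in range(n_strains)]
    for i in range(n_strains):
        for c in range(n_chromosomes):
            cidx = markers.chrom_indices(f"chr{c + 1}")
            state = rng.integers(len(FOUNDERS))
            for p in cidx:
                if p != cidx[0] and rng.random() < recomb_rate:
                    state = (state + 1 + rng.integers(len(FOUNDERS) - 1)) % len(FOUNDERS)
                probs[i, p, state] = 1.0
    return markers, HaplotypeDosageMatrix(strains, markers, probs)


def blur_probabilities(haplo: HaplotypeDosageMatrix, noise: float,
                       seed: int = 0) -> HaplotypeDosageMatrix:
    """Add symmetric probability noise (robustness testing of soft dosages)."""
    rng = np.random.default_rng(seed)
    p = haplo.probs + noise * rng.random(haplo.probs.shape)
    p /= p.sum(axis=2, keepdims=True)
    return HaplotypeDosageMatrix(list(haplo.strains), haplo.markers, p)


# ---------------------------------------------------------------------------
# strain-level latent traits
# ---------------------------------------------------------------------------


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def marker_genetic_values(haplo: HaplotypeDosageMatrix, marker_index: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Unit-variance genetic values from random founder allele effects."""
    beta = rng.normal(size=len(FOUNDERS))
    g = haplo.dosages(marker_index) @ beta
    if g.std() == 0:  # monomorphic marker in this panel: redraw effects once
        beta = rng.normal(size=len(FOUNDERS))
        g = haplo.dosages(marker_index) @ beta
    return _standardize(g)


def polygenic_values(grm_matrix: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance draw from N(0, G)."""
    s, U = np.linalg.eigh(grm_matrix)
    s = np.clip(s, 0.0, None)
    c = U @ (np.sqrt(s) * rng.normal(size=len(s)))
    return _standardize(c)


def simulate_strain_trait(haplo: HaplotypeDosageMatrix, causal_marker: Optional[int] = None,
                          pve: float = 0.0, h2_polygenic: float = 0.0,
                          grm_matrix: Optional[np.ndarray] = None,
                          seed: int = 0) -> pd.Series:
    """One strain-level trait with the stated variance shares (unit total).

    Convenience for mapping-layer studies that do not need the peptide layer.
    """
    if not 0 <= pve < 1 or not 0 <= h2_polygenic < 1 or pve + h2_polygenic >= 1:
        raise ValueError("variance shares must lie in [0, 1) and sum below 1")
    rng = np.random.default_rng(seed)
    n = haplo.n_strains
    y = np.zeros(n)
    if pve > 0:
        if causal_marker is None:
            raise ValueError("pve > 0 requires a causal marker")
        y += np.sqrt(pve) * marker_genetic_values(haplo, causal_marker, rng)
    if h2_polygenic > 0:
        if grm_matrix is None:
            from .qtl import compute_grm
            grm_matrix = compute_grm(haplo).matrix
        y += np.sqrt(h2_polygenic) * polygenic_values(grm_matrix, rng)
    resid = 1.0 - pve - h2_polygenic
    y += np.sqrt(resid) * rng.normal(size=n)
    return pd.Series(y, index=list(haplo.strains))


# ---------------------------------------------------------------------------
# multi-omics design
# ---------------------------------------------------------------------------


@dataclass
class MultiomicsDesign:
    """Planted-effect and noise specification for the observation layer.

    Defaults emulate the study conditions: ~one hundred proteins, local pQTL
    with moderate effect sizes, a polygenic background, mechanism-1 and
    mechanism-2 phosphosites, sex effects of both kinds, 11-plex TMT batches
    (10 samples + 1 bridge), lognormal peptide noise and 10% missing cells.
    """

    n_proteins: int = 100
    n_local_pqtl: int = 25
    pqtl_pve: float = 0.4
    mediator_pve: float = 0.7          # local-pQTL PVE of mechanism-2 mediators
    h2_polygenic: float = 0.15
    n_mech1: int = 8
    n_mech2: int = 8
    n_sex_protein: int = 5             # sex effect on the parent protein
    n_sex_phospho: int = 5             # sex effect on the phosphosite itself
    sex_effect: float = 1.0            # male - female shift in latent SD units
    mech1_slope: float = 1.0
    mech2_slope: float = 1.0
    mech2_parent_coupling: float = 0.2
    site_noise_sd: float = 0.2         # log2 latent noise on phosphosites
    peptide_noise_sd: float = 0.25     # ln-scale multiplicative peptide noise
    transcript_noise_sd: float = 0.3
    peptides_per_protein: tuple[int, int] = (3, 6)
    batch_size: int = 10               # non-bridge samples per TMT batch
    batch_effect_sd: float = 0.3       # residual per-batch-per-protein artifact (log2)
    sample_loading_sd: float = 0.2     # ln-scale per-sample loading variation
    missing_rate: float = 0.1
    polymorphic_fraction: float = 0.044
    n_single_peptide_phospho_parents: int = 2

    def validate(self):
        for name in ("pqtl_pve", "mediator_pve", "h2_polygenic"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.pqtl_pve + self.h2_polygenic >= 1 or self.mediator_pve + self.h2_polygenic >= 1:
            raise ValueError("variance shares must sum below 1")
        if self.n_mech2 > self.n_local_pqtl:
            raise ValueError("each mech2 mediator needs its own local pQTL: "
                             "n_mech2 must not exceed n_local_pqtl")
        n_special = (self.n_local_pqtl + self.n_mech1 + self.n_mech2
                     + self.n_sex_protein + self.n_sex_phospho
                     + self.n_single_peptide_phospho_parents)
        if n_special > self.n_proteins:
            raise ValueError("more planted effects than proteins")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SimulatedStudy:
    """Bundle of everything :func:`simulate_multiomics` produces."""

    peptides: PeptideIntensityTable
    transcripts: AbundanceMatrix
    metadata: SampleMetadata
    truth: GroundTruth
    founder_proteomes: dict            # founder -> {protein_id: sequence}
    genes: pd.DataFrame                # protein_id, gene_chromosome, gene_midpoint_bp
    latents: pd.DataFrame = field(default_factory=pd.DataFrame)  # diagnostics


def simulate_multiomics(haplo: HaplotypeDosageMatrix, design: MultiomicsDesign,
                        seed: int = 0) -> SimulatedStudy:
    """Simulate the observation layer on top of a set of genomes."""
    design.validate()
    rng = np.random.default_rng(seed)
    markers = haplo.markers
    strains = list(haplo.strains)
    n_strains = len(strains)
    from .qtl import compute_grm
    G = compute_grm(haplo).matrix

    # ----- samples: one female + one male per strain, batched with bridges
    order = rng.permutation(n_strains * 2)
    sample_rows = []
    for k, flat in enumerate(order):
        i, sx = divmod(flat, 2)
        sample_rows.append(dict(sample_id=f"{strains[i]}_{'FM'[sx]}", strain=strains[i],
                                sex="FM"[sx], batch=f"batch{k // design.batch_size + 1}",
                                is_bridge=False))
    batches = sorted({r["batch"] for r in sample_rows}, key=lambda b: int(b[5:]))
    for b in batches:
        sample_rows.append(dict(sample_id=f"bridge_{b}", strain="bridge", sex="B",
                                batch=b, is_bridge=True))
    metadata = SampleMetadata(pd.DataFrame(sample_rows))
    samples = metadata.samples.reset_index(drop=True)
    n_samples = len(samples)
    strain_of = samples["strain"].to_numpy()
    strain_idx = np.array([strains.index(s) for s in strain_of])
    is_male = (samples["sex"] == "M").to_numpy()

    # ----- assign planted roles to proteins
    prot_ids = [f"P{j + 1:04d}" for j in range(design.n_proteins)]
    pool = list(rng.permutation(design.n_proteins))
    local_idx = [pool.pop() for _ in range(design.n_local_pqtl)]
    mediator_idx = local_idx[:design.n_mech2]
    mech1_parent_idx = [pool.pop() for _ in range(design.n_mech1)]
    mech2_parent_idx = [pool.pop() for _ in range(design.n_mech2)]
    sex_prot_idx = [pool.pop() for _ in range(design.n_sex_protein)]
    sex_ph_parent_idx = [pool.pop() for _ in range(design.n_sex_phospho)]
    single_pep_idx = [pool.pop() for _ in range(design.n_single_peptide_phospho_parents)]

    # ----- gene positions and causal markers
    n_markers = len(markers)
    gene_chrom = [None] * design.n_proteins
    gene_mid = np.zeros(design.n_proteins)
    causal = np.full(design.n_proteins, -1)
    mdf = markers.df
    for j in range(design.n_proteins):
        p = int(rng.integers(n_markers))
        gene_chrom[j] = mdf["chromosome"].iloc[p]
        gene_mid[j] = mdf["position_bp"].iloc[p] + rng.integers(-500_000, 500_000)
    for j in local_idx:
        causal[j] = markers.index_of(
            _nearest_marker(mdf, gene_chrom[j], gene_mid[j]))
    # mech2 targets: place the gene away from the mediator's marker so the
    # phQTL inherited from the mediator is distant
    for t, j in zip(mech2_parent_idx, mediator_idx):
        med_chrom = mdf["chromosome"].iloc[causal[j]]
        other = [c for c in markers.chromosomes if c != med_chrom]
        chrom = other[int(rng.integers(len(other)))] if other else med_chrom
        cpos = mdf[mdf["chromosome"] == chrom]["position_bp"]
        gene_chrom[t] = chrom
        gene_mid[t] = float(cpos.iloc[int(rng.integers(len(cpos)))])

    # ----- strain-level latent proteins (log2, ~unit variance)
    sex_size = np.zeros(design.n_proteins)
    for j in sex_prot_idx:
        sex_size[j] = design.sex_effect
    pve = np.zeros(design.n_proteins)
    for j in local_idx:
        pve[j] = design.mediator_pve if j in mediator_idx else design.pqtl_pve
    latent_strain = np.zeros((n_strains, design.n_proteins))
    for j in range(design.n_proteins):
        g = (np.sqrt(pve[j]) * marker_genetic_values(haplo, causal[j], rng)
             if pve[j] > 0 else 0.0)
        c = np.sqrt(design.h2_polygenic) * polygenic_values(G, rng)
        latent_strain[:, j] = g + c

    resid_share = 1.0 - pve - design.h2_polygenic
    # residual noise at sample level, scaled so strain averages carry the
    # intended residual share (averaging two samples halves the variance)
    prot_sample = (latent_strain[strain_idx, :]
                   + np.where(is_male[:, None], 0.5, -0.5) * sex_size[None, :]
                   + rng.normal(size=(n_samples, design.n_proteins))
                   * np.sqrt(2.0 * resid_share)[None, :])

    # ----- phosphosites
    ph_rows = []       # (phospho_id, parent_idx, effect_type, mediator_idx or None)
    for j in mech1_parent_idx:
        ph_rows.append((j, "mech1_phQTL", None))
    for t, j in zip(mech2_parent_idx, mediator_idx):
        ph_rows.append((t, "mech2_phQTL", j))
    for j in sex_prot_idx:
        ph_rows.append((j, "sex_on_parent", None))
    for j in sex_ph_parent_idx:
        ph_rows.append((j, "sex_effect", None))
    for j in single_pep_idx:
        ph_rows.append((j, "single_peptide_parent", None))
    ph_meta = []
    ph_sample = np.zeros((n_samples, len(ph_rows)))
    for k, (j, etype, med) in enumerate(ph_rows):
        noise = rng.normal(size=n_samples) * design.site_noise_sd
        if etype == "mech2_phQTL":
            x = (design.mech2_slope * prot_sample[:, med]
                 + design.mech2_parent_coupling * prot_sample[:, j] + noise)
        else:
            x = design.mech1_slope * prot_sample[:, j] + noise
        if etype == "sex_effect":
            x = x + np.where(is_male, 0.5, -0.5) * design.sex_effect
        site_pos = int(rng.integers(20, 200))
        pid = f"{prot_ids[j]}_pS{site_pos}"
        ph_sample[:, k] = x
        ph_meta.append(dict(phospho_id=pid, parent=j, effect_type=etype,
                            mediator=med, site_label=f"pS{site_pos}"))

    # ----- transcripts (log-like scale, provided directly)
    tx_ids = [f"T{j + 1:04d}" for j in range(design.n_proteins)]
    tx_sample = prot_sample + rng.normal(size=prot_sample.shape) * design.transcript_noise_sd
    transcripts = AbundanceMatrix(
        pd.DataFrame(tx_sample, index=list(samples["sample_id"]), columns=tx_ids),
        level="sample", kind="transcript",
        feature_meta=pd.DataFrame({"feature_id": tx_ids, "protein_id": prot_ids,
                                   "gene_chromosome": gene_chrom,
                                   "gene_midpoint_bp": gene_mid}).set_index("feature_id"))

    # ----- peptides, founder proteomes, intensities
    pep_table, proteomes, intensities = _peptide_layer(
        design, rng, prot_ids, prot_sample, ph_meta, ph_sample, samples, metadata)

    genes = pd.DataFrame({"protein_id": prot_ids, "gene_chromosome": gene_chrom,
                          "gene_midpoint_bp": gene_mid})

    truth_rows = []
    for j, pid in enumerate(prot_ids):
        etype = "local_pQTL" if j in local_idx else (
            "sex_effect" if j in sex_prot_idx else "none")
        truth_rows.append(dict(
            feature_id=pid, kind="protein", effect_type=etype,
            causal_marker=mdf["marker_id"].iloc[causal[j]] if causal[j] >= 0 else "",
            mediator_id="", pve=pve[j], h2=pve[j] + design.h2_polygenic,
            sex_effect=sex_size[j], parent_id="", gene_chromosome=gene_chrom[j],
            gene_midpoint_bp=gene_mid[j]))
    for k, m in enumerate(ph_meta):
        j = m["parent"]
        med = m["mediator"]
        etype = m["effect_type"]
        if etype == "sex_on_parent":   # inherits the parent's sex effect only
            etype_out, sex_sz = "sex_effect_via_parent", sex_size[j]
        elif etype == "sex_effect":
            etype_out, sex_sz = "sex_effect", design.sex_effect
        elif etype == "single_peptide_parent":
            etype_out, sex_sz = "none", 0.0
        else:
            etype_out, sex_sz = etype, 0.0
        cm = causal[med] if med is not None else causal[j]
        truth_rows.append(dict(
            feature_id=m["phospho_id"], kind="phospho", effect_type=etype_out,
            causal_marker=mdf["marker_id"].iloc[cm] if cm >= 0 else "",
            mediator_id=prot_ids[med] if med is not None else "",
            pve=pve[med] if med is not None else pve[j],
            h2=design.h2_polygenic, sex_effect=sex_sz, parent_id=prot_ids[j],
            gene_chromosome=gene_chrom[j], gene_midpoint_bp=gene_mid[j]))
    truth = GroundTruth(pd.DataFrame(truth_rows))

    latents = pd.DataFrame(
        np.column_stack([prot_sample, ph_sample]),
        index=list(samples["sample_id"]),
        columns=prot_ids + [m["phospho_id"] for m in ph_meta])

    return SimulatedStudy(peptides=pep_table, transcripts=transcripts,
                          metadata=metadata, truth=truth,
                          founder_proteomes=proteomes, genes=genes, latents=latents)


def _nearest_marker(mdf: pd.DataFrame, chrom, pos: float) -> str:
    sub = mdf[mdf["chromosome"] == chrom]
    k = (sub["position_bp"] - pos).abs().idxmin()
    return str(sub.loc[k, "marker_id"])


def _random_peptide_windows(seq_len: int, k: int, rng) -> list[tuple[int, int]]:
    """k non-overlapping body windows inside a sequence, flank-compatible."""
    windows = []
    pos = 4
    for _ in range(k):
        body = int(rng.integers(8, 15))
        if pos + body + 4 > seq_len:
            break
        windows.append((pos, pos + body))
        pos += body + int(rng.integers(4, 9))
    return windows


def _peptide_layer(design, rng, prot_ids, prot_sample, ph_meta, ph_sample,
                   samples, metadata):
    """Expand latent abundances into peptide intensities + founder proteomes."""
    n_samples = len(samples)
    pep_rows, prot_seqs = [], {}
    windows_of = {}
    for j, pid in enumerate(prot_ids):
        k = int(rng.integers(design.peptides_per_protein[0],
                             design.peptides_per_protein[1] + 1))
        seq_len = 40 + 24 * k
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=seq_len))
        prot_seqs[pid] = seq
        windows_of[pid] = _random_peptide_windows(seq_len, k, rng)
    # a few parents whose only peptide carries the phosphosite (these proteins
    # cannot be quantified once phospho-matching peptides are excluded)
    for m in ph_meta:
        if m["effect_type"] == "single_peptide_parent":
            pid = prot_ids[m["parent"]]
            windows_of[pid] = windows_of[pid][:1]

    def flanked(pid, a, b):
        s = prot_seqs[pid]
        return f"{s[max(a - 3, 0):a]}.{s[a:b]}.{s[b:b + 3]}"

    for j, pid in enumerate(prot_ids):
        for w, (a, b) in enumerate(windows_of[pid]):
            pep_rows.append(dict(peptide_id=f"{pid}_pep{w + 1}", protein_id=pid,
                                 is_phospho=False, site_label="",
                                 sequence_with_flanks=flanked(pid, a, b),
                                 latent_col=j, window=(a, b)))
    for k, m in enumerate(ph_meta):
        pid = prot_ids[m["parent"]]
        a, b = windows_of[pid][0]   # phosphosite sits on the first peptide window
        pep_rows.append(dict(peptide_id=m["phospho_id"], protein_id=pid,
                             is_phospho=True, site_label=m["site_label"],
                             sequence_with_flanks=flanked(pid, a, b),
                             latent_col=len(prot_ids) + k, window=(a, b)))
    pep_df = pd.DataFrame(pep_rows)

    # founder proteomes with injected variants for polymorphic peptides
    proteomes = {f: dict(prot_seqs) for f in FOUNDERS}
    n_poly = int(round(design.polymorphic_fraction * len(pep_df)))
    poly_rows = rng.choice(len(pep_df), size=n_poly, replace=False) if n_poly else []
    polymorphic = np.zeros(len(pep_df), dtype=bool)
    for r in poly_rows:
        row = pep_df.iloc[r]
        a, b = row["window"]
        # substitute one residue in the body, or in the 3-aa flank for some
        # phosphopeptides, in 1-4 founders
        if row["is_phospho"] and rng.random() < 0.5:
            pos = a - 2 if a >= 2 else b + 1
        else:
            pos = int(rng.integers(a, b))
        if pos >= len(prot_seqs[row["protein_id"]]):
            pos = a
        for f in rng.choice(FOUNDERS, size=int(rng.integers(1, 5)), replace=False):
            s = proteomes[f][row["protein_id"]]
            old = s[pos]
            new = AMINO_ACIDS[(AMINO_ACIDS.index(old) + 1) % len(AMINO_ACIDS)]
            proteomes[f][row["protein_id"]] = s[:pos] + new + s[pos + 1:]
        polymorphic[r] = True
    pep_df["is_polymorphic_truth"] = polymorphic

    # intensities: exponentiate latents, split across peptides, add noise
    latents = np.column_stack([prot_sample, ph_sample])  # (n_samples, cols)
    base = rng.uniform(14, 20, size=len(pep_df))         # dynamic range per peptide
    eff = rng.lognormal(0.0, 0.5, size=len(pep_df))
    batch_of_sample = samples["batch"].to_numpy()
    batches = sorted(set(batch_of_sample), key=lambda b: int(b[5:]))
    prot_col = pep_df["latent_col"].to_numpy()
    batch_eff = {b: rng.normal(0.0, design.batch_effect_sd, size=latents.shape[1])
                 for b in batches}
    loading = rng.lognormal(0.0, design.sample_loading_sd, size=n_samples)
    inten = np.empty((n_samples, len(pep_df)))
    for i in range(n_samples):
        lat = latents[i, prot_col] + batch_eff[batch_of_sample[i]][prot_col]
        noise = rng.normal(0.0, design.peptide_noise_sd, size=len(pep_df))
        inten[i] = np.exp2(lat + base) * eff * np.exp(noise) * loading[i]
    if design.missing_rate > 0:
        mask = rng.random(inten.shape) < design.missing_rate
        inten[mask] = np.nan

    # bridge channel: per-batch mean of the non-bridge samples (pooled digest)
    bridge_rows, bridge_ids = [], []
    for b in batches:
        rows = np.flatnonzero(batch_of_sample == b)
        with np.errstate(invalid="ignore"):
            bridge_rows.append(np.nanmean(inten[rows], axis=0))
        bridge_ids.append(metadata.bridge_of(b))
    all_ids = list(samples["sample_id"]) + bridge_ids
    inten_df = pd.DataFrame(np.vstack([inten] + [np.array(bridge_rows)]),
                            index=all_ids, columns=list(pep_df["peptide_id"]))

    pep_out = pep_df.drop(columns=["latent_col", "window"])
    return PeptideIntensityTable(pep_out, inten_df), proteomes, inten_df
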