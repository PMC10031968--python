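"""Core data containers shared across the pipeline.

Conventions
-----------
* Founders are ordered ``AJ, B6, 129, NOD, NZO, CAST, PWK, WSB`` (the eight
  Collaborative Cross founder strains); haplotype dosages are stored as a
  ``(n_strains, n_markers, 8)`` array of probabilities.
* Abundance matrices are pandas DataFrames with observations (samples or
  strains) on the rows and molecular features on the columns; missing
  measurements are ``NaN``.
* Genomic positions are 1-based base pairs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

FOUNDERS: tuple[str, ...] = ("AJ", "B6", "129", "NOD", "NZO", "CAST", "PWK", "WSB")
N_FOUNDERS = len(FOUNDERS)


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------


class MarkerMap:
    """Ordered genotyping marker map.

    Parameters
    ----------
    df : DataFrame with columns ``marker_id``, ``chromosome``, ``position_bp``.
        Markers must be unique and positions strictly increasing within each
        chromosome.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"marker_id", "chromosome", "position_bp"}
        if not required.issubset(df.columns):
            raise ValueError(f"marker map needs columns {sorted(required)}")
        df = df.reset_index(drop=True)
        if df["marker_id"].duplicated().any():
            raise ValueError("marker_ids must be unique")
        for chrom, sub in df.groupby("chromosome", sort=False):
            pos = sub["position_bp"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.df["marker_id"].to_numpy()

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.df["chromosome"]))

    def chrom_indices(self, chromosome) -> np.ndarray:
        """Positional indices of the markers on one chromosome."""
        return np.flatnonzero((self.df["chromosome"] == chromosome).to_numpy())

    def index_of(self, marker_id: str) -> int:
        hits = np.flatnonzero(self.df["marker_id"].to_numpy() == marker_id)
        if len(hits) == 0:
            raise KeyError(marker_id)
        return int(hits[0])


@dataclass
class HaplotypeDosageMatrix:
    """Founder-haplotype probabilities for each strain at each marker.

    ``probs[i, p]`` is the 8-vector of founder-origin probabilities for strain
    ``i`` at marker ``p`` (the regression design of the QTL model).  For
    homozygous inbred strains the vectors are unit basis vectors.
    """

    strains: list[str]
    markers: MarkerMap
    probs: np.ndarray  # (n_strains, n_markers, 8)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        n_s, n_m, n_f = self.probs.shape
        if n_s != len(self.strains) or n_m != len(self.markers) or n_f != N_FOUNDERS:
            raise ValueError("probs shape inconsistent with strains/markers")
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("founder probabilities must sum to 1 at each marker")

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def is_hard(self) -> bool:
        """True when every probability is exactly 0 or 1."""
        return bool(np.all((self.probs == 0) | (self.probs == 1)))

    def founder_labels(self) -> np.ndarray:
        """(n_markers, n_strains) int8 array of most-probable founder."""
        return self.probs.argmax(axis=2).T.astype(np.int8)

    def dosages(self, marker_index: int) -> np.ndarray:
        """(n_strains, 8) dosage matrix at one marker."""
        return self.probs[:, marker_index, :]

    def strain_index(self, strains: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.strains)}
        return np.array([lookup[s] for s in strains], dtype=int)


class SampleMetadata:
    """Sample sheet: one row per sample with strain, sex, TMT batch, bridge flag."""

    def __init__(self, df: pd.DataFrame):
        required = {"sample_id", "strain", "sex", "batch", "is_bridge"}
        if not required.issubset(df.columns):
            raise ValueError(f"metadata needs columns {sorted(required)}")
        df = df.reset_index(drop=True)
        if df["sample_id"].duplicated().any():
            raise ValueError("sample_ids must be unique")
        bad_sex = set(df.loc[~df["is_bridge"], "sex"]) - {"F", "M"}
        if bad_sex:
            raise ValueError(f"sex must be F or M, got {bad_sex}")
        bridge_counts = df.groupby("batch")["is_bridge"].sum()
        if not (bridge_counts == 1).all():
            raise ValueError("each batch must contain exactly one bridge sample")
        dup = df[~df["is_bridge"]].duplicated(subset=["strain", "sex"])
        if dup.any():
            raise ValueError("at most one sample per strain and sex")
        self.df = df

    @property
    def samples(self) -> pd.DataFrame:
        """Non-bridge samples."""
        return self.df[~self.df["is_bridge"]]

    def bridge_of(self, batch) -> str:
        sub = self.df[(self.df["batch"] == batch) & self.df["is_bridge"]]
        return sub["sample_id"].iloc[0]


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------


@dataclass
class PeptideIntensityTable:
    """Raw or scaled peptide-level intensities.

    ``peptides`` has one row per peptide: ``peptide_id``, ``protein_id``,
    ``is_phospho``, ``site_label`` and ``sequence_with_flanks`` in the
    proteomics ``LLL.BODY.RRR`` convention (three flanking residues either
    side, dot-separated).  ``intensities`` is samples x peptides with NaN for
    unobserved cells.
    """

    peptides: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self):
        required = {"peptide_id", "protein_id", "is_phospho", "site_label", "sequence_with_flanks"}
        if not required.issubset(self.peptides.columns):
            raise ValueError(f"peptide table needs columns {sorted(required)}")
        if list(self.intensities.columns) != list(self.peptides["peptide_id"]):
            raise ValueError("intensity columns must match peptide table order")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("intensities must be non-negative")
        ph = self.peptides["is_phospho"].astype(bool)
        if (ph & (self.peptides["site_label"].fillna("") == "")).any():
            raise ValueError("every phosphopeptide needs a site_label")

    def subset(self, keep: Sequence[str]) -> "PeptideIntensityTable":
        keep = list(keep)
        pep = self.peptides[self.peptides["peptide_id"].isin(keep)].reset_index(drop=True)
        return PeptideIntensityTable(pep, self.intensities[list(pep["peptide_id"])])

    @staticmethod
    def split_sequence(seq: str) -> tuple[str, str, str]:
        """Split ``LLL.BODY.RRR`` into (left flank, body, right flank)."""
        left, body, right = seq.split(".")
        return left, body, right


@dataclass
class NormalizationFactors:
    """Per-sample loading scale factors within TMT batch."""

    phi: pd.Series  # per sample, >= 1
    batch_max_total: pd.Series  # per batch


@dataclass
class AbundanceMatrix:
    """Log2, bridge-relative feature abundances.

    ``values``: rows are samples (level="sample") or strains
    (level="strain_avg"/"strain_diff"), columns are features.
    ``feature_meta`` carries per-feature annotation (protein_id for
    phosphopeptides, gene coordinates when known).
    """

    values: pd.DataFrame
    level: str  # sample | strain_avg | strain_diff
    kind: str  # protein | phospho | adj_phospho | transcript
    feature_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    batch_adjusted: bool = False
    parent_adjusted: bool = False

    def __post_init__(self):
        if self.level not in {"sample", "strain_avg", "strain_diff"}:
            raise ValueError(f"bad level {self.level!r}")
        if self.kind not in {"protein", "phospho", "adj_phospho", "transcript"}:
            raise ValueError(f"bad kind {self.kind!r}")

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def feature(self, feature_id: str) -> pd.Series:
        return self.values[feature_id]

    def copy_with(self, values: pd.DataFrame, **updates) -> "AbundanceMatrix":
        kwargs = dict(
            level=self.level,
            kind=self.kind,
            feature_meta=self.feature_meta,
            batch_adjusted=self.batch_adjusted,
            parent_adjusted=self.parent_adjusted,
        )
        kwargs.update(updates)
        return AbundanceMatrix(values, **kwargs)


@dataclass
class BatchModelFit:
    """Per-feature mixed-model fit of the TMT-batch adjustment."""

    feature_id: str
    intercept: float
    sex_effect: float
    strain_var: float
    batch_var: float
    resid_var: float
    batch_effects: dict  # batch id -> predicted (BLUP) effect


# ---------------------------------------------------------------------------
# QTL mapping
# ---------------------------------------------------------------------------


@dataclass
class GenomicRelationshipMatrix:
    """Realized genomic relationship (kinship) between strains."""

    strains: list[str]
    matrix: np.ndarray
    excluded_chromosome: Optional[str] = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.strains)
        if self.matrix.shape != (n, n):
            raise ValueError("GRM must be square over strains")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")

    def subset(self, idx: np.ndarray) -> np.ndarray:
        return self.matrix[np.ix_(idx, idx)]


@dataclass
class HeritabilityFit:
    tau2: float
    sigma2: float
    h2: float
    loglik: float


@dataclass
class ScanResult:
    """Per-marker LOD curve for one feature."""

    feature_id: str
    markers: MarkerMap
    lod: np.ndarray
    level: str = "avg"  # avg | diff
    covariate: Optional[str] = None  # e.g. parent protein id

    def __post_init__(self):
        if len(self.lod) != len(self.markers):
            raise ValueError("LOD length must equal marker count")

    def max_lod(self) -> float:
        return float(np.nanmax(self.lod))

    def peak_index(self) -> int:
        # ties broken by lowest genomic coordinate (markers are in genome order)
        return int(np.nanargmax(self.lod))


@dataclass
class QtlPeak:
    feature_id: str
    marker_id: str
    chromosome: str
    position_bp: int
    lod: float
    pvalue: Optional[float] = None
    qvalue: Optional[float] = None
    qtl_class: str = "unknown"  # local | distant | unknown
    allele_effects: Optional[np.ndarray] = None
    sex_interactive: bool = False


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------


@dataclass
class PermutationNull:
    feature_id: str
    n_perm: int
    max_lods: np.ndarray
    seed: Optional[int] = None

    def __post_init__(self):
        self.max_lods = np.asarray(self.max_lods, dtype=float)
        if len(self.max_lods) != self.n_perm:
            raise ValueError("max_lods length must equal n_perm")


@dataclass
class GevFit:
    """Generalized extreme value fit to permutation maximum LOD scores.

    ``shape`` follows the xi convention (scipy's ``c`` equals ``-shape``).
    """

    feature_id: str
    location: float
    scale: float
    shape: float
    n_perm: int = 0

    def __post_init__(self):
        if not self.scale > 0:
            raise ValueError("GEV scale must be positive")

    def _dist(self):
        from scipy.stats import genextreme

        return genextreme(c=-self.shape, loc=self.location, scale=self.scale)

    def cdf(self, x):
        return self._dist().cdf(x)

    def ppf(self, q):
        return self._dist().ppf(q)


@dataclass
class ThresholdTable:
    """Per-feature permutation p-values, BH q-values and LOD thresholds."""

    table: pd.DataFrame  # feature_id, max_lod, pvalue, qvalue, lambda_fdr, lambda_lenient, significant, lenient
    q_target: float
    lenient_q: float
    p_interp: float
    p_interp_lenient: float
    attained: bool  # False when no feature reaches q_target


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------


@dataclass
class ParentMediationResult:
    phospho_id: str
    parent_id: str
    marker_id: str
    original_lod: float
    mediation_lod: float
    mechanism: str  # mech1 | mech2 | mixed
    unreliable: bool = False

    @property
    def delta_lod(self) -> float:
        return self.mediation_lod - self.original_lod

    @property
    def delta_lod_pct(self) -> float:
        return 100.0 * self.delta_lod / self.original_lod


@dataclass
class MediationScanResult:
    target_id: str
    marker_id: str
    table: pd.DataFrame  # mediator_id, mediator_kind, lod_med, zscore, strong, co_mapping

    def strongest(self) -> pd.Series:
        return self.table.loc[self.table["zscore"].idxmin()]


@dataclass
class PveResult:
    response_id: str
    predictor_id: str
    pve: float
    pvalue: float


@dataclass
class GroundTruth:
    """Planted-effect records emitted by the simulator."""

    table: pd.DataFrame

    def __post_init__(self):
        required = {"feature_id", "kind", "effect_type", "causal_marker", "mediator_id",
                    "pve", "h2", "sex_effect", "parent_id", "gene_chromosome", "gene_midpoint_bp"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"ground truth missing columns {sorted(missing)}")
        mech2 = self.table[self.table["effect_type"] == "mech2_phQTL"]
        by_id = self.table.set_index("feature_id")
        for _, row in mech2.iterrows():
            med = row["mediator_id"]
            if med not in by_id.index or by_id.loc[med, "effect_type"] != "local_pQTL":
                raise ValueError(f"mech2 mediator {med} lacks a planted local QTL")

    def of(self, feature_id: str) -> pd.Series:
        return self.table.set_index("feature_id").loc[feature_id]


def as_dict(obj) -> dict:
    """JSON-friendly view of a result dataclass."""
    d = dataclasses.asdict(obj)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
    return d
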