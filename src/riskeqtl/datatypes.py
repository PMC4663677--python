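"""Core in-memory containers shared by every pipeline stage.

Conventions
-----------
* All genomic coordinates are 1-based inclusive (VCF/GFF style). The BED
  writers convert to 0-based half-open at the file boundary.
* Genotypes are stored as minor/alternate-allele dosages in {0, 1, 2};
  missing calls are ``NaN`` in a float matrix.
* Expression matrices are genes x samples; genotype matrices are
  samples x SNPs (the orientation association scans consume directly).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

SNP_META_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]
GENE_META_COLUMNS = ["id", "chrom", "start", "end", "strand", "gc_fraction", "length_bp"]


def gene_tss_tes(gene_meta: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Transcription start/end sites oriented by strand.

    For a plus-strand gene TSS = genomic start; for a minus-strand gene the
    TSS is the larger genomic coordinate (transcription runs right to left).
    """
    minus = (gene_meta["strand"] == "-").to_numpy()
    start = gene_meta["start"].to_numpy()
    end = gene_meta["end"].to_numpy()
    tss = np.where(minus, end, start)
    tes = np.where(minus, start, end)
    return tss, tes


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes backing a simulated genotype panel."""

    haplotypes: np.ndarray  # (n_hap, n_snp) entries in {0, 1}
    positions: np.ndarray  # 1-based bp, strictly increasing
    chrom: str = "1"

    def __post_init__(self) -> None:
        h = np.asarray(self.haplotypes)
        if h.ndim != 2 or h.shape[0] < 4 or h.shape[0] % 2:
            raise InvalidArgumentError("need an even number (>=4) of haplotypes")
        if not np.isin(h, (0, 1)).all():
            raise InvalidArgumentError("haplotype entries must be 0/1")
        pos = np.asarray(self.positions)
        if pos.shape[0] != h.shape[1] or not (np.diff(pos) > 0).all():
            raise InvalidArgumentError("positions must be strictly increasing, one per SNP")

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snp(self) -> int:
        return self.haplotypes.shape[1]

    def to_dosage(self) -> np.ndarray:
        """Collapse consecutive haplotype pairs into diploid dosages."""
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(float)


@dataclass
class GenotypeMatrix:
    """Per-sample allele dosages with SNP coordinates.

    ``dosage`` is samples x SNPs with entries in {0, 1, 2} or NaN for a
    missing call. ``snp_meta`` has one row per SNP with columns
    ``id, chrom, pos, ref, alt``.
    """

    dosage: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise InvalidArgumentError("dosage must be a 2-D samples x SNPs matrix")
        if self.dosage.shape != (len(self.sample_ids), len(self.snp_meta)):
            raise InvalidArgumentError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_meta)} SNPs"
            )
        if self.snp_meta["id"].duplicated().any():
            raise InvalidArgumentError("SNP ids must be unique")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise InvalidArgumentError("dosage entries must be in {0,1,2} or NaN")
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        self._index = {s: i for i, s in enumerate(self.snp_meta["id"])}

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snp(self) -> int:
        return self.dosage.shape[1]

    def snp_index(self, snp_id: str) -> int:
        from .errors import UnknownSnpError

        try:
            return self._index[snp_id]
        except KeyError:
            raise UnknownSnpError(f"SNP {snp_id!r} not in panel") from None

    def columns(self, snp_ids) -> np.ndarray:
        return self.dosage[:, [self.snp_index(s) for s in snp_ids]]

    def position(self, snp_id: str) -> int:
        return int(self.snp_meta.loc[self.snp_index(snp_id), "pos"])

    def subset_snps(self, keep_idx) -> "GenotypeMatrix":
        keep_idx = np.asarray(keep_idx)
        return GenotypeMatrix(
            dosage=self.dosage[:, keep_idx],
            snp_meta=self.snp_meta.iloc[keep_idx].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
        )

    def imputed_dosage(self) -> np.ndarray:
        """Dosage with missing calls replaced by the per-SNP mean."""
        d = self.dosage.copy()
        if np.isnan(d).any():
            col_mean = np.nanmean(d, axis=0)
            nan_r, nan_c = np.where(np.isnan(d))
            d[nan_r, nan_c] = col_mean[nan_c]
        return d


@dataclass
class ExpressionCounts:
    """Gene-level RNA-seq counts (genes x samples) with gene annotation."""

    counts: np.ndarray
    gene_meta: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise InvalidArgumentError("counts must be genes x samples")
        if self.counts.shape != (len(self.gene_meta), len(self.sample_ids)):
            raise InvalidArgumentError("counts shape does not match annotation/sample ids")
        if (self.counts < 0).any() or not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)) or (self.counts < 0).any():
                raise InvalidArgumentError("counts must be non-negative integers")
            self.counts = self.counts.astype(np.int64)
        if self.gene_meta["id"].duplicated().any():
            raise InvalidArgumentError("gene ids must be unique")
        self.gene_meta = self.gene_meta.reset_index(drop=True)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass
class NormalizedExpression:
    """Depth/GC/length-corrected expression on the log2 scale.

    ``offsets`` holds the removed normalization component per gene x sample
    on the natural-log scale, ready to enter a count GLM as an offset term.
    """

    values: np.ndarray  # genes x samples
    offsets: np.ndarray  # genes x samples, natural-log scale
    gene_meta: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if self.values.shape != self.offsets.shape:
            raise InvalidArgumentError("values and offsets must share a shape")
        if not np.isfinite(self.offsets).all():
            raise InvalidArgumentError("offsets must be finite")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_values(self, gene_id: str) -> np.ndarray:
        idx = self.gene_meta.index[self.gene_meta["id"] == gene_id]
        if len(idx) != 1:
            raise InvalidArgumentError(f"gene {gene_id!r} not found")
        return self.values[idx[0]]


@dataclass
class CovariateTable:
    """Per-sample covariates entering every association model.

    ``table`` rows align with the cohort sample order; PC columns are
    mutually orthogonal sample scores with their variance-explained
    fractions in ``variance_explained``.
    """

    table: pd.DataFrame
    variance_explained: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table.isna().any().any():
            raise InvalidArgumentError("covariate table must have no missing values")

    def matrix(self) -> np.ndarray:
        return self.table.to_numpy(dtype=float)

    @property
    def names(self) -> list[str]:
        return list(self.table.columns)


@dataclass
class RiskInterval:
    """A merged risk region: member risk SNPs plus their pooled LD-SNP set."""

    interval_id: str
    chrom: str
    span_start: int
    span_end: int
    member_risk_snps: list[str]
    ld_snp_ids: list[str]
    window_start: int = 0
    window_end: int = 0

    def __post_init__(self) -> None:
        if self.span_start > self.span_end:
            raise InvalidArgumentError("interval span_start > span_end")
        missing = set(self.member_risk_snps) - set(self.ld_snp_ids)
        if missing:
            raise InvalidArgumentError(f"risk SNPs {missing} missing from their own LD set")


@dataclass
class AssociationResult:
    """One SNP-gene association test."""

    snp_id: str
    gene_id: str
    beta: float
    se: float
    t_stat: float
    p_value: float
    n_samples: int
    stage: str
    significant: bool = False
    threshold_used: float = float("nan")


ASSOC_COLUMNS = [
    "snp_id",
    "gene_id",
    "chrom",
    "snp_pos",
    "beta",
    "se",
    "t_stat",
    "p_value",
    "n_samples",
    "stage",
    "significant",
    "threshold_used",
]


@dataclass
class ScanConfig:
    """Every tuning constant of the two-stage scan in one place."""

    alpha: float = 0.05
    r2_expand: float = 0.5
    flank_stage1: int = 1_000_000
    flank_stage2: int = 1_100_000
    ld_search_flank: int = 2_000_000
    median_min: int = 14
    maf_min: float = 0.01
    callrate_min: float = 0.95
    hwe_min: float = 1e-5
    pc_var_min: float = 0.01
    peak_collinear_r2: float = 0.99
    minimal_region_drop_log10: float = 2.0
    minimal_region_r2_link: float = 0.5
    peak_proximity_bp: int = 20_000

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise InvalidArgumentError("alpha must be in (0,1)")
        if not 0 < self.r2_expand <= 1:
            raise InvalidArgumentError("r2_expand must be in (0,1]")
        for name in ("flank_stage1", "flank_stage2", "ld_search_flank"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PeakRecord:
    """Per-target-gene peak SNP and conditional-analysis classification."""

    gene_id: str
    peak_snp_id: str
    peak_p: float
    peak_beta: float
    conditional_threshold: float
    residual_significant_snps: int = 0
    domain_class: str = "single"  # or "multiple"
    residual_high_ld_with_risk: bool = False


@dataclass
class GeneGroupRecord:
    """LD-based classification of one target gene against its risk SNPs."""

    gene_id: str
    interval_id: str
    best_risk_snp_id: str
    peak_snp_id: str
    r2_risk_peak: float
    group: int
    dist_risk_to_peak: int
    dist_peak_to_tss: int
    dist_peak_to_tes: int
    minimal_region: tuple[int, int]
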