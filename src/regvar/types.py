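"""Domain types shared across the pipeline.

Coordinate conventions: variants, FASTA fetches and gene spans are 1-based
inclusive; BED-derived intervals (peaks, chromatin segments) are 0-based
half-open.  Conversions live in :mod:`regvar.io`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: 18-state ChromHMM vocabulary (Roadmap/ENCODE expanded model).
CHROMHMM_STATES = (
    "TssA", "TssFlnk", "TssFlnkU", "TssFlnkD", "Tx", "TxWk",
    "EnhG1", "EnhG2", "EnhA1", "EnhA2", "EnhWk", "ZNF/Rpts",
    "Het", "TssBiv", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
)

#: States treated as active regulatory regions.
ACTIVE_STATES = frozenset(CHROMHMM_STATES[:12])

#: Brain biosamples with 18-state segmentations used for filtering.
BRAIN_BIOSAMPLES = (
    "Brain Angular Gyrus",
    "Brain Inferior Temporal Lobe",
    "Brain Cingulate Gyrus",
    "Brain Anterior Caudate",
    "Brain Substantia Nigra",
    "Brain Dorsolateral Prefrontal Cortex",
    "Brain Hippocampus Middle",
    "Astrocytes",
)


class ValidationError(ValueError):
    """An input record violates a documented invariant."""


@dataclass
class Variant:
    """A single-nucleotide variant with optional functional annotations."""

    id: str
    chrom: str
    pos: int  # 1-based position of the reference base
    ref: str
    alt: str
    allele_freq: float | None = None
    consequence_terms: frozenset[str] = field(default_factory=frozenset)
    cadd_phred: float | None = None

    def __post_init__(self) -> None:
        self.consequence_terms = frozenset(self.consequence_terms)
        if self.pos < 1:
            raise ValidationError(f"{self.id}: pos must be >= 1, got {self.pos}")
        if self.ref not in BASE_INDEX or self.alt not in BASE_INDEX:
            raise ValidationError(
                f"{self.id}: alleles must be single bases A/C/G/T, got {self.ref}>{self.alt}"
            )
        if self.ref == self.alt:
            raise ValidationError(f"{self.id}: ref and alt alleles are identical")
        if self.allele_freq is not None and not 0.0 <= self.allele_freq <= 1.0:
            raise ValidationError(f"{self.id}: allele_freq outside [0,1]")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValidationError(f"{self.id}: negative CADD score")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class AssociationRecord:
    variant_id: str
    chrom: str
    pos: int
    p_value: float
    is_index: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValidationError(
                f"{self.variant_id}: p_value must be in (0,1], got {self.p_value}"
            )


@dataclass
class PICSRecord:
    """One variant's causal probability within an association locus.

    ``source`` is ``"gwas"`` or ``"eqtl"``; eQTL records also carry the
    tissue and the regulated gene (eGene).
    """

    variant_id: str
    locus_id: str
    pics_prob: float
    source: str = "gwas"
    tissue: str = ""
    egene: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.pics_prob <= 1.0:
            raise ValidationError(
                f"{self.variant_id}: pics_prob outside [0,1]: {self.pics_prob}"
            )
        if self.source not in ("gwas", "eqtl"):
            raise ValidationError(f"unknown PICS source {self.source!r}")


@dataclass(frozen=True)
class LDRecord:
    variant_a: str
    variant_b: str
    r2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0:
            raise ValidationError(f"r2 outside [0,1]: {self.r2}")


@dataclass
class PWMMatrix:
    """Position count matrix: shape (L, 4), column order A,C,G,T per row."""

    matrix_id: str
    tf_name: str
    counts: np.ndarray
    source_db: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValidationError(f"{self.matrix_id}: counts must be (L, 4)")
        if self.counts.shape[0] < 1:
            raise ValidationError(f"{self.matrix_id}: motif length must be >= 1")
        if (self.counts < 0).any():
            raise ValidationError(f"{self.matrix_id}: negative count")
        if (self.counts.sum(axis=1) <= 0).any():
            raise ValidationError(f"{self.matrix_id}: column with no positive count")

    @property
    def length(self) -> int:
        return int(self.counts.shape[0])

    def information_content(self) -> float:
        """Total information content in bits (uniform background)."""
        f = self.counts / self.counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(f > 0, f * np.log2(f), 0.0)
        return float((2.0 + h.sum(axis=1)).sum())


@dataclass
class GeneAnnotation:
    gene_id: str
    gene_name: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be +/-")
        if not self.start <= self.tss <= self.end:
            raise ValidationError(f"{self.gene_id}: TSS outside gene span")


@dataclass
class ChromatinSegment:
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    state_label: str
    biosample: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"segment {self.chrom}:{self.start}-{self.end} empty")
        if self.state_label not in CHROMHMM_STATES:
            raise ValidationError(f"unknown chromatin state label {self.state_label!r}")


@dataclass(frozen=True)
class TFTargetRecord:
    tf_name: str
    target_gene: str
    tissue: str

    def __post_init__(self) -> None:
        if not (self.tf_name and self.target_gene and self.tissue):
            raise ValidationError("TF-target record with empty field")


@dataclass
class Locus:
    """An index variant plus its LD-expanded members (variant_id -> r2)."""

    locus_id: str
    index_variant_id: str
    index_logp: float
    members: dict[str, float]

    def __post_init__(self) -> None:
        if self.index_logp <= 0:
            raise ValidationError(f"{self.locus_id}: index_logp must be > 0")
        self.members.setdefault(self.index_variant_id, 1.0)


@dataclass
class FineMapResult:
    locus_id: str
    probabilities: dict[str, float]


@dataclass
class ColocPair:
    variant_id: str
    egene: str
    tissue: str
    gwas_pics: float
    eqtl_pics: float
    clpp: float


@dataclass
class VariantWindow:
    """Reference and alternate sequence windows centred on a variant."""

    variant_id: str
    ref_seq: str
    alt_seq: str
    flank: int
    variant_offset: int
    consequence_set: str = ""

    def __post_init__(self) -> None:
        if len(self.ref_seq) != len(self.alt_seq):
            raise ValidationError(f"{self.variant_id}: window length mismatch")
        diffs = [i for i, (a, b) in enumerate(zip(self.ref_seq, self.alt_seq)) if a != b]
        if diffs != [self.variant_offset]:
            raise ValidationError(
                f"{self.variant_id}: windows must differ exactly at variant_offset"
            )


@dataclass
class ScanHit:
    variant_id: str
    matrix_id: str
    allele: str  # "ref" | "alt"
    offset: int
    strand: str
    weight: float
    p_value: float


@dataclass
class VariantMatrixResult:
    variant_id: str
    matrix_id: str
    best_ref: ScanHit
    best_alt: ScanHit
    weight_diff: float
    pval_ratio: float
    effect: str  # "disrupt" | "create"
    consequence_set: str = ""


@dataclass
class MatchAttributes:
    variant_id: str
    chrom: str
    tss_distance: int | None
    gene_density: int
    ld_count: int
    coding_class: str  # "coding" | "non-coding"
    variant_type: str  # "SNV" | "other"


@dataclass
class ControlAssignment:
    target_variant_id: str
    control_variant_ids: list[str]
    mode: str  # "strict" | "relaxed"
    ratio: int


@dataclass
class EvidenceTriple:
    variant_id: str
    tf_name: str
    egene: str
    eqtl_tissue: str
    tftarget_tissue: str
    direction: str = ""
    provenance: list[str] = field(default_factory=list)
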