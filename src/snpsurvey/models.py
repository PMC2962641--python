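"""Core domain types for the disease-SNP survey.

Coordinates are 0-based half-open throughout the package; input dialects
(genePred, BED12, VCF) are converted on read. Intron offsets are 0-based
distances from the transcription-direction start of the intron (the first
intronic base has offset 0); serialized outputs print offsets 1-based.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

NUCLEOTIDES = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


class SnpSurveyError(Exception):
    """Base class for all package errors."""


class ValidationError(SnpSurveyError):
    """A record violates a domain invariant."""


class ParseError(SnpSurveyError):
    """A file line could not be parsed."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ReferenceMismatchError(SnpSurveyError):
    """The genome base at a SNP position disagrees with the declared ref allele."""


class GenomeLookupError(SnpSurveyError):
    """A chromosome or position is absent from the reference sequence."""


class ContractError(SnpSurveyError):
    """An operation was called outside its precondition."""


class GenerationError(SnpSurveyError):
    """A synthetic-data configuration is infeasible."""


class FunctionalClass(enum.IntEnum):
    """The nine mutually exclusive functional SNP types.

    The integer value encodes severity: lower value = more severe
    consequence, so ``min()`` over per-transcript calls yields the
    most severe class for a SNP hit by several overlapping transcripts.
    """

    NONSENSE = 1
    NONSYNONYMOUS = 2
    SYNONYMOUS = 3
    UTR5 = 4
    UTR3 = 5
    NEAR_GENE_5 = 6
    NEAR_GENE_3 = 7
    INTRONIC = 8
    INTERGENIC = 9

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "FunctionalClass":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise ValidationError(f"unknown functional class {label!r}") from None


#: All nine classes, most severe first.
SEVERITY_ORDER = tuple(FunctionalClass)

CODING_CLASSES = frozenset(
    {FunctionalClass.NONSENSE, FunctionalClass.NONSYNONYMOUS, FunctionalClass.SYNONYMOUS}
)


@dataclass(frozen=True)
class GeneModel:
    """One transcript: strand, transcription/CDS bounds and exon blocks.

    ``cds_start == cds_end`` marks a non-coding transcript. Exons are
    half-open intervals in ascending genomic order.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: tuple  # tuple of (start, end)

    def __post_init__(self):
        object.__setattr__(self, "exons", tuple((int(s), int(e)) for s, e in self.exons))
        self.validate()

    def validate(self) -> None:
        tid = self.transcript_id
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{tid}: strand must be '+' or '-', got {self.strand!r}")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValidationError(
                f"{tid}: require tx_start <= cds_start <= cds_end <= tx_end, got "
                f"({self.tx_start}, {self.cds_start}, {self.cds_end}, {self.tx_end})"
            )
        if len(self.exons) < 1:
            raise ValidationError(f"{tid}: at least one exon required")
        prev_end = None
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValidationError(f"{tid}: exon ({s},{e}) outside transcript bounds")
            if prev_end is not None and s < prev_end:
                raise ValidationError(f"{tid}: exons overlap or are unsorted at ({s},{e})")
            prev_end = e
        if self.exons[0][0] != self.tx_start or self.exons[-1][1] != self.tx_end:
            raise ValidationError(f"{tid}: exons must span tx_start..tx_end")

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end

    @property
    def introns(self) -> tuple:
        """Half-open intron intervals in ascending genomic order."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    def cds_segments(self) -> tuple:
        """Genomic-order half-open CDS pieces (exon ∩ CDS)."""
        if not self.is_coding:
            return ()
        out = []
        for s, e in self.exons:
            a, b = max(s, self.cds_start), min(e, self.cds_end)
            if a < b:
                out.append((a, b))
        return tuple(out)


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic single-nucleotide variant."""

    chrom: str
    pos: int  # 0-based
    rsid: str
    ref: str
    alt: str

    def __post_init__(self):
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValidationError(
                f"{self.rsid}: alleles must be single bases in ACGT, got "
                f"{self.ref!r}/{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValidationError(f"{self.rsid}: ref and alt alleles are identical")
        if self.pos < 0:
            raise ValidationError(f"{self.rsid}: negative position")


@dataclass(frozen=True)
class IntronPosition:
    """Placement of a SNP inside an intron of one transcript.

    ``intron_index`` counts introns in the direction of transcription
    (1 = first intron). ``offset`` is the 0-based distance from the
    transcription-direction intron start (donor side).
    """

    rsid: str
    transcript_id: str
    intron_index: int
    offset: int
    is_first_intron: bool

    def __post_init__(self):
        if self.intron_index < 1:
            raise ValidationError(f"{self.rsid}: intron_index must be >= 1")
        if self.offset < 0:
            raise ValidationError(f"{self.rsid}: negative intron offset")
        if self.is_first_intron != (self.intron_index == 1):
            raise ValidationError(f"{self.rsid}: is_first_intron inconsistent with index")


@dataclass(frozen=True)
class Association:
    """One curated disease-SNP link.

    ``odds_ratio`` may be None: such rows count for likelihood analyses but
    are excluded from effect sizes (the catalog's "with odds ratio" stratum).
    """

    rsid: str
    disease_id: str
    odds_ratio: Optional[float]
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    p_value: Optional[float] = None
    study_id: str = ""

    def __post_init__(self):
        if self.odds_ratio is not None and self.odds_ratio <= 0:
            raise ValidationError(f"{self.rsid}: odds_ratio must be > 0")
        if self.ci_low is not None and self.ci_high is not None:
            if self.ci_low > self.ci_high:
                raise ValidationError(f"{self.rsid}: inverted confidence interval")
            if self.odds_ratio is not None and not (
                self.ci_low <= self.odds_ratio <= self.ci_high
            ):
                raise ValidationError(f"{self.rsid}: odds_ratio outside its CI")
        if self.p_value is not None and not (0 < self.p_value <= 1):
            raise ValidationError(f"{self.rsid}: p_value must be in (0, 1]")

    @property
    def has_odds_ratio(self) -> bool:
        return self.odds_ratio is not None


@dataclass(frozen=True)
class ReferencePanel:
    """A named set of rsIDs (a HapMap-style list or platform manifest)."""

    name: str
    rsids: frozenset

    def __post_init__(self):
        object.__setattr__(self, "rsids", frozenset(self.rsids))
        if not self.rsids:
            raise ValidationError(f"panel {self.name!r} is empty")

    def __len__(self):
        return len(self.rsids)


@dataclass
class ParseReport:
    """Bookkeeping for a reader: how many rows passed and why rows failed."""

    n_read: int = 0
    n_rejected: int = 0
    rejections: list = field(default_factory=list)  # (line_number, reason)

    def reject(self, line_number: int, reason: str) -> None:
        self.n_rejected += 1
        self.rejections.append((line_number, reason))
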