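"""Functional classification of SNPs against transcript models.

Every SNP is assigned exactly one of the nine functional classes. When a
SNP has different consequences in different overlapping transcripts the
most severe class wins, under the fixed order

    nonsense > nonsynonymous > synonymous > utr5 > utr3 >
    near_gene_5 > near_gene_3 > intronic > intergenic

Coding consequences are obtained by splicing the CDS in transcription
direction (reverse-complementing on the minus strand), substituting the
alternate allele and translating the affected codon with the standard
genetic code.
"""
from __future__ import annotations

import logging
from typing import Iterable, List, Optional, Tuple

import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .models import (
    ContractError,
    FunctionalClass,
    GeneModel,
    GenomeLookupError,
    IntronPosition,
    ReferenceMismatchError,
    SnpRecord,
    SnpSurveyError,
    ValidationError,
    complement,
    revcomp,
)

log = logging.getLogger(__name__)

DEFAULT_NEAR5_WINDOW = 2000
DEFAULT_NEAR3_WINDOW = 500


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


class TranscriptIndex:
    """Interval index over transcripts, with cached spliced-CDS geometry.

    The index covers each transcript body plus its near-gene windows, so a
    single stab query returns every transcript that could classify a SNP.
    """

    def __init__(
        self,
        models: Iterable[GeneModel],
        near5_window: int = DEFAULT_NEAR5_WINDOW,
        near3_window: int = DEFAULT_NEAR3_WINDOW,
    ):
        self.near5_window = near5_window
        self.near3_window = near3_window
        self.models = list(models)
        pad = max(near5_window, near3_window)
        self._trees = {}
        for m in self.models:
            tree = self._trees.setdefault(m.chrom, IntervalTree())
            tree.addi(max(0, m.tx_start - pad), m.tx_end + pad, m)
        self._cds_cache = {}

    def candidates(self, chrom: str, pos: int) -> List[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.at(pos)]
        hits.sort(key=lambda m: m.transcript_id)
        return hits

    def spliced_cds(self, model: GeneModel, genome) -> Tuple[tuple, str]:
        """(cds_segments, genomic-order spliced CDS sequence), cached."""
        key = model.transcript_id
        cached = self._cds_cache.get(key)
        if cached is None:
            segments = model.cds_segments()
            seq = "".join(genome.get_seq(model.chrom, s, e) for s, e in segments).upper()
            cached = (segments, seq)
            self._cds_cache[key] = cached
        return cached


def _coding_consequence(
    snp: SnpRecord, model: GeneModel, genome, index: Optional[TranscriptIndex]
) -> FunctionalClass:
    """Consequence of a SNP that lies inside the CDS of a coding transcript."""
    if index is not None:
        segments, cds_seq = index.spliced_cds(model, genome)
    else:
        segments = model.cds_segments()
        cds_seq = "".join(genome.get_seq(model.chrom, s, e) for s, e in segments).upper()

    offset = 0
    cds_index = None
    for s, e in segments:
        if s <= snp.pos < e:
            cds_index = offset + (snp.pos - s)
            break
        offset += e - s
    if cds_index is None:  # pragma: no cover - guarded by caller
        raise ContractError(f"{snp.rsid}: position not inside CDS")

    genome_base = cds_seq[cds_index]
    if genome_base != snp.ref:
        raise ReferenceMismatchError(
            f"{snp.rsid}: genome has {genome_base!r} at {snp.chrom}:{snp.pos}, "
            f"SNP declares ref {snp.ref!r}"
        )

    if model.strand == "-":
        cds_seq = revcomp(cds_seq)
        cds_index = len(cds_seq) - 1 - cds_index
        alt = complement(snp.alt)
    else:
        alt = snp.alt

    codon_start = 3 * (cds_index // 3)
    within = cds_index - codon_start
    codon = cds_seq[codon_start : codon_start + 3]
    if len(codon) < 3:
        raise ValidationError(
            f"{snp.rsid}: CDS of {model.transcript_id} ends mid-codon "
            f"(length {len(cds_seq)} not a multiple of 3)"
        )
    alt_codon = codon[:within] + alt + codon[within + 1 :]
    aa_ref = _translate_codon(codon)
    aa_alt = _translate_codon(alt_codon)
    if aa_ref == aa_alt:
        return FunctionalClass.SYNONYMOUS
    if aa_alt == "*":
        return FunctionalClass.NONSENSE
    return FunctionalClass.NONSYNONYMOUS


def transcript_consequence(
    snp: SnpRecord,
    model: GeneModel,
    genome,
    near5_window: int = DEFAULT_NEAR5_WINDOW,
    near3_window: int = DEFAULT_NEAR3_WINDOW,
    index: Optional[TranscriptIndex] = None,
) -> Optional[FunctionalClass]:
    """Class contributed by one transcript, or None if it contributes nothing.

    Exonic positions in non-coding transcripts contribute no class: UTR and
    coding consequences require a CDS by definition.
    """
    if snp.chrom != model.chrom:
        return None
    pos, plus = snp.pos, model.strand == "+"

    if model.tx_start <= pos < model.tx_end:
        in_exon = any(s <= pos < e for s, e in model.exons)
        if not in_exon:
            return FunctionalClass.INTRONIC
        if not model.is_coding:
            return None
        if pos < model.cds_start:
            return FunctionalClass.UTR5 if plus else FunctionalClass.UTR3
        if pos >= model.cds_end:
            return FunctionalClass.UTR3 if plus else FunctionalClass.UTR5
        return _coding_consequence(snp, model, genome, index)

    # flanking windows, in the direction of transcription
    if plus:
        if model.tx_start - near5_window <= pos < model.tx_start:
            return FunctionalClass.NEAR_GENE_5
        if model.tx_end <= pos < model.tx_end + near3_window:
            return FunctionalClass.NEAR_GENE_3
    else:
        if model.tx_end <= pos < model.tx_end + near5_window:
            return FunctionalClass.NEAR_GENE_5
        if model.tx_start - near3_window <= pos < model.tx_start:
            return FunctionalClass.NEAR_GENE_3
    return None


def classify_snp(
    snp: SnpRecord,
    models,
    genome,
    near5_window: int = DEFAULT_NEAR5_WINDOW,
    near3_window: int = DEFAULT_NEAR3_WINDOW,
) -> FunctionalClass:
    """Most severe functional class of a SNP across all transcripts.

    ``models`` may be a list of :class:`GeneModel` or a prebuilt
    :class:`TranscriptIndex`.
    """
    cls, _ = classify_snp_with_transcript(snp, models, genome, near5_window, near3_window)
    return cls


def classify_snp_with_transcript(
    snp: SnpRecord,
    models,
    genome,
    near5_window: int = DEFAULT_NEAR5_WINDOW,
    near3_window: int = DEFAULT_NEAR3_WINDOW,
):
    """(class, supporting transcript) pair; transcript is None for intergenic.

    Ties between transcripts assigning the same most-severe class break by
    lexicographic transcript_id, so output never depends on input order.
    """
    if isinstance(models, TranscriptIndex):
        index = models
        candidates = index.candidates(snp.chrom, snp.pos)
        near5_window, near3_window = index.near5_window, index.near3_window
    else:
        index = None
        candidates = sorted(models, key=lambda m: m.transcript_id)

    best = None
    best_model = None
    for m in candidates:
        c = transcript_consequence(snp, m, genome, near5_window, near3_window, index)
        if c is not None and (best is None or c < best):
            best, best_model = c, m
    if best is None:
        return FunctionalClass.INTERGENIC, None
    return best, best_model


def intron_position(snp: SnpRecord, model: GeneModel) -> Optional[IntronPosition]:
    """Intron index and donor-side offset of a SNP within one transcript.

    Returns None when the SNP does not fall inside any intron of the model.
    The index counts introns in transcription direction; on the minus strand
    the genomically last intron is index 1. Offsets are 0-based from the
    transcription-direction intron start.
    """
    if snp.chrom != model.chrom:
        return None
    introns = model.introns
    n = len(introns)
    for i, (s, e) in enumerate(introns):
        if s <= snp.pos < e:
            if model.strand == "+":
                idx, off = i + 1, snp.pos - s
            else:
                idx, off = n - i, e - 1 - snp.pos
            return IntronPosition(
                rsid=snp.rsid,
                transcript_id=model.transcript_id,
                intron_index=idx,
                offset=off,
                is_first_intron=idx == 1,
            )
    return None


def first_intron_assignment(
    snp: SnpRecord, models: Iterable[GeneModel]
) -> Optional[IntronPosition]:
    """Resolve a single intron placement for an intronic SNP.

    A SNP counts as first-intron if it lies in intron 1 of *any* transcript;
    among qualifying transcripts the minimum offset wins. Otherwise the
    transcript with the smallest intron index is reported (ties broken by
    smallest offset, then transcript_id). Raises :class:`ContractError` when
    the SNP is intronic in no transcript.
    """
    if isinstance(models, TranscriptIndex):
        models = models.candidates(snp.chrom, snp.pos)
    placements = [p for m in models if (p := intron_position(snp, m)) is not None]
    if not placements:
        raise ContractError(f"{snp.rsid}: not intronic in any transcript")
    firsts = [p for p in placements if p.intron_index == 1]
    pool = firsts if firsts else placements
    return min(pool, key=lambda p: (p.intron_index, p.offset, p.transcript_id))


def classify_table(
    snps: Iterable[SnpRecord],
    models,
    genome,
    near5_window: int = DEFAULT_NEAR5_WINDOW,
    near3_window: int = DEFAULT_NEAR3_WINDOW,
):
    """Classify a SNP table -> (annotation DataFrame, error report DataFrame).

    One row per successfully classified SNP; per-SNP errors (reference
    mismatches, genome lookups) are collected, tagged by rsid, without
    aborting the remaining rows. Intronic SNPs additionally carry their
    resolved intron index, first-intron flag and 0-based donor offset.
    """
    if not isinstance(models, TranscriptIndex):
        index = TranscriptIndex(models, near5_window, near3_window)
    else:
        index = models

    rows = []
    errors = []
    for snp in snps:
        try:
            cls, model = classify_snp_with_transcript(snp, index, genome)
            intron_index = offset = None
            first = None
            if cls is FunctionalClass.INTRONIC:
                placement = first_intron_assignment(snp, index)
                intron_index = placement.intron_index
                offset = placement.offset
                first = placement.is_first_intron
                model = next(
                    m for m in index.candidates(snp.chrom, snp.pos)
                    if m.transcript_id == placement.transcript_id
                )
            rows.append(
                {
                    "rsid": snp.rsid,
                    "class": cls.label,
                    "transcript_id": model.transcript_id if model else "",
                    "intron_index": intron_index,
                    "offset": offset,
                    "gene_id": model.gene_id if model else "",
                    "is_first_intron": first,
                    "chrom": snp.chrom,
                    "pos": snp.pos,
                }
            )
        except SnpSurveyError as exc:
            errors.append({"rsid": snp.rsid, "error": str(exc)})

    table = pd.DataFrame(
        rows,
        columns=[
            "rsid",
            "class",
            "transcript_id",
            "intron_index",
            "offset",
            "gene_id",
            "is_first_intron",
            "chrom",
            "pos",
        ],
    )
    if len(table):
        table["intron_index"] = table["intron_index"].astype("Int64")
        table["offset"] = table["offset"].astype("Int64")
        table["is_first_intron"] = table["is_first_intron"].astype("boolean")
        table["pos"] = table["pos"].astype(int)
    else:
        table = table.astype(
            {"intron_index": "Int64", "offset": "Int64", "is_first_intron": "boolean"},
            errors="ignore",
        )
    report = pd.DataFrame(errors, columns=["rsid", "error"])
    if len(errors):
        log.warning("classification failed for %d SNPs", len(errors))
    counts = table["class"].value_counts().to_dict() if len(table) else {}
    log.info("classified %d SNPs: %s", len(table), counts)
    return table, report
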