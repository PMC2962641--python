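"""Synthetic genomes, transcript models, SNP panels and association catalogs.

The generator emits every input the pipeline consumes, with ground truth
known by construction: coding SNPs are planted as consequence-forcing
reference codons plus a chosen alternate allele, non-coding SNPs are placed
inside region pools that guarantee their class, disease status is Bernoulli
with per-class probabilities, odds ratios are lognormal with per-class
medians, and disease SNPs in first introns carry a Gaussian positional
excess at a configurable offset.

Default rates mirror a published catalog-wide survey of disease-SNP
associations: per-class disease probabilities around 2.77% (nonsense) down
to 0.08% (intergenic), odds-ratio medians 1.76/1.72/1.70 for
nonsense/nonsynonymous/synonymous, 31% of intronic SNPs in first introns
with a 1.2 relative risk, and a positional excess centered on the 80th
intronic base (sd 30).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as sio
from .models import (
    Association,
    FunctionalClass,
    GeneModel,
    GenerationError,
    ReferencePanel,
    SnpRecord,
    complement,
    revcomp,
)

log = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_ORDS = np.frombuffer(b"ACGT", dtype=np.uint8)

FC = FunctionalClass

#: Paper-scale per-class probabilities that a SNP is disease-associated.
DEFAULT_DISEASE_PROBS = {
    FC.NONSENSE: 0.0277,
    FC.NONSYNONYMOUS: 0.0146,
    FC.UTR5: 0.0138,
    FC.SYNONYMOUS: 0.0126,
    FC.NEAR_GENE_3: 0.0096,
    FC.UTR3: 0.0084,
    FC.NEAR_GENE_5: 0.0071,
    FC.INTRONIC: 0.0030,
    FC.INTERGENIC: 0.0008,
}

#: Per-class median odds ratios for the lognormal effect-size draw.
DEFAULT_OR_MEDIANS = {
    FC.NONSENSE: 1.76,
    FC.NONSYNONYMOUS: 1.72,
    FC.SYNONYMOUS: 1.70,
    FC.UTR5: 1.65,
    FC.UTR3: 1.60,
    FC.NEAR_GENE_5: 1.55,
    FC.NEAR_GENE_3: 1.50,
    FC.INTRONIC: 1.45,
    FC.INTERGENIC: 1.40,
}

#: Share of the SNP panel allocated to each class. Weighted toward the
#: classes whose disease probabilities are close together, so that all are
#: estimated with comparable precision from one panel.
DEFAULT_CLASS_FRACTIONS = {
    FC.NONSENSE: 0.06,
    FC.NONSYNONYMOUS: 0.21,
    FC.SYNONYMOUS: 0.21,
    FC.UTR5: 0.21,
    FC.UTR3: 0.11,
    FC.NEAR_GENE_5: 0.04,
    FC.NEAR_GENE_3: 0.11,
    FC.INTRONIC: 0.025,
    FC.INTERGENIC: 0.025,
}

# Consequence-forcing reference codons: (tx-direction codon, position of the
# substituted base within the codon, tx-direction alternate base).
NONSENSE_FORCING = (("TGG", 2, "A"), ("TGG", 1, "A"), ("CAG", 0, "T"),
                    ("CGA", 0, "T"), ("TAC", 2, "A"), ("GGA", 0, "T"))
MISSENSE_FORCING = (("GCT", 0, "A"), ("AAA", 0, "G"), ("CTT", 1, "A"),
                    ("GAC", 1, "C"), ("TTC", 0, "C"))
SYNONYMOUS_FORCING = (("CTG", 2, "A"), ("GGT", 2, "C"), ("TCT", 2, "C"),
                      ("ACA", 2, "G"), ("GTT", 2, "G"))


@dataclass
class GeneratorConfig:
    """Everything the synthetic-dataset generator needs. ``seed`` is mandatory."""

    seed: int
    n_chroms: int = 4
    chrom_length: int = 3_000_000
    n_genes: int = 350
    exon_count_range: Tuple[int, int] = (3, 8)
    intron_length_range: Tuple[int, int] = (1500, 3000)
    utr5_length_range: Tuple[int, int] = (200, 500)
    utr3_length_range: Tuple[int, int] = (200, 500)
    coding_exon_length_range: Tuple[int, int] = (150, 300)
    n_snps: int = 200_000
    class_fractions: Dict[FunctionalClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    disease_probs: Dict[FunctionalClass, float] = field(
        default_factory=lambda: dict(DEFAULT_DISEASE_PROBS)
    )
    or_medians: Dict[FunctionalClass, float] = field(
        default_factory=lambda: dict(DEFAULT_OR_MEDIANS)
    )
    log_or_sigma: float = 0.4
    first_intron_fraction: float = 0.31
    first_intron_rr: float = 1.2
    peak_center: int = 80  # 1-based intron offset of the positional excess
    peak_sd: float = 30.0
    peak_excess_mass: float = 0.35
    assoc_per_snp: Tuple[int, int] = (1, 3)
    or_present_prob: float = 1.0
    n_diseases: int = 300
    n_studies: int = 800
    n_platforms: int = 6
    platform_inclusion_prob: float = 0.5
    platform_class_skew: Optional[Dict[str, float]] = None
    near5_window: int = 2000
    near3_window: int = 500

    def validate(self) -> None:
        for name, p in [("disease_probs", self.disease_probs)]:
            for fc, v in p.items():
                if not 0 <= v <= 1:
                    raise GenerationError(f"{name}[{fc.label}] = {v} outside [0, 1]")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise GenerationError("class_fractions must sum to 1")
        if not 0 <= self.peak_excess_mass <= 1:
            raise GenerationError("peak_excess_mass outside [0, 1]")
        if self.peak_center < 1:
            raise GenerationError("peak_center is a 1-based offset, must be >= 1")
        if not 0 < self.first_intron_fraction < 1:
            raise GenerationError("first_intron_fraction must be in (0, 1)")
        if self.exon_count_range[0] < 3:
            raise GenerationError("genes need >= 3 exons so non-first introns exist")


@dataclass
class GroundTruth:
    """Generator-known quantities, for recovery tests."""

    configured_likelihood_pct: Dict[str, float]
    realized_likelihood_pct: Dict[str, Optional[float]]
    configured_median_or: Dict[str, float]
    realized_median_or: Dict[str, Optional[float]]
    class_counts: Dict[str, int]
    disease_counts: Dict[str, int]
    peak_center: int
    peak_sd: float
    peak_excess_mass: float
    first_intron_fraction_configured: float
    first_intron_fraction_realized: Optional[float]
    first_intron_rr: float
    summary: dict
    snps: pd.DataFrame = field(repr=False, default=None)


def truth_report(truth: GroundTruth) -> dict:
    """Machine-readable dictionary of all generator-known quantities."""
    d = {k: v for k, v in asdict(truth).items() if k != "snps"}
    return d


@dataclass
class SyntheticDataset:
    outdir: Path
    paths: Dict[str, Path]
    models: List[GeneModel]
    snps: List[SnpRecord]
    associations: List[Association]
    panels: Dict[str, ReferencePanel]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Gene construction
# ---------------------------------------------------------------------------

def _build_gene(rng, cfg: GeneratorConfig, chrom: str, start: int, idx: int) -> GeneModel:
    """One multi-exon coding transcript laid out from ``start``."""
    n_exons = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    introns = rng.integers(
        cfg.intron_length_range[0], cfg.intron_length_range[1] + 1, size=n_exons - 1
    )
    coding = rng.integers(
        cfg.coding_exon_length_range[0],
        cfg.coding_exon_length_range[1] + 1,
        size=n_exons,
    )
    rem = int(coding.sum()) % 3
    coding[-1] -= rem  # keep total CDS a codon multiple
    u5 = int(rng.integers(cfg.utr5_length_range[0], cfg.utr5_length_range[1] + 1))
    u3 = int(rng.integers(cfg.utr3_length_range[0], cfg.utr3_length_range[1] + 1))

    # exon lengths in transcription order
    tx_exons = [u5 + int(coding[0])]
    tx_exons += [int(c) for c in coding[1:-1]]
    tx_exons += [int(coding[-1]) + u3]
    tx_introns = [int(x) for x in introns]

    genomic_exons = tx_exons if strand == "+" else tx_exons[::-1]
    genomic_introns = tx_introns if strand == "+" else tx_introns[::-1]

    exons = []
    cursor = start
    for i, length in enumerate(genomic_exons):
        exons.append((cursor, cursor + length))
        cursor += length
        if i < len(genomic_introns):
            cursor += genomic_introns[i]
    tx_start, tx_end = exons[0][0], exons[-1][1]
    if strand == "+":
        cds_start = tx_start + u5
        cds_end = tx_end - u3
    else:
        cds_start = tx_start + u3
        cds_end = tx_end - u5
    return GeneModel(
        transcript_id=f"TX{idx:05d}",
        gene_id=f"GENE{idx:05d}",
        chrom=chrom,
        strand=strand,
        tx_start=tx_start,
        tx_end=tx_end,
        cds_start=cds_start,
        cds_end=cds_end,
        exons=tuple(exons),
    )


def _place_genes(rng, cfg: GeneratorConfig) -> List[GeneModel]:
    guard = cfg.near5_window + cfg.near3_window + 1000
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    models = []
    ci, cursor = 0, guard
    for idx in range(1, cfg.n_genes + 1):
        placed = False
        while ci < len(chroms):
            gene = _build_gene(rng, cfg, chroms[ci], cursor, idx)
            if gene.tx_end + guard <= cfg.chrom_length:
                models.append(gene)
                cursor = gene.tx_end + guard + int(rng.integers(0, 2000))
                placed = True
                break
            ci += 1
            cursor = guard
        if not placed:
            raise GenerationError(
                f"genes do not fit: placed {len(models)} of {cfg.n_genes} in "
                f"{cfg.n_chroms} x {cfg.chrom_length} bp"
            )
    return models


def _tx_cds_positions(model: GeneModel) -> np.ndarray:
    """Genomic positions of the spliced CDS, in transcription order."""
    parts = [np.arange(s, e) for s, e in model.cds_segments()]
    pos = np.concatenate(parts)
    return pos if model.strand == "+" else pos[::-1]


def _codon_slots(model: GeneModel) -> np.ndarray:
    """(n_codons, 3) tx-order genomic positions of codons fully inside one exon."""
    pos = _tx_cds_positions(model)
    n = (len(pos) // 3) * 3
    codons = pos[:n].reshape(-1, 3)
    span = codons.max(axis=1) - codons.min(axis=1)
    return codons[span == 2]


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(cfg: GeneratorConfig, outdir) -> SyntheticDataset:
    """Generate the full input set plus ground truth.

    Raises :class:`GenerationError` before any file is written when the
    configuration is infeasible (genes cannot fit, a region pool is smaller
    than the SNP count requested from it, ...).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    models = _place_genes(rng, cfg)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    chrom_idx = {c: i for i, c in enumerate(chroms)}

    genome = {
        c: rng.integers(0, 4, size=cfg.chrom_length).astype(np.uint8) for c in chroms
    }  # values 0..3, mapped to ACGT at the end

    # --- region pools -----------------------------------------------------
    def _global(chrom: str, arr: np.ndarray) -> np.ndarray:
        return chrom_idx[chrom] * cfg.chrom_length + arr

    utr5_pool, utr3_pool, near5_pool, near3_pool = [], [], [], []
    slot_rows = []  # (chrom_idx, p0, p1, p2, gene_row)
    for gi, m in enumerate(models):
        plus = m.strand == "+"
        exonic = np.concatenate([np.arange(s, e) for s, e in m.exons])
        left = exonic[exonic < m.cds_start]
        right = exonic[exonic >= m.cds_end]
        (utr5_pool if plus else utr3_pool).append(_global(m.chrom, left))
        (utr3_pool if plus else utr5_pool).append(_global(m.chrom, right))
        if plus:
            n5 = np.arange(m.tx_start - cfg.near5_window, m.tx_start)
            n3 = np.arange(m.tx_end, m.tx_end + cfg.near3_window)
        else:
            n5 = np.arange(m.tx_end, m.tx_end + cfg.near5_window)
            n3 = np.arange(m.tx_start - cfg.near3_window, m.tx_start)
        near5_pool.append(_global(m.chrom, n5))
        near3_pool.append(_global(m.chrom, n3))
        slots = _codon_slots(m)
        if len(slots):
            rows = np.empty((len(slots), 5), dtype=np.int64)
            rows[:, 0] = chrom_idx[m.chrom]
            rows[:, 1:4] = slots
            rows[:, 4] = gi
            slot_rows.append(rows)

    pools = {
        FC.UTR5: np.concatenate(utr5_pool),
        FC.UTR3: np.concatenate(utr3_pool),
        FC.NEAR_GENE_5: np.concatenate(near5_pool),
        FC.NEAR_GENE_3: np.concatenate(near3_pool),
    }
    all_slots = np.concatenate(slot_rows) if slot_rows else np.empty((0, 5), np.int64)

    # intergenic-safe intervals: away from every transcript and its windows
    guard = max(cfg.near5_window, cfg.near3_window) + 10
    safe = {c: [] for c in chroms}
    for c in chroms:
        spans = sorted(
            (m.tx_start - guard, m.tx_end + guard) for m in models if m.chrom == c
        )
        cursor = 10
        for s, e in spans:
            if s > cursor:
                safe[c].append((cursor, s))
            cursor = max(cursor, e)
        if cursor < cfg.chrom_length - 10:
            safe[c].append((cursor, cfg.chrom_length - 10))
    safe_starts, safe_lens = [], []
    for c in chroms:
        for s, e in safe[c]:
            safe_starts.append(chrom_idx[c] * cfg.chrom_length + s)
            safe_lens.append(e - s)
    safe_starts = np.asarray(safe_starts, dtype=np.int64)
    safe_lens = np.asarray(safe_lens, dtype=np.int64)
    safe_cum = np.concatenate([[0], np.cumsum(safe_lens)])

    # --- per-class SNP counts, feasibility --------------------------------
    counts = {
        fc: int(round(cfg.n_snps * cfg.class_fractions.get(fc, 0.0)))
        for fc in FunctionalClass
    }
    counts[FC.INTERGENIC] += cfg.n_snps - sum(counts.values())
    n_coding = counts[FC.NONSENSE] + counts[FC.NONSYNONYMOUS] + counts[FC.SYNONYMOUS]
    if n_coding > len(all_slots):
        raise GenerationError(
            f"{n_coding} coding SNPs requested but only {len(all_slots)} codon slots"
        )
    for fc in (FC.UTR5, FC.UTR3, FC.NEAR_GENE_5, FC.NEAR_GENE_3):
        if counts[fc] > len(pools[fc]):
            raise GenerationError(
                f"{counts[fc]} {fc.label} SNPs requested but pool has {len(pools[fc])}"
            )
    if counts[FC.INTERGENIC] > int(safe_cum[-1]) // 2:
        raise GenerationError("intergenic pool too small")

    # --- coding SNPs: plant forcing codons --------------------------------
    chosen = rng.choice(len(all_slots), size=n_coding, replace=False) if n_coding else []
    slot_iter = iter(np.sort(np.asarray(chosen)))
    forcing = {
        FC.NONSENSE: NONSENSE_FORCING,
        FC.NONSYNONYMOUS: MISSENSE_FORCING,
        FC.SYNONYMOUS: SYNONYMOUS_FORCING,
    }
    snp_rows = []  # dicts: chrom, pos, class, ref, alt, first, idx, offset

    for fc in (FC.NONSENSE, FC.NONSYNONYMOUS, FC.SYNONYMOUS):
        options = forcing[fc]
        picks = rng.integers(0, len(options), size=counts[fc])
        for pick in picks:
            ci, p0, p1, p2, gi = all_slots[next(slot_iter)]
            codon, j, alt_tx = options[pick]
            m = models[gi]
            chrom = chroms[ci]
            arr = genome[chrom]
            tx_positions = (p0, p1, p2)
            minus = m.strand == "-"
            for b, p in zip(codon, tx_positions):
                base = complement(b) if minus else b
                arr[p] = _BASES.index(base)
            pos = int(tx_positions[j])
            ref = complement(codon[j]) if minus else codon[j]
            alt = complement(alt_tx) if minus else alt_tx
            snp_rows.append(
                dict(chrom=chrom, pos=pos, cls=fc, ref=ref, alt=alt)
            )

    # --- non-coding SNPs ---------------------------------------------------
    used = {(r["chrom"], r["pos"]) for r in snp_rows}

    def _push_positions(fc, globals_arr):
        for g in globals_arr:
            chrom = chroms[int(g // cfg.chrom_length)]
            pos = int(g % cfg.chrom_length)
            snp_rows.append(dict(chrom=chrom, pos=pos, cls=fc, ref=None, alt=None))
            used.add((chrom, pos))

    for fc in (FC.UTR5, FC.UTR3, FC.NEAR_GENE_5, FC.NEAR_GENE_3):
        picks = rng.choice(pools[fc], size=counts[fc], replace=False)
        _push_positions(fc, picks)

    # intergenic: uniform over the safe intervals, rejecting duplicates
    n_intergenic = counts[FC.INTERGENIC]
    got = 0
    while got < n_intergenic:
        draws = rng.integers(0, safe_cum[-1], size=(n_intergenic - got) * 2 + 8)
        iv = np.searchsorted(safe_cum, draws, side="right") - 1
        gpos = safe_starts[iv] + (draws - safe_cum[iv])
        for g in gpos:
            if got >= n_intergenic:
                break
            chrom = chroms[int(g // cfg.chrom_length)]
            pos = int(g % cfg.chrom_length)
            if (chrom, pos) in used:
                continue
            snp_rows.append(dict(chrom=chrom, pos=pos, cls=FC.INTERGENIC, ref=None, alt=None))
            used.add((chrom, pos))
            got += 1

    # intronic: first-intron membership, disease-coupled offsets
    n_intronic = counts[FC.INTRONIC]
    f = cfg.first_intron_fraction
    rr = cfg.first_intron_rr
    p_int = cfg.disease_probs.get(FC.INTRONIC, 0.0)
    p_nonfirst = p_int / (1 - f + f * rr)
    p_first = rr * p_nonfirst
    intron_disease = []
    for _ in range(n_intronic):
        is_first = rng.random() < f
        disease = rng.random() < (p_first if is_first else p_nonfirst)
        gi = int(rng.integers(0, len(models)))
        m = models[gi]
        introns = m.introns
        n_int = len(introns)
        if is_first:
            tx_idx = 1
        else:
            tx_idx = int(rng.integers(2, n_int + 1))
        g_idx = tx_idx - 1 if m.strand == "+" else n_int - tx_idx
        s, e = introns[g_idx]
        length = e - s
        for _try in range(200):
            if is_first and disease and rng.random() < cfg.peak_excess_mass:
                off = int(round(rng.normal(cfg.peak_center - 1, cfg.peak_sd)))
                if not 0 <= off < length:
                    continue
            else:
                off = int(rng.integers(0, length))
            pos = s + off if m.strand == "+" else e - 1 - off
            if (m.chrom, pos) not in used:
                break
        else:  # pragma: no cover
            raise GenerationError("could not place an intronic SNP without collision")
        used.add((m.chrom, pos))
        snp_rows.append(
            dict(chrom=m.chrom, pos=pos, cls=FC.INTRONIC, ref=None, alt=None,
                 first=is_first, disease=disease)
        )
        intron_disease.append(disease)

    # --- assemble table, alleles, disease flags ----------------------------
    df = pd.DataFrame(snp_rows)
    if "first" not in df:
        df["first"] = np.nan
        df["disease"] = np.nan
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    df["rsid"] = [f"rs{i + 1}" for i in range(len(df))]

    # alleles for non-coding SNPs, read from the (already planted) genome
    missing_ref = df["ref"].isna()
    for chrom in chroms:
        mask = missing_ref & (df["chrom"] == chrom)
        if not mask.any():
            continue
        positions = df.loc[mask, "pos"].to_numpy()
        ref_codes = genome[chrom][positions]
        alt_codes = (ref_codes + 1 + rng.integers(0, 3, size=len(positions))) % 4
        df.loc[mask, "ref"] = [_BASES[c] for c in ref_codes]
        df.loc[mask, "alt"] = [_BASES[c] for c in alt_codes]

    # disease flags for non-intronic classes
    disease = df["disease"].copy()
    for fc in FunctionalClass:
        if fc is FC.INTRONIC:
            continue
        mask = df["cls"] == fc
        n = int(mask.sum())
        if n:
            disease.loc[mask] = rng.random(n) < cfg.disease_probs.get(fc, 0.0)
    df["disease"] = disease.astype(bool)

    # --- associations -------------------------------------------------------
    disease_pool = [f"C{1000000 + i}" for i in range(cfg.n_diseases)]
    study_pool = [f"PMID{100000 + i}" for i in range(cfg.n_studies)]
    lo, hi = cfg.assoc_per_snp
    associations = []
    for row in df[df["disease"]].itertuples(index=False):
        fc = row.cls
        mu = float(np.log(cfg.or_medians.get(fc, 1.5)))
        for _ in range(int(rng.integers(lo, hi + 1))):
            has_or = rng.random() < cfg.or_present_prob
            if has_or:
                or_value = float(np.exp(rng.normal(mu, cfg.log_or_sigma)))
                half = float(rng.uniform(0.1, 0.4))
                ci_low, ci_high = or_value * np.exp(-half), or_value * np.exp(half)
            else:
                or_value = ci_low = ci_high = None
            associations.append(
                Association(
                    rsid=row.rsid,
                    disease_id=disease_pool[int(rng.integers(0, len(disease_pool)))],
                    odds_ratio=or_value,
                    ci_low=ci_low,
                    ci_high=ci_high,
                    p_value=float(10 ** rng.uniform(-8, -2)),
                    study_id=study_pool[int(rng.integers(0, len(study_pool)))],
                )
            )

    # --- panels -------------------------------------------------------------
    all_rsids = list(df["rsid"])
    panels = {"hapmap3": ReferencePanel("hapmap3", frozenset(all_rsids))}
    skew = cfg.platform_class_skew or {}
    probs = np.full(len(df), cfg.platform_inclusion_prob)
    for label, mult in skew.items():
        probs[df["cls"] == FC.from_label(label)] = np.clip(
            cfg.platform_inclusion_prob * mult, 0, 1
        )
    for i in range(1, cfg.n_platforms + 1):
        take = rng.random(len(df)) < probs
        name = f"platform_{i}"
        rsids = frozenset(np.asarray(all_rsids, dtype=object)[take])
        if rsids:
            panels[name] = ReferencePanel(name, rsids)

    # --- ground truth -------------------------------------------------------
    class_counts, disease_counts = {}, {}
    realized_like, realized_med = {}, {}
    or_by_class = {}
    for a in associations:
        if a.has_odds_ratio:
            or_by_class.setdefault(a.rsid, []).append(a.odds_ratio)
    rsid_class = dict(zip(df["rsid"], df["cls"]))
    med_pool: Dict[FunctionalClass, list] = {fc: [] for fc in FunctionalClass}
    for a in associations:
        if a.has_odds_ratio:
            med_pool[FunctionalClass(rsid_class[a.rsid])].append(a.odds_ratio)
    for fc in FunctionalClass:
        mask = df["cls"] == fc
        n = int(mask.sum())
        nd = int((mask & df["disease"]).sum())
        class_counts[fc.label] = n
        disease_counts[fc.label] = nd
        realized_like[fc.label] = 100.0 * nd / n if n else None
        vals = med_pool[fc]
        realized_med[fc.label] = float(np.median(vals)) if vals else None

    intronic = df[df["cls"] == FC.INTRONIC]
    fi_frac = (
        float(intronic["first"].astype(bool).mean()) if len(intronic) else None
    )
    summary = {
        "associations": len(associations),
        "studies": len({a.study_id for a in associations}),
        "diseases": len({a.disease_id for a in associations}),
        "snps": len({a.rsid for a in associations}),
        "genes": None,  # known only after annotation
    }
    truth_snps = df[["rsid", "chrom", "pos", "disease"]].copy()
    truth_snps["class"] = [FunctionalClass(fc).label for fc in df["cls"]]
    truth_snps["is_first_intron"] = df["first"]
    truth = GroundTruth(
        configured_likelihood_pct={
            fc.label: 100.0 * cfg.disease_probs.get(fc, 0.0) for fc in FunctionalClass
        },
        realized_likelihood_pct=realized_like,
        configured_median_or={fc.label: cfg.or_medians.get(fc) for fc in FunctionalClass},
        realized_median_or=realized_med,
        class_counts=class_counts,
        disease_counts=disease_counts,
        peak_center=cfg.peak_center,
        peak_sd=cfg.peak_sd,
        peak_excess_mass=cfg.peak_excess_mass,
        first_intron_fraction_configured=cfg.first_intron_fraction,
        first_intron_fraction_realized=fi_frac,
        first_intron_rr=cfg.first_intron_rr,
        summary=summary,
        snps=truth_snps,
    )

    # --- write files --------------------------------------------------------
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "panels").mkdir(exist_ok=True)
    base_lookup = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequences = {
        c: base_lookup[genome[c]].tobytes().decode("ascii") for c in chroms
    }
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.genepred",
        "snps": outdir / "snps.tsv",
        "associations": outdir / "associations.tsv",
        "truth": outdir / "truth.json",
    }
    sio.write_fasta(sequences, paths["genome"])
    sio.write_genepred(models, paths["genes"])
    snps = [
        SnpRecord(chrom=r.chrom, pos=int(r.pos), rsid=r.rsid, ref=r.ref, alt=r.alt)
        for r in df.itertuples(index=False)
    ]
    sio.write_snp_table(snps, paths["snps"])
    sio.write_associations(associations, paths["associations"])
    for name, panel in panels.items():
        p = outdir / "panels" / f"{name}.txt"
        sio.write_panel(panel, p)
        paths[f"panel:{name}"] = p
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth_report(truth), fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info(
        "generated %d SNPs, %d genes, %d associations -> %s",
        len(df), len(models), len(associations), outdir,
    )
    return SyntheticDataset(
        outdir=outdir,
        paths=paths,
        models=models,
        snps=snps,
        associations=associations,
        panels=panels,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Focused simulators for the positional and enrichment studies
# ---------------------------------------------------------------------------

def simulate_first_intron_offsets(
    n_snps: int,
    seed: int,
    max_offset: int = 1000,
    base_rate: float = 0.005,
    peak_excess: float = 0.005,
    peak_center: int = 80,
    peak_sd: float = 30.0,
) -> Tuple[pd.DataFrame, set]:
    """First-intron SNP offsets with a Gaussian disease excess.

    Offsets (1-based ``peak_center``; returned 0-based per the package
    convention) are uniform over the first ``max_offset`` bases; the
    probability that a SNP is disease-associated is
    ``base_rate + peak_excess * exp(-(d - center)^2 / (2 sd^2))``.
    Defaults mirror the observed plateau (~0.5%) and peak (~0.85%) of the
    published first-intron profile. Returns (intron table, disease rsIDs).
    """
    rng = np.random.default_rng(seed)
    off1 = rng.integers(1, max_offset + 1, size=n_snps)
    p = base_rate + peak_excess * np.exp(-((off1 - peak_center) ** 2) / (2 * peak_sd**2))
    disease = rng.random(n_snps) < p
    rsids = np.array([f"rs{i + 1}" for i in range(n_snps)], dtype=object)
    table = pd.DataFrame(
        {
            "rsid": rsids,
            "intron_index": 1,
            "offset": off1 - 1,
            "is_first_intron": True,
        }
    )
    return table, set(rsids[disease])


def simulate_intron_panel(
    n_snps: int,
    seed: int,
    first_fraction: float = 0.31,
    base_rate: float = 0.015,
    first_intron_rr: float = 1.2,
) -> Tuple[pd.DataFrame, set]:
    """Intronic SNP panel with a first-intron disease relative risk.

    ``base_rate`` is the non-first-intron disease probability; first-intron
    SNPs carry ``first_intron_rr`` times that rate. The default rate is set
    so that a panel of a few hundred thousand SNPs yields enough disease
    SNPs to estimate a 1.2 ratio with a standard error well inside +-0.1
    (see the methods note). Returns (intron table, disease rsIDs).
    """
    rng = np.random.default_rng(seed)
    first = rng.random(n_snps) < first_fraction
    p = np.where(first, first_intron_rr * base_rate, base_rate)
    disease = rng.random(n_snps) < p
    rsids = np.array([f"rs{i + 1}" for i in range(n_snps)], dtype=object)
    table = pd.DataFrame(
        {
            "rsid": rsids,
            "intron_index": np.where(first, 1, 2),
            "offset": 0,
            "is_first_intron": first,
        }
    )
    return table, set(rsids[disease])


# ---------------------------------------------------------------------------
# Random toy loci (for oracle-equivalence and symmetry testing)
# ---------------------------------------------------------------------------

def random_locus(
    rng,
    chrom: str = "chrT",
    length: int = 5000,
    max_transcripts: int = 4,
):
    """A random locus: sequence plus 1..max_transcripts possibly-overlapping
    coding transcripts with small exons/introns, so codons frequently span
    splice junctions. Returns (sequences dict, models)."""
    seq = "".join(rng.choice(list(_BASES), size=length))
    n_tx = int(rng.integers(1, max_transcripts + 1))
    models = []
    for t in range(n_tx):
        for _attempt in range(50):
            n_exons = int(rng.integers(1, 5))
            coding = rng.integers(30, 121, size=n_exons)
            coding[-1] -= int(coding.sum()) % 3
            introns = rng.integers(20, 101, size=max(0, n_exons - 1))
            u5 = int(rng.integers(0, 41))
            u3 = int(rng.integers(0, 41))
            strand = "+" if rng.random() < 0.5 else "-"
            tx_exons = [u5 + int(coding[0])] if n_exons == 1 else [u5 + int(coding[0])]
            if n_exons == 1:
                tx_exons[0] += u3
            else:
                tx_exons += [int(c) for c in coding[1:-1]]
                tx_exons += [int(coding[-1]) + u3]
            genomic_exons = tx_exons if strand == "+" else tx_exons[::-1]
            genomic_introns = (
                list(introns) if strand == "+" else list(introns)[::-1]
            )
            span = sum(genomic_exons) + sum(genomic_introns)
            if span + 20 >= length:
                continue
            start = int(rng.integers(10, length - span - 10))
            exons = []
            cursor = start
            for i, ln in enumerate(genomic_exons):
                exons.append((cursor, cursor + ln))
                cursor += ln
                if i < len(genomic_introns):
                    cursor += int(genomic_introns[i])
            tx_start, tx_end = exons[0][0], exons[-1][1]
            if strand == "+":
                cds_start, cds_end = tx_start + u5, tx_end - u3
            else:
                cds_start, cds_end = tx_start + u3, tx_end - u5
            models.append(
                GeneModel(
                    transcript_id=f"LOC{t}",
                    gene_id=f"LOCGENE{t}",
                    chrom=chrom,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=tx_end,
                    cds_start=cds_start,
                    cds_end=cds_end,
                    exons=tuple(exons),
                )
            )
            break
    return {chrom: seq}, models


def random_cds_snps(rng, sequences: dict, models, n: int) -> List[SnpRecord]:
    """Random SNPs inside CDS regions of random transcripts of a toy locus."""
    out = []
    coding_models = [m for m in models if m.is_coding]
    for i in range(n):
        m = coding_models[int(rng.integers(0, len(coding_models)))]
        positions = np.concatenate([np.arange(s, e) for s, e in m.cds_segments()])
        pos = int(positions[int(rng.integers(0, len(positions)))])
        ref = sequences[m.chrom][pos]
        alt = _BASES[(_BASES.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
        out.append(SnpRecord(chrom=m.chrom, pos=pos, rsid=f"loc_rs{i}", ref=ref, alt=alt))
    return out


def mirror_locus(sequences: dict, models, snps):
    """Reverse-complement a toy locus: flip strands, remap all coordinates.

    Functional classes and intron index/offset of every SNP are invariant
    under this transformation.
    """
    new_seq = {c: revcomp(s) for c, s in sequences.items()}
    new_models = []
    for m in models:
        L = len(sequences[m.chrom])
        exons = tuple(sorted((L - e, L - s) for s, e in m.exons))
        new_models.append(
            GeneModel(
                transcript_id=m.transcript_id,
                gene_id=m.gene_id,
                chrom=m.chrom,
                strand="-" if m.strand == "+" else "+",
                tx_start=L - m.tx_end,
                tx_end=L - m.tx_start,
                cds_start=L - m.cds_end,
                cds_end=L - m.cds_start,
                exons=exons,
            )
        )
    new_snps = [
        SnpRecord(
            chrom=s.chrom,
            pos=len(sequences[s.chrom]) - 1 - s.pos,
            rsid=s.rsid,
            ref=complement(s.ref),
            alt=complement(s.alt),
        )
        for s in snps
    ]
    return new_seq, new_models, new_snps
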