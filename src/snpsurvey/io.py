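"""Readers and writers for every external format.

All tabular files are UTF-8, tab-separated; ``#`` comment lines are
permitted before (and among) data rows. Writers emit deterministic row
order so that identical inputs give byte-identical outputs.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from pyfaidx import Fasta

from .models import (
    Association,
    FunctionalClass,
    GeneModel,
    NUCLEOTIDES,
    ParseError,
    ParseReport,
    ReferencePanel,
    SnpRecord,
    ValidationError,
)

log = logging.getLogger(__name__)

ANNOTATION_COLUMNS = [
    "rsid",
    "class",
    "transcript_id",
    "intron_index",
    "offset",
    "gene_id",
    "is_first_intron",
    "chrom",
    "pos",
]

ASSOCIATION_COLUMNS = [
    "rsid",
    "disease_id",
    "odds_ratio",
    "ci_low",
    "ci_high",
    "p_value",
    "study_id",
]


def fmt_float(x: Optional[float]) -> str:
    """Format a float with 6 significant digits; empty string for None/NaN."""
    if x is None or (isinstance(x, float) and x != x):
        return ""
    return f"{float(x):.6g}"


def fmt_pct(x: Optional[float]) -> str:
    """Format a percentage at 2 decimal places; empty string for None/NaN."""
    if x is None or (isinstance(x, float) and x != x):
        return ""
    return f"{float(x):.2f}"


def _data_lines(path):
    """Yield (line_number, stripped_line) skipping blanks and # comments."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield i, line


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def _parse_genepred_line(line: str, line_number: int) -> GeneModel:
    f = line.split("\t")
    if len(f) < 10:
        raise ParseError(f"genePred needs >= 10 tab-separated fields, got {len(f)}", line_number)
    try:
        name, chrom, strand = f[0], f[1], f[2]
        tx_start, tx_end = int(f[3]), int(f[4])
        cds_start, cds_end = int(f[5]), int(f[6])
        exon_count = int(f[7])
        starts = [int(x) for x in f[8].rstrip(",").split(",") if x != ""]
        ends = [int(x) for x in f[9].rstrip(",").split(",") if x != ""]
    except ValueError as exc:
        raise ParseError(f"malformed genePred field: {exc}", line_number) from None
    if len(starts) != exon_count or len(ends) != exon_count:
        raise ParseError(
            f"exonCount {exon_count} disagrees with block lists "
            f"({len(starts)} starts, {len(ends)} ends)",
            line_number,
        )
    gene_id = f[11] if len(f) >= 12 and f[11] else name
    return GeneModel(
        transcript_id=name,
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        tx_start=tx_start,
        tx_end=tx_end,
        cds_start=cds_start,
        cds_end=cds_end,
        exons=tuple(zip(starts, ends)),
    )


def _parse_bed12_line(line: str, line_number: int) -> GeneModel:
    f = line.split("\t")
    if len(f) < 12:
        raise ParseError(f"BED12 needs 12 tab-separated fields, got {len(f)}", line_number)
    try:
        chrom = f[0]
        chrom_start, chrom_end = int(f[1]), int(f[2])
        name, strand = f[3], f[5]
        thick_start, thick_end = int(f[6]), int(f[7])
        block_count = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",") if x != ""]
        offsets = [int(x) for x in f[11].rstrip(",").split(",") if x != ""]
    except ValueError as exc:
        raise ParseError(f"malformed BED12 field: {exc}", line_number) from None
    if len(sizes) != block_count or len(offsets) != block_count:
        raise ParseError("blockCount disagrees with block lists", line_number)
    exons = tuple(
        (chrom_start + off, chrom_start + off + sz) for off, sz in zip(offsets, sizes)
    )
    return GeneModel(
        transcript_id=name,
        gene_id=name,
        chrom=chrom,
        strand=strand,
        tx_start=chrom_start,
        tx_end=chrom_end,
        cds_start=thick_start,
        cds_end=thick_end,
        exons=exons,
    )


def read_gene_models(path, dialect: str = "genePred") -> list:
    """Read transcript models from a genePred or BED12 file.

    Malformed lines raise :class:`ParseError` naming the line number;
    records violating GeneModel invariants raise :class:`ValidationError`
    naming the transcript.
    """
    parser = {"genepred": _parse_genepred_line, "bed12": _parse_bed12_line}.get(
        dialect.lower()
    )
    if parser is None:
        raise ValueError(f"unknown gene-model dialect {dialect!r}")
    models = [parser(line, i) for i, line in _data_lines(path)]
    log.info("read %d gene models from %s (%s)", len(models), path, dialect)
    return models


def write_genepred(models: Iterable[GeneModel], path) -> None:
    """Write transcript models as 12-column genePred (name2 carries gene_id)."""
    rows = sorted(models, key=lambda m: (m.chrom, m.tx_start, m.transcript_id))
    with open(path, "w", encoding="utf-8") as fh:
        for m in rows:
            starts = ",".join(str(s) for s, _ in m.exons) + ","
            ends = ",".join(str(e) for _, e in m.exons) + ","
            fh.write(
                "\t".join(
                    [
                        m.transcript_id,
                        m.chrom,
                        m.strand,
                        str(m.tx_start),
                        str(m.tx_end),
                        str(m.cds_start),
                        str(m.cds_end),
                        str(len(m.exons)),
                        starts,
                        ends,
                        "0",
                        m.gene_id,
                    ]
                )
                + "\n"
            )


def write_bed12(models: Iterable[GeneModel], path) -> None:
    rows = sorted(models, key=lambda m: (m.chrom, m.tx_start, m.transcript_id))
    with open(path, "w", encoding="utf-8") as fh:
        for m in rows:
            sizes = ",".join(str(e - s) for s, e in m.exons) + ","
            offsets = ",".join(str(s - m.tx_start) for s, _ in m.exons) + ","
            fh.write(
                "\t".join(
                    [
                        m.chrom,
                        str(m.tx_start),
                        str(m.tx_end),
                        m.transcript_id,
                        "0",
                        m.strand,
                        str(m.cds_start),
                        str(m.cds_end),
                        "0",
                        str(len(m.exons)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------

class GenomeSource:
    """Minimal interface the classifier needs from a reference sequence."""

    def get_base(self, chrom: str, pos: int) -> str:
        raise NotImplementedError

    def get_seq(self, chrom: str, start: int, end: int) -> str:
        raise NotImplementedError


class DictGenome(GenomeSource):
    """In-memory genome: a mapping of chromosome name -> sequence string."""

    def __init__(self, sequences: dict):
        self.sequences = {k: v.upper() for k, v in sequences.items()}

    def _chrom(self, chrom):
        from .models import GenomeLookupError

        try:
            return self.sequences[chrom]
        except KeyError:
            raise GenomeLookupError(f"chromosome {chrom!r} absent from genome") from None

    def get_base(self, chrom, pos):
        seq = self._chrom(chrom)
        if not 0 <= pos < len(seq):
            from .models import GenomeLookupError

            raise GenomeLookupError(f"position {chrom}:{pos} outside sequence")
        return seq[pos]

    def get_seq(self, chrom, start, end):
        return self._chrom(chrom)[start:end]


class FastaGenome(GenomeSource):
    """FASTA-backed genome via pyfaidx (indexed on first use)."""

    def __init__(self, path):
        from .models import GenomeLookupError

        self._lookup_error = GenomeLookupError
        self.fasta = Fasta(str(path), as_raw=True, sequence_always_upper=True)

    def get_base(self, chrom, pos):
        return self.get_seq(chrom, pos, pos + 1)

    def get_seq(self, chrom, start, end):
        if chrom not in self.fasta:
            raise self._lookup_error(f"chromosome {chrom!r} absent from genome")
        return str(self.fasta[chrom][start:end])


def write_fasta(sequences: dict, path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SNP tables
# ---------------------------------------------------------------------------

def _snp_from_fields(chrom, pos, rsid, ref, alt, line_no, report, seen):
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
        report.reject(line_no, "not SNV")
        return None
    if ref == alt:
        report.reject(line_no, "ref equals alt")
        return None
    if rsid in seen:
        report.reject(line_no, "duplicate rsid")
        return None
    seen.add(rsid)
    report.n_read += 1
    return SnpRecord(chrom=chrom, pos=pos, rsid=rsid, ref=ref, alt=alt)


def read_snp_table(path, dialect: str = "tsv"):
    """Read a SNP table (header TSV or minimal VCF) -> (records, report).

    Only biallelic single-nucleotide variants pass; everything else is
    counted in the report with a reason. The first occurrence of a
    duplicated rsID wins.
    """
    dialect = dialect.lower()
    report = ParseReport()
    records = []
    seen = set()
    if dialect == "tsv":
        header = None
        for line_no, line in _data_lines(path):
            fields = line.split("\t")
            if header is None:
                header = [h.strip().lower() for h in fields]
                required = ["chrom", "pos0", "rsid", "ref", "alt"]
                if header[: len(required)] != required:
                    raise ParseError(
                        f"SNP TSV header must start with {required}, got {header}", line_no
                    )
                continue
            if len(fields) < 5:
                report.reject(line_no, "too few columns")
                continue
            try:
                pos = int(fields[1])
            except ValueError:
                report.reject(line_no, "non-integer position")
                continue
            rec = _snp_from_fields(
                fields[0], pos, fields[2], fields[3], fields[4], line_no, report, seen
            )
            if rec is not None:
                records.append(rec)
    elif dialect == "vcf":
        with open(path, "r", encoding="utf-8", newline="") as fh:
            for line_no, raw in enumerate(fh, start=1):
                line = raw.rstrip("\r\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 5:
                    report.reject(line_no, "too few columns")
                    continue
                chrom, pos_s, rsid, ref, alt = fields[:5]
                try:
                    pos = int(pos_s) - 1  # VCF is 1-based
                except ValueError:
                    report.reject(line_no, "non-integer position")
                    continue
                if "," in alt:
                    report.reject(line_no, "multi-allelic")
                    continue
                rec = _snp_from_fields(chrom, pos, rsid, ref, alt, line_no, report, seen)
                if rec is not None:
                    records.append(rec)
    else:
        raise ValueError(f"unknown SNP table dialect {dialect!r}")
    log.info(
        "read %d SNPs from %s (%d rejected)", report.n_read, path, report.n_rejected
    )
    return records, report


def write_snp_table(records: Iterable[SnpRecord], path) -> None:
    rows = sorted(records, key=lambda r: (r.chrom, r.pos, r.rsid))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chrom\tpos0\trsid\tref\talt\n")
        for r in rows:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.rsid}\t{r.ref}\t{r.alt}\n")


# ---------------------------------------------------------------------------
# Associations
# ---------------------------------------------------------------------------

def read_associations(path, disease_synonyms: Optional[dict] = None):
    """Read the curated association table -> (associations, report).

    Rows lacking an odds ratio are retained (they still count for
    likelihoods) but flagged ineligible for effect sizes. ``disease_synonyms``
    optionally maps raw disease names to normalized IDs at read time.
    """
    report = ParseReport()
    out = []
    header = None
    col = {}
    for line_no, line in _data_lines(path):
        fields = line.split("\t")
        if header is None:
            header = [h.strip().lower() for h in fields]
            missing = [c for c in ASSOCIATION_COLUMNS if c not in header]
            if missing:
                raise ParseError(f"association table missing columns {missing}", line_no)
            col = {c: header.index(c) for c in ASSOCIATION_COLUMNS}
            continue
        if len(fields) < len(header):
            fields = fields + [""] * (len(header) - len(fields))

        def get(name):
            v = fields[col[name]].strip()
            return v if v != "" else None

        def get_float(name):
            v = get(name)
            return float(v) if v is not None else None

        try:
            disease = get("disease_id") or ""
            if disease_synonyms:
                disease = disease_synonyms.get(disease, disease)
            assoc = Association(
                rsid=get("rsid") or "",
                disease_id=disease,
                odds_ratio=get_float("odds_ratio"),
                ci_low=get_float("ci_low"),
                ci_high=get_float("ci_high"),
                p_value=get_float("p_value"),
                study_id=get("study_id") or "",
            )
        except (ValueError, ValidationError) as exc:
            report.reject(line_no, str(exc))
            continue
        if not assoc.rsid:
            report.reject(line_no, "missing rsid")
            continue
        report.n_read += 1
        out.append(assoc)
    n_or = sum(1 for a in out if a.has_odds_ratio)
    log.info(
        "read %d associations from %s (%d with odds ratio, %d rejected)",
        report.n_read,
        path,
        n_or,
        report.n_rejected,
    )
    return out, report


def write_associations(associations: Iterable[Association], path) -> None:
    rows = sorted(associations, key=lambda a: (a.rsid, a.disease_id, a.study_id))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(ASSOCIATION_COLUMNS) + "\n")
        for a in rows:
            fh.write(
                "\t".join(
                    [
                        a.rsid,
                        a.disease_id,
                        fmt_float(a.odds_ratio),
                        fmt_float(a.ci_low),
                        fmt_float(a.ci_high),
                        fmt_float(a.p_value),
                        a.study_id,
                    ]
                )
                + "\n"
            )


def read_disease_synonyms(path) -> dict:
    """Two-column (raw name -> normalized ID) synonym file."""
    out = {}
    for line_no, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError("synonym file needs exactly 2 tab-separated columns", line_no)
        out[fields[0].strip()] = fields[1].strip()
    return out


# ---------------------------------------------------------------------------
# Panels
# ---------------------------------------------------------------------------

def read_panel(path, name: Optional[str] = None) -> ReferencePanel:
    """Read a panel manifest (one rsID per line, # comments allowed)."""
    rsids = []
    seen = set()
    n_dup = 0
    for _, line in _data_lines(path):
        rsid = line.strip()
        if rsid in seen:
            n_dup += 1
            continue
        seen.add(rsid)
        rsids.append(rsid)
    if n_dup:
        log.info("panel %s: collapsed %d duplicate rsIDs", path, n_dup)
    if not rsids:
        raise ValidationError(f"panel file {path} contains no rsIDs")
    return ReferencePanel(name=name or Path(path).stem, rsids=frozenset(rsids))


def write_panel(panel: ReferencePanel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# panel: {panel.name}\n")
        for rsid in sorted(panel.rsids):
            fh.write(rsid + "\n")


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

def write_annotation(table: pd.DataFrame, path) -> None:
    """Write an annotation table.

    Column order is fixed; rows are sorted by (chrom, pos, rsid); intron
    offsets are serialized 1-based.
    """
    df = table.sort_values(["chrom", "pos", "rsid"], kind="mergesort")
    df = df[ANNOTATION_COLUMNS]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for rsid, cls, tid, idx, off, gene, fi, chrom, pos in df.itertuples(
            index=False, name=None
        ):
            fh.write(
                "\t".join(
                    [
                        rsid,
                        cls,
                        tid or "",
                        "" if pd.isna(idx) else str(int(idx)),
                        "" if pd.isna(off) else str(int(off) + 1),
                        gene or "",
                        "" if pd.isna(fi) else str(bool(fi)).lower(),
                        chrom,
                        str(int(pos)),
                    ]
                )
                + "\n"
            )


def read_annotation(path) -> pd.DataFrame:
    """Read an annotation table back into the in-memory form (0-based offsets)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={
            "rsid": str,
            "class": str,
            "transcript_id": str,
            "gene_id": str,
            "chrom": str,
            "is_first_intron": str,
        },
        keep_default_na=False,
        na_values=[""],
    )
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"annotation table missing columns {missing}")
    bad = set(df["class"].dropna()) - {c.label for c in FunctionalClass}
    if bad:
        raise ValidationError(f"unknown functional classes in annotation: {sorted(bad)}")
    df["intron_index"] = df["intron_index"].astype("Int64")
    df["offset"] = (df["offset"].astype("Int64") - 1).astype("Int64")
    df["is_first_intron"] = df["is_first_intron"].map(
        {"true": True, "false": False}
    ).astype("boolean")
    df["pos"] = df["pos"].astype(int)
    for c in ("transcript_id", "gene_id"):
        df[c] = df[c].fillna("")
    return df[ANNOTATION_COLUMNS]
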