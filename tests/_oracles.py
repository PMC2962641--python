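"""Independent oracles used to cross-check the implementation.

These deliberately avoid the package's code paths: the coding oracle
rebuilds and translates whole proteins instead of single codons; the
Mann-Whitney and hypergeometric oracles enumerate combinatorially.
"""
from __future__ import annotations

import itertools
from math import comb

from Bio.Seq import Seq

from snpsurvey.models import FunctionalClass, GeneModel, SnpRecord, revcomp


def protein_diff_class(snp: SnpRecord, model: GeneModel, sequences: dict):
    """Coding consequence by translating both alleles' full proteins.

    Returns None when the SNP is not inside the CDS of the model.
    """
    if snp.chrom != model.chrom or not model.is_coding:
        return None
    segments = model.cds_segments()
    if not any(s <= snp.pos < e for s, e in segments):
        return None
    chrom_seq = sequences[snp.chrom]
    ref_cds = "".join(chrom_seq[s:e] for s, e in segments)
    alt_chrom = chrom_seq[: snp.pos] + snp.alt + chrom_seq[snp.pos + 1 :]
    alt_cds = "".join(alt_chrom[s:e] for s, e in segments)
    if model.strand == "-":
        ref_cds, alt_cds = revcomp(ref_cds), revcomp(alt_cds)
    ref_protein = str(Seq(ref_cds).translate())
    alt_protein = str(Seq(alt_cds).translate())
    if ref_protein == alt_protein:
        return FunctionalClass.SYNONYMOUS
    diffs = [(a, b) for a, b in zip(ref_protein, alt_protein) if a != b]
    assert len(diffs) == 1, "a SNP can change at most one residue"
    return (
        FunctionalClass.NONSENSE
        if diffs[0][1] == "*"
        else FunctionalClass.NONSYNONYMOUS
    )


def locus_coding_class(snp: SnpRecord, models, sequences: dict):
    """Most severe protein-diff consequence across a locus's transcripts."""
    calls = [
        c for m in models if (c := protein_diff_class(snp, m, sequences)) is not None
    ]
    return min(calls) if calls else None


def mann_whitney_exact_enumeration(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group labelings."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(sample_x, sample_y):
        return sum(1 for a in sample_x for b in sample_y if a > b)

    u_obs = u_stat(x, y)
    mean_u = n1 * len(y) / 2
    dev = abs(u_obs - mean_u)
    total = extreme = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        u = u_stat(xs, ys)
        total += 1
        if abs(u - mean_u) >= dev - 1e-12:
            extreme += 1
    return extreme / total


def hypergeom_upper_tail_enumeration(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by exact combinatorial summation."""
    denom = comb(N, n)
    num = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1))
    return num / denom
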