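import numpy as np
import pytest
from hypothesis import settings

from snpsurvey.io import DictGenome
from snpsurvey.models import GeneModel, SnpRecord

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture
def toy_model():
    """Two-exon plus-strand transcript: tx 100-400, cds 150-350,
    exons (100,200) and (250,400); intron (200,250)."""
    return GeneModel(
        transcript_id="TXA",
        gene_id="GENEA",
        chrom="chr1",
        strand="+",
        tx_start=100,
        tx_end=400,
        cds_start=150,
        cds_end=350,
        exons=((100, 200), (250, 400)),
    )


@pytest.fixture
def toy_sequences():
    """500 bp chr1 with known codons planted in the toy transcript's CDS.

    Spliced CDS = [150,200) + [250,350); planted, in CDS coordinates:
      codon 0 (genomic 150-152) = TGG  -> G>A at 152 gives TGA (stop)
      codon 1 (genomic 153-155) = CTG  -> G>A at 155 gives CTA (Leu, silent)
      codon 2 (genomic 156-158) = GCT  -> G>A at 156 gives ACT (Ala>Thr)
      codon 16 spans the splice junction: cds 48,49 (genomic 198,199) + cds 50
      (genomic 250) = TGG -> G>A at 250 gives TGA (stop across the junction)
    """
    seq = list("A" * 500)
    seq[150:153] = "TGG"
    seq[153:156] = "CTG"
    seq[156:159] = "GCT"
    seq[198] = "T"
    seq[199] = "G"
    seq[250] = "G"
    return {"chr1": "".join(seq)}


@pytest.fixture
def toy_genome(toy_sequences):
    return DictGenome(toy_sequences)


def snp(pos, ref="A", alt="C", rsid=None, chrom="chr1"):
    return SnpRecord(chrom=chrom, pos=pos, rsid=rsid or f"rs{pos}", ref=ref, alt=alt)


@pytest.fixture
def rng():
    return np.random.default_rng(20251)
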