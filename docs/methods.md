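# Methods

## Problem and scope

`snpsurvey` re-implements, as a reusable and testable pipeline, a
catalog-wide survey of human disease–SNP associations: classify every SNP
into one of nine functional types from transcript models, estimate the
per-type *likelihood* of disease association against reference SNP panels,
compare per-type *effect sizes* (median odds ratios), and profile where
disease SNPs sit inside first introns. No curated catalog or platform
manifest is redistributed; the `simulate` module generates all five inputs
(genome FASTA, gene models, SNP table, panel manifests, association table)
with ground truth known by construction, so every stage is verifiable
offline.

## Functional classification

Coordinates are 0-based half-open throughout; genePred, BED12 and VCF
dialects are converted on read.

A SNP's class per transcript is determined by region: exonic positions
upstream/downstream of the CDS (in transcription direction) are 5′/3′-UTR;
positions inside the CDS are classified by splicing the CDS in transcription
direction (reverse-complementing on the minus strand), substituting the
alternate allele and translating the affected codon with the standard
genetic code — synonymous if the residue is unchanged, nonsense if the
alternate codon is a stop, nonsynonymous otherwise. Positions between exons
are intronic; positions within 2,000 bases upstream of the transcription
start or 500 bases downstream of the transcription end (the dbSNP
near-gene convention; both configurable) are near-gene-5′/3′. A SNP hit by
several overlapping transcripts takes the most severe class under the fixed
order nonsense > nonsynonymous > synonymous > UTR5 > UTR3 > near-5′ >
near-3′ > intronic > intergenic, with lexicographic transcript ID as the
tie-break, so results never depend on input order. Exonic positions of
non-coding transcripts contribute no class (UTR and coding consequences
require a CDS); their introns and flanks still count.

A transcript whose CDS length is not a multiple of 3 raises a validation
error when a SNP lands in the trailing partial codon; batch classification
collects such per-SNP errors into a report instead of aborting.

Intron placements count intron indices in transcription direction (index 1
is the first intron) and measure offsets from the transcription-direction
intron start (donor side). Offsets are 0-based internally — the first
intronic base has offset 0 — and serialized 1-based, so "the 80th base"
appears as offset 80 in output files. A SNP is first-intron if it lies in
intron 1 of *any* transcript; among qualifying transcripts the minimum
offset is reported, otherwise the smallest intron index wins.

## Survey statistics

**Likelihood.** For each panel, the likelihood per class is
100 · (distinct disease-associated rsIDs of that class in the panel) /
(panel rsIDs of that class). A SNP counts once regardless of how many
associations it has. Panel rsIDs absent from the annotation are removed
from denominators and reported separately. Classes with an empty
denominator report null, not 0.

**Effect size.** The unit is the association: a SNP reported by three
studies contributes three odds ratios. The per-class effect size is the
median odds ratio; its standard error is the standard deviation of the
median over B = 1000 seeded nonparametric bootstrap resamples (an
assumption-free choice; a single observation has SE 0). Odds ratios are
used exactly as reported; `fold_or` optionally maps OR < 1 to 1/OR.
Pairwise class comparisons use the two-sided Mann–Whitney U test: the exact
null distribution when both samples have ≤ 8 observations and no ties,
otherwise the normal approximation with tie and continuity corrections
(both via scipy, cross-checked in the tests against a combinatorial
enumeration oracle). Raw p-values by default; Bonferroni and
Benjamini–Hochberg adjustments are available behind a flag.

**Enrichment.** With N intronic SNPs of which K are disease-associated, n
in first introns of which k are disease-associated, the enrichment ratio is
(k/n) / ((K−k)/(N−n)) and the p-value is the hypergeometric upper tail
P(X ≥ k) (scipy's survival function; exact against enumeration to 1e-12 in
the tests). The ratio is null when a denominator vanishes.

**First-intron density profile.** For offsets d = 1..1000 the profile
records cumulative counts cum_disease(d) and cum_all(d) and their ratio as
a percentage. The *peak* of the positional excess is located on a centered
sliding-window density (halfwidth 50 bases, restricted to offsets where the
full window fits, smallest offset on ties), not on the cumulative ratio.
This is deliberate: the argmax of a ratio of cumulative counts
systematically lags a localized excess — for a Gaussian excess at offset c
with spread σ it lands near c + 1.1σ regardless of the excess mass, and
under a uniform null it concentrates at small offsets where the denominator
is noisy. A windowed density peaks at the excess center, is uniform under
the null, and reproduces the rise-to-~0.85%-then-decline-to-~0.5% shape
that motivates the profile, so it is the published behaviour a peak
detector should recover. The cumulative argmax is still exposed
(`cumulative_peak_offset`) for comparison. The halfwidth (50) was fixed
from the visible decay scale of the published curve (~100 bases), before
any recovery experiment.

**Scatter and roll-up.** Likelihood vs median OR is exported per class with
a Spearman rank correlation as a descriptive statistic (no curve is
fitted). `rank_residual` = rank(likelihood) − rank(median OR) flags classes
whose likelihood lags their effect size. The catalog roll-up counts
distinct studies, diseases, SNPs and genes, over all associations and over
the stratum that carries odds ratios, plus the percentage of panel genes
containing a disease SNP.

## Synthetic data: what it emulates and what it does not

`GeneratorConfig` defaults are the study conditions everything downstream
is tested under:

* per-class disease probabilities 2.77 / 1.46 / 1.38 / 1.26 / 0.96 / 0.84 /
  0.71 / 0.30 / 0.08 % (nonsense, nsSNP, 5′-UTR, sSNP, near-3′, 3′-UTR,
  near-5′, intronic, intergenic) — the catalog-scale regime;
* per-class lognormal odds ratios (σ = 0.4) with medians 1.76 / 1.72 / 1.70
  for nonsense/nsSNP/sSNP and 1.65 down to 1.40 for the six classes whose
  medians the source survey does not print;
* 31% of intronic SNPs in first introns, first-intron relative risk 1.2,
  and a Gaussian positional excess for disease first-intron SNPs centered
  on the 80th base (sd 30, mixture mass 0.35);
* 1–3 associations per disease SNP, each with a synthetic disease CUI and
  study ID; every generated association carries an odds ratio by default
  (the missing-OR stratum is exercised explicitly in tests), with
  well-formed CIs and p-values;
* six platform manifests drawn per-SNP Bernoulli(0.5), optionally skewed
  per class, plus a master panel of all SNPs.

Class composition of the panel (6% nonsense, 21% each nsSNP/sSNP/5′-UTR,
11% each 3′-UTR/near-3′, 4% near-5′, 2.5% each intronic/intergenic) is a
variance-informed design: the classes whose disease probabilities differ by
only ~0.1 percentage point receive the largest allocations so all nine
likelihoods are estimated with comparable precision from one 200,000-SNP
panel.

Coding SNPs are planted as consequence-forcing reference codons (e.g. TGG
with a third-base A substitution forces a stop) written into the genome,
rather than random sequence plus rejection, so ground truth requires no
translation at generation time. Genes never overlap and are separated by
more than the near-gene windows, intergenic SNPs are placed outside every
window, and first introns are at least 1,500 bases — so the planted class
is provably the class the annotator must return, and the round-trip test
demands exact recovery.

The generator does **not** emulate linkage disequilibrium, allele
frequencies, real chromosome lengths, overlapping gene structures, or
per-platform ascertainment realism. Passing recovery tests therefore shows
the estimators are correct and calibrated under the stated sampling model,
not that real catalogs are free of LD-driven or curation-driven artifacts.

Two focused simulators serve the positional studies without building full
genomes: `simulate_first_intron_offsets` (uniform offsets over the first
1,000 bases; disease probability 0.5% + 0.5%·exp(−(d−80)²/(2·30²)), which
reproduces the published plateau ~0.5% and windowed peak ~0.85%) and
`simulate_intron_panel` (31% first-intron membership, relative risk 1.2,
non-first-intron disease rate 1.5%). The 1.5% rate is a power-based design
choice made before running any recovery experiment: at a 0.3% rate a
200,000-SNP panel yields SE(log ratio) ≈ 0.083, so the estimate would leave
[1.1, 1.3] in about a third of runs and no estimator could meet a 90%
recovery guarantee; at 1.5% (k ≈ 1,100 disease first-intron SNPs)
SE(log ratio) ≈ 0.037 and recovery is reliable. Likewise the peak-recovery
studies use 464,000 first-intron SNPs — 31% of the ~1.5M intronic SNPs the
original survey analyzed — at which the windowed peak estimator's sampling
SD is ~10 bases.

## Numerical and reproducibility choices

All randomness flows from a single mandatory integer seed through
`numpy.random.default_rng`; identical inputs and seeds give byte-identical
output files (asserted in tests). Bootstrap resampling iterates classes in
a fixed severity order. Output tables are sorted deterministically
(annotations by chromosome, position, rsID); floats print with 6
significant digits and percentages additionally at 2 decimals. Undefined
densities at small offsets (empty denominator) are reported as 0 with a
flag column so profiles remain plottable. Multi-allelic records and indels
are rejected at parse time with per-line reasons; duplicate rsIDs keep the
first occurrence.

## Problem sizes used by the test suite and acceptance script

Parameter recovery runs one 200,000-SNP dataset (≈ 12 Mb genome, 350
genes); peak and enrichment recovery run 50 seeded replicates of the
focused simulators (464,000 and 200,000 SNPs respectively); the codon
oracle check compares ~4,000 classifications on 1,000 random ≤5 kb loci;
determinism reruns the full CLI on a 3,000-SNP dataset. The acceptance
script reports the peak offset and height as medians over 11 replicate
simulations because a single run's argmax has a sampling SD of ~10 bases.

## Known limitations

* Single-transcript genes in the generator: overlapping-transcript severity
  resolution is exercised only by the random-locus property tests.
* The intron-offset base (0- or 1-based) of the original survey is not
  stated; the shipped convention (0-based internal, 1-based serialized) may
  be off by one against the original's "80th base".
* The cumulative-ratio "density" column is reported for fidelity, but its
  argmax is not a usable peak estimator (see above); consumers should use
  `window_density`/`peak_offset`.
* No splice-site, regulatory or miRNA-binding sub-annotation; no meta-
  analytic pooling of odds ratios across studies of the same SNP–disease
  pair; no liftover.
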