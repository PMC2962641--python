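"""Survey statistics over an annotated SNP catalog.

Three result families:

* per-type *likelihood* of disease association against a reference panel —
  the percentage of the panel's SNPs of each functional class that appear in
  the disease catalog (distinct SNPs, regardless of how many associations
  each has);
* per-type *effect size* — the median odds ratio over all curated
  associations of that class, with a bootstrap standard error, plus pairwise
  Mann-Whitney comparisons between classes;
* the positional profile of disease SNPs within first introns, with a
  hypergeometric enrichment test of first vs non-first introns.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import (
    Association,
    ContractError,
    FunctionalClass,
    ReferencePanel,
    ValidationError,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LikelihoodResult:
    """Likelihood of disease association for one class within one panel."""

    panel_name: str
    functional_class: FunctionalClass
    n_disease: int
    n_panel: int
    likelihood: Optional[float]  # percentage, None when n_panel == 0


@dataclass
class EffectSizeResult:
    """Median odds ratio (+ bootstrap SE) for one class."""

    functional_class: FunctionalClass
    n_associations: int
    median_or: float
    se_median: float
    odds_ratios: np.ndarray = field(repr=False, default=None)


@dataclass
class DensityProfile:
    """Positional profile of disease SNPs in first introns.

    ``offsets`` are 1-based; ``density`` is the cumulative-count ratio
    100*cum_disease/cum_all (0 where cum_all == 0, flagged in ``undefined``).
    ``window_density`` is a centered sliding-window density used for peak
    detection: the argmax of a cumulative-count ratio systematically lags a
    localized excess, so the peak is located on the windowed estimate.
    """

    offsets: np.ndarray
    cum_disease: np.ndarray
    cum_all: np.ndarray
    density: np.ndarray
    undefined: np.ndarray
    window_density: np.ndarray
    window_halfwidth: int
    peak_offset: int
    cumulative_peak_offset: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "cum_disease": self.cum_disease,
                "cum_all": self.cum_all,
                "density": self.density,
                "undefined": self.undefined.astype(int),
                "window_density": self.window_density,
            }
        )


@dataclass(frozen=True)
class EnrichmentResult:
    """First-intron vs non-first-intron disease enrichment."""

    n_intronic: int  # N
    n_disease_intronic: int  # K
    n_first_intron: int  # n
    n_disease_first_intron: int  # k
    ratio: Optional[float]
    p_value: float


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def compute_likelihoods(
    annotation: pd.DataFrame,
    disease_rsids: set,
    panel: ReferencePanel,
) -> Tuple[List[LikelihoodResult], List[str]]:
    """Per-class likelihoods of disease association within one panel.

    Panel rsIDs absent from the annotation table are excluded from the
    denominators and returned as the second element, never silently dropped.
    Every disease rsID counts once no matter how many associations it has.
    """
    ann_rsids = set(annotation["rsid"])
    present = panel.rsids & ann_rsids
    missing = sorted(panel.rsids - ann_rsids)
    if missing:
        log.info("panel %s: %d rsIDs absent from annotation", panel.name, len(missing))
    if not present:
        raise ValidationError(
            f"panel {panel.name!r} has no rsIDs in common with the annotation table"
        )
    sub = annotation[annotation["rsid"].isin(present)]
    is_disease = sub["rsid"].isin(disease_rsids)
    results = []
    for fc in FunctionalClass:
        mask = sub["class"] == fc.label
        n_panel = int(mask.sum())
        n_disease = int((mask & is_disease).sum())
        likelihood = 100.0 * n_disease / n_panel if n_panel else None
        results.append(
            LikelihoodResult(
                panel_name=panel.name,
                functional_class=fc,
                n_disease=n_disease,
                n_panel=n_panel,
                likelihood=likelihood,
            )
        )
    return results, missing


def gene_coverage(
    annotation: pd.DataFrame, disease_rsids: set, total_panel_genes: int
) -> float:
    """Percentage of panel genes containing >= 1 disease-associated SNP."""
    if total_panel_genes <= 0:
        raise ContractError("total_panel_genes must be positive")
    sub = annotation[annotation["rsid"].isin(disease_rsids)]
    genes = {g for g in sub["gene_id"] if isinstance(g, str) and g}
    return 100.0 * len(genes) / total_panel_genes


# ---------------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------------

def effect_sizes(
    associations: Iterable[Association],
    annotation: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    fold_or: bool = False,
) -> List[EffectSizeResult]:
    """Median odds ratio (+ seeded bootstrap SE) per functional class.

    The unit is the association, not the distinct SNP: a SNP reported in
    three studies contributes three odds ratios. Rows without an odds ratio
    are skipped. ``fold_or`` maps OR < 1 to 1/OR (magnitude folding);
    defaults to using odds ratios exactly as reported.
    """
    if B < 1:
        raise ContractError("B must be >= 1")
    class_of = dict(zip(annotation["rsid"], annotation["class"]))
    per_class: Dict[FunctionalClass, list] = {fc: [] for fc in FunctionalClass}
    n_unmapped = 0
    for a in associations:
        if not a.has_odds_ratio:
            continue
        label = class_of.get(a.rsid)
        if label is None:
            n_unmapped += 1
            continue
        value = a.odds_ratio
        if fold_or and value < 1:
            value = 1.0 / value
        per_class[FunctionalClass.from_label(label)].append(value)
    if n_unmapped:
        log.warning("%d associations reference rsIDs absent from the annotation", n_unmapped)

    rng = np.random.default_rng(seed)
    results = []
    for fc in FunctionalClass:
        ors = np.asarray(per_class[fc], dtype=float)
        n = ors.size
        if n == 0:
            log.warning("no odds-ratio-bearing associations for class %s", fc.label)
            continue
        median = float(np.median(ors))
        if n == 1:
            se = 0.0
        else:
            idx = rng.integers(0, n, size=(B, n))
            se = float(np.median(ors[idx], axis=1).std(ddof=1))
        results.append(
            EffectSizeResult(
                functional_class=fc,
                n_associations=n,
                median_or=median,
                se_median=se,
                odds_ratios=ors,
            )
        )
    return results


def mann_whitney(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> float:
    """Two-sided Mann-Whitney U p-value.

    ``auto`` uses the exact null distribution when both samples have at most
    8 observations and there are no ties, otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ContractError("mann_whitney requires two non-empty samples")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if mode == "auto":
        method = "exact" if (max(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    elif mode in ("exact", "normal"):
        method = "exact" if mode == "exact" else "asymptotic"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(1.0, max(res.pvalue, np.nextafter(0, 1))))


def pairwise_effect_tests(
    effects: List[EffectSizeResult], adjust: str = "none"
) -> pd.DataFrame:
    """Symmetric matrix of two-sided Mann-Whitney p-values across classes.

    Raw p-values by default; ``adjust`` in {"none", "bonferroni", "bh"}
    applies a multiple-testing correction over the upper triangle.
    """
    present = [e for e in effects if e.n_associations >= 1]
    if len(present) < 2:
        raise ContractError("need >= 2 classes with associations")
    labels = [e.functional_class.label for e in present]
    n = len(labels)
    mat = np.full((n, n), np.nan)
    raw = []
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            p = mann_whitney(present[i].odds_ratios, present[j].odds_ratios)
            raw.append(p)
            pairs.append((i, j))
    if adjust != "none":
        from statsmodels.stats.multitest import multipletests

        method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(adjust)
        if method is None:
            raise ValueError(f"unknown adjustment {adjust!r}")
        raw = list(multipletests(raw, method=method)[1])
    for (i, j), p in zip(pairs, raw):
        mat[i, j] = mat[j, i] = p
    return pd.DataFrame(mat, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------

def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ContractError(
            f"invalid hypergeometric arguments N={N}, K={K}, n={n}, k={k}"
        )
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def first_intron_enrichment(
    intron_table: pd.DataFrame, disease_rsids: set
) -> EnrichmentResult:
    """Enrichment of disease SNPs in first vs non-first introns.

    ``intron_table`` must contain one row per intronic SNP with columns
    ``rsid`` and ``is_first_intron`` (resolved by first-intron assignment).
    """
    if "is_first_intron" not in intron_table or intron_table["is_first_intron"].isna().any():
        raise ContractError("every record needs a resolved is_first_intron flag")
    N = len(intron_table)
    first = intron_table["is_first_intron"].astype(bool)
    disease = intron_table["rsid"].isin(disease_rsids)
    K = int(disease.sum())
    n = int(first.sum())
    k = int((first & disease).sum())
    ratio = None
    if n > 0 and N - n > 0 and K - k > 0:
        ratio = (k / n) / ((K - k) / (N - n))
    elif N == n:
        log.warning("no non-first-intron SNPs: enrichment ratio undefined")
    p = hypergeom_upper_tail(N, K, n, k)
    return EnrichmentResult(
        n_intronic=N,
        n_disease_intronic=K,
        n_first_intron=n,
        n_disease_first_intron=k,
        ratio=ratio,
        p_value=p,
    )


# ---------------------------------------------------------------------------
# First-intron density profile
# ---------------------------------------------------------------------------

DEFAULT_PEAK_WINDOW = 50


def density_profile(
    intron_table: pd.DataFrame,
    disease_rsids: set,
    max_offset: int = 1000,
    window_halfwidth: int = DEFAULT_PEAK_WINDOW,
) -> DensityProfile:
    """Cumulative density of disease SNPs along first introns.

    Input rows must be first-intron placements with a 0-based ``offset``
    column; offsets are reported 1-based. density(d) is the cumulative-count
    ratio. The peak is located as the argmax of a centered sliding-window
    density (halfwidth ``window_halfwidth`` bases, restricted to offsets
    where the full window fits; smallest offset wins ties): unlike the
    cumulative ratio, the windowed estimate peaks at the center of a
    localized excess.
    """
    sub = intron_table[intron_table["is_first_intron"].astype(bool)]
    if sub.empty:
        raise ValidationError("no first-intron SNPs: cannot build a density profile")
    off1 = sub["offset"].to_numpy(dtype=int) + 1  # 1-based
    in_window = off1 <= max_offset
    disease = sub["rsid"].isin(disease_rsids).to_numpy()

    all_counts = np.bincount(off1[in_window], minlength=max_offset + 1)[1:]
    dis_counts = np.bincount(off1[in_window & disease], minlength=max_offset + 1)[1:]

    cum_all = np.cumsum(all_counts)
    cum_disease = np.cumsum(dis_counts)
    undefined = cum_all == 0
    density = np.where(undefined, 0.0, 100.0 * cum_disease / np.maximum(cum_all, 1))

    kernel = np.ones(2 * window_halfwidth + 1)
    win_all = np.convolve(all_counts, kernel, mode="same")
    win_dis = np.convolve(dis_counts, kernel, mode="same")
    window_density = np.where(win_all > 0, 100.0 * win_dis / np.maximum(win_all, 1), 0.0)

    lo, hi = window_halfwidth, max_offset - window_halfwidth
    if lo >= hi:  # window wider than the profile: search everywhere
        lo, hi = 0, max_offset
    peak_offset = int(np.argmax(window_density[lo:hi])) + lo + 1
    cumulative_peak_offset = int(np.argmax(density)) + 1

    return DensityProfile(
        offsets=np.arange(1, max_offset + 1),
        cum_disease=cum_disease,
        cum_all=cum_all,
        density=density,
        undefined=undefined,
        window_density=window_density,
        window_halfwidth=window_halfwidth,
        peak_offset=peak_offset,
        cumulative_peak_offset=cumulative_peak_offset,
    )


# ---------------------------------------------------------------------------
# Likelihood vs effect size, and catalog roll-up
# ---------------------------------------------------------------------------

def likelihood_vs_effect(
    likelihoods: List[LikelihoodResult], effects: List[EffectSizeResult]
) -> Tuple[pd.DataFrame, Optional[float]]:
    """Scatter of per-class likelihood against median odds ratio.

    Returns a nine-row table (classes without data carry NaN) plus the
    Spearman rank correlation across classes where both quantities exist
    (None when fewer than two such classes). ``rank_residual`` is
    rank(likelihood) - rank(median OR): the most negative value flags the
    class whose likelihood lags its effect size the most.
    """
    like = {r.functional_class: r.likelihood for r in likelihoods}
    med = {e.functional_class: e.median_or for e in effects}
    rows = []
    for fc in FunctionalClass:
        rows.append(
            {
                "class": fc.label,
                "likelihood_pct": like.get(fc),
                "median_or": med.get(fc),
            }
        )
    df = pd.DataFrame(rows)
    both = df.dropna(subset=["likelihood_pct", "median_or"])
    rho = None
    if len(both) >= 2:
        lr = both["likelihood_pct"].rank()
        mr = both["median_or"].rank()
        if lr.nunique() > 1 and mr.nunique() > 1:
            rho = float(sps.spearmanr(both["likelihood_pct"], both["median_or"]).statistic)
        else:
            rho = None
        df.loc[both.index, "rank_residual"] = lr - mr
    if "rank_residual" not in df:
        df["rank_residual"] = np.nan
    return df, rho


def summary_counts(
    associations: Iterable[Association], annotation: pd.DataFrame
) -> dict:
    """Catalog roll-up: distinct studies, diseases, SNPs and genes.

    Reported twice — over all associations and over the stratum that has
    odds ratios.
    """
    gene_of = dict(zip(annotation["rsid"], annotation["gene_id"]))

    def roll(assocs: list) -> dict:
        return {
            "associations": len(assocs),
            "studies": len({a.study_id for a in assocs if a.study_id}),
            "diseases": len({a.disease_id for a in assocs if a.disease_id}),
            "snps": len({a.rsid for a in assocs}),
            "genes": len(
                {g for a in assocs if isinstance(g := gene_of.get(a.rsid), str) and g}
            ),
        }

    assocs = list(associations)
    return {
        "all": roll(assocs),
        "with_odds_ratio": roll([a for a in assocs if a.has_odds_ratio]),
    }
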