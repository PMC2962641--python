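import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import kstest

from _oracles import (
    hypergeom_upper_tail_enumeration,
    mann_whitney_exact_enumeration,
)
from snpsurvey.models import Association, ContractError, ReferencePanel, ValidationError
from snpsurvey.stats import (
    compute_likelihoods,
    density_profile,
    effect_sizes,
    first_intron_enrichment,
    gene_coverage,
    hypergeom_upper_tail,
    likelihood_vs_effect,
    mann_whitney,
    pairwise_effect_tests,
    summary_counts,
)


def make_annotation(rows):
    """rows: (rsid, class_label[, gene_id]) -> minimal annotation frame."""
    recs = []
    for i, row in enumerate(rows):
        rsid, label = row[0], row[1]
        gene = row[2] if len(row) > 2 else ""
        recs.append(
            dict(rsid=rsid, **{"class": label}, transcript_id="", intron_index=pd.NA,
                 offset=pd.NA, gene_id=gene, is_first_intron=pd.NA, chrom="chr1", pos=i)
        )
    columns = ["rsid", "class", "transcript_id", "intron_index", "offset",
               "gene_id", "is_first_intron", "chrom", "pos"]
    return pd.DataFrame(recs, columns=columns)


def make_intron_table(offsets0, first_flags, disease_flags):
    rsids = [f"rs{i}" for i in range(len(offsets0))]
    table = pd.DataFrame(
        {
            "rsid": rsids,
            "offset": offsets0,
            "is_first_intron": first_flags,
            "intron_index": [1 if f else 2 for f in first_flags],
        }
    )
    disease = {r for r, d in zip(rsids, disease_flags) if d}
    return table, disease


class TestLikelihoods:
    def test_percentage_arithmetic(self):
        rows = [(f"rs{i}", "synonymous") for i in range(400)]
        ann = make_annotation(rows)
        panel = ReferencePanel("p", frozenset(ann["rsid"]))
        disease = {f"rs{i}" for i in range(5)}
        results, missing = compute_likelihoods(ann, disease, panel)
        syn = next(r for r in results if r.functional_class.label == "synonymous")
        assert syn.likelihood == pytest.approx(1.25)
        assert syn.n_disease == 5 and syn.n_panel == 400
        assert missing == []

    def test_disjoint_disease_set_gives_zero(self):
        ann = make_annotation([(f"rs{i}", "intronic") for i in range(10)])
        panel = ReferencePanel("p", frozenset(ann["rsid"]))
        results, _ = compute_likelihoods(ann, {"rsX"}, panel)
        intr = next(r for r in results if r.functional_class.label == "intronic")
        assert intr.likelihood == 0.0

    def test_multiple_associations_count_a_snp_once(self):
        ann = make_annotation([("rs1", "utr5"), ("rs2", "utr5")])
        assocs = [Association("rs1", f"C{i}", 1.5) for i in range(3)]
        disease = {a.rsid for a in assocs}
        panel = ReferencePanel("p", frozenset(ann["rsid"]))
        results, _ = compute_likelihoods(ann, disease, panel)
        utr5 = next(r for r in results if r.functional_class.label == "utr5")
        assert utr5.n_disease == 1 and utr5.likelihood == pytest.approx(50.0)

    def test_empty_class_is_null_not_zero(self):
        ann = make_annotation([("rs1", "utr5")])
        panel = ReferencePanel("p", frozenset({"rs1"}))
        results, _ = compute_likelihoods(ann, set(), panel)
        nonsense = next(r for r in results if r.functional_class.label == "nonsense")
        assert nonsense.likelihood is None and nonsense.n_panel == 0

    def test_missing_panel_rsids_reported_and_excluded(self):
        ann = make_annotation([("rs1", "utr5")])
        panel = ReferencePanel("p", frozenset({"rs1", "rs_nope"}))
        results, missing = compute_likelihoods(ann, set(), panel)
        assert missing == ["rs_nope"]
        assert sum(r.n_panel for r in results) == 1

    def test_fully_disjoint_panel_is_an_error(self):
        ann = make_annotation([("rs1", "utr5")])
        with pytest.raises(ValidationError, match="ghost"):
            compute_likelihoods(ann, set(), ReferencePanel("ghost", frozenset({"rsX"})))

    def test_panel_partition_sums(self):
        labels = ["utr5", "utr3", "intronic", "synonymous"]
        ann = make_annotation([(f"rs{i}", labels[i % 4]) for i in range(100)])
        disease = {f"rs{i}" for i in range(0, 100, 10)}
        panel = ReferencePanel("p", frozenset(ann["rsid"]))
        results, _ = compute_likelihoods(ann, disease, panel)
        assert sum(r.n_panel for r in results) == 100
        assert sum(r.n_disease for r in results) == len(disease)


class TestGeneCoverage:
    def test_catalog_scale_arithmetic(self):
        # 1,003 genes with a disease SNP over a 21,813-gene panel
        ann = make_annotation(
            [(f"rs{i}", "intronic", f"G{i}") for i in range(1003)]
        )
        pct = gene_coverage(ann, set(ann["rsid"]), 21813)
        assert round(pct, 1) == 4.6

    def test_extremes(self):
        ann = make_annotation([("rs1", "utr5", "G1")])
        assert gene_coverage(ann, set(), 10) == 0.0
        assert gene_coverage(ann, {"rs1"}, 1) == 100.0


class TestEffectSizes:
    def test_median_examples(self):
        ann = make_annotation([("rs1", "synonymous")])
        assocs = [Association("rs1", "C1", v) for v in (1.2, 1.5, 2.0)]
        (res,) = effect_sizes(assocs, ann, B=100, seed=1)
        assert res.median_or == pytest.approx(1.5)

        (res,) = effect_sizes([Association("rs1", "C1", 1.5)], ann, B=100, seed=1)
        assert res.median_or == pytest.approx(1.5) and res.se_median == 0.0

    def test_bootstrap_reproducibility(self):
        ann = make_annotation([("rs1", "utr3")])
        assocs = [Association("rs1", "C1", v) for v in (1.0, 2.0, 3.0, 4.0)]
        a = effect_sizes(assocs, ann, B=1000, seed=17)[0]
        b = effect_sizes(assocs, ann, B=1000, seed=17)[0]
        assert a.median_or == pytest.approx(2.5)
        assert a.se_median == b.se_median > 0

    def test_rows_without_or_are_excluded(self):
        ann = make_annotation([("rs1", "utr3")])
        assocs = [Association("rs1", "C1", 2.0), Association("rs1", "C2", None)]
        (res,) = effect_sizes(assocs, ann, B=10, seed=0)
        assert res.n_associations == 1

    def test_fold_or(self):
        ann = make_annotation([("rs1", "utr3")])
        (res,) = effect_sizes([Association("rs1", "C1", 0.5)], ann, B=10, seed=0,
                              fold_or=True)
        assert res.median_or == pytest.approx(2.0)

    def test_empty_class_omitted(self):
        ann = make_annotation([("rs1", "utr3")])
        assert effect_sizes([], ann, B=10, seed=0) == []


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        assert mann_whitney([1, 2, 3], [4, 5, 6], mode="exact") == pytest.approx(0.1)

    def test_identical_samples_give_p_one(self):
        assert mann_whitney([5], [5]) == 1.0
        assert mann_whitney([1, 2, 3], [1, 2, 3]) == 1.0

    def test_empty_sample_is_contract_error(self):
        with pytest.raises(ContractError):
            mann_whitney([], [1.0])

    @given(
        st.lists(st.integers(1, 40), min_size=1, max_size=5, unique=True),
        st.lists(st.integers(41, 80), min_size=1, max_size=5, unique=True),
    )
    def test_exact_mode_matches_enumeration(self, x, y):
        # shift y down so groups interleave while staying tie-free
        y = [v - 40.5 for v in y]
        assert mann_whitney(x, y, mode="exact") == pytest.approx(
            mann_whitney_exact_enumeration(x, y), abs=1e-12
        )

    def test_normal_mode_close_to_exact_at_n8(self, rng):
        for _ in range(20):
            vals = rng.permutation(np.arange(16, dtype=float))
            x, y = vals[:8], vals[8:]
            assert abs(
                mann_whitney(x, y, mode="normal") - mann_whitney(x, y, mode="exact")
            ) < 0.02

    def test_null_p_values_are_uniform(self, rng):
        ps = []
        for _ in range(2000):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            ps.append(mann_whitney(x, y, mode="normal"))
        assert kstest(ps, "uniform").pvalue > 0.01


class TestPairwiseTests:
    def _effects(self, samples):
        ann = make_annotation([])
        out = []
        labels = ["nonsense", "nonsynonymous", "synonymous"]
        from snpsurvey.models import FunctionalClass
        from snpsurvey.stats import EffectSizeResult

        for label, ors in zip(labels, samples):
            ors = np.asarray(ors, dtype=float)
            out.append(
                EffectSizeResult(
                    functional_class=FunctionalClass.from_label(label),
                    n_associations=len(ors),
                    median_or=float(np.median(ors)),
                    se_median=0.0,
                    odds_ratios=ors,
                )
            )
        return out

    def test_identical_samples_and_symmetry(self):
        mat = pairwise_effect_tests(self._effects([[1, 2, 3], [1, 2, 3]]))
        assert mat.loc["nonsense", "nonsynonymous"] == 1.0
        assert mat.equals(mat.T)

    def test_separated_distributions_detected(self, rng):
        hits = 0
        for _ in range(20):
            x = np.exp(rng.normal(np.log(1.7), 0.4, size=200))
            y = np.exp(rng.normal(np.log(1.2), 0.4, size=200))
            mat = pairwise_effect_tests(self._effects([x, y]))
            hits += mat.loc["nonsense", "nonsynonymous"] < 0.01
        assert hits >= 19

    def test_adjustment_never_decreases_p(self, rng):
        samples = [rng.normal(size=10) + i * 0.1 for i in range(3)]
        raw = pairwise_effect_tests(self._effects(samples))
        bonf = pairwise_effect_tests(self._effects(samples), adjust="bonferroni")
        mask = ~np.eye(3, dtype=bool)
        assert (bonf.values[mask] >= raw.values[mask] - 1e-12).all()


class TestHypergeometric:
    def test_worked_examples(self):
        assert hypergeom_upper_tail(10, 5, 4, 4) == pytest.approx(5 / 210)
        assert hypergeom_upper_tail(10, 5, 5, 5) == pytest.approx(1 / 252)
        assert hypergeom_upper_tail(10, 5, 4, 0) == 1.0

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ContractError):
            hypergeom_upper_tail(10, 5, 4, 5)

    @given(st.integers(1, 8), st.data())
    def test_matches_enumeration(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(K, n)))
        assert hypergeom_upper_tail(N, K, n, k) == pytest.approx(
            hypergeom_upper_tail_enumeration(N, K, n, k), abs=1e-12
        )


class TestEnrichment:
    def test_ratio_arithmetic(self):
        table, disease = make_intron_table(
            [0] * 200, [True] * 100 + [False] * 100,
            [True, True] + [False] * 98 + [True] + [False] * 99,
        )
        res = first_intron_enrichment(table, disease)
        assert res.ratio == pytest.approx(2.0)
        assert (res.n_intronic, res.n_disease_intronic,
                res.n_first_intron, res.n_disease_first_intron) == (200, 3, 100, 2)

    def test_equal_densities_give_unity(self):
        table, disease = make_intron_table(
            [0] * 200, [True] * 100 + [False] * 100,
            ([True] + [False] * 99) * 2,
        )
        assert first_intron_enrichment(table, disease).ratio == pytest.approx(1.0)

    def test_no_non_first_introns_is_undefined(self):
        table, disease = make_intron_table([0, 1], [True, True], [True, False])
        assert first_intron_enrichment(table, disease).ratio is None


class TestDensityProfile:
    def test_cumulative_arithmetic(self):
        # 1-based offsets 10, 20, 30 with only the first disease-associated
        table, disease = make_intron_table([9, 19, 29], [True] * 3, [True, False, False])
        prof = density_profile(table, disease, max_offset=40)
        assert prof.density[9] == pytest.approx(100.0)
        assert prof.density[19] == pytest.approx(50.0)
        assert prof.density[29] == pytest.approx(100 / 3)
        assert prof.undefined[:9].all()

    def test_all_healthy_gives_zero_density(self):
        table, disease = make_intron_table([5, 6, 7], [True] * 3, [False] * 3)
        prof = density_profile(table, disease, max_offset=10)
        assert (prof.density == 0).all()

    def test_counts_are_monotone(self, rng):
        offs = rng.integers(0, 1000, size=5000)
        dis = rng.random(5000) < 0.1
        table, disease = make_intron_table(offs, [True] * 5000, dis)
        prof = density_profile(table, disease)
        assert (np.diff(prof.cum_all) >= 0).all()
        assert (np.diff(prof.cum_disease) >= 0).all()
        assert (prof.cum_disease <= prof.cum_all).all()

    def test_requires_first_intron_snps(self):
        table, disease = make_intron_table([1, 2], [False, False], [False, False])
        with pytest.raises(ValidationError):
            density_profile(table, disease)

    def test_windowed_peak_finds_a_planted_excess(self):
        from snpsurvey.simulate import simulate_first_intron_offsets

        table, disease = simulate_first_intron_offsets(150_000, seed=5)
        prof = density_profile(table, disease)
        assert 60 <= prof.peak_offset <= 100


class TestLikelihoodVsEffect:
    def _inputs(self, likes, meds):
        ann = make_annotation([(f"rs{i}", label) for i, label in enumerate(likes)])
        panel = ReferencePanel("p", frozenset(ann["rsid"]))
        from snpsurvey.models import FunctionalClass
        from snpsurvey.stats import EffectSizeResult, LikelihoodResult

        lres = [
            LikelihoodResult("p", FunctionalClass.from_label(c), 0, 1, v)
            for c, v in likes.items()
        ]
        eres = [
            EffectSizeResult(FunctionalClass.from_label(c), 1, v, 0.0,
                             np.asarray([v]))
            for c, v in meds.items()
        ]
        return lres, eres

    def test_comonotone_inputs_give_rho_one(self):
        likes = {"nonsense": 3.0, "nonsynonymous": 2.0, "synonymous": 1.0}
        meds = {"nonsense": 1.8, "nonsynonymous": 1.7, "synonymous": 1.6}
        _, rho = likelihood_vs_effect(*self._inputs(likes, meds))
        assert rho == pytest.approx(1.0)

    def test_single_class_rho_undefined(self):
        _, rho = likelihood_vs_effect(*self._inputs({"utr5": 1.0}, {"utr5": 1.5}))
        assert rho is None

    def test_deflated_class_has_largest_negative_rank_residual(self):
        likes = {"nonsense": 3.0, "nonsynonymous": 2.0, "synonymous": 1.5,
                 "utr5": 1.2, "utr3": 0.1}
        meds = {"nonsense": 1.8, "nonsynonymous": 1.7, "synonymous": 1.65,
                "utr5": 1.6, "utr3": 1.75}
        df, _ = likelihood_vs_effect(*self._inputs(likes, meds))
        worst = df.loc[df["rank_residual"].idxmin(), "class"]
        assert worst == "utr3"


class TestSummaryCounts:
    def test_distinct_count_semantics(self):
        ann = make_annotation([("rs1", "utr5", "G1"), ("rs2", "intronic", "G1"),
                               ("rs3", "utr3", "G1")])
        assocs = [
            Association("rs1", "C1", 1.5, study_id="S1"),
            Association("rs2", "C1", None, study_id="S2"),
            Association("rs3", "C2", 2.0, study_id="S1"),
        ]
        s = summary_counts(assocs, ann)
        assert s["all"] == dict(associations=3, studies=2, diseases=2, snps=3, genes=1)
        assert s["with_odds_ratio"]["associations"] == 2

    def test_empty_catalog(self):
        s = summary_counts([], make_annotation([]))
        assert s["all"] == dict(associations=0, studies=0, diseases=0, snps=0, genes=0)
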