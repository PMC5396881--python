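"""The resampling enrichment test and its statistical behavior."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from meshddi import synth
from meshddi.corpus import partition
from meshddi.enrichment import (
    SamplingConfig,
    TermEnrichment,
    enrich,
    null_distribution,
    term_article_count,
    z_pvalue,
)
from meshddi.vocab import TermCategory

from conftest import make_article


def _group_b(n, term="X", k=0):
    """n articles, the first k carrying descriptor `term`."""
    return [
        make_article(i, [term] if i < k else ["Filler"]) for i in range(n)
    ]


class TestTermArticleCount:
    def test_absent_term_counts_zero(self):
        assert term_article_count(_group_b(5), "Nope") == 0

    def test_repeated_qualifiers_count_once(self):
        art = make_article(1, ["X/metabolism", "X/blood"])
        assert term_article_count([art], "X") == 1

    def test_matches_generator_truth(self, small_corpus):
        articles, truth, _ = small_corpus
        for term, counts in list(truth["term_counts"].items())[:8]:
            assert term_article_count(articles, term) == counts["a"] + counts["b"]


class TestNullDistribution:
    def test_term_in_all_of_b_is_degenerate(self):
        group_b = _group_b(10, k=10)
        null = null_distribution(group_b, ["X"], 5, SamplingConfig(n_resamples=50, seed=0))
        ns = null["X"]
        assert ns.mean == 5.0 and ns.sd == 0.0
        assert (ns.counts == 5).all()

    def test_converges_to_hypergeometric_moments(self):
        # N=10 articles, K=4 with the term, draws of n=5: exact mean 2.0,
        # exact SD sqrt(n*K/N*(1-K/N)*(N-n)/(N-1))
        N, K, n = 10, 4, 5
        group_b = _group_b(N, k=K)
        cfg = SamplingConfig(n_resamples=1000, seed=123)
        ns = null_distribution(group_b, ["X"], n, cfg)["X"]
        exact_mean = n * K / N
        exact_sd = math.sqrt(n * (K / N) * (1 - K / N) * (N - n) / (N - 1))
        assert abs(ns.mean - exact_mean) < 3 * exact_sd / math.sqrt(cfg.n_resamples)
        assert ns.sd == pytest.approx(exact_sd, rel=0.1)

    def test_exhaustive_enumeration_oracle(self):
        # all C(6,3)=20 subsets enumerated by brute force give the exact law
        N, K, n = 6, 2, 3
        group_b = _group_b(N, k=K)
        counts = [
            sum(1 for i in subset if i < K)
            for subset in itertools.combinations(range(N), n)
        ]
        exact_mean = np.mean(counts)
        exact_sd = np.std(counts, ddof=0)
        ns = null_distribution(
            group_b, ["X"], n, SamplingConfig(n_resamples=2000, seed=9)
        )["X"]
        assert abs(ns.mean - exact_mean) < 3 * exact_sd / math.sqrt(2000)

    def test_same_seed_identical_counts(self):
        group_b = _group_b(20, k=7)
        cfg = SamplingConfig(n_resamples=100, seed=77)
        a = null_distribution(group_b, ["X"], 10, cfg)["X"]
        b = null_distribution(group_b, ["X"], 10, cfg)["X"]
        assert np.array_equal(a.counts, b.counts)

    def test_sample_size_exceeding_b_fatal_with_sizes(self):
        with pytest.raises(ValueError, match="11.*10|10.*11"):
            null_distribution(_group_b(10), ["X"], 11, SamplingConfig())


class TestZPvalue:
    def test_count_at_null_mean_gives_half(self):
        z, p = z_pvalue(3, 3.0, 1.0)
        assert z == 0.0 and p == pytest.approx(0.5)

    def test_against_erf_based_oracle(self):
        z, p = z_pvalue(4, 2.0, 0.8165)
        assert z == pytest.approx(2.449, abs=1e-3)
        # independent upper-tail computation via the complementary error function
        assert p == pytest.approx(0.5 * math.erfc(z / math.sqrt(2)), abs=1e-12)
        assert p == pytest.approx(0.0072, abs=5e-4)

    def test_depletion_never_significant(self):
        z, p = z_pvalue(0, 5.0, 1.0)
        assert z == -5.0 and p == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_sd_sentinels(self):
        assert z_pvalue(6, 5.0, 0.0) == (math.inf, 0.0)
        assert z_pvalue(5, 5.0, 0.0) == (-math.inf, 1.0)
        assert z_pvalue(4, 5.0, 0.0) == (-math.inf, 1.0)

    def test_monotone_in_observed_count(self):
        ps = [z_pvalue(c, 10.0, 2.5)[1] for c in range(0, 30)]
        assert all(p2 <= p1 for p1, p2 in zip(ps, ps[1:]))


class TestEnrich:
    @pytest.fixture(scope="class")
    @staticmethod
    def fitted(enriched_corpus):
        articles, truth, vocab = enriched_corpus
        pc = partition(articles, drug=truth["query_drug"])
        model = TermEnrichment(
            pc, vocab, config=SamplingConfig(n_resamples=1000, seed=21)
        )
        return model, model.fit(), truth

    def test_planted_terms_all_selected(self, fitted):
        _, results, truth = fitted
        planted = {t["term"] for t in truth["planted"]}
        selected = {r.term for r in results.selected()}
        assert planted <= selected

    def test_decoy_false_positive_rate_near_alpha(self, fitted):
        _, results, truth = fitted
        planted = {t["term"] for t in truth["planted"]}
        decoys = [r for r in results if r.term not in planted]
        frac = np.mean([r.p_value < 0.1 for r in decoys])
        # nominal alpha +/- 3 binomial SE at this decoy count
        assert frac <= 0.1 + 3 * math.sqrt(0.1 * 0.9 / len(decoys))

    def test_results_sorted_by_pvalue_then_count_then_term(self, fitted):
        _, results, _ = fitted
        keys = [(r.p_value, -r.count_a, r.term) for r in results]
        assert keys == sorted(keys)

    def test_selection_requires_count_strictly_above_min_freq(self):
        # a term in all 5 group A articles still fails min_freq = 5
        group_a = [make_article(i, ["Drug Interactions", "Ubiquitol"]) for i in range(5)]
        group_b = [make_article(100 + i, ["Filler"]) for i in range(50)]
        vocab = synth.MeshVocabulary(
            descriptors={"Ubiquitol": ["D03.100"], "Filler": ["C01.1"]},
            drug_list={"Ubiquitol"},
        )
        pc = partition(group_a + group_b)
        (res,) = enrich(pc, vocab, cfg=SamplingConfig(n_resamples=200, seed=1))
        assert res.count_a == 5
        assert res.p_value < 0.1
        assert not res.selected

    def test_fixed_seed_bit_identical_results(self, fitted):
        model, results, _ = fitted
        again = model.fit()
        assert again.results == results.results

    def test_null_corpus_pvalues_roughly_uniform(self):
        # identical term distributions in A and B: KS against U(0,1) at 1%
        spec = synth.GeneratorSpec(
            n_a=200, n_b=1000,
            vocab_spec=synth.VocabSpec(10, 10, 10, 0, decoy_prevalence=0.2),
            seed=31,
        )
        articles, truth, vocab = synth.generate(spec)
        pc = partition(articles, drug=truth["query_drug"])
        results = enrich(pc, vocab, cfg=SamplingConfig(n_resamples=1000, seed=32))
        ps = [r.p_value for r in results if r.null_mean >= 10]
        assert len(ps) >= 20
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_shared_null_reused_across_terms(self, fitted):
        model, results, _ = fitted
        null = results.null
        assert len(null) == len(results)
        # one shared resample set: every per-term count array has the
        # configured number of draws
        assert all(ns.counts.shape == (1000,) for ns in null.values())

    def test_empty_group_a_rejected(self, small_corpus):
        articles, _, vocab = small_corpus
        pc = partition(articles)
        pc.group_a.clear()
        with pytest.raises(ValueError):
            TermEnrichment(pc, vocab)

    def test_bh_correction_only_tightens_selection(self, enriched_corpus):
        articles, truth, vocab = enriched_corpus
        pc = partition(articles, drug=truth["query_drug"])
        raw = TermEnrichment(pc, vocab, config=SamplingConfig(seed=5)).fit()
        bh = TermEnrichment(
            pc, vocab, config=SamplingConfig(seed=5, correction="bh")
        ).fit()
        raw_sel = {r.term for r in raw.selected()}
        bh_sel = {r.term for r in bh.selected()}
        assert bh_sel <= raw_sel

    def test_summary_reports_counts(self, fitted):
        _, results, _ = fitted
        text = results.summary()
        assert "group A" in text and "selected:" in text


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs", [dict(n_resamples=0), dict(alpha=0.0), dict(min_freq=-1),
                   dict(correction="bonferroni")]
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SamplingConfig(**kwargs)
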