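"""Resampling-based MeSH term enrichment — the pipeline's core statistic.

For each candidate term the observed number of DDI-related articles
(group A) containing it is compared against a null distribution built by
repeatedly drawing ``|A|`` articles from the DDI-unrelated group B
*without replacement* and counting the term in each draw.  With null
mean :math:`\\mu` and standard deviation :math:`\\sigma` (unbiased,
``n-1`` denominator) the statistic is

.. math:: z = (c_A - \\mu) / \\sigma, \\qquad p = P(Z \\ge z)

a one-sided upper-tail normal probability — the hypothesis is that the
term is *more* frequent in DDI-related literature, so depletion is never
significant.  A term is selected when its group A count exceeds
``min_freq`` (default 5, strict) and :math:`p < \\alpha` (default 0.1).

A single shared set of resamples serves all terms: every draw counts
every candidate term at once, which preserves cross-term correlation and
costs no more than one term would.

The public surface follows the model/results idiom: build a
:class:`TermEnrichment` from a partitioned corpus and a vocabulary, call
:meth:`~TermEnrichment.fit`, and read estimates off the returned
:class:`EnrichmentResults` (or its :meth:`~EnrichmentResults.summary`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._text import norm_term
from .cooccur import build_incidence
from .corpus import PartitionedCorpus
from .medline import Article
from .vocab import CANDIDATE_CATEGORIES, MeshVocabulary, TermCategory, candidate_terms

__all__ = [
    "SamplingConfig",
    "TermEnrichmentResult",
    "NullStats",
    "TermEnrichment",
    "EnrichmentResults",
    "term_article_count",
    "null_distribution",
    "z_pvalue",
    "enrich",
]


@dataclass(frozen=True)
class SamplingConfig:
    """Knobs of the resampling test.

    n_resamples
        Number of random draws from group B building the null (default
        1000).
    seed
        Seed for the resampling RNG; fixed seed means bit-identical
        results.
    alpha
        Significance level on the (optionally BH-adjusted) p-value,
        default 0.1.
    min_freq
        A term must appear in *more than* this many group A articles
        (strict inequality), default 5.
    correction
        ``None`` (raw p-values, as in the original procedure) or ``"bh"``
        for Benjamini–Hochberg adjustment of the selection rule.
    """

    n_resamples: int = 1000
    seed: int = 0
    alpha: float = 0.1
    min_freq: int = 5
    correction: str | None = None

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.min_freq < 0:
            raise ValueError("min_freq must be non-negative")
        if self.correction not in (None, "bh"):
            raise ValueError(f"unknown correction {self.correction!r}")


@dataclass(frozen=True)
class NullStats:
    """Resampled null for one term: mean, SD and the raw per-draw counts."""

    mean: float
    sd: float
    counts: np.ndarray

    def __eq__(self, other) -> bool:  # ndarray-aware equality
        return (
            isinstance(other, NullStats)
            and self.mean == other.mean
            and self.sd == other.sd
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class TermEnrichmentResult:
    """Per-term test outcome."""

    term: str
    category: TermCategory
    count_a: int
    null_mean: float
    null_sd: float
    z: float
    p_value: float
    selected: bool
    p_adjusted: float | None = None


def term_article_count(articles: Iterable[Article], term: str) -> int:
    """Number of articles whose descriptors include ``term``.

    Document-level presence: repeated qualifiers of the same descriptor
    contribute once.
    """
    key = norm_term(term)
    return sum(1 for a in articles if key in a.descriptor_set())


def null_distribution(
    group_b: Sequence[Article],
    terms: Iterable[str],
    sample_size: int,
    cfg: SamplingConfig,
) -> dict[str, NullStats]:
    """Build the shared resampled null for every term at once.

    Each of ``cfg.n_resamples`` iterations draws ``sample_size`` articles
    from group B uniformly without replacement and counts each term.
    Reproducible given ``cfg.seed``.
    """
    term_list = list(dict.fromkeys(terms))
    n_b = len(group_b)
    if sample_size > n_b:
        raise ValueError(
            f"sample_size ({sample_size}) exceeds group B size ({n_b})"
        )
    incidence = build_incidence(group_b, term_list)  # n_b x n_terms
    rng = np.random.default_rng(cfg.seed)
    counts = np.empty((cfg.n_resamples, len(term_list)), dtype=np.int64)
    for i in range(cfg.n_resamples):
        sel = rng.choice(n_b, size=sample_size, replace=False)
        counts[i] = incidence[sel].sum(axis=0)
    means = counts.mean(axis=0)
    sds = counts.std(axis=0, ddof=1) if cfg.n_resamples > 1 else np.zeros(len(term_list))
    return {
        t: NullStats(float(means[j]), float(sds[j]), counts[:, j].copy())
        for j, t in enumerate(term_list)
    }


def z_pvalue(count_a: float, null_mean: float, null_sd: float) -> tuple[float, float]:
    """One-sided upper-tail normal p-value of the observed count.

    Degenerate null (``null_sd == 0``): p is 0 when the observed count
    beats the constant null, else 1, with an infinite-z sentinel.
    """
    if null_sd < 0:
        raise ValueError("null_sd must be >= 0")
    if null_sd == 0:
        if count_a > null_mean:
            return math.inf, 0.0
        return -math.inf, 1.0
    z = (count_a - null_mean) / null_sd
    return z, float(stats.norm.sf(z))


class TermEnrichment:
    """Model object: candidate terms of a partitioned corpus vs. a resampled null.

    Parameters
    ----------
    corpus
        The group A / group B split for the query drug.
    vocab
        MeSH vocabulary used to bucket candidates into drug / protein /
        phenomena categories.
    categories
        Categories to test (default: all three candidate categories).
    config
        Resampling and selection parameters.
    """

    def __init__(
        self,
        corpus: PartitionedCorpus,
        vocab: MeshVocabulary,
        categories: Iterable[TermCategory] = CANDIDATE_CATEGORIES,
        config: SamplingConfig | None = None,
    ):
        if corpus.n_a < 1:
            raise ValueError("group A is empty; nothing to test")
        if corpus.n_b < corpus.n_a:
            raise ValueError(
                f"group B ({corpus.n_b}) must be at least as large as group A ({corpus.n_a})"
            )
        self.corpus = corpus
        self.vocab = vocab
        self.categories = tuple(categories)
        self.config = config or SamplingConfig()
        buckets = candidate_terms(
            vocab, corpus.group_a, self.categories, exclude_drug=corpus.drug
        )
        self.candidates: dict[TermCategory, list[str]] = {
            c: sorted(buckets.get(c, set())) for c in self.categories
        }

    def fit(self, seed: int | None = None) -> "EnrichmentResults":
        """Run the resampling test; ``seed`` overrides the configured seed."""
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        term_cat = [(t, c) for c in self.categories for t in self.candidates[c]]
        terms = [t for t, _ in term_cat]
        null = null_distribution(self.corpus.group_b, terms, self.corpus.n_a, cfg)
        inc_a = build_incidence(self.corpus.group_a, terms) if terms else None
        counts_a = inc_a.sum(axis=0) if inc_a is not None else np.empty(0, dtype=int)

        rows = []
        for j, (term, cat) in enumerate(term_cat):
            ns = null[term]
            c_a = int(counts_a[j])
            z, p = z_pvalue(c_a, ns.mean, ns.sd)
            rows.append((term, cat, c_a, ns.mean, ns.sd, z, p))

        p_adj: list[float | None]
        if cfg.correction == "bh" and rows:
            adjusted = stats.false_discovery_control([r[6] for r in rows], method="bh")
            p_adj = [float(q) for q in adjusted]
        else:
            p_adj = [None] * len(rows)

        results = []
        for (term, cat, c_a, mu, sd, z, p), q in zip(rows, p_adj):
            p_for_selection = q if q is not None else p
            selected = (c_a > cfg.min_freq) and (p_for_selection < cfg.alpha)
            results.append(
                TermEnrichmentResult(
                    term=term, category=cat, count_a=c_a, null_mean=mu,
                    null_sd=sd, z=z, p_value=p, selected=selected, p_adjusted=q,
                )
            )
        results.sort(key=lambda r: (r.p_value, -r.count_a, r.term))
        return EnrichmentResults(results=results, config=cfg, model=self, null=null)


@dataclass
class EnrichmentResults:
    """Fitted enrichment results: per-term estimates, selection flags, exports."""

    results: list[TermEnrichmentResult]
    config: SamplingConfig
    model: TermEnrichment | None = None
    null: Mapping[str, NullStats] | None = None

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    def selected(self, category: TermCategory | str | None = None) -> list[TermEnrichmentResult]:
        cat = TermCategory(category) if category is not None else None
        return [
            r for r in self.results if r.selected and (cat is None or r.category is cat)
        ]

    def to_frame(self) -> pd.DataFrame:
        """Results as a DataFrame ordered by ascending p-value."""
        return pd.DataFrame(
            {
                "term": [r.term for r in self.results],
                "category": [r.category.value for r in self.results],
                "count_a": [r.count_a for r in self.results],
                "null_mean": [r.null_mean for r in self.results],
                "null_sd": [r.null_sd for r in self.results],
                "z": [r.z for r in self.results],
                "p_value": [r.p_value for r in self.results],
                "selected": [r.selected for r in self.results],
            }
        )

    def to_tsv(self, dest, header_comment: str | None = None) -> None:
        df = self.to_frame()
        own = not hasattr(dest, "write")
        handle = open(dest, "w", encoding="utf-8") if own else dest
        try:
            if header_comment:
                handle.write(f"# {header_comment}\n")
            df.to_csv(handle, sep="\t", index=False, float_format="%.10g")
        finally:
            if own:
                handle.close()

    def summary(self, top: int = 20) -> str:
        """Human-readable run summary plus the top of the result table."""
        cfg = self.config
        n_sel = sum(r.selected for r in self.results)
        per_cat = {
            c.value: sum(1 for r in self.results if r.category is c)
            for c in (self.model.categories if self.model else [])
        }
        lines = [
            "MeSH term enrichment (resampled null, Z-statistic)",
            "=" * 58,
        ]
        if self.model is not None:
            lines += [
                f"group A (DDI-related):   {self.model.corpus.n_a:>6d} articles",
                f"group B (DDI-unrelated): {self.model.corpus.n_b:>6d} articles",
            ]
        lines += [
            f"resamples: {cfg.n_resamples}   seed: {cfg.seed}   "
            f"alpha: {cfg.alpha}   min freq: >{cfg.min_freq}"
            + (f"   correction: {cfg.correction}" if cfg.correction else ""),
            f"candidates: {len(self.results)}"
            + (f" ({', '.join(f'{k} {v}' for k, v in per_cat.items())})" if per_cat else ""),
            f"selected:   {n_sel}",
            "-" * 58,
        ]
        df = self.to_frame().head(top)
        with pd.option_context("display.width", 120, "display.max_columns", 20):
            lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def enrich(
    corpus: PartitionedCorpus,
    vocab: MeshVocabulary,
    categories: Iterable[TermCategory] = CANDIDATE_CATEGORIES,
    cfg: SamplingConfig | None = None,
) -> list[TermEnrichmentResult]:
    """Functional wrapper: fit a :class:`TermEnrichment` and return the rows."""
    return TermEnrichment(corpus, vocab, categories, cfg).fit().results
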