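"""Partitioning a drug's literature into DDI-related and DDI-unrelated groups.

An article counts as DDI-related (group A) when at least one of the eight
interaction-type MeSH descriptors appears among its headings; matching is
on the bare descriptor only — qualifiers and abstract text are ignored.
Everything else is group B.  Record-level filters (publication-date
cutoff, review exclusion) are applied before partitioning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Sequence

from ._text import norm_term
from .medline import Article

logger = logging.getLogger(__name__)

__all__ = [
    "INTERACTION_TERMS",
    "PartitionedCorpus",
    "partition",
    "filter_reviews",
    "filter_by_date",
]

#: The eight interaction-type descriptors defining the DDI-related group.
INTERACTION_TERMS: tuple[str, ...] = (
    "Drug Interactions",
    "Drug Agonism",
    "Drug Partial Agonism",
    "Drug Antagonism",
    "Drug Inverse Agonism",
    "Drug Synergism",
    "Food-Drug Interactions",
    "Herb-Drug Interactions",
)


@dataclass
class PartitionedCorpus:
    """Group A (DDI-related) / group B (DDI-unrelated) split for one drug."""

    drug: str | None
    group_a: list[Article]
    group_b: list[Article]
    filters_applied: dict = field(default_factory=dict)

    @property
    def n_a(self) -> int:
        return len(self.group_a)

    @property
    def n_b(self) -> int:
        return len(self.group_b)


def _has_interaction(article: Article, interaction_keys: frozenset[str]) -> bool:
    return not article.descriptor_set().isdisjoint(interaction_keys)


def partition(
    articles: Sequence[Article],
    interaction_terms: Iterable[str] | None = None,
    drug: str | None = None,
) -> PartitionedCorpus:
    """Assign each article to group A or group B.

    An article lands in group A iff any of ``interaction_terms`` (default:
    the eight standard interaction descriptors) appears among its
    qualifier-stripped MeSH descriptors.  The split is a true bipartition
    and idempotent.  A duplicate PMID in the input is fatal.
    """
    terms = tuple(interaction_terms) if interaction_terms is not None else INTERACTION_TERMS
    keys = frozenset(norm_term(t) for t in terms)
    seen: set[str] = set()
    group_a: list[Article] = []
    group_b: list[Article] = []
    for art in articles:
        if art.pmid in seen:
            raise ValueError(f"duplicate pmid in input: {art.pmid}")
        seen.add(art.pmid)
        (group_a if _has_interaction(art, keys) else group_b).append(art)
    return PartitionedCorpus(
        drug=drug,
        group_a=group_a,
        group_b=group_b,
        filters_applied={"interaction_terms": list(terms)},
    )


def filter_reviews(articles: Iterable[Article]) -> list[Article]:
    """Drop every article typed as a review (case-insensitive match on 'Review')."""
    return [
        a for a in articles
        if not any(pt.strip().casefold() == "review" for pt in a.pub_types)
    ]


def filter_by_date(articles: Iterable[Article], date_end: date) -> list[Article]:
    """Keep articles published on or before ``date_end``.

    Year-only dates are compared by year (an article dated just "2015"
    passes a 2015-12-31 cutoff).  Articles with no parsable year are
    excluded and logged.
    """
    kept: list[Article] = []
    dropped_missing = 0
    for art in articles:
        if art.pub_date is None:
            dropped_missing += 1
            continue
        if art.pub_date.on_or_before(date_end):
            kept.append(art)
    if dropped_missing:
        logger.info("date filter: %d article(s) with missing year excluded", dropped_missing)
    return kept
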