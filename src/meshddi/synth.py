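"""Synthetic MEDLINE corpora with known ground truth.

The generator emulates the statistical structure the enrichment test
assumes: a query drug's literature split into a DDI-related group A
(every article carries one of the eight interaction-type descriptors)
and a DDI-unrelated group B, with each candidate term included in an
article by an independent Bernoulli draw at the group's prevalence.
Planted terms have group A prevalence ``min(1, risk_ratio *
prevalence_b)``; decoys use one shared baseline prevalence in both
groups.  Optional pairwise co-mention excess forces joint inclusion with
the stated probability, and a review fraction types articles as reviews.
Every generated corpus ships its exact per-term, per-group counts as a
truth record, so pipeline bookkeeping can be audited cell by cell.

Real literature is denser and far more correlated than this; the
generator only guarantees what the test's null requires —
exchangeability of group B articles — plus known marginal effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._text import norm_term
from .corpus import INTERACTION_TERMS
from .medline import Article, MeshHeading, PubDate, write_medline
from .vocab import MeshVocabulary, write_mesh_tsv

__all__ = [
    "VocabSpec",
    "PlantedTerm",
    "Comention",
    "GeneratorSpec",
    "generate",
    "generate_pair_corpus",
    "save_corpus",
]

#: Default query-drug descriptor used by generated corpora.
DEFAULT_QUERY_DRUG = "Examplinib"


@dataclass(frozen=True)
class VocabSpec:
    """How many auto-named decoy descriptors to create per category.

    Decoy names and tree numbers encode their category (drugs get a
    ``D03`` chemistry tree and drug-list membership, proteins ``D08`` /
    ``D12.776``, phenomena ``G03``/``G04``/``G06``/``G07``, other
    ``C01``), so the vocabulary fixture is self-describing.  Every decoy
    appears in both groups at ``decoy_prevalence``.
    """

    n_drugs: int = 20
    n_proteins: int = 15
    n_phenomena: int = 15
    n_other: int = 10
    decoy_prevalence: float = 0.05


@dataclass(frozen=True)
class PlantedTerm:
    """A term with a controlled enrichment effect.

    prevalence in group A = min(1, risk_ratio * prevalence_b); a
    risk_ratio of 1 plants a null (decoy-like) term at a chosen
    prevalence.
    """

    term: str
    category: str  # drug | protein | phenomena | other
    prevalence_b: float
    risk_ratio: float = 1.0

    @property
    def prevalence_a(self) -> float:
        return min(1.0, self.risk_ratio * self.prevalence_b)


@dataclass(frozen=True)
class Comention:
    """Excess joint-inclusion probability for a term pair.

    With probability ``excess`` both terms are forced into the article;
    otherwise the independent draws stand.
    """

    term_i: str
    term_j: str
    excess: float


@dataclass
class GeneratorSpec:
    """Full recipe for one synthetic corpus (defaults = the standard study
    conditions used throughout the test-bed: |A| = 200, |B| = 1000)."""

    n_a: int = 200
    n_b: int = 1000
    vocab_spec: VocabSpec = field(default_factory=VocabSpec)
    planted_terms: list[PlantedTerm] = field(default_factory=list)
    comention: list[Comention] = field(default_factory=list)
    review_fraction: float = 0.0
    date_range: tuple[int, int] = (2000, 2015)
    seed: int = 0
    query_drug: str = DEFAULT_QUERY_DRUG

    def validate(self) -> None:
        if self.n_a < 0 or self.n_b < 0:
            raise ValueError("group sizes must be non-negative")
        if not 0 <= self.review_fraction <= 1:
            raise ValueError("review_fraction must be in [0, 1]")
        if not 0 <= self.vocab_spec.decoy_prevalence <= 1:
            raise ValueError("decoy_prevalence must be in [0, 1]")
        for t in self.planted_terms:
            if not 0 <= t.prevalence_b <= 1:
                raise ValueError(f"prevalence_b out of [0, 1] for {t.term!r}")
            if t.risk_ratio < 1:
                raise ValueError(f"risk_ratio must be >= 1 for {t.term!r}")
        names = [t.term for t in self.planted_terms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate planted term names")
        term_names = set(names) | set(self._decoy_names())
        for cm in self.comention:
            if not 0 <= cm.excess <= 1:
                raise ValueError(
                    f"co-mention excess out of [0, 1] for ({cm.term_i!r}, {cm.term_j!r})"
                )
            for t in (cm.term_i, cm.term_j):
                if t not in term_names:
                    raise ValueError(f"co-mention names unknown term {t!r}")

    def _decoy_names(self) -> list[str]:
        vs = self.vocab_spec
        return (
            [f"Decoy Drug {i:03d}" for i in range(vs.n_drugs)]
            + [f"Decoy Protein {i:03d}" for i in range(vs.n_proteins)]
            + [f"Decoy Phenomenon {i:03d}" for i in range(vs.n_phenomena)]
            + [f"Decoy Topic {i:03d}" for i in range(vs.n_other)]
        )


_CATEGORY_TREES = {
    "drug": "D03",
    "protein": None,  # alternates D08 / D12.776
    "phenomena": None,  # cycles G03/G04/G06/G07
    "other": "C01",
}
_PHENOMENA_ROOTS = ("G03", "G04", "G06", "G07")


def _category_tree(category: str, index: int) -> str:
    if category == "protein":
        root = "D08.244" if index % 2 == 0 else "D12.776"
        return f"{root}.{500 + index}"
    if category == "phenomena":
        return f"{_PHENOMENA_ROOTS[index % 4]}.{100 + index}"
    root = _CATEGORY_TREES.get(category, "C01")
    return f"{root}.{100 + index}"


def _build_vocabulary(spec: GeneratorSpec) -> tuple[MeshVocabulary, list[tuple[str, str]]]:
    """Vocabulary plus the ordered (term, category) table of content terms."""
    vs = spec.vocab_spec
    table: list[tuple[str, str]] = []
    table += [(f"Decoy Drug {i:03d}", "drug") for i in range(vs.n_drugs)]
    table += [(f"Decoy Protein {i:03d}", "protein") for i in range(vs.n_proteins)]
    table += [(f"Decoy Phenomenon {i:03d}", "phenomena") for i in range(vs.n_phenomena)]
    table += [(f"Decoy Topic {i:03d}", "other") for i in range(vs.n_other)]
    table += [(t.term, t.category) for t in spec.planted_terms]

    vocab = MeshVocabulary()
    for idx, (name, cat) in enumerate(table):
        vocab.add_descriptor(name, [_category_tree(cat, idx)], is_drug=(cat == "drug"))
    vocab.add_descriptor(spec.query_drug, ["D03.999"], is_drug=True)
    for i, term in enumerate(INTERACTION_TERMS):
        vocab.add_descriptor(term, [f"G07.690.{800 + i}"])
    return vocab, table


def generate(spec: GeneratorSpec) -> tuple[list[Article], dict, MeshVocabulary]:
    """Generate (articles, truth record, vocabulary) from a spec.

    Reproducible: the same spec (including seed) yields identical
    output.  The truth record carries exact realized per-group counts for
    every content term, the group A pmid set, and per-group review
    counts.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    vocab, table = _build_vocabulary(spec)
    names = [name for name, _ in table]
    col = {name: j for j, name in enumerate(names)}

    prev_b = np.full(len(table), spec.vocab_spec.decoy_prevalence)
    prev_a = prev_b.copy()
    for t in spec.planted_terms:
        prev_b[col[t.term]] = t.prevalence_b
        prev_a[col[t.term]] = t.prevalence_a

    def draw_group(n: int, prev: np.ndarray) -> np.ndarray:
        mat = rng.random((n, len(table))) < prev
        for cm in spec.comention:
            force = rng.random(n) < cm.excess
            mat[force, col[cm.term_i]] = True
            mat[force, col[cm.term_j]] = True
        return mat

    mat_a = draw_group(spec.n_a, prev_a)
    mat_b = draw_group(spec.n_b, prev_b)

    def make_articles(mat: np.ndarray, is_group_a: bool, pmid_start: int) -> list[Article]:
        out = []
        for i in range(mat.shape[0]):
            pmid = str(pmid_start + i)
            headings = [MeshHeading(spec.query_drug)]
            if is_group_a:
                interaction = INTERACTION_TERMS[rng.integers(len(INTERACTION_TERMS))]
                headings.append(MeshHeading(interaction, ("pharmacology",), True))
            headings += [MeshHeading(names[j]) for j in np.flatnonzero(mat[i])]
            year = int(rng.integers(spec.date_range[0], spec.date_range[1] + 1))
            month = int(rng.integers(1, 13))
            pub_types = ["Journal Article"]
            if rng.random() < spec.review_fraction:
                pub_types.append("Review")
            out.append(
                Article(
                    pmid=pmid,
                    title=f"Synthetic record {pmid}",
                    pub_date=PubDate(year, month),
                    pub_types=pub_types,
                    mesh_headings=headings,
                )
            )
        return out

    articles_a = make_articles(mat_a, True, 9_000_001)
    articles_b = make_articles(mat_b, False, 9_000_001 + spec.n_a)
    articles = articles_a + articles_b
    order = rng.permutation(len(articles))
    articles = [articles[i] for i in order]

    truth = {
        "seed": spec.seed,
        "query_drug": spec.query_drug,
        "n_a": spec.n_a,
        "n_b": spec.n_b,
        "group_a_pmids": sorted(a.pmid for a in articles_a),
        "review_count_a": sum("Review" in a.pub_types for a in articles_a),
        "review_count_b": sum("Review" in a.pub_types for a in articles_b),
        "term_counts": {
            name: {"a": int(mat_a[:, j].sum()), "b": int(mat_b[:, j].sum())}
            for name, j in col.items()
        },
        "prevalence": {
            name: {"a": float(prev_a[j]), "b": float(prev_b[j])}
            for name, j in col.items()
        },
        "planted": [asdict(t) for t in spec.planted_terms],
        "terms_by_category": {
            cat: [n for n, c in table if c == cat]
            for cat in ("drug", "protein", "phenomena", "other")
        },
    }
    return articles, truth, vocab


def generate_pair_corpus(
    spec: GeneratorSpec,
    partner_drug: str,
    mechanism_terms: Sequence[str],
    n_pair_articles: int = 5,
) -> tuple[list[Article], dict, MeshVocabulary]:
    """Corpus with a designated drug-pair co-mention structure.

    The first ``n_pair_articles`` group A articles additionally mention
    ``partner_drug`` together with every mechanism term, giving the pair
    network a known connected core.  Mechanism terms must already exist
    in the generated vocabulary's protein or phenomena sets.
    """
    articles, truth, vocab = generate(spec)
    known = set(truth["terms_by_category"]["protein"]) | set(
        truth["terms_by_category"]["phenomena"]
    )
    missing = [t for t in mechanism_terms if t not in known]
    if missing:
        raise ValueError(f"mechanism terms not in vocabulary protein/phenomena sets: {missing}")
    if partner_drug not in vocab:
        vocab.add_descriptor(partner_drug, ["D03.998"], is_drug=True)

    pair_pmids = truth["group_a_pmids"][:n_pair_articles]
    pair_set = set(pair_pmids)
    for art in articles:
        if art.pmid in pair_set:
            have = art.descriptor_set()
            for term in [partner_drug, *mechanism_terms]:
                if norm_term(term) not in have:
                    art.mesh_headings.append(MeshHeading(term))
            # keep the truth counts exact after the forced co-mentions
            for term in mechanism_terms:
                if norm_term(term) not in have:
                    truth["term_counts"][term]["a"] += 1
    truth["pair_pmids"] = pair_pmids
    truth["partner_drug"] = partner_drug
    truth["mechanism_terms"] = list(mechanism_terms)
    return articles, truth, vocab


def save_corpus(
    articles: Iterable[Article],
    truth: dict,
    vocab: MeshVocabulary,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write corpus.medline, vocab.tsv, drugs.txt and truth.json to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "corpus": outdir / "corpus.medline",
        "vocab": outdir / "vocab.tsv",
        "drugs": outdir / "drugs.txt",
        "truth": outdir / "truth.json",
    }
    write_medline(articles, paths["corpus"])
    write_mesh_tsv(vocab, paths["vocab"])
    paths["drugs"].write_text("\n".join(sorted(vocab.drug_list)) + "\n", encoding="utf-8")
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True), encoding="utf-8")
    return paths
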