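import pytest

from meshddi import synth
from meshddi.medline import Article, MeshHeading, PubDate


def make_article(pmid, descriptors=(), pub_types=("Journal Article",), year=2010,
                 month=None, day=None, title="", abstract=""):
    """Terse article builder: descriptors may be strings or MeshHeading."""
    headings = [
        d if isinstance(d, MeshHeading) else MeshHeading.parse(d) for d in descriptors
    ]
    return Article(
        pmid=str(pmid),
        title=title or f"Article {pmid}",
        pub_date=PubDate(year, month, day) if year else None,
        pub_types=list(pub_types),
        abstract=abstract,
        mesh_headings=headings,
    )


@pytest.fixture(scope="session")
def small_corpus():
    """A small dense synthetic corpus: (articles, truth, vocab)."""
    spec = synth.GeneratorSpec(
        n_a=30,
        n_b=120,
        vocab_spec=synth.VocabSpec(
            n_drugs=5, n_proteins=5, n_phenomena=5, n_other=3, decoy_prevalence=0.2
        ),
        seed=42,
    )
    return synth.generate(spec)


@pytest.fixture(scope="session")
def enriched_corpus():
    """Corpus with 10 planted drug terms (risk ratio 4) and 30 null decoys."""
    planted = [
        synth.PlantedTerm(f"Planted Drug {i:02d}", "drug", 0.05, 4.0) for i in range(10)
    ]
    spec = synth.GeneratorSpec(
        n_a=200,
        n_b=1000,
        vocab_spec=synth.VocabSpec(
            n_drugs=10, n_proteins=10, n_phenomena=10, n_other=0, decoy_prevalence=0.05
        ),
        planted_terms=planted,
        seed=7,
    )
    return synth.generate(spec)
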