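"""MEDLINE flat-text and PubMed XML I/O."""

import io
from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meshddi import synth
from meshddi.medline import (
    Article,
    MedlineFormatError,
    MeshHeading,
    PubDate,
    RecordError,
    fetch_pubmed,
    parse_medline,
    parse_pubmed_xml,
    write_medline,
    write_pubmed_xml,
)

from conftest import make_article


class TestMeshHeadingParsing:
    @pytest.mark.parametrize(
        "raw, descriptor, qualifiers, major",
        [
            ("Cyclosporine/*pharmacokinetics", "Cyclosporine", ("pharmacokinetics",), True),
            ("*Drug Interactions", "Drug Interactions", (), True),
            ("Humans", "Humans", (), False),
            ("Cytochrome P-450 CYP3A/metabolism/genetics",
             "Cytochrome P-450 CYP3A", ("metabolism", "genetics"), False),
        ],
    )
    def test_descriptor_qualifier_major_conventions(self, raw, descriptor, qualifiers, major):
        h = MeshHeading.parse(raw)
        assert h.descriptor == descriptor
        assert h.qualifiers == qualifiers
        assert h.major_topic is major

    def test_empty_descriptor_rejected(self):
        with pytest.raises(ValueError):
            MeshHeading(descriptor="   ")


class TestPubDate:
    @pytest.mark.parametrize(
        "dp, expected",
        [
            ("2015 Dec 31", PubDate(2015, 12, 31)),
            ("2015", PubDate(2015)),
            ("2004 Jan-Feb", PubDate(2004, 1)),
            ("no year here", None),
        ],
    )
    def test_dp_parsing(self, dp, expected):
        assert PubDate.parse(dp) == expected

    def test_year_only_compared_by_year(self):
        assert PubDate(2015).on_or_before(date(2015, 12, 31))
        assert not PubDate(2016, 3).on_or_before(date(2015, 12, 31))
        assert PubDate(2015, 12, 31).on_or_before(date(2015, 12, 31))


class TestFlatTextParsing:
    def test_empty_stream_gives_empty_list(self):
        assert parse_medline(io.StringIO("")) == []

    def test_single_record_fields(self):
        text = (
            "PMID- 100\n"
            "TI  - A study of interactions.\n"
            "DP  - 2014 Jun 2\n"
            "PT  - Journal Article\n"
            "PT  - Review\n"
            "AB  - Some abstract.\n"
            "NM  - Warfarin\n"
            "MH  - Cyclosporine/*pharmacokinetics\n"
            "MH  - Humans\n"
        )
        (art,) = parse_medline(io.StringIO(text))
        assert art.pmid == "100"
        assert art.pub_date == PubDate(2014, 6, 2)
        assert art.pub_types == ["Journal Article", "Review"]
        assert art.substances == ["Warfarin"]
        assert [h.descriptor for h in art.mesh_headings] == ["Cyclosporine", "Humans"]
        assert art.mesh_headings[0].major_topic

    def test_rn_substance_name_extracted_from_parentheses(self):
        text = "PMID- 1\nRN  - 59865-13-3 (Cyclosporine)\n"
        (art,) = parse_medline(io.StringIO(text))
        assert art.substances == ["Cyclosporine"]

    def test_record_without_pmid_collected_not_dropped(self):
        text = "PMID- 1\nTI  - ok\n\nTI  - no pmid here\n\nPMID- 2\nTI  - ok too\n"
        errors: list[RecordError] = []
        articles = parse_medline(io.StringIO(text), errors=errors)
        assert [a.pmid for a in articles] == ["1", "2"]
        assert len(errors) == 1
        # nothing silently dropped: records in == articles + errors
        assert len(articles) + len(errors) == 3

    def test_malformed_date_keeps_year_else_missing(self):
        text = "PMID- 1\nDP  - 1999 Xyzzy\n\nPMID- 2\nDP  - gibberish\n"
        a1, a2 = parse_medline(io.StringIO(text))
        assert a1.pub_date == PubDate(1999)
        assert a2.pub_date is None


class TestRoundTrip:
    def test_write_then_parse_identity_on_synthetic_corpus(self):
        spec = synth.GeneratorSpec(
            n_a=20, n_b=30,
            vocab_spec=synth.VocabSpec(5, 5, 5, 2, 0.3),
            review_fraction=0.3, seed=11,
        )
        articles, _, _ = synth.generate(spec)
        buf = io.StringIO()
        write_medline(articles, buf)
        assert parse_medline(io.StringIO(buf.getvalue())) == articles

    def test_mh_line_count_matches_headings(self):
        art = make_article(1, ["Humans", "Cyclosporine/*blood"])
        buf = io.StringIO()
        write_medline([art], buf)
        assert buf.getvalue().count("MH  - ") == 2

    def test_empty_list_writes_nothing(self):
        buf = io.StringIO()
        write_medline([], buf)
        assert buf.getvalue() == ""

    @pytest.mark.parametrize("bad", ["", "   "])
    def test_invalid_pmid_refused(self, bad):
        with pytest.raises(ValueError):
            write_medline([Article(pmid=bad)], io.StringIO())

    def test_duplicate_pmid_refused_with_name(self):
        arts = [make_article(5), make_article(5)]
        with pytest.raises(ValueError, match="5"):
            write_medline(arts, io.StringIO())


_term = (
    st.text(
        alphabet="abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789 -",
        min_size=1,
        max_size=14,
    )
    .map(str.strip)
    .filter(bool)
)
_articles = st.lists(
    st.builds(
        Article,
        pmid=st.integers(1, 10**6).map(str),
        title=st.one_of(st.just(""), _term),
        pub_date=st.one_of(
            st.none(),
            st.builds(
                PubDate,
                year=st.integers(1900, 2020),
                month=st.one_of(st.none(), st.integers(1, 12)),
            ),
        ),
        pub_types=st.lists(
            st.sampled_from(["Journal Article", "Review", "Letter"]), max_size=2
        ),
        abstract=st.one_of(st.just(""), _term),
        mesh_headings=st.lists(
            st.builds(
                MeshHeading,
                descriptor=_term,
                qualifiers=st.lists(_term, max_size=2).map(tuple),
                major_topic=st.booleans(),
            ),
            max_size=3,
        ),
        substances=st.lists(_term, max_size=2),
    ),
    max_size=6,
    unique_by=lambda a: a.pmid,
)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(_articles)
def test_round_trip_holds_for_arbitrary_valid_articles(articles):
    """Property: parse(write(x)) == x for any syntactically valid article list."""
    buf = io.StringIO()
    write_medline(articles, buf)
    assert parse_medline(io.StringIO(buf.getvalue())) == articles


class TestPubmedXml:
    def test_minimal_document(self):
        xml = """<?xml version="1.0"?>
        <PubmedArticleSet><PubmedArticle><MedlineCitation>
          <PMID>42</PMID>
          <Article>
            <Journal><JournalIssue><PubDate><Year>2012</Year></PubDate></JournalIssue></Journal>
            <ArticleTitle>T</ArticleTitle>
            <PublicationTypeList><PublicationType>Journal Article</PublicationType></PublicationTypeList>
          </Article>
          <MeshHeadingList><MeshHeading>
            <DescriptorName MajorTopicYN="N">Humans</DescriptorName>
          </MeshHeading></MeshHeadingList>
        </MedlineCitation></PubmedArticle></PubmedArticleSet>"""
        (art,) = parse_pubmed_xml(xml)
        assert art.pmid == "42"
        assert art.mesh_headings == [MeshHeading("Humans")]
        assert art.pub_date == PubDate(2012)

    def test_zero_articles_is_empty_list(self):
        assert parse_pubmed_xml("<PubmedArticleSet/>") == []

    def test_malformed_xml_fatal_with_position(self):
        with pytest.raises(MedlineFormatError, match=r"\d"):
            parse_pubmed_xml("<PubmedArticleSet><oops")

    def test_cross_format_agreement_with_flat_text(self):
        spec = synth.GeneratorSpec(
            n_a=10, n_b=15,
            vocab_spec=synth.VocabSpec(4, 4, 4, 2, 0.3),
            review_fraction=0.2, seed=3,
        )
        articles, _, _ = synth.generate(spec)
        flat = io.StringIO()
        write_medline(articles, flat)
        xml = io.BytesIO()
        write_pubmed_xml(articles, xml)
        from_flat = parse_medline(io.StringIO(flat.getvalue()))
        from_xml = parse_pubmed_xml(xml.getvalue())
        assert from_flat == from_xml == articles


class _PagedTransport:
    """Offline test double serving canned XML pages of articles."""

    def __init__(self, pages):
        self.pages = pages
        self.calls = 0

    def __call__(self, query, retstart, retmax):
        self.calls += 1
        idx = retstart // retmax
        batch = self.pages[idx] if idx < len(self.pages) else []
        buf = io.BytesIO()
        write_pubmed_xml(batch, buf)
        return buf.getvalue()


class _FailingTransport:
    def __call__(self, query, retstart, retmax):
        raise IOError("boom")


class TestFetch:
    def _pages(self):
        arts = [make_article(i, ["Humans"], year=2010 + i) for i in range(4)]
        return [arts[:3], arts[3:]]

    def test_pagination_collects_all_pages(self):
        transport = _PagedTransport(self._pages())
        got = fetch_pubmed("cyclosporine [MeSH Terms]", batch_size=3, transport=transport)
        assert [a.pmid for a in got] == ["0", "1", "2", "3"]

    def test_date_cutoff_is_inclusive(self):
        arts = [make_article(1, year=2015, month=12, day=31)]
        transport = _PagedTransport([arts])
        kept = fetch_pubmed("q", date_end=date(2015, 12, 31), batch_size=5,
                            transport=transport)
        assert len(kept) == 1
        none = fetch_pubmed("q", date_end=date(2015, 12, 30), batch_size=5,
                            transport=transport)
        assert none == []

    def test_date_end_before_everything_gives_empty(self):
        transport = _PagedTransport(self._pages())
        got = fetch_pubmed("q", date_end=date(1990, 1, 1), batch_size=3,
                           transport=transport)
        assert got == []

    def test_cache_makes_rerun_offline(self, tmp_path):
        transport = _PagedTransport(self._pages())
        first = fetch_pubmed("q", batch_size=3, transport=transport, cache_dir=tmp_path)
        calls = transport.calls
        second = fetch_pubmed("q", batch_size=3, transport=_FailingTransport(),
                              cache_dir=tmp_path, retries=1, backoff=0)
        assert second == first
        assert calls == 2

    def test_unreachable_service_raises_after_retries(self):
        with pytest.raises(RuntimeError, match="unreachable"):
            fetch_pubmed("q", transport=_FailingTransport(), retries=2, backoff=0)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            fetch_pubmed("", transport=_PagedTransport([]))
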