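"""Reading and writing PubMed records.

Supports the two standard serializations of a PubMed record set — the
MEDLINE flat-text format (``PMID- ``/``TI  - ``/``MH  - `` tagged lines)
and PubMed XML (``PubmedArticleSet``) — plus a paged, cached downloader
for the NCBI E-utilities service.  Flat-text parsing is delegated to
:mod:`Bio.Medline`; XML goes through :mod:`lxml`.

Only the fields the downstream analysis consumes are modeled: PMID,
title, publication date, publication types, abstract, MeSH headings and
substance names.  A MeSH heading is stored as a bare descriptor plus its
subheading qualifiers; the ``*`` major-topic marker becomes a boolean.
"""

from __future__ import annotations

import hashlib
import io
import logging
import os
import re
import time
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Callable, Iterable, TextIO

from Bio import Medline
from lxml import etree

from ._text import norm_term

logger = logging.getLogger(__name__)

__all__ = [
    "Article",
    "MeshHeading",
    "PubDate",
    "RecordError",
    "MedlineFormatError",
    "parse_medline",
    "parse_pubmed_xml",
    "write_medline",
    "write_pubmed_xml",
    "fetch_pubmed",
]


class MedlineFormatError(ValueError):
    """Fatal format error (non-well-formed input)."""


_MONTHS = {
    "jan": 1, "feb": 2, "mar": 3, "apr": 4, "may": 5, "jun": 6,
    "jul": 7, "aug": 8, "sep": 9, "oct": 10, "nov": 11, "dec": 12,
}
_MONTH_NAMES = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
                "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]

_YEAR_RE = re.compile(r"\b(\d{4})\b")
_DAY_RE = re.compile(r"\b(\d{1,2})\b")


@dataclass(frozen=True, order=True)
class PubDate:
    """Publication date with a mandatory year and optional month/day.

    Records indexed with a year-only ``DP`` field are common; comparisons
    against a full calendar cutoff therefore only use the precision a
    record actually carries (a year-only date is compared by year).
    """

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if self.year <= 0:
            raise ValueError(f"publication year must be positive, got {self.year}")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None and not 1 <= self.day <= 31:
            raise ValueError(f"day out of range: {self.day}")

    @classmethod
    def parse(cls, dp: str) -> "PubDate | None":
        """Parse a MEDLINE ``DP`` value ("2015 Dec 31", "2004 Jan-Feb", "1999").

        Returns ``None`` when no 4-digit year is present.
        """
        m = _YEAR_RE.search(dp)
        if m is None:
            return None
        year = int(m.group(1))
        rest = dp[m.end():]
        month = None
        day = None
        # first recognizable month token wins ("Jan-Feb" -> Jan)
        mm = re.search(r"[A-Za-z]{3}", rest)
        if mm and mm.group(0).lower() in _MONTHS:
            month = _MONTHS[mm.group(0).lower()]
            dd = _DAY_RE.search(rest[mm.end():])
            if dd:
                day = int(dd.group(1))
                if not 1 <= day <= 31:
                    day = None
        return cls(year, month, day)

    def to_dp(self) -> str:
        parts = [str(self.year)]
        if self.month is not None:
            parts.append(_MONTH_NAMES[self.month - 1])
            if self.day is not None:
                parts.append(str(self.day))
        return " ".join(parts)

    def on_or_before(self, cutoff: date) -> bool:
        """True if this date is <= ``cutoff`` at this date's own precision."""
        if self.month is None:
            return self.year <= cutoff.year
        if self.day is None:
            return (self.year, self.month) <= (cutoff.year, cutoff.month)
        return (self.year, self.month, self.day) <= (cutoff.year, cutoff.month, cutoff.day)


@dataclass(frozen=True)
class MeshHeading:
    """One MeSH annotation: descriptor, subheading qualifiers, major-topic flag."""

    descriptor: str
    qualifiers: tuple[str, ...] = ()
    major_topic: bool = False

    def __post_init__(self) -> None:
        if not self.descriptor.strip():
            raise ValueError("MeSH heading has an empty descriptor")

    @classmethod
    def parse(cls, raw: str) -> "MeshHeading":
        """Parse an ``MH`` field value like ``Cyclosporine/*pharmacokinetics``.

        The value is split into descriptor and qualifiers at ``/``; a ``*``
        anywhere (descriptor or qualifier) marks the heading as a major topic
        and is stripped from the stored text.
        """
        major = "*" in raw
        parts = [p.replace("*", "").strip() for p in raw.split("/")]
        descriptor, qualifiers = parts[0], tuple(p for p in parts[1:] if p)
        return cls(descriptor=descriptor, qualifiers=qualifiers, major_topic=major)

    def to_mh(self) -> str:
        text = "/".join((self.descriptor,) + self.qualifiers)
        return "*" + text if self.major_topic else text


@dataclass
class Article:
    """One PubMed record (the subset of fields the pipeline uses)."""

    pmid: str
    title: str = ""
    pub_date: PubDate | None = None
    pub_types: list[str] = field(default_factory=list)
    abstract: str = ""
    mesh_headings: list[MeshHeading] = field(default_factory=list)
    substances: list[str] = field(default_factory=list)

    def descriptor_set(self) -> frozenset[str]:
        """Normalized bare descriptors of this article's MeSH headings."""
        return frozenset(norm_term(h.descriptor) for h in self.mesh_headings)


@dataclass(frozen=True)
class RecordError:
    """A record-level parse problem; parsing continues past it."""

    record_index: int
    message: str


def _as_text_handle(source) -> TextIO:
    if hasattr(source, "read"):
        return source
    if isinstance(source, (str, Path)):
        p = Path(source)
        if "\n" not in str(source) and p.exists():
            return p.open("r", encoding="utf-8")
        if isinstance(source, str):
            return io.StringIO(source)
    raise TypeError(f"cannot read MEDLINE text from {type(source)!r}")


_RN_NAME_RE = re.compile(r"\(([^()]+)\)\s*$")


def _substance_name(rn_value: str) -> str:
    """Extract the substance name from an ``RN`` value like ``0 (Warfarin)``."""
    m = _RN_NAME_RE.search(rn_value)
    return m.group(1) if m else rn_value.strip()


def parse_medline(source, errors: list[RecordError] | None = None) -> list[Article]:
    """Parse MEDLINE flat text into :class:`Article` records.

    Parameters
    ----------
    source
        File-like handle, path, or the raw text itself.
    errors
        Optional list that collects :class:`RecordError` entries (e.g. a
        record without a PMID).  When omitted, problems are logged as
        warnings.  Parsing never silently drops a record: every record
        block either yields an Article or an error entry.
    """
    handle = _as_text_handle(source)
    sink = errors if errors is not None else None
    articles: list[Article] = []
    for idx, rec in enumerate(Medline.parse(handle)):
        pmid = rec.get("PMID", "").strip() if isinstance(rec.get("PMID"), str) else rec.get("PMID")
        if not pmid:
            err = RecordError(idx, "record without a PMID")
            if sink is not None:
                sink.append(err)
            else:
                logger.warning("MEDLINE record %d: %s", idx, err.message)
            continue
        dp = rec.get("DP")
        pub_date = PubDate.parse(dp) if dp else None
        if dp and pub_date is None:
            logger.warning("PMID %s: unparsable date %r, date flagged missing", pmid, dp)
        substances = [_substance_name(v) for v in rec.get("RN", [])]
        substances += [v.strip() for v in rec.get("NM", [])]
        articles.append(
            Article(
                pmid=pmid,
                title=rec.get("TI", "").strip(),
                pub_date=pub_date,
                pub_types=list(rec.get("PT", [])),
                abstract=rec.get("AB", "").strip(),
                mesh_headings=[MeshHeading.parse(v) for v in rec.get("MH", [])],
                substances=substances,
            )
        )
    return articles


def write_medline(articles: Iterable[Article], dest) -> None:
    """Serialize articles to MEDLINE flat text; output re-parses to equal input.

    Raises :class:`ValueError` naming the offending pmid when an article
    violates the record invariants (empty or duplicate PMID).
    """
    own = not hasattr(dest, "write")
    handle = Path(dest).open("w", encoding="utf-8") if own else dest
    try:
        seen: set[str] = set()
        for art in articles:
            if not art.pmid or not str(art.pmid).strip():
                raise ValueError("article with empty pmid cannot be serialized")
            if art.pmid in seen:
                raise ValueError(f"duplicate pmid in corpus: {art.pmid}")
            seen.add(art.pmid)
            lines = [f"PMID- {art.pmid}"]
            if art.title:
                lines.append(f"TI  - {art.title}")
            if art.pub_date is not None:
                lines.append(f"DP  - {art.pub_date.to_dp()}")
            for pt in art.pub_types:
                lines.append(f"PT  - {pt}")
            if art.abstract:
                lines.append(f"AB  - {art.abstract}")
            for name in art.substances:
                lines.append(f"NM  - {name}")
            for h in art.mesh_headings:
                lines.append(f"MH  - {h.to_mh()}")
            handle.write("\n".join(lines) + "\n\n")
    finally:
        if own:
            handle.close()


# ---------------------------------------------------------------------------
# PubMed XML

def _month_number(text: str) -> int | None:
    text = text.strip()
    if text.isdigit():
        n = int(text)
        return n if 1 <= n <= 12 else None
    return _MONTHS.get(text[:3].lower())


def _parse_xml_pubdate(node) -> PubDate | None:
    if node is None:
        return None
    year = node.findtext("Year")
    if year and year.strip().isdigit():
        month = _month_number(node.findtext("Month") or "") if node.findtext("Month") else None
        day_text = node.findtext("Day")
        day = int(day_text) if day_text and day_text.strip().isdigit() else None
        return PubDate(int(year), month, day if month is not None else None)
    medline_date = node.findtext("MedlineDate")
    if medline_date:
        return PubDate.parse(medline_date)
    return None


def parse_pubmed_xml(source) -> list[Article]:
    """Parse a ``PubmedArticleSet`` document into :class:`Article` records.

    Non-well-formed XML raises :class:`MedlineFormatError` with the
    parser's reported position.
    """
    if isinstance(source, bytes):
        source = io.BytesIO(source)
    elif isinstance(source, str) and "\n" not in source and Path(source).exists():
        pass  # a path; etree.parse handles it
    elif isinstance(source, str):
        source = io.BytesIO(source.encode("utf-8"))
    try:
        tree = etree.parse(source)
    except etree.XMLSyntaxError as exc:
        raise MedlineFormatError(f"malformed PubMed XML at {exc.position}: {exc}") from exc
    articles: list[Article] = []
    for node in tree.iter("PubmedArticle"):
        citation = node.find("MedlineCitation")
        if citation is None:
            continue
        pmid = citation.findtext("PMID", default="").strip()
        art_node = citation.find("Article")
        title = art_node.findtext("ArticleTitle", default="") if art_node is not None else ""
        pub_date = None
        if art_node is not None:
            pub_date = _parse_xml_pubdate(art_node.find("Journal/JournalIssue/PubDate"))
        pub_types = [pt.text for pt in node.iter("PublicationType") if pt.text]
        abstract = " ".join(
            (t.text or "").strip() for t in node.iter("AbstractText")
        ).strip()
        headings = []
        mh_list = citation.find("MeshHeadingList")
        if mh_list is not None:
            for mh in mh_list.iter("MeshHeading"):
                desc = mh.find("DescriptorName")
                if desc is None or not (desc.text or "").strip():
                    continue
                quals = [(q.text or "").strip() for q in mh.iter("QualifierName")]
                major = desc.get("MajorTopicYN") == "Y" or any(
                    q.get("MajorTopicYN") == "Y" for q in mh.iter("QualifierName")
                )
                headings.append(
                    MeshHeading(desc.text.strip(), tuple(q for q in quals if q), major)
                )
        substances = [
            s.text.strip()
            for s in citation.iter("NameOfSubstance")
            if s.text and s.text.strip()
        ]
        articles.append(
            Article(
                pmid=pmid,
                title=title.strip(),
                pub_date=pub_date,
                pub_types=pub_types,
                abstract=abstract,
                mesh_headings=headings,
                substances=substances,
            )
        )
    return articles


def write_pubmed_xml(articles: Iterable[Article], dest) -> None:
    """Serialize articles as a ``PubmedArticleSet`` document."""
    root = etree.Element("PubmedArticleSet")
    for art in articles:
        pa = etree.SubElement(root, "PubmedArticle")
        cit = etree.SubElement(pa, "MedlineCitation")
        etree.SubElement(cit, "PMID").text = art.pmid
        anode = etree.SubElement(cit, "Article")
        if art.pub_date is not None:
            pd = etree.SubElement(
                etree.SubElement(etree.SubElement(anode, "Journal"), "JournalIssue"),
                "PubDate",
            )
            etree.SubElement(pd, "Year").text = str(art.pub_date.year)
            if art.pub_date.month is not None:
                etree.SubElement(pd, "Month").text = _MONTH_NAMES[art.pub_date.month - 1]
                if art.pub_date.day is not None:
                    etree.SubElement(pd, "Day").text = str(art.pub_date.day)
        etree.SubElement(anode, "ArticleTitle").text = art.title
        if art.abstract:
            etree.SubElement(
                etree.SubElement(anode, "Abstract"), "AbstractText"
            ).text = art.abstract
        ptl = etree.SubElement(anode, "PublicationTypeList")
        for pt in art.pub_types:
            etree.SubElement(ptl, "PublicationType").text = pt
        if art.substances:
            cl = etree.SubElement(cit, "ChemicalList")
            for name in art.substances:
                chem = etree.SubElement(cl, "Chemical")
                etree.SubElement(chem, "NameOfSubstance").text = name
        if art.mesh_headings:
            mhl = etree.SubElement(cit, "MeshHeadingList")
            for h in art.mesh_headings:
                mh = etree.SubElement(mhl, "MeshHeading")
                dn = etree.SubElement(mh, "DescriptorName")
                dn.text = h.descriptor
                dn.set("MajorTopicYN", "Y" if h.major_topic and not h.qualifiers else "N")
                for i, q in enumerate(h.qualifiers):
                    qn = etree.SubElement(mh, "QualifierName")
                    qn.text = q
                    qn.set("MajorTopicYN", "Y" if h.major_topic and i == 0 else "N")
    data = etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    if hasattr(dest, "write"):
        try:
            dest.write(data)
        except TypeError:
            dest.write(data.decode("utf-8"))
    else:
        Path(dest).write_bytes(data)


# ---------------------------------------------------------------------------
# E-utilities fetch

Transport = Callable[[str, int, int], bytes]


class EntrezTransport:
    """Default live transport: esearch + efetch via Bio.Entrez.

    One call returns one XML page of up to ``retmax`` records starting at
    ``retstart`` for the given query.  Requires network access; tests and
    offline runs inject their own transport instead.
    """

    def __init__(self, email: str = "meshddi@example.org", tool: str = "meshddi"):
        from Bio import Entrez

        self._entrez = Entrez
        Entrez.email = email
        Entrez.tool = tool

    def __call__(self, query: str, retstart: int, retmax: int) -> bytes:
        with self._entrez.esearch(
            db="pubmed", term=query, retstart=retstart, retmax=retmax
        ) as h:
            ids = self._entrez.read(h)["IdList"]
        if not ids:
            return b"<?xml version='1.0'?><PubmedArticleSet></PubmedArticleSet>"
        with self._entrez.efetch(db="pubmed", id=",".join(ids), retmode="xml") as h:
            return h.read()


def pubmed_query(drug: str) -> str:
    """The query template for a drug name: ``<drug> [MeSH Terms]``."""
    return f"{drug} [MeSH Terms]"


def fetch_pubmed(
    query: str,
    date_end: date | None = None,
    batch_size: int = 200,
    transport: Transport | None = None,
    cache_dir: str | os.PathLike | None = None,
    retries: int = 3,
    backoff: float = 1.0,
) -> list[Article]:
    """Retrieve all matching records via paged E-utilities calls.

    Records with publication date after ``date_end`` (inclusive cutoff,
    year-only dates compared by year) or with no parsable date are
    dropped.  Raw pages are cached on disk keyed by (query, date_end,
    page) so reruns are offline.  A page failure is retried with
    exponential backoff; if retries are exhausted the partial results are
    discarded and the error propagates.
    """
    if not query:
        raise ValueError("query must be non-empty")
    if transport is None:
        transport = EntrezTransport()
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)

    def one_page(retstart: int) -> bytes:
        if cache is not None:
            key = hashlib.sha256(
                f"{query}|{date_end}|{retstart}|{batch_size}".encode()
            ).hexdigest()[:24]
            path = cache / f"page-{key}.xml"
            if path.exists():
                return path.read_bytes()
        last: Exception | None = None
        for attempt in range(retries):
            try:
                data = transport(query, retstart, batch_size)
                break
            except Exception as exc:  # noqa: BLE001 - transport errors are opaque
                last = exc
                if attempt + 1 < retries:
                    time.sleep(backoff * 2**attempt)
        else:
            raise RuntimeError(
                f"PubMed service unreachable after {retries} attempts: {last}"
            ) from last
        if cache is not None:
            path.write_bytes(data if isinstance(data, bytes) else data.encode())
        return data

    collected: list[Article] = []
    retstart = 0
    while True:
        page_articles = parse_pubmed_xml(one_page(retstart))
        collected.extend(page_articles)
        if len(page_articles) < batch_size:
            break
        retstart += batch_size
    if date_end is not None:
        collected = [
            a for a in collected if a.pub_date is not None and a.pub_date.on_or_before(date_end)
        ]
    return collected
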