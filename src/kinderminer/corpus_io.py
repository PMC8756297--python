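"""Reading and writing dated abstract corpora.

Two on-disk formats are supported: the NLM PubMed citation XML
("Annual Baseline" schema, optionally gzip-compressed), from which only
the ``PubDate`` and ``AbstractText`` fields are consumed, and a JSON
Lines format with one ``{"doc_id", "year", "abstract"}`` object per
line.  Both yield :class:`DocumentRecord` streams.
"""

from __future__ import annotations

import gzip
import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Union

from lxml import etree

logger = logging.getLogger(__name__)

#: Sentinel for documents whose publication year cannot be resolved.
UNKNOWN_YEAR: Optional[int] = None

_YEAR_MIN, _YEAR_MAX = 1000, 2200
_FOUR_DIGITS = re.compile(r"\d{4}")


@dataclass(frozen=True)
class DocumentRecord:
    """One dated abstract.

    Parameters
    ----------
    doc_id
        Non-empty identifier, unique within a corpus (the PMID when the
        record came from PubMed XML).
    pub_year
        Calendar year of publication, or ``None`` when unknown.
    abstract_text
        The abstract body, unmodified; may be empty.
    """

    doc_id: str
    pub_year: Optional[int]
    abstract_text: str

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        if self.pub_year is not None and not (
            _YEAR_MIN <= self.pub_year <= _YEAR_MAX
        ):
            raise ValueError(
                f"pub_year {self.pub_year!r} outside [{_YEAR_MIN}, {_YEAR_MAX}]"
            )


def resolve_pub_year(
    year_field: str = "", medline_date_field: str = ""
) -> Optional[int]:
    """Resolve a publication year from PubDate subfields.

    A 4-digit ``Year`` field wins; otherwise the first 4-digit run in
    ``MedlineDate`` (e.g. ``"1998 Dec-1999 Jan"`` -> 1998); otherwise
    ``None``.  Never raises.
    """
    year_field = (year_field or "").strip()
    if re.fullmatch(r"\d{4}", year_field):
        year = int(year_field)
        if _YEAR_MIN <= year <= _YEAR_MAX:
            return year
    match = _FOUR_DIGITS.search(medline_date_field or "")
    if match:
        year = int(match.group())
        if _YEAR_MIN <= year <= _YEAR_MAX:
            return year
    return UNKNOWN_YEAR


def _maybe_gzip(source: Union[str, Path, IO[bytes]]) -> IO[bytes]:
    if isinstance(source, (str, Path)):
        handle: IO[bytes] = open(source, "rb")
    else:
        handle = source
    magic = handle.read(2)
    handle.seek(0)
    if magic == b"\x1f\x8b":
        return gzip.open(handle, "rb")  # type: ignore[return-value]
    return handle


def parse_pubmed_xml(
    source: Union[str, Path, IO[bytes]],
    keep_empty_abstracts: bool = False,
) -> Iterator[DocumentRecord]:
    """Stream :class:`DocumentRecord` from PubMed citation XML.

    For every ``PubmedArticle`` element the PMID, PubDate and
    AbstractText fields are extracted; everything else is ignored.
    Structured abstracts (several AbstractText sections) are joined with
    single spaces, labels discarded.  Articles without any AbstractText
    are skipped unless ``keep_empty_abstracts`` is true; articles
    without a PMID are always skipped with a logged warning.  Memory use
    is bounded by one article (iterparse with element clearing).  Gzip
    input is detected from its magic bytes and handled transparently.

    Raises
    ------
    lxml.etree.XMLSyntaxError
        On malformed XML, with the offending position in the message.
    """
    stream = _maybe_gzip(source)
    context = etree.iterparse(stream, events=("end",), tag="PubmedArticle")
    for _, article in context:
        pmid_el = article.find(".//MedlineCitation/PMID")
        if pmid_el is None:
            pmid_el = article.find(".//PMID")
        pmid = (pmid_el.text or "").strip() if pmid_el is not None else ""
        if not pmid:
            logger.warning("skipping PubmedArticle without a PMID")
        else:
            sections = [
                " ".join(el.itertext()).strip()
                for el in article.iter("AbstractText")
            ]
            abstract = " ".join(s for s in sections if s)
            if abstract or keep_empty_abstracts:
                pubdate = article.find(".//Article/Journal/JournalIssue/PubDate")
                if pubdate is None:
                    pubdate = article.find(".//PubDate")
                year_text = medline_text = ""
                if pubdate is not None:
                    year_el = pubdate.find("Year")
                    medline_el = pubdate.find("MedlineDate")
                    year_text = year_el.text or "" if year_el is not None else ""
                    medline_text = (
                        medline_el.text or "" if medline_el is not None else ""
                    )
                yield DocumentRecord(
                    pmid, resolve_pub_year(year_text, medline_text), abstract
                )
        article.clear()
        while article.getprevious() is not None:
            del article.getparent()[0]


def deduplicate(records: Iterable[DocumentRecord]) -> list[DocumentRecord]:
    """Collapse duplicate doc_ids, last record winning (ingest-overwrite).

    Baseline + update file overlaps produce duplicate PMIDs; the number
    of overwrites is logged.
    """
    seen: dict[str, DocumentRecord] = {}
    n_dupes = 0
    for rec in records:
        if rec.doc_id in seen:
            n_dupes += 1
        seen[rec.doc_id] = rec
    if n_dupes:
        logger.info("deduplicated %d overwritten doc_id(s)", n_dupes)
    return list(seen.values())


def read_jsonl(path: Union[str, Path]) -> Iterator[DocumentRecord]:
    """Read records from JSON Lines (``doc_id``/``year``/``abstract``).

    ``year: null`` maps to an unknown publication year.  A malformed
    line raises ``ValueError`` naming the 1-based line number.
    Gzip-compressed files are handled transparently.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt", encoding="utf-8") as handle:  # type: ignore[operator]
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                yield DocumentRecord(
                    obj["doc_id"], obj["year"], obj["abstract"]
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: malformed JSONL at line {lineno}: {exc}"
                ) from exc


def write_jsonl(
    records: Iterable[DocumentRecord], path: Union[str, Path]
) -> int:
    """Write records as JSON Lines; returns the number written.

    Inverse of :func:`read_jsonl`: unknown years are written as
    ``null`` and the write/read round trip is the identity.
    """
    n = 0
    with open(path, "w", encoding="utf-8") as handle:
        for rec in records:
            handle.write(
                json.dumps(
                    {
                        "doc_id": rec.doc_id,
                        "year": rec.pub_year,
                        "abstract": rec.abstract_text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
            n += 1
    return n
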