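"""Positional inverted index over tokenized abstracts.

Text is tokenized the way a grammar-based analyzer with a lowercase
filter would: split at every maximal run of non-alphanumeric characters,
lowercase, drop empties.  Hyphenated symbols such as ``NKX2-5`` thus
become two-token phrases.  The index stores token positions so that a
multi-token phrase matches only when its tokens occur consecutively and
in order, and per-document publication years so that counts can be
censored to documents published through the end of a given year.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .corpus_io import DocumentRecord

INDEX_FORMAT_VERSION = 1

# alphanumeric runs, unicode-aware; underscore is a split point
_TOKEN = re.compile(r"[^\W_]+", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lowercase grammar-style tokenization.

    >>> tokenize("Embryonic Stem Cell")
    ['embryonic', 'stem', 'cell']
    >>> tokenize("NKX2-5")
    ['nkx2', '5']
    """
    return _TOKEN.findall(text.lower())


class UnmatchablePhraseError(ValueError):
    """Raised when a phrase tokenizes to the empty sequence."""


@dataclass
class CorpusIndex:
    """Token -> postings map with per-document year metadata.

    ``postings[token]`` is a list of ``(doc_ordinal, positions)`` pairs
    with strictly increasing positions per document; ``doc_table`` maps
    ordinals to ``(doc_id, pub_year)``.
    """

    postings: dict[str, list[tuple[int, list[int]]]] = field(default_factory=dict)
    doc_table: list[tuple[str, Optional[int]]] = field(default_factory=list)

    @property
    def n_docs(self) -> int:
        return len(self.doc_table)

    # -- construction -------------------------------------------------

    @classmethod
    def build(cls, records: Iterable[DocumentRecord]) -> "CorpusIndex":
        """Index every token occurrence of every record.

        Raises ``ValueError`` on duplicate doc_ids (deduplicate
        upstream with :func:`kinderminer.corpus_io.deduplicate`).
        """
        index = cls()
        seen: set[str] = set()
        for rec in records:
            if rec.doc_id in seen:
                raise ValueError(f"duplicate doc_id {rec.doc_id!r}")
            seen.add(rec.doc_id)
            ordinal = len(index.doc_table)
            index.doc_table.append((rec.doc_id, rec.pub_year))
            for pos, token in enumerate(tokenize(rec.abstract_text)):
                plist = index.postings.setdefault(token, [])
                if plist and plist[-1][0] == ordinal:
                    plist[-1][1].append(pos)
                else:
                    plist.append((ordinal, [pos]))
        return index

    # -- querying ------------------------------------------------------

    def _eligible(self, censor_year: Optional[int]) -> Optional[set[int]]:
        """Ordinals eligible under censoring, or None for "all".

        Censoring is inclusive of the censor year; documents with an
        unknown year are excluded from any censored query (they cannot
        be placed on the timeline) but included in uncensored ones.
        """
        if censor_year is None:
            return None
        return {
            i
            for i, (_, year) in enumerate(self.doc_table)
            if year is not None and year <= censor_year
        }

    def _phrase_docs(self, phrase: Sequence[str]) -> set[int]:
        """Ordinals of documents containing the tokens consecutively."""
        if not phrase:
            raise UnmatchablePhraseError("unmatchable phrase (no tokens)")
        first = self.postings.get(phrase[0])
        if first is None:
            return set()
        if len(phrase) == 1:
            return {doc for doc, _ in first}
        rest = [self.postings.get(tok) for tok in phrase[1:]]
        if any(p is None for p in rest):
            return set()
        rest_maps = [dict(p) for p in rest]  # type: ignore[arg-type]
        matches: set[int] = set()
        for doc, positions in first:
            pos_sets = []
            for m in rest_maps:
                plist = m.get(doc)
                if plist is None:
                    break
                pos_sets.append(set(plist))
            else:
                if any(
                    all(p + off + 1 in pos_sets[off] for off in range(len(pos_sets)))
                    for p in positions
                ):
                    matches.add(doc)
        return matches

    def count_phrase(
        self, phrase: Sequence[str], censor_year: Optional[int] = None
    ) -> int:
        """Number of eligible documents containing the phrase at least once."""
        docs = self._phrase_docs(phrase)
        eligible = self._eligible(censor_year)
        return len(docs) if eligible is None else len(docs & eligible)

    def count_cooccurrence(
        self,
        phrase_a: Sequence[str],
        phrase_b: Sequence[str],
        censor_year: Optional[int] = None,
    ) -> int:
        """Eligible documents matching both phrases (anywhere each).

        Symmetric in its phrase arguments; document-level, so several
        matches within one abstract count once.
        """
        docs = self._phrase_docs(phrase_a) & self._phrase_docs(phrase_b)
        eligible = self._eligible(censor_year)
        return len(docs) if eligible is None else len(docs & eligible)

    def corpus_size(self, censor_year: Optional[int] = None) -> int:
        """Number of eligible documents (the N margin)."""
        eligible = self._eligible(censor_year)
        return self.n_docs if eligible is None else len(eligible)

    def year_histogram(self) -> dict[str, int]:
        """Publication-year counts; unknown years under key "unknown"."""
        hist: dict[str, int] = {}
        for _, year in self.doc_table:
            key = "unknown" if year is None else str(year)
            hist[key] = hist.get(key, 0) + 1
        return hist

    # -- persistence ---------------------------------------------------

    def save(self, directory: Union[str, Path]) -> None:
        """Persist to a directory: JSONL postings + JSON metadata."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "postings.jsonl", "w", encoding="utf-8") as fh:
            for token in sorted(self.postings):
                fh.write(
                    json.dumps(
                        {"t": token, "p": self.postings[token]},
                        ensure_ascii=False,
                    )
                    + "\n"
                )
        with open(directory / "docs.jsonl", "w", encoding="utf-8") as fh:
            for doc_id, year in self.doc_table:
                fh.write(json.dumps({"doc_id": doc_id, "year": year}) + "\n")
        meta = {
            "format_version": INDEX_FORMAT_VERSION,
            "n_docs": self.n_docs,
            "n_tokens": len(self.postings),
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: Union[str, Path]) -> "CorpusIndex":
        """Load a persisted index, validating the format version."""
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        if meta.get("format_version") != INDEX_FORMAT_VERSION:
            raise ValueError(
                f"unsupported index format version {meta.get('format_version')!r}"
            )
        index = cls()
        with open(directory / "docs.jsonl", encoding="utf-8") as fh:
            for line in fh:
                obj = json.loads(line)
                index.doc_table.append((obj["doc_id"], obj["year"]))
        with open(directory / "postings.jsonl", encoding="utf-8") as fh:
            for line in fh:
                obj = json.loads(line)
                index.postings[obj["t"]] = [
                    (doc, positions) for doc, positions in obj["p"]
                ]
        if meta["n_docs"] != index.n_docs:
            raise ValueError("index metadata inconsistent with doc table")
        return index
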