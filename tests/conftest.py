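"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the implementation paths they
check: counting is done by a linear scan over re-tokenized documents,
and Fisher tail probabilities by exact rational arithmetic.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pytest

from kinderminer.corpus_io import DocumentRecord
from kinderminer.text_index import tokenize


# -- brute-force counting oracle --------------------------------------

def _contains_consecutive(doc_tokens: list[str], phrase: Sequence[str]) -> bool:
    n, m = len(doc_tokens), len(phrase)
    return any(
        doc_tokens[i : i + m] == list(phrase) for i in range(n - m + 1)
    )


def _eligible(rec: DocumentRecord, censor_year: Optional[int]) -> bool:
    if censor_year is None:
        return True
    return rec.pub_year is not None and rec.pub_year <= censor_year


def scan_count_phrase(records, phrase, censor_year=None) -> int:
    """Document count of a consecutive-token phrase by direct scan."""
    return sum(
        1
        for r in records
        if _eligible(r, censor_year)
        and _contains_consecutive(tokenize(r.abstract_text), phrase)
    )


def scan_count_cooccurrence(records, phrase_a, phrase_b, censor_year=None) -> int:
    count = 0
    for r in records:
        if not _eligible(r, censor_year):
            continue
        toks = tokenize(r.abstract_text)
        if _contains_consecutive(toks, phrase_a) and _contains_consecutive(
            toks, phrase_b
        ):
            count += 1
    return count


def scan_corpus_size(records, censor_year=None) -> int:
    return sum(1 for r in records if _eligible(r, censor_year))


# -- exact-rational Fisher oracle -------------------------------------

def exact_upper_tail(a: int, t: int, k: int, n: int) -> Fraction:
    """Upper-tail hypergeometric probability as an exact rational."""
    hi = min(t, k)
    numer = sum(math.comb(k, x) * math.comb(n - k, t - x) for x in range(a, hi + 1))
    return Fraction(numer, math.comb(n, t))


def exact_lower_tail(a: int, t: int, k: int, n: int) -> Fraction:
    lo = max(0, t + k - n)
    numer = sum(math.comb(k, x) * math.comb(n - k, t - x) for x in range(lo, a + 1))
    return Fraction(numer, math.comb(n, t))


# -- random corpora ----------------------------------------------------

def random_corpus(
    rng: np.random.Generator,
    max_docs: int = 500,
    vocab: Sequence[str] = ("alpha", "beta", "gamma", "delta", "eps",
                            "zeta", "eta", "theta", "iota", "kappa"),
    p_unknown_year: float = 0.1,
) -> list[DocumentRecord]:
    """A small corpus with a deliberately tiny vocabulary so multi-token
    phrases recur often enough to exercise matching."""
    n_docs = int(rng.integers(1, max_docs + 1))
    records = []
    for i in range(n_docs):
        length = int(rng.integers(0, 15))
        words = rng.choice(vocab, size=length)
        year = (
            None
            if rng.random() < p_unknown_year
            else int(rng.integers(1990, 2021))
        )
        records.append(DocumentRecord(f"d{i}", year, " ".join(words)))
    return records


@pytest.fixture
def toy_records() -> list[DocumentRecord]:
    """The hand-enumerable three-document corpus."""
    return [
        DocumentRecord("d1", 1999, "embryonic stem cell line"),
        DocumentRecord("d2", 2004, "stem cell"),
        DocumentRecord("d3", 2010, "embryonic fibroblast"),
    ]


@pytest.fixture
def pubmed_xml_bytes() -> bytes:
    """A three-article PubMed-schema document: a structured abstract, a
    MedlineDate-only year, and an abstract-less citation."""
    return b"""<?xml version="1.0"?>
<PubmedArticleSet>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>123</PMID>
      <Article>
        <Journal><JournalIssue><PubDate><Year>1999</Year></PubDate></JournalIssue></Journal>
        <Abstract><AbstractText>NANOG binds.</AbstractText></Abstract>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>456</PMID>
      <Article>
        <Journal><JournalIssue><PubDate><MedlineDate>1998 Dec-1999 Jan</MedlineDate></PubDate></JournalIssue></Journal>
        <Abstract>
          <AbstractText Label="BACKGROUND">A.</AbstractText>
          <AbstractText Label="METHODS">B.</AbstractText>
        </Abstract>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>789</PMID>
      <Article>
        <Journal><JournalIssue><PubDate><Year>2005</Year></PubDate></JournalIssue></Journal>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
</PubmedArticleSet>
"""
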