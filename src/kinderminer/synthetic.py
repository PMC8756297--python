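"""Synthetic dated-abstract corpora with known statistical structure.

Each document independently receives the key phrase with probability
``key_prob``, each background term with its own probability, and each
planted term with a conditional probability lifted in key-phrase
documents: P(term | key) = min(1, lift * p).  The off-key probability
is then chosen to preserve the marginal P(term) = p whenever feasible,
so the lift concentrates the term's occurrences in key documents
without inflating its overall document frequency.  Publication years
are uniform over an inclusive range and neutral filler tokens from a
disjoint alphabet pad every abstract.  This emulates the statistical
skeleton of a literature corpus — marginal document frequencies and a
controlled term/key dependence — not natural-language abstract style.

Expected contingency cells are available in closed form
(:func:`expected_table`), so empirical counts can be asserted to within
a few binomial standard errors, and a null corpus (lift = 1 everywhere)
calibrates the Fisher filter's type-I behavior.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .corpus_io import DocumentRecord
from .text_index import tokenize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlantedTerm:
    """A term whose co-occurrence with the key phrase is lifted.

    ``prob`` is the target marginal document frequency; ``lift`` >= 1
    multiplies it inside key-phrase documents (clipped at 1).
    """

    term: str
    prob: float
    lift: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError(f"prob must be in [0, 1], got {self.prob}")
        if self.lift < 1.0:
            raise ValueError(f"lift must be >= 1, got {self.lift}")

    @property
    def prob_given_key(self) -> float:
        return min(1.0, self.lift * self.prob)

    def prob_given_not_key(self, key_prob: float) -> float:
        """Off-key probability preserving the marginal, clipped to >= 0."""
        if key_prob >= 1.0:
            return 0.0
        return max(
            0.0,
            (self.prob - key_prob * self.prob_given_key) / (1.0 - key_prob),
        )


@dataclass
class SyntheticCorpusSpec:
    """Generative parameters for a synthetic corpus.

    ``background_terms`` occur independently of the key phrase;
    ``planted_terms`` carry a lift.  ``filler_vocab_size`` sizes the
    disjoint neutral-filler vocabulary and ``fillers_per_doc`` tokens
    are drawn from it per document, guaranteeing no accidental phrase
    collisions.  Everything is reproducible from ``seed``.
    """

    n_docs: int
    key_phrase: str = "embryonic stem cell"
    key_prob: float = 0.1
    background_terms: Sequence[PlantedTerm] = field(default_factory=list)
    planted_terms: Sequence[PlantedTerm] = field(default_factory=list)
    year_range: tuple[int, int] = (2000, 2010)
    filler_vocab_size: int = 200
    fillers_per_doc: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs < 0:
            raise ValueError("n_docs must be non-negative")
        if not 0.0 <= self.key_prob <= 1.0:
            raise ValueError(f"key_prob must be in [0, 1], got {self.key_prob}")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError(f"empty year_range {self.year_range}")
        self.background_terms = [
            t if isinstance(t, PlantedTerm) else PlantedTerm(*t)
            for t in self.background_terms
        ]
        self.planted_terms = [
            t if isinstance(t, PlantedTerm) else PlantedTerm(*t)
            for t in self.planted_terms
        ]
        vocabs = [tokenize(self.key_phrase)] + [
            tokenize(t.term) for t in self.all_terms
        ]
        if any(not v for v in vocabs):
            raise ValueError("key phrase and terms must tokenize to non-empty")
        flat = [tok for v in vocabs for tok in set(v)]
        if len(set(flat)) != len(flat):
            raise ValueError(
                "key/planted/background vocabularies must be disjoint "
                "after tokenization"
            )

    @property
    def all_terms(self) -> list[PlantedTerm]:
        return list(self.background_terms) + list(self.planted_terms)

    def term(self, name: str) -> PlantedTerm:
        for t in self.all_terms:
            if t.term == name:
                return t
        raise KeyError(f"term {name!r} not in spec")

    def to_json(self) -> str:
        obj = {
            "n_docs": self.n_docs,
            "key_phrase": self.key_phrase,
            "key_prob": self.key_prob,
            "background_terms": [
                [t.term, t.prob, t.lift] for t in self.background_terms
            ],
            "planted_terms": [
                [t.term, t.prob, t.lift] for t in self.planted_terms
            ],
            "year_range": list(self.year_range),
            "filler_vocab_size": self.filler_vocab_size,
            "fillers_per_doc": self.fillers_per_doc,
            "seed": self.seed,
        }
        return json.dumps(obj, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticCorpusSpec":
        obj = json.loads(text)
        obj["year_range"] = tuple(obj.get("year_range", (2000, 2010)))
        obj["background_terms"] = [
            PlantedTerm(*t) for t in obj.get("background_terms", [])
        ]
        obj["planted_terms"] = [
            PlantedTerm(*t) for t in obj.get("planted_terms", [])
        ]
        return cls(**obj)


def _filler_vocab(size: int) -> list[str]:
    # "qf" prefix keeps fillers disjoint from any plausible gene symbol
    return [f"qfiller{i:05d}" for i in range(size)]


def generate(spec: SyntheticCorpusSpec) -> list[DocumentRecord]:
    """Generate the corpus a spec describes.

    Deterministic given the seed: the same spec yields byte-identical
    JSONL output.  An infeasible lift (lift * prob > 1) is clipped with
    a warning.
    """
    for t in spec.planted_terms:
        if t.lift * t.prob > 1.0:
            warnings.warn(
                f"term {t.term!r}: lift {t.lift} * prob {t.prob} > 1; "
                "conditional probability clipped to 1",
                stacklevel=2,
            )
    rng = np.random.default_rng(spec.seed)
    fillers = _filler_vocab(spec.filler_vocab_size)
    records: list[DocumentRecord] = []
    lo, hi = spec.year_range
    terms = spec.all_terms
    term_names = [t.term for t in terms]
    p_given_key = np.array([t.prob_given_key for t in terms])
    p_given_not = np.array([t.prob_given_not_key(spec.key_prob) for t in terms])
    for i in range(spec.n_docs):
        year = int(rng.integers(lo, hi + 1))
        has_key = rng.random() < spec.key_prob
        chunks: list[str] = []
        if has_key:
            chunks.append(spec.key_phrase)
        if terms:
            u = rng.random(len(terms))
            hits = np.nonzero(u < (p_given_key if has_key else p_given_not))[0]
            chunks.extend(term_names[j] for j in hits)
        if spec.fillers_per_doc and spec.filler_vocab_size:
            picks = rng.integers(0, spec.filler_vocab_size, spec.fillers_per_doc)
            chunks.extend(fillers[j] for j in picks)
        order = rng.permutation(len(chunks))
        abstract = " ".join(chunks[j] for j in order)
        records.append(DocumentRecord(f"synth{i:07d}", year, abstract))
    return records


def expected_table(
    spec: SyntheticCorpusSpec, term: Union[str, PlantedTerm]
) -> dict[str, float]:
    """Expected contingency cells (real-valued) for one term.

    Returns expected ``n_both`` (a), ``n_term`` (T), ``n_key`` (K) and
    ``n_total`` (N) under the generative model; with lift 1 these
    reduce to independence (a = N * key_prob * prob).
    """
    t = spec.term(term) if isinstance(term, str) else term
    n, q = spec.n_docs, spec.key_prob
    p_key = t.prob_given_key
    p_not = t.prob_given_not_key(q)
    e_a = n * q * p_key
    e_t = n * (q * p_key + (1 - q) * p_not)
    return {
        "n_both": e_a,
        "n_term": e_t,
        "n_key": n * q,
        "n_total": float(n),
    }
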