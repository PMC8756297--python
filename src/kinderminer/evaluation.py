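"""Evaluation of ranked term lists against landmark reference sets.

The rediscovery experiments behind this package score a censored-corpus
ranking of transcription factors against the factors established by the
landmark cell-reprogramming publications (iPS cells, cardiomyocytes,
hepatocytes).  This module reproduces that arithmetic — recall@k and
worst-landmark rank — on any ranked list, emits the sorted p-value
curve used by interactive threshold filtering, and provides the
search-space combinatorics that motivate literature-based
prioritization in the first place.

Landmark matching is exact case-folded string equality, no synonym
expansion: published synonym pairs (HNF1B/TCF2) appear as distinct
terms and are scored as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

from .core import KMResult

NOT_FOUND = None


@dataclass(frozen=True)
class LandmarkHits:
    """Per-landmark ranks plus the overall worst rank of any found
    landmark."""

    ranks: dict[str, Optional[int]]
    max_rank: Optional[int]

    @property
    def found(self) -> list[str]:
        return [t for t, r in self.ranks.items() if r is not None]

    @property
    def not_found(self) -> list[str]:
        return [t for t, r in self.ranks.items() if r is None]


def _check_ranked(ranked: Sequence[str]) -> list[str]:
    folded = [t.casefold() for t in ranked]
    if len(set(folded)) != len(folded):
        raise ValueError("ranked list contains duplicate terms")
    return folded


def _check_landmarks(landmarks: Iterable[str]) -> list[str]:
    landmarks = list(landmarks)
    if not landmarks:
        raise ValueError("landmark set is empty")
    return landmarks


def recall_at_k(ranked: Sequence[str], landmarks: Iterable[str], k: int) -> float:
    """Fraction of landmarks among the top-k ranked terms.

    Case-insensitive exact string match.  ``k`` beyond the list length
    scores recall over the whole list.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    landmarks = _check_landmarks(landmarks)
    top = set(_check_ranked(ranked)[:k])
    hits = sum(1 for t in landmarks if t.casefold() in top)
    return hits / len(landmarks)


def max_landmark_rank(
    ranked: Sequence[str], landmarks: Iterable[str]
) -> LandmarkHits:
    """1-based rank of each landmark in the list and the worst rank
    over those found; absent landmarks are reported as not found."""
    landmarks = _check_landmarks(landmarks)
    position = {t: i + 1 for i, t in enumerate(_check_ranked(ranked))}
    ranks = {t: position.get(t.casefold()) for t in landmarks}
    found = [r for r in ranks.values() if r is not None]
    return LandmarkHits(ranks=ranks, max_rank=max(found) if found else None)


def pvalue_curve(
    results: Iterable[KMResult], cutoff: Optional[float] = None
) -> tuple[list[tuple[int, float]], Optional[int]]:
    """Sorted p-value curve behind the interactive threshold slider.

    Returns ``(curve, n_passing)`` where ``curve`` is 1-based
    ``(index, p_value)`` pairs in ascending p order and ``n_passing``
    counts p strictly below ``cutoff`` (None when no cutoff given).
    """
    ps = sorted(r.p_value for r in results)
    curve = [(i + 1, p) for i, p in enumerate(ps)]
    n_passing = None if cutoff is None else sum(1 for p in ps if p < cutoff)
    return curve, n_passing


def write_curve_tsv(curve: Sequence[tuple[int, float]], handle) -> None:
    handle.write("index\tp_value\n")
    for i, p in curve:
        handle.write(f"{i}\t{p:.6g}\n")


def search_space_size(n_candidates: int, subset_size: int) -> int:
    """Exact number of size-k subsets of n candidates, C(n, k)."""
    if not 0 <= subset_size <= n_candidates:
        raise ValueError(
            f"subset_size must be in [0, {n_candidates}], got {subset_size}"
        )
    return math.comb(n_candidates, subset_size)


_SUPERSCRIPT = str.maketrans("0123456789-", "⁰¹²³⁴⁵⁶⁷⁸⁹⁻")


def render_scientific(value: int | float, sig_figs: int = 2) -> str:
    """Scientific rendering at a given number of significant figures,
    e.g. 1,999,000 -> "2.0×10⁶"."""
    if value == 0:
        return "0"
    mantissa, _, exponent = f"{float(value):.{sig_figs - 1}e}".partition("e")
    return f"{mantissa}×10{str(int(exponent)).translate(_SUPERSCRIPT)}"


# -- packaged rediscovery fixtures ------------------------------------

#: Rediscovery task name -> (ranked-list fixture, landmark fixture).
REDISCOVERY_TASKS = {
    "ips": ("ranked_ips_km2004.txt", "landmarks_ips.txt"),
    "cardiomyocyte": (
        "ranked_cardiomyocyte_km2008.txt",
        "landmarks_cardiomyocyte.txt",
    ),
    "hepatocyte": (
        "ranked_hepatocyte_km2009.txt",
        "landmarks_hepatocyte.txt",
    ),
}


def load_term_list(name_or_path: str) -> list[str]:
    """Load a one-term-per-line list, packaged fixture or file path.

    Lines starting with "#" are comments; duplicates are dropped
    preserving first occurrence.
    """
    fixture = resources.files("kinderminer.data").joinpath(name_or_path)
    text = (
        fixture.read_text(encoding="utf-8")
        if fixture.is_file()
        else open(name_or_path, encoding="utf-8").read()
    )
    seen: set[str] = set()
    terms = []
    for line in text.splitlines():
        term = line.strip()
        if not term or term.startswith("#"):
            continue
        if term.casefold() not in seen:
            seen.add(term.casefold())
            terms.append(term)
    return terms


def rediscovery_task(name: str) -> tuple[list[str], list[str]]:
    """Return (ranked censored-query terms, landmark factors) for one
    of the packaged rediscovery tasks."""
    try:
        ranked_file, landmark_file = REDISCOVERY_TASKS[name]
    except KeyError:
        raise ValueError(
            f"unknown task {name!r}; choose from {sorted(REDISCOVERY_TASKS)}"
        ) from None
    return load_term_list(ranked_file), load_term_list(landmark_file)
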