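"""Contingency construction, the one-sided Fisher test against an
exact-rational oracle, and filtering/ranking semantics."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import fisher_exact

from kinderminer.core import (
    DEFAULT_THRESHOLD,
    ContingencyTable,
    KMResult,
    QuerySpec,
    fisher_one_sided,
    hypergeom_log_pmf,
    km_rank,
    make_contingency,
    run_query,
)
from kinderminer.corpus_io import DocumentRecord
from kinderminer.synthetic import PlantedTerm, SyntheticCorpusSpec, generate
from kinderminer.text_index import CorpusIndex, UnmatchablePhraseError

from conftest import (
    exact_lower_tail,
    exact_upper_tail,
    scan_count_cooccurrence,
    scan_count_phrase,
    scan_corpus_size,
)


class TestMakeContingency:
    def test_derived_cells(self):
        assert make_contingency(4, 10, 8, 100).cells == (4, 6, 4, 86)

    def test_degenerate_empty_term_margin(self):
        table = make_contingency(0, 0, 5, 10)
        assert table.cells == (0, 0, 5, 5)

    @pytest.mark.parametrize(
        "args,fragment",
        [
            ((6, 5, 8, 100), "n_both"),       # a > T
            ((6, 8, 5, 100), "n_both"),       # a > K
            ((0, 11, 5, 10), "n_term"),       # T > N
            ((0, 5, 11, 10), "n_key"),        # K > N
            ((0, 6, 6, 10), "d cell"),        # implied d < 0
            ((-1, 5, 5, 10), "non-negative"),
        ],
    )
    def test_inconsistent_tables_rejected_naming_the_pair(self, args, fragment):
        with pytest.raises(ValueError, match=fragment):
            make_contingency(*args)


class TestFisherOneSided:
    def test_zero_overlap_gives_p_one(self):
        for t, k, n in [(5, 5, 100), (0, 0, 10), (3, 7, 10)]:
            a_min = max(0, t + k - n)
            assert fisher_one_sided(make_contingency(a_min, t, k, n)) == 1.0

    def test_point_mass_closed_form(self):
        # all five term docs among the five key docs of a 20-doc corpus
        p = fisher_one_sided(make_contingency(5, 5, 5, 20))
        assert p == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_matches_rational_tail_sum(self):
        # frozen from the exact oracle: N=100, T=10, K=10, tail from a=3
        expected = float(exact_upper_tail(3, 10, 10, 100))
        assert expected == pytest.approx(0.06001858177500578, rel=1e-12)
        p = fisher_one_sided(make_contingency(3, 10, 10, 100))
        assert p == pytest.approx(expected, rel=1e-12)

    def test_exhaustive_small_n_against_rational_oracle(self):
        """Every feasible table with N <= 25 agrees with exact rational
        arithmetic (the acceptance suite extends this to N <= 60)."""
        for n in range(1, 26):
            for t in range(n + 1):
                for k in range(n + 1):
                    lo, hi = max(0, t + k - n), min(t, k)
                    for a in range(lo, hi + 1):
                        p = fisher_one_sided(make_contingency(a, t, k, n))
                        exact = float(exact_upper_tail(a, t, k, n))
                        assert p == pytest.approx(exact, rel=1e-12, abs=0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_on_large_random_tables(self, seed):
        """Independent cross-check against scipy's implementation on
        corpus-scale tables."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10_000, 1_000_000))
        t = int(rng.integers(1, n // 100))
        k = int(rng.integers(1, n // 100))
        a = int(rng.integers(max(0, t + k - n), min(t, k) + 1))
        table = make_contingency(a, t, k, n)
        ours = fisher_one_sided(table)
        a_, b_, c_, d_ = table.cells
        scipy_p = fisher_exact([[a_, b_], [c_, d_]], alternative="greater")[1]
        assert ours == pytest.approx(scipy_p, rel=1e-9)

    def test_monotone_decreasing_in_overlap(self):
        n, t, k = 200, 30, 40
        ps = [
            fisher_one_sided(make_contingency(a, t, k, n))
            for a in range(0, min(t, k) + 1)
        ]
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))

    def test_margin_symmetry(self):
        assert fisher_one_sided(make_contingency(7, 20, 55, 300)) == (
            fisher_one_sided(make_contingency(7, 55, 20, 300))
        )

    def test_pmf_normalizes(self):
        from scipy.special import logsumexp

        for n, t, k in [(30, 10, 14), (50, 25, 25), (60, 1, 59)]:
            lo, hi = max(0, t + k - n), min(t, k)
            logs = [
                hypergeom_log_pmf(make_contingency(a, t, k, n))
                for a in range(lo, hi + 1)
            ]
            assert float(np.exp(logsumexp(logs))) == pytest.approx(1.0, rel=1e-12)

    def test_depletion_is_lower_tail(self):
        table = make_contingency(1, 10, 10, 100)
        assert fisher_one_sided(table, alternative="depletion") == (
            pytest.approx(float(exact_lower_tail(1, 10, 10, 100)), rel=1e-12)
        )

    def test_no_overflow_at_pubmed_scale(self):
        # margins at the scale of a 3e7-document corpus; expected
        # overlap under independence is ~19, so a=100 is a strong hit
        p = fisher_one_sided(make_contingency(100, 10_000, 60_000, 31_030_308))
        assert math.isfinite(p)
        assert 0.0 < p < 1e-20


class TestKmRank:
    def test_empty_input(self):
        assert km_rank([], n_key=10, n_total=100) == []

    def test_ratio_ordering(self):
        results = km_rank(
            [("Y", 100, 20), ("X", 10, 9)],
            n_key=30, n_total=1000, threshold=0.5,
        )
        assert [r.term for r in results][:2] == ["X", "Y"]
        assert results[0].rank == 1 and results[0].ratio == pytest.approx(0.9)
        assert results[1].rank == 2 and results[1].ratio == pytest.approx(0.2)

    def test_tie_break_p_then_term(self):
        # equal ratios; B has the larger margins hence smaller p
        results = km_rank(
            [("b", 10, 5), ("a", 10, 5), ("c", 100, 50)],
            n_key=200, n_total=10_000, threshold=1.0,
        )
        assert [r.term for r in results] == ["c", "a", "b"]

    def test_zero_margin_term_retained_flagged(self):
        results = km_rank([("ghost", 0, 0)], n_key=10, n_total=100)
        (r,) = results
        assert r.p_value == 1.0 and r.ratio == 0.0
        assert not r.passes and r.rank is None and r.note

    def test_threshold_is_strict(self):
        # engineer a term then filter exactly at its p-value
        p = fisher_one_sided(make_contingency(5, 10, 10, 100))
        results = km_rank([("t", 10, 5)], n_key=10, n_total=100, threshold=p)
        assert not results[0].passes

    def test_ranks_are_permutation_of_passing(self):
        rng = np.random.default_rng(11)
        counts = []
        n_total, n_key = 5000, 400
        for i in range(30):
            n_term = int(rng.integers(1, 200))
            n_both = int(rng.integers(0, min(n_term, n_key) + 1))
            counts.append((f"t{i}", n_term, n_both))
        results = km_rank(counts, n_key, n_total, threshold=0.05)
        ranks = sorted(r.rank for r in results if r.passes)
        assert ranks == list(range(1, len(ranks) + 1))
        assert all(r.rank is None for r in results if not r.passes)
        assert all(0.0 <= r.ratio <= 1.0 for r in results)

    def test_inconsistent_counts_name_the_term(self):
        with pytest.raises(ValueError, match="bad_term"):
            km_rank([("bad_term", 5, 6)], n_key=10, n_total=100)


class TestRunQuery:
    def test_absent_key_phrase_all_p_one(self, toy_records):
        index = CorpusIndex.build(toy_records)
        spec = QuerySpec(key_phrase="zebrafish", target_terms=["stem cell"])
        results = run_query(index, spec)
        assert all(r.p_value == 1.0 and not r.passes for r in results)

    def test_empty_key_phrase_rejected(self, toy_records):
        index = CorpusIndex.build(toy_records)
        with pytest.raises(UnmatchablePhraseError):
            run_query(index, QuerySpec(key_phrase="!!!", target_terms=["a"]))

    def test_duplicate_terms_deduplicated(self, toy_records):
        index = CorpusIndex.build(toy_records)
        spec = QuerySpec(
            key_phrase="embryonic",
            target_terms=["stem cell", "STEM CELL", "stem cell "],
        )
        assert len(run_query(index, spec)) == 1

    def test_unmatchable_target_reported_not_dropped(self, toy_records, caplog):
        index = CorpusIndex.build(toy_records)
        spec = QuerySpec(key_phrase="embryonic", target_terms=["...", "cell"])
        with caplog.at_level("WARNING"):
            results = run_query(index, spec)
        assert len(results) == 2
        ghost = next(r for r in results if r.term == "...")
        assert ghost.n_term == 0 and not ghost.passes

    def test_default_threshold(self):
        spec = QuerySpec(key_phrase="x", target_terms=["y"])
        assert spec.threshold == DEFAULT_THRESHOLD == 1e-5

    def test_planted_terms_rank_on_top(self):
        """End-to-end: planted associations out-rank null terms."""
        spec = SyntheticCorpusSpec(
            n_docs=4000,
            key_prob=0.1,
            background_terms=[
                PlantedTerm(f"bgt{i:02d}", 0.02) for i in range(30)
            ],
            planted_terms=[
                PlantedTerm(f"hit{i}", 0.02, lift=8.0) for i in range(5)
            ],
            seed=7,
        )
        index = CorpusIndex.build(generate(spec))
        results = run_query(
            index,
            QuerySpec(
                key_phrase=spec.key_phrase,
                target_terms=[t.term for t in spec.all_terms],
            ),
        )
        top5 = {r.term for r in results if r.rank is not None and r.rank <= 5}
        assert top5 == {f"hit{i}" for i in range(5)}

    def test_end_to_end_matches_composed_oracle(self):
        """Five-term toy query: counts recomputed by scan, p by rational
        arithmetic, ordering re-derived independently."""
        records = [
            DocumentRecord("d1", 2000, "nanog embryonic stem cell"),
            DocumentRecord("d2", 2001, "nanog expressed in blastocyst"),
            DocumentRecord("d3", 2002, "embryonic stem cell line sox2"),
            DocumentRecord("d4", 2003, "sox2 and actin"),
            DocumentRecord("d5", 2004, "actin cytoskeleton"),
            DocumentRecord("d6", 2005, "nanog embryonic stem cell sox2"),
            DocumentRecord("d7", 2006, "gapdh control"),
        ]
        terms = ["nanog", "sox2", "actin", "gapdh", "absent"]
        key = "embryonic stem cell"
        index = CorpusIndex.build(records)
        results = run_query(
            index, QuerySpec(key_phrase=key, target_terms=terms, threshold=1.0)
        )
        key_toks, n = ["embryonic", "stem", "cell"], len(records)
        n_key = scan_count_phrase(records, key_toks)
        oracle = []
        for term in terms:
            t = scan_count_phrase(records, [term])
            a = scan_count_cooccurrence(records, [term], key_toks)
            p = (
                float(exact_upper_tail(a, t, n_key, n)) if t else 1.0
            )
            oracle.append((term, t, a, p))
        by_term = {r.term: r for r in results}
        for term, t, a, p in oracle:
            r = by_term[term]
            assert (r.n_term, r.n_both) == (t, a)
            assert r.p_value == pytest.approx(p, rel=1e-12)
        # independent ordering of passing terms
        expected_order = [
            term
            for term, t, a, p in sorted(
                (o for o in oracle if o[3] < 1.0 and o[1] > 0),
                key=lambda o: (-(o[2] / o[1]), o[3], o[0]),
            )
        ]
        got_order = [r.term for r in results if r.passes]
        assert got_order == expected_order

    def test_censored_query_uses_censored_margins(self, toy_records):
        index = CorpusIndex.build(toy_records)
        spec = QuerySpec(
            key_phrase="stem cell", target_terms=["embryonic"], censor_year=2003
        )
        (r,) = run_query(index, spec)
        assert r.n_total == scan_corpus_size(toy_records, 2003) == 1
        assert r.n_key == 1 and r.n_term == 1 and r.n_both == 1

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            QuerySpec(key_phrase="x", target_terms=["y"], threshold=0.0)
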